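"""Thermodynamic and kinetic parameter extraction.

Two unfolded-fraction -> equilibrium-constant conventions are supported:

``literal_fu``
    K = f_u, reading the unfolded fraction itself as the equilibrium
    constant.
``ratio``
    K = f_u / (1 - f_u), the conventional two-state constant.

Free energies use dG = -R T ln K with R = 1.987204e-3 kcal/mol/K and T in
kelvin (temperature axes given in degrees C are converted per point).  The
zero-perturbant free energy and the m-value come from an ordinary
least-squares line dG = intercept - slope * x through the transition-region
points; the chemical unfolding rate constant is read off the intercept of
log10 K against denaturant (half-chevron intercept).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .constants import CELSIUS_OFFSET, R_KCAL
from .errors import DataError, ValidationError
from .spectra import AxisKind, FractionCurve, UnfoldingCurve
from .unfolding import SigmoidFit, fit_transition

__all__ = [
    "KConvention",
    "ThermoResult",
    "ChemResult",
    "equilibrium_constant",
    "delta_g",
    "linear_extrapolation",
    "thermal_energetics",
    "chemical_unfolding_constant",
    "chemical_energetics",
]


class KConvention(str, enum.Enum):
    LITERAL_FU = "literal_fu"
    RATIO = "ratio"


@dataclass
class ThermoResult:
    """Linear-extrapolation result on a thermal (or acid) axis."""

    delta_g_h2o: float  # kcal/mol, regression value at x = 0
    m_value: float      # kcal/mol per axis unit, positive = destabilizing
    delta_g_h2o_se: float
    m_value_se: float
    k_convention: KConvention
    regression_axis: str  # 'celsius' or 'kelvin'
    per_point: List[Tuple[float, float, float, float]] = field(default_factory=list)
    # each tuple: (x, f_u, K_eq, dG_u)


@dataclass
class ChemResult:
    """Chemical (denaturant) unfolding result."""

    c_m: float          # M, sigmoid midpoint of the fraction curve
    delta_g0: float     # kcal/mol, dG intercept at zero denaturant
    log_k_obs: float    # log10 K at zero denaturant (half-chevron intercept)
    m_value: float      # kcal/mol/M
    delta_g0_se: float
    m_value_se: float
    log_k_obs_se: float
    n_chains: int
    p_t: Optional[float]
    k_convention: KConvention
    midpoint_fit: Optional[SigmoidFit] = None
    per_point: List[Tuple[float, float, float, float]] = field(default_factory=list)
    # each tuple: (x, f_u, K_ui, dG_ui)


def equilibrium_constant(f_u: float, convention: KConvention | str) -> float:
    """Equilibrium constant from an unfolded fraction, per convention."""
    convention = KConvention(convention)
    f_u = float(f_u)
    if not (0.0 < f_u < 1.0):
        raise DataError(f"f_u must lie strictly in (0, 1); got {f_u:g}")
    if convention is KConvention.LITERAL_FU:
        return f_u
    return f_u / (1.0 - f_u)


def delta_g(k: float, t_kelvin: float) -> float:
    """Unfolding free energy dG = -R T ln K in kcal/mol."""
    if k <= 0:
        raise DataError(f"K must be positive; got {k:g}")
    if t_kelvin <= 0:
        raise DataError(f"T must be positive kelvin; got {t_kelvin:g}")
    return -R_KCAL * t_kelvin * float(np.log(k))


def linear_extrapolation(points) -> Tuple[float, float, float, float]:
    """OLS line through (x, dG) points in the form dG = intercept - slope*x.

    Returns ``(intercept, slope, intercept_se, slope_se)``; ``slope`` is the
    m-value with the sign convention that a positive slope means
    destabilization as the perturbant increases.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DataError("points must be (x, dG) pairs")
    x, g = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise DataError("need at least 2 distinct x values")
    # dG = b0 + b1 x  (so intercept = b0, slope = -b1)
    A = np.column_stack([np.ones_like(x), x])
    coef, residuals, *_ = np.linalg.lstsq(A, g, rcond=None)
    b0, b1 = coef
    fitted = A @ coef
    dof = x.size - 2
    if dof > 0:
        s2 = float(np.sum((g - fitted) ** 2)) / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        se0, se1 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    else:
        se0 = se1 = float("nan")
    return float(b0), float(-b1), se0, se1


def _transition_points(frac: FractionCurve, f_min: float, f_max: float):
    f = frac.f_u_raw
    mask = (f >= f_min) & (f <= f_max)
    return frac.x[mask], f[mask]


def thermal_energetics(
    frac: FractionCurve,
    convention: KConvention | str = KConvention.LITERAL_FU,
    temperature_unit_for_regression: str = "celsius",
    *,
    f_min: float = 0.05,
    f_max: float = 0.95,
) -> ThermoResult:
    """Chain K_eq -> dG_u -> linear extrapolation on a temperature axis.

    Temperatures enter the -RT ln K step in kelvin regardless of the
    regression axis unit.
    """
    if frac.axis_kind is not AxisKind.TEMPERATURE_C:
        raise DataError("thermal_energetics requires a temperature_C axis")
    if temperature_unit_for_regression not in ("celsius", "kelvin"):
        raise ValidationError("temperature_unit_for_regression must be celsius|kelvin")
    convention = KConvention(convention)
    x, f = _transition_points(frac, f_min, f_max)
    if x.size < 2:
        raise DataError(
            f"fewer than 2 points with {f_min:g} <= f_u <= {f_max:g}"
        )
    per_point = []
    reg = []
    for xi, fi in zip(x, f):
        k = equilibrium_constant(fi, convention)
        t_k = xi + CELSIUS_OFFSET
        g = delta_g(k, t_k)
        x_reg = t_k if temperature_unit_for_regression == "kelvin" else xi
        per_point.append((float(xi), float(fi), float(k), float(g)))
        reg.append((x_reg, g))
    b0, slope, se0, se1 = linear_extrapolation(reg)
    return ThermoResult(
        delta_g_h2o=b0,
        m_value=slope,
        delta_g_h2o_se=se0,
        m_value_se=se1,
        k_convention=convention,
        regression_axis=temperature_unit_for_regression,
        per_point=per_point,
    )


def chemical_unfolding_constant(f_u: float, p_t: float = 1.0, n: int = 1) -> float:
    """Unfolding constant K_ui = P_t f_u / [P_t (1 - f_u)]^n.

    For n = 1 the protein concentration P_t cancels and the constant
    reduces to f_u / (1 - f_u).
    """
    f_u = float(f_u)
    if not (0.0 < f_u < 1.0):
        raise DataError(f"f_u must lie strictly in (0, 1); got {f_u:g}")
    if n < 1 or int(n) != n:
        raise DataError(f"n must be an integer >= 1; got {n!r}")
    if n == 1:
        return f_u / (1.0 - f_u)
    if p_t <= 0:
        raise DataError(f"P_t must be positive; got {p_t:g}")
    return p_t * f_u / (p_t * (1.0 - f_u)) ** n


def chemical_energetics(
    frac: FractionCurve,
    p_t: float = 1.0,
    n: int = 1,
    t_kelvin: float = 298.15,
    convention: KConvention | str = KConvention.RATIO,
    *,
    f_min: float = 0.05,
    f_max: float = 0.95,
) -> ChemResult:
    """Denaturant-axis energetics: dG0, m, log10 K_obs and C_m.

    dG0 is the intercept of dG_ui against denaturant molarity; log_k_obs is
    the intercept of log10 K_ui against molarity (half-chevron); C_m is the
    sigmoid midpoint of the fraction curve itself.  With ``convention ==
    'ratio'`` and n = 1 the two intercepts describe the same line, so
    dG0 = -R T ln(10) log_k_obs identically.
    """
    if frac.axis_kind is not AxisKind.DENATURANT_M:
        raise DataError("chemical_energetics requires a denaturant_M axis")
    convention = KConvention(convention)
    x, f = _transition_points(frac, f_min, f_max)
    if x.size < 2:
        raise DataError(f"fewer than 2 points with {f_min:g} <= f_u <= {f_max:g}")
    per_point = []
    g_pts, logk_pts = [], []
    for xi, fi in zip(x, f):
        if convention is KConvention.RATIO:
            k = chemical_unfolding_constant(fi, p_t, n)
        else:
            k = equilibrium_constant(fi, convention)
        g = delta_g(k, t_kelvin)
        per_point.append((float(xi), float(fi), float(k), float(g)))
        g_pts.append((xi, g))
        logk_pts.append((xi, np.log10(k)))
    g0, m_chem, g0_se, m_se = linear_extrapolation(g_pts)
    logk0, _, logk0_se, _ = linear_extrapolation(logk_pts)

    midpoint_fit = None
    c_m = float("nan")
    try:
        curve = UnfoldingCurve(
            axis_kind=frac.axis_kind,
            x=frac.x,
            y=frac.f_u_raw,
            observable_label="f_u",
        )
        midpoint_fit = fit_transition(curve)
        c_m = midpoint_fit.midpoint
    except Exception:
        # midpoint is reported as NaN when the sigmoid is unfittable;
        # the LEM intercepts above remain valid
        pass

    return ChemResult(
        c_m=c_m,
        delta_g0=g0,
        log_k_obs=logk0,
        m_value=m_chem,
        delta_g0_se=g0_se,
        m_value_se=m_se,
        log_k_obs_se=logk0_se,
        n_chains=int(n),
        p_t=p_t if n > 1 else None,
        k_convention=convention,
        midpoint_fit=midpoint_fit,
        per_point=per_point,
    )
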