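"""ANS hydrophobic-exposure midpoint (pKb) and RLS aggregation peak (pKc).

Both operate on pH-axis :class:`~foldstab.spectra.UnfoldingCurve` objects,
typically the 488 nm ANS band and the 450 nm RLS band.  pKb is the midpoint
of a Boltzmann sigmoid whose full-exposure plateau lies at low pH; pKc is
the center of a Gaussian-plus-constant fit of the scattering peak over pH.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, FitError
from .spectra import AxisKind, UnfoldingCurve
from .unfolding import fit_transition

__all__ = ["ProbeParameter", "ProbeResult", "fit_ans_midpoint", "fit_rls_peak"]


class ProbeParameter(str, enum.Enum):
    PKB = "pKb"
    PKC = "pKc"


@dataclass
class ProbeResult:
    parameter_kind: ProbeParameter
    value: float  # pH units
    value_se: float
    model_params: dict
    wavelength_nm: float
    flags: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.parameter_kind = ProbeParameter(self.parameter_kind)


def fit_ans_midpoint(
    curve: UnfoldingCurve,
    wavelength_nm: float = 488.0,
    *,
    half_max_rule: bool = False,
) -> ProbeResult:
    """pKb: pH of half of full hydrophobic exposure from an ANS band curve.

    Default is the Boltzmann-sigmoid midpoint; ``half_max_rule`` instead
    interpolates the pH at which the curve crosses half its observed
    maximum (the literal reading of the definition).
    """
    if curve.axis_kind is not AxisKind.PH:
        raise DataError("fit_ans_midpoint requires a pH axis")
    if curve.n_points < 5:
        raise DataError(f"need >= 5 pH points; got {curve.n_points}")
    fit = fit_transition(curve)
    flags = []
    value = fit.midpoint
    if half_max_rule:
        half = 0.5 * float(np.max(curve.y))
        s = np.flatnonzero(np.diff(np.sign(curve.y - half)) != 0)
        if s.size == 0:
            raise FitError("curve never crosses half of its maximum")
        i = s[0]
        x0, x1 = curve.x[i], curve.x[i + 1]
        y0, y1 = curve.y[i], curve.y[i + 1]
        value = float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
        flags.append("half_max_rule")
    return ProbeResult(
        parameter_kind=ProbeParameter.PKB,
        value=float(value),
        value_se=fit.midpoint_se,
        model_params={
            "midpoint": fit.midpoint,
            "steepness": fit.steepness,
            "baseline_native": fit.baseline_native,
            "baseline_denatured": fit.baseline_denatured,
        },
        wavelength_nm=wavelength_nm,
        flags=flags,
    )


def _gauss_const(x, amplitude, center, sigma, baseline):
    return baseline + amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fit_rls_peak(curve: UnfoldingCurve, wavelength_nm: float = 450.0) -> ProbeResult:
    """pKc: pH of maximal resonance-light-scattering intensity.

    Gaussian-plus-constant least squares over pH; if the Gaussian fit fails,
    falls back to a parabolic refinement of the grid argmax (flagged).  A
    maximum on the boundary of the sampled pH range is reported with a
    boundary flag.
    """
    if curve.axis_kind is not AxisKind.PH:
        raise DataError("fit_rls_peak requires a pH axis")
    if curve.n_points < 4:
        raise DataError(f"need >= 4 pH points; got {curve.n_points}")
    x, y = curve.x.astype(float), curve.y.astype(float)
    j = int(np.argmax(y))
    flags = []
    if j == 0 or j == x.size - 1:
        flags.append("maximum at boundary pH")
        return ProbeResult(
            parameter_kind=ProbeParameter.PKC,
            value=float(x[j]),
            value_se=float("nan"),
            model_params={"method": "boundary argmax"},
            wavelength_nm=wavelength_nm,
            flags=flags,
        )
    amp0 = float(np.max(y) - np.min(y))
    p0 = [amp0 if amp0 > 0 else 1.0, float(x[j]), float(np.ptp(x)) / 6.0, float(np.min(y))]
    lo, hi = float(np.min(x)), float(np.max(x))
    try:
        popt, pcov = curve_fit(_gauss_const, x, y, p0=p0, maxfev=20000)
        center = float(popt[1])
        if not (lo <= center <= hi):
            raise RuntimeError("fitted center escaped the sampled pH range")
        se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
        params = {
            "amplitude": float(popt[0]),
            "center": center,
            "sigma": float(abs(popt[2])),
            "baseline": float(popt[3]),
            "method": "gaussian",
        }
        return ProbeResult(
            parameter_kind=ProbeParameter.PKC,
            value=center,
            value_se=se,
            model_params=params,
            wavelength_nm=wavelength_nm,
            flags=flags,
        )
    except RuntimeError:
        # parabolic refinement through the argmax and neighbours
        y0, y1, y2 = y[j - 1], y[j], y[j + 1]
        denom = y0 - 2 * y1 + y2
        center = float(x[j]) if denom == 0 else float(
            x[j] + 0.5 * (y0 - y2) / denom * (x[j + 1] - x[j])
        )
        flags.append("gaussian fit failed; parabolic argmax refinement")
        return ProbeResult(
            parameter_kind=ProbeParameter.PKC,
            value=center,
            value_se=float("nan"),
            model_params={"method": "parabolic"},
            wavelength_nm=wavelength_nm,
            flags=flags,
        )
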