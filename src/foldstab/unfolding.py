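"""Unfolded-fraction computation and sigmoidal transition fitting.

The transition model is a Boltzmann sigmoid with constant baselines

    y(x) = B_n + (B_d - B_n) / (1 + exp(-(x - x0) / k))

fitted by least squares per segment.  Three-state melts are handled by
fitting each segment independently against its own plateaus (the
intermediate state is segment 1's denatured baseline and segment 2's
native baseline).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import DataError, FitError, ValidationError
from .spectra import AxisKind, FractionCurve, UnfoldingCurve

__all__ = [
    "SigmoidFit",
    "SegmentScheme",
    "boltzmann",
    "unfolded_fraction",
    "fit_transition",
    "fit_two_step",
    "normalize_segment",
]


def boltzmann(x, baseline_native, baseline_denatured, midpoint, steepness):
    """Boltzmann sigmoid with constant baselines."""
    z = np.clip((x - midpoint) / steepness, -500, 500)
    return baseline_native + (baseline_denatured - baseline_native) / (1.0 + np.exp(-z))


@dataclass
class SigmoidFit:
    """One fitted transition segment.

    ``midpoint`` is Tm (degrees C), pKa (pH units) or Cm (M) depending on the
    curve's axis.  ``steepness`` shares the axis unit and its sign follows
    the data direction (negative when the observable completes as x
    decreases, as in acid titrations read native -> unfolded with falling
    pH).
    """

    midpoint: float
    steepness: float
    baseline_native: float
    baseline_denatured: float
    midpoint_se: float
    residual_norm: float
    n_points: int
    segment_bounds: Tuple[float, float] = (float("-inf"), float("inf"))
    axis_kind: Optional[AxisKind] = None

    def __post_init__(self):
        if self.baseline_native == self.baseline_denatured:
            raise ValidationError("degenerate fit: equal native/denatured baselines")
        if self.n_points < 4:
            raise ValidationError("a sigmoid fit needs at least 4 points")
        lo, hi = min(self.segment_bounds), max(self.segment_bounds)
        if not (lo <= self.midpoint <= hi):
            raise ValidationError(
                f"midpoint {self.midpoint:g} outside fitted segment [{lo:g}, {hi:g}]"
            )

    def predict(self, x):
        return boltzmann(
            np.asarray(x, dtype=float),
            self.baseline_native,
            self.baseline_denatured,
            self.midpoint,
            self.steepness,
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["axis_kind"] = None if self.axis_kind is None else self.axis_kind.value
        return json.dumps(d)


@dataclass
class SegmentScheme:
    """Breakpoints splitting a curve into independently fitted segments.

    ``[60.0]`` reproduces a two-step thermal split (20-60, 60-95 degrees C);
    ``[3.0]`` the acid split (pH 7-3, 3-1); ``[]`` a one-step fit.
    """

    breakpoints: List[float] = field(default_factory=list)

    def validate_against(self, x: np.ndarray) -> None:
        lo, hi = float(np.min(x)), float(np.max(x))
        for b in self.breakpoints:
            if not (lo < b < hi):
                raise ValidationError(
                    f"breakpoint {b:g} not strictly inside data range [{lo:g}, {hi:g}]"
                )
        if sorted(self.breakpoints) != list(self.breakpoints) and sorted(
            self.breakpoints, reverse=True
        ) != list(self.breakpoints):
            raise ValidationError("breakpoints must be monotonically ordered")


def unfolded_fraction(curve: UnfoldingCurve, f_n: float, f_d: float) -> FractionCurve:
    """Normalize an observable to unfolded fraction between two baselines:
    f_u = (F_obs - F_n) / (F_d - F_n)."""
    if f_n == f_d:
        raise DataError("degenerate baselines: F_n == F_d")
    raw = (curve.y - f_n) / (f_d - f_n)
    return FractionCurve(
        axis_kind=curve.axis_kind,
        x=curve.x.copy(),
        f_u=np.clip(raw, 0.0, 1.0),
        f_u_raw=raw,
        segment_label=curve.observable_label,
    )


def _segment_mask(x: np.ndarray, segment) -> np.ndarray:
    if segment is None:
        return np.ones_like(x, dtype=bool)
    lo, hi = min(segment), max(segment)
    return (x >= lo) & (x <= hi)


def _initial_guesses(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, float]:
    # plateau seeds: means of the two terminal points at each end
    bn = float(np.mean(y[:2]))
    bd = float(np.mean(y[-2:]))
    mid_level = 0.5 * (bn + bd)
    crossing = np.flatnonzero(np.diff(np.sign(y - mid_level)) != 0)
    x0 = float(x[crossing[0]]) if crossing.size else float(np.median(x))
    span = float(x[-1] - x[0])  # signed: follows the data direction
    k = span / 10.0 if span != 0 else 1.0
    return bn, bd, x0, k


def fit_transition(
    curve: UnfoldingCurve,
    segment: Optional[Tuple[float, float]] = None,
    *,
    flatness_mad_factor: float = 3.0,
    max_restarts: int = 5,
) -> SigmoidFit:
    """Least-squares Boltzmann fit of one transition segment.

    ``segment`` is an inclusive x-range; ``None`` fits the full curve.
    Degenerate (flat) segments are rejected: the observable range must
    exceed ``flatness_mad_factor`` times the plateau noise estimate when one
    is estimable, and must be nonzero always.  Initialization is
    deterministic, with jittered restarts on failure.
    """
    mask = _segment_mask(curve.x, segment)
    x = curve.x[mask].astype(float)
    y = curve.y[mask].astype(float)
    if x.size < 4:
        raise DataError(f"segment has {x.size} points; at least 4 required")

    y_range = float(np.ptp(y))
    if y_range == 0:
        raise DataError("observable is constant over the segment")
    if x.size >= 8 and flatness_mad_factor > 0:
        ends = np.concatenate([y[:3] - np.mean(y[:3]), y[-3:] - np.mean(y[-3:])])
        mad = float(np.median(np.abs(ends)))
        if mad > 0 and y_range <= flatness_mad_factor * mad:
            raise DataError(
                f"observable range {y_range:g} below {flatness_mad_factor:g}x "
                f"plateau MAD {mad:g}; no transition to fit"
            )

    bn, bd, x0, k = _initial_guesses(x, y)
    if bn == bd:
        bd = bn + y_range if y[-1] >= y[0] else bn - y_range
    lo, hi = float(np.min(x)), float(np.max(x))
    rng = np.random.default_rng(0)
    last_exc = None
    fallback = None  # converged but with a singular covariance (step-like fit)
    for attempt in range(max_restarts + 1):
        p0 = [bn, bd, x0, k]
        if attempt > 0:
            jitter = rng.normal(size=4) * np.array(
                [0.1 * y_range, 0.1 * y_range, 0.1 * (hi - lo), 0.5 * abs(k)]
            )
            p0 = list(np.asarray(p0) + jitter)
            if p0[3] == 0:
                p0[3] = k
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(boltzmann, x, y, p0=p0, maxfev=20000)
            if not (lo <= popt[2] <= hi):
                raise RuntimeError(
                    f"fitted midpoint {popt[2]:g} escaped segment [{lo:g}, {hi:g}]"
                )
            resid_norm = float(np.linalg.norm(y - boltzmann(x, *popt)))
            se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
            fit = SigmoidFit(
                midpoint=float(popt[2]),
                steepness=float(popt[3]),
                baseline_native=float(popt[0]),
                baseline_denatured=float(popt[1]),
                midpoint_se=se,
                residual_norm=resid_norm,
                n_points=int(x.size),
                segment_bounds=(lo, hi),
                axis_kind=curve.axis_kind,
            )
            if np.isfinite(se):
                return fit
            # step-function local minimum: keep as fallback, retry jittered
            if fallback is None or fit.residual_norm < fallback.residual_norm:
                fallback = fit
            raise RuntimeError("singular fit covariance; retrying from jittered start")
        except (RuntimeError, ValidationError) as exc:
            last_exc = exc
    if fallback is not None:
        return fallback
    raise FitError(
        f"sigmoid fit failed after {max_restarts} restarts: {last_exc}",
        diagnostics={"segment": (lo, hi), "n_points": int(x.size), "p0": [bn, bd, x0, k]},
    )


def fit_two_step(
    curve: UnfoldingCurve, scheme: SegmentScheme, **fit_kwargs
) -> List[SigmoidFit]:
    """Fit a (possibly multi-)segment melt, one independent sigmoid per
    segment; breakpoint samples are shared by adjacent segments.

    With no breakpoints this is exactly :func:`fit_transition` on the full
    range.
    """
    scheme.validate_against(curve.x)
    if not scheme.breakpoints:
        return [fit_transition(curve, None, **fit_kwargs)]
    edges = [float(curve.x[0])] + [float(b) for b in scheme.breakpoints] + [
        float(curve.x[-1])
    ]
    fits = []
    for i in range(len(edges) - 1):
        seg = (edges[i], edges[i + 1])
        try:
            fits.append(fit_transition(curve, seg, **fit_kwargs))
        except (DataError, FitError) as exc:
            raise type(exc)(f"segment {i + 1} {seg}: {exc}") from exc
    return fits


def normalize_segment(curve: UnfoldingCurve, fit: SigmoidFit) -> FractionCurve:
    """Unfolded fraction over a fitted segment using the fitted baselines."""
    mask = _segment_mask(curve.x, fit.segment_bounds)
    seg_curve = UnfoldingCurve(
        axis_kind=curve.axis_kind,
        x=curve.x[mask],
        y=curve.y[mask],
        observable_label=curve.observable_label,
    )
    frac = unfolded_fraction(seg_curve, fit.baseline_native, fit.baseline_denatured)
    frac.segment_label = (
        f"{curve.observable_label} [{fit.segment_bounds[0]:g}, {fit.segment_bounds[1]:g}]"
    )
    return frac
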