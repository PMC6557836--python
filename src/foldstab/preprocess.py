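"""Inner-filter correction, band extraction, ratio tracking and lambda-max.

All operations consume a :class:`~foldstab.spectra.SpectrumSeries` and emit
either a corrected series or an :class:`~foldstab.spectra.UnfoldingCurve`.
The multiplicative inner-filter factor exp((A_ex + A_em)/2) cancels exactly
in any intensity ratio, so ratio observables never depend on whether the
correction was applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import DataError, RangeError, ValidationError
from .spectra import SpectrumSeries, UnfoldingCurve

__all__ = [
    "CorrectionReport",
    "correct_inner_filter",
    "extract_band",
    "intensity_ratio",
    "lambda_max",
]


@dataclass
class CorrectionReport:
    """Per-condition record of whether inner-filter correction ran."""

    applied: np.ndarray  # bool per condition
    max_correction_factor: float

    def __post_init__(self):
        self.applied = np.asarray(self.applied, dtype=bool)


def correct_inner_filter(series: SpectrumSeries) -> Tuple[SpectrumSeries, CorrectionReport]:
    """Multiply each condition's intensities by exp((A_ex + A_em)/2).

    Non-fluorescence probes or series without absorbances pass through
    unchanged with ``applied`` all false.  The factor is >= 1 whenever the
    absorbances are non-negative; negative absorbances are rejected.
    """
    n = series.n_conditions
    if not series.probe_kind.is_fluorescence or series.absorbances is None:
        report = CorrectionReport(np.zeros(n, dtype=bool), 1.0)
        return series.copy(), report
    if np.any(series.absorbances < 0):
        raise ValidationError("absorbances must be non-negative")
    factors = np.exp(series.absorbances.sum(axis=1) / 2.0)
    corrected = series.copy(intensities=series.intensities * factors[:, None])
    report = CorrectionReport(np.ones(n, dtype=bool), float(factors.max()))
    return corrected, report


def extract_band(series: SpectrumSeries, wavelength_nm: float) -> UnfoldingCurve:
    """Per-condition intensity at one wavelength.

    Exact grid hits return the stored column; off-grid wavelengths are
    linearly interpolated between the two bracketing grid points.
    """
    wl = series.wavelengths_nm
    if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
        raise RangeError(
            f"wavelength {wavelength_nm:g} nm outside recorded range "
            f"[{wl[0]:g}, {wl[-1]:g}] nm"
        )
    exact = np.flatnonzero(wl == wavelength_nm)
    if exact.size:
        y = series.intensities[:, exact[0]].copy()
    else:
        hi = int(np.searchsorted(wl, wavelength_nm))
        lo = hi - 1
        t = (wavelength_nm - wl[lo]) / (wl[hi] - wl[lo])
        y = (1 - t) * series.intensities[:, lo] + t * series.intensities[:, hi]
    return UnfoldingCurve(
        axis_kind=series.axis_kind,
        x=series.condition_values.copy(),
        y=y,
        observable_label=f"I({wavelength_nm:g} nm)",
    )


def intensity_ratio(series: SpectrumSeries, num_nm: float, den_nm: float) -> UnfoldingCurve:
    """Per-condition ratio of two band intensities, e.g. F350/F335."""
    num = extract_band(series, num_nm)
    den = extract_band(series, den_nm)
    zero = np.flatnonzero(den.y == 0)
    if zero.size:
        cond = series.condition_values[zero[0]]
        raise DataError(
            f"zero denominator intensity at {den_nm:g} nm for condition {cond:g}"
        )
    return UnfoldingCurve(
        axis_kind=series.axis_kind,
        x=series.condition_values.copy(),
        y=num.y / den.y,
        observable_label=f"F{num_nm:g}/F{den_nm:g}",
    )


def lambda_max(series: SpectrumSeries) -> UnfoldingCurve:
    """Per-condition wavelength of maximum intensity.

    The grid argmax is refined by a parabola through (argmax - 1, argmax,
    argmax + 1).  Boundary maxima and flat spectra are returned unrefined
    and flagged; ties break toward the lowest wavelength.
    """
    wl = series.wavelengths_nm
    if wl.size < 3:
        raise DataError("lambda_max needs at least 3 wavelengths")
    centers = np.empty(series.n_conditions)
    flags = []
    for i, row in enumerate(series.intensities):
        j = int(np.argmax(row))  # ties -> lowest wavelength
        if np.all(row == row[0]):
            centers[i] = wl[0]
            flags.append(f"condition {series.condition_values[i]:g}: flat spectrum")
            continue
        if j == 0 or j == wl.size - 1:
            centers[i] = wl[j]
            flags.append(
                f"condition {series.condition_values[i]:g}: maximum at grid boundary"
            )
            continue
        y0, y1, y2 = row[j - 1], row[j], row[j + 1]
        denom = y0 - 2 * y1 + y2
        if denom == 0:
            centers[i] = wl[j]
        else:
            # vertex of the parabola through three equally indexed points,
            # mapped back to the (possibly non-uniform) wavelength grid
            delta = 0.5 * (y0 - y2) / denom
            if delta >= 0:
                centers[i] = wl[j] + delta * (wl[j + 1] - wl[j])
            else:
                centers[i] = wl[j] + delta * (wl[j] - wl[j - 1])
    return UnfoldingCurve(
        axis_kind=series.axis_kind,
        x=series.condition_values.copy(),
        y=centers,
        observable_label="lambda_max (nm)",
        flags=flags,
    )
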