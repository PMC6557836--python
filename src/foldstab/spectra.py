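"""Domain types and file I/O for spectral denaturation data.

A :class:`SpectrumSeries` is an intensity grid over (condition value x
wavelength) for one probe.  Condition axes may run in either direction
(acid series are naturally recorded from pH 7 down to pH 1); wavelength
grids are always strictly ascending.  The canonical on-disk representation
is a long-format delimited text table with one row per (condition,
wavelength) cell; wide condition-by-wavelength matrices are accepted on
read only.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "ProbeKind",
    "AxisKind",
    "SpectrumSeries",
    "UnfoldingCurve",
    "FractionCurve",
    "read_spectrum_series",
    "write_spectrum_series",
]


class ProbeKind(str, enum.Enum):
    TRP_FLUORESCENCE = "trp_fluorescence"
    FAR_UV_CD = "far_uv_cd"
    ANS = "ans"
    RLS = "rls"

    @property
    def is_fluorescence(self) -> bool:
        return self in (ProbeKind.TRP_FLUORESCENCE, ProbeKind.ANS, ProbeKind.RLS)


class AxisKind(str, enum.Enum):
    TEMPERATURE_C = "temperature_C"
    PH = "pH"
    DENATURANT_M = "denaturant_M"


def _strictly_monotone(x: np.ndarray) -> bool:
    if x.size < 2:
        return True
    d = np.diff(x)
    return bool(np.all(d > 0) or np.all(d < 0))


@dataclass
class SpectrumSeries:
    """Intensity grid of one probe over (condition x wavelength).

    Parameters
    ----------
    probe_kind : ProbeKind
        Which spectroscopic probe recorded the grid.
    axis_kind : AxisKind
        Semantics of the condition axis (degrees C, pH, or molar denaturant).
    condition_values : ndarray, shape (n_cond,)
        Strictly monotone (ascending or descending) condition values.
    wavelengths_nm : ndarray, shape (n_wl,)
        Strictly ascending wavelength grid in nm.
    intensities : ndarray, shape (n_cond, n_wl)
        Arbitrary units (mdeg for CD).
    excitation_nm : float, optional
        Excitation wavelength, if applicable.
    absorbances : ndarray, shape (n_cond, 2), optional
        Per-condition (A_ex, A_em) pairs for inner-filter correction.
    """

    probe_kind: ProbeKind
    axis_kind: AxisKind
    condition_values: np.ndarray
    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    excitation_nm: Optional[float] = None
    absorbances: Optional[np.ndarray] = None

    def __post_init__(self):
        self.probe_kind = ProbeKind(self.probe_kind)
        self.axis_kind = AxisKind(self.axis_kind)
        self.condition_values = np.asarray(self.condition_values, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.absorbances is not None:
            self.absorbances = np.asarray(self.absorbances, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.condition_values.ndim != 1 or self.condition_values.size == 0:
            raise ValidationError("condition_values must be a non-empty 1-D array")
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.size == 0:
            raise ValidationError("wavelengths_nm must be a non-empty 1-D array")
        expected = (self.condition_values.size, self.wavelengths_nm.size)
        if self.intensities.shape != expected:
            raise ValidationError(
                f"intensities shape {self.intensities.shape} != {expected}"
            )
        if not np.all(np.isfinite(self.condition_values)):
            raise ValidationError("condition_values must be finite")
        if not np.all(np.isfinite(self.wavelengths_nm)):
            raise ValidationError("wavelengths_nm must be finite")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")
        if not _strictly_monotone(self.condition_values):
            raise ValidationError("condition_values must be strictly monotone")
        if self.wavelengths_nm.size > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValidationError("wavelengths_nm must be strictly ascending")
        if self.absorbances is not None:
            if self.absorbances.shape != (self.condition_values.size, 2):
                raise ValidationError(
                    "absorbances must have shape (n_conditions, 2)"
                )
            if not np.all(np.isfinite(self.absorbances)):
                raise ValidationError("absorbances must be finite")

    @property
    def n_conditions(self) -> int:
        return self.condition_values.size

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths_nm.size

    def copy(self, **changes) -> "SpectrumSeries":
        base = dict(
            probe_kind=self.probe_kind,
            axis_kind=self.axis_kind,
            condition_values=self.condition_values.copy(),
            wavelengths_nm=self.wavelengths_nm.copy(),
            intensities=self.intensities.copy(),
            excitation_nm=self.excitation_nm,
            absorbances=None if self.absorbances is None else self.absorbances.copy(),
        )
        base.update(changes)
        return SpectrumSeries(**base)


@dataclass
class UnfoldingCurve:
    """1-D observable against a condition axis (band intensity, CD signal,
    or an intensity ratio)."""

    axis_kind: AxisKind
    x: np.ndarray
    y: np.ndarray
    observable_label: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.axis_kind = AxisKind(self.axis_kind)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if not _strictly_monotone(self.x):
            raise ValidationError("x must be strictly monotone")

    @property
    def n_points(self) -> int:
        return self.x.size


@dataclass
class FractionCurve:
    """Unfolded fraction against a condition axis.

    ``f_u`` holds values clipped to [0, 1] for reporting; ``f_u_raw``
    retains the unclipped normalization for downstream fitting.
    """

    axis_kind: AxisKind
    x: np.ndarray
    f_u: np.ndarray
    segment_label: str = ""
    f_u_raw: Optional[np.ndarray] = None

    def __post_init__(self):
        self.axis_kind = AxisKind(self.axis_kind)
        self.x = np.asarray(self.x, dtype=float)
        self.f_u = np.asarray(self.f_u, dtype=float)
        if self.f_u_raw is None:
            self.f_u_raw = self.f_u.copy()
        else:
            self.f_u_raw = np.asarray(self.f_u_raw, dtype=float)
        self.f_u = np.clip(self.f_u, 0.0, 1.0)
        if self.x.shape != self.f_u.shape or self.x.ndim != 1:
            raise ValidationError("x and f_u must be 1-D arrays of equal length")
        if not _strictly_monotone(self.x):
            raise ValidationError("x must be strictly monotone")
        if np.any(self.f_u < -1e-9) or np.any(self.f_u > 1 + 1e-9):
            raise ValidationError("f_u must lie in [0, 1] within 1e-9")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ("condition", "wavelength_nm", "intensity")
_ABS_COLUMNS = ("a_ex", "a_em")
_FMT = "%.12g"


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_metadata(path) -> dict:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_spectrum_series(series: SpectrumSeries, path) -> None:
    """Write a series as a long-format CSV with ``#``-prefixed metadata.

    The numeric payload is written at 12 significant digits so that
    :func:`read_spectrum_series` inverts it.
    """
    series.validate()
    cond = np.repeat(series.condition_values, series.n_wavelengths)
    wl = np.tile(series.wavelengths_nm, series.n_conditions)
    inten = series.intensities.ravel()
    frame = pd.DataFrame(
        {"condition": cond, "wavelength_nm": wl, "intensity": inten}
    )
    if series.absorbances is not None:
        frame["a_ex"] = np.repeat(series.absorbances[:, 0], series.n_wavelengths)
        frame["a_em"] = np.repeat(series.absorbances[:, 1], series.n_wavelengths)
    buf = io.StringIO()
    buf.write(f"# probe_kind = {series.probe_kind.value}\n")
    buf.write(f"# axis_kind = {series.axis_kind.value}\n")
    if series.excitation_nm is not None:
        buf.write(f"# excitation_nm = {_FMT % series.excitation_nm}\n")
    frame.to_csv(buf, index=False, float_format=_FMT)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_spectrum_series(path, schema: Optional[dict] = None) -> SpectrumSeries:
    """Read a delimited text table into a validated :class:`SpectrumSeries`.

    ``schema`` maps the file onto the domain model::

        {"format": "long" | "wide",
         "probe_kind": ..., "axis_kind": ...,   # required unless in metadata
         "condition": "...", "wavelength": "...", "intensity": "...",  # long
         "a_ex": "...", "a_em": "...",          # optional long columns
         "excitation_nm": float}

    Files written by :func:`write_spectrum_series` carry their metadata in
    ``#`` comment lines and need no schema.  Wide format expects the first
    column to hold condition values and the remaining column headers to be
    wavelengths in nm.
    """
    schema = dict(schema or {})
    meta = _read_metadata(path)
    for key in ("probe_kind", "axis_kind", "excitation_nm"):
        if key in meta and key not in schema:
            schema[key] = meta[key]
    if "probe_kind" not in schema or "axis_kind" not in schema:
        raise SchemaError(
            "probe_kind and axis_kind must be given in the schema or in "
            "'# key = value' metadata lines"
        )
    fmt = schema.get("format", "long")

    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise SchemaError(f"{path}: no header row found")
    sep = _detect_delimiter(lines[0])
    try:
        frame = pd.read_csv(io.StringIO("".join(lines)), sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas edge cases
        raise ParseError(f"{path}: {exc}") from exc

    excitation = schema.get("excitation_nm")
    excitation = float(excitation) if excitation is not None else None

    if fmt == "wide":
        return _from_wide(frame, schema, excitation, path)
    if fmt != "long":
        raise SchemaError(f"unknown format {fmt!r}; expected 'long' or 'wide'")
    return _from_long(frame, schema, excitation, path)


def _to_float_column(frame: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = frame[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column "
            f"{col!r} at data row {row + 1}"
        )
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise ParseError(f"{path}: missing value in column {col!r} at data row {row + 1}")
    return out.to_numpy(dtype=float)


def _from_long(frame, schema, excitation, path) -> SpectrumSeries:
    cols = {
        "condition": schema.get("condition", "condition"),
        "wavelength": schema.get("wavelength", "wavelength_nm"),
        "intensity": schema.get("intensity", "intensity"),
    }
    missing = [c for c in cols.values() if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found {list(frame.columns)}")

    cond = _to_float_column(frame, cols["condition"], path)
    wl = _to_float_column(frame, cols["wavelength"], path)
    inten = _to_float_column(frame, cols["intensity"], path)

    cells = pd.DataFrame({"c": cond, "w": wl})
    dup = cells.duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"{path}: duplicate (condition, wavelength) cell "
            f"({cond[row]:g}, {wl[row]:g}) at data row {row + 1}"
        )

    # preserve the file's condition ordering (descending pH stays descending)
    cond_values = pd.unique(cond)
    wl_values = np.unique(wl)
    n_c, n_w = cond_values.size, wl_values.size
    if n_c * n_w != cond.size:
        raise ValidationError(
            f"{path}: incomplete grid; {cond.size} cells for "
            f"{n_c} conditions x {n_w} wavelengths"
        )
    ci = {v: i for i, v in enumerate(cond_values)}
    wi = {v: i for i, v in enumerate(wl_values)}
    grid = np.full((n_c, n_w), np.nan)
    for c, w, v in zip(cond, wl, inten):
        grid[ci[c], wi[w]] = v

    absorbances = None
    a_ex_col = schema.get("a_ex", "a_ex")
    a_em_col = schema.get("a_em", "a_em")
    if a_ex_col in frame.columns and a_em_col in frame.columns:
        a_ex = _to_float_column(frame, a_ex_col, path)
        a_em = _to_float_column(frame, a_em_col, path)
        absorbances = np.empty((n_c, 2))
        for c, x, m in zip(cond, a_ex, a_em):
            absorbances[ci[c], 0] = x
            absorbances[ci[c], 1] = m

    return SpectrumSeries(
        probe_kind=schema["probe_kind"],
        axis_kind=schema["axis_kind"],
        condition_values=cond_values,
        wavelengths_nm=wl_values,
        intensities=grid,
        excitation_nm=excitation,
        absorbances=absorbances,
    )


def _from_wide(frame, schema, excitation, path) -> SpectrumSeries:
    if frame.shape[1] < 2:
        raise SchemaError(f"{path}: wide format needs a condition column plus wavelengths")
    cond_col = frame.columns[0]
    cond = _to_float_column(frame, cond_col, path)
    try:
        wl_values = np.array([float(c) for c in frame.columns[1:]])
    except ValueError as exc:
        raise SchemaError(
            f"{path}: wide-format column headers must be wavelengths in nm"
        ) from exc
    grid = np.column_stack(
        [_to_float_column(frame, c, path) for c in frame.columns[1:]]
    )
    order = np.argsort(wl_values)
    if pd.Series(cond).duplicated().any():
        raise ValidationError(f"{path}: duplicated condition rows in wide table")
    return SpectrumSeries(
        probe_kind=schema["probe_kind"],
        axis_kind=schema["axis_kind"],
        condition_values=cond,
        wavelengths_nm=wl_values[order],
        intensities=grid[:, order],
        excitation_nm=excitation,
    )
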