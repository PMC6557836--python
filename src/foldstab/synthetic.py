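"""Known-truth generators for every analysis stage.

Each generator draws from a single ``numpy.random.default_rng(seed)``
stream, so identical truths give bit-identical outputs.  Spectral series
are Gaussian emission bands whose center and amplitude interpolate between
native and denatured values with the unfolding progress of a one- or
two-step Boltzmann scheme; toy trajectories are C-alpha chains with
prescribed per-residue jitter, a rigid two-domain separation profile, and
designated hydrogen-bond pair atoms toggled between bound and unbound
distances by Bernoulli draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .constants import CELSIUS_OFFSET, R_KCAL
from .energetics import KConvention
from .errors import DataError, ValidationError
from .spectra import AxisKind, FractionCurve, ProbeKind, SpectrumSeries
from .structure import Structure, Trajectory
from .structure import _mass_for  # internal element->mass rule

__all__ = [
    "SpectralTruth",
    "HBondPairTruth",
    "TrajectoryTruth",
    "generate_denaturation_series",
    "generate_probe_series",
    "generate_energetics_consistent_fractions",
    "generate_trajectory",
]


@dataclass
class SpectralTruth:
    """Ground truth for a synthetic denaturation spectral series."""

    scheme: str = "one_step"  # 'one_step' | 'two_step'
    midpoints: Sequence[float] = (54.57,)
    steepness: Sequence[float] = (2.0,)
    band_center_native_nm: float = 335.0
    band_center_denatured_nm: float = 350.0
    band_width_nm: float = 18.0
    amplitude_native: float = 1000.0
    amplitude_denatured: float = 400.0
    noise_sd: float = 0.0  # fraction of the larger amplitude
    seed: int = 0

    def validate(self, direction: float) -> None:
        if self.scheme not in ("one_step", "two_step"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        n_expected = 1 if self.scheme == "one_step" else 2
        if len(self.midpoints) != n_expected or len(self.steepness) != n_expected:
            raise ValidationError(
                f"{self.scheme} needs {n_expected} midpoint(s) and steepness value(s)"
            )
        if any(k <= 0 for k in self.steepness):
            raise ValidationError("steepness values must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.band_width_nm <= 0:
            raise ValidationError("band_width_nm must be positive")
        if self.scheme == "two_step":
            m1, m2 = self.midpoints
            if direction * (m2 - m1) <= 0:
                raise ValidationError(
                    "two-step midpoints must be ordered along the unfolding direction"
                )


def _progress(truth: SpectralTruth, x: np.ndarray) -> np.ndarray:
    """Overall unfolding progress in [0, 1] along the condition grid."""
    direction = 1.0 if x[-1] >= x[0] else -1.0
    p = np.zeros_like(x, dtype=float)
    for x0, k in zip(truth.midpoints, truth.steepness):
        p += 1.0 / (1.0 + np.exp(-direction * (x - x0) / k))
    return p / len(truth.midpoints)


def generate_denaturation_series(
    truth: SpectralTruth,
    probe_kind: ProbeKind | str = ProbeKind.TRP_FLUORESCENCE,
    axis_kind: AxisKind | str = AxisKind.TEMPERATURE_C,
    condition_values: Optional[Sequence[float]] = None,
    wavelengths_nm: Optional[Sequence[float]] = None,
    absorbances: Optional[np.ndarray] = None,
    excitation_nm: Optional[float] = 295.0,
) -> SpectrumSeries:
    """Synthesize a spectral series from a :class:`SpectralTruth`.

    Default grids follow the measurement layout the analysis expects:
    20-95 degrees C in 5-degree steps and a 310-400 nm emission window.
    """
    axis_kind = AxisKind(axis_kind)
    if condition_values is None:
        if axis_kind is AxisKind.TEMPERATURE_C:
            condition_values = np.arange(20.0, 96.0, 5.0)
        elif axis_kind is AxisKind.PH:
            condition_values = np.arange(7.0, 0.9, -0.25)
        else:
            condition_values = np.arange(0.0, 7.01, 0.25)
    x = np.asarray(condition_values, dtype=float)
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(310.0, 401.0, 1.0)
    wl = np.asarray(wavelengths_nm, dtype=float)
    direction = 1.0 if x[-1] >= x[0] else -1.0
    truth.validate(direction)

    p = _progress(truth, x)
    # two-state spectral superposition: the observed spectrum is the
    # progress-weighted mixture of the native and denatured emission bands,
    # so the intensity at any fixed wavelength is affine in the progress and
    # the apparent band center/amplitude drift native -> denatured with it
    native_band = truth.amplitude_native * np.exp(
        -0.5 * ((wl - truth.band_center_native_nm) / truth.band_width_nm) ** 2
    )
    denat_band = truth.amplitude_denatured * np.exp(
        -0.5 * ((wl - truth.band_center_denatured_nm) / truth.band_width_nm) ** 2
    )
    grid = (1.0 - p)[:, None] * native_band[None, :] + p[:, None] * denat_band[None, :]
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        scale = truth.noise_sd * max(
            abs(truth.amplitude_native), abs(truth.amplitude_denatured)
        )
        grid = grid + rng.normal(scale=scale, size=grid.shape)
    return SpectrumSeries(
        probe_kind=probe_kind,
        axis_kind=axis_kind,
        condition_values=x,
        wavelengths_nm=wl,
        intensities=grid,
        excitation_nm=excitation_nm,
        absorbances=absorbances,
    )


def generate_probe_series(
    kind: ProbeKind | str,
    *,
    midpoint: float = 4.5,
    steepness: float = 0.3,
    peak_center: float = 3.21,
    peak_sigma: float = 0.5,
    amplitude: float = 800.0,
    baseline: float = 30.0,
    band_center_nm: Optional[float] = None,
    band_width_nm: float = 35.0,
    ph_values: Optional[Sequence[float]] = None,
    wavelengths_nm: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SpectrumSeries:
    """Synthesize an ANS (sigmoid-in-pH) or RLS (Gaussian-in-pH) series.

    ANS amplitude rises toward low pH through ``midpoint``; RLS amplitude
    peaks at ``peak_center``.  The emission band is Gaussian in wavelength
    around 488 nm (ANS) or 450 nm (RLS).
    """
    kind = ProbeKind(kind)
    if kind not in (ProbeKind.ANS, ProbeKind.RLS):
        raise ValidationError("generate_probe_series handles ANS and RLS only")
    ph = np.asarray(
        np.arange(7.0, 0.9, -0.25) if ph_values is None else ph_values, dtype=float
    )
    if band_center_nm is None:
        band_center_nm = 488.0 if kind is ProbeKind.ANS else 450.0
    wl = np.asarray(
        np.arange(400.0, 601.0, 2.0) if wavelengths_nm is None else wavelengths_nm,
        dtype=float,
    )
    if kind is ProbeKind.ANS:
        if steepness <= 0:
            raise ValidationError("steepness must be positive")
        level = baseline + amplitude / (1.0 + np.exp((ph - midpoint) / steepness))
    else:
        if peak_sigma <= 0:
            raise ValidationError("peak_sigma must be positive")
        level = baseline + amplitude * np.exp(
            -0.5 * ((ph - peak_center) / peak_sigma) ** 2
        )
    grid = level[:, None] * np.exp(
        -0.5 * ((wl[None, :] - band_center_nm) / band_width_nm) ** 2
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(scale=noise_sd * abs(amplitude), size=grid.shape)
    return SpectrumSeries(
        probe_kind=kind,
        axis_kind=AxisKind.PH,
        condition_values=ph,
        wavelengths_nm=wl,
        intensities=grid,
        excitation_nm=380.0 if kind is ProbeKind.ANS else None,
    )


def generate_energetics_consistent_fractions(
    delta_g0: float,
    m_value: float,
    axis_grid: Sequence[float],
    t_kelvin: float = 298.15,
    convention: KConvention | str = KConvention.RATIO,
    axis_kind: AxisKind | str = AxisKind.DENATURANT_M,
) -> FractionCurve:
    """Invert the linear-extrapolation chain into a two-state fraction curve.

    f_u(x) = 1 / (1 + exp(dG(x) / RT)) with dG(x) = delta_g0 - m * x.  On a
    temperature axis the Boltzmann factor uses the per-point kelvin
    temperature (x + 273.15), matching the forward analysis; otherwise
    ``t_kelvin`` is used throughout.  Only the ratio convention is
    invertible to a two-state curve.
    """
    convention = KConvention(convention)
    if convention is not KConvention.RATIO:
        raise DataError(
            "literal_fu is not invertible to a two-state fraction curve; "
            "use convention='ratio'"
        )
    axis_kind = AxisKind(axis_kind)
    x = np.asarray(axis_grid, dtype=float)
    dg = delta_g0 - m_value * x
    if axis_kind is AxisKind.TEMPERATURE_C:
        t = x + CELSIUS_OFFSET
    else:
        t = np.full_like(x, float(t_kelvin))
    f = 1.0 / (1.0 + np.exp(dg / (R_KCAL * t)))
    return FractionCurve(
        axis_kind=axis_kind, x=x, f_u=np.clip(f, 0, 1), f_u_raw=f,
        segment_label="synthetic LEM curve",
    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class HBondPairTruth:
    """A designed hydrogen-bond pair with its target occupancy."""

    residue_a: int
    atom_name_a: str
    residue_b: int
    atom_name_b: str
    designed_occupancy: float
    bound_distance: float = 3.0
    unbound_distance: float = 5.0

    def validate(self):
        if not (0.0 <= self.designed_occupancy <= 1.0):
            raise ValidationError("designed_occupancy must lie in [0, 1]")
        if self.bound_distance <= 0 or self.unbound_distance <= 0:
            raise ValidationError("pair distances must be positive")


@dataclass
class TrajectoryTruth:
    """Ground truth for a synthetic two-domain C-alpha trajectory."""

    n_residues: int = 40
    n_frames: int = 50
    domain_a_size: int = 20
    per_residue_sigma: float | Sequence[float] = 0.0  # A, isotropic per coordinate
    domain_separation_profile: Optional[Sequence[float]] = None  # A per frame
    hbond_pairs: List[HBondPairTruth] = field(default_factory=list)
    seed: int = 0

    def sigma_array(self) -> np.ndarray:
        s = np.asarray(self.per_residue_sigma, dtype=float)
        if s.ndim == 0:
            s = np.full(self.n_residues, float(s))
        if s.shape != (self.n_residues,):
            raise ValidationError("per_residue_sigma must be scalar or length n_residues")
        if np.any(s < 0):
            raise ValidationError("per_residue_sigma must be >= 0")
        return s

    def validate(self):
        if self.n_residues < 4 or not (1 <= self.domain_a_size < self.n_residues):
            raise ValidationError("need >= 4 residues split into two non-empty domains")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        self.sigma_array()
        if self.domain_separation_profile is not None:
            prof = np.asarray(self.domain_separation_profile, dtype=float)
            if prof.shape != (self.n_frames,):
                raise ValidationError("separation profile length must equal n_frames")
            if np.any(prof <= 0):
                raise ValidationError("separation profile must be positive")
        for pair in self.hbond_pairs:
            pair.validate()
            if not (1 <= pair.residue_a <= self.n_residues) or not (
                1 <= pair.residue_b <= self.n_residues
            ):
                raise ValidationError("hbond pair residues outside the chain")

    def domain_a_ranges(self) -> List[Tuple[int, int]]:
        return [(1, self.domain_a_size)]

    def domain_b_ranges(self) -> List[Tuple[int, int]]:
        return [(self.domain_a_size + 1, self.n_residues)]


def _base_chain(n_residues: int) -> np.ndarray:
    """Deterministic non-collinear C-alpha geometry (coarse helix)."""
    i = np.arange(n_residues, dtype=float)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([1.5 * i, 2.3 * np.cos(theta), 2.3 * np.sin(theta)])


def generate_trajectory(truth: TrajectoryTruth) -> Trajectory:
    """Build a seeded toy trajectory realizing the :class:`TrajectoryTruth`.

    Frame coordinates = base helix + per-residue isotropic Gaussian jitter
    + a rigid displacement of domain B along the inter-domain axis so that
    the C-alpha center-of-mass separation follows the prescribed profile
    (exact when jitter is zero).  Designed hydrogen-bond pair atoms are
    placed at their bound/unbound distance by Bernoulli draws.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n = truth.n_residues
    base = _base_chain(n)
    sigma = truth.sigma_array()

    a_sl = slice(0, truth.domain_a_size)
    b_sl = slice(truth.domain_a_size, n)
    com_a = base[a_sl].mean(axis=0)
    com_b = base[b_sl].mean(axis=0)
    axis = com_b - com_a
    d_base = float(np.linalg.norm(axis))
    axis = axis / d_base

    # atom table: one CA per residue, then designed pair atoms
    names = ["CA"] * n
    resno = list(range(1, n + 1))
    elements = ["C"] * n
    pair_atom_index: List[Tuple[int, int]] = []
    for pair in truth.hbond_pairs:
        pair_atom_index.append((len(names), len(names) + 1))
        names += [pair.atom_name_a, pair.atom_name_b]
        resno += [pair.residue_a, pair.residue_b]
        elements += [pair.atom_name_a[:1], pair.atom_name_b[:1]]
    n_atoms = len(names)
    masses = np.array([_mass_for(e, nm) for e, nm in zip(elements, names)])

    if truth.domain_separation_profile is None:
        profile = np.full(truth.n_frames, d_base)
    else:
        profile = np.asarray(truth.domain_separation_profile, dtype=float)

    bernoulli = [
        rng.random(truth.n_frames) < pair.designed_occupancy
        for pair in truth.hbond_pairs
    ]
    frames = np.empty((truth.n_frames, n_atoms, 3))
    for t in range(truth.n_frames):
        ca = base + rng.normal(size=(n, 3)) * sigma[:, None]
        ca[b_sl] += (profile[t] - d_base) * axis
        coords = np.empty((n_atoms, 3))
        coords[:n] = ca
        for p_i, pair in enumerate(truth.hbond_pairs):
            ia, ib = pair_atom_index[p_i]
            anchor = ca[pair.residue_a - 1] + np.array([0.0, 0.0, 3.0 + 2.0 * p_i])
            d = pair.bound_distance if bernoulli[p_i][t] else pair.unbound_distance
            coords[ia] = anchor
            coords[ib] = anchor + np.array([d, 0.0, 0.0])
        frames[t] = coords

    topology = Structure(
        serial=np.arange(1, n_atoms + 1),
        atom_name=np.array(names, dtype=object),
        residue_name=np.array(["ALA"] * n_atoms, dtype=object),
        chain_id=np.array(["A"] * n_atoms, dtype=object),
        residue_number=np.array(resno, dtype=int),
        element=np.array(elements, dtype=object),
        coords=frames[0],
        masses=masses,
    )
    return Trajectory(topology=topology, frames=frames)
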