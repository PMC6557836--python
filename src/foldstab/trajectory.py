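"""Stability metrics over trajectories.

Superposition uses the Kabsch algorithm (SVD with proper-rotation sign
correction).  Per-domain RMSD superposes each frame on that domain's own
C-alpha atoms by default; RMSF is measured about the post-fit mean
structure; hydrogen-bond occupancy is the fraction of frames in which a
donor/acceptor heavy-atom pair sits within a distance cutoff (3.5 A by
default, matching the motif analysis convention), with an optional
donor-H-acceptor angle criterion when hydrogens exist.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import DataError, SelectionError, ValidationError
from .structure import (
    AtomAddress,
    DomainDefinition,
    Structure,
    Trajectory,
    resolve_atom,
    select,
)

__all__ = [
    "MetricKind",
    "MetricSeries",
    "HBondSpec",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "radius_of_gyration",
    "interdomain_distance",
    "pair_distance_series",
    "hbond_occupancy",
    "backbone_hbond_count",
]


class MetricKind(str, enum.Enum):
    RMSD = "rmsd"
    RMSF = "rmsf"
    RG = "rg"
    DISTANCE = "distance"
    PAIR_DISTANCE = "pair_distance"
    HBOND_COUNT = "hbond_count"


@dataclass
class MetricSeries:
    """Per-frame (or per-atom, for RMSF) metric values with units A/count."""

    metric_kind: MetricKind
    values: np.ndarray
    selection_label: str = ""
    unit: str = "A"
    flags: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.metric_kind = MetricKind(self.metric_kind)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError(f"{self.metric_kind.value} values must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class HBondSpec:
    """A donor/acceptor heavy-atom pair with distance (and optional angle)
    criterion."""

    donor_heavy: AtomAddress
    acceptor_heavy: AtomAddress
    distance_cutoff: float = 3.5
    angle_cutoff_deg: Optional[float] = None

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValidationError("distance_cutoff must be positive")
        if self.donor_heavy == self.acceptor_heavy:
            raise ValidationError("donor and acceptor must differ")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, float, List[str]]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd, flags)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    weighted least-squares sense; the rotation is always proper
    (det = +1), with degenerate reflection cases sign-corrected and
    flagged.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DataError(f"point count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise DataError("need >= 3 points of dimension 3")
    if weights is None:
        w = np.ones(mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (mobile.shape[0],) or np.any(w < 0) or w.sum() == 0:
            raise DataError("weights must be non-negative with positive sum")
    wsum = w.sum()
    mu_m = (w[:, None] * mobile).sum(axis=0) / wsum
    mu_r = (w[:, None] * reference).sum(axis=0) / wsum
    pm = mobile - mu_m
    pr = reference - mu_r
    h = (w[:, None] * pm).T @ pr
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flags = []
    if d < 0:
        flags.append("reflection corrected")
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_r - rotation @ mu_m
    moved = pm @ rotation.T
    rmsd = float(np.sqrt((w * np.sum((moved - pr) ** 2, axis=1)).sum() / wsum))
    return rotation, translation, rmsd, flags


def _frames_of(traj_or_structure):
    if isinstance(traj_or_structure, Trajectory):
        return traj_or_structure.frames, traj_or_structure.topology
    if isinstance(traj_or_structure, Structure):
        return traj_or_structure.coords[None, :, :], traj_or_structure
    raise DataError(f"expected Structure or Trajectory, got {type(traj_or_structure)}")


def _require(idx: np.ndarray, what: str) -> np.ndarray:
    if np.size(idx) == 0:
        raise SelectionError(f"empty selection for {what}")
    return np.asarray(idx, dtype=int)


def rmsd_series(
    traj: Trajectory,
    fit_selection: np.ndarray,
    measure_selection: Optional[np.ndarray] = None,
    reference_frame: int = 0,
    weights: Optional[np.ndarray] = None,
    label: str = "",
) -> MetricSeries:
    """Per-frame RMSD over ``measure_selection`` after superposing each
    frame onto the reference frame by ``fit_selection``."""
    fit_idx = _require(fit_selection, "fit_selection")
    meas_idx = fit_idx if measure_selection is None else _require(
        measure_selection, "measure_selection"
    )
    if not (0 <= reference_frame < traj.n_frames):
        raise DataError(f"reference frame {reference_frame} out of range")
    ref = traj.frames[reference_frame]
    out = np.empty(traj.n_frames)
    for t, frame in enumerate(traj.frames):
        rot, trans, fit_rmsd, _ = kabsch_superpose(
            frame[fit_idx], ref[fit_idx], weights
        )
        if np.array_equal(meas_idx, fit_idx):
            out[t] = fit_rmsd
        else:
            moved = frame[meas_idx] @ rot.T + trans
            out[t] = float(
                np.sqrt(np.mean(np.sum((moved - ref[meas_idx]) ** 2, axis=1)))
            )
    return MetricSeries(MetricKind.RMSD, out, selection_label=label)


def rmsf_profile(
    traj: Trajectory,
    selection: np.ndarray,
    fit_selection: Optional[np.ndarray] = None,
    about_reference: bool = False,
    label: str = "",
) -> MetricSeries:
    """Per-atom RMS fluctuation about the mean structure (or the reference
    frame when ``about_reference``) after superposing every frame."""
    if traj.n_frames < 2:
        raise DataError("RMSF needs at least 2 frames")
    sel = _require(selection, "selection")
    fit_idx = sel if fit_selection is None else _require(fit_selection, "fit_selection")
    ref = traj.frames[0]
    aligned = np.empty((traj.n_frames, sel.size, 3))
    for t, frame in enumerate(traj.frames):
        rot, trans, _, _ = kabsch_superpose(frame[fit_idx], ref[fit_idx])
        aligned[t] = frame[sel] @ rot.T + trans
    center = ref[sel] if about_reference else aligned.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((aligned - center) ** 2, axis=2), axis=0))
    return MetricSeries(MetricKind.RMSF, fluct, selection_label=label)


def radius_of_gyration(
    traj_or_structure,
    selection: np.ndarray,
    mass_weighted: bool = True,
    label: str = "",
) -> MetricSeries:
    """Per-frame Rg = sqrt(sum w_i |r_i - r_com|^2 / sum w_i)."""
    frames, topo = _frames_of(traj_or_structure)
    sel = _require(selection, "selection")
    w = topo.masses[sel] if mass_weighted else np.ones(sel.size)
    wsum = w.sum()
    out = np.empty(frames.shape[0])
    for t, frame in enumerate(frames):
        r = frame[sel]
        com = (w[:, None] * r).sum(axis=0) / wsum
        out[t] = float(np.sqrt((w * np.sum((r - com) ** 2, axis=1)).sum() / wsum))
    return MetricSeries(MetricKind.RG, out, selection_label=label)


def interdomain_distance(
    traj: Trajectory,
    domain_a: DomainDefinition,
    domain_b: DomainDefinition,
    atom_names: Sequence[str] = ("CA",),
) -> MetricSeries:
    """Per-frame distance between the mass-weighted centers of two domains'
    C-alpha selections."""
    topo = traj.topology
    idx_a = _require(
        np.flatnonzero(domain_a.mask(topo) & np.isin(topo.atom_name, list(atom_names))),
        f"domain {domain_a.name}",
    )
    idx_b = _require(
        np.flatnonzero(domain_b.mask(topo) & np.isin(topo.atom_name, list(atom_names))),
        f"domain {domain_b.name}",
    )
    wa = topo.masses[idx_a]
    wb = topo.masses[idx_b]
    out = np.empty(traj.n_frames)
    for t, frame in enumerate(traj.frames):
        ca = (wa[:, None] * frame[idx_a]).sum(axis=0) / wa.sum()
        cb = (wb[:, None] * frame[idx_b]).sum(axis=0) / wb.sum()
        out[t] = float(np.linalg.norm(ca - cb))
    return MetricSeries(
        MetricKind.DISTANCE,
        out,
        selection_label=f"{domain_a.name}-{domain_b.name}",
    )


def pair_distance_series(traj_or_structure, atom_a: AtomAddress, atom_b: AtomAddress) -> MetricSeries:
    """Per-frame Euclidean distance between two uniquely addressed atoms."""
    frames, topo = _frames_of(traj_or_structure)
    ia = resolve_atom(topo, atom_a)
    ib = resolve_atom(topo, atom_b)
    d = np.linalg.norm(frames[:, ia, :] - frames[:, ib, :], axis=1)
    return MetricSeries(
        MetricKind.PAIR_DISTANCE, d, selection_label=f"{atom_a}-{atom_b}"
    )


def _hydrogens_on(topo: Structure, donor_idx: int) -> np.ndarray:
    same_res = (
        (topo.residue_number == topo.residue_number[donor_idx])
        & (topo.chain_id == topo.chain_id[donor_idx])
    )
    is_h = np.array([str(e).upper() == "H" for e in topo.element])
    return np.flatnonzero(same_res & is_h)


def hbond_occupancy(
    traj: Trajectory, spec: HBondSpec
) -> Tuple[float, MetricSeries]:
    """Fraction of frames in which the donor/acceptor pair satisfies the
    hydrogen-bond criterion, plus the pair-distance series.

    The angle criterion (donor-H-acceptor within ``angle_cutoff_deg`` of
    linear) only applies when it is configured and hydrogens exist on the
    donor residue.
    """
    dist = pair_distance_series(traj, spec.donor_heavy, spec.acceptor_heavy)
    ok = dist.values <= spec.distance_cutoff
    if spec.angle_cutoff_deg is not None:
        topo = traj.topology
        di = resolve_atom(topo, spec.donor_heavy)
        ai = resolve_atom(topo, spec.acceptor_heavy)
        h_idx = _hydrogens_on(topo, di)
        if h_idx.size:
            min_angle = np.deg2rad(180.0 - spec.angle_cutoff_deg)
            for t in range(traj.n_frames):
                if not ok[t]:
                    continue
                frame = traj.frames[t]
                angles = []
                for h in h_idx:
                    v1 = frame[di] - frame[h]
                    v2 = frame[ai] - frame[h]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    angles.append(np.arccos(np.clip(cosang, -1, 1)))
                ok[t] = max(angles) >= min_angle
    occupancy = float(np.mean(ok))
    return occupancy, dist


def backbone_hbond_count(
    traj: Trajectory,
    distance_cutoff: float = 3.5,
    angle_cutoff_deg: float = 30.0,
) -> MetricSeries:
    """Per-frame count of backbone N(i)...O(j) pairs within the cutoff.

    Pairs with residue separation |i - j| < 2 are excluded.  When amide
    hydrogens are present in the topology the N-H...O angle must be within
    ``angle_cutoff_deg`` of linear; otherwise the criterion is
    distance-only.
    """
    topo = traj.topology
    n_idx = np.flatnonzero(topo.atom_name == "N")
    o_idx = np.flatnonzero(topo.atom_name == "O")
    flags = []
    if n_idx.size == 0 or o_idx.size == 0:
        return MetricSeries(
            MetricKind.HBOND_COUNT,
            np.zeros(traj.n_frames),
            unit="count",
            flags=["missing backbone N/O atoms"],
        )
    # amide H for each donor N, when present ('H' or 'HN' on the same residue)
    h_for_n = {}
    for i in n_idx:
        same = (
            (topo.residue_number == topo.residue_number[i])
            & (topo.chain_id == topo.chain_id[i])
            & np.isin(topo.atom_name, ["H", "HN"])
        )
        hh = np.flatnonzero(same)
        if hh.size:
            h_for_n[int(i)] = int(hh[0])
    use_angle = bool(h_for_n)
    if not use_angle:
        flags.append("no amide hydrogens; distance-only criterion")

    n_res = topo.residue_number[n_idx]
    o_res = topo.residue_number[o_idx]
    sep_ok = np.abs(n_res[:, None] - o_res[None, :]) >= 2
    counts = np.zeros(traj.n_frames)
    min_angle = np.deg2rad(180.0 - angle_cutoff_deg)
    for t, frame in enumerate(traj.frames):
        dn = frame[n_idx]
        do = frame[o_idx]
        d = np.linalg.norm(dn[:, None, :] - do[None, :, :], axis=2)
        pair_ok = (d <= distance_cutoff) & sep_ok
        if use_angle:
            for a, b in zip(*np.nonzero(pair_ok)):
                h = h_for_n.get(int(n_idx[a]))
                if h is None:
                    continue
                v1 = frame[n_idx[a]] - frame[h]
                v2 = frame[o_idx[b]] - frame[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.arccos(np.clip(cosang, -1, 1)) < min_angle:
                    pair_ok[a, b] = False
        counts[t] = int(pair_ok.sum())
    return MetricSeries(MetricKind.HBOND_COUNT, counts, unit="count", flags=flags)
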