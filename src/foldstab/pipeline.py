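"""Pipeline orchestration: configuration, stage chaining and report assembly.

A run is driven by a declarative YAML config (see :class:`RunConfig`).  The
denaturation pipeline chains correct -> extract -> segmental sigmoid fit ->
energetics / probe analyses per input table and assembles a stability
report whose columns mirror the fitted-parameter tables of a denaturation
study (midpoints per segment, dG_H2O and m, pKb, pKc, Cm, dG0, log K_obs).
A stage failure for one probe is recorded and the remaining probes still
run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import preprocess, probes, spectra, structure, synthetic, trajectory as traj_mod
from .energetics import KConvention, chemical_energetics, thermal_energetics
from .errors import FoldstabError, ValidationError
from .spectra import AxisKind, ProbeKind
from .structure import AtomAddress, DomainDefinition
from .trajectory import HBondSpec
from .unfolding import SegmentScheme, fit_two_step, normalize_segment

log = logging.getLogger("foldstab")

REPORT_SCHEMA_VERSION = 1

DEFAULT_DOMAINS = {"WW": [(6, 39)], "PPIase": [(50, 163)]}
DEFAULT_MOTIF_PAIRS = [
    (113, "SG", 59, "NE2"),
    (59, "ND1", 157, "ND1"),
    (157, "NE2", 152, "OG1"),
]


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run."""

    probes: List[dict] = field(default_factory=list)
    trajectory: Optional[dict] = None
    convention: str = "literal_fu"
    regression_axis: str = "celsius"
    t_kelvin: float = 298.15
    n_chains: int = 1
    p_t: float = 1.0
    transition_filter: tuple = (0.05, 0.95)
    seed: int = 0
    output_dir: str = "foldstab_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.transition_filter is not None:
            cfg.transition_filter = tuple(cfg.transition_filter)
        KConvention(cfg.convention)
        if cfg.regression_axis not in ("celsius", "kelvin"):
            raise ValidationError("regression_axis must be celsius|kelvin")
        return cfg

    def to_dict(self) -> dict:
        return {
            "probes": self.probes,
            "trajectory": self.trajectory,
            "convention": self.convention,
            "regression_axis": self.regression_axis,
            "t_kelvin": self.t_kelvin,
            "n_chains": self.n_chains,
            "p_t": self.p_t,
            "transition_filter": list(self.transition_filter),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def _observable_curve(series, entry):
    obs = entry.get("observable", {"type": "band", "wavelength_nm": 340.0})
    if obs.get("type") == "ratio":
        return preprocess.intensity_ratio(
            series, float(obs.get("num_nm", 350.0)), float(obs.get("den_nm", 335.0))
        )
    return preprocess.extract_band(series, float(obs.get("wavelength_nm", 340.0)))


def _fit_entry(fit) -> dict:
    return {
        "midpoint": fit.midpoint,
        "midpoint_se": fit.midpoint_se,
        "steepness": fit.steepness,
        "baseline_native": fit.baseline_native,
        "baseline_denatured": fit.baseline_denatured,
        "residual_norm": fit.residual_norm,
        "n_points": fit.n_points,
        "segment_bounds": list(fit.segment_bounds),
    }


def analyze_probe(entry: dict, config: RunConfig) -> dict:
    """Run the full denaturation chain for one probe input."""
    # only pass through what the entry states; file metadata supplies the rest
    schema = {
        k: entry[k] for k in ("probe_kind", "axis_kind") if k in entry
    }
    if "schema" in entry:
        schema.update(entry["schema"])
    series = spectra.read_spectrum_series(entry["path"], schema)
    series, correction = preprocess.correct_inner_filter(series)
    result: dict = {
        "analysis": entry.get("analysis", "thermal"),
        "inner_filter_applied": bool(correction.applied.any()),
        "max_correction_factor": correction.max_correction_factor,
    }
    analysis = result["analysis"]

    if analysis in ("ans", "rls"):
        wavelength = float(entry.get("wavelength_nm", 488.0 if analysis == "ans" else 450.0))
        curve = preprocess.extract_band(series, wavelength)
        if analysis == "ans":
            probe_result = probes.fit_ans_midpoint(curve, wavelength)
            result["pKb"] = probe_result.value
        else:
            probe_result = probes.fit_rls_peak(curve, wavelength)
            result["pKc"] = probe_result.value
        result["value_se"] = probe_result.value_se
        result["model_params"] = probe_result.model_params
        result["flags"] = probe_result.flags
        return result

    curve = _observable_curve(series, entry)
    scheme = SegmentScheme([float(b) for b in entry.get("segments", [])])
    fits = fit_two_step(curve, scheme)
    result["segments"] = [_fit_entry(f) for f in fits]
    midpoint_name = {"thermal": "Tm", "acid": "pKa", "chemical": "Cm"}.get(analysis)
    if midpoint_name:
        result[midpoint_name] = [f.midpoint for f in fits]

    seg_index = int(entry.get("energetics_segment", 1)) - 1
    frac = normalize_segment(curve, fits[seg_index])
    f_lo, f_hi = config.transition_filter
    if analysis == "thermal":
        thermo = thermal_energetics(
            frac,
            convention=config.convention,
            temperature_unit_for_regression=config.regression_axis,
            f_min=f_lo,
            f_max=f_hi,
        )
        result["delta_g_h2o"] = thermo.delta_g_h2o
        result["m_value"] = thermo.m_value
        result["delta_g_h2o_se"] = thermo.delta_g_h2o_se
        result["m_value_se"] = thermo.m_value_se
        result["per_point"] = thermo.per_point
    elif analysis == "chemical":
        chem = chemical_energetics(
            frac,
            p_t=config.p_t,
            n=config.n_chains,
            t_kelvin=config.t_kelvin,
            convention=entry.get("convention", "ratio"),
            f_min=f_lo,
            f_max=f_hi,
        )
        result["Cm_fit"] = chem.c_m
        result["delta_g0"] = chem.delta_g0
        result["log_k_obs"] = chem.log_k_obs
        result["m_value"] = chem.m_value
        result["delta_g0_se"] = chem.delta_g0_se
        result["log_k_obs_se"] = chem.log_k_obs_se
        result["per_point"] = chem.per_point
    return result


def run_denaturation(config: RunConfig) -> dict:
    """Execute every configured probe; failures are recorded per probe."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "probes": {},
        "errors": {},
    }
    for entry in config.probes:
        name = entry.get("name", Path(entry.get("path", "probe")).stem)
        try:
            log.info("probe %s: path=%s analysis=%s", name, entry.get("path"),
                     entry.get("analysis"))
            report["probes"][name] = analyze_probe(entry, config)
        except (FoldstabError, OSError) as exc:
            log.warning("probe %s failed: %s", name, exc)
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
    _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    rows = []
    for name, res in report.get("probes", {}).items():
        row = {"probe": name, "analysis": res.get("analysis")}
        for key in ("Tm", "pKa", "Cm"):
            for i, v in enumerate(res.get(key, []), start=1):
                row[f"{key}_{i}"] = v
        for key in ("pKb", "pKc", "delta_g_h2o", "m_value", "delta_g0",
                    "log_k_obs", "Cm_fit"):
            if key in res:
                row[key] = res[key]
        rows.append(row)
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "report.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Trajectory pipeline
# ---------------------------------------------------------------------------


def run_trajectory_analysis(
    traj_path,
    config: Optional[RunConfig] = None,
    output_dir: Optional[str] = None,
) -> dict:
    """Compute the full set of trajectory stability metrics.

    RMSD (global + per domain, each domain superposed on its own C-alpha
    atoms), RMSF, Rg (global + per domain), inter-domain distance, the
    configured motif pair distances/occupancies, and the backbone
    hydrogen-bond count.  Single-frame inputs skip RMSF with a warning;
    selection failures are reported per metric and the rest proceed.
    """
    config = config or RunConfig()
    tcfg = dict(config.trajectory or {})
    out_dir = Path(output_dir or config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    traj = structure.read_multimodel_pdb(traj_path)
    topo = traj.topology
    domains = {
        name: DomainDefinition(name, [tuple(r) for r in ranges])
        for name, ranges in (tcfg.get("domains") or DEFAULT_DOMAINS).items()
    }
    pair_specs = [
        HBondSpec(
            donor_heavy=AtomAddress(int(ra), na),
            acceptor_heavy=AtomAddress(int(rb), nb),
            distance_cutoff=float(tcfg.get("hbond_cutoff", 3.5)),
        )
        for ra, na, rb, nb in (tcfg.get("hbond_pairs") or DEFAULT_MOTIF_PAIRS)
    ]

    summary: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_frames": traj.n_frames,
        "n_atoms": topo.n_atoms,
        "metrics": {},
        "warnings": [],
        "errors": {},
    }
    frames_tables: Dict[str, np.ndarray] = {}

    ca = structure.select(traj, atom_names=["CA"])

    def _stage(name, fn):
        try:
            return fn()
        except FoldstabError as exc:
            summary["errors"][name] = f"{type(exc).__name__}: {exc}"
            return None

    ms = _stage("rmsd_global", lambda: traj_mod.rmsd_series(traj, ca, label="global CA"))
    if ms is not None:
        summary["metrics"]["rmsd_global_mean"] = ms.mean
        frames_tables["rmsd_global"] = ms.values
    for name, dom in domains.items():
        idx = np.flatnonzero(dom.mask(topo) & (topo.atom_name == "CA"))
        ms = _stage(
            f"rmsd_{name}", lambda idx=idx, name=name: traj_mod.rmsd_series(
                traj, idx, label=f"{name} CA"
            )
        )
        if ms is not None:
            summary["metrics"][f"rmsd_{name}_mean"] = ms.mean
            frames_tables[f"rmsd_{name}"] = ms.values
        rg = _stage(
            f"rg_{name}", lambda idx=idx, name=name: traj_mod.radius_of_gyration(
                traj, idx, label=name
            )
        )
        if rg is not None:
            summary["metrics"][f"rg_{name}_mean"] = rg.mean
            frames_tables[f"rg_{name}"] = rg.values

    rg = _stage("rg_global", lambda: traj_mod.radius_of_gyration(traj, ca, label="global"))
    if rg is not None:
        summary["metrics"]["rg_global_mean"] = rg.mean
        frames_tables["rg_global"] = rg.values

    if traj.n_frames >= 2:
        prof = _stage("rmsf", lambda: traj_mod.rmsf_profile(traj, ca, label="global CA"))
        if prof is not None:
            summary["metrics"]["rmsf_mean"] = prof.mean
            pd.DataFrame(
                {
                    "residue_number": topo.residue_number[ca],
                    "rmsf_A": prof.values,
                }
            ).to_csv(out_dir / "rmsf.csv", index=False)
    else:
        summary["warnings"].append("single frame: RMSF skipped")

    if len(domains) >= 2:
        names = list(domains)
        ms = _stage(
            "interdomain_distance",
            lambda: traj_mod.interdomain_distance(traj, domains[names[0]], domains[names[1]]),
        )
        if ms is not None:
            summary["metrics"]["interdomain_distance_mean"] = ms.mean
            frames_tables["interdomain_distance"] = ms.values

    summary["hbond_pairs"] = {}
    for spec in pair_specs:
        label = f"{spec.donor_heavy}-{spec.acceptor_heavy}"

        def _pair(spec=spec):
            occ, dist = traj_mod.hbond_occupancy(traj, spec)
            return occ, dist

        res = _stage(f"hbond {label}", _pair)
        if res is not None:
            occ, dist = res
            summary["hbond_pairs"][label] = {
                "occupancy": occ,
                "mean_distance_A": dist.mean,
                "cutoff_A": spec.distance_cutoff,
            }
            frames_tables[f"dist_{label}"] = dist.values

    ms = _stage(
        "backbone_hbonds",
        lambda: traj_mod.backbone_hbond_count(
            traj,
            distance_cutoff=float(tcfg.get("backbone_hbond_cutoff", 3.5)),
            angle_cutoff_deg=float(tcfg.get("backbone_hbond_angle", 30.0)),
        ),
    )
    if ms is not None:
        summary["metrics"]["backbone_hbond_mean"] = ms.mean
        summary["warnings"].extend(ms.flags)
        frames_tables["backbone_hbonds"] = ms.values

    if frames_tables:
        table = {"frame": np.arange(traj.n_frames)}
        if traj.frame_times is not None:
            table["time_ps"] = traj.frame_times
        table.update(frames_tables)
        pd.DataFrame(table).to_csv(out_dir / "per_frame_metrics.csv", index=False)
    with open(out_dir / "trajectory_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


# ---------------------------------------------------------------------------
# Synthetic bundle (used by the CLI `simulate` subcommand and tests)
# ---------------------------------------------------------------------------


def simulate_bundle(out_dir, seed: int = 0) -> dict:
    """Write a complete synthetic input bundle plus its truth parameters.

    Produces thermal/acid/chemical spectral tables, ANS and RLS series, a
    toy multi-model PDB trajectory and a ready-to-run YAML config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths: dict = {"seed": seed}

    thermal = synthetic.SpectralTruth(
        scheme="two_step", midpoints=(54.57, 71.54), steepness=(2.0, 2.0), seed=seed
    )
    spectra.write_spectrum_series(
        synthetic.generate_denaturation_series(thermal), out / "thermal.csv"
    )
    truths["thermal"] = {"midpoints": list(thermal.midpoints)}

    acid = synthetic.SpectralTruth(
        scheme="two_step", midpoints=(3.87, 2.43), steepness=(0.25, 0.2), seed=seed + 1
    )
    spectra.write_spectrum_series(
        synthetic.generate_denaturation_series(acid, axis_kind=AxisKind.PH),
        out / "acid.csv",
    )
    truths["acid"] = {"midpoints": list(acid.midpoints)}

    chem = synthetic.SpectralTruth(
        scheme="one_step", midpoints=(3.51,), steepness=(0.35,),
        band_center_native_nm=342.0, seed=seed + 2,
    )
    spectra.write_spectrum_series(
        synthetic.generate_denaturation_series(chem, axis_kind=AxisKind.DENATURANT_M),
        out / "chemical.csv",
    )
    truths["chemical"] = {"midpoints": list(chem.midpoints)}

    spectra.write_spectrum_series(
        synthetic.generate_probe_series(ProbeKind.ANS, midpoint=4.50, seed=seed + 3),
        out / "ans.csv",
    )
    truths["ans"] = {"pKb": 4.50}
    spectra.write_spectrum_series(
        synthetic.generate_probe_series(ProbeKind.RLS, peak_center=3.21, seed=seed + 4),
        out / "rls.csv",
    )
    truths["rls"] = {"pKc": 3.21}

    traj_truth = synthetic.TrajectoryTruth(
        n_residues=40,
        n_frames=100,
        domain_a_size=20,
        per_residue_sigma=0.3,
        domain_separation_profile=np.linspace(12.0, 18.0, 100),
        hbond_pairs=[
            synthetic.HBondPairTruth(10, "SG", 30, "NE2", designed_occupancy=0.7)
        ],
        seed=seed + 5,
    )
    traj = synthetic.generate_trajectory(traj_truth)
    structure.write_multimodel_pdb(traj, out / "trajectory.pdb")
    truths["trajectory"] = {
        "separation_range": [12.0, 18.0],
        "hbond_occupancy": 0.7,
    }

    config = {
        "seed": seed,
        "output_dir": str(out / "results"),
        "convention": "ratio",
        "probes": [
            {"name": "thermal", "path": str(out / "thermal.csv"),
             "analysis": "thermal", "segments": [63.0],
             "observable": {"type": "band", "wavelength_nm": 340.0}},
            {"name": "acid", "path": str(out / "acid.csv"),
             "analysis": "acid", "segments": [3.15]},
            {"name": "chemical", "path": str(out / "chemical.csv"),
             "analysis": "chemical", "segments": []},
            {"name": "ans", "path": str(out / "ans.csv"), "analysis": "ans"},
            {"name": "rls", "path": str(out / "rls.csv"), "analysis": "rls"},
        ],
        "trajectory": {
            "path": str(out / "trajectory.pdb"),
            "domains": {"A": [[1, 20]], "B": [[21, 40]]},
            "hbond_pairs": [[10, "SG", 30, "NE2"]],
        },
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truths, fh, indent=2, default=_jsonable)
    return truths
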