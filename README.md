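# foldstab

Protein fold-stability analysis in two halves:

1. **Spectroscopic denaturation thermodynamics** — thermal, acidic and
   chemical unfolding curves from intrinsic Trp fluorescence, far-UV CD,
   ANS and RLS spectra: inner-filter correction, band/ratio observables,
   one- and two-step (three-state) Boltzmann transition fitting, and
   linear-extrapolation energetics yielding Tm, pKa, pKb, pKc, Cm,
   ΔG(H₂O), m-values, ΔG₀ and log₁₀ K_obs (half-chevron intercept).
2. **Structure/trajectory stability metrics** — PDB and multi-model-PDB
   input, Kabsch superposition, global/per-domain Cα-RMSD, Cα-RMSF, radius
   of gyration, inter-domain distance, atom-pair distances, hydrogen-bond
   occupancy at a distance cutoff (default 3.5 Å) and backbone H-bond
   counts.

A synthetic-data module generates spectra, LEM-consistent fraction curves
and toy two-domain trajectories with known ground truth, so every stage is
testable without downloads.

## Command line

```sh
# write a complete synthetic input bundle + ready-to-run config
foldstab simulate --out demo --seed 1

# denaturation fits (Tm/pKa/Cm, energetics, pKb/pKc) from a YAML config
foldstab denature-fit --config demo/config.yaml

# trajectory metrics from a multi-model PDB
foldstab traj-analyze --traj demo/trajectory.pdb --config demo/config.yaml --out demo/traj

# merge the JSON summaries
foldstab report --results demo/results
```

Exit codes: 0 success, 2 validation/configuration error, 3 fit failure.
Reports are written as `report.json`/`report.csv` (denaturation),
`trajectory_summary.json` + `per_frame_metrics.csv` (trajectory), with the
effective configuration echoed alongside.

Selections use compact strings such as `chain:A,res:50-163,atom:CA`.
Domain defaults follow Pin1 author numbering (WW 6–39, PPIase 50–163) and
are configurable, as are the probe wavelengths (ANS 488 nm, RLS 450 nm
with a 440 nm override), the equilibrium-constant convention
(`literal_fu` vs `ratio`), the regression axis unit and all cutoffs.

## Package layout

| module | contents |
| --- | --- |
| `foldstab.spectra` | `SpectrumSeries`/`UnfoldingCurve`/`FractionCurve`, CSV/TSV I/O |
| `foldstab.preprocess` | inner-filter correction, band extraction, F350/F335 ratio, λmax |
| `foldstab.unfolding` | unfolded fraction, Boltzmann transition fits, segment schemes |
| `foldstab.energetics` | K conventions, ΔG = −RT ln K, linear extrapolation, chevron intercepts |
| `foldstab.probes` | ANS sigmoid midpoint (pKb), RLS Gaussian peak (pKc) |
| `foldstab.structure` | PDB/multi-model-PDB read/write, selections, domains |
| `foldstab.trajectory` | Kabsch, RMSD/RMSF/Rg, distances, H-bond occupancy/counts |
| `foldstab.synthetic` | known-truth generators for all of the above |
| `foldstab.pipeline` / `foldstab.cli` | YAML-configured orchestration and the `foldstab` CLI |
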