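# tred — transmembrane receptor dynamics phenotyping

`tred` is a simulation and analysis toolkit for biophysical phenotyping of
membrane receptors by single-particle tracking (SPT). The underlying idea:
the cortical actin meshwork beneath the plasma membrane corrals
transmembrane receptors (such as EGFR) into compartments, so the lateral
diffusivity *D* and the compartment ("linear confinement") size *L* of a
receptor read out the state of the cortical cytoskeleton — which in turn
tracks metastatic potential of the cell. The package is aimed at
quantitative cell biologists who want a tested, reproducible pipeline for
this class of assay, and at method developers who need a ground-truthed
synthetic benchmark.

## What it computes

For a receptor undergoing hop diffusion in square corrals of side *L*, the
time-averaged mean-squared displacement (MSD) of a trajectory is modelled
as

    ρ(Δt) = (L²/3)·(1 − e^(−Δt/τ)) + 4·D_M·Δt + c

where `L²/3` is the confinement plateau (two axes of a square corral),
`τ` the relaxation time, `D_M` the long-time (inter-compartment hop)
diffusivity, and `c = 4σ_loc²` the static offset from localization noise.
The headline short-time diffusivity *D* is slope/4 of an offset-corrected
weighted linear fit to MSD lags 2–5. Groups of trajectories are summarized
as mean ± SEM and compared with an F-test-selected Student/Welch *t*-test
(or one-way ANOVA for >2 groups), with `* p<0.05, ** p<0.01, *** p<0.001`.

Modules:

| module             | role                                                              |
|--------------------|-------------------------------------------------------------------|
| `membrane_sim`     | generators: corral/hop trajectories, PSF movie rendering, 3D internalization tracks, actin z-stack phantoms, wound-mask series |
| `spot_tracking`    | spot detection (matched filter + Gaussian fit) and greedy mutual-NN linking |
| `msd_dynamics`     | MSD curves, confined-model fit (*D*, *L*), group summaries        |
| `internalization3d`| time-weighted inward movement and internalization velocity        |
| `actin_quant`      | orthogonal strip projections, normalized cortical-actin density   |
| `phenostats`       | relative wound density, confluence, t/F/ANOVA scheme, Pearson r, hypergeometric overlap |
| `pipeline_io`      | trajectory CSV / TIFF / YAML config I/O and the `run_tred` runner |

## Worked example

Simulate two cell-line-like groups at published group means
(a highly invasive line: D = 0.0177 µm²/s, L = 132.1 nm; a non-invasive
line: D = 0.0080 µm²/s, L = 92.4 nm; hard corrals, 1200 frames at
20 frames/s, 20 nm localization noise) and run the full analysis:

```python
from tred.pipeline_io import TredConfig, GroupSpec, run_tred

cfg = TredConfig(groups=(
    GroupSpec(label="PC3-like",   n_tracks=300, D_micro=0.0177, L_comp_nm=132.1),
    GroupSpec(label="LNCaP-like", n_tracks=300, D_micro=0.0080, L_comp_nm=92.4),
), seed=1)
report = run_tred(cfg)
```

The report (abridged) prints:

```json
{
 "groups": {
  "PC3-like":   {"mean_D_um2_s": 0.00271, "mean_L_nm": 131.95, "sem_L_nm": 0.37, "n": 300},
  "LNCaP-like": {"mean_D_um2_s": 0.00137, "mean_L_nm":  91.76, "sem_L_nm": 0.26, "n": 300}
 },
 "comparisons": [
  {"quantity": "D", "test": "welch-t", "p": 1.8e-222, "stars": "***"},
  {"quantity": "L", "test": "welch-t", "p": 0.0,      "stars": "***"}
 ],
 "percent_differences": [
  {"quantity": "D", "higher": "PC3-like", "percent": 97},
  {"quantity": "L", "higher": "PC3-like", "percent": 44}
 ]
}
```

Reading the numbers: the confinement sizes are recovered essentially
unbiased (131.95 vs 132.1 nm and 91.76 vs 92.4 nm true), and the group
ordering is highly significant on both observables. The short-time *D*
from hard-corral tracks is much lower than the microscopic input
diffusivity — confinement saturates the MSD within a few lags, which is
exactly why *D* and *L* carry complementary information. The relative
*D* difference between groups (97%) is preserved.

A CLI mirrors the library (`tred simulate|track|msd|inward|actin|pheno|run`),
e.g.

```sh
tred simulate trajectories --seed 3 --out fix --n-tracks 10
tred msd --trajectories fix/trajectories.csv --group demo
```

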