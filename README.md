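# gliaclone

Clonal-lineage analysis of cerebellar astrocytes.

During cerebellar development, ventricular-zone radial glia give rise to the
three major astrocyte types — Bergmann glia (BG) in the Purkinje cell layer,
granular-layer astrocytes (GLA), and white-matter astrocytes (WMA).
Multicolor lineage tracing (12-mark combinatorial labeling, or 4-color
stochastic reporters) tags progenitors so that all descendants of one cell
share a color identity, turning "which astrocytes are siblings?" into a
measurable question. `gliaclone` is a toolkit for the quantitative side of
such experiments, aimed at developmental biologists and modellers analysing
clone tables (one row per labeled cell: animal, color identity, astrocyte
type, lobule, lobular wall, section, optional 3D coordinates in µm).

It provides:

- **Clone model & census** (`gliaclone.model`) — clone tables in/out
  (CSV/TSV, plus an XLSX adapter), homogeneous-vs-heterogeneous clone
  classification (HomC/HetC; "triple" = BG+GLA+WMA, "double" = BG+GLA),
  and class censuses.
- **Clone statistics** (`gliaclone.stats`) — medio-lateral dispersion from
  the parasagittal section span, antero-posterior lobule spread, clone-wise
  cell-type stoichiometry aggregated as geometric means (natural-log
  domain: a mean ratio of 1.772 ↔ 0.572 log units), size–dispersion
  correlation, cleavage-angle binning, BCa bootstrap CIs (N = 1,000).
- **Subclone modularity** (`gliaclone.modularity`) — nearest-neighbor-distance
  (NND) clustering test against uniform random references with a
  Monte-Carlo-calibrated p-value and Richards sigmoid fits, and a k-means
  subclone detector (`SubcloneKMeans`, scikit-learn estimator) that grows k
  from 1 to 5 until 95% of variance is accounted, with ≥ 6 cells per clone
  and ≥ 3 cells per cluster.
- **Label-collision errors** (`gliaclone.color_errors`) — Monte-Carlo
  estimators of *splitting* errors (one clone's combination recurring by
  chance among 2¹² = 4,096 theoretical combinations; a birthday problem
  with closed form `(n − K(1 − (1 − 1/K)ⁿ))/n`) and *lumping* errors
  (independent progenitors sharing a combination, resampled from an
  observed reference multiset).
- **Lineage simulator** (`gliaclone.lineage`) — a discrete-time stochastic
  branching model of a single multipotent-progenitor (MP) pool: each MP
  divides synchronously; each daughter remains an MP with probability
  `pMP` or differentiates with generation-dependent BG/GLA/WMA
  probabilities (the fate schedule). Includes the grid fit of `pMP`
  (`ReentryProbabilityFit`), generation↔age mapping by size-distribution
  matching, birth-time (P0) snapshots, and simulated-vs-observed
  comparison reports.
- **Confetti clone calling** (`gliaclone.confetti`) — growth-scaled minimal
  clone distance (137.62 µm × 2.3 ≈ 317 µm) and single-linkage clone
  identification under same-color / same-lobule / same-wall / contiguity
  rules (`ConfettiCloneCaller`).
- **Synthetic data** (`gliaclone.synth`) — generators for both labeling
  styles with ground-truth sidecars, so every stage is testable without
  microscopy data.
- **CLI** (`gliaclone`) — `synth`, `census`, `stats`, `modularity`,
  `errors`, `simulate`, `fit`, `confetti`, `run`, with seed-derived
  reproducible manifests.

## Worked example

```python
import gliaclone as gc

# a synthetic early-electroporation-like sample with known ground truth
ds, truth = gc.generate_startrack_dataset(gc.SynthConfig(seed=11, n_clones=200))
print(gc.clone_census([ds]))

r, p = gc.size_dispersion_correlation(ds.clones)
print(f"size-dispersion Pearson r = {r:.3f}, p = {p:.2e}")

split = gc.splitting_error(244, gc.ErrorSimConfig(reps=300_000, seed=1))
print(f"splitting error: {split['probability']:.4f}")

sched = gc.FateSchedule.uniform()
cohort = gc.simulate_cohort(gc.SimParams(pmp=0.465, root_mp_fraction=0.7, seed=2),
                            sched, n_clones=20_000)
print(f"mean clone size: {cohort.final_sizes().mean():.2f}")
```

prints

```
analysis_age category    subtype  count  fraction
         P30     HetC     BG+GLA     60     0.300
         P30     HetC BG+GLA+WMA     37     0.185
         P30     HomC         BG     49     0.245
         P30     HomC        GLA     32     0.160
         P30     HomC        WMA     22     0.110
size-dispersion Pearson r = 0.420, p = 6.29e-10
splitting error: 0.0291
mean clone size: 10.98
```

Reading the numbers: about half the generated clones are heterogeneous
(double + triple = 48.5%), matching the configured mixture; clone size and
medio-lateral dispersion correlate positively (r = 0.42); a sample of 244
clones drawn over 4,096 equiprobable color combinations mislabels ~2.9% of
clones as duplicates of an earlier one; and the branching process at
pMP = 0.465 with 70% multipotent roots has mean final clone size
0.7·2(1−p)/(1−2p) + 0.3 = 11.0.

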