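# Methods

This note documents the models, conventions and numerical choices behind
`gliaclone`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
do not themselves compute.

## Data model and conventions

A clone table has one row per labeled cell: sample, electroporation or
induction age, analysis age (P0 or P30), color identity, cell type, lobule,
lobular wall, 1-based parasagittal section index, and optional 3D
coordinates in µm (M-L, A-P, D-V axes). Cells sharing a color identity
within one animal form a clone; identical combinations in different animals
are distinct clones, because collision-error analyses treat animals
independently.

Type vocabularies are age-specific: BG / GLA / WMA / CNA at P30, and
PCLp / GLAp / PWM / VC precursor categories at birth. Conventions adopted
where a choice had to be fixed:

- **CNA cells** stay in the data model but are excluded from quantitative
  clone-type statistics and from all simulator comparisons; clones
  containing CNA classify as "other" heterogeneous clones.
- **VZ-resident P0 clones** (all-VC) form their own homogeneous subtype
  "VZ" and are kept out of cortical/PWM comparisons.
- **M-L dispersion** uses the inclusive section-span convention:
  `(max_section − min_section + 1) × thickness` (default 50 µm), so a
  single-section clone spans one thickness. When 3D coordinates exist, a
  max-pairwise-M-L-difference metric is also available, but the
  section-span metric is the default because it is defined for every
  digitized clone.
- **Cleavage-angle bins** are left-closed: [0°, 30°) horizontal,
  [30°, 60°) oblique, [60°, 90°] vertical. The interval labels in common
  usage overlap at the boundaries; a convention had to be fixed, and
  left-closed bins make the partition exhaustive and disjoint.

## Ratio statistics

Cell-type count ratios are bounded below by zero and right-skewed, so all
ratio aggregation happens in natural-log units: per-clone (or per-subclone)
ratios are logged, averaged, and the mean is back-transformed — i.e. means
of ratios are geometric means, and a ratio r and its reciprocal 1/r are
symmetric around 0 log units (1.772 ↔ 0.572 log units). Uncertainty is
reported two ways, because the convention is ambiguous in the field: the
log-domain SEM (back-transformed into a multiplicative interval, the
default) and the linear-domain SEM. Confidence intervals use the
bias-corrected and accelerated (BCa) bootstrap with N = 1,000 resamples
(scipy's implementation). Kurtosis of ratio distributions is the *excess*
kurtosis of the log-ratio sample (a uniform log-ratio distribution sits
near −1.2).

## Subclone modularity

Two analyses address whether the cells of a heterogeneous clone aggregate
in spaced-out clusters (subclones).

**NND clustering test.** For a clone's 3D coordinates, per-cell
nearest-neighbor distances are compared against a uniform random reference
of identical size drawn from the sample's axis-aligned bounding box (the
"corresponding volume" is not further specified by any digitization
standard, so the box is the least-arbitrary choice and is recorded).
Both cumulative NND curves are fitted with a 4-parameter Richards
asymmetric sigmoid with asymptotes fixed at 0 and 1,
`y = (1 + q·exp(−rate·(x − midpoint)))^(−1/ν)`, initialized from the
empirical quartiles and fitted by least squares.

The comparison statistic is the two-sample Kolmogorov-Smirnov statistic.
NNDs within one sample are positively correlated — mutual nearest-neighbor
pairs contribute duplicated distances — so the textbook KS p-value is
anti-conservative on NND data (we measured ~12.6% type-I error at
α = 0.05 under a uniform null with n = 25). The reported `p_value` is
therefore Monte-Carlo calibrated: the null distribution of the KS statistic
is simulated from pairs of independent uniform draws of the same size and
box, and the p-value is the (mid-p corrected) exceedance fraction. The
mid-p correction matters because the KS statistic is discrete (multiples of
1/n) and the uncorrected Monte-Carlo p is markedly conservative. The plain
KS p-value is still returned as `ks_p_value` for comparability with the
classical procedure. The null table depends only on n and the box shape
and can be precomputed and reused.

**K-means subclone detection.** `SubcloneKMeans` tests k = 1…5 clusters
(100 random restarts each, best by within-cluster sum of squares, ties by
restart order under a fixed seed) and keeps the smallest k whose
*accounted variance* — defined here as between-cluster sum of squares over
total sum of squares, a definition that had to be fixed and is
configurable — reaches 95%. Clones with fewer than 6 cells are excluded;
clusters must hold at least 3 cells. When the variance-selected k violates
the minimum-cells constraint, k is decremented until it holds (minimum 1)
and the clone is flagged rather than silently re-split: the historical
workflow resolved such cases by visual inspection, which an automated
pipeline cannot reproduce. The `robustness_check` operation reruns the
analysis at 90% and 99% thresholds (which over- and under-split) and
reports the induced changes in subclone-category fractions and mean
BG:GLA log ratio; it is the automated surrogate for manual curation.
Subclones lacking either BG or GLA are excluded from ratio distributions
(the log ratio is undefined there).

## Color-mark collision errors

With 6 fluorophores in 2 subcellular locations there are 2¹² = 4,096
theoretical combinations, *including* the all-absent one — the arithmetic
of 4,096 forces that inclusion, and the all-false combination is permitted
only in theoretical counting, never as a cell label.

**Splitting error** (one clone read as several because its combination
recurred by chance): per repetition, n clone labels are drawn uniformly
with replacement from the K = 4,096 combinations and the fraction of draws
duplicating an earlier draw is recorded; the estimate is the mean over
300,000 repetitions. The expectation has the closed birthday-problem form
`(n − K(1 − (1 − 1/K)ⁿ))/n`, which the Monte Carlo must match within 3
standard errors (a standing test). It is increasing in n and decreasing
in K.

**Lumping error** (independent progenitors sharing a combination): a
reference vector is built from the observed combination multiset, so
repeated combinations are proportionally more likely to be drawn; per
repetition and per animal, that animal's clone count is drawn with
replacement and the fraction of drawn elements that belong to a repeated
combination *and* collide within the draw is recorded. Drawing with
replacement is the only reading consistent with resampling fixed-size
samples hundreds of thousands of times from one designed vector. The
"compared one-to-one" phrasing of the historical procedure is ambiguous;
the within-draw-collision reading is the default and the alternative
(membership in the repeated set regardless of within-draw collision, an
upper bound) is exposed as `mode="reference"`. A reference with no
repeated combination gives exactly zero under either mode. Probabilities
are kept raw everywhere; rounding to whole percent happens only in
reporting.

## The lineage simulator

The simulator asks whether a single homogeneous multipotent-progenitor
pool can generate the observed clone structure. It is a discrete-time
branching process with synchronous generations:

- The root (generation 0) is an MP with probability `root_mp_fraction`
  (defaults: 0.70 for the early cohort, 0.60 for the late one, matching
  observed unicellular-clone fractions); otherwise the clone is a single
  postmitotic astrocyte typed from the observed unicellular type
  fractions.
- Every MP alive at generation g divides into exactly 2 daughters; each
  daughter independently remains an MP with probability `pMP` (defaults
  0.465 / 0.44) or differentiates into BG, GLA or WMA with probabilities
  from the fate schedule row of its birth generation. Fate schedules are
  generation-indexed probability rows built from birthdating anchor
  fractions with piecewise-constant (step) interpolation, because ages
  convert to generations discretely.
- The process ends when no MPs remain. With 2·pMP < 1 the MP line is
  subcritical and termination is almost sure, with expected final clone
  size `root_mp_fraction · 2(1 − p)/(1 − 2p) + (1 − root_mp_fraction)`
  (11.0 at the 0.465/0.70 defaults) — a standing analytic oracle in the
  tests. The safety cap is 200 generations: the surviving fraction decays
  like (2·pMP)^g ≈ 0.93^g, so a 50-generation cap would still leave ~0.4%
  of lineages unterminated while 200 leaves < 10⁻⁶.

Conventions that had to be fixed: the root is generation 0 and daughters
of the first division are generation 1 (making "generation 6"
well-defined); fate-schedule row g applies to daughters born *into*
generation g; lineages outliving the schedule repeat its last row by
default.

**Fitting pMP** (`ReentryProbabilityFit`, a scikit-learn estimator): a
grid of 21 candidate values from 0.40 to 0.50 in steps of 0.005 (the grid
may touch the critical value 0.5 because the generation cap bounds every
lineage); per candidate, 5 replicates of 3,000 simulated clones; the SSR
between the replicate-mean simulated and the observed clone-size
relative-frequency histograms selects the fit. Size histograms use
unit-width bins up to the observed 99th percentile plus one overflow bin —
the least-arbitrary binning for count data. Ties break toward the lower
pMP. Self-recovery of a planted pMP is within one grid step at 5,000
observed clones (a standing test at planted 0.41 / 0.45 / 0.49).

**Generation↔age mapping**: the generation whose simulated alive-size
distribution (MPs plus differentiated cells born so far) minimizes the
same SSR against the observed birth-age clone sizes; ties break toward the
smaller generation. Mean-matching is a reasonable alternative; SSR on the
full binned distribution is the default because it uses all of the shape.

**Birth-time snapshots** map simulated mature types onto precursor
categories (BG→PCLp, GLA→GLAp, WMA→PWM). MPs alive at the snapshot are
counted in the PWM compartment by default — undifferentiated precursors
reside in the prospective white matter at birth — with an `"exclude"` mode
available, since the right handling is genuinely open.

**Comparison reports** put simulated and observed clone-subtype fractions,
astrocyte-type proportions and size distributions side by side with
chi-squared tests on the count tables. On synthetic data the expected
signature of a wrong single-pool model is reproduced in the tests: sizes
match while subtype proportions deviate.

## Confetti clone calling

Four reporter colors cannot identify clones alone, so clone calling
combines color, lobule, lobular wall and spatial contiguity. The
contiguity scale is anchored at induction: the mean NND between same-color
progenitors (137.62 µm in the reference protocol), scaled by tissue growth
between induction and analysis — the ratio of geometric means of 3D lobule
measurements (2.3-fold from P8 to P30) — giving a minimal inter-clone
distance of ≈ 317 µm. Clone calling is single-linkage clustering: cells of
the same (color, lobule, wall) group closer than the linkage cutoff are
connected, and clones are the connected components. The default cutoff is
half the minimal clone distance: observed clone extents (~104 µm mean) sit
far below the minimal distance (~317 µm), so any cutoff strictly between
them yields the same partition on conforming data; the factor is
configurable. The manual serial-section procedure is not fully
algorithmic; single linkage is this package's documented
operationalization. Cells without coordinates fall back to
section-spacing-based positions; cells lacking a required lobule/wall
label are held out and reported, never silently clustered. Nuclear-GFP
cells are expected to be excluded upstream.

Raising the cutoff can only merge clones (clone count is non-increasing),
a standing property test.

## Synthetic-data generators

The generators exist so every stage has ground truth. Defaults describe an
early-electroporation-like condition and are fixed once:

- clone-class mixture {BG 0.25, GLA 0.15, WMA 0.13, double 0.294,
  triple 0.176} — an approximately even HomC/HetC split with triples near
  18%;
- heterogeneous clone sizes from the branching process at pMP = 0.465
  (doubles conditioned on ≥ 2 cells; triples on ≥ 9 cells, the smallest
  count that can carry ≥ 1 WMA plus the 1:4:4 WMA:GLA:BG stoichiometry —
  triples are the biggest clone type); homogeneous clones 1 + Poisson(0.8)
  cells;
- triple-clone composition anchored on the WMA count with log-normal
  clone-to-clone spread (σ = 0.3 log units) and stochastic rounding, so
  clone-wise geometric-mean ratios are centered on the planted
  stoichiometry; double clones split at 1.5 BG per GLA the same way;
- subclones: isotropic Gaussian scatter (σ = 50 µm per axis) around
  centers placed uniformly with ≥ 600 µm spacing; 2 subclones per double
  and 3 per triple; 85% of subclones planted as BG+GLA-mixed. For an
  isotropic 3D Gaussian the induced mean intercell distance is
  ≈ 2.26 σ (≈ 113 µm at the default), which is the quantity comparable to
  reported intra-subclone distances — the generator exposes σ, not the
  mean distance. Planted subclones are rebalanced to ≥ 3 cells so ground
  truth stays recoverable by the detector's own rules;
- combinations unique by default (repeat probability 0; configurable to
  plant repeated combinations for lumping analyses).

The Confetti generator plants sparse clones whose centers respect the
minimal clone distance, scatters cells within 20% of it, draws one of four
colors per clone, and emits induction-time positions obtained by dividing
analysis positions by the growth factor (growth factor 1 is the identity).

What the generators deliberately do *not* emulate: microscopy noise,
section loss, segmentation or typing errors, anisotropic tissue growth,
lobule geometry beyond labels, or spatial correlation between clone class
and position. Passing recovery tests on this synthetic data therefore
demonstrates correctness of the algorithms under the stated statistical
structure — not robustness to imaging artifacts or to manual-curation
differences on real material.

## Reproducibility and problem sizes

All randomness flows through explicit `numpy` generators or integer seeds;
the CLI derives per-stage seeds from one master seed via SHA-256 and
records them in a manifest. Fixed seeds give byte-identical outputs.

Problem sizes used by the test suite and acceptance script are the
package's own choices: 300,000 repetitions for collision Monte Carlos (the
published repetition count), 50,000 clones for branching-process oracles,
5,000 clones per grid point for pMP recovery, 1,000 simulations (with a
4,999-sample null table) for the spatial test's type-I calibration, and
40-120-clone synthetic samples for recovery tests.

## Known limitations

- The k-means procedure inherits the ambiguity of the variance threshold:
  planted clusters at marginal separation (accounted variance near 95%)
  can be over- or under-split; the robustness check quantifies, not
  removes, this.
- Lumping-error results depend on the observed reference multiset; without
  a sample's real repetition table only the procedure, not the published
  per-animal values, can be checked.
- The simulator deliberately tests only the single-pool null model;
  committed-progenitor alternatives appear solely as synthetic truths in
  comparison tests, not as fittable models.
- GEE-based group comparisons are delegated to established statistical
  packages and are not re-implemented here.
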