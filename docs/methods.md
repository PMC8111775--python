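# Methods

## The model of the leaf gradient

The pipeline treats the first leaf of a young wheat seedling as a steady
developmental conveyor: cells are born in the basal meristem, displaced
tip-ward by the expansion of younger cells below them, and mature in
place. Fifteen ordered samples cover the gradient — sample 1 the shoot
apex (meristem and leaf primordia, position 0), samples 2–9 consecutive
5-mm segments from the base, samples 10–14 discontinuous 10-mm segments
further up the blade, and sample 15 the mature blade of an older leaf
(no position; its age, default 8 days, is a label only and never enters
rate calculations because the sampling there is non-adjacent).

**Position → age.** Cell age at a segment midpoint comes from a monotone
lookup table (packaged default: a saturating curve in which a cell
traverses the first 8–9 mm in its first day and reaches ~30 mm at just
under two days). The lookup can be replaced by the user's own table; the
measured elongation rates of the sampled leaves (defaults 44, 43 and
42 mm/day on successive days) enter as a single multiplicative time
correction, reference rate ÷ observed rate, which is the identity when
the lookup was calibrated at the observed rate.

**Cell-division correction.** Without endoreduplication, every nucleus
that passes through S phase subsequently divides, so the S fraction
relative to the fully cycling meristem measures the fraction of cells
that divide during a transition. The factor `C = 1 + min(1, f_S/f_ref)`,
clipped to [1, 2], reproduces the two anchor cases — exactly 2 at full
cycling, exactly 1 at zero S — and assumes at most one division per
transition, consistent with only one-to-two further division rounds at
the leaf base. Two conventions are deliberate choices, exposed as
configuration: the *upstream* sample's S fraction is used for each
transition (which flanking sample to use is genuinely open; averaging
flanking samples changes cumulative corrections by <5% here), and S
fractions below a floor of 0.01 are treated as zero because they are
indistinguishable from instrument background.

**Rates.** Both the organelle division rate and the compartment growth
rate are log2 fold per day of the division-corrected quantity, on the
cell-age axis. Log2 makes "rounds of division" literal (one round
doubles the corrected count) and makes proliferation and growth directly
comparable. Rates may be negative: the late, small decline in plastid
number is reported as observed, never clipped.

**Phase detection.** The growth-rate series of a developing mesophyll
cell is biphasic. The transition is defined as the interior local
minimum of the 3-point-smoothed series that separates its two largest
local maxima; ties resolve to the earliest index; a monotone series is
an error ("no biphasic structure") rather than a forced answer. The
smoothing window and the tie-break are fixed, documented conventions;
detection without smoothing is available.

## qPCR quantitation

Standard curves are least-squares fits of Cq against log10
concentration over a dilution ladder spanning four orders of magnitude
(25 → 0.0025 pg/μl, five points, two technical replicates). Efficiency
is `10^(−1/slope) − 1`; a slope of −3.3219 is a perfect doubling.
Technical-replicate Cq values are averaged *before* interpolation
through the curve (averaging Cq, not concentration — standard qPCR
practice), then scaled by the dilution factor (10× nuclear, 100×
plastid). The copy-number ratio implements the printed formula verbatim,
halving the inverted-repeat amplicon; per-amplicon mass→copy conversion
weights are configurable and default to equal weights, since the ratio
of means is invariant under any common rescaling. How many of the three
homoeogenomes the nuclear primers amplify in hexaploid wheat is not
resolvable here; no extra ploidy correction is applied beyond the
formula itself. Replicate aggregation averages technical replicates
first, then reports mean ± SEM (sample sd/√n) across biological
replicates; a single biological replicate yields an undefined (NaN) SEM
rather than zero.

## Expression map

Counts are normalized to reads per million per replicate. The expressed
set requires RPM ≥ 1 in *all* replicates of at least one sample; the
dynamic (DYG) filter requires, on replicate-averaged sample means,
max ≥ 5, max/min ≥ 2 and CV ≥ 0.2. Conventions chosen where the
procedure is under-specified, all exposed as arguments: the CV uses the
sample (n−1) standard deviation; a zero minimum makes the fold change
infinite and passes the fold criterion (a gene switched fully on or off
is maximally dynamic); Z-scores use the sample-sd convention. PCA runs
on the gene-standardized replicate matrix (45 observations × genes), so
biological replicates plot as near-coincident points; the top and bottom
5% of genes by loading (ceil) are exported per component for enrichment.

Module clustering builds an **unsigned** weighted correlation network,
`|r|^β` with soft threshold β = 14, converts it to topological-overlap
dissimilarity, clusters with average linkage and cuts the tree at a
fixed module count (default 12). A fixed-count cut was chosen over a
dynamic cut because it is deterministic and testable and matches the
expected module count; the signed/unsigned choice is genuinely open and
unsigned was selected — note that an unsigned network cannot separate
*perfectly* anti-correlated profiles, which does not arise for the
staggered-peak profiles of a developmental gradient. Modules are
relabelled 1..k by the peak sample of their mean profile. Enrichment is
the two-sided hypergeometric test (upper tail for over-, lower for
under-representation), reported as −log10 of the raw probabilities;
multiple-testing adjustment is left to the caller since the module ×
class grid is small and the display convention is raw.

## Regulator ranking

For each target gene a random forest (default 1000 trees, √p feature
subsampling, impurity importance — the established defaults for
tree-ensemble network inference) predicts the target's Z-scored profile
from the candidate regulators' profiles; importances are normalized to
sum to one per target, and a constant target yields an all-zero, flagged
row. The 45 replicate observations are used rather than the 15 sample
means, tripling the sample size (a flagged choice). Each target's forest
is seeded from a stable hash of (seed, target) and predictors are sorted
canonically before fitting, so results are deterministic and invariant
to regulator column order. Phase summaries average normalized importance
over the targets whose module peaks fall in each phase.

## The synthetic experiment

The generator's defaults are the study conditions, set once: 15 samples,
3 replicates, 48 cells per sample, ≥10,000 nuclei per cytometry run, an
S fraction of 0.30 in the meristem declining to below background by
sample 4, 4.5 total organelle division rounds, 12 modules with staggered
peaks (early-weighted: peaks at samples 1–9, 11, 13, 15), qPCR
efficiency 0.95 with Cq noise sd 0.15, standards 25 → 0.0025 pg/μl, and
600 genes (60% dynamic) — a deliberately scaled-down transcriptome that
preserves the module structure and filter margins of the full one.

Planted structure, where the defaults required choices the study design
does not pin down:

* **Counts.** The per-sample true plastid count is
  `N(i) = N₀ · 2^(O(i) − D(i))` with N₀ = 12 proplastids, O the
  cumulative organelle rounds (logistic rise in age, saturating at the
  configured total before the phase boundary, then a planted decline of
  0.03 rounds/sample) and D the cumulative cell doublings implied by the
  planted S fractions through the same correction rule the pipeline
  uses. Per-cell counts are Poisson draws around a lognormally jittered
  mean (microscopy CV 0.15).
* **Areas.** Individual plastid area follows a double sigmoid in age —
  rise, pre-greening plateau, second rapid enlargement — positioned so
  the true growth-rate series has its trough at the configured boundary
  (sample 8) and so that roughly three quarters of compartment growth
  falls after the transition. Cell area saturates early with a small
  late second bout of expansion. The planted boundary stored in the
  ground truth is obtained by applying the detection rule to the
  noise-free series, never asserted independently of it.
* **Expression.** Dynamic genes follow Gaussian bumps *on the cell-age
  axis* (width 0.35 days, per-gene jitter), so the age mapping is
  genuinely exercised; baselines are lognormal around 10 RPM and fold
  changes lognormal around 4 (floored at 2.8, comfortably above the
  filter threshold). Flat genes sit at lognormal levels around 50 RPM.
  Counts are negative binomial (dispersion parameter k = 50, i.e. ~15%
  extra-Poisson replicate CV — typical bulk RNA-seq biological
  replicates) with lognormal ±20% library sizes; a single BACKGROUND row
  absorbs the remaining library mass so that RPM values computed from
  the counts sit on the true scale. Two active regulators drive six
  plastid-phase and six chloroplast-phase targets additively with unit
  effect size; eight decoy regulators carry bumps at other samples.
* **qPCR.** The planted cpDNA/gDNA ratio rises logistically from ~8 to
  ~154 and halves in the mature sample; the 16S/18S ratio rises from
  below 1% to ~0.30. Cq values are generated through the same
  curve model the fitting inverts, with independent noise per technical
  replicate and 5% lognormal biological-replicate variation.

One global seed feeds fixed per-table substreams, so adding a table
never perturbs the others, and a fixed seed yields a byte-identical
bundle (fixed float formatting on write).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: genome-scale transcriptomes with homoeolog
triads and correlated gene families; mappability, GC and 3′ biases in
counting; amplification inhibitors or primer-efficiency drift between
standards and extracts; cytometry histogram-fitting artefacts; the
spatial mixture of cell types within a segment (the generator plants
pure mesophyll trajectories); and any real uncertainty in the
position→age lookup itself. Recovery results here demonstrate that the
estimators invert the stated measurement models at realistic noise, not
that those models are complete for field data.

## Numerical conventions and degenerate inputs

Quartiles use linear interpolation (numpy defaults); the total-area
identity A = N·a is enforced by construction (A is computed as the
product, never measured independently). Argmax ties resolve to the
earliest sample everywhere. Errors are raised — never silently patched —
for: empty or undersized samples (<5 cells), non-positive counts or
ages in rates, zero libraries (named replicate), constant profiles in
Z-scoring/clustering/PCA, standard curves with <3 distinct
concentrations or non-negative slope, zero nuclear quantities, and
monotone growth-rate series. Pipeline outputs are written with fixed
float formatting; reports are validated against a pydantic schema (also
exported as JSON) and reruns with the same configuration are
byte-identical.

## Problem sizes

The shipped tests and the acceptance script run the generator at its
default size (600 genes + 10 regulators, 45 libraries, 48 cells × 15
samples) across up to 100 seeds per property; forests in tests use
50–500 trees. These sizes were chosen so the full suite exercises every
recovery property in about a minute while leaving the estimators'
operating margins (filter sensitivity, clustering ARI, ranking
recovery) essentially at their asymptotic values; the library-facing
defaults (1000 trees) are the field-standard ones.

## Known limitations

* The correction rule caps cell doublings at one per transition; a
  sampling design coarse enough for two doublings per interval would
  need a different estimator.
* Phase detection assumes exactly two growth phases; a third phase (for
  example senescence-driven shrinkage sampled densely) would require
  extending the rule.
* The unsigned co-expression network merges perfectly anti-correlated
  profiles by construction.
* Plan areas are 2-D proxies; no 3-D volume reconstruction is
  attempted, so the chloroplast index can exceed 1 for stacked
  organelles.
* GO-style gene-set enrichment, homoeolog triad analysis and read-level
  processing (trimming, alignment, counting) are out of scope; counts
  and annotation tables are inputs.
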