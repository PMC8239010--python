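# Methods

This note documents the models and procedures implemented in `euscreen`,
the assumptions behind them, the defaults that matter, and what the
synthetic-screen generator does and does not emulate.

## The analysis problem

Global RNA production rates scale with cell size, and both are coupled to
cell-cycle stage.  An arrayed siRNA screen that reads out per-cell nascent
RNA (a 30-minute EU pulse, imaged after click labelling) therefore
confounds three things in every perturbation: a genuine change in
transcription rate, a change in cell size, and a shift in cell-cycle
distribution.  The pipeline's job is to remove technical structure
(staining and imaging artefacts), assign each cell a cycle phase, and
express each cell's EU signal relative to an unperturbed cell *of the same
size and phase*, so that well-level phenotypes isolate the rate component.

## Clean-up

Per-cell rules, in precedence order (a cell is counted once, in the first
matching category): acquisition errors (consumed as an upstream flag when
present), border cells, cytoplasmic DAPI, DAPI outliers, missegmented,
mitotic/apoptotic, out-of-focus site.

* **Cytoplasmic DAPI**: `(DAPI_sum_cell − DAPI_sum_nuclear)/DAPI_sum_cell >
  0.20`, strict inequality; a nuclear signal exceeding the whole-cell
  signal is a data-integrity error because it cannot arise from a
  consistent segmentation.
* **DAPI outliers**: sum nuclear DAPI above `mean + 4·sd`.  The statistic's
  scope is each plate's non-border, non-mitotic cells — the plate is the
  natural scope because every other normalization statistic is plate-wise,
  and cells already condemned by upstream flags should not inflate the
  spread.
* **Out-of-focus sites**: per well, the mean of single-cell DAPI and PCNA
  mean intensities is computed per imaging site.  A well is *z-range
  affected* when its site-mean range (max − min) exceeds
  `well_range_threshold` (default 1.5 a.u., calibrated once against the
  generator's DAPI mean-nuclear scale of ≈ 4.5 a.u. so that roughly 0.3 %
  of sites are removed at the default artefact rate).  Within affected
  wells a site is excluded when it deviates from the well's median site
  value by more than `3 × MAD` (raw median absolute deviation — chosen for
  robustness with ~6 sites) **and** by more than half the well-range
  threshold, **in both channels**.  The absolute floor prevents wells whose
  site means are tightly clustered (vanishing MAD) from losing a site to
  noise, and makes the clean-up idempotent in practice.  Site means are
  computed on cells that survive the per-cell rules, so re-running the
  clean-up on its own output changes nothing.

On generator data at default settings this detects 100 % of occupied
out-of-focus sites with a false-positive site rate well below 1 % (the
suite asserts ≥ 95 % / ≤ 1 %).

## Normalization

Order: background subtraction → row/column correction → plate rescaling →
nucleolar standardization.  Background constants are per-channel config
values defaulting to 0 (the generator injects no constant background; on
real data they would be estimated from cell-free image regions).

**Row/column correction.**  `I_corrected = I_raw + 2·I_p − I_{p,r} −
I_{p,c}`, medians over all cleaned cells of the plate, row and column,
computed independently per feature.  On a full grid an additive row+column
bias is removed *exactly* (the row median carries the row offset plus the
median column offset, and symmetrically, so all offsets cancel); the test
suite checks this against a brute-force construction.  The correction is
applied to DAPI, PCNA and SE features only: the EU channel's row/column
structure is dominated by true perturbation effects, so correcting it
injects biological signal into the correction terms and increases replicate
variability.  In secondary-screen mode (`mode="secondary"`) no channel is
corrected.

**Plate rescaling.**  For each feature, each plate's scrambled-control
median (over cells, after excluding control wells whose well median falls
outside ±1.5·IQR of that plate's control-well medians) is equalized across
plates by a multiplicative factor.  The common target is the median of the
plate control medians — any common target is equivalent up to a global
scale, and the median keeps the data near their original units.  Outlier
wells are excluded from factor *estimation* only; their cells are still
rescaled.  After rescaling, the control medians (same outlier rule) agree
across plates to machine precision.

**Nucleolar standardization.**  Median rescaling does not remove
plate-dependent nucleolus-segmentation bias, so nucleolar intensity and
morphology features are z-scored per plate against scrambled-control cells:
`z = (x − mean_ctrl)/sd_ctrl`.  A zero control sd marks the feature missing
on that plate.

Corrected intensities may be negative; no stage clips.

## Cell-cycle classification

S phase is not readable from DNA content alone.  Dedicated ground-truth
plates receive EdU (marking DNA replication) instead of EU; cells with sum
nuclear EdU above a threshold define S.  The automatic threshold is the
valley of a Gaussian-KDE (Silverman bandwidth) of log sum-EdU between the
two highest modes; peaks need a prominence of at least 1 % of the density
maximum to count as modes, so numerical wiggles cannot fake bimodality, and
a unimodal distribution raises an error carrying the density grid for
diagnostics.

A random forest (100 trees, unlimited depth, class-balanced, seeded; the
forest hyperparameters are deliberately vanilla) is trained on these labels
from DAPI and PCNA nuclear intensity and texture features — EU and EdU
features are rejected by construction, since EdU defines the labels and EU
is the phenotype.  A stratified 25 % hold-out provides the accuracy report,
broken down by control role.  Non-S cells are then split per plate at the
valley of the log sum-DAPI density between the 2N and 4N modes; the split
is monotone in DAPI by construction.  One classifier per staining batch is
the intended deployment; the pipeline here trains one per run.

## Phenotypes

* `residual_mean_eu` = mean nuclear EU − (screen-wide scrambled-control
  mean of mean nuclear EU for the cell's phase).  Mean intensity divides by
  nuclear area, which scales with cell size, so this phenotype accounts for
  size only indirectly.  By construction the pooled control mean of this
  residual is exactly zero.
* `residual_sum_eu` = sum nuclear EU − OLS prediction from an intercept,
  cell size (sum SE over the whole cell, a total-protein proxy for volume
  in flat adherent cells) and categorical phase indicators (G1 reference).
  The model is fitted per plate on that plate's scrambled controls
  (`per_plate=False` switches to a single screen-wide fit, applied
  plate-wise — both readings of "plate-wise application" are supported).

Well phenotypes are the means of these residuals over the well's retained
cells.  The pair discriminates size-driven from rate-driven EU changes: in
the generator, a 1.5× size perturbation (EU following proportionally)
leaves `mean_residual_sum_eu` at control levels while raw sum EU rises
~1.5×, whereas a 1.5× rate perturbation moves the residual strongly — the
suite asserts a ≥ 5× separation.

## Hit scoring

Putative hits: well phenotype below the 1st or above the 99th empirical
percentile of that screen's scrambled-control wells (boundary values are
non-hits).  Reproducible class `c`: +1/−1 when the directional annotation
agrees in the primary screen and in *every* secondary replicate, else 0.
Posterior `P(c|v) = P(c)·P(v|c)/P(v)` over the primary phenotype `v`:
priors are class fractions among conditions assayed in both screens (the
same set on which the evidence is defined; counting all genome-wide
conditions instead would deflate the priors by the retest sampling rate),
likelihoods are Gaussian KDEs with Silverman bandwidth per class (classes
with < 2 members get a zero posterior), and the evidence is the
prior-weighted mixture of the class KDEs by default — a separate empirical
KDE of `v` (`evidence="empirical"`) is retained for fidelity to the
formula's literal reading but does not guarantee posteriors summing to one.
Calls: `up`/`down` when the matching posterior exceeds 0.85; controls and
conditions with fewer than 500 cells receive no call.

At the default two-screen noise level the up-posterior is not perfectly
monotone through the moderate tail (sparsely populated non-reproducible
genes put KDE mass there); it increases window-by-window and approaches 1
asymptotically, which is what the suite asserts.

## QC

SSMD uses the method-of-moments estimator with sample (n−1) variances on
well-level values — the estimator variant matters at small well counts and
this is the conventional default.  Z′ is `1 − 3(σ_p+σ_n)/|μ_p−μ_n|`,
unclipped.  The uniformity report gives, per plate and feature, the IQR of
scrambled-control well values normalized by the plate median — the quantity
that must shrink when row/column correction removes staining bias (asserted
on the generator) — plus KIF11-vs-scrambled cell counts (transfection
efficacy) and mock/PIM2-vs-scrambled phenotype deltas.

## The synthetic screen generator

`SimulationConfig` defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| plates × wells | 4 × 384, full 16×24 grid | smallest multi-plate screen exercising plate rescaling |
| controls/plate | 22 scrambled, 6 KIF11, 8 PIM2, 8 SLC25A3, 3 mock | the screen's control layout, pseudo-randomized positions |
| cells/well | NB(mean 150, size 20) | desk-scale default; the physical screen has ~2,500/well — scale this up for realism, down for speed |
| cycle fractions | 0.56 / 0.31 / 0.13 | unperturbed HeLa G1/S/G2 distribution |
| DNA content | G1 N(2N, 6 % CV), G2 N(4N), S uniform(2N, 4N) | uniform S is simple and sufficient for valley-finding |
| size (sum SE) | log-normal, σ_log 0.2, phase scale 1/1.3/1.6 | protein content roughly doubles over the cycle |
| nuclear area | ∝ size^γ, γ = 1 | makes mean nuclear EU size-independent, so the two phenotypes diverge only when size is perturbed — the property the analysis exploits |
| EU | k·size·phase(1/1.4/1.8)·gene_effect·plate_factor·lognormal(0.2) | transcription scales with size and template number |
| PCNA | mean ×1.6 in S; texture shifted +3 sd in S | replication foci brighten and texture PCNA staining in S |
| EdU | log-normal modes 6σ apart (σ_log 0.4) | cleanly bimodal, as real EdU gating is |
| row/col offsets | additive, N(0, 3 % of channel mean), DAPI/PCNA/SE | edge/gradient staining bias; EU biases are left out because the analysis never corrects EU |
| plate factors | log-normal σ 0.05, all channels | staining-batch variation |
| out-of-focus | 0.3 % of sites, ×0.5 attenuation, all stains | the dim-site artefact |
| artefact cells | 12.5 % border, 5 % missegmented, 4 % mitotic, 0.65 % high-cytoplasmic-DAPI, 0.66 % DAPI doublets | matched to the proportions a real screen's clean-up removes |
| gene effects | 70 % null, 15 % up / 15 % down log-normal tails (median ±30 %) | the true perturbation effect-size distribution is unknown; these are free parameters |
| SLC25A3 effect | ×1.3 on EU | weak-to-intermediate positive control |
| KIF11 wells | cell counts ×0.03 | knockdown kills cells |

Row/column offsets enter each feature additively with a fixed per-feature
scale (the offset itself for mean features, offset × a typical area for sum
features, the *same* scale for nuclear and whole-cell sums so the
cytoplasmic DAPI difference stays physical).  Out-of-focus attenuation
multiplies all stain features of the site.  `noiseless=True` switches off
all technical noise (staining noise, offsets, plate factors, artefacts)
while keeping the biological size distribution, giving exact
proportionality checks.  Identical config + seed ⇒ byte-identical output.

**Two-screen model** (`simulate_two_screens`): gene effect
`g ~ N(0, 1)` shared across screens; primary well value `g + N(0, scr²) +
N(0, rep²)`; each secondary replicate `g + N(0, rep²)` with
`rep = 0.143` and `scr = 0.672`, over a 439-gene panel plus 200 control
wells per screen.  Expected correlations are closed-form:
`corr(rep1, rep2) = 1/(1+rep²) = 0.980` and
`corr(primary, rep mean) = 1/√((1+scr²+rep²)(1+rep²/2)) = 0.82`.  The two
noise scales are free parameters calibrated analytically (inverting those
formulas) to the reproducibility a well-run screen pair achieves; they are
not derived from first principles.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: no pixel-level imaging (segmentation quality
is reduced to boolean flags), no spatial structure within wells or
population-context effects, no off-target siRNA effects, no correlation
between a gene's effect on EU and its effect on viability or cycle
distribution (beyond the dedicated controls), Gaussian/log-normal noise
throughout (real feature distributions are heavier-tailed), and the
perturbation effect-size mixture is an assumption, not a measurement.
Recovery results on the generator demonstrate internal consistency of the
pipeline, not field performance.

## Numerical choices and degenerate inputs

Valley finding runs on log-transformed intensities (stabilizes 2N/4N
spacing), 512-point grid, Silverman bandwidth, 1 %-prominence peaks;
unimodal inputs raise with diagnostics rather than guessing.  OLS uses
statsmodels with an explicit design matrix; single-phase control sets are
rejected as rank-deficient.  Thresholding ties resolve conservatively (at a
percentile threshold → non-hit; at the cytoplasmic-DAPI boundary → keep).
Empty wells produce no summary row; zero-cell denominators yield missing
values, not zeros.  Plate-rescale factors require strictly positive control
medians (a multiplicative correction is meaningless otherwise).  All
randomness flows from explicit seeds; the random forest is seeded and
single-threaded for reproducibility.

## Problem sizes used by the acceptance script

The acceptance script runs the EdU-plate training at the full default plate
(≈ 57,000 cells, ≥ 20,000 required), the cycle-fraction recovery on a
4-plate screen (≈ 230,000 cells), the SSMD on 664 positive vs 1,826
negative control wells (an 83-plate screen's 8 and 22 wells per plate), and
the two-screen correlations on the 439-gene panel — sizes chosen so every
statistic is estimated at the precision its comparison needs while a full
run stays around half a minute.
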