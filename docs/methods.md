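# Methods

`cardiomat` implements a discovery pipeline for transcription factors (TFs)
associated with cardiomyocyte maturation, together with the bespoke
phenotype quantifications used to characterize matured cells. Because the
workflow spans several very different measurement modalities, this note
describes each stage's model, its tunable parameters, and the design
choices made where the procedure was genuinely open.

## The discovery procedure

The RNA-seq stage consumes a compendium of bulk count matrices organized
into datasets: one in-house time-course/format experiment (early-stage
cells `D12`, 2D and 3D cultures at days 26 and 40), adult-vs-fetal
comparator datasets, and a panel of independent "maturation model"
datasets. Each dataset is processed independently:

1. **Normalization** — median-of-ratios size factors: the reference is the
   per-gene geometric mean over samples (genes with any zero excluded);
   each sample's factor is the median ratio to the reference, rescaled to
   geometric mean 1.
2. **Dispersion** — per-gene method-of-moments estimates of the
   negative-binomial dispersion α (variance = μ + αμ²) pooled across
   conditions, floored at 1e-8, then shrunk toward a fitted mean–dispersion
   trend α(μ) = a₀ + a₁/μ with weight 0.9 by default. At 3-vs-3 replication
   the gene-wise moment estimate carries about four degrees of freedom, so
   the trend dominates deliberately; the weight is a parameter for designs
   with more replication.
3. **Wald contrast** — condition means are fitted on the normalized scale;
   log2FC = log2((μ_a + c)/(μ_b + c)) with pseudo-count c = 0.5; the
   standard error follows from the NB variance by the delta method. The
   p-value uses an **Edgeworth-corrected normal reference**: the 3rd and 4th
   cumulants of the log fold change are computed from the NB model itself
   and removed with a Cornish–Fisher adjustment (capped at ±1 so the cubic
   term stays monotone for extreme statistics). Without this correction the
   plain normal tail is visibly anti-conservative at small n; with it the
   empirical type-I rate at p < 0.005 sits within ~6% of nominal in the
   package's own null simulations. Genes with mean normalized count < 1
   are flagged and not tested. BH-adjusted p-values are reported, but DEG
   calling uses the raw p (cutoffs |log2FC| > 0.5, p < 0.005, both strict),
   matching the workflow this pipeline reproduces; whether that published
   cutoff was raw or adjusted is not stated there, so the literal reading
   (raw) was chosen and both columns are exported.
4. **TF activity** — regulons arrive as signed, confidence-graded edge
   tables (`tf, confidence, target, mor`). Edges below grade C are dropped,
   targets must be expressed (mean normalized count ≥ 1), and TFs with
   fewer than 5 usable targets are excluded with a reported reason. The
   activity of a TF in sample j is Σ_t mode_t·z_tj / √|R|, where z is the
   per-gene z-score of log2(normalized+1) across the dataset's samples.
   Under an independent-target null this is approximately standard normal,
   which the suite verifies at regulon sizes 5–100. The statistic is a
   normalized-enrichment analog of the regulon-scoring family of methods;
   the upstream tool this emulates does not document its exact statistic,
   so scores are comparable in structure, not numerically.
5. **Activity comparison** — "fold-greater activity" is ill-defined for
   signed scores, so the criterion is total by construction: if the
   reference mean is positive, pass iff A_a ≥ 1.5·A_b (ratio branch);
   otherwise pass iff A_a > 0 and A_a ≥ A_b + δ with margin δ = 0.5 score
   units (sign-guard branch). Branch and inputs are recorded per TF.
6. **Selection** — *core* tier: expression fold ≥ 1.5 in both in-house
   contrasts (3D-D40 vs 2D-D40 and 3D-D40 vs D12, evaluated on the Wald
   log2FC with no p requirement), plus the activity criterion, plus the
   same expression and activity criteria in every adult-vs-fetal
   comparator. *Extended* tier: expression criteria plus membership in a
   declared gene family (regulon resources cover a limited TF set, so
   activity is not required). *Manual* tier: an allow-list with recorded
   rationales. Curation is always declarative configuration, never code.
7. **Model voting** — per candidate, the number of model datasets in which
   it meets the criteria (counted once per model). The default rule is the
   **conjunction** (expression AND activity): the sign-guard activity
   branch alone passes inactive TFs far too often at triplicate scale
   (its null pass rate is ~25%, since δ = 0.5 is only ~0.6 SD of a null
   condition-mean difference), which would make votes meaningless as a
   truth signal. The disjunction reading remains available as
   `vote_rule="any"`.
8. **Concordance and structure** — signed DEG overlap (count, Jaccard,
   directional concordance) between the in-house contrast and each
   comparator; average-linkage hierarchical clustering on Euclidean sample
   distances and covariance-eigendecomposition PCA of centered
   log2(normalized+1).

## Synthetic data

The in-house RNA-seq behind the original analysis is not public, so the
package ships generators that emulate the statistical structure the
analysis assumes, with exported ground truth. All distributional choices
are stand-ins — the source describes only processed analyses, not raw data
distributions — and are therefore explicit, seeded configuration:

* **Counts**: NB(mean = s_j·q_gj, variance = μ + αμ²) with α = 0.01 by
  default (replicate-culture bulk RNA-seq scale), library factors
  log-uniform on [0.7, 1.4], baseline means log-normal (median 2⁷,
  log2-sd 1.5). 200 TFs, regulon sizes 20–60 with 25% repressive edges and
  a configurable A–E grade distribution.
* **Planted signal**: 10 planted TFs drawn from well-expressed regulators
  (baseline mean ≥ 300); their true log2 offsets are monotone along the 3D
  arm (half effect at D26, full effect = 1.0 log2 at D40), full effect in
  adult samples, zero in 2D/early/fetal. Each regulon target shifts by
  mode·coupling·offset with coupling 0.5. Each of 6 model datasets
  activates a random half of the planted TFs with effects 1.0–1.6× the
  planted log2FC. All effects, activations and implied vote counts are
  exported as the truth table.
* **Calcium traces**: F(t) = F0·(1 + Σ A·k(t−t_i)) + drift·t + ε with the
  unit-peak kernel k(t) = (1−e^{−t/τ_r})·e^{−t/τ_d}. Defaults: τ_r = 50 ms,
  τ_d = 250 ms, 0.5 Hz beating, amplitude 1.0 ΔF/F0, Gaussian noise 0.2%
  of F0 (an ROI-mean trace), optional linear drift. The closed-form kernel
  kinetics (peak, FWHM, 10–90% rise, 90–10% decay) are computed by
  root-finding on k and exported as truth. Defaults keep transients well
  separated (tail < 0.1% of amplitude at the next onset) so the
  single-transient closed forms are the correct reference.
* **Striation images**: tiled sinusoidal grating, one axial orientation
  per tile drawn from a von Mises distribution on doubled angles
  (mean 30°, concentration κ; κ = ∞ by default), period 1.8 µm at
  0.1 µm/px, contrast 0.4, optional Gaussian pixel noise. Tile size is
  shared with the analysis so truth maps 1:1 onto the orientation field.
* **Assay tables**: Ct = base − log2(fold) + noise with a constant
  housekeeping gene (DDB1 by convention); plate wells with known
  luminescence/absorbance group ratios.

What the generators deliberately do **not** model: batch effects,
per-gene dispersion heterogeneity (available but off by default),
photobleaching beyond linear drift, motion artifacts, non-sinusoidal
striation profiles, segmentation errors. Passing tests therefore
demonstrate correctness of the computations under the stated model, not
robustness to every pathology of real recordings.

## Phenotype quantifications

**Calcium transients.** Traces are normalized to ΔF/F0 with F0 the 5%
quantile of a lightly smoothed (9-sample moving average) copy of the
trace after drift removal; the drift slope is fitted through per-window
baseline quantiles and anchored at the trace start (ordinary least squares
on the raw trace would be biased by the transients themselves; the 5%
quantile sits in pre-stimulus baseline rather than on decay tails).
Transients are located by peak prominence (default 0.2 ΔF/F0, minimum
separation 0.3 s). Per transient: baseline = median of a 0.2 s window
ending at the pre-peak minimum; amplitude = peak − baseline; FWHM, rise
(10→90%) and decay (90→10%) times by linear interpolation of the level
crossings. The percentage bounds are parameters because the upstream
protocol does not state them; 10–90% is the common electrophysiology
convention. Truncated transients are skipped with a warning. Group
summaries draw a seeded random subset of cells per video (default 5),
then report per-video means and condition mean ± SEM.

**Sarcomere organization.** Tiles (48 px default) get a structure-tensor
orientation refined by the dominant FFT peak direction (sub-bin centroid
of the 3×3 peak neighborhood), weighted by coherence and relative peak
power; tile energy = coherence × peak power, with tiles below 10% of the
90th-percentile energy masked. Orientations are axial throughout (angle
doubling). "Within 20% of the principal axis" is interpreted as ±18°
(20% of the 90° maximal axial deviation) and is an explicit parameter,
since the original units are ambiguous; the alignment fraction is
energy-weighted because the original counting unit is unspecified.
Sarcomere length comes from the first significant side peak of the
autocorrelation of the intensity profile projected across the striations,
with parabolic sub-pixel refinement; the significance floor is
max(0.1, 3/√n) so finite-profile ACF noise (e.g. a white-noise image)
cannot produce a spurious period. Shape metrics on binary masks: area,
best-fit-ellipse aspect ratio, circularity 4π·area/perimeter² with the
Crofton perimeter, clipped to [0, 1].

**qPCR and ATP.** Relative expression by the comparative cycle-threshold
method: ΔCt against the housekeeping gene per sample, ΔΔCt against the
reference-group mean ΔCt, relative expression 2^(−ΔΔCt). ATP: per-well
luminescence/absorbance ratio, group means normalized to the control
(mCherry) group.

## Numerical conventions and degenerate inputs

Ties in variance-based gene selection break by gene id; all angular
statistics live in [0, 180); zero-variance activity targets are dropped
from the score sum with a warning; a constant expression matrix is a
degenerate-covariance error for PCA/clustering; empty DEG overlaps report
NaN concordance; a flat trace reports zero transients with NaN kinetics;
a mask with several components uses the largest, with a warning. All
randomness flows from explicit seeds; two runs of the same manifest are
byte-identical, which the suite checks at file level.

## Problem sizes used in the shipped checks

The self-checks run at desk scale: 2,000 null genes for calibration, 200
power replicates at 300 genes, 100 noisy traces, 1,000 random regulons on
4,000 genes × 20 samples, and the default compendium (6,000 genes × 63
samples across 9 datasets). These sizes give tight Monte-Carlo error on
every reported rate while the whole suite stays fast.

## Known limitations

* The DE stage is a transparent analog of the standard NB workflow, not a
  numerical replica: no outlier refitting, no independent filtering, no
  fold-change shrinkage.
* Activity scores are structurally, not numerically, comparable to the
  upstream regulon tool; regulon inference itself is out of scope.
* The selection thresholds (1.5-fold, 0.5 score-unit margin) are the
  published workflow's constants, exposed as configuration; nothing in the
  package claims they are optimal.
* Real striation images with curved or branching myofibrils violate the
  per-tile single-orientation model; the tile size trades locality against
  angular resolution.
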