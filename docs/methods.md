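# Methods

`phosphopipe` re-implements, as a tested and reusable pipeline, the
computational analysis used to characterize impaired and emergent insulin
signaling in iPS-derived hepatocytes from type-2-diabetic (T2D) donors:
phosphoproteomics preprocessing, empirical-Bayes differential statistics on
a paired insulin-stimulation design, a six-way signaling-class taxonomy,
pattern clustering with over-representation analysis, and kinase-motif
enrichment. Because no public LC-MS/MS dataset accompanies that analysis,
the package ships a synthetic-data generator that emulates the study's
statistical structure with planted ground truth, so every stage is
verifiable end to end.

## The emulated experiment

The design is 8 control and 8 T2D donor-derived cell lines with equal
sexes, each sampled in a basal and an insulin-stimulated state; two T2D
donors (one of each sex) are excluded, leaving 8 + 6 lines and 28 samples.
Per site and cell, the generator produces a log2 intensity

    y = baseline(site) + donor(site, line) + planted effects
        + loading(site) * batch(sample) + noise

with defaults: baseline ~ N(23, 2) (log2 units typical of phosphosite
LC-MS/MS intensities), a per-site donor offset ~ N(0, 0.3) shared by both
treatments of a line (this is what paired tests exploit), residual noise
~ N(0, 0.5), and a rank-one batch term whose per-sample score is a
standardized Gaussian vector and whose per-site loading is ~ N(0, 0.5).
Cells are then masked missing-not-at-random with probability
`logistic((20 − y)/0.7)`, i.e. dropout rises steeply about 3 log2 units
below the mean intensity; at defaults ~12–13% of cells are missing,
concentrated in the low-intensity tail.

Planted site classes (100 each by default, in 2,000 sites):

* **1A/2A** — insulin log2FC δ ~ U(0.6, 2.0) (sign − for class 2) in both
  phenotypes;
* **1B/2B** — "impaired": control response δ, T2D response δ(1 − a) with
  the attenuation fraction a ~ U(0.75, 1.0). The interval was fixed by a
  design-time power analysis: at the study's noise and sample sizes an
  impairment below ~50% is statistically invisible, so impaired sites lose
  75–100% of the control response;
* **1C/2C** — "emergent": no control response, T2D response ±δ;
* **sexF/sexM** — a 1.5 log2-unit offset for all samples of one sex;
* **basal-shift** — a phenotype offset in both treatment states;
* the remainder are null.

Localization probabilities are U(0.75, 1) for planted sites; 10% of null
sites draw U(0, 0.75) so the class-I filter is exercised without censoring
the planted truth at random.

Driver kinases are planted only where the emulated study maps classes to
kinases: the emergent-up class (1C), the impaired insulin-stimulated class
(1B) and the emergent-down class (2C) each carry one distinct driver whose
sites receive sequence windows sampled from that kinase's PSSM. This
leaves exactly one planted driver per enrichment side of the insulin-state
phenotype comparison, so driver inference has an unambiguous ground truth.
Kinase PSSMs have 2–4 sharply preferred positions (one residue carrying
most of the mass) dealt as (position, residue) pairs *without replacement*
across kinases; with independent draws ~5% of kinase pairs coincide
exactly and the planted driver becomes unidentifiable in principle.
Windows use the 20 standard amino acids with an S/T center; no
phospho-residue tokens are modeled.

What the generator does **not** emulate: peptide-level structure and
roll-up, retention-time or fragment-level effects, correlated co-regulation
modules beyond the planted classes, realistic residue composition
(flanks are uniform outside planted motifs), and paralogous kinase
families with near-identical specificities. Passing recovery tests
therefore demonstrates the statistical machinery under the modeled
conditions; they do not certify performance on real spectra.

## Preprocessing

Intensities are log2 transformed (zero/negative values are errors, missing
values propagate), filtered to class-I sites (localization probability
≥ 0.75, inclusive), imputed, median-normalized (each sample shifted
additively to the median of sample medians), and adjusted for one
surrogate variable.

**KNN-TN imputation.** Each site's observed values are fit by a
left-truncated normal MLE, with the truncation point per observation set
to that sample's minimum observed log2 intensity (a proxy for the
per-sample detection limit; the convention is configurable). The
likelihood is maximized by bounded L-BFGS-B around the sample moments —
with few observations piled near the truncation point the unbounded MLE
diverges (μ → −∞), so the search is restricted to μ ∈ m ± (4 sd, 2 sd)
and σ ∈ [0.05, 4 sd]; σ is floored at 0.05 log2 units throughout. Sites
are standardized by their fit; neighbors are the k = 10 sites closest in
root-mean-square distance over jointly observed standardized entries
(≥ 4 shared entries; RMS rather than raw Euclidean so that pairs with
different overlap are comparable; ties break by row order). A missing
entry is the mean of the neighbors' standardized values at that sample,
mapped back through the target's (μ, σ). Sites with < 3 observations and
cells without any observed neighbor fall back to the site mean, logged.
Observed entries are never altered. Note the residual MNAR bias: imputed
values average ~0.8 log2 units above the (selected-low) truth at defaults;
KNN-TN still beats per-sample-minimum substitution by ~0.8 log2 RMSE.

**Surrogate variable.** The SV is the first right singular vector of the
residual matrix after projecting out the known design (treatment,
phenotype, sex, treatment×phenotype), unit-norm and orthogonal to the
design by construction; `variance_explained` is its squared singular value
over total residual variance. For *model adjustment* the pipeline uses a
factor-score refinement: the residual loadings (first left singular
vector) score every raw sample column, centered and normalized. The
orthogonalized vector cannot represent the part of the batch vector that
happens to align with the design in a finite sample; regression-scoring
recovers it (correlation with the planted batch ≈ 0.999 vs ≈ 0.92), and in
simulation the refined covariate keeps null type-I error at 3–4.5% where
the orthogonalized one inflates it to 8–24% in the paired subsets.
The SV-subtracted matrix is used only for visualization, PCA QC and
clustering; all tests include the SV as a covariate.

## Differential statistics

Per-site ordinary least squares with a shared design matrix, and
empirical-Bayes moderation of the residual variances: `log s²_g` moments
are matched to a log-F distribution, `d0` by monotone trigamma inversion
and `s0²` from the mean equation (verified against `limma::squeezeVar`).
The moderated t uses the posterior variance
`(d0·s0² + d_g·s²_g)/(d0 + d_g)` with `d0 + d_g` degrees of freedom
(Gaussian when d0 = ∞); the moderated F whitens a contrast set by the
Cholesky factor of its unscaled covariance. All differential p-values are
two-sided; BH FDR is applied within each contrast family.

Canonical contrasts: paired insulin-vs-basal within each phenotype
(cell-line fixed effects + SV); unpaired T2D-vs-CTL within each treatment
state (+ SV); the impaired/emergent interaction as an unpaired moderated t
comparing per-cell-line log2(insulin/basal) ratios between phenotypes,
with the per-line SV score difference as covariate (ratios cancel donor
effects but not batch drift); and the sex contrast (F − M) on basal
samples with phenotype and SV covariates — basal samples give one
observation per donor, keeping the test calibrated without a donor random
effect. The squared sex t is the single-contrast moderated F screen.

## Signaling classes

A site is class 1 (2) if its stimulation log2FC is ≥ +log2(1.5)
(≤ −log2(1.5); the constant is computed, not hard-coded) with p < 0.05 in
control cells, T2D cells, or both. Subclass A: interaction p ≥ 0.05;
B ("impaired"): interaction p < 0.05 and |T2D response| < |CTL response|;
C ("emergent"): interaction p < 0.05 and |T2D response| > |CTL response|.
The strict emergent flag additionally requires the T2D response itself to
pass the ±1.5-fold / p < 0.05 thresholds. A site significant in opposite
directions in the two phenotypes takes the control-cell direction and is
flagged `sign_discordant`. Sex dominance is called at FDR < 0.1 with the
direction of the sex coefficient.

Under the emulated conditions the impaired/emergent subclasses are
recovered for ~61% / ~67% of planted sites (10 seeds). This is close to
the design's information limit: sites with δ near the 0.6 lower bound pass
the estimated-1.5-fold cut with only ~50% probability (SE ≈ 0.25–0.29 per
arm), the interaction test at δ = 0.6 has ~35% power (SE ≈ 0.38), and
MNAR imputation attenuates the stimulation estimate of affected sites by
~0.2 log2 units; even complete attenuation cannot push subclass-B recovery
past ~0.72. Null sites are misclassified at ~6–7%, sex-dimorphic sites
are called with correct direction for ~85–88%.

## Clustering and ORA

Sites at moderated-F FDR < 0.1 (F over treatment, phenotype and their
interaction) are z-scored per row on the SV-adjusted matrix and
agglomerated by Euclidean distance with complete linkage (linkage
configurable; the reference method's linkage is unstated). Clusters come
from a deterministic variable-height rule: a node splits iff both children
have ≥ 20 leaves and its merge height exceeds 0.8 × the root height;
unsplit subtrees are clusters. ORA collapses each cluster's sites to
parent genes (deduplicated), tests hypergeometric upper tails against the
GMT sets intersected with the universe — all genes of the analyzed
(class-I) site table, not the genome — and adjusts by BH across sets.

## Kinome analysis

A site's window is scored against each kinase PSSM as the sum of log2
position weights over the flanks (center excluded, probabilities floored
at 1e-4, non-standard or out-of-range residues contribute 0; tyrosine
centers are excluded from the S/T kinome). Raw scores become percentiles
against the score distribution of all scored sites in the dataset (the
stand-in for a reference phosphoproteome; an external background table is
accepted by the loader). The top 15 kinases per site, ranked by percentile
with ties broken by raw score then name, are its predicted kinases.

For a regulated-set definition (FDR < 0.5 for the basal phenotype
comparison, FDR < 0.25 for the insulin-state comparison; strict
inequalities, with unregulated = FDR above the cut), each kinase and side
yields a 2×2 table of predicted vs not among regulated-side vs unregulated
sites. The one-sided Fisher exact p runs on the raw integer counts; the
frequency factor is the log2 ratio of predicted percentages after adding
0.5 to all four cells (Haldane) — correction and test are separable
because a Fisher test on non-integer counts is undefined. BH runs across
kinases within each side; each kinase reports its more significant side
(ties prefer up) and is display-significant at adjusted p ≤ 0.1. A
log-scale p accompanies each row so rankings remain deterministic below
double-precision underflow.

## Numerical and design choices

* Determinism: every stochastic step draws from `numpy` Generators seeded
  from the single experiment seed; writers emit fixed column order and
  `%.10g` floats, so identical seeds give byte-identical outputs.
* PCA and SVD sign conventions: the largest-|entry| element of each
  score vector is made positive.
* Degenerate inputs: empty backgrounds, zero-residual matrices, rank
  deficient designs, all-zero variance vectors and sub-3-observation fits
  raise informative errors rather than guessing.
* Problem sizes: simulations use the study-sized design (2,000 sites,
  28 samples, 50 kinases, 5,000 background windows) — large enough for
  stable rates, small enough that the full pipeline runs in seconds.

## Known limitations

* The KNN-TN neighbor average inherits an upward MNAR selection bias;
  downstream stimulation estimates of heavily-missing sites are attenuated.
* The single-SV model handles one dominant batch direction only.
* The variable-height cut is a deterministic simplification of dynamic
  dendrogram cutting (no hybrid/PAM refinement stage).
* The kinome stand-in cannot emulate paralog families with near-identical
  specificities; on real atlases closely related kinases are expected to
  share enrichment, as reference analyses report them in groups.
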