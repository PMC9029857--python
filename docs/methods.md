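# Methods

## Model and procedure

The pipeline treats biomarker discovery as wrapper feature selection: a
classifier's cross-validated performance on a candidate gene subset is the
objective a genetic algorithm optimizes. The stages are deliberately
decoupled — each consumes and produces plain-text artifacts — so any stage
can be run, audited or replaced independently.

**Normalization.** Raw linear intensities are made comparable across
arrays by a per-sample multiplicative factor that fixes the two-sided
trimmed mean at a target intensity (default 500, trim fraction 0.02 —
conventional linear-scaling values for microarray processing). The
operation is idempotent and rank-preserving within a sample. log2 follows
with a floor of 1, mapping non-positive intensities to 0. Probe-level
summarization (background correction, present/absent calls) is out of
scope; data already processed upstream should enter at the log2 stage.

**Signal-to-noise ranking.** SNR = (μ⁺−μ⁻)/(σ⁺+σ⁻) with sample standard
deviations (ddof=1) floored at max(0.2·|μ|, 0.2) per class. The floor is
the GSEA desktop convention; it prevents near-constant genes from
dominating the ranking. Ties in the ranking are broken lexicographically
by gene id so the ranking is a pure function of the data.

**Enrichment score.** The running sum rises by |SNR|^w (normalized to
total 1 over set members) at hits and falls by 1/(N−|S|) at misses; the
EC score is the *signed maximum* of the running sum (not the maximum
absolute deviation; the latter is available via a flag). The weight
exponent defaults to 1, the standard choice for this statistic; w = 0
gives the unweighted statistic in which a set wholly at the head of the
list scores exactly 1. Permutation significance (NES/FDR) is not
computed — the screen uses the raw score only.

**Candidate screening.** The panel takes the top and bottom
`n_per_tail` (default 50) genes of the SNR ranking, tagged
over/underexpressed. Screening can reasonably be read as ranking *genes*
or as gating on enriched *sets*; both readings are exposed:
`restrict_to_sets=True` (default, mirroring the pathway-based screen)
admits only genes belonging to at least one gene set with positive EC
score, `False` screens on SNR alone (the natural choice for synthetic
data without a meaningful set collection). A shortfall of eligible genes
is an error, never silently padded.

**GA/SVM selection.** Fitness of a bit vector is the maximum over an
exponential (C, γ) grid (2⁻¹⁵…2¹⁵; full 31×31 grid by default, step 4 →
8×8 under `--fast`) of the pooled 5-fold cross-validated measure:
out-of-fold predictions from all folds form one confusion table per grid
point, from which accuracy, MCC, F1 or the hybrid score is computed.
Pooling (rather than averaging per-fold measures) was chosen because MCC
and F1 are unstable on 20-sample folds. Folds are stratified and fixed for the
whole run from a seed derived from the master seed, making fitness a
deterministic, memoisable function of the bit vector. The all-zero
chromosome receives a sentinel (0 for accuracy/F1/hybrid, −1 for MCC) so
it can never become an elite.

Selection follows the half-elitist scheme: α is the best of the first
half of the population and the previous α, β likewise for the second
half, ω the better of the two; the next population is filled with copies
of α (odd 1-based slots) and β (even slots). Ties go to the current
population at the lowest index. In the first generation, where the
"previous" elites are virtual (defined with fitness 0 but no bit
vector), the half's argmax is always installed — a bitless elite cannot
be copied into a population, and with MCC an all-negative half would
otherwise have no representative. Mutation then flips each first-half
bit independently with probability 0.1 and exactly one uniformly chosen
bit per second-half chromosome; one-point crossover swaps tails between
adjacent pairs with probability 0.5 (cut λ uniform over positions, λ = 1
swapping everything). Each generation's ω is archived; elitism makes the
archived fitness sequence non-decreasing. The full procedure repeats the
GA (fresh RNG stream per repeat, spawned from the master seed) 10 times
under each of the four measures; per measure, records are deduplicated
by bit vector (first occurrence kept — fitness is identical by
determinism), ranked by fitness (stable sort, so tied records keep
collection order), and the top 10 retained for scoring. Fewer than 10
unique solutions simply contribute fewer terms; the missing ranks count
as 0 rather than renormalizing, which keeps the score monotone.

**Selective score and signature.** r_j averages, over the four measures,
a gene's presence in the top 10, top 5 and single best solutions, giving
[0, 3]; 3 is attained iff the gene is in every counted solution. The
default signature threshold is 2. Combining two runs reports the union
with per-run membership, the intersection, over/under counts and any
direction conflicts (conflicts are flagged, never dropped). The heatmap
export z-scales each signature gene across samples and orders rows
over-then-under, columns positive-class-first.

## SVM implementation

Training goes through scikit-learn's bundled libsvm bindings with
kernels precomputed from per-chromosome pairwise squared distances. This
is the same optimizer, tolerances and prediction rule as
`sklearn.svm.SVC(kernel="rbf")` — the test suite asserts equality of the
resulting fitness against a public-API reimplementation — but avoids
estimator-construction overhead that would dominate at the pipeline's
scale (a full selection procedure evaluates ~10⁵ chromosomes × grid ×
folds). Solver tolerance and class weights stay at solver defaults.
Three shortcuts never change the returned grid maximum: the scan stops
once a grid point attains the measure's theoretical maximum; the most
recently winning grid point is tried first; and for γ large enough that
every off-diagonal kernel entry underflows to exactly 0.0 the kernel is
exactly the identity for *any* chromosome, so those grid rows are
computed once per run and shared.

## Synthetic data

The generator emulates two-class log2 microarray intensities: a Gaussian
baseline (mean 8, sd `noise_sd` = 1) with `n_up`/`n_down` planted genes
shifted ±`effect_size` (default 2 log2 units) in the positive class.
Default sample sizes are 228 positive vs 148 negative, the GBM-vs-
astrocytoma design the pipeline targets; desk-scale runs shrink these via
config. The companion gene-set generator emits REACTOME-like collections
in which a configurable fraction of sets draws at least half its members
from the planted genes. What the simulation does *not* model: probe-level
structure, batch effects, correlated co-expression modules, heavy-tailed
noise, class-dependent variance. Passing tests therefore demonstrate the
pipeline's mechanics and statistical behavior under idealized
independence, not performance on real arrays.

A consequence worth knowing: with 10 planted genes at effect size 2 and
100 samples, many gene subsets already achieve *perfect* pooled
cross-validated fitness somewhere on the hyperparameter grid. Once
fitness saturates at the measure's maximum, the GA cannot distinguish
tied solutions and the archive fills with near-arbitrary perfect
chromosomes, so planted genes outscore null genes on average but only
moderately. Harder designs (smaller effects, fewer samples, or more
noise genes) restore selection pressure.

## Problem sizes in tests and the acceptance script

Unit and acceptance tests run the GA at reduced scale — tens of samples,
10–100-gene panels, 5–20 generations, 2×2 to 8×8 grids — chosen as the
smallest sizes at which each property is meaningful; the structural
record-count check runs the full default depth (10 repeats × 200
generations) on a 40-sample, 20-gene-panel dataset with a 2×2 grid,
since the count depends only on depth. The acceptance script mirrors
these sizes. Defaults in the library itself are the full-scale settings.

## Known limitations

- Real-data mode expects an already-normalized series matrix; no CEL/
  probe-level ingestion.
- The GA's archive under saturated fitness reflects drift more than
  selection (above); selective scores remain well-defined but their
  contrast weakens.
- Single-threaded by design for reproducibility; no parallel evaluation.
- Gene-set screening treats sets as plain membership lists; overlap and
  hierarchy are ignored.
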