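# Methods

This note documents the models and procedures `tfnet` implements, the
parameters that matter, the design choices made where the design was
genuinely open, what the synthetic-data generator does and does not
emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Per-line differential genes and TF regulation scores

Each cell line is assayed in 2–3 replicate columns. For a given line,
each gene's replicate values are compared with the pooled values of all
other columns by a two-sample Kolmogorov–Smirnov test. With 2–3 points
against a large pool the asymptotic KS tail is unreliable, so the exact
small-sample distribution is used whenever the total number of points is
≤ 25 (`KS_EXACT_MAX_N`), and the asymptotic one otherwise. Significance
is expressed as an e-value, p × (number of genes tested), and genes with
e ≤ 10 (`evalue_max`) are called regulated in that line. The KS test is
rank-based, so any common monotone transformation of the data leaves the
calls unchanged.

TF scoring is catalogue-based enrichment: for each line's regulated gene
list and each TF with at least one catalogue target among the measured
genes, the one-sided hypergeometric tail P(X ≥ overlap) is computed with
the measured genes as population. The e-value multiplier is the number
of TFs actually tested for that query (the catalogue-wide count is
available via `multiplier="catalogue"`; catalogue-enrichment services
rarely document which multiplier they apply, so both are supported).
The score is max(0, −log₁₀ e): strictly positive exactly when e < 1,
which is the significance rule. TFs with score 0 in every line are
flagged and excluded from the regression roster. p-values are floored at
1e-300 before the logarithm so scores stay finite.

*Caveat.* With L lines and m TFs tested at the e < 1 rule, a TF with no
real signal still enters the roster with probability ≈ 1 − (1 − 1/m)^L
(≈ 0.5 at the default synthetic scale). This roster "pollution" is a
property of the positive-score rule itself; it dilutes the regression in
stage 3 and is the main reason per-TF selection sensitivity saturates
below 1 in the end-to-end runs.

## 2. CNV normalization

The input is a GISTIC-style table of significantly altered regions with
per-sample log₂-ratio peak values. Rows with q ≤ 0.25 (`q_max`,
boundary inclusive) are kept. Within a region, multiple peak rows are
reduced to a per-sample median (the alternative reading — median across
samples per peak — is not implemented; the region-wise reading keeps one
value per region and sample, which is what the downstream matrix needs).
Every gene overlapping a significant region by at least one base
inherits the region's per-sample median (`assignment="midpoint"`
switches to midpoint containment); genes overlapping several regions take
the one with smallest q, then larger |median| (median over samples),
then lexicographically smallest region id. Genes outside all significant
regions carry 0, the log₂-ratio of no change. Chromosomes X and Y are
excluded by default. A consequence of the 0 sentinel: a TF whose locus is
never altered has a zero-variance CNV row, its CNV correlations are
undefined, and it drops out of the regression with a logged flag — the
analysis is restricted to TFs with altered loci.

## 3. Correlation-profile regression and TF selection

Three TF × line matrices are built over the roster (TFs significant in
≥ 1 line): regulation scores R, TF-gene expression E (replicate columns
collapsed to per-line means), TF-locus CNV C. Within each matrix the
TF–TF Pearson correlation matrix is computed; a TF's profile is its row
with the self-correlation removed. For each TF, R-profile is regressed
on E- and C-profiles by OLS with intercept; slope significance is the
two-sided t-test. Profile entries with a missing value in any of the
three matrices are dropped pairwise; fits with fewer than 4 points, a
rank-deficient design, or a constant response are returned with status
`degenerate`, never silently dropped. A TF is selected when both slope
p-values are ≤ α = 0.05; no multiplicity correction is applied across
TFs by default (`correct="fdr_bh"` is available). Correlations require at least 3 shared cell lines by policy.

The OLS inference is exact for data generated at the profile level
(`generate_profile_dataset`), which is how confidence-interval coverage
and per-slope type-I error are validated. In the full generative chain
the profile entries are themselves estimates with dependent errors, so
coverage there is only approximate — an inherent limitation of
regressing estimated correlation profiles on one another.

## 4. Minimal connected network

Seeds (selected TFs) are mapped onto the interactome after filtering
edges to evidence ≥ 2 (`min_evidence`). The subnetwork keeps every direct
seed–seed edge and, for every seed pair at graph distance exactly 2, all
common neighbors with both incident edges (one tolerated intermediate; a
pair at distance 1 contributes only its direct edge, and pairs at
distance ≥ 3 contribute nothing). Components are ordered by interaction
count; the largest (ties: node count, then smallest node id) is the MCN.
Unmapped seeds are reported and the run proceeds when ≥ 2 seeds map.

Node metrics on the MCN subgraph (not the whole interactome):
unnormalized shortest-path betweenness (pairs counted once, fractional
credit across multiple shortest paths), degree ("connections"), and the
local clustering coefficient (0 for degree < 2). Central nodes are those
with betweenness strictly above the MCN mean, plus a top-k list
(default k = 10; ties broken by degree, then id) whose share of the
total betweenness is reported.

**Significance.** `n_random` (default 1,000) uniform node sets of the
mapped-seed size are drawn from the graph, each set's MCN is extracted,
and node metrics are pooled across all random MCNs. The default report
is the raw two-sided two-sample KS p of the observed MCN's metric values
against the pool, per metric; this is what the pipeline and the negative
control write out. These raw p-values are **not calibrated**, however: node metrics within one MCN are mutually
dependent and heavily tied, so under uniform random seeds the raw
betweenness KS p rejects at well above its nominal level while the
degree and clustering KS p's are strongly conservative (measured in the
test suite's calibration study). `method="empirical"` instead ranks the
observed KS statistic among the random MCNs' own leave-self-out KS
statistics with randomized tie-breaking; by exchangeability this p is
exactly uniform under the null, at the cost of power against small-
sample extremes. Use the raw mode for the conventional KS report and the
empirical mode whenever a calibrated error rate matters.

**Negative control.** `n_control_lists` (default 100) random TF lists of
the seed-list size are drawn from the catalogue's TF universe, each
list's MCN betweenness values are pooled, and the observed MCN's
betweenness distribution is compared to the pool by a KS test. This
controls for the possibility that upstream false positives alone would
produce an equally central subnetwork. Random node sets are uniform, not
degree-matched (a degree-matched null is a documented extension point).

## 5. Patient normalization, cancer specificity, survival screen

Patient expression is standardized per gene: (x − median)/IQR, with
type-7 (linear interpolation) quartiles; zero-IQR genes are dropped with
a log message. Candidate genes are the pooled catalogue targets of the
top-k central MCN TFs, restricted to the union of the "secreted" and
"transmembrane" annotation sets (set-level enrichment p-values are
reported for transparency but never used as a filter).

Cancer specificity uses two contrasts with per-gene Welch t-tests and
Benjamini–Hochberg correction across the candidates within each
contrast: contrast A compares cancer vs all other samples; contrast B
compares inflammation vs healthy samples. A gene is cancer-specific when
q_A ≤ 0.05 and q_B > 0.05. Contrast B deliberately excludes the cancer
samples from its reference: with cancer at 78% of the cohort a pooled
reference is dominated by the cancer shift itself, which would flag
every cancer-only gene as "inflammation-regulated" and exclude it while
letting cancer+inflammation genes through — the opposite of the
filter's purpose. The moderated-statistics (empirical-Bayes) variant of
the per-gene test is a documented extension point; Welch's t is used
here.

The survival screen standardizes each gene per cohort (median/IQR),
splits patients at the empirical 1/3 and 2/3 quantiles into low/mid/high
tertiles (boundary ties go to the lower group; all-tied genes are
untestable and logged), fits the three Kaplan–Meier curves (lifelines)
and compares them with the k-group log-rank test (χ², k−1 df). A gene
passes when p ≤ 0.05 in at least one cohort; no cross-cohort correction
is applied — the at-least-one-cohort rule is deliberate, and under the null a gene passes somewhere with probability
≈ 1 − 0.95^(number of cohorts), an inflation the tests quantify and the
caller should keep in mind.

## 6. The synthetic study

The generator plants every structure the pipeline is supposed to find,
at a deliberately reduced scale (defaults): a catalogue of 150 TFs with
Poisson(25) targets over 1,000 genes; 100 cell lines in triplicate; 40
"driver" TFs whose latent activity is b₁·expression + b₂·CNV + noise
(b₁ = b₂ = 1, noise SD 0.2); 15 "active null" TFs with independent
activity; the remaining TFs never active in the panel, as most
catalogue TFs would be in any one study. A TF active in a line (top
decile of its own activity) shifts all its targets by +3 log₂ units in
that line. TF expression and CNV each follow a one-factor model across
lines (loadings ±[0.7, 1]), which gives the TF–TF correlation profiles
their structure. CNV is emitted directly as a GISTIC-style region table
(one significant region per TF locus on a toy chromosome, plus
non-significant decoy regions), since the region-calling algorithm
itself is out of scope.

The PPI graph has an Erdős–Rényi background (p₀ = 0.01) and a two-tier
planted module: a core of 7 drivers plus 3 hub intermediates, pairwise
wired at p₁ = 0.5, with every other driver attached to each module node
at 0.35 — so the module is a bridge layer that carries the shortest
paths between peripheral drivers, betweenness ranking is informative,
and the top-10 central set is stable. Two peripheral drivers are left
out of the graph to exercise the unmapped-seed path. Module drivers
draw 12 of their targets from a shared 40-gene program (co-regulating
modules share targets), so each planted biomarker is covered by several
central TFs and survives the loss of one of them.

The patient cohort (500 patients, 78/8/14% cancer/inflammation/healthy)
shifts the 12 planted cancer-specific genes (program targets) by 1.5
noise-SD in cancer samples only and 6 decoy genes in cancer and
inflammation; the annotation sets contain all planted genes plus a
random 15% padding. Survival cohorts (3 × 300 patients) give 8 of the
planted genes a log-hazard of log 3 per expression SD in 1–2 cohorts,
with exponential event times and independent exponential censoring
calibrated to a 30% rate. Every generator draws from its own RNG stream
derived from the config seed, so all outputs are bit-identical under a
fixed seed.

**What the generator does not emulate** — probe-level microarray
structure, genome-scale coordinates, batch effects, tissue-of-origin
structure among cell lines, line-specific biology beyond TF-driven
regulation (per-gene line noise is kept small at SD 0.15 so that planted
regulation dominates the per-line differential calls), correlated
censoring, or cohort heterogeneity. Passing tests therefore show that
the pipeline recovers the planted mechanism under its own model
assumptions, not that it would perform equally on real arrays.

## 7. Numerical and degenerate-input policy

Scores and p-values are floored/clipped only where documented (p ≥
1e-300 before logs; KS exact below 26 points). Empty regulated lists
give all-zero score columns (logged, not an error). Empty enrichment
queries return p = 1. Degenerate regressions carry a status flag.
Constant survival genes and empty tertile groups are flagged and
skipped, with the log-rank falling back to the remaining groups when at
least two are non-empty. Region tables filtered to nothing yield an
all-zero CNV matrix. All writers use a fixed float format so pipeline
reruns are byte-identical; the pipeline fans a single seed out to fixed
per-stage child seeds, so stage results do not depend on execution
order, and resuming a stage from its on-disk outputs reproduces a fresh
run exactly.

## 8. Problem sizes used in validation

The test suite exercises exact oracles at enumerable sizes (hypergeometric
universes ≤ 20; betweenness/clustering on 100 random graphs of ≤ 12
nodes; all 2¹⁵ six-node graphs for the MCN rule; a 10⁵-shuffle
permutation null for the log-rank test), statistical recovery at the
default synthetic scale (500 profile-regression datasets; 50 PPI-module
replicates; 100 patient-cohort simulations; 40 survival replicates; 200
calibration replicates at n_random = 200), and one full end-to-end run
with a byte-identity rerun. These sizes are the package's chosen
validation conditions; the generator accepts larger ones.
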