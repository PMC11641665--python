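# Methods

This note documents the statistical model behind `subnetmark`, the defaults
and why they were chosen, the numerical conventions that make runs exactly
reproducible, and the limits of what the synthetic benchmark can show.

## The marker model

A subnetwork marker is a connected gene set S in a PPI network together with
a per-gene direction label (up- or down-regulated in tumors). Its activity
in sample j is the metagene

    a_j(S) = mean_{g ∈ Up(S)} x_gj − mean_{g ∈ Down(S)} x_gj,

with x the log2 expression matrix. Directions are estimated **once, on
training samples only**, as the sign of the gene-level statistic, and are
frozen before any evaluation on held-out samples; inside nested
cross-validation they are re-estimated per outer-training fold so that no
test sample influences its own feature definition. By default Up/Down cover
every member gene with a finite statistic (`gene_scope="all_genes"`); the
alternative `"representatives"` scope uses only the five selected genes.
The all-genes default reflects that every member gene of a discovered
subnetwork carries a direction label in this analysis style, and it averages
noise over more genes.

## Gene-level statistic

Differential expression is measured by an IQR-modified Welch statistic:
medians replace means and the Gaussian-consistent robust scale s = IQR/1.349
replaces the standard deviation,

    t_IQR = (median_T − median_N) / sqrt(s_T²/n_T + s_N²/n_N).

Quantiles use linear interpolation (the numpy default) — IQR values differ
across quantile conventions, so the convention is fixed and tested. Genes
whose IQR is zero in both groups get an undefined statistic and are excluded
from representative selection rather than assigned ±∞. A plain mean/SD Welch
variant is available (`statistic="welch"`) for sensitivity analysis.

## Network partition

Candidates come from recursive spectral bisection of the PPI graph: any
connected component larger than `max_size` (default 50) is split by the sign
of its Fiedler vector (second-smallest eigenvector of the weighted
combinatorial Laplacian; STRING scores scaled to [0, 1] as edge weights),
recursing until all clusters fit. Two determinism conventions are fixed: the
eigenvector's first nonzero entry is made positive, and entries exactly zero
go to the positive side. Nodes are processed in sorted order, so the
partition is independent of graph insertion order.

Each raw sign split is repaired by a deterministic Fiduccia–Mattheyses
refinement pass. This matters: the global Fiedler vector of a ~1000-node
scale-free graph is near-blind to 20-node dense modules and the raw split
frequently slices through them; because such modules have many internal
edges, FM's best-prefix move sequences (which permit temporary uphill moves)
reunite split fragments. In benchmark terms the refinement raised
planted-module host-rank recovery from roughly a third of seeds to
essentially all of them. Neither side of a split may shrink below
min(|A|, |B|, n/4), keeping the recursion useful.

Clusters below `min_size` (default 8) are absorbed into the neighboring
cluster sharing the most edges (isolated undersized components are kept but
flagged). With `boundary_expansion` on (default), each cluster then adds
1-hop neighbors having a strict majority of their edges inside it — the
mechanism by which candidates can overlap, which in turn makes the merge
step non-vacuous. Expansion is capped at doubling a cluster. The size band
8–50 brackets subnetworks of a few tens of genes, the scale at which such
markers are typically reported; both bounds are configurable. Cluster
quality is reported as conductance (cut edges over the smaller side's
volume).

## Entropy ranking

For each candidate the five largest-|t_IQR| member genes (ties broken by
gene id) are its representatives. Samples are k-means clustered (k = number
of classes = 2) on the standardized representative-gene matrix. K-means uses
a deterministic seeding — the two samples at maximum city-block distance,
ties to the smallest index pair — and Lloyd iterations (tol 1e-8, ≤ 300
iterations), so clustering has no random state. The candidate's score is the
cluster-size-weighted class entropy H = Σ_c (n_c/N)·H_c in bits (0·log 0 = 0);
H = 0 iff every cluster is class-pure, and the binary-class ceiling is
exactly 1 bit. Candidates are ranked by ascending entropy, ties by
conductance then id. Pairs with Jaccard overlap ≥ 0.5 (configurable) are
merged, highest overlap first with deterministic tie-breaking, and rescored
until a fixpoint; each merge reduces the count by one, so this terminates.

Degenerate cases are explicit: if all samples coincide in representative
space, everything goes to one cluster and the subnetwork is flagged
`degenerate`; a candidate with no finite gene statistic is flagged
`unusable` and assigned the ceiling entropy.

## Significance

Subnetwork activity is compared between classes with the classical Welch
t-test (Satterthwaite df; degenerate zero-variance input yields p = 1 and a
flag), corrected across subnetworks by Benjamini–Hochberg, and selected at
adjusted p strictly below α = 10⁻⁵.

An important caveat is documented here deliberately: because directions are
estimated from the same samples the test uses, the *discovery-stage* test is
anti-conservative — under a global null the oriented activity difference is
biased away from zero (each gene contributes |noise| in its fitted
direction). This double-dipping is inherent to the procedure, not an
implementation artifact; the package's null-calibration test therefore
checks the Welch test with *a priori fixed* directions, where its p-values
are uniform, and the classifier's honesty rests on the anti-leakage
contract (directions refit per training fold), not on the discovery-stage
p-values. Users should treat discovery-stage adjusted p-values as a ranking
device rather than calibrated error rates.

## Classification

City-block (Manhattan) KNN with k = 5. Tie-breaks are fully deterministic:
neighbors sort by (distance, training-sample index); the tumor vote fraction
is the prediction score; a split vote (score exactly 0.5) goes to the
positive class (tumor). The default k grid {1,3,5,7,9} is odd-only, so split
votes cannot occur unless k is forced even. Nested CV uses stratified outer
folds (fold count shrinks to the smallest class size when needed, e.g. 6
folds at 34 vs 6) and inner CV on the outer-training portion to select k
(ties to smallest k); `select_k=False` freezes k = 5. Metrics are pooled
over outer-fold test predictions; AUC is the Mann–Whitney statistic
P(score_T > score_N) + ½P(equal). With k = 5 the vote fraction is a 6-level
score, so AUC is coarse — a known cost of hard-voting KNN. PCA components
are sign-fixed (largest-magnitude loading positive) for reproducibility.

## Survival

The stratifier is the mean of z-standardized activity rows over the selected
subnetworks, each oriented by the sign of its training Welch t so higher =
more tumor-like; zero-variance rows are excluded with a warning. Patients
strictly above the median (configurable quantile) are high-risk; scores
exactly at the cut go low-risk. Kaplan–Meier curves use the product-limit
estimator with the standard tie convention (records censored at t remain at
risk for events at t); groups are compared by the two-group log-rank test
(chi-square, 1 df, two-sided p, threshold 0.05), overall and within ER
strata; a stratum missing a risk group is skipped with a warning, and a
no-event comparison returns p = 1 with a flag.

## Synthetic benchmark

The generator emulates the structure this analysis assumes:

- **Network**: Barabási–Albert graph (attachment m = 2) on `n_genes` = 1000
  nodes — scale-free, matching PPI degree heuristics. Each of 4 planted
  modules is a random disjoint set of 20 nodes whose missing internal pairs
  are added with probability 0.5, giving expected internal degree ≈ 9.5
  against a background mean degree ≈ 4; "densely connected" is the premise
  of module discovery, and at much lower densities modules are structurally
  indistinguishable from background. All edges carry confidence 999.
- **Expression**: gene baselines ~ N(7, 1) (log2-intensity convention),
  homoscedastic N(0, 1) noise; planted genes shift ±2.0 log2 units in tumor
  samples, half of each module down. Default cohort 34 tumor / 6 normal,
  mirroring a small training cohort with severe class imbalance.
- **Survival**: per tumor sample, z = standardized composite planted
  activity; event times ~ Exponential(0.02·exp(1.5·z)) months, censoring ~
  Uniform(0, 120) months; ER status assigned independently (60% positive) so
  ER strata are exchangeable under the null.

Every generator is a pure function of (config, seed), with independent
per-stage RNG streams. What the generator does **not** emulate: probe-level
microarray artifacts, batch effects, RNA-seq count distributions,
heteroscedastic or correlated background noise, overlapping modules, or
hub-biased module placement. Passing tests on this benchmark therefore show
the pipeline recovers the signal it is designed for under clean conditions;
they do not certify performance on real cohorts.

Two published-style claims are *not* reproducible even in simulation, and
the corresponding checks fail by design of the conditions rather than by
implementation error. First, with only 6 normal samples the Welch df is ~7,
so a 2σ effect cannot reliably reach BH-adjusted p < 10⁻⁵ (the attainable
rate is ~20–35% of seeds, and the double-dip bias above also breaks the
zero-effect analog). Second, strict pointwise KM dominance at every event
time fails in ~8% of strong-effect seeds because the very first event falls
in the low-risk group with probability ≈ 1/(1 + hazard ratio) ≈ 1/12 — a
single-event violation at S = 1 vs 1 − 1/n. Both are asserted at face value
in the acceptance tests and left failing, with the measured rates reported.

## Problem sizes and determinism

Default analyses run at 1000 genes / 40 samples (discovery), 522 samples
(independent test), and 500 patients (survival); repeated-seed experiments
in the test-suite and acceptance script use 10–200 replicates per quantity,
chosen so the whole suite completes in a few minutes on one CPU while
keeping Monte-Carlo error well inside the asserted margins. All reports
serialize with sorted keys and 10-significant-digit floats, so identical
analyses are byte-identical on disk; the pipeline derives per-stage child
seeds from the global seed via a stage-name CRC, making each stage
independently reproducible.
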