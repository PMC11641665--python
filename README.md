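# subnetmark

Subnetwork biomarker discovery from gene expression and protein–protein
interaction (PPI) networks.

Single-gene expression markers are notoriously unstable across cohorts. A
more robust alternative treats a *connected set of interacting genes* as one
marker: its member genes are aggregated into a per-sample **activity score**,
and that score — not any individual gene — is used for diagnosis and
prognosis. `subnetmark` implements this analysis end to end for a two-class
(tumor vs. normal) design:

1. **Integrate** a genes × samples log2 expression matrix with a STRING-style
   PPI edge list (`combined_score` ≥ a confidence cutoff, default 700).
2. **Partition** the network into small, closely connected candidate
   subnetworks by recursive spectral bisection (Fiedler-vector sign splits
   with deterministic Fiduccia–Mattheyses cut refinement), size band 8–50.
3. **Rank** candidates: for each, the five most differentially expressed
   member genes are chosen by an IQR-modified Welch statistic

   t_IQR = (median_T − median_N) / √(s_T²/n_T + s_N²/n_N),  s = IQR/1.349,

   samples are k-means clustered on those representatives, and the candidate
   is scored by the weighted class entropy of the clusters,
   H = Σ_c (n_c/N)·H_c (bits). H = 0 means the clusters separate tumor from
   normal perfectly; lower is better. Candidates with Jaccard overlap ≥ 0.5
   are merged and rescored.
4. **Score & select**: per-sample activity a_j = mean of up-regulated member
   genes − mean of down-regulated member genes (directions from the sign of
   t_IQR on training data only); Welch t-tests on activity with
   Benjamini–Hochberg correction select subnetworks at adjusted p < 10⁻⁵.
5. **Classify**: city-block KNN (k = 5) on the activity features, evaluated
   on an independent test set or under two-level nested cross-validation
   (10 outer / 10 inner stratified folds, inner folds select k from
   {1,3,5,7,9}), reporting accuracy, sensitivity, specificity and
   Mann–Whitney AUC; plus an unsupervised PCA projection.
6. **Stratify survival**: a composite score (mean of oriented z-scored
   activities) median-splits patients into high-/low-risk groups compared by
   Kaplan–Meier curves and the log-rank test (p < 0.05), optionally within
   ER-status strata.

Because real cohorts cannot ship with a package, `subnetmark` includes a
first-class synthetic benchmark: a scale-free (preferential-attachment) PPI
network with densely connected *planted modules* whose genes are shifted up
or down in tumor samples, and exponential proportional-hazards survival
coupled to planted-module activity. Every stage of the pipeline is validated
against this generator's ground truth.

## Worked example

```python
import subnetmark as sm

cfg = sm.SimulationConfig(seed=7)          # 1000 genes, 4 planted modules,
net, truth = sm.simulate_network(cfg)      # 34 tumor / 6 normal samples
dataset = sm.simulate_expression(net, truth, cfg)

candidates = sm.partition(net)
scored = sm.score_subnetworks(candidates, dataset, net)
ranked = sm.rank_subnetworks(sm.merge_overlapping(scored, dataset, net))

activity = sm.activity_matrix(ranked, dataset)
records = sm.significance_table(activity, dataset)   # Welch + BH, alpha 1e-5
```

Printed summary of that run:

```
32 candidates -> 32 ranked subnetworks, 4 significant
rank  id     size  entropy  conductance  adj_p      planted_overlap
   1  S0021    24  0.000    0.225        1.44e-06   20/20
   2  S0015    35  0.000    0.234        8.90e-11   20/20
   3  S0008    47  0.000    0.282        1.03e-05   20/20
   4  S0014    49  0.162    0.409        4.24e-06   17/20
   5  S0027    40  0.427    0.393        2.76e-03   0/20
planted-module host ranks: [2, 3, 4, 1]
```

Reading this: the partitioner produced 32 candidate subnetworks; the four
ranked first by entropy each carry one of the four planted modules (the
top-3 contain a module intact, rank 4 carries 17 of 20 genes), with entropy
0 meaning their representative genes cluster the 40 samples into perfectly
class-pure groups, while the first background subnetwork (rank 5) has
entropy 0.427 and a far weaker adjusted p. The host ranks line confirms the
four planted modules occupy ranks 1–4.

The same pipeline runs from the shell:

```sh
subnetmark run --seed 4 --outdir out/            # simulation mode
subnetmark run --config my_analysis.yaml         # file-based inputs
```

writing `membership.tsv`, `discovery.json`, `activity.tsv`,
`significance.json`, `classification.json`, `survival.json` and a
`manifest.json` with input hashes and per-stage seeds. Individual stages are
available as `subnetmark simulate|partition|discover|score|classify|pca|
survive`. Reruns with the same config and seed are byte-identical.

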