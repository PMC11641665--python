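"""Score and rank candidate subnetworks by sample-clustering entropy.

For each candidate cluster the five most differentially expressed member
genes are selected by an IQR-modified Welch statistic

    t_IQR = (median(tumor) - median(normal)) / sqrt(s_t^2/n_t + s_n^2/n_n),
    s = IQR / 1.349,

a robust analog of Welch's t (IQR/1.349 is the Gaussian-consistent robust
sigma; quantiles use linear interpolation). Samples are then k-means
clustered on the standardized expression of those representatives, and the
subnetwork's entropy score is the risk-set-weighted class entropy of the
clusters:

    H = sum_c (n_c/N) * ( -sum_k p_ck log2 p_ck ).

H = 0 means every cluster is class-pure — a perfect marker; lower is better.
Significantly overlapping candidates (Jaccard >= threshold) are merged and
rescored. A plain mean/SD Welch variant of the gene statistic is available
for sensitivity analysis (``statistic="welch"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .io_formats import (
    NORMAL,
    TUMOR,
    ExpressionDataset,
    InteractionNetwork,
    SubnetmarkError,
)
from .partition import CandidateSubnetwork, conductance

logger = logging.getLogger("subnetmark")

#: Gaussian-consistency constant: IQR of N(0,1) is ~1.349, so IQR/1.349
#: estimates sigma under normality.
IQR_TO_SIGMA = 1.349

N_REPRESENTATIVES = 5


@dataclass(frozen=True)
class GeneStatistic:
    gene_id: str
    t_iqr: float
    direction: str  # "up" iff t_iqr > 0 (higher in tumor)


@dataclass
class ScoredSubnetwork:
    """A candidate with representatives, directions and its entropy score."""

    id: str
    gene_set: frozenset[str]
    representatives: list[GeneStatistic]
    entropy_score: float
    conductance: float
    directions: dict[str, str] = field(default_factory=dict)
    degenerate: bool = False
    unusable: bool = False


# ---------------------------------------------------------------------------
# Gene-level statistic
# ---------------------------------------------------------------------------

def _robust_scale(x: np.ndarray, axis: int = -1) -> np.ndarray:
    q75, q25 = np.percentile(x, [75, 25], axis=axis)
    return (q75 - q25) / IQR_TO_SIGMA


def iqr_welch_t(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """IQR-modified Welch statistic for two groups (a minus b).

    Returns NaN when both robust scales are zero (degenerate gene).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SubnetmarkError("each group needs at least 2 values")
    sa, sb = _robust_scale(a), _robust_scale(b)
    denom = np.sqrt(sa**2 / a.size + sb**2 / b.size)
    if denom == 0:
        return float("nan")
    return float((np.median(a) - np.median(b)) / denom)


def gene_statistics(
    dataset: ExpressionDataset, statistic: str = "iqr"
) -> dict[str, GeneStatistic]:
    """Per-gene tumor-vs-normal statistic for every gene, vectorized.

    Genes whose scale is zero in both groups get ``t_iqr = NaN`` and are
    excluded downstream.
    """
    tumor = dataset.class_mask(TUMOR)
    normal = dataset.class_mask(NORMAL)
    a = dataset.values[:, tumor]
    b = dataset.values[:, normal]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise SubnetmarkError("each class needs at least 2 samples")
    if statistic == "iqr":
        loc_a, loc_b = np.median(a, axis=1), np.median(b, axis=1)
        sa, sb = _robust_scale(a, axis=1), _robust_scale(b, axis=1)
    elif statistic == "welch":
        loc_a, loc_b = a.mean(axis=1), b.mean(axis=1)
        sa, sb = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    else:
        raise SubnetmarkError(f"unknown statistic {statistic!r}")
    denom = np.sqrt(sa**2 / a.shape[1] + sb**2 / b.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (loc_a - loc_b) / denom, np.nan)
    return {
        g: GeneStatistic(g, float(ti), "up" if ti > 0 else "down")
        for g, ti in zip(dataset.gene_ids, t)
    }


def select_representatives(
    subnetwork: CandidateSubnetwork | frozenset[str],
    dataset: ExpressionDataset,
    stats: dict[str, GeneStatistic] | None = None,
    statistic: str = "iqr",
) -> list[GeneStatistic]:
    """Top-5 member genes by |t_IQR|, ties broken by gene id ascending.

    Genes with an undefined (NaN) statistic are excluded; an empty result
    marks the subnetwork unusable.
    """
    genes = subnetwork.gene_set if hasattr(subnetwork, "gene_set") else subnetwork
    if stats is None:
        stats = gene_statistics(dataset, statistic=statistic)
    usable = [stats[g] for g in genes if g in stats and np.isfinite(stats[g].t_iqr)]
    usable.sort(key=lambda s: (-abs(s.t_iqr), s.gene_id))
    return usable[:N_REPRESENTATIVES]


# ---------------------------------------------------------------------------
# Sample clustering and entropy
# ---------------------------------------------------------------------------

def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _farthest_seeds(x: np.ndarray, k: int) -> np.ndarray:
    """Deterministic seeding: the city-block-farthest sample pair, then
    farthest-point additions; ties go to the smallest index pair."""
    n = x.shape[0]
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, k=1)
    flat = d[iu]
    best = int(np.argmax(flat))
    chosen = [int(iu[0][best]), int(iu[1][best])]
    while len(chosen) < k:
        mind = d[:, chosen].min(axis=1)
        mind[chosen] = -1.0
        chosen.append(int(np.argmax(mind)))
    return x[chosen]


def cluster_samples(
    representatives: list[GeneStatistic],
    dataset: ExpressionDataset,
    n_clusters: int = 2,
) -> tuple[np.ndarray, bool]:
    """K-means on samples in representative-gene space.

    Each representative gene is standardized across samples; Lloyd
    iterations run from the deterministic farthest-pair seeding (tol 1e-8,
    max 300 iterations). Returns (assignments, degenerate); when all samples
    coincide every sample goes to cluster 0 and ``degenerate`` is True.
    """
    if n_clusters < 2:
        raise SubnetmarkError("n_clusters must be >= 2")
    if dataset.n_samples < n_clusters:
        raise SubnetmarkError("fewer samples than clusters")
    if not representatives:
        raise SubnetmarkError("no representative genes")
    idx = dataset.gene_index([r.gene_id for r in representatives])
    x = _standardize_columns(dataset.values[idx, :].T)  # samples x genes
    if np.allclose(x, x[0], atol=1e-12):
        return np.zeros(x.shape[0], dtype=int), True
    seeds = _farthest_seeds(x, n_clusters)
    km = KMeans(
        n_clusters=n_clusters,
        init=seeds,
        n_init=1,
        max_iter=300,
        tol=1e-8,
        algorithm="lloyd",
    )
    labels = km.fit_predict(x)
    return labels.astype(int), False


def entropy_score(assignments: np.ndarray, class_labels: list[str]) -> float:
    """Cluster-size-weighted class entropy in bits; 0 iff clusters are pure."""
    assignments = np.asarray(assignments)
    if assignments.shape[0] != len(class_labels):
        raise SubnetmarkError("assignments and class_labels differ in length")
    n = assignments.shape[0]
    labels = np.asarray(class_labels)
    h = 0.0
    for c in np.unique(assignments):
        members = labels[assignments == c]
        _, counts = np.unique(members, return_counts=True)
        p = counts / counts.sum()
        h_c = float(-(p * np.log2(p)).sum())
        h += (members.size / n) * h_c
    return h


# ---------------------------------------------------------------------------
# Scoring, merging, ranking
# ---------------------------------------------------------------------------

def _safe_conductance(network: InteractionNetwork, genes: frozenset[str]) -> float:
    try:
        return conductance(network, set(genes))
    except SubnetmarkError:
        return 0.0  # gene_set spans the whole (sub)network


def score_subnetwork(
    sid: str,
    genes: frozenset[str],
    dataset: ExpressionDataset,
    network: InteractionNetwork,
    stats: dict[str, GeneStatistic],
    n_clusters: int = 2,
) -> ScoredSubnetwork:
    reps = select_representatives(genes, dataset, stats=stats)
    directions = {
        g: stats[g].direction
        for g in sorted(genes)
        if g in stats and np.isfinite(stats[g].t_iqr)
    }
    if not reps:
        logger.warning("subnetwork %s has no usable gene statistic", sid)
        return ScoredSubnetwork(
            sid, genes, [], float(np.log2(2)), _safe_conductance(network, genes),
            directions, unusable=True,
        )
    labels, degenerate = cluster_samples(reps, dataset, n_clusters=n_clusters)
    h = entropy_score(labels, dataset.class_labels)
    return ScoredSubnetwork(
        sid, genes, reps, h, _safe_conductance(network, genes), directions,
        degenerate=degenerate,
    )


def score_subnetworks(
    candidates: list[CandidateSubnetwork],
    dataset: ExpressionDataset,
    network: InteractionNetwork,
    statistic: str = "iqr",
    n_clusters: int = 2,
) -> list[ScoredSubnetwork]:
    stats = gene_statistics(dataset, statistic=statistic)
    return [
        score_subnetwork(c.id, c.gene_set, dataset, network, stats, n_clusters)
        for c in candidates
    ]


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def merge_overlapping(
    scored: list[ScoredSubnetwork],
    dataset: ExpressionDataset,
    network: InteractionNetwork,
    jaccard_threshold: float = 0.5,
    statistic: str = "iqr",
    n_clusters: int = 2,
) -> list[ScoredSubnetwork]:
    """Merge pairs with Jaccard overlap >= threshold, highest overlap first.

    The merged subnetwork is the union of gene sets, rescored from scratch;
    the loop repeats until no pair qualifies. Pair choice is deterministic
    (max Jaccard, ties by the pair's sorted ids), so the fixpoint does not
    depend on input order. Each merge reduces the count by one, so the loop
    terminates.
    """
    if not (0.0 < jaccard_threshold <= 1.0):
        raise SubnetmarkError("jaccard_threshold must be in (0, 1]")
    stats = gene_statistics(dataset, statistic=statistic)
    current = list(scored)
    while len(current) > 1:
        best = None
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                jac = _jaccard(current[i].gene_set, current[j].gene_set)
                if jac < jaccard_threshold:
                    continue
                ids = tuple(sorted((current[i].id, current[j].id)))
                key = (-jac, ids)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = current[i], current[j]
        merged_id = "+".join(sorted(set(a.id.split("+")) | set(b.id.split("+"))))
        merged = score_subnetwork(
            merged_id, a.gene_set | b.gene_set, dataset, network, stats, n_clusters
        )
        current = [s for k, s in enumerate(current) if k not in (i, j)] + [merged]
    return current


def rank_subnetworks(scored: list[ScoredSubnetwork]) -> list[ScoredSubnetwork]:
    """Ascending entropy (lower = better marker); ties by conductance, then id."""
    return sorted(scored, key=lambda s: (s.entropy_score, s.conductance, s.id))


def discovery_report(ranked: list[ScoredSubnetwork]) -> dict:
    """JSON-ready summary of a ranked discovery run."""
    return {
        "subnetworks": [
            {
                "rank": i + 1,
                "id": s.id,
                "genes": sorted(s.gene_set),
                "representatives": [
                    {"gene_id": r.gene_id, "t_iqr": r.t_iqr, "direction": r.direction}
                    for r in s.representatives
                ],
                "directions": s.directions,
                "entropy_score": s.entropy_score,
                "conductance": s.conductance,
                "degenerate": s.degenerate,
                "unusable": s.unusable,
            }
            for i, s in enumerate(ranked)
        ]
    }
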