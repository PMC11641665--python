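"""Per-sample subnetwork activity scores and tumor-vs-normal significance.

The activity of subnetwork S in sample j is the metagene

    a_j = mean_{g in Up(S)} x_gj  -  mean_{g in Down(S)} x_gj,

with gene directions frozen from training-set statistics (an explicit
anti-leakage contract: directions are never re-estimated on evaluation
samples). ``gene_scope`` chooses whether Up/Down cover all member genes with
a finite statistic (default) or only the five representatives. Group
differences are tested with classical Welch t-tests (Satterthwaite df),
corrected by Benjamini–Hochberg; a subnetwork is selected when its adjusted
p is strictly below alpha (default 1e-5).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .discovery import ScoredSubnetwork
from .io_formats import NORMAL, TUMOR, ExpressionDataset, SubnetmarkError, _fmt_float

DEFAULT_ALPHA = 1e-5

__all__ = [
    "ActivityMatrix",
    "SignificanceRecord",
    "activity_score",
    "activity_matrix",
    "welch_test",
    "bh_adjust",
    "significance_table",
    "select_significant",
]


@dataclass
class ActivityMatrix:
    subnetwork_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray  # subnetworks x samples

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.subnetwork_ids), len(self.sample_ids)):
            raise SubnetmarkError("activity matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise SubnetmarkError("activity scores must be finite")

    def row(self, subnetwork_id: str) -> np.ndarray:
        return self.scores[self.subnetwork_ids.index(subnetwork_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, index=self.subnetwork_ids, columns=self.sample_ids)
        df.index.name = "subnetwork_id"
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ActivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))


@dataclass
class SignificanceRecord:
    subnetwork_id: str
    welch_t: float
    df: float
    p_raw: float
    p_adjusted: float
    selected: bool
    degenerate: bool = False


def _direction_sets(
    subnetwork: ScoredSubnetwork, gene_scope: str
) -> tuple[list[str], list[str]]:
    if gene_scope == "representatives":
        pairs = [(r.gene_id, r.direction) for r in subnetwork.representatives]
    elif gene_scope == "all_genes":
        pairs = sorted(subnetwork.directions.items())
    else:
        raise SubnetmarkError(f"unknown gene_scope {gene_scope!r}")
    up = [g for g, d in pairs if d == "up"]
    down = [g for g, d in pairs if d == "down"]
    return up, down


def activity_score(
    subnetwork: ScoredSubnetwork,
    dataset: ExpressionDataset,
    gene_scope: str = "all_genes",
) -> np.ndarray:
    """Up-minus-down metagene score for every sample of ``dataset``.

    One-sided conventions: with no down genes the score is the up mean; with
    no up genes it is minus the down mean. Both sets empty is an error.
    """
    up, down = _direction_sets(subnetwork, gene_scope)
    if not up and not down:
        raise SubnetmarkError(f"subnetwork {subnetwork.id} has no directed genes")
    score = np.zeros(dataset.n_samples)
    if up:
        score += dataset.values[dataset.gene_index(up), :].mean(axis=0)
    if down:
        score -= dataset.values[dataset.gene_index(down), :].mean(axis=0)
    return score


def activity_matrix(
    subnetworks: list[ScoredSubnetwork],
    dataset: ExpressionDataset,
    gene_scope: str = "all_genes",
) -> ActivityMatrix:
    rows = [activity_score(s, dataset, gene_scope) for s in subnetworks]
    return ActivityMatrix(
        [s.id for s in subnetworks], list(dataset.sample_ids), np.vstack(rows)
    )


def welch_test(
    scores_tumor: np.ndarray, scores_normal: np.ndarray
) -> tuple[float, float, float]:
    """Classical Welch t-test (tumor minus normal): (t, Satterthwaite df, p).

    Degenerate input (zero combined variance) returns (0, nan, 1) so a
    constant subnetwork never looks significant.
    """
    a = np.asarray(scores_tumor, dtype=float)
    b = np.asarray(scores_normal, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SubnetmarkError("each group needs at least 2 values")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        return 0.0, float("nan"), 1.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise SubnetmarkError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_table(
    activity: ActivityMatrix,
    dataset: ExpressionDataset,
    alpha: float = DEFAULT_ALPHA,
) -> list[SignificanceRecord]:
    """Welch-test every subnetwork's activity, BH-adjust, and select."""
    if not (0.0 < alpha <= 1.0):
        raise SubnetmarkError("alpha must be in (0, 1]")
    if list(activity.sample_ids) != list(dataset.sample_ids):
        raise SubnetmarkError("activity and dataset sample ids differ")
    tumor = dataset.class_mask(TUMOR)
    normal = dataset.class_mask(NORMAL)
    rows = []
    for sid, row in zip(activity.subnetwork_ids, activity.scores):
        t, df, p = welch_test(row[tumor], row[normal])
        rows.append((sid, t, df, p, not np.isfinite(df)))
    adj = bh_adjust(np.array([r[3] for r in rows]))
    return [
        SignificanceRecord(sid, t, df, p, float(q), bool(q < alpha), degenerate=deg)
        for (sid, t, df, p, deg), q in zip(rows, adj)
    ]


def select_significant(
    records: list[SignificanceRecord], alpha: float = DEFAULT_ALPHA
) -> list[SignificanceRecord]:
    """Records with adjusted p strictly below alpha (boundary excluded)."""
    return [
        SignificanceRecord(
            r.subnetwork_id, r.welch_t, r.df, r.p_raw, r.p_adjusted,
            bool(r.p_adjusted < alpha), r.degenerate,
        )
        for r in records
        if r.p_adjusted < alpha
    ]
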