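"""Risk stratification by subnetwork activity and Kaplan–Meier comparison.

Patients are combined into one stratifier — the mean of z-standardized
activity scores over the selected subnetworks, each oriented so that higher
means more tumor-like (the sign of its training Welch t) — and split at the
median into high- and low-risk groups (scores exactly at the median go to
low risk). Groups are compared with the product-limit (Kaplan–Meier)
estimator and the two-group log-rank test (chi-square, 1 df); analyses can
be repeated within ER-status strata. Censored records at time t remain at
risk for events at t (standard convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from lifelines.statistics import logrank_test as _lifelines_logrank

from .activity import ActivityMatrix
from .io_formats import ExpressionDataset, SubnetmarkError

logger = logging.getLogger("subnetmark")

HIGH, LOW = "high_risk", "low_risk"
SURVIVAL_ALPHA = 0.05

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "composite_score",
    "assign_risk_groups",
    "km_estimate",
    "logrank_test",
    "stratified_analysis",
    "survival_report",
]


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float
    event: int
    group: Optional[str] = None  # high_risk | low_risk
    stratum: str = "all"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise SubnetmarkError(f"negative time for {self.sample_id}")
        if self.event not in (0, 1):
            raise SubnetmarkError("event must be 0 or 1")


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: list[float]
    survival_prob: list[float]
    at_risk: list[int]

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times,
            "survival_prob": self.survival_prob,
            "at_risk": self.at_risk,
        }


def composite_score(
    activity: ActivityMatrix,
    selected_ids: Sequence[str],
    orientation_t: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Mean of oriented, z-standardized activity rows over selected subnetworks.

    ``orientation_t`` maps subnetwork id to its training Welch t; rows with
    negative t are sign-flipped so high composite = tumor-like. Rows with
    zero variance are excluded with a warning.
    """
    if not selected_ids:
        raise SubnetmarkError("no subnetworks selected for the composite score")
    rows = []
    for sid in selected_ids:
        row = activity.row(sid)
        sd = row.std()
        if sd == 0:
            logger.warning("composite_score: %s has zero variance; excluded", sid)
            continue
        z = (row - row.mean()) / sd
        if orientation_t is not None and orientation_t.get(sid, 0.0) < 0:
            z = -z
        rows.append(z)
    if not rows:
        raise SubnetmarkError("all selected subnetworks are degenerate")
    return np.mean(rows, axis=0)


def assign_risk_groups(scores: np.ndarray, quantile: float = 0.5) -> list[str]:
    """Quantile split (default median): strictly above the cut is high risk."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise SubnetmarkError("need at least 2 samples")
    if not (0.0 < quantile < 1.0):
        raise SubnetmarkError("quantile must be in (0, 1)")
    med = float(np.quantile(s, quantile))
    groups = [HIGH if v > med else LOW for v in s]
    if HIGH not in groups:
        logger.warning("assign_risk_groups: degenerate scores, all low_risk")
    return groups


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i/n_i) over distinct event times t_i with
    d_i events and n_i at risk; records censored at t_i are still at risk for
    events at t_i. With no events the curve is empty (S = 1 everywhere).
    """
    if not records:
        raise SubnetmarkError("no records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    event_times = np.unique(times[events == 1])
    surv, probs, at_risk = 1.0, [], []
    for t in event_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d_i / n_i
        probs.append(surv)
        at_risk.append(n_i)
    return KMCurve([float(t) for t in event_times], probs, at_risk)


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square on 1 df, two-sided p).

    With no events in either group the test is undefined; returns (0, 1).
    """
    if not group_a or not group_b:
        raise SubnetmarkError("both groups must be non-empty")
    if all(r.event == 0 for r in group_a) and all(r.event == 0 for r in group_b):
        logger.warning("logrank_test: no events in either group")
        return 0.0, 1.0
    res = _lifelines_logrank(
        [r.time for r in group_a],
        [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


def _split(records: Sequence[SurvivalRecord]) -> tuple[list, list]:
    return ([r for r in records if r.group == HIGH],
            [r for r in records if r.group == LOW])


def stratified_analysis(
    records: Sequence[SurvivalRecord],
    strata: Mapping[str, str] | None = None,
) -> dict[str, dict]:
    """High- vs low-risk KM + log-rank, overall and within each stratum.

    ``strata`` maps sample id to a stratum label (e.g. ER status); the
    unstratified analysis is always reported under ``"all"``. Strata with
    only one risk group (or no samples) are skipped with a warning.
    """
    out: dict[str, dict] = {}
    layers: dict[str, list[SurvivalRecord]] = {"all": list(records)}
    if strata:
        for r in records:
            label = strata.get(r.sample_id)
            if label is None:
                continue
            layers.setdefault(str(label), []).append(r)
    for name in sorted(layers):
        recs = layers[name]
        high, low = _split(recs)
        if not high or not low:
            if name != "all":
                logger.warning("stratum %s has a single risk group; skipped", name)
                continue
            raise SubnetmarkError("need both risk groups")
        chi2, p = logrank_test(high, low)
        out[name] = {
            "n_high": len(high),
            "n_low": len(low),
            "km_high": km_estimate(high).to_dict(),
            "km_low": km_estimate(low).to_dict(),
            "logrank_chi_square": chi2,
            "logrank_p": p,
            "significant": bool(p < SURVIVAL_ALPHA),
        }
    return out


def survival_report(
    activity: ActivityMatrix,
    dataset: ExpressionDataset,
    selected_ids: Sequence[str],
    orientation_t: Mapping[str, float] | None = None,
    quantile: float = 0.5,
) -> dict:
    """End-to-end stratification of the dataset's clinical tumor samples."""
    if dataset.clinical is None:
        raise SubnetmarkError("dataset has no clinical records")
    clin = dataset.clinical.dropna(subset=["survival_time", "event"])
    keep = [s for s in activity.sample_ids if s in clin.index]
    if len(keep) < 2:
        raise SubnetmarkError("fewer than 2 samples with follow-up")
    idx = [activity.sample_ids.index(s) for s in keep]
    sub = ActivityMatrix(
        list(activity.subnetwork_ids), keep, activity.scores[:, idx]
    )
    scores = composite_score(sub, selected_ids, orientation_t)
    groups = assign_risk_groups(scores, quantile=quantile)
    records = [
        SurvivalRecord(
            s,
            float(clin.loc[s, "survival_time"]),
            int(clin.loc[s, "event"]),
            group=g,
        )
        for s, g in zip(keep, groups)
    ]
    strata = None
    if "er_status" in clin.columns:
        strata = {s: f"er_{clin.loc[s, 'er_status']}" for s in keep}
    analysis = stratified_analysis(records, strata)
    return {
        "n_samples": len(records),
        "composite_scores": {s: float(v) for s, v in zip(keep, scores)},
        "risk_groups": dict(zip(keep, groups)),
        "strata": analysis,
    }
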