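"""Tabular I/O and deterministic report serialization.

The pipeline touches three external formats: a genes-by-samples expression
table (TSV/CSV, first column gene identifiers, header row sample identifiers),
a per-sample annotation table (columns ``sample_id``, ``class`` and optional
``survival_time``, ``event``, ``er_status``), and a STRING-style edge list
(``protein1  protein2  combined_score`` with scores on the native 0-1000
scale). Structured reports are serialized as JSON with sorted keys and floats
formatted to 10 significant digits so identical reports are byte-identical on
disk; matrices go to TSV with the same float convention.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("subnetmark")

#: Sample-class label conventions used throughout the package.
TUMOR = "tumor"
NORMAL = "normal"

#: STRING combined_score bounds.
CONFIDENCE_MAX = 1000.0


class SubnetmarkError(Exception):
    """Base class for all user-facing errors raised by this package."""


class MissingFileError(SubnetmarkError):
    """An input file does not exist."""


class DuplicateGeneError(SubnetmarkError):
    """The expression table lists a gene identifier more than once."""


class NonNumericValueError(SubnetmarkError):
    """The expression table contains a cell that is not a finite number."""


class MissingLabelError(SubnetmarkError):
    """The requested class-label column is absent from the annotation."""


class NetworkParseError(SubnetmarkError):
    """An edge-list line is malformed (wrong column count or bad score)."""


class EmptyIntersectionError(SubnetmarkError):
    """Expression genes and network nodes share no identifiers."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """A genes x samples log2-scale expression matrix with sample metadata.

    Parameters
    ----------
    gene_ids
        Ordered, duplicate-free gene identifiers (matrix rows).
    sample_ids
        Ordered, duplicate-free sample identifiers (matrix columns).
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; missing
        values are disallowed.
    class_labels
        Per-sample class, ``"tumor"`` or ``"normal"``; optional.
    clinical
        Optional per-sample clinical table indexed by sample id with columns
        ``survival_time`` (months, >= 0), ``event`` (1 = observed) and
        ``er_status`` (``positive`` / ``negative`` / ``unknown``). Samples
        without clinical follow-up carry NaN in ``survival_time``/``event``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    class_labels: Optional[list[str]] = None
    clinical: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise SubnetmarkError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DuplicateGeneError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SubnetmarkError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise NonNumericValueError("expression matrix contains non-finite values")
        if self.class_labels is not None:
            self.class_labels = [str(c) for c in self.class_labels]
            if len(self.class_labels) != len(self.sample_ids):
                raise SubnetmarkError("class_labels length mismatch")
            present = set(self.class_labels)
            if not {TUMOR, NORMAL} <= present:
                raise SubnetmarkError(
                    f"need at least one sample of each class, found {sorted(present)}"
                )
        if self.clinical is not None:
            clin = self.clinical
            if "survival_time" in clin.columns or "event" in clin.columns:
                if not {"survival_time", "event"} <= set(clin.columns):
                    raise SubnetmarkError("survival_time and event must come together")
                times = clin["survival_time"].dropna()
                if (times < 0).any():
                    raise SubnetmarkError("negative survival_time")

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in genes], dtype=int)

    def class_mask(self, label: str) -> np.ndarray:
        if self.class_labels is None:
            raise MissingLabelError("dataset has no class labels")
        return np.array([c == label for c in self.class_labels], dtype=bool)

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = list(idx)
        clin = None
        if self.clinical is not None:
            keep = [self.sample_ids[i] for i in idx]
            clin = self.clinical.loc[[s for s in keep if s in self.clinical.index]]
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            class_labels=(
                [self.class_labels[i] for i in idx] if self.class_labels else None
            ),
            clinical=clin,
        )


@dataclass
class InteractionNetwork:
    """Undirected protein/gene interaction graph with confidence weights.

    Thin wrapper around :class:`networkx.Graph`; edge attribute
    ``confidence`` holds the STRING-style combined score in [0, 1000].
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise SubnetmarkError(f"self-loops not allowed: {loops[:3]}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for u, v, c in edges:
            u, v = str(u), str(v)
            if u == v:
                continue
            if g.has_edge(u, v):
                g[u][v]["confidence"] = max(g[u][v]["confidence"], float(c))
            else:
                g.add_edge(u, v, confidence=float(c))
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, float(d["confidence"])))
        return sorted(out)

    def subgraph(self, genes: Iterable[str]) -> "InteractionNetwork":
        return InteractionNetwork(nx.Graph(self.graph.subgraph(set(genes))))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    annotation_path: str | Path | None = None,
    label_column: str = "class",
) -> ExpressionDataset:
    """Read an expression matrix (and optional sample annotation) from disk.

    ``path`` is a TSV/CSV with gene identifiers in the first column and sample
    identifiers in the header. ``annotation_path`` is a TSV with a
    ``sample_id`` column, the class column named by ``label_column``, and
    optional ``survival_time``, ``event``, ``er_status`` columns.

    Raises
    ------
    MissingFileError, DuplicateGeneError, NonNumericValueError,
    MissingLabelError
        Each distinct failure mode raises its named error.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise DuplicateGeneError(f"duplicate gene ids: {dupes[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise NonNumericValueError(f"non-numeric expression cell: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise NonNumericValueError("expression matrix contains NaN/inf")

    class_labels = None
    clinical = None
    if annotation_path is not None:
        ann_path = Path(annotation_path)
        if not ann_path.exists():
            raise MissingFileError(str(ann_path))
        ann = pd.read_csv(ann_path, sep=_sep_for(ann_path), dtype={"sample_id": str})
        if label_column not in ann.columns:
            raise MissingLabelError(
                f"label column {label_column!r} not in {list(ann.columns)}"
            )
        ann = ann.set_index("sample_id")
        missing = [s for s in df.columns if s not in ann.index]
        if missing:
            raise MissingLabelError(f"samples without annotation: {missing[:5]}")
        ann = ann.loc[list(df.columns)]
        class_labels = [str(c) for c in ann[label_column]]
        clin_cols = [c for c in ("survival_time", "event", "er_status") if c in ann.columns]
        if clin_cols:
            clinical = ann[clin_cols].copy()

    return ExpressionDataset(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        values=values,
        class_labels=class_labels,
        clinical=clinical,
    )


def write_expression(
    dataset: ExpressionDataset,
    path: str | Path,
    annotation_path: str | Path | None = None,
    label_column: str = "class",
) -> None:
    """Write the matrix (and annotation, if requested) with 10-digit floats."""
    path = Path(path)
    df = pd.DataFrame(dataset.values, index=dataset.gene_ids, columns=dataset.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.10g", lineterminator="\n")
    if annotation_path is not None:
        rows = {"sample_id": dataset.sample_ids}
        if dataset.class_labels is not None:
            rows[label_column] = dataset.class_labels
        ann = pd.DataFrame(rows).set_index("sample_id")
        if dataset.clinical is not None:
            ann = ann.join(dataset.clinical)
        ann.to_csv(Path(annotation_path), sep="\t", float_format="%.10g",
                   lineterminator="\n")


def read_network(
    path: str | Path,
    min_confidence: float = 700.0,
    id_map: Mapping[str, str] | str | Path | None = None,
) -> InteractionNetwork:
    """Read a STRING-style edge list, filter by score, and dedupe edges.

    Lines with columns ``protein1 protein2 combined_score`` (whitespace- or
    tab-separated; an optional header naming those columns is skipped). Edges
    below ``min_confidence`` are dropped; duplicate undirected pairs keep the
    maximum score; self-loops are discarded. ``id_map`` optionally translates
    protein ids to gene symbols (a mapping, or a two-column TSV path);
    identifiers without a mapping are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    mapping: Mapping[str, str] | None
    if id_map is None or isinstance(id_map, Mapping):
        mapping = id_map
    else:
        map_df = pd.read_csv(Path(id_map), sep=None, engine="python", header=None,
                             dtype=str, comment="#")
        mapping = dict(zip(map_df.iloc[:, 0], map_df.iloc[:, 1]))

    net = InteractionNetwork()
    g = net.graph
    n_unmapped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            if lineno == 1 and parts[2].lower() in ("combined_score", "score"):
                continue  # header row
            u, v, raw = parts
            try:
                score = float(raw)
            except ValueError as exc:
                raise NetworkParseError(
                    f"{path}:{lineno}: non-numeric score {raw!r}"
                ) from exc
            if mapping is not None:
                if u not in mapping or v not in mapping:
                    n_unmapped += 1
                    continue
                u, v = mapping[u], mapping[v]
            if u == v or score < min_confidence:
                continue
            if g.has_edge(u, v):
                g[u][v]["confidence"] = max(g[u][v]["confidence"], score)
            else:
                g.add_edge(u, v, confidence=score)
    if n_unmapped:
        logger.info("read_network: dropped %d edges with unmapped ids", n_unmapped)
    return net


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, c in network.edge_list():
            fh.write(f"{u}\t{v}\t{_fmt_float(c)}\n")


def restrict_to_common_genes(
    dataset: ExpressionDataset, network: InteractionNetwork
) -> tuple[ExpressionDataset, InteractionNetwork]:
    """Project both inputs onto the intersection of their gene universes.

    Gene order is preserved from the dataset. Raises
    :class:`EmptyIntersectionError` if the universes are disjoint.
    """
    common = set(dataset.gene_ids) & network.nodes
    if not common:
        raise EmptyIntersectionError("expression genes and network nodes are disjoint")
    keep = [g for g in dataset.gene_ids if g in common]
    idx = dataset.gene_index(keep)
    ds = ExpressionDataset(
        gene_ids=keep,
        sample_ids=list(dataset.sample_ids),
        values=dataset.values[idx, :],
        class_labels=list(dataset.class_labels) if dataset.class_labels else None,
        clinical=dataset.clinical,
    )
    sub = network.subgraph(common)
    sub.graph.add_nodes_from(keep)
    return ds, sub


# ---------------------------------------------------------------------------
# Deterministic report serialization
# ---------------------------------------------------------------------------

def _fmt_float(x: float) -> str:
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return str(x)
    return format(float(x), ".10g")


def _normalize(obj):
    """Recursively convert a report to JSON-safe primitives.

    Floats are rounded to 10 significant digits so serialization is a pure
    function of the report's value, not of accumulated rounding noise.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _normalize(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _normalize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = [_normalize(v) for v in obj]
        return sorted(items, key=str) if isinstance(obj, (set, frozenset)) else items
    if isinstance(obj, np.ndarray):
        return _normalize(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if math.isnan(x):
            return None
        return float(_fmt_float(x))
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def write_report(report, path: str | Path) -> None:
    """Serialize a report deterministically.

    Objects exposing ``to_tsv`` (matrices) are written as TSV; everything else
    (dataclasses, dicts, lists) goes to JSON with sorted keys. Writing the
    same report twice yields byte-identical files.
    """
    path = Path(path)
    if hasattr(report, "to_tsv"):
        report.to_tsv(path)
        return
    payload = _normalize(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
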