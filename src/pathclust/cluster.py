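"""Hierarchical clustering of subtype distance matrices and nearest-neighbor
subtype prediction.

Agglomerative clustering (average linkage by default; single and complete
also supported) turns a labelled distance matrix into a merge tree /
dendrogram, exportable as Newick.  Nearest-neighbor prediction assigns each
patient the subtype of the closest exemplar under one of the four distance
metrics; accuracy is summarized both over all five subtype classes
(including Unknown) and over the four known subtypes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix, _pair_distance
from .subtypes import SUBTYPE_ORDER, Subtype

__all__ = [
    "MergeTree",
    "hierarchical_cluster",
    "to_newick",
    "nn_predict",
    "evaluate",
    "PredictionReport",
]

_LINKAGES = ("average", "single", "complete")


@dataclass
class MergeTree:
    """Sequence of agglomerative merges over labelled leaves."""

    labels: list[str]
    merges: list[tuple[frozenset[str], frozenset[str], float]]
    method: str
    linkage_matrix: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def merge_members(self, i: int) -> frozenset[str]:
        a, b, _ = self.merges[i]
        return a | b


def _as_frame(D: DistanceMatrix | pd.DataFrame) -> pd.DataFrame:
    return D.values if isinstance(D, DistanceMatrix) else D


def hierarchical_cluster(
    D: DistanceMatrix | pd.DataFrame, method: str = "average"
) -> MergeTree:
    """Agglomerative clustering of a labelled distance matrix.

    Ties are broken deterministically by the label order of the input
    matrix (scipy processes candidate merges in index order).
    """
    frame = _as_frame(D)
    if method not in _LINKAGES:
        raise ValueError(f"unsupported linkage {method!r}; choose from {_LINKAGES}")
    v = frame.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError("distance matrix contains NaN")
    if v.shape[0] < 2:
        raise ValueError("need at least two leaves")
    Z = linkage(squareform(v, checks=True), method=method)
    labels = list(frame.index.astype(str))
    clusters: dict[int, frozenset[str]] = {
        i: frozenset([lab]) for i, lab in enumerate(labels)
    }
    merges = []
    n = len(labels)
    for row_idx, (a, b, h, _size) in enumerate(Z):
        ca, cb = clusters[int(a)], clusters[int(b)]
        merges.append((ca, cb, float(h)))
        clusters[n + row_idx] = ca | cb
    return MergeTree(labels=labels, merges=merges, method=method, linkage_matrix=Z)


def cophenetic_matrix(tree: MergeTree) -> pd.DataFrame:
    """Pairwise cophenetic (merge-height) distances between leaves."""
    coph = cophenet(tree.linkage_matrix)
    frame = pd.DataFrame(
        squareform(coph), index=tree.labels, columns=tree.labels
    )
    return frame


def to_newick(tree: MergeTree) -> str:
    """Serialize the merge tree as a Newick string with branch lengths.

    The dendrogram is ultrametric: a child hanging from a merge at height h
    gets branch length (h - h_child) / 2, with leaves at height 0, so
    leaf-to-root path lengths all equal half the root height.
    """
    Z = tree.linkage_matrix
    n = len(tree.labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        bl = (parent_h - height(node)) / 2.0
        if node < n:
            return f"{tree.labels[node]}:{bl:g}"
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return f"({render(a, h)},{render(b, h)}):{bl:g}"

    root = n + Z.shape[0] - 1
    a, b = int(Z[root - n, 0]), int(Z[root - n, 1])
    h = height(root)
    return f"({render(a, h)},{render(b, h)});"


_CANON = [s.value for s in SUBTYPE_ORDER]


def nn_predict(
    patient_profile,
    exemplars: Mapping[str, object],
    metric: str,
    mode: str = "mean",
    **kwargs,
) -> tuple[str, dict[str, float], bool]:
    """Predict a subtype as the argmin-distance exemplar.

    Returns (predicted label, per-exemplar distances, tie flag); exact ties
    are broken by the canonical subtype order (LuminalA, LuminalB,
    HER2Plus, BasalLike, Unknown).
    """
    if len(exemplars) < 2:
        raise ValueError("need at least two exemplars")
    distances: dict[str, float] = {}
    errors = []
    for label, ex in exemplars.items():
        try:
            distances[label] = _pair_distance(patient_profile, ex, metric, mode, **kwargs)
        except ValueError as exc:
            errors.append((label, str(exc)))
    if not distances:
        raise ValueError(f"distance undefined for every exemplar: {errors}")
    dmin = min(distances.values())
    ties = [lab for lab, d in distances.items() if d == dmin]
    order = {lab: i for i, lab in enumerate(_CANON)}
    ties.sort(key=lambda lab: (order.get(lab, len(order)), lab))
    return ties[0], distances, len(ties) > 1


@dataclass
class PredictionReport:
    """Per-patient predictions with dual accuracy summaries."""

    table: pd.DataFrame
    true_positives_all: int
    n_all: int
    accuracy_all: float
    true_positives_known: int
    n_known: int
    accuracy_known: float

    def summary(self) -> dict:
        return {
            "true_positives_all": self.true_positives_all,
            "n_all": self.n_all,
            "accuracy_all": self.accuracy_all,
            "true_positives_known": self.true_positives_known,
            "n_known": self.n_known,
            "accuracy_known": self.accuracy_known,
        }


def evaluate(
    predicted: Mapping[str, str] | pd.Series,
    truth: Mapping[str, str] | pd.Series,
) -> PredictionReport:
    """True positives and accuracy over all five subtypes and the four known.

    ``predicted`` and ``truth`` map patient id -> subtype label and must
    cover the same patients.  Patients whose *true* subtype is Unknown are
    excluded from the known-subtype summary.
    """
    pred = pd.Series(dict(predicted), dtype=str)
    true = pd.Series(dict(truth), dtype=str)
    if set(pred.index) != set(true.index):
        raise ValueError("predicted and true labels cover different patients")
    true = true.reindex(pred.index)
    correct = pred == true
    known = true != Subtype.UNKNOWN.value
    table = pd.DataFrame(
        {"predicted": pred, "true": true, "correct": correct}
    ).rename_axis("patient")
    tp_all = int(correct.sum())
    tp_known = int((correct & known).sum())
    n_all = int(len(pred))
    n_known = int(known.sum())
    return PredictionReport(
        table=table,
        true_positives_all=tp_all,
        n_all=n_all,
        accuracy_all=tp_all / n_all if n_all else float("nan"),
        true_positives_known=tp_known,
        n_known=n_known,
        accuracy_known=tp_known / n_known if n_known else float("nan"),
    )
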