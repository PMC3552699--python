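"""The four subtype distance metrics and labelled distance matrices.

Three metrics are one minus the Pearson correlation of per-subtype (or
per-patient) profile vectors:

* **protein intensity** — the vectors of per-protein subtype fixed effects
  from the mixed model;
* **q-value** — the vectors of per-protein q-values from the three-step
  significance screen;
* **pathway profile** — the vectors of per-pathway significant-protein
  counts.

The fourth, the **distance score**, compares two merged pathway-protein
matrices entrywise: score(i, j) = |q_ij^s - q_ij^t|, summed over the common
m x n index and, in ``mean`` mode, divided by m x n (bounded by 3).  ``sum``
mode omits the normalization; hierarchical clustering is invariant to this
positive constant, so both modes give the same dendrogram topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .pathways import PathwayProteinMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "corr_distance",
    "dist_protein_intensity",
    "dist_qvalue",
    "dist_pathway_profile",
    "dist_score",
    "build_distance_matrix",
    "patient_intensity_profile",
    "patient_qvalue_profile",
]

Metric = Literal["protein_intensity", "q_value", "pathway_profile", "distance_score"]


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with its metric recorded."""

    values: pd.DataFrame
    metric: str
    mode: str = ""

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("self-distances must be zero")
        if v.size and v.min() < -1e-10:
            raise ValueError("distances must be nonnegative")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)


def corr_distance(
    u: Sequence[float],
    v: Sequence[float],
    min_pairs: int = 3,
    on_constant: Literal["error", "one"] = "error",
) -> float:
    """1 - Pearson correlation over pairwise-complete entries.

    Lies in [0, 2].  Vectors with fewer than *min_pairs* shared finite
    entries, or with zero variance on the shared entries, are undefined;
    ``on_constant="one"`` degrades the latter to distance 1 with a warning.
    """
    ua = np.asarray(u, dtype=float).ravel()
    va = np.asarray(v, dtype=float).ravel()
    if ua.shape != va.shape:
        raise ValueError("profile vectors differ in length")
    mask = np.isfinite(ua) & np.isfinite(va)
    if mask.sum() < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} pairwise-complete entries, got {int(mask.sum())}"
        )
    uu, vv = ua[mask], va[mask]
    if uu.std() == 0.0 or vv.std() == 0.0:
        if on_constant == "one":
            logger.debug("constant profile; correlation undefined, distance := 1")
            return 1.0
        raise ValueError("zero variance; correlation distance undefined")
    r = float(np.corrcoef(uu, vv)[0, 1])
    return 1.0 - r


def dist_protein_intensity(
    effects: pd.DataFrame, s: str, t: str, **kwargs
) -> float:
    """1 - correlation of the two subtypes' per-protein fixed-effect vectors."""
    return corr_distance(effects[f"S_{s}"], effects[f"S_{t}"], **kwargs)


def dist_qvalue(q_s: Sequence[float], q_t: Sequence[float], **kwargs) -> float:
    """1 - correlation of per-protein q-value vectors on the common protein set."""
    if isinstance(q_s, pd.Series) and isinstance(q_t, pd.Series):
        common = q_s.index.intersection(q_t.index)
        q_s, q_t = q_s.loc[common], q_t.loc[common]
    return corr_distance(q_s, q_t, **kwargs)


def dist_pathway_profile(n_s: Sequence[float], n_t: Sequence[float], **kwargs) -> float:
    """1 - correlation of per-pathway significant-protein count vectors."""
    if isinstance(n_s, pd.Series) and isinstance(n_t, pd.Series):
        n_t = n_t.reindex(n_s.index)
    return corr_distance(n_s, n_t, **kwargs)


def dist_score(
    q_s: pd.DataFrame | PathwayProteinMatrix,
    q_t: pd.DataFrame | PathwayProteinMatrix,
    mode: Literal["mean", "sum"] = "mean",
) -> float:
    """Distance score between two merged pathway-protein matrices.

    Sum over all (pathway, protein) cells of |entry_s - entry_t|; ``mean``
    mode divides by the number of cells (so the result lies in [0, 3]),
    ``sum`` mode reports the raw sum.
    """
    a = q_s.values if isinstance(q_s, PathwayProteinMatrix) else q_s
    b = q_t.values if isinstance(q_t, PathwayProteinMatrix) else q_t
    if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
        raise ValueError("pathway-protein matrices must share the common index")
    if a.size == 0:
        raise ValueError("empty pathway-protein matrix")
    total = float(np.abs(a.to_numpy() - b.to_numpy()).sum())
    if mode == "mean":
        return total / a.size
    if mode == "sum":
        return total
    raise ValueError(f"unknown mode: {mode!r}")


def _pair_distance(pu, pv, metric: str, mode: str, **kwargs) -> float:
    if metric == "distance_score":
        return dist_score(pu, pv, mode=mode or "mean")
    if metric == "pathway_profile":
        return dist_pathway_profile(pu, pv, **kwargs)
    if metric == "q_value":
        return dist_qvalue(pu, pv, **kwargs)
    if metric == "protein_intensity":
        return corr_distance(pu, pv, **kwargs)
    raise ValueError(f"unknown metric: {metric!r}")


def build_distance_matrix(
    profiles: Mapping[str, object],
    metric: Metric,
    mode: str = "mean",
    **kwargs,
) -> DistanceMatrix:
    """All pairwise distances between labelled profiles.

    ``profiles`` maps label -> profile of the type the metric expects
    (vector for the correlation metrics, merged matrix for the distance
    score).  Any undefined pair aborts matrix construction.
    """
    labels = list(profiles)
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = _pair_distance(
                    profiles[labels[i]], profiles[labels[j]], metric, mode, **kwargs
                )
            except ValueError as exc:
                raise ValueError(
                    f"distance undefined for pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            d[i, j] = d[j, i] = dij
    frame = pd.DataFrame(d, index=labels, columns=labels)
    return DistanceMatrix(values=frame, metric=metric, mode=mode if metric == "distance_score" else "")


def patient_intensity_profile(
    matrix: pd.DataFrame, annotation: pd.DataFrame, individual_id: str
) -> pd.Series:
    """Per-protein mean of the patient's replicate columns."""
    ann = annotation.set_index("sample_id")
    cols = [
        c
        for c in matrix.columns
        if c in ann.index and str(ann.loc[c, "individual_id"]) == str(individual_id)
    ]
    if not cols:
        raise ValueError(f"no columns for individual {individual_id!r}")
    return matrix[cols].mean(axis=1)


def patient_qvalue_profile(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    individual_id: str,
    B: int = 1000,
    seed: int = 0,
    f_alpha: float = 0.05,
    estimator: str = "plain",
) -> pd.Series:
    """Per-protein q-values testing one patient against the healthy cohort.

    Runs the full three-step screen with the patient's replicate injections
    as the second group; the patient needs at least two replicates for the
    test to be defined.  Permutation is at the injection (column) level:
    with a single-patient group, individual-level blocks would admit only
    n_healthy + 1 relabellings, a p-value grid far too coarse to rank
    proteins through the q-value cutoffs.
    """
    from .diffstats import differential_test

    ann = annotation.set_index("sample_id")
    healthy_cols = [
        c for c in matrix.columns if str(ann.loc[c, "group"]).lower() == "healthy"
    ]
    if not healthy_cols:
        raise ValueError("no healthy samples available")
    patient_cols = [
        c
        for c in matrix.columns
        if str(ann.loc[c, "individual_id"]) == str(individual_id)
    ]
    if len(patient_cols) < 2:
        raise ValueError(
            f"patient {individual_id!r} has {len(patient_cols)} replicate(s); "
            "need >= 2 for a within-patient variance"
        )
    table = differential_test(
        matrix,
        annotation,
        subtype="__patient__",
        B=B,
        seed=seed,
        f_alpha=f_alpha,
        estimator=estimator,
        cancer_columns=patient_cols,
        unit="replicate",
        share_permutations=True,
    )
    return table.set_index("protein_id")["q"]
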