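"""Variance-adaptive permutation testing with BH adjustment and Storey q-values.

Differential protein abundance between healthy plasma and a cancer subtype
is assessed by a three-step screen:

1. a **permutation test** whose resampled statistic is *variance-adaptive*:
   at the observed labelling and again at every permutation, an F test
   compares the two group variances; if equality cannot be rejected the
   pooled-variance two-sample t statistic is used, otherwise Welch's t
   statistic with Satterthwaite degrees of freedom.  The permutation
   p-value is the proportion of permutations whose t-test p-value is less
   than or equal to the observed t-test p-value;
2. **Benjamini–Hochberg** step-up adjustment of the permutation p-values;
3. **Storey–Tibshirani q-values** computed from the permutation p-values
   with a smoothed pi0 estimate.

Proteins are then declared significant at three nested q-value cutoffs
(q < 0.2, q < 0.1, q < 0.05), and the expected number of false positives
per cutoff is threshold x (number declared).

Permutations shuffle *individuals*: technical replicate injections of one
plasma sample always travel together, because replicates are not
exchangeable with biological samples.  When the number of distinct
relabellings C(n1+n2, n1) does not exceed the permutation budget the test
switches to exhaustive enumeration and is exact.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FTestOutcome",
    "TTestOutcome",
    "SignificanceCutoffs",
    "DiffTestResult",
    "f_variance_test",
    "student_t",
    "welch_t",
    "adaptive_t",
    "permutation_test",
    "bh_adjust",
    "storey_qvalue",
    "declare_significant",
    "differential_test",
]


class DegenerateInputError(ValueError):
    """Raised when a sample has too little variation to test."""


@dataclass(frozen=True)
class FTestOutcome:
    statistic: float
    pvalue: float
    df1: int
    df2: int


@dataclass(frozen=True)
class TTestOutcome:
    """Two-sample t test result with the component statistics recorded."""

    statistic: float
    df: float
    pvalue: float
    branch: Literal["pooled", "welch"]
    mean1: float
    mean2: float
    var1: float
    var2: float
    n1: int
    n2: int
    pooled_sd: float | None = None
    f_test: FTestOutcome | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.pvalue}")
        if self.df <= 0:
            raise ValueError(f"non-positive degrees of freedom: {self.df}")


@dataclass(frozen=True)
class SignificanceCutoffs:
    """Three nested q-value screening thresholds, loosest first."""

    thresholds: tuple[float, float, float] = (0.2, 0.1, 0.05)

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) != 3 or not (t[0] > t[1] > t[2] > 0):
            raise ValueError("cutoffs must be three strictly decreasing thresholds")


@dataclass
class DiffTestResult:
    """Per-protein outcome of the three-step significance screen."""

    protein_id: str
    observed: TTestOutcome
    permutation_p: float
    adjusted_p: float = float("nan")
    qvalue: float = float("nan")
    direction: Literal["up", "down"] = "up"
    n_permutations: int = 0
    exhaustive: bool = False
    seed: int | None = None
    branch_counts: dict[str, int] = field(default_factory=dict)


def _as_clean_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise DegenerateInputError(f"sample {name} needs >= 2 observations")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name} contains non-finite values")
    return arr


def f_variance_test(x: Sequence[float], y: Sequence[float]) -> FTestOutcome:
    """Two-sided F test for equality of variances, first sample over second.

    F = s1^2 / s2^2 against F(n1-1, n2-1); the two-sided p-value is
    2 * min(P(F <= f), P(F >= f)), capped at 1.
    """
    xa, ya = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    v1, v2 = xa.var(ddof=1), ya.var(ddof=1)
    if v1 == 0.0 or v2 == 0.0:
        raise DegenerateInputError("zero variance in a sample; F test undefined")
    f = v1 / v2
    df1, df2 = xa.size - 1, ya.size - 1
    cdf = stats.f.cdf(f, df1, df2)
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    return FTestOutcome(statistic=float(f), pvalue=float(p), df1=df1, df2=df2)


def student_t(x: Sequence[float], y: Sequence[float]) -> TTestOutcome:
    """Pooled-variance two-sample t test, df = n1 + n2 - 2."""
    xa, ya = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    n1, n2 = xa.size, ya.size
    v1, v2 = xa.var(ddof=1), ya.var(ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        raise DegenerateInputError("zero pooled variance; t test undefined")
    res = stats.ttest_ind(xa, ya, equal_var=True)
    return TTestOutcome(
        statistic=float(res.statistic),
        df=float(res.df),
        pvalue=float(res.pvalue),
        branch="pooled",
        mean1=float(xa.mean()),
        mean2=float(ya.mean()),
        var1=float(v1),
        var2=float(v2),
        n1=n1,
        n2=n2,
        pooled_sd=float(math.sqrt(pooled_var)),
    )


def welch_t(x: Sequence[float], y: Sequence[float]) -> TTestOutcome:
    """Welch's unequal-variance t test with Satterthwaite degrees of freedom."""
    xa, ya = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    v1, v2 = xa.var(ddof=1), ya.var(ddof=1)
    if v1 + v2 == 0.0:
        raise DegenerateInputError("both variances zero; t test undefined")
    res = stats.ttest_ind(xa, ya, equal_var=False)
    return TTestOutcome(
        statistic=float(res.statistic),
        df=float(res.df),
        pvalue=float(res.pvalue),
        branch="welch",
        mean1=float(xa.mean()),
        mean2=float(ya.mean()),
        var1=float(v1),
        var2=float(v2),
        n1=xa.size,
        n2=ya.size,
    )


def adaptive_t(
    x: Sequence[float], y: Sequence[float], f_alpha: float = 0.05
) -> TTestOutcome:
    """F-test-gated two-sample t test.

    If the F test for equal variances is not rejected at *f_alpha* the
    pooled-variance statistic is used, otherwise Welch's statistic.  The
    chosen branch and the F test outcome are recorded.
    """
    ft = f_variance_test(x, y)
    if ft.pvalue >= f_alpha:
        out = student_t(x, y)
    else:
        out = welch_t(x, y)
    return TTestOutcome(**{**out.__dict__, "f_test": ft})


# ---------------------------------------------------------------------------
# vectorized permutation machinery


def _group_stats(
    assign: np.ndarray,
    unit_sum: np.ndarray,
    unit_sumsq: np.ndarray,
    unit_n: np.ndarray,
) -> tuple[np.ndarray, ...]:
    """Group means/variances/sizes for each row of a boolean assignment matrix.

    Units (individuals) carry precomputed sums so replicate blocks move as
    one; a (B, U) boolean matrix selects group-1 units per permutation.
    """
    a = assign.astype(float)
    s1 = a @ unit_sum
    ss1 = a @ unit_sumsq
    n1 = a @ unit_n
    s2 = unit_sum.sum() - s1
    ss2 = unit_sumsq.sum() - ss1
    n2 = unit_n.sum() - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1, m2 = s1 / n1, s2 / n2
        v1 = (ss1 - s1**2 / n1) / (n1 - 1)
        v2 = (ss2 - s2**2 / n2) / (n2 - 1)
    return m1, m2, np.maximum(v1, 0.0), np.maximum(v2, 0.0), n1, n2


def _adaptive_pvalues(
    m1, m2, v1, v2, n1, n2, f_alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized adaptive-t p-values plus the branch mask (True = pooled).

    Permutations where either group variance collapses to zero get p = 1;
    such degenerate relabellings carry no evidence against the null.
    """
    degenerate = ~np.isfinite(v1) | ~np.isfinite(v2) | (v1 <= 0) | (v2 <= 0)
    v1s, v2s = np.where(degenerate, 1.0, v1), np.where(degenerate, 1.0, v2)

    fcdf = stats.f.cdf(v1s / v2s, n1 - 1, n2 - 1)
    f_p = np.minimum(1.0, 2.0 * np.minimum(fcdf, 1.0 - fcdf))
    pooled_mask = f_p >= f_alpha

    diff = m1 - m2
    # pooled branch
    pooled_var = ((n1 - 1) * v1s + (n2 - 1) * v2s) / (n1 + n2 - 2)
    se_pooled = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t_pooled = diff / se_pooled
    p_pooled = 2.0 * stats.t.sf(np.abs(t_pooled), n1 + n2 - 2)
    # welch branch
    w1, w2 = v1s / n1, v2s / n2
    se_welch = np.sqrt(w1 + w2)
    t_welch = diff / se_welch
    df_welch = (w1 + w2) ** 2 / (w1**2 / (n1 - 1) + w2**2 / (n2 - 1))
    p_welch = 2.0 * stats.t.sf(np.abs(t_welch), df_welch)

    p = np.where(pooled_mask, p_pooled, p_welch)
    p = np.where(degenerate, 1.0, p)
    return p, pooled_mask


def _unit_blocks(
    values: np.ndarray, units: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-unit sum, sum of squares and count (one unit per value if no ids)."""
    if units is None:
        return values.copy(), values**2, np.ones_like(values)
    units = np.asarray(units)
    uniq, inv = np.unique(units, return_inverse=True)
    s = np.zeros(uniq.size)
    ss = np.zeros(uniq.size)
    n = np.zeros(uniq.size)
    np.add.at(s, inv, values)
    np.add.at(ss, inv, values**2)
    np.add.at(n, inv, 1.0)
    return s, ss, n


def permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 1000,
    seed: int | np.random.Generator | None = 0,
    f_alpha: float = 0.05,
    estimator: Literal["plain", "plus-one"] = "plain",
    units_x: Sequence | None = None,
    units_y: Sequence | None = None,
) -> DiffTestResult:
    """Variance-adaptive permutation test for one protein.

    Group labels are shuffled *B* times preserving group sizes; at every
    relabelling the F-branch decision and the t-test p-value are recomputed,
    and the permutation p-value is ``#{permuted p <= observed p} / B``
    (``estimator="plain"``) or the positively biased-corrected
    ``(1 + count) / (1 + B)`` (``estimator="plus-one"``).  When units
    (individual ids) are supplied all values of one individual are permuted
    as a block, and group sizes are preserved in units.  If the number of
    distinct relabellings is at most *B*, all of them are enumerated and the
    p-value is exact.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    xa, ya = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    if xa.size + ya.size < 4:
        raise ValueError("need at least 4 observations in total")
    observed = adaptive_t(xa, ya, f_alpha=f_alpha)

    sx, ssx, nx = _unit_blocks(xa, None if units_x is None else units_x)
    sy, ssy, ny = _unit_blocks(ya, None if units_y is None else units_y)
    unit_sum = np.concatenate([sx, sy])
    unit_sumsq = np.concatenate([ssx, ssy])
    unit_n = np.concatenate([nx, ny])
    u1, u_total = sx.size, sx.size + sy.size

    n_distinct = math.comb(u_total, u1)
    exhaustive = n_distinct <= B
    if exhaustive:
        assign = np.zeros((n_distinct, u_total), dtype=bool)
        for i, idx in enumerate(combinations(range(u_total), u1)):
            assign[i, list(idx)] = True
        n_perm = n_distinct
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        order = np.argsort(rng.random((B, u_total)), axis=1)
        assign = np.zeros((B, u_total), dtype=bool)
        np.put_along_axis(assign, order[:, :u1], True, axis=1)
        n_perm = B

    m1, m2, v1, v2, n1, n2 = _group_stats(assign, unit_sum, unit_sumsq, unit_n)
    if np.any((v1 <= 0) | (v2 <= 0)):
        logger.debug("degenerate permuted samples encountered; their p set to 1")
    perm_p, pooled_mask = _adaptive_pvalues(m1, m2, v1, v2, n1, n2, f_alpha)

    count = int(np.sum(perm_p <= observed.pvalue + 1e-12))
    if estimator == "plain":
        p = count / n_perm
    elif estimator == "plus-one":
        p = (1 + count) / (1 + n_perm)
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")

    return DiffTestResult(
        protein_id="",
        observed=observed,
        permutation_p=float(p),
        direction="up" if observed.mean2 >= observed.mean1 else "down",
        n_permutations=n_perm,
        exhaustive=exhaustive,
        seed=seed if isinstance(seed, int) else None,
        branch_counts={
            "pooled": int(pooled_mask.sum()),
            "welch": int(n_perm - pooled_mask.sum()),
        },
    )


def _batch_permutation_pvalues(
    h_values: np.ndarray,
    c_values: np.ndarray,
    B: int,
    rng: np.random.Generator,
    f_alpha: float,
    estimator: str,
    units_h: np.ndarray | None,
    units_c: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Permutation p-values for all proteins at once, sharing one set of
    label shuffles across proteins.

    Shared shuffles make the whole screen a few matrix products: per-unit
    sum/sum-of-squares matrices (proteins x units) against a (B x units)
    assignment matrix.  The Monte-Carlo noise is then correlated across
    proteins (as in other permutation screens that reuse shuffles), which
    does not bias any single protein's p-value.

    Returns (perm_p, t_obs, df_obs, p_obs, pooled_obs_mask, exhaustive).
    """
    P = h_values.shape[0]

    def unit_mats(vals: np.ndarray, units) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if units is None:
            return vals, vals**2, np.ones(vals.shape[1])
        uniq, inv = np.unique(np.asarray(units), return_inverse=True)
        ind = np.zeros((vals.shape[1], uniq.size))
        ind[np.arange(vals.shape[1]), inv] = 1.0
        return vals @ ind, (vals**2) @ ind, ind.sum(axis=0)

    S_h, SS_h, n_h = unit_mats(h_values, units_h)
    S_c, SS_c, n_c = unit_mats(c_values, units_c)
    S = np.concatenate([S_h, S_c], axis=1)  # (P, U)
    SS = np.concatenate([SS_h, SS_c], axis=1)
    counts = np.concatenate([n_h, n_c])
    u1, U = S_h.shape[1], S.shape[1]

    n_distinct = math.comb(U, u1)
    exhaustive = n_distinct <= B
    if exhaustive:
        assign = np.zeros((n_distinct, U))
        for i, idx in enumerate(combinations(range(U), u1)):
            assign[i, list(idx)] = 1.0
    else:
        order = np.argsort(rng.random((B, U)), axis=1)
        assign = np.zeros((B, U))
        np.put_along_axis(assign, order[:, :u1], 1.0, axis=1)
    n_perm = assign.shape[0]

    tot_s = S.sum(axis=1, keepdims=True)
    tot_ss = SS.sum(axis=1, keepdims=True)
    tot_n = counts.sum()
    s1 = S @ assign.T  # (P, n_perm)
    ss1 = SS @ assign.T
    n1 = counts @ assign.T  # (n_perm,)
    s2, ss2, n2 = tot_s - s1, tot_ss - ss1, tot_n - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1, m2 = s1 / n1, s2 / n2
        v1 = (ss1 - s1**2 / n1) / (n1 - 1)
        v2 = (ss2 - s2**2 / n2) / (n2 - 1)
    v1, v2 = np.maximum(v1, 0.0), np.maximum(v2, 0.0)
    perm_p, _ = _adaptive_pvalues(m1, m2, v1, v2, n1, n2, f_alpha)

    # observed statistics, vectorized over proteins
    obs_assign = np.zeros((1, U))
    obs_assign[0, :u1] = 1.0
    so, sso = S @ obs_assign.T, SS @ obs_assign.T
    no1 = float(counts[:u1].sum())
    no2 = tot_n - no1
    with np.errstate(divide="ignore", invalid="ignore"):
        mo1, mo2 = so[:, 0] / no1, (tot_s[:, 0] - so[:, 0]) / no2
        vo1 = (sso[:, 0] - so[:, 0] ** 2 / no1) / (no1 - 1)
        vo2 = (tot_ss[:, 0] - sso[:, 0] - (tot_s[:, 0] - so[:, 0]) ** 2 / no2) / (no2 - 1)
    vo1, vo2 = np.maximum(vo1, 0.0), np.maximum(vo2, 0.0)
    p_obs, pooled_obs = _adaptive_pvalues(
        mo1, mo2, vo1, vo2, np.full(P, no1), np.full(P, no2), f_alpha
    )
    diff = mo1 - mo2
    pooled_var = ((no1 - 1) * vo1 + (no2 - 1) * vo2) / (no1 + no2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_pooled = diff / np.sqrt(pooled_var * (1 / no1 + 1 / no2))
        w1, w2 = vo1 / no1, vo2 / no2
        t_welch = diff / np.sqrt(w1 + w2)
        df_welch = (w1 + w2) ** 2 / (w1**2 / (no1 - 1) + w2**2 / (no2 - 1))
    t_obs = np.where(pooled_obs, t_pooled, t_welch)
    df_obs = np.where(pooled_obs, no1 + no2 - 2, df_welch)
    obs_degenerate = (vo1 <= 0) | (vo2 <= 0)
    t_obs = np.where(obs_degenerate, np.nan, t_obs)
    df_obs = np.where(obs_degenerate, np.nan, df_obs)

    count = (perm_p <= p_obs[:, None] + 1e-12).sum(axis=1)
    if estimator == "plain":
        p = count / n_perm
    else:
        p = (1 + count) / (1 + n_perm)
    return p, t_obs, df_obs, p_obs, pooled_obs, exhaustive


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalue(
    pvalues: Sequence[float],
    lambda_grid: Sequence[float] | None = None,
    pi0: float | None = None,
) -> tuple[np.ndarray, float]:
    """Storey–Tibshirani q-values with smoothed pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the grid
    0, 0.05, ..., 0.90, a cubic smoothing spline is fitted, and pi0 is the
    spline value at the largest lambda, clamped to (0, 1].  For fewer than
    100 p-values the estimate is too unstable and pi0 = 1 is used (making
    q identical to BH-adjusted p).  ``pi0`` may be forced explicitly.

    Returns (q-values in input order, pi0 estimate).
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")

    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            if lambda_grid is None:
                lambda_grid = np.arange(0.0, 0.9001, 0.05)
            lam = np.asarray(lambda_grid, dtype=float)
            pi0_lam = np.array(
                [np.mean(p > l) / (1.0 - l) for l in lam]  # noqa: E741
            )
            from scipy.interpolate import UnivariateSpline

            spline = UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(spline(lam.max()))
    if pi0 <= 0.0:
        warnings.warn("pi0 estimate <= 0; clamping to 1/m", stacklevel=2)
        pi0 = 1.0 / m
    pi0 = min(1.0, float(pi0))

    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def declare_significant(
    results: Sequence[DiffTestResult] | pd.DataFrame,
    cutoffs: SignificanceCutoffs = SignificanceCutoffs(),
) -> dict[int, dict]:
    """Nested significant-protein sets at the three q-value cutoffs.

    Returns ``{k: {"threshold", "proteins", "expected_false_positives"}}``
    for k = 1 (loosest) .. 3 (strictest); the expected number of false
    positives at a cutoff is threshold x (number declared).
    """
    if isinstance(results, pd.DataFrame):
        ids = results["protein_id"].tolist()
        qs = results["q"].to_numpy(dtype=float)
    else:
        ids = [r.protein_id for r in results]
        qs = np.array([r.qvalue for r in results], dtype=float)
    out: dict[int, dict] = {}
    for k, thr in enumerate(cutoffs.thresholds, start=1):
        sel = {pid for pid, q in zip(ids, qs) if q < thr}
        out[k] = {
            "threshold": thr,
            "proteins": sel,
            "expected_false_positives": thr * len(sel),
        }
    return out


def differential_test(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    subtype: str,
    B: int = 1000,
    seed: int = 0,
    f_alpha: float = 0.05,
    estimator: Literal["plain", "plus-one"] = "plain",
    cancer_columns: Sequence[str] | None = None,
    unit: Literal["individual", "replicate"] = "individual",
    share_permutations: bool = False,
) -> pd.DataFrame:
    """Run the three-step screen for every protein: healthy vs one subtype.

    *matrix* is proteins x sample-replicate columns of normalized log2
    intensities; *annotation* has one row per column with ``sample_id``,
    ``individual_id``, ``group`` and ``subtype``.  Each protein gets its own
    permutation stream spawned from *seed*, so results do not depend on
    protein order.  ``unit`` selects the exchangeable block: by default all
    replicate injections of an individual are permuted together;
    ``"replicate"`` permutes columns independently (used for the
    single-patient screen, where individual-level blocks admit far too few
    relabellings to rank proteins).  Returns a frame with columns
    protein_id, t, df, branch, p_obs, p_perm, p_bh, q, direction.
    """
    ann = annotation.set_index("sample_id")
    healthy_cols = [
        c for c in matrix.columns if str(ann.loc[c, "group"]).lower() == "healthy"
    ]
    if cancer_columns is None:
        cancer_columns = [
            c
            for c in matrix.columns
            if str(ann.loc[c, "group"]).lower() == "cancer"
            and str(ann.loc[c, "subtype"]) == str(subtype)
        ]
    if not healthy_cols:
        raise ValueError("no healthy columns found")
    if not cancer_columns:
        raise ValueError(f"no columns for subtype {subtype!r}")

    if unit == "individual":
        units_h = ann.loc[healthy_cols, "individual_id"].to_numpy()
        units_c = ann.loc[list(cancer_columns), "individual_id"].to_numpy()
    elif unit == "replicate":
        units_h = units_c = None
    else:
        raise ValueError(f"unknown permutation unit: {unit!r}")
    h_values = matrix[healthy_cols].to_numpy(dtype=float)
    c_values = matrix[list(cancer_columns)].to_numpy(dtype=float)

    if share_permutations:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        perm_p, t_obs, df_obs, p_obs, pooled_obs, exhaustive = (
            _batch_permutation_pvalues(
                h_values,
                c_values,
                B,
                rng,
                f_alpha,
                estimator,
                units_h,
                units_c,
            )
        )
        degenerate = ~np.isfinite(t_obs)
        table = pd.DataFrame(
            {
                "protein_id": matrix.index,
                "t": np.where(degenerate, np.nan, t_obs),
                "df": np.where(degenerate, np.nan, df_obs),
                "branch": np.where(
                    degenerate, "degenerate", np.where(pooled_obs, "pooled", "welch")
                ),
                "p_obs": p_obs,
                "p_perm": perm_p,
                "direction": np.where(
                    c_values.mean(axis=1) >= h_values.mean(axis=1), "up", "down"
                ),
                "n_permutations": B,
                "exhaustive": exhaustive,
            }
        )
        if degenerate.any():
            logger.info(
                "%d/%d proteins untestable (zero within-group variance); p set to 1",
                int(degenerate.sum()),
                len(table),
            )
        table["p_bh"] = bh_adjust(table["p_perm"].to_numpy())
        q, pi0 = storey_qvalue(table["p_perm"].to_numpy())
        table["q"] = q
        table.attrs["pi0"] = pi0
        table.attrs["subtype"] = str(subtype)
        return table

    children = np.random.SeedSequence(seed).spawn(len(matrix.index))
    rows = []
    n_degenerate = 0
    for i, pid in enumerate(matrix.index):
        rng = np.random.default_rng(children[i])
        try:
            res = permutation_test(
                h_values[i],
                c_values[i],
                B=B,
                seed=rng,
                f_alpha=f_alpha,
                estimator=estimator,
                units_x=units_h,
                units_y=units_c,
            )
        except DegenerateInputError:
            # a group with no within-group spread (e.g. tied normalized
            # replicate values) carries no testable evidence for this protein
            n_degenerate += 1
            rows.append(
                {
                    "protein_id": pid,
                    "t": np.nan,
                    "df": np.nan,
                    "branch": "degenerate",
                    "p_obs": 1.0,
                    "p_perm": 1.0,
                    "direction": "up"
                    if np.mean(c_values[i]) >= np.mean(h_values[i])
                    else "down",
                    "n_permutations": 0,
                    "exhaustive": False,
                }
            )
            continue
        rows.append(
            {
                "protein_id": pid,
                "t": res.observed.statistic,
                "df": res.observed.df,
                "branch": res.observed.branch,
                "p_obs": res.observed.pvalue,
                "p_perm": res.permutation_p,
                "direction": res.direction,
                "n_permutations": res.n_permutations,
                "exhaustive": res.exhaustive,
            }
        )
    if n_degenerate:
        logger.info(
            "%d/%d proteins untestable (zero within-group variance); p set to 1",
            n_degenerate,
            len(rows),
        )
    table = pd.DataFrame(rows)
    table["p_bh"] = bh_adjust(table["p_perm"].to_numpy())
    q, pi0 = storey_qvalue(table["p_perm"].to_numpy())
    table["q"] = q
    table.attrs["pi0"] = pi0
    table.attrs["subtype"] = str(subtype)
    return table
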