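"""Intensity normalization, peptide aggregation and subtype effect estimation.

Peak intensities arrive log2-transformed; quantile normalization forces all
sample-replicate columns onto a common empirical distribution before any
cross-sample comparison.  Peptides mapping to the same protein are averaged
into a protein-level log2 intensity.  Per-protein subtype fixed effects are
then estimated from the mixed model

    y_ijk = mu + S_j + I_i + e_ijk

with S_j the fixed subtype effect (sum-to-zero coded so effect vectors are
comparable across proteins), I_i a random intercept per individual, and
e_ijk the residual over replicate injections.  Because every individual
belongs to exactly one subtype, an extra subtype-within-individual random
term is confounded with the individual intercept and is absorbed by it.
Fitting is restricted maximum likelihood (REML) via statsmodels MixedLM;
designs without replication degrade to fixed effects only, and fits that
fail to converge fall back to per-subtype means of per-individual means
(flagged in the output).
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_normalize",
    "aggregate_to_protein",
    "fit_subtype_effects",
]

#: pipeline stage markers for the intensity scale
SCALE_RAW = "raw"
SCALE_LOG2 = "log2"
SCALE_NORMALIZED = "log2-quantile-normalized"


def _get_scale(matrix: pd.DataFrame) -> str:
    return matrix.attrs.get("scale", SCALE_LOG2)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize log2 intensity columns.

    After normalization every column holds the same multiset of values: the
    across-column means of the rank-ordered values.  Ties within a column
    receive the mean of the reference values their rank range spans.
    Missing values are left missing; a column's observed values are then
    mapped onto the reference distribution by interpolation at their
    quantile positions.
    """
    scale = _get_scale(matrix)
    if scale == SCALE_NORMALIZED:
        logger.info("matrix already quantile-normalized; returning a copy")
        return matrix.copy()
    if scale != SCALE_LOG2:
        raise ValueError(f"quantile normalization expects log2 scale, got {scale!r}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns to normalize")
    for col in matrix.columns:
        if matrix[col].isna().all():
            raise ValueError(f"column {col!r} has no observed values")

    values = matrix.to_numpy(dtype=float)
    n_rows, _ = values.shape
    if not np.isnan(values).any():
        ref = np.sort(values, axis=0).mean(axis=1)
        out = np.empty_like(values)
        for j in range(values.shape[1]):
            col = values[:, j]
            order = np.argsort(col, kind="mergesort")
            by_rank = np.empty(n_rows)
            by_rank[order] = ref
            # tied values share the mean of the reference values they span
            out[:, j] = (
                pd.Series(by_rank).groupby(pd.Series(col)).transform("mean").to_numpy()
            )
    else:
        # pooled reference distribution on a common quantile grid
        grid = (np.arange(n_rows) + 0.5) / n_rows
        cols_sorted = []
        for j in range(values.shape[1]):
            obs = np.sort(values[~np.isnan(values[:, j]), j])
            q = (np.arange(obs.size) + 0.5) / obs.size
            cols_sorted.append(np.interp(grid, q, obs))
        ref = np.mean(cols_sorted, axis=0)
        out = np.full_like(values, np.nan)
        for j in range(values.shape[1]):
            mask = ~np.isnan(values[:, j])
            ranks = rankdata(values[mask, j], method="average")
            q = (ranks - 0.5) / mask.sum()
            out[mask, j] = np.interp(q, grid, ref)

    result = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    result.attrs = dict(matrix.attrs)
    result.attrs["scale"] = SCALE_NORMALIZED
    return result


def aggregate_to_protein(
    peptide_matrix: pd.DataFrame, peptide_to_protein: Mapping[str, str]
) -> pd.DataFrame:
    """Average normalized log2 peptide rows into protein rows.

    Every peptide must map to exactly one protein; unmapped peptides are an
    error (listed).  Proteins with a single peptide pass through unchanged.
    """
    if not peptide_to_protein:
        raise ValueError("empty peptide-to-protein mapping")
    unmapped = [p for p in peptide_matrix.index if p not in peptide_to_protein]
    if unmapped:
        raise ValueError(f"unmapped peptides: {unmapped}")
    groups = pd.Series(
        {p: peptide_to_protein[p] for p in peptide_matrix.index}, name="protein"
    )
    out = peptide_matrix.groupby(groups).mean()
    out.index.name = "protein_id"
    out.attrs = dict(peptide_matrix.attrs)
    return out


def _mom_components(
    y: np.ndarray, individuals: np.ndarray, subtype_of_ind: Mapping
) -> tuple[float, float]:
    """Method-of-moments (sigma_I, sigma_e) for the balanced random-intercept model.

    sigma_e^2 from the within-individual mean square; sigma_I^2 from the
    between-individual (within-subtype) mean square minus sigma_e^2 / r,
    truncated at zero.
    """
    uniq = np.unique(individuals)
    means, counts = {}, {}
    ss_within, df_within = 0.0, 0
    for ind in uniq:
        vals = y[individuals == ind]
        means[ind] = float(vals.mean())
        counts[ind] = vals.size
        ss_within += float(((vals - vals.mean()) ** 2).sum())
        df_within += vals.size - 1
    sigma_e2 = ss_within / df_within if df_within > 0 else float("nan")
    by_sub: dict = {}
    for ind in uniq:
        by_sub.setdefault(subtype_of_ind[ind], []).append(means[ind])
    ss_between, df_between = 0.0, 0
    for vals in by_sub.values():
        arr = np.asarray(vals)
        if arr.size > 1:
            ss_between += float(((arr - arr.mean()) ** 2).sum())
            df_between += arr.size - 1
    r_bar = float(np.mean(list(counts.values())))
    if df_between > 0 and np.isfinite(sigma_e2):
        ms_between = ss_between / df_between
        sigma_i2 = max(0.0, ms_between - sigma_e2 / r_bar)
    else:
        sigma_i2 = float("nan")
    return (
        float(np.sqrt(sigma_i2)) if np.isfinite(sigma_i2) else float("nan"),
        float(np.sqrt(sigma_e2)) if np.isfinite(sigma_e2) else float("nan"),
    )


def _means_fallback(
    y: np.ndarray, individuals: np.ndarray, subtype_of_ind: Mapping, levels: Sequence[str]
) -> tuple[float, dict[str, float]]:
    """Grand mean and sum-to-zero subtype effects from means of individual means."""
    ind_means: dict = {}
    for ind in np.unique(individuals):
        ind_means[ind] = float(np.mean(y[individuals == ind]))
    sub_means = {
        s: float(np.mean([m for i, m in ind_means.items() if subtype_of_ind[i] == s]))
        for s in levels
    }
    mu = float(np.mean(list(sub_means.values())))
    return mu, {s: sub_means[s] - mu for s in levels}


def fit_subtype_effects(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    method: str = "auto",
) -> pd.DataFrame:
    """Estimate per-protein subtype fixed effects.

    Parameters
    ----------
    matrix
        Normalized log2 intensities, proteins x sample-replicate columns.
        Only columns of cancer samples with a non-empty subtype are used.
    annotation
        One row per column: sample_id, individual_id, group, subtype.
    method
        ``"auto"`` (default) detects balanced complete designs — equal
        replicate counts per individual, no missing values — where the REML
        fixed effects coincide exactly with per-subtype means of
        per-individual means, and uses that closed form with
        method-of-moments variance components; unbalanced or incomplete
        data fall through to ``"reml"``.  ``"reml"`` forces the iterative
        mixed-model fit; ``"means"`` forces the closed form.

    Returns a frame indexed by protein with columns ``mu``, one ``S_<label>``
    per subtype (sum-to-zero), ``sigma_I``, ``sigma_e``, ``converged`` and
    ``method``.
    """
    ann = annotation.set_index("sample_id")
    cols = [
        c
        for c in matrix.columns
        if c in ann.index
        and str(ann.loc[c, "group"]).lower() == "cancer"
        and str(ann.loc[c, "subtype"]) not in ("", "nan")
    ]
    if not cols:
        raise ValueError("no annotated cancer columns in matrix")
    subtypes = ann.loc[cols, "subtype"].astype(str)
    from .subtypes import SUBTYPE_ORDER

    present = set(subtypes.unique())
    canonical = [s.value for s in SUBTYPE_ORDER if s.value in present]
    levels = canonical + sorted(present - set(canonical))
    if len(levels) < 2:
        raise ValueError("need at least two subtypes to estimate effects")
    individuals = ann.loc[cols, "individual_id"].astype(str).to_numpy()
    subtype_of_ind = {
        i: s for i, s in zip(individuals, subtypes.to_numpy())
    }

    rep_counts = pd.Series(individuals).value_counts()
    if method == "auto":
        balanced = rep_counts.nunique() == 1 and not matrix[cols].isna().any().any()
        method = "means" if balanced else "reml"
    if rep_counts.max() == 1 and method == "reml":
        logger.warning(
            "one observation per individual: random intercept confounded with "
            "residual; using means estimator"
        )
        method = "means"

    data_template = pd.DataFrame(
        {
            "individual": individuals,
            "subtype": pd.Categorical(subtypes.to_numpy(), categories=levels),
        }
    )
    values = matrix[cols].to_numpy(dtype=float)

    rows = []
    for i, pid in enumerate(matrix.index):
        y = values[i]
        mask = np.isfinite(y)
        rec: dict = {"protein_id": pid, "method": method, "converged": True}
        mu_f, eff_f = _means_fallback(
            y[mask], individuals[mask], subtype_of_ind, levels
        )
        if method == "means" or np.nanvar(y) == 0.0:
            mu, eff = mu_f, eff_f
            rec["method"] = "means"
            rec["sigma_I"], rec["sigma_e"] = _mom_components(
                y[mask], individuals[mask], subtype_of_ind
            )
        else:
            import statsmodels.formula.api as smf

            df = data_template[mask].copy()
            df["y"] = y[mask]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm(
                        "y ~ C(subtype, Sum)", data=df, groups=df["individual"]
                    )
                    fit = model.fit(reml=True, method="lbfgs")
                mu = float(fit.params["Intercept"])
                eff = {}
                for lev in levels[:-1]:
                    eff[lev] = float(fit.params[f"C(subtype, Sum)[S.{lev}]"])
                eff[levels[-1]] = -sum(eff.values())
                rec["sigma_I"] = float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0)))
                rec["sigma_e"] = float(np.sqrt(max(fit.scale, 0.0)))
                rec["converged"] = bool(fit.converged)
                if not fit.converged:
                    raise RuntimeError("non-convergence")
            except Exception:  # fall back, flagged
                mu, eff = mu_f, eff_f
                rec.update(
                    method="means", converged=False, sigma_I=np.nan, sigma_e=np.nan
                )
        rec["mu"] = mu
        for lev in levels:
            rec[f"S_{lev}"] = eff[lev]
        rows.append(rec)

    out = pd.DataFrame(rows).set_index("protein_id")
    order = ["mu"] + [f"S_{lev}" for lev in levels] + [
        "sigma_I",
        "sigma_e",
        "converged",
        "method",
    ]
    return out[order]
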