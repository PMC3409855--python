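"""Quantile normalisation, covariate-adjusted fold-change differential
expression with FDR control, and extreme-group sample selection.

The differential-expression rule is the fold-change-plus-FDR criterion used
in leukocyte array studies: a transcript is called regulated when its
covariate-adjusted group difference on the log2 scale corresponds to at
least a 1.5-fold change AND its Benjamini–Hochberg q-value is at or below
5%. Both thresholds are configurable, and either-only modes are available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quantile_normalize",
    "select_matched_extremes",
    "adjusted_differential_expression",
    "bh_fdr",
    "call_de",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) to share one empirical distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; tied values within a column receive the mean of their
    rank range. Idempotent: a second application is a no-op.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile normalisation requires a complete matrix")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to quantile normalise")
    vals = matrix.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)  # mean of k-th smallest across columns
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        order = np.argsort(vals[:, j], kind="stable")
        sv = vals[order, j]
        # tie groups share the mean of ref over their occupied rank range
        grp = np.concatenate([[0], np.cumsum(sv[1:] != sv[:-1])])
        means = np.bincount(grp, weights=ref) / np.bincount(grp)
        out[order, j] = means[grp]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def select_matched_extremes(
    patients: pd.DataFrame,
    k_high: int = 15,
    k_low: int = 16,
    match_on: tuple[str, ...] = ("sex", "smoking", "risk_group"),
    age_col: str = "age",
    cesd_col: str = "cesd",
    cutoff: float = 16,
) -> tuple[list[str], list[str]]:
    """Pick the k_high highest scorers (>= cutoff) and k_low matched low scorers.

    The high group is the top-``k_high`` CES-D scores at or above the
    screening cutoff. The low group comes from the lowest scorers below the
    cutoff: starting from a candidate pool of the ``2·k_low`` lowest scores
    (expanded by ``k_low`` whenever matching stalls), the selection cycles
    over the high group in descending score order and each round picks the
    unused candidate in the same exact stratum of `match_on` with the
    nearest age (ties broken by lowest CES-D, then index order), until
    ``k_low`` are selected.

    Returns (high_ids, low_ids). Raises if matching is infeasible even with
    the full low pool, listing the unmatched strata.
    """
    df = patients.set_index("patient_id") if "patient_id" in patients.columns else patients
    high_pool = df[df[cesd_col] >= cutoff].sort_values(
        [cesd_col], ascending=False, kind="stable"
    )
    if len(high_pool) < k_high:
        raise ValueError(
            f"only {len(high_pool)} patients at CES-D >= {cutoff}; need {k_high}"
        )
    high = high_pool.head(k_high)
    low_all = df[df[cesd_col] < cutoff].sort_values([cesd_col], kind="stable")
    if len(low_all) < k_low:
        raise ValueError(f"only {len(low_all)} low scorers; need {k_low}")
    if k_high == 0 or k_low == 0:
        # nothing to match against: plain rank selection of lowest scorers
        return list(high.index), list(low_all.head(k_low).index)

    hi_rows = list(high.iterrows())
    pool_size = min(2 * k_low, len(low_all))
    while True:
        pool = low_all.head(pool_size)
        chosen: list = []
        used: set = set()
        unmatched: set = set()
        stalled = False
        i = 0
        progress_in_cycle = False
        while len(chosen) < k_low:
            _, hrow = hi_rows[i % len(hi_rows)]
            if i and i % len(hi_rows) == 0:
                if not progress_in_cycle:
                    stalled = True
                    break
                progress_in_cycle = False
            i += 1
            stratum = tuple(hrow[c] for c in match_on)
            cand = pool[~pool.index.isin(used)]
            for c, v in zip(match_on, stratum):
                cand = cand[cand[c] == v]
            if cand.empty:
                unmatched.add(stratum)
                continue
            cand = cand.assign(_agediff=(cand[age_col] - hrow[age_col]).abs())
            pick = cand.sort_values(["_agediff", cesd_col], kind="stable").index[0]
            chosen.append(pick)
            used.add(pick)
            progress_in_cycle = True
        if len(chosen) == k_low:
            return list(high.index), chosen
        if stalled and pool_size >= len(low_all):
            raise ValueError(
                f"matching infeasible; unmatched strata: {sorted(unmatched)}"
            )
        pool_size = min(pool_size + k_low, len(low_all))


def _design_matrix(group, covariates: pd.DataFrame | None):
    g = np.asarray(group, dtype=float)
    if np.unique(g).size < 2:
        raise ValueError("group indicator must have both levels")
    cols = {"intercept": np.ones_like(g), "group": g}
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.copy()
        for c in list(cov.columns):
            if not pd.api.types.is_numeric_dtype(cov[c]):
                # indicator coding; reference level = most frequent
                ref = cov[c].mode().iloc[0]
                for lvl in sorted(x for x in cov[c].unique() if x != ref):
                    cols[f"{c}[{lvl}]"] = (cov[c] == lvl).to_numpy(dtype=float)
                cov = cov.drop(columns=c)
        for c in cov.columns:
            cols[c] = cov[c].to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    return X, names


def adjusted_differential_expression(
    log2_matrix: pd.DataFrame,
    group,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene linear model of log2 expression on group + covariates.

    Returns a table with the adjusted log2 group difference (high minus
    low), the fold change ``2**diff``, and a two-sided t-test p-value for
    the group coefficient. Gene order follows the input matrix.
    """
    X, _ = _design_matrix(group, covariates)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} samples for {p} design columns")
    Y = log2_matrix.to_numpy(dtype=float).T  # samples × genes
    if Y.shape[0] != n:
        raise ValueError("matrix columns must align with the group vector")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # p × genes
    resid = Y - X @ B
    df_resid = n - p
    sigma2 = (resid**2).sum(axis=0) / df_resid
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    diff = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf))
    pvals = 2 * stats.t.sf(np.abs(tstat), df=df_resid)
    return pd.DataFrame(
        {
            "gene": log2_matrix.index,
            "log2_diff": diff,
            "fold": 2.0**diff,
            "p": pvals,
        }
    ).set_index("gene")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q is monotone in p and lies in [0, 1]; input order is preserved.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_de(
    results: pd.DataFrame,
    fc_threshold: float = 1.5,
    fdr_level: float = 0.05,
    require_fold: bool = True,
    require_fdr: bool = True,
) -> pd.DataFrame:
    """Classify each gene as up, down, or none.

    Up: fold >= ``fc_threshold`` (and q <= ``fdr_level`` when coupled);
    down: fold <= 1/``fc_threshold`` symmetric on the log scale. Adds
    ``q`` and ``call`` columns to a copy of `results`.
    """
    if fc_threshold <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    if not (require_fold or require_fdr):
        raise ValueError("at least one of the fold / FDR criteria must apply")
    out = results.copy()
    out["q"] = bh_fdr(out["p"].to_numpy())
    up = np.ones(len(out), dtype=bool)
    down = np.ones(len(out), dtype=bool)
    if require_fold:
        up &= out["fold"].to_numpy() >= fc_threshold
        down &= out["fold"].to_numpy() <= 1.0 / fc_threshold
    if require_fdr:
        sig = out["q"].to_numpy() <= fdr_level
        up &= sig
        down &= sig
    if require_fold:
        pass
    else:  # direction from the sign of the difference
        d = out["log2_diff"].to_numpy()
        up &= d > 0
        down &= d < 0
    out["call"] = np.where(up, "up", np.where(down, "down", "none"))
    return out
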