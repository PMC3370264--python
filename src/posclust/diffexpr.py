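"""Selection of significantly regulated transcripts from replicated intensities.

The filter chain mirrors the classical two-colour-era microarray workflow:

1. quantile normalization — every sample's intensity distribution is forced
   onto the common reference (the row-wise mean of the sorted columns);
2. a replicate-consistency filter — a gene is dropped when the coefficient
   of variation of its replicates exceeds a threshold (default 20%) in
   either condition ("SD > 20% within replicates" read as CV, since an
   absolute SD on arbitrary intensity units is not meaningful);
3. per-gene fold change of condition means and a Welch two-sample t-test on
   log2 intensities (the test is pluggable: replicated designs of this era
   delegated testing to vendor software, so no single test is canonical);
4. Benjamini-Hochberg step-up FDR adjustment;
5. selection at fold >= 2 and q <= 0.05 in the requested direction.

The result is a per-gene table (the ``DETable``) carrying means, CVs, fold
change, direction, p, q and every filter flag, so that any step can be
audited or re-thresholded without recomputation.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneList, ValidationError

__all__ = [
    "quantile_normalize",
    "cv_filter",
    "fold_and_test",
    "bh_adjust",
    "build_de_table",
    "select_regulated",
    "DE_COLUMNS",
]

DE_COLUMNS = [
    "mean_control", "mean_treatment", "fold_change", "direction",
    "cv_control", "cv_treatment", "p_value", "q_value",
    "passes_cv_filter", "passes_fold", "passes_fdr", "selected",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force all samples onto the common quantile reference.

    The reference is the row-wise mean of the per-sample sorted intensity
    vectors; each sample's values are replaced by the reference value at
    their rank.  Ties within a sample receive the mean of the reference
    values at the tied ranks, which makes the operation idempotent.
    """
    X = matrix.values.to_numpy(float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n_genes)
        ranked[order] = reference
        # average reference values over tied input values
        s = pd.Series(ranked)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.design.copy())


# ---------------------------------------------------------------------------
# filters and tests
# ---------------------------------------------------------------------------

def _condition_blocks(matrix: ExpressionMatrix) -> dict[str, np.ndarray]:
    return {
        cond: matrix.values[matrix.samples_of(cond)].to_numpy(float)
        for cond in ("control", "treatment")
    }


def cv_filter(matrix: ExpressionMatrix, threshold: float = 0.20) -> pd.DataFrame:
    """Per-gene replicate-consistency flags.

    A gene passes iff in *every* condition sd(replicates)/mean(replicates)
    <= threshold (sample SD, n-1 denominator).  A zero replicate mean fails
    the gene with reason ``zero_mean`` rather than raising.  Needs >= 2
    replicates per condition.
    """
    blocks = _condition_blocks(matrix)
    for cond, block in blocks.items():
        if block.shape[1] < 2:
            raise ValidationError(f"cv_filter needs >= 2 replicates in {cond!r}")
    n = len(matrix.values)
    passes = np.ones(n, bool)
    reason = np.array([""] * n, dtype=object)
    cvs = {}
    for cond, block in blocks.items():
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean != 0, sd / mean, np.inf)
        cvs[cond] = cv
        zero = mean == 0
        fail = zero | (cv > threshold)
        reason[fail & passes] = np.where(zero[fail & passes], "zero_mean", f"cv>{threshold}")
        passes &= ~fail
    return pd.DataFrame(
        {
            "cv_control": cvs["control"],
            "cv_treatment": cvs["treatment"],
            "passes_cv_filter": passes,
            "cv_fail_reason": reason,
        },
        index=matrix.values.index,
    )


def welch_t_log2(control: np.ndarray, treatment: np.ndarray) -> np.ndarray:
    """Welch two-sample t on log2 intensities, vectorised over genes."""
    import warnings

    with warnings.catch_warnings():
        # near-identical replicate vectors trigger a precision warning; the
        # resulting large p-values are exactly what we want for such genes
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(np.log2(treatment), np.log2(control), axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def fold_and_test(
    matrix: ExpressionMatrix,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_t_log2,
) -> pd.DataFrame:
    """Per-gene fold change, direction and p-value from condition means.

    fold_change = max(m_t/m_c, m_c/m_t) >= 1; direction follows the sign of
    m_t - m_c (``none`` when equal).  With fewer than 2 replicates in a
    condition the p-value is reported missing (NaN) and the gene can never
    be selected.
    """
    blocks = _condition_blocks(matrix)
    mc = blocks["control"].mean(axis=1)
    mt = blocks["treatment"].mean(axis=1)
    ratio = mt / mc
    fold = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(mt > mc, "up", np.where(mt < mc, "down", "none"))
    if min(b.shape[1] for b in blocks.values()) < 2:
        p = np.full(len(mc), np.nan)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = test(blocks["control"], blocks["treatment"])
        # identical replicate vectors give 0/0 -> no evidence of change
        p = np.where(np.isnan(p) & (mt == mc), 1.0, p)
    return pd.DataFrame(
        {
            "mean_control": mc,
            "mean_treatment": mt,
            "fold_change": fold,
            "direction": direction,
            "p_value": p,
        },
        index=matrix.values.index,
    )


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q(i) = min over j with p(j) >= p(i) of min(1, p(j) * n / rank(j)); the
    adjustment is monotone, elementwise >= p and capped at 1.  NaN p-values
    propagate as NaN and do not enter n.  Delegates to statsmodels'
    ``multipletests(method="fdr_bh")``.
    """
    p = np.asarray(p_values, float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def build_de_table(
    matrix: ExpressionMatrix,
    cv_threshold: float | None = 0.20,
    fold_cut: float = 2.0,
    q_cut: float = 0.05,
    direction: str | None = "down",
    use_q: bool = True,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_t_log2,
) -> pd.DataFrame:
    """Assemble the full per-gene DE table with all filter flags.

    ``cv_threshold=None`` disables the replicate-consistency filter;
    ``use_q=False`` thresholds raw p-values instead of BH q-values (for
    emulation studies of pipelines that reported unadjusted P = 0.05).
    """
    ft = fold_and_test(matrix, test=test)
    if cv_threshold is not None:
        cv = cv_filter(matrix, threshold=cv_threshold)
    else:
        blocks = _condition_blocks(matrix)
        cv = pd.DataFrame(
            {
                "cv_control": blocks["control"].std(axis=1, ddof=1) / blocks["control"].mean(axis=1)
                if blocks["control"].shape[1] > 1 else np.nan,
                "cv_treatment": blocks["treatment"].std(axis=1, ddof=1) / blocks["treatment"].mean(axis=1)
                if blocks["treatment"].shape[1] > 1 else np.nan,
                "passes_cv_filter": True,
                "cv_fail_reason": "",
            },
            index=matrix.values.index,
        )
    det = ft.join(cv[["cv_control", "cv_treatment", "passes_cv_filter"]])
    det["q_value"] = bh_adjust(det["p_value"])
    det["passes_fold"] = det["fold_change"] >= fold_cut
    stat = det["q_value"] if use_q else det["p_value"]
    det["passes_fdr"] = stat.notna() & (stat <= q_cut)
    dir_ok = True if direction is None else det["direction"] == direction
    det["selected"] = det["passes_cv_filter"] & det["passes_fold"] & det["passes_fdr"] & dir_ok
    return det[DE_COLUMNS]


def select_regulated(
    de_table: pd.DataFrame,
    fold_cut: float = 2.0,
    q_cut: float = 0.05,
    direction: str | None = "down",
) -> GeneList:
    """Apply the selection rule to a DE table and return the gene list.

    selected = passes_cv_filter AND fold_change >= fold_cut AND q <= q_cut
    AND matching direction (any direction when ``direction`` is None); genes
    with missing q can never be selected.  Returned ids are sorted.
    """
    q = de_table["q_value"]
    sel = (
        de_table["passes_cv_filter"]
        & (de_table["fold_change"] >= fold_cut)
        & q.notna()
        & (q <= q_cut)
    )
    if direction is not None:
        sel &= de_table["direction"] == direction
    ids = tuple(sorted(de_table.index[sel].astype(str)))
    return GeneList(ids, label="selected_regulated", direction=direction)
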