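"""Descriptive faller vs non-faller comparisons.

Per characteristic: Shapiro–Wilk normality check on each group gates the
choice between Student's t-test (both groups consistent with normality)
and the Mann–Whitney U test; the standardised group difference is reported
as z_effect = (faller mean − non-faller mean) / non-faller SD, treating
non-fallers as the reference group.  No multiple-testing correction is
applied by default (optional Bonferroni / Benjamini–Hochberg).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .table import FALLER, NON_FALLER, GaitFeatureTable

__all__ = ["compare_groups", "correlation_matrix"]

NORMALITY_ALPHA = 0.05


def compare_groups(
    table: GaitFeatureTable,
    alpha: float = 0.05,
    welch: bool = False,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-feature two-group comparison with a normality-gated test choice.

    Returns a frame indexed by feature with columns: test_used, statistic,
    p_value, z_effect, significant.  ``correction`` may be None,
    'bonferroni' or 'fdr_bh'.
    """
    fallers = table.group(FALLER)
    non_fallers = table.group(NON_FALLER)
    if fallers.shape[0] < 3 or non_fallers.shape[0] < 3:
        raise ValueError("each group needs at least 3 subjects")

    rows = []
    for j, name in enumerate(table.schema.names):
        a, b = fallers[:, j], non_fallers[:, j]
        normal = (
            stats.shapiro(a).pvalue > NORMALITY_ALPHA
            and stats.shapiro(b).pvalue > NORMALITY_ALPHA
        )
        if normal:
            res = stats.ttest_ind(a, b, equal_var=not welch)
            test = "t_test"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann_whitney"
        ref_sd = b.std(ddof=1)
        z = (a.mean() - b.mean()) / ref_sd if ref_sd > 0 else np.nan
        rows.append((name, test, float(res.statistic), float(res.pvalue), float(z)))

    out = pd.DataFrame(rows, columns=["feature", "test_used", "statistic", "p_value", "z_effect"])
    out = out.set_index("feature")
    p = out["p_value"].to_numpy()
    if correction == "bonferroni":
        p_adj = np.minimum(p * len(p), 1.0)
    elif correction == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        p_adj = multipletests(p, method="fdr_bh")[1]
    elif correction is None:
        p_adj = p
    else:
        raise ValueError(f"unknown correction: {correction!r}")
    out["significant"] = p_adj < alpha
    return out


def correlation_matrix(table: GaitFeatureTable) -> pd.DataFrame:
    """Pairwise Pearson correlations of the 27 characteristics.

    Constant features yield NaN rows/columns with a warning; the diagonal
    is forced to exactly 1 where defined.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 subjects")
    X = table.features
    good = np.ptp(X, axis=0) > 0
    constant = [table.schema.names[i] for i in np.flatnonzero(~good)]
    if constant:
        warnings.warn(f"correlation undefined for constant feature(s): {constant}", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[~good, :] = np.nan
    corr[:, ~good] = np.nan
    diag = np.diag_indices_from(corr)
    corr[diag] = np.where(good, 1.0, np.nan)
    names = list(table.schema.names)
    return pd.DataFrame(corr, index=names, columns=names)
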