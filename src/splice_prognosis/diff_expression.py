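"""Two-group differential expression between expression strata.

Counts are normalized by median-of-ratios size factors, transformed to
log2(x + 1), and compared with a per-gene Welch t test; p-values are
adjusted by Benjamini-Hochberg. This is a deliberately dependency-light
stand-in for a shrinkage-based count model: it controls type-I error on
the synthetic surface but makes no claim of parity with negative-binomial
DE engines.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = ["size_factors", "deg_test", "bh_adjust", "top_fraction", "significant"]

#: Default FDR threshold for calling a gene differentially expressed.
DEFAULT_DEG_FDR = 1e-5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    The reference is the per-gene geometric mean across samples,
    restricted to genes with all-positive counts; each sample's factor is
    the median ratio of its counts to the reference.
    """
    positive = counts.loc[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has all-positive counts; cannot derive size factors")
    log_ref = np.log(positive).mean(axis=1)
    log_ratios = np.log(positive).sub(log_ref, axis=0)
    return np.exp(log_ratios.median(axis=0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def deg_test(
    counts: ExpressionMatrix,
    high_samples: Sequence[str],
    low_samples: Sequence[str],
) -> pd.DataFrame:
    """Differential expression of ``high_samples`` versus ``low_samples``.

    Returns a DEG table with one row per gene: ``gene``, ``log2fc``
    (high minus low on the normalized log2(x+1) scale), ``pvalue``
    (two-sided Welch t), ``qvalue`` (BH) and ``direction`` (``"up"`` =
    higher in the high stratum). Rows are sorted by ascending p-value,
    ties broken by descending \\|log2fc\\| then gene id, stably.
    """
    high = list(high_samples)
    low = list(low_samples)
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(high) & set(low):
        raise ValueError("high and low groups overlap")
    if counts.unit != "count":
        raise ValueError("deg_test expects raw counts")
    sub = counts.subset_samples(high + low).data.astype(float)
    nonzero = (sub.sum(axis=1) > 0)
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} all-zero gene rows", stacklevel=2)
        sub = sub.loc[nonzero]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    logged = np.log2(norm + 1.0)
    a = logged[high].to_numpy()
    b = logged[low].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, float)
    # degenerate rows (zero variance in both groups): exact equality -> null
    degenerate = np.isnan(pvals)
    pvals[degenerate & (lfc == 0)] = 1.0
    pvals[degenerate & (lfc != 0)] = 0.0
    table = pd.DataFrame(
        {
            "gene": sub.index,
            "log2fc": lfc,
            "pvalue": pvals,
            "qvalue": bh_adjust(pvals),
            "direction": np.where(lfc > 0, "up", "down"),
        }
    )
    table = table.sort_values(
        ["pvalue", "log2fc", "gene"],
        ascending=[True, True, True],
        key=lambda col: -col.abs() if col.name == "log2fc" else col,
        kind="stable",
    )
    return table.reset_index(drop=True)


def significant(table: pd.DataFrame, fdr: float = DEFAULT_DEG_FDR) -> pd.DataFrame:
    """Rows passing the FDR threshold (default 1e-5)."""
    return table[table["qvalue"] < fdr].reset_index(drop=True)


def top_fraction(table: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """The ``floor(fraction * m)`` rows with smallest raw p-value.

    Ties on p are broken by descending \\|log2fc\\|, then by gene id.
    """
    if table.empty:
        raise ValueError("empty DEG table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    m = len(table)
    k = int(np.floor(fraction * m))
    ranked = table.sort_values(
        ["pvalue", "log2fc", "gene"],
        ascending=[True, True, True],
        key=lambda col: -col.abs() if col.name == "log2fc" else col,
        kind="stable",
    )
    return ranked.head(k).reset_index(drop=True)
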