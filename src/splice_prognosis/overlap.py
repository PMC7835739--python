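"""Cumulative hypergeometric significance of DEG-list overlap and the
direction-concordance score.

Given a background of L genes and two DEG lists of sizes L1 and L2
sharing k genes, of which s agree in regulation direction, the tail
probability of observing at least s direction-consistent genes by chance
is

    P = 1 - sum_{i=0}^{s-1} C(L2, i) C(L - L2, L1 - i) / C(L, L1),

i.e. the upper tail of Hypergeometric(L, L2, L1) at s, with the
consistent count s plugged into the plain overlap null. The concordance
score s/k measures how directionally consistent the shared genes are.

The tail is evaluated in log space so that astronomically small values
(the interesting regime) keep an exact log10 magnitude even when the
linear-scale probability underflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = ["OverlapResult", "overlap_pvalue", "overlap_log10_pvalue", "concordance"]

#: Linear-scale floor: values whose true magnitude is below this are
#: reported as this strict upper bound; the exact magnitude remains
#: available via the log10 tail.
_P_FLOOR = 1e-300


@dataclass
class OverlapResult:
    """Overlap of two directional gene lists against a common background."""

    background: int  # L
    size1: int  # L1
    size2: int  # L2
    overlap: int  # k: shared genes
    consistent: int  # s: shared genes with identical direction
    p_value: float  # upper tail at s (floored at 1e-300 on underflow)
    log10_p: float  # exact log10 of the tail
    concordance: float  # s/k, NaN when k == 0
    significant: bool  # p < 0.05


def _check_overlap_ints(L: int, L1: int, L2: int, s: int) -> None:
    for name, v in (("L", L), ("L1", L1), ("L2", L2), ("s", s)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if L1 > L or L2 > L:
        raise ValueError("list sizes cannot exceed the background")
    if s > min(L1, L2):
        raise ValueError("consistent count cannot exceed the smaller list")


def _log_tail(L: int, L1: int, L2: int, s: int) -> float:
    """Natural log of P(X >= s), X ~ Hypergeom(L, L2, L1)."""
    if s <= max(0, L1 + L2 - L):
        return 0.0
    hi = min(L1, L2)
    i = np.arange(s, hi + 1)
    log_terms = (
        gammaln(L2 + 1) - gammaln(i + 1) - gammaln(L2 - i + 1)
        + gammaln(L - L2 + 1) - gammaln(L1 - i + 1) - gammaln(L - L2 - L1 + i + 1)
        - (gammaln(L + 1) - gammaln(L1 + 1) - gammaln(L - L1 + 1))
    )
    return float(logsumexp(log_terms))


def overlap_log10_pvalue(L: int, L1: int, L2: int, s: int) -> float:
    """log10 of the cumulative hypergeometric overlap tail at ``s``."""
    _check_overlap_ints(L, L1, L2, s)
    return _log_tail(int(L), int(L1), int(L2), int(s)) / math.log(10.0)


def overlap_pvalue(L: int, L1: int, L2: int, s: int) -> float:
    """P(at least ``s`` of the overlap by chance); never exactly zero.

    Below the linear-scale floor of 1e-300 the returned value is a strict
    upper bound; use :func:`overlap_log10_pvalue` for the exact magnitude.
    """
    _check_overlap_ints(L, L1, L2, s)
    log_p = _log_tail(int(L), int(L1), int(L2), int(s))
    p = math.exp(log_p) if log_p > math.log(_P_FLOOR) else 0.0
    return max(p, _P_FLOOR) if log_p < 0 else min(p, 1.0)


def concordance(list1: pd.DataFrame, list2: pd.DataFrame, background: int) -> OverlapResult:
    """Overlap statistics for two DEG tables sharing a background.

    Each table must carry ``gene`` and ``direction`` columns. ``k`` is
    the number of shared genes, ``s`` the shared genes whose directions
    agree, and the tail probability uses ``s`` against the background of
    size ``background``. With no overlap the concordance score is
    undefined (NaN) and the tail is evaluated at s = 0 (P = 1).
    """
    for name, tbl in (("list1", list1), ("list2", list2)):
        missing = {"gene", "direction"} - set(tbl.columns)
        if missing:
            raise ValueError(f"{name} lacks columns {sorted(missing)}")
    d1 = dict(zip(list1["gene"], list1["direction"]))
    d2 = dict(zip(list2["gene"], list2["direction"]))
    if len(d1) != len(list1) or len(d2) != len(list2):
        raise ValueError("duplicate genes within a DEG list")
    if background < len(set(d1) | set(d2)):
        raise ValueError("background smaller than the union of the lists")
    shared = set(d1) & set(d2)
    k = len(shared)
    s = sum(1 for g in shared if d1[g] == d2[g])
    p = overlap_pvalue(background, len(d1), len(d2), s)
    log10_p = overlap_log10_pvalue(background, len(d1), len(d2), s)
    return OverlapResult(
        background=int(background),
        size1=len(d1),
        size2=len(d2),
        overlap=k,
        consistent=s,
        p_value=p,
        log10_p=log10_p,
        concordance=(s / k) if k else float("nan"),
        significant=p < 0.05,
    )
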