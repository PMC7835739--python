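"""Hypergeometric gene-set over-representation, cross-cohort term
summaries (generality / direction), and clustering of log-rank p-value
matrices by Spearman correlation distance with Ward (ward.D2) linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diff_expression import bh_adjust
from .io import GeneSetCollection

__all__ = [
    "enrich",
    "summarize_terms",
    "cluster_pvalue_matrix",
    "ClusteringResult",
    "DEFAULT_ENRICH_FDR",
]

#: Default FDR threshold for calling a term enriched.
DEFAULT_ENRICH_FDR = 1e-3


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    fdr: float = DEFAULT_ENRICH_FDR,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    Sets are intersected with the universe before testing; terms with no
    gene left in the universe are dropped. Returns one row per term with
    the overlap, the upper-tail p-value, the BH q-value and a
    significance flag at ``q < fdr``.
    """
    q = set(query)
    u = set(universe)
    if not q or not u:
        raise ValueError("query and universe must be non-empty")
    if not q <= u:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for term, (name, genes) in sets:
        in_universe = genes & u
        if not in_universe:
            continue
        k = len(q & in_universe)
        p = float(stats.hypergeom.sf(k - 1, len(u), len(in_universe), len(q)))
        rows.append((term, name, len(q), len(in_universe), len(u), k, min(p, 1.0)))
    table = pd.DataFrame(
        rows,
        columns=["term", "name", "query_size", "set_size", "universe_size", "overlap", "pvalue"],
    )
    if table.empty:
        table["qvalue"] = []
        table["significant"] = []
        return table
    table["qvalue"] = bh_adjust(table["pvalue"].to_numpy())
    table["significant"] = table["qvalue"] < fdr
    return table.sort_values(["pvalue", "term"], kind="stable").reset_index(drop=True)


def summarize_terms(results: pd.DataFrame, min_generality: int = 10) -> pd.DataFrame:
    """Summarize per-cohort, per-direction enrichment calls term by term.

    ``results`` holds one row per significant enrichment with columns
    ``cohort``, ``direction`` (``"up"``/``"down"``: direction of the DEG
    query), ``term`` and optionally ``overlap`` (gene count behind the
    call). For each term:

    * ``generality`` -- number of distinct cohorts where the term is
      enriched in either direction;
    * ``direction_score`` -- cohorts enriched in upregulated genes minus
      cohorts enriched in downregulated genes;
    * ``mean_gene_count`` -- mean overlap across the calls.

    Only terms with ``generality > min_generality`` are returned (set
    ``min_generality=0`` to keep everything with at least one call).
    """
    required = {"cohort", "direction", "term"}
    if not required <= set(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    bad = set(results["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"unknown directions: {sorted(bad)}")
    rows = []
    for term, grp in results.groupby("term", sort=True):
        cohorts = grp["cohort"].nunique()
        n_up = grp.loc[grp["direction"] == "up", "cohort"].nunique()
        n_down = grp.loc[grp["direction"] == "down", "cohort"].nunique()
        mean_count = float(grp["overlap"].mean()) if "overlap" in grp else float("nan")
        rows.append((term, cohorts, n_up - n_down, mean_count))
    summary = pd.DataFrame(rows, columns=["term", "generality", "direction_score", "mean_gene_count"])
    return summary[summary["generality"] > min_generality].reset_index(drop=True)


@dataclass
class ClusteringResult:
    row_order: np.ndarray
    col_order: np.ndarray
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    row_labels: list[str]
    col_labels: list[str]


def _spearman_ward_linkage(x: np.ndarray) -> np.ndarray:
    """Ward.D2 linkage on 1 - Spearman correlation between rows of ``x``."""
    n = x.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s): Spearman correlation undefined, "
            "distance to all other rows set to 1",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        denom = np.outer(sd, sd) * x.shape[1]
        rho = (centered @ centered.T) / denom
    dist = 1.0 - rho
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    # scipy's 'ward' on a precomputed condensed distance implements the
    # ward.D2 Lance-Williams update (distances, not squared distances)
    return hierarchy.linkage(condensed, method="ward")


def cluster_pvalue_matrix(pmat: pd.DataFrame) -> ClusteringResult:
    """Hierarchically cluster a feature x cohort matrix of log-rank p-values.

    P-values are transformed to -log10 before clustering; rows (and
    columns, when there are at least three) are clustered by Spearman
    correlation distance with Ward.D2 linkage. Ordering is the
    deterministic left-to-right dendrogram leaf order.
    """
    vals = pmat.to_numpy(float)
    if vals.ndim != 2 or vals.shape[0] < 2:
        raise ValueError("need a 2-d matrix with at least 2 rows")
    if np.any(vals <= 0) or np.any(vals > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -np.log10(vals)
    row_linkage = _spearman_ward_linkage(x)
    row_order = hierarchy.leaves_list(row_linkage)
    if x.shape[1] >= 3:
        col_linkage = _spearman_ward_linkage(x.T)
        col_order = hierarchy.leaves_list(col_linkage)
    else:
        col_linkage = None
        col_order = np.arange(x.shape[1])
    return ClusteringResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        row_labels=[str(pmat.index[i]) for i in row_order],
        col_labels=[str(pmat.columns[i]) for i in col_order],
    )
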