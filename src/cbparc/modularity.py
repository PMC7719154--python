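"""Hierarchical module structure of the subregions, with automatic
(metric, linkage) selection by cophenetic correlation.

Subregion fingerprints are hierarchically clustered under a grid of distance
metrics and linkage methods; each dendrogram is scored by its cophenetic
correlation coefficient — the correlation between the original pairwise
distances and the dendrogram merge-height (cophenetic) distances — and the
best-scoring pair wins.  The winning dendrogram is then cut into
"connectivity families", either at a requested count or automatically at the
largest merge-height gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ModularSolution",
    "DEFAULT_METRICS",
    "DEFAULT_LINKAGES",
    "fingerprint_correlation_matrix",
    "cophenetic_coefficient",
    "search_best_clustering",
    "cut_families",
]

DEFAULT_METRICS = ("euclidean", "seuclidean", "cityblock", "cosine", "correlation")
# Linkages ordered by their typical cophenetic fidelity; average linkage is
# the canonical choice for dendrogram faithfulness and breaks exact ties.
DEFAULT_LINKAGES = ("average", "weighted", "complete", "single", "ward")


@dataclass
class ModularSolution:
    """Winning dendrogram over subregions plus the full search table."""

    items: list  # subregion identifiers, in input order
    best_metric: str
    best_linkage: str
    cophenetic: float
    search_table: pd.DataFrame  # columns: metric, linkage, cophenetic
    linkage_matrix: np.ndarray  # scipy linkage (Z) of the winner
    distances: np.ndarray  # condensed distances of the winning metric
    tied: bool = False


def fingerprint_correlation_matrix(strengths: np.ndarray, items=None) -> np.ndarray:
    """Pearson correlation between subregion fingerprint vectors.

    ``strengths`` is an (items x targets) matrix, typically group-averaged
    across subjects.  A constant fingerprint has no defined correlation and
    raises, naming the item.
    """
    x = np.asarray(strengths, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 items")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        names = [items[i] for i in bad] if items is not None else bad.tolist()
        raise ValueError(f"constant fingerprint(s): correlation undefined for {names}")
    c = np.corrcoef(x)
    np.fill_diagonal(c, 1.0)
    return c


def cophenetic_coefficient(distances: np.ndarray, linkage_matrix: np.ndarray) -> float:
    """Cophenetic correlation between original and dendrogram distances.

    ``distances`` is a condensed (pdist-style) vector or a square matrix.
    Values near 1 mean the dendrogram faithfully preserves the original
    pairwise distances.  Negative values are possible for pathological trees
    and are reported raw with a warning rather than clamped.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim == 2:
        d = squareform(d, checks=False)
    n = int((1 + np.sqrt(1 + 8 * d.size)) / 2)
    if n < 3:
        raise ValueError("need at least 3 items")
    score, _ = hierarchy.cophenet(linkage_matrix, d)
    score = float(score)
    if score < 0:
        warnings.warn(f"negative cophenetic coefficient ({score:.3f})", stacklevel=2)
    return score


def search_best_clustering(
    strengths: np.ndarray,
    items: list | None = None,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    linkages: tuple[str, ...] = DEFAULT_LINKAGES,
) -> ModularSolution:
    """Grid-search (metric, linkage) pairs; keep the highest cophenetic score.

    Invalid combinations (Ward linkage requires Euclidean distances) are
    skipped with a note in the search table.  Exact ties go to the first pair
    in grid order (metrics outer, linkages inner) and are flagged.
    """
    x = np.asarray(strengths, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items")
    if items is None:
        items = list(range(n))
    if len(metrics) < 1 or len(linkages) < 1:
        raise ValueError("empty search grid")
    rows = []
    best = None
    for metric in metrics:
        try:
            d = pdist(x, metric=metric)
        except Exception as exc:
            rows.append(
                {"metric": metric, "linkage": "*", "cophenetic": np.nan,
                 "note": f"metric failed: {exc}"}
            )
            continue
        for link in linkages:
            if link == "ward" and metric != "euclidean":
                rows.append(
                    {"metric": metric, "linkage": link, "cophenetic": np.nan,
                     "note": "ward requires euclidean"}
                )
                continue
            z = hierarchy.linkage(d, method=link)
            score, _ = hierarchy.cophenet(z, d)
            score = float(score)
            rows.append(
                {"metric": metric, "linkage": link, "cophenetic": score, "note": ""}
            )
            if best is None or score > best[0] + 1e-12:
                best = (score, metric, link, z, d)
    if best is None:
        raise ValueError("no valid (metric, linkage) combination")
    table = pd.DataFrame(rows)
    valid = table["cophenetic"].dropna()
    tied = bool((np.isclose(valid, best[0], atol=1e-12)).sum() > 1)
    if tied:
        warnings.warn(
            "multiple (metric, linkage) pairs tie on the cophenetic score; "
            "keeping the first in grid order",
            stacklevel=2,
        )
    score, metric, link, z, d = best
    if score < 0:
        warnings.warn(f"winning cophenetic coefficient is negative ({score:.3f})",
                      stacklevel=2)
    return ModularSolution(
        items=list(items),
        best_metric=metric,
        best_linkage=link,
        cophenetic=score,
        search_table=table,
        linkage_matrix=z,
        distances=d,
        tied=tied,
    )


def cut_families(
    solution: ModularSolution, n_families: int | None = None
) -> np.ndarray:
    """Cut the winning dendrogram into connectivity families.

    With ``n_families`` given, cut to exactly that many clusters.  In
    automatic mode the cut is placed in the largest gap between consecutive
    merge heights, which by construction yields between 2 and n-1 families.
    Returns an item -> family id array (1-based), invariant to item order.
    """
    z = solution.linkage_matrix
    n = len(solution.items)
    if n_families is not None:
        if not 1 <= n_families <= n:
            raise ValueError(f"n_families must lie in 1..{n}")
        return hierarchy.fcluster(z, t=n_families, criterion="maxclust")
    heights = z[:, 2]
    if heights.size < 2:
        return hierarchy.fcluster(z, t=2, criterion="maxclust")
    gaps = np.diff(heights)
    i = int(np.argmax(gaps))  # cut between merge i and merge i+1
    return hierarchy.fcluster(z, t=n - (i + 1), criterion="maxclust")
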