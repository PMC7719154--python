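"""Cluster-number selection: cross-validation indices and PCA criteria.

Two independent lines of evidence pick the number of parcels ``k``:

* **Cross-validation indices.**  Cramer's V measures how consistently two
  subjects' parcellations agree (chi-square association of the label
  contingency table, in [0, 1]); the topological distance TpD measures how
  similar the parcel-adjacency graphs of the two hemispheres are (0 =
  isomorphic arrangements).  Interior local maxima of the subject-averaged V
  and local minima of TpD mark good candidate k.

* **PCA criteria.**  Per subject, the spectrum of the seed-voxel correlation
  matrix yields three component-count estimates: the smallest count whose
  cumulative proportion of variance clears 80% (with a 1% lower-limit
  allowance), the Kaiser count of eigenvalues above 1 (optionally extended by
  the next eigenvalue closest to 1), and the elbow of a power curve fitted to
  the sorted eigenvalues.  The cross-subject mean of the elbow estimate,
  after excluding subjects that deviate from the cohort mean by more than a
  stability threshold (default 0.5), breaks ties between candidates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import quadratic_assignment
from scipy.stats.contingency import association, crosstab

from .connectivity import ConnectivityMatrix
from .parcellation import Parcellation

__all__ = [
    "ValidityProfile",
    "KSelection",
    "cramers_v",
    "mean_cramers_v",
    "parcel_adjacency",
    "tpd",
    "pca_criteria",
    "pca_criteria_from_eigenvalues",
    "correlation_eigenvalues",
    "scree_inflexion",
    "select_k",
]

# Exhaustive permutation search for the TpD matching is used up to this k;
# beyond it, a seeded quadratic-assignment heuristic takes over (flagged).
_TPD_EXACT_MAX_K = 8


# ---------------------------------------------------------------------------
# Cramer's V
# ---------------------------------------------------------------------------

def cramers_v(a: Parcellation | np.ndarray, b: Parcellation | np.ndarray) -> float:
    """Cramer's V between two labelings of the same voxel set.

    ``V = sqrt(chi2 / (n * (min(r, c) - 1)))`` on the r x c contingency
    table; 1 for identical partitions (up to label permutation), 0 for
    independent ones.  Undefined when both labelings have a single cluster.
    """
    la = a.labels if isinstance(a, Parcellation) else np.asarray(a)
    lb = b.labels if isinstance(b, Parcellation) else np.asarray(b)
    if la.shape != lb.shape:
        raise ValueError("labelings must cover the same voxel set")
    (_, _), table = crosstab(la, lb)
    if min(table.shape) < 2:
        raise ValueError("Cramer's V undefined: a labeling has a single cluster")
    return float(association(table, method="cramer", correction=False))


def mean_cramers_v(parcellations: list[Parcellation]) -> float:
    """Average pairwise Cramer's V over all subject pairs at a fixed k.

    V is invariant to label permutation, so no cross-subject label matching
    is needed before averaging.  Pairs on which V is undefined are excluded
    with a warning; if every pair is undefined an error is raised.
    """
    if len(parcellations) < 2:
        raise ValueError("need at least two parcellations")
    vals = []
    skipped = 0
    for pa, pb in itertools.combinations(parcellations, 2):
        try:
            vals.append(cramers_v(pa, pb))
        except ValueError:
            skipped += 1
    if not vals:
        raise ValueError("Cramer's V undefined on every subject pair")
    if skipped:
        warnings.warn(f"{skipped} subject pair(s) excluded (V undefined)", stacklevel=2)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Topological distance (TpD)
# ---------------------------------------------------------------------------

def parcel_adjacency(p: Parcellation) -> np.ndarray:
    """k x k boolean parcel-adjacency matrix.

    Two parcels are adjacent when any of their voxels are 6-connected across
    the shared boundary.  The diagonal is False.
    """
    if p.degenerate:
        raise ValueError("adjacency undefined for a degenerate parcellation")
    index = {tuple(c): lab for c, lab in zip(p.seed_coords, p.labels)}
    adj = np.zeros((p.k, p.k), dtype=bool)
    offs = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for coord, lab in index.items():
        for o in offs:
            nb = index.get((coord[0] + o[0], coord[1] + o[1], coord[2] + o[2]))
            if nb is not None and nb != lab:
                adj[lab - 1, nb - 1] = True
                adj[nb - 1, lab - 1] = True
    return adj


def _mismatch_fraction(a: np.ndarray, b: np.ndarray, perm: np.ndarray) -> float:
    k = a.shape[0]
    pa = a[np.ix_(perm, perm)]
    return float(np.sum(pa != b) / (k * (k - 1)))


def tpd(a: Parcellation, b: Parcellation) -> float:
    """Topological distance between two parcellations' adjacency graphs.

    The parcel-correspondence permutation minimizing the fraction of
    mismatched off-diagonal adjacency entries defines the score: 0 iff the
    two parcel-adjacency graphs are isomorphic under some matching, 1 when
    no adjacency relation can be matched.  Parcellations with different k
    are maximally dissimilar by convention (score 1), which suits the
    index's role of finding a k shared by both hemispheres.
    """
    if a.k != b.k:
        return 1.0
    if a.k == 1:
        return 0.0
    adj_a = parcel_adjacency(a)
    adj_b = parcel_adjacency(b)
    k = a.k
    if k <= _TPD_EXACT_MAX_K:
        best = 1.0
        for perm in itertools.permutations(range(k)):
            best = min(best, _mismatch_fraction(adj_a, adj_b, np.array(perm)))
            if best == 0.0:
                break
        return best
    warnings.warn(
        f"k={k} > {_TPD_EXACT_MAX_K}: TpD matching is heuristic (QAP), "
        "an upper bound on the exact score",
        stacklevel=2,
    )
    best = 1.0
    for seed in range(8):
        res = quadratic_assignment(
            adj_a.astype(float),
            adj_b.astype(float),
            method="faq",
            options={"maximize": True, "rng": seed},
        )
        best = min(best, _mismatch_fraction(adj_a, adj_b, res.col_ind))
    return best


# ---------------------------------------------------------------------------
# PCA criteria
# ---------------------------------------------------------------------------

def correlation_eigenvalues(m: ConnectivityMatrix) -> np.ndarray:
    """Eigenvalues of the seed-voxel correlation matrix, sorted descending.

    Seed voxels are the variables and whole-brain columns the observations
    (the matrix is transposed and z-scored per seed voxel), so the number of
    dominant components estimates the number of distinct connectivity
    patterns — i.e. of clusters.  Constant seed profiles are dropped from
    the spectrum with a warning.
    """
    x = np.asarray(m.counts, dtype=float).T  # observations x variables
    sd = x.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"{int((~keep).sum())} constant seed profile(s) excluded from PCA",
            stacklevel=2,
        )
    x = x[:, keep]
    if x.shape[1] < 3:
        raise ValueError("need at least 3 non-constant seed voxels for PCA")
    corr = np.corrcoef(x, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    return np.clip(eig, 0.0, None)


def pca_criteria_from_eigenvalues(
    eigenvalues: np.ndarray,
    cpv_threshold: float = 0.80,
    cpv_tolerance: float = 0.01,
    eigen_closeness: float = 0.2,
) -> tuple[int, int, int | None]:
    """Three component-count criteria from a descending eigenvalue spectrum.

    Returns ``(c1, c2, c3)``: the cumulative-variance count (threshold 80%
    with a 1% lower-limit allowance, i.e. cpv >= 0.79 accepted), the Kaiser
    count of eigenvalues > 1 extended by the next eigenvalue when it lies
    within ``eigen_closeness`` of 1, and the scree-curve elbow (``None`` when
    no elbow exists, e.g. a flat spectrum).
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(eig) > 1e-12):
        raise ValueError("eigenvalues must be sorted in descending order")
    total = eig.sum()
    if total <= 0:
        raise ValueError("spectrum has no variance")
    cpv = np.cumsum(eig) / total
    c1 = int(np.argmax(cpv >= cpv_threshold - cpv_tolerance)) + 1
    c2 = int(np.sum(eig > 1.0))
    if c2 < eig.size and abs(eig[c2] - 1.0) <= eigen_closeness:
        c2 += 1
    try:
        c3: int | None = scree_inflexion(eig)
    except ValueError as exc:
        warnings.warn(f"scree elbow undefined: {exc}", stacklevel=2)
        c3 = None
    return c1, c2, c3


def pca_criteria(
    m: ConnectivityMatrix,
    cpv_threshold: float = 0.80,
    cpv_tolerance: float = 0.01,
    eigen_closeness: float = 0.2,
) -> tuple[int, int, int | None]:
    """Apply the three PCA component-count criteria to a connectivity matrix."""
    eig = correlation_eigenvalues(m)
    return pca_criteria_from_eigenvalues(
        eig, cpv_threshold, cpv_tolerance, eigen_closeness
    )


def scree_inflexion(eigenvalues: np.ndarray) -> int:
    """Elbow of a power curve fitted to a descending eigenvalue spectrum.

    A power curve ``lambda(x) = a * x**(-b)`` is fitted by least squares in
    log-log space to the positive eigenvalues; the elbow is the rank (1-based)
    at which the fitted curve, with both axes normalized to [0, 1], lies
    farthest from the chord joining its endpoints.  Raises when fewer than 4
    positive eigenvalues are available or when the spectrum is flat (no elbow
    exists).
    """
    eig = np.asarray(eigenvalues, dtype=float)
    pos = eig[eig > 0]
    n = pos.size
    if n < 4:
        raise ValueError("need at least 4 positive eigenvalues")
    ranks = np.arange(1, n + 1, dtype=float)
    slope, intercept = np.polyfit(np.log(ranks), np.log(pos), 1)
    b = -slope
    if b <= 1e-9:
        raise ValueError("flat (non-decaying) spectrum has no elbow")
    fitted = math.exp(intercept) * ranks ** (-b)
    u = (ranks - 1.0) / (n - 1.0)
    span = fitted[0] - fitted[-1]
    v = (fitted - fitted[-1]) / span
    # Perpendicular distance to the chord from (0, 1) to (1, 0) is
    # |u + v - 1| / sqrt(2); the fitted curve is convex decreasing, hence
    # below the chord, so the distance is proportional to 1 - u - v.
    dist = 1.0 - u - v
    return int(np.argmax(dist)) + 1


# ---------------------------------------------------------------------------
# Combining the evidence
# ---------------------------------------------------------------------------

@dataclass
class ValidityProfile:
    """Per-k validity evidence for a cohort."""

    k_values: np.ndarray
    mean_cramers_v: np.ndarray
    mean_tpd: np.ndarray
    pca_inflexions: dict[str, float] = field(default_factory=dict)  # per subject

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.mean_cramers_v = np.asarray(self.mean_cramers_v, dtype=float)
        self.mean_tpd = np.asarray(self.mean_tpd, dtype=float)
        if not (
            self.k_values.size == self.mean_cramers_v.size == self.mean_tpd.size
        ):
            raise ValueError("per-k series must share one length")


@dataclass
class KSelection:
    """Outcome of the k decision with its evidence trail."""

    selected_k: int
    candidates: list[int]
    pca_mean: float | None
    excluded_subjects: list[str]
    used_fallback: bool


def _interior_extrema(y: np.ndarray, kind: str) -> np.ndarray:
    """Interior local extrema of a per-k series.

    An index counts when it is no worse than both neighbours and strictly
    better than at least one (plateau edges count), or when it attains the
    series' global optimum (an index cannot be beaten by moving off a
    shared-optimum plateau, which these indices produce when many k are
    equally consistent).  Boundary indices never count.
    """
    s = np.greater if kind == "max" else np.less
    ns = np.greater_equal if kind == "max" else np.less_equal
    opt = y.max() if kind == "max" else y.min()
    idx = [
        i
        for i in range(1, y.size - 1)
        if y[i] == opt
        or (
            ns(y[i], y[i - 1]) and ns(y[i], y[i + 1])
            and (s(y[i], y[i - 1]) or s(y[i], y[i + 1]))
        )
    ]
    return np.asarray(idx, dtype=int)


def _stable_pca_mean(
    inflexions: dict[str, float], stability_delta: float
) -> tuple[float | None, list[str]]:
    vals = {s: v for s, v in inflexions.items() if v is not None and np.isfinite(v)}
    if not vals:
        return None, []
    # Greedy outlier trimming: drop the single most deviant subject while it
    # exceeds the stability threshold, recomputing the mean each round.
    kept = dict(vals)
    excluded: list[str] = []
    while len(kept) > 1:
        mean = float(np.mean(list(kept.values())))
        worst = max(kept, key=lambda s: abs(kept[s] - mean))
        if abs(kept[worst] - mean) <= stability_delta:
            break
        excluded.append(worst)
        del kept[worst]
    return float(np.mean(list(kept.values()))), excluded


def select_k(profile: ValidityProfile, stability_delta: float = 0.5) -> KSelection:
    """Choose k from validity indices, tie-broken by the PCA evidence.

    Candidates are the interior local maxima of mean Cramer's V intersected
    with the interior local minima of mean TpD.  Ties are broken by proximity
    to the rounded cross-subject mean of the per-subject scree-elbow values,
    computed after excluding subjects deviating from the cohort mean by more
    than ``stability_delta``.  When no candidate exists the rounded PCA mean
    itself is used, with a prominent warning.
    """
    if profile.k_values.size < 3:
        raise ValueError("need at least 3 k values")
    order = np.argsort(profile.k_values)
    ks = profile.k_values[order]
    v = profile.mean_cramers_v[order]
    t = profile.mean_tpd[order]
    v_max = set(ks[_interior_extrema(v, "max")].tolist())
    t_min = set(ks[_interior_extrema(t, "min")].tolist())
    candidates = sorted(v_max & t_min)
    pca_mean, excluded = _stable_pca_mean(profile.pca_inflexions, stability_delta)
    if candidates:
        if pca_mean is not None and len(candidates) > 1:
            target = round(pca_mean)
            selected = min(candidates, key=lambda k: (abs(k - target), k))
        else:
            selected = candidates[0]
        return KSelection(int(selected), candidates, pca_mean, excluded, False)
    if pca_mean is None:
        raise ValueError("no validity-index candidate and no PCA evidence")
    warnings.warn(
        "no interior extremum shared by Cramer's V and TpD; "
        "falling back to the rounded PCA mean",
        stacklevel=2,
    )
    selected = int(np.clip(round(pca_mean), ks[0], ks[-1]))
    return KSelection(selected, [], pca_mean, excluded, True)
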