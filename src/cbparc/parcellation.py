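"""Spectral parcellation of seed regions from cross-correlation matrices.

Seed voxels whose connectivity profiles correlate strongly are grouped by
normalized spectral clustering: the correlation matrix is mapped onto a
non-negative affinity ``a = (r + 1) / 2``, embedded via the leading
eigenvectors of the normalized graph Laplacian, and partitioned by k-means
(10 restarts, best inertia, fixed seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import SpectralClustering

from .connectivity import CrossCorrelationMatrix

__all__ = ["Parcellation", "spectral_parcellate", "parcellate_cohort"]


@dataclass
class Parcellation:
    """Assignment of every seed voxel to one of ``k`` cluster labels (1..k)."""

    labels: np.ndarray
    k: int
    seed_coords: np.ndarray
    subject_id: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.k:
            raise ValueError("labels must lie in 1..k")

    @property
    def degenerate(self) -> bool:
        """True when some of the k labels are unused."""
        return np.unique(self.labels).size < self.k

    @property
    def n_voxels(self) -> int:
        return self.labels.size


def correlation_affinity(values: np.ndarray) -> np.ndarray:
    """Map correlations in [-1, 1] onto affinities in [0, 1], order-preserving."""
    return (np.asarray(values, dtype=float) + 1.0) / 2.0


def spectral_parcellate(
    c: CrossCorrelationMatrix,
    k: int,
    rng_seed: int = 0,
    subject_id: str | None = None,
    hemisphere: str = "",
) -> Parcellation:
    """Cluster seed voxels into ``k`` parcels by normalized spectral clustering.

    Deterministic for a fixed ``rng_seed``.  A disconnected affinity graph is
    tolerated (the spectral embedding separates components); an outcome with
    empty clusters is returned flagged as degenerate rather than relabelled.
    """
    m = c.n_seed_voxels
    if not 1 <= k <= m:
        raise ValueError(f"k={k} outside 1..{m}")
    sid = c.subject_id if subject_id is None else subject_id
    if k == 1:
        return Parcellation(
            labels=np.ones(m, dtype=int),
            k=1,
            seed_coords=c.seed_coords,
            subject_id=sid,
            hemisphere=hemisphere,
        )
    affinity = correlation_affinity(c.values)
    model = SpectralClustering(
        n_clusters=k,
        affinity="precomputed",
        random_state=int(rng_seed) % (2**31),
        n_init=10,
        assign_labels="kmeans",
    )
    with warnings.catch_warnings():
        # The graph-connectivity warning is informational here.
        warnings.simplefilter("ignore")
        raw = model.fit_predict(affinity)
    parc = Parcellation(
        labels=raw + 1,
        k=k,
        seed_coords=c.seed_coords,
        subject_id=sid,
        hemisphere=hemisphere,
    )
    if parc.degenerate:
        warnings.warn(
            f"degenerate parcellation (empty cluster) for subject {sid!r}, k={k}",
            stacklevel=2,
        )
    return parc


def parcellate_cohort(
    correlations: list[CrossCorrelationMatrix],
    k_range: list[int] | range,
    rng_seed: int = 0,
    hemisphere: str = "",
) -> dict[tuple[str, int], Parcellation]:
    """Run spectral parcellation for every subject and every k.

    Per-run seeds are spawned deterministically from ``rng_seed`` so the full
    grid is reproducible while runs stay independent.  Returns a dict keyed
    by ``(subject_id, k)``.
    """
    k_list = list(k_range)
    if not k_list:
        raise ValueError("k_range must be non-empty")
    seeder = np.random.SeedSequence(rng_seed)
    seeds = seeder.generate_state(len(correlations) * len(k_list)) % (2**31)
    out: dict[tuple[str, int], Parcellation] = {}
    i = 0
    for c in correlations:
        for k in k_list:
            try:
                out[(c.subject_id, k)] = spectral_parcellate(
                    c, k, rng_seed=int(seeds[i]), hemisphere=hemisphere
                )
            except Exception as exc:
                raise RuntimeError(
                    f"parcellation failed for subject {c.subject_id!r}, k={k}"
                ) from exc
            i += 1
    return out
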