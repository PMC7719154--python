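"""Connectivity-matrix containers and profile preprocessing.

A connectivity matrix stores, for every voxel of a seed mask, the number of
probabilistic-tractography streamlines that arrived at each whole-brain
column (a native-resolution voxel, or a target region after aggregation).
Preprocessing consists of removing low-count (likely false-positive)
connections, spatially down-sampling the whole-brain profiles, and computing
the seed-voxel cross-correlation matrix that drives the parcellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "CrossCorrelationMatrix",
    "threshold_counts",
    "downsample_profiles",
    "cross_correlation",
]


@dataclass
class ConnectivityMatrix:
    """Seed-voxel x whole-brain streamline-count matrix.

    Parameters
    ----------
    counts
        ``(M, N)`` non-negative array; row ``i`` is the connectivity profile
        of seed voxel ``i``.
    seed_coords
        ``(M, 3)`` integer voxel indices ``(i, j, k)`` of the seed voxels,
        0-based.
    voxel_size
        Edge length in mm of the voxels the *columns* live on, per axis.
    samples_per_voxel
        Number of streamlines seeded per voxel; the denominator turning
        counts into connection probabilities.
    column_coords
        ``(N, 3)`` integer voxel indices of the columns, or ``None`` when
        columns are abstract target regions.
    column_labels
        Optional ``(N,)`` integer region id per column (``0`` = background);
        used when mapping columns onto a target atlas.
    subject_id
        Free-form identifier carried through the pipeline.
    """

    counts: np.ndarray
    seed_coords: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    samples_per_voxel: int = 15000
    column_coords: np.ndarray | None = None
    column_labels: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.seed_coords = np.asarray(self.seed_coords)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (seed x column) array")
        if self.seed_coords.shape != (self.counts.shape[0], 3):
            raise ValueError("seed_coords must be (M, 3) matching counts rows")
        if np.any(self.counts < 0):
            raise ValueError("streamline counts must be non-negative")

    @property
    def n_seed_voxels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        """Counts divided by the per-voxel sample number."""
        return self.counts / float(self.samples_per_voxel)


@dataclass
class CrossCorrelationMatrix:
    """Symmetric matrix of Pearson correlations between seed-voxel profiles."""

    values: np.ndarray
    seed_coords: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.values.shape[0]
        if self.values.shape != (m, m):
            raise ValueError("correlation matrix must be square")
        if self.zero_variance is None:
            self.zero_variance = np.zeros(m, dtype=bool)

    @property
    def n_seed_voxels(self) -> int:
        return self.values.shape[0]


def threshold_counts(m: ConnectivityMatrix, min_count: float = 20) -> ConnectivityMatrix:
    """Zero out entries whose streamline count falls below ``min_count``.

    With the default of 20 (out of 15,000 samples per voxel) this removes
    connections whose probability is below 20/15000, the conventional
    false-positive filter for probabilistic tractography counts.  Entries
    with count >= ``min_count`` pass unchanged, so the filter is idempotent
    and monotone in ``min_count``.
    """
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    counts = np.where(m.counts >= min_count, m.counts, 0)
    return replace(m, counts=counts)


def downsample_profiles(
    m: ConnectivityMatrix, target_voxel_mm: float = 2.0
) -> ConnectivityMatrix:
    """Aggregate whole-brain columns onto a coarser isotropic grid.

    Columns are summed within axis-aligned blocks tiled from the volume
    origin; each block spans ``ceil(target_voxel_mm / native)`` native voxels
    per axis (half-open index intervals).  Summation preserves per-row totals
    exactly, so probability thresholds applied later keep their count
    semantics.  Seed rows are untouched.
    """
    if m.column_coords is None:
        raise ValueError("down-sampling requires column voxel coordinates")
    native = np.asarray(m.voxel_size, dtype=float)
    if np.any(target_voxel_mm < native):
        raise ValueError(
            f"target resolution {target_voxel_mm} mm is finer than native {tuple(native)} mm"
        )
    block = np.ceil(target_voxel_mm / native).astype(int)  # voxels per block, per axis
    block_idx = m.column_coords // block
    # Group columns by block index (lexicographic order keeps output deterministic).
    uniq, inverse = np.unique(block_idx, axis=0, return_inverse=True)
    agg = np.zeros((m.counts.shape[0], uniq.shape[0]), dtype=m.counts.dtype)
    np.add.at(agg, (slice(None), inverse), m.counts)
    labels = None
    if m.column_labels is not None:
        # A block keeps a region id only if all its columns agree; mixed blocks get 0.
        labels = np.zeros(uniq.shape[0], dtype=int)
        for b in range(uniq.shape[0]):
            ids = np.unique(m.column_labels[inverse == b])
            labels[b] = ids[0] if ids.size == 1 else 0
    new_size = tuple(float(e) for e in native * block)
    return replace(
        m,
        counts=agg,
        column_coords=uniq,
        column_labels=labels,
        voxel_size=new_size,
    )


def cross_correlation(m: ConnectivityMatrix) -> CrossCorrelationMatrix:
    """Pearson correlation between every pair of seed-voxel profiles.

    Rows with zero variance (constant profiles, typically all-zero after
    thresholding) have no defined correlation; they are kept in the matrix
    with off-diagonal correlation 0 and flagged, so that row/voxel
    bookkeeping stays aligned with the seed mask.
    """
    x = np.asarray(m.counts, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two seed voxels")
    sd = x.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} seed voxel(s) have constant profiles; "
            "their correlations are set to 0",
            stacklevel=2,
        )
    vals = np.zeros((x.shape[0], x.shape[0]), dtype=float)
    good = ~flat
    if good.sum() >= 2:
        sub = np.corrcoef(x[good])
        vals[np.ix_(good, good)] = sub
    np.fill_diagonal(vals, 1.0)
    vals = np.clip((vals + vals.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    return CrossCorrelationMatrix(
        values=vals,
        seed_coords=m.seed_coords,
        zero_variance=flat,
        subject_id=m.subject_id,
    )
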