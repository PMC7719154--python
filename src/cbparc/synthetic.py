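"""Synthetic multi-subject connectivity cohorts with known ground truth.

The generator emulates the data shape produced by probabilistic diffusion
tractography from a seed mask: for every seed voxel, an integer vector of
streamline-arrival counts over whole-brain columns, one matrix per subject.
Structure is planted as ``k`` spatially contiguous parcels on the seed grid,
each with its own preference profile over a set of target regions; a "sink"
category absorbs streamlines that real tractography would lose to implausible
or truncated paths, so per-voxel totals stay at or below the nominal number
of samples seeded per voxel.

Inter-subject variability enters as a Dirichlet perturbation of the cluster
profiles per subject, plus a weaker per-voxel Dirichlet overdispersion;
both scale with ``subject_noise``.  ``profile_separation`` interpolates the
cluster profiles between a shared baseline (0: structure unrecoverable) and
fully distinct target sets (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_cohort",
    "mirror_hemisphere",
    "planted_family_fingerprints",
    "ultrametric_seuclidean_data",
]

# Each target region occupies a 2x2x2 block of native (1 mm) brain voxels, so
# that 2 mm down-sampling aggregates a region into exactly one column.
_TARGET_BLOCK = 2


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic cohort.

    ``grid_shape`` is the seed-mask grid of ONE hemisphere; with
    ``bilateral=True`` a mirrored copy is appended along the first axis.
    ``profile_separation`` in [0, 1] sets how distinct the planted clusters'
    target preferences are; ``subject_noise`` >= 0 scales inter-subject and
    voxel-level Dirichlet perturbations (0 disables both).  ``sink_fraction``
    is the expected share of streamlines lost to the sink category.
    """

    n_subjects: int = 8
    grid_shape: tuple[int, int, int] = (6, 6, 2)
    k_planted: int = 4
    n_targets: int = 12
    samples_per_voxel: int = 15000
    profile_separation: float = 0.9
    subject_noise: float = 0.1
    sink_fraction: float = 0.3
    bilateral: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.k_planted < 1:
            raise ValueError("k_planted must be >= 1")
        if not 0.0 <= self.profile_separation <= 1.0:
            raise ValueError("profile_separation must lie in [0, 1]")
        if self.subject_noise < 0:
            raise ValueError("subject_noise must be >= 0")
        if not 0.0 <= self.sink_fraction < 1.0:
            raise ValueError("sink_fraction must lie in [0, 1)")


@dataclass
class SyntheticDataset:
    """A generated cohort plus its ground truth."""

    config: SyntheticConfig
    matrices: list[ConnectivityMatrix]
    labels: np.ndarray  # (M,) planted cluster id per seed voxel, 1..k
    hemispheres: np.ndarray  # (M,) "L" or "R"
    seed_coords: np.ndarray  # (M, 3)
    target_profiles: np.ndarray  # (k, n_targets + 1); last column = sink
    subject_profiles: np.ndarray  # (n_subjects, k, n_targets + 1)
    target_atlas: np.ndarray  # (N,) region id per column, 1..n_targets
    reflection_map: np.ndarray | None = None  # row index of a voxel's mirror image
    seed_grid_shape: tuple[int, int, int] = field(default=(0, 0, 0))

    @property
    def bilateral(self) -> bool:
        return bool(np.any(self.hemispheres == "R"))

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    def hemisphere_index(self, side: str) -> np.ndarray:
        return np.flatnonzero(self.hemispheres == side)


def _grow_parcels(
    grid_shape: tuple[int, int, int], k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a voxel grid into k contiguous parcels by region growing.

    Seeds are placed by farthest-point sampling; parcels then claim
    unassigned 6-neighbours in round-robin order, which guarantees that every
    parcel is a connected component of the grid graph.
    """
    coords = np.argwhere(np.ones(grid_shape, dtype=bool))
    n = coords.shape[0]
    if k > n:
        raise ValueError(
            f"cannot host {k} contiguous parcels on a grid of {n} voxels"
        )
    # Farthest-point seed placement (Euclidean on voxel indices).
    seeds = [int(rng.integers(n))]
    for _ in range(k - 1):
        d = np.min(
            np.linalg.norm(coords[:, None, :] - coords[seeds][None, :, :], axis=2),
            axis=1,
        )
        seeds.append(int(np.argmax(d)))
    labels = np.zeros(n, dtype=int)
    index = {tuple(c): i for i, c in enumerate(coords)}
    frontiers: list[list[int]] = []
    for c, s in enumerate(seeds, start=1):
        labels[s] = c
        frontiers.append([s])
    offs = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    remaining = n - k
    while remaining > 0:
        progressed = False
        for c in range(1, k + 1):
            frontier = frontiers[c - 1]
            claimed = None
            while frontier and claimed is None:
                cand: list[int] = []
                for v in frontier:
                    for o in offs:
                        nb = index.get(tuple(coords[v] + o))
                        if nb is not None and labels[nb] == 0:
                            cand.append(nb)
                if cand:
                    claimed = int(rng.choice(np.unique(cand)))
                else:
                    frontiers[c - 1] = []
                    frontier = []
            if claimed is not None:
                labels[claimed] = c
                frontiers[c - 1].append(claimed)
                remaining -= 1
                progressed = True
        if not progressed:  # pragma: no cover - grid graph is connected
            raise RuntimeError("region growing stalled")
    return coords, labels


def _profile_components(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Shared and cluster-specific probability components over targets + sink.

    Preferred targets are dealt round-robin to clusters, guaranteeing
    separation, and each cluster additionally carries a random (seeded)
    Dirichlet tilt over all targets.  Without the tilt the k cluster
    directions would be exactly complementary (equal pairwise correlation
    -1/(k-1)), an algebraic degeneracy real tract systems do not have, and a
    PCA of the seed-voxel correlation matrix would see only k - 1 components.
    ``profile_separation`` mixes the two components downstream (per subject),
    so at separation 0 every cluster collapses onto the shared profile and
    the planted structure is genuinely unrecoverable.
    """
    k, t = cfg.k_planted, cfg.n_targets
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 7]))
    shared = np.empty(t + 1)
    shared[:t] = (1.0 - cfg.sink_fraction) / t
    shared[t] = cfg.sink_fraction
    specific = np.empty((k, t + 1))
    for c in range(k):
        preferred = np.arange(c, t, k)
        if preferred.size == 0:
            preferred = np.array([c % t])
        spec = np.zeros(t)
        spec[preferred] = 1.0 / preferred.size
        spec = 0.6 * spec + 0.4 * rng.dirichlet(np.ones(t))
        specific[c, :t] = (1.0 - cfg.sink_fraction) * spec
        specific[c, t] = cfg.sink_fraction
    return shared, specific


def _mix_profiles(
    shared: np.ndarray, specific: np.ndarray, separation: float
) -> np.ndarray:
    return (1.0 - separation) * shared[None, :] + separation * specific


def _target_atlas(n_targets: int) -> tuple[np.ndarray, np.ndarray]:
    """Column voxel coordinates and region labels for the target volume.

    Regions are 2x2x2 blocks laid out along the first axis of a native-
    resolution (1 mm) brain grid.
    """
    b = _TARGET_BLOCK
    coords = []
    labels = []
    for t in range(n_targets):
        base = np.array([t * b, 0, 0])
        for dx in range(b):
            for dy in range(b):
                for dz in range(b):
                    coords.append(base + (dx, dy, dz))
                    labels.append(t + 1)
    return np.array(coords), np.array(labels)


def _sample_counts(
    cfg: SyntheticConfig,
    labels: np.ndarray,
    subject_profile: np.ndarray,
    col_labels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one subject's count matrix: multinomial per seed voxel."""
    t = cfg.n_targets
    n_cols = col_labels.size
    # Probability per column: region mass spread uniformly over its voxels.
    per_region_voxels = np.bincount(col_labels, minlength=t + 1)[1:]
    counts = np.zeros((labels.size, n_cols), dtype=np.int64)
    kappa_vox = 4.0 / cfg.subject_noise**2 if cfg.subject_noise > 0 else None
    for i, lab in enumerate(labels):
        p = subject_profile[lab - 1]
        if kappa_vox is not None:
            p = rng.dirichlet(np.maximum(p * kappa_vox, 1e-8))
        col_p = np.empty(n_cols + 1)
        col_p[:n_cols] = p[col_labels - 1] / per_region_voxels[col_labels - 1]
        col_p[n_cols] = p[t]
        col_p /= col_p.sum()
        draw = rng.multinomial(cfg.samples_per_voxel, col_p)
        counts[i] = draw[:n_cols]  # sink column dropped; row sum <= samples
    return counts


def generate_cohort(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a deterministic multi-subject cohort from ``config``.

    The same config (including ``rng_seed``) always yields bit-identical
    matrices.  With ``bilateral=True`` the seed mask is two mirror-image
    hemispheres with identical planted parcel topology; counts are sampled
    independently per hemisphere.
    """
    rng = np.random.default_rng(config.rng_seed)
    coords_l, labels_l = _grow_parcels(config.grid_shape, config.k_planted, rng)
    gx = config.grid_shape[0]
    if config.bilateral:
        coords_r = coords_l.copy()
        coords_r[:, 0] = 2 * gx - 1 - coords_r[:, 0]
        coords = np.vstack([coords_l, coords_r])
        labels = np.concatenate([labels_l, labels_l])
        hemis = np.array(["L"] * len(labels_l) + ["R"] * len(labels_l))
        n_l = len(labels_l)
        reflection = np.concatenate([np.arange(n_l) + n_l, np.arange(n_l)])
    else:
        coords, labels = coords_l, labels_l
        hemis = np.array(["L"] * len(labels_l))
        reflection = None

    shared, specific = _profile_components(config)
    base = _mix_profiles(shared, specific, config.profile_separation)
    col_coords, col_labels = _target_atlas(config.n_targets)
    # Shift target columns away from the seed grid so coordinates never clash;
    # the offset stays even so 2 mm blocks remain aligned to region boundaries.
    offset = config.grid_shape[1] + 4
    offset += offset % 2
    col_coords = col_coords + np.array([0, offset, 0])

    kappa_subj = 1.0 / config.subject_noise**2 if config.subject_noise > 0 else None
    subject_profiles = np.empty((config.n_subjects, config.k_planted, base.shape[1]))
    matrices: list[ConnectivityMatrix] = []
    for s in range(config.n_subjects):
        if kappa_subj is None:
            prof = base.copy()
        else:
            # The shared component is perturbed ONCE per subject and the
            # cluster-specific components per cluster, then mixed: subject
            # variability never re-creates separation the config removed.
            shared_s = rng.dirichlet(np.maximum(shared * kappa_subj, 1e-8))
            specific_s = np.vstack(
                [rng.dirichlet(np.maximum(row * kappa_subj, 1e-8)) for row in specific]
            )
            prof = _mix_profiles(shared_s, specific_s, config.profile_separation)
        subject_profiles[s] = prof
        counts = _sample_counts(config, labels, prof, col_labels, rng)
        matrices.append(
            ConnectivityMatrix(
                counts=counts,
                seed_coords=coords,
                voxel_size=(1.0, 1.0, 1.0),
                samples_per_voxel=config.samples_per_voxel,
                column_coords=col_coords,
                column_labels=col_labels,
                subject_id=f"S{s + 1:02d}",
            )
        )
    return SyntheticDataset(
        config=config,
        matrices=matrices,
        labels=labels,
        hemispheres=hemis,
        seed_coords=coords,
        target_profiles=base,
        subject_profiles=subject_profiles,
        target_atlas=col_labels,
        reflection_map=reflection,
        seed_grid_shape=config.grid_shape,
    )


def mirror_hemisphere(dataset: SyntheticDataset) -> SyntheticDataset:
    """Append a mirror-image hemisphere to a unilateral dataset.

    The mirrored voxels are reflections across the first axis; their planted
    labels equal the originals under the reflection map, so the two
    hemispheres' parcel-adjacency graphs are isomorphic by construction.
    Counts are copied row-for-row (a topological mirror, not a resample).
    """
    if dataset.bilateral:
        raise ValueError("dataset is already bilateral")
    coords_l = dataset.seed_coords
    gx = dataset.seed_grid_shape[0]
    coords_r = coords_l.copy()
    coords_r[:, 0] = 2 * gx - 1 - coords_r[:, 0]
    coords = np.vstack([coords_l, coords_r])
    n_l = coords_l.shape[0]
    labels = np.concatenate([dataset.labels, dataset.labels])
    hemis = np.array(["L"] * n_l + ["R"] * n_l)
    reflection = np.concatenate([np.arange(n_l) + n_l, np.arange(n_l)])
    matrices = []
    for m in dataset.matrices:
        matrices.append(
            ConnectivityMatrix(
                counts=np.vstack([m.counts, m.counts]),
                seed_coords=coords,
                voxel_size=m.voxel_size,
                samples_per_voxel=m.samples_per_voxel,
                column_coords=m.column_coords,
                column_labels=m.column_labels,
                subject_id=m.subject_id,
            )
        )
    return SyntheticDataset(
        config=dataset.config,
        matrices=matrices,
        labels=labels,
        hemispheres=hemis,
        seed_coords=coords,
        target_profiles=dataset.target_profiles,
        subject_profiles=dataset.subject_profiles,
        target_atlas=dataset.target_atlas,
        reflection_map=reflection,
        seed_grid_shape=dataset.seed_grid_shape,
    )


def planted_family_fingerprints(
    family_sizes: tuple[int, ...] = (6, 6, 4),
    n_targets: int = 12,
    noise: float = 0.05,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic subregion fingerprints grouped into known families.

    Each family's center profile puts its mass on a disjoint block of
    targets, so family centers are mutually equidistant (well separated);
    members are the center plus Gaussian perturbations of scale ``noise``
    (clipped at 0).  Returns ``(strengths, family_labels)`` with labels
    1-based, for testing family recovery by hierarchical clustering.
    """
    rng = np.random.default_rng(rng_seed)
    n_fam = len(family_sizes)
    blocks = np.array_split(np.arange(n_targets), n_fam)
    strengths = []
    labels = []
    for fam, size in enumerate(family_sizes, start=1):
        center = np.zeros(n_targets)
        block = blocks[fam - 1]
        center[block] = 1.0 / block.size
        for _ in range(size):
            v = np.clip(center + noise * rng.normal(size=n_targets), 0.0, None)
            strengths.append(v)
            labels.append(fam)
    return np.array(strengths), np.array(labels)


def _equalize_column_variance(y: np.ndarray, tol: float = 1e-14) -> np.ndarray:
    """Rotate a point cloud so every coordinate has the same sample variance.

    Plane (Jacobi) rotations applied to the two most extreme coordinates
    preserve all pairwise Euclidean distances while driving the diagonal of
    the covariance matrix to its mean (such a rotation always exists).
    """
    x = np.array(y, dtype=float)
    for _ in range(10000):
        var = x.var(axis=0, ddof=1)
        i, j = int(np.argmax(var)), int(np.argmin(var))
        if var[i] - var[j] <= tol * max(var[i], 1.0):
            break
        a = var[i]
        c = var[j]
        b = np.cov(x[:, i], x[:, j], ddof=1)[0, 1]
        # Rotation by theta gives a' - c' = (a - c) cos 2t + 2b sin 2t,
        # which vanishes at 2t = atan2(c - a, 2b).
        theta = 0.5 * np.arctan2(c - a, 2.0 * b)
        ct, st = np.cos(theta), np.sin(theta)
        xi = ct * x[:, i] + st * x[:, j]
        xj = -st * x[:, i] + ct * x[:, j]
        x[:, i], x[:, j] = xi, xj
    return x


def ultrametric_seuclidean_data(
    n_items: int = 10, rng_seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Points whose *standardized*-Euclidean distances are exactly ultrametric.

    Construction: take the cophenetic (merge-height) distances of an
    average-linkage dendrogram over random points — an exact ultrametric D —
    embed D in Euclidean space by classical multidimensional scaling
    (ultrametrics are always Euclidean-embeddable), rotate the embedding so
    all coordinates share one sample variance, normalize that variance to 1,
    and finally stretch each coordinate by a distinct factor.  The stretch
    cancels inside the standardized-Euclidean metric (which divides by the
    per-coordinate variance), so seuclidean(X) reproduces D, while plain
    Euclidean and other metrics on X are no longer ultrametric.

    Returns ``(X, D)`` with D square.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist, squareform

    rng = np.random.default_rng(rng_seed)
    raw = rng.normal(size=(n_items, n_items))
    z = hierarchy.linkage(pdist(raw), method="average")
    d = squareform(hierarchy.cophenet(z))
    # Classical MDS: exact embedding of the ultrametric.
    j = np.eye(n_items) - np.ones((n_items, n_items)) / n_items
    bmat = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(bmat)
    keep = w > 1e-10 * w.max()
    y = v[:, keep] * np.sqrt(w[keep])
    y = _equalize_column_variance(y)
    y /= np.sqrt(y.var(axis=0, ddof=1, keepdims=True))
    scale = np.linspace(0.5, 2.0, y.shape[1])
    x = y * scale
    # seuclidean divides by ddof=1 variances, i.e. by scale**2, recovering
    # the unit-variance embedding whose Euclidean distances equal D (up to
    # the global normalization applied above).
    d_target = squareform(pdist(x, metric="seuclidean"))
    return x, d_target


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["grid_shape"] = list(config.grid_shape)
    return d
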