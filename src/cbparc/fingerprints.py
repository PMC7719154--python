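"""Subregion-to-target connectivity fingerprints and their comparisons.

A fingerprint summarizes, for each extracted subarea, the strength of its
connection to every named target region: per-voxel connection probabilities
(counts / samples) are thresholded at the individual level, summed over each
target's columns, and averaged over the subarea's seed voxels (a mean, so
subarea size does not dominate).  On top of fingerprints sit population
tract maps, inter-subject similarity statistics, a set-coherence comparison
against tracer-derived region lists, and normalized per-network connection
shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMatrix

__all__ = [
    "Fingerprint",
    "CoherenceReport",
    "compute_fingerprint",
    "population_map",
    "similarity_analysis",
    "coherence_with_tracer",
    "network_shares",
]


@dataclass
class Fingerprint:
    """Subarea x target connection-strength matrix for one subject."""

    strengths: np.ndarray  # (n_subareas, n_targets), mean probability per seed voxel
    subarea_ids: np.ndarray
    target_ids: np.ndarray
    subject_id: str = ""
    empty_subareas: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        if np.any(self.strengths < 0):
            raise ValueError("fingerprint strengths must be non-negative")
        if self.empty_subareas is None:
            self.empty_subareas = np.zeros(len(self.subarea_ids), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sa in enumerate(self.subarea_ids):
            for j, t in enumerate(self.target_ids):
                rows.append(
                    {
                        "subject": self.subject_id,
                        "subarea": sa,
                        "target": t,
                        "strength": self.strengths[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CoherenceReport:
    """Overlap of tracer-reported and tractography-found region sets."""

    tracer_set: frozenset
    found_set: frozenset
    coherence_percent: float
    missing: frozenset  # tracer regions we did not find
    extra: frozenset  # found regions absent from the tracer list


def compute_fingerprint(
    m: ConnectivityMatrix,
    subarea_masks: dict[int, np.ndarray],
    target_atlas: np.ndarray | None = None,
    seed_threshold: float = 3.08e-5,
) -> Fingerprint:
    """Connectivity fingerprint of each subarea of one subject.

    Per-column probabilities (counts / samples_per_voxel) below
    ``seed_threshold`` are zeroed at the individual level; the strength of a
    (subarea, target) pair is the mean over the subarea's seed voxels of the
    summed surviving probability into the target's columns.  ``target_atlas``
    gives a region id per column (0 = background, excluded); when omitted the
    matrix's own ``column_labels`` are used.
    """
    atlas = m.column_labels if target_atlas is None else np.asarray(target_atlas)
    if atlas is None:
        raise ValueError("a target atlas (region id per column) is required")
    if atlas.shape[0] != m.n_columns:
        raise ValueError("target atlas must label every column")
    prob = m.probabilities
    prob = np.where(prob >= seed_threshold, prob, 0.0)
    target_ids = np.unique(atlas[atlas > 0])
    # Sum probabilities into targets: (M, n_targets)
    per_target = np.zeros((m.n_seed_voxels, target_ids.size))
    for j, t in enumerate(target_ids):
        per_target[:, j] = prob[:, atlas == t].sum(axis=1)
    subarea_ids = np.array(sorted(subarea_masks))
    strengths = np.zeros((subarea_ids.size, target_ids.size))
    empty = np.zeros(subarea_ids.size, dtype=bool)
    for i, sa in enumerate(subarea_ids):
        mask = np.asarray(subarea_masks[sa], dtype=bool)
        if not mask.any():
            empty[i] = True
            continue
        strengths[i] = per_target[mask].mean(axis=0)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty subarea mask(s): fingerprint rows are zero",
            stacklevel=2,
        )
    return Fingerprint(
        strengths=strengths,
        subarea_ids=subarea_ids,
        target_ids=target_ids,
        subject_id=m.subject_id,
        empty_subareas=empty,
    )


def population_map(binary_maps: np.ndarray, min_fraction: float = 0.5) -> np.ndarray:
    """Group mask of voxels present in at least ``min_fraction`` of subjects.

    With 8 subjects and the default 50% cut, a voxel present in 4 subjects is
    kept and one present in 3 is dropped.  Monotone: raising the fraction can
    only shrink the mask.
    """
    maps = np.asarray(binary_maps)
    if maps.ndim < 2:
        raise ValueError("expected an array of per-subject maps")
    if not np.isin(maps, (0, 1)).all():
        raise ValueError("maps must be binarized (0/1)")
    return maps.mean(axis=0) >= min_fraction


def similarity_analysis(
    fingerprints: list[Fingerprint], alpha: float = 0.001
) -> pd.DataFrame:
    """Pairwise inter-subject similarity of subarea fingerprints.

    For each subarea, the Pearson correlation between every pair of subjects'
    target-strength vectors, with the two-sided p-value for the
    no-relationship null and a significance flag at ``alpha`` (default
    0.001).  Constant vectors make r undefined; such pairs are reported with
    NaN statistics.
    """
    if len(fingerprints) < 2:
        raise ValueError("need at least two subjects")
    ref = fingerprints[0]
    rows = []
    for si, sa in enumerate(ref.subarea_ids):
        for a in range(len(fingerprints)):
            for b in range(a + 1, len(fingerprints)):
                va = fingerprints[a].strengths[si]
                vb = fingerprints[b].strengths[si]
                if np.std(va) == 0 or np.std(vb) == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(va, vb)
                rows.append(
                    {
                        "subarea": sa,
                        "subject_a": fingerprints[a].subject_id,
                        "subject_b": fingerprints[b].subject_id,
                        "r": float(r),
                        "p": float(p),
                        "significant": bool(p < alpha) if np.isfinite(p) else False,
                    }
                )
    return pd.DataFrame(rows)


def coherence_with_tracer(tracer_set, found_set) -> CoherenceReport:
    """Percentage of tracer-reported regions recovered by tractography.

    ``coherence = |tracer ∩ found| / |tracer| * 100``; regions found beyond
    the tracer list do not penalize the score.  Region names must be
    harmonized by the caller (e.g. via an alias table).
    """
    tracer = frozenset(tracer_set)
    found = frozenset(found_set)
    if not tracer:
        raise ValueError("tracer set must be non-empty")
    inter = tracer & found
    pct = 100.0 * len(inter) / len(tracer)
    return CoherenceReport(
        tracer_set=tracer,
        found_set=found,
        coherence_percent=pct,
        missing=tracer - found,
        extra=found - tracer,
    )


def network_shares(
    fingerprint: Fingerprint, network_definitions: dict[str, set]
) -> pd.DataFrame:
    """Normalized per-network connection share of each subarea.

    A network's raw share is the fingerprint strength summed over its member
    regions (regions in several networks count in each); shares are then
    normalized per subarea to sum to 1.  Subareas with zero total connection
    get NaN shares and a flag.
    """
    names = list(network_definitions)
    target_index = {t: j for j, t in enumerate(fingerprint.target_ids)}
    raw = np.zeros((len(fingerprint.subarea_ids), len(names)))
    for n, name in enumerate(names):
        cols = [target_index[t] for t in network_definitions[name] if t in target_index]
        if cols:
            raw[:, n] = fingerprint.strengths[:, cols].sum(axis=1)
    totals = raw.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = raw / totals[:, None]
    rows = []
    for i, sa in enumerate(fingerprint.subarea_ids):
        undefined = totals[i] == 0
        if undefined:
            warnings.warn(f"subarea {sa} has zero network connection", stacklevel=2)
        for n, name in enumerate(names):
            rows.append(
                {
                    "subarea": sa,
                    "network": name,
                    "share": np.nan if undefined else float(shares[i, n]),
                    "undefined": bool(undefined),
                }
            )
    return pd.DataFrame(rows)
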