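"""Cross-subject label matching, maximum probability maps, subarea masks.

Subjects' cluster labels are arbitrary, so before any group map can be
computed each subject's labels are matched one-to-one onto a reference
subject by maximizing total voxel overlap (Hungarian assignment).  The
maximum probability map (MPM) then assigns each voxel the label it carries
most frequently across subjects; per-label probability maps record those
frequencies, and subarea masks are extracted by thresholding them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .parcellation import Parcellation

__all__ = ["GroupMaps", "match_labels", "compute_mpm", "extract_subarea_mask"]


@dataclass
class GroupMaps:
    """Group-level label maps over a common voxel space."""

    labels: np.ndarray  # the k label ids, 1..k
    prob_maps: np.ndarray  # (k, M): per-label frequency across subjects
    mpm: np.ndarray  # (M,): winning label per voxel
    seed_coords: np.ndarray
    ties: np.ndarray  # (M,) bool: argmax not unique (lowest id kept)
    n_subjects: int


def overlap_matrix(ref: Parcellation, other: Parcellation) -> np.ndarray:
    """k x k matrix of shared-voxel counts between two labelings."""
    k = ref.k
    o = np.zeros((k, k), dtype=int)
    np.add.at(o, (ref.labels - 1, other.labels - 1), 1)
    return o


def match_labels(
    parcellations: list[Parcellation], reference: int = 0
) -> tuple[list[Parcellation], pd.DataFrame]:
    """Permute each subject's labels to best agree with a reference subject.

    The optimal one-to-one assignment maximizes total voxel overlap with the
    reference (Hungarian algorithm on the overlap matrix).  All subjects must
    share the voxel space and the cluster count.  Returns the relabeled
    cohort plus a report with one row per (subject, reference label):
    the matched original label and the overlap it contributed; zero-overlap
    assignments (arbitrary but deterministic) are flagged.
    """
    if not parcellations:
        raise ValueError("empty cohort")
    ks = {p.k for p in parcellations}
    if len(ks) != 1:
        raise ValueError(f"cluster counts differ across subjects: {sorted(ks)}")
    ref = parcellations[reference]
    rows = []
    relabeled: list[Parcellation] = []
    for p in parcellations:
        o = overlap_matrix(ref, p)
        ref_idx, other_idx = linear_sum_assignment(-o)
        perm = np.empty(p.k, dtype=int)  # original label index -> new label index
        perm[other_idx] = ref_idx
        relabeled.append(replace(p, labels=perm[p.labels - 1] + 1))
        for r, c in zip(ref_idx, other_idx):
            rows.append(
                {
                    "subject": p.subject_id,
                    "reference_label": int(r + 1),
                    "matched_label": int(c + 1),
                    "overlap_voxels": int(o[r, c]),
                    "zero_overlap": bool(o[r, c] == 0),
                }
            )
    report = pd.DataFrame(rows)
    if report["zero_overlap"].any():
        warnings.warn(
            "some label assignments have zero voxel overlap with the reference",
            stacklevel=2,
        )
    return relabeled, report


def compute_mpm(relabeled: list[Parcellation]) -> GroupMaps:
    """Maximum probability map of a label-matched cohort.

    For each voxel, the frequency of every label across subjects is the
    per-label probability map; the MPM keeps the most frequent label.  Exact
    frequency ties are broken deterministically toward the lowest label id
    and flagged.  Invariant to subject ordering.
    """
    if not relabeled:
        raise ValueError("empty cohort")
    k = relabeled[0].k
    m = relabeled[0].n_voxels
    counts = np.zeros((k, m), dtype=int)
    for p in relabeled:
        if p.n_voxels != m or p.k != k:
            raise ValueError("cohort voxel spaces or cluster counts differ")
        counts[p.labels - 1, np.arange(m)] += 1
    freq = counts / float(len(relabeled))
    mpm = np.argmax(freq, axis=0) + 1  # argmax takes the lowest index on ties
    top = freq.max(axis=0)
    ties = (freq == top).sum(axis=0) > 1
    if ties.any():
        warnings.warn(f"{int(ties.sum())} voxel(s) with tied MPM labels", stacklevel=2)
    return GroupMaps(
        labels=np.arange(1, k + 1),
        prob_maps=freq,
        mpm=mpm,
        seed_coords=relabeled[0].seed_coords,
        ties=ties,
        n_subjects=len(relabeled),
    )


def extract_subarea_mask(prob_map: np.ndarray, threshold: float = 0.25) -> np.ndarray:
    """Boolean mask of voxels whose label frequency reaches ``threshold``.

    Inclusive at the threshold: a voxel carried by 2 of 8 subjects survives a
    25% cut.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    mask = np.asarray(prob_map, dtype=float) >= threshold
    if not mask.any():
        warnings.warn("subarea mask is empty at this threshold", stacklevel=2)
    return mask
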