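"""End-to-end connectivity-based parcellation pipeline.

Binds the stages together: synthetic-cohort generation, profile
preprocessing (count threshold, spatial down-sampling, cross-correlation),
per-subject spectral parcellation over a k range, cluster-number selection,
cross-subject label matching and maximum probability maps, connectivity
fingerprints with similarity/coherence/network summaries, and the
hierarchical modularity analysis.  Every stage writes its outputs under the
results directory and is recorded, with file hashes, in a run manifest, so a
run is fully reproducible from its manifest (config + seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import io as cio
from .connectivity import cross_correlation, downsample_profiles, threshold_counts
from .fingerprints import (
    coherence_with_tracer,
    compute_fingerprint,
    network_shares,
    population_map,
    similarity_analysis,
)
from .group_maps import compute_mpm, extract_subarea_mask, match_labels
from .modularity import cut_families, search_best_clustering
from .parcellation import parcellate_cohort
from .selection import ValidityProfile, mean_cramers_v, pca_criteria, select_k, tpd
from .synthetic import SyntheticConfig, SyntheticDataset, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = (
    "generate",
    "preprocess",
    "parcellate",
    "select_k",
    "group_maps",
    "fingerprints",
    "modularity",
)


@dataclass
class PipelineConfig:
    """All numeric defaults of the pipeline plus stage toggles.

    The thresholds keep their conventional tractography semantics: counts
    below ``min_count`` (of ``synthetic.samples_per_voxel`` samples) are
    false-positive candidates and removed; profiles are down-sampled to
    ``downsample_mm`` isotropic columns; fingerprint probabilities below
    ``seed_threshold`` are zeroed at the individual level; probability maps
    are cut at ``prob_threshold`` to extract subarea masks, and population
    tract maps keep voxels present in at least ``population_fraction`` of
    subjects.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    min_count: float = 20.0
    downsample_mm: float = 2.0
    k_range: tuple[int, ...] = tuple(range(2, 8))
    prob_threshold: float = 0.25
    population_fraction: float = 0.5
    seed_threshold: float = 3.08e-5
    cpv_threshold: float = 0.80
    cpv_tolerance: float = 0.01
    eigen_closeness: float = 0.2
    stability_delta: float = 0.5
    significance: float = 0.001
    bilateral_modularity: bool = False
    n_families: int | None = None  # None = automatic largest-gap cut
    stages: tuple[str, ...] = ALL_STAGES
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prob_threshold <= 1:
            raise ValueError("prob_threshold must lie in (0, 1]")
        if not 0 < self.population_fraction <= 1:
            raise ValueError("population_fraction must lie in (0, 1]")
        if self.min_count < 0 or self.seed_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["grid_shape"] = list(self.synthetic.grid_shape)
        d["k_range"] = list(self.k_range)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        if "grid_shape" in syn:
            syn["grid_shape"] = tuple(syn["grid_shape"])
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name == "synthetic":
                continue
            if f.name in d:
                v = d[f.name]
                if f.name in ("k_range", "stages"):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(synthetic=SyntheticConfig(**syn), **kwargs)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    out_dir: Path
    dataset: SyntheticDataset | None = None
    correlations: dict = field(default_factory=dict)  # side -> list per subject
    matrices: dict = field(default_factory=dict)  # side -> list per subject
    native_matrices: dict = field(default_factory=dict)  # thresholded, not down-sampled
    parcellations: dict = field(default_factory=dict)  # side -> {(subject,k): Parcellation}
    validity: dict = field(default_factory=dict)  # side -> ValidityProfile
    selection: dict = field(default_factory=dict)  # side -> KSelection
    group_maps: dict = field(default_factory=dict)  # side -> GroupMaps
    subarea_masks: dict = field(default_factory=dict)  # side -> {label: mask}
    fingerprints: dict = field(default_factory=dict)  # side -> list per subject
    group_fingerprint: dict = field(default_factory=dict)  # side -> (items x targets)
    similarity: dict = field(default_factory=dict)  # side -> DataFrame
    coherence: dict = field(default_factory=dict)  # side -> CoherenceReport
    shares: dict = field(default_factory=dict)  # side -> DataFrame
    modular: dict = field(default_factory=dict)  # scope -> ModularSolution
    families: dict = field(default_factory=dict)  # scope -> labels array
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sides(ds: SyntheticDataset) -> list[str]:
    return ["L", "R"] if ds.bilateral else ["L"]


def _newick(z: np.ndarray, names: list[str]) -> str:
    tree = hierarchy.to_tree(z)

    def rec(node) -> str:
        if node.is_leaf():
            return f"{names[node.id]}:{node.dist:.6g}"
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"


def _hemisphere_matrix(m, idx):
    return dataclasses.replace(
        m, counts=m.counts[idx], seed_coords=np.asarray(m.seed_coords)[idx]
    )


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute the configured stages in order, writing results to ``out_dir``.

    Stage failures abort with a stage-tagged error; outputs of completed
    stages stay on disk.  A fixed ``config.rng_seed`` makes the whole run,
    including the manifest hashes, bit-reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(config=config, out_dir=out)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "results": {}}
    cio.write_config(out / "config.yaml", config.to_dict())

    stages = [s for s in ALL_STAGES if s in config.stages]
    for stage in stages:
        try:
            _STAGE_FUNCS[stage](config, res, out)
        except Exception as exc:
            _write_manifest(out, manifest, res)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = "completed"
    _write_manifest(out, manifest, res)
    return res


def _write_manifest(out: Path, manifest: dict, res: PipelineResult) -> None:
    for side, sel in res.selection.items():
        manifest["results"][f"selected_k_{side}"] = sel.selected_k
    for scope, sol in res.modular.items():
        manifest["results"][f"best_metric_{scope}"] = sol.best_metric
        manifest["results"][f"best_linkage_{scope}"] = sol.best_linkage
        manifest["results"][f"cophenetic_{scope}"] = sol.cophenetic
    for side, rep in res.coherence.items():
        manifest["results"][f"coherence_percent_{side}"] = rep.coherence_percent
    manifest["files"] = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    res.manifest = manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_generate(cfg: PipelineConfig, res: PipelineResult, out: Path) -> None:
    ds = generate_cohort(cfg.synthetic)
    res.dataset = ds
    d = out / "dataset"
    d.mkdir(exist_ok=True)
    truth = pd.DataFrame(
        {
            "voxel": np.arange(ds.labels.size),
            "i": ds.seed_coords[:, 0],
            "j": ds.seed_coords[:, 1],
            "k": ds.seed_coords[:, 2],
            "label": ds.labels,
            "hemisphere": ds.hemispheres,
        }
    )
    cio.write_table(d / "ground_truth.csv", truth)
    shape = (
        2 * ds.seed_grid_shape[0] if ds.bilateral else ds.seed_grid_shape[0],
        ds.seed_grid_shape[1],
        ds.seed_grid_shape[2],
    )
    cio.write_label_volume(d / "ground_truth.nii.gz", ds.labels, ds.seed_coords, shape)
    for m in ds.matrices:
        cio.write_matrix(d / f"counts_{m.subject_id}", m)


def _stage_preprocess(cfg: PipelineConfig, res: PipelineResult, out: Path) -> None:
    ds = res.dataset
    if ds is None:
        raise ValueError("no dataset (enable the generate stage or load one)")
    d = out / "preprocess"
    d.mkdir(exist_ok=True)
    for side in _sides(ds):
        idx = ds.hemisphere_index(side)
        native, mats, corrs = [], [], []
        for m in ds.matrices:
            hm = threshold_counts(_hemisphere_matrix(m, idx), cfg.min_count)
            native.append(hm)
            hm = downsample_profiles(hm, cfg.downsample_mm)
            mats.append(hm)
            corrs.append(cross_correlation(hm))
        res.native_matrices[side] = native
        res.matrices[side] = mats
        res.correlations[side] = corrs
        np.save(d / f"correlation_{side}_{mats[0].subject_id}.npy", corrs[0].values)


def _stage_parcellate(cfg: PipelineConfig, res: PipelineResult, out: Path) -> None:
    d = out / "parcellation"
    d.mkdir(exist_ok=True)
    rows = []
    for i, side in enumerate(sorted(res.correlations)):
        parcs = parcellate_cohort(
            res.correlations[side],
            cfg.k_range,
            rng_seed=cfg.rng_seed + i,
            hemisphere=side,
        )
        res.parcellations[side] = parcs
        for (subject, k), p in parcs.items():
            for v, lab in enumerate(p.labels):
                rows.append(
                    {"hemisphere": side, "subject": subject, "k": k,
                     "voxel": v, "label": int(lab)}
                )
    cio.write_table(d / "parcellations.csv", pd.DataFrame(rows))


def _validity_profile(cfg: PipelineConfig, res: PipelineResult, side: str) -> ValidityProfile:
    ds = res.dataset
    parcs = res.parcellations[side]
    subjects = [m.subject_id for m in ds.matrices]
    ks = sorted(cfg.k_range)
    v_series, t_series = [], []
    for k in ks:
        per_subj = [parcs[(s, k)] for s in subjects]
        v_series.append(mean_cramers_v(per_subj))
        if ds.bilateral:
            other = res.parcellations["R" if side == "L" else "L"]
            tvals = [tpd(parcs[(s, k)], other[(s, k)]) for s in subjects]
        else:  # unilateral: topological consistency across subject pairs
            tvals = [
                tpd(per_subj[a], per_subj[b])
                for a in range(len(per_subj))
                for b in range(a + 1, len(per_subj))
            ]
        t_series.append(float(np.mean(tvals)))
    inflexions = {}
    # PCA runs on the native-resolution (thresholded) matrices: the richer
    # column space gives a full-rank spectrum for the scree fit.
    for m in res.native_matrices[side]:
        _, _, c3 = pca_criteria(
            m, cfg.cpv_threshold, cfg.cpv_tolerance, cfg.eigen_closeness
        )
        inflexions[m.subject_id] = np.nan if c3 is None else float(c3)
    return ValidityProfile(
        k_values=np.array(ks),
        mean_cramers_v=np.array(v_series),
        mean_tpd=np.array(t_series),
        pca_inflexions=inflexions,
    )


def _stage_select_k(cfg: PipelineConfig, res: PipelineResult, out: Path) -> None:
    d = out / "selection"
    d.mkdir(exist_ok=True)
    for side in sorted(res.parcellations):
        prof = _validity_profile(cfg, res, side)
        res.validity[side] = prof
        sel = select_k(prof, cfg.stability_delta)
        res.selection[side] = sel
        cio.write_table(
            d / f"validity_{side}.csv",
            pd.DataFrame(
                {"k": prof.k_values, "mean_cramers_v": prof.mean_cramers_v,
                 "mean_tpd": prof.mean_tpd}
            ),
        )
        cio.write_table(
            d / f"pca_inflexions_{side}.csv",
            pd.DataFrame(
                [{"subject": s, "inflexion": v} for s, v in prof.pca_inflexions.items()]
            ),
        )
        (d / f"selected_k_{side}.json").write_text(
            json.dumps(
                {
                    "selected_k": sel.selected_k,
                    "candidates": sel.candidates,
                    "pca_mean": sel.pca_mean,
                    "excluded_subjects": sel.excluded_subjects,
                    "used_fallback": sel.used_fallback,
                }
            )
        )


def _stage_group_maps(cfg: PipelineConfig, res: PipelineResult, out: Path) -> None:
    ds = res.dataset
    d = out / "group_maps"
    d.mkdir(exist_ok=True)
    for side in sorted(res.selection):
        k = res.selection[side].selected_k
        subjects = [m.subject_id for m in ds.matrices]
        cohort = [res.parcellations[side][(s, k)] for s in subjects]
        relabeled, report = match_labels(cohort)
        gm = compute_mpm(relabeled)
        res.group_maps[side] = gm
        masks = {
            int(lab): extract_subarea_mask(gm.prob_maps[i], cfg.prob_threshold)
            for i, lab in enumerate(gm.labels)
        }
        res.subarea_masks[side] = masks
        cio.write_table(d / f"label_matching_{side}.csv", report)
        shape = (
            2 * ds.seed_grid_shape[0] if ds.bilateral else ds.seed_grid_shape[0],
            ds.seed_grid_shape[1],
            ds.seed_grid_shape[2],
        )
        idx = ds.hemisphere_index(side)
        cio.write_label_volume(
            d / f"mpm_{side}.nii.gz", gm.mpm, ds.seed_coords[idx], shape
        )
        for i, lab in enumerate(gm.labels):
            cio.write_label_volume(
                d / f"prob_{side}_C{lab}.nii.gz",
                gm.prob_maps[i],
                ds.seed_coords[idx],
                shape,
            )


def _default_networks(target_ids: np.ndarray) -> dict[str, set]:
    """Three contiguous blocks of targets standing in for functional networks."""
    thirds = np.array_split(np.asarray(target_ids), 3)
    return {f"network_{i + 1}": set(map(int, t)) for i, t in enumerate(thirds)}


def _stage_fingerprints(cfg: PipelineConfig, res: PipelineResult, out: Path) -> None:
    ds = res.dataset
    d = out / "fingerprints"
    d.mkdir(exist_ok=True)
    for side in sorted(res.subarea_masks):
        idx = ds.hemisphere_index(side)
        masks = res.subarea_masks[side]
        fps = []
        for m in ds.matrices:
            hm = threshold_counts(_hemisphere_matrix(m, idx), cfg.min_count)
            fps.append(
                compute_fingerprint(hm, masks, seed_threshold=cfg.seed_threshold)
            )
        res.fingerprints[side] = fps
        group = np.mean([f.strengths for f in fps], axis=0)
        res.group_fingerprint[side] = group
        cio.write_table(
            d / f"fingerprints_{side}.csv",
            pd.concat([f.to_frame() for f in fps], ignore_index=True),
        )
        sim = similarity_analysis(fps, alpha=cfg.significance)
        res.similarity[side] = sim
        cio.write_table(d / f"similarity_{side}.csv", sim)

        # Population tract maps: per subject, the binarized set of columns any
        # subarea voxel reaches after the individual-level threshold.
        hm0 = threshold_counts(_hemisphere_matrix(ds.matrices[0], idx), cfg.min_count)
        n_cols = hm0.n_columns
        pop = {}
        for lab, mask in masks.items():
            binmaps = []
            for m in ds.matrices:
                hm = threshold_counts(_hemisphere_matrix(m, idx), cfg.min_count)
                prob = hm.probabilities
                prob = np.where(prob >= cfg.seed_threshold, prob, 0.0)
                reach = (prob[np.asarray(mask, bool)] > 0).any(axis=0) if mask.any() else np.zeros(n_cols, bool)
                binmaps.append(reach.astype(int))
            pop[lab] = population_map(np.array(binmaps), cfg.population_fraction)
        np.save(d / f"population_maps_{side}.npy", np.array([pop[k] for k in sorted(pop)]))

        # Tracer coherence: the planted preferred targets are the "tracer"
        # ground truth; targets any subarea reaches in the group fingerprint
        # are the "found" set.
        tracer = {
            int(t) + 1
            for c in range(ds.target_profiles.shape[0])
            for t in np.flatnonzero(
                ds.target_profiles[c, :-1] > 1.0 / ds.config.n_targets
            )
        }
        found = {
            int(t)
            for j, t in enumerate(fps[0].target_ids)
            if np.any(group[:, j] > 0)
        }
        rep = coherence_with_tracer(tracer, found)
        res.coherence[side] = rep
        (d / f"coherence_{side}.json").write_text(
            json.dumps(
                {
                    "coherence_percent": rep.coherence_percent,
                    "tracer": sorted(rep.tracer_set),
                    "found": sorted(rep.found_set),
                    "missing": sorted(rep.missing),
                    "extra": sorted(rep.extra),
                }
            )
        )
        group_fp = dataclasses.replace(
            fps[0], strengths=group, subject_id="group"
        )
        shares = network_shares(group_fp, _default_networks(fps[0].target_ids))
        res.shares[side] = shares
        cio.write_table(d / f"network_shares_{side}.csv", shares)


def _stage_modularity(cfg: PipelineConfig, res: PipelineResult, out: Path) -> None:
    d = out / "modularity"
    d.mkdir(exist_ok=True)
    scopes: dict[str, tuple[list[str], np.ndarray]] = {}
    for side in sorted(res.group_fingerprint):
        items = [f"{side}_C{lab}" for lab in sorted(res.subarea_masks[side])]
        scopes[side] = (items, res.group_fingerprint[side])
    if cfg.bilateral_modularity and len(scopes) == 2:
        items = scopes["L"][0] + scopes["R"][0]
        strengths = np.vstack([scopes["L"][1], scopes["R"][1]])
        scopes = {"bilateral": (items, strengths)}
    for scope, (items, strengths) in scopes.items():
        sol = search_best_clustering(strengths, items=items)
        fam = cut_families(sol, cfg.n_families)
        res.modular[scope] = sol
        res.families[scope] = fam
        cio.write_table(d / f"search_table_{scope}.csv", sol.search_table)
        cio.write_table(
            d / f"families_{scope}.csv",
            pd.DataFrame({"item": items, "family": fam}),
        )
        (d / f"dendrogram_{scope}.nwk").write_text(
            _newick(sol.linkage_matrix, items)
        )


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "preprocess": _stage_preprocess,
    "parcellate": _stage_parcellate,
    "select_k": _stage_select_k,
    "group_maps": _stage_group_maps,
    "fingerprints": _stage_fingerprints,
    "modularity": _stage_modularity,
}
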