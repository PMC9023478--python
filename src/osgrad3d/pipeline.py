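"""End-to-end orchestration: register -> osmap -> segment -> pom -> gradients -> summarize.

A single JSON (or YAML) config drives the whole protocol; every stage
writes its outputs under the output directory and records parameters,
seeds, software version and output checksums in a manifest, so a rerun
with the same config and seeds reproduces the tables byte for byte and a
partially complete run resumes from the intermediates already on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accounting import cohort_table, summarize_aggregate
from .gradients import (
    bulk_statistics,
    connected_pores,
    detect_extent,
    distance_map,
    interior_core,
    profile,
)
from .morphology import assign_pom_classes, label_pom, pom_object_table
from .osmap import NormalizationAnchors, difference, normalize
from .registration import estimate_similarity, read_landmarks, resample
from .segmentation import aggregate_mask, compute_features, harvest_training_set, segment, train_voxel_classifier
from .volumes import LabelVolume, read_labels, read_volume, write_volume

log = logging.getLogger("osgrad3d")

STAGES = ("register", "osmap", "segment", "pom", "gradients", "summarize")


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the protocol's stated values."""

    pre_path: str = ""
    post_path: str = ""
    landmarks_fixed: str | None = None
    landmarks_moving: str | None = None
    scribbles_path: str = ""
    pom_training_csv: str | None = None
    out_dir: str = "osgrad3d_out"
    voxel_size_um: float | None = None
    plastic_box: list | None = None  # [z0, z1, y0, y1, x0, x1]
    quartz_box: list | None = None
    plastic_target: float = 40.0
    quartz_target: float = 120.0
    sigmas: tuple[float, ...] = (0.3, 0.7, 1.0)
    median_radius: int = 1
    majority_radius: int = 1
    min_pom_voxels: int = 5000
    voxel_forest_trees: int = 100
    pom_forest_trees: int = 500
    pom_forest_mtry: int = 2
    seed: int = 0
    bin_width_um: float | None = None
    bulk_quantile: float = 0.75
    persistence_bins: int = 3
    drainage_diameter_um: float = 30.0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        cfg = cls(**raw)
        return cfg


def _box_mask(shape: tuple[int, int, int], box: list) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    z0, z1, y0, y1, x0, x1 = box
    m[z0:z1, y0:y1, x0:x1] = True
    return m


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    Stage outputs already present in ``out_dir`` are reused (resume); any
    stage failure is re-raised annotated with the stage name and input.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        "stages": {},
    }

    def run_stage(name, fn):
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest["stages"][name] = {"status": "complete", "seconds": round(time.time() - t0, 3)}
        log.info("stage %s: done (%.1fs)", name, time.time() - t0)

    state: dict = {}

    def stage_register():
        pre = read_volume(config.pre_path, voxel_size_um=config.voxel_size_um, stage="pre_stain")
        state["pre"] = pre
        reg_path = out / "post_registered.nrrd"
        if reg_path.exists():
            state["post_reg"] = read_volume(reg_path, stage="registered")
            state["valid"] = np.isfinite(state["post_reg"].data)
            return
        post = read_volume(config.post_path, voxel_size_um=config.voxel_size_um, stage="post_stain")
        if config.landmarks_fixed and config.landmarks_moving:
            tf = estimate_similarity(
                read_landmarks(config.landmarks_fixed), read_landmarks(config.landmarks_moving)
            )
            manifest["stages"].setdefault("register", {})
            manifest["registration_rms_um"] = tf.residual_rms_um
            post_reg, valid = resample(post, tf, pre)
        else:  # already aligned (e.g. phantom pairs)
            post_reg, valid = post, np.ones(post.shape, dtype=bool)
            post_reg.stage = "registered"
        state["post_reg"], state["valid"] = post_reg, valid
        write_volume(post_reg, reg_path)

    def stage_osmap():
        pre, post_reg = state["pre"], state["post_reg"]
        anchors = NormalizationAnchors(
            plastic_mask=_box_mask(pre.shape, config.plastic_box),
            quartz_mask=_box_mask(pre.shape, config.quartz_box),
            plastic_target=config.plastic_target,
            quartz_target=config.quartz_target,
        )
        pre_n = normalize(pre, anchors)
        post_n = normalize(post_reg, anchors)
        state["pre_norm"] = pre_n
        state["os"] = difference(pre_n, post_n, median_radius=config.median_radius)
        write_volume(state["os"], out / "os_ct.nrrd")
        write_volume(pre_n, out / "pre_norm.nrrd")

    def stage_segment():
        pre_n = state["pre_norm"]
        labels_path = out / "labels.nrrd"
        if labels_path.exists():
            state["labels"] = read_labels(labels_path)
            return
        scribbles = read_volume(config.scribbles_path, voxel_size_um=pre_n.voxel_size_um).data.astype(int)
        feats = compute_features(pre_n, tuple(config.sigmas))
        X, y = harvest_training_set(feats, scribbles)
        clf = train_voxel_classifier(X, y, n_trees=config.voxel_forest_trees, rng_seed=config.seed)
        agg = aggregate_mask(pre_n)
        labels = segment(pre_n, clf, agg, majority_radius=config.majority_radius, features=feats)
        state["labels"] = labels
        write_volume(labels, labels_path)

    def stage_pom():
        labels, osv = state["labels"], state["os"]
        objects, table = label_pom(labels, min_voxels=config.min_pom_voxels)
        pore_dist = distance_map(labels, labels.mask("pore")) if labels.mask("pore").any() else None
        table = pom_object_table(objects, table, osv, pore_distance_um=pore_dist)
        if config.pom_training_csv and not table.empty:
            from .morphology import PomTrainingSplit, train_pom_classifier

            lab = pd.read_csv(config.pom_training_csv).set_index("id")
            feats = table.set_index("id")
            common = feats.index.intersection(lab.index)
            split = PomTrainingSplit.from_labels(
                feats.loc[common], lab.loc[common, "pom_class"], rng_seed=config.seed
            )
            clf, val_acc, oob = train_pom_classifier(
                split, n_trees=config.pom_forest_trees, mtry=config.pom_forest_mtry, rng_seed=config.seed
            )
            manifest["pom_validation_accuracy"] = val_acc
            manifest["pom_oob_error"] = oob
            table, tagged = assign_pom_classes(table, clf, objects)
        else:
            tagged = np.zeros(labels.shape, dtype=np.uint8)
        state["pom_table"], state["pom_tagged"], state["pore_dist"] = table, tagged, pore_dist
        table.to_csv(out / "pom_objects.csv", index=False)

    def stage_gradients():
        labels, osv = state["labels"], state["os"]
        matrix = labels.mask("matrix") & interior_core(labels, radius=config.median_radius)
        results = {}
        for ref_name, ref_mask in (
            ("pore", labels.mask("pore")),
            ("connected_pore", connected_pores(labels)),
        ):
            if not ref_mask.any():
                continue
            d = distance_map(labels, ref_mask)
            prof = profile(osv, d, matrix, bin_width_um=config.bin_width_um, reference_phase=ref_name)
            prof.bins.to_csv(out / f"profile_{ref_name}.csv", index=False)
            bm, bs, cutoff = bulk_statistics(osv, d, matrix, far_field_quantile=config.bulk_quantile)
            ext = detect_extent(
                prof, bm, bs, persistence_bins=config.persistence_bins, distances_um=d, restricted_mask=matrix
            )
            results[ref_name] = {
                "extent_um": ext.extent_um,
                "direction": ext.direction,
                "affected_volume_fraction": ext.affected_volume_fraction,
                "bulk_mean": bm,
                "bulk_sd": bs,
                "bulk_cutoff_um": cutoff,
                "censored": ext.censored,
            }
        (out / "extents.json").write_text(json.dumps(results, indent=1))
        state["extents"] = results

    def stage_summarize():
        summary = summarize_aggregate(
            state["labels"], state["os"], state["pre_norm"], pom_class_volume=state.get("pom_tagged")
        )
        table, _ = cohort_table([summary])
        table.to_csv(out / "summary.csv", index=False)

    for name, fn in (
        ("register", stage_register),
        ("osmap", stage_osmap),
        ("segment", stage_segment),
        ("pom", stage_pom),
        ("gradients", stage_gradients),
        ("summarize", stage_summarize),
    ):
        run_stage(name, fn)

    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*")) if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
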