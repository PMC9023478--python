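"""POM labeling, shape descriptors, fibrous/compact random forest."""

import numpy as np
import pandas as pd
import pytest

import osgrad3d as og
from osgrad3d.morphology import (
    FEATURE_COLUMNS,
    POM_COMPACT,
    POM_FIBROUS,
    shape_descriptors,
)
from osgrad3d.volumes import LabelVolume, ScalarVolume


def _labels_with_pom(blobs):
    """Build a LabelVolume with given POM blobs on a matrix background."""
    data = np.full((64, 64, 64), 3, dtype=np.uint8)
    for center, r in blobs:
        zz, yy, xx = np.mgrid[:64, :64, :64]
        data[(zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= r**2] = 2
    return LabelVolume(data, 5.0)


def test_two_blobs_above_threshold_two_objects():
    lab = _labels_with_pom([((16, 16, 16), 12), ((46, 46, 46), 12)])  # ~7200 voxels each
    objects, table = og.label_pom(lab, min_voxels=5000)
    assert len(table) == 2
    assert sorted(table["id"]) == [1, 2]
    assert (table["volume_um3"] == table["voxel_count"] * 125.0).all()


def test_size_filter_strictly_greater():
    lab = _labels_with_pom([((32, 32, 32), 10)])  # ~4169 voxels < 5000
    objects, table = og.label_pom(lab, min_voxels=5000)
    assert len(table) == 0
    assert (objects == 0).all()
    assert lab.mask("POM").sum() > 0  # voxels still POM for accounting
    # exactly-at-threshold component is excluded too (strict >)
    n = int(lab.mask("POM").sum())
    _, table_eq = og.label_pom(lab, min_voxels=n)
    assert len(table_eq) == 0
    _, table_lt = og.label_pom(lab, min_voxels=n - 1)
    assert len(table_lt) == 1


def test_component_count_matches_phantom_truth(small_phantom):
    _, _, _, truth = small_phantom
    n_true = len(truth.pom_classes)
    _, table = og.label_pom(truth.labels, min_voxels=500)
    # phantom objects are placed non-adjacent, so components match objects
    assert len(table) == n_true


def test_descriptors_ball_tube_plate():
    zz, yy, xx = np.mgrid[-15:16, -15:16, -15:16]
    ball = zz**2 + yy**2 + xx**2 <= 12**2
    d = shape_descriptors(ball)
    assert abs(d["elongation"] - 1) < 0.05 and abs(d["plateness"] - 1) < 0.05
    assert d["compactness"] > 0.7  # near the digital-sphere maximum

    tube = np.zeros((110, 21, 21), dtype=bool)
    zz, yy, xx = np.mgrid[:110, :21, :21]
    tube[(zz >= 5) & (zz < 105) & ((yy - 10) ** 2 + (xx - 10) ** 2 <= 25)] = True
    d = shape_descriptors(tube)
    assert d["elongation"] > 5 and abs(d["plateness"] - 1) < 0.1

    plate = np.zeros((70, 70, 16), dtype=bool)
    plate[5:65, 5:65, 5:11] = True
    d = shape_descriptors(plate)
    assert abs(d["elongation"] - 1) < 0.05 and d["plateness"] > 5


def test_descriptor_invariances():
    rng = np.random.default_rng(0)
    blob = np.zeros((40, 40, 40), dtype=bool)
    zz, yy, xx = np.mgrid[:40, :40, :40]
    blob[((zz - 20) / 12.0) ** 2 + ((yy - 20) / 8.0) ** 2 + ((xx - 20) / 6.0) ** 2 <= 1] = True
    base = shape_descriptors(blob)
    # translation: embed at an offset in a larger grid
    big = np.zeros((60, 60, 60), dtype=bool)
    big[7:47, 11:51, 3:43] = blob
    moved = shape_descriptors(big)
    for k in ("elongation", "plateness", "compactness"):
        assert np.isclose(moved[k], base[k], rtol=1e-6)
    # axis permutation
    perm = shape_descriptors(np.transpose(blob, (2, 0, 1)))
    for k in ("elongation", "plateness", "compactness"):
        assert np.isclose(perm[k], base[k], rtol=1e-6)


def test_degenerate_collinear_mask_plateness_inf():
    line = np.zeros((30, 5, 5), dtype=bool)
    line[2:28, 2, 2] = True
    d = shape_descriptors(line)
    assert d["elongation"] > 5
    assert d["plateness"] < np.inf  # voxel extent keeps c > 0 for a 1-wide line
    single_plane = np.zeros((5, 30, 30), dtype=bool)
    single_plane[2, 5:25, 5:25] = True
    assert shape_descriptors(single_plane)["plateness"] > 5


def test_mean_os_and_empty_mask():
    mask = np.zeros((10, 10, 10), dtype=bool)
    with pytest.raises(ValueError):
        shape_descriptors(mask)
    mask[4:6, 4:6, 4:6] = True
    vol = ScalarVolume(np.full((10, 10, 10), 42.0), 5.0, stage="difference")
    assert shape_descriptors(mask, vol)["mean_os"] == 42.0


def _feature_frame(shapes, os_levels=None):
    rows = []
    for i, (mask, cls) in enumerate(shapes):
        d = shape_descriptors(mask)
        d["mean_os"] = 0.0 if os_levels is None else os_levels[i]
        d["id"] = i
        d["cls"] = cls
        rows.append(d)
    return pd.DataFrame(rows).set_index("id")


def test_pom_classifier_separable_shapes_perfect(shape_bank):
    df, _ = shape_bank
    split = og.PomTrainingSplit.from_labels(df[list(FEATURE_COLUMNS)], df["cls"], rng_seed=3)
    clf, val_acc, oob = og.train_pom_classifier(split, rng_seed=3)
    assert val_acc == 1.0
    assert oob <= 0.15
    assert set(split.train_ids) & set(split.val_ids) == set()
    assert len(split.train_ids) + len(split.val_ids) == len(df)


def test_conflicting_labels_give_chance_accuracy():
    """Identical features with contradictory labels: ~50% is the ceiling."""
    n = 200
    feats = pd.DataFrame(
        {c: np.ones(n) for c in FEATURE_COLUMNS}, index=pd.RangeIndex(n, name="id")
    )
    labels = pd.Series(np.where(np.arange(n) % 2 == 0, "fibrous", "compact"), index=feats.index)
    split = og.PomTrainingSplit.from_labels(feats, labels, rng_seed=0)
    _, val_acc, oob = og.train_pom_classifier(split, n_trees=100, rng_seed=0)
    assert 0.3 < val_acc < 0.7
    assert 0.3 < oob < 0.7


def test_overlapping_clouds_track_bayes_rate():
    """Two Gaussian feature clouds with known ~90% Bayes accuracy."""
    rng = np.random.default_rng(5)
    n = 400
    # 1D separation d' such that Phi(d'/2) ~ 0.90 -> d' ~ 2.563
    x_f = rng.normal(0.0, 1.0, n)
    x_c = rng.normal(2.563, 1.0, n)
    feats = pd.DataFrame(
        {
            "elongation": np.r_[x_f, x_c],
            "plateness": rng.normal(1.5, 0.2, 2 * n),
            "compactness": rng.uniform(0.1, 0.9, 2 * n),
            "mean_os": rng.normal(80, 20, 2 * n),
        },
        index=pd.RangeIndex(2 * n, name="id"),
    )
    labels = pd.Series(["fibrous"] * n + ["compact"] * n, index=feats.index)
    split = og.PomTrainingSplit.from_labels(feats, labels, rng_seed=1)
    _, val_acc, _ = og.train_pom_classifier(split, n_trees=200, rng_seed=1)
    assert abs(val_acc - 0.90) <= 0.05


def test_single_class_training_raises(shape_bank):
    df, _ = shape_bank
    fib = df[df.cls == "fibrous"]
    split = og.PomTrainingSplit(
        features=fib[list(FEATURE_COLUMNS)],
        labels=fib["cls"],
        train_ids=np.asarray(fib.index),
        val_ids=np.asarray([], dtype=int),
    )
    with pytest.raises(ValueError, match="single class"):
        og.train_pom_classifier(split)


def test_assign_classes_tags_volume(shape_bank):
    df, _ = shape_bank
    split = og.PomTrainingSplit.from_labels(df[list(FEATURE_COLUMNS)], df["cls"], rng_seed=0)
    clf, _, _ = og.train_pom_classifier(split, rng_seed=0)

    lab = _labels_with_pom([((16, 16, 16), 12), ((46, 46, 46), 12)])
    objects, table = og.label_pom(lab, min_voxels=5000)
    osv = ScalarVolume(np.full(lab.shape, 10.0), 5.0, stage="difference")
    table = og.pom_object_table(objects, table, osv)
    out, tagged = og.assign_pom_classes(table, clf, objects)
    assert set(out["pom_class"]) <= {"fibrous", "compact"}
    # spherical blobs classify as compact; tags land on the object voxels
    assert (out["pom_class"] == "compact").all()
    assert set(np.unique(tagged[objects > 0])) == {POM_COMPACT}
    assert (tagged[objects == 0] == 0).all()


def test_assign_classes_empty_table_noop():
    objects = np.zeros((8, 8, 8), dtype=np.int32)
    table = pd.DataFrame(columns=["id", *FEATURE_COLUMNS])
    from sklearn.ensemble import RandomForestClassifier

    out, tagged = og.assign_pom_classes(table, RandomForestClassifier(), objects)
    assert out.empty and (tagged == 0).all()


def test_unfitted_classifier_raises(shape_bank):
    from sklearn.ensemble import RandomForestClassifier

    lab = _labels_with_pom([((16, 16, 16), 12)])
    objects, table = og.label_pom(lab, min_voxels=5000)
    osv = ScalarVolume(np.zeros(lab.shape), 5.0, stage="difference")
    table = og.pom_object_table(objects, table, osv)
    with pytest.raises(ValueError, match="not fitted"):
        og.assign_pom_classes(table, RandomForestClassifier(), objects)


def test_object_voxel_counts_bounded_by_class_total(small_phantom):
    _, _, _, truth = small_phantom
    _, table = og.label_pom(truth.labels, min_voxels=500)
    assert table["voxel_count"].sum() <= int(truth.labels.mask("POM").sum())
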