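"""POM object extraction, 3D shape descriptors, fibrous/compact classification.

Particulate organic matter (POM) voxels are grouped into 26-connected
components; objects above the size threshold (strictly more than 5000
voxels, i.e. > 6.25e5 µm³ at 5 µm voxels) enter the object table. Each
object is described by its inertia-ellipsoid elongation (a/b) and plateness
(b/c), its sphericity (36*pi*V^2/S^3 with a marching-cubes surface
estimate), and its mean Os_CT. A random forest (500 trees, 2 features tried
per split) trained on manually labeled objects assigns the fibrous/compact
class; fibrous POM is fresh litter and roots with conserved cell structure,
compact POM the sub-rounded decomposed residue.

The descriptor formulas are this package's operationalization of the
morphological traits; they are invariant to translation, axis permutation
and uniform scaling of coordinates (except mean Os, which is intensity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area
from sklearn.ensemble import RandomForestClassifier

from .volumes import LabelVolume, ScalarVolume

#: strict ">" threshold: clusters of more than this many voxels are analyzed
MIN_POM_VOXELS = 5000

FEATURE_COLUMNS = ("elongation", "plateness", "compactness", "mean_os")

#: codes in the class-tagged POM volume
POM_UNASSIGNED, POM_FIBROUS, POM_COMPACT = 0, 1, 2
POM_CLASS_NAMES = {POM_FIBROUS: "fibrous", POM_COMPACT: "compact"}

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def label_pom(labels: LabelVolume, min_voxels: int = MIN_POM_VOXELS) -> tuple[np.ndarray, pd.DataFrame]:
    """Connected-components labeling of the POM class with a size filter.

    Returns the labeled object volume (ids dense from 1, 0 = background)
    and the object table. Components with ``voxel_count <= min_voxels`` are
    dropped from both — they stay POM voxels for volume accounting but are
    not analyzed as objects.
    """
    pom = labels.mask("POM")
    lab, n = ndimage.label(pom, structure=_CONN26)
    if n == 0:
        return np.zeros(labels.shape, dtype=np.int32), _empty_table(labels)
    counts = np.bincount(lab.ravel())
    keep = np.flatnonzero(counts > min_voxels)
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    objects = remap[lab]
    vox = labels.voxel_size_um
    rows = [
        {
            "id": int(new_id),
            "voxel_count": int(counts[old_id]),
            "volume_um3": int(counts[old_id]) * vox**3,
        }
        for new_id, old_id in enumerate(keep, start=1)
    ]
    table = pd.DataFrame(rows) if rows else _empty_table(labels)
    return objects, table


def _empty_table(labels: LabelVolume) -> pd.DataFrame:
    return pd.DataFrame(columns=["id", "voxel_count", "volume_um3"]).astype(
        {"id": int, "voxel_count": int, "volume_um3": float}
    )


def shape_descriptors(mask: np.ndarray, os_vol: ScalarVolume | None = None) -> dict[str, float]:
    """Inertia-ellipsoid and surface descriptors of one object mask.

    Semi-axes a >= b >= c come from the eigenvalues of the second central
    moment matrix of the voxel centers (lambda = axis^2 / 5 for a uniform
    ellipsoid). Sphericity is 36*pi*V^2/S^3 with S from a marching-cubes
    surface mesh — exposed-face counting would bias digital-sphere
    sphericity low by roughly half. A degenerate (collinear) mask reports
    plateness = +inf.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    if coords.size == 0:
        raise ValueError("empty object mask")
    centered = coords - coords.mean(axis=0)
    # + I/12: second moment of the unit cube about its center, so a single
    # voxel has the moments of a cube rather than a point
    cov = centered.T @ centered / len(coords) + np.eye(3) / 12.0
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    a, b, c = np.sqrt(np.maximum(5.0 * eigvals, 0.0))
    elongation = a / b if b > 0 else np.inf
    plateness = b / c if c > 0 else np.inf

    padded = np.pad(mask, 1).astype(np.uint8)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    surface = mesh_surface_area(verts, faces)
    volume = float(mask.sum())
    compactness = min(36.0 * np.pi * volume**2 / surface**3, 1.0)

    out = {
        "elongation": float(elongation),
        "plateness": float(plateness),
        "compactness": float(compactness),
    }
    if os_vol is not None:
        out["mean_os"] = float(np.nanmean(os_vol.data[mask]))
    return out


def pom_object_table(
    objects: np.ndarray,
    table: pd.DataFrame,
    os_vol: ScalarVolume,
    pore_distance_um: np.ndarray | None = None,
) -> pd.DataFrame:
    """Extend the object table with shape descriptors and Os / distance stats."""
    if table.empty:
        cols = list(table.columns) + list(FEATURE_COLUMNS) + ["mean_pore_distance_um", "pom_class"]
        return pd.DataFrame(columns=cols)
    rows = []
    slices = ndimage.find_objects(objects)
    for rec in table.itertuples(index=False):
        sl = slices[rec.id - 1]
        mask = objects[sl] == rec.id
        desc = shape_descriptors(mask, None)
        desc["mean_os"] = float(np.nanmean(os_vol.data[sl][mask]))
        row = rec._asdict() | desc
        if pore_distance_um is not None:
            row["mean_pore_distance_um"] = float(np.nanmean(pore_distance_um[sl][mask]))
        rows.append(row)
    out = pd.DataFrame(rows)
    out["pom_class"] = "unassigned"
    return out


@dataclass
class PomTrainingSplit:
    """Manually labeled objects split into disjoint training/validation sets."""

    features: pd.DataFrame  # columns FEATURE_COLUMNS, indexed by object id
    labels: pd.Series  # "fibrous" / "compact"
    train_ids: np.ndarray
    val_ids: np.ndarray

    @classmethod
    def from_labels(
        cls,
        features: pd.DataFrame,
        labels: pd.Series,
        train_fraction: float = 324 / 463,
        rng_seed: int = 0,
    ) -> "PomTrainingSplit":
        """Random split; the default fraction mirrors a 324/139 partition."""
        ids = np.asarray(labels.index)
        rng = np.random.default_rng(rng_seed)
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        return cls(
            features=features,
            labels=labels,
            train_ids=ids[perm[:n_train]],
            val_ids=ids[perm[n_train:]],
        )


def train_pom_classifier(
    split: PomTrainingSplit,
    n_trees: int = 500,
    mtry: int = 2,
    rng_seed: int = 0,
) -> tuple[RandomForestClassifier, float, float]:
    """Random forest on (elongation, plateness, compactness, mean_os).

    Returns (classifier, validation accuracy, OOB error). Deterministic for
    a given seed; raises if the training subset contains a single class.
    """
    X_train = split.features.loc[split.train_ids, list(FEATURE_COLUMNS)].to_numpy()
    y_train = split.labels.loc[split.train_ids].to_numpy()
    if len(np.unique(y_train)) < 2:
        raise ValueError("training subset contains a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        oob_score=True,
        random_state=rng_seed,
        n_jobs=1,
    )
    clf.fit(X_train, y_train)
    oob_error = 1.0 - float(clf.oob_score_)
    if len(split.val_ids) > 0:
        X_val = split.features.loc[split.val_ids, list(FEATURE_COLUMNS)].to_numpy()
        y_val = split.labels.loc[split.val_ids].to_numpy()
        val_accuracy = float(np.mean(clf.predict(X_val) == y_val))
    else:
        val_accuracy = np.nan
    return clf, val_accuracy, oob_error


def assign_pom_classes(
    object_table: pd.DataFrame,
    classifier: RandomForestClassifier,
    objects: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Predict fibrous/compact for every object and tag the label image.

    Returns the updated table and a volume coding object voxels as
    1 = fibrous, 2 = compact (0 elsewhere).
    """
    tagged = np.zeros(objects.shape, dtype=np.uint8)
    if object_table.empty:
        return object_table.copy(), tagged
    if not hasattr(classifier, "estimators_"):
        raise ValueError("classifier is not fitted")
    X = object_table[list(FEATURE_COLUMNS)].to_numpy()
    pred = classifier.predict(X)
    out = object_table.copy()
    out["pom_class"] = pred
    code = {"fibrous": POM_FIBROUS, "compact": POM_COMPACT}
    lut = np.zeros(int(objects.max()) + 1, dtype=np.uint8)
    for oid, cls_name in zip(out["id"], pred):
        lut[int(oid)] = code[cls_name]
    tagged = lut[objects]
    return out, tagged
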