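"""Trainable random-forest voxel classification of the pre-stain volume.

The normalized pre-stain tomogram is classified into pore / POM / matrix /
dense from a multi-scale feature stack: for each Gaussian scale
sigma in {0.3, 0.7, 1.0} voxels the smoothed value, the gradient magnitude
(1st derivative) and the Laplacian (2nd derivative) — 9 features per voxel.
Training samples come from sparse "scribble" labels; the prediction is
cleaned with a 3x3x3 majority filter and the exterior is imposed from an
aggregate mask obtained by Otsu thresholding (a reproducible stand-in for
interactive boundary tracing).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.ensemble import RandomForestClassifier

from .volumes import EXTERIOR, LabelVolume, ScalarVolume

#: Gaussian scales in voxel units (the convention of voxel-classification
#: tools this workflow mirrors); configurable per call.
DEFAULT_SIGMAS = (0.3, 0.7, 1.0)


def compute_features(vol: ScalarVolume, sigmas: tuple[float, ...] = DEFAULT_SIGMAS) -> np.ndarray:
    """Per-voxel feature stack, shape ``(n_features, nz, ny, nx)``.

    For each scale: Gaussian-smoothed value, gradient magnitude of the
    smoothed field, Laplacian of the smoothed field. Boundaries are handled
    by reflection; the stack is deterministic.
    """
    data = vol.data.astype(np.float32)
    feats = []
    for sigma in sigmas:
        smoothed = ndimage.gaussian_filter(data, sigma, mode="reflect")
        # derivatives by central differences of the smoothed field: exact
        # zero response on constants even at sub-voxel sigma, where sampled
        # Gaussian-derivative kernels are badly truncated
        gz, gy, gx = np.gradient(smoothed)
        feats.append(smoothed)
        feats.append(np.sqrt(gz**2 + gy**2 + gx**2))
        feats.append(ndimage.laplace(smoothed, mode="reflect"))
    return np.stack(feats, axis=0)


def harvest_training_set(features: np.ndarray, scribbles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collect (feature vector, class) pairs from a sparse scribble volume.

    ``scribbles`` shares the grid; 0 = unlabeled, codes 1..4 = pore, POM,
    matrix, dense (the non-exterior label codes). Every class that appears
    must have at least one sample; exterior is never scribbled — it is
    imposed geometrically.
    """
    scribbles = np.asarray(scribbles)
    labeled = scribbles > 0
    if not labeled.any():
        raise ValueError("scribble volume contains no labeled voxels")
    X = features[:, labeled].T
    y = scribbles[labeled].astype(int)
    return X, y


def train_voxel_classifier(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    rng_seed: int = 0,
) -> RandomForestClassifier:
    """Fit the voxel random forest (sqrt feature subsetting, fixed seed)."""
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=rng_seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    counts = np.bincount(y)
    clf.training_counts_ = {int(c): int(n) for c, n in enumerate(counts) if n > 0}
    return clf


def majority_filter(labels: np.ndarray, valid: np.ndarray, radius: int = 1) -> np.ndarray:
    """Majority vote over a cubic neighborhood, restricted to valid voxels.

    Votes are counted per class with a box filter over one-hot indicators;
    out-of-mask voxels contribute no votes. Ties break toward the smaller
    class code, and a class absent from the neighborhood can never win
    (its count is zero while the center's own class counts at least one).
    """
    size = 2 * radius + 1
    classes = np.unique(labels[valid])
    counts = np.empty((len(classes),) + labels.shape, dtype=np.float32)
    for i, c in enumerate(classes):
        onehot = ((labels == c) & valid).astype(np.float32)
        counts[i] = ndimage.uniform_filter(onehot, size=size, mode="constant", cval=0.0)
    winner = classes[np.argmax(counts, axis=0)]  # argmax -> first max -> smaller code
    out = labels.copy()
    out[valid] = winner[valid]
    return out


def aggregate_mask(vol: ScalarVolume, smoothing_sigma: float = 1.0, closing_radius: int = 4) -> np.ndarray:
    """Binary mask of the soil aggregate from the pre-stain volume.

    Otsu threshold on the smoothed volume, largest connected component,
    morphological closing, then hole filling (interior pores belong to the
    aggregate). The closing radius must exceed the radius of pore mouths at
    the surface, or boundary-connected pores stay outside the mask.
    """
    smoothed = ndimage.gaussian_filter(vol.data.astype(float), smoothing_sigma)
    thresh = threshold_otsu(smoothed)
    fg = smoothed > thresh
    if not fg.any():
        raise ValueError("no foreground found above the Otsu threshold")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        fg = lab == np.argmax(sizes)
    if closing_radius > 0:
        ball = _ball(closing_radius)
        fg = ndimage.binary_closing(fg, structure=ball)
    return ndimage.binary_fill_holes(fg)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz**2 + yy**2 + xx**2 <= r**2


def segment(
    vol: ScalarVolume,
    classifier: RandomForestClassifier,
    aggregate: np.ndarray,
    majority_radius: int = 1,
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS,
    features: np.ndarray | None = None,
) -> LabelVolume:
    """Classify every aggregate voxel, denoise, impose exterior.

    Precomputed ``features`` may be passed to avoid recomputation when the
    same stack served training.
    """
    aggregate = np.asarray(aggregate, dtype=bool)
    if aggregate.shape != vol.shape:
        raise ValueError("aggregate mask geometry mismatch")
    if features is None:
        features = compute_features(vol, sigmas)
    labels = np.zeros(vol.shape, dtype=np.uint8)
    if aggregate.any():
        X = features[:, aggregate].T
        labels[aggregate] = classifier.predict(X).astype(np.uint8)
    if majority_radius > 0:
        labels = majority_filter(labels, aggregate, radius=majority_radius)
    labels[~aggregate] = EXTERIOR
    return LabelVolume(data=labels, voxel_size_um=vol.voxel_size_um)
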