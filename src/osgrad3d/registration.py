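"""Landmark-based similarity registration.

The post-stain scan is aligned onto the pre-stain scan with a similarity
transform (rotation + isotropic scale + translation) estimated in closed form
from paired landmarks by least squares (Umeyama/Procrustes). Intensity-driven
registration is deliberately avoided: the two scans differ in intensity by
construction (that difference is the signal), which makes intensity metrics
fragile, while a handful of landmarks pins the geometry down exactly.

Coordinates follow the package convention: (z, y, x) in micrometers, with
voxel centers at ``(index + 0.5) * voxel_size_um``. Landmark files on disk
are "x y z" per line and are axis-swapped on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import SimilarityTransform as _SkSimilarity

from .volumes import ScalarVolume


@dataclass
class SimilarityTransform:
    """x_fixed = scale * rotation @ x_moving + translation, in µm (z, y, x)."""

    rotation: np.ndarray  # 3x3, orthonormal, det +1
    scale: float
    translation: np.ndarray  # 3-vector, µm
    residual_rms_um: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of moving-space points into fixed space."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        sinv = 1.0 / self.scale
        tinv = -sinv * Rinv @ self.translation
        return SimilarityTransform(rotation=Rinv, scale=sinv, translation=tinv)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform applying ``other`` first, then ``self``."""
        R = self.rotation @ other.rotation
        s = self.scale * other.scale
        t = self.scale * self.rotation @ other.translation + self.translation
        return SimilarityTransform(rotation=R, scale=s, translation=t)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(rotation=np.eye(3), scale=1.0, translation=np.zeros(3))


def estimate_similarity(fixed_landmarks: np.ndarray, moving_landmarks: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform from paired landmarks.

    Finds the rotation, isotropic scale and translation minimizing
    ``sum_i || s R m_i + t - f_i ||^2`` in closed form (SVD of the cross
    covariance; Umeyama's solution). Requires at least 3 non-collinear pairs.

    Returns the transform mapping moving landmarks onto fixed ones, with the
    residual RMS (µm) recorded on the result.
    """
    fixed = np.atleast_2d(np.asarray(fixed_landmarks, dtype=float))
    moving = np.atleast_2d(np.asarray(moving_landmarks, dtype=float))
    if fixed.shape != moving.shape or fixed.shape[1] != 3:
        raise ValueError("landmark lists must be equal-length (N, 3) arrays")
    if len(fixed) < 3:
        raise ValueError("at least 3 landmark pairs are required")
    centered = moving - moving.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("degenerate landmark configuration (collinear points)")

    if hasattr(_SkSimilarity, "from_estimate"):
        tf = _SkSimilarity.from_estimate(moving, fixed)
        if not tf:
            raise ValueError("similarity estimation failed")
    else:  # scikit-image < 0.26
        tf = _SkSimilarity(dimensionality=3)
        if not tf.estimate(moving, fixed):
            raise ValueError("similarity estimation failed")
    M = tf.params
    A = M[:3, :3]
    scale = float(np.cbrt(np.linalg.det(A)))
    rotation = A / scale
    # re-orthonormalize against accumulated floating-point error
    u, _, vt = np.linalg.svd(rotation)
    rotation = u @ vt
    translation = M[:3, 3]
    out = SimilarityTransform(rotation=rotation, scale=scale, translation=translation)
    resid = out.apply(moving) - fixed
    # per-coordinate RMS, directly comparable to the landmark noise SD
    out.residual_rms_um = float(np.sqrt(np.mean(resid**2)))
    return out


def resample(
    moving: ScalarVolume,
    transform: SimilarityTransform,
    reference: ScalarVolume,
    fill_value: float = np.nan,
) -> tuple[ScalarVolume, np.ndarray]:
    """Resample ``moving`` onto the grid of ``reference`` under ``transform``.

    Trilinear interpolation (monotone; no overshoot into the subtraction
    step). Output voxels that map outside the moving volume are set to
    ``fill_value`` (NaN by default) and flagged False in the returned
    validity mask; all downstream statistics exclude them.

    Returns
    -------
    (ScalarVolume, ndarray of bool)
        The resampled volume (stage ``registered``) and the validity mask.
    """
    inv = transform.inverse()
    vox_f = reference.voxel_size_um
    vox_m = moving.voxel_size_um
    # index_moving = A @ index_fixed + b, derived from voxel-center coords
    A = inv.scale * inv.rotation * vox_f / vox_m
    half = np.full(3, 0.5 * vox_f)
    b = (inv.scale * inv.rotation @ half + inv.translation) / vox_m - 0.5

    out = ndimage.affine_transform(
        moving.data.astype(float),
        A,
        offset=b,
        output_shape=reference.shape,
        order=1,
        mode="constant",
        cval=np.nan,
    )
    valid = np.isfinite(out)
    if not np.isnan(fill_value):
        out = np.where(valid, out, fill_value)
    return ScalarVolume(data=out, voxel_size_um=vox_f, stage="registered"), valid


def read_landmarks(path: str | Path) -> np.ndarray:
    """Read a plain-text landmark file: one "x y z" triple (µm) per line.

    Returns (N, 3) points in the internal (z, y, x) order. Blank lines and
    ``#`` comments are ignored; pairing across files is by line number.
    """
    pts = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        x, y, z = (float(v) for v in line.split())
        pts.append((z, y, x))
    if not pts:
        raise ValueError(f"no landmarks found in {path}")
    return np.asarray(pts, dtype=float)
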