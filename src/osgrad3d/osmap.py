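"""Two-anchor grayscale normalization and the Os_CT difference map.

Both tomograms are linearly rescaled so that the mean gray value over a
plastic-holder ROI maps to 40 and over a quartz-grain ROI to 120 (arbitrary
units). Subtracting the normalized pre-stain from the normalized post-stain
volume yields the Os_CT map: a voxel that moves from the plastic level to the
quartz level scores Os_CT = 80. A median filter removes salt-and-pepper
noise from the difference image. Negative Os_CT values are retained, not
clipped — they carry the noise information used by the extent statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import ScalarVolume

PLASTIC_TARGET = 40.0
QUARTZ_TARGET = 120.0


@dataclass
class NormalizationAnchors:
    """ROI masks for the two reference materials and their target gray values."""

    plastic_mask: np.ndarray
    quartz_mask: np.ndarray
    plastic_target: float = PLASTIC_TARGET
    quartz_target: float = QUARTZ_TARGET

    def __post_init__(self) -> None:
        self.plastic_mask = np.asarray(self.plastic_mask, dtype=bool)
        self.quartz_mask = np.asarray(self.quartz_mask, dtype=bool)
        if not self.plastic_mask.any() or not self.quartz_mask.any():
            raise ValueError("anchor masks must be non-empty")
        if (self.plastic_mask & self.quartz_mask).any():
            raise ValueError("anchor masks must be disjoint")
        if self.quartz_target <= self.plastic_target:
            raise ValueError("quartz target must exceed plastic target")


def normalize(vol: ScalarVolume, anchors: NormalizationAnchors) -> ScalarVolume:
    """Affine-rescale a volume so anchor ROI means hit their targets.

    The map v -> a*v + b is chosen so the mean over the plastic mask maps to
    ``plastic_target`` and the mean over the quartz mask to ``quartz_target``.
    Anchor statistics use the ROI mean (not median) so the calibration is
    exactly linear, which makes the operation idempotent.
    """
    if anchors.plastic_mask.shape != vol.shape:
        raise ValueError("anchor masks must share the volume's geometry")
    p_mean = float(np.nanmean(vol.data[anchors.plastic_mask]))
    q_mean = float(np.nanmean(vol.data[anchors.quartz_mask]))
    if q_mean <= p_mean:
        raise ValueError(
            f"quartz anchor mean ({q_mean:g}) must exceed plastic anchor mean "
            f"({p_mean:g}); zero or inverted dynamic range"
        )
    a = (anchors.quartz_target - anchors.plastic_target) / (q_mean - p_mean)
    b = anchors.plastic_target - a * p_mean
    return ScalarVolume(data=a * vol.data + b, voxel_size_um=vol.voxel_size_um, stage=vol.stage)


def _nanmedian_filter(data: np.ndarray, radius: int) -> np.ndarray:
    """Exact median filter ignoring NaN voxels (cubic neighborhood).

    Built by stacking shifted copies (reflect boundary) and taking
    ``nanmedian`` across the stack; memory scales with the window volume,
    which is fine for the radius-1 default.
    """
    w = 2 * radius + 1
    padded = np.pad(data.astype(np.float32), radius, mode="reflect")
    shifts = []
    for dz in range(w):
        for dy in range(w):
            for dx in range(w):
                shifts.append(
                    padded[
                        dz : dz + data.shape[0],
                        dy : dy + data.shape[1],
                        dx : dx + data.shape[2],
                    ]
                )
    stack = np.stack(shifts, axis=0)
    with np.errstate(all="ignore"):
        out = np.nanmedian(stack, axis=0)
    # voxels with no valid neighbor at all stay NaN
    out[np.isnan(data) & np.isnan(out)] = np.nan
    return out.astype(float)


def difference(
    pre_norm: ScalarVolume, post_norm: ScalarVolume, median_radius: int = 1
) -> ScalarVolume:
    """Os_CT = median_filter(post_norm - pre_norm).

    NaN voxels (e.g. outside the registration validity mask) stay NaN; the
    median around them is taken over the valid neighbors only. Radius 0
    skips the filter.
    """
    if pre_norm.shape != post_norm.shape:
        raise ValueError("pre/post volumes differ in shape")
    if not np.isclose(pre_norm.voxel_size_um, post_norm.voxel_size_um):
        raise ValueError("pre/post volumes differ in voxel spacing")
    diff = post_norm.data - pre_norm.data
    if median_radius > 0:
        if np.isnan(diff).any():
            diff = _nanmedian_filter(diff, median_radius)
        else:
            diff = ndimage.median_filter(diff, size=2 * median_radius + 1, mode="reflect")
    return ScalarVolume(data=diff, voxel_size_um=pre_norm.voxel_size_um, stage="difference")


def reference_material_stats(os_vol: ScalarVolume, material_masks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-material Os_CT percentiles after one-pass Tukey outlier removal.

    For each named mask, voxels outside the Tukey fences
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are dropped once (no iteration), then the
    count and the 0/25/50/75/100% percentiles of the remainder are reported.
    """
    rows = []
    for name, mask in material_masks.items():
        vals = os_vol.data[np.asarray(mask, dtype=bool)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"mask {name!r} is empty (or all-NaN)")
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        keep = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
        pcts = np.percentile(keep, [0, 25, 50, 75, 100])
        rows.append(
            {
                "material": name,
                "n": int(keep.size),
                "p0": pcts[0],
                "p25": pcts[1],
                "p50": pcts[2],
                "p75": pcts[3],
                "p100": pcts[4],
            }
        )
    df = pd.DataFrame(rows).set_index("material")
    df.attrs["outlier_rule"] = "tukey_1.5_iqr_single_pass"
    return df
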