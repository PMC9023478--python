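"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import osgrad3d as og


def make_scribbles(truth, n_per_class: int = 200, seed: int = 0) -> np.ndarray:
    """Sample sparse training scribbles from the ground-truth labels."""
    rng = np.random.default_rng(seed)
    scrib = np.zeros(truth.labels.shape, dtype=np.uint8)
    for c in range(1, 5):
        idx = np.argwhere(truth.labels.data == c)
        if len(idx) == 0:
            continue
        pick = idx[rng.choice(len(idx), size=min(n_per_class, len(idx)), replace=False)]
        scrib[tuple(pick.T)] = c
    return scrib


def inside_box(mask: np.ndarray, size: tuple[int, int, int]) -> list[int]:
    """A box of the given (odd) size fully inside a mask, as [z0,z1,y0,y1,x0,x1]."""
    er = ndimage.minimum_filter(mask.astype(np.uint8), size=size, mode="constant")
    idx = np.argwhere(er > 0)
    if len(idx) == 0:
        raise ValueError("no box of that size fits inside the mask")
    z, y, x = idx[0]
    h = [s // 2 for s in size]
    return [
        int(z - h[0]),
        int(z - h[0] + size[0]),
        int(y - h[1]),
        int(y - h[1] + size[1]),
        int(x - h[2]),
        int(x - h[2] + size[2]),
    ]


def phantom_anchors(truth) -> og.NormalizationAnchors:
    return og.NormalizationAnchors(
        plastic_mask=truth.anchor_regions["plastic"],
        quartz_mask=truth.anchor_regions["quartz"],
    )


def os_ct_from_phantom(pre, post, truth, median_radius: int = 1):
    anchors = phantom_anchors(truth)
    return og.difference(
        og.normalize(pre, anchors), og.normalize(post, anchors), median_radius=median_radius
    )


@pytest.fixture(scope="session")
def small_phantom():
    """96^3 default-condition phantom shared across tests (read-only)."""
    spec = og.PhantomSpec(shape=(96, 96, 96), rng_seed=5)
    pre, post, truth = og.generate_phantom(spec)
    return spec, pre, post, truth


@pytest.fixture(scope="session")
def sparse_pore_phantom():
    """Sparse-pore, depletion-only phantom for gradient analysis."""
    spec = og.PhantomSpec(
        shape=(96, 96, 96),
        rng_seed=2,
        porosity_target=0.02,
        n_fibrous=0,
        n_compact=0,
        enrichment_amplitude=0.0,
    )
    pre, post, truth = og.generate_phantom(spec)
    return spec, pre, post, truth


@pytest.fixture(scope="session")
def shape_bank():
    """Labeled tube/blob masks with descriptor features, one fixed seed."""
    import pandas as pd
    from osgrad3d.morphology import shape_descriptors

    shapes = og.generate_labeled_shapes(12, rng_seed=7)
    rows = []
    for i, (mask, cls) in enumerate(shapes):
        d = shape_descriptors(mask)
        d["mean_os"] = 0.0
        d["id"] = i
        d["cls"] = cls
        rows.append(d)
    return pd.DataFrame(rows).set_index("id"), shapes
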