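"""Synthetic pre-/post-stain aggregate pairs with full ground truth.

Every downstream stage is benchmarked against phantoms instead of real
scans: a quasi-spherical soil aggregate in air, a plastic-holder slab and
quartz grains outside it as normalization references, pores carved as
planar cracks and cylindrical biopores, fibrous POM as tortuous tubes
seeded at pore walls, compact POM as rounded (super)ellipsoids deeper in
the matrix, and a few dense mineral inclusions.

The true Os field follows single-length-scale exponentials — depletion
toward pores, ``matrix_os_mean * (1 - exp(-d_pore/lambda_pore))``, plus an
enrichment halo around POM, ``amplitude * exp(-d_POM/lambda_POM)`` — so the
band-crossing extent is known in closed form. The post-stain scan is the
pre-stain scan plus the Os field mapped onto the raw gray scale, arranged
so that two-anchor normalization and subtraction recover the truth up to
acquisition noise. Same seed, same volumes, bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import DENSE, EXTERIOR, MATRIX, POM, PORE, LabelVolume, ScalarVolume

#: raw gray levels per material; the plastic/quartz anchors imply the
#: normalized levels pore 15 < POM 50 < matrix 90 < dense 140
DEFAULT_PRE_LEVELS = {
    "exterior": 5000.0,
    "pore": 5000.0,
    "POM": 12000.0,
    "matrix": 20000.0,
    "dense": 30000.0,
    "plastic": 10000.0,
    "quartz": 26000.0,
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic aggregate.

    Lengths are in µm unless suffixed ``_vox``. ``noise_sd`` is the
    per-scan acquisition noise and ``matrix_os_sd`` the intrinsic spatial
    variability of the matrix Os field, both in normalized (Os_CT) units.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = 5.0
    porosity_target: float = 0.12
    n_fibrous: int = 3
    n_compact: int = 3
    n_dense: int = 2
    depletion_length_um: float = 30.0
    enrichment_length_um: float = 20.0
    enrichment_amplitude: float = 10.0
    matrix_os_mean: float = 40.0
    matrix_os_sd: float = 2.0
    pre_stain_levels: dict = field(default_factory=lambda: dict(DEFAULT_PRE_LEVELS))
    noise_sd: float = 2.0
    rng_seed: int = 0
    # geometry knobs (voxel units); defaults sized for ~128^3 grids
    compact_semiaxis_vox: tuple[float, float] = (6.0, 10.0)
    fibrous_radius_vox: tuple[float, float] = (2.5, 3.5)
    fibrous_length_vox: tuple[int, int] = (60, 100)
    pom_os_log_mean: float = float(np.log(80.0))
    pom_os_log_sd: float = 0.5

    def validate(self) -> None:
        if not (0 < self.porosity_target < 0.5):
            raise ValueError("porosity_target must be in (0, 0.5)")
        if self.depletion_length_um <= 0 or self.enrichment_length_um <= 0:
            raise ValueError("gradient length scales must be positive")
        if min(self.shape) < 32:
            raise ValueError("grid too small to host an aggregate with references")


@dataclass
class PhantomTruth:
    """Ground truth of one generated phantom."""

    labels: LabelVolume
    pom_ids: np.ndarray  # per-voxel object id, 0 = background
    pom_classes: dict[int, str]  # id -> fibrous | compact
    pom_os: dict[int, float]  # id -> per-object Os level
    os_field: np.ndarray  # true Os_CT per voxel
    anchor_regions: dict[str, np.ndarray]  # plastic / quartz masks
    porosity: float
    spec: PhantomSpec

    def save_json(self, path: str | Path) -> None:
        """Scalar ground truth (classes, parameters, porosity) as JSON."""
        spec_dict = asdict(self.spec)
        payload = {
            "pom_classes": {str(k): v for k, v in self.pom_classes.items()},
            "pom_os": {str(k): v for k, v in self.pom_os.items()},
            "porosity": self.porosity,
            "spec": spec_dict,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=list))


def _coords(shape: tuple[int, int, int]) -> np.ndarray:
    return np.indices(shape, dtype=np.float32)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _aggregate_region(spec: PhantomSpec, rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    center = np.array(spec.shape, dtype=float) / 2.0
    r0 = 0.38 * min(spec.shape)
    bump = ndimage.gaussian_filter(rng.normal(size=spec.shape), sigma=8.0)
    bump /= max(bump.std(), 1e-9)
    dist = np.sqrt(((coords - center[:, None, None, None]) ** 2).sum(axis=0))
    return dist < r0 * (1.0 + 0.06 * bump), r0, center


def _carve_pores(
    spec: PhantomSpec, rng: np.random.Generator, coords: np.ndarray, labels: np.ndarray, aggregate: np.ndarray, r0: float
) -> None:
    """Add cylindrical biopores and planar cracks until the target porosity."""
    agg_idx = np.argwhere(aggregate)
    n_agg = len(agg_idx)
    flat = coords.reshape(3, -1)
    for attempt in range(400):
        pore_frac = np.count_nonzero(labels == PORE) / n_agg
        if pore_frac >= spec.porosity_target:
            break
        p0 = agg_idx[rng.integers(n_agg)].astype(np.float32)
        n = _random_unit(rng).astype(np.float32)
        rel = flat - p0[:, None]
        if attempt % 2 == 0:  # cylinder through the whole aggregate
            radius = rng.uniform(1.5, 3.0)
            along = n @ rel
            perp2 = (rel**2).sum(axis=0) - along**2
            mask = (perp2 < radius**2).reshape(spec.shape)
        else:  # bounded planar crack
            thickness = rng.uniform(1.0, 2.0)
            extent = rng.uniform(r0 / 3.0, 2.0 * r0 / 3.0)
            planar = np.abs(n @ rel) < thickness / 2.0
            near = (rel**2).sum(axis=0) < extent**2
            mask = (planar & near).reshape(spec.shape)
        labels[mask & aggregate] = PORE
    else:
        raise ValueError("infeasible spec: porosity target not reached")


def _rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    return q * np.sign(np.diag(r))


def _ellipsoid_mask(
    shape: tuple[int, int, int], center: np.ndarray, semiaxes: np.ndarray, rot: np.ndarray, power: float = 2.0
) -> np.ndarray:
    lo = np.maximum((center - semiaxes.max() - 1).astype(int), 0)
    hi = np.minimum((center + semiaxes.max() + 2).astype(int), shape)
    sub = np.indices(tuple(hi - lo), dtype=np.float32) + lo[:, None, None, None]
    rel = np.tensordot(rot.T, sub - center[:, None, None, None], axes=1)
    inside = (np.abs(rel / semiaxes[:, None, None, None]) ** power).sum(axis=0) <= 1.0
    out = np.zeros(shape, dtype=bool)
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return out


def _tortuous_tube_mask(
    shape: tuple[int, int, int],
    start: np.ndarray,
    length: int,
    radius: float,
    rng: np.random.Generator,
    keep_inside: np.ndarray | None = None,
    waviness: float = 0.35,
) -> np.ndarray:
    """Random-walk centerline with momentum, dilated to a tube."""
    pos = start.astype(float)
    direction = _random_unit(rng)
    line = np.zeros(shape, dtype=bool)
    for _ in range(length):
        direction = direction + waviness * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        nxt = pos + direction
        if keep_inside is not None:
            idx = tuple(np.clip(np.round(nxt).astype(int), 0, np.array(shape) - 1))
            if not keep_inside[idx]:
                direction = -direction  # bounce back into the aggregate
                nxt = pos + direction
        pos = np.clip(nxt, 0, np.array(shape, dtype=float) - 1)
        line[tuple(np.round(pos).astype(int))] = True
    dist = ndimage.distance_transform_edt(~line)
    return dist <= radius


def _place_pom(
    spec: PhantomSpec, rng: np.random.Generator, labels: np.ndarray, aggregate: np.ndarray
) -> tuple[np.ndarray, dict[int, str]]:
    """Place compact then fibrous POM; overwrite matrix voxels only."""
    shape = labels.shape
    pom_ids = np.zeros(shape, dtype=np.int16)
    classes: dict[int, str] = {}
    next_id = 1

    pore_dist = ndimage.distance_transform_edt(labels != PORE)

    def commit(mask: np.ndarray, cls: str) -> bool:
        nonlocal next_id
        body = mask & (labels == MATRIX)
        if body.any():  # crossing a pore may split the mask; keep one piece
            cc, n = ndimage.label(body, structure=np.ones((3, 3, 3)))
            sizes = np.bincount(cc.ravel())
            sizes[0] = 0
            body = cc == np.argmax(sizes)
        if body.sum() < 0.6 * mask.sum():  # mostly swallowed by pores/others
            return False
        grown = ndimage.binary_dilation(body, np.ones((3, 3, 3)))
        if (pom_ids[grown] > 0).any():  # would merge with an existing object
            return False
        labels[body] = POM
        pom_ids[body] = next_id
        classes[next_id] = cls
        next_id += 1
        return True

    deep = np.argwhere((labels == MATRIX) & (pore_dist > 3))
    for _ in range(spec.n_compact):
        for _attempt in range(60):
            c = deep[rng.integers(len(deep))].astype(float)
            lo, hi = spec.compact_semiaxis_vox
            cax = rng.uniform(lo, hi)
            semis = np.array([cax * rng.uniform(1.0, 2.0), cax * rng.uniform(1.0, 1.5), cax])
            mask = _ellipsoid_mask(shape, c, np.sort(semis)[::-1], _rotation(rng), power=rng.uniform(2.0, 3.0))
            if commit(mask, "compact"):
                break
        else:
            raise ValueError("infeasible spec: could not place compact POM")

    pore_wall = np.argwhere((labels == MATRIX) & (pore_dist <= 2) & aggregate)
    for _ in range(spec.n_fibrous):
        for _attempt in range(60):
            start = pore_wall[rng.integers(len(pore_wall))]
            length = int(rng.integers(spec.fibrous_length_vox[0], spec.fibrous_length_vox[1] + 1))
            radius = rng.uniform(*spec.fibrous_radius_vox)
            mask = _tortuous_tube_mask(shape, start, length, radius, rng, keep_inside=aggregate)
            if commit(mask, "fibrous"):
                break
        else:
            raise ValueError("infeasible spec: could not place fibrous POM")
    return pom_ids, classes


def generate_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, ScalarVolume, PhantomTruth]:
    """Build one pre-/post-stain pair plus ground truth. Deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.shape)
    coords = _coords(shape)

    aggregate, r0, center = _aggregate_region(spec, rng, coords)
    labels = np.full(shape, EXTERIOR, dtype=np.uint8)
    labels[aggregate] = MATRIX
    _carve_pores(spec, rng, coords, labels, aggregate, r0)

    # dense mineral inclusions
    matrix_idx = np.argwhere(labels == MATRIX)
    for _ in range(spec.n_dense):
        c = matrix_idx[rng.integers(len(matrix_idx))].astype(float)
        semis = np.sort(rng.uniform(3.0, 7.0, size=3))[::-1]
        mask = _ellipsoid_mask(shape, c, semis, _rotation(rng))
        labels[mask & (labels == MATRIX)] = DENSE

    pom_ids, pom_classes = _place_pom(spec, rng, labels, aggregate)

    # normalization references, strictly outside the aggregate
    dist_c = np.sqrt(((coords - center[:, None, None, None]) ** 2).sum(axis=0))
    outside = dist_c > 1.10 * r0
    plastic = outside & (coords[0] < 4)
    quartz = np.zeros(shape, dtype=bool)
    ref_sites = np.argwhere(outside & (coords[0] > shape[0] * 0.6))
    for _ in range(4):
        c = ref_sites[rng.integers(len(ref_sites))].astype(float)
        grain = _ellipsoid_mask(shape, c, np.array([5.0, 4.0, 4.0]), _rotation(rng))
        quartz |= grain & outside & ~plastic
    if not plastic.any() or not quartz.any():
        raise ValueError("infeasible spec: no room for reference regions")

    # --- true Os field -------------------------------------------------
    os_field = np.zeros(shape, dtype=np.float64)
    matrix_mask = labels == MATRIX
    pore_mask = labels == PORE
    lam_p = spec.depletion_length_um
    lam_e = spec.enrichment_length_um
    if pore_mask.any():
        d_pore = ndimage.distance_transform_edt(~pore_mask) * spec.voxel_size_um
        depletion = spec.matrix_os_mean * (1.0 - np.exp(-d_pore / lam_p))
    else:
        depletion = np.full(shape, spec.matrix_os_mean)
    pom_mask = labels == POM
    if pom_mask.any() and spec.enrichment_amplitude != 0:
        d_pom = ndimage.distance_transform_edt(~pom_mask) * spec.voxel_size_um
        enrichment = spec.enrichment_amplitude * np.exp(-d_pom / lam_e)
    else:
        enrichment = 0.0
    total = depletion + enrichment
    if spec.matrix_os_sd > 0:
        total = total + rng.normal(0.0, spec.matrix_os_sd, size=shape)
    os_field[matrix_mask] = total[matrix_mask]

    pom_os: dict[int, float] = {}
    for oid in pom_classes:
        level = float(rng.lognormal(spec.pom_os_log_mean, spec.pom_os_log_sd))
        pom_os[oid] = level
        os_field[pom_ids == oid] = level

    # --- raw grayscale pair --------------------------------------------
    lv = spec.pre_stain_levels
    pre_clean = np.empty(shape, dtype=np.float64)
    pre_clean[labels == EXTERIOR] = lv["exterior"]
    pre_clean[pore_mask] = lv["pore"]
    pre_clean[pom_mask] = lv["POM"]
    pre_clean[matrix_mask] = lv["matrix"]
    pre_clean[labels == DENSE] = lv["dense"]
    pre_clean[plastic] = lv["plastic"]
    pre_clean[quartz] = lv["quartz"]

    # gain of the two-anchor normalization; Os enters the raw scale as Os/a
    a = (120.0 - 40.0) / (lv["quartz"] - lv["plastic"])
    raw_noise = spec.noise_sd / a
    pre = pre_clean + rng.normal(0.0, raw_noise, size=shape) if spec.noise_sd > 0 else pre_clean.copy()
    post = pre_clean + os_field / a
    if spec.noise_sd > 0:
        post = post + rng.normal(0.0, raw_noise, size=shape)

    label_vol = LabelVolume(data=labels, voxel_size_um=spec.voxel_size_um)
    porosity = float(np.count_nonzero(pore_mask) / np.count_nonzero(labels != EXTERIOR))
    truth = PhantomTruth(
        labels=label_vol,
        pom_ids=pom_ids,
        pom_classes=pom_classes,
        pom_os=pom_os,
        os_field=os_field,
        anchor_regions={"plastic": plastic, "quartz": quartz},
        porosity=porosity,
        spec=spec,
    )
    pre_vol = ScalarVolume(data=pre, voxel_size_um=spec.voxel_size_um, stage="pre_stain")
    post_vol = ScalarVolume(data=post, voxel_size_um=spec.voxel_size_um, stage="post_stain")
    return pre_vol, post_vol, truth


def generate_labeled_shapes(n_per_class: int, rng_seed: int = 0) -> list[tuple[np.ndarray, str]]:
    """Standalone fibrous (tube) and compact (blob) masks for classifier work.

    Tubes have centerline length at least five diameters; blobs are
    superellipsoids with all aspect ratios at most 2. Every mask has at
    least 5000 voxels, matching the object-analysis size filter.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(rng_seed)
    shapes: list[tuple[np.ndarray, str]] = []
    for _ in range(n_per_class):
        length = int(rng.integers(100, 140))
        diameter = rng.uniform(9.0, min(14.0, length / 5.0))
        mask = _bent_tube_mask(length, diameter, rng)
        while mask.sum() < 5000:
            diameter += 1.0
            mask = _bent_tube_mask(length, diameter, rng)
        shapes.append((_tight_crop(mask), "fibrous"))
    for _ in range(n_per_class):
        c_ax = rng.uniform(11.0, 14.0)
        semis = np.sort(
            np.array([c_ax, c_ax * rng.uniform(1.0, 2.0), c_ax * rng.uniform(1.0, 2.0)])
        )[::-1]
        size = int(2 * semis.max()) + 6
        mask = _ellipsoid_mask(
            (size,) * 3,
            np.full(3, size / 2.0),
            semis,
            _rotation(rng),
            power=rng.uniform(2.0, 4.0),
        )
        shapes.append((_tight_crop(mask), "compact"))
    return shapes


def _bent_tube_mask(length: int, diameter: float, rng: np.random.Generator) -> np.ndarray:
    """Gently curved tube: quadratic Bezier centerline, bounded curvature.

    The bend offset is capped at 15% of the axis length so the
    inertia-ellipsoid elongation stays well above the fibrous/compact
    boundary regardless of the draw.
    """
    pad = int(diameter) + 4
    grid = (length + 2 * pad,) * 3
    u = _random_unit(rng)
    a = np.full(3, float(grid[0]) / 2.0) - u * length / 2.0
    b = a + u * length
    perp = np.cross(u, _random_unit(rng))
    perp /= max(np.linalg.norm(perp), 1e-9)
    ctrl = (a + b) / 2.0 + perp * rng.uniform(0.0, 0.15) * length
    t = np.linspace(0.0, 1.0, 3 * length)[:, None]
    pts = (1 - t) ** 2 * a + 2 * t * (1 - t) * ctrl + t**2 * b
    line = np.zeros(grid, dtype=bool)
    idx = np.clip(np.round(pts).astype(int), 0, grid[0] - 1)
    line[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~line)
    return dist <= diameter / 2.0


def _tight_crop(mask: np.ndarray, pad: int = 2) -> np.ndarray:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    return mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]


def generate_cohort(
    n_aggregates: int = 8,
    base_spec: PhantomSpec | None = None,
    rng_seed: int = 0,
    gray_os_slope: float = -1.0,
) -> list[tuple[ScalarVolume, ScalarVolume, PhantomTruth]]:
    """A cohort of aggregates with a built-in negative relation between
    matrix Os level and pre-stain matrix gray value.

    Each aggregate perturbs the normalized matrix gray by delta in
    [-10, 10] and shifts ``matrix_os_mean`` by ``gray_os_slope * delta``,
    emulating the observed trend of darker (more organic) matrix staining
    more strongly.
    """
    rng = np.random.default_rng(rng_seed)
    base = base_spec or PhantomSpec()
    out = []
    deltas = rng.uniform(-10.0, 10.0, size=n_aggregates)
    lv = base.pre_stain_levels
    a = (120.0 - 40.0) / (lv["quartz"] - lv["plastic"])
    for i, delta in enumerate(deltas):
        levels = dict(lv)
        levels["matrix"] = lv["matrix"] + delta / a
        spec = PhantomSpec(
            **{
                **asdict(base),
                "pre_stain_levels": levels,
                "matrix_os_mean": base.matrix_os_mean + gray_os_slope * delta,
                "rng_seed": int(rng.integers(2**31 - 1)),
            }
        )
        out.append(generate_phantom(spec))
    return out
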