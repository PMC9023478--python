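"""Distance maps, radial Os profiles, extent detection, pore connectivity."""

import numpy as np
import pytest
from scipy import ndimage

import osgrad3d as og
from osgrad3d.volumes import LabelVolume, ScalarVolume
from conftest import os_ct_from_phantom


def brute_force_distance(ref_mask: np.ndarray, voxel: float) -> np.ndarray:
    """All-pairs minimum Euclidean distance — the independent oracle."""
    ref = np.argwhere(ref_mask)
    probe = np.indices(ref_mask.shape).reshape(3, -1).T
    d2 = ((probe[:, None, :] - ref[None, :, :]) ** 2).sum(-1).min(1)
    return np.sqrt(d2).reshape(ref_mask.shape) * voxel


def _all_interior_labels(ref_mask):
    """LabelVolume with no exterior: pore where ref, matrix elsewhere."""
    data = np.where(ref_mask, 1, 3).astype(np.uint8)
    return LabelVolume(data, 5.0)


def test_distance_map_neighbors():
    ref = np.zeros((7, 7, 7), dtype=bool)
    ref[3, 3, 3] = True
    d = og.distance_map(_all_interior_labels(ref), ref)
    assert d[3, 3, 3] == 0.0
    assert np.isclose(d[3, 3, 4], 5.0)  # face neighbor
    assert np.isclose(d[4, 4, 4], np.sqrt(3) * 5.0)  # diagonal neighbor


def test_distance_map_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        shape = tuple(rng.integers(5, 15, 3))
        ref = rng.uniform(size=shape) < 0.08
        if not ref.any():
            continue
        labels = _all_interior_labels(ref)
        assert np.allclose(og.distance_map(labels, ref), brute_force_distance(ref, 5.0))


def test_distance_map_masks_exterior_and_rejects_empty():
    data = np.full((6, 6, 6), 3, dtype=np.uint8)
    data[0] = 0  # exterior slab
    data[3, 3, 3] = 1
    lab = LabelVolume(data, 5.0)
    d = og.distance_map(lab, lab.mask("pore"))
    assert np.isnan(d[0]).all()
    assert np.isfinite(d[1:]).all()
    with pytest.raises(ValueError, match="empty"):
        og.distance_map(lab, np.zeros(lab.shape, dtype=bool))


def _pore_connectivity_fixture():
    """Aggregate with one boundary-reaching tube and one isolated pore."""
    data = np.zeros((32, 32, 32), dtype=np.uint8)
    interior = np.zeros_like(data, dtype=bool)
    interior[4:28, 4:28, 4:28] = True
    data[interior] = 3
    tube = np.zeros_like(interior)
    tube[4:20, 15:17, 15:17] = True  # touches the exterior-facing shell
    data[tube & interior] = 1
    hole = np.zeros_like(interior)
    hole[22:25, 22:25, 22:25] = True  # fully interior sphere-ish pore
    data[hole] = 1
    return LabelVolume(data, 5.0), tube & interior, hole


def test_connected_pores_retains_tube_excludes_isolated():
    lab, tube, hole = _pore_connectivity_fixture()
    conn = og.connected_pores(lab)
    assert conn[tube].all()
    assert not conn[hole].any()
    assert (conn <= lab.mask("pore")).all()


def test_adding_isolated_pore_never_changes_connected_set():
    lab, tube, hole = _pore_connectivity_fixture()
    base = og.connected_pores(lab)
    data = lab.data.copy()
    data[10:12, 24:26, 8:10] = 1  # another isolated pore
    lab2 = LabelVolume(data, 5.0)
    conn2 = og.connected_pores(lab2)
    assert np.array_equal(conn2 & base, base)
    assert not conn2[10:12, 24:26, 8:10].any()


def test_profile_flat_field_and_partition_identity():
    ref = np.zeros((24, 24, 24), dtype=bool)
    ref[0] = True
    lab = _all_interior_labels(ref)
    d = og.distance_map(lab, ref)
    matrix = lab.mask("matrix")
    const = ScalarVolume(np.full(lab.shape, 12.5), 5.0, stage="difference")
    prof = og.profile(const, d, matrix)
    filled = prof.bins["n_voxels"].to_numpy() > 0
    assert np.allclose(prof.bins["mean_os"].to_numpy()[filled], 12.5)
    assert np.allclose(prof.bins["sd_os"].to_numpy()[filled], 0.0)
    assert prof.bins["n_voxels"].sum() == matrix.sum()

    rng = np.random.default_rng(1)
    noisy = ScalarVolume(rng.normal(30, 5, lab.shape), 5.0, stage="difference")
    prof2 = og.profile(noisy, d, matrix)
    assert np.isclose(prof2.overall_mean(), noisy.data[matrix].mean(), rtol=1e-12)


def test_profile_recovers_known_function_of_distance():
    ref = np.zeros((40, 40, 40), dtype=bool)
    ref[:, :, 0] = True
    lab = _all_interior_labels(ref)
    d = og.distance_map(lab, ref)
    f = 40.0 * (1.0 - np.exp(-d / 30.0))
    vol = ScalarVolume(f, 5.0, stage="difference")
    matrix = lab.mask("matrix")
    prof = og.profile(vol, d, matrix)
    # oracle: f evaluated at the mean truth distance of each bin
    idx = np.minimum((d[matrix] / 5.0).astype(int), len(prof.bins) - 1)
    n = np.bincount(idx, minlength=len(prof.bins))
    mean_d = np.bincount(idx, weights=d[matrix], minlength=len(prof.bins)) / np.maximum(n, 1)
    expected = 40.0 * (1.0 - np.exp(-mean_d / 30.0))
    sel = n > 0
    assert np.allclose(prof.bins["mean_os"].to_numpy()[sel], expected[sel], atol=0.2)


def test_detect_extent_flat_profile_inside_band():
    ref = np.zeros((24, 24, 24), dtype=bool)
    ref[0] = True
    lab = _all_interior_labels(ref)
    d = og.distance_map(lab, ref)
    const = ScalarVolume(np.full(lab.shape, 20.0), 5.0, stage="difference")
    prof = og.profile(const, d, lab.mask("matrix"))
    ext = og.detect_extent(prof, bulk_mean=20.0, bulk_sd=1.0, persistence_bins=3)
    assert ext.extent_um == prof.bin_centers_um[0]
    assert not ext.censored


def test_detect_extent_censored_when_never_in_band():
    ref = np.zeros((24, 24, 24), dtype=bool)
    ref[0] = True
    lab = _all_interior_labels(ref)
    d = og.distance_map(lab, ref)
    const = ScalarVolume(np.full(lab.shape, 0.0), 5.0, stage="difference")
    prof = og.profile(const, d, lab.mask("matrix"))
    ext = og.detect_extent(prof, bulk_mean=50.0, bulk_sd=1.0, persistence_bins=3)
    assert ext.censored
    assert ext.extent_um == prof.bin_centers_um[-1]
    assert ext.direction == "depletion"


def _extent_run(lam, seed, **spec_kw):
    spec = og.PhantomSpec(
        shape=(96, 96, 96), rng_seed=seed, porosity_target=0.02,
        n_fibrous=0, n_compact=0, enrichment_amplitude=0.0,
        depletion_length_um=lam, **spec_kw,
    )
    pre, post, truth = og.generate_phantom(spec)
    osct = os_ct_from_phantom(pre, post, truth)
    labels = truth.labels
    matrix = labels.mask("matrix") & og.interior_core(labels)
    d = og.distance_map(labels, labels.mask("pore"))
    prof = og.profile(osct, d, matrix)
    bm, bs, _ = og.bulk_statistics(osct, d, matrix)
    ext = og.detect_extent(prof, bm, bs, persistence_bins=3, distances_um=d, restricted_mask=matrix)
    analytic = lam * np.log(spec.matrix_os_mean / (spec.matrix_os_mean - bm + bs))
    return ext, analytic, prof.bin_width_um


@pytest.mark.parametrize("lam", [15.0, 30.0])
def test_depletion_extent_matches_analytic_crossing(lam):
    """Detected extent within one bin of the closed-form band crossing."""
    ext, analytic, bw = _extent_run(lam, seed=1)
    assert ext.direction == "depletion"
    assert not ext.censored
    analytic_center = (np.floor(analytic / bw) + 0.5) * bw
    assert abs(ext.extent_um - analytic_center) <= bw + 1e-9
    assert 0.0 <= ext.affected_volume_fraction <= 1.0


def test_affected_fraction_monotone_in_lambda():
    fractions = [
        _extent_run(lam, seed=4)[0].affected_volume_fraction for lam in (15.0, 30.0, 60.0)
    ]
    assert fractions[0] <= fractions[1] <= fractions[2]


def test_enrichment_halo_detected_around_pom():
    """Enrichment around POM: direction flips and extent tracks lambda_POM."""
    spec = og.PhantomSpec(
        shape=(96, 96, 96), rng_seed=6, porosity_target=0.02,
        n_fibrous=0, n_compact=2, enrichment_amplitude=15.0,
        enrichment_length_um=20.0, depletion_length_um=1e-3,
        compact_semiaxis_vox=(5.0, 8.0),
    )
    pre, post, truth = og.generate_phantom(spec)
    osct = os_ct_from_phantom(pre, post, truth)
    labels = truth.labels
    matrix = labels.mask("matrix") & og.interior_core(labels)
    d = og.distance_map(labels, labels.mask("POM"))
    prof = og.profile(osct, d, matrix)
    bm, bs, _ = og.bulk_statistics(osct, d, matrix)
    ext = og.detect_extent(prof, bm, bs, persistence_bins=3, distances_um=d, restricted_mask=matrix)
    assert ext.direction == "enrichment"
    lam = spec.enrichment_length_um
    analytic = lam * np.log(spec.enrichment_amplitude / (bm + bs - spec.matrix_os_mean))
    assert abs(ext.extent_um - analytic) <= 2 * prof.bin_width_um


def test_local_thickness_tube_threshold():
    tube = np.zeros((16, 40, 40), dtype=bool)
    zz, yy, xx = np.mgrid[:16, :40, :40]
    tube[(yy - 20) ** 2 + (xx - 20) ** 2 <= 25] = True  # diameter 10 vox = 50 um
    lt = og.local_thickness_um(tube, 5.0)
    assert np.isclose(lt[8, 20, 20], 50.0)

    data = np.full((16, 40, 40), 3, dtype=np.uint8)
    data[0] = 0  # exterior: tube reaches it
    data[tube] = 1
    lab = LabelVolume(data, 5.0)
    assert og.air_filled_pores(lab, 30.0)[8, 20, 20]
    assert not og.air_filled_pores(lab, 60.0).any()
    assert np.array_equal(og.air_filled_pores(lab, 0.0), og.connected_pores(lab))
    with pytest.raises(ValueError):
        og.air_filled_pores(lab, -1.0)
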