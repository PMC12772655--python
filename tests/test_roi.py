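"""ROI placement, measurement, pooling, CNR, CoV and percent differences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ctphantom as cp
from _oracles import roi_stats_bruteforce


@pytest.fixture(scope="module")
def canonical_rois():
    specs = cp.canonical_phantoms()
    out = {}
    for spec in specs:
        _, mask = cp.rasterize_phantom(spec, cp.DEFAULT_MATERIALS, "PCCT", seed=1)
        out[spec.phantom_id] = (
            spec,
            mask,
            cp.place_rois(mask, spec, include_water=spec.phantom_id == 1),
        )
    return out


def test_thirteen_rois_per_slice_across_phantom_pair(canonical_rois):
    """The phantom pair carries 13 labeled ROIs per slice (6 lesion + 6
    parenchyma + 1 water) on 3 slices: 39 ROI specs per scan pair."""
    n1 = len(canonical_rois[1][2])
    n2 = len(canonical_rois[2][2])
    assert n1 == 9 * 3  # 4 lesions + 4 parenchyma + water, 3 slices
    assert n2 == 4 * 3  # 2 lesions + 2 parenchyma
    assert n1 + n2 == 39
    per_slice = {}
    for _, _, rois in canonical_rois.values():
        for r in rois:
            per_slice.setdefault(r.slice_index is not None and r.slice_index, 0)
    slices1 = {r.slice_index for r in canonical_rois[1][2]}
    assert len(slices1) == 3


def test_single_lesion_mask_gives_three_rois_per_slice(toy_phantom, toy_scan):
    _, mask = toy_scan
    rois = cp.place_rois(mask, toy_phantom)
    per_slice = len({r.slice_index for r in rois})
    assert len(rois) == 3 * per_slice  # lesion + background + water per slice


def test_roi_voxels_carry_only_their_region_label(canonical_rois):
    """Exhaustive voxel-label purity check for every placed ROI."""
    for spec, mask, rois in canonical_rois.values():
        x = mask.origin[0] + mask.spacing[0] * np.arange(mask.shape[0])
        y = mask.origin[1] + mask.spacing[1] * np.arange(mask.shape[1])
        for roi in rois:
            disc = ((x - roi.center_xy[0]) ** 2)[:, None] + (
                (y - roi.center_xy[1]) ** 2
            )[None, :] <= (roi.diameter / 2) ** 2
            labels = np.unique(mask.data[:, :, roi.slice_index][disc])
            assert list(labels) == [mask.label_for(roi.region_name)]


def test_part_solid_roi_sits_in_shell(canonical_rois):
    spec, mask, rois = canonical_rois[1]
    x = mask.origin[0] + mask.spacing[0] * np.arange(mask.shape[0])
    y = mask.origin[1] + mask.spacing[1] * np.arange(mask.shape[1])
    for roi in rois:
        if roi.material == "part_solid":
            disc = ((x - roi.center_xy[0]) ** 2)[:, None] + (
                (y - roi.center_xy[1]) ** 2
            )[None, :] <= (roi.diameter / 2) ** 2
            assert not mask.components[:, :, roi.slice_index][disc].any()


def test_measure_roi_matches_bruteforce(canonical_rois):
    spec, mask, rois = canonical_rois[2]
    rng = np.random.default_rng(0)
    vol = cp.ImageVolume(
        rng.normal(-800, 50, mask.shape).astype(np.float32),
        mask.spacing,
        mask.origin,
    )
    for roi in rois[:6]:
        m = cp.measure_roi(vol, roi)
        mean, sd, n = roi_stats_bruteforce(
            vol.data, vol.origin, vol.spacing, roi.center_xy, roi.slice_index,
            roi.diameter / 2,
        )
        assert m.n_voxels == n >= 20
        assert m.mean == pytest.approx(mean, rel=1e-9)
        assert m.sd == pytest.approx(sd, rel=1e-9)


def test_measure_roi_constant_and_two_voxel_cases():
    vol = cp.ImageVolume(np.full((5, 5, 3), 100.0), (1.0, 1.0, 1.0))
    roi = cp.RoiSpec((2.0, 2.0), 1, 4.0, "water", "water")
    m = cp.measure_roi(vol, roi)
    assert (m.mean, m.sd) == (100.0, 0.0)

    data = np.zeros((3, 3, 3))
    data[2, 1, 1] = 2.0  # voxels (1,1) and (2,1) -> {0, 2}
    vol2 = cp.ImageVolume(data, (1.0, 1.0, 1.0))
    m2 = cp.measure_roi(vol2, cp.RoiSpec((1.5, 1.0), 1, 1.6, "x", "x"))
    assert m2.n_voxels == 2
    assert m2.mean == pytest.approx(1.0)
    assert m2.sd == pytest.approx(np.sqrt(2.0))


def _meas(mean, material="lung_parenchyma"):
    roi = cp.RoiSpec((0.0, 0.0), 0, 8.0, material, material)
    return cp.RoiMeasurement(roi=roi, mean=mean, sd=1.0, n_voxels=100)


def test_pool_material_stats_hand_arithmetic():
    stats = cp.pool_material_stats([_meas(-870.0), _meas(-878.0)], "lung_parenchyma")
    assert stats.mean == pytest.approx(-874.0)
    assert stats.se == pytest.approx(4.0 / np.sqrt(2))
    assert stats.n_rois == 2


def test_pool_single_roi_flagged():
    stats = cp.pool_material_stats([_meas(-100.0)], "lung_parenchyma")
    assert stats.mean == -100.0 and stats.se == 0.0 and stats.single_roi


def test_pooling_invariant_to_order(rng):
    ms = [_meas(float(v)) for v in rng.normal(-870, 5, 40)]
    a = cp.pool_material_stats(ms, "lung_parenchyma")
    b = cp.pool_material_stats(list(reversed(ms)), "lung_parenchyma")
    assert a == b


def test_cnr_formula_examples():
    lesion = cp.RoiMeasurement(
        cp.RoiSpec((0, 0), 0, 8.0, "solid", "s"), mean=-100.0, sd=50.0, n_voxels=100
    )
    bg = cp.RoiMeasurement(
        cp.RoiSpec((0, 0), 0, 8.0, "lung_parenchyma", "p"),
        mean=-870.0, sd=40.0, n_voxels=100,
    )
    assert cp.compute_cnr(lesion, bg) == pytest.approx(15.4)
    same = cp.RoiMeasurement(lesion.roi, mean=-870.0, sd=50.0, n_voxels=100)
    assert cp.compute_cnr(same, bg) == 0.0
    doubled = cp.RoiMeasurement(lesion.roi, mean=-100.0, sd=100.0, n_voxels=100)
    assert cp.compute_cnr(doubled, bg) == pytest.approx(
        cp.compute_cnr(lesion, bg) / 2
    )
    degenerate = cp.RoiMeasurement(lesion.roi, mean=-100.0, sd=0.0, n_voxels=100)
    with pytest.warns(UserWarning):
        assert np.isnan(cp.compute_cnr(degenerate, bg))


def test_coefficient_of_variation_examples():
    assert cp.coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0
    assert cp.coefficient_of_variation([1.0, 3.0]) == pytest.approx(
        np.sqrt(2.0) / 2.0
    )
    with pytest.warns(UserWarning):
        cp.coefficient_of_variation([1.0, -1.0, 0.5, -0.5])


def test_percent_change_printed_pairs():
    assert round(cp.percent_change(134.4, 116.9), 1) == 13.0
    assert round(cp.percent_change(88.2, 76.8), 1) == 12.9
    assert cp.percent_change(5.0, 5.0) == 0.0
    assert cp.percent_change(10.0, 12.0, kind="increase") == pytest.approx(20.0)
    with pytest.raises(ValueError):
        cp.percent_change(0.0, 1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    ref=st.floats(1e-3, 1e4),
    comp=st.floats(0.0, 1e4),
)
def test_percent_change_reduction_increase_symmetry(ref, comp):
    assert cp.percent_change(ref, comp) == pytest.approx(
        -cp.percent_change(ref, comp, kind="increase"), abs=1e-9
    )
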