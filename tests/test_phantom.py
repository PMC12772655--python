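"""Phantom rasterization: geometry, mask fidelity, determinism."""

import numpy as np
import pytest

import ctphantom as cp
from ctphantom.materials import GeometryError, LesionSpec, MaterialTable, PhantomSpec
from ctphantom.phantom import layout_phantom


@pytest.fixture(scope="module")
def ph1_pcct():
    spec = cp.canonical_phantoms()[0]
    vol, mask = cp.rasterize_phantom(spec, cp.DEFAULT_MATERIALS, "PCCT", seed=7)
    return spec, vol, mask


def test_canonical_lesion_mask_means(ph1_pcct, ph2_truth_eidct):
    """Mean HU under each lesion mask matches the lesion spec within 2 HU
    (the large solid lesion's -94.8 HU target among them)."""
    for spec, vol, mask in (ph1_pcct, ph2_truth_eidct):
        for les in spec.lesions:
            got = vol.data[mask.region(les.lesion_id)].mean()
            assert got == pytest.approx(les.mean_intensity, abs=2.0)


def test_background_and_ring_values(ph1_pcct):
    spec, vol, mask = ph1_pcct
    hu = cp.DEFAULT_MATERIALS.for_scanner("PCCT")
    assert vol.data[mask.region("lung_parenchyma")].mean() == pytest.approx(
        hu["lung_parenchyma"], abs=0.01
    )
    assert vol.data[mask.region("water")].mean() == pytest.approx(
        hu["water"], abs=0.01
    )
    assert vol.data[mask.data == 0].max() == -1000.0


def test_zero_texture_cylinder_is_constant(toy_phantom):
    vol, mask = cp.rasterize_phantom(
        toy_phantom, cp.DEFAULT_MATERIALS, "EIDCT", fov_mm=110.0, texture=None
    )
    hu = cp.DEFAULT_MATERIALS.for_scanner("EIDCT")
    paren = vol.data[mask.region("lung_parenchyma")]
    assert np.all(paren == np.float32(hu["lung_parenchyma"]))
    lesion = vol.data[mask.region("toy_solid")]
    assert np.all(lesion == np.float32(-200.0))


def test_lesion_voxel_count_matches_ellipsoid_volume(ph2_truth_eidct):
    """Voxelized lesion volume agrees with the analytic ellipsoid volume
    within 5% (large ground-glass, 48.6 mm diameter)."""
    spec, vol, mask = ph2_truth_eidct
    layout = {l.lesion_id: l for l in mask.layout.lesions}["large_ground_glass"]
    a, _, c = layout.semi_axes
    analytic = 4.0 / 3.0 * np.pi * a * a * c
    count = int(mask.region("large_ground_glass").sum())
    voxel = count * vol.voxel_volume
    assert voxel == pytest.approx(analytic, rel=0.05)


def test_part_solid_core_labeled_and_mean_exact(ph1_pcct):
    spec, vol, mask = ph1_pcct
    hu = cp.DEFAULT_MATERIALS.for_scanner("PCCT")
    region = mask.region("large_part_solid")
    core = region & (mask.components == 1)
    shell = region & (mask.components == 0)
    assert core.any() and shell.any()
    # core denser than shell on the noise-free truth
    assert vol.data[core].mean() > vol.data[shell].mean() + 100


def test_oversized_lesion_raises_geometry_error():
    big = LesionSpec("huge", "solid", "large", 90.0, -100.0, "quarter", 1)
    with pytest.raises(GeometryError):
        layout_phantom(PhantomSpec(1, 200.0, 32.0, (big,)))


def test_unknown_material_raises_config_error():
    with pytest.raises(Exception):
        MaterialTable({"EIDCT": {"lung_parenchyma": -870.0}})
    with pytest.raises(Exception):
        cp.DEFAULT_MATERIALS.for_scanner("nope")


def test_material_ordering_enforced():
    bad = {k: dict(v) for k, v in cp.DEFAULT_MATERIALS.hu.items()}
    bad["EIDCT"]["ground_glass"] = -900.0  # below parenchyma
    with pytest.raises(Exception):
        MaterialTable(bad)


def test_rasterize_deterministic(toy_phantom):
    v1, m1 = cp.rasterize_phantom(
        toy_phantom, cp.DEFAULT_MATERIALS, "PCCT", fov_mm=110.0, seed=5
    )
    v2, m2 = cp.rasterize_phantom(
        toy_phantom, cp.DEFAULT_MATERIALS, "PCCT", fov_mm=110.0, seed=5
    )
    assert np.array_equal(v1.data, v2.data)
    assert np.array_equal(m1.data, m2.data)


def test_every_lesion_is_connected(ph1_pcct):
    from scipy.ndimage import label

    spec, vol, mask = ph1_pcct
    for les in spec.lesions:
        _, n = label(mask.region(les.lesion_id))
        assert n == 1
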