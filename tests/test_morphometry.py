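import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from glomquant.io import VoxelSpacing
from glomquant.morphometry import (
    aspect_length_ratios,
    effective_diameter,
    measure_all,
    object_volume,
    principal_extents,
    sphericity,
    surface_area,
)
from tests.conftest import digitize_shape, mask_points


class TestVolumeAndDiameter:
    def test_object_volume_with_override_and_product(self, paper_spacing):
        override = VoxelSpacing(1.76, 1.76, 5.0, voxel_volume_override=15.40)
        assert object_volume(1, override) == pytest.approx(15.40)
        assert object_volume(10_000, paper_spacing) == pytest.approx(154_880.0)
        with pytest.raises(ValueError):
            object_volume(0, paper_spacing)

    def test_effective_diameter_inverts_sphere_volume(self):
        assert effective_diameter(np.pi / 6 * 100**3) == pytest.approx(100.0)
        assert effective_diameter(15.40) == pytest.approx(3.087, abs=5e-4)
        assert effective_diameter(272_504) == pytest.approx(80.44, abs=5e-3)
        # machine-precision round trip through the sphere-volume formula
        for d in (1.0, 27.13, 77.54, 158.28):
            assert effective_diameter(np.pi / 6 * d**3) == pytest.approx(d, rel=1e-12)
        with pytest.raises(ValueError):
            effective_diameter(0.0)


class TestPrincipalExtents:
    def test_single_point_floors_all_axes(self, paper_spacing):
        ext = principal_extents(np.array([[3.0, 4.0, 5.0]]), floor=1.76)
        assert ext == (1.76, 1.76, 1.76)
        with pytest.raises(ValueError):
            principal_extents(np.empty((0, 3)))

    def test_axis_aligned_ellipsoid_extents(self, iso_spacing):
        mask = digitize_shape("ellipsoid", (40.0, 25.0, 10.0), iso_spacing)
        pts = mask_points(mask, iso_spacing)
        lx, ly, lz = principal_extents(pts)
        # half a voxel per axis on the voxelized oracle
        assert lx == pytest.approx(80.0, abs=1.5)
        assert ly == pytest.approx(50.0, abs=1.5)
        assert lz == pytest.approx(20.0, abs=1.5)

    def test_rotation_equivariance(self, iso_spacing):
        rot = Rotation.from_euler("z", 30, degrees=True)
        m0 = digitize_shape("ellipsoid", (40.0, 25.0, 10.0), iso_spacing)
        m1 = digitize_shape("ellipsoid", (40.0, 25.0, 10.0), iso_spacing, rotation=rot)
        e0 = principal_extents(mask_points(m0, iso_spacing))
        e1 = principal_extents(mask_points(m1, iso_spacing))
        assert np.allclose(e0, e1, atol=1.5)

    def test_continuum_rotation_invariance(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(400, 3)) * [9.0, 4.0, 1.5]
        rot = Rotation.random(random_state=np.random.default_rng(1))
        e0 = principal_extents(pts)
        e1 = principal_extents(pts @ rot.as_matrix().T)
        assert np.allclose(e0, e1, rtol=1e-9)


class TestAspectLengthRatios:
    @pytest.mark.parametrize("extents,expected", [
        ((10.0, 10.0, 10.0), (1.0, 1.0)),
        ((4.0, 2.0, 2.0), (2.0, 1.0)),
        ((80.0, 50.0, 20.0), (4.0, 2.5)),
    ])
    def test_ratio_examples(self, extents, expected):
        assert aspect_length_ratios(extents) == pytest.approx(expected)

    def test_zero_shortest_extent_rejected(self):
        with pytest.raises(ValueError):
            aspect_length_ratios((2.0, 1.0, 0.0))


class TestSurfaceArea:
    def test_single_voxel_matches_triangle_sum_oracle(self, iso_spacing):
        from skimage.measure import marching_cubes

        mask = np.zeros((1, 1, 1), dtype=bool)
        mask[0, 0, 0] = True
        # independent oracle: explicit cross-product triangle-area sum
        # over the same raw-mask mesh
        verts, faces, _, _ = marching_cubes(
            np.pad(mask, 1).astype(np.uint8), 0.5, spacing=iso_spacing.zyx)
        tri = verts[faces]
        oracle = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum()
        assert surface_area(mask, iso_spacing, smoothing_sigma=0.0) == pytest.approx(oracle)
        # the tiny-object fallback makes the smoothed call agree too
        assert surface_area(mask, iso_spacing) == pytest.approx(oracle)

    def test_sphere_area_isotropic(self, iso_spacing):
        mask = digitize_shape("sphere", (40.0, 40.0, 40.0), iso_spacing)
        analytic = 4 * np.pi * 40.0**2
        assert surface_area(mask, iso_spacing) == pytest.approx(analytic, rel=0.05)

    def test_prolate_spheroid_closed_form(self, iso_spacing):
        a, b = 20.0, 10.0
        e = np.sqrt(1 - (b / a) ** 2)
        analytic = 2 * np.pi * b**2 * (1 + (a / (b * e)) * np.arcsin(e))
        assert analytic == pytest.approx(2147.8, abs=0.5)
        mask = digitize_shape("ellipsoid", (a, b, b), iso_spacing)
        assert surface_area(mask, iso_spacing) == pytest.approx(analytic, rel=0.05)

    def test_raw_mask_mesh_overestimates_smooth_areas(self, iso_spacing):
        # the staircase bias the smoothed default removes
        mask = digitize_shape("sphere", (40.0, 40.0, 40.0), iso_spacing)
        raw = surface_area(mask, iso_spacing, smoothing_sigma=0.0)
        assert raw > 4 * np.pi * 40.0**2 * 1.05

    def test_empty_mask_rejected(self, iso_spacing):
        with pytest.raises(ValueError):
            surface_area(np.zeros((3, 3, 3), dtype=bool), iso_spacing)


class TestSphericity:
    def test_continuum_closed_forms(self):
        r = 3.7
        assert sphericity(4 / 3 * np.pi * r**3, 4 * np.pi * r**2) == pytest.approx(1.0)
        # prolate spheroid a=2, b=c=1
        a, b = 2.0, 1.0
        e = np.sqrt(1 - (b / a) ** 2)
        vol = 4 / 3 * np.pi * a * b * b
        area = 2 * np.pi * b**2 * (1 + (a / (b * e)) * np.arcsin(e))
        assert sphericity(vol, area) == pytest.approx(0.9287, abs=5e-4)
        s = 2.0
        assert sphericity(s**3, 6 * s**2) == pytest.approx(
            np.pi ** (1 / 3) * 6 ** (2 / 3) / 6, rel=1e-12)

    def test_values_above_one_are_reported_not_clamped(self, caplog):
        # slightly inflated volume pushes the quotient above 1
        r = 5.0
        psi = sphericity(4 / 3 * np.pi * r**3 * 1.05, 4 * np.pi * r**2)
        assert psi > 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            sphericity(1.0, -2.0)


class TestMeasureAll:
    def test_single_digitized_sphere_record(self, paper_spacing):
        from glomquant.io import LabelVolume

        mask = digitize_shape("sphere", (40.0, 40.0, 40.0), paper_spacing)
        arr = np.zeros(np.array(mask.shape) + 4, dtype=np.uint16)
        arr[2:-2, 2:-2, 2:-2][mask] = 1
        table = measure_all(LabelVolume(arr, paper_spacing))
        assert len(table) == 1
        row = table.iloc[0]
        assert row["alr_xz"] == pytest.approx(1.0, abs=0.1)
        assert row["alr_yz"] == pytest.approx(1.0, abs=0.1)
        assert row["sphericity"] == pytest.approx(1.0, abs=0.05)
        assert row["volume_um3"] == row["voxel_count"] * paper_spacing.voxel_volume

    def test_generated_bulb_bookkeeping(self, small_bulb_measurements):
        spec, vol, truth, table = small_bulb_measurements
        assert len(table) == spec.n_objects
        assert list(table["label"]) == sorted(truth["label"])
        # voxel-count volumes are exact by construction
        counts = dict(zip(table["label"], table["voxel_count"]))
        for label, count in counts.items():
            assert count == int((vol.array == label).sum())

    def test_empty_volume_warns_and_returns_empty(self, paper_spacing):
        from glomquant.io import LabelVolume

        vol = LabelVolume(np.zeros((3, 5, 5), dtype=np.uint16), paper_spacing)
        with pytest.warns(UserWarning):
            table = measure_all(vol)
        assert table.empty

    def test_median_diameter_commutes_for_odd_samples(self):
        rng = np.random.default_rng(3)
        volumes = rng.gamma(2.36, 122_291.05, size=501)
        diam = np.array([effective_diameter(v) for v in volumes])
        assert np.median(diam) == pytest.approx(
            effective_diameter(np.median(volumes)), rel=1e-12)


def test_alr_converges_with_resolution():
    """Digitized ellipsoid ALR approaches (a/c, b/c) as spacing shrinks."""
    semi = (30.0, 18.0, 12.0)
    errors = []
    for h in (3.0, 1.0):
        sp = VoxelSpacing(h, h, h)
        pts = mask_points(digitize_shape("ellipsoid", semi, sp), sp)
        alr = aspect_length_ratios(principal_extents(pts))
        errors.append(abs(alr[0] - semi[0] / semi[2]) + abs(alr[1] - semi[1] / semi[2]))
    assert errors[1] < errors[0]
    assert errors[1] < 0.1
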