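"""TPMS field evaluation, voxelization and surface extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tpmsflow as tf
from tpmsflow.geometry import EmptySurfaceError, extract_surface, sample_tpms_grid


class TestPSurfaceField:
    @pytest.mark.parametrize("lam", [1.0, 2.5, 5.0])
    def test_reference_points(self, lam):
        pts = np.array([[0.0, 0.0, 0.0], [lam / 2, lam / 2, lam / 2], [lam, 0, 0]])
        vals = tf.evaluate_p_surface(pts, lam)
        assert vals == pytest.approx([3.5, -2.5, 3.5])

    def test_preset_matches_general_form(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-10, 10, (200, 3))
        spec = tf.TPMSSpec.p_surface(wavelength=2.5)
        np.testing.assert_allclose(
            tf.evaluate_tpms(spec, pts), tf.evaluate_p_surface(pts, 2.5), atol=1e-12
        )

    def test_single_term_phase(self):
        spec = tf.TPMSSpec(
            terms=(tf.TPMSTerm(1.0, (1, 0, 0), 2.0, np.pi),), level_constant=0.3
        )
        val = tf.evaluate_tpms(spec, np.zeros(3))
        assert val == pytest.approx(-1.0 - 0.3)

    @given(
        st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
        st.integers(-3, 3),
        st.sampled_from([0, 1, 2]),
    )
    def test_periodicity(self, point, shift, axis):
        spec = tf.TPMSSpec.p_surface(wavelength=3.0)
        p = np.array(point)
        q = p.copy()
        q[axis] += shift * 3.0
        assert tf.evaluate_tpms(spec, p) == pytest.approx(
            tf.evaluate_tpms(spec, q), abs=1e-9
        )

    def test_permutation_symmetry_of_field_and_labels(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-5, 5, (100, 3))
        spec = tf.TPMSSpec.p_surface(wavelength=2.0)
        base = tf.evaluate_tpms(spec, pts)
        for perm in ((1, 0, 2), (2, 1, 0), (1, 2, 0)):
            np.testing.assert_allclose(
                tf.evaluate_tpms(spec, pts[:, perm]), base, atol=1e-12
            )
        block = tf.fixtures.make_tpms_block(wavelength_mm=2.0, resolution=24)
        for perm in ((1, 0, 2), (2, 1, 0)):
            np.testing.assert_array_equal(
                np.transpose(block.labels, perm), block.labels
            )

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            tf.evaluate_p_surface(np.array([[np.nan, 0, 0]]), 1.0)
        with pytest.raises(ValueError):
            tf.evaluate_p_surface(np.zeros(3), 0.0)
        with pytest.raises(ValueError):
            tf.TPMSSpec(terms=())


class TestBuildDomain:
    def test_default_slab_voxel_counts(self):
        spec = tf.TPMSSpec.p_surface(wavelength=5.0)
        layout = tf.ChannelLayout()
        domain = tf.build_domain(spec, layout, spacing=0.5)
        (i0, i1), (j0, j1), (k0, k1) = domain.meta["slab_index_box"]
        assert (i1 - i0, j1 - j0, k1 - k0) == (132, 60, 20)

    def test_open_level_makes_all_slab_fluid(self):
        # level constant far below the field minimum: whole slab is pore
        spec = tf.TPMSSpec.p_surface(wavelength=5.0)
        spec.level_constant = -3.6
        layout = tf.ChannelLayout(
            slab_length=8.0, slab_width=6.0, slab_height=6.0, port_length=1.0
        )
        domain = tf.build_domain(spec, layout, spacing=0.5)
        slab = domain.labels[tuple(map(lambda b: slice(*b), domain.meta["slab_index_box"]))]
        assert (slab == tf.FLUID).all()
        assert tf.measure_porosity(domain) == 1.0

    def test_port_cap_area_matches_disc(self):
        spec = tf.TPMSSpec.p_surface(wavelength=5.0)
        spec.level_constant = -3.6
        layout = tf.ChannelLayout(
            slab_length=8.0, slab_width=8.0, slab_height=8.0, port_diameter=3.08
        )
        domain = tf.build_domain(spec, layout, spacing=0.25)
        n_cap = domain.count(tf.INLET)
        disc_area = np.pi * (3.08 / 2) ** 2 / 0.25**2
        assert abs(n_cap - disc_area) / disc_area < 0.15

    def test_spacing_validation(self):
        spec = tf.TPMSSpec.p_surface()
        with pytest.raises(ValueError, match="spacing"):
            tf.build_domain(spec, tf.ChannelLayout(), spacing=4.0)

    def test_under_resolved_port_warns(self):
        spec = tf.TPMSSpec.p_surface(wavelength=5.0)
        spec.level_constant = -3.6
        layout = tf.ChannelLayout(
            slab_length=10.0, slab_width=8.0, slab_height=8.0, port_diameter=3.0
        )
        with pytest.warns(UserWarning, match="port"):
            tf.build_domain(spec, layout, spacing=1.0)

    def test_sheet_mode_thickens_surface(self):
        spec = tf.TPMSSpec.p_surface(wavelength=4.0, mode="sheet", half_thickness=0.3)
        block = tf.fixtures.make_tpms_block(wavelength_mm=4.0, resolution=32, spec=spec)
        # sheet solid is a thin shell: much less solid than either labyrinth
        porosity = tf.measure_porosity(block)
        assert 0.7 < porosity < 0.95


def sphere_field(n: int, box_mm: float = 12.0, r0: float = 5.0):
    dx = box_mm / n
    c = box_mm / 2
    ax = (np.arange(n) + 0.5) * dx
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return r0**2 - ((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2), dx


class TestSurfaceExtraction:
    def test_sphere_area_volume_converge(self):
        r0 = 5.0
        errors = []
        for n in (16, 32, 64):
            field, dx = sphere_field(n)
            mesh = extract_surface(field, spacing=dx)
            errors.append(abs(mesh.total_area - 4 * np.pi * r0**2))
        assert errors[2] < errors[1] < errors[0]

    def test_plane_cross_section_area(self):
        # half-space x < 6 inside a 10 mm box: open planar iso-surface
        # spanning the sampled lattice, whose extent is (n-1) voxel pitches
        n, box = 40, 10.0
        dx = box / n
        ax = (np.arange(n) + 0.5) * dx
        X = np.meshgrid(ax, ax, ax, indexing="ij")[0]
        mesh = extract_surface(6.0 - X, spacing=dx, pad=False)
        section = ((n - 1) * dx) ** 2
        assert abs(mesh.total_area - section) / section < 0.01

    def test_no_crossing_raises(self):
        with pytest.raises(EmptySurfaceError):
            extract_surface(np.ones((8, 8, 8)), spacing=1.0)

    def test_tpms_spec_source(self):
        spec = tf.TPMSSpec.p_surface(wavelength=4.0)
        mesh = extract_surface(
            spec, spacing=0.125, bounds=((0, 4.0), (0, 4.0), (0, 4.0))
        )
        assert mesh.total_area > 0 and mesh.enclosed_volume > 0

    def test_field_sampling_origin(self):
        spec = tf.TPMSSpec.p_surface(wavelength=4.0)
        field, origin = sample_tpms_grid(spec, ((0, 4), (0, 4), (0, 4)), 0.5)
        assert field.shape == (8, 8, 8)
        assert origin == pytest.approx([0.25, 0.25, 0.25])


class TestPorosity:
    def test_all_solid(self):
        labels = np.full((4, 4, 4), tf.SOLID, dtype=np.int8)
        dom = tf.VoxelDomain(labels, 1.0, np.zeros(3))
        assert tf.measure_porosity(dom) == 0.0

    def test_no_slab_raises(self):
        labels = np.full((4, 4, 4), tf.EXTERIOR, dtype=np.int8)
        dom = tf.VoxelDomain(labels, 1.0, np.zeros(3))
        with pytest.raises(ValueError):
            tf.measure_porosity(dom)
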