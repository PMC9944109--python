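"""Perfusion post-processing: wall pressure, section maxima, dead zones."""

import numpy as np
import pytest

import tpmsflow as tf
from tpmsflow.analysis import UnconvergedFieldError

from conftest import make_mini_tube


def field_on(dom, speed=None, pressure=None, converged=True):
    """Hand-built FlowField: uniform or per-voxel speed along x."""
    velocity = np.zeros(dom.shape + (3,))
    active = dom.active_mask
    if speed is not None:
        if np.isscalar(speed):
            velocity[active, 0] = speed
        else:
            velocity[..., 0] = np.where(active, speed, 0.0)
    p = np.full(dom.shape, np.nan)
    p[active] = pressure if pressure is not None else 0.0
    return tf.FlowField(velocity=velocity, pressure=p, converged=converged, iterations=0)


def open_box(n=10):
    """All-fluid box with port caps and no solid anywhere."""
    labels = np.full((n, n, n), tf.FLUID, dtype=np.int8)
    labels[0] = tf.INLET
    labels[-1] = tf.OUTLET
    return tf.VoxelDomain(labels, 0.1, np.zeros(3))


class TestWallPressure:
    def test_uniform_pressure(self):
        dom = make_mini_tube()
        field = field_on(dom, speed=0.01, pressure=42.0)
        p_max, p_mean, profile = tf.wall_pressure_stats(field, dom)
        assert p_max == p_mean == pytest.approx(42.0)
        assert np.allclose(profile, 42.0)

    def test_profile_length_equals_wall_slices(self):
        dom = make_mini_tube()
        field = field_on(dom, speed=0.01, pressure=1.0)
        _, _, profile = tf.wall_pressure_stats(field, dom)
        # caps are ports (not FLUID): every interior slice has wall voxels
        assert len(profile) == dom.shape[0] - 2

    def test_all_fluid_box_warns_and_falls_back(self):
        dom = open_box()
        field = field_on(dom, speed=0.01, pressure=7.0)
        with pytest.warns(UserWarning, match="wall"):
            p_max, p_mean, _ = tf.wall_pressure_stats(field, dom)
        assert p_max == pytest.approx(7.0)


class TestSectionMax:
    def test_zero_field(self):
        dom = make_mini_tube()
        field = field_on(dom, speed=0.0)
        assert tf.section_velocity_max(field, dom, dom.shape[0] // 2) == 0.0

    def test_out_of_range_index(self):
        dom = make_mini_tube()
        field = field_on(dom, speed=0.0)
        with pytest.raises(ValueError):
            tf.section_velocity_max(field, dom, dom.shape[0] + 5)

    def test_section_without_fluid(self):
        dom = make_mini_tube()
        dom.labels[3] = tf.SOLID
        field = field_on(dom, speed=0.0)
        with pytest.raises(ValueError, match="fluid"):
            tf.section_velocity_max(field, dom, 3)


class TestDeadZones:
    def make_box_with_dead_corner(self):
        # 25 x 20 x 20 fluid voxels, one 10^3 corner at rest
        labels = np.full((27, 22, 22), tf.SOLID, dtype=np.int8)
        labels[1:26, 1:21, 1:21] = tf.FLUID
        labels[0, 1:21, 1:21] = tf.INLET
        labels[26, 1:21, 1:21] = tf.OUTLET
        dom = tf.VoxelDomain(labels, 0.1, np.zeros(3))
        speed = np.zeros(dom.shape)
        speed[dom.active_mask] = 0.1
        speed[1:11, 1:11, 1:11] = 0.0
        return dom, speed

    def test_corner_block_fraction_and_single_component(self):
        dom, speed = self.make_box_with_dead_corner()
        field = field_on(dom, speed=speed)
        fraction, labels = tf.detect_dead_zones(field, dom)
        assert fraction == pytest.approx(1000 / 10000)
        comp_ids = set(np.unique(labels)) - {0}
        assert len(comp_ids) == 1
        assert (labels > 0).sum() == 1000

    def test_uniform_flow_has_no_dead_zones(self):
        dom = make_mini_tube()
        field = field_on(dom, speed=0.05)
        fraction, labels = tf.detect_dead_zones(field, dom)
        assert fraction == 0.0
        assert not labels.any()

    def test_zero_threshold_flags_nothing_on_positive_field(self):
        dom, speed = self.make_box_with_dead_corner()
        speed[speed == 0.0] = 1e-6  # strictly positive everywhere
        field = field_on(dom, speed=speed)
        fraction, _ = tf.detect_dead_zones(field, dom, dead_rel_threshold=0.0)
        assert fraction == 0.0

    def test_small_components_discarded_as_noise(self):
        dom, speed = self.make_box_with_dead_corner()
        speed[1:11, 1:11, 1:11] = 0.1  # undo the corner
        speed[13, 13, 13] = 0.0  # single stagnant voxel
        field = field_on(dom, speed=speed)
        fraction, labels = tf.detect_dead_zones(field, dom)
        assert fraction == 0.0 and not labels.any()

    def test_fraction_matches_label_count_exactly(self):
        dom, speed = self.make_box_with_dead_corner()
        field = field_on(dom, speed=speed)
        fraction, labels = tf.detect_dead_zones(field, dom)
        n_fluid = int((dom.labels == tf.FLUID).sum())
        assert fraction == np.count_nonzero(labels) / n_fluid

    def test_refuses_unconverged_field(self):
        dom = make_mini_tube()
        field = field_on(dom, speed=0.01, converged=False)
        with pytest.raises(UnconvergedFieldError):
            tf.detect_dead_zones(field, dom)


class TestRealizedReynolds:
    def test_zero_flow_warns_and_returns_zero(self, blood):
        dom = make_mini_tube()
        field = field_on(dom, speed=0.0)
        with pytest.warns(UserWarning, match="blocked"):
            assert tf.realized_reynolds(field, dom, blood) == 0.0

    def test_matches_hand_computation(self, blood):
        dom = make_mini_tube()
        field = field_on(dom, speed=0.1)
        d = dom.meta["layout"]["port_diameter_mm"] * 1e-3
        expected = 1060 * 0.1 * d / 0.005
        assert tf.realized_reynolds(field, dom, blood) == pytest.approx(expected)


class TestReportValidation:
    def test_dead_fraction_bounds(self):
        with pytest.raises(ValueError):
            tf.PerfusionReport(
                max_wall_pressure=1.0,
                mean_wall_pressure=0.5,
                axial_pressure_profile=np.array([1.0]),
                max_inlet_section_speed=0.1,
                max_outlet_section_speed=0.1,
                realized_Re=1.0,
                dead_zone_fraction=1.5,
                dead_zone_labels=np.zeros((2, 2, 2), dtype=int),
            )
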