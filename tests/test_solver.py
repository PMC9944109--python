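"""Flow-solver properties on small benchmark domains.

Quantitative validation against the Hagen-Poiseuille solution lives in
the acceptance suite (20 voxels across the diameter); here small, fast
domains exercise the solver's structural properties: zero forcing, Stokes
linearity, plane-Poiseuille accuracy, conservation, axis equivariance,
grid convergence and failure modes.
"""

import warnings

import numpy as np
import pytest

import tpmsflow as tf
from tpmsflow.domain import NoPercolationError

from conftest import make_mini_tube


@pytest.fixture(scope="module")
def blood_m():
    return tf.FluidProperties()


def solve_quiet(domain, fluid, bc, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tf.solve_steady_flow(domain, fluid, bc, **kw)


def test_zero_pressure_drop_means_no_flow(blood_m):
    dom = make_mini_tube()
    field = solve_quiet(dom, blood_m, tf.BoundaryConditions(100.0, 100.0))
    assert field.converged
    assert field.speed().max() < 1e-10


def test_stokes_linearity_flux_doubles(blood_m):
    # matched density contrasts give both runs the same time step and
    # relaxation time, so the discretization is identical and only the
    # forcing doubles
    dom = make_mini_tube()
    q = []
    for dp, contrast in ((2.0, 0.015), (4.0, 0.03)):
        settings = tf.SolverSettings(density_contrast=contrast)
        field = solve_quiet(dom, blood_m, tf.BoundaryConditions(dp, 0.0), settings=settings)
        q_in, _ = tf.port_fluxes(field, dom)
        q.append(q_in)
    assert q[1] / q[0] == pytest.approx(2.0, rel=0.02)


def test_plane_poiseuille_max_speed(blood_m):
    h = 0.25e-3  # half-gap, m
    L = 4.0e-3
    dp = 5.0
    dom = tf.fixtures.make_plane_channel(
        half_gap_mm=0.25, length_mm=4.0, width_mm=3.0, spacing_mm=0.05
    )
    field = solve_quiet(dom, blood_m, tf.BoundaryConditions(dp, 0.0))
    expected = dp * h**2 / (2 * 0.005 * L)
    assert field.converged
    assert field.speed().max() == pytest.approx(expected, rel=0.05)


def test_mass_conserved_at_convergence(blood_m):
    dom = make_mini_tube()
    field = solve_quiet(dom, blood_m, tf.BoundaryConditions(5.0, 0.0))
    assert field.converged
    assert tf.mass_flux_balance(field, dom) < 1e-3


def test_interior_pressure_within_port_bounds(solved_tube):
    """On a resolved fixture the interior (fluid) pressure stays between
    the port values to within 2% of the drop.  The cap layers are
    excluded: their recorded pressure belongs to the boundary treatment
    and carries a dynamic contribution of the inflow."""
    domain, field = solved_tube
    bc = field.bc
    p = field.pressure[domain.labels == tf.FLUID]
    delta = 0.02 * bc.pressure_drop
    assert np.nanmin(p) > bc.outlet_pressure - delta
    assert np.nanmax(p) < bc.inlet_pressure + delta


def test_axis_equivariance(blood_m):
    dom = make_mini_tube()
    field_x = solve_quiet(dom, blood_m, tf.BoundaryConditions(5.0, 0.0))
    # same tube with the flow axis moved to z
    dom_z = tf.VoxelDomain(
        np.transpose(dom.labels, (2, 1, 0)).copy(),
        dom.spacing,
        dom.origin[[2, 1, 0]],
        dict(dom.meta),
    )
    field_z = solve_quiet(dom_z, blood_m, tf.BoundaryConditions(5.0, 0.0))
    np.testing.assert_allclose(
        field_z.velocity[..., 2],
        np.transpose(field_x.velocity[..., 0], (2, 1, 0)),
        rtol=1e-6,
        atol=1e-12,
    )
    np.testing.assert_allclose(
        field_z.pressure,
        np.transpose(field_x.pressure, (2, 1, 0)),
        rtol=1e-6,
        atol=1e-9,
    )


def test_grid_convergence_toward_poiseuille(blood_m):
    """Doubling the voxels across the diameter shrinks the centreline error."""
    r, length, dp = 0.5, 4.0, 5.0
    expected = dp * (r * 1e-3) ** 2 / (4 * 0.005 * length * 1e-3)
    errs = []
    for spacing in (0.1, 0.05):
        dom = tf.fixtures.make_tube(r, length, spacing)
        field = solve_quiet(dom, blood_m, tf.BoundaryConditions(dp, 0.0))
        errs.append(abs(field.speed().max() - expected))
    assert errs[1] < errs[0]


def test_warm_start_reaches_same_solution(blood_m):
    dom = make_mini_tube()
    bc = tf.BoundaryConditions(4.0, 0.0)
    cold = solve_quiet(dom, blood_m, bc)
    seed = solve_quiet(dom, blood_m, tf.BoundaryConditions(2.0, 0.0))
    warm = solve_quiet(dom, blood_m, bc, initial_field=seed)
    assert warm.converged
    # agreement to a small multiple of the convergence tolerance,
    # referenced to the flow scale
    scale = np.abs(cold.velocity).max()
    np.testing.assert_allclose(
        warm.velocity, cold.velocity, rtol=1e-3, atol=1e-5 * scale
    )


def test_unconverged_run_is_flagged(blood_m):
    dom = make_mini_tube()
    settings = tf.SolverSettings(max_iterations=40, check_every=20)
    with pytest.warns(UserWarning, match="unconverged"):
        field = tf.solve_steady_flow(
            dom, blood_m, tf.BoundaryConditions(5.0, 0.0), settings
        )
    assert not field.converged


def test_non_percolating_domain_rejected(blood_m):
    dom = make_mini_tube()
    dom.labels[dom.shape[0] // 2] = tf.SOLID
    with pytest.raises(NoPercolationError):
        tf.solve_steady_flow(dom, blood_m, tf.BoundaryConditions(5.0, 0.0))


def test_impossible_pressure_drop_raises_named_divergence(blood_m):
    dom = make_mini_tube()
    with pytest.raises(tf.SolverDivergenceError, match="density contrast"):
        tf.solve_steady_flow(dom, blood_m, tf.BoundaryConditions(1e7, 0.0))


def test_missing_bcs_rejected(blood_m):
    with pytest.raises(ValueError):
        tf.solve_steady_flow(make_mini_tube(), blood_m, None)


class TestMassFluxBalanceDefinition:
    def make_uniform_field(self, dom, ux=0.01):
        velocity = np.zeros(dom.shape + (3,))
        velocity[dom.active_mask, 0] = ux
        pressure = np.where(dom.active_mask, 1.0, np.nan)
        return tf.FlowField(
            velocity=velocity, pressure=pressure, converged=True, iterations=0
        )

    def test_symmetric_field_balances_exactly(self):
        dom = make_mini_tube()
        field = self.make_uniform_field(dom)
        assert tf.mass_flux_balance(field, dom) == 0.0

    def test_zeroed_outlet_gives_full_imbalance(self):
        dom = make_mini_tube()
        field = self.make_uniform_field(dom)
        field.velocity[dom.labels == tf.OUTLET] = 0.0
        assert tf.mass_flux_balance(field, dom) == pytest.approx(1.0)
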