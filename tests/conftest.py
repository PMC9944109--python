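"""Shared fixtures: the expensive solves are session-scoped so the
validation, monotonicity, gradient and dead-zone tests reuse them."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import tpmsflow as tf

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

TUBE_RADIUS_MM = 1.0
TUBE_LENGTH_MM = 10.0
TUBE_DP_PA = 10.0


@pytest.fixture(scope="session")
def blood() -> tf.FluidProperties:
    return tf.FluidProperties()


@pytest.fixture(scope="session")
def solved_tube(blood):
    """Hagen-Poiseuille benchmark: R=1 mm, L=10 mm, 20 voxels across the
    diameter, 10 Pa drop."""
    domain = tf.fixtures.make_tube(TUBE_RADIUS_MM, TUBE_LENGTH_MM, spacing_mm=0.1)
    field = tf.solve_steady_flow(
        domain, blood, tf.BoundaryConditions(TUBE_DP_PA, 0.0)
    )
    return domain, field


@pytest.fixture(scope="session")
def tpms_sweep(blood):
    """Quarter-scale scaffold slab solved at 12..15 mmHg inlet, 11 mmHg
    outlet; each solve warm-starts from the previous pressure."""
    domain = tf.fixtures.make_scaled_slab()
    out = {}
    prev = None
    for p_in in (12, 13, 14, 15):
        bc = tf.BoundaryConditions.from_mmhg(p_in, 11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            field = tf.solve_steady_flow(domain, blood, bc, initial_field=prev)
            report = tf.analyze(field, domain)
        prev = field
        out[p_in] = (field, report)
    return domain, out


@pytest.fixture(scope="session")
def culdesac_solved(blood):
    """Cul-de-sac fixture solved at 12 -> 11 mmHg."""
    domain = tf.fixtures.make_cul_de_sac()
    field = tf.solve_steady_flow(domain, blood, tf.BoundaryConditions.from_mmhg(12, 11))
    return domain, field


@pytest.fixture(scope="session")
def culdesac_pipeline(blood, culdesac_solved):
    """Detect the pocket, prune it, re-solve, re-analyze."""
    domain, field = culdesac_solved
    report = tf.analyze(field, domain)
    pocket = tf.fixtures.pocket_mask(domain)
    # components overlapping the ground-truth pocket
    ids = sorted(set(np.unique(report.dead_zone_labels[pocket])) - {0})
    plan = tf.PruningPlan(
        component_ids=ids, dead_labels=report.dead_zone_labels
    )
    pruned = tf.prune(domain, plan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        field_after = tf.solve_steady_flow(
            pruned, blood, tf.BoundaryConditions.from_mmhg(12, 11)
        )
        report_after = tf.analyze(field_after, pruned)
    return {
        "domain": domain,
        "field": field,
        "report": report,
        "pruned": pruned,
        "field_after": field_after,
        "report_after": report_after,
    }


def make_mini_tube() -> tf.VoxelDomain:
    """Cheap under-resolved tube for property tests (not for validation)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tf.fixtures.make_tube(radius_mm=0.3, length_mm=2.0, spacing_mm=0.1)
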