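"""Chain grid construction and rigid-rotation wall velocities."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chainlfa import (GeometryError, MicroModelParams, build_chain_grid,
                      wall_velocity)

# Table positions: (x, y) in units of spacing for chains 1..9.
GRID_SIGNS = [(-1, -1), (0, -1), (1, -1),
              (-1, 0), (0, 0), (1, 0),
              (-1, 1), (0, 1), (1, 1)]


@pytest.fixture(scope="module")
def params():
    return MicroModelParams()


def test_grid_positions_match_table(params):
    geom = build_chain_grid(params, "seeded_random", seed=7)
    assert len(geom.placements) == 9
    s = params.spacing
    for placement, (sx, sy) in zip(geom.placements, GRID_SIGNS):
        assert placement.ref_x == pytest.approx(sx * s, abs=1e-18)
        assert placement.ref_y == pytest.approx(sy * s, abs=1e-18)
    assert geom.placements[4].ref_x == 0.0 and geom.placements[4].ref_y == 0.0
    assert geom.placements[0].ref_x == pytest.approx(-5e-6)
    assert geom.placements[0].ref_y == pytest.approx(-5e-6)


def test_seeded_orientations_deterministic(params):
    a = build_chain_grid(params, "seeded_random", seed=11)
    b = build_chain_grid(params, "seeded_random", seed=11)
    c = build_chain_grid(params, "seeded_random", seed=12)
    assert [p.angle for p in a.placements] == [p.angle for p in b.placements]
    assert [p.angle for p in a.placements] != [p.angle for p in c.placements]
    assert all(0.0 <= p.angle < math.pi for p in a.placements)


def test_aligned_mode_zero_angles(params):
    geom = build_chain_grid(params, "aligned")
    assert all(p.angle == 0.0 for p in geom.placements)


def test_fluid_area_closed_form(params):
    geom = build_chain_grid(params, "seeded_random")
    expected = params.domain_size**2 - 9 * params.L_chain * params.W_chain
    assert geom.fluid_area == pytest.approx(expected, rel=1e-14)
    assert geom.fluid_area == pytest.approx(2.235825e-10, rel=1e-12)


def test_wall_velocity_examples(params):
    geom = build_chain_grid(params, "aligned")
    chain = geom.placements[4]
    assert wall_velocity(chain, 100.0, (chain.ref_x, chain.ref_y)) == (0.0, 0.0)
    assert wall_velocity(chain, 0.0, (1e-6, 2e-6)) == (0.0, 0.0)
    # chain tip at r = L/2 = 5.25e-7 m, omega = 2*pi*3
    u, v = wall_velocity(chain, 18.8496, (chain.ref_x + 5.25e-7, chain.ref_y))
    assert u == pytest.approx(0.0, abs=1e-18)
    assert v == pytest.approx(9.8960e-6, rel=1e-3)


@settings(deadline=None, max_examples=100)
@given(st.floats(0.0, 200.0), st.floats(-7e-6, 7e-6), st.floats(-7e-6, 7e-6),
       st.integers(0, 8))
def test_wall_speed_is_omega_times_radius(omega, x, y, index):
    geom = build_chain_grid(MicroModelParams(), "seeded_random", seed=3)
    chain = geom.placements[index]
    u, v = wall_velocity(chain, omega, (x, y))
    r = math.hypot(x - chain.ref_x, y - chain.ref_y)
    assert math.hypot(u, v) == pytest.approx(omega * r, rel=1e-12, abs=1e-18)


def test_overlapping_chains_rejected(params):
    big = params.replace(L_chain=4.5e-6, spacing=4e-6)  # pitch < length
    with pytest.raises(GeometryError, match="overlap"):
        build_chain_grid(big, "aligned")


def test_out_of_domain_placement_rejected(params):
    wide = params.replace(spacing=7.4e-6)   # corner chains poke outside
    with pytest.raises(GeometryError, match="domain"):
        build_chain_grid(wide, "seeded_random", seed=1)


def test_polygon_export_and_report_serializable(params):
    geom = build_chain_grid(params, "seeded_random", seed=5)
    polys = geom.polygons()
    assert len(polys["chains"]) == 9
    assert all(len(c) == 4 for c in polys["chains"].values())
    json.dumps(geom.placement_report())   # must be JSON-serializable


def test_corner_pivot_moves_centre_keeps_reference(params):
    geom = build_chain_grid(params, "seeded_random", seed=5, pivot="corner")
    chain = geom.placements[0]
    assert chain.ref_x == pytest.approx(-5e-6)
    centre = chain.corners().mean(axis=0)
    # rotated about the corner: geometric centre leaves the grid node
    assert not np.allclose(centre, [chain.ref_x, chain.ref_y], atol=1e-9)


def test_tangential_projection_removes_normal_component(params):
    geom = build_chain_grid(params, "aligned")
    chain = geom.placements[4]
    # point on the long (top) face: outward normal is +y
    x = chain.ref_x + 2e-7
    y = chain.ref_y + chain.width / 2
    ut, vt = chain.tangential_wall_velocity(10.0, x, y)
    assert vt == pytest.approx(0.0, abs=1e-18)     # normal component removed
    u, _ = chain.wall_velocity(10.0, x, y)
    assert ut == pytest.approx(u)                  # tangential kept
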