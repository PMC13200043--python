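"""Cooperative test-line capture: rate algebra, conservation, asymmetry."""

import numpy as np
import pytest

from chainlfa import (MembraneGrid, MembraneModelParams, asymmetry_index,
                      parameter_sweep, reaction_rates,
                      simulate_membrane_assay)
from chainlfa import testline_complex_integral as tl_complex_integral
from chainlfa.cooperative import SpeciesState


@pytest.fixture(scope="module")
def params():
    return MembraneModelParams()


@pytest.fixture(scope="module")
def grid(params):
    return MembraneGrid(params=params, nx=140, ny=4)


def test_reaction_rates_examples():
    assert reaction_rates(0, 0, 0, 1e3, 1e-9, 7e4) == (0.0, 0.0, 0.0)
    rc, rc2, rc3 = reaction_rates(7e-8, 1e-5, 0.0, 1000.0, 1e-9, 0.0)
    assert rc3 == pytest.approx(7e-10, rel=1e-12)
    assert rc == rc2 == -rc3


def test_reaction_rates_pairwise_conservation_without_recruitment():
    rng = np.random.default_rng(0)
    c, c2, c3 = rng.uniform(0, 1e-5, (3, 50))
    rc, rc2, rc3 = reaction_rates(c, c2, c3, 1e3, 1e-9, 0.0)
    assert np.allclose(rc, rc2)
    assert np.allclose(rc2, -rc3)


def test_no_formation_pathway_without_association(params, grid):
    hist = simulate_membrane_assay(params, N_Abs=0.0, k_recruit=0.0,
                                   grid=grid, dt=0.5, t_end=60.0,
                                   output_times=[0.0, 30.0, 60.0])
    for state in hist.states:
        assert np.all(state.c3 == 0.0)


def test_antibody_complex_sum_conserved_without_recruitment(params, grid):
    hist = simulate_membrane_assay(params, N_Abs=700.0, k_recruit=0.0,
                                   grid=grid, dt=0.5, t_end=120.0,
                                   output_times=[0.0, 120.0])
    first, last = hist.states[0], hist.states[-1]
    total0 = first.c2 + first.c3
    total1 = last.c2 + last.c3
    mask = total0 > 0
    assert np.abs(total1[mask] / total0[mask] - 1.0).max() < 1e-6
    assert np.any(last.c3 > 0)     # the reaction actually ran


def test_nanochain_mass_audit(params, grid):
    hist = simulate_membrane_assay(params, N_Abs=600.0, k_recruit=7e4,
                                   grid=grid, dt=0.5, t_end=120.0,
                                   output_times=[0.0, 120.0])
    audit = hist.audit
    scale = audit.inflow.max()
    assert (audit.residual.abs() / scale).max() < 0.01


def test_species_stay_nonnegative(params, grid):
    hist = simulate_membrane_assay(params, N_Abs=1000.0, k_recruit=7e4,
                                   grid=grid, dt=0.5, t_end=120.0,
                                   output_times=[0.0, 120.0])
    last = hist.states[-1]
    floor = -1e-12 * params.C_Ab_init
    assert last.c.min() >= floor
    assert last.c2.min() >= floor
    assert last.c3.min() >= floor


def test_recruitment_amplifies_asymmetry(params, grid):
    runs = {}
    for kr in (0.0, 7e4):
        hist = simulate_membrane_assay(params, N_Abs=600.0, k_recruit=kr,
                                       grid=grid, dt=0.5, t_end=360.0,
                                       output_times=[0.0, 360.0])
        runs[kr] = asymmetry_index(hist.states[-1], grid)
    assert runs[7e4] > runs[0.0] > -0.05
    assert runs[7e4] > 2.0 * max(runs[0.0], 0.0)


def test_linear_regime_complex_scales_with_n_abs(params, grid):
    # linear regime: C0 scaled down 100x (no c2 depletion) and C_Ab_init
    # down 10x (no along-line depletion of c); total complex ~ kon ~ N_Abs
    dilute = params.replace(C0_mol=params.C0_mol / 100.0,
                            C_Ab_init=params.C_Ab_init / 10.0)
    totals = {}
    for na in (300.0, 1000.0):
        hist = simulate_membrane_assay(dilute, N_Abs=na, k_recruit=0.0,
                                       grid=grid, dt=0.5, t_end=150.0,
                                       output_times=[0.0, 150.0])
        totals[na] = tl_complex_integral(hist.states[-1], grid)
    assert 3.0 <= totals[1000.0] / totals[300.0] <= 3.7


def test_asymmetry_index_worked_cases(params, grid):
    nx, ny = grid.nx, grid.ny
    mask = grid.testline_mask()
    uniform = SpeciesState(0.0, np.zeros((nx, ny)), np.zeros((nx, ny)),
                           np.where(mask[:, None], 1.0, 0.0) * np.ones((nx, ny)))
    assert asymmetry_index(uniform, grid) == pytest.approx(0.0, abs=1e-12)

    mid = params.x_testline + params.w_testline / 2
    upstream_only = SpeciesState(0.0, np.zeros((nx, ny)), np.zeros((nx, ny)),
                                 np.where((mask & (grid.x_centers < mid))[:, None],
                                          1.0, 0.0) * np.ones((nx, ny)))
    assert asymmetry_index(upstream_only, grid) == pytest.approx(1.0)

    # linear ramp from 2a at the upstream edge to 0 downstream -> +0.5
    s = (grid.x_centers - params.x_testline) / params.w_testline
    ramp = np.where(mask, 2.0 * (1.0 - s), 0.0)
    ramp_state = SpeciesState(0.0, np.zeros((nx, ny)), np.zeros((nx, ny)),
                              ramp[:, None] * np.ones((nx, ny)))
    assert asymmetry_index(ramp_state, grid) == pytest.approx(0.5, abs=1e-12)

    empty = SpeciesState(0.0, np.zeros((nx, ny)), np.zeros((nx, ny)),
                         np.zeros((nx, ny)))
    assert asymmetry_index(empty, grid) is None


def test_parameter_sweep_structure_and_monotonicity(params, grid):
    df = parameter_sweep(params, N_Abs_list=[300, 600, 1000],
                         k_recruit_list=[0.0], grid=grid, dt=0.5,
                         t_end=150.0)
    assert len(df) == 3
    assert (df.status == "ok").all()
    totals = df.sort_values("N_Abs").total_complex.values
    assert np.all(np.diff(totals) > 0)


def test_parameter_sweep_marks_failures(params, grid):
    df = parameter_sweep(params, N_Abs_list=[300, -1], k_recruit_list=[0.0],
                         grid=grid, dt=0.5, t_end=30.0)
    assert df.status.iloc[0] == "ok"
    assert df.status.iloc[1].startswith("failed")
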