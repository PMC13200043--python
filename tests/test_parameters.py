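"""Parameter housing: table defaults, derived quantities, config validation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from chainlfa import (ConfigError, MembraneModelParams, MicroModelParams,
                      angular_velocity, capillary_pressure, dump_config,
                      load_config, per_molar_rate_to_si, si_association_rate)

# Reference values of the microscale global-parameter table.
MICRO_DEFAULTS = {
    "L_chain": 1050e-9, "W_chain": 150e-9, "domain_size": 15e-6,
    "C_bulk": 6.67e-8, "mu_fluid": 1.8e-3, "rho_fluid": 1000.0,
    "k_on": 1.0, "k_off": 0.1, "freq": 0.0, "Gamma_max": 1e-8,
    "t_end": 360.0, "spacing": 5e-6, "D_analyte": 1.1e-10,
    "M_analyte": 15000.0,
}

# Reference values of the membrane global-parameter table.
MEMBRANE_DEFAULTS = {
    "L_model": 3e-3, "H_membrane": 2.5e-3, "porosity": 0.75,
    "k_perm": 1e-13, "pore_size": 20e-6, "rho_fluid": 1000.0,
    "eta_fluid": 1e-3, "gamma_surface": 0.072, "C0_mol": 7e-8,
    "D0": 2e-13, "delta_smooth": 100e-6, "power_contrast": 2.0,
    "P_inlet": 25000.0, "k_min": 0.01, "W_TL": 1e-3, "H_TL": 2.5e-3,
    "x_testline": 3e-3, "w_testline": 1e-3, "C_Ab_init": 1e-5,
    "koff": 1e-9, "N_Abs": 100.0, "k_recruit": 7e4,
    "V_chain": 2e-20, "c3_max": 70e-6, "d_z": 3e-6,
}


def test_micro_defaults_reproduce_table():
    p = MicroModelParams()
    for key, expected in MICRO_DEFAULTS.items():
        assert getattr(p, key) == expected, key
    assert p.K_D == pytest.approx(0.1, rel=1e-15)
    assert p.fluid_area == pytest.approx(2.235825e-10, rel=1e-12)


def test_membrane_defaults_reproduce_table():
    p = MembraneModelParams()
    for key, expected in MEMBRANE_DEFAULTS.items():
        assert getattr(p, key) == expected, key
    assert p.P_cap == pytest.approx(7200.0, rel=1e-12)
    assert p.kon == pytest.approx(1000.0, rel=1e-15)
    assert p.domain_length == pytest.approx(7e-3)


@pytest.mark.parametrize("freq, expected", [
    (0.0, 0.0),
    (1.0, 2.0 * math.pi),
    (3.0, 18.8496),
])
def test_angular_velocity(freq, expected):
    assert angular_velocity(freq) == pytest.approx(expected, abs=1e-4)


def test_angular_velocity_rejects_negative():
    with pytest.raises(ValueError):
        angular_velocity(-1.0)


@pytest.mark.parametrize("gamma, pore, expected", [
    (0.072, 20e-6, 7200.0),
    (0.0, 20e-6, 0.0),
    (0.036, 20e-6, 3600.0),
])
def test_capillary_pressure(gamma, pore, expected):
    assert capillary_pressure(gamma, pore) == pytest.approx(expected, rel=1e-12)


def test_capillary_pressure_rejects_nonpositive_pore():
    with pytest.raises(ValueError):
        capillary_pressure(0.072, 0.0)


@pytest.mark.parametrize("n_abs, expected", [
    (100.0, 1000.0),
    (0.0, 0.0),
    (700.0, 7000.0),
])
def test_si_association_rate(n_abs, expected):
    assert si_association_rate(n_abs) == pytest.approx(expected, rel=1e-12)


def test_per_molar_conversion_is_factor_1e_minus_3():
    assert per_molar_rate_to_si(1e4) == pytest.approx(10.0, rel=1e-15)


def test_derived_quantities_recompute_after_mutation():
    p = MicroModelParams()
    p.k_off = 0.2
    assert p.K_D == pytest.approx(0.2)
    p.freq = 3.0
    assert p.omega == pytest.approx(6.0 * math.pi)
    m = MembraneModelParams()
    m.pore_size = 10e-6
    assert m.P_cap == pytest.approx(14400.0)
    m.N_Abs = 500.0
    assert m.kon == pytest.approx(5000.0)


@pytest.mark.parametrize("kwargs", [
    {"freq": -1.0}, {"mu_fluid": 0.0}, {"domain_size": -1e-6},
])
def test_micro_invariants_rejected(kwargs):
    with pytest.raises(ValueError):
        MicroModelParams(**kwargs)


@pytest.mark.parametrize("kwargs", [
    {"porosity": 0.0}, {"porosity": 1.5}, {"k_min": 0.0}, {"k_min": 1.5},
    {"N_Abs": -5.0},
])
def test_membrane_invariants_rejected(kwargs):
    with pytest.raises(ValueError):
        MembraneModelParams(**kwargs)


def test_config_roundtrip_bit_exact(tmp_path):
    micro, membrane = MicroModelParams(), MembraneModelParams()
    path = tmp_path / "config.yaml"
    dump_config(micro, membrane, path)
    micro2, membrane2 = load_config(path)
    assert micro2 == micro
    assert membrane2 == membrane


def test_empty_config_gives_defaults(tmp_path):
    path = tmp_path / "empty.yaml"
    path.write_text("")
    micro, membrane = load_config(path)
    assert micro == MicroModelParams()
    assert membrane == MembraneModelParams()


def test_config_single_override(tmp_path):
    path = tmp_path / "freq.yaml"
    path.write_text("micro:\n  freq: 3\n")
    micro, _ = load_config(path)
    assert micro.freq == 3.0
    assert micro.replace(freq=0.0) == MicroModelParams()


def test_config_unknown_key_named_in_error(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("micro:\n  k_onn: 1\n")
    with pytest.raises(ConfigError, match="k_onn"):
        load_config(path)


def test_config_unit_sanity_bounds(tmp_path):
    path = tmp_path / "units.yaml"
    path.write_text("micro:\n  L_chain: 1.05\n")   # metres vs micrometres slip
    with pytest.raises(ConfigError, match="units"):
        load_config(path)


@settings(deadline=None, max_examples=50)
@given(st.floats(min_value=1e-3, max_value=1e3),
       st.floats(min_value=1e-8, max_value=1e-3))
def test_capillary_pressure_scaling_property(gamma, pore):
    # P_cap is homogeneous of degree 1 in gamma and -1 in pore size
    base = capillary_pressure(gamma, pore)
    assert capillary_pressure(2 * gamma, pore) == pytest.approx(2 * base, rel=1e-12)
    assert capillary_pressure(gamma, 2 * pore) == pytest.approx(base / 2, rel=1e-12)
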