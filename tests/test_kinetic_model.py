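import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polgk.errors import InvalidParameterError, SchemeError
from polgk.kinetic_model import (
    InitialState,
    ProcessiveRates,
    RateConstants,
    build_scheme1,
    build_scheme2,
    burst_model,
    derived_parameters,
    equilibrate_binding,
    exponential_decay,
    simulate,
)
from polgk.presets import rate_constants


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    dict(k1=-0.01, k_minus1=1, k2=0.5, k_minus2=600, k3=12),
    dict(k1=0.01, k_minus1=np.nan, k2=0.5, k_minus2=600, k3=12),
])
def test_negative_or_nonfinite_rates_rejected(bad):
    with pytest.raises(InvalidParameterError):
        RateConstants(**bad)


def test_derived_dissociation_constants(s305r):
    assert s305r.kd_app == pytest.approx(1200.0)   # nM
    assert s305r.kd_dna == pytest.approx(100.0)    # nM


def test_processive_rates_validation():
    with pytest.raises(InvalidParameterError):
        ProcessiveRates(kpol=[], kd_dna=15.0)
    with pytest.raises(InvalidParameterError):
        ProcessiveRates(kpol=[65, -1], kd_dna=15.0)
    p = ProcessiveRates(kpol=[65, 36], kd_dna=15.0, k_on=0.002)
    assert p.k_off == pytest.approx(0.03)


# ---------------------------------------------------------------------------
# scheme 1
# ---------------------------------------------------------------------------

def test_scheme1_structure(s305r):
    sch = build_scheme1(s305r)
    assert set(sch.species) == {"E", "D25", "ED25", "N", "ED25N", "ED26", "D26"}
    assert len(sch.reactions) == 7  # 3 reversible pairs + 1 irreversible
    assert sch.observables["product26"] == ("ED26", "D26")


def test_scheme1_chemistry_off_gives_no_product(s305r):
    rates = RateConstants(s305r.k1, s305r.k_minus1, s305r.k2, s305r.k_minus2, 0.0)
    sim = simulate(build_scheme1(rates),
                   {"ED25": 75.0, "E": 25.0, "N": 5000.0},
                   np.linspace(0.01, 5, 20))
    assert np.allclose(sim["product26"].values, 0.0, atol=1e-9)


def test_no_nucleotide_no_product(s305r):
    sim = simulate(build_scheme1(s305r), {"ED25": 75.0, "E": 25.0},
                   np.linspace(0.01, 5, 20))
    assert np.allclose(sim["product26"].values, 0.0, atol=1e-9)


def test_all_rates_zero_everything_constant():
    rates = RateConstants(0, 0, 0, 0, 0)
    init = {"E": 10.0, "D25": 5.0, "ED25": 3.0, "N": 100.0}
    sch = build_scheme1(rates)
    sch.observables = {s: (s,) for s in sch.species}
    sim = simulate(sch, init, np.linspace(0.1, 10, 5))
    for sp in sch.species:
        assert np.allclose(sim[sp].values, init.get(sp, 0.0), atol=1e-9)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    k1=st.floats(1e-4, 0.1), k_minus1=st.floats(1e-3, 10.0),
    k_minus2=st.floats(1.0, 2000.0), k3=st.floats(0.1, 100.0),
    n_uM=st.floats(0.05, 50.0),
)
def test_mass_conservation_under_simulation(k1, k_minus1, k_minus2, k3, n_uM):
    """Total enzyme and total DNA are invariant along any trajectory."""
    rates = RateConstants(k1, k_minus1, 0.5, k_minus2, k3)
    sch = build_scheme1(rates)
    sch.observables = {"enzyme": sch.conserved["enzyme"],
                       "dna": sch.conserved["dna"]}
    init = {"E": 60.0, "D25": 30.0, "ED25": 40.0, "N": n_uM * 1000.0}
    sim = simulate(sch, init, np.geomspace(1e-3, 5.0, 15))
    assert np.allclose(sim["enzyme"].values, 100.0, rtol=1e-6)
    assert np.allclose(sim["dna"].values, 70.0, rtol=1e-6)


def test_simulated_concentrations_nonnegative(s305r):
    sch = build_scheme1(s305r)
    sch.observables = {s: (s,) for s in sch.species}
    sim = simulate(sch, {"ED25": 75.0, "E": 25.0, "N": 50.0},
                   np.geomspace(1e-3, 10, 30))
    for tc in sim.values():
        assert np.all(tc.values >= -1e-9)


def test_product_formation_monotone(s305r):
    """Without excision, product26 never decreases."""
    sim = simulate(build_scheme1(s305r), {"ED25": 75.0, "E": 25.0, "N": 400.0},
                   np.geomspace(1e-3, 20, 40))
    assert np.all(np.diff(sim["product26"].values) >= -1e-8)


def test_rapid_equilibrium_closed_form_oracle():
    """In the fast-equilibrium limit (k2*N, k-2 >> k3, no DNA exchange) the
    ODE product course matches A(1 - exp(-k3*N/(N+Kd) t)) within 1%."""
    n = 2000.0  # nM, in large excess over 10 nM DNA so [N] stays constant
    k3 = 2.0
    k_minus2 = 100.0 * k3 * 5  # k-2 = 1000 >> k3
    rates = RateConstants(k1=0.0, k_minus1=0.0, k2=0.5, k_minus2=k_minus2, k3=k3)
    kd = rates.kd_app
    assert rates.k2 * n >= 100 * k3 and k_minus2 >= 100 * k3
    times = np.geomspace(0.1, 10.0, 25)
    sim = simulate(build_scheme1(rates), {"ED25": 10.0, "N": n}, times)
    k_obs = k3 * n / (n + kd)
    analytic = 10.0 * (1.0 - np.exp(-k_obs * times))
    assert np.allclose(sim["product26"].values, analytic, rtol=0.01)


def test_simulate_input_validation(s305r):
    sch = build_scheme1(s305r)
    with pytest.raises(SchemeError):
        simulate(sch, {"bogus": 1.0}, [0.1, 1.0])
    with pytest.raises(InvalidParameterError):
        simulate(sch, {"E": 1.0}, [1.0, 0.5])
    with pytest.raises(InvalidParameterError):
        InitialState({"E": -5.0})


# ---------------------------------------------------------------------------
# scheme 2
# ---------------------------------------------------------------------------

def test_scheme2_five_step_bands():
    p = ProcessiveRates(kpol=[65, 36, 48, 28, 7], kd_dna=15.0)
    sch = build_scheme2(p)
    assert sorted(sch.observables) == [f"band{L}" for L in range(25, 31)]
    assert "kpol5" in sch.rates


def test_scheme2_ten_step_bands():
    p = ProcessiveRates(kpol=[37, 75, 60, 65, 70, 37, 73, 58, 70, 46], kd_dna=15.0)
    sch = build_scheme2(p)
    assert f"band35" in sch.observables and len(sch.observables) == 11


def test_scheme2_ladder_count_mismatch():
    p = ProcessiveRates(kpol=[65, 36], kd_dna=15.0)
    with pytest.raises(InvalidParameterError):
        build_scheme2(p, n_products=5)


def test_scheme2_single_step_reduces_to_exponential():
    """One incorporation with negligible dissociation: the 25-mer band decays
    as a single exponential at kpol."""
    p = ProcessiveRates(kpol=[12.0], kd_dna=1e-6)
    times = np.geomspace(0.005, 0.6, 20)
    sch = build_scheme2(p)
    sim = simulate(sch, {"ED25": 75.0, "E": 25.0}, times)
    assert np.allclose(sim["band25"].values,
                       exponential_decay(times, 75.0, 12.0), rtol=1e-5)


def test_scheme2_weak_binding_stalls_product():
    """With dissociation dominant (huge Kd) almost no DNA is extended."""
    p = ProcessiveRates(kpol=[50.0], kd_dna=1e6, k_on=0.002)
    times = np.geomspace(0.01, 2.0, 10)
    eq = equilibrate_binding(150.0, 75.0, p.kd_dna)
    sim = simulate(build_scheme2(p), {"E": eq["E"], "D25": eq["D"], "ED25": eq["ED"]},
                   times)
    assert sim["band26"].values[-1] < 0.05 * 75.0


def test_scheme2_conservation():
    p = ProcessiveRates(kpol=[65, 36, 48, 28, 7], kd_dna=15.0)
    sch = build_scheme2(p)
    times = np.geomspace(0.005, 2.0, 15)
    sim = simulate(sch, {"ED25": 64.0, "E": 86.0, "D25": 11.0}, times)
    total = sum(tc.values for tc in sim.values())
    assert np.allclose(total, 75.0, rtol=1e-6)


# ---------------------------------------------------------------------------
# closed-form models
# ---------------------------------------------------------------------------

def test_burst_model_identities():
    assert burst_model(0.0, 75.0, 20.0, 90.0) == 0.0
    assert burst_model(1e4, 75.0, 20.0, 0.0) == pytest.approx(75.0)
    t = np.linspace(0, 5, 10)
    assert np.allclose(burst_model(t, 0.0, 20.0, 3.0), 3.0 * t)
    with pytest.raises(InvalidParameterError):
        burst_model(-1.0, 75.0, 20.0, 90.0)


def test_burst_encodes_dissociation_rate():
    """k_ss/A is the steady-state DNA off-rate: 90/75 = 1.2 s^-1."""
    A, k_ss = 75.0, 90.0
    t = np.array([50.0, 60.0])
    slope = np.diff(burst_model(t, A, 20.0, k_ss))[0] / 10.0
    assert slope / A == pytest.approx(1.2, rel=1e-6)


def test_exponential_decay_identities():
    assert exponential_decay(0.0, 1.0, 0.34, 0.2) == pytest.approx(1.2)
    t = np.linspace(0, 9, 5)
    assert np.allclose(exponential_decay(t, 2.0, 0.0, 1.0), 3.0)
    # half-life identity at the wild-type excision rate
    assert exponential_decay(np.log(2) / 0.34, 1.0, 0.34, 0.0) == pytest.approx(0.5)
    with pytest.raises(InvalidParameterError):
        exponential_decay(1.0, 1.0, -0.1)


# ---------------------------------------------------------------------------
# derived parameters
# ---------------------------------------------------------------------------

def test_derived_parameters_s305r(s305r, wt):
    d = derived_parameters(s305r, reference=wt)
    assert d.kd_app_uM == pytest.approx(1.2)
    assert d.kd_dna_nM == pytest.approx(100.0)
    assert d.processivity_nt == pytest.approx(12.4 / 1.2, rel=1e-9)  # ~10 nt
    assert round(d.processivity_nt) == 10
    assert d.fold_change["k_off"] == pytest.approx(60.0)
    assert d.fold_change["kd_dna_nM"] == pytest.approx(100 / 9.9, rel=1e-9)


def test_processivity_unity_when_rates_equal():
    r = RateConstants(0.01, 5.0, 0.5, 100.0, 5.0)
    assert derived_parameters(r).processivity_nt == pytest.approx(1.0)


def test_derived_parameters_zero_denominator():
    r = RateConstants(0.0, 1.0, 0.5, 100.0, 5.0)
    with pytest.raises(InvalidParameterError):
        derived_parameters(r)


# ---------------------------------------------------------------------------
# equilibrium partitioning
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(e=st.floats(1.0, 500.0), d=st.floats(1.0, 500.0), kd=st.floats(0.01, 1e4))
def test_equilibrate_binding_satisfies_mass_action(e, d, kd):
    eq = equilibrate_binding(e, d, kd)
    assert eq["E"] >= 0 and eq["D"] >= 0 and eq["ED"] >= 0
    assert eq["E"] + eq["ED"] == pytest.approx(e, rel=1e-9)
    assert eq["D"] + eq["ED"] == pytest.approx(d, rel=1e-9)
    if eq["ED"] > 1e-12:
        assert eq["E"] * eq["D"] / eq["ED"] == pytest.approx(kd, rel=1e-6)
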