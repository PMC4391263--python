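import numpy as np
import pytest

from polgk.errors import DegenerateFitError, FitError, InvalidParameterError
from polgk.global_fit import (
    ExperimentSet,
    chi_square,
    fit_burst,
    fit_exponential,
    fit_global,
    fit_processive,
    scheme2_band_model,
)
from polgk.kinetic_model import ProcessiveRates, TimeCourse, burst_model, exponential_decay
from polgk.presets import rate_constants

from conftest import make_titration_set


# ---------------------------------------------------------------------------
# chi-square objective
# ---------------------------------------------------------------------------

def _one_course_set(times, values):
    tc = TimeCourse(times, values, "product26", {"series_value": 1.0})
    return ExperimentSet([tc], "scheme1",
                         [{"E_total": 1, "D_total": 1, "N": 1}], "dNTP")


def test_chi_square_zero_for_perfect_model():
    t = np.array([0.1, 0.2, 0.3])
    es = _one_course_set(t, np.array([1.0, 2.0, 3.0]))
    assert chi_square([np.array([1.0, 2.0, 3.0])], es) == 0.0


def test_chi_square_single_point_residual():
    es = _one_course_set(np.array([1.0]), np.array([5.0]))
    assert chi_square([np.array([3.0])], es) == pytest.approx(4.0)


def test_chi_square_hand_computed_three_points():
    # residuals (0.5, -1.0, 2.0), weights (1, 2, 0.5):
    # 0.25*1 + 1*2 + 4*0.5 = 4.25
    es = _one_course_set(np.array([1.0, 2.0, 3.0]), np.array([1.5, 1.0, 4.0]))
    model = [np.array([1.0, 2.0, 2.0])]
    assert chi_square(model, es, weights=[np.array([1.0, 2.0, 0.5])]) == pytest.approx(4.25)


def test_chi_square_shape_mismatch():
    es = _one_course_set(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
    with pytest.raises(InvalidParameterError):
        chi_square([np.array([1.0])], es)


# ---------------------------------------------------------------------------
# global mechanistic fits
# ---------------------------------------------------------------------------

def test_noiseless_roundtrip_recovers_kpol(s305r_noiseless_set):
    """Noiseless titration data regenerate every free rate within 1%."""
    fr = fit_global(s305r_noiseless_set, n_starts=2, seed=0)
    truth = rate_constants("S305R")
    assert fr.params["k3"] == pytest.approx(truth.k3, rel=0.01)
    assert fr.params["k_minus2"] == pytest.approx(truth.k_minus2, rel=0.01)
    assert fr.params["k_minus1"] == pytest.approx(truth.k_minus1, rel=0.01)
    assert fr.fixed["k2"] == 0.5
    assert fr.success


def test_refitting_from_optimum_does_not_improve(s305r_noiseless_set):
    fr = fit_global(s305r_noiseless_set, n_starts=1)
    fr2 = fit_global(s305r_noiseless_set, guesses=fr.all_params, n_starts=1)
    assert fr2.chi2 <= fr.chi2 * 1.001 + 1e-12


def test_dna_titration_recovers_kd_dna(s305r):
    """DNA-concentration series pins K_d,DNA = k-1/k1 within 5%."""
    times = np.geomspace(0.01, 3.0, 8)
    courses, specs = [], []
    from polgk.global_fit import scheme1_course_model
    for d in (10.0, 50.0, 300.0):
        spec = {"E_total": 55.0, "D_total": d, "N": 100000.0}
        v = scheme1_course_model(s305r.as_dict(), spec, times)
        courses.append(TimeCourse(times, v, "product26",
                                  {"series_value": d, "series_unit": "nM"}))
        specs.append(spec)
    es = ExperimentSet(courses, "scheme1", specs, "DNA")
    fr = fit_global(es, free=["k1", "k_minus1"],
                    fixed={"k2": 0.5, "k_minus2": s305r.k_minus2, "k3": s305r.k3},
                    n_starts=1)
    assert fr.params["k_minus1"] / fr.params["k1"] == pytest.approx(100.0, rel=0.05)


def test_course_order_does_not_change_optimum(s305r_noiseless_set):
    es = s305r_noiseless_set
    perm = ExperimentSet(list(reversed(es.courses)), es.scheme_id,
                         list(reversed(es.initial_specs)), es.titration)
    f1 = fit_global(es, free=["k_minus2", "k3"],
                    fixed={"k1": 0.012, "k_minus1": 1.2, "k2": 0.5}, n_starts=1)
    f2 = fit_global(perm, free=["k_minus2", "k3"],
                    fixed={"k1": 0.012, "k_minus1": 1.2, "k2": 0.5}, n_starts=1)
    assert f2.chi2 == pytest.approx(f1.chi2, rel=1e-6, abs=1e-9)
    assert f2.params["k3"] == pytest.approx(f1.params["k3"], rel=1e-4)


def test_single_concentration_is_flagged(s305r):
    """One dNTP concentration cannot separate k-2 from k3."""
    times = np.geomspace(0.01, 2.0, 12)
    es = make_titration_set(s305r, [6.0], times)
    with pytest.warns(UserWarning, match="single course"):
        fr = fit_global(es, free=["k_minus2", "k3"],
                        fixed={"k1": s305r.k1, "k_minus1": s305r.k_minus1,
                               "k2": 0.5},
                        n_starts=1)
    assert fr.warnings  # correlation/identifiability diagnostic recorded


def test_guess_outside_bounds_rejected(s305r_noiseless_set):
    with pytest.raises(InvalidParameterError):
        fit_global(s305r_noiseless_set, guesses={"k3": 1e9}, n_starts=1)


# ---------------------------------------------------------------------------
# burst fits
# ---------------------------------------------------------------------------

def _burst_course(A=75.0, k=20.0, k_ss=90.0, t_end=3.0, n=25):
    t = np.unique(np.concatenate([np.geomspace(0.005, 0.35, 12),
                                  np.linspace(0.35, t_end, n - 12)]))
    return TimeCourse(t, burst_model(t, A, k, k_ss), "product26")


def test_burst_fit_exact_recovery():
    fb = fit_burst(_burst_course())
    assert fb["A"] == pytest.approx(75.0, rel=1e-4)
    assert fb["k_obs"] == pytest.approx(20.0, rel=1e-4)
    assert fb["k_ss"] == pytest.approx(90.0, rel=1e-4)
    assert fb["k_off"] == pytest.approx(1.2, rel=1e-4)


def test_burst_fit_no_steady_state():
    fb = fit_burst(_burst_course(k_ss=0.0))
    assert fb["k_off"] == pytest.approx(0.0, abs=1e-6)


def test_burst_fit_fixed_amplitude():
    fb = fit_burst(_burst_course(), active_E=75.0)
    assert fb["A"] == 75.0
    assert fb["k_off"] == pytest.approx(1.2, rel=1e-4)


def test_burst_fold_change_between_variants():
    """Steady-state off-rates of 0.02 vs 1.2 s^-1 give a 60-fold change."""
    slow = fit_burst(_burst_course(A=75.0, k=30.0, k_ss=75.0 * 0.02, t_end=60.0))
    fast = fit_burst(_burst_course(A=75.0, k=12.0, k_ss=75.0 * 1.2, t_end=3.0))
    assert fast["k_off"] / slow["k_off"] == pytest.approx(60.0, rel=1e-3)


def test_burst_fit_degenerate_on_linear_data():
    t = np.linspace(0.1, 5, 20)
    tc = TimeCourse(t, 3.0 * t, "product26")
    with pytest.raises(DegenerateFitError):
        fit_burst(tc)


def test_burst_fit_needs_enough_points():
    t = np.array([0.1, 0.2, 0.3])
    with pytest.raises(FitError):
        fit_burst(TimeCourse(t, t, "product26"))


# ---------------------------------------------------------------------------
# exponential (excision) fits
# ---------------------------------------------------------------------------

def test_exponential_fit_noiseless():
    t = np.geomspace(0.05, 12.0, 15)
    tc = TimeCourse(t, exponential_decay(t, 75.0, 0.34), "primer25")
    fe = fit_exponential(tc)
    assert fe["k_exo"] == pytest.approx(0.34, rel=1e-3)


def test_exponential_fit_constant_data_warns():
    t = np.linspace(0.1, 5, 8)
    fe = fit_exponential(TimeCourse(t, np.full_like(t, 10.0), "primer25"))
    assert fe["k_exo"] == pytest.approx(0.0, abs=1e-3)
    assert fe["warnings"]


def test_exponential_fit_noisy_replicates_unbiased():
    """S305R-like excision (0.11 s^-1) at 5% noise: 20-replicate mean lands
    within the +-0.02 uncertainty of the measurement."""
    t = np.geomspace(0.2, 30.0, 14)
    clean = exponential_decay(t, 75.0, 0.11)
    rates = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        noisy = clean + rng.normal(0, 0.05 * clean.max(), t.shape)
        rates.append(fit_exponential(TimeCourse(t, noisy, "primer25"))["k_exo"])
    assert np.mean(rates) == pytest.approx(0.11, abs=0.02)


def test_recovery_error_shrinks_with_noise():
    """Estimator consistency: the excision-rate error decreases as sigma -> 0."""
    t = np.geomspace(0.2, 30.0, 14)
    clean = exponential_decay(t, 75.0, 0.11)
    errs = []
    for sigma_rel in (0.10, 0.02, 0.0):
        rep = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, sigma_rel * clean.max(), t.shape)
            rep.append(fit_exponential(TimeCourse(t, noisy, "primer25"))["k_exo"])
        errs.append(np.sqrt(np.mean((np.array(rep) - 0.11) ** 2)))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# processive-ladder fits
# ---------------------------------------------------------------------------

def _band_set(p: ProcessiveRates, times, e_total=150.0, d_total=75.0):
    bands = scheme2_band_model(p, {"E_total": e_total, "D_total": d_total}, times)
    courses, specs = [], []
    for name in sorted(bands, key=lambda n: int(n[4:])):
        courses.append(TimeCourse(times, bands[name], name,
                                  {"series_value": int(name[4:]), "series_unit": "nt"}))
        specs.append({"E_total": e_total, "D_total": d_total})
    return ExperimentSet(courses, "scheme2", specs, "band")


def test_processive_fit_noiseless_five_step():
    truth = ProcessiveRates(kpol=[65, 36, 48, 28, 7], kd_dna=15.0)
    es = _band_set(truth, np.geomspace(0.003, 1.5, 12))
    fr = fit_processive(es, 5, n_starts=1)
    for i, k in enumerate(truth.kpol):
        assert fr.params[f"kpol{i + 1}"] == pytest.approx(k, rel=0.02)
    assert fr.params["kd_dna"] == pytest.approx(15.0, rel=0.05)


def test_processive_single_step_matches_exponential_oracle():
    truth = ProcessiveRates(kpol=[12.0], kd_dna=1e-3)
    times = np.geomspace(0.005, 0.6, 15)
    es = _band_set(truth, times)
    fr = fit_processive(es, 1, n_starts=1)
    fe = fit_exponential(es.courses[0])  # 25-mer band decay
    assert fr.params["kpol1"] == pytest.approx(12.0, rel=0.01)
    assert fe["k_exo"] == pytest.approx(fr.params["kpol1"], rel=0.01)


def test_processive_more_steps_than_bands():
    truth = ProcessiveRates(kpol=[12.0], kd_dna=15.0)
    es = _band_set(truth, np.geomspace(0.01, 1.0, 8))
    with pytest.raises(FitError):
        fit_processive(es, 10)
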