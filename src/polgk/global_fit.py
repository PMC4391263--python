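"""Global nonlinear least-squares fitting of kinetic mechanisms to time courses.

A titration experiment is represented as an :class:`ExperimentSet`: several
:class:`~polgk.kinetic_model.TimeCourse` objects sharing one mechanism but
differing in a single titrated concentration (dNTP or DNA).  ``fit_global``
minimizes the summed squared residual over all courses simultaneously, with
any subset of the elementary rate constants free; the nucleotide association
rate k2 is fixed at its diffusion-limited value of 0.5 nM^-1 s^-1 by default.

Initial enzyme-DNA partitioning is recomputed from the *current* K_d,DNA at
every objective evaluation, so the pre-incubation equilibrium is part of the
model rather than a frozen input — this is what lets a DNA-titration series
determine k1 and k-1.

Simpler closed-form fits (burst equation, single-exponential excision decay)
and the processive-ladder fit are provided alongside.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np

from .errors import DegenerateFitError, FitError, InvalidParameterError
from .kinetic_model import (
    DerivedParams,
    InitialState,
    ProcessiveRates,
    RateConstants,
    TimeCourse,
    build_scheme1,
    build_scheme2,
    burst_model,
    derived_parameters,
    equilibrate_binding,
    exponential_decay,
    simulate,
)

__all__ = [
    "ExperimentSet",
    "FitResult",
    "chi_square",
    "fit_global",
    "fit_burst",
    "fit_exponential",
    "fit_processive",
    "scheme1_course_model",
    "scheme2_band_model",
    "KineticObjective",
    "SCHEME1_PARAMS",
    "DEFAULT_BOUNDS",
]

SCHEME1_PARAMS = ("k1", "k_minus1", "k2", "k_minus2", "k3")

#: Default box bounds on rate constants in native units.
DEFAULT_BOUNDS = (1e-6, 1e6)

#: Correlation above which a parameter pair is flagged as unidentifiable.
_CORR_FLAG = 0.995


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSet:
    """A group of time courses sharing a mechanism, differing in one variable.

    ``initial_specs`` holds one mapping per course with the total
    concentrations defining its starting condition:

    * scheme1 — ``{"E_total", "D_total", "N"}`` (nM); optional
      ``"preequilibrate": False`` to start from free enzyme and DNA.
    * scheme2 — ``{"E_total", "D_total"}`` shared across band courses;
      optional ``"trap": True`` disables DNA rebinding.
    """

    courses: list[TimeCourse]
    scheme_id: str
    initial_specs: list[dict]
    titration: str = ""

    def __post_init__(self) -> None:
        if not self.courses:
            raise InvalidParameterError("ExperimentSet needs at least one course")
        if len(self.initial_specs) != len(self.courses):
            raise InvalidParameterError("one initial spec per course is required")
        series = [c.meta.get("series_value") for c in self.courses]
        if all(s is not None for s in series) and len(set(series)) != len(series):
            raise InvalidParameterError(
                f"titrated values must be distinct across courses, got {series}"
            )

    @property
    def n_points(self) -> int:
        return sum(len(c) for c in self.courses)


@dataclass
class FitResult:
    """Outcome of a global fit.

    ``params``/``stderr`` cover the free parameters; ``fixed`` the ones held
    constant; ``chi2`` is the weighted sum of squared residuals.  ``derived``
    holds reporting-scale quantities (K_d,app, specificity, processivity)
    recomputable from the stored rates.  ``warnings`` records
    identifiability diagnostics; ``success`` is the optimizer's convergence
    flag — a failed fit is returned flagged, never silently.
    """

    params: dict[str, float]
    fixed: dict[str, float]
    chi2: float
    residuals: list[np.ndarray]
    n_points: int
    stderr: dict[str, float | None] = field(default_factory=dict)
    derived: dict | None = None
    success: bool = True
    message: str = ""
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None
    n_starts: int = 1
    start_chi2: list[float] = field(default_factory=list)
    guesses: dict[str, float] = field(default_factory=dict)
    scheme_id: str = ""

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise InvalidParameterError("chi2 must be >= 0")
        if len(self.params) >= self.n_points:
            raise InvalidParameterError(
                f"{len(self.params)} free parameters for {self.n_points} points"
            )

    @property
    def all_params(self) -> dict[str, float]:
        return {**self.fixed, **self.params}

    def rate_constants(self) -> RateConstants:
        return RateConstants(**{k: self.all_params[k] for k in SCHEME1_PARAMS})

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme_id,
            "params": self.params,
            "stderr": self.stderr,
            "fixed": self.fixed,
            "chi2": self.chi2,
            "n_points": self.n_points,
            "n_free": len(self.params),
            "derived": self.derived,
            "success": self.success,
            "message": self.message,
            "warnings": self.warnings,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "start_chi2": self.start_chi2,
            "guesses": self.guesses,
            "residuals": [r.tolist() for r in self.residuals],
        }


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _as_sets(data) -> list[ExperimentSet]:
    if isinstance(data, ExperimentSet):
        return [data]
    return list(data)


def scheme1_course_model(params: Mapping[str, float], spec: Mapping[str, float],
                         times: np.ndarray, observable: str = "product26") -> np.ndarray:
    """Simulate one scheme-1 course from totals, pre-equilibrating E + DNA."""
    rates = RateConstants(**{k: params[k] for k in SCHEME1_PARAMS})
    if spec.get("preequilibrate", True) and rates.k1 > 0:
        eq = equilibrate_binding(spec["E_total"], spec["D_total"], rates.kd_dna)
        init = {"E": eq["E"], "D25": eq["D"], "ED25": eq["ED"], "N": spec["N"]}
    else:
        init = {"E": spec["E_total"], "D25": spec["D_total"], "N": spec["N"]}
    sim = simulate(build_scheme1(rates), InitialState(init), times)
    return sim[observable].values


def scheme2_band_model(p: ProcessiveRates, spec: Mapping[str, float],
                       times: np.ndarray, start_length: int = 25) -> dict[str, np.ndarray]:
    """Simulate all gel bands of a processive ladder at the given times."""
    scheme = build_scheme2(p, trap=bool(spec.get("trap", False)),
                           start_length=start_length)
    eq = equilibrate_binding(spec["E_total"], spec["D_total"], p.kd_dna)
    init = InitialState({"E": eq["E"], f"D{start_length}": eq["D"],
                         f"ED{start_length}": eq["ED"]})
    sim = simulate(scheme, init, times)
    return {name: tc.values for name, tc in sim.items()}


class KineticObjective:
    """Residual function for a mechanism over one or more experiment sets.

    Shared by :func:`fit_global`, :func:`fit_processive` and the contour
    module (which re-optimizes nuisance parameters with some rates pinned).
    """

    def __init__(self, data, free: Sequence[str], fixed: Mapping[str, float],
                 weights: Sequence[np.ndarray] | None = None):
        self.sets = _as_sets(data)
        self.scheme_id = self.sets[0].scheme_id
        for s in self.sets:
            if s.scheme_id != self.scheme_id:
                raise InvalidParameterError("all experiment sets must share a scheme")
        self.free = tuple(free)
        self.fixed = dict(fixed)
        self.n_points = sum(s.n_points for s in self.sets)
        flat: list[np.ndarray] = []
        if weights is not None:
            courses = [c for s in self.sets for c in s.courses]
            if len(weights) != len(courses):
                raise InvalidParameterError("one weight array per course required")
            for w, c in zip(weights, courses):
                w = np.asarray(w, dtype=float)
                if w.shape != c.times.shape:
                    raise InvalidParameterError("weight/course shape mismatch")
                flat.append(np.sqrt(w))
        self.sqrt_w = flat or None

    def model_values(self, params: Mapping[str, float]) -> list[np.ndarray]:
        """Model prediction for every course, in data order."""
        out: list[np.ndarray] = []
        for s in self.sets:
            if self.scheme_id == "scheme1":
                for course, spec in zip(s.courses, s.initial_specs):
                    out.append(scheme1_course_model(params, spec, course.times,
                                                    course.observable))
            elif self.scheme_id == "scheme2":
                n = max(int(k[4:]) for k in params if k.startswith("kpol"))
                ladder = ProcessiveRates(
                    kpol=[params[f"kpol{i + 1}"] for i in range(n)],
                    kd_dna=params["kd_dna"], k_on=params.get("k_on", 0.002))
                union = np.unique(np.concatenate([c.times for c in s.courses]))
                bands = scheme2_band_model(ladder, s.initial_specs[0], union)
                for course in s.courses:
                    idx = np.searchsorted(union, course.times)
                    out.append(bands[course.observable][idx])
            else:
                raise InvalidParameterError(
                    f"no mechanistic model for scheme {self.scheme_id!r}")
        return out

    def residuals(self, params: Mapping[str, float]) -> np.ndarray:
        model = self.model_values(params)
        res = []
        i = 0
        for s in self.sets:
            for course in s.courses:
                r = course.values - model[i]
                if self.sqrt_w is not None:
                    r = r * self.sqrt_w[i]
                res.append(r)
                i += 1
        return np.concatenate(res)

    def chi2(self, params: Mapping[str, float]) -> float:
        r = self.residuals(params)
        return float(r @ r)

    def _lmfit_residual(self, lmpars: lmfit.Parameters) -> np.ndarray:
        # free parameters are carried as log10(rate) for conditioning
        values = {}
        for k in lmpars:
            v = lmpars[k].value
            values[k] = 10.0 ** v if k in self._log_free else v
        return self.residuals(values)

    def minimize(self, guesses: Mapping[str, float],
                 bounds: Mapping[str, tuple[float, float]] | None = None,
                 max_nfev: int | None = None):
        """Single trust-region least-squares run from the given start.

        Rate constants are optimized as log10 values (they are positive and
        span decades); the finite-difference step is widened to 1e-4 so
        numerical derivatives stay above ODE integration noise.
        """
        pars = lmfit.Parameters()
        bounds = bounds or {}
        self._log_free = set(self.free)
        for name in self.free:
            lo, hi = bounds.get(name, DEFAULT_BOUNDS)
            lo = max(lo, 1e-12)
            g = float(np.clip(guesses[name], lo, hi))
            pars.add(name, value=np.log10(g), min=np.log10(lo), max=np.log10(hi))
        for name, val in self.fixed.items():
            pars.add(name, value=val, vary=False)
        return lmfit.minimize(self._lmfit_residual, pars, method="least_squares",
                              diff_step=1e-4, max_nfev=max_nfev)

    @staticmethod
    def linear_params(mres) -> tuple[dict[str, float], dict[str, float | None]]:
        """Back-transform an lmfit result from log10 to native units."""
        params, stderr = {}, {}
        for n in mres.var_names:
            v = 10.0 ** mres.params[n].value
            params[n] = float(v)
            se = mres.params[n].stderr
            stderr[n] = float(v * np.log(10.0) * se) if se is not None else None
        return params, stderr


def chi_square(model_curves, data: ExperimentSet, weights=None) -> float:
    """Weighted sum of squared residuals between model curves and data.

    ``model_curves`` is a sequence of arrays (or a mapping keyed by
    experiment id) aligned course-by-course with ``data``.
    """
    if isinstance(model_curves, Mapping):
        model_curves = [model_curves[c.meta.get("experiment_id")] for c in data.courses]
    if len(model_curves) != len(data.courses):
        raise InvalidParameterError("one model curve per course required")
    total = 0.0
    for i, (m, c) in enumerate(zip(model_curves, data.courses)):
        m = np.asarray(m, dtype=float)
        if m.shape != c.values.shape:
            raise InvalidParameterError(
                f"course {i}: model shape {m.shape} != data shape {c.values.shape}")
        w = 1.0 if weights is None else np.asarray(weights[i], dtype=float)
        total += float(np.sum(w * (c.values - m) ** 2))
    return total


# ---------------------------------------------------------------------------
# global mechanistic fit
# ---------------------------------------------------------------------------

def _restart_guesses(guesses: dict[str, float], free: Sequence[str],
                     n_starts: int, seed: int | None,
                     bounds: Mapping[str, tuple[float, float]]) -> list[dict[str, float]]:
    """First start is the user guess; later starts perturb it in log space."""
    starts = [dict(guesses)]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        # spread restarts over one decade either side of the guess
        for k in range(1, n_starts):
            g = dict(guesses)
            for name in free:
                lo, hi = bounds.get(name, DEFAULT_BOUNDS)
                factor = 10.0 ** rng.uniform(-1.0, 1.0)
                g[name] = float(np.clip(guesses[name] * factor, lo, hi))
            starts.append(g)
    return starts


def _identifiability_warnings(mres, free: Sequence[str]) -> list[str]:
    out: list[str] = []
    covar = getattr(mres, "covar", None)
    if covar is None:
        out.append("covariance unavailable: parameters may be unidentifiable")
        return out
    var_names = [n for n in mres.var_names]
    sd = np.sqrt(np.clip(np.diag(covar), 0, None))
    for i, ni in enumerate(var_names):
        # parameters are log10-scaled: sd > 1.5 means >30-fold uncertainty
        if sd[i] > 1.5:
            out.append(f"parameter {ni} poorly constrained (>1.5 decades uncertainty)")
        for j in range(i + 1, len(var_names)):
            denom = sd[i] * sd[j]
            if denom > 0 and abs(covar[i, j] / denom) > _CORR_FLAG:
                out.append(f"parameters {ni} and {var_names[j]} strongly correlated")
    return out


def fit_global(data, free: Sequence[str] | None = None,
               fixed: Mapping[str, float] | None = None,
               guesses: Mapping[str, float] | None = None,
               bounds: Mapping[str, tuple[float, float]] | None = None,
               weights=None, n_starts: int = 5, seed: int | None = None) -> FitResult:
    """Fit a mechanism globally across titration courses.

    Parameters
    ----------
    data : ExperimentSet or sequence of ExperimentSet
        Courses to fit jointly (e.g. a dNTP titration and a DNA titration).
    free, fixed : parameter names / values
        For scheme1 the defaults free (k1, k-1, k-2, k3) and fix k2 at
        0.5 nM^-1 s^-1.
    guesses, bounds : per-parameter start values and (low, high) boxes.
        Rates default to [1e-6, 1e6] in native units.
    n_starts : int
        Number of optimizer starts; restarts perturb the guesses in log
        space (seeded) to guard against local minima.

    Returns
    -------
    FitResult, flagged (never silently) if the optimizer did not converge
    or parameters look unidentifiable.
    """
    sets = _as_sets(data)
    scheme_id = sets[0].scheme_id
    titrations = {id(s): len(s.courses) for s in sets}
    if scheme_id == "scheme1" and all(n < 2 for n in titrations.values()):
        _warnings.warn("titration fit with a single course: parameters are "
                       "likely underdetermined", stacklevel=2)

    fixed = dict(fixed or {})
    if scheme_id == "scheme1":
        fixed.setdefault("k2", 0.5)
        if free is None:
            free = [p for p in SCHEME1_PARAMS if p not in fixed]
        default_guess = {"k1": 0.005, "k_minus1": 0.5, "k2": 0.5,
                         "k_minus2": 500.0, "k3": 10.0}
    else:
        if free is None:
            raise InvalidParameterError("free parameter names are required")
        default_guess = {}
    free = list(free)
    guesses = {**default_guess, **(guesses or {})}
    missing = [p for p in free if p not in guesses]
    if missing:
        raise InvalidParameterError(f"no guess for free parameter(s) {missing}")
    bounds = dict(bounds or {})
    for name in free:
        lo, hi = bounds.get(name, DEFAULT_BOUNDS)
        if not (lo <= guesses[name] <= hi):
            raise InvalidParameterError(
                f"guess for {name} ({guesses[name]}) outside bounds [{lo}, {hi}]")

    obj = KineticObjective(data, free, fixed, weights=weights)
    starts = _restart_guesses({k: guesses[k] for k in free}, free, n_starts, seed, bounds)
    best = None
    start_chi2: list[float] = []
    for g in starts:
        mres = obj.minimize(g, bounds)
        c2 = float(mres.chisqr)
        start_chi2.append(c2)
        if best is None or c2 < best[1]:
            best = (mres, c2)
    mres, chi2 = best

    params, stderr = KineticObjective.linear_params(mres)
    warn = _identifiability_warnings(mres, free)
    if scheme_id == "scheme1" and {"k_minus2", "k3"} <= set(free):
        n_vals = {spec.get("N") for s in sets for spec in s.initial_specs}
        if len(n_vals) < 2:
            warn.append("k_minus2 and k3 cannot be separated at a single "
                        "nucleotide concentration (k_obs depends only on "
                        "their combination); titrate the nucleotide")
    all_p = {**fixed, **params}
    derived = None
    if scheme_id == "scheme1":
        try:
            derived = derived_parameters(RateConstants(**{k: all_p[k] for k in SCHEME1_PARAMS})).as_dict()
        except InvalidParameterError:
            pass

    res_vec = obj.residuals(all_p)
    residuals, i = [], 0
    for s in sets:
        for c in s.courses:
            residuals.append(res_vec[i:i + len(c)])
            i += len(c)

    result = FitResult(
        params=params, fixed=fixed, chi2=chi2, residuals=residuals,
        n_points=obj.n_points, stderr=stderr, derived=derived,
        success=bool(mres.success), message=str(mres.message),
        warnings=warn, seed=seed, n_starts=n_starts, start_chi2=start_chi2,
        guesses={k: guesses[k] for k in free}, scheme_id=scheme_id,
    )
    result._objective = obj  # for contour re-fits; not serialized
    return result


# ---------------------------------------------------------------------------
# closed-form fits
# ---------------------------------------------------------------------------

def fit_burst(tc: TimeCourse, active_E: float | None = None) -> dict:
    """Fit the burst equation and derive k_off = k_ss / A.

    ``active_E`` pins the amplitude at an independently measured active
    enzyme-DNA concentration; otherwise A is free.  Raises
    :class:`DegenerateFitError` when the data show no resolvable burst
    curvature.
    """
    if len(tc) < 5:
        raise FitError("burst fit needs >= 5 points spanning burst and linear phases")
    t, y = tc.times, tc.values
    # initial estimates: late linear slope, then amplitude as the intercept
    tail = max(3, len(t) // 3)
    slope, intercept = np.polyfit(t[-tail:], y[-tail:], 1)
    a0 = max(float(intercept), 1e-3 * (y.max() - y.min()) + 1e-9)
    half = a0 / 2.0
    k0 = np.log(2.0) / max(float(np.interp(half, y, t, left=t[1], right=t[-1])), t[1])

    pars = lmfit.Parameters()
    if active_E is not None:
        pars.add("A", value=float(active_E), vary=False)
    else:
        pars.add("A", value=a0, min=1e-12, max=1e6)
    pars.add("k_obs", value=float(np.clip(k0, 1e-6, 1e4)), min=1e-6, max=1e6)
    pars.add("k_ss", value=float(max(slope, 0.0)), min=0.0, max=1e6)

    def resid(p):
        return burst_model(t, p["A"].value, p["k_obs"].value, p["k_ss"].value) - y

    mres = lmfit.minimize(resid, pars, method="least_squares")
    A = float(mres.params["A"].value)
    k_obs = float(mres.params["k_obs"].value)
    k_ss = float(mres.params["k_ss"].value)

    span = float(y.max() - y.min()) or 1.0
    if A < 1e-6 * span or k_obs * t[-1] < 0.05:
        raise DegenerateFitError(
            "no burst curvature detectable: amplitude or rate collapsed to zero")
    return {
        "A": A, "k_obs": k_obs, "k_ss": k_ss, "k_off": k_ss / A,
        "chi2": float(mres.chisqr), "success": bool(mres.success),
        "stderr": {n: (float(mres.params[n].stderr) if mres.params[n].stderr is not None else None)
                   for n in ("A", "k_obs", "k_ss")},
    }


def fit_exponential(tc: TimeCourse) -> dict:
    """Fit ``A0 exp(-k_exo t) + C`` to an excision decay.

    Non-decaying data yield k_exo ~ 0 with a warning recorded in the result.
    """
    if len(tc) < 4:
        raise FitError("exponential fit needs >= 4 points")
    t, y = tc.times, tc.values
    c0 = float(y[-1])
    a0 = float(y[0] - y[-1])
    decaying = a0 > 0.02 * (abs(y).max() or 1.0)
    if decaying:
        half_y = c0 + a0 / 2.0
        t_half = float(np.interp(half_y, y[::-1], t[::-1]))
        k0 = np.log(2.0) / max(t_half, t[1] if len(t) > 1 else 1e-3)
    else:
        a0, k0 = max(a0, 1e-9), 1e-3

    pars = lmfit.Parameters()
    pars.add("A0", value=max(a0, 1e-9), min=0.0, max=1e6)
    pars.add("k_exo", value=float(np.clip(k0, 1e-9, 1e4)), min=0.0, max=1e6)
    pars.add("C", value=c0, min=-1e6, max=1e6)

    def resid(p):
        return exponential_decay(t, p["A0"].value, p["k_exo"].value, p["C"].value) - y

    mres = lmfit.minimize(resid, pars, method="least_squares")
    out = {n: float(mres.params[n].value) for n in ("A0", "k_exo", "C")}
    out["chi2"] = float(mres.chisqr)
    out["success"] = bool(mres.success)
    out["stderr"] = {n: (float(mres.params[n].stderr) if mres.params[n].stderr is not None else None)
                     for n in ("A0", "k_exo", "C")}
    out["warnings"] = []
    if not decaying or out["k_exo"] * (t[-1] - t[0]) < 0.01:
        out["warnings"].append("data show no measurable decay; k_exo ~ 0")
    return out


# ---------------------------------------------------------------------------
# processive-ladder fit
# ---------------------------------------------------------------------------

def fit_processive(data: ExperimentSet, n_steps: int, k_on: float = 0.002,
                   guesses: Mapping[str, float] | None = None,
                   bounds: Mapping[str, tuple[float, float]] | None = None,
                   n_starts: int = 1, seed: int | None = None) -> FitResult:
    """Jointly estimate the per-position rate ladder and K_d,DNA from bands.

    One time course per gel band (total DNA of each length).  The
    association rate ``k_on`` is held fixed; only the equilibrium K_d,DNA
    is identifiable from band data.
    """
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be >= 1")
    if n_steps > len(data.courses):
        raise FitError(
            f"{n_steps}-step ladder cannot be fit to {len(data.courses)} band course(s)")
    free = [f"kpol{i + 1}" for i in range(n_steps)] + ["kd_dna"]
    g = {f"kpol{i + 1}": 20.0 for i in range(n_steps)}
    g["kd_dna"] = 30.0
    g.update(guesses or {})
    b = {name: (1e-3, 1e4) for name in free}
    b.update(bounds or {})
    result = fit_global(data, free=free, fixed={"k_on": k_on}, guesses=g,
                        bounds=b, n_starts=n_starts, seed=seed)
    result.processive_rates = ProcessiveRates(
        kpol=[result.params[f"kpol{i + 1}"] for i in range(n_steps)],
        kd_dna=result.params["kd_dna"], k_on=k_on)
    return result
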