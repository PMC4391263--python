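"""Seeded synthetic rapid-quench datasets for every experiment class.

No raw gel data accompany the published designs, so the pipeline is
exercised end-to-end on simulated experiments: single-nucleotide
incorporation titrations (dNTP varied), DNA-concentration titrations,
multiple-turnover burst assays, mismatch-excision decays, and
processive-polymerization band ladders.  Zero-noise output is exactly the
deterministic forward model; Gaussian noise is added with a per-course
standard deviation of (relative σ × course maximum) + additive σ, the
scatter typical of quantified gel bands.

Identical (design, seed) pairs regenerate identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping
import warnings as _warnings

import numpy as np

from .errors import InvalidParameterError
from .global_fit import ExperimentSet, scheme1_course_model, scheme2_band_model
from .kinetic_model import (
    ProcessiveRates,
    RateConstants,
    TimeCourse,
    burst_model,
    equilibrate_binding,
    exponential_decay,
)
from . import presets

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "gen_single_turnover",
    "gen_dna_titration",
    "gen_burst",
    "gen_excision",
    "gen_processive",
    "single_turnover_design",
    "dna_titration_design",
    "burst_design",
    "excision_design",
    "processive_design",
]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise for quantified gel bands.

    ``rel`` — σ as a fraction of the course maximum; ``add`` — additive σ in
    nM; ``seed`` — default RNG seed (generators accept an override).
    """

    rel: float = 0.05
    add: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel < 0 or self.add < 0:
            raise InvalidParameterError("noise sigmas must be >= 0")

    def sigma(self, values: np.ndarray) -> float:
        return self.rel * float(np.max(np.abs(values), initial=0.0)) + self.add

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        s = self.sigma(values)
        if s == 0:
            return values.copy()
        return values + rng.normal(0.0, s, size=values.shape)


@dataclass(frozen=True)
class ExperimentDesign:
    """Everything needed to generate one synthetic experiment.

    ``truth`` holds the generating parameters (elementary rates for
    scheme 1, ladder + K_d,DNA for scheme 2, model parameters for the
    closed-form assays).  ``titration_values`` are in ``titration_unit``;
    dNTP grids are given in uM and converted internally to nM.
    """

    scheme_id: str
    truth: Mapping[str, float]
    e_total: float
    d_total: float
    titration_name: str = ""
    titration_values: tuple = ()
    titration_unit: str = ""
    times: tuple | None = None
    n_times: int = 12
    noise: NoiseModel = field(default_factory=NoiseModel)
    label: str = ""
    datp_nM: float | None = None
    t_end: float = 8.0

    def __post_init__(self) -> None:
        if len(set(self.titration_values)) != len(self.titration_values):
            raise InvalidParameterError("titration values must be distinct")
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if np.any(t <= 0) or np.any(np.diff(t) <= 0):
                raise InvalidParameterError("sample times must be positive and increasing")

    def with_noise(self, **kw) -> "ExperimentDesign":
        return replace(self, noise=replace(self.noise, **kw))


def _times_for(k_fast: float, n: int, k_slow: float | None = None,
               t_cap: float = 30.0) -> np.ndarray:
    """Log-spaced sample times spanning three half-lives of the fast phase,
    extended to cover a slower phase when one is present."""
    t_half = np.log(2.0) / k_fast
    t_end = 3.0 * t_half
    if k_slow is not None and k_slow > 0:
        t_end = max(t_end, min(3.0 / k_slow, t_cap))
    return np.geomspace(t_half / 20.0, min(t_end, t_cap), n)


def _rates(truth: Mapping[str, float]) -> RateConstants:
    return RateConstants(**{k: truth[k] for k in
                            ("k1", "k_minus1", "k2", "k_minus2", "k3")})


# ---------------------------------------------------------------------------
# design presets
# ---------------------------------------------------------------------------

def single_turnover_design(variant: str = "S305R", *, e_total: float = 100.0,
                           d_total: float = 75.0,
                           noise: NoiseModel | None = None) -> ExperimentDesign:
    """Single-nucleotide incorporation titration: preformed enzyme-DNA
    complex mixed with a grid of dATP concentrations (uM)."""
    return ExperimentDesign(
        scheme_id="scheme1", truth=presets.rate_constants(variant).as_dict(),
        e_total=e_total, d_total=d_total, titration_name="dATP",
        titration_values=presets.DNTP_GRIDS_UM.get(variant, presets.DNTP_GRIDS_UM["S305R"]),
        titration_unit="uM", noise=noise or NoiseModel(),
        label=f"single_turnover_{variant}")


def dna_titration_design(variant: str = "S305R", *, e_total: float = 55.0,
                         datp_uM: float = 100.0,
                         noise: NoiseModel | None = None) -> ExperimentDesign:
    """DNA-concentration titration at saturating dATP (55 nM enzyme,
    DNA 10-300 nM, 100 uM dATP)."""
    d = ExperimentDesign(
        scheme_id="scheme1", truth=presets.rate_constants(variant).as_dict(),
        e_total=e_total, d_total=0.0, titration_name="DNA",
        titration_values=(10.0, 30.0, 50.0, 100.0, 200.0, 300.0),
        titration_unit="nM", noise=noise or NoiseModel(),
        label=f"dna_titration_{variant}", datp_nM=datp_uM * 1000.0)
    return d


def burst_design(variant: str = "S305R", *, e_total: float = 100.0,
                 d_total: float = 350.0, datp_uM: float = 50.0,
                 t_end: float = 8.0,
                 noise: NoiseModel | None = None) -> ExperimentDesign:
    """Multiple-turnover burst assay: enzyme limiting (100 nM E, 350 nM
    DNA), 50 uM dATP, product followed to 8 s."""
    d = ExperimentDesign(
        scheme_id="burst", truth=presets.rate_constants(variant).as_dict(),
        e_total=e_total, d_total=d_total, noise=noise or NoiseModel(),
        label=f"burst_{variant}", datp_nM=datp_uM * 1000.0, t_end=t_end)
    return d


def excision_design(variant: str = "WT", *, e_total: float = 100.0,
                    d_total: float = 75.0,
                    noise: NoiseModel | None = None) -> ExperimentDesign:
    """Mismatch-excision decay: enzyme preincubated with 75 nM mismatched
    DNA; loss of full-length primer follows a single exponential."""
    return ExperimentDesign(
        scheme_id="exponential",
        truth={"A0": d_total, "k_exo": presets.EXCISION_RATES[variant], "C": 0.0},
        e_total=e_total, d_total=d_total, noise=noise or NoiseModel(),
        label=f"excision_{variant}")


def processive_design(variant: str = "P1073L", *, e_total: float = 150.0,
                      d_total: float = 75.0,
                      noise: NoiseModel | None = None) -> ExperimentDesign:
    """Processive-polymerization ladder (gel bands 25-mer upward)."""
    p = presets.processive_rates(variant)
    truth = {f"kpol{i + 1}": k for i, k in enumerate(p.kpol)}
    truth["kd_dna"] = p.kd_dna
    truth["k_on"] = p.k_on
    return ExperimentDesign(
        scheme_id="scheme2", truth=truth, e_total=e_total, d_total=d_total,
        noise=noise or NoiseModel(), label=f"processive_{variant}")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _rng(design: ExperimentDesign, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(design.noise.seed if seed is None else seed)


def gen_single_turnover(design: ExperimentDesign,
                        seed: int | None = None) -> ExperimentSet:
    """Generate a dNTP-titration ExperimentSet of product-formation courses."""
    if design.scheme_id != "scheme1":
        raise InvalidParameterError("single-turnover design must use scheme1")
    if design.e_total < design.d_total:
        _warnings.warn("single-turnover design has [enzyme] < [DNA]; courses "
                       "will not be single turnover", stacklevel=2)
    rates = _rates(design.truth)
    rng = _rng(design, seed)
    courses, specs = [], []
    for conc_uM in design.titration_values:
        n_nM = conc_uM * 1000.0
        spec = {"E_total": design.e_total, "D_total": design.d_total, "N": n_nM}
        k_obs = rates.k3 * n_nM / (n_nM + rates.kd_app)
        t = (np.asarray(design.times, dtype=float) if design.times is not None
             else _times_for(k_obs, design.n_times, k_slow=rates.k_minus1))
        clean = scheme1_course_model(rates.as_dict(), spec, t)
        courses.append(TimeCourse(
            t, design.noise.apply(clean, rng), "product26",
            {"series_value": conc_uM, "series_unit": "uM",
             "experiment_id": f"{design.label}_{conc_uM}uM"}))
        specs.append(spec)
    return ExperimentSet(courses, "scheme1", specs, design.titration_name)


def gen_dna_titration(design: ExperimentDesign,
                      seed: int | None = None) -> ExperimentSet:
    """Generate a DNA-titration ExperimentSet at saturating dATP.

    The pre-incubation equilibrium partitions enzyme and DNA at the truth
    K_d,DNA before t = 0, as in the generating model used for fitting.
    """
    if design.scheme_id != "scheme1":
        raise InvalidParameterError("DNA-titration design must use scheme1")
    rates = _rates(design.truth)
    rng = _rng(design, seed)
    n_nM = design.datp_nM or 100000.0
    k_obs = rates.k3 * n_nM / (n_nM + rates.kd_app)
    courses, specs = [], []
    for d_nM in design.titration_values:
        spec = {"E_total": design.e_total, "D_total": float(d_nM), "N": n_nM}
        t = (np.asarray(design.times, dtype=float) if design.times is not None
             else _times_for(k_obs, design.n_times, k_slow=rates.k_minus1))
        clean = scheme1_course_model(rates.as_dict(), spec, t)
        courses.append(TimeCourse(
            t, design.noise.apply(clean, rng), "product26",
            {"series_value": float(d_nM), "series_unit": "nM",
             "experiment_id": f"{design.label}_{d_nM:g}nM"}))
        specs.append(spec)
    return ExperimentSet(courses, "scheme1", specs, design.titration_name or "DNA")


def burst_truth(design: ExperimentDesign) -> dict[str, float]:
    """Burst-equation parameters implied by a design's rate constants:
    amplitude from the binding equilibrium, k_obs from nucleotide saturation,
    k_ss = k_off * A."""
    rates = _rates(design.truth)
    eq = equilibrate_binding(design.e_total, design.d_total, rates.kd_dna)
    A = eq["ED"]
    n_nM = design.datp_nM or 50000.0
    k_obs = rates.k3 * n_nM / (n_nM + rates.kd_app)
    return {"A": A, "k_obs": k_obs, "k_ss": rates.k_minus1 * A}


def gen_burst(design: ExperimentDesign, seed: int | None = None) -> TimeCourse:
    """Generate one multiple-turnover burst course (burst then linear phase)."""
    if design.scheme_id != "burst":
        raise InvalidParameterError("burst design must use scheme 'burst'")
    p = burst_truth(design)
    rng = _rng(design, seed)
    if design.times is not None:
        t = np.asarray(design.times, dtype=float)
    else:
        t_half = np.log(2.0) / p["k_obs"]
        t_end = design.t_end
        if p["k_ss"] > 0:
            # product cannot exceed the total DNA present: stop observing
            # where the (depletion-free) burst model would violate that
            t_end = min(t_end, (design.d_total - p["A"]) / p["k_ss"])
        t_end = max(t_end, 4.0 * t_half)
        t = np.unique(np.concatenate([
            np.geomspace(t_half / 10.0, 3.0 * t_half, 12),
            np.linspace(3.0 * t_half, t_end, 9)[1:],
        ]))
    clean = burst_model(t, p["A"], p["k_obs"], p["k_ss"])
    return TimeCourse(t, design.noise.apply(clean, rng), "product26",
                      {"experiment_id": design.label, "series_value": None,
                       "series_unit": "", "truth": p})


def gen_excision(design: ExperimentDesign, seed: int | None = None) -> TimeCourse:
    """Generate one mismatch-excision decay course (remaining full-length
    primer, nM)."""
    if design.scheme_id != "exponential":
        raise InvalidParameterError("excision design must use scheme 'exponential'")
    tr = design.truth
    rng = _rng(design, seed)
    t = (np.asarray(design.times, dtype=float) if design.times is not None
         else _times_for(tr["k_exo"], design.n_times))
    clean = exponential_decay(t, tr["A0"], tr["k_exo"], tr.get("C", 0.0))
    return TimeCourse(t, design.noise.apply(clean, rng), "primer25",
                      {"experiment_id": design.label, "series_value": None,
                       "series_unit": ""})


def gen_processive(design: ExperimentDesign,
                   seed: int | None = None) -> ExperimentSet:
    """Generate per-band time courses of a processive-polymerization ladder.

    Band values follow the gel-quantification convention: the fractional
    intensity of each length times the total DNA concentration, so at every
    time the clean bands sum to the total DNA.
    """
    if design.scheme_id != "scheme2":
        raise InvalidParameterError("processive design must use scheme2")
    n = max(int(k[4:]) for k in design.truth if k.startswith("kpol"))
    p = ProcessiveRates(
        kpol=[design.truth[f"kpol{i + 1}"] for i in range(n)],
        kd_dna=design.truth["kd_dna"], k_on=design.truth.get("k_on", 0.002))
    rng = _rng(design, seed)
    if design.times is not None:
        t = np.asarray(design.times, dtype=float)
    else:
        k_fast = max(p.kpol)
        t = np.geomspace(np.log(2.0) / k_fast / 10.0,
                         3.0 * np.log(2.0) / min(p.kpol), design.n_times)
    spec = {"E_total": design.e_total, "D_total": design.d_total}
    bands = scheme2_band_model(p, spec, t)
    courses, specs = [], []
    for i, (name, clean) in enumerate(sorted(bands.items(),
                                             key=lambda kv: int(kv[0][4:]))):
        length = int(name[4:])
        courses.append(TimeCourse(
            t, design.noise.apply(clean, rng), name,
            {"series_value": length, "series_unit": "nt",
             "experiment_id": f"{design.label}_{name}"}))
        specs.append(dict(spec))
    return ExperimentSet(courses, "scheme2", specs, "band")
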