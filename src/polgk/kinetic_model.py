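"""Mechanistic models of single-nucleotide incorporation and processive synthesis.

The polymerase mechanism is expressed as a :class:`KineticScheme` — an ordered
species list plus elementary mass-action reactions — which is compiled to a
stoichiometry matrix and integrated with a stiff ODE solver.  Two mechanisms
are provided:

* ``scheme1`` — single-nucleotide incorporation: DNA binding (k1/k-1),
  ground-state nucleotide binding (k2/k-2), and an irreversible chemistry step
  (k3 = k_pol) producing the n+1-mer.  Product DNA exchanges with free enzyme
  with the same binding constants as substrate DNA.
* ``scheme2`` — processive polymerization: a ladder of sequential irreversible
  incorporations (kpol_1 … kpol_n), each intermediate able to dissociate from
  the enzyme with equilibrium constant K_d,DNA.

Closed-form models for burst kinetics and exonucleolytic decay, and the
derived-parameter algebra (K_d,app, specificity constant, processivity), live
here as well.

Units: concentrations in nM, time in s, first-order rates in s^-1,
second-order rates in nM^-1 s^-1.  Micromolar appears only in I/O and
reporting, with explicit conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidParameterError, SchemeError, SimulationError

__all__ = [
    "RateConstants",
    "ProcessiveRates",
    "Reaction",
    "KineticScheme",
    "InitialState",
    "TimeCourse",
    "DerivedParams",
    "build_scheme1",
    "build_scheme2",
    "simulate",
    "burst_model",
    "exponential_decay",
    "derived_parameters",
    "equilibrate_binding",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

#: Integration tolerances: relative, and absolute in nM.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-6


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateConstants:
    """Elementary rate constants of the single-incorporation mechanism.

    Parameters
    ----------
    k1 : float
        DNA association rate (k_on), nM^-1 s^-1.
    k_minus1 : float
        DNA dissociation rate (k_off), s^-1.
    k2 : float
        Nucleotide association rate, nM^-1 s^-1; diffusion limited and
        conventionally fixed at 0.5 nM^-1 s^-1 in global fits.
    k_minus2 : float
        Nucleotide dissociation rate, s^-1.
    k3 : float
        Rate of the irreversible chemistry step (k_pol), s^-1.
    """

    k1: float
    k_minus1: float
    k2: float
    k_minus2: float
    k3: float

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2", "k_minus2", "k3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(
                    f"rate constant {name} must be finite and >= 0, got {v!r}"
                )

    @property
    def kd_app(self) -> float:
        """Apparent nucleotide dissociation constant k-2/k2, in nM."""
        if self.k2 <= 0:
            raise InvalidParameterError("K_d,app requires k2 > 0")
        return self.k_minus2 / self.k2

    @property
    def kd_dna(self) -> float:
        """DNA dissociation constant k-1/k1, in nM."""
        if self.k1 <= 0:
            raise InvalidParameterError("K_d,DNA requires k1 > 0")
        return self.k_minus1 / self.k1

    def as_dict(self) -> dict[str, float]:
        return {
            "k1": self.k1,
            "k_minus1": self.k_minus1,
            "k2": self.k2,
            "k_minus2": self.k_minus2,
            "k3": self.k3,
        }


@dataclass(frozen=True)
class ProcessiveRates:
    """Per-position incorporation rates and DNA affinity for scheme 2.

    ``kpol[i]`` is the rate (s^-1) of the i-th sequential incorporation;
    ``kd_dna`` (nM) governs exchange of every enzyme-DNA intermediate with
    free enzyme; ``k_on`` (nM^-1 s^-1) sets the absolute timescale of that
    exchange (only the equilibrium constant is usually identifiable, so the
    association rate defaults to the diffusion-like wild-type value).
    """

    kpol: tuple[float, ...]
    kd_dna: float
    k_on: float = 0.002

    def __post_init__(self) -> None:
        object.__setattr__(self, "kpol", tuple(float(k) for k in self.kpol))
        if len(self.kpol) < 1:
            raise InvalidParameterError("rate ladder must have >= 1 step")
        if any((not np.isfinite(k)) or k <= 0 for k in self.kpol):
            raise InvalidParameterError("all ladder rates must be finite and > 0")
        if not (np.isfinite(self.kd_dna) and self.kd_dna > 0):
            raise InvalidParameterError("K_d,DNA must be finite and > 0")
        if not (np.isfinite(self.k_on) and self.k_on > 0):
            raise InvalidParameterError("k_on must be finite and > 0")

    @property
    def k_off(self) -> float:
        """DNA dissociation rate implied by K_d,DNA and k_on, s^-1."""
        return self.kd_dna * self.k_on

    @property
    def n_steps(self) -> int:
        return len(self.kpol)


# ---------------------------------------------------------------------------
# scheme definition and compilation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``reactants`` and ``products`` are species names (repeat a name for a
    stoichiometric coefficient of two); ``rate`` names an entry of the
    scheme's rate table.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: str


@dataclass
class KineticScheme:
    """Executable mechanism: species, reactions, rate table, observables.

    ``observables`` maps an observable name to the species whose
    concentrations are summed to produce it (the quantity read off a gel
    band).  ``conserved`` maps a label (e.g. ``"enzyme"``) to the species
    that carry that moiety, used for conservation checks.
    """

    name: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    rates: dict[str, float]
    observables: dict[str, tuple[str, ...]]
    conserved: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = {s: i for i, s in enumerate(self.species)}
        if len(idx) != len(self.species):
            raise SchemeError(f"{self.name}: duplicate species")
        for rxn in self.reactions:
            for s in (*rxn.reactants, *rxn.products):
                if s not in idx:
                    raise SchemeError(f"{self.name}: reaction uses undeclared species {s!r}")
            if rxn.rate not in self.rates:
                raise SchemeError(f"{self.name}: reaction references undeclared rate {rxn.rate!r}")
            if self.rates[rxn.rate] < 0:
                raise InvalidParameterError(f"{self.name}: rate {rxn.rate!r} is negative")
        for obs, members in self.observables.items():
            for s in members:
                if s not in idx:
                    raise SchemeError(f"{self.name}: observable {obs!r} uses undeclared species {s!r}")
        self._index = idx
        self._compile()

    def _compile(self) -> None:
        """Build the stoichiometry matrix and reactant index lists."""
        n_s, n_r = len(self.species), len(self.reactions)
        S = np.zeros((n_s, n_r))
        reactant_idx: list[np.ndarray] = []
        for j, rxn in enumerate(self.reactions):
            for s in rxn.reactants:
                S[self._index[s], j] -= 1.0
            for s in rxn.products:
                S[self._index[s], j] += 1.0
            reactant_idx.append(np.array([self._index[s] for s in rxn.reactants], dtype=int))
        self._S = S
        self._reactant_idx = reactant_idx
        self._k = np.array([self.rates[r.rate] for r in self.reactions])

    def species_index(self, name: str) -> int:
        return self._index[name]

    def rhs(self, t: float, c: np.ndarray) -> np.ndarray:
        v = self._k.copy()
        for j, ridx in enumerate(self._reactant_idx):
            for i in ridx:
                v[j] *= c[i]
        return self._S @ v

    def jac(self, t: float, c: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the mass-action rate law."""
        n_s = len(self.species)
        dv = np.zeros((len(self.reactions), n_s))
        for j, ridx in enumerate(self._reactant_idx):
            for pos, i in enumerate(ridx):
                term = self._k[j]
                for pos2, i2 in enumerate(ridx):
                    if pos2 != pos:
                        term *= c[i2]
                dv[j, i] += term
        return self._S @ dv


class InitialState(dict):
    """Species concentrations (nM) at t = 0; unlisted species start at zero."""

    def __init__(self, concentrations: Mapping[str, float]):
        super().__init__({k: float(v) for k, v in concentrations.items()})
        for sp, v in self.items():
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"initial [{sp}] must be finite and >= 0, got {v}")

    def vector(self, scheme: KineticScheme) -> np.ndarray:
        unknown = set(self) - set(scheme.species)
        if unknown:
            raise SchemeError(f"initial state names species not in {scheme.name}: {sorted(unknown)}")
        return np.array([self.get(s, 0.0) for s in scheme.species])


@dataclass
class TimeCourse:
    """One observed trajectory: sampling times (s) and values (nM or fraction).

    ``meta`` records the titrated concentration and experiment id so a set of
    courses can be fit globally.
    """

    times: np.ndarray
    values: np.ndarray
    observable: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and values must be 1-D arrays of equal length")
        if len(self.times) and self.times[0] < 0:
            raise InvalidParameterError("times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("values must be finite")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# scheme builders
# ---------------------------------------------------------------------------

def build_scheme1(rates: RateConstants) -> KineticScheme:
    """Single-nucleotide incorporation mechanism.

    Species: free enzyme E, substrate DNA D25, binary complex ED25, nucleotide
    N, ternary complex ED25N, extended complex ED26, free product DNA D26.
    Chemistry (k3) is irreversible; pyrophosphate is not tracked.  Product
    DNA shares the substrate's binding constants (k1/k-1).
    """
    r = rates.as_dict()
    return KineticScheme(
        name="scheme1",
        species=("E", "D25", "ED25", "N", "ED25N", "ED26", "D26"),
        reactions=(
            Reaction(("E", "D25"), ("ED25",), "k1"),
            Reaction(("ED25",), ("E", "D25"), "k_minus1"),
            Reaction(("ED25", "N"), ("ED25N",), "k2"),
            Reaction(("ED25N",), ("ED25", "N"), "k_minus2"),
            Reaction(("ED25N",), ("ED26",), "k3"),
            Reaction(("E", "D26"), ("ED26",), "k1"),
            Reaction(("ED26",), ("E", "D26"), "k_minus1"),
        ),
        rates=r,
        observables={"product26": ("ED26", "D26")},
        conserved={
            "enzyme": ("E", "ED25", "ED25N", "ED26"),
            "dna": ("D25", "ED25", "ED25N", "ED26", "D26"),
        },
    )


def build_scheme2(p: ProcessiveRates, n_products: int | None = None,
                  trap: bool = False, start_length: int = 25) -> KineticScheme:
    """Processive-incorporation mechanism (sequential ladder).

    ``ED{L} -> ED{L+1}`` at kpol_i for each position, and every ``ED{L}``
    exchanges with ``E + D{L}`` with dissociation rate ``k_off = K_d * k_on``.
    With ``trap=True`` rebinding is disabled (enzyme trap present), leaving
    dissociation irreversible.  Observables ``band{L} = ED{L} + D{L}`` match
    gel quantification of total DNA at each length.
    """
    n = p.n_steps
    if n_products is not None and n_products != n:
        raise InvalidParameterError(
            f"rate ladder has {n} steps but n_products={n_products}"
        )
    lengths = list(range(start_length, start_length + n + 1))
    species = ["E"] + [f"ED{L}" for L in lengths] + [f"D{L}" for L in lengths]
    rates: dict[str, float] = {"k_on": p.k_on, "k_off": p.k_off}
    reactions: list[Reaction] = []
    for i, L in enumerate(lengths[:-1]):
        rates[f"kpol{i + 1}"] = p.kpol[i]
        reactions.append(Reaction((f"ED{L}",), (f"ED{L + 1}",), f"kpol{i + 1}"))
    for L in lengths:
        reactions.append(Reaction((f"ED{L}",), ("E", f"D{L}"), "k_off"))
        if not trap:
            reactions.append(Reaction(("E", f"D{L}"), (f"ED{L}",), "k_on"))
    observables = {f"band{L}": (f"ED{L}", f"D{L}") for L in lengths}
    return KineticScheme(
        name="scheme2",
        species=tuple(species),
        reactions=tuple(reactions),
        rates=rates,
        observables=observables,
        conserved={
            "enzyme": ("E",) + tuple(f"ED{L}" for L in lengths),
            "dna": tuple(f"ED{L}" for L in lengths) + tuple(f"D{L}" for L in lengths),
        },
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(scheme: KineticScheme, init: InitialState | Mapping[str, float],
             times: Sequence[float], rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL) -> dict[str, TimeCourse]:
    """Integrate the mass-action ODEs and return each observable's time course.

    Uses LSODA (switching stiff/non-stiff) with the scheme's analytic
    Jacobian.  Raises :class:`SimulationError` naming the scheme and rate
    table if the integrator fails.
    """
    if not isinstance(init, InitialState):
        init = InitialState(init)
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise InvalidParameterError("times must be a non-empty 1-D sequence")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise InvalidParameterError("times must be >= 0 and strictly increasing")

    c0 = init.vector(scheme)
    # integrate from 0 even when the first sample is later
    t_eval = t if t[0] == 0 else np.concatenate(([0.0], t))
    sol = solve_ivp(
        scheme.rhs, (0.0, float(t_eval[-1]) if t_eval[-1] > 0 else 1e-12), c0,
        t_eval=t_eval, method="LSODA", jac=scheme.jac, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed for scheme {scheme.name!r} "
            f"(rates={scheme.rates}): {sol.message}"
        )
    y = sol.y if t[0] == 0 else sol.y[:, 1:]
    out: dict[str, TimeCourse] = {}
    for obs, members in scheme.observables.items():
        vals = np.zeros(len(t))
        for s in members:
            vals += y[scheme.species_index(s)]
        out[obs] = TimeCourse(times=t, values=vals, observable=obs)
    return out


def equilibrate_binding(e_total: float, d_total: float, kd: float) -> dict[str, float]:
    """Partition enzyme and DNA at binding equilibrium (pre-incubation).

    Solves the one-site quadratic ``ED^2 - (E0+D0+Kd) ED + E0 D0 = 0`` for the
    complex concentration; returns ``{"E": free E, "D": free D, "ED": complex}``
    in nM.
    """
    if e_total < 0 or d_total < 0 or kd < 0:
        raise InvalidParameterError("totals and Kd must be >= 0")
    if kd == 0:
        ed = min(e_total, d_total)
    else:
        b = e_total + d_total + kd
        ed = (b - np.sqrt(b * b - 4.0 * e_total * d_total)) / 2.0
    ed = float(min(max(ed, 0.0), min(e_total, d_total)))
    return {"E": e_total - ed, "D": d_total - ed, "ED": ed}


# ---------------------------------------------------------------------------
# closed-form models
# ---------------------------------------------------------------------------

def burst_model(t, A: float, k_obs: float, k_ss: float):
    """Biphasic burst: ``A (1 - exp(-k_obs t)) + k_ss t``.

    ``A`` is the active enzyme-DNA amplitude (nM), ``k_obs`` the burst rate
    (s^-1), and ``k_ss`` the steady-state rate (nM s^-1) whose ratio to A
    gives the DNA dissociation rate, k_off = k_ss / A.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("time must be >= 0")
    if A < 0 or k_obs < 0 or k_ss < 0:
        raise InvalidParameterError("burst parameters must be >= 0")
    return A * (1.0 - np.exp(-k_obs * t)) + k_ss * t


def exponential_decay(t, A0: float, k_exo: float, C: float = 0.0):
    """Single-exponential decay ``A0 exp(-k_exo t) + C`` (mismatch excision)."""
    t = np.asarray(t, dtype=float)
    if k_exo < 0:
        raise InvalidParameterError("k_exo must be >= 0")
    return A0 * np.exp(-k_exo * t) + C


# ---------------------------------------------------------------------------
# derived parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerivedParams:
    """Derived kinetic quantities on reporting scales.

    * ``kd_app_uM`` — apparent nucleotide K_d (k-2/k2), uM.
    * ``kd_dna_nM`` — DNA K_d (k-1/k1), nM.
    * ``specificity_uM_s`` — k_pol / K_d,app, uM^-1 s^-1 (equals k_cat/K_m).
    * ``processivity_nt`` — k_pol / k_off, expected nucleotides per binding
      event.
    * ``fold_change`` — ratios this/reference per parameter, present when a
      reference was supplied (values > 1 mean larger than the reference).
    """

    kd_app_uM: float
    kd_dna_nM: float
    k_pol: float
    k_off: float
    specificity_uM_s: float
    processivity_nt: float
    fold_change: dict[str, float] | None = None

    def as_dict(self) -> dict:
        d = {
            "kd_app_uM": self.kd_app_uM,
            "kd_dna_nM": self.kd_dna_nM,
            "k_pol": self.k_pol,
            "k_off": self.k_off,
            "specificity_uM_s": self.specificity_uM_s,
            "processivity_nt": self.processivity_nt,
        }
        if self.fold_change is not None:
            d["fold_change"] = dict(self.fold_change)
        return d


def derived_parameters(rates: RateConstants,
                       reference: RateConstants | None = None) -> DerivedParams:
    """Compute K_d,app, K_d,DNA, the specificity constant, and processivity.

    With a ``reference`` (typically wild type), fold changes are attached as
    this/reference ratios for K_d,DNA, k_pol, K_d,app, specificity, k_off and
    processivity.
    """
    for nm, v in (("k1", rates.k1), ("k2", rates.k2)):
        if v <= 0:
            raise InvalidParameterError(f"derived parameters require {nm} > 0")
    if rates.k_minus1 <= 0:
        raise InvalidParameterError("processivity requires k_off = k-1 > 0")
    kd_app_nM = rates.kd_app
    kd_dna = rates.kd_dna
    spec = rates.k3 / (kd_app_nM / 1000.0)  # s^-1 per uM -> uM^-1 s^-1
    out = DerivedParams(
        kd_app_uM=kd_app_nM / 1000.0,
        kd_dna_nM=kd_dna,
        k_pol=rates.k3,
        k_off=rates.k_minus1,
        specificity_uM_s=spec,
        processivity_nt=rates.k3 / rates.k_minus1,
    )
    if reference is not None:
        ref = derived_parameters(reference)
        out = DerivedParams(
            **{k: getattr(out, k) for k in (
                "kd_app_uM", "kd_dna_nM", "k_pol", "k_off",
                "specificity_uM_s", "processivity_nt")},
            fold_change={
                "kd_dna_nM": out.kd_dna_nM / ref.kd_dna_nM,
                "k_pol": out.k_pol / ref.k_pol,
                "kd_app_uM": out.kd_app_uM / ref.kd_app_uM,
                "specificity_uM_s": out.specificity_uM_s / ref.specificity_uM_s,
                "k_off": out.k_off / ref.k_off,
                "processivity_nt": out.processivity_nt / ref.processivity_nt,
            },
        )
    return out
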