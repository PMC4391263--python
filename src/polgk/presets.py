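"""Published parameter sets and experiment designs for Pol-γ variants.

These encode the measured kinetic constants of wild-type Pol-γ and the two
Alpers-syndrome mutants S305R and P1073L, together with the rapid-quench
experiment designs used to characterize them (dNTP titrations, a DNA
titration, burst and excision assays, processive-polymerization ladders).
All concentrations are in nM internally; dNTP grids are quoted in uM as in
the original designs and converted on use.
"""

from __future__ import annotations

from .kinetic_model import ProcessiveRates, RateConstants

__all__ = [
    "rate_constants",
    "processive_rates",
    "EXCISION_RATES",
    "DNTP_GRIDS_UM",
    "VARIANTS",
]

VARIANTS = ("WT", "S305R", "P1073L")

# k2 (nucleotide association) is diffusion limited: 0.5 nM^-1 s^-1 throughout.
_K2 = 0.5

# Measured constants: K_d,DNA (nM), k_pol (s^-1), K_d,app (uM), k_exo (s^-1).
_TABLE = {
    "WT": {"kd_dna": 9.9, "k_pol": 30.0, "kd_app_uM": 0.7, "k_off": 0.02},
    "S305R": {"kd_dna": 100.0, "k_pol": 12.4, "kd_app_uM": 1.2, "k_off": 1.2},
    "P1073L": {"kd_dna": 10.2, "k_pol": 54.2, "kd_app_uM": 1.5, "k_off": 0.02},
}

#: Mismatch excision rates k_exo (s^-1).
EXCISION_RATES = {"WT": 0.34, "S305R": 0.11, "P1073L": 0.28}

#: dNTP (dATP) titration grids for single-turnover experiments, uM.
DNTP_GRIDS_UM = {
    "S305R": (0.05, 0.2, 0.4, 1.0, 6.0, 17.0),
    "P1073L": (0.2, 0.5, 1.5, 3.0, 5.0, 10.0),
}

#: Processive-incorporation rate ladders (s^-1) with K_d,DNA = 15 nM.
_LADDERS = {
    "P1073L": (65.0, 36.0, 48.0, 28.0, 7.0),
    "WT": (37.0, 75.0, 60.0, 65.0, 70.0, 37.0, 73.0, 58.0, 70.0, 46.0),
}


def rate_constants(variant: str) -> RateConstants:
    """Elementary scheme-1 rate constants implied by the measured values.

    k-1 = k_off; k1 = k_off / K_d,DNA; k-2 = K_d,app * k2; k3 = k_pol.
    """
    t = _TABLE[variant]
    return RateConstants(
        k1=t["k_off"] / t["kd_dna"],
        k_minus1=t["k_off"],
        k2=_K2,
        k_minus2=t["kd_app_uM"] * 1000.0 * _K2,
        k3=t["k_pol"],
    )


def processive_rates(variant: str) -> ProcessiveRates:
    """Published processive-polymerization ladder for a variant."""
    return ProcessiveRates(kpol=_LADDERS[variant], kd_dna=15.0)
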