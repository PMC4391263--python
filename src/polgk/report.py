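"""Human-readable report tables for fit results and recovery studies."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["parameter_table", "recovery_summary", "format_table"]

#: Columns of the standard parameter report, mirroring how polymerase
#: kinetics are tabulated: DNA affinity, chemistry rate, nucleotide
#: affinity, specificity constant, excision rate.
REPORT_COLUMNS = (
    ("kd_dna_nM", "K_d,DNA (nM)"),
    ("k_pol", "k_pol (s^-1)"),
    ("kd_app_uM", "K_d,app (uM)"),
    ("specificity_uM_s", "k_pol/K_d,app (uM^-1 s^-1)"),
    ("k_exo", "k_exo (s^-1)"),
)


def parameter_table(rows: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Build the standard report table from {label: derived-parameter dict}.

    Missing quantities (e.g. k_exo for a fit that had no excision data) are
    left blank.
    """
    table = {}
    for label, derived in rows.items():
        table[label] = {pretty: derived.get(key, np.nan)
                        for key, pretty in REPORT_COLUMNS}
    return pd.DataFrame(table).T


def recovery_summary(truth: Mapping[str, float],
                     estimates: Sequence[Mapping[str, float]],
                     limits: Sequence[Mapping[str, Mapping]] | None = None) -> pd.DataFrame:
    """Per-parameter bias/RMSE across replicate recovery fits.

    ``estimates`` is one parameter dict per replicate; ``limits`` optionally
    holds per-replicate confidence intervals keyed like
    ``{param: {"low", "high"}}``, from which empirical coverage of the truth
    is reported.
    """
    params = sorted(truth)
    rows = []
    for p in params:
        vals = np.array([e[p] for e in estimates if p in e])
        if len(vals) == 0:
            continue
        row = {
            "parameter": p,
            "truth": truth[p],
            "mean": float(vals.mean()),
            "bias": float(vals.mean() - truth[p]),
            "rmse": float(np.sqrt(np.mean((vals - truth[p]) ** 2))),
            "n": int(len(vals)),
        }
        if limits is not None:
            covered = [lim[p]["low"] <= truth[p] <= lim[p]["high"]
                       for lim in limits if p in lim]
            if covered:
                row["coverage"] = float(np.mean(covered))
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def format_table(df: pd.DataFrame, float_fmt: str = "{:.3g}") -> str:
    """Plain-text rendering used by the CLI report command."""
    shown = df.copy()
    for col in shown.columns:
        if shown[col].dtype.kind == "f":
            shown[col] = shown[col].map(
                lambda v: "" if np.isnan(v) else float_fmt.format(v))
    return shown.to_string()
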