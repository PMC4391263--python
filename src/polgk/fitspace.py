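"""Confidence-contour error analysis for globally fitted rate constants.

For a pair of parameters the χ² surface is mapped on a log-spaced grid: at
each node the pair is pinned and *all remaining free parameters are
re-optimized*, so the surface is a two-dimensional profile likelihood.  The
surface is displayed as normalized χ² (χ²_min / χ², in (0, 1]) and the
confidence region is the set of nodes whose χ² exceeds the minimum by no
more than a fixed fraction — 10% by default, i.e. normalized χ² ≥ 1/1.1.
The extreme parameter values on that contour give the lower and upper
confidence limits.

The same construction in one dimension (:func:`profile_1d`) yields a
per-parameter profile, which is cheaper when only limits are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol

import numpy as np

from .errors import FitError, InvalidParameterError
from .global_fit import FitResult, KineticObjective

__all__ = [
    "ContourGrid",
    "ProfileCurve",
    "ProfileObjective",
    "profile_pair",
    "profile_1d",
    "confidence_limits",
]

#: Grid-expansion factor applied per side when the threshold is not crossed.
_EXPAND = 2.0
_MAX_EXPANSIONS = 6


class ProfileObjective(Protocol):
    """What contour analysis needs from a fitted model."""

    free_names: tuple[str, ...]
    best_values: dict[str, float]
    chi2_min: float

    def refit(self, pinned: Mapping[str, float],
              start: Mapping[str, float] | None = None) -> tuple[float, dict[str, float]]:
        """Re-optimize all non-pinned free parameters; return (χ², values)."""
        ...


class _KineticAdapter:
    """Adapts a FitResult + KineticObjective to the profile protocol."""

    def __init__(self, fit: FitResult, objective: KineticObjective,
                 bounds: Mapping[str, tuple[float, float]] | None = None,
                 max_nfev: int | None = 40):
        self.free_names = tuple(objective.free)
        self.best_values = dict(fit.params)
        self.chi2_min = fit.chi2
        self._obj = objective
        self._bounds = dict(bounds or {})
        self._max_nfev = max_nfev

    def refit(self, pinned, start=None):
        remaining = [n for n in self.free_names if n not in pinned]
        fixed = {**self._obj.fixed, **{k: float(v) for k, v in pinned.items()}}
        if not remaining:
            obj = KineticObjective(self._obj.sets, (), fixed,)
            chi2 = obj.chi2(fixed)
            return chi2, {}
        obj = KineticObjective(self._obj.sets, remaining, fixed)
        guesses = {n: (start or self.best_values)[n] for n in remaining}
        mres = obj.minimize(guesses, self._bounds, max_nfev=self._max_nfev)
        params, _ = KineticObjective.linear_params(mres)
        return float(mres.chisqr), params


def _adapt(fit_or_obj, data=None, bounds=None, max_nfev=40) -> ProfileObjective:
    if isinstance(fit_or_obj, FitResult):
        obj = getattr(fit_or_obj, "_objective", None)
        if obj is None:
            if data is None:
                raise InvalidParameterError(
                    "FitResult carries no objective; pass the data it was fit to")
            obj = KineticObjective(data, tuple(fit_or_obj.params), fit_or_obj.fixed)
        return _KineticAdapter(fit_or_obj, obj, bounds, max_nfev)
    return fit_or_obj


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ContourGrid:
    """Normalized χ² surface over one parameter pair plus confidence limits.

    ``norm_chi2[i, j]`` is χ²_min / χ² at (p_values[i], q_values[j]);
    ``limits`` maps each parameter of the pair to its (low, high) confidence
    limits at ``threshold`` (fractional χ² increase); ``open_bounds`` flags
    sides where the surface never crossed the threshold (flat direction).
    """

    p_name: str
    q_name: str
    p_values: np.ndarray
    q_values: np.ndarray
    norm_chi2: np.ndarray
    chi2_min: float
    threshold: float
    best: dict[str, float]
    limits: dict[str, tuple[float, float]] = field(default_factory=dict)
    open_bounds: dict[str, tuple[bool, bool]] = field(default_factory=dict)
    node_ok: np.ndarray | None = None

    @property
    def level(self) -> float:
        """Normalized-χ² value of the threshold contour, 1/(1+threshold)."""
        return 1.0 / (1.0 + self.threshold)

    def profile(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """1-D profile of one parameter: max of norm χ² over the partner."""
        if name == self.p_name:
            return self.p_values, self.norm_chi2.max(axis=1)
        if name == self.q_name:
            return self.q_values, self.norm_chi2.max(axis=0)
        raise InvalidParameterError(f"{name!r} is not a parameter of this grid")

    def to_dict(self) -> dict:
        return {
            "pair": [self.p_name, self.q_name],
            "p_values": self.p_values.tolist(),
            "q_values": self.q_values.tolist(),
            "norm_chi2": self.norm_chi2.tolist(),
            "chi2_min": self.chi2_min,
            "threshold": self.threshold,
            "best": self.best,
            "limits": {k: list(v) for k, v in self.limits.items()},
            "open_bounds": {k: list(v) for k, v in self.open_bounds.items()},
        }

    def plot(self, path=None, ax=None):
        """Render the normalized-χ² surface as a heat map."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        mesh = ax.pcolormesh(self.q_values, self.p_values, self.norm_chi2,
                             shading="nearest", cmap="RdYlGn_r", vmin=0, vmax=1)
        ax.contour(self.q_values, self.p_values, self.norm_chi2,
                   levels=[self.level], colors="k", linewidths=1)
        ax.set_xscale("log"); ax.set_yscale("log")
        ax.set_xlabel(self.q_name); ax.set_ylabel(self.p_name)
        plt.colorbar(mesh, ax=ax, label="normalized chi2")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


@dataclass
class ProfileCurve:
    """1-D profile: normalized χ² versus one parameter, nuisances re-fit."""

    name: str
    values: np.ndarray
    norm_chi2: np.ndarray
    chi2_min: float
    threshold: float
    best: float
    limits: tuple[float, float] | None = None
    open_bounds: tuple[bool, bool] = (False, False)

    @property
    def level(self) -> float:
        return 1.0 / (1.0 + self.threshold)


# ---------------------------------------------------------------------------
# profiling
# ---------------------------------------------------------------------------

def _log_axis(center: float, factor: float, n: int) -> np.ndarray:
    return np.geomspace(center / factor, center * factor, n)


def _extend(axis: np.ndarray, side: str, n_extra: int) -> np.ndarray:
    """Continue the log spacing of an axis beyond one edge."""
    ratio = axis[1] / axis[0]
    if side == "low":
        extra = axis[0] / ratio ** np.arange(1, n_extra + 1)
        return np.concatenate([extra[::-1], axis])
    extra = axis[-1] * ratio ** np.arange(1, n_extra + 1)
    return np.concatenate([axis, extra])


def _crossings(values: np.ndarray, prof: np.ndarray, level: float,
               best: float) -> tuple[tuple[float, float], tuple[bool, bool]]:
    """Threshold crossings of a profile, log-interpolated; flags open sides."""
    above = prof >= level
    if not above.any():
        raise FitError("profile never reaches the confidence region "
                       "(grid does not contain the best fit)")
    lo_open = bool(above[0])
    hi_open = bool(above[-1])
    logv = np.log(values)
    lo = values[0] if lo_open else None
    hi = values[-1] if hi_open else None
    idx = np.where(above)[0]
    i0, i1 = idx[0], idx[-1]
    if not lo_open:
        # interpolate between the last below-level node and the first above
        x0, x1 = logv[i0 - 1], logv[i0]
        y0, y1 = prof[i0 - 1], prof[i0]
        lo = float(np.exp(x0 + (level - y0) / (y1 - y0) * (x1 - x0)))
    if not hi_open:
        x0, x1 = logv[i1], logv[i1 + 1]
        y0, y1 = prof[i1], prof[i1 + 1]
        hi = float(np.exp(x0 + (level - y0) / (y1 - y0) * (x1 - x0)))
    lo = min(lo, best)
    hi = max(hi, best)
    return (float(lo), float(hi)), (lo_open, hi_open)


def profile_pair(fit, p: str, q: str, data=None, n_grid: int = 21,
                 span: float = 3.0, threshold: float = 0.10,
                 bounds=None, max_nfev: int | None = 40) -> ContourGrid:
    """Map normalized χ² over a parameter pair with nuisance re-optimization.

    Parameters
    ----------
    fit : FitResult or ProfileObjective
        A converged global fit (or any object implementing the profile
        protocol, e.g. an analytic toy objective in tests).
    p, q : str
        Names of the two parameters to pin; both must have been free.
    n_grid : int
        Nodes per axis of the initial grid (log-spaced, centered on the
        best-fit values, spanning ``span``-fold each side).
    threshold : float
        Fractional χ² increase defining the confidence contour (0.10 = the
        10%-increase criterion).

    The grid auto-expands (doubling the reach of a side) until the profile
    of each parameter falls below the threshold on both sides, or the side
    is flagged open after repeated expansion.  Nodes whose nuisance
    re-optimization fails are flagged in ``node_ok``, never interpolated.
    """
    obj = _adapt(fit, data, bounds, max_nfev)
    for name in (p, q):
        if name not in obj.free_names:
            raise InvalidParameterError(f"{name!r} was not free in the fit")
    p0, q0 = obj.best_values[p], obj.best_values[q]
    p_ax = _log_axis(p0, span, n_grid)
    q_ax = _log_axis(q0, span, n_grid)

    cache: dict[tuple[float, float], tuple[float, dict]] = {}

    def node(pv: float, qv: float, warm: dict | None) -> tuple[float, dict]:
        key = (pv, qv)
        if key not in cache:
            try:
                cache[key] = obj.refit({p: pv, q: qv}, start=warm)
            except Exception:
                cache[key] = (np.nan, warm or dict(obj.best_values))
        return cache[key]

    def evaluate(p_ax: np.ndarray, q_ax: np.ndarray) -> np.ndarray:
        chi2 = np.empty((len(p_ax), len(q_ax)))
        # sweep columns outward from the best-fit column, warm-starting each
        # node from its nearest solved neighbor
        j_order = np.argsort(np.abs(np.log(q_ax / q0)))
        for j in j_order:
            col_warm: dict | None = None
            i_order = np.argsort(np.abs(np.log(p_ax / p0)))
            for i in i_order:
                c2, vals = node(p_ax[i], q_ax[j], col_warm)
                chi2[i, j] = c2
                if np.isfinite(c2):
                    col_warm = vals
        return chi2

    level = 1.0 / (1.0 + threshold)
    for _ in range(_MAX_EXPANSIONS):
        chi2 = evaluate(p_ax, q_ax)
        finite = np.isfinite(chi2)
        cmin = min(float(np.nanmin(chi2[finite])) if finite.any() else np.inf,
                   obj.chi2_min)
        norm = np.where(finite, cmin / np.where(chi2 > 0, chi2, np.inf), np.nan)
        if cmin == 0:  # perfect fit: normalized surface is 1 only at the optimum
            norm = np.where(finite & (chi2 == 0), 1.0, 0.0)
        grew = False
        for name, ax, axis_prof in ((p, p_ax, np.nanmax(norm, axis=1)),
                                    (q, q_ax, np.nanmax(norm, axis=0))):
            if axis_prof[0] >= level:
                if name == p:
                    p_ax = _extend(p_ax, "low", max(2, n_grid // 4))
                else:
                    q_ax = _extend(q_ax, "low", max(2, n_grid // 4))
                grew = True
            if axis_prof[-1] >= level:
                if name == p:
                    p_ax = _extend(p_ax, "high", max(2, n_grid // 4))
                else:
                    q_ax = _extend(q_ax, "high", max(2, n_grid // 4))
                grew = True
        if not grew:
            break

    grid = ContourGrid(
        p_name=p, q_name=q, p_values=p_ax, q_values=q_ax, norm_chi2=norm,
        chi2_min=cmin, threshold=threshold, best={p: p0, q: q0},
        node_ok=np.isfinite(chi2),
    )
    for name in (p, q):
        vals, prof = grid.profile(name)
        lim, open_b = _crossings(vals, np.nan_to_num(prof), level, grid.best[name])
        grid.limits[name] = lim
        grid.open_bounds[name] = open_b
    return grid


def profile_1d(fit, p: str, data=None, n_grid: int = 13, span: float = 3.0,
               threshold: float = 0.10, bounds=None,
               max_nfev: int | None = 40) -> ProfileCurve:
    """1-D profile of one parameter with all other free parameters re-fit."""
    obj = _adapt(fit, data, bounds, max_nfev)
    if p not in obj.free_names:
        raise InvalidParameterError(f"{p!r} was not free in the fit")
    p0 = obj.best_values[p]
    ax = _log_axis(p0, span, n_grid)
    level = 1.0 / (1.0 + threshold)
    cache: dict[float, float] = {}

    def evaluate(ax):
        chi2 = np.empty(len(ax))
        warm = None
        order = np.argsort(np.abs(np.log(ax / p0)))
        for i in order:
            if ax[i] in cache:
                chi2[i] = cache[ax[i]]
                continue
            try:
                c2, vals = obj.refit({p: ax[i]}, start=warm)
                warm = vals
            except Exception:
                c2 = np.nan
            cache[ax[i]] = c2
            chi2[i] = c2
        return chi2

    for _ in range(_MAX_EXPANSIONS):
        chi2 = evaluate(ax)
        cmin = min(float(np.nanmin(chi2)), obj.chi2_min)
        if cmin == 0:
            norm = np.where(chi2 == 0, 1.0, 0.0)
        else:
            norm = cmin / chi2
        grew = False
        if norm[0] >= level:
            ax = _extend(ax, "low", max(2, n_grid // 4)); grew = True
        if norm[-1] >= level:
            ax = _extend(ax, "high", max(2, n_grid // 4)); grew = True
        if not grew:
            break

    curve = ProfileCurve(name=p, values=ax, norm_chi2=np.nan_to_num(norm),
                         chi2_min=cmin, threshold=threshold, best=p0)
    lim, open_b = _crossings(curve.values, curve.norm_chi2, level, p0)
    curve.limits = lim
    curve.open_bounds = open_b
    return curve


def confidence_limits(grid_or_profile, threshold: float = 0.10) -> dict:
    """Confidence limits at a fractional χ² increase from a grid or profile.

    Returns ``{param: {"low", "high", "open_low", "open_high"}}``.  An open
    flag means the χ² surface never rose above the threshold on that side
    within the (already auto-expanded) grid — the parameter is unbounded in
    that direction at this confidence level.
    """
    level = 1.0 / (1.0 + threshold)
    out: dict[str, dict] = {}
    if isinstance(grid_or_profile, ContourGrid):
        items = [(n, *grid_or_profile.profile(n), grid_or_profile.best[n])
                 for n in (grid_or_profile.p_name, grid_or_profile.q_name)]
    elif isinstance(grid_or_profile, ProfileCurve):
        c = grid_or_profile
        items = [(c.name, c.values, c.norm_chi2, c.best)]
    else:
        raise InvalidParameterError("expected a ContourGrid or ProfileCurve")
    for name, vals, prof, best in items:
        (lo, hi), (olo, ohi) = _crossings(vals, prof, level, best)
        out[name] = {"low": lo, "high": hi, "open_low": olo, "open_high": ohi}
    return out
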