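"""Nonlinear least-squares fitting of stopped-flow traces and confidence contours.

A :class:`FitProblem` couples a mechanism, an absorbance observable and an
averaged trace; :func:`fit_mechanism` minimizes the sum of squared residuals
over a named subset of rate constants and observable parameters, honoring
fixed and ratio-linked constraints.  :func:`fitspace_2d` maps the profile
sum-of-squares surface over a parameter pair, re-optimizing all remaining
free parameters at every grid node, and thresholds the SSE ratio
(SSE_min / SSE_xy, default 0.83, i.e. fits within ~20% of the minimum) to
produce two-dimensional confidence regions and per-parameter intervals.

Rate constants and extinction coefficients are optimized on a log10 scale to
enforce positivity across the many decades they can span; the y-axis offset
``c`` is fitted untransformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from dopadiox.mechanism import (
    KineticTrace,
    Mechanism,
    ObservableModel,
    SimulationError,
    observe,
    simulate,
)

__all__ = [
    "Speciation",
    "speciation_ratio",
    "average_traces",
    "FitProblem",
    "FitResult",
    "FitSpaceGrid",
    "fit_mechanism",
    "fit_least_squares",
    "fitspace_2d",
]


@dataclass(frozen=True)
class Speciation:
    """Charge-state split of a titratable substrate at a given pH."""

    fraction_deprotonated: float
    ratio: float  # raw [base]/[acid] = 10^(pH - pKa)


def speciation_ratio(pka: float, ph: float) -> Speciation:
    """Henderson-Hasselbalch speciation: fraction deprotonated and raw ratio."""
    r = 10.0 ** (ph - pka)
    return Speciation(fraction_deprotonated=r / (1.0 + r), ratio=r)


def average_traces(traces: list[KineticTrace]) -> KineticTrace:
    """Pointwise mean of replicate traces recorded under identical conditions.

    Traces must share wavelength, pH and temperature; traces on different
    time grids are linearly interpolated onto the grid of the first.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces to average")
    ref = traces[0]
    for tr in traces[1:]:
        for attr in ("wavelength_nm", "ph", "temperature_c"):
            if not math.isclose(
                getattr(tr.metadata, attr), getattr(ref.metadata, attr), abs_tol=1e-9
            ):
                raise ValueError(f"metadata mismatch on {attr}")
    stack = []
    for tr in traces:
        if tr.times.shape == ref.times.shape and np.allclose(tr.times, ref.times):
            stack.append(tr.absorbance)
        else:
            stack.append(np.interp(ref.times, tr.times, tr.absorbance))
    mean = np.mean(stack, axis=0)
    md = replace(ref.metadata, replicates=sum(t.metadata.replicates for t in traces))
    return KineticTrace(ref.times.copy(), mean, md)


# ---------------------------------------------------------------------------
# Fit problems


_OBSERVABLE_PARAMS = ("a", "c")


@dataclass
class FitProblem:
    """A trace, a mechanism and the subset of parameters allowed to float.

    ``free_parameters`` may name rate constants (``k6``, ``k-10``...) and the
    observable parameters ``a`` and ``c``.  The product extinction
    coefficient ``b`` is always independently determined and held fixed, so
    it may not be freed.  ``fit_window`` restricts the residuals to
    ``t_start <= t <= t_end``; the default start of 0.8 s excludes the early
    low-intensity features of real traces.
    """

    mechanism: Mechanism
    observable: ObservableModel
    data: KineticTrace
    free_parameters: tuple[str, ...]
    fit_window: tuple[float, float] = (0.8, np.inf)

    def __post_init__(self) -> None:
        self.free_parameters = tuple(self.free_parameters)
        if "b" in self.free_parameters:
            raise ValueError(
                "b is independently determined and fixed during fitting"
            )
        for name in self.free_parameters:
            if name not in _OBSERVABLE_PARAMS:
                self.mechanism.get_rate(name)  # raises KeyError if unknown
        t0, t1 = self.fit_window
        mask = (self.data.times >= t0) & (self.data.times <= t1)
        if mask.sum() < max(2, len(self.free_parameters) + 1):
            raise ValueError("fit window contains too few data points")
        self._mask = mask
        self._times = self.data.times[mask]
        self._target = self.data.absorbance[mask]

    # parameter transforms: everything positive goes on log10 scale
    def transform(self, name: str) -> str:
        return "linear" if name == "c" else "log"

    def current_values(self) -> dict[str, float]:
        out = {}
        for name in self.free_parameters:
            if name == "a":
                out[name] = self.observable.a
            elif name == "c":
                out[name] = self.observable.c
            else:
                out[name] = self.mechanism.get_rate(name)
        return out

    def residuals(self, values: dict[str, float]) -> np.ndarray:
        mech = self.mechanism.copy()
        rates = {k: v for k, v in values.items() if k not in _OBSERVABLE_PARAMS}
        if rates:
            mech.set_rates(rates)
        obs = replace(
            self.observable,
            a=values.get("a", self.observable.a),
            c=values.get("c", self.observable.c),
        )
        try:
            traj = simulate(mech, self._times)
        except SimulationError:
            # step rejection: a huge but finite residual sends the optimizer back
            return np.full(self._times.shape, 1e3)
        model = observe(traj, obs, self.data.metadata).absorbance
        return model - self._target

    def sse(self, values: dict[str, float]) -> float:
        r = self.residuals(values)
        return float(r @ r)


@dataclass
class FitResult:
    parameter_values: dict[str, float]
    sse: float
    n_points: int
    converged: bool
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")


_DEFAULT_BOUNDS = {"log": (1e-12, 1e9), "linear": (-10.0, 10.0)}


def _encode(problem, names, values):
    x = []
    for n in names:
        v = values[n]
        x.append(math.log10(max(v, 1e-300)) if problem.transform(n) == "log" else v)
    return np.array(x)


def _decode(problem, names, x):
    return {
        n: (10.0 ** xi if problem.transform(n) == "log" else xi)
        for n, xi in zip(names, x)
    }


def fit_least_squares(
    problem,
    initial_guess: dict[str, float],
    bounds: dict[str, tuple[float, float]] | None = None,
    free: tuple[str, ...] | None = None,
    fixed: dict[str, float] | None = None,
    max_nfev: int | None = None,
) -> FitResult:
    """Trust-region least squares over any object exposing ``residuals``.

    ``free`` defaults to ``problem.free_parameters``; ``fixed`` pins a subset
    of them (used by the profile-contour scan).  Positivity of log-scale
    parameters is enforced by the transform rather than by hard walls.
    """
    names = tuple(free if free is not None else problem.free_parameters)
    fixed = dict(fixed or {})
    names = tuple(n for n in names if n not in fixed)
    if not names:
        raise ValueError("no free parameters left to fit")
    bounds = dict(bounds or {})

    lo, hi = [], []
    for n in names:
        b = bounds.get(n, _DEFAULT_BOUNDS[problem.transform(n)])
        if problem.transform(n) == "log":
            lo.append(math.log10(b[0]))
            hi.append(math.log10(b[1]))
        else:
            lo.append(b[0])
            hi.append(b[1])
    x0 = _encode(problem, names, initial_guess)
    x0 = np.clip(x0, lo, hi)

    def fun(x):
        values = _decode(problem, names, x)
        values.update(fixed)
        return problem.residuals(values)

    res = least_squares(fun, x0, bounds=(lo, hi), method="trf", max_nfev=max_nfev)
    values = _decode(problem, names, res.x)
    values.update(fixed)
    return FitResult(
        parameter_values=values,
        sse=float(2.0 * res.cost),
        n_points=len(res.fun),
        converged=bool(res.status > 0),
        n_evaluations=int(res.nfev),
    )


def fit_mechanism(
    problem: FitProblem,
    initial_guess: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    max_nfev: int | None = None,
) -> FitResult:
    """Fit the free parameters of a mechanism/observable to the trace."""
    guess = problem.current_values()
    if initial_guess:
        guess.update(initial_guess)
    return fit_least_squares(problem, guess, bounds=bounds, max_nfev=max_nfev)


# ---------------------------------------------------------------------------
# FitSpace-style confidence contours


@dataclass
class FitSpaceGrid:
    """Profile SSE-ratio surface over a parameter pair.

    ``sse_ratio[i, j]`` is SSE_min / SSE(x_i, y_j) with all remaining free
    parameters re-optimized at the node; the confidence region is the set of
    nodes with ratio >= ``threshold`` and the reported per-parameter
    intervals are its axis projections.
    """

    parameter_pair: tuple[str, str]
    grid_values: tuple[np.ndarray, np.ndarray]
    sse: np.ndarray
    sse_ratio: np.ndarray
    threshold: float
    sse_min: float
    interval_per_parameter: dict[str, tuple[float, float]]
    node_converged: np.ndarray
    region_empty: bool = False


def _default_axis(problem, name: str, center: float, n: int, span: float) -> np.ndarray:
    if problem.transform(name) == "log":
        return np.geomspace(center / span, center * span, n)
    half = span if center == 0 else abs(center) * (span - 1)
    return np.linspace(center - half, center + half, n)


def fitspace_2d(
    problem,
    best: FitResult,
    pair: tuple[str, str],
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    threshold: float = 0.83,
    n_nodes: int = 21,
    span: float = 5.0,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitSpaceGrid:
    """Scan a parameter pair, re-optimizing all other free parameters.

    The default grid is ``n_nodes`` x ``n_nodes`` with logarithmic axes
    spanning a factor of ``span`` on either side of the best fit (linear
    axes for untransformed parameters), with the best-fit value as the
    exact center node.  Inner refits are warm-started from the neighboring
    node's solution for continuity of the profile surface.
    """
    p1, p2 = pair
    if not best.converged:
        raise ValueError("best fit must be converged before profiling")
    for p in pair:
        if p not in problem.free_parameters:
            raise KeyError(f"{p!r} is not a free parameter of this problem")
    others = tuple(n for n in problem.free_parameters if n not in pair)

    if grid is None:
        if n_nodes % 2 == 0:
            n_nodes += 1  # keep the best fit as an exact center node
        ax1 = _default_axis(problem, p1, best.parameter_values[p1], n_nodes, span)
        ax2 = _default_axis(problem, p2, best.parameter_values[p2], n_nodes, span)
        ax1[n_nodes // 2] = best.parameter_values[p1]
        ax2[n_nodes // 2] = best.parameter_values[p2]
    else:
        ax1, ax2 = (np.asarray(g, float) for g in grid)

    sse = np.empty((len(ax1), len(ax2)))
    ok = np.ones(sse.shape, bool)
    warm_row = {n: best.parameter_values[n] for n in others}
    for i, v1 in enumerate(ax1):
        cols = range(len(ax2)) if i % 2 == 0 else range(len(ax2) - 1, -1, -1)
        warm = dict(warm_row)
        first_in_row = True
        for j in cols:
            fixed = {p1: float(v1), p2: float(ax2[j])}
            if others:
                res = fit_least_squares(
                    problem, warm, bounds=bounds, free=others, fixed=fixed
                )
                sse[i, j] = res.sse
                ok[i, j] = res.converged
                warm = {n: res.parameter_values[n] for n in others}
                if first_in_row:
                    warm_row = dict(warm)
                    first_in_row = False
            else:
                full = dict(fixed)
                sse[i, j] = problem.sse(full)

    sse_min = min(float(best.sse), float(np.min(sse)))
    if sse_min <= 0:
        # perfect fit: ratio defined as 1 at zero-SSE nodes, 0 elsewhere
        ratio = np.where(sse <= 0, 1.0, np.where(sse > 0, 0.0, 1.0))
    else:
        ratio = sse_min / np.maximum(sse, sse_min)

    inside = ratio >= threshold - 1e-12
    intervals: dict[str, tuple[float, float]] = {}
    empty = not inside.any()
    if not empty:
        rows = inside.any(axis=1)
        cols = inside.any(axis=0)
        intervals[p1] = (float(ax1[rows].min()), float(ax1[rows].max()))
        intervals[p2] = (float(ax2[cols].min()), float(ax2[cols].max()))
    return FitSpaceGrid(
        parameter_pair=(p1, p2),
        grid_values=(ax1, ax2),
        sse=sse,
        sse_ratio=ratio,
        threshold=threshold,
        sse_min=sse_min,
        interval_per_parameter=intervals,
        node_converged=ok,
        region_empty=empty,
    )
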