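"""Initial-rate extraction and Michaelis-Menten analysis.

Rates are expressed in uM/min and normalized by the enzyme concentration
before fitting (y = rate/E0, 1/min), matching the convention in which the
specificity constant kSP = kcat/KM comes out in uM^-1 min^-1 while kcat is
reported in 1/s.  Two algebraically equivalent parameterizations of the
hyperbola are provided:

* traditional:  y = kcat * x / (KM + x), kSP derived as 60*kcat/KM
* direct kSP:   y = kSP * x / (1 + (kSP/kcat) * x), KM derived as kcat/kSP
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from dopadiox.mechanism import KineticTrace

__all__ = [
    "RateDataset",
    "MMFit",
    "EpsilonFit",
    "initial_rate",
    "fit_mm_traditional",
    "fit_mm_ksp",
    "o2_percent_to_conc",
    "extinction_from_endpoint",
    "O2_SATURATION_UM_22C",
]

#: Dissolved [O2] under 100% O2 at 22 C, uM (linear anchor 21% -> ~270 uM).
O2_SATURATION_UM_22C = 1300.0


@dataclass
class RateDataset:
    """Initial rates (uM/min) versus varied-substrate concentration (uM)."""

    substrate_concentrations: np.ndarray
    rates: np.ndarray
    enzyme_concentration: float
    varied_substrate: str = "catechol"
    temperature_c: float = 22.0

    def __post_init__(self) -> None:
        self.substrate_concentrations = np.asarray(self.substrate_concentrations, float)
        self.rates = np.asarray(self.rates, float)
        if self.substrate_concentrations.shape != self.rates.shape:
            raise ValueError("concentration and rate arrays must match")
        if np.any(self.substrate_concentrations <= 0):
            raise ValueError("substrate concentrations must be > 0")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")
        if self.enzyme_concentration <= 0:
            raise ValueError("enzyme concentration must be > 0")
        if self.varied_substrate not in ("catechol", "O2"):
            raise ValueError("varied_substrate must be 'catechol' or 'O2'")


@dataclass
class MMFit:
    """Michaelis-Menten constants with standard errors.

    ``ksp`` always satisfies ksp = 60*kcat/km (kcat in 1/s, km in uM,
    ksp in uM^-1 min^-1) regardless of which parameterization was fitted.
    """

    kcat: float  # 1/s
    km: float  # uM
    ksp: float  # uM^-1 min^-1
    standard_errors: dict[str, float] = field(default_factory=dict)
    parameterization: str = "traditional"
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if min(self.kcat, self.km, self.ksp) <= 0:
            raise ValueError("fitted constants must be > 0")

    @property
    def ksp_x100(self) -> float:
        """kSP on the x100 display scale used for tabulation."""
        return 100.0 * self.ksp

    def predict(self, s: np.ndarray) -> np.ndarray:
        """Fitted rate/E0 curve (1/min) at substrate concentrations s (uM)."""
        s = np.asarray(s, float)
        return 60.0 * self.kcat * s / (self.km + s)


def initial_rate(
    trace: KineticTrace,
    epsilon: float,
    min_points: int = 8,
    r2_threshold: float = 0.995,
) -> float:
    """Slope of the earliest linear region of a progress curve, in uM/min.

    Absorbance is converted to product concentration through ``epsilon``
    (1/(M cm)) and the trace pathlength; the earliest window of at least
    ``min_points`` whose linear fit reaches R^2 >= ``r2_threshold`` is
    expanded until R^2 drops, and its slope (converted s -> min) returned.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if len(trace.times) < 10:
        raise ValueError("progress curve needs at least 10 points")
    conc = trace.absorbance / (1e-6 * epsilon * trace.metadata.pathlength_cm)
    t = trace.times
    n = len(t)

    def window_fit(i0, i1):
        res = linregress(t[i0:i1], conc[i0:i1])
        if np.ptp(conc[i0:i1]) < 1e-12:  # flat region: perfectly linear
            return 0.0, 1.0
        return res.slope, res.rvalue**2

    best_r2 = -np.inf
    for start in range(0, n - min_points + 1):
        slope, r2 = window_fit(start, start + min_points)
        best_r2 = max(best_r2, r2)
        if r2 < r2_threshold:
            continue
        end = start + min_points
        while end < n:
            s2, r2_new = window_fit(start, end + 1)
            if r2_new < r2_threshold:
                break
            slope, end = s2, end + 1
        return slope * 60.0
    raise ValueError(
        f"no window of >= {min_points} points reached R^2 >= {r2_threshold} "
        f"(best R^2 = {best_r2:.4f})"
    )


def _validate_for_fit(data: RateDataset) -> tuple[np.ndarray, np.ndarray]:
    s = data.substrate_concentrations
    if len(np.unique(s)) < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    y = data.rates / data.enzyme_concentration  # 1/min
    return s, y


def _package(kcat_min, km, perr_kcat_min, perr_km, parameterization, s_max):
    kcat = kcat_min / 60.0
    ksp = kcat_min / km
    rel = np.hypot(
        perr_kcat_min / kcat_min if kcat_min else 0.0, perr_km / km if km else 0.0
    )
    fit = MMFit(
        kcat=kcat,
        km=km,
        ksp=ksp,
        standard_errors={
            "kcat": perr_kcat_min / 60.0,
            "km": perr_km,
            "ksp": ksp * rel,
        },
        parameterization=parameterization,
        extrapolated=bool(s_max < km),
    )
    if fit.extrapolated:
        warnings.warn(
            "maximum substrate concentration is below the fitted KM; "
            "kcat and KM are extrapolated",
            stacklevel=3,
        )
    return fit


def fit_mm_traditional(data: RateDataset) -> MMFit:
    """Fit y = kcat*x/(KM + x) to rate/E0 and derive kSP = 60*kcat/KM."""
    s, y = _validate_for_fit(data)

    def hyperbola(x, vmax, km):
        return vmax * x / (km + x)

    p0 = (y.max() * 1.5, np.median(s))
    popt, pcov = curve_fit(hyperbola, s, y, p0=p0, bounds=(0, np.inf), maxfev=10000)
    perr = np.sqrt(np.diag(pcov))
    return _package(popt[0], popt[1], perr[0], perr[1], "traditional", s.max())


def fit_mm_ksp(data: RateDataset) -> MMFit:
    """Fit y = kSP*x/(1 + (kSP/kcat)*x), extracting kSP and kcat directly.

    This is the algebraic equivalent of the traditional hyperbola, so both
    parameterizations produce identical fitted curves; KM is derived as
    kcat/kSP.
    """
    s, y = _validate_for_fit(data)

    def form(x, ksp, vmax):
        return ksp * x / (1.0 + (ksp / vmax) * x)

    km0 = np.median(s)
    p0 = (y.max() * 1.5 / km0, y.max() * 1.5)
    popt, pcov = curve_fit(form, s, y, p0=p0, bounds=(0, np.inf), maxfev=10000)
    perr = np.sqrt(np.diag(pcov))
    ksp, vmax = popt
    km = vmax / ksp
    # propagate the KM standard error from the fitted pair (uncorrelated bound)
    km_se = km * np.hypot(perr[0] / ksp, perr[1] / vmax)
    fit = _package(vmax, km, perr[1], km_se, "ksp_form", s.max())
    fit.standard_errors["ksp"] = perr[0]
    return fit


def o2_percent_to_conc(
    percent: float,
    temperature_c: float = 22.0,
    saturation_um: float | None = None,
) -> float:
    """Convert an O2 gas percentage to dissolved concentration in uM.

    The linear map percent/100 * 1300 uM applies at the 22 C reference
    temperature; any other temperature requires an explicit user-supplied
    saturation constant.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must be in [0, 100]")
    if saturation_um is None:
        if temperature_c != 22.0:
            raise ValueError(
                "no built-in O2 saturation constant for temperatures other "
                "than 22 C; pass saturation_um explicitly"
            )
        saturation_um = O2_SATURATION_UM_22C
    return percent / 100.0 * saturation_um


@dataclass
class EpsilonFit:
    """Extinction coefficient from an endpoint Beer-Lambert series."""

    epsilon: float  # 1/(M cm)
    standard_error: float
    n_points: int
    monotone: bool = True


def extinction_from_endpoint(
    concentrations: np.ndarray,
    endpoint_absorbances: np.ndarray,
    pathlength_cm: float = 1.0,
    weights: np.ndarray | None = None,
) -> EpsilonFit:
    """Through-origin weighted fit of endpoint absorbance vs concentration.

    The slope of A against 1e-6 * c * pathlength is the product extinction
    coefficient in 1/(M cm), assuming the reactions ran to completion.
    """
    c = np.asarray(concentrations, float)
    a = np.asarray(endpoint_absorbances, float)
    if c.size < 3 and c.size != 1:
        raise ValueError("need >= 3 concentrations (or a single point)")
    x = 1e-6 * c * pathlength_cm
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    slope = float(np.sum(w * x * a) / np.sum(w * x * x))
    if slope <= 0:
        raise ValueError("negative or zero slope: endpoint series is not a Beer-Lambert line")
    monotone = bool(np.all(np.diff(a[np.argsort(c)]) >= 0))
    if not monotone:
        warnings.warn("endpoint absorbances are not monotone in concentration", stacklevel=2)
    if c.size > 1:
        resid = a - slope * x
        dof = max(c.size - 1, 1)
        se = float(np.sqrt(np.sum(w * resid**2) / dof / np.sum(w * x * x)))
    else:
        se = 0.0
    return EpsilonFit(slope, se, int(c.size), monotone)
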