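"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one of the experiments the analysis stages consume:

* single-turnover stopped-flow traces at the canonical conditions
  (5.6 uM substrate, 56 uM enzyme, ~1000 uM dissolved O2, 380 nm, pH 7.35,
  14 C, 0-45 s) with replicate Gaussian noise;
* Michaelis-Menten initial-rate datasets at given kcat/KM;
* two-state microplate titration spectra (210-600 nm in 2-nm steps) built
  from two Gaussian bands whose weights follow the Henderson-Hasselbalch
  fractions at the generating pKa, on top of a nonzero blank;
* endpoint Beer-Lambert concentration series.

All randomness flows through a single integer seed, so identical generator
specs produce bit-identical data, and every generator returns the
ground-truth parameter set alongside the data for recovery assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from dopadiox.mechanism import (
    KineticTrace,
    ObservableModel,
    TraceMetadata,
    build_scheme1,
    observe,
    simulate,
)
from dopadiox.physchem import TitrationDataset
from dopadiox.steady_state import RateDataset

__all__ = [
    "GeneratorSpec",
    "gen_stopped_flow",
    "gen_mm_rates",
    "gen_titration",
    "gen_endpoint_series",
]


@dataclass
class GeneratorSpec:
    """Shared knobs of the generators.

    ``noise_sd`` is an absolute absorbance SD for traces and spectra and a
    relative fraction for rates.
    """

    seed: int = 0
    noise_sd: float = 0.002
    replicate_count: int = 15
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: Default single-turnover conditions for the stopped-flow generator.
STOPPED_FLOW_DEFAULTS = {
    "pka": 7.51,
    "ph": 7.35,
    "e0": 56.0,
    "s0": 5.6,
    "o2_0": 1000.0,
    "competent_state": "B",
}


def _log_grid(t_min: float = 0.002, t_max: float = 45.0, n: int = 500) -> np.ndarray:
    """Logarithmically dense sampling grid, instrument-like (2 ms to 45 s)."""
    return np.geomspace(t_min, t_max, n)


def gen_stopped_flow(
    mechanism_params: dict[str, Any] | None = None,
    observable_params: dict[str, Any] | None = None,
    spec: GeneratorSpec | None = None,
) -> tuple[list[KineticTrace], dict[str, Any]]:
    """Simulate replicate single-turnover traces with Gaussian noise.

    ``mechanism_params`` may override the condition keys
    (pka/ph/e0/s0/o2_0/competent_state) and carry a ``rates`` dict of rate
    constant overrides; ``observable_params`` override the ObservableModel
    fields.  Returns the noisy replicates and the generating ground truth.
    """
    spec = spec or GeneratorSpec()
    mp = dict(STOPPED_FLOW_DEFAULTS)
    mp.update(mechanism_params or {})
    rates = mp.pop("rates", None)
    grid = mp.pop("time_grid", None)
    mech = build_scheme1(rate_spec=rates, **mp)
    obs = ObservableModel(**(observable_params or {}))
    times = _log_grid() if grid is None else np.asarray(grid, float)
    traj = simulate(mech, times)
    metadata = TraceMetadata(
        wavelength_nm=380.0,
        ph=mp["ph"],
        temperature_c=14.0,
        enzyme_um=mp["e0"],
        substrate_um=mp["s0"],
        o2_um=mp["o2_0"],
        pathlength_cm=obs.pathlength_cm,
    )
    clean = observe(traj, obs, metadata)
    rng = spec.rng()
    traces = []
    for _ in range(spec.replicate_count):
        noisy = clean.absorbance + rng.normal(0.0, spec.noise_sd, clean.times.shape)
        traces.append(KineticTrace(clean.times.copy(), noisy, metadata))
    truth = {
        "conditions": dict(mp),
        "rates": {name: mech.get_rate(name) for name in mech.rate_names()},
        "observable": {"a": obs.a, "b": obs.b, "c": obs.c},
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "clean_absorbance": clean.absorbance,
    }
    return traces, truth


def gen_mm_rates(
    kcat: float,
    km: float,
    e0: float = 1.0,
    s_grid: np.ndarray | None = None,
    spec: GeneratorSpec | None = None,
    varied_substrate: str = "catechol",
) -> tuple[RateDataset, dict[str, Any]]:
    """Hyperbolic initial rates with relative Gaussian noise.

    rate(s) = 60 * e0 * kcat * s / (km + s) in uM/min, with kcat in 1/s.
    """
    if min(kcat, km, e0) <= 0:
        raise ValueError("kcat, km and e0 must be > 0")
    spec = spec or GeneratorSpec()
    if s_grid is None:
        s_grid = np.geomspace(0.2 * km, 5.0 * km, 10)
    s_grid = np.asarray(s_grid, float)
    clean = 60.0 * e0 * kcat * s_grid / (km + s_grid)
    rng = spec.rng()
    noisy = clean * (1.0 + rng.normal(0.0, spec.noise_sd, s_grid.shape))
    data = RateDataset(
        substrate_concentrations=s_grid,
        rates=np.clip(noisy, 0.0, None),
        enzyme_concentration=e0,
        varied_substrate=varied_substrate,
    )
    truth = {"kcat": kcat, "km": km, "ksp": 60.0 * kcat / km, "e0": e0,
             "noise_sd": spec.noise_sd, "seed": spec.seed}
    return data, truth


def _gaussian(x: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((x - center) / width) ** 2)


def gen_titration(
    pka: float,
    band_ha: tuple[float, float, float] = (280.0, 25.0, 0.8),
    band_a: tuple[float, float, float] = (350.0, 30.0, 0.9),
    ph_list: np.ndarray | None = None,
    spec: GeneratorSpec | None = None,
    s_t_um: float = 200.0,
) -> tuple[TitrationDataset, dict[str, Any]]:
    """Two-state microplate titration spectra with a nonzero blank.

    Bands are (center nm, width nm, peak height AU at full occupancy); the
    acid band is weighted by the protonated fraction and the base band by
    the deprotonated fraction at each pH.  The blank is a smooth nonzero
    baseline shared across columns, as a buffer row would produce.
    """
    spec = spec or GeneratorSpec()
    for center, _, _ in (band_ha, band_a):
        if not 210.0 <= center <= 600.0:
            raise ValueError("band centers must lie within 210-600 nm")
    wavelengths = np.arange(210.0, 600.0 + 1e-9, 2.0)
    ph = np.linspace(3.0, 12.5, 20) if ph_list is None else np.asarray(ph_list, float)
    frac_a = 1.0 / (1.0 + 10.0 ** (pka - ph))  # deprotonated fraction
    spectrum_ha = _gaussian(wavelengths, *band_ha)
    spectrum_a = _gaussian(wavelengths, *band_a)
    clean = np.outer(spectrum_ha, 1.0 - frac_a) + np.outer(spectrum_a, frac_a)
    # smooth nonzero blank: buffer/plate baseline falling off with wavelength
    blank_col = 0.05 + 0.10 * np.exp(-(wavelengths - 210.0) / 60.0)
    blank = np.tile(blank_col[:, None], (1, len(ph)))
    rng = spec.rng()
    absorbance = clean + blank + rng.normal(0.0, spec.noise_sd, clean.shape)
    blank_read = blank + rng.normal(0.0, spec.noise_sd, blank.shape)
    data = TitrationDataset(
        wavelengths=wavelengths,
        ph_values=ph,
        absorbance=absorbance,
        blank=blank_read,
        compound_concentration_um=s_t_um,
    )
    truth = {"pka": pka, "band_ha": band_ha, "band_a": band_a,
             "noise_sd": spec.noise_sd, "seed": spec.seed}
    return data, truth


def gen_endpoint_series(
    epsilon: float,
    concentrations: np.ndarray | None = None,
    spec: GeneratorSpec | None = None,
    pathlength_cm: float = 1.0,
) -> tuple[tuple[np.ndarray, np.ndarray], dict[str, Any]]:
    """Endpoint Beer-Lambert series A = 1e-6 * epsilon * c * pathlength + noise."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    spec = spec or GeneratorSpec()
    c = (
        np.arange(2.0, 21.0, 2.0)
        if concentrations is None
        else np.asarray(concentrations, float)
    )
    clean = 1e-6 * epsilon * c * pathlength_cm
    rng = spec.rng()
    a = clean + rng.normal(0.0, spec.noise_sd, c.shape)
    truth = {"epsilon": epsilon, "pathlength_cm": pathlength_cm,
             "noise_sd": spec.noise_sd, "seed": spec.seed}
    return (c, a), truth
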