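"""Spectrophotometric pKa determination, Hammett correlation, and summaries.

The titration pipeline mirrors the microplate workflow: blank subtraction,
per-column normalization to zero absorbance at 600 nm, difference spectra
against a low-pH reference column, selection of the wavelengths of maximum
positive and negative difference, and a two-state Henderson-Hasselbalch
regression of absorbance against pH:

    A(pH) = [S_t] * (e_HA + e_A * 10^(pH - pKa)) / (1 + 10^(pH - pKa))

with [S_t] the total compound concentration and e_HA / e_A the effective
extinction coefficients of the acid and base forms (for difference data
these are difference coefficients and may take either sign).

Also here: the Hammett linear free-energy regression of pKa against
substituent sigma constants, cyclic-voltammetry summary arithmetic
(E1/2, peak separation, peak-current ratio), the chromophore-count protein
extinction coefficient at 280 nm, and percent-relative substrate profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "TitrationDataset",
    "TitrationFit",
    "DifferenceSpectra",
    "VoltammetrySummary",
    "SubstrateProfile",
    "HammettFit",
    "preprocess_titration",
    "difference_spectra",
    "fit_pka",
    "titration_pipeline",
    "hammett_regression",
    "cv_summary",
    "protein_epsilon280",
    "relative_profile",
]


@dataclass
class TitrationDataset:
    """Wavelength x pH absorbance matrices from a microplate titration."""

    wavelengths: np.ndarray  # nm
    ph_values: np.ndarray
    absorbance: np.ndarray  # shape (n_wavelengths, n_ph)
    blank: np.ndarray  # same shape
    compound_concentration_um: float = 200.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.ph_values = np.asarray(self.ph_values, float)
        self.absorbance = np.asarray(self.absorbance, float)
        self.blank = np.asarray(self.blank, float)
        shape = (len(self.wavelengths), len(self.ph_values))
        if self.absorbance.shape != shape or self.blank.shape != shape:
            raise ValueError("matrix dimensions inconsistent with axes")
        if len(np.unique(self.ph_values)) != len(self.ph_values):
            raise ValueError("pH values must be distinct")


def preprocess_titration(data: TitrationDataset) -> np.ndarray:
    """Blank-subtract, then shift each pH column so A(600 nm) = 0."""
    corrected = data.absorbance - data.blank
    idx600 = np.nonzero(np.isclose(data.wavelengths, 600.0))[0]
    if idx600.size == 0:
        raise ValueError("600 nm row required for normalization")
    corrected = corrected - corrected[idx600[0], :][None, :]
    return corrected


@dataclass
class DifferenceSpectra:
    """Difference spectra against a low-pH reference column."""

    delta: np.ndarray  # (n_wavelengths, n_ph), reference column is zero
    wavelengths: np.ndarray
    ph_values: np.ndarray
    reference_ph: float
    lambda_positive: float | None
    lambda_negative: float | None
    usable: bool


def difference_spectra(
    corrected: np.ndarray,
    wavelengths: np.ndarray,
    ph_values: np.ndarray,
    reference_ph: float = 3.0,
    min_amplitude: float = 1e-6,
) -> DifferenceSpectra:
    """Subtract the reference-pH spectrum and locate the extreme wavelengths.

    The wavelengths of maximum positive and maximum negative difference are
    read from the highest-pH column; a pH-independent spectrum yields no
    usable wavelength and is flagged.
    """
    wavelengths = np.asarray(wavelengths, float)
    ph_values = np.asarray(ph_values, float)
    ref_idx = np.nonzero(np.isclose(ph_values, reference_ph))[0]
    if ref_idx.size == 0:
        raise ValueError(f"reference pH {reference_ph} not present")
    delta = corrected - corrected[:, ref_idx[0]][:, None]
    top = delta[:, np.argmax(ph_values)]
    if np.max(np.abs(top)) < min_amplitude:
        return DifferenceSpectra(
            delta, wavelengths, ph_values, reference_ph, None, None, False
        )
    return DifferenceSpectra(
        delta,
        wavelengths,
        ph_values,
        reference_ph,
        float(wavelengths[np.argmax(top)]),
        float(wavelengths[np.argmin(top)]),
        True,
    )


@dataclass
class TitrationFit:
    """Two-state spectrophotometric pKa regression result."""

    pka: float
    pka_se: float
    epsilon_HA: float  # effective acid-form coefficient, 1/(M cm)
    epsilon_A: float  # effective base-form coefficient, 1/(M cm)
    chosen_wavelengths: tuple[float | None, float | None] = (None, None)
    reference_ph: float | None = None
    s_t_um: float = 200.0


def fit_pka(
    ph_values: np.ndarray,
    absorbance: np.ndarray,
    s_t_um: float = 200.0,
    p0_pka: float | None = None,
) -> TitrationFit:
    """Fit the two-state titration model to absorbance (or difference) vs pH."""
    ph = np.asarray(ph_values, float)
    a = np.asarray(absorbance, float)
    if ph.size < 6:
        raise ValueError("need >= 6 pH points spanning the transition")
    if np.ptp(a) < 1e-9:
        raise ValueError("no titration transition detected (flat absorbance)")
    scale = 1e-6 * s_t_um

    def model(x, pka, e_ha, e_a):
        r = 10.0 ** (x - pka)
        return scale * (e_ha + e_a * r) / (1.0 + r)

    if p0_pka is None:
        # initial pKa guess: pH at half-crossing of the absorbance range
        half = 0.5 * (a.min() + a.max())
        p0_pka = float(ph[np.argmin(np.abs(a - half))])
    p0 = (p0_pka, a[np.argmin(ph)] / scale, a[np.argmax(ph)] / scale)
    popt, pcov = curve_fit(model, ph, a, p0=p0, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    pka = float(popt[0])
    if not (ph.min() - 1.0 <= pka <= ph.max() + 1.0):
        raise ValueError(f"fitted pKa {pka:.2f} falls outside the scanned pH range")
    return TitrationFit(
        pka=pka,
        pka_se=float(perr[0]),
        epsilon_HA=float(popt[1]),
        epsilon_A=float(popt[2]),
        s_t_um=s_t_um,
    )


def titration_pipeline(
    data: TitrationDataset,
    reference_ph: float = 3.0,
    mode: str = "total",
) -> TitrationFit:
    """Full pKa determination from a raw plate: preprocess, difference, fit.

    ``mode`` selects the pH series handed to the regression: ``"single"``
    uses the difference at the maximum-positive wavelength alone, while
    ``"total"`` uses |delta(lambda+)| + |delta(lambda-)| per pH.
    """
    if mode not in ("single", "total"):
        raise ValueError("mode must be 'single' or 'total'")
    corrected = preprocess_titration(data)
    diff = difference_spectra(
        corrected, data.wavelengths, data.ph_values, reference_ph
    )
    if not diff.usable:
        raise ValueError("pH-independent spectrum: no usable wavelength")
    i_pos = int(np.argmin(np.abs(data.wavelengths - diff.lambda_positive)))
    i_neg = int(np.argmin(np.abs(data.wavelengths - diff.lambda_negative)))
    if mode == "single":
        series = diff.delta[i_pos, :]
    else:
        series = np.abs(diff.delta[i_pos, :]) + np.abs(diff.delta[i_neg, :])
    fit = fit_pka(data.ph_values, series, s_t_um=data.compound_concentration_um)
    fit.chosen_wavelengths = (diff.lambda_positive, diff.lambda_negative)
    fit.reference_ph = reference_ph
    return fit


# ---------------------------------------------------------------------------
# Hammett correlation


@dataclass(frozen=True)
class HammettFit:
    rho: float  # slope of pKa vs sigma
    intercept: float
    r_squared: float


def hammett_regression(
    pka_values: np.ndarray, sigma_values: np.ndarray
) -> HammettFit:
    """Ordinary least-squares line of pKa against substituent sigma constants."""
    y = np.asarray(pka_values, float)
    x = np.asarray(sigma_values, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired (sigma, pKa) points; >= 3 recommended")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in sigma constants")
    if np.ptp(y) == 0:
        warnings.warn("pKa values are constant; R^2 is 0 by definition", stacklevel=2)
        return HammettFit(0.0, float(y[0]), 0.0)
    res = linregress(x, y)
    return HammettFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


# ---------------------------------------------------------------------------
# Cyclic voltammetry arithmetic


@dataclass
class VoltammetrySummary:
    """Midpoint potential and peak separation from CV peak potentials (mV)."""

    ep_a: float
    ep_c: float | None
    e_half: float | None
    delta_ep: float | None
    peak_ratio: float | None
    ph: float | None = None


def cv_summary(
    ep_a: float,
    ep_c: float | None = None,
    i_pa: float | None = None,
    i_pc: float | None = None,
    ph: float | None = None,
) -> VoltammetrySummary:
    """E1/2 = (Epa + Epc)/2 and dEp = Epa - Epc; undefined without a cathodic peak."""
    if not np.isfinite(ep_a):
        raise ValueError("anodic peak potential must be finite")
    if ep_c is None or not np.isfinite(ep_c):
        e_half = delta = None
    else:
        e_half = (ep_a + ep_c) / 2.0
        delta = ep_a - ep_c
    if i_pa is not None and i_pc is not None:
        if i_pa <= 0 or i_pc <= 0:
            raise ValueError("peak currents must be > 0")
        ratio = i_pa / i_pc
    else:
        ratio = None
    return VoltammetrySummary(ep_a, ep_c, e_half, delta, ratio, ph)


# ---------------------------------------------------------------------------
# Protein extinction coefficient (chromophore counting)

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def protein_epsilon280(
    sequence: str, n_cystine: int = 0, skip_unknown: bool = False
) -> float:
    """Predicted epsilon_280 = #Tyr*1280 + #Trp*5690 + #cystine*125 (1/(M cm))."""
    seq = sequence.upper().replace("*", "")
    unknown = set(seq) - _AA20
    if unknown and not skip_unknown:
        raise ValueError(f"unknown residue letters: {sorted(unknown)}")
    n_tyr = seq.count("Y")
    n_trp = seq.count("W")
    n_cys = seq.count("C")
    if n_cystine > n_cys // 2:
        raise ValueError("n_cystine exceeds floor(#Cys / 2)")
    return n_tyr * 1280.0 + n_trp * 5690.0 + n_cystine * 125.0


# ---------------------------------------------------------------------------
# Percent-relative substrate profiles


@dataclass
class SubstrateProfile:
    """Physical and kinetic properties of one catecholic substrate.

    ``csev_a3`` is the computed solvent-excluded active-site/substrate volume
    supplied as a user annotation (volume computation is out of scope here).
    """

    name: str
    csev_a3: float | None = None
    e_half_mv: float | None = None
    pka: float | None = None
    ksp_o2: dict[str, float] = field(default_factory=dict)  # per enzyme


def relative_profile(
    profiles: list[SubstrateProfile], reference_name: str
) -> pd.DataFrame:
    """Express every numeric field as a percentage of the reference compound."""
    by_name = {p.name: p for p in profiles}
    if reference_name not in by_name:
        raise ValueError(f"reference {reference_name!r} not among profiles")
    ref = by_name[reference_name]
    enzymes = sorted({e for p in profiles for e in p.ksp_o2})
    columns = ["csev_a3", "e_half_mv", "pka"] + [f"ksp_o2[{e}]" for e in enzymes]

    def fields(p: SubstrateProfile) -> dict[str, float | None]:
        d = {"csev_a3": p.csev_a3, "e_half_mv": p.e_half_mv, "pka": p.pka}
        for e in enzymes:
            d[f"ksp_o2[{e}]"] = p.ksp_o2.get(e)
        return d

    ref_fields = fields(ref)
    rows = {}
    for p in profiles:
        row = {}
        for col, value in fields(p).items():
            ref_value = ref_fields[col]
            if value is None or ref_value is None:
                row[col] = np.nan
            elif ref_value == 0:
                raise ZeroDivisionError(f"reference value for {col} is zero")
            else:
                row[col] = 100.0 * value / ref_value
        rows[p.name] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
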