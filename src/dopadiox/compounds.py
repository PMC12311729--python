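"""Built-in measured properties of the catecholic substrates.

These tables collect the experimentally determined constants for L-DOPA,
dopamine, 3,4-dihydroxyhydrocinnamic acid (DHHCA, hydrocaffeic acid) and its
6-substituted bromo/cyano/nitro derivatives reacting with the two L-DOPA
2,3-dioxygenase homologues (LmbB1 from S. lincolnensis and ShjDDO from
S. hygroscopicus jingganensis), plus the standard Hansch substituent
constants used for Hammett correlations.  They serve as inputs to the
analysis stages and as ground-truth parameter sets for the synthetic-data
generators.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SIGMA_PARA",
    "SIGMA_META",
    "SUBSTITUENT",
    "PKA_VALUES",
    "CVRow",
    "CV_PEAKS",
    "MMRow",
    "MM_PARAMS",
    "PRODUCT_EXTINCTION",
    "ESQ_EXTINCTION",
    "TRANSIENT_BRANCH_RATES",
]

#: Hansch sigma-para substituent constants (Chem. Rev. 1991, 91, 165).
SIGMA_PARA = {"H": 0.00, "Br": 0.23, "CN": 0.66, "NO2": 0.78}
#: Hansch sigma-meta substituent constants.
SIGMA_META = {"H": 0.00, "Br": 0.39, "CN": 0.56, "NO2": 0.71}

#: Ring substituent at position 6 of each DHHCA scaffold.
SUBSTITUENT = {
    "DHHCA": "H",
    "6-bromoDHHCA": "Br",
    "6-cyanoDHHCA": "CN",
    "6-nitroDHHCA": "NO2",
}

#: First catecholic pKa determined spectrophotometrically (value, SE).
PKA_VALUES = {
    "L-DOPA": (8.81, 0.19),
    "dopamine": (8.99, 0.05),
    "DHHCA": (8.87, 0.12),
    "6-bromoDHHCA": (8.36, 0.07),
    "6-cyanoDHHCA": (7.51, 0.06),
    "6-nitroDHHCA": (6.94, 0.06),
}


@dataclass(frozen=True)
class CVRow:
    """Cyclic-voltammetry peak data on a glassy carbon electrode (mV vs SCE).

    ``e_half`` / ``delta_ep`` / ``peak_ratio`` are the published summary
    values; rows lacking a cathodic peak carry ``None`` where undefined.
    """

    ep_a: float
    ep_c: float | None
    e_half: float | None
    delta_ep: float | None
    peak_ratio: float | None


#: Measured anodic/cathodic peak potentials, keyed (compound, pH).
CV_PEAKS: dict[tuple[str, float], CVRow] = {
    ("L-DOPA", 7.4): CVRow(315, None, None, None, None),
    ("dopamine", 7.4): CVRow(178, 54, 116, 124, 1.32),
    ("DHHCA", 7.4): CVRow(333, -95, 119, 428, 1.30),
    ("6-bromoDHHCA", 7.4): CVRow(195, 59, 127, 136, 1.21),
    ("6-cyanoDHHCA", 7.4): CVRow(272, 147, 209.5, 125, 1.96),
    ("6-nitroDHHCA", 7.4): CVRow(288, None, None, None, None),
    ("L-DOPA", 6.0): CVRow(362, 101, 231.5, 261, 5.90),
    ("dopamine", 6.0): CVRow(354, 84, 219, 270, 2.89),
    # cathodic peak recorded here as +9 mV: the reported midpoint (198.5)
    # and separation (379) are only consistent with a positive value
    ("DHHCA", 6.0): CVRow(388, 9, 198.5, 379, 2.54),
    ("6-bromoDHHCA", 6.0): CVRow(267, 154, 210.5, 113, 1.43),
    ("6-cyanoDHHCA", 6.0): CVRow(358, 260, 309, 98, 3.92),
    ("6-nitroDHHCA", 6.0): CVRow(444, None, None, None, None),
}


@dataclass(frozen=True)
class MMRow:
    """Steady-state constants at 22 C and 100% O2 saturation.

    ``km_um``: Michaelis constant for the catechol (uM); ``kcat_s``:
    turnover number (1/s); ``ksp_x100``: specificity constant on the x100
    display scale (uM^-1 min^-1); ``km_o2_um`` and ``ksp_o2_x100`` are the
    analogous constants with O2 as the varied substrate.
    """

    km_um: float
    kcat_s: float
    ksp_x100: float
    km_o2_um: float
    ksp_o2_x100: float


#: Measured steady-state parameters, keyed (compound, enzyme).
MM_PARAMS: dict[tuple[str, str], MMRow] = {
    ("DHHCA", "LmbB1"): MMRow(922, 2.1, 13.4, 192, 19.2),
    ("DHHCA", "ShjDDO"): MMRow(422, 6.7e-1, 9.5, 1059, 17.7),
    ("6-bromoDHHCA", "LmbB1"): MMRow(205, 1.6e-1, 4.6, 280, 3.5),
    ("6-bromoDHHCA", "ShjDDO"): MMRow(926, 1.5, 9.8, 759, 15.8),
    ("6-cyanoDHHCA", "LmbB1"): MMRow(131, 6.7e-4, 3.1e-2, 563, 1.4e-2),
    ("6-cyanoDHHCA", "ShjDDO"): MMRow(228, 1.1e-3, 2.8e-2, 1019, 4.0e-2),
}

#: Semialdehyde product extinction coefficients: compound -> (lambda_max nm,
#: epsilon M^-1 cm^-1, SE).
PRODUCT_EXTINCTION = {
    "DHHCA": (380, 40740, 820),
    "6-cyanoDHHCA": (385, 33256, 484),
    "6-bromoDHHCA": (380, 35282, 1190),
}

#: Fitted semiquinone extinction coefficient at 380 nm (value, FitSpace range).
ESQ_EXTINCTION = (38950, 9250)

#: Single-turnover branch rates for 6-cyanoDHHCA + ShjDDO: productive decay
#: of the semiquinone (k6) vs nonproductive quenching (k7), both 1/s.
TRANSIENT_BRANCH_RATES = {"k6": 0.55, "k7": 0.30}
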