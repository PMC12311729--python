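"""Mass-action kinetic mechanisms and their numerical integration.

This module represents a reaction mechanism as an ordered list of species and
elementary (uni- or bimolecular) steps, integrates the resulting mass-action
ODE system with a stiff solver and an analytically assembled Jacobian, and
maps species trajectories to a predicted stopped-flow absorbance signal.

Unit contract
-------------
Concentrations are in uM, time in s, first-order rate constants in 1/s,
second-order rate constants in 1/(uM*s).  Extinction coefficients are stored
in 1/(M*cm); :func:`observe` applies the explicit 1e-6 factor that reconciles
molar extinction coefficients with micromolar concentrations.

The canonical single-turnover mechanism of the catechol ring-cleavage
reaction (enzyme E, substrate charge states S_A/S_B, ternary oxygen complex
ESO2, semiquinone ESQ, quenched semiquinone ESQ_X, UV-silent intermediates
EI, enzyme-product complex EP, free product P and its silent form P_X) is
instantiated by :func:`build_scheme1`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FIXED_FAST",
    "FIXED_SLOW",
    "Species",
    "RateStatus",
    "ReactionStep",
    "Mechanism",
    "ObservableModel",
    "Trajectory",
    "KineticTrace",
    "TraceMetadata",
    "build_scheme1",
    "simulate",
    "observe",
    "henderson_hasselbalch_ratio",
]

#: Numerical stand-ins for rate constants declared "fast" or "very slow".
FIXED_FAST = 1.0e9
FIXED_SLOW = 1.0e-12

#: Negative-concentration slack tolerated from the stiff solver (uM).
EPS_CONC = 1.0e-9

_STATUS_KINDS = frozenset({"free", "fixed", "fixed_fast", "fixed_slow", "ratio_linked"})


@dataclass(frozen=True)
class Species:
    """A chemical species with its initial concentration in uM."""

    name: str
    initial_concentration: float = 0.0
    spectroscopically_active: bool = False

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ValueError(
                f"initial concentration of {self.name!r} must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass(frozen=True)
class RateStatus:
    """Fitting status of a single rate constant.

    ``kind`` is one of ``free``, ``fixed``, ``fixed_fast``, ``fixed_slow`` or
    ``ratio_linked``.  A ``ratio_linked`` constant is slaved to another
    constant: after any parameter update it satisfies
    ``value = ratio * value(partner)``, i.e. ``k_self / k_partner = ratio``.
    """

    kind: str = "fixed"
    partner: str | None = None
    ratio: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _STATUS_KINDS:
            raise ValueError(f"unknown status keyword {self.kind!r}")
        if self.kind == "ratio_linked":
            if self.partner is None or self.ratio is None:
                raise ValueError("ratio_linked status requires partner and ratio")
        elif self.partner is not None or self.ratio is not None:
            raise ValueError(f"ratio specified for a non-linked constant ({self.kind})")


@dataclass
class ReactionStep:
    """An elementary mass-action step with at most two reactants/products."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k_forward: float = 0.0
    k_reverse: float = 0.0
    forward_status: RateStatus = field(default_factory=RateStatus)
    reverse_status: RateStatus = field(default_factory=RateStatus)

    def __post_init__(self) -> None:
        self.reactants = tuple(self.reactants)
        self.products = tuple(self.products)
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError("a step needs 1 or 2 reactant molecules")
        if not 1 <= len(self.products) <= 2:
            raise ValueError("a step needs 1 or 2 product molecules")
        if self.k_forward < 0 or self.k_reverse < 0:
            raise ValueError("rate constants must be >= 0")

    @property
    def reversible(self) -> bool:
        return self.k_reverse > 0


class Mechanism:
    """An ordered set of species plus mass-action reaction steps.

    Rate constants are addressed by name: step ``i`` (1-based) has forward
    constant ``k{i}`` and reverse constant ``k-{i}``.
    """

    def __init__(self, species: list[Species], steps: list[ReactionStep], label: str = ""):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        for st in steps:
            for nm in (*st.reactants, *st.products):
                if nm not in names:
                    raise ValueError(f"step references unknown species {nm!r}")
        self.species = list(species)
        self.steps = list(steps)
        self.label = label
        self._index = {s.name: i for i, s in enumerate(self.species)}
        self._resolve_statuses()
        self._apply_ratio_links()

    # -- parameter access -------------------------------------------------

    def _locate(self, name: str) -> tuple[int, str]:
        m = re.fullmatch(r"k(-?)(\d+)", name)
        if not m:
            raise KeyError(f"not a rate-constant name: {name!r}")
        i = int(m.group(2)) - 1
        if not 0 <= i < len(self.steps):
            raise KeyError(f"no step {i + 1} in mechanism")
        return i, ("reverse" if m.group(1) else "forward")

    def get_rate(self, name: str) -> float:
        i, d = self._locate(name)
        return self.steps[i].k_reverse if d == "reverse" else self.steps[i].k_forward

    def get_status(self, name: str) -> RateStatus:
        i, d = self._locate(name)
        return self.steps[i].reverse_status if d == "reverse" else self.steps[i].forward_status

    def set_rates(self, values: dict[str, float]) -> None:
        """Assign rate constants by name, then re-enforce all ratio links."""
        for name, v in values.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
            i, d = self._locate(name)
            if d == "reverse":
                self.steps[i].k_reverse = float(v)
            else:
                self.steps[i].k_forward = float(v)
        self._apply_ratio_links()

    def rate_names(self) -> list[str]:
        names = []
        for i, st in enumerate(self.steps, start=1):
            names.append(f"k{i}")
            if st.reversible or st.reverse_status.kind != "fixed":
                names.append(f"k-{i}")
        return names

    def free_rate_names(self) -> list[str]:
        out = []
        for i, st in enumerate(self.steps, start=1):
            if st.forward_status.kind == "free":
                out.append(f"k{i}")
            if st.reverse_status.kind == "free":
                out.append(f"k-{i}")
        return out

    def _resolve_statuses(self) -> None:
        for st in self.steps:
            if st.forward_status.kind == "fixed_fast":
                st.k_forward = FIXED_FAST
            elif st.forward_status.kind == "fixed_slow":
                st.k_forward = FIXED_SLOW
            if st.reverse_status.kind == "fixed_fast":
                st.k_reverse = FIXED_FAST
            elif st.reverse_status.kind == "fixed_slow":
                st.k_reverse = FIXED_SLOW

    def _apply_ratio_links(self) -> None:
        for i, st in enumerate(self.steps, start=1):
            if st.forward_status.kind == "ratio_linked":
                st.k_forward = st.forward_status.ratio * self.get_rate(st.forward_status.partner)
            if st.reverse_status.kind == "ratio_linked":
                st.k_reverse = st.reverse_status.ratio * self.get_rate(st.reverse_status.partner)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], float)

    def copy(self) -> "Mechanism":
        return Mechanism(
            list(self.species),
            [
                ReactionStep(
                    st.reactants, st.products, st.k_forward, st.k_reverse,
                    st.forward_status, st.reverse_status,
                )
                for st in self.steps
            ],
            self.label,
        )

    def with_initial(self, **conc: float) -> "Mechanism":
        """Return a copy with some initial concentrations replaced."""
        new_species = []
        for s in self.species:
            if s.name in conc:
                new_species.append(replace(s, initial_concentration=float(conc.pop(s.name))))
            else:
                new_species.append(s)
        if conc:
            raise KeyError(f"unknown species: {sorted(conc)}")
        return Mechanism(new_species, self.copy().steps, self.label)

    # -- serialization -----------------------------------------------------

    def to_text(self) -> str:
        """Plain-text reaction-list serialization (lossless round trip)."""
        lines = [f"# mechanism: {self.label}"]
        for s in self.species:
            act = " active" if s.spectroscopically_active else ""
            lines.append(f"species {s.name} {s.initial_concentration!r}{act}")
        for st in self.steps:
            lhs = " + ".join(st.reactants)
            rhs = " + ".join(st.products)
            parts = [
                f"{lhs} -> {rhs}",
                f"kf={st.k_forward!r}",
                f"kr={st.k_reverse!r}",
                f"kf_status={_status_text(st.forward_status)}",
                f"kr_status={_status_text(st.reverse_status)}",
            ]
            lines.append(" ; ".join(parts))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Mechanism":
        label = ""
        species: list[Species] = []
        steps: list[ReactionStep] = []
        for ln, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("# mechanism:"):
                label = line.split(":", 1)[1].strip()
                continue
            if line.startswith("#"):
                continue
            if line.startswith("species "):
                toks = line.split()
                if len(toks) not in (3, 4):
                    raise ValueError(f"line {ln}: malformed species line")
                species.append(
                    Species(toks[1], float(toks[2]), len(toks) == 4 and toks[3] == "active")
                )
                continue
            fields = [p.strip() for p in line.split(";")]
            if "->" not in fields[0]:
                raise ValueError(f"line {ln}: expected a reaction arrow")
            lhs, rhs = (side.strip() for side in fields[0].split("->"))
            kv = dict(p.split("=", 1) for p in fields[1:])
            steps.append(
                ReactionStep(
                    tuple(t.strip() for t in lhs.split("+")),
                    tuple(t.strip() for t in rhs.split("+")),
                    float(kv["kf"]),
                    float(kv["kr"]),
                    _status_parse(kv["kf_status"]),
                    _status_parse(kv["kr_status"]),
                )
            )
        return cls(species, steps, label)


def _status_text(st: RateStatus) -> str:
    if st.kind == "ratio_linked":
        return f"ratio_linked({st.partner},{st.ratio!r})"
    return st.kind


def _status_parse(text: str) -> RateStatus:
    text = text.strip()
    m = re.fullmatch(r"ratio_linked\(([^,]+),([^)]+)\)", text)
    if m:
        return RateStatus("ratio_linked", m.group(1).strip(), float(m.group(2)))
    return RateStatus(text)


# ---------------------------------------------------------------------------
# Observables and traces


@dataclass
class TraceMetadata:
    """Experimental conditions attached to a stopped-flow trace."""

    wavelength_nm: float = 380.0
    ph: float = 7.35
    temperature_c: float = 14.0
    enzyme_um: float = 56.0
    substrate_um: float = 5.6
    o2_um: float = 1000.0
    pathlength_cm: float = 1.0
    replicates: int = 1


@dataclass
class KineticTrace:
    """A time/absorbance series with its experimental metadata."""

    times: np.ndarray
    absorbance: np.ndarray
    metadata: TraceMetadata = field(default_factory=TraceMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.absorbance = np.asarray(self.absorbance, float)
        if self.times.shape != self.absorbance.shape:
            raise ValueError("times and absorbance must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.absorbance))):
            raise ValueError("trace values must be finite")


@dataclass
class Trajectory:
    """Species concentration time courses from a simulation (uM)."""

    times: np.ndarray
    concentrations: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.concentrations[name]


@dataclass
class ObservableModel:
    """Map species trajectories to predicted absorbance at one wavelength.

    In ``literal_mode`` the signal follows a*([ESQ]-[ESQ_X]) + b*([EP]+[P]) - c
    exactly as the fitting convention writes it; with ``literal_mode=False``
    the quenched semiquinone is treated as truly silent and its term dropped.
    ``a`` and ``b`` are in 1/(M*cm) and the 1e-6 factor converts uM
    concentrations to molar.
    """

    a: float = 38950.0
    b: float = 33256.0
    c: float = 0.0
    pathlength_cm: float = 1.0
    literal_mode: bool = True

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("extinction coefficients must be >= 0")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be > 0")


def observe(
    trajectory: Trajectory,
    observable: ObservableModel,
    metadata: TraceMetadata | None = None,
) -> KineticTrace:
    """Apply the absorbance observable to a simulated trajectory."""
    conc = trajectory.concentrations
    for needed in ("ESQ", "EP", "P") + (("ESQ_X",) if observable.literal_mode else ()):
        if needed not in conc:
            raise KeyError(f"trajectory lacks species {needed!r}")
    esq = conc["ESQ"] - conc["ESQ_X"] if observable.literal_mode else conc["ESQ"]
    signal = observable.a * esq + observable.b * (conc["EP"] + conc["P"])
    absorbance = 1e-6 * observable.pathlength_cm * signal - observable.c
    md = metadata if metadata is not None else TraceMetadata(
        pathlength_cm=observable.pathlength_cm
    )
    return KineticTrace(trajectory.times, absorbance, md)


# ---------------------------------------------------------------------------
# Simulation


class SimulationError(RuntimeError):
    pass


def _compiled(mechanism: Mechanism):
    """Index arrays for vectorized rate/Jacobian evaluation."""
    idx = mechanism._index
    n_sp = len(mechanism.species)
    n_st = len(mechanism.steps)
    # pad reactant/product index lists to length 2 with -1 sentinel
    r_idx = np.full((n_st, 2), -1, int)
    p_idx = np.full((n_st, 2), -1, int)
    kf = np.empty(n_st)
    kr = np.empty(n_st)
    net = np.zeros((n_sp, n_st))
    for j, st in enumerate(mechanism.steps):
        for a, nm in enumerate(st.reactants):
            r_idx[j, a] = idx[nm]
            net[idx[nm], j] -= 1
        for a, nm in enumerate(st.products):
            p_idx[j, a] = idx[nm]
            net[idx[nm], j] += 1
        kf[j] = st.k_forward
        kr[j] = st.k_reverse
    return r_idx, p_idx, kf, kr, net


def simulate(
    mechanism: Mechanism,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the mass-action ODE system over a strictly increasing grid.

    The Jacobian is assembled analytically from the mass-action structure,
    which is what keeps the integration stable when some constants are fixed
    "fast" (1e9) and the system becomes extremely stiff.
    """
    times = np.asarray(times, float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    if times[0] < 0:
        raise ValueError("times must start at or after 0")
    r_idx, p_idx, kf, kr, net = _compiled(mechanism)
    y0 = mechanism.initial_state()

    def _prod(y, pair):
        out = np.ones(pair.shape[0])
        for col in range(2):
            sel = pair[:, col] >= 0
            out[sel] *= y[pair[sel, col]]
        return out

    def rhs(_t, y):
        rates = kf * _prod(y, r_idx) - kr * _prod(y, p_idx)
        return net @ rates

    n_st = len(mechanism.steps)
    n_sp = len(mechanism.species)

    def jac(_t, y):
        # d(rate_j)/d(y_i): product rule over the (<=2) molecules on each side
        drdy = np.zeros((n_st, n_sp))
        for j in range(n_st):
            for side, pair, k in ((1, r_idx[j], kf[j]), (-1, p_idx[j], kr[j])):
                if k == 0.0:
                    continue
                mols = pair[pair >= 0]
                if len(mols) == 1:
                    drdy[j, mols[0]] += side * k
                else:
                    drdy[j, mols[0]] += side * k * y[mols[1]]
                    drdy[j, mols[1]] += side * k * y[mols[0]]
        return net @ drdy

    if times[0] > 0.0:
        t_eval = np.concatenate(([0.0], times))
        drop_first = True
    else:
        t_eval = times
        drop_first = False
    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), y0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol, jac=jac,
    )
    if not sol.success:
        raise SimulationError(f"stiff solver failed: {sol.message}")
    y = sol.y[:, 1:] if drop_first else sol.y
    if np.any(y < -EPS_CONC * max(1.0, y0.max())):
        # clip tiny negative excursions, refuse big ones
        worst = float(y.min())
        if worst < -1e-6 * max(1.0, y0.max()):
            raise SimulationError(f"solver produced negative concentration {worst}")
    y = np.clip(y, 0.0, None)
    conc = {s.name: y[i] for i, s in enumerate(mechanism.species)}
    return Trajectory(times.copy(), conc)


# ---------------------------------------------------------------------------
# The canonical single-turnover mechanism


def henderson_hasselbalch_ratio(pka: float, ph: float) -> float:
    """Equilibrium ratio [base]/[acid] = 10^(pH - pKa)."""
    return 10.0 ** (ph - pka)


SCHEME1_SPECIES = (
    "E", "S_A", "S_B", "ES", "O2", "ESO2", "ESQ", "ESQ_X", "EI", "EP", "P", "P_X",
)

#: Enzyme-containing species (the quenched complex retains the enzyme).
ENZYME_TAGGED = ("E", "ES", "ESO2", "ESQ", "ESQ_X", "EI", "EP")
#: Substrate-derived species.
SUBSTRATE_TAGGED = ("S_A", "S_B", "ES", "ESO2", "ESQ", "ESQ_X", "EI", "EP", "P", "P_X")


def build_scheme1(
    pka: float,
    ph: float,
    rate_spec: dict[str, tuple[float, RateStatus] | float] | None = None,
    e0: float = 56.0,
    s0: float = 5.6,
    o2_0: float = 1000.0,
    competent_state: str = "B",
    protonated_initial: bool = False,
) -> Mechanism:
    """Instantiate the canonical 10-step single-turnover mechanism.

    Steps (1-based, fixed convention):

    1.  S_A <-> S_B       k1 ratio-linked to k-1 so that k1/k-1 = 10^(pH-pKa)
    2.  E + S_A <-> ES    binding of the protonated state
    3.  E + S_B <-> ES    binding of the monoanion
    4.  ES + O2 -> ESO2   oxygen binding, fast and irreversible by default
    5.  ESO2 -> ESQ       semiquinone formation
    6.  ESQ -> EI         productive decay toward cleavage (k6)
    7.  ESQ -> ESQ_X      nonproductive quenching / inactivation (k7)
    8.  EI -> EP          lumped UV-silent chemistry through to product
    9.  EP -> E + P       product release
    10. P <-> P_X         product equilibrium with its silent form

    S_A is the more protonated charge state, S_B its conjugate base;
    ``competent_state`` selects which binding pathway (2 or 3) is active,
    the other being fixed very slow ("A", "B", or "both").  The substrate
    pool is started at the Henderson-Hasselbalch equilibrium split unless
    ``protonated_initial`` puts all of it in S_A.
    """
    if not (0 < pka < 14 and 0 < ph < 14):
        raise ValueError("pKa and pH must lie in (0, 14)")
    if min(e0, s0, o2_0) < 0:
        raise ValueError("initial concentrations must be >= 0")
    if competent_state not in ("A", "B", "both"):
        raise ValueError("competent_state must be 'A', 'B' or 'both'")

    ratio = henderson_hasselbalch_ratio(pka, ph)
    if protonated_initial:
        sa0, sb0 = s0, 0.0
    else:
        sa0, sb0 = s0 / (1.0 + ratio), s0 * ratio / (1.0 + ratio)

    species = [
        Species("E", e0),
        Species("S_A", sa0),
        Species("S_B", sb0),
        Species("ES", 0.0),
        Species("O2", o2_0),
        Species("ESO2", 0.0),
        Species("ESQ", 0.0, spectroscopically_active=True),
        Species("ESQ_X", 0.0),
        Species("EI", 0.0),
        Species("EP", 0.0, spectroscopically_active=True),
        Species("P", 0.0, spectroscopically_active=True),
        Species("P_X", 0.0),
    ]

    free = RateStatus("free")
    fixed = RateStatus("fixed")
    slow = RateStatus("fixed_slow")

    binding_a = fixed if competent_state in ("A", "both") else slow
    binding_b = fixed if competent_state in ("B", "both") else slow

    # Default rate set; any entry can be overridden through rate_spec.
    defaults: dict[str, tuple[float, RateStatus]] = {
        "k1": (0.0, RateStatus("ratio_linked", partner="k-1", ratio=ratio)),
        "k-1": (1000.0, fixed),
        "k2": (1.0, binding_a),
        "k-2": (0.5, binding_a if binding_a is not slow else slow),
        "k3": (1.0, binding_b),
        "k-3": (0.5, binding_b if binding_b is not slow else slow),
        "k4": (0.0, RateStatus("fixed_fast")),
        "k5": (0.5, free),
        "k6": (0.55, free),
        "k7": (0.30, free),
        "k8": (0.15, free),
        "k9": (1.0, free),
        "k10": (0.01, free),
        "k-10": (0.02, free),
    }
    if rate_spec:
        for name, entry in rate_spec.items():
            if name not in defaults:
                raise KeyError(f"unknown rate constant {name!r}")
            if isinstance(entry, tuple):
                defaults[name] = (float(entry[0]), entry[1])
            else:
                defaults[name] = (float(entry), defaults[name][1])

    def pair(i: int) -> tuple[float, float, RateStatus, RateStatus]:
        vf, sf = defaults[f"k{i}"]
        vr, sr = defaults.get(f"k-{i}", (0.0, fixed))
        return vf, vr, sf, sr

    steps = []
    topo = [
        (("S_A",), ("S_B",)),
        (("E", "S_A"), ("ES",)),
        (("E", "S_B"), ("ES",)),
        (("ES", "O2"), ("ESO2",)),
        (("ESO2",), ("ESQ",)),
        (("ESQ",), ("EI",)),
        (("ESQ",), ("ESQ_X",)),
        (("EI",), ("EP",)),
        (("EP",), ("E", "P")),
        (("P",), ("P_X",)),
    ]
    for i, (lhs, rhs) in enumerate(topo, start=1):
        vf, vr, sf, sr = pair(i)
        steps.append(ReactionStep(lhs, rhs, vf, vr, sf, sr))

    return Mechanism(species, steps, label="scheme1-single-turnover")


def conservation_totals(trajectory: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Enzyme-tag and substrate-tag totals over time for the canonical scheme."""
    enz = sum(trajectory[name] for name in ENZYME_TAGGED)
    sub = sum(trajectory[name] for name in SUBSTRATE_TAGGED)
    return enz, sub
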