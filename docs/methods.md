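# Methods

`dopadiox` analyzes the kinetics and physical chemistry of catechol
ring-cleavage by L-DOPA 2,3-dioxygenases. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Single-turnover mechanism and its simulation

The presteady-state model is a mass-action reaction network for one turnover
of a catecholic substrate S by enzyme E under excess enzyme and oxygen:

```
 1.  S_A <-> S_B          substrate charge-state equilibrium
 2.  E + S_A <-> ES       binding of the protonated state
 3.  E + S_B <-> ES       binding of the monoanion
 4.  ES + O2 -> ESO2      oxygen binding (fast, irreversible)
 5.  ESO2 -> ESQ          semiquinone formation
 6.  ESQ -> EI            productive decay toward ring cleavage (k6)
 7.  ESQ -> ESQ_X         nonproductive quenching / inactivation (k7)
 8.  EI -> EP             lumped UV-silent chemistry to product
 9.  EP -> E + P          product release
10.  P <-> P_X            product equilibrium with a silent species
```

S_A is defined as the more protonated charge state and S_B as its conjugate
base; the step-1 constants are ratio-linked so that k1/k-1 equals the
Henderson–Hasselbalch ratio `10^(pH - pKa)` at the configured pH and the
substrate's measured pKa, and the link is re-enforced after every parameter
update. Because the UV-silent intermediates between the semiquinone and the
product are not constrained by a single-wavelength trace, step 8 lumps all
of them into one first-order rate.

Which charge state is binding-competent is not established; the default
activates the monoanion pathway (step 3) and pins step 2 very slow, because
the mechanistic consensus for extradiol dioxygenases has the substrate bind
as a monoanion, but `competent_state="A" | "B" | "both"` exposes all three
choices. Rate constants declared `fixed_fast` resolve to 1e9 and
`fixed_slow` to 1e-12 (effectively zero).

Units: concentrations in uM, time in s, first-order constants in 1/s,
second-order constants in 1/(uM s). Extinction coefficients stay in
1/(M cm); the observable applies the explicit 1e-6 conversion.

The ODE system is integrated with `scipy.integrate.solve_ivp` using an
analytically assembled Jacobian (product rule over the at-most-two molecules
on each side of every step), relative tolerance 1e-8 and absolute tolerance
1e-12 uM. LSODA is the default method: with the analytic Jacobian it handles
the extreme stiffness introduced by `fixed_fast` = 1e9 about three times
faster than BDF at the same accuracy, and both are selectable. Enzyme and
substrate totals are conserved to well below 1e-6 relative over the full
0-45 s window; tiny negative excursions (below 1e-9 uM slack) are clipped,
larger ones are treated as solver failure.

## Observable

The absorbance predicted at 380 nm is

```
A(t) = 1e-6 * l * ( a*([ESQ] - [ESQ_X]) + b*([EP] + [P]) ) - c
```

with `a` the semiquinone extinction coefficient, `b` the independently
determined product extinction coefficient (always fixed during fitting), `c`
a y-axis offset, and `l` the pathlength (default 1 cm; the stopped-flow
pathlength is configurable because instruments differ). The subtraction of
the quenched complex `[ESQ_X]` is the literal fitting convention
(`literal_mode=True`, the default); it is physically odd for a species
described as spectroscopically silent, so `literal_mode=False` drops that
term. The toggle is explicit, never silent.

## Transient fitting

Free parameters (any subset of the rate constants plus `a` and `c`) are
optimized by trust-region least squares (`scipy.optimize.least_squares`,
method `trf`). Positive parameters — rate constants and `a` — are fitted on
a log10 scale, which enforces positivity without hard walls across the
twelve decades a constant may span; `c` is fitted untransformed. Ratio
links and fixed statuses are re-applied at every trial point, so constraints
hold exactly in the result. A simulation failure at a trial point returns a
large finite residual (step rejection) rather than crashing the optimizer,
and a maximum-iteration exit is reported as not converged.

The default fit window is 0.8-45 s: the first 800 ms of real traces carries
low-intensity features outside the model and is excluded; the window is
configurable per problem.

## Confidence contours

`fitspace_2d` maps the profile sum-of-squares surface over a parameter
pair: at each node of a 21 x 21 grid (logarithmic axes spanning a factor of
5 either side of the best fit, the best-fit value as the exact center node)
the pair is fixed and every remaining free parameter re-optimized,
warm-started from the neighboring node for continuity. The confidence
region is `{SSE_min / SSE_xy >= threshold}` with threshold 0.83 by default,
i.e. fits within roughly 20% of the minimum SSE; reported per-parameter
intervals are the axis projections of the region. Whether the threshold is
applied to the SSE ratio or to a reduced chi-square ratio is immaterial
under homoscedastic noise (the two differ by a constant factor that cancels
in the ratio); it is implemented on the SSE ratio. An empty region above
the threshold is reported, never silently clipped, and non-converged inner
fits are flagged per node.

## Steady state

Initial rates are taken from progress curves by converting absorbance to
product concentration through the product extinction coefficient and
finding the earliest window of at least 8 points whose linear fit reaches
R^2 >= 0.995, expanding it until R^2 drops. The rule implements "slope of
the linear region" reproducibly; both the window size and the threshold are
arguments, and a trace with no qualifying window fails loudly with the best
R^2 seen.

Rates are expressed in uM/min and divided by the enzyme concentration
before fitting. The hyperbola is fitted in two parameterizations —
`y = kcat*x/(KM + x)` and `y = kSP*x/(1 + (kSP/kcat)*x)` — which are
algebraically identical, so fitted curves agree pointwise and the reported
kSP satisfies `kSP = 60*kcat/KM` (kcat in 1/s) from either route. The
second form is sometimes typeset with the denominator parenthesized as
`(1 + kSP*x)/kcat`, which is not dimensionally consistent; the standard
equivalent is implemented. Non-saturating data (max S below the fitted KM)
are flagged as extrapolated.

Oxygen percentages convert to dissolved concentration linearly,
`percent/100 * 1300 uM`, anchored at 100% -> 1300 uM and 21% -> ~270 uM at
the 22 C reference temperature; other temperatures require an explicit
saturation constant. Product extinction coefficients come from endpoint
series via a through-origin weighted regression of A against
`1e-6 * c * l`.

## Spectrophotometric pKa and Hammett correlation

Plate matrices (210-600 nm in 2-nm steps, one column per buffer pH) are
blank-subtracted and each column shifted so A(600 nm) = 0. Difference
spectra against a low-pH reference column (pH 3.0 by default; 4.0 exposed
as a parameter) locate the wavelengths of maximum positive and negative
difference in the highest-pH column. The pH series handed to the regression
is either the single-wavelength difference or, by default, the total
difference `|d(lambda+)| + |d(lambda-)|` per pH. The two-state model

```
A(pH) = [S_t] * (e_HA + e_A * 10^(pH - pKa)) / (1 + 10^(pH - pKa))
```

is fitted by least squares for pKa and the two effective coefficients
(difference coefficients may take either sign; the fit is invariant to
exchanging their roles with a sign flip of the data). Flat series and
transitions outside the scanned range are refused with diagnostics.

The Hammett analysis regresses pKa on built-in Hansch sigma constants
(para: H 0.00, Br 0.23, CN 0.66, NO2 0.78; meta: H 0.00, Br 0.39, CN 0.56,
NO2 0.71), user-overridable, and reports slope, intercept and R^2.

Voltammetric summaries are pure arithmetic: E1/2 = (Epa + Epc)/2,
dEp = Epa - Epc, peak ratio Ipa/Ipc; rows lacking a cathodic peak carry
undefined summaries. One built-in cathodic value (DHHCA at pH 6.0) is
stored as +9 mV because the recorded midpoint and separation are only
mutually consistent with a positive sign. Normalization of scans against
the dopamine midpoint is reported as a ratio (percent) by default, with the
subtractive alternative also available in the profile table, since the
convention is ambiguous. Active-site/substrate volumes (CSEV) are accepted
as user-supplied annotations only; no volume computation is performed.

## Synthetic data: what it does and does not emulate

The generators exist so every stage is testable with known ground truth.

* Stopped flow: 500 points log-spaced from 2 ms to 45 s (resolving both the
  early transient and the slow product rise), homoscedastic Gaussian noise
  of 0.002 AU per replicate, 15 replicates — nominal instrument-like values.
  Default conditions are the single-turnover experiment: 5.6 uM substrate,
  56 uM enzyme, 1000 uM O2, pH 7.35, pKa 7.51, 14 C, 380 nm. The default
  rate set (k5 = 0.5, k6 = 0.55, k7 = 0.30, k8 = 0.15, k9 = 1.0,
  k10 = 0.01/k-10 = 0.02 1/s; binding 1.0 1/(uM s); protonation 1000 1/s)
  uses the two measured branch rates and otherwise values chosen so the
  noiseless trace shows the characteristic shape: a semiquinone maximum
  within the first 5 s and a slower product feature accumulating between 10
  and 20 s.
* Rates: relative Gaussian noise on a hyperbola, the simplest model
  consistent with least-squares assumptions.
* Titrations: two Gaussian bands (acid form at 280 nm, base form at 350 nm
  by default) mixed by the Henderson-Hasselbalch fractions, on a smooth
  nonzero blank.
* Endpoints: Beer-Lambert lines with additive noise.

Not emulated: mixing dead-time artifacts, photobleaching, baseline drift,
heteroscedastic detector noise, buffer-specific spectral shifts, or real
band shapes. Passing recovery tests therefore demonstrates the estimators
are unbiased and well-conditioned under the stated noise model at the
published parameter values — not that real instrument data are free of
systematic effects the model omits.

## Problem sizes

The test suite and the acceptance script run at desk scale: 20 replicate
datasets per stochastic recovery check, 500-point traces, 21 x 21 contour
grids, 50-seed Monte Carlo checks for the fast scalar estimators. These
sizes give medians stable to well within the asserted tolerances.

## Known limitations

* No thermodynamic-cycle consistency enforcement, no diffusion or
  temperature dependence in the mechanism.
* No global multi-wavelength or multi-experiment simultaneous fitting; no
  Bayesian posterior sampling.
* Steady-state analysis fits catechol and O2 saturation curves
  independently; no bisubstrate rate law, no substrate/product inhibition.
* No raw voltammogram processing (baseline, peak picking) — peak potentials
  are inputs.
* The mechanism fit reports local least-squares minima; multistart from
  jittered guesses is the tested mitigation, not a global guarantee.
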