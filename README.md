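# dopadiox

Kinetic and physicochemical analysis of catechol ring cleavage by L-DOPA
2,3-dioxygenases — the small, Fe(II)-dependent extradiol dioxygenases (VOC
superfamily) that open the aromatic ring of L-DOPA and of lignin-derived
catechols such as 3,4-dihydroxyhydrocinnamic acid (DHHCA, hydrocaffeic
acid) and its 6-bromo/cyano/nitro derivatives, yielding muconic
semialdehydes.

The package is for enzymologists working with these (or similar) systems
who need to go from raw instrument exports — stopped-flow progress curves,
microplate titration spectra, initial-rate tables, voltammetric peak
potentials, protein sequences — to fitted mechanistic and thermodynamic
constants with honest uncertainty estimates.

## What it computes

**Presteady state.** A mass-action model of one substrate turnover:
charge-state equilibrium S_A &harr; S_B fixed at the Henderson–Hasselbalch
ratio 10^(pH−pKa), binding, fast irreversible O2 capture, semiquinone
(ESQ) formation, and the branch that defines substrate quality — productive
decay toward product (k6) versus nonproductive quenching to the inactivated
complex ESQ_X (k7). The stiff ODE system is integrated with an analytic
Jacobian, traces are predicted through the observable

    A(t) = 1e-6 · l · ( a·([ESQ] − [ESQ_X]) + b·([EP] + [P]) ) − c ,

and free rate constants/extinction coefficients are fitted by trust-region
least squares on a log scale. Confidence regions come from profile
contours: each parameter pair is scanned on a grid, all other free
parameters re-optimized per node, and the region is thresholded at
SSE_min/SSE_xy ≥ 0.83 (fits within ~20% of the minimum).

**Steady state.** Initial-rate extraction from progress curves (earliest
linear window with R² ≥ 0.995), Michaelis–Menten fits in both the
traditional form y = kcat·x/(KM + x) and the direct specificity-constant
form y = kSP·x/(1 + (kSP/kcat)·x) with kSP = kcat/KM in uM⁻¹ min⁻¹, O2
percent-to-concentration conversion (100% → 1300 uM at 22 °C), and product
extinction coefficients from endpoint Beer–Lambert series.

**Physical chemistry.** Spectrophotometric pKa from plate titrations
(blank subtraction, 600-nm normalization, difference spectra, two-state
regression), Hammett correlation of pKa against built-in sigma constants,
cyclic-voltammetry summary arithmetic (E1/2, ΔEp, Ipa/Ipc), the
chromophore-count protein ε280, and percent-relative substrate property
tables.

**Synthetic data.** Generators for every input format with known ground
truth (seeded, bit-reproducible), so the full pipeline is testable without
instrument data.

See `docs/methods.md` for models, assumptions, defaults, and limitations.

## Worked example

Simulate the canonical single-turnover experiment (5.6 uM 6-cyanoDHHCA,
56 uM enzyme, ~1000 uM O2, 380 nm, pH 7.35), average 15 noisy replicates,
and re-fit the branch rates and semiquinone extinction coefficient:

```python
from dopadiox.mechanism import ObservableModel, build_scheme1
from dopadiox.synthetic import GeneratorSpec, gen_stopped_flow
from dopadiox.transient import FitProblem, average_traces, fit_mechanism, fitspace_2d

traces, truth = gen_stopped_flow(spec=GeneratorSpec(seed=1))   # k6=0.55, k7=0.30
avg = average_traces(traces)
problem = FitProblem(build_scheme1(pka=7.51, ph=7.35), ObservableModel(),
                     avg, free_parameters=("k6", "k7", "a"))
fit = fit_mechanism(problem, initial_guess={"k6": 1.2, "k7": 0.12, "a": 2e4})
print(f"k6 = {fit.parameter_values['k6']:.3f} 1/s")
print(f"k7 = {fit.parameter_values['k7']:.3f} 1/s")
print(f"a  = {fit.parameter_values['a']:.0f} 1/(M cm)")
print(f"SSE = {fit.sse:.2e} over {fit.n_points} points")
```

prints

```
k6 = 0.549 1/s
k7 = 0.300 1/s
a  = 38903 1/(M cm)
SSE = 5.10e-05 over 201 points
```

i.e. the fit recovers the generating branch rates (0.55 and 0.30 1/s — a
productive-to-quenching ratio of ~1.8, the signature of a strongly
inactivating substrate) and the semiquinone coefficient (38,950 1/(M cm))
from data with 0.002 AU replicate noise. Profile contours quantify how
sharply the trace pins each rate:

```python
grid = fitspace_2d(problem, fit, ("k6", "k7"), n_nodes=11, span=1.04)
print(grid.interval_per_parameter["k6"])   # (0.5444, 0.5530)
```

At this noise level the 0.83-threshold interval on k6 is under ±1% — on
real traces, with structure the model does not capture, the regions are
much wider, which is exactly what the contours are for.

The same loop closes for the titration stage:

```python
from dopadiox.physchem import titration_pipeline
from dopadiox.synthetic import gen_titration

plate, truth = gen_titration(7.51, spec=GeneratorSpec(seed=1, noise_sd=0.005))
fit = titration_pipeline(plate)
print(f"pKa = {fit.pka:.3f} +/- {fit.pka_se:.3f} at {fit.chosen_wavelengths}")
# pKa = 7.512 +/- 0.010 at (352.0, 274.0)
```

recovering the generating pKa of 7.51 and selecting the difference
wavelengths at the synthetic band centers (350/280 nm within the 2-nm
plate resolution).

## Command line

The same stages are available as subcommands of `dopadiox`:

```bash
dopadiox generate --preset single-turnover-cyano --seed 1 --out-dir data/
dopadiox fit-transient data/single-turnover-cyano_rep*.csv --free k6 --free k7 --free a
dopadiox fitspace data/single-turnover-cyano_rep*.csv --pair k6 k7
dopadiox fit-mm rates.csv
dopadiox fit-pka plate.csv blank.csv
dopadiox hammett
dopadiox cv-summary
dopadiox profile-table profiles.csv --reference L-DOPA
dopadiox report run1/ run2/
```

Every run writes its resolved configuration beside its outputs and logs
fit windows, thresholds, and constraint resolutions.

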