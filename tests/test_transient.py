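"""Trace averaging, mechanism fitting, and profile-contour confidence regions."""

import numpy as np
import pytest

from dopadiox.mechanism import KineticTrace, ObservableModel, TraceMetadata, build_scheme1
from dopadiox.synthetic import GeneratorSpec, gen_stopped_flow
from dopadiox.transient import (
    FitProblem,
    FitResult,
    average_traces,
    fit_least_squares,
    fit_mechanism,
    fitspace_2d,
    speciation_ratio,
)

SHORT_GRID = np.geomspace(0.002, 45.0, 120)


class TestSpeciation:
    @pytest.mark.parametrize(
        "pka,ph,fraction",
        [
            (7.0, 7.0, 0.5),
            (7.51, 7.35, 0.409),  # measured pKa of the cyano derivative
            (5.0, 8.0, 0.999),
        ],
    )
    def test_fraction_deprotonated(self, pka, ph, fraction):
        sp = speciation_ratio(pka, ph)
        assert sp.fraction_deprotonated == pytest.approx(fraction, abs=5e-4)
        assert sp.ratio == pytest.approx(10 ** (ph - pka), rel=1e-12)


class TestAverageTraces:
    def _trace(self, values, **meta):
        t = np.linspace(0, 1, len(values))
        return KineticTrace(t, np.asarray(values, float), TraceMetadata(**meta))

    def test_idempotent_on_identical_traces(self):
        tr = self._trace([0.1, 0.2, 0.3])
        avg = average_traces([tr, tr])
        assert np.allclose(avg.absorbance, tr.absorbance)
        assert avg.metadata.replicates == 2

    def test_symmetric_traces_cancel(self):
        up = self._trace([0.1, 0.2, 0.3])
        down = self._trace([-0.1, -0.2, -0.3])
        assert np.allclose(average_traces([up, down]).absorbance, 0.0)

    def test_noise_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(11)
        sigma, n_rep = 0.01, 15
        clean = np.sin(np.linspace(0, 3, 200))
        traces = [
            KineticTrace(np.linspace(0, 1, 200), clean + rng.normal(0, sigma, 200))
            for _ in range(n_rep)
        ]
        resid_sd = np.std(average_traces(traces).absorbance - clean)
        assert resid_sd == pytest.approx(sigma / np.sqrt(n_rep), rel=0.35)

    def test_metadata_mismatch_rejected(self):
        a = self._trace([0.0, 1.0], wavelength_nm=380.0)
        b = self._trace([0.0, 1.0], wavelength_nm=420.0)
        with pytest.raises(ValueError, match="wavelength"):
            average_traces([a, b])


def _noiseless_problem(free=("k6", "k7"), grid=SHORT_GRID):
    traces, truth = gen_stopped_flow(
        mechanism_params={"time_grid": grid},
        spec=GeneratorSpec(seed=0, noise_sd=0.0, replicate_count=1),
    )
    mech = build_scheme1(7.51, 7.35)
    return FitProblem(mech, ObservableModel(), traces[0], free), truth


class TestFitMechanism:
    def test_product_extinction_never_free(self):
        traces, _ = gen_stopped_flow(
            mechanism_params={"time_grid": SHORT_GRID},
            spec=GeneratorSpec(seed=0, noise_sd=0.0, replicate_count=1),
        )
        with pytest.raises(ValueError, match="independently determined"):
            FitProblem(build_scheme1(7.51, 7.35), ObservableModel(), traces[0], ("b",))

    def test_zero_noise_self_consistency(self):
        problem, truth = _noiseless_problem()
        res = fit_mechanism(problem, initial_guess={"k6": 1.0, "k7": 0.15})
        assert res.converged
        for name in ("k6", "k7"):
            assert res.parameter_values[name] == pytest.approx(
                truth["rates"][name], rel=1e-4
            )

    def test_multistart_reaches_same_minimum(self):
        problem, _ = _noiseless_problem()
        rng = np.random.default_rng(7)
        sses = []
        for _ in range(10):
            jitter = {
                "k6": 0.55 * 10 ** rng.uniform(-0.4, 0.4),
                "k7": 0.30 * 10 ** rng.uniform(-0.4, 0.4),
            }
            sses.append(fit_mechanism(problem, initial_guess=jitter).sse)
        assert np.ptp(sses) <= 1e-8 * max(max(sses), 1e-12) + 1e-14

    def test_ratio_links_hold_after_fit(self):
        problem, _ = _noiseless_problem(free=("k5", "k6"))
        fit_mechanism(problem, initial_guess={"k5": 0.8, "k6": 0.4})
        mech = problem.mechanism
        assert mech.get_rate("k1") / mech.get_rate("k-1") == pytest.approx(
            10 ** (7.35 - 7.51), rel=1e-12
        )

    def test_noisy_single_turnover_recovery(self):
        # replicate-averaged trace at instrument-like noise: the branch rates
        # and the semiquinone extinction coefficient come back within the
        # tolerances expected of a single experiment
        traces, truth = gen_stopped_flow(spec=GeneratorSpec(seed=5))
        avg = average_traces(traces)
        problem = FitProblem(
            build_scheme1(7.51, 7.35), ObservableModel(), avg, ("k6", "k7", "a")
        )
        res = fit_mechanism(
            problem, initial_guess={"k6": 1.2, "k7": 0.12, "a": 2.0e4}
        )
        assert res.converged
        assert res.parameter_values["k6"] == pytest.approx(0.55, rel=0.10)
        assert res.parameter_values["a"] == pytest.approx(38950.0, rel=0.15)

    def test_all_fixed_rejected(self):
        problem, _ = _noiseless_problem()
        with pytest.raises(ValueError, match="free parameters"):
            fit_least_squares(problem, {}, free=())

    def test_sse_nonnegative_enforced(self):
        with pytest.raises(ValueError):
            FitResult({}, sse=-1.0, n_points=3, converged=True)


# ---------------------------------------------------------------------------
# Profile-contour (FitSpace) analysis on exact quadratic fixtures


class LinearModelProblem:
    """y = X theta + noise: the SSE surface is exactly quadratic, so the
    confidence region has a closed-form ellipse to compare against."""

    def __init__(self, X, y, names):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        self.free_parameters = tuple(names)

    def transform(self, name):
        return "linear"

    def residuals(self, values):
        theta = np.array([values[n] for n in self.free_parameters])
        return self.X @ theta - self.y

    def sse(self, values):
        r = self.residuals(values)
        return float(r @ r)


@pytest.fixture
def quadratic_fixture():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(60, 2))
    theta_true = np.array([1.5, -0.7])
    y = X @ theta_true + rng.normal(0, 0.3, 60)
    theta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    problem = LinearModelProblem(X, y, ("t1", "t2"))
    best = FitResult(
        dict(zip(("t1", "t2"), theta_hat)),
        sse=problem.sse(dict(zip(("t1", "t2"), theta_hat))),
        n_points=60,
        converged=True,
    )
    return problem, best, X, y, theta_hat


class TestFitSpace:
    def test_quadratic_surface_matches_analytic_ellipse(self, quadratic_fixture):
        problem, best, X, y, theta_hat = quadratic_fixture
        grid = fitspace_2d(problem, best, ("t1", "t2"), threshold=0.83, n_nodes=21)
        H = X.T @ X  # SSE(theta) = SSE_min + d^T H d exactly
        ax1, ax2 = grid.grid_values
        for i, v1 in enumerate(ax1):
            for j, v2 in enumerate(ax2):
                d = np.array([v1, v2]) - theta_hat
                analytic = best.sse + d @ H @ d
                assert grid.sse[i, j] == pytest.approx(analytic, rel=1e-9)
        # region boundary within one grid cell of the SSE = SSE_min/0.83 ellipse
        level = best.sse * (1.0 / 0.83 - 1.0)
        inside = grid.sse_ratio >= 0.83 - 1e-12
        for i, v1 in enumerate(ax1):
            for j, v2 in enumerate(ax2):
                d = np.array([v1, v2]) - theta_hat
                assert inside[i, j] == (d @ H @ d <= level + 1e-12)

    def test_threshold_one_keeps_only_best_node(self, quadratic_fixture):
        problem, best, *_ = quadratic_fixture
        grid = fitspace_2d(problem, best, ("t1", "t2"), threshold=1.0, n_nodes=11)
        inside = grid.sse_ratio >= 1.0 - 1e-12
        assert inside.sum() == 1
        i, j = np.argwhere(inside)[0]
        assert grid.grid_values[0][i] == pytest.approx(best.parameter_values["t1"])
        assert grid.grid_values[1][j] == pytest.approx(best.parameter_values["t2"])

    def test_separable_parameters_give_axis_aligned_region(self):
        # disjoint design columns: the SSE splits into independent terms and
        # the region must be the product of its own projections
        rng = np.random.default_rng(3)
        X = np.zeros((80, 2))
        X[:40, 0] = rng.normal(size=40)
        X[40:, 1] = rng.normal(size=40)
        theta_true = np.array([0.8, -1.2])
        y = X @ theta_true + rng.normal(0, 0.2, 80)
        theta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
        problem = LinearModelProblem(X, y, ("t1", "t2"))
        best = FitResult(
            dict(zip(("t1", "t2"), theta_hat)),
            sse=problem.sse(dict(zip(("t1", "t2"), theta_hat))),
            n_points=80,
            converged=True,
        )
        grid = fitspace_2d(problem, best, ("t1", "t2"), threshold=0.83, n_nodes=15)
        inside = grid.sse_ratio >= 0.83 - 1e-12
        rows = inside.any(axis=1)
        cols = inside.any(axis=0)
        assert np.array_equal(inside, np.outer(rows, cols))

    def test_profiled_third_parameter_matches_schur_complement(self):
        # re-optimizing a nuisance parameter at each node must reproduce the
        # analytic profile SSE of the quadratic surface
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 0.5, 50)
        theta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
        names = ("t1", "t2", "t3")
        problem = LinearModelProblem(X, y, names)
        best = FitResult(
            dict(zip(names, theta_hat)),
            sse=problem.sse(dict(zip(names, theta_hat))),
            n_points=50,
            converged=True,
        )
        grid = fitspace_2d(problem, best, ("t1", "t2"), threshold=0.83, n_nodes=7)
        H = X.T @ X
        Hpp = H[:2, :2]
        Hpn = H[:2, 2:]
        Hnn = H[2:, 2:]
        schur = Hpp - Hpn @ np.linalg.solve(Hnn, Hpn.T)
        ax1, ax2 = grid.grid_values
        for i, v1 in enumerate(ax1):
            for j, v2 in enumerate(ax2):
                d = np.array([v1, v2]) - theta_hat[:2]
                assert grid.sse[i, j] == pytest.approx(
                    best.sse + d @ schur @ d, rel=1e-7, abs=1e-10
                )

    def test_intervals_contain_best_fit(self, quadratic_fixture):
        problem, best, *_ = quadratic_fixture
        grid = fitspace_2d(problem, best, ("t1", "t2"), threshold=0.83, n_nodes=13)
        for name in ("t1", "t2"):
            lo, hi = grid.interval_per_parameter[name]
            assert lo <= best.parameter_values[name] <= hi
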