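"""Global least-squares fit: residual contract, initialization, recovery."""

import numpy as np
import pytest

from blifit import (
    FitOptions,
    GlobalKineticsFit,
    ParameterVector,
    fit_global,
    initial_guess,
    residuals,
    sse,
)
from blifit.dataset import BLIDataset
from blifit.exceptions import DegenerateDesignError
from blifit.fitting import default_bounds
from blifit.model import CurveNuisance, KineticParameters
from blifit.simulate import SimulationDesign, simulate_dataset

from conftest import make_small_design


def _true_params(kin, dataset):
    """Generating ParameterVector for a simulated dataset (noise-free model
    comparison gives the per-curve nuisances used by the simulator)."""
    nuis = []
    noiseless = simulate_dataset(
        kin,
        SimulationDesign(
            concentrations=tuple(dataset.concentrations),
            samples_per_phase=dataset.curves[0].assoc_t.size,
            noise_sigma=0.0,
        ),
    )
    for c in noiseless.curves:
        a_on = 0.0 if c.concentration == 0 else c.concentration / (c.concentration + kin.kd)
        nuis.append(
            CurveNuisance(a_on=a_on, b_on=0.0, a_off=float(c.dissoc_y[0]), b_off=0.0)
        )
    return ParameterVector(kin=kin, nuisances=nuis)


class TestResiduals:
    def test_noiseless_dataset_gives_zero_residuals(self, lam8):
        design = make_small_design(noise_sigma=0.0)
        ds = simulate_dataset(lam8, design)
        params = _true_params(lam8, ds)
        np.testing.assert_allclose(residuals(ds, params), 0.0, atol=1e-12)

    def test_residuals_equal_injected_noise_at_generating_params(self, lam8):
        noisy = simulate_dataset(lam8, make_small_design(seed=4, noise_sigma=0.02))
        clean = simulate_dataset(lam8, make_small_design(seed=4, noise_sigma=0.0))
        params = _true_params(lam8, noisy)
        r = residuals(noisy, params)
        injected = np.concatenate(
            [
                np.concatenate([n.assoc_y - c.assoc_y, n.dissoc_y - c.dissoc_y])
                for n, c in zip(noisy.curves, clean.curves)
            ]
        )
        np.testing.assert_allclose(r, injected, atol=1e-12)

    def test_fixed_ordering_curve_then_phase_then_time(self, lam8):
        ds = simulate_dataset(lam8, make_small_design(seed=2))
        params = _true_params(lam8, ds)
        r = residuals(ds, params)
        n = ds.curves[0].assoc_t.size
        # first block is curve 0's association phase, in time order
        first = ds.curves[0]
        from blifit.model import eval_binding

        expected = first.assoc_y - eval_binding(
            first.assoc_t, first.concentration, params.kin, params.nuisances[0]
        )
        np.testing.assert_allclose(r[:n], expected, atol=0)

    def test_sse_matches_naive_loop_accumulation(self, lam8):
        ds = simulate_dataset(lam8, make_small_design(seed=9, noise_sigma=0.05))
        params = _true_params(lam8, ds)
        r = residuals(ds, params)
        acc = 0.0
        for v in r:
            acc += float(v) * float(v)
        assert sse(ds, params) == pytest.approx(acc, rel=1e-12)


class TestInitialGuess:
    def test_guess_within_50pct_on_noiseless_data(self, lam8):
        ds = simulate_dataset(lam8, make_small_design(noise_sigma=0.0))
        guess = initial_guess(ds)
        assert guess.kin.k_on == pytest.approx(lam8.k_on, rel=0.5)
        assert guess.kin.k_off == pytest.approx(lam8.k_off, rel=0.5)

    def test_all_zero_concentrations_is_degenerate(self, lam8):
        ds = simulate_dataset(lam8, make_small_design())
        zeroed = BLIDataset(
            curves=[
                type(c)(
                    curve_id=c.curve_id,
                    concentration=0.0,
                    assoc_t=c.assoc_t,
                    assoc_y=c.assoc_y,
                    dissoc_t=c.dissoc_t,
                    dissoc_y=c.dissoc_y,
                )
                for c in ds.curves
            ]
        )
        with pytest.raises(DegenerateDesignError):
            initial_guess(zeroed)

    def test_guess_satisfies_default_bounds(self, lam8):
        ds = simulate_dataset(lam8, make_small_design(seed=13, noise_sigma=0.03))
        guess = initial_guess(ds).to_array()
        lo, hi = default_bounds(ds)
        assert np.all(guess >= lo) and np.all(guess <= hi)


class TestGlobalFit:
    def test_noiseless_round_trip_recovers_rates(self, lam8):
        ds = simulate_dataset(lam8, SimulationDesign(seed=1, noise_sigma=0.0))
        res = fit_global(ds)
        assert res.params_opt.kin.k_on == pytest.approx(lam8.k_on, rel=1e-4)
        assert res.params_opt.kin.k_off == pytest.approx(lam8.k_off, rel=1e-4)
        assert res.sse_opt <= 1e-12 * ds.n_data

    def test_eight_curves_expose_35_parameters(self, lam8):
        ds = simulate_dataset(lam8, SimulationDesign(seed=1, noise_sigma=0.0))
        assert ds.n_curves == 8
        res = fit_global(ds)
        assert res.n_params == 35
        assert res.residuals.size == res.n_data == ds.n_data

    def test_descent_from_start_and_idempotence_at_optimum(self, lam8, small_dataset):
        start = initial_guess(small_dataset)
        res = fit_global(small_dataset, start=start)
        assert res.sse_opt <= sse(small_dataset, start) + 1e-15
        again = fit_global(small_dataset, start=res.params_opt)
        assert again.sse_opt == pytest.approx(res.sse_opt, rel=1e-8)
        np.testing.assert_allclose(
            again.params_opt.to_array(), res.params_opt.to_array(), rtol=1e-4, atol=1e-10
        )

    def test_curve_order_does_not_change_shared_estimates(self, lam8, small_dataset):
        res = fit_global(small_dataset)
        permuted = BLIDataset(curves=list(reversed(small_dataset.curves)))
        res_p = fit_global(permuted)
        for attr in ("k_on", "k_off", "k_leak"):
            assert getattr(res_p.params_opt.kin, attr) == pytest.approx(
                getattr(res.params_opt.kin, attr), rel=1e-5, abs=1e-9
            )

    def test_deterministic_given_same_inputs(self, small_dataset):
        r1 = fit_global(small_dataset)
        r2 = fit_global(small_dataset)
        np.testing.assert_array_equal(r1.params_opt.to_array(), r2.params_opt.to_array())
        assert r1.sse_opt == r2.sse_opt

    def test_sigma_data_does_not_affect_point_estimates(self, small_dataset):
        r1 = fit_global(small_dataset, opts=FitOptions(sigma_data=1.0))
        r2 = fit_global(small_dataset, opts=FitOptions(sigma_data=10.0))
        np.testing.assert_array_equal(r1.params_opt.to_array(), r2.params_opt.to_array())
        # sigma scales the reported chi-squared but nothing else
        assert r1.chi2() == pytest.approx(100.0 * r2.chi2(), rel=1e-12)

    def test_noisy_recovery_within_10pct(self, lam8):
        ds = simulate_dataset(lam8, SimulationDesign(seed=21, noise_sigma=0.005))
        res = fit_global(ds)
        assert res.params_opt.kin.k_on == pytest.approx(lam8.k_on, rel=0.1)
        assert res.params_opt.kin.k_off == pytest.approx(lam8.k_off, rel=0.1)


class TestEstimatorInterface:
    def test_fitted_attributes_and_prediction(self, lam8, small_dataset, small_fit):
        est = small_fit
        assert est.n_params_ == 4 * small_dataset.n_curves + 3
        assert est.kd_ == pytest.approx(est.k_off_ / est.k_on_, rel=1e-12)
        assert est.score(small_dataset) > 0.99
        df = small_dataset.to_frame()
        pred = est.predict(df)
        np.testing.assert_allclose(
            df["signal"].to_numpy() - pred, est.result_.residuals, atol=1e-9
        )

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = GlobalKineticsFit(tolerance=1e-8, max_iterations=100)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        cloned.set_params(tolerance=1e-6)
        assert cloned.tolerance == 1e-6 and est.tolerance == 1e-8

    def test_unfitted_predict_raises(self, small_dataset):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            GlobalKineticsFit().predict(small_dataset.to_frame())


def test_fold_change_ordering_recovered(scenarios):
    """Simulated dark/lit pairs fit independently keep the published
    affinity ordering: GG15 dark tighter, AK74 lit tighter."""
    fits = {}
    for name in ("LaM8-GG15-pseudo-dark", "LaM8-GG15-pseudo-lit",
                 "LaM8-AK74-pseudo-dark", "LaM8-AK74-pseudo-lit"):
        ds = simulate_dataset(
            scenarios[name].kinetics, make_small_design(seed=31, noise_sigma=0.005)
        )
        fits[name] = GlobalKineticsFit().fit(ds).kd_
    assert fits["LaM8-GG15-pseudo-dark"] < fits["LaM8-GG15-pseudo-lit"]
    assert fits["LaM8-AK74-pseudo-lit"] < fits["LaM8-AK74-pseudo-dark"]
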