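"""Marginal likelihood, type-II MLE and posterior prediction."""

import numpy as np
import pytest
from scipy import stats

from meltgp.covariance import (
    DesignCache,
    HierarchySpec,
    HyperParams,
    assemble_covariance,
)
from meltgp.datasets import ProteinDataset, read_long_table
from meltgp.inference import (
    FitConfig,
    _nll_and_grad_fast3,
    _nll_and_grad_general,
    _ParamPacker,
    derive_seed,
    fit_type2_mle,
    log_marginal_likelihood,
    posterior_predict,
)
from meltgp.scaling import apply_scaling
from meltgp.simulate import SimulationDesign, simulate_dataset

from conftest import make_toy_table, toy_theta
import pandas as pd


def _random_instance(rng, n_temps=5, n_cond=2, n_rep=2):
    temps = np.sort(rng.uniform(30, 70, n_temps))
    rows = []
    for c in range(n_cond):
        for r in range(n_rep):
            for t in temps:
                rows.append((f"C{c}", f"R{r}", t, 1.0))
    ds = ProteinDataset(
        "X",
        pd.DataFrame(rows, columns=["condition", "replicate", "temperature", "abundance"]),
    )
    theta = HyperParams(
        lambda1=rng.uniform(2, 30),
        lambda2=rng.uniform(2, 30),
        sigma2_h=rng.uniform(0, 0.5),
        sigma2_g=rng.uniform(0, 0.5),
        sigma2_f={u: rng.uniform(0, 0.2) for u in ds.units()},
        beta2=rng.uniform(1e-4, 0.1),
    )
    return ds, theta


class TestLogMarginalLikelihood:
    def test_standard_normal_scalar(self):
        ds = ProteinDataset(
            "X",
            pd.DataFrame(
                {"condition": ["Ctrl"], "replicate": ["R1"],
                 "temperature": [40.0], "abundance": [1.0]}
            ),
        )
        theta = HyperParams(
            lambda1=1.0, lambda2=1.0, sigma2_h=0.0, sigma2_g=0.0,
            sigma2_f={("Ctrl", "R1"): 0.0}, beta2=1.0,
        )
        model = assemble_covariance(ds, HierarchySpec(3), theta)
        assert log_marginal_likelihood(np.array([0.0]), model) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-9
        )

    def test_matches_dense_multivariate_normal_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            ds, theta = _random_instance(rng)
            model = assemble_covariance(ds, HierarchySpec(3), theta)
            y = rng.standard_normal(model.n)
            ours = log_marginal_likelihood(y, model)
            oracle = stats.multivariate_normal.logpdf(
                y, mean=np.zeros(model.n), cov=model.full(), allow_singular=True
            )
            assert abs(ours - oracle) < 1e-8

    def test_maximised_at_zero_observation(self):
        rng = np.random.default_rng(5)
        ds, theta = _random_instance(rng)
        model = assemble_covariance(ds, HierarchySpec(3), theta)
        at_zero = log_marginal_likelihood(np.zeros(model.n), model)
        for _ in range(10):
            assert at_zero >= log_marginal_likelihood(rng.standard_normal(model.n), model)


class TestGradients:
    def test_fast_path_equals_general_path(self, toy_dataset):
        cache = DesignCache(toy_dataset, HierarchySpec(3))
        packer = _ParamPacker(cache, FitConfig())
        assert packer.fast3
        y = toy_dataset.scaled() - toy_dataset.scaled().mean()
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = packer.initial(rng, y.var())
            n1, g1 = _nll_and_grad_fast3(x, packer, y)
            n2, g2 = _nll_and_grad_general(x, packer, y)
            assert n1 == pytest.approx(n2, abs=1e-9)
            np.testing.assert_allclose(g1, g2, atol=1e-10)

    def test_analytic_gradient_matches_finite_differences(self, toy_dataset):
        from scipy.optimize import approx_fprime

        cache = DesignCache(toy_dataset, HierarchySpec(3))
        packer = _ParamPacker(cache, FitConfig())
        y = toy_dataset.scaled() - toy_dataset.scaled().mean()
        x = packer.initial(np.random.default_rng(1), y.var())
        num = approx_fprime(x, lambda v: _nll_and_grad_fast3(v, packer, y)[0], 1e-6)
        ana = _nll_and_grad_fast3(x, packer, y)[1]
        np.testing.assert_allclose(ana, num, rtol=1e-3, atol=1e-4)


class TestFit:
    def test_seed_determinism_bit_identical(self, toy_dataset):
        a = fit_type2_mle(toy_dataset, seed=3)
        b = fit_type2_mle(toy_dataset, seed=3)
        assert a.theta.lambda1 == b.theta.lambda1
        assert a.theta.sigma2_f == b.theta.sigma2_f
        assert a.log_marginal_likelihood == b.log_marginal_likelihood

    def test_fit_beats_generating_parameters_usually(self):
        design = SimulationDesign(n_identifiers=12, fraction_differential=0.0, seed=21)
        obs, _ = simulate_dataset(design)
        datasets = read_long_table(obs, require_positive=False)
        theta_gen = design.hyperparams()
        wins = 0
        for ds in datasets.values():
            apply_scaling(ds, "none")
            fit = fit_type2_mle(ds, seed=21)
            y = ds.scaled() - fit.offset
            model = assemble_covariance(ds, HierarchySpec(3), theta_gen)
            at_gen = log_marginal_likelihood(y, model)
            wins += fit.log_marginal_likelihood >= at_gen - 1e-3
        assert wins >= 11

    def test_four_level_fit_runs_and_is_deterministic(self):
        design = SimulationDesign(
            levels=4, n_identifiers=1, n_peptides=2, seed=6,
            temperatures=np.linspace(37, 67, 6),
        )
        obs, _ = simulate_dataset(design)
        ds = read_long_table(obs, require_positive=False)["sim_0000"]
        apply_scaling(ds, "none")
        a = fit_type2_mle(ds, seed=6)
        b = fit_type2_mle(ds, seed=6)
        assert np.isfinite(a.log_marginal_likelihood)
        assert a.theta.lambda3 is not None and a.theta.sigma2_eta
        assert a.log_marginal_likelihood == b.log_marginal_likelihood

    def test_derive_seed_stable_and_bounded(self):
        assert derive_seed(1, "ABC") == derive_seed(1, "ABC")
        assert derive_seed(1, "ABC") != derive_seed(2, "ABC")
        assert 0 <= derive_seed(2**31 - 1, "x") < 2**31


class TestPosterior:
    def test_single_gp_regression_oracle(self):
        # one condition, one replicate, sigma_h = 0: the replicate-level
        # posterior must equal textbook GP regression with kernel
        # sigma_g^2 k1 + sigma_f^2 k2
        temps = np.linspace(35, 65, 8)
        rng = np.random.default_rng(2)
        y = np.sin(temps / 8.0) + 0.05 * rng.standard_normal(8)
        tab = pd.DataFrame(
            {"condition": "Ctrl", "replicate": "R1", "temperature": temps,
             "abundance": y, "y": y}
        )
        ds = ProteinDataset("X", tab)
        theta = HyperParams(
            lambda1=10.0, lambda2=5.0, sigma2_h=0.0, sigma2_g=0.3,
            sigma2_f={("Ctrl", "R1"): 0.2}, beta2=0.01,
        )
        grid = np.linspace(35, 65, 21)
        curve = posterior_predict(ds, HierarchySpec(3), theta, ("f", "Ctrl", "R1"), grid)

        def k(a, b):
            d2 = np.subtract.outer(a, b) ** 2
            return 0.3 * np.exp(-d2 / (2 * 10.0**2)) + 0.2 * np.exp(-d2 / (2 * 5.0**2))

        kxx = k(temps, temps) + 0.01 * np.eye(8)
        kgx = k(grid, temps)
        mean_oracle = kgx @ np.linalg.solve(kxx, y)
        var_oracle = np.diag(k(grid, grid) - kgx @ np.linalg.solve(kxx, kgx.T))
        np.testing.assert_allclose(curve.mean, mean_oracle, atol=1e-8)
        np.testing.assert_allclose(curve.variance, var_oracle, atol=1e-6)

    def test_noiseless_interpolation_limit(self, toy_dataset):
        theta = toy_theta(toy_dataset.units(), beta2=1e-10)
        unit = toy_dataset.units()[0]
        idx = toy_dataset.unit_index(unit)
        grid = toy_dataset.temperatures[idx]
        curve = posterior_predict(
            toy_dataset, HierarchySpec(3), theta, ("f", *unit), grid
        )
        np.testing.assert_allclose(curve.mean, toy_dataset.scaled()[idx], atol=1e-3)

    def test_prior_reversion_far_from_data(self, toy_dataset):
        theta = toy_theta(toy_dataset.units())
        offset = float(toy_dataset.scaled().mean())
        curve = posterior_predict(
            toy_dataset, HierarchySpec(3), theta, ("g", "Ctrl"),
            np.array([500.0, 600.0]), offset=offset,
        )
        # far beyond the data the posterior reverts to the (restored) prior mean
        np.testing.assert_allclose(curve.mean, offset, atol=1e-6)

    def test_condition_mean_shrinks_between_replicates(self, toy_dataset):
        # with a shared lengthscale and equal replicate output-scales the
        # condition-level posterior lies (to a small tolerance — g also
        # borrows strength across conditions through h) inside the envelope
        # of its replicate-level posteriors
        fit_theta = toy_theta(toy_dataset.units(), lambda1=10.0, lambda2=10.0)
        offset = float(toy_dataset.scaled().mean())
        grid = np.linspace(38, 66, 15)
        kw = dict(offset=offset)
        g = posterior_predict(
            toy_dataset, HierarchySpec(3), fit_theta, ("g", "Ctrl"), grid, **kw
        )
        f1 = posterior_predict(
            toy_dataset, HierarchySpec(3), fit_theta, ("f", "Ctrl", "R1"), grid, **kw
        )
        f2 = posterior_predict(
            toy_dataset, HierarchySpec(3), fit_theta, ("f", "Ctrl", "R2"), grid, **kw
        )
        span = float(np.ptp(np.concatenate([f1.mean, f2.mean])))
        lo = np.minimum(f1.mean, f2.mean) - 0.03 * span
        hi = np.maximum(f1.mean, f2.mean) + 0.03 * span
        assert np.all((g.mean >= lo) & (g.mean <= hi))

    def test_unknown_level_rejected(self, toy_dataset):
        from meltgp.datasets import ValidationError

        with pytest.raises(ValidationError):
            posterior_predict(
                toy_dataset, HierarchySpec(3), toy_theta(toy_dataset.units()),
                ("q", "Ctrl"), np.array([40.0, 50.0]),
            )
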