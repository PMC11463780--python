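"""Hierarchical covariance assembly: dense formula, Kronecker path, draws."""

import numpy as np
import pandas as pd
import pytest

from meltgp.covariance import (
    DesignCache,
    HierarchySpec,
    HyperParams,
    ParameterError,
    assemble_covariance,
    assemble_covariance_kronecker,
    generative_draw,
    joint_structure,
    median_hyperparams,
    rbf_correlation,
)
from meltgp.datasets import ProteinDataset, ValidationError, read_long_table
from meltgp.simulate import SimulationDesign, simulate_dataset

from conftest import make_toy_table, toy_theta


class TestRbf:
    def test_identity_and_closed_form(self):
        assert rbf_correlation(3.0, 3.0, 5.0) == 1.0
        assert rbf_correlation(0.0, 1.0, 1.0) == pytest.approx(
            np.exp(-0.5), abs=1e-9
        )

    def test_long_lengthscale_limit_monotone(self):
        vals = [rbf_correlation(0.0, 2.0, lam) for lam in (1.0, 5.0, 50.0, 5e3)]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(1.0, abs=1e-6)

    def test_invalid_lengthscale(self):
        with pytest.raises(ParameterError):
            rbf_correlation(0.0, 1.0, 0.0)


def _single_unit_dataset(temps):
    tab = pd.DataFrame(
        {
            "condition": "Ctrl",
            "replicate": "R1",
            "temperature": temps,
            "abundance": 1.0,
        }
    )
    return ProteinDataset("X", tab)


class TestAssemble:
    def test_two_point_closed_form(self):
        ds = _single_unit_dataset([0.0, 1.0])
        theta = HyperParams(
            lambda1=1.0, lambda2=1.0, sigma2_h=0.0, sigma2_g=1.0,
            sigma2_f={("Ctrl", "R1"): 0.0}, beta2=0.0,
        )
        model = assemble_covariance(ds, HierarchySpec(3), theta)
        e = np.exp(-0.5)
        np.testing.assert_allclose(model.sigma, [[1.0, e], [e, 1.0]])

    def test_hierarchical_composition_at_equal_temperature(self, toy_table):
        ds = read_long_table(toy_table)["P0"]
        theta = toy_theta(ds.units(), sigma2_f=3.0, sigma2_h=1.0, sigma2_g=2.0)
        model = assemble_covariance(ds, HierarchySpec(3), theta)
        t = ds.temperatures
        cond = ds.table["condition"].to_numpy()
        rep = ds.table["replicate"].to_numpy()
        i = 0  # (Ctrl, R1, t0)
        same_rep = np.flatnonzero((t == t[i]) & (cond == "Ctrl") & (rep == "R1"))[0]
        cross_rep = np.flatnonzero((t == t[i]) & (cond == "Ctrl") & (rep == "R2"))[0]
        cross_cond = np.flatnonzero((t == t[i]) & (cond == "Trt"))[0]
        assert model.sigma[i, same_rep] == pytest.approx(6.0)
        assert model.sigma[i, cross_rep] == pytest.approx(3.0)
        assert model.sigma[i, cross_cond] == pytest.approx(1.0)

    def test_kronecker_matches_dense_exactly(self, toy_table):
        ds = read_long_table(toy_table)["P0"]
        theta = toy_theta(ds.units())
        dense = assemble_covariance(ds, HierarchySpec(3), theta)
        kron = assemble_covariance_kronecker(ds, HierarchySpec(3), theta)
        assert np.array_equal(dense.sigma, kron.sigma)

    def test_kronecker_rejects_asynchronous(self, toy_table):
        tab = toy_table.drop(index=[0])
        ds = read_long_table(tab)["P0"]
        with pytest.raises(ValidationError):
            assemble_covariance_kronecker(ds, HierarchySpec(3), toy_theta(ds.units()))

    def test_permutation_equivariance(self, toy_table):
        ds = read_long_table(toy_table)["P0"]
        theta = toy_theta(ds.units())
        sigma = assemble_covariance(ds, HierarchySpec(3), theta).sigma
        shuffled = read_long_table(toy_table.sample(frac=1.0, random_state=1))["P0"]
        sigma2 = assemble_covariance(shuffled, HierarchySpec(3), theta).sigma
        # canonical internal ordering makes the matrices identical
        assert np.array_equal(sigma, sigma2)

    def test_merging_conditions_changes_only_cross_blocks(self):
        design = SimulationDesign(n_identifiers=1, n_conditions=3, seed=0)
        obs, _ = simulate_dataset(design)
        ds = read_long_table(obs, require_positive=False)["sim_0000"]
        theta = toy_theta(ds.units())
        spec = HierarchySpec(3)
        full = assemble_covariance(ds, spec, theta).sigma
        joint = assemble_covariance(
            ds, joint_structure(spec, ("Ctrl", "C1"), ds), theta
        ).sigma
        cond = ds.table["condition"].to_numpy()
        c2 = cond == "C2"
        assert np.array_equal(full[c2], joint[c2])
        assert np.array_equal(full[:, c2], joint[:, c2])
        merged_cross = np.ix_(cond == "Ctrl", cond == "C1")
        assert np.all(joint[merged_cross] > full[merged_cross])

    def test_sigma_g_zero_makes_conditions_exchangeable(self, toy_table):
        ds = read_long_table(toy_table)["P0"]
        theta = toy_theta(ds.units(), sigma2_g=0.0)
        spec = HierarchySpec(3)
        full = assemble_covariance(ds, spec, theta).sigma
        joint = assemble_covariance(
            ds, joint_structure(spec, ("Ctrl", "Trt"), ds), theta
        ).sigma
        np.testing.assert_allclose(full, joint)

    def test_four_level_reduces_to_three(self):
        design3 = SimulationDesign(n_identifiers=1, seed=5)
        obs3, _ = simulate_dataset(design3)
        obs4 = obs3.assign(peptide="pep1")
        ds3 = read_long_table(obs3, require_positive=False)["sim_0000"]
        ds4 = read_long_table(obs4, require_positive=False)["sim_0000"]
        units3 = ds3.units()
        theta3 = toy_theta(units3, sigma2_f=0.005)
        theta4 = HyperParams(
            lambda1=15.0, lambda2=8.0, lambda3=8.0,
            sigma2_h=0.05, sigma2_g=0.01,
            sigma2_f={(c, "pep1"): 0.0 for c in ds4.conditions},
            sigma2_eta={(c, "pep1", r): 0.005 for c, r in units3},
            beta2=0.002,
        )
        s3 = assemble_covariance(ds3, HierarchySpec(3), theta3).sigma
        s4 = assemble_covariance(ds4, HierarchySpec(4), theta4).sigma
        np.testing.assert_allclose(s3, s4)

    def test_missing_unit_scale_is_validation_error(self, toy_table):
        ds = read_long_table(toy_table)["P0"]
        theta = toy_theta(ds.units()[:-1])
        with pytest.raises(ValidationError):
            assemble_covariance(ds, HierarchySpec(3), theta)


class TestJointStructure:
    def test_two_condition_merge_covers_all(self, toy_table):
        ds = read_long_table(toy_table)["P0"]
        spec = joint_structure(HierarchySpec(3), ("Ctrl", "Trt"), ds)
        cache = DesignCache(ds, spec)
        assert cache.mask_group.all()

    def test_self_merge_rejected(self):
        with pytest.raises(ValidationError):
            joint_structure(HierarchySpec(3), ("Ctrl", "Ctrl"))

    def test_unknown_label_rejected(self, toy_table):
        ds = read_long_table(toy_table)["P0"]
        with pytest.raises(ValidationError):
            joint_structure(HierarchySpec(3), ("Ctrl", "nope"), ds)


class TestGenerativeDraw:
    def test_zero_covariance_gives_zero_vector(self):
        ds = _single_unit_dataset([0.0, 1.0, 2.0])
        theta = HyperParams(
            lambda1=1.0, lambda2=1.0, sigma2_h=0.0, sigma2_g=0.0,
            sigma2_f={("Ctrl", "R1"): 0.0}, beta2=0.0,
        )
        model = assemble_covariance(ds, HierarchySpec(3), theta)
        assert np.all(generative_draw(model, seed=0) == 0.0)

    def test_seed_determinism(self, toy_dataset):
        model = assemble_covariance(
            toy_dataset, HierarchySpec(3), toy_theta(toy_dataset.units())
        )
        a = generative_draw(model, seed=42, size=3)
        b = generative_draw(model, seed=42, size=3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, generative_draw(model, seed=43, size=3))

    def test_monte_carlo_covariance_small(self):
        # 4-dimensional model: sample covariance of draws matches the target
        ds = _single_unit_dataset([0.0, 1.0, 2.0, 3.0])
        theta = HyperParams(
            lambda1=2.0, lambda2=1.0, sigma2_h=0.0, sigma2_g=1.0,
            sigma2_f={("Ctrl", "R1"): 0.5}, beta2=0.1,
        )
        model = assemble_covariance(ds, HierarchySpec(3), theta)
        target = model.full()
        n = 50_000
        draws = generative_draw(model, seed=11, size=n)
        emp = draws.T @ draws / n
        # Monte-Carlo SE of cov(i,j) ~ sqrt((s_ii s_jj + s_ij^2)/n)
        se = np.sqrt(
            (np.outer(np.diag(target), np.diag(target)) + target**2) / n
        )
        assert np.all(np.abs(emp - target) < 3.5 * se)


def test_median_hyperparams_componentwise():
    units = [("Ctrl", "R1")]
    thetas = [
        HyperParams(lambda1=l, lambda2=l / 2, sigma2_h=s, sigma2_g=s,
                    sigma2_f={units[0]: s}, beta2=s / 10)
        for l, s in [(10, 0.1), (20, 0.2), (90, 0.9)]
    ]
    med = median_hyperparams(thetas)
    assert med.lambda1 == 20 and med.sigma2_f[units[0]] == 0.2
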