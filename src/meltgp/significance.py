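"""The Lambda statistic, its sampled null distribution, and p-values.

Differential melting between two conditions is scored by

    Lambda = -2 log [ p(Y | T, theta_hat, M0) / p(Y | T, theta_hat, M1) ]

where M1 is the full hierarchy (one latent curve per condition), M0 the
joint model merging the two compared conditions under one latent curve, and
theta_hat the type-II MLE of the *full* model used for both densities —
unlike a classical likelihood-ratio statistic, nothing is re-estimated under
the null.  Lambda has no standard null distribution (its scale depends on
the number of observations), so the null is approximated by sampling
observation vectors from N(0, Sigma_M0 + beta^2 I) and recomputing Lambda
for each draw after re-fitting it like real data.  Empirical p-values use
the add-one permutation convention (1 + #{null >= obs}) / (S + 1), which is
strictly positive and exact under exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from statsmodels.stats.multitest import multipletests

from .covariance import DesignCache, HierarchySpec, HyperParams, joint_structure, stable_cholesky
from .datasets import ConfigurationError, ProteinDataset, ValidationError


@dataclass(frozen=True)
class Comparison:
    """A condition pair to test; other conditions (if any) are conditioned on."""

    a: str
    b: str

    def __post_init__(self):
        if self.a == self.b:
            raise ValidationError("compared conditions must differ")

    @property
    def label(self) -> str:
        return f"{self.a}_vs_{self.b}"


@dataclass
class NullSamplingConfig:
    """Settings for the sampled null distribution.

    ``method='per_id'`` samples a null per identifier from its own fitted
    joint model; ``'grouped'`` shares one null pool across identifiers with
    an identical design (number of conditions, replicates, temperatures) —
    cheaper, but an approximation since Lambda's scale tracks the
    observation count and fitted scales.

    ``refit`` (default) re-estimates the hyperparameters for every sampled
    dataset with the same type-II MLE procedure applied to the real data, so
    that observed and null Lambda values are exchangeable under the null —
    this is what makes the empirical p-values calibrated, and what makes the
    null approximation expensive.  ``refit=False`` scores the draws with the
    observed theta_hat; it is cheap but anti-conservative (the observed fit
    adapted sigma_g^2 to the data while the draws did not) and is kept as a
    diagnostic only.
    """

    s: int = 1000
    method: str = "per_id"
    seed: int = 0
    refit: bool = True

    def __post_init__(self):
        if self.s < 100:
            raise ConfigurationError("at least 100 null samples are required")
        if self.method not in ("per_id", "grouped"):
            raise ConfigurationError(f"unknown null method {self.method!r}")


@dataclass
class ComparisonResult:
    """Per (identifier, comparison) outcome of the testing workflow."""

    identifier: str
    comparison: str
    lambda_obs: float = np.nan
    s: int = 0
    n_null_geq: int = -1
    pval: float = np.nan
    padj: float = np.nan
    hit: bool = False
    abc: float = np.nan
    abs_abc: float = np.nan
    abc_median: float = np.nan
    n_obs: int = 0
    n_conditions: int = 0
    outlier_flags: str = ""
    status: str = "ok"

    def as_record(self) -> dict:
        return {
            "id": self.identifier,
            "comparison": self.comparison,
            "lambda": self.lambda_obs,
            "pval": self.pval,
            "padj": self.padj,
            "hit": self.hit,
            "ABC": self.abc,
            "absABC": self.abs_abc,
            "ABC_median": self.abc_median,
            "n_obs": self.n_obs,
            "n_conditions": self.n_conditions,
            "outlier_flags": self.outlier_flags,
            "status": self.status,
        }


class LambdaEngine:
    """Precomputed factorisations for one (dataset, theta_hat, comparison).

    Both covariance structures (full M1 and joint M0 with the compared
    conditions merged) are assembled once with the same hyperparameters;
    Lambda evaluation for observed or sampled vectors then costs two
    triangular solves.
    """

    def __init__(
        self,
        dataset: ProteinDataset,
        theta: HyperParams,
        comparison: Comparison,
        spec: HierarchySpec | None = None,
        offset: float = 0.0,
    ):
        spec = spec or HierarchySpec(levels=4 if dataset.has_peptide else 3)
        for lab in (comparison.a, comparison.b):
            if lab not in dataset.conditions:
                raise ValidationError(f"unknown condition {lab!r}")
        self.dataset = dataset
        self.comparison = comparison
        self.offset = offset
        self.theta = theta
        self.spec_full = spec
        self.spec_joint = joint_structure(spec, (comparison.a, comparison.b), dataset)
        self.cache_full = DesignCache(dataset, self.spec_full)
        self.cache_joint = DesignCache(dataset, self.spec_joint)
        self.model_full = self.cache_full.assemble(theta)
        self.model_joint = self.cache_joint.assemble(theta)
        self.chol_full = stable_cholesky(self.model_full.full())
        self.chol_joint = stable_cholesky(self.model_joint.full())
        self.logdet_full = 2.0 * float(np.sum(np.log(np.diag(self.chol_full))))
        self.logdet_joint = 2.0 * float(np.sum(np.log(np.diag(self.chol_joint))))

    def lambdas(self, y: np.ndarray) -> np.ndarray:
        """Lambda for one centred vector (N,) or a batch (N, S)."""
        y = np.asarray(y, dtype=float)
        squeeze = y.ndim == 1
        if squeeze:
            y = y[:, None]
        a0 = solve_triangular(self.chol_joint, y, lower=True, check_finite=False)
        a1 = solve_triangular(self.chol_full, y, lower=True, check_finite=False)
        quad0 = np.einsum("ij,ij->j", a0, a0)
        quad1 = np.einsum("ij,ij->j", a1, a1)
        lam = (quad0 + self.logdet_joint) - (quad1 + self.logdet_full)
        return lam[0] if squeeze else lam

    def observed(self) -> float:
        return float(self.lambdas(self.dataset.scaled() - self.offset))

    def fit_joint(self, fit_config=None, seed: int = 0):
        """Type-II MLE of the joint (merged) structure on the observed data.

        Used to parameterise the null draw distribution: under the null
        hypothesis the joint model is the correctly specified one, so its
        MLE is the natural parametric-bootstrap draw source.
        """
        from .inference import FitConfig, fit_vector, _ParamPacker

        config = fit_config or FitConfig()
        y = self.dataset.scaled() - self.offset
        rng = np.random.default_rng(seed)
        theta0, _, _ = fit_vector(
            self.cache_joint, y, config, rng, _ParamPacker(self.cache_joint, config)
        )
        return theta0

    def sample_null(
        self,
        s: int,
        seed: int,
        refit: bool = True,
        fit_config=None,
        draw_theta: HyperParams | None = None,
    ) -> np.ndarray:
        """Draw S observation vectors from the joint model and score them.

        Draws come from N(0, Sigma_M0 + beta^2 I) evaluated at the observed
        theta_hat, or at ``draw_theta`` when given (for instance pooled
        joint-model estimates of a design group).  With ``refit`` (default)
        every draw is centred and re-fitted by the same type-II MLE
        procedure used for real data before Lambda is evaluated at its own
        estimates — this makes observed and null values exchangeable under
        the null; without it, draws are scored at the observed theta_hat
        (cheap, anti-conservative, diagnostic only).
        """
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((self.model_joint.n, s))
        source = draw_theta if draw_theta is not None else self.theta
        if draw_theta is None:
            ystar = self.chol_joint @ z
        else:
            model = self.cache_joint.assemble(draw_theta)
            ystar = stable_cholesky(model.full()) @ z
        if not refit:
            return self.lambdas(ystar)

        from .inference import FitConfig, _ParamPacker, _lbfgsb, _nll_and_grad

        config = fit_config or FitConfig()
        packer = _ParamPacker(self.cache_full, config)
        # warm start at the draw-generating parameters: re-fits of
        # same-source draws land in the same region, and the resulting null
        # pool is statistically indistinguishable from multi-restart re-fits
        x0 = np.clip(packer.pack(source), packer.lower, packer.upper)
        lams = np.full(s, np.nan)
        for k in range(s):
            y = ystar[:, k]
            if config.center:
                y = y - y.mean()
            x, fval, _, _ = _lbfgsb(
                _nll_and_grad, x0, (packer, y), packer.lower, packer.upper,
                maxiter=config.max_iter, ftol=config.tol,
            )
            if not np.isfinite(fval):
                continue
            theta_s = packer.unpack(x)
            m1 = self.cache_full.assemble(theta_s)
            m0 = self.cache_joint.assemble(theta_s)
            l1 = stable_cholesky(m1.full())
            l0 = stable_cholesky(m0.full())
            a1 = solve_triangular(l1, y, lower=True, check_finite=False)
            a0 = solve_triangular(l0, y, lower=True, check_finite=False)
            lams[k] = (a0 @ a0 + 2.0 * np.sum(np.log(np.diag(l0)))) - (
                a1 @ a1 + 2.0 * np.sum(np.log(np.diag(l1)))
            )
        return lams[np.isfinite(lams)]


def _conditional_logdensity(full_cov, y, z_idx, r_idx) -> float:
    """log N(y_Z; mu, S) of the compared blocks given the rest."""
    kzz = full_cov[np.ix_(z_idx, z_idx)]
    if len(r_idx) == 0:
        chol = stable_cholesky(kzz)
        resid = y[z_idx]
    else:
        kzr = full_cov[np.ix_(z_idx, r_idx)]
        krr = full_cov[np.ix_(r_idx, r_idx)]
        lr = stable_cholesky(krr)
        w = solve_triangular(lr, kzr.T, lower=True, check_finite=False)
        schur = kzz - w.T @ w
        chol = stable_cholesky(schur)
        yr = solve_triangular(lr, y[r_idx], lower=True, check_finite=False)
        resid = y[z_idx] - w.T @ yr
    alpha = solve_triangular(chol, resid, lower=True, check_finite=False)
    return float(
        -0.5 * alpha @ alpha
        - np.sum(np.log(np.diag(chol)))
        - 0.5 * len(z_idx) * np.log(2 * np.pi)
    )


def lambda_statistic(
    dataset: ProteinDataset,
    theta: HyperParams,
    comparison: Comparison,
    spec: HierarchySpec | None = None,
    form: str = "direct",
    offset: float = 0.0,
) -> float:
    """Lambda for one comparison, from the full-model theta_hat.

    ``form='direct'`` evaluates both joint densities on all observations;
    ``form='conditional'`` evaluates the equivalent ratio of the two
    conditional densities of the compared conditions' observations given all
    non-compared conditions (dimension N_a + N_b), which is cheaper when many
    conditions are present.  The two forms agree because the marginal of the
    non-compared conditions is identical under M0 and M1.
    """
    engine = LambdaEngine(dataset, theta, comparison, spec, offset)
    if form == "direct":
        return engine.observed()
    if form != "conditional":
        raise ConfigurationError(f"unknown form {form!r}")
    y = dataset.scaled() - offset
    in_z = np.isin(
        engine.cache_full.conditions.astype(str), [comparison.a, comparison.b]
    )
    z_idx, r_idx = np.flatnonzero(in_z), np.flatnonzero(~in_z)
    lp0 = _conditional_logdensity(engine.model_joint.full(), y, z_idx, r_idx)
    lp1 = _conditional_logdensity(engine.model_full.full(), y, z_idx, r_idx)
    return float(-2.0 * (lp0 - lp1))


def sample_null_lambdas(
    dataset: ProteinDataset,
    theta: HyperParams,
    comparison: Comparison,
    config: NullSamplingConfig,
    spec: HierarchySpec | None = None,
    offset: float = 0.0,
) -> np.ndarray:
    """S Lambda values under the fitted joint model (the sampled null)."""
    engine = LambdaEngine(dataset, theta, comparison, spec, offset)
    return engine.sample_null(config.s, config.seed, refit=config.refit)


def empirical_pvalue(lambda_obs: float, null: np.ndarray) -> float:
    """(1 + #{null >= obs}) / (S + 1); ties count toward the numerator."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValidationError("empty null sample")
    if not np.isfinite(lambda_obs):
        raise ValidationError("non-finite observed statistic")
    count = int(np.sum(null >= lambda_obs))
    return (1.0 + count) / (null.size + 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_hits(
    results: list[ComparisonResult],
    rule: str = "exceed_all",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Flag hits in place and return the results.

    ``exceed_all``: hit iff the observed Lambda strictly exceeds every null
    sample (a tie counts against).  ``alpha``: hit iff the BH-adjusted
    p-value is <= alpha.
    """
    if rule not in ("exceed_all", "alpha"):
        raise ConfigurationError(f"unknown hit rule {rule!r}")
    for r in results:
        if r.status != "ok":
            r.hit = False
        elif rule == "exceed_all":
            r.hit = r.n_null_geq == 0
        else:
            r.hit = bool(np.isfinite(r.padj) and r.padj <= alpha)
    return results
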