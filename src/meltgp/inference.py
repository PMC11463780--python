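"""Marginal likelihood, type-II MLE fitting and posterior prediction.

The hierarchical GP marginalises to Y ~ N(0, Sigma(theta) + beta^2 I), so the
log marginal likelihood is an ordinary multivariate-normal log density and
hyperparameters are fitted by maximising it (type-II maximum likelihood /
empirical Bayes).  Optimisation runs on log-transformed parameters with
analytic gradients (L-BFGS-B, multiple seeded restarts); the marginal
covariance is linear in every output-scale, which keeps the gradient cheap.

Because the prior mean is fixed at zero while mean-scaled abundances sit near
one, observations are centred by subtracting the per-identifier global mean
before fitting; the offset is restored for prediction and effect sizes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_solve, lapack, solve_triangular

from .covariance import (
    CovarianceModel,
    DesignCache,
    HierarchySpec,
    HyperParams,
    NumericError,
    rbf_correlation,
    stable_cholesky,
)
from .datasets import ProteinDataset, ValidationError

LOG2PI = float(np.log(2.0 * np.pi))


class FitFailure(RuntimeError):
    """All optimizer restarts diverged for an identifier."""


def derive_seed(seed: int, identifier: str) -> int:
    """Stable per-identifier seed: parallel execution order cannot matter."""
    return (int(seed) ^ zlib.crc32(identifier.encode("utf-8"))) & 0x7FFFFFFF


def log_marginal_likelihood(y: np.ndarray, model: CovarianceModel) -> float:
    """log N(y; 0, Sigma + beta^2 I) via a stabilised Cholesky factorisation."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != model.n:
        raise ValidationError(
            f"dimension mismatch: y has {y.shape[0]}, covariance {model.n}"
        )
    chol = model.cholesky()
    alpha = solve_triangular(chol, y, lower=True, check_finite=False)
    return float(
        -0.5 * alpha @ alpha
        - np.sum(np.log(np.diag(chol)))
        - 0.5 * y.shape[0] * LOG2PI
    )


@dataclass
class FitConfig:
    """Optimiser settings for type-II MLE."""

    restarts: int = 3
    max_iter: int = 1000
    tol: float = 1e-8
    center: bool = True
    lengthscale_bounds: tuple[float, float] | None = None  # auto from data
    beta2_min: float = 1e-6
    # output-scales are bounded below at exp(-7) ~ 9e-4 (squared scaled-
    # abundance units): an unconstrained fit can collapse sigma_g^2 to zero
    # on null-like data, which makes the test statistic degenerate at
    # machine scale and its sampled null ill-ordered; a small positive
    # floor keeps Lambda continuous without touching real signal scales
    log_sigma2_bounds: tuple[float, float] = (-7.0, 8.0)


@dataclass
class FitResult:
    """Fitted hyperparameters and optimiser diagnostics for one identifier."""

    identifier: str
    theta: HyperParams
    log_marginal_likelihood: float
    offset: float
    converged: bool
    n_iter: int
    restart_index: int
    seed: int
    cache: DesignCache = field(repr=False, default=None)

    @property
    def spec(self) -> HierarchySpec:
        return self.cache.spec


class _ParamPacker:
    """Map HyperParams <-> flat log-parameter vector for one design.

    With a single condition the protein- and condition-level kernels are
    identical (same lengthscale, both applying to every pair), so sigma_h^2
    is not identifiable and is pinned to zero.
    """

    def __init__(self, cache: DesignCache, config: FitConfig):
        self.cache = cache
        self.config = config
        self.levels = cache.spec.levels
        self.fix_sigma_h = len(cache.dataset.conditions) < 2
        self.third_keys = cache.third_level_keys()
        self.eta_keys = cache.units if self.levels == 4 else []

        t = np.unique(cache.t)
        if config.lengthscale_bounds is not None:
            lo, hi = config.lengthscale_bounds
        else:
            spacing = np.diff(t)
            lo = float(spacing.min()) if len(spacing) else 1.0
            hi = 4.0 * float(t.max() - t.min()) if len(t) > 1 else 100.0
        self.ls_bounds = (max(lo, 1e-3), max(hi, 2 * max(lo, 1e-3)))

        names: list[str] = ["lambda1", "lambda2"]
        if self.levels == 4:
            names.append("lambda3")
        if not self.fix_sigma_h:
            names.append("sigma2_h")
        names.append("sigma2_g")
        names += [f"f{i}" for i in range(len(self.third_keys))]
        names += [f"e{i}" for i in range(len(self.eta_keys))]
        names.append("beta2")
        self.names = names

        self.i_sh = None if self.fix_sigma_h else names.index("sigma2_h")
        self.i_sg = names.index("sigma2_g")
        f0 = self.i_sg + 1
        self.f_slice = slice(f0, f0 + len(self.third_keys))
        self.fast3 = self.levels == 3 and all(
            s is not None for s in cache.unit_slices
        )
        bnds = self.bounds()
        self.lower = np.array([b[0] for b in bnds])
        self.upper = np.array([b[1] for b in bnds])

    @property
    def n_params(self) -> int:
        return len(self.names)

    def bounds(self) -> list[tuple[float, float]]:
        lb, ub = np.log(self.ls_bounds[0]), np.log(self.ls_bounds[1])
        s_lo, s_hi = self.config.log_sigma2_bounds
        out = []
        for name in self.names:
            if name.startswith("lambda"):
                out.append((lb, ub))
            elif name == "beta2":
                out.append((max(np.log(self.config.beta2_min), s_lo), s_hi))
            else:
                out.append((s_lo, s_hi))
        return out

    def unpack(self, x: np.ndarray) -> HyperParams:
        vals = dict(zip(self.names, np.exp(x)))
        nf = len(self.third_keys)
        f_vals = [vals[f"f{i}"] for i in range(nf)]
        kwargs = dict(
            lambda1=vals["lambda1"],
            lambda2=vals["lambda2"],
            sigma2_h=0.0 if self.fix_sigma_h else vals["sigma2_h"],
            sigma2_g=vals["sigma2_g"],
            sigma2_f=dict(zip(self.third_keys, f_vals)),
            beta2=vals["beta2"],
        )
        if self.levels == 4:
            kwargs["lambda3"] = vals["lambda3"]
            kwargs["sigma2_eta"] = {
                k: vals[f"e{i}"] for i, k in enumerate(self.eta_keys)
            }
        return HyperParams(**kwargs)

    def pack(self, theta: HyperParams) -> np.ndarray:
        vals = {
            "lambda1": theta.lambda1,
            "lambda2": theta.lambda2,
            "sigma2_g": theta.sigma2_g,
            "beta2": theta.beta2,
        }
        if not self.fix_sigma_h:
            vals["sigma2_h"] = theta.sigma2_h
        if self.levels == 4:
            vals["lambda3"] = theta.lambda3
            for i, k in enumerate(self.eta_keys):
                vals[f"e{i}"] = theta.sigma2_eta[k]
        for i, k in enumerate(self.third_keys):
            vals[f"f{i}"] = theta.sigma2_f[k]
        return np.log(np.maximum([vals[n] for n in self.names], 1e-300))

    def initial(self, rng: np.random.Generator, y_var: float) -> np.ndarray:
        lo, hi = np.log(self.ls_bounds)
        scale = max(y_var, 1e-8)
        x = []
        for name in self.names:
            if name.startswith("lambda"):
                x.append(rng.uniform(lo, hi))
            elif name == "beta2":
                x.append(np.log(0.1 * scale) + rng.uniform(-1.0, 1.0))
            else:
                # output-scales log-uniform in [1e-2, 1] x data variance
                x.append(np.log(scale) + rng.uniform(np.log(1e-2), 0.0))
        return np.array(x)


_EPSMCH = np.finfo(float).eps


def _lbfgsb(fun, x0, args, lower, upper, maxiter=1000, ftol=1e-8, pgtol=1e-5,
            maxls=20, m=10):
    """Minimal L-BFGS-B driver around scipy's low-level routine.

    Null-distribution approximation runs hundreds of thousands of small
    re-fits; this strips the per-call overhead of the generic optimizer
    front-end while using the identical underlying algorithm.  Returns
    (x, f, n_iterations, converged).
    """
    from scipy.optimize import _lbfgsb as _lb

    n = len(x0)
    x = np.clip(np.asarray(x0, dtype=float), lower, upper)
    nbd = np.full(n, 2, dtype=np.int32)  # all parameters two-sided bounded
    f = np.array(0.0)
    g = np.zeros(n)
    wa = np.zeros(2 * m * n + 5 * n + 11 * m * m + 8 * m)
    iwa = np.zeros(3 * n, dtype=np.int32)
    task = np.zeros(2, dtype=np.int32)
    ln_task = np.zeros(2, dtype=np.int32)
    lsave = np.zeros(4, dtype=np.int32)
    isave = np.zeros(44, dtype=np.int32)
    dsave = np.zeros(29)
    factr = ftol / _EPSMCH
    nit = 0
    while True:
        _lb.setulb(m, x, lower, upper, nbd, f, g, factr, pgtol, wa, iwa,
                   task, lsave, isave, dsave, maxls, ln_task)
        if task[0] == 3:  # evaluate f and g
            fval, gval = fun(x, *args)
            f = np.array(fval)
            g = np.asarray(gval)
        elif task[0] == 1:  # new iterate
            nit += 1
            if nit >= maxiter:
                task[0] = 5
                task[1] = 504
        else:
            break
    return x, float(f), nit, bool(task[0] == 4)


def _nll_and_grad_fast3(x: np.ndarray, packer: _ParamPacker, y: np.ndarray):
    """Fused objective for three-level designs with contiguous unit blocks.

    Identical mathematics to the general path, written with direct LAPACK
    calls and block slicing because null-distribution approximation re-fits
    this objective hundreds of thousands of times.
    """
    cache = packer.cache
    ex = np.exp(x)
    l1, l2 = ex[0], ex[1]
    sh = ex[packer.i_sh] if packer.i_sh is not None else 0.0
    sg = ex[packer.i_sg]
    f = ex[packer.f_slice]
    b2 = ex[-1]
    n = cache.n

    k1 = np.exp(cache.nhd2 / (l1 * l1))
    k2 = np.exp(cache.nhd2 / (l2 * l2))
    idx_top = sh + sg * cache.mask_groupf
    vobs = f[cache.unit_code]
    kmat = idx_top * k1 + (cache.mask_unitf * vobs[:, None]) * k2
    diag = np.einsum("ii->i", kmat)
    diag += b2

    scale = float(diag.mean())
    chol, info = lapack.dpotrf(kmat, lower=1, overwrite_a=0, clean=0)
    if info != 0:
        for expo in (-6, -5, -4, -3):
            chol, info = lapack.dpotrf(
                kmat + 10.0**expo * scale * np.eye(n), lower=1, clean=0
            )
            if info == 0:
                break
        else:
            return np.inf, np.zeros_like(x)

    alpha, info = lapack.dtrtrs(chol, y, lower=1, trans=0)
    if info != 0:
        return np.inf, np.zeros_like(x)
    cdiag = np.einsum("ii->i", chol)
    nll = float(0.5 * alpha @ alpha + np.sum(np.log(cdiag)) + 0.5 * n * LOG2PI)
    if not np.isfinite(nll):
        return np.inf, np.zeros_like(x)

    a2, info = lapack.dtrtrs(chol, alpha, lower=1, trans=1)  # K^{-1} y
    kinv, info = lapack.dpotri(chol, lower=1)
    kinv = np.tril(kinv) + np.tril(kinv, -1).T
    w = np.outer(a2, a2) - kinv  # dL/dtheta = 0.5 tr(W dK/dtheta)

    wk1 = w * k1
    wk2 = w * k2
    grad = np.empty_like(x)
    grad[0] = ((wk1 * idx_top) * cache.d2).sum() / (l1 * l1)
    if packer.i_sh is not None:
        grad[packer.i_sh] = sh * wk1.sum()
    grad[packer.i_sg] = sg * (wk1 * cache.mask_groupf).sum()
    lam2_acc = 0.0
    for i, (s0, s1) in enumerate(cache.unit_slices):
        block = wk2[s0:s1, s0:s1]
        grad[packer.f_slice.start + i] = f[i] * block.sum()
        lam2_acc += f[i] * (block * cache.d2[s0:s1, s0:s1]).sum()
    grad[1] = lam2_acc / (l2 * l2)
    grad[-1] = b2 * np.trace(w)
    return nll, -0.5 * grad


def _nll_and_grad(x: np.ndarray, packer: _ParamPacker, y: np.ndarray):
    if packer.fast3:
        return _nll_and_grad_fast3(x, packer, y)
    return _nll_and_grad_general(x, packer, y)


def _nll_and_grad_general(x: np.ndarray, packer: _ParamPacker, y: np.ndarray):
    cache = packer.cache
    theta = packer.unpack(x)
    model = cache.assemble(theta)
    full = model.full()
    try:
        chol = stable_cholesky(full)
    except NumericError:
        return np.inf, np.zeros_like(x)
    alpha = solve_triangular(chol, y, lower=True, check_finite=False)
    nll = float(
        0.5 * alpha @ alpha + np.sum(np.log(np.diag(chol))) + 0.5 * len(y) * LOG2PI
    )
    if not np.isfinite(nll):
        return np.inf, np.zeros_like(x)

    kinv = cho_solve((chol, True), np.eye(len(y)), check_finite=False)
    a = cho_solve((chol, True), y, check_finite=False)
    w = np.outer(a, a) - kinv  # dL/dtheta = 0.5 tr(W dK/dtheta)

    d2 = cache.d2
    k1 = np.exp(-d2 / (2.0 * theta.lambda1**2))
    idx_top = theta.sigma2_h + theta.sigma2_g * cache.mask_group

    grad = {}
    wk1 = w * k1
    if not packer.fix_sigma_h:
        grad["sigma2_h"] = theta.sigma2_h * wk1.sum()
    grad["sigma2_g"] = theta.sigma2_g * (wk1 * cache.mask_group).sum()
    grad["lambda1"] = ((w * (idx_top * k1) * d2).sum()) / theta.lambda1**2
    grad["beta2"] = theta.beta2 * np.trace(w)

    if packer.levels == 3:
        k2 = np.exp(-d2 / (2.0 * theta.lambda2**2))
        wk2 = w * k2
        lam2_acc = 0.0
        for i, key in enumerate(packer.third_keys):
            idx = cache.unit_indices[key]
            s2 = theta.sigma2_f[key]
            block = wk2[np.ix_(idx, idx)]
            grad[f"f{i}"] = s2 * block.sum()
            lam2_acc += s2 * (block * d2[np.ix_(idx, idx)]).sum()
        grad["lambda2"] = lam2_acc / theta.lambda2**2
    else:
        k2 = np.exp(-d2 / (2.0 * theta.lambda2**2))
        k3 = np.exp(-d2 / (2.0 * theta.lambda3**2))
        wk2, wk3 = w * k2, w * k3
        lam2_acc = 0.0
        for i, key in enumerate(packer.third_keys):
            idx = cache.pep_indices[key]
            s2 = theta.sigma2_f[key]
            block = wk2[np.ix_(idx, idx)]
            grad[f"f{i}"] = s2 * block.sum()
            lam2_acc += s2 * (block * d2[np.ix_(idx, idx)]).sum()
        grad["lambda2"] = lam2_acc / theta.lambda2**2
        lam3_acc = 0.0
        for i, key in enumerate(packer.eta_keys):
            idx = cache.unit_indices[key]
            s2 = theta.sigma2_eta[key]
            block = wk3[np.ix_(idx, idx)]
            grad[f"e{i}"] = s2 * block.sum()
            lam3_acc += s2 * (block * d2[np.ix_(idx, idx)]).sum()
        grad["lambda3"] = lam3_acc / theta.lambda3**2

    g = -0.5 * np.array([grad[n] for n in packer.names])
    return nll, g


def fit_vector(
    cache: DesignCache,
    y: np.ndarray,
    config: FitConfig,
    rng: np.random.Generator,
    packer: _ParamPacker | None = None,
):
    """Fit the hierarchy to one centred observation vector.

    The workhorse behind :func:`fit_type2_mle`, reused to re-estimate
    hyperparameters for sampled null datasets with the identical procedure.
    Returns (theta, scipy result, restart index) of the best restart or
    raises :class:`FitFailure`.
    """
    packer = packer or _ParamPacker(cache, config)
    y_var = float(np.var(y)) or 1e-6
    best = None
    for restart in range(config.restarts):
        x0 = packer.initial(rng, y_var)
        try:
            x, fval, nit, converged = _lbfgsb(
                _nll_and_grad, x0, (packer, y), packer.lower, packer.upper,
                maxiter=config.max_iter, ftol=config.tol,
            )
        except (NumericError, np.linalg.LinAlgError):
            continue
        if not np.isfinite(fval):
            continue
        if best is None or fval < best[1]:
            best = (x, fval, nit, converged, restart)
    if best is None:
        raise FitFailure("all restarts diverged")
    x, fval, nit, converged, restart = best
    info = {"fun": fval, "nit": nit, "success": converged}
    return packer.unpack(x), info, restart


def fit_type2_mle(
    dataset: ProteinDataset,
    spec: HierarchySpec | None = None,
    config: FitConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit the full hierarchical model M1 by type-II maximum likelihood.

    Runs ``config.restarts`` seeded restarts of L-BFGS-B on log-parameters
    and returns the best; deterministic for fixed (seed, config).  Raises
    :class:`FitFailure` if every restart diverges.
    """
    spec = spec or HierarchySpec(levels=4 if dataset.has_peptide else 3)
    if spec.is_joint:
        raise ValidationError("fit the full model M1; joint models reuse its theta")
    config = config or FitConfig()
    cache = DesignCache(dataset, spec)
    y_raw = dataset.scaled()
    offset = float(np.mean(y_raw)) if config.center else 0.0
    y = y_raw - offset

    rng = np.random.default_rng(derive_seed(seed, dataset.identifier))
    try:
        theta, info, restart = fit_vector(cache, y, config, rng)
    except FitFailure as err:
        raise FitFailure(f"{dataset.identifier}: {err}") from err
    return FitResult(
        identifier=dataset.identifier,
        theta=theta,
        log_marginal_likelihood=float(-info["fun"]),
        offset=offset,
        converged=bool(info["success"]),
        n_iter=int(info["nit"]),
        restart_index=restart,
        seed=seed,
        cache=cache,
    )


@dataclass
class PosteriorCurve:
    """Posterior predictive mean and variance of one latent level on a grid."""

    level: tuple
    grid: np.ndarray
    mean: np.ndarray
    variance: np.ndarray


def _cross_and_prior(
    cache: DesignCache, theta: HyperParams, level: tuple, grid: np.ndarray
):
    """Cross-covariance cov(level(grid), Y) and prior cov at the grid."""
    spec = cache.spec
    t = cache.t
    k1x = theta.sigma2_h * rbf_correlation(grid, t, theta.lambda1)
    k1g = theta.sigma2_h * rbf_correlation(grid, grid, theta.lambda1)

    kind = level[0]
    if kind == "h":
        return k1x, k1g

    cond = level[1]
    if spec.merged_conditions and cond in spec.merged_conditions:
        group = spec.merged_conditions
    else:
        group = {cond}
    in_group = np.array([c in group for c in cache.conditions])
    kg = rbf_correlation(grid, t, theta.lambda1) * in_group[None, :]
    cross = k1x + theta.sigma2_g * kg
    prior = k1g + theta.sigma2_g * rbf_correlation(grid, grid, theta.lambda1)
    if kind == "g":
        return cross, prior

    if spec.levels == 3:
        if kind != "f":
            raise ValidationError(f"unknown level {level!r}")
        unit = tuple(level[1:])
        if unit not in theta.sigma2_f:
            raise ValidationError(f"unknown replicate unit {unit!r}")
        sel = np.zeros(cache.n, dtype=bool)
        sel[cache.unit_indices[unit]] = True
        k2 = rbf_correlation(grid, t, theta.lambda2) * sel[None, :]
        cross = cross + theta.sigma2_f[unit] * k2
        prior = prior + theta.sigma2_f[unit] * rbf_correlation(
            grid, grid, theta.lambda2
        )
        return cross, prior

    # four-level: peptide ("f", c, peptide) then replicate ("eta", c, pep, r)
    pep_unit = tuple(level[1:3])
    if pep_unit not in theta.sigma2_f:
        raise ValidationError(f"unknown peptide unit {pep_unit!r}")
    sel = np.zeros(cache.n, dtype=bool)
    sel[cache.pep_indices[pep_unit]] = True
    k2 = rbf_correlation(grid, t, theta.lambda2) * sel[None, :]
    cross = cross + theta.sigma2_f[pep_unit] * k2
    prior = prior + theta.sigma2_f[pep_unit] * rbf_correlation(
        grid, grid, theta.lambda2
    )
    if kind == "f":
        return cross, prior
    if kind != "eta":
        raise ValidationError(f"unknown level {level!r}")
    unit = tuple(level[1:])
    sel = np.zeros(cache.n, dtype=bool)
    sel[cache.unit_indices[unit]] = True
    k3 = rbf_correlation(grid, t, theta.lambda3) * sel[None, :]
    cross = cross + theta.sigma2_eta[unit] * k3
    prior = prior + theta.sigma2_eta[unit] * rbf_correlation(
        grid, grid, theta.lambda3
    )
    return cross, prior


def posterior_predict(
    dataset: ProteinDataset,
    spec: HierarchySpec,
    theta: HyperParams,
    level: tuple | str,
    grid: np.ndarray,
    offset: float = 0.0,
) -> PosteriorCurve:
    """GP posterior of a latent level given all observations of the dataset.

    ``level`` selects the latent function: ``"h"`` (protein trend),
    ``("g", condition)``, ``("f", condition, replicate)`` (three-level) or
    ``("f", condition, peptide)`` / ``("eta", condition, peptide, replicate)``
    (four-level).  ``offset`` restores the centring applied before fitting.
    """
    if isinstance(level, str):
        level = (level,)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or (len(grid) > 1 and np.any(np.diff(grid) <= 0)):
        raise ValidationError("prediction grid must be strictly increasing")
    cache = DesignCache(dataset, spec)
    model = cache.assemble(theta)
    y = dataset.scaled() - offset

    cross, prior = _cross_and_prior(cache, theta, tuple(level), grid)
    chol = stable_cholesky(model.full())
    alpha = cho_solve((chol, True), y, check_finite=False)
    mean = cross @ alpha + offset
    v = solve_triangular(chol, cross.T, lower=True, check_finite=False)
    variance = np.clip(np.diag(prior) - np.einsum("ij,ij->j", v, v), 0.0, None)
    return PosteriorCurve(level=tuple(level), grid=grid, mean=mean, variance=variance)
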