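"""Hierarchical GP covariance assembly for melting-curve models.

The hierarchical model places a zero-mean GP prior on a protein-level trend
``h``, condition-level trends ``g_c`` centred on ``h``, and replicate-level
curves ``f_cr`` centred on their condition's ``g_c`` (three levels); the
peptide-level variant inserts peptide curves ``f_cpi`` between condition and
replicate (four levels).  All kernels are RBF; ``h`` and ``g`` share a
lengthscale ``lambda1``, the lower levels use ``lambda2`` (and ``lambda3``
for the four-level replicates).  Marginalising the latent functions, the
observations of one identifier are jointly Gaussian:

    Y ~ N(0, Sigma + beta^2 I)

with, in the three-level model,

    Sigma[(c,r,t),(c',r',t')] = sigma_h^2 k(t,t'|l1)
                              + 1[same g-group] sigma_g^2 k(t,t'|l1)
                              + 1[c=c', r=r'] sigma_fcr^2 k(t,t'|l2)

where "same g-group" is c = c' in the full model M1, or membership of both
conditions in the merged set for a joint model M0 (the null structure used
for testing).  On a synchronous temperature grid this is a Kronecker product
of a per-level index kernel with an RBF correlation matrix; the dense
elementwise construction below is the definition and also covers
asynchronous designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.linalg import cholesky

from .datasets import ProteinDataset, ValidationError


class ParameterError(ValueError):
    """Invalid kernel or hierarchy parameter."""


class NumericError(RuntimeError):
    """Covariance not positive definite even after jitter escalation."""


def rbf_correlation(t, t_prime, lengthscale: float):
    """RBF correlation exp(-|t - t'|^2 / (2 lambda^2)); equals 1 at t = t'."""
    if lengthscale <= 0:
        raise ParameterError(f"lengthscale must be > 0, got {lengthscale}")
    t = np.asarray(t, dtype=float)
    t_prime = np.asarray(t_prime, dtype=float)
    d2 = np.subtract.outer(t, t_prime) ** 2 if t.ndim else (t - t_prime) ** 2
    return np.exp(-d2 / (2.0 * lengthscale**2))


@dataclass(frozen=True)
class HierarchySpec:
    """Declarative description of the model hierarchy.

    ``levels`` is 3 (protein -> condition -> replicate) or 4 (protein ->
    condition -> peptide -> replicate).  ``merged_conditions`` — when set —
    makes the listed conditions share one condition-level latent curve (the
    joint model M0); all other conditions keep their own, exactly as in the
    full model M1.
    """

    levels: int = 3
    merged_conditions: frozenset | None = None

    def __post_init__(self):
        if self.levels not in (3, 4):
            raise ParameterError("levels must be 3 or 4")
        if self.merged_conditions is not None:
            object.__setattr__(
                self, "merged_conditions", frozenset(self.merged_conditions)
            )
            if len(self.merged_conditions) < 2:
                raise ParameterError("merged_conditions needs >= 2 members")

    @property
    def is_joint(self) -> bool:
        return self.merged_conditions is not None


def joint_structure(
    spec: HierarchySpec,
    compare: tuple[str, str],
    dataset: ProteinDataset | None = None,
) -> HierarchySpec:
    """Return the joint-model structure merging the two compared conditions.

    Hyperparameters are *not* re-estimated for the joint model: the same
    fitted values are plugged into the merged structure, only the
    condition-level grouping changes.
    """
    a, b = compare
    if a == b:
        raise ValidationError(f"cannot merge condition {a!r} with itself")
    if dataset is not None:
        known = set(dataset.conditions)
        for lab in (a, b):
            if lab not in known:
                raise ValidationError(f"unknown condition {lab!r}")
    return replace(spec, merged_conditions=frozenset((a, b)))


@dataclass
class HyperParams:
    """Hyperparameters theta of the hierarchical model.

    ``sigma2_f`` maps each third-level unit to its output-scale: keyed by
    (condition, replicate) in the three-level model, by (condition, peptide)
    in the four-level model where ``sigma2_eta`` additionally maps
    (condition, peptide, replicate) to the replicate-level output-scale.
    Lengthscales are in degC; output-scales and ``beta2`` (i.i.d. noise
    variance) in squared scaled-abundance units.
    """

    lambda1: float
    lambda2: float
    sigma2_h: float
    sigma2_g: float
    sigma2_f: dict
    beta2: float
    lambda3: float | None = None
    sigma2_eta: dict | None = None

    def validate(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ParameterError("lengthscales must be positive")
        if min(self.sigma2_h, self.sigma2_g, self.beta2) < 0:
            raise ParameterError("variances must be non-negative")
        if any(v < 0 for v in self.sigma2_f.values()):
            raise ParameterError("sigma2_f entries must be non-negative")
        if self.sigma2_eta is not None:
            if self.lambda3 is None or self.lambda3 <= 0:
                raise ParameterError("four-level model requires lambda3 > 0")
            if any(v < 0 for v in self.sigma2_eta.values()):
                raise ParameterError("sigma2_eta entries must be non-negative")


def median_hyperparams(thetas: list[HyperParams]) -> HyperParams:
    """Component-wise median of hyperparameter sets sharing one design.

    Robust pooling across identifiers with identical designs: per-identifier
    type-II MLEs are individually noisy (lengthscales can run to their
    bounds), but their medians track the design's typical scales.
    """
    if not thetas:
        raise ParameterError("no hyperparameter sets to pool")
    keys = list(thetas[0].sigma2_f)
    med = lambda vals: float(np.median(vals))
    kwargs = dict(
        lambda1=med([t.lambda1 for t in thetas]),
        lambda2=med([t.lambda2 for t in thetas]),
        sigma2_h=med([t.sigma2_h for t in thetas]),
        sigma2_g=med([t.sigma2_g for t in thetas]),
        sigma2_f={k: med([t.sigma2_f[k] for t in thetas]) for k in keys},
        beta2=med([t.beta2 for t in thetas]),
    )
    if thetas[0].sigma2_eta is not None:
        eta_keys = list(thetas[0].sigma2_eta)
        kwargs["lambda3"] = med([t.lambda3 for t in thetas])
        kwargs["sigma2_eta"] = {
            k: med([t.sigma2_eta[k] for t in thetas]) for k in eta_keys
        }
    return HyperParams(**kwargs)


def pooled_hyperparams(thetas: list[HyperParams]) -> HyperParams:
    """Pool hyperparameter sets sharing one design for a draw distribution.

    Variance components are pooled by the component-wise mean — their
    per-identifier MLE distributions are strongly right-skewed, so the
    median underestimates them badly, while the mean is nearly unbiased.
    Lengthscales are pooled by the median, which resists the minority of
    fits that run to a bound.
    """
    if not thetas:
        raise ParameterError("no hyperparameter sets to pool")
    keys = list(thetas[0].sigma2_f)
    med = lambda vals: float(np.median(vals))
    avg = lambda vals: float(np.mean(vals))
    kwargs = dict(
        lambda1=med([t.lambda1 for t in thetas]),
        lambda2=med([t.lambda2 for t in thetas]),
        sigma2_h=avg([t.sigma2_h for t in thetas]),
        sigma2_g=avg([t.sigma2_g for t in thetas]),
        sigma2_f={k: avg([t.sigma2_f[k] for t in thetas]) for k in keys},
        beta2=avg([t.beta2 for t in thetas]),
    )
    if thetas[0].sigma2_eta is not None:
        eta_keys = list(thetas[0].sigma2_eta)
        kwargs["lambda3"] = med([t.lambda3 for t in thetas])
        kwargs["sigma2_eta"] = {
            k: avg([t.sigma2_eta[k] for t in thetas]) for k in eta_keys
        }
    return HyperParams(**kwargs)


@dataclass
class CovarianceModel:
    """Assembled prior covariance Sigma (N x N) plus the noise variance.

    ``index_terms`` records the multi-task decomposition: pairs of
    (index-kernel matrix K^y, RBF correlation matrix K^{t,lambda}) whose
    elementwise products sum to Sigma.
    """

    sigma: np.ndarray
    beta2: float
    index_terms: list = field(default_factory=list, repr=False)

    @property
    def n(self) -> int:
        return self.sigma.shape[0]

    def full(self) -> np.ndarray:
        """Sigma + beta^2 I — the marginal covariance of the observations."""
        return self.sigma + self.beta2 * np.eye(self.n)

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor of Sigma + beta^2 I with escalating jitter."""
        return stable_cholesky(self.full())


def stable_cholesky(mat: np.ndarray) -> np.ndarray:
    """Lower Cholesky with jitter 1e-6 x mean(diag), escalating x10 to 1e-3."""
    scale = float(np.mean(np.diag(mat)))
    if scale <= 0:
        scale = 1.0
    jitter = 0.0
    for exponent in (None, -6, -5, -4, -3):
        if exponent is not None:
            jitter = 10.0**exponent * scale
        try:
            return cholesky(
                mat + jitter * np.eye(mat.shape[0]), lower=True, check_finite=False
            )
        except np.linalg.LinAlgError:
            continue
        except Exception:
            continue
    raise NumericError("covariance not positive definite after jitter escalation")


class DesignCache:
    """Precomputed masks and distances for one dataset + hierarchy.

    Assembling Sigma(theta) during optimisation only requires elementwise
    products of cached masks with freshly evaluated RBF matrices, so the
    cache is built once per identifier.
    """

    def __init__(self, dataset: ProteinDataset, spec: HierarchySpec):
        if spec.levels == 4 and not dataset.has_peptide:
            raise ValidationError("four-level hierarchy requires peptide labels")
        self.dataset = dataset
        self.spec = spec
        tab = dataset.table
        self.t = tab["temperature"].to_numpy(dtype=float)
        self.d2 = np.subtract.outer(self.t, self.t) ** 2
        self.conditions = np.asarray(tab["condition"], dtype=object)
        self.n = len(self.t)

        cond = self.conditions
        if spec.merged_conditions:
            missing = spec.merged_conditions - set(dataset.conditions)
            if missing:
                raise ValidationError(
                    f"merged conditions not in dataset: {sorted(missing)}"
                )
            group = np.array(
                [c if c not in spec.merged_conditions else "\0merged" for c in cond],
                dtype=object,
            )
        else:
            group = cond
        self.mask_group = np.equal.outer(group, group)

        self.units = dataset.units()
        unit_keys = (
            ["condition", "peptide", "replicate"]
            if dataset.has_peptide
            else ["condition", "replicate"]
        )
        obs_units = list(tab[unit_keys].itertuples(index=False, name=None))
        unit_code = np.array([self.units.index(u) for u in obs_units])
        self.unit_code = unit_code
        self.mask_unit = np.equal.outer(unit_code, unit_code)
        self.unit_indices = {
            u: np.flatnonzero(unit_code == i) for i, u in enumerate(self.units)
        }
        # canonical table order keeps each unit's rows contiguous; the fast
        # likelihood path exploits the resulting block structure
        self.nhd2 = -0.5 * self.d2
        self.mask_groupf = self.mask_group.astype(float)
        self.mask_unitf = self.mask_unit.astype(float)
        self.unit_slices = []
        for u in self.units:
            idx = self.unit_indices[u]
            contiguous = len(idx) and np.all(np.diff(idx) == 1)
            self.unit_slices.append(
                (int(idx[0]), int(idx[-1]) + 1) if contiguous else None
            )

        if spec.levels == 4:
            pep = list(
                tab[["condition", "peptide"]].itertuples(index=False, name=None)
            )
            self.peptide_units = sorted(set(pep))
            pep_code = np.array([self.peptide_units.index(u) for u in pep])
            self.pep_code = pep_code
            self.mask_pep = np.equal.outer(pep_code, pep_code)
            self.pep_indices = {
                u: np.flatnonzero(pep_code == i)
                for i, u in enumerate(self.peptide_units)
            }
        else:
            self.peptide_units = None
            self.mask_pep = None
            self.pep_indices = None

    def third_level_keys(self) -> list[tuple]:
        """Units carrying sigma2_f: leaves (3-level) or peptides (4-level)."""
        return self.peptide_units if self.spec.levels == 4 else self.units

    def per_obs_values(self, mapping: Mapping, units: list, codes: np.ndarray) -> np.ndarray:
        try:
            vals = np.array([mapping[u] for u in units], dtype=float)
        except KeyError as err:
            raise ValidationError(f"missing output-scale for unit {err}") from err
        return vals[codes]

    def assemble(self, theta: HyperParams) -> CovarianceModel:
        theta.validate()
        k1 = np.exp(-self.d2 / (2.0 * theta.lambda1**2))
        k2 = np.exp(-self.d2 / (2.0 * theta.lambda2**2))

        idx_top = theta.sigma2_h + theta.sigma2_g * self.mask_group
        sigma = idx_top * k1
        index_terms = [(idx_top, k1)]

        if self.spec.levels == 3:
            v = self.per_obs_values(theta.sigma2_f, self.units, self.unit_code)
            idx_leaf = self.mask_unit * v[:, None]
            sigma = sigma + idx_leaf * k2
            index_terms.append((idx_leaf, k2))
        else:
            vp = self.per_obs_values(theta.sigma2_f, self.peptide_units, self.pep_code)
            idx_pep = self.mask_pep * vp[:, None]
            sigma = sigma + idx_pep * k2
            index_terms.append((idx_pep, k2))
            k3 = np.exp(-self.d2 / (2.0 * theta.lambda3**2))
            vr = self.per_obs_values(theta.sigma2_eta, self.units, self.unit_code)
            idx_rep = self.mask_unit * vr[:, None]
            sigma = sigma + idx_rep * k3
            index_terms.append((idx_rep, k3))

        if not np.all(np.isfinite(sigma)):
            raise NumericError("non-finite covariance entries")
        return CovarianceModel(sigma=sigma, beta2=theta.beta2, index_terms=index_terms)


def assemble_covariance(
    dataset: ProteinDataset, spec: HierarchySpec, theta: HyperParams
) -> CovarianceModel:
    """Build the dense N x N hierarchical prior covariance for one identifier."""
    return DesignCache(dataset, spec).assemble(theta)


def assemble_covariance_kronecker(
    dataset: ProteinDataset, spec: HierarchySpec, theta: HyperParams
) -> CovarianceModel:
    """Kronecker fast path for synchronous three-level designs.

    Requires every replicate to be observed on the same temperature grid.
    Each shared-lengthscale term is K^y (kron with the unit-level index
    kernel) times the grid's RBF matrix; results are bit-comparable to the
    dense construction.
    """
    if spec.levels != 3:
        raise ValidationError("Kronecker path implemented for 3-level designs")
    cache = DesignCache(dataset, spec)
    units = cache.units
    grids = []
    for u in units:
        idx = dataset.unit_index(u)
        grids.append(cache.t[idx])
    grid = grids[0]
    if any(len(g) != len(grid) or not np.allclose(g, grid) for g in grids):
        raise ValidationError("asynchronous design: use the dense construction")

    u_cond = np.asarray([u[0] for u in units], dtype=object)
    if spec.merged_conditions:
        u_group = np.asarray(
            [c if c not in spec.merged_conditions else "\0merged" for c in u_cond],
            dtype=object,
        )
    else:
        u_group = u_cond
    ky1 = theta.sigma2_h + theta.sigma2_g * np.equal.outer(u_group, u_group)
    v = np.array([theta.sigma2_f[u] for u in units], dtype=float)
    ky2 = np.diag(v)
    k1 = rbf_correlation(grid, grid, theta.lambda1)
    k2 = rbf_correlation(grid, grid, theta.lambda2)
    sigma = np.kron(ky1, k1) + np.kron(ky2, k2)
    return CovarianceModel(sigma=sigma, beta2=theta.beta2, index_terms=[(ky1, k1), (ky2, k2)])


def generative_draw(
    model: CovarianceModel,
    seed: int | np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw ``size`` vectors from N(0, Sigma + beta^2 I).

    Returns an array of shape (size, N); reproducible for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    full = model.full()
    if not np.any(full):
        return np.zeros((size, model.n))
    chol = stable_cholesky(full)
    z = rng.standard_normal((model.n, size))
    return (chol @ z).T
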