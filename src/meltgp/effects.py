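"""Effect sizes (area between melting curves) and outlier diagnostics.

The signed Area Between the Curves (ABC) replaces the melting-point shift
delta-Tm as an effect size valid for arbitrary curve shapes: it integrates
the difference (treatment minus control) of the two condition-level curves
over the shared temperature range.  Two estimators are provided — a quick
one from per-temperature medians of the scaled observations, and a refined
one from the posterior means of the condition-level latent curves, which is
more robust to outlier observations.  The absolute ABC integrates
|difference| and stays large when equal-area stabilisation and
destabilisation cancel in the signed version.

The replicate-level output-scale sigma_fcr^2 measures how far a replicate
strays from its condition's trend, so unusually large fitted values flag
replicates containing outlier observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance import HierarchySpec, HyperParams
from .datasets import ProteinDataset, ValidationError
from .inference import FitResult, posterior_predict

logger = logging.getLogger(__name__)

#: resolution of the uniform integration grid for the posterior ABC
DEFAULT_GRID_POINTS = 301


def _shared_range(dataset: ProteinDataset, pair: tuple[str, str]):
    tab = dataset.table
    ranges = []
    for cond in pair:
        t = tab.loc[tab["condition"] == cond, "temperature"]
        if t.empty:
            raise ValidationError(f"condition {cond!r} has no observations")
        ranges.append((t.min(), t.max()))
    lo = max(r[0] for r in ranges)
    hi = min(r[1] for r in ranges)
    return float(lo), float(hi)


def abc_median(dataset: ProteinDataset, pair: tuple[str, str]) -> float:
    """ABC from per-temperature medians of the scaled observations.

    ``pair`` is (control, treatment): the integrand is treatment minus
    control, evaluated at temperatures observed in both conditions and
    integrated by the trapezoidal rule.  Returns NaN (recorded as a missing
    effect size) when fewer than two shared temperatures exist.
    """
    tab = dataset.table
    if "y" not in tab.columns:
        raise ValidationError("apply a scaling before computing effect sizes")
    med = {}
    for cond in pair:
        sub = tab[tab["condition"] == cond]
        med[cond] = sub.groupby("temperature")["y"].median()
    shared = np.array(sorted(set(med[pair[0]].index) & set(med[pair[1]].index)))
    if len(shared) < 2:
        logger.warning(
            "%s: fewer than 2 shared temperatures for %s", dataset.identifier, pair
        )
        return float("nan")
    diff = med[pair[1]].loc[shared].to_numpy() - med[pair[0]].loc[shared].to_numpy()
    return float(np.trapezoid(diff, shared))


def abc_posterior(
    dataset: ProteinDataset,
    fit: FitResult | None = None,
    pair: tuple[str, str] = None,
    theta: HyperParams | None = None,
    spec: HierarchySpec | None = None,
    offset: float = 0.0,
    n_grid: int = DEFAULT_GRID_POINTS,
) -> tuple[float, float]:
    """(ABC, |ABC|) from the posterior means of the condition-level curves.

    The posterior mean of g_c for each condition in ``pair`` (control,
    treatment) is evaluated on a uniform grid spanning the shared observed
    temperature range; signed and absolute differences are integrated by the
    trapezoidal rule.
    """
    if fit is not None:
        theta, spec, offset = fit.theta, fit.spec, fit.offset
    if theta is None or spec is None:
        raise ValidationError("provide either a FitResult or (theta, spec)")
    lo, hi = _shared_range(dataset, pair)
    if hi <= lo:
        return float("nan"), float("nan")
    grid = np.linspace(lo, hi, n_grid)
    means = {}
    for cond in pair:
        curve = posterior_predict(dataset, spec, theta, ("g", cond), grid, offset)
        means[cond] = curve.mean
    diff = means[pair[1]] - means[pair[0]]
    return float(np.trapezoid(diff, grid)), float(np.trapezoid(np.abs(diff), grid))


@dataclass
class OutlierFlags:
    """Pool-wide thresholds plus the per-replicate flag table."""

    threshold_p95: float
    threshold_iqr: float
    table: pd.DataFrame  # id, condition, replicate, sigma2, percentile, flag95, flagIQR

    def per_identifier(self) -> pd.DataFrame:
        """Any-replicate aggregation: one row per identifier."""
        grp = self.table.groupby("id")
        return pd.DataFrame(
            {
                "flag95": grp["flag95"].any(),
                "flagIQR": grp["flagIQR"].any(),
                "max_sigma2": grp["sigma2"].max(),
            }
        ).reset_index()


def flag_outliers(fits: dict[str, FitResult] | pd.DataFrame) -> OutlierFlags:
    """Flag replicates whose fitted sigma_fcr^2 is extreme in the pooled
    distribution across all identifiers.

    Two rules, both strict inequalities against pooled thresholds computed
    with linear-interpolation percentiles: above the 95th percentile, and
    above q75 + 1.5 x IQR.
    """
    if isinstance(fits, pd.DataFrame):
        table = fits.copy()
        required = {"id", "condition", "replicate", "sigma2"}
        if not required <= set(table.columns):
            raise ValidationError(f"sigma2 table needs columns {sorted(required)}")
    else:
        rows = []
        for ident, fit in fits.items():
            for unit, s2 in fit.theta.sigma2_f.items():
                rows.append(
                    {
                        "id": ident,
                        "condition": unit[0],
                        "replicate": unit[-1],
                        "sigma2": float(s2),
                    }
                )
        table = pd.DataFrame(rows)
    if table.empty:
        raise ValidationError("empty sigma2 pool")
    if table["id"].nunique() < 20:
        warnings.warn(
            "fewer than 20 identifiers in the sigma2 pool; percentile "
            "thresholds will be unstable",
            stacklevel=2,
        )
    pool = table["sigma2"].to_numpy(dtype=float)
    p95 = float(np.percentile(pool, 95))
    q25, q75 = np.percentile(pool, [25, 75])
    thr_iqr = float(q75 + 1.5 * (q75 - q25))
    order = np.argsort(pool, kind="mergesort")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, len(pool) + 1)
    table["percentile"] = 100.0 * ranks / len(pool)
    table["flag95"] = pool > p95
    table["flagIQR"] = pool > thr_iqr
    return OutlierFlags(threshold_p95=p95, threshold_iqr=thr_iqr, table=table)
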