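"""Per-replicate scaling of raw abundances and replicate-divergence diagnostics.

Two scalings are supported, both dividing every observation of a replicate by
a single scalar rho:

* **fold change** — rho is the abundance at the lowest measured temperature,
  forcing each scaled curve to start at 1.  This is the field's traditional
  choice but is fragile to a measurement error at the first temperature,
  which then propagates to every scaled value of the replicate.
* **mean scaling** — rho is the across-temperature mean of the replicate, so
  each scaled curve has mean exactly 1.  It is robust to single-temperature
  outliers and lets curves start at different values, which the hierarchical
  GP model accommodates.

The divergence diagnostics quantify between-replicate reproducibility within
a condition: per-temperature differences of the scaled replicates, their
median M and variance V.  Reproducible replicates give small M and small V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ProteinDataset, ValidationError

SCALINGS = ("fold_change", "mean", "none")


class ScalingError(ValueError):
    """Raised when a replicate cannot be scaled (non-positive divisor)."""


@dataclass(frozen=True)
class DivergenceMetrics:
    """Replicate-pair divergence for one (identifier, condition)."""

    identifier: str
    condition: str
    pair: tuple[str, str]
    deltas: np.ndarray  # per shared temperature
    median: float  # M^c
    variance: float  # V^c (unbiased sample variance)


def scale_fold_change(gamma: np.ndarray) -> np.ndarray:
    """Divide by the first (lowest-temperature) abundance; Y[0] == 1 exactly."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size == 0:
        raise ScalingError("empty abundance vector")
    if gamma[0] <= 0:
        raise ScalingError(
            f"fold-change scaling requires a positive first abundance, got {gamma[0]}"
        )
    return gamma / gamma[0]


def scale_mean(gamma: np.ndarray) -> np.ndarray:
    """Divide by the across-temperature mean; mean(Y) == 1 to float tolerance."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size == 0:
        raise ScalingError("empty abundance vector")
    m = gamma.mean()
    if m <= 0:
        raise ScalingError(f"mean scaling requires a positive mean, got {m}")
    return gamma / m


def apply_scaling(dataset: ProteinDataset, method: str = "mean") -> ProteinDataset:
    """Attach a scaled-abundance column ``y`` to the dataset (in place).

    ``method`` is one of ``fold_change``, ``mean`` or ``none`` (copy raw
    abundances unchanged, for pre-scaled input).
    """
    if method not in SCALINGS:
        raise ScalingError(f"unknown scaling {method!r}; expected one of {SCALINGS}")
    tab = dataset.table
    if method == "none":
        tab["y"] = tab["abundance"].astype(float)
        return dataset
    fn = scale_fold_change if method == "fold_change" else scale_mean
    y = np.empty(len(tab), dtype=float)
    for unit in dataset.units():
        idx = dataset.unit_index(unit)
        try:
            y[idx] = fn(tab["abundance"].to_numpy(dtype=float)[idx])
        except ScalingError as err:
            raise ScalingError(f"{dataset.identifier} {unit}: {err}") from err
    tab["y"] = y
    return dataset


def replicate_divergence(
    dataset: ProteinDataset,
    method: str = "mean",
    exclude_first: bool = True,
) -> list[DivergenceMetrics]:
    """Between-replicate divergence per condition and replicate pair.

    For each unordered pair of replicates within a condition, computes the
    per-temperature differences of the scaled abundances on the shared
    temperature grid, their median M and unbiased sample variance V.  The
    lowest shared temperature is excluded by default (under fold change its
    difference is identically zero; excluding it for every scaling keeps the
    scalings comparable).

    Designs with two replicates per condition are typical; with more, one
    record per pair is returned.
    """
    if dataset.has_peptide:
        raise ValidationError("replicate divergence is a protein-level diagnostic")
    fn = {"fold_change": scale_fold_change, "mean": scale_mean, "none": lambda g: np.asarray(g, float)}[method]
    out: list[DivergenceMetrics] = []
    tab = dataset.table
    for cond in dataset.conditions:
        reps = dataset.replicates(cond)
        if len(reps) < 2:
            raise ValidationError(
                f"{dataset.identifier}/{cond}: need >= 2 replicates for divergence"
            )
        series = {}
        for r in reps:
            sub = tab[(tab["condition"] == cond) & (tab["replicate"] == r)]
            sub = sub.sort_values("temperature")
            series[r] = pd.Series(
                fn(sub["abundance"].to_numpy(dtype=float)).tolist(),
                index=sub["temperature"].to_numpy(dtype=float),
            )
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                a, b = series[reps[i]], series[reps[j]]
                shared = np.array(sorted(set(a.index) & set(b.index)))
                if exclude_first and len(shared):
                    shared = shared[1:]
                if len(shared) < 2:
                    raise ValidationError(
                        f"{dataset.identifier}/{cond}: fewer than 2 shared "
                        "temperatures between replicates"
                    )
                delta = a.loc[shared].to_numpy() - b.loc[shared].to_numpy()
                out.append(
                    DivergenceMetrics(
                        identifier=dataset.identifier,
                        condition=cond,
                        pair=(reps[i], reps[j]),
                        deltas=delta,
                        median=float(np.median(delta)),
                        variance=float(np.var(delta, ddof=1)),
                    )
                )
    return out


def divergence_table(metrics: list[DivergenceMetrics]) -> pd.DataFrame:
    """Flatten divergence records to a frame (id, condition, pair, M, V)."""
    return pd.DataFrame(
        {
            "id": [m.identifier for m in metrics],
            "condition": [m.condition for m in metrics],
            "pair": ["|".join(m.pair) for m in metrics],
            "M": [m.median for m in metrics],
            "V": [m.variance for m in metrics],
        }
    )
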