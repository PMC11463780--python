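"""Synthetic TPP-TR data drawn from the hierarchical model, plus evaluation.

The generator mirrors the model's own data-generating process: null
identifiers are drawn from the joint model (all conditions share one
condition-level curve), differential identifiers from the full model (each
condition its own curve, separated through sigma_g^2).  Draws live on the
mean-scaled scale and are shifted to sit around 1, so a simulated table is a
valid pipeline input with scaling "none".

``noise_multiplier`` scales the replicate-level output-scale sigma_f^2 (the
correlated, GP-structured noise of each replicate) before drawing, emulating
increasingly noisy datasets; the i.i.d. measurement noise beta^2 is left
untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .covariance import (
    DesignCache,
    HierarchySpec,
    HyperParams,
    generative_draw,
)
from .datasets import ProteinDataset, ValidationError

#: typical-scale generating hyperparameters on mean-scaled, centred data
DEFAULT_THETA = dict(
    lambda1=15.0,
    lambda2=8.0,
    sigma2_h=0.05,
    sigma2_g=0.01,
    sigma2_f=0.005,
    beta2=0.002,
)


@dataclass
class SimulationDesign:
    """Study conditions for one synthetic dataset.

    ``theta`` holds scalar generating values; the per-replicate output-scale
    ``sigma2_f`` (and ``sigma2_eta`` for four-level designs) is expanded to
    every unit.  ``fraction_differential`` identifiers are drawn from the
    full model, the rest from the joint model with the same remaining
    hyperparameters.
    """

    levels: int = 3
    n_identifiers: int = 100
    n_conditions: int = 2
    n_replicates: int = 2
    n_peptides: int = 2  # four-level designs only
    temperatures: np.ndarray = field(
        default_factory=lambda: np.linspace(37.0, 67.0, 10)
    )
    theta: dict = field(default_factory=lambda: dict(DEFAULT_THETA))
    fraction_differential: float = 0.0
    #: condition-level output-scale for the differential identifiers; the
    #: default gives a strong separation (>= 5x the replicate-plus-noise
    #: residual scale) so that differential curves are actually detectable
    #: at the simulated sample sizes
    sigma2_g_differential: float = 0.05
    noise_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_differential <= 1.0:
            raise ValidationError("fraction_differential must lie in [0, 1]")
        if self.noise_multiplier < 1.0:
            raise ValidationError("noise_multiplier must be >= 1")
        if self.levels == 4 and "lambda3" not in self.theta:
            self.theta.setdefault("lambda3", 5.0)
            self.theta.setdefault("sigma2_eta", 0.003)
        bad = [k for k, v in self.theta.items() if k != "sigma2_eta" and v is not None and v < 0]
        if bad:
            raise ValidationError(f"negative theta components: {bad}")

    @property
    def condition_names(self) -> list[str]:
        return ["Ctrl"] + [f"C{i}" for i in range(1, self.n_conditions)]

    def template_table(self, identifier: str) -> pd.DataFrame:
        rows = []
        for c in self.condition_names:
            if self.levels == 4:
                for j in range(1, self.n_peptides + 1):
                    for r in range(1, self.n_replicates + 1):
                        for t in self.temperatures:
                            rows.append((c, f"pep{j}", f"R{r}", t))
                continue
            for r in range(1, self.n_replicates + 1):
                for t in self.temperatures:
                    rows.append((c, None, f"R{r}", t))
        df = pd.DataFrame(rows, columns=["condition", "peptide", "replicate", "temperature"])
        if self.levels == 3:
            df = df.drop(columns="peptide")
        df.insert(0, "id", identifier)
        return df

    def hyperparams(self) -> HyperParams:
        th = self.theta
        template = ProteinDataset(
            "template",
            self.template_table("template").drop(columns="id").assign(abundance=1.0),
            has_peptide=self.levels == 4,
        )
        units = template.units()
        if self.levels == 3:
            sigma2_f = {u: th["sigma2_f"] * self.noise_multiplier for u in units}
            return HyperParams(
                lambda1=th["lambda1"],
                lambda2=th["lambda2"],
                sigma2_h=th["sigma2_h"],
                sigma2_g=th["sigma2_g"],
                sigma2_f=sigma2_f,
                beta2=th["beta2"],
            )
        pep_units = sorted({(u[0], u[1]) for u in units})
        return HyperParams(
            lambda1=th["lambda1"],
            lambda2=th["lambda2"],
            lambda3=th["lambda3"],
            sigma2_h=th["sigma2_h"],
            sigma2_g=th["sigma2_g"],
            sigma2_f={u: th["sigma2_f"] for u in pep_units},
            sigma2_eta={u: th["sigma2_eta"] * self.noise_multiplier for u in units},
            beta2=th["beta2"],
        )


def simulate_dataset(design: SimulationDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic dataset.

    Returns (observation table, truth table).  The observation table has
    columns ``id, condition, replicate, [peptide,] temperature, abundance``
    with abundance = 1 + draw; the truth table has ``id, differential``.
    """
    theta = design.hyperparams()
    theta_diff = dataclasses.replace(
        theta, sigma2_g=design.sigma2_g_differential
    )
    template = ProteinDataset(
        "template",
        design.template_table("template").drop(columns="id").assign(abundance=1.0),
        has_peptide=design.levels == 4,
    )
    spec_full = HierarchySpec(levels=design.levels)
    spec_joint = HierarchySpec(
        levels=design.levels,
        merged_conditions=frozenset(design.condition_names),
    )
    model_full = DesignCache(template, spec_full).assemble(theta_diff)
    model_joint = DesignCache(template, spec_joint).assemble(theta)

    n_diff = int(round(design.fraction_differential * design.n_identifiers))
    rng = np.random.default_rng(design.seed)
    width = max(4, len(str(design.n_identifiers)))
    tables, truths = [], []
    for i in range(design.n_identifiers):
        differential = i < n_diff
        model = model_full if differential else model_joint
        y = generative_draw(model, rng)[0]
        tab = design.template_table(f"sim_{i:0{width}d}")
        tab["abundance"] = 1.0 + y
        tables.append(tab)
        truths.append((f"sim_{i:0{width}d}", differential))
    obs = pd.concat(tables, ignore_index=True)
    truth = pd.DataFrame(truths, columns=["id", "differential"])
    return obs, truth


@dataclass
class EvaluationReport:
    """Detection-performance summary of a pipeline run against truth labels."""

    roc_auc: float
    fdr: dict  # BH alpha -> realized FDR
    tpr: dict  # BH alpha -> sensitivity among truly differential identifiers
    hit_counts: dict  # BH alpha -> (n_hits, n_false_hits)
    ks_statistic: float
    ks_pvalue: float
    type1_error_at_05: float
    lambda_summary: pd.DataFrame
    n_evaluated: int

    def to_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            **{f"fdr_at_{a}": v for a, v in self.fdr.items()},
            **{f"tpr_at_{a}": v for a, v in self.tpr.items()},
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
            "type1_error_at_05": self.type1_error_at_05,
            "n_evaluated": self.n_evaluated,
        }


def evaluate(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    alphas: tuple[float, ...] = (0.01, 0.05),
) -> EvaluationReport:
    """Score pipeline results against simulation truth labels.

    ``results`` is the results table (columns ``id, lambda, pval, padj``);
    identifiers with a failed fit are excluded from ROC/FDR but counted.
    """
    merged = results.merge(truth, on="id", how="inner")
    ok = merged[np.isfinite(merged["pval"].astype(float))].copy()
    if ok.empty:
        raise ValidationError("no successfully tested identifiers to evaluate")
    labels = ok["differential"].astype(bool).to_numpy()
    lam = ok["lambda"].astype(float).to_numpy()

    if labels.any() and not labels.all():
        auc = float(roc_auc_score(labels, lam))
    else:
        auc = float("nan")

    fdr, tpr, hit_counts = {}, {}, {}
    padj = ok["padj"].astype(float).to_numpy()
    for a in alphas:
        hits = padj <= a
        n_hits = int(hits.sum())
        false_hits = int((hits & ~labels).sum())
        fdr[a] = false_hits / max(1, n_hits)
        hit_counts[a] = (n_hits, false_hits)
        n_diff = int(labels.sum())
        tpr[a] = float((hits & labels).sum() / n_diff) if n_diff else float("nan")

    null_p = ok.loc[~labels, "pval"].astype(float).to_numpy()
    if null_p.size:
        ks_stat, ks_p = stats.kstest(null_p, "uniform")
        type1 = float(np.mean(null_p <= 0.05))
    else:
        ks_stat, ks_p, type1 = float("nan"), float("nan"), float("nan")

    summary = (
        ok.assign(label=np.where(labels, "differential", "null"))
        .groupby("label")["lambda"]
        .agg(["count", "mean", "std", "min", "max"])
        .reset_index()
    )
    return EvaluationReport(
        roc_auc=auc,
        fdr=fdr,
        tpr=tpr,
        hit_counts=hit_counts,
        ks_statistic=float(ks_stat),
        ks_pvalue=float(ks_p),
        type1_error_at_05=type1,
        lambda_summary=summary,
        n_evaluated=len(ok),
    )
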