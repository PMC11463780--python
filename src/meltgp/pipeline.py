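"""Per-identifier analysis workflow: scale, fit, test, effect sizes, flags.

For every identifier the full model M1 is fitted exactly once; every
requested condition comparison then reuses the fitted hyperparameters to
build its joint structure, compute the observed Lambda, sample the null and
derive an empirical p-value.  BH correction is applied per comparison family
(all identifiers for one condition pair).  Per-identifier seeds are derived
from the top-level seed and the identifier, so results are bit-identical for
any worker count and any input row order.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .covariance import HierarchySpec, pooled_hyperparams
from .datasets import (
    ConfigurationError,
    ProteinDataset,
    ValidationError,
    read_long_table,
    write_results,
)
from .effects import abc_median, abc_posterior, flag_outliers
from .inference import FitConfig, FitFailure, derive_seed, fit_type2_mle
from .scaling import apply_scaling
from .significance import (
    Comparison,
    ComparisonResult,
    LambdaEngine,
    bh_adjust,
    call_hits,
    empirical_pvalue,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    scaling: str = "mean"
    levels: int | None = None  # auto: 4 when a peptide column is present
    comparisons: list[tuple[str, str]] | None = None
    control: str | None = None  # all-vs-control when comparisons is None
    s: int = 1000
    null_method: str = "per_id"
    null_refit: bool = True
    null_draw: str = "full_fit"  # full_fit | joint_fit | group_pooled
    null_tol: float = 1e-6  # refit tolerance; warm starts need less than 1e-8
    hit_rule: str = "exceed_all"
    alpha: float = 0.05
    restarts: int = 3
    max_iter: int = 1000
    tol: float = 1e-8
    center: bool = True
    seed: int = 0
    workers: int = 1
    min_temperatures: int = 4
    min_replicates: int = 1
    min_conditions: int = 2
    compute_effects: bool = True
    out_dir: str | Path | None = None

    def fit_config(self) -> FitConfig:
        return FitConfig(
            restarts=self.restarts,
            max_iter=self.max_iter,
            tol=self.tol,
            center=self.center,
        )


@dataclass
class PipelineOutput:
    """Results of a pipeline run."""

    results: list[ComparisonResult]
    table: pd.DataFrame
    fits: dict
    outliers: object | None
    diagnostics: pd.DataFrame

    def __iter__(self):
        return iter(self.results)


def _comparisons_for(dataset: ProteinDataset, config: RunConfig) -> list[Comparison]:
    conds = dataset.conditions
    if config.comparisons:
        return [Comparison(a, b) for a, b in config.comparisons]
    if config.control is not None:
        if config.control not in conds:
            raise ConfigurationError(
                f"control condition {config.control!r} not in {conds}"
            )
        return [Comparison(config.control, c) for c in conds if c != config.control]
    if len(conds) == 2:
        return [Comparison(conds[0], conds[1])]
    raise ConfigurationError(
        "with more than two conditions, name a control or list comparisons"
    )


def _design_signature(dataset: ProteinDataset) -> tuple:
    """Identifiers share a null pool only with bit-identical designs:
    same condition/replicate labels and same temperature grids."""
    sig = []
    for u in dataset.units():
        temps = dataset.temperatures[dataset.unit_index(u)]
        sig.append((u, tuple(np.round(temps, 6))))
    return tuple(sig)


def _analyse_one(dataset: ProteinDataset, config: RunConfig):
    """Fit M1 and score all comparisons for one identifier."""
    t0 = time.perf_counter()
    ident = dataset.identifier
    spec = HierarchySpec(
        levels=config.levels or (4 if dataset.has_peptide else 3)
    )
    try:
        comparisons = _comparisons_for(dataset, config)
    except (ValidationError, ConfigurationError) as err:
        return ident, None, [
            ComparisonResult(ident, "invalid", status=f"error: {err}")
        ], {}

    if not dataset.passes_min_filter(
        config.min_temperatures, config.min_replicates, config.min_conditions
    ):
        return ident, None, [
            ComparisonResult(ident, c.label, status="filtered: minimum-data")
            for c in comparisons
        ], {}

    apply_scaling(dataset, config.scaling)
    try:
        fit = fit_type2_mle(dataset, spec, config.fit_config(), seed=config.seed)
    except FitFailure as err:
        logger.warning("%s", err)
        return ident, None, [
            ComparisonResult(ident, c.label, status="fit_failed")
            for c in comparisons
        ], {}

    results, nulls = [], {}
    for comp in comparisons:
        engine = LambdaEngine(dataset, fit.theta, comp, spec, fit.offset)
        lam_obs = engine.observed()
        res = ComparisonResult(
            identifier=ident,
            comparison=comp.label,
            lambda_obs=lam_obs,
            s=config.s,
            n_obs=dataset.n_obs,
            n_conditions=len(dataset.conditions),
        )
        nulls[comp.label] = engine  # null sampling happens in phase two
        if config.compute_effects:
            pair = (comp.a, comp.b)
            res.abc_median = abc_median(dataset, pair)
            res.abc, res.abs_abc = abc_posterior(dataset, fit=fit, pair=pair)
        results.append(res)
    elapsed = time.perf_counter() - t0
    return ident, fit, results, {"engines": nulls, "time_s": elapsed}


def run_pipeline(
    data,
    config: RunConfig | None = None,
    column_map: dict | None = None,
) -> PipelineOutput:
    """Run the full workflow on a long-format table or prepared datasets.

    ``data`` may be a file path, a DataFrame, or a dict of
    :class:`ProteinDataset`.  Returns results for every identifier; failures
    become recorded rows (status column) and never abort the run.
    """
    config = config or RunConfig()
    if isinstance(data, dict):
        datasets = data
    else:
        datasets = read_long_table(
            data, column_map, require_positive=config.scaling != "none"
        )
    idents = sorted(datasets)

    parallel = Parallel(n_jobs=config.workers, prefer="processes") \
        if config.workers > 1 else None
    if parallel is not None:
        triples = parallel(
            delayed(_analyse_one)(datasets[i], config) for i in idents
        )
    else:
        triples = [_analyse_one(datasets[i], config) for i in idents]

    fits, all_results, extras = {}, [], {}
    for ident, fit, results, extra in triples:
        if fit is not None:
            fits[ident] = fit
        all_results.extend(results)
        extras[ident] = extra

    # phase two: null distributions.  The draw distribution is the joint
    # (merged) structure parameterised by `null_draw`: each identifier's own
    # joint-model MLE (parametric bootstrap; default), the full-model
    # theta_hat plugged into the merged structure, or the component-wise
    # median of the joint-model MLEs across a design group.  `per_id` gives
    # every identifier an independent refitted pool; `grouped` (method E)
    # shares one pool across identifiers with an identical design.
    fit_cfg = config.fit_config()
    refit_cfg = dataclasses.replace(fit_cfg, tol=config.null_tol)
    by_key: dict[str, dict[str, ComparisonResult]] = {}
    for res in all_results:
        by_key.setdefault(res.identifier, {})[res.comparison] = res

    def _joint_theta(ident, label):
        engine = extras[ident]["engines"][label]
        try:
            return engine.fit_joint(
                fit_cfg, derive_seed(config.seed, f"{ident}|{label}|m0")
            )
        except FitFailure:
            return None

    groups: dict[tuple, list[str]] = {}
    for ident in idents:
        if ident in fits:
            groups.setdefault(_design_signature(datasets[ident]), []).append(ident)

    # resolve the draw-source hyperparameters per (identifier, comparison)
    draw_thetas: dict[tuple, object] = {}
    if config.null_draw == "full_fit":
        pass  # engine defaults to the observed full-model theta_hat
    elif config.null_draw == "joint_fit":
        for ident in idents:
            if ident not in fits:
                continue
            for label in extras[ident]["engines"]:
                draw_thetas[(ident, label)] = _joint_theta(ident, label)
    elif config.null_draw == "group_pooled":
        for sig, members in groups.items():
            labels = sorted({c for m in members for c in extras[m]["engines"]})
            for label in labels:
                thetas0 = [
                    t for m in members if (t := _joint_theta(m, label)) is not None
                ]
                if not thetas0:
                    continue
                med = pooled_hyperparams(thetas0)
                for m in members:
                    draw_thetas[(m, label)] = med
    else:
        raise ConfigurationError(f"unknown null_draw {config.null_draw!r}")

    def _score(res, pool):
        if pool is None or pool.size == 0:
            res.status = "null_sampling_failed"
            return
        res.n_null_geq = int(np.sum(pool >= res.lambda_obs))
        res.s = int(pool.size)
        res.pval = empirical_pvalue(res.lambda_obs, pool)

    if config.null_method == "per_id":
        jobs = []
        for ident in idents:
            if ident not in fits:
                continue
            for label, engine in extras[ident]["engines"].items():
                seed_i = derive_seed(config.seed, f"{ident}|{label}|null")
                jobs.append((ident, label, engine, seed_i))
        def _pool_for(job):
            ident, label, engine, seed_i = job
            return engine.sample_null(
                config.s, seed_i, refit=config.null_refit,
                fit_config=refit_cfg, draw_theta=draw_thetas.get((ident, label)),
            )
        if parallel is not None:
            pools_list = parallel(delayed(_pool_for)(j) for j in jobs)
        else:
            pools_list = [_pool_for(j) for j in jobs]
        for (ident, label, _, _), pool in zip(jobs, pools_list):
            res = by_key.get(ident, {}).get(label)
            if res is not None and res.status == "ok":
                _score(res, pool)
    else:  # grouped
        pools: dict[tuple, np.ndarray] = {}
        for sig, members in groups.items():
            labels = sorted({c for m in members for c in extras[m]["engines"]})
            for label in labels:
                rep = members[0]
                engine = extras[rep]["engines"].get(label)
                if engine is None:
                    continue
                pool_seed = derive_seed(config.seed, f"{rep}|{label}|pool")
                pools[(sig, label)] = engine.sample_null(
                    config.s, pool_seed, refit=config.null_refit,
                    fit_config=refit_cfg, draw_theta=draw_thetas.get((rep, label)),
                )
        for ident in idents:
            if ident not in fits:
                continue
            sig = _design_signature(datasets[ident])
            for res in by_key.get(ident, {}).values():
                if res.status == "ok":
                    _score(res, pools.get((sig, res.comparison)))

    # BH per comparison family
    families: dict[str, list[ComparisonResult]] = {}
    for res in all_results:
        if res.status == "ok" and np.isfinite(res.pval):
            families.setdefault(res.comparison, []).append(res)
    for family in families.values():
        adj = bh_adjust([r.pval for r in family])
        for r, a in zip(family, adj):
            r.padj = float(a)
    call_hits(
        [r for fam in families.values() for r in fam],
        rule=config.hit_rule,
        alpha=config.alpha,
    )

    outliers = None
    if fits and not next(iter(datasets.values())).has_peptide:
        outliers = flag_outliers(fits)
        flagged = outliers.table[outliers.table["flag95"] | outliers.table["flagIQR"]]
        by_id: dict[str, list[str]] = {}
        for row in flagged.itertuples():
            marks = ("95" if row.flag95 else "") + ("+IQR" if row.flagIQR else "")
            by_id.setdefault(row.id, []).append(
                f"{row.condition}/{row.replicate}:{marks}"
            )
        for res in all_results:
            res.outlier_flags = ";".join(by_id.get(res.identifier, []))

    diagnostics = pd.DataFrame(
        {
            "id": idents,
            "status": [
                "ok" if i in fits else "failed_or_filtered" for i in idents
            ],
            "restarts_used": [
                fits[i].restart_index if i in fits else -1 for i in idents
            ],
            "converged": [fits[i].converged if i in fits else False for i in idents],
            "log_marginal_likelihood": [
                fits[i].log_marginal_likelihood if i in fits else np.nan
                for i in idents
            ],
            "time_s": [extras[i].get("time_s", np.nan) for i in idents],
        }
    )

    order = {ident: k for k, ident in enumerate(idents)}
    all_results.sort(key=lambda r: (order[r.identifier], r.comparison))
    table = pd.DataFrame.from_records([r.as_record() for r in all_results])

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(all_results, out / "results.tsv")
        diagnostics.to_csv(out / "diagnostics.tsv", sep="\t", index=False)
        if outliers is not None:
            outliers.table.to_csv(out / "outlier_flags.tsv", sep="\t", index=False)

    return PipelineOutput(
        results=all_results,
        table=table,
        fits=fits,
        outliers=outliers,
        diagnostics=diagnostics,
    )


def group_peptides(
    dataset: ProteinDataset,
    reference: str,
    max_conditions: int = 20,
) -> list[ProteinDataset]:
    """Partition a many-peptide identifier into batches fit together.

    Peptide groups act as conditions; each batch holds at most
    ``max_conditions - 1`` of them plus the designated reference condition
    (for instance the median trace of the non-modified peptides), so a batch
    never exceeds ``max_conditions`` conditions.  Peptide groups are sorted
    lexicographically and chunked, which keeps batch assignment
    deterministic.
    """
    conds = dataset.conditions
    if reference not in conds:
        raise ConfigurationError(f"reference condition {reference!r} missing")
    if max_conditions < 2:
        raise ConfigurationError("max_conditions must be >= 2")
    others = sorted(c for c in conds if c != reference)
    size = max_conditions - 1
    batches = []
    for k in range(0, max(len(others), 1), size):
        chunk = others[k : k + size]
        if not chunk:
            break
        keep = [reference] + chunk
        tab = dataset.table[dataset.table["condition"].isin(keep)].copy()
        batches.append(
            ProteinDataset(
                identifier=f"{dataset.identifier}#batch{len(batches)}",
                table=tab,
                has_peptide=dataset.has_peptide,
            )
        )
    return batches
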