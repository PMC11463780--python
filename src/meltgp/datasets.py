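"""Long-format TPP-TR tables and per-identifier datasets.

Thermal proteome profiling (temperature range, TPP-TR) experiments quantify
the soluble fraction of each protein at ~10 temperatures, per replicate and
condition, optionally resolved to the peptide level.  This module reads such
long-format tables, validates and indexes them into one
:class:`ProteinDataset` per identifier, and writes result tables back out.

Replicates need not share a temperature grid (asynchronous designs are
first-class); rows missing at some temperatures are simply omitted, never
imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical internal column names
CORE_COLUMNS = ("id", "condition", "replicate", "temperature", "abundance")
OPTIONAL_COLUMNS = ("peptide",)

#: columns of the results table written by :func:`write_results`
RESULT_COLUMNS = (
    "id",
    "comparison",
    "lambda",
    "pval",
    "padj",
    "hit",
    "ABC",
    "absABC",
    "ABC_median",
    "n_obs",
    "n_conditions",
    "outlier_flags",
    "status",
)


class ValidationError(ValueError):
    """Raised when an input table violates the format contract."""


class ConfigurationError(ValueError):
    """Raised for bad column mappings or option values."""


@dataclass
class ProteinDataset:
    """All observations for one identifier.

    The table is kept in canonical order (condition, replicate, [peptide],
    temperature ascending) so that covariance construction and likelihood
    evaluation are invariant to the input row order.

    Attributes
    ----------
    identifier : str
        Protein / gene / peptide-group identifier.
    table : pandas.DataFrame
        Columns ``condition, replicate, [peptide], temperature, abundance``
        and, once a scaling has been applied, ``y`` (scaled abundance).
    """

    identifier: str
    table: pd.DataFrame
    has_peptide: bool = field(default=False)

    def __post_init__(self) -> None:
        keys = self._group_keys()
        self.table = (
            self.table.sort_values([*keys, "temperature"], kind="mergesort")
            .reset_index(drop=True)
        )

    def _group_keys(self) -> list[str]:
        return (
            ["condition", "peptide", "replicate"]
            if self.has_peptide
            else ["condition", "replicate"]
        )

    # -- bookkeeping ------------------------------------------------------

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def replicates(self, condition: str) -> list[str]:
        sub = self.table.loc[self.table["condition"] == condition, "replicate"]
        return sorted(sub.unique())

    @property
    def n_obs(self) -> int:
        """Total number of observations N_p."""
        return len(self.table)

    def n_obs_condition(self, condition: str) -> int:
        """N_pc: total dimension of the observations for one condition."""
        return int((self.table["condition"] == condition).sum())

    def units(self) -> list[tuple]:
        """Leaf units of the hierarchy: (condition, replicate) tuples, or
        (condition, peptide, replicate) for peptide-level data, in canonical
        order."""
        keys = self._group_keys()
        seen: list[tuple] = []
        for tup in self.table[keys].itertuples(index=False, name=None):
            if not seen or seen[-1] != tup:
                seen.append(tup)
        return seen

    def unit_index(self, unit: tuple) -> np.ndarray:
        keys = self._group_keys()
        mask = np.ones(len(self.table), dtype=bool)
        for k, v in zip(keys, unit):
            mask &= (self.table[k] == v).to_numpy()
        return np.flatnonzero(mask)

    @property
    def temperatures(self) -> np.ndarray:
        return self.table["temperature"].to_numpy(dtype=float)

    def scaled(self) -> np.ndarray:
        if "y" not in self.table.columns:
            raise ValidationError(
                f"{self.identifier}: no scaling applied yet (column 'y' missing)"
            )
        return self.table["y"].to_numpy(dtype=float)

    # -- filters ----------------------------------------------------------

    def passes_min_filter(
        self,
        min_temperatures: int = 4,
        min_replicates: int = 1,
        min_conditions: int = 2,
    ) -> bool:
        """Minimum-data filter below which the GP fit is degenerate.

        Defaults: every replicate observed at >= 4 distinct temperatures,
        >= 1 replicate per condition, >= 2 conditions for testing.
        """
        if len(self.conditions) < min_conditions:
            return False
        for c in self.conditions:
            if len(self.replicates(c)) < min_replicates:
                return False
        for unit in self.units():
            idx = self.unit_index(unit)
            if len(np.unique(self.temperatures[idx])) < min_temperatures:
                return False
        return True


def read_long_table(
    path: str | Path | pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    require_positive: bool = True,
) -> dict[str, ProteinDataset]:
    """Read a long-format abundance table into per-identifier datasets.

    Parameters
    ----------
    path
        Delimited text file (TSV/CSV, sniffed from the extension unless
        ``sep`` is given) or an already-loaded DataFrame.
    column_map
        Mapping from canonical names (``id, condition, replicate,
        temperature, abundance, peptide``) to the column names used in the
        file.
    require_positive
        Drop rows with non-positive abundance (raw MS intensities must be
        positive).  Set to ``False`` for pre-scaled input such as simulated
        tables, where values near zero are legitimate.

    Returns
    -------
    dict mapping identifier -> ProteinDataset, insertion order sorted by
    identifier.
    """
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        path = Path(path)
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)

    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items() if v in df.columns}
    df = df.rename(columns=rename)

    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"missing required column(s): {', '.join(missing)}"
        )
    has_peptide = "peptide" in df.columns

    keep = ["id", "condition", "replicate", "temperature", "abundance"]
    if has_peptide:
        keep.append("peptide")
    df = df[keep]

    for col in ("id", "condition", "replicate") + (("peptide",) if has_peptide else ()):
        df[col] = df[col].astype(str)
    df["temperature"] = pd.to_numeric(df["temperature"], errors="coerce")
    df["abundance"] = pd.to_numeric(df["abundance"], errors="coerce")

    n0 = len(df)
    bad = df["abundance"].isna() | ~np.isfinite(df["temperature"])
    if require_positive:
        bad |= df["abundance"] <= 0
    df = df.loc[~bad]
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("dropped %d row(s) with missing/non-positive values", n_dropped)

    key_cols = ["id", "condition", "replicate", "temperature"] + (
        ["peptide"] if has_peptide else []
    )
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        grp = df.loc[dup].groupby(key_cols)["abundance"].nunique()
        conflicting = grp[grp > 1]
        if len(conflicting):
            raise ValidationError(
                "duplicate keys with differing abundance: "
                + "; ".join(map(str, conflicting.index.tolist()[:10]))
            )
        df = df.drop_duplicates(subset=key_cols, keep="first")
        logger.info("deduplicated identical repeated rows")

    out: dict[str, ProteinDataset] = {}
    for ident in sorted(df["id"].unique()):
        sub = df.loc[df["id"] == ident].drop(columns="id")
        out[ident] = ProteinDataset(
            identifier=ident, table=sub, has_peptide=has_peptide
        )
    return out


def write_results(results: Iterable, path: str | Path) -> pd.DataFrame:
    """Write comparison results as a TSV, one row per (identifier, comparison).

    ``results`` may be ComparisonResult objects (anything exposing
    ``as_record()``) or plain dicts.  Returns the written frame.
    """
    records = []
    for r in results:
        rec = r.as_record() if hasattr(r, "as_record") else dict(r)
        records.append({c: rec.get(c) for c in RESULT_COLUMNS})
    if not records:
        raise ValidationError("no results to write")
    frame = pd.DataFrame.from_records(records, columns=list(RESULT_COLUMNS))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return frame
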