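"""Reading, validating, aligning and writing genus-level count tables.

The canonical orientation is samples as rows and genera as columns; genus
names are opaque strings (no taxonomy parsing). Count tables travel as TSV,
metadata as CSV, nested results (SEM fits, ROC curves) as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, InsufficientDataError

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
GROUPS = ("case", "control")


@dataclass
class CountTable:
    """Samples x taxa non-negative integer abundance matrix.

    Attributes
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers (rows).
    taxon_ids : list of str
        Ordered, unique genus names (columns).
    counts : ndarray of int, shape (n_samples, n_taxa)
    zero_taxa : list of str
        Taxa whose total count is zero; retained but flagged by validation.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    zero_taxa: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def subset_samples(self, ids: Sequence[str]) -> "CountTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return CountTable(list(ids), list(self.taxon_ids), self.counts[idx].copy(),
                          list(self.zero_taxa))


@dataclass
class SampleMetadata:
    """Per-sample covariates: sex, case/control group, optional age and BMI."""

    sample_id: str
    sex: str
    group: str
    age: float | None = None
    bmi: float | None = None


def _validate_counts(df: pd.DataFrame, min_depth: int = 0) -> CountTable:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate taxon id {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = np.argwhere(~np.vectorize(np.isreal)(arr))
        r, c = bad[0]
        raise FormatError(f"non-numeric entry at sample {df.index[r]!r}, taxon {df.columns[c]!r}")
    if np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise FormatError(f"negative count at sample {df.index[r]!r}, taxon {df.columns[c]!r}")
    if not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise FormatError(f"non-integer count at sample {df.index[r]!r}, taxon {df.columns[c]!r}")
    counts = arr.astype(np.int64)

    totals = counts.sum(axis=1)
    keep = totals > max(0, min_depth)
    dropped = [s for s, k in zip(df.index, keep) if not k]
    if dropped:
        logger.info("dropping %d sample(s) below depth %d: %s", len(dropped), min_depth, dropped)
        counts = counts[keep]
        df = df.loc[keep]
    if counts.shape[0] == 0:
        raise FormatError("no samples remain after depth filtering")

    zero_taxa = [t for t, tot in zip(df.columns, counts.sum(axis=0)) if tot == 0]
    if zero_taxa:
        logger.info("%d taxa have zero total count (retained, flagged)", len(zero_taxa))
    return CountTable([str(s) for s in df.index], [str(t) for t in df.columns],
                      counts, zero_taxa)


def read_count_table(path: str | Path, dialect: str = "auto",
                     min_depth: int = 0) -> CountTable:
    """Read a TSV/CSV count table.

    dialect: "samples-as-rows", "taxa-as-rows", or "auto" (transpose when the
    index header names a taxon column, e.g. "taxon"/"genus").
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if dialect not in ("auto", "samples-as-rows", "taxa-as-rows"):
        raise FormatError(f"unknown dialect {dialect!r}")
    index_name = (df.index.name or "").strip().lower()
    if dialect == "taxa-as-rows" or (
            dialect == "auto" and index_name in {"taxon", "taxon_id", "genus", "otu"}):
        df = df.T
    return _validate_counts(df, min_depth=min_depth)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write as TSV, sample id in the first column, taxa as columns."""
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise FormatError("metadata must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate metadata sample id {dup!r}")
    records = []
    for _, row in df.iterrows():
        sex = str(row.get("sex", "")).strip().lower()
        group = str(row.get("group", "")).strip().lower()
        group = {"mci": "case"}.get(group, group)
        if sex not in SEXES:
            raise FormatError(f"sample {row['sample_id']!r}: sex must be one of {SEXES}, got {sex!r}")
        if group not in GROUPS:
            raise FormatError(f"sample {row['sample_id']!r}: group must be one of {GROUPS}, got {group!r}")
        age = float(row["age"]) if "age" in df.columns and pd.notna(row["age"]) else None
        bmi = float(row["bmi"]) if "bmi" in df.columns and pd.notna(row["bmi"]) else None
        records.append(SampleMetadata(str(row["sample_id"]), sex, group, age, bmi))
    return records


def write_metadata(meta: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame([vars(m) for m in meta]).to_csv(path, index=False)


def align(counts: CountTable, meta: Sequence[SampleMetadata]
          ) -> tuple[CountTable, list[SampleMetadata]]:
    """Restrict counts and metadata to their id intersection, in counts order.

    Requires at least 2 samples per group afterwards.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    common = [s for s in counts.sample_ids if s in meta_by_id]
    dropped = sorted(set(counts.sample_ids) - set(common)) + \
        sorted(set(meta_by_id) - set(common))
    if dropped:
        logger.info("align dropped %d sample(s): %s", len(dropped), dropped)
    aligned_meta = [meta_by_id[s] for s in common]
    for g in GROUPS:
        n_g = sum(1 for m in aligned_meta if m.group == g)
        if n_g < 2:
            raise InsufficientDataError(
                f"group {g!r} has {n_g} sample(s) after alignment; need >= 2")
    return counts.subset_samples(common), aligned_meta


def write_results(results, path: str | Path, format: str = "auto") -> None:
    """Write tabular results as TSV and nested results as JSON.

    DataFrames go to TSV; dicts (and dataclass-like mappings) go to JSON.
    """
    path = Path(path)
    if format == "auto":
        format = "tsv" if isinstance(results, pd.DataFrame) else "json"
    if format == "tsv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        results.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, default=_json_default)
            fh.write("\n")
    else:
        raise FormatError(f"unknown result format {format!r}")


def read_results(path: str | Path):
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return json.load(fh)
    return pd.read_csv(path, sep="\t")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
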