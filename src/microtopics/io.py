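"""Tabular I/O for count matrices, sample metadata, and result reports.

The on-disk convention is tab-delimited UTF-8 with a single header row of
identifiers.  A sparse triplet reader (sample, taxon, count) is provided as
an alternate carrier for large ASV tables.  Missing metadata values use the
token ``NA`` (case-sensitive).  Reports are written at 6 significant digits
so a fixed model always produces byte-identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .lda import LdaModel

NA_TOKEN = "NA"
FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """Raised for malformed input tables (duplicates, bad cells, missing columns)."""


@dataclass
class CountMatrix:
    """A sample x taxon table of non-negative integer counts.

    The microbiome analogue of a document-term matrix: samples are
    documents, taxa are words.  Stored as a pandas DataFrame with sample
    identifiers on the index and taxon identifiers on the columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon identifiers: {dupes}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (values < 0).any():
            s, t = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at sample {df.index[s]!r}, taxon {df.columns[t]!r}"
            )
        zero = df.sum(axis=1) == 0
        if zero.any():
            warnings.warn(
                f"samples with zero total count: {df.index[zero].tolist()}",
                stacklevel=2,
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def taxon_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def total(self) -> int:
        return int(self.data.to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.data.equals(other.data) and (
            list(self.data.index) == list(other.data.index)
        ) and (list(self.data.columns) == list(other.data.columns))


@dataclass
class SampleMetadata:
    """Per-sample categorical conditions and continuous traits.

    Conditions are experimental factors (e.g. watering, generation) with at
    least two levels; traits are numeric measurements (e.g. stem height)
    where missing values are allowed and never imputed.
    """

    conditions: pd.DataFrame
    traits: pd.DataFrame
    condition_levels: dict[str, list[str]] = field(default_factory=dict)
    all_missing_traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.condition_levels:
            self.condition_levels = {
                c: list(dict.fromkeys(self.conditions[c].astype(str)))
                for c in self.conditions.columns
            }
        if not self.all_missing_traits:
            self.all_missing_traits = [
                t for t in self.traits.columns if self.traits[t].isna().all()
            ]
        for name, levels in self.condition_levels.items():
            if len(levels) < 2:
                warnings.warn(
                    f"condition {name!r} has a single observed level "
                    f"({levels}); retained but uninformative",
                    stacklevel=2,
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.conditions.index)

    def validate_pairing(self, counts: CountMatrix) -> None:
        """Check every metadata sample id exists in the paired count matrix."""
        missing = set(self.sample_ids) - set(counts.sample_ids)
        if missing:
            raise FormatError(
                f"metadata samples absent from count matrix: {sorted(missing)}"
            )


def read_count_table(path: str | Path, orientation: str = "samples-as-rows") -> CountMatrix:
    """Read a delimited count table into a :class:`CountMatrix`.

    Parameters
    ----------
    path
        Tab-delimited text with one header row and identifiers in the first
        column.
    orientation
        ``"samples-as-rows"`` (default) or ``"taxa-as-rows"``; the result is
        always normalized to samples x taxa.
    """
    if orientation not in ("samples-as-rows", "taxa-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round()) | (converted < 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"cell at row {row!r}, column {col!r} is not a "
                f"non-negative integer: {df.loc[row, col]!r}"
            )
        parsed[col] = converted.astype(np.int64)
    if orientation == "taxa-as-rows":
        parsed = parsed.T
    return CountMatrix(parsed)


def read_count_triplets(path: str | Path) -> CountMatrix:
    """Read a sparse three-column (sample, taxon, count) table.

    Identifier order follows first appearance; absent pairs are zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, keep_default_na=False)
    if df.shape[1] != 3:
        raise FormatError("triplet table must have exactly 3 columns")
    df.columns = ["sample", "taxon", "count"]
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts != counts.round()) | (counts < 0)
    if bad.any():
        i = bad.to_numpy().nonzero()[0][0]
        raise FormatError(
            f"triplet row {i} has a non-integer or negative count: "
            f"{df['count'].iloc[i]!r}"
        )
    samples = list(dict.fromkeys(df["sample"]))
    taxa = list(dict.fromkeys(df["taxon"]))
    wide = pd.DataFrame(0, index=samples, columns=taxa, dtype=np.int64)
    for s, t, c in zip(df["sample"], df["taxon"], counts.astype(np.int64)):
        wide.loc[s, t] += c
    return CountMatrix(wide)


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(
    path: str | Path,
    condition_cols: list[str],
    trait_cols: list[str],
) -> SampleMetadata:
    """Read sample metadata, splitting condition and trait columns.

    Categorical levels are recorded in first-appearance order.  Trait cells
    equal to ``NA`` (or empty) become missing; they are flagged, never
    imputed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    unknown = [c for c in list(condition_cols) + list(trait_cols) if c not in df.columns]
    if unknown:
        raise FormatError(f"columns not found in metadata: {unknown}")
    conditions = df[list(condition_cols)].astype(str)
    traits = pd.DataFrame(index=df.index)
    for t in trait_cols:
        raw = df[t].replace({NA_TOKEN: None, "": None})
        traits[t] = pd.to_numeric(raw, errors="raise")
    return SampleMetadata(conditions=conditions, traits=traits)


def _write_float_table(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def write_reports(
    model: "LdaModel",
    associations: pd.DataFrame | None,
    tests: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the standard result tables for a fitted model.

    Emits the topic-taxon probability table (phi), the sample-topic
    proportion table (theta), the topic-condition association table, and
    the trait-test table, all as TSV at fixed precision.  Returns a
    manifest mapping report name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    k = model.K
    if associations is not None and len(associations) and "topic" in associations:
        if associations["topic"].max() >= k:
            raise FormatError(
                f"association table references topic "
                f"{int(associations['topic'].max())} but model has K={k}"
            )

    phi_df = pd.DataFrame(
        model.phi, index=[f"topic_{i}" for i in range(k)], columns=model.vocab
    )
    p = out / "topic_taxon_probabilities.tsv"
    _write_float_table(phi_df, p, "topic")
    manifest["phi"] = p

    theta_df = pd.DataFrame(
        model.theta, index=model.sample_ids, columns=[f"topic_{i}" for i in range(k)]
    )
    p = out / "sample_topic_proportions.tsv"
    _write_float_table(theta_df, p, "sample_id")
    manifest["theta"] = p

    if associations is not None:
        p = out / "topic_condition_associations.tsv"
        associations.to_csv(p, sep="\t", float_format=FLOAT_FMT, index=False)
        manifest["associations"] = p
    if tests is not None:
        p = out / "trait_tests.tsv"
        tests.to_csv(p, sep="\t", float_format=FLOAT_FMT, index=False)
        manifest["trait_tests"] = p
    return manifest
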