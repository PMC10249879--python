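"""Collapse ASV-level counts to a chosen taxonomic rank.

Many environmental ASVs lack a complete lineage.  Rather than discarding
them, an ASV unidentified at the target rank is aggregated under its finest
known rank with a fallback label such as ``c_Cyanobacteriia_NA`` (an ASV
known only to class Cyanobacteriia, aggregated at order level).  Aggregated
tables are then thinned of very rare taxa (total count < 4 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .io import CountMatrix, FormatError

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_CODES = dict(zip(RANKS, "kpcofgs"))
#: ranks supported for aggregation by default; genus/species need allow_deep
SUPPORTED_LEVELS = ("phylum", "class", "order", "family", "asv")
UNCLASSIFIED_LABEL = "unclassified_NA"


@dataclass(frozen=True)
class TaxonLineage:
    """A ranked lineage for one ASV; ``None`` marks an unknown rank.

    Once a rank is unknown, every finer rank is treated as unknown too.
    """

    asv_id: str
    ranks: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"lineage needs {len(RANKS)} ranks, got {len(self.ranks)}")
        # enforce prefix-known structure: truncate below the first unknown
        seen_unknown = False
        cleaned = []
        for name in self.ranks:
            if name is None or seen_unknown:
                seen_unknown = True
                cleaned.append(None)
            else:
                cleaned.append(name)
        object.__setattr__(self, "ranks", tuple(cleaned))

    def rank(self, level: str) -> str | None:
        return self.ranks[RANKS.index(level)]

    def finest_known(self) -> tuple[str, str] | None:
        """Return (rank name, taxon name) of the deepest identified rank."""
        for level, name in zip(reversed(RANKS), reversed(self.ranks)):
            if name is not None:
                return level, name
        return None


@dataclass
class AggregatedMatrix:
    """A count matrix collapsed to one taxonomic level, with provenance."""

    base: CountMatrix
    level: str
    label_map: dict[str, frozenset[str]]
    zero_total_samples: list[str] = field(default_factory=list)


def read_taxonomy_table(path) -> list[TaxonLineage]:
    """Read a taxonomy TSV with columns asv_id, kingdom..species.

    Empty cells or ``NA`` mark unknown ranks.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["asv_id", *RANKS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"taxonomy table missing columns: {missing}")
    lineages = []
    for _, row in df.iterrows():
        ranks = tuple(
            None if row[r] in ("", "NA") else row[r] for r in RANKS
        )
        lineages.append(TaxonLineage(asv_id=str(row["asv_id"]), ranks=ranks))
    return lineages


def write_taxonomy_table(lineages: list[TaxonLineage], path) -> None:
    rows = [
        {"asv_id": lin.asv_id, **{r: (n if n is not None else "NA")
                                  for r, n in zip(RANKS, lin.ranks)}}
        for lin in lineages
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def resolve_label(lineage: TaxonLineage, level: str) -> str:
    """Aggregation label for one ASV at the target level.

    Identified at `level` -> that rank's name verbatim.  Unidentified ->
    ``<rankcode>_<FinestKnownName>_NA`` from the deepest known rank, or
    ``unclassified_NA`` if nothing is known.  At ASV level the ASV id is
    returned unchanged.
    """
    if level == "asv":
        return lineage.asv_id
    if level not in RANKS:
        raise ValueError(f"unknown taxonomic level {level!r}")
    name = lineage.rank(level)
    if name is not None:
        return name
    finest = lineage.finest_known()
    if finest is None:
        return UNCLASSIFIED_LABEL
    rank, taxon = finest
    return f"{RANK_CODES[rank]}_{taxon}_NA"


def aggregate_counts(
    counts: CountMatrix,
    lineages: list[TaxonLineage],
    level: str,
    allow_deep: bool = False,
) -> AggregatedMatrix:
    """Sum ASV counts over lineages sharing a resolved label at `level`.

    Per-sample totals are conserved; aggregated column order follows the
    first appearance of each label in the input taxon order.  Genus and
    species levels are refused unless ``allow_deep`` (they are typically
    mostly unidentified in environmental data).
    """
    if level not in SUPPORTED_LEVELS and not (allow_deep and level in RANKS):
        raise ValueError(
            f"level {level!r} not supported (use one of {SUPPORTED_LEVELS}, "
            "or allow_deep=True for genus/species)"
        )
    by_asv = {lin.asv_id: lin for lin in lineages}
    missing = [t for t in counts.taxon_ids if t not in by_asv]
    if missing:
        raise FormatError(f"no lineage entry for taxa: {missing[:5]}")

    labels = [resolve_label(by_asv[t], level) for t in counts.taxon_ids]
    label_order = list(dict.fromkeys(labels))
    grouped = counts.data.T.groupby(pd.Series(labels, index=counts.taxon_ids)).sum().T
    grouped = grouped[label_order]

    label_map = {
        lab: frozenset(t for t, l in zip(counts.taxon_ids, labels) if l == lab)
        for lab in label_order
    }
    return AggregatedMatrix(
        base=CountMatrix(grouped), level=level, label_map=label_map
    )


def filter_rare_taxa(
    matrix: AggregatedMatrix,
    min_total: int = 4,
    apply_at_asv: bool = False,
) -> AggregatedMatrix:
    """Drop aggregated taxa whose total count across all samples is below
    ``min_total``.

    The filter targets aggregated levels; at ASV level it is a no-op unless
    ``apply_at_asv``.  Samples are never dropped: a sample left with zero
    total is retained and flagged with a warning.
    """
    if matrix.level == "asv" and not apply_at_asv:
        return matrix
    totals = matrix.base.taxon_totals()
    keep = totals[totals >= min_total].index
    data = matrix.base.data[keep]
    zero = data.sum(axis=1) == 0
    flagged = data.index[zero].tolist()
    if flagged:
        warnings.warn(
            f"samples with zero total after rare-taxon filtering: {flagged}",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-total warning already issued above
        base = CountMatrix(data)
    return AggregatedMatrix(
        base=base,
        level=matrix.level,
        label_map={k: v for k, v in matrix.label_map.items() if k in set(keep)},
        zero_total_samples=flagged,
    )
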