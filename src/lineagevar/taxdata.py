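"""Sequence records with full taxonomic lineage: reading, filtering, summarizing.

The data backbone of the pipeline.  Every sequence carries an accession, an
aligned amino-acid string, a fragment flag, and (optionally) a seven-rank
taxonomic lineage running kingdom -> phylum -> class -> order -> family ->
genus -> organism.  Only records whose lineage is complete at all seven ranks
take part in the downstream distance and variance analyses.

Rank names are *not* assumed globally unique: the same genus name may occur
under two different families.  All distinct-taxon bookkeeping therefore keys
taxa by their full path from the kingdom down, so homonymous taxa under
different parents are never silently merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlphabetError,
    InputError,
    PreconditionError,
    SchemaError,
)

#: Ordered rank names, shallowest first.  Index 0 = kingdom ... 6 = organism.
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "organism",
)

#: The 20 standard amino-acid one-letter codes.
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AMBIGUOUS = "X"


@dataclass(frozen=True)
class Lineage:
    """A complete seven-rank taxonomic path for one sequence."""

    kingdom: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    organism: str

    def rank(self, rank: str) -> str:
        """Taxon name at ``rank`` (one of :data:`RANKS`)."""
        if rank not in RANKS:
            raise InputError(f"unknown rank name: {rank!r}")
        return getattr(self, "class_" if rank == "class" else rank)

    def path(self, rank: str) -> tuple[str, ...]:
        """Full-path key from kingdom down to ``rank`` (inclusive)."""
        depth = RANKS.index(rank) if rank in RANKS else None
        if depth is None:
            raise InputError(f"unknown rank name: {rank!r}")
        return tuple(self.rank(r) for r in RANKS[: depth + 1])

    @property
    def is_complete(self) -> bool:
        return all(self.rank(r) for r in RANKS)


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned amino-acid sequence plus its metadata."""

    accession: str
    residues: str
    is_fragment: bool = False
    lineage: Optional[Lineage] = None

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)


@dataclass(frozen=True)
class Alignment:
    """An ordered collection of equal-length aligned sequences."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentError(
                f"ragged alignment: residue lengths {sorted(lengths)}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(r.accession for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class RankSummary:
    """Distinct-taxon counts per rank (full-path keyed) and the record count."""

    phyla: int
    classes: int
    orders: int
    families: int
    genera: int
    organisms: int
    n_records: int

    def as_dict(self) -> dict[str, int]:
        return {
            "phyla": self.phyla,
            "classes": self.classes,
            "orders": self.orders,
            "families": self.families,
            "genera": self.genera,
            "organisms": self.organisms,
        }


def _validate_residues(accession: str, residues: str, alphabet_policy: str) -> None:
    allowed = set(AA_LETTERS + GAP)
    if alphabet_policy == "allow-X":
        allowed.add(AMBIGUOUS)
    elif alphabet_policy != "strict":
        raise InputError(f"unknown alphabet policy: {alphabet_policy!r}")
    bad = sorted(set(residues.upper()) - allowed)
    if bad:
        raise AlphabetError(
            f"record {accession}: illegal symbols {bad} under "
            f"{alphabet_policy!r} policy"
        )


def read_alignment_fasta(path, alphabet_policy: str = "allow-X") -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    The accession is the first whitespace-delimited token of each header.
    Gap characters are preserved.  ``alphabet_policy`` is ``"strict"`` (20
    amino-acid letters plus gap) or ``"allow-X"`` (also the ambiguity code X).
    """
    records = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        accession = seq_rec.id.split()[0]
        residues = str(seq_rec.seq).upper()
        if not residues:
            raise InputError(f"record {accession}: empty sequence")
        _validate_residues(accession, residues, alphabet_policy)
        records.append(SequenceRecord(accession=accession, residues=residues))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return Alignment(records=tuple(records))


def write_alignment_fasta(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rec in alignment:
            fh.write(f">{rec.accession}\n{rec.residues}\n")


_LINEAGE_COLUMNS = list(RANKS)
_TABLE_COLUMNS = ["accession"] + _LINEAGE_COLUMNS + ["fragment"]


def read_lineage_table(path) -> dict[str, tuple[Optional[Lineage], bool]]:
    """Read a lineage TSV into ``accession -> (Lineage | None, is_fragment)``.

    The table must carry a header row with columns ``accession``, the seven
    rank names, and ``fragment`` (0/1).  Rows with any empty rank field map to
    ``None`` (incomplete lineage).  Duplicate accessions are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"lineage table missing required columns: {missing}")
    dupes = df["accession"][df["accession"].duplicated()].tolist()
    if dupes:
        raise InputError(f"duplicate accessions in lineage table: {sorted(set(dupes))}")
    table: dict[str, tuple[Optional[Lineage], bool]] = {}
    columns = [df[c].tolist() for c in _TABLE_COLUMNS]
    for acc, *ranks, frag in zip(*columns):
        ranks = [r.strip() for r in ranks]
        lineage = Lineage(*ranks) if all(ranks) else None
        table[acc] = (lineage, frag.strip() in ("1", "true", "True"))
    return table


def write_lineage_table(
    table: Mapping[str, tuple[Optional[Lineage], bool]], path
) -> None:
    rows = []
    for acc, (lineage, frag) in table.items():
        ranks = [lineage.rank(r) if lineage else "" for r in RANKS]
        rows.append([acc] + ranks + ["1" if frag else "0"])
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_fragments(
    records: Iterable[SequenceRecord],
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (kept, removed-as-fragment), preserving order."""
    kept, removed = [], []
    for rec in records:
        (removed if rec.is_fragment else kept).append(rec)
    return kept, removed


def bind_taxonomy(
    alignment: Alignment,
    table: Mapping[str, tuple[Optional[Lineage], bool]],
    superkingdom_filter: Optional[str] = None,
) -> Alignment:
    """Attach lineages and restrict to complete, optionally same-kingdom records.

    A record is retained iff it appears in ``table``, its lineage is complete
    at all seven ranks, and (when ``superkingdom_filter`` is given) its
    kingdom matches the filter.  Fragment flags from the table are carried
    onto the records.
    """
    retained = []
    for rec in alignment:
        entry = table.get(rec.accession)
        if entry is None:
            continue
        lineage, is_fragment = entry
        if lineage is None or not lineage.is_complete:
            continue
        if superkingdom_filter is not None and lineage.kingdom != superkingdom_filter:
            continue
        retained.append(replace(rec, lineage=lineage, is_fragment=is_fragment))
    if len(retained) < 2:
        raise InputError(
            f"taxonomy binding retained {len(retained)} record(s); "
            "at least 2 are required for any distance computation"
        )
    return Alignment(records=tuple(retained))


def rank_summary(alignment: Alignment) -> RankSummary:
    """Distinct-taxon counts per rank over full-path keys.

    Requires every record to carry a complete lineage.
    """
    for rec in alignment:
        if rec.lineage is None or not rec.lineage.is_complete:
            raise PreconditionError(
                f"record {rec.accession} lacks a complete lineage"
            )
    counts = {}
    for rank in RANKS[1:]:
        counts[rank] = len({rec.lineage.path(rank) for rec in alignment})
    return RankSummary(
        phyla=counts["phylum"],
        classes=counts["class"],
        orders=counts["order"],
        families=counts["family"],
        genera=counts["genus"],
        organisms=counts["organism"],
        n_records=len(alignment),
    )


def write_rank_summary(summary: RankSummary, path) -> None:
    rows = [["rank", "distinct_count"]]
    rows += [[k, str(v)] for k, v in summary.as_dict().items()]
    rows.append(["records", str(summary.n_records)])
    with open(path, "w") as fh:
        fh.write("\n".join("\t".join(r) for r in rows) + "\n")


def sequence_length_stats(
    records: Iterable[SequenceRecord],
) -> tuple[float, Optional[float], int]:
    """Mean and sample SD (n-1 denominator) of ungapped sequence lengths.

    Returns ``(mean, sd, n)``; ``sd`` is ``None`` when n = 1.
    """
    lengths = [rec.ungapped_length for rec in records]
    n = len(lengths)
    if n == 0:
        raise InputError("sequence_length_stats requires at least one record")
    mean = sum(lengths) / n
    if n == 1:
        return mean, None, 1
    sd = math.sqrt(sum((x - mean) ** 2 for x in lengths) / (n - 1))
    return mean, sd, n
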