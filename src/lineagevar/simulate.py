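"""Synthetic taxonomically structured sequence datasets with known ground truth.

The generator grows a rank-structured guide tree (kingdom at the root, then
configurable fan-outs at phylum, class, order, family, genus and organism),
draws a uniform-random root sequence over the 20 amino-acid alphabet, and
evolves it down the tree under a symmetric substitution model: on the branch
entering rank level r, every site independently substitutes with probability
``m[r]``, uniformly to one of the 19 other residues.  Leaves are the aligned
(gap-free) sequences; their lineages are read straight off the tree, so the
taxonomy is correct by construction.

Because the model is the symmetric 20-state chain with uniform stationary
frequencies, the probability that the two endpoints of a path with branch
probabilities m_1..m_t differ at a site has the closed form

    p = 1 - [ 1/20 + (19/20) * prod_i (1 - 20 m_i / 19) ]

(:func:`expected_p_distance`), which ties the simulation to the distance
analysis analytically.

Optionally, horizontal transfer is emulated after the fact: a leaf's sequence
is replaced by a re-mutated copy of a donor from a *different* clan at a
chosen crossing rank, while its taxonomic labels stay put — the signature of
HGT is precisely that the sequence moves and the taxonomy does not.

All randomness flows from one master seed through named substreams (tree
shape, root sequence, branch mutations, HGT), so switching HGT on does not
perturb the base sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import dendropy
import numpy as np

from .errors import ConfigError, InputError
from .taxdata import (
    AA_LETTERS,
    RANKS,
    Alignment,
    Lineage,
    SequenceRecord,
    write_alignment_fasta,
    write_lineage_table,
)

Fanout = Union[int, tuple[int, int]]

#: Rank transitions along a root-to-leaf path, in order: the branch entering
#: each phylum, class, order, family, genus, organism, and finally the
#: per-sequence branch below the organism.
TRANSITIONS: tuple[str, ...] = RANKS[1:] + ("sequence",)

_MAX_M = 19.0 / 20.0


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    ``fanout`` maps each of phylum..organism to a child count or an inclusive
    ``(lo, hi)`` range (drawn independently per parent); ``m`` gives one
    substitution probability per rank transition (7 entries, see
    :data:`TRANSITIONS`), each in [0, 19/20).  Defaults are a desk-scale
    vertical-descent regime: per-rank divergence decreasing toward the
    leaves, ragged fan-outs so clan sizes are unequal (large protein-family
    taxonomies are heavily unbalanced, and unequal n_i is what the
    unbalanced ANOVA is for), on the order of 100 sequences of length 160.
    """

    fanout: dict = field(
        default_factory=lambda: {
            "phylum": (2, 3),
            "class": (1, 2),
            "order": (1, 2),
            "family": (1, 2),
            "genus": (2, 3),
            "organism": (2, 4),
        }
    )
    seqs_per_organism: Fanout = (1, 2)
    L: int = 160
    m: tuple[float, ...] = (0.30, 0.15, 0.10, 0.06, 0.04, 0.02, 0.005)
    hgt_rate: float = 0.0
    hgt_crossing_rank: str = "genus"
    seed: int = 0

    def validate(self) -> None:
        if self.L < 1:
            raise ConfigError("L must be >= 1")
        if len(self.m) != len(TRANSITIONS):
            raise ConfigError(
                f"m must have {len(TRANSITIONS)} entries (one per rank transition)"
            )
        for mi in self.m:
            if not (0.0 <= mi < _MAX_M):
                raise ConfigError(f"branch probability {mi} outside [0, 19/20)")
        for rank in ("phylum", "class", "order", "family", "genus", "organism"):
            if rank not in self.fanout:
                raise ConfigError(f"fanout missing rank {rank!r}")
            f = self.fanout[rank]
            lo = f[0] if isinstance(f, tuple) else f
            if lo < 1:
                raise ConfigError(f"fanout at {rank!r} must be >= 1")
        if not (0.0 <= self.hgt_rate <= 1.0):
            raise ConfigError("hgt_rate must be a probability")
        if self.hgt_crossing_rank not in RANKS[1:]:
            raise ConfigError(f"unknown crossing rank {self.hgt_crossing_rank!r}")


@dataclass(frozen=True)
class HgtEvent:
    recipient: str
    donor: str
    crossing_rank: str


@dataclass(frozen=True)
class SimResult:
    """A generated dataset plus its ground truth."""

    alignment: Alignment
    lineage_table: dict
    guide_tree: dendropy.Tree
    hgt_events: tuple[HgtEvent, ...]
    config: SimConfig
    seed: int


def expected_p_distance(path_m: Sequence[float]) -> float:
    """Closed-form expected p-distance across a path of branch probabilities.

    Under the symmetric 20-state chain, a branch with substitution
    probability m has transition eigenvalue ``1 - 20 m / 19``; eigenvalues
    multiply along a path, and the endpoint-disagreement probability is
    ``1 - [1/20 + (19/20) * prod(eigenvalues)]``.
    """
    prod = 1.0
    for m in path_m:
        if not (0.0 <= m < _MAX_M):
            raise InputError(f"branch probability {m} outside [0, 19/20)")
        prod *= 1.0 - 20.0 * m / 19.0
    return 1.0 - (1.0 / 20.0 + (19.0 / 20.0) * prod)


def _draw_count(f: Fanout, rng: np.random.Generator) -> int:
    if isinstance(f, tuple):
        lo, hi = f
        return int(rng.integers(lo, hi + 1))
    return int(f)


def _mutate(seq: np.ndarray, m: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of the symmetric model: hit sites move to one of the
    19 other residues uniformly."""
    if m == 0.0:
        return seq.copy()
    hits = rng.random(seq.size) < m
    out = seq.copy()
    if hits.any():
        shift = rng.integers(1, 20, size=int(hits.sum()))
        out[hits] = (out[hits] + shift) % 20
    return out


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate a dataset under ``config``; fully reproducible from its seed."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    ss_tree, ss_root, ss_mut, ss_hgt = master.spawn(4)
    rng_tree = np.random.default_rng(ss_tree)
    rng_root = np.random.default_rng(ss_root)
    rng_mut = np.random.default_rng(ss_mut)

    root_seq = rng_root.integers(0, 20, size=config.L).astype(np.int64)

    taxon_namespace = dendropy.TaxonNamespace()
    guide = dendropy.Tree(taxon_namespace=taxon_namespace)
    guide.seed_node.label = "Bacteria"

    records: list[SequenceRecord] = []
    table: dict = {}
    counter = [0]

    def recurse(node, seq, path: tuple[str, ...], level: int) -> None:
        # level indexes TRANSITIONS: the branches leaving this node
        if level == len(TRANSITIONS) - 1:
            n_children = _draw_count(config.seqs_per_organism, rng_tree)
        else:
            n_children = _draw_count(config.fanout[TRANSITIONS[level]], rng_tree)
        for i in range(n_children):
            child_seq = _mutate(seq, config.m[level], rng_mut)
            child = dendropy.Node()
            node.add_child(child)
            child.edge.length = config.m[level]
            if level == len(TRANSITIONS) - 1:
                counter[0] += 1
                acc = f"SYN{counter[0]:05d}"
                child.taxon = taxon_namespace.new_taxon(acc)
                lineage = Lineage(*path)
                residues = "".join(AA_LETTERS[c] for c in child_seq)
                records.append(
                    SequenceRecord(
                        accession=acc,
                        residues=residues,
                        is_fragment=False,
                        lineage=lineage,
                    )
                )
                table[acc] = (lineage, False)
            else:
                rank = TRANSITIONS[level]
                name = f"{rank[0].upper()}{i + 1}"
                child.label = name
                recurse(child, child_seq, path + (name,), level + 1)

    recurse(guide.seed_node, root_seq, ("Bacteria",), 0)

    result = SimResult(
        alignment=Alignment(records=tuple(records)),
        lineage_table=table,
        guide_tree=guide,
        hgt_events=(),
        config=config,
        seed=config.seed,
    )
    if config.hgt_rate > 0.0:
        result = inject_hgt(
            result,
            config.hgt_rate,
            config.hgt_crossing_rank,
            seed=int(np.random.default_rng(ss_hgt).integers(0, 2**31 - 1)),
        )
    return result


def inject_hgt(
    result: SimResult,
    hgt_rate: float,
    crossing_rank: str = "genus",
    seed: int = 0,
) -> SimResult:
    """Emulate horizontal transfer: replace some leaves' sequences with
    re-mutated copies from a different clan at ``crossing_rank``.

    Each leaf is independently hit with probability ``hgt_rate``; its donor
    is drawn uniformly from the leaves outside its own clan, and the donated
    sequence is passed through one organism-level branch (the last entry of
    ``m``) so the copy is not byte-identical.  Lineage labels are left
    unchanged.  Leaves with no out-of-clan donor are skipped (and simply do
    not generate events).
    """
    if not (0.0 <= hgt_rate <= 1.0):
        raise InputError("hgt_rate must be a probability")
    if crossing_rank not in RANKS[1:]:
        raise InputError(f"unknown crossing rank {crossing_rank!r}")
    if hgt_rate == 0.0:
        return replace(result, hgt_events=())

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = list(result.alignment.records)
    clans = [rec.lineage.path(crossing_rank) for rec in records]
    code = {ch: i for i, ch in enumerate(AA_LETTERS)}
    m_leaf = result.config.m[-1]

    new_records = list(records)
    events: list[HgtEvent] = []
    for idx, rec in enumerate(records):
        if rng.random() >= hgt_rate:
            continue
        donors = [j for j in range(len(records)) if clans[j] != clans[idx]]
        if not donors:
            continue
        j = int(donors[int(rng.integers(0, len(donors)))])
        donor_seq = np.array([code[c] for c in records[j].residues], dtype=np.int64)
        transferred = _mutate(donor_seq, m_leaf, rng)
        new_records[idx] = replace(
            rec, residues="".join(AA_LETTERS[c] for c in transferred)
        )
        events.append(
            HgtEvent(
                recipient=rec.accession,
                donor=records[j].accession,
                crossing_rank=crossing_rank,
            )
        )
    return replace(
        result,
        alignment=Alignment(records=tuple(new_records)),
        hgt_events=tuple(events),
    )


def write_dataset(result: SimResult, outdir) -> dict:
    """Write FASTA + lineage TSV + ground-truth JSON; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    fasta = os.path.join(outdir, "alignment.fasta")
    tsv = os.path.join(outdir, "lineage.tsv")
    truth = os.path.join(outdir, "ground_truth.json")
    write_alignment_fasta(result.alignment, fasta)
    write_lineage_table(result.lineage_table, tsv)
    payload = {
        "seed": result.seed,
        "config": {
            "fanout": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in result.config.fanout.items()},
            "seqs_per_organism": result.config.seqs_per_organism
            if not isinstance(result.config.seqs_per_organism, tuple)
            else list(result.config.seqs_per_organism),
            "L": result.config.L,
            "m": list(result.config.m),
            "hgt_rate": result.config.hgt_rate,
            "hgt_crossing_rank": result.config.hgt_crossing_rank,
        },
        "guide_tree_newick": result.guide_tree.as_string(schema="newick"),
        "hgt_events": [
            {"recipient": e.recipient, "donor": e.donor, "rank": e.crossing_rank}
            for e in result.hgt_events
        ],
    }
    with open(truth, "w") as fh:
        json.dump(payload, fh, indent=2)
    return {"fasta": fasta, "lineage_tsv": tsv, "ground_truth": truth}


# ---------------------------------------------------------------------------
# Synthetic emulation of the study's bookkeeping marginals
# ---------------------------------------------------------------------------

def _distribute(total: int, parents: int) -> list[int]:
    """Split ``total`` children over ``parents`` as evenly as possible."""
    base, rem = divmod(total, parents)
    return [base + 1 if i < rem else base for i in range(parents)]


def reference_study_dataset() -> tuple[list[SequenceRecord], dict]:
    """A synthetic stand-in for the study's supplementary lineage tables.

    Deterministically constructs 5162 records whose bookkeeping marginals
    match the published dataset: 21 fragments; of the 5141 non-fragments, 1
    archaeal, 3 eukaryotic and 3813 bacterial records carry complete
    seven-rank lineages (the bacterial ones covering exactly 4 phyla, 11
    classes, 41 orders, 82 families, 269 genera and 3744 organisms) and the
    remaining 1324 are lineage-incomplete.  Ungapped lengths are laid out so
    the non-fragment records average 157 +/- 27 and the fragments 113 +/- 50
    (mean +/- sample SD).  The *sequences themselves are synthetic
    placeholders* — only the bookkeeping structure is meaningful.
    """
    counts = [4, 11, 41, 82, 269, 3744]
    # children-per-parent lists down the bacterial hierarchy
    child_lists = []
    for upper, lower in zip(counts, counts[1:]):
        child_lists.append(_distribute(lower, upper))
    seqs_per_org = _distribute(3813, 3744)

    lineages: list[Lineage] = []

    def walk(depth: int, index_path: list[int], names: list[str], flat_idx: list[int]):
        if depth == len(counts):
            for _ in range(seqs_per_org[flat_idx[-1]]):
                lineages.append(Lineage("Bacteria", *names))
            return
        if depth == 0:
            n_children = counts[0]
        else:
            n_children = child_lists[depth - 1][flat_idx[-1]]
        for i in range(n_children):
            child_flat = _next_flat(depth, flat_idx, i)
            label = f"{RANKS[depth + 1].capitalize()}{child_flat + 1}"
            walk(depth + 1, index_path + [i], names + [label], flat_idx + [child_flat])

    # flat child indexing: running counters per depth
    counters = [0] * (len(counts) + 1)

    def _next_flat(depth: int, flat_idx: list[int], i: int) -> int:
        idx = counters[depth]
        counters[depth] += 1
        return idx

    walk(0, [], [], [-1])
    assert len(lineages) == 3813

    records: list[SequenceRecord] = []
    table: dict = {}

    def lengths(n: int, mean: int, dev: int) -> list[int]:
        # symmetric +/-dev layout with one record at the mean when n is odd:
        # sample mean = mean exactly, sample SD = dev exactly
        half = n // 2
        out = [mean + dev] * half + [mean - dev] * half
        if n % 2:
            out.append(mean)
        return out

    nonfrag_lengths = lengths(5141, 157, 27)
    frag_lengths = lengths(21, 113, 50)
    max_len = max(nonfrag_lengths + frag_lengths)

    def make(acc: str, length: int, frag: bool, lineage: Optional[Lineage]):
        residues = "A" * length + "-" * (max_len - length)
        records.append(
            SequenceRecord(
                accession=acc, residues=residues, is_fragment=frag, lineage=lineage
            )
        )
        table[acc] = (lineage, frag)

    acc_no = 0

    def next_acc() -> str:
        nonlocal acc_no
        acc_no += 1
        return f"REF{acc_no:05d}"

    li = iter(nonfrag_lengths)
    for lineage in lineages:  # 3813 complete bacterial
        make(next_acc(), next(li), False, lineage)
    make(next_acc(), next(li), False,
         Lineage("Archaea", "Phylum_A1", "Class_A1", "Order_A1",
                 "Family_A1", "Genus_A1", "Organism_A1"))
    for i in range(3):
        make(next_acc(), next(li), False,
             Lineage("Eukaryota", f"Phylum_E{i+1}", f"Class_E{i+1}",
                     f"Order_E{i+1}", f"Family_E{i+1}", f"Genus_E{i+1}",
                     f"Organism_E{i+1}"))
    for _ in range(1324):  # incomplete bacterial records
        make(next_acc(), next(li), False, None)
    for length in frag_lengths:
        make(next_acc(), length, True, None)
    assert len(records) == 5162
    return records, table
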