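"""Pairwise p-distances, per-taxon distance statistics, and the group contrast.

The p-distance between two aligned sequences is the proportion of compared
columns at which they differ.  Which columns are compared is set by the
deletion policy:

* ``pairwise`` — for each pair separately, drop only columns where either
  sequence shows a gap or an X ambiguity code;
* ``complete`` — drop every column containing a gap or X in *any* sequence,
  once, before all comparisons.

Group statistics follow a per-sequence observation unit by default: each
sequence contributes one observation, namely its mean distance to all other
members of its group.  This makes the reported n a sequence count and the
group SD a spread over sequences, matching how per-taxon averages are usually
tabulated for large protein families.  An all-pairs unit (one observation per
unordered pair) is available as an alternative policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedDistanceError
from .taxdata import AA_LETTERS, AMBIGUOUS, GAP, RANKS, Alignment, Lineage

_CODE = {ch: i for i, ch in enumerate(AA_LETTERS)}
_CODE[GAP] = 20
_CODE[AMBIGUOUS] = 21
_N_VALID = 20  # codes 0..19 are confident residues


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """Encode an alignment as an (n, L) uint8 matrix; gap=20, X=21."""
    n, L = len(alignment), alignment.n_columns
    out = np.empty((n, L), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.uint8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    for i, rec in enumerate(alignment):
        out[i] = lut[np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8)]
    return out


@dataclass
class DistanceMatrix:
    """Symmetric labeled matrix of p-distances with per-pair site counts."""

    labels: tuple[str, ...]
    d: np.ndarray
    comparable_sites: np.ndarray
    deletion_policy: str = "pairwise"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self._index[lab] for lab in labels])
        return DistanceMatrix(
            labels=tuple(labels),
            d=self.d[np.ix_(idx, idx)],
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)],
            deletion_policy=self.deletion_policy,
        )


def _encode_pair(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise InputError(
            f"sequences have unequal lengths ({len(a)} vs {len(b)})"
        )
    lut = np.zeros(128, dtype=np.uint8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    try:
        ea = lut[np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)]
        eb = lut[np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)]
    except UnicodeEncodeError as exc:
        raise InputError(f"non-ASCII residue symbol: {exc}") from exc
    return ea, eb


def p_distance(
    a: str,
    b: str,
    policy: str = "pairwise",
    complete_mask: Optional[np.ndarray] = None,
) -> tuple[float, int]:
    """p-distance between two aligned residue strings.

    Returns ``(d, sites)`` where ``sites`` is the number of compared columns.
    Raises :class:`UndefinedDistanceError` when no column is comparable.
    """
    ea, eb = _encode_pair(a, b)
    if policy == "pairwise":
        valid = (ea < _N_VALID) & (eb < _N_VALID)
    elif policy == "complete":
        if complete_mask is None:
            raise InputError("complete policy requires a precomputed column mask")
        valid = np.asarray(complete_mask, dtype=bool)
        if valid.shape != ea.shape:
            raise InputError("complete_mask length does not match alignment")
    else:
        raise InputError(f"unknown deletion policy: {policy!r}")
    sites = int(valid.sum())
    if sites == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    diffs = int((valid & (ea != eb)).sum())
    return diffs / sites, sites


def complete_deletion_mask(alignment: Alignment) -> np.ndarray:
    """Boolean mask of columns free of gaps and X in every record."""
    enc = encode_alignment(alignment)
    return np.all(enc < _N_VALID, axis=0)


def distance_matrix(
    alignment: Alignment, policy: str = "pairwise", mode: str = "strict"
) -> DistanceMatrix:
    """All-pairs p-distance matrix under the given deletion policy.

    ``mode="strict"`` raises on any pair with zero comparable sites, listing
    the offending pairs; ``mode="permissive"`` records those entries as NaN.
    """
    if len(alignment) < 2:
        raise InputError("distance matrix requires at least 2 records")
    enc = encode_alignment(alignment)
    n, L = enc.shape
    if policy == "complete":
        mask = np.all(enc < _N_VALID, axis=0)
        enc = enc[:, mask]
        valid = np.ones_like(enc, dtype=bool)
    elif policy == "pairwise":
        valid = enc < _N_VALID
    else:
        raise InputError(f"unknown deletion policy: {policy!r}")

    v = valid.astype(np.float64)
    sites = v @ v.T
    # matches = sum over the 20 confident letters of per-letter co-occurrence
    matches = np.zeros((n, n))
    for code in range(_N_VALID):
        ind = (enc == code).astype(np.float64)
        matches += ind @ ind.T
    sites_i = np.rint(sites).astype(np.int64)
    diffs = np.rint(sites - matches).astype(np.int64)

    undefined = sites_i == 0
    np.fill_diagonal(undefined, False)
    if undefined.any():
        pairs = [
            (alignment.accessions[i], alignment.accessions[j])
            for i, j in zip(*np.nonzero(np.triu(undefined)))
        ]
        if mode == "strict":
            raise UndefinedDistanceError(
                f"pairs with no comparable sites: {pairs}"
            )

    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(sites_i > 0, diffs / np.maximum(sites_i, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        labels=alignment.accessions,
        d=d,
        comparable_sites=sites_i,
        deletion_policy=policy,
    )


def percent_identity(a: str, b: str) -> float:
    """Percent identity of a two-sequence alignment.

    Denominator convention: the full alignment length including gap columns;
    a column counts as identical only when both symbols are equal, non-gap
    confident residues.
    """
    ea, eb = _encode_pair(a, b)
    if ea.size == 0:
        raise InputError("zero-column alignment")
    identical = int(((ea == eb) & (ea < _N_VALID)).sum())
    return 100.0 * identical / ea.size


@dataclass(frozen=True)
class GroupStats:
    """Distance statistics for one taxon at one rank."""

    rank: str
    taxon: tuple[str, ...]  # full path from kingdom; ("all",) for the global row
    n: int
    mean: Optional[float]
    sd: Optional[float]
    unit_policy: str

    @property
    def taxon_name(self) -> str:
        return self.taxon[-1]


def _per_sequence_means(sub: np.ndarray) -> np.ndarray:
    """Each row's mean distance to the other rows of a square matrix."""
    m = sub.shape[0]
    return (sub.sum(axis=1)) / (m - 1)


def group_distance_table(
    matrix: DistanceMatrix,
    lineages: Mapping[str, Lineage],
    rank: str,
    unit_policy: str = "per-sequence-mean",
) -> list[GroupStats]:
    """Per-taxon mean/SD of p-distances at a rank (or ``rank="all"``).

    Under the default per-sequence-mean policy each member sequence
    contributes its mean distance to the other members of the same taxon;
    singleton taxa report mean and SD absent.  Under ``all-pairs`` the
    observations are the within-taxon pairwise distances themselves.
    The special rank ``"all"`` yields one global row over every sequence's
    mean distance to all the others.
    """
    if unit_policy not in ("per-sequence-mean", "all-pairs"):
        raise InputError(f"unknown unit policy: {unit_policy!r}")
    if rank != "all" and rank not in RANKS:
        raise InputError(f"unknown rank name: {rank!r}")

    if rank == "all":
        groups = {("all",): list(matrix.labels)}
    else:
        groups: dict[tuple[str, ...], list[str]] = {}
        for lab in matrix.labels:
            lin = lineages[lab]
            groups.setdefault(lin.path(rank), []).append(lab)

    out = []
    for taxon in sorted(groups):
        members = groups[taxon]
        n = len(members)
        sub = matrix.submatrix(members).d
        if unit_policy == "per-sequence-mean":
            if n < 2:
                out.append(GroupStats(rank, taxon, n, None, None, unit_policy))
                continue
            obs = _per_sequence_means(sub)
        else:
            if n < 2:
                out.append(GroupStats(rank, taxon, n, None, None, unit_policy))
                continue
            obs = sub[np.triu_indices(n, k=1)]
        mean = float(np.mean(obs))
        sd = float(np.std(obs, ddof=1)) if obs.size > 1 else None
        out.append(GroupStats(rank, taxon, n, mean, sd, unit_policy))
    return out


def group_observations(
    matrix: DistanceMatrix,
    members: Sequence[str],
    within: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Per-sequence mean-distance observations for ``members``.

    Each member's observation is its mean distance to all *other* sequences
    in ``within`` (defaults to ``members`` itself).
    """
    within = list(within) if within is not None else list(members)
    sub = matrix.submatrix(within)
    pos = {lab: i for i, lab in enumerate(within)}
    m = len(within)
    if m < 2:
        raise InputError("observations require at least 2 reference sequences")
    sums = sub.d.sum(axis=1)
    return np.array([sums[pos[lab]] / (m - 1) for lab in members])


def welch_t_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Welch unequal-variance t test; returns (t, Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("each group needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
        raise InputError("both groups have zero variance but unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def write_group_table(groups: Sequence[GroupStats], path) -> None:
    """Write per-taxon distance statistics as a TSV report."""
    with open(path, "w") as fh:
        fh.write("rank\ttaxon\tn\tmean\tsd\tunit_policy\n")
        for g in groups:
            mean = f"{g.mean:.6f}" if g.mean is not None else "NA"
            sd = f"{g.sd:.6f}" if g.sd is not None else "NA"
            fh.write(
                f"{g.rank}\t{'/'.join(g.taxon)}\t{g.n}\t{mean}\t{sd}\t{g.unit_policy}\n"
            )


def write_phylip(matrix: DistanceMatrix, path) -> None:
    """Write a square PHYLIP distance matrix (relaxed label widths)."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix)}\n")
        for i, lab in enumerate(matrix.labels):
            row = " ".join(f"{x:.6f}" for x in matrix.d[i])
            fh.write(f"{lab}  {row}\n")


def read_phylip(path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix written by :func:`write_phylip`."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    header = tokens[0].strip()
    if not header.isdigit():
        raise InputError(f"bad PHYLIP header line: {header!r}")
    n = int(header)
    labels, rows = [], []
    for line in tokens[1 : n + 1]:
        parts = line.split()
        if len(parts) != n + 1:
            raise InputError(f"bad PHYLIP row (expected {n + 1} fields): {line!r}")
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    d = np.array(rows)
    if not np.allclose(d, d.T):
        raise InputError("PHYLIP matrix is not symmetric")
    return DistanceMatrix(
        labels=tuple(labels),
        d=d,
        comparable_sites=np.zeros_like(d, dtype=np.int64),
        deletion_policy="unknown",
    )
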