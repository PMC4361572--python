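"""Inter- vs intra-clan variance partitioning of p-distances.

At each taxonomic bifurcation (a parent taxon split into its child taxa,
its "clans"), the spread of p-distance observations is decomposed with an
unbalanced one-way random-effects (model II) ANOVA:

    SS_A = sum_i n_i (ybar_i - ybar)^2          MS_A = SS_A / (k - 1)
    SS_W = sum_i sum_j (y_ij - ybar_i)^2        MS_W = SS_W / (N - k)
    n0   = (N - sum_i n_i^2 / N) / (k - 1)
    s2_A = max(0, (MS_A - MS_W) / n0)           s2_W = MS_W

with k clans, n_i observations in clan i, N = sum n_i.  The reported
percentages are

    pct_inter = 100 s2_A / (s2_A + s2_W)        pct_intra = 100 - pct_inter.

A large inter-clan share means the observations separate cleanly along the
taxonomic boundary (the vertical-descent signal); an inflated intra-clan
share means sequences vary as much within a clan as across clans, which is
what repeated cross-clan (horizontal) transfer produces.

The observation unit is per-sequence.  Three units are implemented; every
report names the one used:

* ``global`` (default) — sequence j's observation is its mean p-distance to
  all other sequences in the dataset.  A clan's realized stem divergence
  shifts its members' global profiles coherently, so the among-clan variance
  picks up between-clan divergence while the within-clan variance reflects
  only the clan's internal spread.  This mirrors how per-sequence averages
  are tabulated for the dataset as a whole (each sequence versus all the
  rest).
* ``parent-wide`` — the mean is restricted to the parent taxon's members.
  Caution: for a bifurcation into clans of similar size this unit is
  structurally blind — a clan's divergence inflates every clan's group mean
  by nearly the same amount (exactly the same for two equal clans), so
  pct_inter collapses toward noise regardless of how divergent the clans
  are.  It is informative only under strongly unequal clan sizes.
* ``within-clan`` — the mean is restricted to the sequence's own clan;
  group means then compare internal diversities, not divergence between
  clans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .distances import DistanceMatrix, group_observations
from .taxdata import RANKS, Lineage


@dataclass(frozen=True)
class ClanObservations:
    """Observations grouped by the child clans of one parent taxon."""

    parent_taxon: tuple[str, ...]
    parent_rank: str
    child_rank: str
    groups: tuple[tuple[str, np.ndarray], ...]
    unit_policy: str = "parent-wide"

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n_total(self) -> int:
        return int(sum(len(obs) for _, obs in self.groups))


@dataclass(frozen=True)
class VarianceComponents:
    """One bifurcation's model-II ANOVA decomposition."""

    parent_taxon: tuple[str, ...]
    parent_rank: str
    child_rank: str
    k: int
    N: int
    n_i: tuple[int, ...]
    n0: Optional[float]
    MS_A: Optional[float]
    MS_W: Optional[float]
    F: Optional[float]
    s2_A: Optional[float]
    s2_W: Optional[float]
    pct_inter: Optional[float]
    pct_intra: Optional[float]
    computable: bool
    reason: str = ""


def clan_groups(
    matrix: DistanceMatrix,
    lineages: Mapping[str, Lineage],
    parent_taxon: Sequence[str],
    unit_policy: str = "global",
) -> ClanObservations:
    """Group per-sequence distance observations by the parent's child clans.

    ``parent_taxon`` is a full path from kingdom down to the parent rank.
    Children are the parent's immediate sub-taxa at the next rank.  The
    observation for each member sequence is its mean distance to all other
    sequences in the dataset (``global``, default), in the parent taxon
    (``parent-wide``), or in its own clan (``within-clan``; singleton clans
    then carry no observation).  See the module docstring for the trade-offs.
    """
    if unit_policy not in ("global", "parent-wide", "within-clan"):
        raise InputError(f"unknown unit policy: {unit_policy!r}")
    parent_taxon = tuple(parent_taxon)
    depth = len(parent_taxon) - 1
    if depth >= len(RANKS) - 1:
        raise InputError("parent taxon must be above the organism rank")
    parent_rank = RANKS[depth]
    child_rank = RANKS[depth + 1]

    members = [
        lab
        for lab in matrix.labels
        if lineages[lab].path(parent_rank) == parent_taxon
    ]
    if not members:
        raise InputError(f"no sequences under parent taxon {parent_taxon}")

    clans: dict[str, list[str]] = {}
    for lab in members:
        clans.setdefault(lineages[lab].rank(child_rank), []).append(lab)

    groups = []
    for clan in sorted(clans):
        labs = clans[clan]
        if unit_policy == "global":
            if len(matrix) < 2:
                continue
            obs = group_observations(matrix, labs, within=list(matrix.labels))
        elif unit_policy == "parent-wide":
            if len(members) < 2:
                continue
            obs = group_observations(matrix, labs, within=members)
        else:
            if len(labs) < 2:
                continue
            obs = group_observations(matrix, labs)
        groups.append((clan, obs))
    return ClanObservations(
        parent_taxon=parent_taxon,
        parent_rank=parent_rank,
        child_rank=child_rank,
        groups=tuple(groups),
        unit_policy=unit_policy,
    )


def model2_anova(obs: ClanObservations) -> VarianceComponents:
    """Unbalanced one-way model-II ANOVA on grouped observations.

    Negative among-clan variance estimates are truncated at zero and flagged
    in ``reason``; degenerate layouts (fewer than two clans, no within-clan
    degrees of freedom, zero total variance) come back with
    ``computable=False`` or a stated reason rather than raising.
    """
    base = dict(
        parent_taxon=obs.parent_taxon,
        parent_rank=obs.parent_rank,
        child_rank=obs.child_rank,
    )
    n_i = tuple(len(o) for _, o in obs.groups)
    k = len(n_i)
    N = int(sum(n_i))
    if k < 2:
        return VarianceComponents(
            **base, k=k, N=N, n_i=n_i, n0=None, MS_A=None, MS_W=None, F=None,
            s2_A=None, s2_W=None, pct_inter=None, pct_intra=None,
            computable=False, reason="k<2",
        )
    if N <= k:
        return VarianceComponents(
            **base, k=k, N=N, n_i=n_i, n0=None, MS_A=None, MS_W=None, F=None,
            s2_A=None, s2_W=None, pct_inter=None, pct_intra=None,
            computable=False, reason="no within-group degrees of freedom (N<=k)",
        )

    values = [np.asarray(o, dtype=float) for _, o in obs.groups]
    grand = float(np.concatenate(values).mean())
    means = [float(v.mean()) for v in values]
    SS_A = float(sum(n * (m - grand) ** 2 for n, m in zip(n_i, means)))
    SS_W = float(sum(((v - m) ** 2).sum() for v, m in zip(values, means)))
    MS_A = SS_A / (k - 1)
    MS_W = SS_W / (N - k)
    n0 = (N - sum(n * n for n in n_i) / N) / (k - 1)

    reason = ""
    if SS_A + SS_W == 0.0:
        return VarianceComponents(
            **base, k=k, N=N, n_i=n_i, n0=n0, MS_A=MS_A, MS_W=MS_W, F=None,
            s2_A=0.0, s2_W=0.0, pct_inter=0.0, pct_intra=100.0,
            computable=True, reason="degenerate: zero total variance",
        )
    s2_A_raw = (MS_A - MS_W) / n0
    s2_A = max(0.0, s2_A_raw)
    if s2_A_raw < 0.0:
        reason = "s2_A truncated at 0"
    s2_W = MS_W
    F = MS_A / MS_W if MS_W > 0 else None
    if s2_A + s2_W == 0.0:
        pct_inter = 0.0
        reason = (reason + "; " if reason else "") + "degenerate: zero variance"
    else:
        pct_inter = 100.0 * s2_A / (s2_A + s2_W)
    return VarianceComponents(
        **base, k=k, N=N, n_i=n_i, n0=float(n0), MS_A=MS_A, MS_W=MS_W, F=F,
        s2_A=s2_A, s2_W=s2_W, pct_inter=pct_inter, pct_intra=100.0 - pct_inter,
        computable=True, reason=reason,
    )


def lineage_variance_partition(
    matrix: DistanceMatrix,
    lineages: Mapping[str, Lineage],
    unit_policy: str = "global",
) -> list[VarianceComponents]:
    """Model-II decomposition at every taxonomic bifurcation.

    One row per parent taxon with children at the next rank, from the kingdom
    (children = phyla) down to genera (children = organisms).  Genus-level
    parents enter only when at least two distinct organisms are represented.
    Uncomputable bifurcations are retained with their reasons — they are
    data, not errors.  Output order is deterministic: by rank depth, then by
    full-path taxon name.
    """
    parents: set[tuple[str, ...]] = set()
    for lab in matrix.labels:
        lin = lineages[lab]
        for rank in RANKS[:-1]:
            parents.add(lin.path(rank))

    out = []
    for parent in sorted(parents, key=lambda p: (len(p), p)):
        obs = clan_groups(matrix, lineages, parent, unit_policy=unit_policy)
        if obs.parent_rank == "genus" and obs.k < 2:
            # genus with a single organism: no organism-level bifurcation
            continue
        out.append(model2_anova(obs))
    return out


def write_varpart_table(rows: Sequence[VarianceComponents], path) -> None:
    """Write the per-bifurcation decomposition as a TSV report."""
    df = varpart_frame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def varpart_frame(rows: Sequence[VarianceComponents]) -> pd.DataFrame:
    recs = []
    for r in rows:
        recs.append(
            {
                "parent_rank": r.parent_rank,
                "parent_taxon": "/".join(r.parent_taxon),
                "child_rank": r.child_rank,
                "k": r.k,
                "N": r.N,
                "n0": r.n0,
                "MS_A": r.MS_A,
                "MS_W": r.MS_W,
                "s2_A": r.s2_A,
                "s2_W": r.s2_W,
                "pct_inter": r.pct_inter,
                "pct_intra": r.pct_intra,
                "computable": r.computable,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(
        recs,
        columns=[
            "parent_rank", "parent_taxon", "child_rank", "k", "N", "n0",
            "MS_A", "MS_W", "s2_A", "s2_W", "pct_inter", "pct_intra",
            "computable", "reason",
        ],
    )
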