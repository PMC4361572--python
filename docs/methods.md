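# Methods

## Scope and data model

`lineagevar` analyzes an aligned amino-acid family in which every sequence
carries an accession, a fragment flag, and a seven-rank taxonomic lineage
(kingdom, phylum, class, order, family, genus, organism).  Records flagged as
fragments are excluded first; records lacking any rank, or outside the chosen
superkingdom (default `Bacteria`), are excluded at taxonomy binding.  Taxon
names are keyed by their *full path* from the kingdom down, so a genus name
reused under two families is never merged.  Ungapped lengths are used for
length statistics, since lengths describe the sequences, not the alignment.

## p-distances

The p-distance between two aligned sequences is the fraction of compared
columns at which they differ.  Compared columns are set by the deletion
policy: *pairwise* (default) drops, per pair, only columns where either
sequence shows a gap or the ambiguity code `X`; *complete* drops every column
containing a gap or `X` in any sequence before all comparisons.  Pairwise
deletion is the default because it wastes no data on alignments with
scattered indels; complete deletion is available for sensitivity analysis.
`X` is treated like a gap everywhere: a p-distance counts confident
differences only.  A pair with zero comparable columns has no distance; in
strict mode this is an error naming the offending pairs, in permissive mode
a flagged missing entry.

Percent identity for a two-sequence alignment uses the full alignment length
(gap columns included) as denominator and counts a column as identical only
when both symbols are equal confident residues.  Conventions differ between
tools on this point (some divide by the shorter sequence length); the choice
is stated in every output so reported identities are reproducible.  Under
this convention a 169-column alignment of a 155- and a 161-residue chain
with 82 identical positions scores 100·82/169 = 48.521%.

## Group statistics and the observation unit

Per-taxon distance statistics use a per-sequence observation unit: each
member sequence contributes one observation, its mean distance to the other
members of its group, so the reported `n` is a sequence count and the SD is
a spread over sequences.  An all-pairs unit (one observation per unordered
pair) is available.  A pseudo-rank `all` yields the global statistic over
each sequence's mean distance to every other sequence.  Welch's
unequal-variance t test (Satterthwaite degrees of freedom, via
`scipy.stats.ttest_ind`) serves for two-group contrasts of such
observations.

## Variance partitioning (model II ANOVA)

At a bifurcation — a parent taxon with `k ≥ 2` child clans — observations are
grouped by clan and decomposed with the unbalanced one-way random-effects
estimator based on expected mean squares:

    SS_A = Σ n_i (ȳ_i − ȳ)²         MS_A = SS_A / (k − 1)
    SS_W = Σ_i Σ_j (y_ij − ȳ_i)²    MS_W = SS_W / (N − k)
    n0   = (N − Σ n_i²/N) / (k − 1)
    s²_A = max(0, (MS_A − MS_W)/n0)  s²_W = MS_W

with `pct_inter = 100·s²_A/(s²_A+s²_W)` and `pct_intra` its complement
(summing to 100 exactly).  Negative among-clan estimates are truncated at
zero and flagged, so a reported 0% inter is distinguishable from a truncated
estimate.  Degenerate layouts are data, not errors: `k < 2` (the bifurcation
cannot be computed), `N = k` (no within-clan degrees of freedom) and zero
total variance are all retained in the report with a reason string.  The
F ratio `MS_A/MS_W` is emitted as a diagnostic only.

### Observation units, and a structural caveat

Three per-sequence units are implemented; every report names the unit used.

* **global** (default): observation = mean distance to all other sequences
  in the dataset.  A clan's realized stem divergence shifts all its members'
  global profiles coherently, so group means separate when clans are
  genuinely divergent, while the within-clan spread reflects only the clan's
  internal heterogeneity.
* **parent-wide**: the mean is restricted to the parent taxon's members.
  This unit is structurally blind at near-balanced bifurcations: with two
  clans of equal size, a clan's divergence raises *both* group means by
  exactly the same amount, so the among-clan component collapses to noise
  regardless of how divergent the clans are.  It becomes informative only
  under strongly unequal clan sizes (which heavily unbalanced real
  taxonomies often provide).  The global unit escapes this because any one
  clan is small relative to the whole dataset.
* **within-clan**: the mean is restricted to the sequence's own clan; group
  means then compare internal diversities rather than divergence between
  clans.

The global unit is the default for both reasons: it matches the per-sequence
averaging used for the dataset-wide statistic (each sequence versus all the
rest), and it is the only unit whose among-clan component responds to
between-clan divergence across balanced and unbalanced designs alike.

The partition table contains one row per parent taxon with children at the
next rank, from the kingdom (children = phyla) down to genera (children =
organisms); genus-level parents enter only when at least two organisms are
represented.  Rows are ordered by rank depth and then full-path name, so
output is deterministic.

## Neighbor joining and bootstrap

The NJ implementation is canonical: at each step join the active pair
minimizing `Q(i,j) = (r−2)d(i,j) − R(i) − R(j)`, assign pendant lengths
`v_i = d(i,j)/2 + (R(i)−R(j))/(2(r−2))`, and reduce with
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`; the final three nodes join at a
trifurcating seed node ("last-join" display root).  Two policies are pinned
for reproducibility: ties in `Q` break by the lexicographically smallest
pair in current label order, and negative branch lengths (possible on
non-additive input) are clamped to zero by default (`keep` preserves raw
values for diagnostics).  On additive matrices the algorithm recovers the
generating topology and branch lengths exactly; the test suite verifies
recovery to 1e-9 on random binary trees and cross-checks topologies against
an independent NJ implementation (scikit-bio).

Bootstrap support for an internal edge is the percentage of replicates —
column resamples of the alignment, each re-run through distance matrix and
NJ — whose tree contains the same bipartition of the leaf set.  Replicate
`r` draws from a generator seeded by `(seed, r)`, so partial re-runs and
parallel schedules agree.  Supports are attached to the point-estimate tree
and serialized as internal node labels in Newick (branch lengths with six
decimals); reading a tree back restores topology, lengths and supports.

Bifurcation counts (the number of internal nodes on the display-root-to-leaf
path, root included) depend on the display rooting, which is therefore an
explicit parameter: `midpoint` (default) or `last-join`.  Midpoint rooting
is implemented directly: the root is placed at the midpoint of the longest
leaf-to-leaf path, *at* an existing node when the midpoint falls on one, so
no spurious degree-2 node inflates counts.

## The synthetic generator

The generator emulates the structure of a lineage-annotated family: a
rank-structured guide tree (one kingdom; configurable, possibly ragged
fan-outs at phylum through organism; one or more sequences per organism), a
uniform-random root sequence over the 20-letter alphabet, and independent
site evolution along branches.  On the branch entering rank level `r` every
site substitutes with probability `m[r]`, uniformly to one of the 19 other
residues.  This symmetric chain has transition eigenvalue `1 − 20m/19` per
branch; eigenvalues multiply along a path, giving the exact endpoint
disagreement probability

    p = 1 − [1/20 + (19/20)·Π_i (1 − 20·m_i/19)]

implemented as `expected_p_distance` — the analytic oracle tying the
simulator to the distance code.  Rates must stay below 19/20 (saturation).

Defaults (chosen once as a desk-scale analogue of a large, heavily
unbalanced bacterial family, and used as the standard conditions throughout
the verification suite): fan-out ranges phylum (2–3), class (1–2),
order (1–2), family (1–2), genus (2–3), organism (2–4), sequences per
organism (1–2) — ragged on purpose, because real clan sizes are strongly
unequal and unequal `n_i` is what the unbalanced estimator is for; alignment
length `L = 160` columns (matching a short chaperone-sized protein); branch
probabilities `m = (0.30, 0.15, 0.10, 0.06, 0.04, 0.02, 0.005)` per rank
transition, decreasing toward the leaves (the vertical-descent regime:
deeper splits carry more divergence).  A default dataset has on the order of
50–180 sequences.

Horizontal transfer is emulated post hoc: each leaf independently with
probability `hgt_rate` has its sequence replaced by a copy of a donor drawn
from a different clan at the chosen crossing rank, re-mutated along one
organism-level branch so the copy is not byte-identical; its lineage labels
are unchanged (the defining signature: the sequence moves, the taxonomy does
not).  All randomness flows from one master seed through named substreams
(tree shape, root sequence, branch mutations, transfer), so enabling
transfer does not perturb the base sequences, and equal seeds give
byte-identical datasets.

What the simulator deliberately does **not** emulate: indels (sequences are
generated aligned and gap-free, so pairwise- and complete-deletion policies
coincide on simulated data and must be exercised on hand-built fixtures);
empirical amino-acid exchangeabilities and frequencies (the closed form
requires the symmetric uniform chain); site-rate heterogeneity and
selection; and the extreme clan-size skew of real databases (ranges are
uniform, real abundances are closer to power laws).  Passing tests on
synthetic data therefore validate the estimators and the pipeline plumbing,
not the biological fidelity of any particular dataset.

A separate deterministic constructor builds a bookkeeping-only reference
table (5162 records: 21 fragments; 3813 complete bacterial lineages covering
4 phyla, 11 classes, 41 orders, 82 families, 269 genera, 3744 organisms;
ungapped lengths averaging 157±27 for non-fragments and 113±50 for
fragments).  Its sequences are placeholders; only the lineage structure and
length layout are meaningful, and it exists so the filtering and counting
machinery can be exercised at realistic scale without downloads.

## Verification suite: regimes and sizes

The verification suite runs at sizes chosen to make each check sharp:
distance matrices against a brute-force column-counting oracle on 200 random
alignments (≤10 sequences × ≤50 columns, with gaps and `X`); the ANOVA
against a hand-worked unbalanced example (`n0 = 2.4`, inter share 92.15%)
and an independent plain-loop evaluation on random unbalanced layouts; NJ
recovery on 100 random additive matrices (n ≤ 12); estimator recovery on
100 simulated layouts with `k = 20` clans of `n_i = 30` drawn from
`y_ij = a_i + e_ij`, `a_i ~ N(0, 9)`, `e_ij ~ N(0, 1)` — a 90% true inter
share, the inter-dominant regime the generator emulates, where the
estimator's sampling SD (~2.9 points) sits inside the ±5-point check (at a
50% true share the sampling SD is ~8 points and no estimator could pass such
a band); Monte-Carlo agreement of mean leaf-pair distance with the closed
form within 3σ over 200 replicates; a paired 20-seed contrast showing that
cross-clan transfer at rate 0.5 collapses the genus-level inter share; and a
byte-level determinism audit of the full report bundle on a 192-sequence
dataset with 100 bootstrap replicates.

Because a bifurcation with `k = 2` clans estimates the among-clan variance
from a single degree of freedom, *individual* bifurcations are intrinsically
noisy — roughly half of all k=2 bifurcations will under-shoot their true
inter share no matter how strong the signal.  Aggregate statements are
therefore made on the median across bifurcations, which exceeds 50% in
essentially every seeded run of the default vertical-descent regime.

## Known limitations

* p-distances are uncorrected; no Poisson/JTT/Kimura correction is offered,
  so saturated distances compress deep divergences.
* The variance decomposition treats observations as exchangeable within
  clans, but per-sequence mean distances are correlated through shared
  history; the percentages are descriptive decompositions, not tested
  effect sizes (the F ratio is a diagnostic only).
* Bootstrap on thousands of sequences at 1000 replicates is cluster-scale;
  the CLI exposes `bootstrap_reps` so desk runs can scale it down, and
  reports always echo the value used.
* Midpoint rooting of a tree with many zero-length branches can sit on a
  plateau; ties resolve deterministically but arbitrarily.
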