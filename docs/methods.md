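# Methods

## Problem and data model

The package analyzes matrices of discrete morphological characters coded
0–9 per taxon, with `?` for states that could not be observed and `-` for
characters that logically do not apply (e.g. wing venation in a wingless
taxon). All characters are unordered ("non-additive"): a change between any
two states costs one step. Both `?` and `-` are optimization-neutral — the
taxon is assigned the full set of states observed in that column, so it can
never force a step. This mirrors the convention of the classic
NONA/WinClada lineage of programs, and the reproduced study statistics
depend on it; structured treatments of inapplicability (e.g. composite
coding or explicit controller characters) are out of scope.

The packaged study data are the 33 × 67 Helopini matrix transcribed
verbatim (including cells that disagree with the prose character
descriptions, such as state 3 in character 5 — transcription fidelity wins
over internal consistency), with taxon metadata (tribe, subtribe, region,
outgroup/root flags) and the 67 character descriptions. One spelling
conflict between the taxon table and the matrix ("peryronis" vs
"peyronis") was resolved in favor of the matrix spelling.

## Parsimony engine

Lengths are computed two independent ways:

1. **Bitmask Hartigan pass** (`tree_length`, `per_character_lengths`): each
   cell is a ≤10-bit state-set mask; a postorder pass keeps, at every
   vertex, the states present in the maximum number K of child sets and
   adds (children − K) steps. Exact on trees of any vertex degree; on
   binary trees it reduces to Fitch's intersection/union rule. All
   characters are processed simultaneously as numpy arrays.
2. **Uniform-cost dynamic program over states** (`edge_analysis`,
   `reconstruct`): Sankoff-style down- and up-passes give, for every branch
   and character, the cost of every (parent state, child state)
   combination. From these the engine derives most-parsimonious state sets
   per vertex, whether a branch change is *forced* (present in every
   most-parsimonious reconstruction: min over equal end states exceeds the
   optimum) and whether the derived state is unique. This is exact —
   verified against explicit enumeration of all optimal labelings on small
   trees — and stricter than the common ACCTRAN/DELTRAN-agreement
   approximation.

The two paths are cross-checked against each other and against an
independent pure-Python Sankoff oracle in the test suite. Minimum steps
m = (observed states − 1) and maximum steps g = (scored taxa − count of the
most frequent state) exclude `?`/`-` cells; an all-missing column has
m = g = 0.

**Index display convention.** ci = m/s, ri = (g−s)/(g−m), ensembles from
summed M, S, G. Displayed values are *truncated* at two decimals
(`truncate2`: 2/3 → 0.66), because that is demonstrably how the reference
programs print them (the study's own per-character list prints 1/6 as 0.16
and 3/8 as 0.37, and an ensemble RI of 0.5665 as 0.56). Full precision is
kept internally. ci is reported as undefined ("—") when s = 0 rather than
inflated to 1. Ensembles are reported both over all characters and over
parsimony-informative ones (g > m); for the packaged matrix the two
coincide because every column is informative.

## Heuristic search

Each replicate draws a random taxon addition order from a per-replicate
child seed (`SeedSequence([seed, i])`), builds a Wagner tree (stepwise
addition at the branch minimizing total length, first-found branch on
ties), and hill-climbs with TBR. Reconnection costs are exact: cutting an
edge splits the tree into T1, T2, and rejoining at edges e1, e2 costs, per
character, L1 + L2 + [R1(e1) ∩ R2(e2) = ∅], where Ri is the Fitch root
state set of component i rooted on the reattachment edge. A full TBR scan
is therefore two directional-set passes per bisection plus one vectorized
pairwise comparison. Moves are evaluated in deterministic edge order;
steepest descent, first of the equal-best moves applied.

At a local optimum the replicate collects up to `hold_per_replicate`
equal-length neighbors. Best trees pooled over replicates then undergo
"TBR to completion": every tree on the plateau receives a full
neighborhood scan, equal-length neighbors are absorbed (deduplicated by
bipartition set) up to `max_trees`, and any strictly shorter discovery
restarts the pool. Defaults follow the study protocol (1000 replicates,
hold 20, cap 10000); with the compiled scan the full 1000-replicate
protocol takes under half a minute for the packaged matrix, and the matrix
converges far earlier — 10 replicates plus the closure sweep already find
the 301-step optimum and all 12 collapsed trees — so the test suite uses
20 replicates while the acceptance script runs the full protocol.

**Collapsing.** "Ambiguously supported" branches are those on which no
character change is forced (minimum branch length zero over all
most-parsimonious reconstructions); collapsing contracts all such branches
and iterates to a fixed point, making the operation idempotent. The
12-tree count for the study matrix arises under exactly this rule.

**Exhaustive oracle.** For ≤9 taxa every unrooted binary topology is
enumerated ((2n−5)!! of them); the heuristic equals the oracle's best
length on every tested instance. Single-start TBR can stall in genuine
local optima (observed on ~4% of random 7-taxon instances, verified by
exhaustive neighbor scoring); random-addition replication is what makes
the search reliable.

## Consensus and bootstrap

Strict consensus = bipartition-set intersection; majority rule keeps splits
in > cutoff% of trees (cutoff ≥ 50 enforced so retained splits are
compatible). Both rebuild the tree from the kept splits by nesting.

The bootstrap resamples the 67 columns with replacement, kept as integer
column weights (identical lengths to materialized duplicates, much
cheaper). Each replicate reruns the heuristic search; one vote per
bipartition is taken from the strict consensus of the replicate's
equal-best trees (vote-per-tree averaging is available as
`vote_mode="pertree"`). Frequencies are percentages of effective
replicates; values at or above the threshold annotate the reference
consensus. Support values for the study matrix are sensitive to
within-replicate search effort: shallow inner searches over-resolve each
replicate's consensus and inflate marginal frequencies (we measured 8–9
clades above 50% with 2-replicate inner searches, but a stable 7 across
seeds with 5-replicate collapsed inner searches at 300 bootstrap
replicates, against the study's 6 — with one or two clades barely above
the 50% line in every run). The test suite uses the 300 × 5 collapsed
protocol as its standard condition; `BootstrapConfig` defaults to the
full published protocol (1000 × 100).

## Sequential character removal

Leave-one-out: for each character, re-search the reduced matrix, build the
strict consensus, score it with polytomy-general optimization, and compare
against the full-matrix baseline. A character is flagged when the
consensus shortens by more than the threshold (30 steps in the original
protocol — such large drops signal topology shifts, not the character's
own steps). "Sequential" means iterating over characters, not cumulative
deletion. Sub-searches default to a reduced replicate budget (the original
protocol used full settings; configurable).

## Synapomorphy mapping

A transformation is mapped onto a consensus branch only if it is
unambiguous there *and* the same branch (matched by bipartition) carries
the same unambiguous derived state in every MPT. Characters unambiguous in
all trees but on no common branch are listed as orphans. A mapped
transformation is *unique* when the character's consensus steps equal its
minimum m (hence ci = ri = 1). Polarity (ancestral vs derived side) comes
from rooting on the designated outgroup taxon.

## Synthetic data

Characters are simulated by placing Poisson(change_rate) state changes
directly on uniformly chosen branches of a known (or random) tree, new
state uniform among the other states, then masking cells to `?`/`-` at
configured rates. This branch-placement design — rather than a
continuous-time Mk process — gives exact truth bookkeeping (every change's
branch, source and target state) and direct control of homoplasy, which is
what oracle tests need; it does not emulate rate heterogeneity, correlated
characters, or logically structured inapplicability, so passing recovery
tests demonstrate algorithmic correctness, not realism of any biological
inference. The two-signal generator marks clades of tree A with binary
characters and adds a conflict block of identical characters marking one
clade of an independent tree B chosen to clash with as few A-clades as
possible; sized to tie with the support of the clade it contradicts, it
reproduces the phenomenon the removal screen detects (consensus length
drop plus resolution gain on removal). In a perfect tie the characters on
the contested clade are statistically indistinguishable from the conflict
block — the screen flags the conflict, not its direction.

Uniformity of `random_tree` (sequential addition on a uniformly chosen
branch) is checked by a frequency test over the three 4-taxon topologies.

## Numerical and convention notes

- All randomness flows through numpy `SeedSequence`; identical seeds give
  bit-identical results including replicate logs.
- Tree identity = equality of informative bipartition sets; canonical
  newick (children sorted by smallest descendant label) makes equality
  visible as string equality.
- Ties in Wagner addition and TBR move selection break to the first
  candidate in deterministic traversal order.
- Degenerate inputs: matrices need ≥4 taxa for search; all-missing columns
  contribute nothing anywhere; an empty tree set is rejected.

## Known limitations

Ordered/additive characters, step matrices, implied weighting and
support measures other than the bootstrap (jackknife, Bremer) are not
implemented. The search is single-threaded. Bootstrap clade counts near
the 50% line depend on inner-search effort (see above); exact
reproduction of a legacy program's support values is not guaranteed, only
statistical agreement.
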