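# Methods

## Evolution model and cost closure

A minisatellite map is a sequence of unit symbols over a finite alphabet
of variant types.  The model prices unit mutation by a symmetric,
zero-diagonal matrix `d_M`; tandem duplication (one unit gains an adjacent
copy) by `c_dup`; insertion and deletion by `c_ins`, `c_del`.  Defaults
(`default_cost_model`): uniform mutation cost 1, `c_dup = 0.5`,
`c_ins = c_del = 1.5`, satisfying the standard ordering
duplication < mutation ≤ indel.  Exact values are configuration, not
constants; a TSV cost file can override all of them.

All dynamic programs use the min-plus closure `d_M*` of the user matrix,
so a chain of mutations x→y→z is priced optimally even for non-metric
input, and each derivation node needs at most one effective mutation.
The closure is idempotent and never increases an entry; zero off-diagonal
entries are honoured as free edges.

## Duplication histories

The derivation of a string `s` from one seed unit of type `c` is an
ordered binary tree: each node may mutate (closed cost) and each internal
node is a duplication (`c_dup`) whose two children derive a split of the
node's interval.  The interval DP is

    D(i, j, c) = min_{c'} d_M*(c, c') + E(i, j, c')
    E(i, i+1, c') = [units[i] == c'] ? 0 : ∞
    E(i, j, c')  = min_{i<k<j} c_dup + D(i, k, c') + D(k, j, c')

(0-based half-open intervals throughout).  Because neither the recurrence
nor its cost semantics is published in closed form anywhere we know of,
the DP is pinned to an independent uniform-cost-search oracle
(`oracle_derivation_cost`, raw single-step mutations and duplications over
explicit strings) on exhaustive small instances.

Run generation from a flanking inherited unit `x` partitions the run into
blocks, each costing `c_dup` plus the derivation of the block from a fresh
copy of `x`; the seed's own symbol is fixed by the alignment column it
occupies, so it does not mutate here.  Right-side generation is the exact
mirror by string reversal.

History reconstruction tie-breaks deterministically: leftmost duplication
split, lexicographically smallest intermediate symbol.  Reconstructed
event lists re-price to the DP total exactly.

## Map alignment

An alignment is a monotone matching; matched pairs cost `d_M*`.  Each
maximal unmatched run is explained as one left-generated prefix, one
indel-priced middle (`c_del` for runs in map A, `c_ins` in map B), and one
right-generated suffix, seeded by the run's nearest matched units (absent
at map ends).  The all-indel, zero-match alignment is always a candidate.
The three-segment split is this package's concretization of the model —
interleavings of indels *between* generated blocks of one flank are not
modelled — and is pinned to a brute-force matcher that enumerates all
monotone matchings with exhaustively enumerated run splits on small maps.

The DP runs in O(n·m·(n+m)) after O(n³·k) per-map interval tables; the
per-map tables are cached and reused across all pairs of a dataset.  No
attempt is made to match the compression-based accelerations of optimized
aligners; cost-equivalence, not speed, is the contract.  Traceback
tie-breaks: among minimum-cost alignments, maximise matches, then prefer
leftmost matches; run splits take the smallest (u, v).

Direction modes: `left_to_right` permits generation only from left
flanks, `right_to_left` only from right flanks; leading/trailing runs that
lose their only flank fall back to indels.  Restricted optima can never
beat the unrestricted one — the foundation of the bias counts.

Distances for phylogeny are raw alignment costs by default; `--normalize`
divides by the summed map lengths.

## Double-copy heuristic

Arrays `xyxy…` (x ≠ y) are rewritten over composite types `X = xy` (token
`@x+y`).  Detection requires at least two full periods (≥ 4 units),
scanning left to right, greedy, non-overlapping, with odd remainders left
untouched; a second pass also rewrites lone `xy` occurrences of types
discovered elsewhere in the dataset, so that maps sharing the pattern stay
comparable.  Composite distances: d(X, z) = derivation cost of `xy` from
`z` (generation and contraction coincide under symmetric costs);
d(X, X') = alignment cost of the two pairs; composite duplication costs
one `c_dup` (one double-copy event); composite indels span two physical
units.  The feature is optional and off by default.

## BIONJ

Standard neighbor joining with the variance-weighted reduction: pair
selection by the Q-criterion, branch lengths by the two-point formulas,
reduction `d(u,k) = λ d(i,k) + (1−λ) d(j,k) − λ b_i − (1−λ) b_j` and
`v(u,k) = λ v(i,k) + (1−λ) v(j,k) − λ(1−λ) v(i,j)` with λ minimising the
new variances, clamped to [0, 1]; variances initialise to the distances.
Negative branch lengths are clamped to zero with the deficit moved to the
sibling branch.  Two taxa split their distance evenly; the last three
clusters join in an unrooted star by the three-point formulas.  Trees are
unrooted; dendropy supplies the container and Newick serialization
(spaces preserved by quoting).

## Pivot points and directional bias

**Pivot point.**  Alignment columns (matched pairs and run units, in map
order; a run's cost spread uniformly over its units; between two matches
the A-run precedes the B-run) are scanned left to right; at the first
column where the cumulative cost reaches half the total, the mean of the
two maps' consumed-units fractions is returned.  Zero-cost pairs are
skipped and counted.  With this (example-mandated) convention the mirror
identity pivot(reversed) = 1 − pivot holds up to one column of
discretization, and only when cost ties do not flip the aligner to a
structurally different optimum.

**Bias counts.**  Every pair is aligned in the three modes;
`E_l` counts pairs with left-to-right-restricted cost strictly above the
unrestricted optimum (tolerance 1e-9), `E_r` the mirror, and
`E_n = (E_l − E_r)/(E_l + E_r)` (0 when both counts vanish).

**Scramble tests.**  Replicate datasets shuffle each map's units with a
seeded generator; both tests are reproducible bit for bit.  Defaults:
2 iterations for the pivot test, 25 for the bias test, 20 histogram bins.
For the bias test, maps are first reduced to their modular structure
(adjacent equal units collapsed) — the standard approximation, since type
transitions carry the direction signal; the real counts and the
replicates use the same reduced maps (replicates shuffle the reduced
units), keeping the two phases comparable.

## Synthetic data

`simulate` grows independent lineages from a shared root by unit events:

- **duplication** (default p = 0.7): an internal insertion point is
  chosen; with probability `beta` the *right* neighbour is copied into the
  gap (right-to-left origin), else the left.  With probability
  `p_copy_divergence` (default 0.15) the fresh copy diverges by one
  mutation step.  This colocation of growth and divergence is what makes
  direction readable: identical copies are explainable from either flank
  at equal cost by re-matching, so a process without copy divergence
  leaves no direction signal at all.
- **mutation** (p = 0.2): position sampled with weight `rank^(bias−1)`
  (`mut_end_bias = 1` is exactly uniform; larger skews to the 3' end);
  the target is an adjacent type in alphabet order (`mut_local`, default),
  reflecting single point-mutation steps between variants, or uniform
  over the other types.
- **indel** (p = 0.1): insert a uniform type at a uniform gap, or delete
  a uniform unit (never emptying the map).

Defaults describe one realistic study condition: 8 variant types on a
mutational pathway, a palindromic 42-unit root of three-unit blocks whose
order interleaves the type chain (adjacent blocks ≥ 2 steps apart, so
one-step offspring are not confused with a neighbouring block), 30 events
per lineage.  The matching `chain_cost_model` prices mutation as chain
distance with indels at 2.0 — strictly above `c_dup` + one step, which is
the identifiability condition for direction (at `c_ind ≤ c_dup + step`,
every one-step offspring ties with a direction-free indel).

What the generator does *not* emulate: nucleotide-level unit sequences and
typing noise, recombination/gene conversion between lineages, population
structure, and multi-copy duplications.  Passing recovery tests therefore
show that the statistics read out the modelled signals, not that real
loci evolve by this process.

Problem sizes in the test studies (chosen as desk-scale defaults): the
direction study uses 3 replicate datasets × 20 maps × 30 pure-duplication
events with counts pooled across replicates and 25 scramble iterations;
the polarity study uses 12 maps with mutation-dominated evolution
(p = 0.3/0.6/0.1) and `mut_end_bias` 4 versus the uniform control; the
phylogeny study uses 100 random additive 8–12-leaf matrices and two
6-lineage populations from distant roots.

## Numerical and degenerate-input conventions

Strict-inequality tolerance 1e-9 for bias counts and cost comparisons;
histogram bins half-open with a closed last bin and out-of-range values
clamped; empty runs cost 0; single-symbol alphabets and single-unit maps
are legal; duplicate map ids are rejected everywhere; PHYLIP labels are
truncated at 10 characters unless the relaxed dialect is requested, with
truncation collisions an error.

## Known limitations

- The three-segment run model may diverge from aligners that interleave
  indels between generated blocks of one flank; exhaustive oracles pin
  this package's model, not theirs.
- Pair-level bias counting saturates on heavily diverged datasets; E_n is
  a sign statistic, not an effect size.
- The double-copy rewrite is greedy and phase-fixed; `yxyx` is only
  rewritten if `(y, x)` itself is discovered as a type.
- Multiple-copy (> 2) duplication models and block-exchange operations are
  out of scope.
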