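# Methods

This note documents the models and procedures implemented in `mthapnet`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Circular coordinates and the gap policy

Positions are 1-based on a circular reference and intervals are closed;
an interval whose start anchor exceeds its end anchor wraps through the
origin (so the tRNA/control-region/12S amplicon spanning the origin is one
interval, and a variant at position 108 sorts naturally with the
15,000-range variants of the same amplicon). Alignment columns absent from
the reference are insertion columns named `anchor.k` — `15581.1` is the
first inserted column after base 15581 — anchored to the *preceding*
reference base. The anchor-after convention is a documented choice: a
polymorphism table row like "15932 ins" does not itself say on which side
of the base the insertion sits.

Closed-interval arithmetic is computed, never transcribed: the
origin-spanning amplicon (15,308–16,357 plus 1–109) has
1,050 + 109 = 1,159 reference positions, and that is what
`interval_length` returns.

Before network analysis every column containing a gap character in any
sequence is removed — alignment indels are dominated by alignment
ambiguity and (in 454 data) homopolymer artefacts — *except* columns
explicitly whitelisted as phylogenetically informative indels, which are
retained as a single multistate character over {absent, A, C, G, T}. This
lets one insertion column carry two independent insertion events with
different bases, each labelling its own branch. `N` is missing data, not
a gap, and never causes column removal.

## Consensus and variant tables

The per-amplicon consensus is the column-wise majority over non-N read
states; the gap counts as a state, so a genuine deletion can reach
consensus. Depth is the count of non-N states. Tie-breaking default is the
IUPAC code of the tied bases (`tie_rule="ambiguity"`), avoiding bias
toward the reference; `tie_rule="reference"` is available. A tie that
involves the gap state resolves to the tied bases' code — the gap wins
only on strict majority — because indel evidence in amplicon pools is
weaker than substitution evidence.

Variant calling emits one record per consensus/reference difference:
substitutions, insertions (`anchor.k`, observed base), deletions
(reference base, absent). An ambiguity code compatible with the reference
base yields no record; an incompatible one is reported in a separate
ambiguity list rather than being forced to a call. Applying the records
back to the reference reconstructs the consensus exactly (round-trip
identity, tested).

## Misincorporation spectra

For every read column whose state is a base differing from the consensus
base, the directed change consensus→read is counted; N and gap columns are
skipped on either side, and indels are excluded throughout. Composition is
taken from the group's consensus over the same analysed columns — the same
columns that generate countable mismatches.

Scaling is conditional on which origin class is underrepresented in the
fragment: with A+T > G+C, changes originating from C or G are multiplied
by (A+T)/(G+C); mirrored when A+T is the minority; balanced composition
changes nothing. Type 1 = scaled A→G + T→C; type 2 = scaled C→T + G→A;
the pooled ratio across groups uses summed scaled type counts. Because
which convention (raw or scaled) underlies a printed "∼2:1" is usually
unstated, the per-group table reports both.

The ratio is undefined (flagged, not NaN-propagated) when no type-1 events
exist; the CLI exits non-zero in that case.

## Median-joining networks

Haplotypes identical over the region's variable columns collapse into
clusters. In the default "permissive" missing-data mode an N matches any
base; sequences merge into the first compatible cluster in input order and
residual Ns are filled with the column majority (order dependence is the
price of permissiveness and is documented; "strict" mode requires exact
identity).

Distances are weighted Hamming distances with non-negative integer
weights; missing states contribute zero; a zero weight removes a column
from the distance (but a differing zero-weight column still labels an
edge, since edge labels are defined as the positions at which the
endpoint vectors differ).

Feasible links are computed with the bottleneck characterisation: u–v is
a link iff d(u,v) ≤ b(u,v) + ε, where b(u,v) is the minimax path
bottleneck over the complete distance graph. For ε = 0 this is exactly
the minimum spanning network, and raising ε only ever adds links
(monotonicity is tested). ε defaults to 0 — the minimal reproducible
network.

Median generation follows the classic iteration: for every triplet with
at least two linked pairs, the column-wise majority vector is proposed
(three-way ties branch into all quasi-median variants, which is what
handles the multistate indel character); per round, all new medians within
ε of the minimal connection cost are added, and synthetic nodes are pruned
when they have at most two links *and* their removal does not lengthen the
network — a degree-2 median can still be a Steiner branching point of the
minimal tree, in which case it stays.

**Tree length.** The network's tree length is the minimal total weighted
length of a tree connecting every observed node using any subset of the
network's medians as optional branching points (the network intentionally
displays alternative, equally parsimonious medians; a tree is only charged
for the medians it routes through). Exact by enumeration over median
subsets up to 14 medians, deterministic hill-climbing beyond.

**Completion sweep.** The greedy per-round rule (only minimal-cost medians
are added) can, at ε = 0, strand a helpful median behind links that
earlier medians made infeasible. For networks of at most 12 observed
haplotypes the construction therefore finishes with a sweep that proposes
quasi-medians of *all* node triplets and accepts any that strictly reduce
the tree length, iterating to a true fixed point; on instances of up to 5
haplotypes and 8 variable sites this matches exhaustive Steiner
enumeration on thousands of random instances. The sweep's cost grows
exponentially with the median count, so larger networks use the canonical
greedy iteration alone, matching the behaviour of the established
median-joining implementations.

Determinism: observed nodes are processed in cluster-id order, candidate
medians in (cost, vector) order; identical inputs give byte-identical node
and edge tables.

## Frequencies, weights, motifs

A position's frequency is the number of network edges (branches, including
those incident to median vectors) whose label set contains it; hotspots
are the argmax positions, all ties reported. Inverse-frequency weights are
w = clamp(round(scale/f), 1, 99) with scale defaulting to 10 — the integer
convention of the established network software; positions without observed
mutations keep the full scale. The default pipeline is two-pass: the
weights require frequencies, which require a network, so a unit-weight
pass precedes the weighted pass. Whether published frequencies derive from
the weighted or unweighted network is typically unstated; this package
recomputes them on the final weighted network.

A haplogroup's stem is the minimal edge cut separating its observed nodes
from the other observed nodes; median vectors are unsampled intermediates
and are assigned to whichever side the minimum cut prefers (computed by
max-flow with observed nodes as contracted terminals). The motif is the
frequency-1 subset of the stem labels; stem positions recurring elsewhere
in the network are listed with their frequencies but excluded from the
motif. The external cut endpoint nearest the haplogroup is reported as an
ancestor candidate. If the haplogroup side or its complement is
disconnected — the reticulate-haplogroup situation — the module raises a
topology error rather than guessing.

Haplogroup membership is always an input (node lists or per-label metadata
tags); no clustering criterion is invented.

## Synthetic data

`simulate_haplotypes` emulates the structure of a control-region haplotype
set: star-like clusters (founder + leaves with private transition
mutations) joined to a common ancestor by multi-mutation stems, optional
hotspot positions recurring on independent terminal branches in different
clusters, an optional two-event multistate insertion column, and optional
missing data. Defaults (3 haplogroups, stars of 4, stems of 3, 327-bp
alignments anchored at 15,573) mirror a small control-region panel. All
mutated positions are otherwise unique (perfect phylogeny), which makes
oracle comparisons exact; recurrence is opt-in via hotspots. The truth
record scores collapsing, network length, frequency and motif recovery.

`simulate_clone_group` emulates an amplicon read pool: independent reads
from a template with symmetric per-change polymerase error ε (each wrong
base, so 3ε per site) plus lesion rate δ added to C→T and G→A at C/G
sites, and optional missing calls. The scaled expected type2/type1 ratio
is 1 + δ/ε regardless of template composition, because the composition
scaling multiplies the type-2 expectation n_{GC}(δ+ε) by (A+T)/(G+C)
(or divides type 1 symmetrically), cancelling the base-count imbalance
exactly. Defaults for recovery experiments use 500 reads over 300 bp at
GC ≈ 0.42 (mammalian mtDNA-like), with δ = ε for the 2:1 condition.

What the generators do **not** emulate: position-along-read damage
gradients (the implemented estimator is position-agnostic, so lesions are
uniform), 454 homopolymer indel errors (indels are excluded from the
spectra anyway), fragment-length variation, alignment errors, and
contamination. Passing tests therefore validate the estimators and the
network algebra under their stated assumptions, not robustness to
misalignment or end-enriched damage.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng` seeds; both
  generators are byte-deterministic given their config.
- Quasi-median branching is capped (4,096 variants per triplet) to bound
  pathological multistate ties; exceeding the cap is an error, not a
  silent truncation.
- Zero-count compositions (A+T or G+C absent) raise a composition error;
  an all-N column has consensus N and depth 0; an empty clone group or an
  alignment collapsing to fewer than two clusters is an input error.
- The Steiner oracle refuses instances whose candidate product space
  exceeds 20,000 vertices rather than silently subsampling.

## Known limitations

- The completion sweep guarantees parsimony-minimal tree length only in
  the small-instance regime where it runs; large networks inherit the
  greedy heuristic's known ability to miss rare cost-reducing medians.
- Permissive missing-data collapsing is input-order dependent when an
  ambiguous sequence is compatible with several clusters.
- Motif inference requires a single-cut separable haplogroup; reticulate
  haplogroups are refused by design.
- No statistical test accompanies the damage ratio or the motifs; the
  ratio is a descriptive authenticity signal, not a hypothesis test.
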