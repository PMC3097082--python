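# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `phylodiscord`, in the package's own terms. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Trees, splits, and supports

Trees are rooted, with optional non-negative branch lengths and optional
clade supports in [0, 1] on internal nodes. Supports are read from and
written to newick internal-node labels — the dominant convention for
Bayesian consensus trees, where the label is the clade's posterior
probability. Bracketed newick comments and non-numeric internal labels
are rejected rather than guessed at, so parsing is bit-exact and
round-trips (`parse ∘ write = id` is property-tested).

A **split** is the unrooted bipartition induced by an internal edge. The
stored side is canonicalized (the side containing the lexicographically
smallest taxon), so a split and its complement are one object; the
original clade side is kept as metadata because event attribution (below)
needs to know which side was a clade in which tree. In a rooted tree the
two edges below the root induce the same unrooted split; extraction
deduplicates them, keeping the better-supported label.

**Majority-rule consensus** includes exactly the clades whose sample
frequency strictly exceeds the cutoff (default 0.5; strictness avoids
ties at exactly 50%), annotated with support = frequency. One deliberate
exception: unanimous clades are always retained, so cutoff = 1.0 gives
the strict consensus instead of a star tree (frequency 1.0 is never
*strictly* greater than a 1.0 cutoff). Consensus supports are checked
against direct frequency counting and against dendropy's consensus on the
same samples.

**Pruning** suppresses unifurcations by summing branch lengths and
keeping the support of the edge closest to the leaves (the surviving
label still describes "support for this clade's content").
**Polytomy resolution** combines children strictly left-to-right with
zero-length, unlabeled branches; zero-length branches contribute identity
transition matrices, so Mk likelihoods are provably unchanged (tested to
1e-10).

## Conflict detection

Two splits on the same taxon set conflict iff all four pairwise side
intersections are non-empty — the classical incompatibility criterion,
equivalent to "no single tree displays both" (verified exhaustively
against tree enumeration for up to 6 taxa). Trees are first restricted to
their shared taxon set and compared as unrooted splits, so differing
outgroup sampling or rooting cannot manufacture conflict. Only splits
supported at ≥ thr in their own tree enter the comparison (default
0.95/0.95, matching the convention that a clade is contradicted only by a
clade with posterior probability ≥ 0.95 in the other analysis); edges
without a support label are conservatively treated as unsupported.

### Clustering conflicts into events

Raw conflicting split pairs over-count: one taxon that moved between the
trees contradicts every split along both of its placement paths. Events
are therefore built by iterative rogue-clade removal. Candidates are the
descendant sets of nodes of either restricted tree; at each step the
candidate maximizing **conflict pairs resolved per taxon removed** is
deleted from both trees and becomes one event (ties: smaller clade, then
lexicographically smallest taxon). A pair is resolved when, after
deletion, its splits become compatible or trivial. The per-taxon
normalization is essential: scoring by raw resolved count lets one large
clade near the root "resolve" every conflict at once, collapsing
genuinely distinct events into a single meaningless removal. Each step
resolves at least one pair, so the procedure terminates, and the
attributed pairs partition the input list.

An event's **involved taxa** are its rogue clade plus the clade sides of
its attributed pairs' splits that intersect the rogue. This keeps
involvement local to the clades actually in contradiction: for a cherry
conflict (x with a in tree 1, x with b in tree 2) it gives {x, a, b}; it
does not sweep in the large complement side that merely completes each
bipartition.

Identifiability caveat: "A moved next to B" and "B moved next to A" can
be observationally equivalent. The planted-move generator (below) only
builds scenarios in the regime where the true clade is the strictly most
efficient explanation; on real data, rogue identity for symmetric
switches (e.g. two taxa exchanging positions) is a labelling choice, and
the event itself — not the choice of which side "moved" — is the result.

## Ploidy flagging

Ploidal-level strings are parsed into plain levels ("8x"), uncertain
levels ("8x?"), parenthesized levels ("(2x)") and an aneuploid marker;
bracketed citations are stripped; anything else is an error naming the
row and token. A record is **polyploid** if any level ≥ 3x; uncertain and
parenthesized levels count by default (a strict mode excludes uncertain
ones), and taxa with no report are conservatively non-polyploid. An event
is an allopolyploidy candidate iff any involved taxon is polyploid, with
the per-taxon evidence attached. The 3x threshold encodes the biological
argument: discordance plus elevated ploidy makes hybridization followed
by genome doubling the favoured explanation, whereas discordance among
diploids is better explained by lineage sorting or introgression.

## Simple indel coding

Each distinct interior gap run (identical start and end columns, present
in ≥ 1 taxon) becomes one binary character, emitted in ascending
(start, end) order. A taxon scores 1 with exactly that gap, 0 with no gap
overlapping the range, and '?' with an overlapping gap of different
extent or missing data in the range — absence of a gap cannot be asserted
without data. Terminal gap runs are missing data, never characters
(leading/trailing incompleteness, not indel events); in the intended
workflow ends are truncated before coding anyway. All user-facing
coordinates are 1-based inclusive, matching how reference positions are
quoted in practice ("positions 599–671 of accession X"); the
reference-coordinate mapper skips reference gaps so such ranges can be
excluded from an alignment exactly. Concatenation takes the taxon union,
fills absent blocks with '?', and records a partition table (name, span,
nucleotide/binary) so the binary block can be given its own model
downstream.

## Mk models and ancestral states

The Mk model is a continuous-time Markov chain on k character states.
Parameterizations: **ER** one shared rate; **SYM** one rate per unordered
pair (upper-triangle row-major order); **ARD** one rate per ordered pair
(row-major). Transition probabilities are matrix exponentials, computed
by symmetric eigendecomposition where the generator is symmetric (ER,
SYM) and by general eigendecomposition with a scipy `expm` fallback for
defective cases (ARD); rows are clipped and renormalized, with row-sum
accuracy tested at 1e-10 and the 2-state closed form matched at 1e-12.

Likelihoods use Felsenstein pruning with per-character rescaling; missing
states ('?') are all-ones partial vectors, so they inform results only
through topology and branch lengths (an all-'?' leaf provably changes
nothing). The root prior is uniform over states by default — the common
default of reconstruction software when nothing is known about the root —
and configurable to any probability vector. Likelihood and marginal
reconstructions are verified against brute-force enumeration over all
internal-node state assignments (≤ 5 leaves, k ≤ 3, 100 seeded parameter
draws, tolerance 1e-10).

**Fitting** maximizes over rates in log space within [1e-8, 1e3] by
L-BFGS-B (ftol 1e-12). The first start is the maximum-likelihood
*equal-rates* point found by a 1-D bounded search — cheap, deterministic,
and it makes fitted likelihoods respect ER ≤ SYM ≤ ARD numerically, since
the optimizer never moves below its start. The remaining starts (5 total
by default) are deterministic random draws, log-uniform in [1e-2, 10].
Convergence status is reported; if no start converges an error carrying
the best fit so far is raised.

**Model selection** uses likelihood-ratio tests between nested
parameterizations (ER ⊂ SYM ⊂ ARD): statistic 2ΔlogL clamped at 0,
df = parameter-count difference, p from the upper tail of chi-square(df).
Pairs with df = 0 (ER vs SYM at k = 2, where the parameterizations
coincide) are rejected as errors rather than given a meaningless p. The
pipeline steps up from ER only where p < 0.05. Calibration is tested:
under ER-simulated data the ER-vs-SYM test rejects at the nominal 5% rate
(±2% band over 1000 seeded replicates; k = 3, 12 leaves, 200 characters —
a scale chosen a priori for chi-square adequacy within the test budget).

**Marginal ASR** combines each node's subtree partials (down-pass) with
the likelihood of the rest of the tree (up-pass) and normalizes per node
and character, giving scaled likelihood vectors that sum to 1 (enforced
at 1e-9). Results are invariant to taxon input order and to
polytomy-resolution order.

## Synthetic data

All generators are byte-identical per seed and emit truth tables so every
detector can be scored automatically.

* `sim_tree`: rooted binary trees by sequential random leaf attachment;
  all branch lengths Exponential with mean 0.1 — a generic neutral
  choice giving a few expected changes per path at the simulated rates
  (Monte-Carlo checked to 0.1 ± 0.01).
* `sim_hybrid_pair`: the chloroplast tree is the species tree; the
  nuclear tree re-grafts each listed clade elsewhere. Destination edges
  are chosen outside every moved clade, away from the source, and such
  that both source and destination hang more than |clade| + 1 edges below
  their junction. That last constraint is the identifiability regime: a
  moved clade of size c breaks a·b split pairs (a, b = broken splits on
  the two paths) at efficiency ab/c, while a bystander sibling resolves
  only one path's worth — so the planted clade dominates exactly when
  a, b > c. Supports default to 1.0 on unaffected edges and 0.99 on
  move-adjacent ones, both above any reasonable threshold.
  `random_hybrid_scenario` additionally keeps multiple moves disjoint
  with disjoint source neighbourhoods, retrying on trees where that
  cannot be arranged. Planted-rogue recovery is tested at ≥ 95% over 200
  seeded 5-move scenarios on 64-leaf trees; the residual failures are
  adjacent moves merging into one event — a real ambiguity, not noise.
* `sim_mk_characters`: root states uniform, evolved edge-wise via the
  model's transition probabilities (empirical transition frequencies
  match exp(Qt) to 1%).
* `sim_indel_alignment`: identical baseline sequences with planted gap
  runs; events touching one taxon may not overlap or abut (runs would
  merge and falsify the truth table).

What a green synthetic test does **not** establish: the generators plant
clean, well-separated signals with maximal supports; real posterior
trees have correlated supports, rogue taxa with partial signal, and
conflicts below threshold. The fixture — not the simulations — is the
realism anchor.

## The Potentilla fixture

The fixture transcribes a published two-marker study of *Potentilla*:
two consensus topologies (nuclear ITS+ETS, chloroplast trnL/F+trnS/G)
encoding six major clades (Anserina, Alba, Fragarioides, Reptans,
ivesioid, Argentea), their published supports, and the five described
between-tree conflicts; plus a specimen table with ploidal levels, clade
assignments, and style/anther shapes (7 outgroup taxa, 65 ingroup rows).
Encoding choices:

* Clade-internal structure reported as unresolved is encoded as
  polytomies with absent supports, so it can never generate supported
  conflict.
* Supports on conflicting placements are ≥ 0.98 as published, so
  thresholds 0.95 and 0.98 yield the same five events.
* *P. clusiana* appears in the table but not the trees (it was dropped
  from the molecular analyses after a recombination screen).
* The Alba-clade conflict is encoded as an articulata–micrantha clade in
  the chloroplast tree (pp 0.98), following the study's explicit
  event list over its more ambiguous running text.
* Branch lengths are a uniform 1.0 — the published figures carry no
  usable lengths — so fixture ASR is qualitative (state identities, not
  calibrated probabilities), and fixture LRT p-values are not comparable
  to published ones. With that caveat, LRT model selection on the fixture
  picks SYM for both style and anther shape, the same choice the original
  analysis reported.

## Pipeline

`run_pipeline` composes conflicts → flagging → optional ASR, returning a
versioned report dict and optionally writing `report.json`, `events.tsv`
and `summary.txt`. Reports contain no timestamps; identical configuration
and inputs give byte-identical output (tested). Failures abort with
partial outputs removed. There is no command-line interface: the
functions and the `examples/` scripts are the interface.

## Known limitations

* The detector cannot distinguish hybridization from incomplete lineage
  sorting or chloroplast capture; it only localizes and labels conflict.
  Flagging expresses plausibility, not demonstration, of allopolyploidy.
* Greedy event clustering is order-dependent by construction; the
  efficiency criterion with deterministic tie-breaks makes it
  reproducible, not optimal in a set-cover sense.
* Rate optimization is bounded at [1e-8, 1e3]; boundary MLEs (e.g.
  constant characters) are reported at the bound without a warning.
* Only a minimal newick dialect is supported; NEXUS files and comment
  annotations must be converted upstream.
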