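# phylodiscord

Detection of cytonuclear discordance, flagging of allopolyploidy
candidates, and maximum-likelihood ancestral state reconstruction of
discrete morphological characters — packaged for studies that compare a
nuclear and a chloroplast gene tree across one genus.

## The problem

Hybridization followed by genome doubling (allopolyploidy) leaves two
signatures: elevated ploidal levels, and conflict between gene trees from
the biparentally inherited nuclear genome and the maternally inherited
plastid genome. Given two consensus trees with posterior supports, a
table of reported ploidal levels, and discrete morphological characters,
this package answers three questions:

1. **Where do the trees disagree, and how strongly?** Two splits conflict
   iff all four pairwise side intersections are non-empty (no single tree
   can display both). Conflicts are evaluated on unrooted splits over the
   shared taxon set, and only between clades supported at a threshold
   (default posterior probability ≥ 0.95) in *both* trees.
2. **Which disagreements involve polyploids?** Raw conflicting split
   pairs are clustered into discrete *incongruence events* by greedy
   rogue-clade removal: at each step remove the clade resolving the most
   remaining conflicts per taxon removed. An event is an allopolyploidy
   candidate when any involved taxon has a reported ploidal level ≥ 3x.
3. **Do morphological characters track the phylogeny?** Discrete
   characters are modelled with k-state Mk rate matrices — ER (one rate),
   SYM (k(k−1)/2 symmetric rates), ARD (k(k−1) rates) — fitted by maximum
   likelihood (Felsenstein pruning, uniform root prior), compared by
   likelihood-ratio tests, and summarized as per-node scaled marginal
   likelihoods of each ancestral state.

The package also provides the supporting plumbing: newick I/O with
supports on internal-node labels, majority-rule consensus, pruning,
polytomy resolution, simple indel coding of aligned matrices with
partitioned concatenation, and seeded generators for every input — plus a
bundled *Potentilla* (Rosaceae) fixture encoding the published nuclear and
chloroplast topologies, supports, ploidal levels, and style/anther shapes.

## Worked example

```python
from phylodiscord import (
    cluster_events, find_conflicting_pairs, flag_events, potentilla_fixture,
)

fx = potentilla_fixture()
pairs = find_conflicting_pairs(fx.nuclear, fx.chloroplast, 0.95, 0.95)
events = cluster_events(pairs, fx.nuclear, fx.chloroplast)
events, _ = flag_events(events, fx.ploidy_records)
print(len(pairs), len(events), sum(e.allopolyploid_candidate for e in events))
```

prints `6 5 3`: six conflicting split pairs cluster into five incongruence
events, of which three involve polyploid taxa. The five rogue clades are
*P. articulata* (Alba clade, no polyploids — not flagged), *P. dickinsii*
(Fragarioides, diploids only — not flagged), *P. microphylla* (switches
with *P. stenophylla* inside Anserina; 4x — flagged), *P. norvegica*
(Argentea vs sister-to-ivesioids; 8x, 10x — flagged), and the
Fragarioides–Reptans switch (Reptans taxa up to 12x — flagged).

Running the style-shape reconstruction (`examples/ancestral_states.py`)
prints

```
ER: logL -38.588 (1 rates)
SYM: logL -31.574 (6 rates)
ARD: logL -31.251 (12 rates)
ER vs SYM: LR=14.029, df=5, p=0.0154
SYM vs ARD: LR=0.646, df=6, p=0.9956
selected model: SYM
Argentea clade MRCA: L=0.00, N=0.00, G=0.00, C=1.00
```

— the symmetric-rates model is preferred over equal rates, adding
direction-specific rates is not justified, and the cone-shaped
(Conostylae) style is reconstructed at the Argentea ancestor. Scaled
likelihoods on this fixture are qualitative because its branch lengths
are a uniform 1.0 (see `docs/methods.md`).

Each script in `examples/` is a short narrative of one capability:
conflict detection on the fixture, consensus building, indel coding,
ancestral states, and a synthetic round-trip of the detector.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full fixture pipeline from scratch (conflict detection →
event clustering → ploidy flagging → ER/SYM/ARD fits with LRT model
selection → marginal ancestral states) and a seeded batch of synthetic
detector round-trips, printing what it computes and writing the results
JSON to `--out`.

## Layout

| module | contents |
| --- | --- |
| `phylodiscord.trees` | newick parse/write, splits, consensus, prune, polytomy resolution |
| `phylodiscord.alignments` | simple indel coding, truncation, reference-coordinate exclusion, concatenation |
| `phylodiscord.conflicts` | split conflict predicate, conflict pairs, event clustering |
| `phylodiscord.ploidy` | ploidal-level parsing, polyploid rule, event flagging |
| `phylodiscord.mk` | Mk likelihoods, ER/SYM/ARD fits, LRT, marginal ASR |
| `phylodiscord.simulate` | seeded generators: trees, hybrid pairs, Mk characters, indel alignments |
| `phylodiscord.fixture` | the bundled Potentilla trees and specimen table |
| `phylodiscord.pipeline` | `run_pipeline`: end-to-end run with deterministic JSON/TSV reports |
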