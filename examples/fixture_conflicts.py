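"""Detect cytonuclear incongruences in the bundled Potentilla fixture.

Compares the nuclear (ITS+ETS) and chloroplast (trnL/F+trnS/G) consensus
trees, clusters the well-supported conflicts (pp >= 0.95 on both sides)
into discrete events, and flags events involving polyploid taxa as
allopolyploidy candidates.
"""

from phylodiscord import (
    cluster_events,
    find_conflicting_pairs,
    flag_events,
    potentilla_fixture,
)

fx = potentilla_fixture()
pairs = find_conflicting_pairs(fx.nuclear, fx.chloroplast, thr1=0.95, thr2=0.95)
events = cluster_events(pairs, fx.nuclear, fx.chloroplast)
events, missing = flag_events(events, fx.ploidy_records)

print(f"{len(pairs)} conflicting split pairs -> {len(events)} events\n")
for ev in events:
    flag = "ALLOPOLYPLOIDY CANDIDATE" if ev.allopolyploid_candidate else "no polyploids involved"
    print(f"rogue clade : {', '.join(sorted(ev.rogue_clade))}")
    print(f"  involves  : {len(ev.involved_taxa)} taxa, "
          f"{len(ev.attributed_pairs)} conflict pair(s)")
    print(f"  verdict   : {flag}")
    for taxon, levels in ev.evidence:
        print(f"              {taxon}: {', '.join(f'{x}x' for x in levels)}")
    print()

# Each event is one clade whose placement differs between the two gene
# trees; a flag means at least one involved taxon has a reported ploidal
# level of 3x or more, making hybridization-plus-genome-doubling a
# plausible cause of the discordance.
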