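"""Summarize a sample of trees in a 50% majority-rule consensus.

Builds a small posterior-like sample (one topology dominating, one
alternative) and shows that consensus supports are exactly the split
frequencies in the sample.
"""

from phylodiscord import TreeSample, majority_consensus, parse_newick, write_newick

main_topology = "(((A,B),C),(D,E));"
alternative = "(((A,C),B),(D,E));"
sample = TreeSample(
    [parse_newick(main_topology) for _ in range(7)]
    + [parse_newick(alternative) for _ in range(3)]
)

consensus = majority_consensus(sample, cutoff=0.5)
print("consensus:", write_newick(consensus))
for node, clade in consensus.clades(include_leaves=False):
    if node is not consensus.root:
        print(f"  clade {{{','.join(sorted(clade))}}}: support {node.support:.2f}")

# {A,B} appears in 7 of 10 trees -> support 0.70; {A,C} (3/10) falls below
# the 50% cutoff and is collapsed into a polytomy; {D,E} is unanimous.
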