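"""Simple indel coding and matrix concatenation.

Codes each distinct interior gap as one binary presence/absence
character (identical start and end = the same event), then concatenates
the nucleotide block and the binary block into a single partitioned
matrix, filling taxa missing from a block with '?'.
"""

from phylodiscord import Alignment, code_indels, concatenate

aln = Alignment(
    {
        "taxonA": "ACGTAC--GTACGT",
        "taxonB": "ACGTAC--GTACGT",
        "taxonC": "ACGTACGTG---GT",
        "taxonD": "ACGTACGTGTACGT",
    }
)
indels = code_indels(aln)
print("coded indel characters (start-end):", indels.descriptors)
for taxon, row in indels.scores.items():
    print(f"  {taxon}: {row}")

combined = concatenate([aln, indels], names=["sequence", "indels"])
print("\npartitions (name, first col, last col, type):")
for part in combined.partitions:
    print("  ", part)
print("combined row for taxonC:", combined.rows["taxonC"])

# taxonA and taxonB share the 7-8 gap (scored 1), taxonC has a different
# gap (11-13); taxa whose gaps do not overlap a character's range score 0.
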