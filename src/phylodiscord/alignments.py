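"""Concatenated character matrices: indel coding, truncation, exclusion.

Implements the *simple* indel coding scheme: every distinct interior gap
(identical start and end columns, shared by at least one taxon) becomes one
binary presence/absence character.  A taxon scores 1 if it has exactly that
gap, 0 if no gap overlaps the range, and '?' (inapplicable) if it has an
overlapping gap of different extent or missing data anywhere in the range.
Terminal gap runs are treated as missing data, never coded.

All user-facing coordinates are 1-based inclusive, matching the way
reference positions are quoted in the systematics literature.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from Bio import AlignIO

from .errors import ValidationError

__all__ = [
    "Alignment",
    "BinaryIndelMatrix",
    "ConcatenatedMatrix",
    "read_fasta_alignment",
    "code_indels",
    "truncate_ends",
    "map_reference_positions",
    "exclude_columns",
    "concatenate",
]

_ALPHABET = set("ACGTURYSWKMBDHVN-?")


@dataclass
class Alignment:
    """taxon -> gapped sequence over {A,C,G,T, IUPAC ambiguity, -, ?}."""

    sequences: dict

    def __post_init__(self):
        if not self.sequences:
            raise ValidationError("empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}
        for taxon, seq in self.sequences.items():
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValidationError(
                    f"invalid characters {sorted(bad)} in sequence for {taxon!r}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list:
        return list(self.sequences)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, seq in self.sequences.items():
                fh.write(f">{taxon}\n{seq}\n")

    def write_phylip(self, path) -> None:
        """Relaxed PHYLIP: name, whitespace, full sequence on one line."""
        width = max(len(t) for t in self.sequences) + 2
        with open(path, "w") as fh:
            fh.write(f"{len(self.sequences)} {self.length}\n")
            for taxon, seq in self.sequences.items():
                fh.write(f"{taxon.ljust(width)}{seq}\n")


@dataclass
class BinaryIndelMatrix:
    """taxon -> string over {0,1,?}; one column per coded indel."""

    scores: dict
    descriptors: list  # [(start_col, end_col)] 1-based inclusive

    def __post_init__(self):
        for start, end in self.descriptors:
            if start > end:
                raise ValidationError(f"descriptor {start}-{end} has start > end")
        n = len(self.descriptors)
        for taxon, row in self.scores.items():
            if len(row) != n:
                raise ValidationError(f"row length mismatch for {taxon!r}")

    @property
    def n_characters(self) -> int:
        return len(self.descriptors)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            header = "\t".join(f"indel_{s}_{e}" for s, e in self.descriptors)
            fh.write(f"taxon\t{header}\n")
            for taxon, row in self.scores.items():
                fh.write(taxon + "\t" + "\t".join(row) + "\n")


def read_fasta_alignment(path) -> Alignment:
    aln = AlignIO.read(path, "fasta")
    return Alignment({rec.id: str(rec.seq) for rec in aln})


def _gap_runs(seq: str) -> list:
    """Maximal '-' runs as 1-based inclusive (start, end) tuples."""
    return [
        (m.start() + 1, m.end()) for m in re.finditer(r"-+", seq)
    ]


def code_indels(aln: Alignment) -> BinaryIndelMatrix:
    """Simple indel coding of interior gap runs."""
    if len(aln.sequences) < 2:
        raise ValidationError("need >= 2 taxa to code indels")
    length = aln.length
    interior: dict[str, list] = {}
    terminal: dict[str, list] = {}
    for taxon, seq in aln.sequences.items():
        interior[taxon], terminal[taxon] = [], []
        for run in _gap_runs(seq):
            if run[0] == 1 or run[1] == length:
                terminal[taxon].append(run)
            else:
                interior[taxon].append(run)

    descriptors = sorted({run for runs in interior.values() for run in runs})
    scores = {}
    for taxon, seq in aln.sequences.items():
        row = []
        for start, end in descriptors:
            if (start, end) in interior[taxon]:
                row.append("1")
            elif any(
                r[0] <= end and r[1] >= start
                for r in interior[taxon] + terminal[taxon]
            ):
                row.append("?")  # overlapping gap of different extent
            elif "?" in seq[start - 1 : end]:
                row.append("?")  # missing data anywhere in the range
            else:
                row.append("0")
        scores[taxon] = "".join(row)
    return BinaryIndelMatrix(scores, descriptors)


def truncate_ends(aln: Alignment, lead: int, trail: int) -> Alignment:
    """Drop ``lead`` leading and ``trail`` trailing columns."""
    if lead < 0 or trail < 0:
        raise ValidationError("truncation margins must be non-negative")
    if lead + trail >= aln.length:
        raise ValidationError(
            f"truncating {lead}+{trail} of {aln.length} columns leaves nothing"
        )
    return Alignment(
        {t: s[lead : aln.length - trail] for t, s in aln.sequences.items()}
    )


def map_reference_positions(
    aln: Alignment, ref_taxon: str, start: int, end: int
):
    """Alignment columns holding ungapped positions start..end (1-based,
    inclusive) of the reference sequence; its gaps consume no positions."""
    if ref_taxon not in aln.sequences:
        raise ValidationError(f"reference taxon {ref_taxon!r} not in alignment")
    if not 1 <= start <= end:
        raise ValidationError(f"bad position range {start}-{end}")
    seq = aln.sequences[ref_taxon]
    cols = [i + 1 for i, ch in enumerate(seq) if ch != "-"]
    if end > len(cols):
        raise ValidationError(
            f"position {end} beyond ungapped length {len(cols)} of {ref_taxon!r}"
        )
    return (cols[start - 1], cols[end - 1])


def _merge_ranges(ranges):
    merged = []
    for start, end in sorted(ranges):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def exclude_columns(aln: Alignment, ranges: list) -> Alignment:
    """Remove 1-based inclusive column ranges (overlaps merged) from all
    taxa.  Excluding every column yields a zero-length alignment and a
    warning."""
    for start, end in ranges:
        if not 1 <= start <= end <= aln.length:
            raise ValidationError(
                f"range {start}-{end} outside alignment of length {aln.length}"
            )
    if not ranges:
        return aln
    drop = set()
    for start, end in _merge_ranges(ranges):
        drop.update(range(start, end + 1))
    keep = [i for i in range(1, aln.length + 1) if i not in drop]
    if not keep:
        warnings.warn("all columns excluded; returning zero-length alignment")
    return Alignment(
        {t: "".join(s[i - 1] for i in keep) for t, s in aln.sequences.items()}
    )


@dataclass
class ConcatenatedMatrix:
    """Concatenation of nucleotide and binary blocks with a partition table."""

    rows: dict  # taxon -> full-width string
    partitions: list  # [(name, start_col, end_col, kind)] 1-based inclusive

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def write_partitions(self, path) -> None:
        with open(path, "w") as fh:
            for name, start, end, kind in self.partitions:
                fh.write(f"{name}\t{start}\t{end}\t{kind}\n")


def concatenate(matrices: list, names: list | None = None) -> ConcatenatedMatrix:
    """Concatenate Alignment/BinaryIndelMatrix blocks over the taxon union.

    A taxon absent from a block is filled with '?' across that block.
    """
    if not matrices:
        raise ValidationError("nothing to concatenate")
    if names is None:
        names = [f"block_{i + 1}" for i in range(len(matrices))]
    taxa: list[str] = []
    for m in matrices:
        source = m.sequences if isinstance(m, Alignment) else m.scores
        for t in source:
            if t not in taxa:
                taxa.append(t)
    rows = {t: [] for t in taxa}
    partitions = []
    offset = 0
    for name, m in zip(names, matrices):
        if isinstance(m, Alignment):
            source, width, kind = m.sequences, m.length, "nucleotide"
        else:
            source, width, kind = m.scores, m.n_characters, "binary"
        for t in taxa:
            rows[t].append(source.get(t, "?" * width))
        partitions.append((name, offset + 1, offset + width, kind))
        offset += width
    return ConcatenatedMatrix({t: "".join(parts) for t, parts in rows.items()}, partitions)
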