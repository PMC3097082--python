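"""Ploidal-level tables and allopolyploidy-candidate flagging.

Ploidal levels are multiples of the base chromosome number x (2x diploid,
4x tetraploid, ...).  Reported level strings mix plain levels ("8x, 10x"),
uncertain levels ("8x?"), rarely-reported levels in parentheses ("(2x)"),
and "aneuploids" for non-exact multiples.  A taxon counts as polyploid when
any reported level is >= 3x; taxa with no report are conservatively treated
as non-polyploid.

An incongruence event between the nuclear and chloroplast trees is flagged
as an allopolyploidy candidate when any taxon involved in the event is
polyploid -- the rationale being that hybridization followed by genome
duplication (allopolyploidy) both elevates ploidy and decouples the
maternally inherited plastid from the biparental nuclear genome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

__all__ = [
    "PloidyRecord",
    "parse_ploidy_string",
    "parse_ploidy_table",
    "read_ploidy_table",
    "is_polyploid",
    "flag_events",
]

_LEVEL_RE = re.compile(r"^(\()?(\d+)x(\))?(\?)?$")
_CITATION_RE = re.compile(r"\[[^\]]*\]")


@dataclass
class PloidyRecord:
    taxon: str
    levels: set = field(default_factory=set)
    uncertain_levels: set = field(default_factory=set)
    parenthesized_levels: set = field(default_factory=set)
    aneuploid: bool = False
    clade: str | None = None
    style_shape: str | None = None
    anther_shape: str | None = None

    @property
    def unknown(self) -> bool:
        return (
            not self.levels
            and not self.uncertain_levels
            and not self.parenthesized_levels
            and not self.aneuploid
        )

    def all_levels(self, include_uncertain: bool = True) -> set:
        out = set(self.levels) | set(self.parenthesized_levels)
        if include_uncertain:
            out |= set(self.uncertain_levels)
        return out


def parse_ploidy_string(taxon: str, text: str) -> PloidyRecord:
    """Parse one "Ploidal level(s)" cell, e.g. "2x, 3x, (4x), 8x?, aneuploids"."""
    rec = PloidyRecord(taxon=taxon)
    cleaned = _CITATION_RE.sub("", text or "").strip()
    if not cleaned:
        return rec
    for token in (t.strip() for t in cleaned.split(",")):
        if not token:
            continue
        if token.lower() in ("aneuploid", "aneuploids"):
            rec.aneuploid = True
            continue
        m = _LEVEL_RE.match(token)
        if not m or bool(m.group(1)) != bool(m.group(3)):
            raise ValidationError(
                f"unparseable ploidy token {token!r} for taxon {taxon!r}"
            )
        level = int(m.group(2))
        if level < 2:
            raise ValidationError(
                f"ploidal level {level}x below 2x for taxon {taxon!r}"
            )
        if m.group(4):
            rec.uncertain_levels.add(level)
        elif m.group(1):
            rec.parenthesized_levels.add(level)
        else:
            rec.levels.add(level)
    return rec


def parse_ploidy_table(table: pd.DataFrame) -> list:
    """Parse a table with columns taxon, ploidy_string and, optionally,
    clade, style_shape, anther_shape."""
    required = {"taxon", "ploidy_string"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"ploidy table lacks columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        raw = row["ploidy_string"]
        rec = parse_ploidy_string(row["taxon"], "" if pd.isna(raw) else str(raw))
        for col in ("clade", "style_shape", "anther_shape"):
            if col in table.columns and not pd.isna(row[col]) and row[col] != "":
                setattr(rec, col, str(row[col]))
        records.append(rec)
    return records


def read_ploidy_table(path) -> list:
    return parse_ploidy_table(pd.read_csv(path, sep="\t", dtype=str))


def is_polyploid(rec: PloidyRecord, include_uncertain: bool = True) -> bool:
    """>= 3x on any reported level; unknown ploidy is non-polyploid."""
    return any(level >= 3 for level in rec.all_levels(include_uncertain))


def flag_events(
    events: list, records: list, include_uncertain: bool = True
) -> list:
    """Annotate incongruence events with the allopolyploidy-candidate flag.

    An event is flagged iff any of its involved taxa is polyploid; the
    per-event ``evidence`` lists (taxon, sorted levels) for those taxa.
    Event taxa absent from the table are treated as unknown ploidy and
    returned in the second element for logging.
    """
    by_taxon = {r.taxon: r for r in records}
    missing: set = set()
    for event in events:
        evidence = []
        for taxon in sorted(event.involved_taxa):
            rec = by_taxon.get(taxon)
            if rec is None:
                missing.add(taxon)
                continue
            if is_polyploid(rec, include_uncertain):
                evidence.append((taxon, sorted(rec.all_levels(include_uncertain))))
        event.allopolyploid_candidate = bool(evidence)
        event.evidence = evidence
    return events, sorted(missing)
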