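"""Well-supported topological conflict between two gene trees.

The contradiction predicate is the classical split-incompatibility
criterion: two bipartitions of the same taxon set conflict iff all four
pairwise side intersections are non-empty, i.e. no single tree can display
both.  Conflicts are evaluated on unrooted splits over the shared taxon
set, so differing outgroup composition or rooting cannot create spurious
conflicts.

Raw conflicting split pairs are then clustered into discrete incongruence
*events* by iterative rogue-clade removal: at each step the candidate clade
(a descendant set of either restricted tree) whose deletion from both trees
resolves the most remaining conflict pairs *per taxon removed* is removed
and becomes one event.  Normalizing by clade size keeps the events local --
a single taxon or small clade that moved between the trees -- rather than
letting one large containing clade swallow several independent conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .trees import Split, Tree, extract_splits, prune

__all__ = [
    "ConflictPair",
    "IncongruenceEvent",
    "restrict_to_shared",
    "splits_conflict",
    "find_conflicting_pairs",
    "cluster_events",
    "shared_supported_clades",
]


@dataclass(frozen=True)
class ConflictPair:
    """A supported split from each tree that cannot coexist on one tree."""

    split_1: Split
    split_2: Split
    shared_universe: frozenset

    def sort_key(self):
        return (self.split_1.sort_key(), self.split_2.sort_key())


@dataclass
class IncongruenceEvent:
    """A clustered conflict: one rogue clade and the pairs it explains."""

    rogue_clade: frozenset
    attributed_pairs: list
    involved_taxa: frozenset
    label: str = ""
    allopolyploid_candidate: bool | None = None
    evidence: list = field(default_factory=list)


def restrict_to_shared(t1: Tree, t2: Tree):
    """Prune both trees to their common leaf set."""
    shared = t1.leaves & t2.leaves
    if len(shared) < 4:
        raise ValidationError(
            f"only {len(shared)} shared taxa; need >= 4 for non-trivial conflict"
        )
    r1 = t1 if t1.leaves == shared else prune(t1, shared)
    r2 = t2 if t2.leaves == shared else prune(t2, shared)
    return r1, r2, shared


def splits_conflict(s1: Split, s2: Split) -> bool:
    """Incompatibility criterion (symmetric)."""
    if s1.universe != s2.universe:
        raise ValidationError("splits are on different taxon universes")
    a1, b1 = s1.side_a, s1.side_b
    a2, b2 = s2.side_a, s2.side_b
    return bool(a1 & a2) and bool(a1 & b2) and bool(b1 & a2) and bool(b1 & b2)


def find_conflicting_pairs(
    t1: Tree, t2: Tree, thr1: float = 0.95, thr2: float = 0.95
) -> list:
    """All conflicting (split from t1, split from t2) pairs at the given
    support thresholds, over the shared taxon set, in deterministic order."""
    r1, r2, shared = restrict_to_shared(t1, t2)
    s1s = sorted(extract_splits(r1, thr1), key=Split.sort_key)
    s2s = sorted(extract_splits(r2, thr2), key=Split.sort_key)
    pairs = [
        ConflictPair(s1, s2, shared)
        for s1 in s1s
        for s2 in s2s
        if splits_conflict(s1, s2)
    ]
    pairs.sort(key=ConflictPair.sort_key)
    return pairs


def _pair_resolved(pair: ConflictPair, removed: frozenset) -> bool:
    """Does deleting ``removed`` from the universe dissolve the conflict?"""
    return _cells_resolved(_pair_cells(pair, frozenset()), removed)


def _pair_cells(pair: ConflictPair, removed: frozenset):
    """The four split-side intersections, minus already-removed taxa."""
    a1 = pair.split_1.side_a - removed
    b1 = pair.split_1.side_b - removed
    a2 = pair.split_2.side_a - removed
    b2 = pair.split_2.side_b - removed
    return (a1 & a2, a1 & b2, b1 & a2, b1 & b2)


def _cells_resolved(cells, cand) -> bool:
    """True iff removing ``cand`` leaves a trivial side or an empty cell."""
    aa, ab, ba, bb = (c - cand for c in cells)
    if not (aa and ab and ba and bb):
        return True  # a cell emptied: splits now compatible
    if len(aa) + len(ab) < 2 or len(ba) + len(bb) < 2:
        return True  # split 1 side trivial
    if len(aa) + len(ba) < 2 or len(ab) + len(bb) < 2:
        return True  # split 2 side trivial
    return False


def cluster_events(pairs: list, t1: Tree, t2: Tree) -> list:
    """Cluster conflict pairs into incongruence events by greedy
    rogue-clade removal.

    Candidates are descendant sets of nodes in either restricted tree; the
    candidate maximizing pairs-resolved per taxon removed wins each step
    (ties: smaller clade, then lexicographically smallest taxon).  Each
    removal is one event; its ``involved_taxa`` are the rogue clade plus the
    clade sides of the attributed pairs' splits that intersect the rogue.
    """
    if not pairs:
        return []
    r1, r2, shared = restrict_to_shared(t1, t2)
    candidates = set()
    for tree in (r1, r2):
        for _node, clade in tree.clades():
            if clade < shared:
                candidates.add(clade)

    events: list[IncongruenceEvent] = []
    remaining = list(pairs)
    removed: frozenset = frozenset()
    while remaining:
        # remaining pairs are unresolved under `removed` by construction
        cells = [_pair_cells(p, removed) for p in remaining]
        best = None
        for cand in candidates:
            cand_live = cand - removed
            if not cand_live or cand_live >= (shared - removed):
                continue
            hit = [
                p
                for p, pc in zip(remaining, cells)
                if _cells_resolved(pc, cand_live)
            ]
            if not hit:
                continue
            key = (
                -len(hit) / len(cand_live),
                len(cand_live),
                tuple(sorted(cand_live)),
            )
            if best is None or key < best[0]:
                best = (key, cand_live, hit)
        if best is None:  # every remaining pair already dissolved
            for p in remaining:
                assert _pair_resolved(p, removed)
            break
        _key, rogue, hit = best
        involved = set(rogue)
        for p in hit:
            for split in (p.split_1, p.split_2):
                side = split.clade_side or split.side_a
                if side & rogue:
                    involved |= side
        events.append(
            IncongruenceEvent(
                rogue_clade=rogue,
                attributed_pairs=hit,
                involved_taxa=frozenset(involved),
                label=f"event_{len(events) + 1}:" + ",".join(sorted(rogue)),
            )
        )
        removed |= rogue
        remaining = [p for p in remaining if p not in hit]
    return events


def shared_supported_clades(t1: Tree, t2: Tree, thr: float) -> list:
    """Splits supported at >= thr in both trees (on the shared taxon set),
    sorted by clade size descending."""
    r1, r2, _shared = restrict_to_shared(t1, t2)
    s1s = extract_splits(r1, thr)
    s2s = {s: s for s in extract_splits(r2, thr)}
    out = []
    for s in s1s:
        if s in s2s:
            partner = s2s[s]
            support = min(s.support, partner.support)
            out.append(
                Split(
                    s.side_a, s.universe, support=support, clade_side=s.clade_side
                )
            )
    out.sort(key=lambda s: (-s.size, tuple(sorted(s.side_a))))
    return out
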