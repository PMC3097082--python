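"""Seeded generators for every input the pipeline consumes.

These emulate, at desk scale, the structures the analysis operates on:

* random rooted binary trees (sequential random leaf attachment,
  exponential branch lengths);
* pairs of gene trees that agree except for a controlled set of planted
  clade moves, mimicking cytonuclear discordance, with a truth table that
  lets detector output be scored automatically;
* discrete characters evolved under a known Mk generator;
* alignments with planted gap runs for exercising indel coding.

All generators are byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignments import Alignment
from .errors import ValidationError
from .mk import MISSING, CharacterMatrix, RateModel, _Propagator
from .trees import Node, Tree

__all__ = [
    "HybridScenario",
    "sim_tree",
    "sim_hybrid_pair",
    "random_hybrid_scenario",
    "sim_mk_characters",
    "sim_indel_alignment",
]


def sim_tree(n_leaves: int, seed: int, mean_length: float = 0.1) -> Tree:
    """Random rooted binary tree by sequential random leaf attachment;
    every branch length is Exponential(mean ``mean_length``)."""
    if n_leaves < 3:
        raise ValidationError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    width = len(str(n_leaves))
    names = [f"t{str(i + 1).zfill(width)}" for i in range(n_leaves)]
    root = Node(children=[Node(name=names[0]), Node(name=names[1])])
    attachable = list(root.children)
    for name in names[2:]:
        target = attachable[rng.integers(len(attachable))]
        parent = target.parent
        leaf = Node(name=name)
        joint = Node(children=[target, leaf])
        parent.children[parent.children.index(target)] = joint
        joint.parent = parent
        attachable.extend([joint, leaf])
    for node in root.postorder():
        if node is not root:
            node.length = float(rng.exponential(mean_length))
    return Tree(root)


@dataclass
class HybridScenario:
    """A species tree plus clades to re-graft in the nuclear copy.

    ``support_true`` is assigned to every internal node of both trees and
    ``support_moved`` to the edges created/modified by a move (the default
    policy keeps both above any reasonable support threshold, so planted
    conflicts are always "well supported").
    """

    species_tree: Tree
    moved_clades: list
    seed: int
    support_true: float = 1.0
    support_moved: float = 0.99

    def __post_init__(self):
        self.moved_clades = [frozenset(c) for c in self.moved_clades]
        leaves = self.species_tree.leaves
        clades = {c for _n, c in self.species_tree.clades()}
        for mc in self.moved_clades:
            if mc not in clades:
                raise ValidationError(f"{sorted(mc)} is not a clade of the tree")
            if mc >= leaves:
                raise ValidationError("cannot move the whole tree")
        for a in self.moved_clades:
            for b in self.moved_clades:
                if a is not b and a & b:
                    raise ValidationError("moved clades must be disjoint")


def _find_clade_node(tree: Tree, clade: frozenset) -> Node:
    for node, s in tree.clades():
        if s == clade:
            return node
    raise ValidationError(f"clade {sorted(clade)} not found")


def _detach(tree: Tree, node: Node) -> None:
    parent = node.parent
    parent.children.remove(node)
    if len(parent.children) == 1 and parent.parent is not None:
        only = parent.children[0]
        grand = parent.parent
        if parent.length is not None or only.length is not None:
            only.length = (parent.length or 0.0) + (only.length or 0.0)
        grand.children[grand.children.index(parent)] = only
        only.parent = grand
    elif len(parent.children) == 1 and parent.parent is None:
        # root became unary: promote the surviving child
        tree.root = parent.children[0]
        tree.root.parent = None


def sim_hybrid_pair(scenario: HybridScenario):
    """(nuclear tree, chloroplast tree, truth table).

    The chloroplast tree is the species tree; the nuclear tree has each
    moved clade pruned and re-grafted onto a different branch.  Attachment
    branches are chosen (seeded) outside every moved clade, away from the
    source position but at a moderate topological distance from it (the
    kind of local switch seen in real cytonuclear discordance), so each
    move yields a detectable, separable incongruence.  The truth table
    lists each planted rogue clade and the clade it was attached next to.
    """
    rng = np.random.default_rng(scenario.seed)
    chloroplast = scenario.species_tree.copy()
    nuclear = scenario.species_tree.copy()
    forbidden = frozenset().union(frozenset(), *scenario.moved_clades)
    truth = []
    for clade in scenario.moved_clades:
        mover = _find_clade_node(nuclear, clade)
        old_parent_set = mover.parent.leaf_names()
        source_spot = mover.parent.parent
        _detach(nuclear, mover)
        mover.parent = None
        depth = {}
        for node in nuclear.preorder():
            depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1

        def lca_depths(a, b):
            da, db = depth[id(a)], depth[id(b)]
            ra, rb = da, db
            while ra > rb:
                a, ra = a.parent, ra - 1
            while rb > ra:
                b, rb = b.parent, rb - 1
            while a is not b:
                a, b, ra = a.parent, b.parent, ra - 1
            return da - ra, db - ra

        # candidate attachment points: nodes whose subtree avoids every
        # moved clade and which are not where the clade just came from.
        # Both the destination and the source must hang more than
        # |clade| + 1 edges below their junction: that is the regime in
        # which the planted clade is the unique most-parsimonious rogue
        # (it breaks more splits per removed taxon than any bystander).
        min_depth = len(clade) + 1
        candidates = []
        for node, s in nuclear.clades():
            if node is nuclear.root:
                continue
            if s & forbidden:
                continue
            if s <= old_parent_set or s >= (old_parent_set - clade):
                continue  # too close to the source position to conflict
            if source_spot is not None:
                d_t, d_s = lca_depths(node, source_spot)
                if d_t < min_depth or d_s + 1 < min_depth:
                    continue
            candidates.append(node)
        if not candidates:
            raise ValidationError(
                f"no legal attachment point for clade {sorted(clade)}"
            )
        candidates.sort(key=lambda n: sorted(n.leaf_names())[0])
        target = candidates[rng.integers(len(candidates))]
        parent = target.parent
        joint = Node(length=None, support=None)
        half = None if target.length is None else target.length / 2.0
        joint.length = half
        target.length = half
        parent.children[parent.children.index(target)] = joint
        joint.parent = parent
        joint.add_child(target)
        joint.add_child(mover)
        joint.support = -1.0  # placeholder, re-labelled below
        truth.append(
            {"rogue_clade": clade, "attached_next_to": target.leaf_names()}
        )
    for tree in (nuclear, chloroplast):
        for node in tree.postorder():
            if node.is_leaf or node is tree.root:
                continue
            if node.support == -1.0:
                node.support = scenario.support_moved
            else:
                node.support = scenario.support_true
    nuclear.validate()
    return nuclear, chloroplast, truth


def random_hybrid_scenario(
    n_leaves: int,
    n_moves: int,
    seed: int,
    max_clade_size: int = 3,
) -> HybridScenario:
    """A seeded scenario with ``n_moves`` small, well-separated clade moves.

    Moved clades (size 1..max_clade_size) are chosen disjoint, away from
    the root, and with mutually disjoint source neighbourhoods, so every
    planted move produces its own separable incongruence event.
    """
    rng = np.random.default_rng(seed)
    for _attempt in range(50):
        species = sim_tree(n_leaves, int(rng.integers(2**31)))
        node_sets = [
            (node, s, node.parent.leaf_names())
            for node, s in species.clades()
            if node.parent is not None and node.parent.parent is not None
        ]
        # small moves with compact source neighbourhoods keep the planted
        # events separable (no candidate near the root blocking everything)
        node_sets = [
            (node, s, p)
            for node, s, p in node_sets
            if len(s) <= max_clade_size and len(p) <= max(8, 3 * max_clade_size)
        ]
        rng.shuffle(node_sets)
        chosen: list[frozenset] = []
        blocked: set = set()
        for _node, s, parent_set in node_sets:
            neighbourhood = s | parent_set
            if neighbourhood & blocked:
                continue
            chosen.append(s)
            blocked |= neighbourhood
            if len(chosen) == n_moves:
                break
        if len(chosen) == n_moves:
            scenario = HybridScenario(
                species_tree=species,
                moved_clades=chosen,
                seed=int(rng.integers(2**31)),
            )
            try:  # verify every move has a legal attachment point
                sim_hybrid_pair(scenario)
            except ValidationError:
                continue
            return scenario
    raise ValidationError(
        f"could not place {n_moves} separated moves on {n_leaves} leaves"
    )


def sim_mk_characters(
    tree: Tree,
    model: RateModel,
    n_chars: int,
    seed: int,
    alphabet: list | None = None,
) -> CharacterMatrix:
    """Evolve ``n_chars`` independent characters down the tree.

    Root states are drawn from the uniform prior; each edge applies the
    model's transition probabilities for its branch length.
    """
    if alphabet is None:
        alphabet = [str(i) for i in range(model.k)]
    if len(alphabet) != model.k:
        raise ValidationError("alphabet size must equal the model's k")
    rng = np.random.default_rng(seed)
    prop = _Propagator(model.generator)
    states: dict[int, np.ndarray] = {}
    data: dict[str, list] = {}
    for node in tree.preorder():
        if node.parent is None:
            states[id(node)] = rng.integers(model.k, size=n_chars)
        else:
            if node.length is None:
                raise ValidationError("branch lengths required for simulation")
            P = prop(np.array([node.length]))[0]
            cum = np.cumsum(P, axis=1)
            u = rng.random(n_chars)
            parent_states = states[id(node.parent)]
            states[id(node)] = (
                u[:, None] > cum[parent_states]
            ).sum(axis=1)
        if node.is_leaf:
            data[node.name] = [alphabet[s] for s in states[id(node)]]
    return CharacterMatrix(data, list(alphabet))


def sim_indel_alignment(
    n_taxa: int, length: int, gap_events: list, seed: int
):
    """Random nucleotide alignment with planted gap runs.

    ``gap_events`` is a list of (start, end, taxa) with 1-based inclusive
    columns; each listed taxon receives a '-' run over exactly that range.
    Events touching the same taxon must not overlap or abut (their runs
    would merge into one, breaking the truth table).  Returns
    (Alignment, truth) where truth mirrors ``gap_events`` with taxon names.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    names = [f"s{str(i + 1).zfill(width)}" for i in range(n_taxa)]
    events = []
    for start, end, taxa in gap_events:
        if not 1 <= start <= end <= length:
            raise ValidationError(f"gap {start}-{end} outside 1..{length}")
        idx = sorted(taxa)
        if any(i < 0 or i >= n_taxa for i in idx):
            raise ValidationError(f"taxon index out of range in gap {start}-{end}")
        events.append((start, end, idx))
    per_taxon: dict[int, list] = {}
    for start, end, idx in events:
        for i in idx:
            for s, e in per_taxon.get(i, ()):
                if start <= e + 1 and end >= s - 1:
                    raise ValidationError(
                        f"gap events {s}-{e} and {start}-{end} collide on "
                        f"taxon {i} (runs would merge)"
                    )
            per_taxon.setdefault(i, []).append((start, end))
    base = rng.integers(4, size=length)  # one ancestral sequence, no mutations
    seqs = {}
    for i, name in enumerate(names):
        seq = list("ACGT"[b] for b in base)
        for start, end in per_taxon.get(i, ()):
            seq[start - 1 : end] = "-" * (end - start + 1)
        seqs[name] = "".join(seq)
    truth = [
        {"start": s, "end": e, "taxa": [names[i] for i in idx]}
        for s, e, idx in events
    ]
    return Alignment(seqs), truth
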