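"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, direct
counting) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm


# ---------------------------------------------------------------------------
# tree enumeration


def enumerate_rooted_binary_trees(taxa):
    """All rooted binary tree shapes on ``taxa`` as nested tuples."""
    taxa = list(taxa)
    if len(taxa) == 1:
        return [taxa[0]]
    trees = []
    first, rest = taxa[0], taxa[1:]
    for sub in enumerate_rooted_binary_trees(rest):
        for edited in _insert_everywhere(sub, first):
            trees.append(edited)
    return trees


def _insert_everywhere(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for sub in _insert_everywhere(left, leaf):
            yield (sub, right)
        for sub in _insert_everywhere(right, leaf):
            yield (left, sub)


def tree_leafset(tree):
    if isinstance(tree, tuple):
        return tree_leafset(tree[0]) | tree_leafset(tree[1])
    return frozenset([tree])


def tree_splits(tree, universe):
    """Non-trivial unrooted splits displayed by a nested-tuple tree,
    each canonicalized as a frozenset pair."""
    splits = set()

    def walk(sub):
        s = tree_leafset(sub)
        if 1 < len(s) < len(universe) - 1:
            splits.add(frozenset([s, universe - s]))
        if isinstance(sub, tuple):
            walk(sub[0])
            walk(sub[1])

    walk(tree)
    return splits


def some_tree_displays_both(universe, side1, side2):
    """Ground truth for split compatibility by exhaustive tree search."""
    u = frozenset(universe)
    want = {frozenset([side1, u - side1]), frozenset([side2, u - side2])}
    for tree in enumerate_rooted_binary_trees(sorted(u)):
        if want <= tree_splits(tree, u):
            return True
    return False


# ---------------------------------------------------------------------------
# Mk likelihood by state enumeration


def _collect_nodes(tree):
    """(internal nodes, all non-root nodes) of a phylodiscord Tree."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    nonroot = [n for n in tree.postorder() if n.parent is not None]
    return internals, nonroot


def brute_force_likelihood(tree, chars, Q, prior):
    """Sum over every internal-node state assignment of the product of
    transition probabilities; characters independent."""
    k = Q.shape[0]
    P = {}
    internals, nonroot = _collect_nodes(tree)
    for n in nonroot:
        P[id(n)] = expm(Q * n.length)
    state_index = {s: i for i, s in enumerate(chars.alphabet)}
    total = 0.0
    for c in range(chars.n_characters):
        site = 0.0
        for assignment in itertools.product(range(k), repeat=len(internals)):
            states = {id(n): s for n, s in zip(internals, assignment)}
            ok_weight = prior[states[id(tree.root)]]
            for n in tree.postorder():
                if n.parent is None:
                    continue
                parent_state = states[id(n.parent)]
                if n.is_leaf:
                    obs = chars.data[n.name][c]
                    if obs == "?":
                        contrib = 1.0  # any tip state
                    else:
                        contrib = P[id(n)][parent_state, state_index[obs]]
                else:
                    contrib = P[id(n)][parent_state, states[id(n)]]
                ok_weight *= contrib
            site += ok_weight
        total += np.log(site)
    return total


def brute_force_marginals(tree, chars, Q, prior):
    """Per-internal-node marginal state probabilities by enumeration."""
    k = Q.shape[0]
    P = {}
    internals, nonroot = _collect_nodes(tree)
    for n in nonroot:
        P[id(n)] = expm(Q * n.length)
    state_index = {s: i for i, s in enumerate(chars.alphabet)}
    clade_of = {}
    for node, clade in tree.clades(include_leaves=False):
        clade_of[id(node)] = clade
    out = {
        clade_of[id(n)]: np.zeros((chars.n_characters, k)) for n in internals
    }
    for c in range(chars.n_characters):
        for assignment in itertools.product(range(k), repeat=len(internals)):
            states = {id(n): s for n, s in zip(internals, assignment)}
            weight = prior[states[id(tree.root)]]
            for n in tree.postorder():
                if n.parent is None:
                    continue
                parent_state = states[id(n.parent)]
                if n.is_leaf:
                    obs = chars.data[n.name][c]
                    weight *= (
                        1.0
                        if obs == "?"
                        else P[id(n)][parent_state, state_index[obs]]
                    )
                else:
                    weight *= P[id(n)][parent_state, states[id(n)]]
            for n in internals:
                out[clade_of[id(n)]][c, states[id(n)]] += weight
    for arr in out.values():
        arr /= arr.sum(axis=1, keepdims=True)
    return out


def count_clade_frequencies(sample):
    """Direct clade counting over a tree sample (consensus oracle)."""
    counts = {}
    for t in sample:
        universe = t.leaves
        for _node, clade in t.clades(include_leaves=False):
            if 1 < len(clade) < len(universe):
                counts[clade] = counts.get(clade, 0) + 1
    return {c: k / len(sample.trees) for c, k in counts.items()}
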