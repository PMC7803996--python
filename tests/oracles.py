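"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's parsimony algorithms: step counts are
found by exhaustive enumeration of ancestral assignments, and the best
6-taxon tree by scanning every unrooted binary topology.
"""

from __future__ import annotations

from itertools import product

from ramphylo._tree import MISSING, IndexedTree


def brute_force_steps(tree, character):
    """Minimum changes by trying every internal-node state assignment.

    ``character`` maps leaf label -> 0 / 1 / None. Exponential in the number
    of internal nodes; fine for <= 8 leaves.
    """
    itree = IndexedTree.from_dendropy(tree)
    leaf_state = {}
    for slot, node in enumerate(itree.leaf_nodes):
        st = character[itree.leaf_labels[slot]]
        leaf_state[int(node)] = MISSING if st is None else int(st)
    internal = [v for v in range(itree.n_nodes) if itree.children[v]]
    best = None
    for combo in product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, combo))
        changes = 0
        for v in range(itree.n_nodes - 1):
            p = state[int(itree.parent[v])]
            if v in state:
                changes += state[v] != p
            else:
                s = leaf_state[v]
                if s != MISSING:
                    changes += s != p
        if best is None or changes < best:
            best = changes
    return best


def random_tree_with_polytomies(rng, n_leaves):
    """Random rooted tree, some internal edges collapsed into polytomies."""
    from ramphylo.synth import simulate_tree

    tree = simulate_tree(n_leaves, int(rng.integers(2 ** 31)))
    for node in list(tree.preorder_internal_node_iter()):
        if node is tree.seed_node:
            continue
        if rng.random() < 0.3:
            node.edge.collapse()
    return tree


def random_character(rng, labels, missing_prob=0.15):
    out = {}
    for lab in labels:
        r = rng.random()
        out[lab] = None if r < missing_prob else int(r * 1e6) % 2
    return out


def all_unrooted_newicks(taxa):
    """Every unrooted binary topology on ``taxa`` as newick strings.

    Trees are represented rooted at ``taxa[0]``; each later taxon is inserted
    on every edge (1 x 3 x 5 x ... topologies: 105 for six taxa).
    """

    def insert_all(tree, t):
        yield (tree, t)
        if isinstance(tree, tuple):
            a, b = tree
            for na in insert_all(a, t):
                yield (na, b)
            for nb in insert_all(b, t):
                yield (a, nb)

    trees = [(taxa[1], taxa[2])]
    for t in taxa[3:]:
        trees = [nt for tr in trees for nt in insert_all(tr, t)]

    def fmt(tree):
        if isinstance(tree, tuple):
            return f"({fmt(tree[0])},{fmt(tree[1])})"
        return tree

    return [f"({taxa[0]},{fmt(tr)});" for tr in trees]
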