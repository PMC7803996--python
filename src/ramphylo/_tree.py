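"""Array-backed tree representation used by the parsimony machinery.

Public modules accept and return :class:`dendropy.Tree`; internally everything
that scores characters converts once to an :class:`IndexedTree`, whose nodes
are numbered in postorder (root last, every parent after its children). This
makes the bottom-up Hartigan pass a single loop over node indices and lets one
tree be reused across thousands of characters and label permutations.
"""

from __future__ import annotations

import numpy as np

#: sentinel for a missing ('?') leaf state in integer state arrays
MISSING = -1


class IndexedTree:
    """A rooted (possibly multifurcating) tree flattened to index arrays.

    Parameters
    ----------
    children : list of list of int
        ``children[v]`` are the child node indices of node ``v``; empty for
        leaves. Indices must be postorder: every parent greater than each of
        its children, root last.
    leaf_labels : sequence of str
        Label of leaf slot ``i``; leaf slots are the order in which state
        columns are supplied to the parsimony routines.
    leaf_nodes : sequence of int
        Node index of leaf slot ``i``.
    """

    def __init__(self, children, leaf_labels, leaf_nodes):
        self.children = [list(c) for c in children]
        self.n_nodes = len(self.children)
        self.root = self.n_nodes - 1
        self.leaf_labels = list(leaf_labels)
        self.leaf_nodes = np.asarray(leaf_nodes, dtype=np.intp)
        self.n_leaves = len(self.leaf_labels)
        self.leaf_index = {lab: i for i, lab in enumerate(self.leaf_labels)}
        parent = np.full(self.n_nodes, -1, dtype=np.intp)
        for v, ch in enumerate(self.children):
            for c in ch:
                if c >= v:
                    raise ValueError("children must be in postorder (parent after child)")
                parent[c] = v
        self.parent = parent

    @classmethod
    def from_dendropy(cls, tree):
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children, leaf_labels, leaf_nodes = [], [], []
        for i, nd in enumerate(nodes):
            kids = nd.child_nodes()
            children.append([index[id(c)] for c in kids])
            if not kids:
                label = nd.taxon.label if nd.taxon is not None else nd.label
                leaf_labels.append(label)
                leaf_nodes.append(i)
        return cls(children, leaf_labels, leaf_nodes)

    def leaf_set_below(self, v):
        """Leaf-slot indices in the subtree rooted at node ``v``."""
        out, stack = [], [v]
        node_to_slot = {int(n): i for i, n in enumerate(self.leaf_nodes)}
        while stack:
            u = stack.pop()
            ch = self.children[u]
            if ch:
                stack.extend(ch)
            else:
                out.append(node_to_slot[u])
        return out


def hartigan_steps(itree, states):
    """Minimum parsimony steps for binary characters with missing data.

    Hartigan's generalization of Fitch counting: at each internal node the
    children "vote" for the states their upper sets contain; the node keeps
    the majority states and pays one step per dissenting child. Missing
    leaves carry the full state set {0, 1} and never force a change.

    Parameters
    ----------
    itree : IndexedTree
    states : array-like, shape (n_characters, n_leaves) or (n_leaves,)
        Entries in {0, 1, MISSING}; column order = ``itree.leaf_labels``.

    Returns
    -------
    numpy.ndarray of int, shape (n_characters,)
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.int8))
    if states.shape[1] != itree.n_leaves:
        raise ValueError(
            f"states has {states.shape[1]} columns for {itree.n_leaves} leaves"
        )
    n_chars = states.shape[0]
    in0 = np.zeros((itree.n_nodes, n_chars), dtype=bool)
    in1 = np.zeros_like(in0)
    in0[itree.leaf_nodes] = (states != 1).T
    in1[itree.leaf_nodes] = (states != 0).T
    steps = np.zeros(n_chars, dtype=np.int64)
    for v in range(itree.n_nodes):
        ch = itree.children[v]
        if not ch:
            continue
        n0 = in0[ch].sum(axis=0)
        n1 = in1[ch].sum(axis=0)
        k = np.maximum(n0, n1)
        steps += len(ch) - k
        in0[v] = n0 == k
        in1[v] = n1 == k
    return steps


def hartigan_assignment(itree, states_row, root_tie=0):
    """One most-parsimonious ancestral assignment for a single character.

    Bottom-up Hartigan sets, then a top-down pass that keeps the parent's
    state whenever it is in the child's upper set (so no spurious flips),
    with root ties resolved to ``root_tie`` (default 0 = absence ancestral).

    Returns
    -------
    (assignment, steps) : (numpy.ndarray of int8 per node, int)
    """
    states_row = np.asarray(states_row, dtype=np.int8).reshape(1, -1)
    n_chars = 1
    in0 = np.zeros((itree.n_nodes, n_chars), dtype=bool)
    in1 = np.zeros_like(in0)
    in0[itree.leaf_nodes] = (states_row != 1).T
    in1[itree.leaf_nodes] = (states_row != 0).T
    steps = 0
    for v in range(itree.n_nodes):
        ch = itree.children[v]
        if not ch:
            continue
        n0 = in0[ch].sum(axis=0)
        n1 = in1[ch].sum(axis=0)
        k = np.maximum(n0, n1)
        steps += int((len(ch) - k)[0])
        in0[v] = n0 == k
        in1[v] = n1 == k
    a0 = in0[:, 0]
    a1 = in1[:, 0]
    assign = np.empty(itree.n_nodes, dtype=np.int8)
    r = itree.root
    if a0[r] and a1[r]:
        assign[r] = root_tie
    else:
        assign[r] = 0 if a0[r] else 1
    for v in range(itree.n_nodes - 2, -1, -1):
        p = assign[itree.parent[v]]
        if p == 0 and a0[v]:
            assign[v] = 0
        elif p == 1 and a1[v]:
            assign[v] = 1
        else:
            assign[v] = 0 if a0[v] else 1
    return assign, steps
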