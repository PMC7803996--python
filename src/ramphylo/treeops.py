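"""Tree I/O, bipartition comparison, and heuristic maximum-parsimony search.

Trees are :class:`dendropy.Tree` objects throughout the public surface;
newick is the interchange format (polytomies and absent branch lengths are
accepted). The branch percent identity metric expresses, of the non-trivial
bipartitions in a recovered tree, the percentage also present in a reference
tree — the reference may be partially unresolved (polytomous), which is why
the denominator defaults to the source tree's bipartition count.

The parsimony search is a deliberately small heuristic: random stepwise
addition followed by hill-climbing NNI (optionally SPR) rearrangement,
retaining equally-best distinct topologies. It stands in for large-scale
parsimony software at the scale of tens of taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from ._tree import MISSING, IndexedTree, hartigan_steps
from .errors import IncomparableTreesError, LabelError, NewickParseError

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "parse_newick",
    "write_newick",
    "bipartition_set",
    "branch_percent_identity",
    "parsimony_score",
    "parsimony_search",
]


def parse_newick(text):
    """Parse newick text into a rooted :class:`dendropy.Tree`.

    Polytomies and missing branch lengths are accepted; leaf labels are
    preserved verbatim (underscores are not turned into spaces). Duplicate
    leaf labels or malformed syntax raise :class:`NewickParseError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed newick: {exc}") from exc
    labels = []
    for lf in tree.leaf_node_iter():
        lab = lf.taxon.label if lf.taxon is not None else lf.label
        if lab is None or lab == "":
            raise NewickParseError("empty leaf label")
        labels.append(lab)
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree):
    """Serialize a tree to newick (no rooting token, labels verbatim)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def _leaf_label(node):
    return node.taxon.label if node.taxon is not None else node.label


def bipartition_set(tree):
    """Non-trivial bipartitions of the unrooted form of ``tree``.

    Each bipartition is canonicalized as the frozenset of leaf labels on the
    side *not* containing the lexicographically smallest leaf, so identical
    splits from different trees compare equal. Trees with fewer than four
    leaves have no non-trivial splits and yield the empty set.
    """
    itree = IndexedTree.from_dendropy(tree)
    all_leaves = frozenset(itree.leaf_labels)
    n = len(all_leaves)
    if n < 4:
        return set()
    ref = min(all_leaves)
    node_label = {int(nd): lab for nd, lab in zip(itree.leaf_nodes, itree.leaf_labels)}
    below = [None] * itree.n_nodes
    out = set()
    for v in range(itree.n_nodes):
        ch = itree.children[v]
        if not ch:
            below[v] = frozenset([node_label[v]])
            continue
        s = frozenset().union(*(below[c] for c in ch))
        below[v] = s
        if v == itree.root:
            continue
        side = s if ref not in s else all_leaves - s
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def _pruned_to(tree, labels):
    pruned = tree.extract_tree_with_taxa_labels(labels=labels)
    pruned.suppress_unifurcations()
    return pruned


def branch_percent_identity(source, reference, symmetric=False):
    """Percentage of the source tree's bipartitions found in the reference.

    Both trees are first pruned to their shared leaf set. With
    ``symmetric=True`` the denominator is the mean bipartition count of the
    two trees (a Robinson–Foulds-style similarity) instead of the source's
    count. Returns ``None`` (with a logged warning) when the source carries
    no non-trivial bipartitions after pruning.
    """
    src_leaves = {_leaf_label(lf) for lf in source.leaf_node_iter()}
    ref_leaves = {_leaf_label(lf) for lf in reference.leaf_node_iter()}
    shared = src_leaves & ref_leaves
    if len(shared) < 4:
        raise IncomparableTreesError(
            f"only {len(shared)} shared leaves; need at least 4"
        )
    src_bi = bipartition_set(_pruned_to(source, sorted(shared)))
    ref_bi = bipartition_set(_pruned_to(reference, sorted(shared)))
    inter = len(src_bi & ref_bi)
    if symmetric:
        denom = (len(src_bi) + len(ref_bi)) / 2.0
    else:
        denom = float(len(src_bi))
    if denom == 0:
        logger.warning("source tree has no non-trivial bipartitions; identity undefined")
        return None
    return 100.0 * inter / denom


def _states_for_leaves(matrix, leaf_labels):
    """(n_chars, n_leaves) int8 state array for the given leaf order."""
    df = matrix.to_dataframe()
    missing_rows = [lab for lab in leaf_labels if lab not in df.index]
    if missing_rows:
        raise LabelError(f"tree leaves absent from matrix: {missing_rows}")
    arr = df.loc[list(leaf_labels)].to_numpy(dtype=float).T  # chars x leaves
    states = np.full(arr.shape, MISSING, dtype=np.int8)
    states[arr == 0.0] = 0
    states[arr == 1.0] = 1
    return states


def parsimony_score(tree, matrix):
    """Total Fitch/Hartigan parsimony steps of ``matrix`` on ``tree``.

    Missing cells ('?') carry the full state set and never force a change;
    an all-missing character contributes zero steps.
    """
    itree = IndexedTree.from_dendropy(tree)
    states = _states_for_leaves(matrix, itree.leaf_labels)
    return int(hartigan_steps(itree, states).sum())


@dataclass
class SearchConfig:
    """Settings for the heuristic parsimony search."""

    n_replicates: int = 10
    rearrangement: str = "nni"  # or "spr"
    max_retained: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.rearrangement not in ("nni", "spr"):
            raise ValueError("rearrangement must be 'nni' or 'spr'")


# ---------------------------------------------------------------------------
# adjacency-list helpers for the search (taxa are nodes 0..n-1, internals above)

def _adj_edges(adj):
    return sorted(
        (u, v) for u in adj for v in adj[u] if u < v
    )


def _score_adj(adj, states, n_taxa):
    root = max(adj)
    parent = {root: None}
    pre = []
    stack = [root]
    while stack:
        u = stack.pop()
        pre.append(u)
        for w in sorted(adj[u]):
            if w != parent[u]:
                parent[w] = u
                stack.append(w)
    order = list(reversed(pre))
    index = {u: i for i, u in enumerate(order)}
    children = [[] for _ in order]
    for u in order:
        if parent[u] is not None:
            children[index[parent[u]]].append(index[u])
    present = sorted(t for t in adj if t < n_taxa)  # partial trees during addition
    leaf_nodes = [index[t] for t in present]
    itree = IndexedTree(children, present, leaf_nodes)
    return int(hartigan_steps(itree, states[:, present]).sum())


def _attach(adj, p, q, w, t):
    adj[p].remove(q)
    adj[q].remove(p)
    adj[w] = {p, q, t}
    adj[p].add(w)
    adj[q].add(w)
    adj[t] = {w}


def _detach(adj, p, q, w, t):
    del adj[w]
    del adj[t]
    adj[p].remove(w)
    adj[q].remove(w)
    adj[p].add(q)
    adj[q].add(p)


def _nni_swap(adj, u, x, v, y):
    adj[u].remove(x)
    adj[x].remove(u)
    adj[v].remove(y)
    adj[y].remove(v)
    adj[u].add(y)
    adj[y].add(u)
    adj[v].add(x)
    adj[x].add(v)


def _nni_moves(adj, n_taxa):
    for u, v in _adj_edges(adj):
        if u < n_taxa or v < n_taxa:
            continue  # pendant edge: no NNI
        a, b = sorted(adj[u] - {v})
        c, d = sorted(adj[v] - {u})
        yield (u, b, v, c)
        yield (u, b, v, d)


def _component(adj, start, blocked):
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w != blocked and w not in seen and not (u == start and w == blocked):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
    return seen


def _spr_candidates(adj, n_taxa):
    """Yield fresh adjacency dicts for every subtree-prune-regraft move."""
    for u, v in _adj_edges(adj):
        # prune the subtree hanging off v away from u; u must be internal
        for a, b in ((u, v), (v, u)):
            if len(adj[a]) != 3:
                continue
            sub = _component(adj, b, a)
            rest = set(adj) - sub
            p, q = sorted(adj[a] - {b})
            for e0, e1 in _adj_edges(adj):
                if e0 not in rest or e1 not in rest:
                    continue
                if {e0, e1} & {a}:
                    continue
                if {e0, e1} == {p, q}:
                    continue  # regrafting where it came from
                new = {k: set(s) for k, s in adj.items()}
                # detach: remove a, reconnect p-q
                new[p].remove(a)
                new[q].remove(a)
                new[p].add(q)
                new[q].add(p)
                new[b].remove(a)
                del new[a]
                # regraft a on edge (e0, e1)
                new[e0].remove(e1)
                new[e1].remove(e0)
                new[a] = {e0, e1, b}
                new[e0].add(a)
                new[e1].add(a)
                new[b].add(a)
                yield new


def _canonical_newick(adj, labels, n_taxa):
    def build(v, parent):
        if v < n_taxa:
            return labels[v], labels[v]
        parts = sorted(build(w, v) for w in sorted(adj[v] - {parent}))
        # sort by (min-leaf key) for a canonical child order
        parts = sorted(parts, key=lambda sm: sm[1])
        return "(" + ",".join(s for s, _ in parts) + ")", min(m for _, m in parts)

    anchor = 0
    nb = next(iter(adj[anchor]))
    parts = sorted((build(w, nb) for w in sorted(adj[nb] - {anchor})), key=lambda sm: sm[1])
    inner = ",".join(s for s, _ in parts)
    return f"({labels[anchor]},{inner});"


def parsimony_search(matrix, config=None):
    """Heuristic maximum-parsimony search over unrooted binary topologies.

    Random stepwise addition (one replicate per addition order) followed by
    hill-climbing rearrangement until no move improves the score. Distinct
    equally-best topologies are retained up to ``config.max_retained``.
    Deterministic under a fixed ``config.seed``.

    Returns
    -------
    (trees, best_score) : (list of dendropy.Tree, int)
    """
    if config is None:
        config = SearchConfig()
    taxa = list(matrix.species)
    n_taxa = len(taxa)
    if n_taxa < 4:
        raise ValueError("parsimony search needs at least 4 species")
    states = _states_for_leaves(matrix, taxa)
    rng = np.random.default_rng(config.seed)
    best_score = None
    best = {}  # canonical newick -> None, insertion ordered

    for _ in range(config.n_replicates):
        order = [int(x) for x in rng.permutation(n_taxa)]
        a, b, c = order[:3]
        hub = n_taxa
        adj = {a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}
        next_internal = n_taxa + 1
        for t in order[3:]:
            best_edge, best_s = None, None
            w = next_internal
            for p, q in _adj_edges(adj):
                _attach(adj, p, q, w, t)
                s = _score_adj(adj, states, n_taxa)
                _detach(adj, p, q, w, t)
                if best_s is None or s < best_s:
                    best_s, best_edge = s, (p, q)
            p, q = best_edge
            _attach(adj, p, q, w, t)
            next_internal += 1

        score = _score_adj(adj, states, n_taxa)
        improved = True
        while improved:
            improved = False
            if config.rearrangement == "nni":
                best_move, best_s = None, score
                for move in _nni_moves(adj, n_taxa):
                    _nni_swap(adj, *move)
                    s = _score_adj(adj, states, n_taxa)
                    _nni_swap(adj, move[0], move[3], move[2], move[1])
                    if s < best_s:
                        best_s, best_move = s, move
                if best_move is not None:
                    _nni_swap(adj, *best_move)
                    score = best_s
                    improved = True
            else:  # spr
                best_adj, best_s = None, score
                for cand in _spr_candidates(adj, n_taxa):
                    s = _score_adj(cand, states, n_taxa)
                    if s < best_s:
                        best_s, best_adj = s, cand
                if best_adj is not None:
                    adj, score = best_adj, best_s
                    improved = True

        key = _canonical_newick(adj, taxa, n_taxa)
        if best_score is None or score < best_score:
            best_score = score
            best = {key: None}
        elif score == best_score and key not in best and len(best) < config.max_retained:
            best[key] = None

    trees = [parse_newick(nwk) for nwk in sorted(best)]
    logger.info(
        "parsimony search: best score %d, %d topology(ies) retained", best_score, len(trees)
    )
    return trees, best_score
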