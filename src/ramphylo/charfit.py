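"""Homoplasy scoring of binary characters on a reference tree.

Each character (presence/absence of a ramp sequence in one ortholog) is
mapped onto the reference phylogeny with Hartigan's parsimony algorithm,
which handles polytomies and missing data ('?' = full state set {0,1}).
From the minimum step count s, the character's retention index is

    RI = (g - s) / (g - m)

with m = 1 (the minimum conceivable steps for an informative binary
character) and g = min(#non-missing 0s, #non-missing 1s) (the steps a star
phylogeny would need). RI = 1 means no homoplasy; RI = 0 means the character
is as homoplasious as possible. Changes in one most-parsimonious
reconstruction are classified as gains (0 -> 1, parallelisms when repeated)
and losses (1 -> 0, reversals); ties during the top-down pass keep the
parent's state, and root ties default to 0 (ramp absence ancestral).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._tree import MISSING, IndexedTree, hartigan_assignment, hartigan_steps
from .errors import LabelError, RequiresRootError

__all__ = [
    "CharacterFit",
    "fitch_steps",
    "classify_changes",
    "retention_index",
    "is_completely_orthologous",
]


@dataclass
class CharacterFit:
    """Parsimony mapping summary for one binary character on one tree."""

    ortholog_id: str
    steps: int                  # s: observed minimum changes
    min_steps: int              # m: 1 for informative binary characters
    max_steps: int              # g: min of the two non-missing state counts
    gains: int
    losses: int
    retention: Optional[float]  # None when g == m (uninformative)

    @property
    def informative(self):
        return self.retention is not None


def _states_row(itree, character):
    row = np.empty(itree.n_leaves, dtype=np.int8)
    for i, lab in enumerate(itree.leaf_labels):
        if lab not in character:
            raise LabelError(f"leaf {lab!r} has no state in the character")
        st = character[lab]
        if st is None or (isinstance(st, float) and math.isnan(st)) or st == "?":
            row[i] = MISSING
        elif int(st) in (0, 1):
            row[i] = int(st)
        else:
            raise ValueError(f"invalid state {st!r} for leaf {lab!r}")
    return row


def fitch_steps(tree, character):
    """Minimum number of state changes of ``character`` on ``tree``.

    ``character`` maps every leaf label to 0, 1, or a missing marker
    (None / NaN / '?'). Missing leaves never force a change. Works on
    multifurcating trees (Hartigan's generalization).
    """
    itree = IndexedTree.from_dendropy(tree)
    row = _states_row(itree, character)
    if np.all(row == MISSING):
        return 0
    return int(hartigan_steps(itree, row)[0])


def classify_changes(tree, character, root_tie=0):
    """(gains, losses) under one fixed most-parsimonious reconstruction.

    An edge whose parent is 0 and child is 1 is a gain; 1 -> 0 is a loss;
    gains + losses equals :func:`fitch_steps`. The tree must be rooted
    (direction matters); dendropy trees carry a seed node, so any parsed
    newick qualifies.
    """
    if tree.seed_node is None:
        raise RequiresRootError("classification requires a rooted tree")
    itree = IndexedTree.from_dendropy(tree)
    row = _states_row(itree, character)
    assign, _ = hartigan_assignment(itree, row, root_tie=root_tie)
    gains = losses = 0
    for v in range(itree.n_nodes - 1):
        p = assign[itree.parent[v]]
        c = assign[v]
        if p == 0 and c == 1:
            gains += 1
        elif p == 1 and c == 0:
            losses += 1
    return gains, losses


def retention_index(tree, character, ortholog_id="", root_tie=0):
    """Full parsimony fit (steps, gains/losses, retention index) of a character.

    Uninformative characters (fewer than two non-missing species in either
    state) get ``retention=None`` and are excluded from means upstream.
    """
    itree = IndexedTree.from_dendropy(tree)
    row = _states_row(itree, character)
    n0 = int(np.sum(row == 0))
    n1 = int(np.sum(row == 1))
    g = min(n0, n1)
    if n0 + n1 == 0:
        return CharacterFit(ortholog_id, 0, 1, g, 0, 0, None)
    s = int(hartigan_steps(itree, row)[0])
    gains, losses = classify_changes(tree, character, root_tie=root_tie)
    m = 1
    retention = (g - s) / (g - m) if g > m else None
    return CharacterFit(ortholog_id, s, m, g, gains, losses, retention)


def is_completely_orthologous(fit):
    """True when the character maps with a single gain-or-loss event.

    A single change means the ramp-bearing species (or the ramp-lacking
    species) form a group concordant with the tree.
    """
    return fit.steps == 1
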