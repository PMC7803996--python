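"""Synthetic trees, binary characters, and coding sequences with implanted ramps.

Everything downstream (detection, matrix building, homoplasy scoring, null
models) is testable against data whose true history is known:

* ``simulate_tree`` — uniform random-joining topology sampler (rooted binary).
* ``simulate_binary_characters`` — presence/absence characters evolved on a
  known tree in one of three modes: ``clean`` (exactly one gain on a random
  edge — zero homoplasy by construction), ``markov`` (independent gain/loss
  events per edge from an ancestral absence state), ``random`` (i.i.d.
  Bernoulli(0.5) leaf states — no signal at all).
* ``simulate_cds`` — coding genes where a configurable fraction carries a 5'
  implant of low-adaptiveness codons; each synonymous family has one
  designated high-usage codon, tails draw from the high pool and implants
  from the low pool, so the implant is detectable by construction. An
  optional ``tail_low_rate`` sprinkles low codons through tails to make
  genes noisier (off by default: under the geometric-mean outlier rule a
  noisy tail widens the window IQR until genuine implants stop being
  outliers).
* ``simulate_dataset`` — ties the two together: one gene per (species,
  ortholog) whose implant status follows the simulated character state.

The generator emulates per-species CDS FASTA sets with an ortholog table and
missing annotations; it does not model substitution along the tree, indels,
or ortholog-inference error.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._tree import IndexedTree
from .charmatrix import CharacterMatrix
from .rampdetect import GeneRecord, STOP_CODONS, SYNONYMOUS_FAMILIES
from .treeops import parse_newick, write_newick

__all__ = [
    "SynthConfig",
    "CharacterTruth",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_binary_characters",
    "simulate_cds",
    "simulate_dataset",
    "write_species_fastas",
]


@dataclass
class CharacterTruth:
    """Ground truth for one simulated character: where changes happened.

    ``change_edges`` holds (edge id, direction) pairs, where the edge id is
    the postorder index of the child node and direction is 'gain' or 'loss'.
    Clean-mode characters have exactly one entry, a gain.
    """

    character_id: str
    mode: str
    change_edges: list = field(default_factory=list)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults aim at desk-scale versions of a vertebrate-genome study: ~10%
    of genes carry a ramp, ramps span 30-50 codons, and genes span 300-500
    codons (so ramp windows stay a minority of each gene's profile).
    """

    n_leaves: int = 16
    n_characters: int = 100
    n_genes: int = 200
    mode: str = "clean"             # clean | markov | random
    missing_rate: float = 0.0
    gain_rate: float = 0.2          # per unit branch length (markov mode)
    loss_rate: float = 0.2
    ramp_fraction: float = 0.1
    gene_length_range: tuple = (300, 500)   # codons, inclusive
    ramp_length_range: tuple = (30, 50)     # codons, inclusive
    tail_low_rate: float = 0.0      # chance a tail codon comes from the low pool
    ancestral_state: int = 0
    species_missing_multipliers: Optional[dict] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 3:
            raise ValueError("n_leaves must be >= 3")
        if self.n_characters < 1:
            raise ValueError("n_characters must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.ramp_fraction <= 1.0:
            raise ValueError("ramp_fraction must lie in [0, 1]")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.mode not in ("clean", "markov", "random"):
            raise ValueError("mode must be clean, markov or random")
        lo, hi = self.ramp_length_range
        glo, ghi = self.gene_length_range
        if not (1 <= lo <= hi):
            raise ValueError("bad ramp_length_range")
        if not (lo >= 1 and hi < glo <= ghi):
            raise ValueError("ramp_length_range must fit strictly inside gene_length_range")


def simulate_tree(n_leaves, seed):
    """Rooted binary tree with uniquely labeled leaves (sp01, sp02, ...).

    Uniform random joining: repeatedly merge two uniformly chosen lineages.
    Topology only — no branch lengths. Deterministic in ``seed``.
    """
    if n_leaves < 3:
        raise ValueError("n_leaves must be >= 3")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_leaves)))
    lineages = [f"sp{str(i + 1).zfill(width)}" for i in range(n_leaves)]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        lineages[i] = f"({lineages[i]},{lineages[j]})"
        del lineages[j]
    return parse_newick(lineages[0] + ";")


def _char_ids(n):
    width = max(4, len(str(n)))
    return [f"og{str(i + 1).zfill(width)}" for i in range(n)]


def simulate_binary_characters(tree, config):
    """(CharacterMatrix, truths) for characters evolved on ``tree``.

    clean: one gain on a uniformly random edge; the subtree below is 1.
    markov: state walks down the tree from ``ancestral_state`` with per-edge
        change probability 1 - exp(-rate) (unit edge lengths).
    random: each leaf is 1 with probability 0.5, independently.

    After state assignment each cell is replaced by missing with probability
    ``missing_rate`` (optionally scaled per species).
    """
    rng = np.random.default_rng(config.seed)
    itree = IndexedTree.from_dendropy(tree)
    n_leaves = itree.n_leaves
    labels = itree.leaf_labels
    ids = _char_ids(config.n_characters)
    states = np.zeros((n_leaves, config.n_characters), dtype=float)
    truths = []

    if config.mode == "clean":
        leaf_sets = [itree.leaf_set_below(v) for v in range(itree.n_nodes)]
        for k, cid in enumerate(ids):
            edge_child = int(rng.integers(itree.n_nodes - 1))  # any non-root node
            states[leaf_sets[edge_child], k] = 1.0
            truths.append(CharacterTruth(cid, "clean", [(str(edge_child), "gain")]))
    elif config.mode == "markov":
        p_gain = 1.0 - np.exp(-config.gain_rate)
        p_loss = 1.0 - np.exp(-config.loss_rate)
        slot = {int(n): i for i, n in enumerate(itree.leaf_nodes)}
        for k, cid in enumerate(ids):
            node_state = np.empty(itree.n_nodes, dtype=np.int8)
            node_state[itree.root] = config.ancestral_state
            changes = []
            for v in range(itree.n_nodes - 2, -1, -1):
                s = node_state[itree.parent[v]]
                if s == 0 and rng.random() < p_gain:
                    s = 1
                    changes.append((str(v), "gain"))
                elif s == 1 and rng.random() < p_loss:
                    s = 0
                    changes.append((str(v), "loss"))
                node_state[v] = s
            for v, i in slot.items():
                states[i, k] = node_state[v]
            truths.append(CharacterTruth(cid, "markov", changes))
    else:  # random
        states = (rng.random((n_leaves, config.n_characters)) < 0.5).astype(float)
        truths = [CharacterTruth(cid, "random", []) for cid in ids]

    if config.missing_rate > 0:
        rates = np.full(n_leaves, config.missing_rate)
        if config.species_missing_multipliers:
            for i, lab in enumerate(labels):
                rates[i] = min(
                    config.missing_rate * config.species_missing_multipliers.get(lab, 1.0),
                    0.999,
                )
        mask = rng.random(states.shape) < rates[:, None]
        states[mask] = np.nan

    matrix = CharacterMatrix(pd.DataFrame(states, index=labels, columns=ids))
    return matrix, truths


# ---------------------------------------------------------------------------
# coding-sequence generation

#: designated high-usage codon per family (alphabetically first) and the rest
_HIGH = {aa: fam[0] for aa, fam in SYNONYMOUS_FAMILIES.items()}
_LOWS = {aa: fam[1:] for aa, fam in SYNONYMOUS_FAMILIES.items()}
_AAS = sorted(SYNONYMOUS_FAMILIES)
_MULTI_AAS = sorted(aa for aa in SYNONYMOUS_FAMILIES if len(SYNONYMOUS_FAMILIES[aa]) > 1)
_STOPS = sorted(STOP_CODONS)


def _tail_codon(rng, tail_low_rate):
    aa = _AAS[rng.integers(len(_AAS))]
    lows = _LOWS[aa]
    if not lows or tail_low_rate <= 0.0 or rng.random() >= tail_low_rate:
        return _HIGH[aa]
    return lows[rng.integers(len(lows))]


def _low_codon(rng):
    aa = _MULTI_AAS[rng.integers(len(_MULTI_AAS))]
    lows = _LOWS[aa]
    return lows[rng.integers(len(lows))]


def _make_gene(rng, n_codons, implant_len, tail_low_rate):
    """One CDS: ATG, n_codons-1 body codons, one stop. Implant after the ATG."""
    codons = ["ATG"]
    for i in range(1, n_codons):
        if implant_len and i <= implant_len:
            codons.append(_low_codon(rng))
        else:
            codons.append(_tail_codon(rng, tail_low_rate))
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def simulate_cds(config, species="synthA"):
    """(genes, ramp_labels) — coding genes with implanted 5' ramps.

    A fraction ``ramp_fraction`` of genes carries an implant of L low-pool
    codons (L uniform over ``ramp_length_range``) right after the start
    codon; everything else draws from the high-biased pool. Every gene
    starts with ATG, ends with a stop, has no internal stop, and a length
    divisible by 3.
    """
    rng = np.random.default_rng(config.seed)
    glo, ghi = config.gene_length_range
    rlo, rhi = config.ramp_length_range
    width = max(4, len(str(config.n_genes)))
    genes, labels = [], []
    for i in range(config.n_genes):
        n_codons = int(rng.integers(glo, ghi + 1))
        implanted = bool(rng.random() < config.ramp_fraction)
        implant_len = int(rng.integers(rlo, rhi + 1)) if implanted else 0
        seq = _make_gene(rng, n_codons, implant_len, config.tail_low_rate)
        genes.append(GeneRecord(species, f"g{str(i + 1).zfill(width)}", seq))
        labels.append(implanted)
    return genes, labels


@dataclass
class SyntheticDataset:
    """A full synthetic study: tree, true character matrix, and sequences."""

    tree: object
    matrix: CharacterMatrix            # true presence/absence with missing
    truths: list
    genes_by_species: dict             # species -> list of GeneRecord


def simulate_dataset(config):
    """End-to-end synthetic study linking characters to sequences.

    Characters are evolved on a simulated tree; then, for every non-missing
    (species, ortholog) cell, one gene is generated whose 5' implant status
    equals the character state. Missing cells have no gene (an annotation
    gap), mirroring how ortholog tables acquire holes.
    """
    tree = simulate_tree(config.n_leaves, config.seed)
    matrix, truths = simulate_binary_characters(tree, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    glo, ghi = config.gene_length_range
    rlo, rhi = config.ramp_length_range
    genes_by_species = {}
    df = matrix.to_dataframe()
    for species in df.index:
        out = []
        for ortholog in df.columns:
            v = df.at[species, ortholog]
            if pd.isna(v):
                continue
            n_codons = int(rng.integers(glo, ghi + 1))
            implant_len = int(rng.integers(rlo, rhi + 1)) if v == 1.0 else 0
            seq = _make_gene(rng, n_codons, implant_len, config.tail_low_rate)
            out.append(GeneRecord(species, ortholog, seq))
        genes_by_species[species] = out
    return SyntheticDataset(tree, matrix, truths, genes_by_species)


def write_species_fastas(genes_by_species, outdir):
    """One FASTA per species, headers '>{ortholog_id}'. Returns paths."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for species in sorted(genes_by_species):
        path = os.path.join(outdir, f"{species}.fasta")
        records = [
            SeqRecord(Seq(g.sequence), id=g.ortholog_id, description="")
            for g in genes_by_species[species]
        ]
        SeqIO.write(records, path, "fasta")
        paths.append(path)
    return paths


def write_truth_table(truths, path):
    """Character ground truth as TSV (id, mode, change edges)."""
    rows = [
        {
            "character_id": t.character_id,
            "mode": t.mode,
            "n_changes": len(t.change_edges),
            "change_edges": ";".join(f"{e}:{d}" for e, d in t.change_edges),
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_tree(tree, path):
    with open(path, "w") as fh:
        fh.write(write_newick(tree))
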