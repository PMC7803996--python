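"""Ramp-sequence detection from codon-usage-derived efficiency profiles.

A ramp sequence is a stretch of roughly 30-50 slowly-translated codons at
the 5' end of a gene that paces early ribosome movement. Detection works per
species:

1. Count genome-wide sense-codon usage over the species' coding sequences.
2. Convert counts to relative codon adaptiveness: each codon's count divided
   by the count of the most frequent codon in its synonymous family (the
   proxy for translational efficiency; unobserved codons receive a
   pseudocount so every weight is positive).
3. Slide a nine-codon window (the approximate ribosome footprint) along each
   gene and take the window mean of the weights — geometric by default, so a
   single near-zero codon depresses the window the way a bottleneck would.
4. Call a ramp when the 5' end of the profile is a run of low outliers
   (below Q1 - 1.5 IQR of the gene's own window distribution) and the
   gene-wide efficiency minimum falls within the first ``max_ramp_extent``
   codons.

The truncation control re-runs detection after chopping the first 50 codons
off every gene; genuine ramps disappear, so the ramp-bearing count must drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .errors import EmptyInputError, TooShortError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "CodonUsageTable",
    "AdaptivenessWeights",
    "RampCall",
    "RampConfig",
    "SENSE_CODONS",
    "STOP_CODONS",
    "SYNONYMOUS_FAMILIES",
    "validate_gene",
    "count_codon_usage",
    "codon_adaptiveness",
    "windowed_efficiency",
    "call_ramp",
    "detect_all",
    "truncation_control",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD.forward_table))  # 61 codons

#: amino acid -> sorted tuple of its codons (standard genetic code)
SYNONYMOUS_FAMILIES = {}
for _codon, _aa in _STANDARD.forward_table.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, []).append(_codon)
SYNONYMOUS_FAMILIES = {aa: tuple(sorted(cs)) for aa, cs in SYNONYMOUS_FAMILIES.items()}


@dataclass
class GeneRecord:
    """One coding sequence for one species."""

    species: str
    ortholog_id: str
    sequence: str


@dataclass
class CodonUsageTable:
    """Genome-wide sense-codon counts (stop codons never counted)."""

    counts: dict
    total: int


@dataclass
class AdaptivenessWeights:
    """Per-codon relative adaptiveness in (0, 1]; family maxima are 1."""

    weights: dict

    def __getitem__(self, codon):
        return self.weights[codon]


@dataclass
class RampCall:
    """The ramp decision for one gene.

    ``ramp_end`` is a 0-based exclusive codon index; ``ramp_sequence`` +
    ``tail_sequence`` reconstructs the input nucleotide sequence exactly.
    """

    ortholog_id: str
    species: str
    has_ramp: bool
    ramp_end: Optional[int] = None
    ramp_sequence: Optional[str] = None
    tail_sequence: str = ""


@dataclass
class RampConfig:
    """Detection parameters.

    window
        Sliding-window length in codons; nine approximates the ribosome span.
    max_ramp_extent
        The gene-wide efficiency minimum must start within this many codons
        of the 5' end for a ramp to be called.
    outlier_iqr
        A window is a low outlier when its efficiency is below
        Q1 - outlier_iqr * IQR of the gene's own window distribution.
    mean
        'geometric' (default) or 'arithmetic' window mean.
    pseudocount
        Added to zero counts only, before family normalization.
    min_gene_length
        Genes with fewer sense codons are excluded (default window + 1).
    """

    window: int = 9
    max_ramp_extent: int = 50
    outlier_iqr: float = 1.5
    mean: str = "geometric"
    pseudocount: float = 0.5
    min_gene_length: Optional[int] = None

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_ramp_extent < self.window:
            raise ValueError("max_ramp_extent must be >= window")
        if self.mean not in ("geometric", "arithmetic"):
            raise ValueError("mean must be 'geometric' or 'arithmetic'")
        if self.min_gene_length is None:
            self.min_gene_length = self.window + 1


def _codons(seq):
    return [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def validate_gene(gene):
    """Return None if usable, else a human-readable exclusion reason.

    Usable: nucleotides over {A,C,G,T,N}, length divisible by 3, no internal
    stop codon. A trailing stop codon is allowed and ignored downstream.
    """
    seq = gene.sequence.upper()
    if len(seq) == 0:
        return "empty sequence"
    if len(seq) % 3 != 0:
        return f"length {len(seq)} not divisible by 3"
    if set(seq) - set("ACGTN"):
        return "invalid nucleotide characters"
    codons = _codons(seq)
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            return f"internal stop codon at codon {i}"
    return None


def _sense_codons(gene):
    """Codon list with a trailing stop removed (N codons retained)."""
    codons = _codons(gene.sequence.upper())
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def count_codon_usage(genes):
    """Count every sense codon across ``genes``.

    Stop codons and codons containing N are skipped. Genes must already be
    validated (length divisible by 3, no internal stops).
    """
    genes = list(genes)
    if not genes:
        raise EmptyInputError("no genes to count codon usage from")
    counts = {c: 0 for c in SENSE_CODONS}
    total = 0
    for gene in genes:
        for codon in _codons(gene.sequence.upper()):
            if codon in STOP_CODONS or "N" in codon:
                continue
            counts[codon] += 1
            total += 1
    return CodonUsageTable(counts=counts, total=total)


def codon_adaptiveness(table, pseudocount=0.5):
    """Relative adaptiveness: count / max count within the synonymous family.

    Unobserved codons get ``pseudocount`` in the numerator (the denominator
    stays the raw family maximum) so every weight is strictly positive and
    geometric window means remain defined.
    """
    if table.total <= 0:
        raise EmptyInputError("all-zero codon usage table")
    weights = {}
    for family in SYNONYMOUS_FAMILIES.values():
        fam_max = max(table.counts.get(c, 0) for c in family)
        denom = fam_max if fam_max > 0 else pseudocount
        for c in family:
            num = table.counts.get(c, 0)
            weights[c] = (num if num > 0 else pseudocount) / denom
    return AdaptivenessWeights(weights=weights)


def windowed_efficiency(gene, weights, config=None):
    """Per-window mean translational efficiency along the gene.

    Element k is the (geometric or arithmetic) mean of the adaptiveness
    weights of sense codons k .. k+window-1; the trailing stop codon is
    excluded and codons containing N contribute a neutral weight of 1.
    Output length is (#sense codons - window + 1).
    """
    if config is None:
        config = RampConfig()
    codons = _sense_codons(gene)
    w = config.window
    if len(codons) < w:
        raise TooShortError(
            f"gene {gene.ortholog_id!r} has {len(codons)} sense codons; window is {w}"
        )
    vals = np.array(
        [1.0 if "N" in c else weights[c] for c in codons], dtype=float
    )
    if config.mean == "geometric":
        logs = np.log(vals)
        csum = np.concatenate([[0.0], np.cumsum(logs)])
        return np.exp((csum[w:] - csum[:-w]) / w)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    return (csum[w:] - csum[:-w]) / w


def call_ramp(gene, weights, config=None):
    """Decide whether ``gene`` starts with a ramp sequence.

    A ramp is called when (a) the profile has at least one low-outlier
    window, (b) the gene-wide minimum window starts within the first
    ``max_ramp_extent`` codons, and (c) the 5' outlier run begins at the
    very start of the profile (i.e. no non-outlier window precedes it).
    The ramp boundary is the last window of that run plus window - 1, at
    codon resolution; the gene splits into ramp and tail at 3x that codon.
    """
    if config is None:
        config = RampConfig()
    prof = windowed_efficiency(gene, weights, config)
    seq = gene.sequence

    def no_ramp():
        return RampCall(
            ortholog_id=gene.ortholog_id,
            species=gene.species,
            has_ramp=False,
            tail_sequence=seq,
        )

    q1, q3 = np.percentile(prof, [25, 75])
    threshold = q1 - config.outlier_iqr * (q3 - q1)
    outlier = prof < threshold
    if not outlier.any():
        return no_ramp()
    min_idx = int(np.argmin(prof))
    if min_idx >= config.max_ramp_extent:
        return no_ramp()  # bottleneck not at the beginning of the gene
    non_outlier = np.nonzero(~outlier)[0]
    first_non_outlier = int(non_outlier[0]) if non_outlier.size else len(prof)
    if first_non_outlier == 0:
        return no_ramp()  # the 5' run would start after a non-outlier window
    last_run_window = first_non_outlier - 1
    ramp_end = max(last_run_window + config.window - 1, 1)
    ramp_seq = seq[: 3 * ramp_end]
    return RampCall(
        ortholog_id=gene.ortholog_id,
        species=gene.species,
        has_ramp=True,
        ramp_end=ramp_end,
        ramp_sequence=ramp_seq,
        tail_sequence=seq[3 * ramp_end:],
    )


def detect_all(genes_by_species, config=None):
    """Run detection for every species, with per-species adaptiveness weights.

    Each species' weights come from that species' own gene set (genome-wide
    usage), so codon-usage differences never leak between species. Invalid
    or too-short genes are excluded with a logged reason; species with zero
    valid genes are recorded and skipped.
    """
    if config is None:
        config = RampConfig()
    if not genes_by_species:
        raise EmptyInputError("no species supplied")
    calls = []
    for species in sorted(genes_by_species):
        genes = genes_by_species[species]
        valid = []
        for g in genes:
            reason = validate_gene(g)
            if reason is not None:
                logger.info("excluding %s/%s: %s", species, g.ortholog_id, reason)
            else:
                valid.append(g)
        if not valid:
            logger.warning("species %s has no valid genes; skipped", species)
            continue
        table = count_codon_usage(valid)
        weights = codon_adaptiveness(table, pseudocount=config.pseudocount)
        n_ramps = 0
        for g in valid:
            if len(_sense_codons(g)) < max(config.window, config.min_gene_length):
                logger.info("excluding %s/%s: shorter than window", species, g.ortholog_id)
                continue
            call = call_ramp(g, weights, config)
            calls.append(call)
            n_ramps += int(call.has_ramp)
        logger.info("species %s: %d/%d genes carry a ramp", species, n_ramps,
                    len([c for c in calls if c.species == species]))
    return calls


@dataclass
class TruncationResult:
    """Outcome of the shortened-sequence control analysis."""

    ramps_before: int
    ramps_after: int
    chi_square: float
    p_value: float
    table: list = field(default_factory=list)  # 2x2 [[ramp, no-ramp] x 2 runs]

    def __iter__(self):  # allows tuple unpacking (before, after, chi2, p)
        return iter((self.ramps_before, self.ramps_after, self.chi_square, self.p_value))


def truncation_control(genes_by_species, config=None, n_trunc=50):
    """Re-run detection after removing the first ``n_trunc`` codons of every gene.

    Genuine 5' ramps are destroyed by the truncation, so the number of
    ramp-bearing genes should drop. Returns counts for genes analyzed in
    both runs plus a 2x2 chi-square (ramp vs no-ramp x original vs
    truncated) without continuity correction.
    """
    if config is None:
        config = RampConfig()
    before = detect_all(genes_by_species, config)
    truncated = {}
    for species, genes in genes_by_species.items():
        kept = []
        for g in genes:
            if validate_gene(g) is not None:
                continue
            short = GeneRecord(g.species, g.ortholog_id, g.sequence[3 * n_trunc:])
            if len(short.sequence) >= 3 * max(config.window, config.min_gene_length):
                kept.append(short)
        if kept:
            truncated[species] = kept
    after = detect_all(truncated, config) if truncated else []

    before_map = {(c.species, c.ortholog_id): c.has_ramp for c in before}
    after_map = {(c.species, c.ortholog_id): c.has_ramp for c in after}
    shared = sorted(set(before_map) & set(after_map))
    rb = sum(before_map[k] for k in shared)
    ra = sum(after_map[k] for k in shared)
    n = len(shared)
    table = [[rb, n - rb], [ra, n - ra]]
    if n == 0 or min(rb + ra, 2 * n - rb - ra) == 0 or rb + ra == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        chi2, p = float(chi2), float(p)
    logger.info("truncation control: %d -> %d ramp-bearing genes (chi2=%.3f, p=%.3g)",
                rb, ra, chi2, p)
    return TruncationResult(rb, ra, chi2, p, table)
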