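"""End-to-end orchestration: simulate/detect -> matrix -> score -> nulls -> report.

A single :class:`RunConfig` drives the whole analysis in the order the
stages depend on each other: obtain coding sequences (synthetic or FASTA
files on disk), detect ramps per species, build and filter the binary
presence/absence matrix, map every informative character onto the reference
tree, run the permutation and monophyly nulls, and (optionally) search for
maximum-parsimony trees and compare them to the reference. Every random
draw flows from the single global seed through named per-stage substreams,
and each run writes a config snapshot plus a machine-readable summary, so
re-running with the same config reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import charfit, charmatrix, nullmodels, rampdetect, synth, treeops

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

_STAGE_NAMES = ("synth", "permute", "search")


@dataclass
class RunConfig:
    """Configuration for :func:`run_all`.

    Exactly one sequence source is required: a ``synth`` block, a
    ``fasta_dir`` of per-species FASTA files, or a prebuilt ``matrix_path``
    (which skips detection entirely). ``reference_tree`` may be omitted when
    a synth block is present (the generating tree is then the reference).
    """

    output_dir: str = "ramphylo_run"
    seed: int = 0
    synth: Optional[synth.SynthConfig] = None
    fasta_dir: Optional[str] = None
    matrix_path: Optional[str] = None
    reference_tree: Optional[str] = None
    ramp: rampdetect.RampConfig = field(default_factory=rampdetect.RampConfig)
    filter: charmatrix.FilterConfig = field(default_factory=charmatrix.FilterConfig)
    search: treeops.SearchConfig = field(default_factory=treeops.SearchConfig)
    n_permutations: int = 1000
    run_search: bool = True
    log_level: str = "INFO"


def _stage_seeds(seed):
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2 ** 31))
        for name, child in zip(_STAGE_NAMES, children)
    }


def _snapshot(config):
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return enc(config)


def _load_fasta_dir(path):
    from Bio import SeqIO

    genes_by_species = {}
    for fname in sorted(os.listdir(path)):
        if not fname.endswith((".fasta", ".fa", ".fna")):
            continue
        species = os.path.splitext(fname)[0]
        records = [
            rampdetect.GeneRecord(species, rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(os.path.join(path, fname), "fasta")
        ]
        genes_by_species[species] = records
    if not genes_by_species:
        raise FileNotFoundError(f"no FASTA files found in {path!r}")
    return genes_by_species


def run_all(config):
    """Execute all configured stages and return the summary report dict.

    Artifacts written to ``config.output_dir``: config snapshot (YAML), ramp
    calls and character fits (TSV), the filtered matrix (TSV), the null
    distribution (TSV), recovered trees (newick), and ``summary.json``. A
    stage failure propagates with partial artifacts retained.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    with open(os.path.join(out, "config.yaml"), "w") as fh:
        yaml.safe_dump(_snapshot(config), fh, sort_keys=True)

    report = {"seed": config.seed, "stage_seeds": seeds}

    # --- stage 1: sequences / matrix source -------------------------------
    reference = None
    dataset = None
    if config.synth is not None:
        sy = dataclasses.replace(config.synth, seed=seeds["synth"])
        dataset = synth.simulate_dataset(sy)
        genes_by_species = dataset.genes_by_species
        reference = dataset.tree
        synth.write_tree(dataset.tree, os.path.join(out, "generating_tree.nwk"))
        synth.write_truth_table(dataset.truths, os.path.join(out, "character_truth.tsv"))
    elif config.fasta_dir is not None:
        genes_by_species = _load_fasta_dir(config.fasta_dir)
    elif config.matrix_path is None:
        raise ValueError("config needs a synth block, fasta_dir, or matrix_path")

    if config.reference_tree is not None:
        with open(config.reference_tree) as fh:
            reference = treeops.parse_newick(fh.read())
    if reference is None:
        raise ValueError("no reference tree available (supply reference_tree)")

    # --- stage 2: detection ----------------------------------------------
    if config.matrix_path is not None:
        with open(config.matrix_path) as fh:
            matrix = charmatrix.read_matrix(fh.read(), "tsv")
        report["n_species_input"] = len(matrix.species)
        report["n_orthologs_input"] = len(matrix.orthologs)
    else:
        calls = rampdetect.detect_all(genes_by_species, config.ramp)
        with open(os.path.join(out, "ramp_calls.tsv"), "w") as fh:
            fh.write("species\tortholog\thas_ramp\tramp_end_codon\n")
            for c in calls:
                fh.write(
                    f"{c.species}\t{c.ortholog_id}\t{int(c.has_ramp)}\t"
                    f"{'' if c.ramp_end is None else c.ramp_end}\n"
                )
        matrix = charmatrix.build_matrix(calls)
        report["n_species_input"] = len(genes_by_species)
        report["n_orthologs_input"] = len(matrix.orthologs)
        report["n_species_with_ramps"] = len(
            {c.species for c in calls if c.has_ramp}
        )
        report["n_orthologs_with_ramps"] = len(
            {c.ortholog_id for c in calls if c.has_ramp}
        )

    # --- stage 3: filtering ----------------------------------------------
    filtered, filt_report = charmatrix.filter_matrix(matrix, config.filter)
    report["n_species_after_filter"] = len(filtered.species)
    report["n_orthologs_after_filter"] = len(filtered.orthologs)
    report["missing_percent_mean"] = round(filt_report.missing_mean, 4)
    report["missing_percent_std"] = round(filt_report.missing_std, 4)
    with open(os.path.join(out, "matrix.tsv"), "w") as fh:
        fh.write(charmatrix.write_matrix(filtered, "tsv"))

    shared = sorted(
        set(filtered.species)
        & {lf.taxon.label for lf in reference.leaf_node_iter()}
    )
    if len(shared) < 4:
        raise ValueError("fewer than 4 species shared between matrix and reference tree")
    ref_pruned = reference.extract_tree_with_taxa_labels(labels=shared)
    ref_pruned.suppress_unifurcations()
    matrix_shared = filtered.restrict_species(shared)

    # --- stage 4: character scoring --------------------------------------
    informative = charmatrix.informative_characters(matrix_shared, config.filter)
    fits = []
    with open(os.path.join(out, "character_fits.tsv"), "w") as fh:
        fh.write("ortholog\tsteps\tgains\tlosses\tmax_steps\tretention\tcompletely_orthologous\n")
        for o in informative:
            fit = charfit.retention_index(ref_pruned, matrix_shared.column(o), ortholog_id=o)
            fits.append(fit)
            fh.write(
                f"{o}\t{fit.steps}\t{fit.gains}\t{fit.losses}\t{fit.max_steps}\t"
                f"{'' if fit.retention is None else round(fit.retention, 6)}\t"
                f"{int(charfit.is_completely_orthologous(fit))}\n"
            )
    defined = [f.retention for f in fits if f.retention is not None]
    report["n_informative_characters"] = len(informative)
    report["mean_retention_index"] = round(float(np.mean(defined)), 6) if defined else None
    report["n_completely_orthologous"] = sum(
        1 for f in fits if charfit.is_completely_orthologous(f)
    )

    # --- stage 5: permutation null ---------------------------------------
    summary = nullmodels.permutation_test(
        ref_pruned, matrix_shared, n_perm=config.n_permutations,
        seed=seeds["permute"], config=config.filter,
    )
    report["permutation_p"] = summary.empirical_p
    report["fraction_beating_null"] = round(summary.fraction_beating_null, 6)
    with open(os.path.join(out, "null_means.tsv"), "w") as fh:
        fh.write("permutation\tmean_retention_index\n")
        for i, m in enumerate(summary.null_means):
            fh.write(f"{i}\t{m:.6f}\n")

    # --- stage 6: monophyly null -----------------------------------------
    records = nullmodels.monophyly_records(ref_pruned, matrix_shared, config.filter)
    mono = nullmodels.monophyly_chisq(records)
    report["monophyly_chi_square"] = round(mono.statistic, 6)
    report["monophyly_p"] = mono.p_value
    report["n_bonferroni_significant"] = int(mono.verdicts["significant"].sum()) if len(mono.verdicts) else 0
    mono.group_table.to_csv(os.path.join(out, "monophyly_groups.tsv"), sep="\t", index=False)
    mono.verdicts.to_csv(os.path.join(out, "monophyly_verdicts.tsv"), sep="\t", index=False)

    # --- stage 7: parsimony search + tree comparison ---------------------
    if config.run_search:
        search_cfg = dataclasses.replace(config.search, seed=seeds["search"])
        trees, best = treeops.parsimony_search(matrix_shared, search_cfg)
        identities = []
        with open(os.path.join(out, "parsimony_trees.nwk"), "w") as fh:
            for t in trees:
                fh.write(treeops.write_newick(t))
                bpi = treeops.branch_percent_identity(t, ref_pruned)
                identities.append(bpi)
        report["parsimony_best_score"] = best
        report["branch_percent_identity"] = [
            None if b is None else round(b, 4) for b in identities
        ]
        defined_b = [b for b in identities if b is not None]
        report["branch_percent_identity_mean"] = (
            round(float(np.mean(defined_b)), 4) if defined_b else None
        )

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete; summary at %s", os.path.join(out, "summary.json"))
    return report
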