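"""Statistical nulls for the phylogenetic signal of ramp characters.

Two nulls are implemented:

* **Taxa-label permutation.** The reference topology is held fixed while the
  leaf labels are shuffled; recomputing every character's step count and
  retention index on each permuted tree yields a null distribution of mean
  retention indices. The empirical p-value is the +1-smoothed proportion of
  null means at least as large as the observed mean (a high observed RI is
  evidence of signal, so large values are extreme).

* **Monophyly probability.** For one character with t non-missing species,
  s of them in the smaller state group, the probability that the group would
  be concordant with a fixed topology by chance is

      P(t, s) = prod_{i=1..s-1} i / prod_{j=t-s+1..t-1} j
              = (s-1)! (t-s)! / (t-1)!  =  1 / C(t-1, s-1)

  evaluated exactly as a Fraction. Characters sharing a taxonomic
  distribution (t, s) form a group whose expected number of concordant
  characters is P * group size; a goodness-of-fit chi-square compares
  observed concordant counts to those expectations, and per-gene Bonferroni
  verdicts flag individually significant concordant characters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
import numpy as np
import pandas as pd
from scipy import stats

from ._tree import IndexedTree, hartigan_steps
from .charmatrix import FilterConfig
from .errors import EmptyInputError
from .treeops import _states_for_leaves, parse_newick, write_newick

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationSummary",
    "MonophylyRecord",
    "MonophylyTestResult",
    "permute_leaf_labels",
    "permutation_test",
    "monophyly_probability",
    "monophyly_records",
    "monophyly_chisq",
]


@dataclass
class PermutationSummary:
    """Result of the taxa-label permutation test."""

    observed_mean_ri: float
    null_means: list
    empirical_p: float
    fraction_beating_null: float
    n_permutations: int
    n_characters: int
    seed: int
    per_character_steps: dict = field(default_factory=dict)
    per_character_mean_null_steps: dict = field(default_factory=dict)


def permute_leaf_labels(tree, seed):
    """A copy of ``tree`` with leaf labels uniformly permuted.

    Topology, node count, and the label multiset are unchanged — only which
    label sits on which leaf moves.
    """
    rng = np.random.default_rng(seed)
    out = parse_newick(write_newick(tree))
    leaves = [lf for lf in out.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    perm = rng.permutation(len(labels))
    for leaf, idx in zip(leaves, perm):
        leaf.taxon.label = labels[int(idx)]
    return out


def _informative_states(tree, matrix, config):
    itree = IndexedTree.from_dendropy(tree)
    states = _states_for_leaves(matrix, itree.leaf_labels)
    n1 = (states == 1).sum(axis=1)
    n0 = (states == 0).sum(axis=1)
    k = config.min_informative_count
    keep = (n1 >= k) & (n0 >= k)
    ids = [o for o, kp in zip(matrix.orthologs, keep) if kp]
    return itree, states[keep], ids, n0[keep], n1[keep]


def permutation_test(tree, matrix, n_perm=1000, seed=0, config=None):
    """Shuffle leaf labels ``n_perm`` times and rescore every character.

    Only informative characters (>= 2 species in each state among the tree's
    leaves) enter the test. Deterministic under a fixed seed. The empirical
    p is never exactly zero thanks to the +1 smoothing.
    """
    if config is None:
        config = FilterConfig()
    itree, states, ids, n0, n1 = _informative_states(tree, matrix, config)
    if len(ids) == 0:
        raise EmptyInputError("no informative characters for the permutation test")
    g = np.minimum(n0, n1).astype(float)
    s_obs = hartigan_steps(itree, states).astype(float)
    ri_obs = (g - s_obs) / (g - 1.0)
    observed_mean = float(ri_obs.mean())

    rng = np.random.default_rng(seed)
    null_means = []
    step_sums = np.zeros_like(s_obs)
    for _ in range(n_perm):
        perm = rng.permutation(itree.n_leaves)
        s_p = hartigan_steps(itree, states[:, perm]).astype(float)
        step_sums += s_p
        ri_p = (g - s_p) / (g - 1.0)
        null_means.append(float(ri_p.mean()))

    null_arr = np.asarray(null_means)
    empirical_p = (1.0 + int((null_arr >= observed_mean).sum())) / (1.0 + n_perm)
    if n_perm > 0:
        mean_null_steps = step_sums / n_perm
        fraction = float((s_obs < mean_null_steps).mean())
    else:
        mean_null_steps = np.full_like(s_obs, np.nan)
        fraction = float("nan")
    logger.info(
        "permutation test: observed mean RI %.4f over %d characters, p = %.4g",
        observed_mean, len(ids), empirical_p,
    )
    return PermutationSummary(
        observed_mean_ri=observed_mean,
        null_means=null_means,
        empirical_p=float(empirical_p),
        fraction_beating_null=fraction,
        n_permutations=n_perm,
        n_characters=len(ids),
        seed=seed,
        per_character_steps={o: int(s) for o, s in zip(ids, s_obs)},
        per_character_mean_null_steps={o: float(m) for o, m in zip(ids, mean_null_steps)},
    )


def monophyly_probability(t, s):
    """Exact chance probability that the smaller state group is concordant.

    Evaluated as the printed product formula with exact rational arithmetic;
    equal to 1 / C(t-1, s-1). Requires t >= 4 and 2 <= s <= t - 2 (invariant
    and autapomorphic characters are filtered upstream).
    """
    t, s = int(t), int(s)
    if t < 4:
        raise ValueError("t must be >= 4")
    if not 2 <= s <= t - 2:
        raise ValueError(f"s={s} out of range [2, t-2] for t={t}")
    num = 1
    for i in range(1, s):
        num *= i
    den = 1
    for j in range(t - s + 1, t):
        den *= j
    return Fraction(num, den)


@dataclass
class MonophylyRecord:
    """One character's taxonomic distribution and concordance status."""

    ortholog_id: str
    t: int                      # total non-missing species
    s: int                      # size of the smaller state group
    probability: Fraction
    concordant: bool            # maps with a single change (steps == 1)


def monophyly_records(tree, matrix, config=None):
    """Build MonophylyRecords for every informative character of ``matrix``.

    t counts non-missing species among the tree's leaves; s is the smaller
    of the two state groups regardless of which state it is. Characters with
    s < 2 (autapomorphies) are skipped.
    """
    if config is None:
        config = FilterConfig()
    itree, states, ids, n0, n1 = _informative_states(tree, matrix, config)
    steps = hartigan_steps(itree, states)
    records = []
    for i, ortholog in enumerate(ids):
        t = int(n0[i] + n1[i])
        s = int(min(n0[i], n1[i]))
        if t < 4 or s < 2:
            continue
        records.append(
            MonophylyRecord(
                ortholog_id=ortholog,
                t=t,
                s=s,
                probability=monophyly_probability(t, s),
                concordant=bool(steps[i] == 1),
            )
        )
    return records


@dataclass
class MonophylyTestResult:
    """Observed vs expected concordant counts across (t, s) distributions."""

    group_table: pd.DataFrame    # one row per (t, s): n, probability, expected, observed
    pooled_table: pd.DataFrame   # after pooling sparse expectations
    statistic: float
    p_value: float
    df: int
    verdicts: pd.DataFrame       # concordant genes with Bonferroni significance


def monophyly_chisq(records, alpha=0.05, pool_below=1.0):
    """Goodness-of-fit chi-square of concordant counts against Eq.-style nulls.

    Records are grouped by (t, s); each group's expected concordant count is
    P(t, s) times the group size. Groups with expected < ``pool_below`` are
    pooled into the group with the nearest expected count before the test
    (df = number of final groups - 1, floored at 1). Per-gene Bonferroni: a
    concordant gene is significant iff P(t, s) < alpha / (number of
    concordant genes tested).
    """
    records = list(records)
    if not records:
        raise EmptyInputError("no monophyly records")
    groups = {}
    for r in records:
        key = (r.t, r.s)
        g = groups.setdefault(key, {"n": 0, "observed": 0, "probability": r.probability})
        g["n"] += 1
        g["observed"] += int(r.concordant)
    rows = []
    for (t, s), g in sorted(groups.items()):
        rows.append(
            {
                "t": t,
                "s": s,
                "n": g["n"],
                "probability": float(g["probability"]),
                "expected": float(g["probability"]) * g["n"],
                "observed": g["observed"],
            }
        )
    group_table = pd.DataFrame(rows)

    pooled = [
        {"members": [(r["t"], r["s"])], "expected": r["expected"], "observed": r["observed"], "n": r["n"]}
        for r in rows
    ]
    while len(pooled) > 1:
        idx = min(range(len(pooled)), key=lambda i: pooled[i]["expected"])
        if pooled[idx]["expected"] >= pool_below:
            break
        small = pooled.pop(idx)
        j = min(
            range(len(pooled)),
            key=lambda i: abs(pooled[i]["expected"] - small["expected"]),
        )
        pooled[j]["members"] += small["members"]
        pooled[j]["expected"] += small["expected"]
        pooled[j]["observed"] += small["observed"]
        pooled[j]["n"] += small["n"]
    pooled_table = pd.DataFrame(
        [
            {
                "members": ";".join(f"{t},{s}" for t, s in p["members"]),
                "n": p["n"],
                "expected": p["expected"],
                "observed": p["observed"],
            }
            for p in pooled
        ]
    )
    statistic = float(
        sum((p["observed"] - p["expected"]) ** 2 / p["expected"] for p in pooled)
    )
    df = max(len(pooled) - 1, 1)
    p_value = float(stats.chi2.sf(statistic, df))

    concordant = [r for r in records if r.concordant]
    n_tests = len(concordant)
    verdicts = pd.DataFrame(
        [
            {
                "ortholog_id": r.ortholog_id,
                "t": r.t,
                "s": r.s,
                "probability": float(r.probability),
                "significant": bool(
                    n_tests > 0 and r.probability < Fraction(alpha).limit_denominator() / n_tests
                ),
            }
            for r in concordant
        ]
    )
    logger.info(
        "monophyly chi-square: statistic %.3f on %d df, p = %.3g (%d concordant of %d)",
        statistic, df, p_value, n_tests, len(records),
    )
    return MonophylyTestResult(group_table, pooled_table, statistic, p_value, df, verdicts)
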