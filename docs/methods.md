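# Methods

This note documents the models, parameter choices, and numerical
conventions behind `ramphylo`, and what its synthetic benchmarks do and do
not demonstrate about real data.

## Ramp detection

A ramp sequence is operationalized as a 5′ region of a coding sequence
whose estimated translation rate is an outlier relative to the rest of the
gene.

**Adaptiveness weights.** Per species, sense-codon counts are taken over
the whole gene set ("its frequency in the genome"); stop codons and codons
containing N are never counted. Within each synonymous family the weight is
`count / max family count`, so the most frequent codon has weight exactly 1.
Codons with zero counts receive a pseudocount (default 0.5) in the
numerator only, keeping every weight strictly positive so that geometric
means are defined. Weights are computed per species, never pooled:
codon-usage differences between species must not leak into each other's
calls.

**Window profile.** The efficiency profile is the mean weight over a
sliding window of `window = 9` codons, the approximate ribosome footprint.
The default mean is geometric — a single near-zero codon should depress a
window the way a physical bottleneck would; an arithmetic option is
available (`RampConfig(mean="arithmetic")`). The trailing stop codon is
excluded; codons containing N contribute a neutral weight of 1 so that
window indices remain aligned with codon coordinates. Genes shorter than
the window are excluded with a logged reason, as are genes whose length is
not divisible by 3 or that contain internal stop codons.

**Outlier rule and boundary.** A window is a low outlier when its value is
below `Q1 − k·IQR` of the gene's own window distribution (`k = 1.5` by
default, configurable). A ramp is called when (a) at least one outlier
window exists, (b) the gene-wide minimum window starts within the first
`max_ramp_extent = 50` codons, and (c) the outlier run begins at the very
start of the profile. The boundary is codon-resolved: the last window of
the 5′ outlier run plus `window − 1`, used as a 0-based exclusive codon
index; ramp plus tail always reconstruct the input sequence exactly. The
outlier criterion and boundary convention are this package's own documented
choices — different reasonable choices shift boundaries by at most about
one window, which is why the tests assert boundary recovery only to within
one window of a known implant.

**Truncation control.** Removing the first 50 codons of every gene and
re-running the full pipeline (including usage re-counting) must reduce the
number of ramp-bearing genes if calls are genuine 5′ phenomena rather than
artifacts; the comparison is a 2×2 Pearson chi-square (ramp vs no-ramp ×
original vs truncated, no continuity correction) over genes analyzable in
both runs. Implants of exactly 50 codons leave one low codon behind after
truncation and can legitimately still be called; the control therefore
asserts a strict decrease, not elimination.

## Characters, filtering, and homoplasy

Ramp presence/absence per ortholog forms a species × ortholog binary matrix
with `?` for species lacking the annotation. Filtering is two-pass, with
fractions over non-missing species and inclusive boundaries: pass 1 keeps
orthologs with presence ≥ 5% *and* absence ≥ 5%; pass 2 drops species
annotated for < 5% of the surviving orthologs. Characters entering
homoplasy scoring must be present in ≥ 2 and absent in ≥ 2 species;
autapomorphies carry no signal and get an undefined retention index,
excluded from all means. Conflicting duplicate calls for one
(species, ortholog) pair are an error, not a vote — silent resolution could
mask upstream bugs.

**Parsimony mapping.** Step counts use Hartigan's algorithm, the
generalization of Fitch counting to multifurcating trees: each internal
node keeps the states voted for by the plurality of its children and pays
one step per dissenting child. Missing leaves carry the full state set
{0,1} and never force a change. The implementation is array-based
(postorder index arrays, characters vectorized with numpy) so thousands of
characters × permutations stay cheap; it is verified against exhaustive
enumeration of all ancestral assignments on trees of up to 8 leaves,
including polytomies and missing data.

**Gains vs losses.** Classification requires fixing one
most-parsimonious reconstruction: the top-down pass keeps the parent's
state whenever the child's Hartigan set allows it (avoiding spurious
flips), and root ties resolve to state 0 — ramp absence ancestral — which
is configurable. Only the total step count enters the retention index, so
this choice affects the gain/loss split but no downstream statistic.

**Retention index.** `RI = (g − s)/(g − m)` with `m = 1` and
`g = min(n0, n1)` over non-missing states; undefined when `g = m`.
`s = 1 ⇔ RI = 1` for informative binary characters, and `s = 1` is also the
definition of a *completely orthologous* character (the state groups are
concordant with the tree).

## Null models

**Permutation test.** Leaf labels are shuffled uniformly on the fixed
reference topology (`n_perm = 1000` by default; the acceptance benchmarks
use 99–199 to stay desk-scale), and all step counts and retention indices
are recomputed per permutation. The empirical p is
`(1 + #{null mean ≥ observed mean}) / (1 + n_perm)`: a large observed mean
RI is the signal direction, and the +1 smoothing keeps p strictly positive.
The per-character "fraction beating the null" is the share of informative
characters whose observed steps are strictly below their own mean permuted
steps. Permutation is implemented as column permutation of the leaf-state
matrix, so the tree structure is built once.

**Monophyly probability.** The chance that the smaller state group of size
`s` among `t` scored species is concordant with the reference topology is
evaluated with the exact product formula (equal to `1 / C(t−1, s−1)`) in
rational arithmetic — no overflow or rounding for any `t` (verified
exhaustively to t = 200). `t` and `s` count non-missing species only; `s`
is always the smaller group regardless of which state it carries. The
formula is topology-independent by construction; no topology-conditional
variant is attempted. Expected concordant counts per `(t, s)` group are
`P·n`; groups with expected < 1 are pooled into the group with the nearest
expected count before the goodness-of-fit chi-square
(`df = #groups − 1`, floored at 1 — the statistic is conservative when only
one group remains). Per-gene Bonferroni verdicts compare `P(t, s)` against
`0.05 / #concordant genes tested`.

## Tree comparison and search

Bipartitions are canonicalized as the leaf set on the side away from the
lexicographically smallest leaf; only non-trivial splits (≥ 2 leaves per
side) count. Branch percent identity prunes both trees to their shared leaf
set (suppressing degree-2 nodes) and reports
`100 · |shared splits| / |source splits|` — the source (recovered) tree is
the denominator because the reference may be polytomous; a symmetric
Robinson–Foulds-style mode is available. A fully unresolved source yields
an undefined marker rather than a number.

The parsimony search is a deliberately small heuristic standing in for
large-scale parsimony software: random stepwise addition (default 10
replicates) followed by steepest-descent NNI (optionally SPR) until no move
improves the score, retaining up to 10 equally-best distinct topologies,
deterministic under the configured seed. Scores never increase during hill
climbing, and the 6-taxon search provably attains the exhaustive minimum in
the test suite. It is adequate for tens of taxa; it makes no claims at
hundreds.

## Synthetic data: what it emulates and what it does not

The generator stands in for a multi-species genome study: per-species CDS
sets, an ortholog table with annotation gaps, and a known reference tree.

* **Trees**: uniform random joining (topology only). Branch lengths are not
  modeled; the Markov character mode uses unit-length edges, so its rates
  are per-edge probabilities `1 − exp(−rate)`.
* **Characters**: `clean` plants exactly one gain on a uniformly random
  edge (zero homoplasy by construction — the parameter-recovery target);
  `markov` evolves gain/loss down the tree from an ancestral absence state
  (configurable); `random` is i.i.d. Bernoulli(0.5) — the calibration
  target. Missingness is i.i.d. per cell (default rate 0); real annotation
  gaps are species-correlated, so an optional per-species multiplier
  exists, off by default.
* **Sequences**: genes of 300–500 codons (a realistic vertebrate CDS
  scale, and long enough that ramp windows stay a minority of each gene's
  profile, keeping the gene-level quartiles anchored in the tail), ~10% of
  genes carrying an implant of 30–50 low-pool codons after the start codon
  (implant lengths uniform on that range — their empirical distribution
  beyond the range is not characterized anywhere, so uniform is the
  assumption-free choice). Each synonymous family designates its
  alphabetically first codon as the high-usage codon; implants draw from
  the remaining (low) codons and tails from the high pool. A
  `tail_low_rate` option sprinkles low codons through tails: it is off by
  default because, under the geometric-mean Q1 − 1.5·IQR rule, even a 10%
  sprinkle gives the window distribution a heavy low tail that widens the
  IQR until genuine implants are no longer outliers — with pure tails,
  implant detectability is guaranteed by construction, which is what the
  recovery benchmarks require.

Consequently, passing benchmarks demonstrate internal correctness —
detection finds what was implanted, parsimony counts match oracles, nulls
are calibrated — not that real genes separate as cleanly: real codon usage
is far less bimodal, real ramps have no sharp boundary, and real
missingness is phylogenetically structured. Sequence evolution along the
tree, indels, isoforms, and ortholog-inference error are out of scope.

## Determinism and problem sizes

Every random draw flows from an explicit integer seed; the pipeline derives
named per-stage substreams from a single global seed (stage seeds are
recorded in the summary, and a user-supplied `SynthConfig.seed` is
superseded by the derived stream inside `run_all` so that one seed governs
the whole run). Benchmarks use desk-scale sizes chosen to exercise the
asymptotics that matter: 64 leaves × 200 characters for parameter recovery,
20 replicate datasets for null calibration, 500 genes for
detection/truncation, and the exact-arithmetic sweep to t = 200.
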