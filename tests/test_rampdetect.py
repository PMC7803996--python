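import numpy as np
import pytest

from ramphylo.errors import EmptyInputError, TooShortError
from ramphylo.rampdetect import (
    AdaptivenessWeights,
    CodonUsageTable,
    GeneRecord,
    RampConfig,
    SENSE_CODONS,
    call_ramp,
    codon_adaptiveness,
    count_codon_usage,
    detect_all,
    truncation_control,
    validate_gene,
    windowed_efficiency,
)
from ramphylo.synth import SynthConfig, simulate_cds


def _gene(seq, species="sp", og="g1"):
    return GeneRecord(species, og, seq)


def _table(counts):
    full = {c: 0 for c in SENSE_CODONS}
    full.update(counts)
    return CodonUsageTable(counts=full, total=sum(counts.values()))


def _uniform_weights(value=0.5):
    return AdaptivenessWeights({c: value for c in SENSE_CODONS})


class TestValidation:
    def test_length_not_divisible_by_three(self):
        assert "divisible" in validate_gene(_gene("ATGAAAT"))

    def test_internal_stop_rejected_trailing_stop_ok(self):
        assert "stop" in validate_gene(_gene("ATGTAAAAATAA"))
        assert validate_gene(_gene("ATGAAATAA")) is None

    def test_ambiguous_bases_allowed(self):
        assert validate_gene(_gene("ATGNNNAAATAA")) is None


class TestCodonUsage:
    def test_stop_codons_excluded(self):
        tab = count_codon_usage([_gene("ATGAAATAA")])
        assert tab.counts["ATG"] == 1 and tab.counts["AAA"] == 1
        assert tab.total == 2
        assert "TAA" not in tab.counts

    def test_counts_are_additive(self):
        g = _gene("ATGAAATAA")
        one = count_codon_usage([g])
        two = count_codon_usage([g, g])
        assert two.total == 2 * one.total
        assert all(two.counts[c] == 2 * one.counts[c] for c in SENSE_CODONS)

    def test_codons_with_n_skipped(self):
        tab = count_codon_usage([_gene("ATGNNNAAATAA")])
        assert tab.counts["ATG"] == 1 and tab.counts["AAA"] == 1 and tab.total == 2

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            count_codon_usage([])


class TestAdaptiveness:
    def test_family_normalized_to_most_frequent(self):
        w = codon_adaptiveness(_table({"AAA": 3, "AAG": 1}))
        assert w["AAA"] == 1.0
        assert w["AAG"] == pytest.approx(1 / 3)

    def test_single_codon_family_is_one(self):
        w = codon_adaptiveness(_table({"ATG": 5}))
        assert w["ATG"] == 1.0

    def test_pseudocount_applies_to_zero_counts_only(self):
        w = codon_adaptiveness(_table({"GGA": 8, "GGT": 2}), pseudocount=0.5)
        assert w["GGA"] == 1.0
        assert w["GGT"] == pytest.approx(0.25)
        assert w["GGC"] == pytest.approx(0.5 / 8) == pytest.approx(0.0625)
        assert w["GGG"] == pytest.approx(0.0625)

    def test_all_weights_strictly_positive(self):
        w = codon_adaptiveness(_table({"AAA": 10}))
        assert all(v > 0 for v in w.weights.values())

    def test_all_zero_table_rejected(self):
        with pytest.raises(EmptyInputError):
            codon_adaptiveness(_table({}))


class TestWindowedEfficiency:
    def test_constant_weights_give_constant_profile(self):
        gene = _gene("ATG" + "AAA" * 11 + "TAA")  # 12 sense codons
        prof = windowed_efficiency(gene, _uniform_weights(0.5), RampConfig())
        assert prof.shape == (4,)
        assert np.allclose(prof, 0.5)

    def test_window_equal_to_gene_length_gives_single_value(self):
        gene = _gene("ATG" + "AAA" * 8 + "TAA")  # 9 sense codons
        prof = windowed_efficiency(gene, _uniform_weights(1.0), RampConfig())
        assert prof.shape == (1,)

    def test_geometric_mean_hand_computed(self):
        # 11 sense codons; the lone 0.1-weight codon sits at index 1, so the
        # first two windows contain it and the third does not
        weights = {c: 1.0 for c in SENSE_CODONS}
        weights["AAG"] = 0.1
        gene = _gene("ATG" + "AAG" + "AAA" * 9 + "TAA")
        prof = windowed_efficiency(gene, AdaptivenessWeights(weights), RampConfig())
        assert prof[0] == pytest.approx(0.1 ** (1 / 9))
        assert prof[1] == pytest.approx(0.1 ** (1 / 9))
        assert prof[2] == pytest.approx(1.0)

    def test_arithmetic_mean_option(self):
        weights = {c: 1.0 for c in SENSE_CODONS}
        weights["AAG"] = 0.1
        gene = _gene("ATG" + "AAG" + "AAA" * 9 + "TAA")
        prof = windowed_efficiency(
            gene, AdaptivenessWeights(weights), RampConfig(mean="arithmetic")
        )
        assert prof[0] == pytest.approx((8 + 0.1) / 9)

    def test_profile_length_conservation(self):
        cfg = RampConfig()
        for n in (9, 15, 40, 101):
            gene = _gene("ATG" + "AAA" * (n - 1) + "TAA")
            prof = windowed_efficiency(gene, _uniform_weights(), cfg)
            assert len(prof) + cfg.window - 1 == n

    def test_too_short_gene_rejected(self):
        gene = _gene("ATG" + "AAA" * 4 + "TAA")
        with pytest.raises(TooShortError):
            windowed_efficiency(gene, _uniform_weights(), RampConfig())


def _implant_gene(weights_low, n_low=30, n_high=200):
    """Gene with n_low low-weight codons after ATG, then a high tail."""
    return _gene("ATG" + "GGG" * n_low + "AAA" * n_high + "TAA")


def _implant_weights(low=0.1):
    w = {c: 1.0 for c in SENSE_CODONS}
    w["GGG"] = low
    return AdaptivenessWeights(w)


class TestCallRamp:
    def test_constant_profile_has_no_outliers_hence_no_ramp(self):
        gene = _gene("ATG" + "AAA" * 100 + "TAA")
        call = call_ramp(gene, _uniform_weights(1.0), RampConfig())
        assert not call.has_ramp
        assert call.tail_sequence == gene.sequence

    def test_implanted_gene_called_with_boundary_near_implant(self):
        call = call_ramp(_implant_gene(0.1), _implant_weights(), RampConfig())
        assert call.has_ramp
        assert 30 - 9 <= call.ramp_end <= 30 + 9
        assert call.ramp_sequence + call.tail_sequence == _implant_gene(0.1).sequence
        assert len(call.ramp_sequence) == 3 * call.ramp_end

    def test_three_prime_bottleneck_is_not_a_ramp(self):
        gene = _gene("ATG" + "AAA" * 200 + "GGG" * 30 + "TAA")
        call = call_ramp(gene, _implant_weights(), RampConfig())
        assert not call.has_ramp

    def test_detection_fraction_monotone_in_implant_status(self):
        genes, labels = simulate_cds(
            SynthConfig(n_genes=120, ramp_fraction=0.5, seed=77)
        )
        for multiplier in (0.5, 1.5, 3.0):
            calls = detect_all(
                {"sp": genes}, RampConfig(outlier_iqr=multiplier)
            )
            detected = {c.ortholog_id for c in calls if c.has_ramp}
            frac_implanted = np.mean(
                [g.ortholog_id in detected for g, l in zip(genes, labels) if l]
            )
            frac_other = np.mean(
                [g.ortholog_id in detected for g, l in zip(genes, labels) if not l]
            )
            assert frac_implanted >= frac_other


class TestDetectAll:
    def test_no_implants_means_no_calls(self):
        genes, labels = simulate_cds(SynthConfig(n_genes=10, ramp_fraction=0.0, seed=5))
        assert not any(labels)
        calls = detect_all({"sp": genes})
        assert calls and not any(c.has_ramp for c in calls)

    def test_deterministic(self):
        genes, _ = simulate_cds(SynthConfig(n_genes=30, ramp_fraction=0.3, seed=6))
        a = detect_all({"sp": genes})
        b = detect_all({"sp": genes})
        assert [(c.ortholog_id, c.has_ramp, c.ramp_end) for c in a] == [
            (c.ortholog_id, c.has_ramp, c.ramp_end) for c in b
        ]

    def test_species_weights_are_isolated(self):
        genes_a, _ = simulate_cds(SynthConfig(n_genes=25, ramp_fraction=0.4, seed=7), species="spA")
        genes_b, _ = simulate_cds(SynthConfig(n_genes=25, ramp_fraction=0.4, seed=8), species="spB")
        solo = [c for c in detect_all({"spB": genes_b})]
        # skew species A's usage heavily; B's calls must not move
        skewed = [GeneRecord("spA", f"x{i}", "ATG" + "GGG" * 120 + "TAA") for i in range(25)]
        joint = [c for c in detect_all({"spA": genes_a + skewed, "spB": genes_b}) if c.species == "spB"]
        assert [(c.ortholog_id, c.has_ramp) for c in solo] == [
            (c.ortholog_id, c.has_ramp) for c in joint
        ]

    def test_splitting_invariant_on_synthetic_set(self):
        genes, _ = simulate_cds(SynthConfig(n_genes=40, ramp_fraction=0.5, seed=9))
        for call in detect_all({"sp": genes}):
            gene = next(g for g in genes if g.ortholog_id == call.ortholog_id)
            if call.has_ramp:
                assert call.ramp_sequence + call.tail_sequence == gene.sequence


class TestTruncationControl:
    def test_truncation_reduces_ramp_count_with_significant_chisq(self):
        genes, labels = simulate_cds(SynthConfig(n_genes=150, ramp_fraction=0.4, seed=10))
        result = truncation_control({"sp": genes}, n_trunc=50)
        assert result.ramps_after < result.ramps_before
        assert result.p_value < 0.05

    def test_no_ramps_anywhere_gives_zero_statistic(self):
        genes, _ = simulate_cds(SynthConfig(n_genes=20, ramp_fraction=0.0, seed=11))
        result = truncation_control({"sp": genes}, n_trunc=50)
        assert result.ramps_before == result.ramps_after == 0
        assert result.chi_square == 0.0 and result.p_value == 1.0

    def test_pearson_two_by_two_matches_hand_formula(self):
        # (300 ramp / 700 no-ramp) vs (100 ramp / 900 no-ramp), no continuity
        # correction: sum (O-E)^2/E with E = 200/800 per column gives 125.0
        from scipy.stats import chi2_contingency

        stat, _, _, _ = chi2_contingency([[300, 700], [100, 900]], correction=False)
        hand = (100 ** 2) / 200 + (100 ** 2) / 800 + (100 ** 2) / 200 + (100 ** 2) / 800
        assert stat == pytest.approx(hand) == pytest.approx(125.0)
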