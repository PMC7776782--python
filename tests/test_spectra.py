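"""Substitution spectra, strand bias, consequences, and the chi-square test."""

import numpy as np
import pytest

from duplexmut import (
    annotate_consequence,
    calls_from_truth,
    chi_square_spectrum_test,
    generate_reference_panel,
    named_signatures,
    simple_spectrum,
    simulate_true_mutations,
    strand_bias,
    trinucleotide_spectrum,
)
from duplexmut.contexts import SBS6, SBS96, revcomp
from duplexmut.panel import TargetRegion
from duplexmut.variants import VariantCall


def _call(target, pos, ref, alt, alt_count=1, depth=10_000, **kw):
    return VariantCall(
        target=target, position=pos, ref=ref, alt=alt, alt_count=alt_count,
        depth=depth, **kw,
    )


class TestSimpleSpectrum:
    def test_purine_reference_complemented(self, toy_target):
        pos = toy_target.sequence.index("G", 1)
        calls = [_call("toy", pos, "G", "T")]
        vec = simple_spectrum(calls, [toy_target])
        assert vec.counts[SBS6.index("C>A")] == 1
        assert vec.counts.sum() == 1

    def test_uniform_composition_equal_counts_give_sixths(self):
        # composition-balanced toy target: every base appears equally often
        seq = "ACGT" * 15
        t = TargetRegion("u", "u", 0, 60, seq)
        calls = []
        picks = {
            ("C", "A"): 1, ("C", "G"): 1, ("C", "T"): 1,
            ("T", "A"): 3, ("T", "C"): 3, ("T", "G"): 3,
        }
        for (ref, alt), pos in picks.items():
            calls.append(_call("u", pos, ref, alt))
        vec = simple_spectrum(calls, [t])
        assert vec.proportions == pytest.approx(np.full(6, 1 / 6))

    def test_skewed_composition_matches_direct_tally(self, small_panel):
        """Normalised proportions equal a brute-force count/abundance
        computation done independently here."""
        rng = np.random.default_rng(3)
        sig = named_signatures()["enu_like"]
        truth = simulate_true_mutations(small_panel, 1e-3, sig, 500, rng)
        calls = calls_from_truth(truth, small_panel, 500)
        vec = simple_spectrum(calls, [t for t in small_panel])
        # brute force: double-stranded pyrimidine abundance and class tally
        comp = {"G": "C", "A": "T", "C": "G", "T": "A"}
        pyr = {"C": 0, "T": 0}
        for t in small_panel:
            for b in t.sequence:
                pyr["C" if b in "CG" else "T"] += 1
        counts = dict.fromkeys(SBS6, 0)
        for c in calls:
            ref, alt = c.ref, c.alt
            if ref in "AG":
                ref, alt = comp[ref], comp[alt]
            counts[f"{ref}>{alt}"] += c.alt_count
        rates = np.array([counts[lab] / pyr[lab[0]] for lab in SBS6])
        assert vec.proportions == pytest.approx(rates / rates.sum())

    def test_identity_substitution_is_error(self, toy_target):
        with pytest.raises(ValueError):
            _call("toy", 1, "T", "T")


class TestTrinucleotideSpectrum:
    def test_96_classes(self, toy_target):
        vec = trinucleotide_spectrum([], [toy_target])
        assert len(vec.labels) == 96
        assert not vec.normalized
        assert vec.counts.sum() == 0

    def test_boundary_calls_dropped(self, toy_target):
        ref0 = toy_target.sequence[0]
        calls = [_call("toy", 0, ref0, "C" if ref0 != "C" else "G")]
        vec = trinucleotide_spectrum(calls, [toy_target])
        assert vec.n_dropped == 1
        assert vec.counts.sum() == 0

    def test_toy_target_matches_exhaustive_enumeration(self, toy_target):
        """Spectrum equals a brute-force (context, substitution) tally
        normalised by directly-counted 3-mer abundance."""
        seq = toy_target.sequence
        positions = [5, 10, 17, 22, 30]
        calls = []
        for pos in positions:
            ref = seq[pos]
            alt = {"A": "T", "C": "A", "G": "C", "T": "G"}[ref]
            calls.append(_call("toy", pos, ref, alt))
        vec = trinucleotide_spectrum(calls, [toy_target])
        # brute force in pyrimidine space
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        abundance = {}
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1 : i + 2]
            if tri[1] in "AG":
                tri = "".join(comp[b] for b in reversed(tri))
            abundance[tri] = abundance.get(tri, 0) + 1
        rates = {}
        for c in calls:
            tri = seq[c.position - 1 : c.position + 2]
            ref, alt = c.ref, c.alt
            if ref in "AG":
                tri = "".join(comp[b] for b in reversed(tri))
                ref, alt = comp[ref], comp[alt]
            label = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
            rates[label] = rates.get(label, 0) + 1 / abundance[tri]
        total = sum(rates.values())
        for label, rate in rates.items():
            assert vec.proportions[SBS96.index(label)] == pytest.approx(
                rate / total
            )
        assert vec.proportions.sum() == pytest.approx(1.0)

    def test_mirror_panel_involution(self, small_panel):
        """Reverse-complementing the panel and every call leaves the
        pyrimidine-space spectrum unchanged."""
        rng = np.random.default_rng(8)
        sig = named_signatures()["bap_like"]
        truth = simulate_true_mutations(small_panel, 1e-3, sig, 300, rng)
        calls = calls_from_truth(truth, small_panel, 300)
        vec = trinucleotide_spectrum(calls, small_panel)

        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        mirrored_panel = [
            TargetRegion(
                t.name, t.contig, t.start, t.end, revcomp(t.sequence),
                transcribed=t.transcribed,
                transcribed_strand=(
                    {"+": "-", "-": "+"}[t.transcribed_strand]
                    if t.transcribed_strand
                    else None
                ),
                frame_offset=None,
                copies_per_genome=t.copies_per_genome,
            )
            for t in small_panel
        ]
        lengths = {t.name: t.length for t in small_panel}
        mirrored_calls = [
            VariantCall(
                target=c.target,
                position=lengths[c.target] - 1 - c.position,
                ref=comp[c.ref], alt=comp[c.alt],
                alt_count=c.alt_count, depth=c.depth,
            )
            for c in calls
        ]
        mirrored = trinucleotide_spectrum(mirrored_calls, mirrored_panel)
        assert mirrored.proportions == pytest.approx(vec.proportions)

    def test_spectra_sum_to_one_when_normalized(self, small_panel):
        rng = np.random.default_rng(4)
        truth = simulate_true_mutations(
            small_panel, 5e-4, named_signatures()["background"], 400, rng
        )
        calls = calls_from_truth(truth, small_panel, 400)
        for vec in (
            simple_spectrum(calls, small_panel),
            trinucleotide_spectrum(calls, small_panel),
        ):
            assert vec.normalized
            assert vec.proportions.sum() == pytest.approx(1.0)


class TestStrandBias:
    def _simulate(self, factor, seed=5):
        panel = generate_reference_panel(2, 2000, seed=31)
        sig = named_signatures()["urethane_like"]
        rng = np.random.default_rng(seed)
        n_genomes = 5000
        truth = simulate_true_mutations(
            panel, 1e-4, sig, n_genomes, rng, strand_bias_factor=factor
        )
        calls = calls_from_truth(truth, panel, n_genomes)
        return panel, calls, n_genomes

    def test_unbiased_generator_folds_near_one(self):
        panel, calls, depth = self._simulate(1.0)
        target = next(t for t in panel if t.transcribed)
        result = strand_bias(
            [c for c in calls if c.target == target.name], target, depth
        )
        row = result.table[result.table["substitution"] == "T>A"].iloc[0]
        assert row["fold_low"] <= 1.0 <= row["fold_high"]

    def test_nontranscribed_target_not_applicable(self):
        panel, calls, depth = self._simulate(10.0)
        target = next(t for t in panel if not t.transcribed)
        result = strand_bias(calls, target, depth)
        assert not result.applicable
        with pytest.raises(ValueError):
            result.fold("T>A")

    def test_generator_factor_recovered_within_ci(self):
        panel, calls, depth = self._simulate(10.0)
        target = next(t for t in panel if t.transcribed)
        result = strand_bias(
            [c for c in calls if c.target == target.name], target, depth
        )
        row = result.table[result.table["substitution"] == "T>A"].iloc[0]
        assert row["fold_low"] <= 10.0 <= row["fold_high"]
        assert row["fold"] == pytest.approx(10.0, rel=0.6)


class TestConsequence:
    @pytest.mark.parametrize(
        "codon,pos_in_codon,alt,expected",
        [
            ("TAC", 2, "A", "nonsense"),  # TAC (Tyr) -> TAA (stop)
            ("CTG", 2, "A", "synonymous"),  # CTG -> CTA, both Leu
            ("ATG", 2, "A", "missense"),  # ATG (Met) -> ATA (Ile)
        ],
    )
    def test_genetic_code_classes(self, codon, pos_in_codon, alt, expected):
        seq = codon + "GGTTCCAAGGTTCCAAGGTTCCAAGGTACGT"[: 30 - 3]
        t = TargetRegion("c", "c", 0, 30, seq, frame_offset=0)
        call = _call("c", pos_in_codon, codon[pos_in_codon], alt)
        assert annotate_consequence(call, t) == expected

    def test_noncoding_target(self):
        t = TargetRegion("nc", "nc", 0, 30, "ACGT" * 7 + "AC")
        call = _call("nc", 5, t.sequence[5], "A" if t.sequence[5] != "A" else "T")
        assert annotate_consequence(call, t) == "noncoding"

    def test_incomplete_codon_unclassified(self):
        t = TargetRegion("c", "c", 0, 31, "A" * 31, frame_offset=0)
        call = _call("c", 30, "A", "T")  # last base, codon truncated
        assert annotate_consequence(call, t) == "unclassified"

    def test_dnds_matches_genetic_code_expectation(self, small_panel):
        """Uniform random coding mutations show the synonymous fraction
        expected from exhaustive enumeration of the target's codons."""
        t = small_panel[0]
        # exhaustive expectation over every possible substitution
        from duplexmut.spectra import _translate

        syn = total = 0
        for pos in range(t.length - t.length % 3):
            codon_start = (pos // 3) * 3
            codon = t.sequence[codon_start : codon_start + 3]
            off = pos - codon_start
            for alt in "ACGT":
                if alt == t.sequence[pos]:
                    continue
                mutant = codon[:off] + alt + codon[off + 1 :]
                total += 1
                syn += _translate(mutant) == _translate(codon)
        expected_syn_fraction = syn / total
        rng = np.random.default_rng(0)
        n = 3000
        observed = 0
        for _ in range(n):
            pos = int(rng.integers(0, t.length - t.length % 3))
            ref = t.sequence[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            out = annotate_consequence(_call(t.name, pos, ref, alt), t)
            observed += out == "synonymous"
        p_hat = observed / n
        se = np.sqrt(expected_syn_fraction * (1 - expected_syn_fraction) / n)
        assert abs(p_hat - expected_syn_fraction) < 4 * se


class TestChiSquare:
    def test_identical_spectra_p_near_one(self):
        counts = np.array([30, 20, 10, 25, 5, 10])
        stat, p = chi_square_spectrum_test(counts, counts)
        assert stat == pytest.approx(0.0)
        assert p > 0.999

    def test_disjoint_spectra_strongly_rejected(self):
        stat, p = chi_square_spectrum_test(
            np.array([10, 0]), np.array([0, 10])
        )
        assert p < 0.01

    def test_statistic_matches_hand_computation(self):
        a = np.array([20, 30, 50])
        b = np.array([30, 30, 40])
        table = np.vstack([a, b])
        expected = (
            table.sum(axis=1, keepdims=True)
            * table.sum(axis=0, keepdims=True)
            / table.sum()
        )
        by_hand = ((table - expected) ** 2 / expected).sum()
        stat, _ = chi_square_spectrum_test(a, b)
        assert stat == pytest.approx(by_hand)

    def test_sparse_classes_pooled(self):
        a = np.array([50, 40, 1, 1, 1])
        b = np.array([45, 42, 2, 1, 0])
        stat, p = chi_square_spectrum_test(a, b)
        assert np.isfinite(stat) and 0 <= p <= 1

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            chi_square_spectrum_test(np.zeros(4), np.zeros(4))
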