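"""Mutant-frequency estimation, fold induction, and clonality."""

import numpy as np
import pandas as pd
import pytest

from duplexmut import (
    ClonalityModel,
    classify_clonality,
    cohort_summary,
    fold_induction,
    hotspot_report,
    mutant_frequency,
    poisson_ci,
)
from duplexmut.variants import VariantCall


def _call(pos, alt_count=1, depth=10_000, alt="T", sample="s1", tissue="",
          germline=False, clonal=False, target="t"):
    return VariantCall(
        target=target, position=pos, ref="A", alt=alt, alt_count=alt_count,
        depth=depth, sample=sample, tissue=tissue, germline=germline,
        clonal=clonal,
    )


class TestPoissonCI:
    def test_zero_count_lower_bound_is_zero(self):
        lo, hi = poisson_ci(0)
        assert lo == 0.0
        assert hi == pytest.approx(3.6889, abs=1e-3)

    def test_known_exact_interval_for_five(self):
        # Garwood 95% CI for k=5: chi2-based closed form
        lo, hi = poisson_ci(5)
        assert lo == pytest.approx(1.6235, abs=1e-3)
        assert hi == pytest.approx(11.6683, abs=1e-3)

    @pytest.mark.parametrize("k", [1, 10, 100])
    def test_interval_contains_count(self, k):
        lo, hi = poisson_ci(k)
        assert lo < k < hi


class TestMutantFrequency:
    def test_no_calls(self):
        est = mutant_frequency([], duplex_bp=10_000)
        assert est.mf == 0.0
        assert est.ci[0] == 0.0
        assert est.ci[1] > 0

    def test_simple_arithmetic(self):
        calls = [_call(i) for i in range(3)]
        est = mutant_frequency(calls, duplex_bp=int(2e7))
        assert est.mf == pytest.approx(1.5e-7)
        assert est.ci[0] < est.mf < est.ci[1]

    def test_zero_duplex_bp_is_error(self):
        with pytest.raises(ValueError):
            mutant_frequency([], duplex_bp=0)

    def test_germline_excluded(self):
        calls = [_call(0), _call(1, alt_count=5000, germline=True)]
        est = mutant_frequency(calls, duplex_bp=10_000)
        assert est.n_mutant == 1

    def test_clone_collapse_counts_expansion_once(self):
        calls = [_call(0), _call(1, alt_count=50, clonal=True)]
        est = mutant_frequency(calls, duplex_bp=10_000)
        assert est.n_mutant == 2  # 1 singlet + 1 collapsed clone
        assert est.n_mutant_uncollapsed == 51
        est_raw = mutant_frequency(calls, duplex_bp=10_000, clone_collapse=False)
        assert est_raw.mf == pytest.approx(51 / 10_000)

    def test_independent_multiplet_counts_molecules(self):
        calls = [_call(0, alt_count=3)]
        est = mutant_frequency(calls, duplex_bp=10_000)
        assert est.n_mutant == 3

    def test_reemitting_call_table_leaves_mf_unchanged(self):
        """MF from a fixed call table is invariant to recomputing it."""
        calls = [_call(i, alt_count=1 + i % 2) for i in range(10)]
        a = mutant_frequency(calls, duplex_bp=123_456)
        b = mutant_frequency(list(calls), duplex_bp=123_456)
        assert a.mf == b.mf and a.ci == b.ci

    def test_adding_a_site_never_decreases_mf(self):
        calls = [_call(i) for i in range(5)]
        base = mutant_frequency(calls, duplex_bp=10_000).mf
        more = mutant_frequency(calls + [_call(99)], duplex_bp=10_000).mf
        assert more > base

    def test_parameter_recovery_median_estimate(self):
        """Median estimate across seeds recovers true MF within 25% at
        1e7 duplex bp for rates 1e-7 .. 1e-5."""
        from duplexmut import (
            calls_from_truth, generate_reference_panel, named_signatures,
            simulate_true_mutations,
        )
        from duplexmut.simulate import PanelSiteIndex

        panel = generate_reference_panel(5, 2000, seed=100)
        idx = PanelSiteIndex(panel)
        bp_per_genome = sum(t.length * t.copies_per_genome for t in panel)
        n_genomes = round(1e7 / bp_per_genome)
        sig = named_signatures()["background"]
        for true_mf in (1e-7, 1e-6, 1e-5):
            estimates = []
            for seed in range(25):
                rng = np.random.default_rng(1000 + seed)
                truth = simulate_true_mutations(
                    panel, true_mf, sig, n_genomes, rng, site_index=idx
                )
                calls = calls_from_truth(truth, panel, n_genomes)
                est = mutant_frequency(
                    calls, duplex_bp=bp_per_genome * n_genomes
                )
                estimates.append(est.mf)
            median = float(np.median(estimates))
            assert abs(median - true_mf) / true_mf < 0.25

    def test_ci_coverage_at_1e6(self):
        """95% Poisson CI covers the true MF in >= 90% of replicates."""
        from duplexmut import (
            calls_from_truth, generate_reference_panel, named_signatures,
            simulate_true_mutations,
        )
        from duplexmut.simulate import PanelSiteIndex

        panel = generate_reference_panel(5, 2000, seed=100)
        idx = PanelSiteIndex(panel)
        bp_per_genome = sum(t.length * t.copies_per_genome for t in panel)
        n_genomes = round(1e7 / bp_per_genome)
        sig = named_signatures()["background"]
        covered = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(2000 + seed)
            truth = simulate_true_mutations(
                panel, 1e-6, sig, n_genomes, rng, site_index=idx
            )
            calls = calls_from_truth(truth, panel, n_genomes)
            est = mutant_frequency(calls, duplex_bp=bp_per_genome * n_genomes)
            if est.ci[0] <= 1e-6 <= est.ci[1]:
                covered += 1
        assert covered >= 0.9 * n_rep


class TestFoldInduction:
    def test_identity(self):
        assert fold_induction(3.2e-7, 3.2e-7) == pytest.approx(1.0)

    def test_simple_ratio(self):
        assert fold_induction(2e-6, 5e-7) == pytest.approx(4.0)

    def test_zero_control_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="control MF is 0"):
            out = fold_induction(1e-6, 0.0)
        assert np.isnan(out)


class TestClonality:
    def _background(self, rng, n=300, depth_mu=4.0, depth_sd=0.15):
        calls = []
        for i in range(n):
            depth = int(10 ** rng.normal(depth_mu, depth_sd))
            calls.append(_call(i, alt_count=1, depth=depth))
        return calls

    def test_uniform_vaf_background_has_no_clonal_calls(self):
        calls = [_call(i, alt_count=1, depth=10_000) for i in range(100)]
        results = classify_clonality(calls)
        assert results.n_clonal == 0
        assert all(not c.clonal for c in calls)

    def test_high_vaf_multiplet_flagged(self, rng):
        """Brute-force oracle: mean/sd of log10 VAF computed directly, the
        outlier call must exceed mean + 3 sd and carry >= 2 molecules."""
        calls = self._background(rng)
        outlier = _call(999, alt_count=20, depth=2000)  # VAF 1e-2
        calls.append(outlier)
        results = classify_clonality(calls, cutoff_sd=3.0)
        log_vaf = np.log10([c.vaf for c in calls])
        assert results.mean_log_vaf == pytest.approx(log_vaf.mean())
        assert results.sd_log_vaf == pytest.approx(log_vaf.std())
        assert np.log10(outlier.vaf) > results.threshold_log_vaf
        assert outlier.clonal

    def test_single_observation_outlier_never_clonal(self, rng):
        calls = self._background(rng)
        lonely = _call(999, alt_count=1, depth=10)  # VAF 0.1, single molecule
        calls.append(lonely)
        classify_clonality(calls)
        assert not lonely.clonal

    def test_too_few_calls_warns_and_labels_conservatively(self):
        calls = [_call(0, alt_count=3), _call(1)]
        with pytest.warns(UserWarning, match="clonality not fitted"):
            results = classify_clonality(calls)
        assert not results.fitted
        assert set(results.labels) == {"multiplet-independent", "singlet"}

    def test_germline_excluded_from_fit(self):
        calls = [_call(i) for i in range(10)]
        calls.append(_call(50, alt_count=5000, depth=10_000, germline=True))
        model = ClonalityModel(calls)
        assert len(model.calls) == 10

    def test_false_positive_rate_on_clone_free_data(self):
        """<= 1 false clonal call per 1e4 background calls."""
        total = fp = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            calls = self._background(rng, n=500)
            results = classify_clonality(calls)
            fp += results.n_clonal
            total += len(calls)
        assert total == 10_000
        assert fp <= 1

    def test_injected_clones_detected_across_seeds(self):
        """Clones at >= 10x background VAF flagged in >= 95% of seeds."""
        detected = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            calls = self._background(rng)
            clone_depth = int(10 ** rng.normal(4.0, 0.15))
            clone_vaf = 10 * 10 ** (-4.0)  # 10x median background VAF
            clone = _call(
                999,
                alt_count=max(2, round(clone_vaf * clone_depth)),
                depth=clone_depth,
            )
            calls.append(clone)
            classify_clonality(calls)
            detected += clone.clonal
        assert detected >= 0.95 * n_seeds


class TestHotspotReport:
    def test_recurrent_clone_summary(self):
        calls = []
        for i in range(4):  # 4 of 5 lung samples carry the clone
            calls.append(
                _call(
                    61, alt_count=10, depth=1000, sample=f"lung_{i}",
                    tissue="lung", clonal=True, target="HRAS",
                )
            )
        calls.append(
            _call(61, alt_count=1, depth=1000, sample="lung_4", tissue="lung",
                  target="HRAS")
        )
        samples = [(f"lung_{i}", "lung") for i in range(5)]
        report = hotspot_report(
            calls, [("codon61", "HRAS", 60, 63)], samples=samples
        )
        assert len(report) == 1
        row = report.iloc[0]
        assert row["samples_with_clonal"] == 4
        assert row["samples_total"] == 5
        assert row["alt_alleles"] == "T"

    def test_no_clones_yields_empty_table(self):
        report = hotspot_report([], [("codon61", "HRAS", 60, 63)], samples=[])
        assert report.empty


class TestCohortSummary:
    def test_duplex_bp_grand_total(self):
        df = pd.DataFrame(
            {
                "sample": ["a", "b"],
                "tissue": ["liver", "liver"],
                "treatment": ["VC", "ENU"],
                "duplex_bp": [1000, 2000],
                "mf": [1e-7, 1e-6],
            }
        )
        out = cohort_summary(df)
        assert out["duplex_bp_total"] == 3000
        folds = out["fold_inductions"]
        assert folds.iloc[0]["fold_induction"] == pytest.approx(10.0)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            cohort_summary(pd.DataFrame({"mf": [1.0]}))
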