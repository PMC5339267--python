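"""The SIP percentage-enrichment statistic and its noise threshold."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_table
from peptide_sip.enrichment_stats import (
    FractionTaxonTable,
    collapse_to_class,
    flag_enriched,
    noise_threshold,
    percent_enrichment,
    relative_copy_numbers,
    taxon_copy_numbers,
)
from peptide_sip.gradient_model import Fraction, GradientProfile, HeavyWindow


def profile_from(densities, copies):
    return GradientProfile(
        treatment="13C",
        depth="surface",
        fractions=[
            Fraction(index=i + 1, density=float(d), copies=float(c))
            for i, (d, c) in enumerate(zip(densities, copies))
        ],
    )


class TestTaxonCopyNumbers:
    def test_single_fraction_product(self):
        p = profile_from([1.73], [1000])
        t = make_table({"X": [200], "Y": [800]}, columns=[1])
        got = taxon_copy_numbers(t, p, HeavyWindow(1.72, 1.74))
        assert got["X"] == pytest.approx(200)
        assert got["Y"] == pytest.approx(800)

    def test_weighted_sum_over_window(self):
        p = profile_from([1.73, 1.735], [100, 300])
        t = make_table({"X": [50, 50], "Y": [50, 50]}, columns=[1, 2])
        got = taxon_copy_numbers(t, p, HeavyWindow(1.72, 1.74))
        assert got["X"] == pytest.approx(200)

    def test_mismatched_fraction_ids_rejected(self):
        p = profile_from([1.73], [1000])
        t = make_table({"X": [200]}, columns=[9])
        with pytest.raises(ValueError, match="9"):
            taxon_copy_numbers(t, p, HeavyWindow(1.72, 1.74))

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        """Vectorized result equals an explicit taxon-by-fraction double loop."""
        window = HeavyWindow(1.70, 1.74)
        for _ in range(100):
            n_taxa, n_frac = rng.integers(2, 6), rng.integers(2, 7)
            densities = rng.uniform(1.66, 1.77, size=n_frac)
            copies = rng.uniform(10, 1e5, size=n_frac)
            counts = rng.integers(0, 500, size=(n_taxa, n_frac)).astype(float)
            taxa = [f"t{i}" for i in range(n_taxa)]
            table = FractionTaxonTable(
                counts=pd.DataFrame(counts, index=taxa, columns=range(1, n_frac + 1))
            )
            profile = profile_from(densities, copies)
            got = taxon_copy_numbers(table, profile, window)
            for i, taxon in enumerate(taxa):
                expected = 0.0
                for j in range(n_frac):
                    if not window.contains(densities[j]):
                        continue
                    col_total = counts[:, j].sum()
                    if col_total == 0:
                        continue
                    expected += counts[i, j] / col_total * copies[j]
                assert got[taxon] == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_zero_read_fraction_contributes_nothing(self):
        p = profile_from([1.73, 1.735], [100, 999])
        t = make_table({"X": [50, 0], "Y": [50, 0]}, columns=[1, 2])
        got = taxon_copy_numbers(t, p, HeavyWindow(1.72, 1.74))
        assert got["X"] == pytest.approx(50)


class TestRelativeCopyNumbers:
    def test_normalizes_to_window_total(self):
        rel = relative_copy_numbers(pd.Series({"X": 200.0, "Y": 800.0}))
        assert rel.to_dict() == {"X": 0.2, "Y": 0.8}

    def test_single_taxon_is_one(self):
        assert relative_copy_numbers(pd.Series({"X": 7.0}))["X"] == 1.0

    def test_scale_invariance(self):
        a = relative_copy_numbers(pd.Series({"X": 2.0, "Y": 3.0}))
        b = relative_copy_numbers(pd.Series({"X": 20.0, "Y": 30.0}))
        pd.testing.assert_series_equal(a, b)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            relative_copy_numbers(pd.Series({"X": 0.0}))


class TestPercentEnrichment:
    def test_doubling_gives_100_percent(self):
        enr = percent_enrichment(pd.Series({"X": 0.4}), pd.Series({"X": 0.2}))
        assert enr["X"] == pytest.approx(100.0)

    def test_no_change_gives_zero(self):
        enr = percent_enrichment(pd.Series({"X": 0.3}), pd.Series({"X": 0.3}))
        assert enr["X"] == pytest.approx(0.0)

    def test_total_depletion_gives_minus_100(self):
        enr = percent_enrichment(pd.Series({"X": 0.0}), pd.Series({"X": 0.5}))
        assert enr["X"] == pytest.approx(-100.0)

    def test_zero_reference_yields_undefined_marker(self):
        enr = percent_enrichment(pd.Series({"X": 0.5}), pd.Series({"X": 0.0}))
        assert np.isnan(enr["X"])  # undefined, not infinite, not dropped

    def test_outer_join_keeps_one_sided_taxa(self):
        enr = percent_enrichment(pd.Series({"X": 0.5}), pd.Series({"Y": 0.5}))
        assert set(enr.index) == {"X", "Y"}
        assert enr.isna().all()

    def test_common_rescaling_cancels(self, rng):
        """The statistic is invariant to rescaling raw copies in either gradient."""
        copies13 = pd.Series(rng.uniform(1, 100, 5), index=list("abcde"))
        copies12 = pd.Series(rng.uniform(1, 100, 5), index=list("abcde"))
        base = percent_enrichment(
            relative_copy_numbers(copies13), relative_copy_numbers(copies12)
        )
        scaled = percent_enrichment(
            relative_copy_numbers(copies13 * 123.0),
            relative_copy_numbers(copies12 * 0.007),
        )
        pd.testing.assert_series_equal(base, scaled)

    def test_two_taxon_enrichments_cannot_both_be_positive(self, rng):
        """Sum-to-one: if one taxon's share rises the other's must fall."""
        for _ in range(50):
            rel12 = relative_copy_numbers(pd.Series(rng.uniform(0.1, 10, 2), index=["X", "Y"]))
            rel13 = relative_copy_numbers(pd.Series(rng.uniform(0.1, 10, 2), index=["X", "Y"]))
            enr = percent_enrichment(rel13, rel12)
            assert not (enr > 0).all()


class TestNoiseThreshold:
    def test_identical_positive_values_give_zero_width(self):
        out = noise_threshold(pd.Series([50.0, 50.0, 50.0]))
        assert out["threshold"] == pytest.approx(50.0)
        assert out["noise"] == pytest.approx(0.0)

    def test_ci_mean_matches_textbook_t_interval(self):
        """Frozen against the closed-form t-interval for {100, 200, 300}."""
        out = noise_threshold(pd.Series([100.0, 200.0, 300.0]), method="ci_mean")
        sem = 100.0 / np.sqrt(3)
        expected_half = stats.t.ppf(0.975, df=2) * sem
        assert out["mean"] == pytest.approx(200.0)
        assert out["noise"] == pytest.approx(expected_half)
        assert out["threshold"] == pytest.approx(200.0 + expected_half)
        # hand value of the same interval
        assert out["threshold"] == pytest.approx(448.414, abs=0.01)

    def test_negative_values_are_excluded(self):
        base = noise_threshold(pd.Series([100.0, 200.0, 300.0]))
        with_neg = noise_threshold(pd.Series([100.0, 200.0, 300.0, -40.0]))
        assert with_neg == base

    def test_percentile_method(self):
        vals = pd.Series(np.arange(1.0, 101.0))
        out = noise_threshold(vals, method="percentile")
        assert out["threshold"] == pytest.approx(np.percentile(vals, 97.5))

    def test_fewer_than_two_positive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            noise_threshold(pd.Series([100.0, -5.0]))


class TestFlagging:
    def make_report(self, enrichment, abundance):
        return pd.DataFrame(
            {"percent_enrichment": [enrichment], "mean_abundance": [abundance]},
            index=["X"],
        )

    def test_above_threshold_flagged(self):
        out = flag_enriched(self.make_report(90.0, 0.01), threshold=84.0)
        assert bool(out.loc["X", "above_threshold"])

    def test_threshold_boundary_is_strict(self):
        out = flag_enriched(self.make_report(84.0, 0.01), threshold=84.0)
        assert not bool(out.loc["X", "above_threshold"])

    def test_abundance_floor(self):
        out = flag_enriched(self.make_report(90.0, 0.0005), threshold=84.0)
        assert not bool(out.loc["X", "abundance_filter_passed"])


class TestCollapseToClass:
    def test_counts_are_summed_before_proportions(self):
        t = make_table({"g1": [10, 0], "g2": [30, 10], "g3": [60, 90]}, columns=[1, 2])
        cls = collapse_to_class(t, {"g1": "A", "g2": "A", "g3": "B"})
        assert cls.rank == "class"
        assert cls.counts.loc["A"].tolist() == [40, 10]
        assert cls.proportions.loc["A", 1] == pytest.approx(0.4)

    def test_missing_assignment_rejected(self):
        t = make_table({"g1": [1]}, columns=[1])
        with pytest.raises(ValueError, match="g1"):
            collapse_to_class(t, {})
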