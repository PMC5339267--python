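"""Generator structure: band placement, noise models, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from peptide_sip.enrichment_stats import (
    percent_enrichment,
    relative_copy_numbers,
    taxon_copy_numbers,
)
from peptide_sip.gradient_model import HeavyWindow, default_heavy_window
from peptide_sip.kinetics import fit_zero_order
from peptide_sip.synthetic_data import (
    SimulationConfig,
    SyntheticCommunity,
    TaxonSpec,
    analytic_depletion_time,
    band_center,
    default_community,
    simulate_gradient_pair,
    simulate_incubation,
    unlabeled_density,
)


def two_taxon_community(atom_fraction: float) -> SyntheticCommunity:
    return SyntheticCommunity(
        [
            TaxonSpec("hot", "C1", "g1", 0.5, 0.50, atom_fraction),
            TaxonSpec("cold", "C2", "g2", 0.5, 0.50, 0.0),
        ]
    )


class TestCommunityValidation:
    def test_abundances_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticCommunity([TaxonSpec("x", "C", "g", 0.5, 0.5)])

    def test_atom_fraction_capped_by_substrate_labeling(self):
        with pytest.raises(ValueError, match="17/20"):
            TaxonSpec("x", "C", "g", 1.0, 0.5, atom_fraction_13c=0.9)

    def test_unlabel_zeroes_every_atom_fraction(self):
        comm = default_community().unlabel()
        assert all(t.atom_fraction_13c == 0 for t in comm.taxa)

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCommunity([])


class TestBandPlacement:
    def test_gc_density_relation(self):
        cfg = SimulationConfig()
        assert unlabeled_density(0.5, cfg) == pytest.approx(1.660 + 0.098 * 0.5)

    def test_full_label_shift_in_band_center(self):
        cfg = SimulationConfig()
        hot = TaxonSpec("hot", "C", "g", 1.0, 0.5, 0.85)
        cold = TaxonSpec("cold", "C", "g", 1.0, 0.5, 0.0)
        shift = band_center(hot, cfg) - band_center(cold, cfg)
        assert shift == pytest.approx(0.85 * 0.036)


class TestGradientPair:
    def test_unlabeled_scenario_gives_identical_pair_and_zero_enrichment(self):
        comm = two_taxon_community(0.0)
        cfg = SimulationConfig()
        pair = simulate_gradient_pair(comm, cfg, seed=3, noise=False)
        assert np.allclose(pair["profile_12c"].copies, pair["profile_13c"].copies)
        window = HeavyWindow(1.70, 1.75)
        enr = percent_enrichment(
            relative_copy_numbers(
                taxon_copy_numbers(pair["table_13c"], pair["profile_13c"], window)
            ),
            relative_copy_numbers(
                taxon_copy_numbers(pair["table_12c"], pair["profile_12c"], window)
            ),
        )
        assert np.allclose(enr, 0.0, atol=1e-9)

    def test_mass_conserved_across_fractions_before_noise(self):
        from peptide_sip.synthetic_data import _taxon_mass_matrix

        cfg = SimulationConfig()
        mass = _taxon_mass_matrix(default_community(), cfg)
        np.testing.assert_allclose(
            mass.sum(axis=1),
            [t.abundance * t.growth_response for t in default_community().taxa],
            rtol=1e-12,
        )

    def test_same_seed_bit_identical(self):
        comm = default_community()
        cfg = SimulationConfig()
        a = simulate_gradient_pair(comm, cfg, seed=11)
        b = simulate_gradient_pair(comm, cfg, seed=11)
        assert a["profile_12c"].copies.tolist() == b["profile_12c"].copies.tolist()
        assert a["profile_13c"].copies.tolist() == b["profile_13c"].copies.tolist()
        pd.testing.assert_frame_equal(a["table_12c"].counts, b["table_12c"].counts)
        pd.testing.assert_frame_equal(a["table_13c"].counts, b["table_13c"].counts)

    def test_different_seed_differs(self):
        comm = default_community()
        cfg = SimulationConfig()
        a = simulate_gradient_pair(comm, cfg, seed=11)
        b = simulate_gradient_pair(comm, cfg, seed=12)
        assert a["profile_13c"].copies.tolist() != b["profile_13c"].copies.tolist()

    def test_enrichment_monotone_in_atom_fraction_noise_off(self):
        """More labeling never lowers a taxon's enrichment (noise off)."""
        cfg = SimulationConfig()
        window = HeavyWindow(1.725, 1.77)
        previous = -np.inf
        for atom in (0.0, 0.2, 0.4, 0.6, 0.85):
            pair = simulate_gradient_pair(
                two_taxon_community(atom), cfg, seed=0, noise=False
            )
            enr = percent_enrichment(
                relative_copy_numbers(
                    taxon_copy_numbers(pair["table_13c"], pair["profile_13c"], window)
                ),
                relative_copy_numbers(
                    taxon_copy_numbers(pair["table_12c"], pair["profile_12c"], window)
                ),
            )
            assert enr["hot"] >= previous - 1e-9
            previous = enr["hot"]

    def test_labeled_taxa_take_top_ranks_at_seed_42(self):
        comm = default_community()
        pair = simulate_gradient_pair(comm, SimulationConfig(), seed=42)
        window = default_heavy_window(pair["profile_12c"], pair["profile_13c"])
        enr = percent_enrichment(
            relative_copy_numbers(
                taxon_copy_numbers(pair["table_13c"], pair["profile_13c"], window)
            ),
            relative_copy_numbers(
                taxon_copy_numbers(pair["table_12c"], pair["profile_12c"], window)
            ),
        )
        labeled = {t.label for t in comm.taxa if t.atom_fraction_13c > 0}
        top3 = set(enr.sort_values(ascending=False).head(3).index)
        assert top3 == labeled

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCommunity([])


class TestIncubation:
    def test_analytic_depletion_time(self):
        assert analytic_depletion_time(0.40, 0.02) == pytest.approx(20.0)

    def test_noise_free_series_follow_construction(self):
        cfg = SimulationConfig(peptide_noise_sd=0.0)
        series = simulate_incubation(cfg, seed=5)
        surface = [
            s for s in series if s.treatment == "12C" and s.depth == "surface"
        ][0]
        t = np.array(surface.times)
        expected = np.clip(
            cfg.initial_peptide_um - cfg.decay_rate_surface * t, 0, None
        )
        np.testing.assert_allclose(surface.peptide, expected, atol=1e-12)

    def test_killed_control_is_flat_and_fits_zero_rate(self):
        cfg = SimulationConfig(peptide_noise_sd=0.0)
        series = simulate_incubation(cfg, seed=5)
        killed = [s for s in series if s.treatment == "killed"][0]
        assert not killed.killed_control_drifted()
        assert fit_zero_order(killed).k == pytest.approx(0.0, abs=1e-12)

    def test_generator_rate_recovered_by_kinetics_fit(self):
        """k = 0.018 recovered within 10% on average over 500 seeded bottles."""
        cfg = SimulationConfig(
            decay_rate_surface=0.018, peptide_noise_sd=0.01, initial_peptide_um=0.40
        )
        # depleted samples read half-normal noise, so the quantitation floor
        # for the fit must sit above the 0.01 uM measurement noise
        floor = 0.03
        ks = []
        for seed in range(250):
            series = simulate_incubation(cfg, seed=seed)
            for s in series:
                if s.depth == "surface" and s.treatment == "12C":
                    ks.append(fit_zero_order(s, floor=floor).k)
        assert len(ks) == 500
        assert np.mean(ks) == pytest.approx(0.018, rel=0.10)

    def test_duplicates_share_structure_but_not_noise(self):
        series = simulate_incubation(SimulationConfig(), seed=9)
        a, b = [
            s for s in series if s.treatment == "13C" and s.depth == "bottom"
        ]
        assert a.peptide != b.peptide
        assert a.times == b.times

    def test_same_seed_reproduces_incubation_exactly(self):
        a = simulate_incubation(SimulationConfig(), seed=21)
        b = simulate_incubation(SimulationConfig(), seed=21)
        assert a == b

    def test_ammonium_rises_after_depletion_in_active_bottles(self):
        cfg = SimulationConfig(peptide_noise_sd=0.0)
        series = simulate_incubation(cfg, seed=2)
        active = [s for s in series if s.treatment == "13C" and s.depth == "surface"][0]
        assert active.ammonium[-1] > active.ammonium[0]
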