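"""Synthetic-data generator: envelopes, dynamics, flux series, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from siampeat import (
    expected_envelope,
    generate_feature_table,
    generate_nmr_block,
    generate_species,
    simulate_envelope,
    simulate_flux_series,
)
from siampeat.design import SampleDesign, TIMEPOINT_DAYS, design_from_frame, design_to_frame
from siampeat.synth import (
    DynamicsConfig,
    FluxConfig,
    MolecularSpecies,
    NoiseConfig,
    _origin_multiplier,
    multinomial_envelope,
)


# ----------------------------------------------------------------------
# design
# ----------------------------------------------------------------------
class TestDesign:
    def test_structure(self, design):
        lo = [s for s in design if s.treatment == "LO"]
        po = [s for s in design if s.treatment == "PO"]
        pl = [s for s in design if s.treatment == "PL"]
        assert all(s.timepoint == "T0" for s in lo)
        assert all(s.label_status == "unlabeled" for s in po)
        assert {s.timepoint for s in pl} == {"T1", "T2", "T3"}
        # 2 replicates in every treatment x timepoint x label cell
        cells = {}
        for s in design:
            cells.setdefault((s.treatment, s.timepoint, s.label_status), []).append(s)
        assert all(len(v) == 2 for v in cells.values())

    def test_day_codec(self):
        assert TIMEPOINT_DAYS == {"T0": 0, "T1": 7, "T2": 18, "T3": 40}

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            SampleDesign("x", "LO", "labeled", "T2", 1)
        with pytest.raises(ValueError):
            SampleDesign("x", "PO", "labeled", "T1", 1)

    def test_metadata_round_trip(self, design):
        frame = design_to_frame(design)
        assert design_from_frame(frame) == design


# ----------------------------------------------------------------------
# species
# ----------------------------------------------------------------------
class TestGenerateSpecies:
    def test_all_litter_mix_gets_configured_enrichment(self):
        mix = {"litter": 1.0}
        sp = generate_species(20, origin_mix=mix, enrichment=0.524, seed=1)
        assert all(s.origin == "litter" for s in sp)
        assert all(s.enrichment == pytest.approx(0.524) for s in sp)

    def test_zero_enrichment_reduces_to_natural_abundance(self):
        sp = generate_species(20, origin_mix={"litter": 1.0}, enrichment=0.0, seed=1)
        assert all(s.enrichment == pytest.approx(0.0107) for s in sp)

    def test_non_litter_species_sit_at_natural_abundance(self):
        sp = generate_species(200, seed=3)
        for s in sp:
            if s.origin != "litter":
                assert s.enrichment == pytest.approx(0.0107)

    def test_carbon_count_consistent_with_mass(self):
        for s in generate_species(100, seed=2):
            assert np.ceil(s.neutral_mass / 30.0) <= s.n_carbon
            assert s.n_carbon <= max(
                np.floor(s.neutral_mass / 12.0), np.ceil(s.neutral_mass / 30.0)
            )
            assert 100 <= s.neutral_mass <= 1200

    def test_deterministic_under_seed(self):
        assert generate_species(50, seed=9) == generate_species(50, seed=9)
        assert generate_species(50, seed=9) != generate_species(50, seed=10)

    def test_errors(self):
        with pytest.raises(ValueError):
            generate_species(0, seed=1)
        with pytest.raises(ValueError):
            generate_species(5, mass_range=(500, 500), seed=1)
        with pytest.raises(ValueError):
            generate_species(5, origin_mix={"litter": 0.5}, seed=1)


# ----------------------------------------------------------------------
# envelopes
# ----------------------------------------------------------------------
def convolve_one_carbon(n_carbon: int, p: float) -> np.ndarray:
    """Brute-force oracle: convolve n single-carbon distributions."""
    env = np.array([1.0])
    for _ in range(n_carbon):
        env = np.convolve(env, [1.0 - p, p])
    return env


class TestEnvelopes:
    def test_binomial_closed_form(self):
        env = expected_envelope(6, 0.5)
        comb = np.array([1, 6, 15, 20, 15, 6, 1]) / 64.0
        np.testing.assert_allclose(env, comb, atol=1e-12)

    def test_natural_two_carbon_matches_convolution_oracle(self):
        env = expected_envelope(2, 0.0107)
        oracle = convolve_one_carbon(2, 0.0107)
        np.testing.assert_allclose(env, oracle, atol=1e-12)
        np.testing.assert_allclose(
            env, [0.97871449, 0.02117102, 0.00011449], atol=1e-8
        )

    @pytest.mark.parametrize("n_carbon,p", [(1, 0.1), (5, 0.524), (12, 0.9)])
    def test_matches_convolution_oracle(self, n_carbon, p):
        np.testing.assert_allclose(
            expected_envelope(n_carbon, p),
            convolve_one_carbon(n_carbon, p),
            atol=1e-12,
        )

    def test_single_ion_is_one_hot(self):
        sp = MolecularSpecies("s", 6, 180.0, 10.0, "litter", 0.524, 1e7)
        env = simulate_envelope(sp, ion_count=1, seed=4)
        assert env.sum() == 1
        assert (env >= 0).all() and len(env) == 7

    def test_counts_sum_to_ion_count(self):
        rng = np.random.default_rng(0)
        env = multinomial_envelope(10, 0.3, 5000, rng)
        assert env.sum() == 5000

    def test_goodness_of_fit_at_large_ion_count(self):
        """Sampled envelope matches the binomial law (chi-square GOF)."""
        rng = np.random.default_rng(11)
        n_carbon, p, ions = 8, 0.4, 10_000
        counts = multinomial_envelope(n_carbon, p, ions, rng)
        expected = expected_envelope(n_carbon, p) * ions
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=n_carbon)

    def test_natural_enrichment_indistinguishable_from_unlabeled(self):
        """Envelopes at enrichment = natural abundance match the natural law."""
        rng = np.random.default_rng(21)
        ions = 20_000
        a = multinomial_envelope(6, 0.0107, ions, rng)
        expected = expected_envelope(6, 0.0107) * ions
        keep = expected > 5
        chi2 = ((a[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=keep.sum() - 1)


# ----------------------------------------------------------------------
# feature table
# ----------------------------------------------------------------------
class TestGenerateFeatureTable:
    def test_noiseless_single_species_single_sample(self):
        sp = [MolecularSpecies("s0", 6, 180.063, 10.0, "peat_native", 0.0107, 1e8)]
        design = [SampleDesign("PO-T0-unl-1", "PO", "unlabeled", "T0", 1)]
        table, truth = generate_feature_table(
            sp, design, noise=NoiseConfig.noiseless(), seed=1
        )
        env = expected_envelope(6, 0.0107)
        k_set = np.nonzero(env >= 1e-4)[0]
        assert len(table) == len(k_set)
        vals = table.df["PO-T0-unl-1"].to_numpy()
        np.testing.assert_allclose(vals / vals.sum(), env[k_set] / env[k_set].sum(),
                                   rtol=1e-9)

    def test_peat_primed_declines_in_pl_constant_in_po(self):
        dyn = DynamicsConfig()
        days = [0, 7, 18, 40]
        pl = [_origin_multiplier("peat_primed", "PL", d, dyn) for d in days]
        po = [_origin_multiplier("peat_primed", "PO", d, dyn) for d in days]
        assert all(a > b for a, b in zip(pl, pl[1:]))  # strictly decreasing
        assert po == [1.0] * 4

    def test_primed_truth_declines_across_pl_harvests(self, design):
        sp = generate_species(40, seed=8)
        _, truth = generate_feature_table(sp, design, noise=NoiseConfig.noiseless(), seed=9)
        primed = [s.species_id for s in sp if s.origin == "peat_primed"]
        for spid in primed:
            row = truth.true_abundance.loc[spid]
            series = [row[f"PL-{tp}-lab-1"] for tp in ("T1", "T2", "T3")]
            assert series[0] > series[1] > series[2]
            po = [row[f"PO-{tp}-unl-1"] for tp in ("T0", "T1", "T2", "T3")]
            assert len(set(po)) == 1

    def test_byte_identical_under_seed(self, design):
        sp = generate_species(20, seed=3)
        t1, _ = generate_feature_table(sp, design, seed=44)
        t2, _ = generate_feature_table(sp, design, seed=44)
        assert t1.df.to_csv(index=False) == t2.df.to_csv(index=False)

    def test_feature_map_covers_all_rows(self, design):
        sp = generate_species(20, seed=3)
        table, truth = generate_feature_table(sp, design, seed=44)
        assert set(truth.feature_map["feature_id"]) == set(table.feature_ids)

    def test_errors(self):
        sp = generate_species(5, seed=1)
        with pytest.raises(ValueError):
            generate_feature_table(sp, [], seed=1)
        with pytest.raises(ValueError):
            NoiseConfig(mass_ppm_sd=-1.0)


# ----------------------------------------------------------------------
# NMR block
# ----------------------------------------------------------------------
class TestNmrBlock:
    def test_labeled_fraction_forty_percent_of_45_is_18(self, design):
        table, flags = generate_nmr_block(45, design, labeled_fraction=0.4, seed=1)
        assert len(table) == 45
        assert flags.sum() == 18
        assert table["neutral_mass"].between(32, 355).all()

    def test_zero_fraction_no_flags(self, design):
        _, flags = generate_nmr_block(10, design, labeled_fraction=0.0, seed=1)
        assert flags.sum() == 0

    def test_reproducible(self, design):
        a, _ = generate_nmr_block(12, design, seed=5)
        b, _ = generate_nmr_block(12, design, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_errors(self, design):
        with pytest.raises(ValueError):
            generate_nmr_block(0, design, seed=1)
        with pytest.raises(ValueError):
            generate_nmr_block(5, design, labeled_fraction=1.5, seed=1)


# ----------------------------------------------------------------------
# flux series
# ----------------------------------------------------------------------
class TestFluxSeries:
    def test_no_amendment_limit_pl_equals_po(self):
        cfg = FluxConfig(litter_l0=0.0, priming_amplitude=0.0, cv=0.0)
        obs, _ = simulate_flux_series(cfg, seed=1)
        po = sorted((o.day, o.f_net, o.r_net) for o in obs if o.treatment == "PO")
        pl = sorted((o.day, o.f_net, o.r_net) for o in obs if o.treatment == "PL")
        for a, b in zip(po, pl):
            assert a == pytest.approx(b)

    def test_day7_mixture_arithmetic(self):
        """Hand-computed R_net: B=2 at soil ratio, litter flux 4 at 0.524."""
        k = np.log(2.0) / 7.0  # day-7 litter flux = 8 * exp(-k*7) = 4
        cfg = FluxConfig(
            baseline=2.0, litter_l0=8.0, litter_decay=k, priming_amplitude=0.0,
            r_soil=0.0108, r_litter=0.524, cv=0.0, days=(7,),
        )
        obs, _ = simulate_flux_series(cfg, seed=1)
        pl = [o for o in obs if o.treatment == "PL"][0]
        assert pl.f_net == pytest.approx(6.0)
        assert pl.r_net == pytest.approx((2 * 0.0108 + 4 * 0.524) / 6.0)

    def test_truth_components_close_exactly(self):
        _, truth = simulate_flux_series(FluxConfig(), seed=2)
        c = truth.components
        np.testing.assert_allclose(c["litter"] + c["peat"], c["f_net"], rtol=1e-12)
        assert (c["litter"] >= 0).all() and (c["peat"] >= 0).all()

    def test_pulse_raises_pl_peat_component_above_baseline(self):
        cfg = FluxConfig()
        _, truth = simulate_flux_series(cfg, seed=3)
        c = truth.components
        near_peak = c[(c["treatment"] == "PL") & (c["day"] == 5)]
        assert (near_peak["peat"] > cfg.baseline).all()

    def test_deterministic_and_seed_sensitive(self):
        a, _ = simulate_flux_series(FluxConfig(), seed=4)
        b, _ = simulate_flux_series(FluxConfig(), seed=4)
        c, _ = simulate_flux_series(FluxConfig(), seed=5)
        assert a == b
        assert a != c

    def test_ill_posed_ratios_rejected(self):
        with pytest.raises(ValueError):
            simulate_flux_series(FluxConfig(r_litter=0.0108, r_soil=0.0108), seed=1)
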