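"""Isotopologue core: filtering, clustering, correction, enrichment, calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from siampeat import (
    DetectionSummary,
    classify_labeled,
    cluster_isotopologues,
    estimate_enrichment,
    estimate_n_carbon,
    expected_envelope,
    filter_features,
    natural_abundance_correct,
    summarize_detection,
    total_atom_percent,
)
from siampeat.constants import C13_MASS_DIFF
from siampeat.isotopologue import (
    IsotopologueCluster,
    cluster_abundance_matrix,
    correction_matrix,
    estimate_n_carbon_natural,
    round_half_up,
)
from siampeat.synth import multinomial_envelope
from siampeat.tables import FeatureRecord, FeatureTable

from conftest import classification_confusion


def make_table(rows, sample_ids=("s1",)):
    """rows: (mass, rt, snr, intensities...)"""
    mass = [r[0] for r in rows]
    rt = [r[1] for r in rows]
    snr = [r[2] for r in rows]
    inten = np.array([r[3:] for r in rows], dtype=float)
    return FeatureTable.from_arrays(mass, rt, snr, inten, list(sample_ids))


def make_cluster(envelope, n_carbon=None, base_mass=300.0, sample="s1"):
    """Build a cluster carrying the given envelope as intensities."""
    members = []
    for k, v in enumerate(envelope):
        if v <= 0:
            continue
        rec = FeatureRecord(
            feature_id=f"MW_{base_mass + k * C13_MASS_DIFF:.5f}@RT_10.000",
            neutral_mass=base_mass + k * C13_MASS_DIFF,
            rt=10.0,
            snr=50.0,
            intensities={sample: float(v)},
        )
        members.append((k, rec))
    return IsotopologueCluster("c0", members[0][1], members)


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------
class TestFilterFeatures:
    def test_mass_bounds_inclusive(self):
        t = make_table([(99.9, 5, 10, 3e6), (100.0, 5, 10, 3e6), (1200.0, 6, 10, 3e6),
                        (1200.1, 6, 10, 3e6)])
        out = filter_features(t)
        assert out.df["neutral_mass"].tolist() == [100.0, 1200.0]

    def test_intensity_and_snr_gates(self):
        t = make_table(
            [(200, 5, 10, 1.9e6), (200.5, 5, 10, 2e6), (201, 5, 3.0, 3e6),
             (201.5, 5, 3.01, 3e6)]
        )
        out = filter_features(t)
        assert out.df["neutral_mass"].tolist() == [200.5, 201.5]

    def test_identity_when_all_pass(self, default_studies):
        f = default_studies[0]["filtered"]
        again = filter_features(f)
        pd.testing.assert_frame_equal(f.df, again.df)

    def test_matches_brute_force_row_scan(self, default_studies):
        table = default_studies[0]["table"]
        out = filter_features(table)
        expected = []
        for rec in table.records():
            peak = max(rec.intensities.values())
            if 100 <= rec.neutral_mass <= 1200 and peak >= 2e6 and rec.snr > 3:
                expected.append(rec.feature_id)
        assert out.feature_ids == expected

    def test_row_order_invariance(self, default_studies):
        table = default_studies[0]["table"]
        shuffled = FeatureTable(
            table.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        a = set(filter_features(table).feature_ids)
        b = set(filter_features(shuffled).feature_ids)
        assert a == b

    def test_empty_table_passes_through(self):
        t = make_table([(200, 5, 10, 3e6)])
        empty = FeatureTable(t.df.iloc[0:0])
        assert len(filter_features(empty)) == 0

    def test_negative_threshold_rejected(self):
        t = make_table([(200, 5, 10, 3e6)])
        with pytest.raises(ValueError):
            filter_features(t, min_mass=-1)


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------
class TestClusterIsotopologues:
    def test_exact_heavy_shift_groups(self):
        t = make_table([(300.0, 10.0, 50, 1e7), (300.0 + C13_MASS_DIFF, 10.0, 50, 5e6)])
        clusters = cluster_isotopologues(t)
        assert len(clusters) == 1
        assert [k for k, _ in clusters[0].members] == [0, 1]

    def test_non_integer_shift_stays_separate(self):
        t = make_table([(300.0, 10.0, 50, 1e7), (300.5, 10.0, 50, 5e6)])
        assert len(cluster_isotopologues(t)) == 2

    def test_rt_gate(self):
        t = make_table([(300.0, 10.0, 50, 1e7), (300.0 + C13_MASS_DIFF, 10.5, 50, 5e6)])
        assert len(cluster_isotopologues(t, rt_tol=0.2)) == 2

    def test_each_feature_in_exactly_one_cluster(self, default_studies):
        st_ = default_studies[0]
        clusters = st_["clusters"]
        seen = [rec.feature_id for c in clusters for _, rec in c.members]
        assert sorted(seen) == sorted(st_["filtered"].feature_ids)

    def test_ground_truth_recovery_at_default_noise(self, default_studies):
        """>= 99% of non-noise features land in their species' main cluster."""
        ok = tot = 0
        for st_ in default_studies:
            fmap = st_["truth"].feature_map.set_index("feature_id")
            assign = {
                rec.feature_id: c.cluster_id
                for c in st_["clusters"]
                for _, rec in c.members
            }
            df = pd.DataFrame({"fid": st_["filtered"].feature_ids})
            df["sp"] = [fmap.loc[f, "species_id"] for f in df["fid"]]
            df["clu"] = [assign[f] for f in df["fid"]]
            sig = df[df["sp"] != ""]
            for _, grp in sig.groupby("sp"):
                main = grp["clu"].value_counts().idxmax()
                ok += (grp["clu"] == main).sum()
                tot += len(grp)
        assert ok / tot >= 0.99

    def test_invariant_to_sample_column_order(self, default_studies):
        table = default_studies[0]["filtered"]
        cols = table.sample_ids[::-1]
        reordered = FeatureTable(
            table.df[["feature_id", "neutral_mass", "rt_min", "snr"] + cols]
        )
        a = [[r.feature_id for _, r in c.members] for c in cluster_isotopologues(table)]
        b = [[r.feature_id for _, r in c.members] for c in cluster_isotopologues(reordered)]
        assert a == b


# ----------------------------------------------------------------------
# natural-abundance correction
# ----------------------------------------------------------------------
def forward_convolve(f_corr, n_carbon, p_nat):
    """Oracle: molecule with j tracer atoms shows j + Binomial(nC - j, p_nat)."""
    from scipy.stats import binom

    out = np.zeros(n_carbon + 1)
    for j, w in enumerate(f_corr):
        rem = n_carbon - j
        for i in range(rem + 1):
            out[j + i] += w * binom.pmf(i, rem, p_nat)
    return out


class TestNaturalAbundanceCorrection:
    def test_pure_natural_envelope_corrects_to_delta(self):
        f_obs = expected_envelope(2, 0.0107)
        f_corr = natural_abundance_correct(f_obs, 2)
        np.testing.assert_allclose(f_corr, [1.0, 0.0, 0.0], atol=1e-8)

    def test_zero_p_nat_is_identity(self):
        f_obs = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(
            natural_abundance_correct(f_obs, 4, p_nat=0.0),
            [0.5, 0.3, 0.2, 0.0, 0.0],
        )

    def test_correction_matrix_column_stochastic(self):
        C = correction_matrix(12)
        np.testing.assert_allclose(C.sum(axis=0), 1.0, atol=1e-12)
        assert (C >= 0).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n_carbon=st.integers(1, 20),
        weights=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=21),
    )
    def test_round_trip_recovers_input(self, n_carbon, weights):
        """Forward-convolve any tracer distribution, correct, recover it."""
        w = np.zeros(n_carbon + 1)
        vals = np.asarray(weights[: n_carbon + 1])
        if vals.sum() <= 0:
            vals = np.ones_like(vals)
        w[: len(vals)] = vals / vals.sum()
        f_obs = forward_convolve(w, n_carbon, 0.0107)
        f_corr = natural_abundance_correct(f_obs, n_carbon)
        np.testing.assert_allclose(f_corr, w, atol=1e-6)

    def test_oversized_envelope_rejected(self):
        with pytest.raises(ValueError):
            natural_abundance_correct(np.array([0.5, 0.3, 0.2]), 1)

    def test_inconsistent_carbon_count_rejected(self):
        with pytest.raises(ValueError):
            natural_abundance_correct(np.array([0.7, 0.3]), 0)


# ----------------------------------------------------------------------
# carbon-count estimation
# ----------------------------------------------------------------------
class TestEstimateNCarbon:
    def test_glucose_like_noiseless_recovers_six(self):
        env = expected_envelope(6, 0.524)
        cluster = make_cluster(env, base_mass=180.063)
        assert estimate_n_carbon(cluster, 180.063) == 6

    def test_sub_carbon_mass_rejected(self):
        cluster = make_cluster(expected_envelope(1, 0.5), base_mass=11.0)
        with pytest.raises(ValueError):
            estimate_n_carbon(cluster, 11.0)

    def test_recovery_sweep_noiseless(self):
        """Full-support noiseless envelopes recover nC for every nC <= 40."""
        rng = np.random.default_rng(17)
        hits = total = 0
        for nc in range(2, 41):
            mass = nc * float(rng.uniform(13.0, 28.0))
            env = expected_envelope(nc, 0.524)
            cluster = make_cluster(env, base_mass=mass)
            hits += estimate_n_carbon(cluster, mass) == nc
            total += 1
        assert hits / total >= 0.90

    def test_natural_envelope_estimator_on_controls(self, noiseless_study, unlabeled_ids):
        """nC from the unlabeled-control envelope is exact on noiseless data."""
        truth = noiseless_study["truth"]
        fmap = truth.feature_map.set_index("feature_id")
        spmap = truth.species.set_index("species_id")
        checked = 0
        for c in noiseless_study["clusters"]:
            sp = fmap.loc[c.base_feature.feature_id, "species_id"]
            if sp == "":
                continue
            nc = estimate_n_carbon_natural(
                c, c.base_feature.neutral_mass, unlabeled_ids
            )
            if nc is None:
                continue
            assert nc == spmap.loc[sp, "n_carbon"]
            checked += 1
        assert checked > 20


# ----------------------------------------------------------------------
# enrichment
# ----------------------------------------------------------------------
class TestEnrichment:
    def test_binomial_mean(self):
        assert estimate_enrichment(expected_envelope(6, 0.5), 6) == pytest.approx(50.0)

    def test_unlabeled_is_zero(self):
        f = np.zeros(8)
        f[0] = 1.0
        assert estimate_enrichment(f, 7) == 0.0

    def test_zero_carbon_rejected(self):
        with pytest.raises(ValueError):
            estimate_enrichment(np.array([1.0]), 0)

    def test_total_atom_percent_inverts_correction(self):
        """Correcting a 52.4 at-% envelope and converting back to the total
        scale recovers 52.4 exactly (the tracer/total atom-percent map)."""
        for nc in (5, 12, 30):
            f_obs = expected_envelope(nc, 0.524)
            f_corr = natural_abundance_correct(f_obs, nc)
            excess = estimate_enrichment(f_corr, nc)
            assert total_atom_percent(excess) == pytest.approx(52.4, abs=1e-6)

    def test_mean_recovery_at_litter_enrichment(self):
        """Sampled envelopes at 52.4 at-%: mean recovered total within 0.5."""
        rng = np.random.default_rng(123)
        ests = []
        for _ in range(200):
            nc = int(rng.integers(5, 41))
            counts = multinomial_envelope(nc, 0.524, 10_000, rng)
            f_corr = natural_abundance_correct(counts, nc)
            ests.append(total_atom_percent(estimate_enrichment(f_corr, nc)))
        assert np.mean(ests) == pytest.approx(52.4, abs=0.5)


# ----------------------------------------------------------------------
# label classification
# ----------------------------------------------------------------------
class TestClassifyLabeled:
    def test_pure_natural_is_unlabeled(self):
        cluster = make_cluster(expected_envelope(8, 0.0107), base_mass=200.0)
        cluster.f_corr = natural_abundance_correct(cluster.observed_envelope(), 8)
        call, ratio = classify_labeled(cluster)
        assert not call and ratio == pytest.approx(0.0, abs=1e-6)

    def test_litter_enrichment_ten_carbons_saturates(self):
        """At 52.4 at-% and nC = 10 essentially every molecule carries
        tracer: ratio ~ 1 - (1 - p_tracer)^10."""
        cluster = make_cluster(expected_envelope(10, 0.524), base_mass=240.0)
        cluster.f_corr = natural_abundance_correct(cluster.observed_envelope(), 10)
        call, ratio = classify_labeled(cluster)
        p_tracer = (0.524 - 0.0107) / (1 - 0.0107)
        assert call
        assert ratio == pytest.approx(1 - (1 - p_tracer) ** 10, abs=1e-3)
        assert ratio == pytest.approx(1 - (1 - 0.524) ** 10, abs=1e-3)

    def test_single_member_cluster_never_labeled(self):
        cluster = make_cluster([1.0], base_mass=200.0)
        cluster.f_corr = np.array([0.5, 0.5])  # even with heavy mass present
        call, _ = classify_labeled(cluster)
        assert not call

    def test_sensitivity_and_specificity_on_default_tables(
        self, default_studies, labeled_ids
    ):
        tp, fp, tn, fn = classification_confusion(default_studies, labeled_ids)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        assert sens >= 0.95
        assert spec >= 0.95

    def test_noiseless_calls_match_ground_truth_exactly(self, noiseless_study):
        truth = noiseless_study["truth"]
        fmap = truth.feature_map.set_index("feature_id")
        for c in noiseless_study["clusters"]:
            sp = fmap.loc[c.base_feature.feature_id, "species_id"]
            if sp == "":
                continue
            assert c.label_call == truth.labeled[sp]


# ----------------------------------------------------------------------
# detection summary
# ----------------------------------------------------------------------
class TestDetectionSummary:
    @pytest.mark.parametrize(
        "total,count,pct",
        [
            (320, 164, 51.25),
            (45, 18, 40.0),
            (320, 103, 32.19),
            (320, 61, 19.06),
            (320, 92, 28.75),
            (320, 152, 47.5),
        ],
    )
    def test_printed_percentages(self, total, count, pct):
        s = DetectionSummary.from_counts(total, count)
        assert s.pct_labeled == pct

    def test_rounding_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(19.0625, 2) == 19.06
        assert round_half_up(32.1875, 2) == 32.19

    def test_category_pass_through(self):
        s = DetectionSummary.from_counts(320, 164, {"annotated": 103})
        assert s.categories["annotated"] == (103, 32.19)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            DetectionSummary.from_counts(0, 0)
        with pytest.raises(ValueError):
            DetectionSummary.from_counts(10, 11)

    def test_summarize_over_clusters(self):
        clusters = []
        for i, call in enumerate([True, False, True, False]):
            c = make_cluster([1.0], base_mass=200.0 + i)
            c.label_call = call
            clusters.append(c)
        s = summarize_detection(clusters)
        assert s.n_features_total == 4
        assert s.n_labeled == 2
        assert s.pct_labeled == 50.0


# ----------------------------------------------------------------------
# compound-level aggregation
# ----------------------------------------------------------------------
class TestCompoundMatrix:
    def test_sums_members_and_equalizes_label_states(self, noiseless_study, design):
        """At compound level, labeled and unlabeled samples of the same
        material have identical abundances on noiseless data."""
        ids = [s.sample_id for s in design]
        mat = cluster_abundance_matrix(noiseless_study["clusters"], ids)
        fmap = noiseless_study["truth"].feature_map.set_index("feature_id")
        checked = 0
        for fid in mat.index:
            sp = fmap.loc[fid, "species_id"]
            if sp == "" or not noiseless_study["truth"].labeled[sp]:
                continue
            for tp in ("T1", "T2", "T3"):
                lab = mat.loc[fid, f"PL-{tp}-lab-1"]
                unl = mat.loc[fid, f"PL-{tp}-unl-1"]
                if lab > 0:
                    # envelope truncation loses a sliver of mass at most
                    assert unl == pytest.approx(lab, rel=0.05)
                    checked += 1
        assert checked > 10
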