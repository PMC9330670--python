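"""Synthetic cohort generator: inventory, planted effects, missingness,
clusters and waveform round trips."""

import numpy as np
import pandas as pd
import pytest

import erpstrat as es
from erpstrat import erp, synth
from erpstrat.groupstats import cohens_d


class TestInventory:
    def test_layout(self, inventory):
        assert len(inventory) == 56
        contrasts = ("face_noise", "direct_averted", "toward_away")
        assert all(not n.endswith(contrasts) for n in inventory[:36])
        assert all(n.endswith(contrasts) for n in inventory[36:54])
        assert inventory[-2:] == ["gender", "age"]
        assert len(set(inventory)) == 56

    def test_helper_views(self, inventory):
        assert synth.averaged_feature_names() == inventory[:36]
        assert synth.contrast_feature_names() == inventory[36:54]
        assert synth.erp_feature_names() == inventory[:54]


class TestFeatureTable:
    def test_seeded_determinism_is_bitwise(self):
        cfg = es.GeneratorConfig(seed=42)
        a = es.generate_feature_table(cfg).feature_table
        b = es.generate_feature_table(es.GeneratorConfig(seed=42)).feature_table
        pd.testing.assert_frame_equal(a, b)

    def test_null_config_has_no_group_differences(self, null_cohort, inventory):
        tab = null_cohort.feature_table
        se3 = 3.0 * np.sqrt(2.0 / 60.0) * np.sqrt(2.0)  # contrast columns widest
        for col in inventory[:54]:
            means = tab.groupby("group")[col].mean()
            assert means.max() - means.min() < se3 * 2.5

    def test_planted_effect_recovered_at_large_n(self):
        # standardized group difference of 0.74 on the toward-away latency
        # contrast, recovered within Monte-Carlo bands at n = 2000/group
        cfg = es.GeneratorConfig(
            n_per_group={"TL": 2000, "EL-noASD": 2000, "EL-ASD": 2000},
            effects=[es.EffectSpec("P1_lat_toward_away", "EL-ASD", 0.74)],
            outcome_beta={}, seed=9)
        tab = es.generate_feature_table(cfg).feature_table
        col = tab["P1_lat_toward_away"]
        d = cohens_d(col[tab["group"] == "EL-ASD"], col[tab["group"] == "TL"])
        assert 0.67 <= d <= 0.81

    def test_differential_features_are_exact_parent_differences(self, study_cohort):
        tab = study_cohort.feature_table
        for contrast, (a, b) in erp.CONTRAST_PARENTS.items():
            for comp in synth.COMPONENTS:
                for meas in synth.MEASURES:
                    lhs = tab[f"{comp}_{meas}_{contrast}"]
                    rhs = tab[f"{comp}_{meas}_{a}"] - tab[f"{comp}_{meas}_{b}"]
                    np.testing.assert_array_equal(lhs.to_numpy(), rhs.to_numpy())

    def test_null_outcome_model_uncorrelated(self, null_cohort, inventory):
        tab = null_cohort.feature_table
        y = tab["outcome"].to_numpy()
        for col in inventory[:54]:
            r = np.corrcoef(tab[col], y)[0, 1]
            assert abs(r) < 4.0 / np.sqrt(len(tab))

    def test_unknown_effect_feature_rejected(self):
        with pytest.raises(synth.ConfigurationError):
            es.EffectSpec("P9_amp_FD", "TL", 0.5)
        with pytest.raises(synth.ConfigurationError):
            es.GeneratorConfig(outcome_beta={"nope": 1.0}).validate()


class TestMissingness:
    def test_zero_rate_leaves_table_unchanged(self, study_cohort):
        out = es.inject_missingness(study_cohort, 0.0)
        pd.testing.assert_frame_equal(out.feature_table, study_cohort.feature_table)

    def test_mcar_rate_within_binomial_band(self):
        cfg = es.GeneratorConfig(n_per_group={"TL": 100, "EL-noASD": 100,
                                              "EL-ASD": 100},
                                 effects=[], seed=4)
        cohort = es.generate_feature_table(cfg)
        out = es.inject_missingness(cohort, 0.10, "MCAR", seed=5)
        frac = out.feature_table[synth.averaged_feature_names()].isna().to_numpy().mean()
        assert 0.08 <= frac <= 0.12  # 10800 cells

    def test_mar_on_age_depends_on_age_not_values(self):
        cfg = es.GeneratorConfig(n_per_group={"TL": 400, "EL-noASD": 400,
                                              "EL-ASD": 400},
                                 effects=[], seed=6)
        cohort = es.generate_feature_table(cfg)
        base = cohort.feature_table["P1_amp_FD"].to_numpy().copy()
        out = es.inject_missingness(cohort, 0.25, "MAR-on-age", seed=7)
        tab = out.feature_table
        miss = tab["P1_amp_FD"].isna().to_numpy().astype(float)
        n = len(tab)
        r_age = np.corrcoef(miss, tab["age"])[0, 1]
        r_val = np.corrcoef(miss, base)[0, 1]
        assert r_age > 0.15           # masking driven by age
        assert abs(r_val) < 4.0 / np.sqrt(n)  # not by the value itself
        assert abs(miss.mean() - 0.25) < 0.03

    def test_rate_one_rejected(self, study_cohort):
        with pytest.raises(ValueError):
            es.inject_missingness(study_cohort, 1.0)


class TestClusters:
    def test_single_component(self):
        cfg = es.GeneratorConfig(n_per_group={"TL": 0, "EL-noASD": 20, "EL-ASD": 0},
                                 effects=[], cluster_spec=synth.ClusterSpec(1),
                                 seed=1)
        cohort = es.plant_clusters(cfg)
        assert set(cohort.truth["cluster_assignments"]) == {0}

    def test_six_sd_separation_trivially_recoverable(self):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score

        cfg = es.GeneratorConfig(n_per_group={"TL": 0, "EL-noASD": 60, "EL-ASD": 0},
                                 effects=[],
                                 cluster_spec=synth.ClusterSpec(2, separation=6.0),
                                 seed=3)
        cohort = es.plant_clusters(cfg)
        X = cohort.feature_table[synth.averaged_feature_names()].to_numpy()
        truth = np.array(cohort.truth["cluster_assignments"])
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        assert adjusted_rand_score(truth, km.labels_) == 1.0

    def test_more_clusters_than_subjects_rejected(self):
        cfg = es.GeneratorConfig(n_per_group={"TL": 0, "EL-noASD": 3, "EL-ASD": 0},
                                 effects=[], cluster_spec=synth.ClusterSpec(5),
                                 seed=1)
        with pytest.raises(synth.ConfigurationError):
            es.plant_clusters(cfg)

    def test_mixing_weights_validated(self):
        with pytest.raises(synth.ConfigurationError):
            synth.ClusterSpec(2, weights=(0.5, 0.4))


def _narrow_components():
    # well-separated narrow bumps so component tails do not interact
    return {
        "P1": synth.ComponentParams(110.0, 8.0, 22.0, 8.0, 2.0),
        "N290": synth.ComponentParams(290.0, -10.0, 30.0, 8.0, 2.5),
        "P400": synth.ComponentParams(480.0, 7.0, 38.0, 8.0, 2.0),
    }


class TestWaveforms:
    def test_noiseless_round_trip_matches_planted_parameters(self):
        cfg = es.GeneratorConfig(n_per_group={"TL": 2, "EL-noASD": 0, "EL-ASD": 0},
                                 effects=[], noise_sd_uv=0.0, n_epochs=2,
                                 component_params=_narrow_components(), seed=8)
        cohort = es.generate_waveforms(cfg)
        params = _narrow_components()
        step = 1000.0 / cfg.sample_rate
        for eset in cohort.epochs:
            avg = erp.average_epochs(eset)
            for comp, win in erp.default_windows().items():
                pk = erp.detect_peak(avg, eset.times, win, eset.ot_channels)
                truth = cohort.truth["waveform_params"][(eset.subject,
                                                         eset.condition, comp)]
                assert pk.flag == erp.FLAG_OK
                # latency exact to one sample of the acquisition grid
                assert abs(pk.latency - truth["latency"]) <= step
                # amplitude exact up to evaluating the planted bumps on the
                # grid (the peak sample sits within half a step of the true
                # latency)
                expected = sum(
                    cohort.truth["waveform_params"][(eset.subject,
                                                     eset.condition, c)]["amplitude"]
                    * np.exp(-0.5 * ((pk.latency
                                      - cohort.truth["waveform_params"][
                                          (eset.subject, eset.condition, c)]["latency"])
                                     / params[c].width_ms) ** 2)
                    for c in params)
                assert pk.amplitude == pytest.approx(expected, abs=1e-3)

    def test_amplitude_scaling_is_linear(self):
        base = _narrow_components()
        doubled = {k: synth.ComponentParams(v.latency_ms, 2 * v.amplitude_uv,
                                            v.width_ms, 1e-9, 1e-12)
                   for k, v in base.items()}
        frozen = {k: synth.ComponentParams(v.latency_ms, v.amplitude_uv,
                                           v.width_ms, 1e-9, 1e-12)
                  for k, v in base.items()}
        out = {}
        for tag, params in (("x1", frozen), ("x2", doubled)):
            cfg = es.GeneratorConfig(n_per_group={"TL": 1, "EL-noASD": 0,
                                                  "EL-ASD": 0},
                                     effects=[], noise_sd_uv=0.0, n_epochs=1,
                                     component_params=params, seed=3)
            cohort = es.generate_waveforms(cfg)
            eset = cohort.epochs[0]
            avg = erp.average_epochs(eset)
            pk = erp.detect_peak(avg, eset.times, erp.default_windows()["P1"],
                                 eset.ot_channels)
            out[tag] = pk.amplitude
        assert out["x2"] == pytest.approx(2.0 * out["x1"], rel=1e-6)

    def test_overlapping_components_rejected(self):
        params = {"P1": synth.ComponentParams(120.0, 8.0, 80.0),
                  "N290": synth.ComponentParams(150.0, -10.0, 80.0),
                  "P400": synth.ComponentParams(450.0, 7.0, 70.0)}
        with pytest.raises(synth.ConfigurationError):
            es.GeneratorConfig(component_params=params).validate()


def test_cohort_summary_reports_el_percentages(study_cohort):
    s = synth.cohort_summary(study_cohort.feature_table)
    assert s.loc["EL-ASD", "n"] == 33
    assert s.loc["EL-noASD", "n"] == 115
    assert round(s.loc["EL-ASD", "percent_of_EL"], 1) == 22.3
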