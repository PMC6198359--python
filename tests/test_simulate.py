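import numpy as np
import pandas as pd
import pytest

import spermclock as sc
from spermclock import InputError, SimulationConfig, ValidationError


def noise_free(**kw):
    base = dict(probe_noise_sd=0.0, probe_offset_sd=0.0, bio_age_sd=0.0,
                n_background_probes=0, include_panel=False)
    base.update(kw)
    return SimulationConfig(**base)


class TestCohortGeneration:
    def test_noise_free_region_means_follow_the_linear_law_exactly(self):
        config = noise_free(n_samples=30, n_signal_regions=1, n_hyper=0,
                            slope_magnitude=(0.004, 0.004), seed=2)
        cohort = sc.simulate_cohort(config)
        feats = sc.build_features(cohort.betas, cohort.manifest, cohort.regions)
        ages = cohort.truth.effective_age
        means = feats.values.iloc[:, 0]
        # slope is exactly -0.004/yr: a 20-year age gap moves the mean by -0.08
        i, j = ages.idxmin(), ages.idxmax()
        gap = ages[j] - ages[i]
        assert means[j] - means[i] == pytest.approx(-0.004 * gap, abs=1e-12)

    def test_noise_free_betas_equal_analytic_expectation(self):
        config = noise_free(n_samples=20, n_signal_regions=6, n_hyper=2, seed=3)
        cohort = sc.simulate_cohort(config)
        feats = sc.build_features(cohort.betas, cohort.manifest, cohort.regions)
        expected = cohort.truth.expected_region_means()
        pd.testing.assert_frame_equal(feats.values[expected.columns], expected,
                                      check_names=False, atol=1e-12, rtol=0)

    def test_same_seed_is_byte_identical(self):
        a = sc.simulate_cohort(SimulationConfig(n_samples=15, n_signal_regions=8,
                                                n_background_probes=40, seed=9))
        b = sc.simulate_cohort(SimulationConfig(n_samples=15, n_signal_regions=8,
                                                n_background_probes=40, seed=9))
        assert np.array_equal(a.betas.values, b.betas.values)
        assert a.betas.probe_ids == b.betas.probe_ids
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)

    def test_betas_always_within_unit_interval(self):
        config = SimulationConfig(n_samples=25, n_signal_regions=10,
                                  probe_noise_sd=0.5, n_background_probes=100,
                                  seed=4)
        cohort = sc.simulate_cohort(config)
        assert np.nanmin(cohort.betas.values) >= 0.0
        assert np.nanmax(cohort.betas.values) <= 1.0

    def test_directional_split_and_slope_signs(self):
        cohort = sc.simulate_cohort(SimulationConfig(
            n_samples=10, n_background_probes=0, seed=5))
        truth = cohort.truth.region_truth
        assert (truth["direction"] == "hyper").sum() == 8
        assert (truth["direction"] == "hypo").sum() == 140
        assert (truth.loc[truth["direction"] == "hypo", "slope"] < 0).all()
        assert (truth.loc[truth["direction"] == "hyper", "slope"] > 0).all()

    def test_ages_within_configured_range(self):
        cohort = sc.simulate_cohort(SimulationConfig(
            n_samples=200, n_signal_regions=2, n_hyper=1,
            n_background_probes=0, seed=6))
        assert cohort.truth.ages.between(20.0, 45.0).all()

    def test_smoking_inflates_effective_age(self):
        config = SimulationConfig(n_samples=50, n_signal_regions=3, n_hyper=1,
                                  n_background_probes=0, smoker_fraction=0.4,
                                  smoking_effect_pct=3.0, bio_age_sd=0.0, seed=7)
        cohort = sc.simulate_cohort(config)
        smokers = cohort.truth.smoking_status == "smoker"
        ratio = cohort.truth.effective_age[smokers] / cohort.truth.ages[smokers]
        assert np.allclose(ratio, 1.03)
        never = cohort.truth.smoking_status == "never"
        assert np.allclose(cohort.truth.effective_age[never],
                           cohort.truth.ages[never])

    def test_slope_recovery_by_ols_across_seeds(self):
        """Empirical region-mean slopes match configured slopes within 20%."""
        hits = total = 0
        for seed in range(20):
            config = SimulationConfig(n_samples=200, n_background_probes=0,
                                      include_panel=False, seed=400 + seed)
            cohort = sc.simulate_cohort(config)
            feats = sc.build_features(cohort.betas, cohort.manifest, cohort.regions)
            ages = cohort.truth.ages.to_numpy()
            ac = ages - ages.mean()
            denom = (ac ** 2).sum()
            truth = cohort.truth.region_truth.set_index("name")["slope"]
            for region in feats.region_names:
                y = feats.values[region].to_numpy()
                est = float(ac @ (y - y.mean()) / denom)
                total += 1
                hits += int(abs(est - truth[region]) <= 0.2 * abs(truth[region]))
        assert hits / total >= 0.90

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_signal_regions=5, n_hyper=8).validate()
        with pytest.raises(ValidationError):
            SimulationConfig(noise_model="bogus").validate()


class TestReplicates:
    def test_zero_noise_replicates_identical(self, small_cohort):
        betas, meta = sc.simulate_replicates(small_cohort, n_individuals=3,
                                             n_replicates=4, replicate_noise_sd=0.0)
        groups = meta.groupby("replicate_group")["sample_id"]
        for _, ids in groups:
            block = betas.subset_samples(list(ids)).values
            assert (block == block[:, [0]]).all()

    def test_default_design_has_60_rows(self, small_cohort):
        betas, meta = sc.simulate_replicates(small_cohort)
        assert len(meta) == 60
        assert betas.n_samples == 60
        assert meta["replicate_group"].nunique() == 10
        assert meta.groupby("replicate_group").size().eq(6).all()

    def test_downstream_sd_increases_with_replicate_noise(self, small_cohort,
                                                          small_features):
        model = sc.fit_elastic_net(small_features.values,
                                   small_cohort.truth.ages, lam=0.05)
        summary_sds = []
        for sd in (0.005, 0.02, 0.08):
            betas, meta = sc.simulate_replicates(small_cohort, replicate_noise_sd=sd,
                                                 seed=77)
            feats = sc.build_features(betas, small_cohort.manifest,
                                      small_cohort.regions)
            pred = sc.predict_age(model, feats.values)
            groups = meta.set_index("sample_id")["replicate_group"]
            rep = sc.replicate_precision(pred, groups.loc[pred.index])
            summary_sds.append(rep.summary_sd)
        assert summary_sds[0] > 0.0
        assert summary_sds[0] < summary_sds[1] < summary_sds[2]

    def test_too_few_replicates_rejected(self, small_cohort):
        with pytest.raises(InputError):
            sc.simulate_replicates(small_cohort, n_replicates=1)


class TestWriters:
    def test_written_cohort_reloads_identically(self, tmp_path, small_cohort):
        paths = sc.write_cohort(small_cohort, tmp_path / "cohort")
        betas = sc.load_beta_matrix(paths["betas"])
        assert np.array_equal(betas.values, small_cohort.betas.values,
                              equal_nan=True)
        manifest = sc.load_probe_manifest(paths["manifest"])
        pd.testing.assert_frame_equal(manifest, small_cohort.manifest)
        regions_csv = sc.parse_region_table(paths["regions_csv"], dialect="table1")
        regions_bed = sc.parse_region_table(paths["regions_bed"], dialect="bed")
        assert regions_csv.regions == small_cohort.regions.regions
        assert regions_bed.regions == small_cohort.regions.regions
        meta = sc.load_sample_metadata(paths["metadata"])
        assert list(meta["sample_id"]) == small_cohort.betas.sample_ids
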