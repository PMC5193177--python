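"""Synthetic cohort generator: determinism, planted effects, roster."""

import numpy as np
import pytest

from gmpredict.cohort import classify_illness_course
from gmpredict.simulate import (
    EffectMap,
    SimulationError,
    SiteProfile,
    SyntheticConfig,
    config_from_yaml,
    config_to_yaml,
    five_center_roster,
    generate_cohort,
    generate_subject_map,
    preset_config,
    pseudo_brain,
    simulate_episode_history,
    sphere_region,
)


def clean_site(**kw):
    defaults = dict(intensity_offset=0.0, intensity_gain=1.0, noise_sd=0.0, psf_fwhm_mm=0.0)
    defaults.update(kw)
    return SiteProfile("s", **defaults)


class TestSubjectMaps:
    def test_identity_case_returns_baseline_exactly(self):
        config = SyntheticConfig(sites=(clean_site(),))
        gm = generate_subject_map(config, "s", "male", "continuous", subject_seed=0)
        np.testing.assert_array_equal(gm.values, config.baseline())

    def test_same_seed_reproduces_bitwise_different_seed_differs(self):
        config = SyntheticConfig(sites=(clean_site(noise_sd=0.05),))
        a = generate_subject_map(config, "s", "male", "continuous", subject_seed=42)
        b = generate_subject_map(config, "s", "male", "continuous", subject_seed=42)
        c = generate_subject_map(config, "s", "male", "continuous", subject_seed=43)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.any(a.values != c.values)

    def test_planted_sex_effect_is_additive_in_noise_units(self):
        """On noiseless volumes the male-female difference over the effect
        region equals effect_size * noise_sd exactly."""
        d, sd = 3.0, 0.05
        eff = EffectMap("sex", d, center_frac=(0.5, 0.5, 0.5), n_voxels=50)
        config = SyntheticConfig(
            sites=(clean_site(noise_sd=sd),),
            effects=(eff,),
            baseline_value=0.4,
        )
        male = generate_subject_map(config, "s", "male", "remitting", 0, add_noise=False)
        female = generate_subject_map(config, "s", "female", "remitting", 0, add_noise=False)
        region = eff.region(config.grid_shape)
        diff = male.values - female.values
        assert np.allclose(diff[region], d * sd)
        assert np.allclose(diff[~region], 0.0)

    def test_unknown_site_or_label_rejected(self):
        config = SyntheticConfig(sites=(clean_site(),))
        with pytest.raises(SimulationError):
            generate_subject_map(config, "nope", "male", "continuous", 0)
        with pytest.raises(SimulationError):
            generate_subject_map(config, "s", "other", "continuous", 0)
        with pytest.raises(SimulationError):
            generate_subject_map(config, "s", "male", "chronic", 0)

    def test_output_stays_within_probability_range(self):
        config = SyntheticConfig(
            sites=(clean_site(noise_sd=0.3, intensity_offset=0.2, psf_fwhm_mm=2.0),)
        )
        gm = generate_subject_map(config, "s", "male", "continuous", 7)
        assert gm.values.min() >= 0.0 and gm.values.max() <= 1.0


class TestCohortGeneration:
    def test_bookkeeping_counts(self):
        config = SyntheticConfig(
            sites=(clean_site(),),
            per_site_counts={("s", "male", "continuous"): 2, ("s", "female", "remitting"): 3},
        )
        maps, cohort = generate_cohort(config)
        assert len(maps) == len(cohort) == 5
        assert sum(s.sex == "male" for s in cohort) == 2
        assert sum(s.sex == "female" for s in cohort) == 3
        assert all(s.site == "s" for s in cohort)
        assert len({s.subject_id for s in cohort}) == 5

    def test_zero_counts_gives_empty_cohort(self):
        config = SyntheticConfig(sites=(clean_site(),), per_site_counts={})
        maps, cohort = generate_cohort(config)
        assert maps == [] and len(cohort) == 0

    def test_cohort_is_pure_function_of_config(self):
        config = preset_config("tiny", seed=5)
        maps_a, cohort_a = generate_cohort(config)
        maps_b, cohort_b = generate_cohort(config)
        assert cohort_a == cohort_b
        for a, b in zip(maps_a, maps_b):
            np.testing.assert_array_equal(a.values, b.values)

    def test_course_labels_round_trip_through_histories(self):
        _, cohort = generate_cohort(preset_config("tiny", seed=2))
        for s in cohort:
            assert classify_illness_course(s.history) == s.course_label


class TestRoster:
    def test_total_and_marginals(self):
        counts = five_center_roster()
        total = sum(counts.values())
        assert total == 389
        females = sum(v for (site, sex, c), v in counts.items() if sex == "female")
        assert females == 133
        continuous = sum(v for (s, x, c), v in counts.items() if c == "continuous")
        remitting = sum(v for (s, x, c), v in counts.items() if c == "remitting")
        assert (continuous, remitting) == (94, 118)
        males_outcome = sum(
            v for (s, sex, c), v in counts.items()
            if sex == "male" and c in ("continuous", "remitting")
        )
        assert males_outcome == 141

    def test_per_site_totals_and_sex_split(self):
        counts = five_center_roster()
        expected = {
            "london": (97, 61, 36),
            "utrecht": (67, 58, 9),
            "melbourne": (54, 37, 17),
            "santander": (107, 62, 45),
            "saopaulo": (64, 38, 26),
        }
        for site, (total, males, females) in expected.items():
            site_counts = {k: v for k, v in counts.items() if k[0] == site}
            assert sum(site_counts.values()) == total
            assert sum(v for (s, sex, c), v in site_counts.items() if sex == "male") == males
            assert sum(v for (s, sex, c), v in site_counts.items() if sex == "female") == females


class TestEpisodeSimulation:
    @pytest.mark.parametrize("course", ["continuous", "remitting", "excluded"])
    def test_round_trip_over_many_seeds(self, course):
        for seed in range(120):
            h = simulate_episode_history(course, follow_up_years=4.0, seed=seed)
            assert classify_illness_course(h) == course

    def test_continuous_has_no_long_remission(self):
        h = simulate_episode_history("continuous", 5.0, seed=1)
        assert all(d <= 183 for _, d in h.remissions)

    def test_excluded_has_both_long_remission_and_long_episode(self):
        h = simulate_episode_history("excluded", 5.0, seed=1)
        assert any(d >= 183 for _, d in h.remissions)
        assert any(d > 183 for _, d in h.episodes)

    def test_nonpositive_or_too_short_follow_up_rejected(self):
        with pytest.raises(SimulationError):
            simulate_episode_history("remitting", 0.0, seed=0)
        with pytest.raises(SimulationError):
            simulate_episode_history("remitting", 0.5, seed=0)


class TestEffectRecoverability:
    def test_in_region_difference_exceeds_out_of_region(self):
        """With effect size 2 the mean class difference inside the planted
        region dominates the difference elsewhere (20+ subjects/class)."""
        eff = EffectMap("course", 2.0, center_frac=(0.6, 0.55, 0.45), n_voxels=50)
        config = SyntheticConfig(
            sites=(clean_site(noise_sd=0.05),),
            per_site_counts={
                ("s", "male", "continuous"): 20,
                ("s", "male", "remitting"): 20,
            },
            effects=(eff,),
            seed=77,
        )
        maps, cohort = generate_cohort(config)
        vols = np.stack([m.values for m in maps])
        labels = np.array([s.course_label for s in cohort])
        diff = vols[labels == "continuous"].mean(axis=0) - vols[labels == "remitting"].mean(axis=0)
        region = eff.region(config.grid_shape, support=config.baseline() > 0)
        assert diff[region].mean() > np.abs(diff[~region]).mean() + 0.05


class TestTemplateAndRegions:
    def test_pseudo_brain_range_and_support(self):
        t = pseudo_brain((16, 16, 16))
        inside = t[t > 0]
        assert inside.min() >= 0.05 - 1e-12 and inside.max() <= 0.95 + 1e-12
        assert t[0, 0, 0] == 0.0  # corners outside the ellipsoid

    def test_sphere_region_has_requested_size(self):
        r = sphere_region((16, 16, 16), (0.5, 0.5, 0.5), 50)
        assert r.sum() == 50
        with pytest.raises(SimulationError):
            sphere_region((4, 4, 4), (0.5, 0.5, 0.5), 100)

    def test_config_yaml_round_trip(self, tmp_path):
        config = preset_config("tiny", seed=9)
        path = tmp_path / "sim.yaml"
        config_to_yaml(config, path)
        assert config_from_yaml(path) == config
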