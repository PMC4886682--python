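"""Generator tests: mixture sampling, the aggregation simulator, and the
event/image converters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pelletmix import (
    EmptyInputError,
    ImageSpec,
    MixtureGenParams,
    ParameterError,
    PlacementError,
    SimParams,
    SimParticle,
    particles_to_events,
    particles_to_sizes,
    render_channels,
    sample_mixture,
    simulate_germling_aggregation,
)


class TestSampleMixture:
    def test_degenerate_point_masses(self):
        gen = MixtureGenParams(p=0.5, mu1=1.0, mu2=1.0, sigma1=1e-9, sigma2=1e-9, n=4, seed=0)
        assert np.allclose(sample_mixture(gen).values, 1.0)

    @pytest.mark.parametrize("bad", [dict(p=1.0), dict(p=0.0), dict(sigma1=0.0), dict(n=0),
                                     dict(mu1=0.9, mu2=0.3)])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(p=0.5, mu1=0.3, mu2=0.9, sigma1=0.05, sigma2=0.05, n=100, seed=0)
        kw.update(bad)
        with pytest.raises(ParameterError):
            MixtureGenParams(**kw)

    def test_extreme_weight_mean_matches_analytic(self):
        # p=0.999: sample mean ~ analytic mixture mean within 3 standard errors
        gen = MixtureGenParams(p=0.999, mu1=0.3, mu2=0.9, sigma1=0.05, sigma2=0.05,
                               n=1000, seed=3)
        x = sample_mixture(gen).values
        mean = 0.999 * 0.3 + 0.001 * 0.9
        assert abs(x.mean() - mean) < 3 * x.std() / np.sqrt(x.size)

    def test_draws_positive_and_reproducible(self):
        gen = MixtureGenParams(p=0.3, mu1=0.1, mu2=0.5, sigma1=0.2, sigma2=0.2, n=500, seed=9)
        a = sample_mixture(gen).values
        b = sample_mixture(gen).values
        assert np.array_equal(a, b)
        assert (a > 0).all()

    def test_empirical_cdf_converges_to_mixture_cdf(self):
        gen = MixtureGenParams(p=0.4, mu1=0.35, mu2=0.7, sigma1=0.08, sigma2=0.08,
                               n=100_000, seed=1)
        x = sample_mixture(gen).values

        def cdf(v):
            raw = 0.4 * stats.norm.cdf(v, 0.35, 0.08) + 0.6 * stats.norm.cdf(v, 0.7, 0.08)
            trunc = 0.4 * stats.norm.cdf(0, 0.35, 0.08) + 0.6 * stats.norm.cdf(0, 0.7, 0.08)
            return (raw - trunc) / (1 - trunc)  # positives-only truncation

        d = stats.kstest(x, cdf).statistic
        assert d < 0.01


class TestSimulator:
    def test_zero_adhesion_keeps_every_spore_separate(self):
        parts = simulate_germling_aggregation(
            SimParams(n_spores=500, adhesion=0.0, t_end=12, seed=1)
        )
        assert len(parts) == 500
        assert all(p.n_founders == 1 for p in parts)

    def test_no_germination_means_no_aggregation(self):
        # spores that never germinate within the run cannot join aggregates
        parts = simulate_germling_aggregation(
            SimParams(n_spores=300, germ_mean=100.0, germ_sd=0.1, adhesion=1.0,
                      collision_rate=10.0, t_end=12, seed=2)
        )
        assert len(parts) == 300
        assert not any(p.germinated for p in parts)

    def test_heavy_aggregation_yields_dual_particles(self):
        # calibration run: near-complete coalescence of a mixed inoculum
        parts = simulate_germling_aggregation(
            SimParams(n_spores=1000, adhesion=1.0, collision_rate=10.0, seed=3)
        )
        multi = [p for p in parts if p.n_founders > 1]
        assert len(multi) / len(parts) > 0.9
        dual = sum(1 for p in multi if p.is_dual)
        assert dual / len(multi) > 0.99

    @given(seed=st.integers(0, 50), adhesion=st.sampled_from([0.0, 0.3, 1.0]),
           frac_green=st.sampled_from([0.0, 0.3, 0.7, 1.0]))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_founder_conservation(self, seed, adhesion, frac_green):
        n = 200
        params = SimParams(n_spores=n, frac_green=frac_green, adhesion=adhesion,
                           collision_rate=3.0, t_end=12, seed=seed)
        parts = simulate_germling_aggregation(params)
        assert sum(p.n_founders for p in parts) == n
        # color counts are set at inoculation and must survive every merge
        ref = simulate_germling_aggregation(
            SimParams(**{**params.__dict__, "adhesion": 0.0})
        )
        assert sum(p.founders_green for p in parts) == sum(p.founders_green for p in ref)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_volume_conservation_without_growth(self, seed):
        params = SimParams(n_spores=300, growth_rate=0.0, adhesion=1.0,
                           collision_rate=5.0, t_end=12, seed=seed)
        parts = simulate_germling_aggregation(params)
        total = sum(p.diameter**3 for p in parts)
        assert total == pytest.approx(300 * params.spore_diameter**3, rel=1e-9)
        assert len(parts) <= 300

    def test_same_seed_is_bit_identical(self):
        params = SimParams(n_spores=400, seed=11, t_end=14)
        a = simulate_germling_aggregation(params)
        b = simulate_germling_aggregation(params)
        assert [(p.founders_green, p.founders_red, p.diameter) for p in a] == [
            (p.founders_green, p.founders_red, p.diameter) for p in b
        ]

    def test_size_cap_blocks_large_partners(self):
        capped = simulate_germling_aggregation(
            SimParams(n_spores=400, collision_rate=10.0, max_merge_diameter=5.0, seed=4)
        )
        free = simulate_germling_aggregation(
            SimParams(n_spores=400, collision_rate=10.0, seed=4)
        )
        assert max(p.diameter for p in capped) < max(p.diameter for p in free)


class TestParticlesToSizes:
    def test_single_particle(self):
        s = particles_to_sizes([SimParticle(1, 0, 2.0, True, 4.0)])
        assert s.values.tolist() == [2.0]

    def test_merge_is_volume_additive(self):
        parts = simulate_germling_aggregation(
            SimParams(n_spores=2, frac_green=0.5, growth_rate=0.0, adhesion=1.0,
                      collision_rate=50.0, t_end=12, seed=0)
        )
        assert len(parts) == 1
        assert parts[0].diameter == pytest.approx(2 ** (1 / 3))

    def test_empty_list_rejected(self):
        with pytest.raises(EmptyInputError):
            particles_to_sizes([])


class TestParticlesToEvents:
    def test_pure_green_no_bleed_has_zero_red(self):
        spec = ImageSpec(noise_sd=0.0, bleed_red_into_green=0.0, bleed_green_into_red=0.0)
        ev = particles_to_events([SimParticle(1, 0, 50.0, True, 4.0)], spec=spec)
        assert ev["red"].iloc[0] == 0.0
        assert ev["green"].iloc[0] > 0

    def test_bleed_through_arithmetic(self):
        # true (g=100, r=50) with bleed 0.04/0.05 -> observed (102, 55)
        spec = ImageSpec(noise_sd=0.0)
        ev = particles_to_events(
            [SimParticle(2, 1, 50.0, True, 4.0)], gain_fluor=50.0, spec=spec
        )
        assert ev["green"].iloc[0] == pytest.approx(100 + 0.04 * 50)
        assert ev["red"].iloc[0] == pytest.approx(50 + 0.05 * 100)

    def test_debris_events_appended_below_threshold(self):
        spec = ImageSpec(noise_sd=0.0)
        ev = particles_to_events(
            [SimParticle(1, 0, 100.0, True, 4.0)], spec=spec, n_debris=50, seed=1
        )
        assert len(ev) == 51
        assert (ev["extinction"].iloc[1:] < 25).all()


class TestRenderChannels:
    def test_dual_particle_present_in_both_channels(self, clean_image_spec):
        g, r = render_channels([SimParticle(1, 1, 10.0, True, 4.0)], 0, clean_image_spec)
        bg = clean_image_spec.background
        assert g.max() > bg + 100 and r.max() > bg + 100
        assert np.unravel_index(g.argmax(), g.shape) == np.unravel_index(r.argmax(), r.shape)

    def test_zero_particles_gives_background_only(self, clean_image_spec):
        g, r = render_channels([], 0, clean_image_spec)
        assert np.allclose(g, clean_image_spec.background)
        assert np.allclose(r, clean_image_spec.background)
        assert g.shape == (clean_image_spec.height, clean_image_spec.width)

    def test_overcrowded_canvas_raises_placement_error(self):
        spec = ImageSpec(width=64, height=64, blob_sigma=8.0)
        parts = [SimParticle(1, 0, 5.0, True, 4.0) for _ in range(50)]
        with pytest.raises(PlacementError):
            render_channels(parts, 0, spec)
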