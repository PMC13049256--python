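import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest, pearsonr

from jpresskit.datagen import (ConcentrationPrior, GenConfig, LineshapePFL,
                               SampleGenerator, add_noise_and_artifacts,
                               apply_relaxation_and_lineshape, assign_t2,
                               average_t2, eval_lineshape, generate_dataset,
                               load_dataset)
from jpresskit.simulator import BasisFid


def flat_pfl(n_te=4, lam=0.0, g=0.0, b1=0.0, b2=0.0, b3=0.0):
    return LineshapePFL(lam=lam, g=g, b1=b1, b2=b2, b3=b3,
                        phases_deg=np.zeros(n_te),
                        freq_offsets_hz=np.zeros(n_te))


class TestLineshape:
    def test_unity_at_time_zero_for_any_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = LineshapePFL(lam=rng.uniform(0, 30), g=rng.uniform(0, 30),
                             b1=rng.uniform(-2, 3), b2=rng.uniform(-3, 30),
                             b3=rng.uniform(0, 210), phases_deg=np.zeros(1),
                             freq_offsets_hz=np.zeros(1))
            assert eval_lineshape(np.array([0.0]), p)[0] == pytest.approx(1.0)

    def test_printed_formula_value(self):
        """lam=2pi, g=10, b1=1 at t=0.1 s: exp(-0.2 pi - 0.1) x 0.9."""
        p = flat_pfl(lam=2 * np.pi, g=10.0, b1=1.0)
        expected = np.exp(-0.2 * np.pi - 0.1) * 0.9
        assert eval_lineshape(np.array([0.1]), p)[0] == pytest.approx(expected,
                                                                      rel=1e-12)
        assert expected == pytest.approx(0.4345, abs=5e-4)

    def test_lorentzian_limit_log_linear(self):
        t = np.linspace(0, 0.5, 200)
        p = flat_pfl(lam=7.0)
        vals = eval_lineshape(t, p)
        slopes = np.diff(np.log(vals)) / np.diff(t)
        np.testing.assert_allclose(slopes, -7.0, atol=1e-9)

    def test_cubic_factor_may_go_negative_unclipped(self):
        p = flat_pfl(b3=210.0)
        assert eval_lineshape(np.array([0.5]), p)[0] < 0


class TestT2Assignment:
    def test_direct_evaluation(self):
        assert assign_t2(5.0, 1.0, 0.0) == pytest.approx(1 / 6)

    def test_identity_when_offsets_vanish(self):
        assert assign_t2(4.0, 0.0, 0.0) == pytest.approx(0.25)

    def test_upper_metabolite_bound(self):
        """Slowest preset with the most negative offsets lands at the
        ~590 ms upper end of the metabolite subgroup T2 range."""
        t2 = assign_t2(1 / 0.276, -1.3, -0.63)
        assert t2 == pytest.approx(0.591, abs=0.001)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            assign_t2(1.0, -1.5, 0.0)

    @given(st.lists(st.floats(0.05, 1.5), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_average_is_permutation_invariant_mean(self, values):
        avg = average_t2(values)
        assert avg == pytest.approx(np.mean(values))
        rng = np.random.default_rng(0)
        shuffled = list(values)
        rng.shuffle(shuffled)
        assert average_t2(shuffled) == pytest.approx(avg)

    def test_average_of_empty_rejected(self):
        with pytest.raises(ValueError):
            average_t2([])


class TestRelaxationAndLineshape:
    def make_basis(self, n=64, te=0.05, dwell=4e-4):
        t = np.arange(n) * dwell
        samples = np.exp(1j * 2 * np.pi * 50 * t)
        return BasisFid("S", "a", te, samples, dwell)

    def test_identity_limit(self):
        basis = self.make_basis()
        out = apply_relaxation_and_lineshape(basis, t2=1e12, p=flat_pfl())
        np.testing.assert_allclose(out, basis.samples, atol=1e-9)

    def test_doubling_te_scales_by_echo_decay(self):
        basis = self.make_basis(te=0.05)
        t2 = 0.2
        out1 = apply_relaxation_and_lineshape(basis, t2, flat_pfl(), te=0.05)
        out2 = apply_relaxation_and_lineshape(basis, t2, flat_pfl(), te=0.10)
        np.testing.assert_allclose(out2, out1 * np.exp(-0.05 / t2), rtol=1e-10)

    def test_phase_180_negates_but_preserves_magnitude(self):
        basis = self.make_basis()
        p0, p180 = flat_pfl(), flat_pfl()
        p180.phases_deg = np.full(4, 180.0)
        out0 = apply_relaxation_and_lineshape(basis, 0.2, p0)
        out180 = apply_relaxation_and_lineshape(basis, 0.2, p180)
        np.testing.assert_allclose(out180, -out0, atol=1e-9)
        np.testing.assert_allclose(np.abs(out180), np.abs(out0), atol=1e-12)


class TestNoiseAndArtifacts:
    def test_zero_config_gives_zero_background(self, small_grid):
        cfg = GenConfig(noise_sigma=(0.0, 0.0), max_artifacts=0)
        clean = np.ones((small_grid.n_te, small_grid.n_points), dtype=complex)
        noisy, bg = add_noise_and_artifacts(clean, np.random.default_rng(0),
                                            cfg, small_grid)
        np.testing.assert_array_equal(bg, 0)
        np.testing.assert_array_equal(noisy, clean)

    def test_deterministic_under_seed(self, small_grid):
        cfg = GenConfig()
        clean = np.zeros((small_grid.n_te, small_grid.n_points), dtype=complex)
        _, bg1 = add_noise_and_artifacts(clean, np.random.default_rng(42),
                                         cfg, small_grid)
        _, bg2 = add_noise_and_artifacts(clean, np.random.default_rng(42),
                                         cfg, small_grid)
        np.testing.assert_array_equal(bg1, bg2)

    def test_empirical_sigma_matches_configured(self, small_grid):
        sigma = 0.7
        cfg = GenConfig(noise_sigma=(sigma, sigma), max_artifacts=0)
        clean = np.zeros((64, 2048), dtype=complex)
        grid = small_grid
        _, bg = add_noise_and_artifacts(clean, np.random.default_rng(3), cfg,
                                        grid)
        est = np.std(np.concatenate([bg.real.ravel(), bg.imag.ravel()]))
        assert est == pytest.approx(sigma, rel=0.05)


class TestSampleGeneration:
    def test_conservation_exact(self, smoke_basis):
        gen = SampleGenerator(smoke_basis)
        for i in range(20):
            s = gen.generate_sample(gen.rng_for(11, i))
            resid = s.input - (s.component_fids.sum(axis=0) + s.background)
            assert np.all(resid == 0)

    def test_water_only_limit(self, smoke_basis):
        """With all metabolite medians collapsed to zero, the input is the
        water component plus background."""
        cfg = GenConfig(medians_mm={m: 0.0 for m in ["NAA", "Cr", "GABA"]})
        gen = SampleGenerator(smoke_basis, cfg)
        s = gen.generate_sample(gen.rng_for(5, 0))
        widx = s.component_names.index("water")
        np.testing.assert_allclose(
            s.input, s.component_fids[widx] + s.background, atol=1e-12)

    def test_combined_component_concentrations_are_sums(self, smoke_basis):
        gen = SampleGenerator(smoke_basis)
        s = gen.generate_sample(gen.rng_for(2, 7))
        mets = s.meta["metabolite_concs"]
        names = s.component_names
        assert s.concentrations[names.index("tNAA")] == pytest.approx(mets["NAA"])
        assert s.concentrations[names.index("tCr")] == pytest.approx(mets["Cr"])

    def test_avg_t2_label_matches_weighted_subgroup_mean(self, smoke_basis):
        gen = SampleGenerator(smoke_basis)
        s = gen.generate_sample(gen.rng_for(9, 3))
        t2s = s.meta["subgroup_t2"]
        names = s.component_names
        # Cr: two subgroups, weights proportional to proton counts (3, 2)
        expected = (3 * t2s["Cr/methyl"] + 2 * t2s["Cr/methylene"]) / 5
        assert s.avg_t2[names.index("tCr")] == pytest.approx(expected, rel=1e-9)

    def test_unweighted_average_option(self, smoke_basis):
        gen = SampleGenerator(smoke_basis, GenConfig(t2_weighted_average=False))
        s = gen.generate_sample(gen.rng_for(9, 3))
        t2s = s.meta["subgroup_t2"]
        expected = (t2s["Cr/methyl"] + t2s["Cr/methylene"]) / 2
        assert s.avg_t2[s.component_names.index("tCr")] == pytest.approx(
            expected, rel=1e-9)

    def test_first_point_amplitudes_match_components(self, smoke_basis):
        gen = SampleGenerator(smoke_basis)
        s = gen.generate_sample(gen.rng_for(4, 1))
        np.testing.assert_allclose(
            s.amplitudes, np.abs(s.component_fids[:, :, 0]).T, rtol=1e-12)


class TestPriorStatistics:
    def test_concentration_medians(self):
        """Empirical medians of the uniform priors land on the configured
        per-metabolite medians (NAA 10 mM, NAAG 5 mM)."""
        prior = ConcentrationPrior()
        rng = np.random.default_rng(123)
        draws = {m: [] for m in ["NAA", "NAAG"]}
        for _ in range(20000):
            c = prior.draw(["NAA", "NAAG"], rng)
            for m in draws:
                draws[m].append(c[m])
        assert np.median(draws["NAA"]) == pytest.approx(10.0, abs=0.2)
        assert np.median(draws["NAAG"]) == pytest.approx(5.0, abs=0.1)
        assert max(draws["NAA"]) <= 20.0

    def test_naag_draws_uniform_on_0_10(self):
        prior = ConcentrationPrior()
        rng = np.random.default_rng(7)
        vals = [prior.draw(["NAAG"], rng)["NAAG"] for _ in range(10000)]
        assert kstest(np.array(vals) / 10.0, "uniform").pvalue > 0.01

    def test_t2_draws_within_stated_ranges(self, smoke_basis):
        """Realized metabolite subgroup T2s stay within ~[90, 590] ms and
        water within ~[75, 1400] ms."""
        gen = SampleGenerator(smoke_basis)
        met_vals, water_vals = [], []
        for i in range(300):
            t2s, _, _ = gen._draw_t2s(gen.rng_for(77, i))
            for (met, _), v in t2s.items():
                (water_vals if met == "water" else met_vals).append(v)
        met_vals, water_vals = np.array(met_vals), np.array(water_vals)
        assert met_vals.min() >= 0.089 and met_vals.max() <= 0.592
        assert water_vals.min() >= 0.074 and water_vals.max() <= 1.41

    def test_water_pfl_independent_of_metabolite_pfl(self, smoke_basis):
        gen = SampleGenerator(smoke_basis)
        met_phase, water_phase = [], []
        for i in range(2000):
            s_rng = gen.rng_for(13, i)
            cfg = gen.cfg
            pfl = LineshapePFL.draw(gen.grid.n_te, cfg, s_rng)
            wpfl = LineshapePFL.draw(gen.grid.n_te, cfg, s_rng)
            met_phase.append(pfl.phases_deg[0])
            water_phase.append(wpfl.phases_deg[0])
        r = pearsonr(met_phase, water_phase)[0]
        assert abs(r) < 0.05


class TestDataset:
    def test_reproducible_files(self, smoke_basis, tmp_path):
        gen = SampleGenerator(smoke_basis)
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        generate_dataset(gen, 2, seed=5, path=p1)
        generate_dataset(gen, 2, seed=5, path=p2)
        d1, d2 = load_dataset(p1), load_dataset(p2)
        for key in ("input", "concentration", "t2", "amplitude"):
            np.testing.assert_array_equal(d1[key], d2[key])

    def test_in_memory_matches_layout(self, smoke_basis):
        gen = SampleGenerator(smoke_basis)
        ds = generate_dataset(gen, 3, seed=5, store_components=True)
        n_comp = gen.n_components
        assert ds["input"].shape == (3, 8, 512, 2)
        assert ds["concentration"].shape == (3, n_comp)
        assert ds["components"].shape == (3, n_comp, 8, 512, 2)
        assert np.all(np.isfinite(ds["concentration"]))
        assert np.all(ds["concentration"] >= 0)

    def test_invalid_n_rejected(self, smoke_basis):
        gen = SampleGenerator(smoke_basis)
        with pytest.raises(ValueError):
            generate_dataset(gen, 0, seed=1)
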