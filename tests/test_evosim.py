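"""Wright-Fisher dynamics, variance decomposition, depletion and birth cycle."""

import numpy as np
import pytest
from scipy import stats

import segvar as sv
from segvar.evosim import _recombine


class TestWrightFisher:
    def test_neutral_fixation_probability_is_initial_frequency(self):
        p, se = sv.wf_fixation_probability(100, 0.0, 0.5, 2000, seed=1)
        assert abs(p - 0.5) < 3 * se

    def test_neutral_mean_frequency_is_conserved(self):
        # martingale property of drift
        rng = np.random.default_rng(2)
        N, n_runs, p0 = 200, 10_000, 0.3
        p = np.full(n_runs, p0)
        for _ in range(25):
            p = rng.binomial(N, p) / N
        se = p.std() / np.sqrt(n_runs)
        assert abs(p.mean() - p0) < 3 * se

    def test_overwhelming_selection_fixes_fast(self):
        fixed, gens = [], []
        for i in range(50):
            r = sv.wf_trajectory(500, 10.0, 0.5, seed=100 + i)
            fixed.append(r.fixed)
            gens.append(r.generations_to_absorption)
        assert np.mean([f is True for f in fixed]) >= 0.95
        assert np.median(gens) < 50

    def test_invalid_p0_rejected(self):
        with pytest.raises(ValueError):
            sv.wf_trajectory(100, 0.1, 0.0)

    def test_diploid_matches_haploid_diffusion_scaling(self):
        # additive diploid with N uses Ne = 2N in the diffusion formula
        hap = sv.diffusion_fixation_probability(2000, 0.01, 0.001, "haploid")
        dip = sv.diffusion_fixation_probability(1000, 0.01, 0.001, "diploid")
        assert hap == pytest.approx(dip, rel=1e-12)

    def test_neutral_conditional_fixation_time_close_to_2N(self):
        t = sv.diffusion_conditional_fixation_time(500, 1e-10, 1 / 500)
        assert t == pytest.approx(2 * 500, rel=0.05)

    def test_simulated_conditional_time_matches_diffusion(self):
        times = []
        for i in range(800):
            r = sv.wf_trajectory(200, 0.02, 1 / 200, seed=5000 + i)
            if r.fixed:
                times.append(r.generations_to_absorption)
        oracle = sv.diffusion_conditional_fixation_time(200, 0.02, 1 / 200)
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - oracle) < 4 * se


class TestVarianceDecomposition:
    def test_purely_additive_single_locus(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])[:, None]
        y = 2.0 * x.ravel()
        dec = sv.decompose_variance(x, y)
        assert dec.V_NonA == pytest.approx(0.0, abs=1e-12)
        assert dec.h2 == pytest.approx(dec.H2, abs=1e-12)
        assert dec.h2 == pytest.approx(1.0)

    def test_xor_trait_is_purely_epistatic(self):
        # brute force over the four two-locus classes at frequency 0.5
        g = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        G = np.tile(g, (25, 1))
        centered = G - 0.5
        y = centered[:, 0] * centered[:, 1]
        dec = sv.decompose_variance(G, y)
        assert dec.V_A == pytest.approx(0.0, abs=1e-12)
        assert dec.V_NonA == pytest.approx(dec.V_G, abs=1e-12)
        assert dec.V_G == pytest.approx(np.var(y), abs=1e-12)

    def test_noiseless_conservation(self):
        rng = np.random.default_rng(3)
        G = rng.integers(0, 2, size=(200, 10)).astype(float)
        y = G @ rng.normal(size=10) + \
            (G[:, 0] - 0.5) * (G[:, 1] - 0.5) * 2.0
        dec = sv.decompose_variance(G, y, genetic_values=y)
        assert abs(dec.V_P - (dec.V_A + dec.V_NonA)) < 1e-8

    def test_matches_generator_recorded_truth(self, small_cross,
                                              adaptive_panel):
        _, geno = small_cross
        archs, *_ = adaptive_panel
        a = archs[-1]
        loci = np.unique(np.concatenate(
            [a.additive_loci, a.epistatic_pairs.ravel()]).astype(int))
        if loci.size == 0:
            loci = a.additive_loci.astype(int)
        # rebuild the noiseless genetic values from the architecture
        Xc = geno.codes - geno.codes.mean(axis=0)
        gv = Xc[:, a.additive_loci.astype(int)] @ a.additive_effects
        if len(a.epistatic_pairs):
            gv = gv + (Xc[:, a.epistatic_pairs[:, 0]]
                       * Xc[:, a.epistatic_pairs[:, 1]]) @ a.epistatic_effects
        if a.coupling == 0.0:
            dec = sv.decompose_variance(geno.codes[:, loci], gv,
                                        genetic_values=gv)
            assert dec.V_G == pytest.approx(a.V_G * (399 / 400), rel=1e-6)

    def test_ridge_fallback_flagged(self):
        rng = np.random.default_rng(4)
        G = rng.integers(0, 2, size=(10, 30)).astype(float)
        dec = sv.decompose_variance(G, rng.normal(size=10))
        assert dec.ridge_used

    def test_degenerate_genotypes_rejected(self):
        with pytest.raises(ValueError):
            sv.decompose_variance(np.ones((5, 2)), np.arange(5.0))


class TestRecombination:
    def test_zero_recombination_transmits_whole_parents(self):
        rng = np.random.default_rng(5)
        mothers = np.zeros((50, 10))
        fathers = np.ones((50, 10))
        out = _recombine(mothers, fathers, np.zeros(9), rng)
        assert np.all((out == 0).all(axis=1) | (out == 1).all(axis=1))

    def test_free_recombination_mixes_parents(self):
        rng = np.random.default_rng(6)
        mothers = np.zeros((2000, 2))
        fathers = np.ones((2000, 2))
        out = _recombine(mothers, fathers, np.array([0.5]), rng)
        recomb = np.mean(out[:, 0] != out[:, 1])
        assert abs(recomb - 0.5) < 0.05


def _depletion_setup(seed, N=500, n_loci=20, target_h2=0.6):
    _, geno = sv.simulate_segregant_panel(
        sv.PanelConfig(n_chromosomes=16, n_markers=n_loci), N, seed)
    rng = np.random.default_rng(seed + 1)
    effects = rng.normal(size=n_loci)
    gv = (geno.codes - geno.codes.mean(0)) @ effects
    dec = sv.decompose_variance(geno.codes, gv, genetic_values=gv)
    noise_sd = np.sqrt(dec.V_A * (1 - target_h2) / target_h2)
    r = geno.marker_map.interval_recomb_fractions()
    return geno.codes, effects, r, float(noise_sd)


class TestDepletion:
    def test_neutral_trajectory_flat_up_to_drift(self):
        # drift erodes V_A by (1 - 1/N) per generation even without selection;
        # the neutral h2 decline must not exceed that expectation
        N, gens = 400, 20
        excess = []
        for rep in range(15):
            G, eff, r, sd = _depletion_setup(3000 + 7 * rep, N=N)
            res = sv.simulate_depletion(G, eff, recomb_r=r, noise_sd=sd,
                                        n_generations=gens, selection="none",
                                        seed=rep)
            tr = res.trajectory
            va0 = tr["V_A"].iloc[0]
            f = (1.0 - 1.0 / N) ** gens
            expected_end = f * va0 / (f * va0 + sd ** 2)
            excess.append(res.h2_trajectory()[-1] - expected_end)
        assert abs(np.mean(excess)) < 4 * stats.sem(excess)

    def test_truncation_selection_rapidly_depletes_h2(self):
        ends = []
        for rep in range(10):
            G, eff, r, sd = _depletion_setup(4000 + 11 * rep, N=1000)
            res = sv.simulate_depletion(G, eff, recomb_r=r, noise_sd=sd,
                                        n_generations=25,
                                        truncation_fraction=0.2, seed=rep)
            assert res.h2_trajectory()[0] == pytest.approx(0.6, abs=0.05)
            ends.append(res.h2_trajectory()[-1])
        assert np.mean(ends) < 0.3

    def test_favoured_alleles_rise_in_expectation(self):
        shifts = []
        for rep in range(10):
            G, eff, r, sd = _depletion_setup(5000 + 13 * rep, N=500)
            res = sv.simulate_depletion(G, eff, recomb_r=r, noise_sd=sd,
                                        n_generations=10, seed=rep)
            dp = res.allele_freqs[-1] - res.allele_freqs[0]
            shifts.append(np.mean(np.sign(eff) * dp))
        assert np.mean(shifts) > 0

    def test_fixation_events_are_frequency_one_loci(self):
        G, eff, r, sd = _depletion_setup(6000, N=300)
        res = sv.simulate_depletion(G, eff, recomb_r=r, noise_sd=sd,
                                    n_generations=30,
                                    truncation_fraction=0.1, seed=0)
        for _, ev in res.fixation_events.iterrows():
            assert res.allele_freqs[int(ev["generation"]), int(ev["locus"])] \
                == 1.0

    def test_monomorphic_start_warns_flat(self):
        G = np.zeros((100, 5))
        with pytest.warns(UserWarning, match="monomorphic"):
            res = sv.simulate_depletion(G, np.ones(5), noise_sd=1.0,
                                        n_generations=3, seed=0)
        assert np.allclose(res.h2_trajectory(), 0.0)


class TestBirthCycle:
    def test_neutral_control_treats_classes_alike(self):
        fa, fe = [], []
        for rep in range(15):
            res = sv.simulate_birth_cycle(N=300, s=0.0, generations=60,
                                          seed=rep)
            fa.append(res.fixation_fraction_additive)
            fe.append(res.fixation_fraction_epistatic)
        assert abs(np.mean(fa) - np.mean(fe)) < 0.05

    def test_selection_prefers_additive_variants(self):
        fa, fe = [], []
        for rep in range(10):
            res = sv.simulate_birth_cycle(N=500, seed=100 + rep)
            fa.append(res.fixation_fraction_additive)
            fe.append(res.fixation_fraction_epistatic)
        assert np.mean(fa) > np.mean(fe)

    def test_admixture_restores_additive_variance(self):
        res = sv.simulate_birth_cycle(N=500, seed=7)
        assert res.h2_hybrid > max(res.h2_demes)
        assert res.decomposition_hybrid.V_A > \
            max(d.V_A for d in res.decomposition_demes)

    def test_fixation_bookkeeping_is_exact(self):
        res = sv.simulate_birth_cycle(N=300, seed=9)
        assert (res.per_deme_fixed["n_fixed"]
                <= res.per_deme_fixed["n_seeded"]).all()
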