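"""Deconvolution model: prior calibration, NB likelihood, fitting, counts."""

import numpy as np
import pytest
from scipy import stats

from segdecon.deconv import (
    DeconvModelSpec,
    GammaPrior,
    ReferenceProfile,
    SpotDeconvolver,
    absolute_counts,
    calibrate_prior_roi,
    fit_deconvolution,
    moment_match_prior,
    nb_loglik,
)
from segdecon.spot_mapping import CountMoments, SpotCounts, count_moments
from segdecon.synthetic import SynthStSpec, synth_st


def moments(n_bar, sigma2, n=10):
    return CountMoments(n_bar, sigma2, sigma2 / n_bar, n)


class TestMomentMatchPrior:
    def test_closed_form_on_2_4_6(self):
        prior = moment_match_prior(count_moments(np.array([2, 4, 6])))
        assert (prior.kappa, prior.theta) == (4.0, 1.0)

    def test_unit_vmr_gives_unit_rate(self):
        for n_bar in (1.0, 3.7, 50.0):
            prior = moment_match_prior(moments(n_bar, n_bar))
            assert prior.theta == pytest.approx(1.0)

    def test_halving_vmr_doubles_both_parameters(self):
        loose = moment_match_prior(moments(8.0, 16.0))    # vmr 2
        tight = moment_match_prior(moments(8.0, 8.0))     # vmr 1
        assert tight.kappa == pytest.approx(2 * loose.kappa)
        assert tight.theta == pytest.approx(2 * loose.theta)

    def test_moment_identity_exact(self, rng):
        for _ in range(20):
            n = rng.integers(2, 40, size=30)
            if n.var(ddof=1) == 0 or n.mean() == 0:
                continue
            m = count_moments(n)
            prior = moment_match_prior(m)
            assert prior.mean == pytest.approx(m.n_bar, rel=1e-12)
            assert prior.variance == pytest.approx(m.sigma2, rel=1e-12)

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError):
            moment_match_prior(moments(5.0, 0.0))


class TestNbLoglik:
    def test_poisson_limit(self):
        # y=0, mu=1, alpha -> inf: log p -> -mu = -1
        assert nb_loglik(np.array([0]), np.array([1.0]), 1e8) == pytest.approx(
            -1.0, abs=1e-6
        )

    def test_matches_scipy_nbinom(self, rng):
        y = rng.integers(0, 30, 50)
        mu = rng.uniform(0.5, 20, 50)
        alpha = rng.uniform(1, 10, 50)
        want = stats.nbinom.logpmf(y, alpha, alpha / (alpha + mu)).sum()
        assert nb_loglik(y, mu, alpha) == pytest.approx(want, rel=1e-10)

    def test_variance_identity_by_simulation(self):
        from segdecon._utils import rng_stream
        from segdecon.synthetic import sample_nb_counts

        draws = sample_nb_counts(
            np.full(100_000, 10.0), 2.0, rng_stream(4, 99)
        )
        assert draws.mean() == pytest.approx(10.0, rel=0.05)
        assert draws.var() == pytest.approx(60.0, rel=0.05)

    def test_gene_permutation_symmetry(self, rng):
        y = rng.integers(0, 20, 30)
        mu = rng.uniform(1, 10, 30)
        perm = rng.permutation(30)
        assert nb_loglik(y, mu, 5.0) == pytest.approx(
            nb_loglik(y[perm], mu[perm], 5.0)
        )

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            nb_loglik(np.array([-1]), np.array([1.0]), 1.0)
        with pytest.raises(ValueError):
            nb_loglik(np.array([0.5]), np.array([1.0]), 1.0)


class TestFitDeconvolution:
    def test_single_type_forces_unit_proportions(self, rng):
        S, G = 20, 40
        r = rng.uniform(0.5, 2.0, (G, 1))
        m = rng.uniform(3, 12, S)
        y = rng.poisson(m[:, None] * r[:, 0][None, :])
        ref = ReferenceProfile([f"g{i}" for i in range(G)], ["t0"], r)
        fit = fit_deconvolution(y, ref, DeconvModelSpec(alpha_g=1e6))
        assert np.allclose(fit.w_ks, 1.0)
        # m_s tracks the scaled library size
        expected = y.sum(axis=1) / r.sum()
        assert np.corrcoef(fit.m_s, expected)[0, 1] > 0.99

    def test_all_zero_counts_prior_dominated(self):
        # few genes with tiny reference expression: the likelihood pull at
        # zero counts is negligible next to a concentrated prior
        G, S = 5, 10
        ref = ReferenceProfile(
            [f"g{i}" for i in range(G)], ["t0", "t1"], np.full((G, 2), 1e-3)
        )
        prior = GammaPrior(100.0, 10.0)   # mean 10, sd 1
        y = np.zeros((S, G), dtype=int)
        fit = fit_deconvolution(y, ref, DeconvModelSpec(prior=prior))
        assert np.all(np.abs(fit.m_s - prior.mean) / prior.mean < 0.10)

    def test_seed_determinism_map(self, st_instance):
        ref = ReferenceProfile(
            st_instance.genes, st_instance.cell_types, st_instance.r_gk
        )
        spec = DeconvModelSpec(prior=GammaPrior(2.0, 0.5), iterations=150)
        a = fit_deconvolution(st_instance.y, ref, spec)
        b = fit_deconvolution(st_instance.y, ref, spec)
        assert a.diagnostics["objective_trace"] == b.diagnostics["objective_trace"]
        assert np.array_equal(a.m_s, b.m_s)

    def test_vi_deterministic_given_seed(self, st_instance):
        ref = ReferenceProfile(
            st_instance.genes, st_instance.cell_types, st_instance.r_gk
        )
        spec = DeconvModelSpec(
            prior=GammaPrior(2.0, 0.5), inference="vi", iterations=100, seed=5
        )
        a = fit_deconvolution(st_instance.y, ref, spec)
        b = fit_deconvolution(st_instance.y, ref, spec)
        assert np.array_equal(a.m_s, b.m_s)

    def test_simplex_constraint(self, st_instance):
        ref = ReferenceProfile(
            st_instance.genes, st_instance.cell_types, st_instance.r_gk
        )
        fit = fit_deconvolution(
            st_instance.y, ref, DeconvModelSpec(prior=GammaPrior(2.0, 0.5))
        )
        assert np.allclose(fit.w_ks.sum(axis=1), 1.0, atol=1e-6)
        assert (fit.w_ks >= 0).all()

    def test_gene_alignment_intersects_and_collapses_duplicates(self, rng):
        r = np.array([[1.0], [2.0], [3.0]])
        ref = ReferenceProfile(["a", "b", "c"], ["t0"], r)
        # counts carry an extra gene and a duplicated identifier
        y = np.array([[4, 1, 1, 9]])
        fit = fit_deconvolution(
            y, ref, DeconvModelSpec(alpha_g=1e6), genes=["a", "b", "b", "zzz"]
        )
        assert fit.m_s.shape == (1,)

    def test_disjoint_gene_sets_error(self):
        ref = ReferenceProfile(["a"], ["t0"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="overlap"):
            fit_deconvolution(np.array([[1]]), ref, genes=["x"])

    def test_tighter_prior_pulls_m_toward_prior_mean(self):
        res = synth_st(SynthStSpec(S=40, G=80, K=3), seed=9)
        ref = ReferenceProfile(res.genes, res.cell_types, res.r_gk)
        n_bar = res.n_s.mean()
        s2 = res.n_s.var(ddof=1)
        pulls = []
        for shrink in (1.0, 0.1, 0.001):
            prior = moment_match_prior(
                CountMoments(n_bar, s2 * shrink, s2 * shrink / n_bar, 40)
            )
            fit = fit_deconvolution(res.y, ref, DeconvModelSpec(prior=prior))
            pulls.append(np.abs(fit.m_s - n_bar).mean())
        assert pulls[0] > pulls[1] > pulls[2]


class TestAbsoluteCounts:
    def test_single_type(self):
        counts = SpotCounts(["s0"], np.array([7]))
        C = absolute_counts(np.array([[1.0]]), counts)
        assert C.tolist() == [[7.0]]

    def test_hand_multiplication(self):
        counts = SpotCounts(["s0"], np.array([8]))
        C = absolute_counts(np.array([[0.25, 0.75]]), counts)
        assert C.tolist() == [[2.0, 6.0]]

    def test_empty_spot(self):
        counts = SpotCounts(["s0"], np.array([0]))
        C = absolute_counts(np.array([[0.3, 0.7]]), counts)
        assert C.tolist() == [[0.0, 0.0]]

    def test_row_sums_recover_n_s(self, rng):
        w = rng.dirichlet(np.ones(4), size=12)
        counts = SpotCounts(list(range(12)), rng.integers(0, 20, 12))
        C = absolute_counts(w, counts)
        assert np.allclose(C.sum(axis=1), counts.n_s)

    def test_mismatched_spots_error(self):
        counts = SpotCounts(["s0"], np.array([3]))
        with pytest.raises(ValueError):
            absolute_counts(np.array([[1.0]]), counts, spot_ids=["nope"])


class TestCalibratePriorRoi:
    def test_single_region_equals_global(self):
        counts = SpotCounts(list("abcd"), np.array([2, 4, 6, 8]))
        priors = calibrate_prior_roi(counts, {s: "all" for s in "abcd"})
        want = moment_match_prior(count_moments(counts))
        assert priors["all"].kappa == pytest.approx(want.kappa)

    def test_vmr_ratio_maps_to_kappa_ratio(self):
        # equal n_bar, vmr 0.5 vs 2.0 -> kappa ratio 4:1
        a = moment_match_prior(moments(4.0, 2.0))
        b = moment_match_prior(moments(4.0, 8.0))
        assert a.kappa / b.kappa == pytest.approx(4.0)

    def test_single_spot_region_falls_back_to_global(self):
        counts = SpotCounts(list("abcde"), np.array([2, 4, 6, 8, 5]))
        priors = calibrate_prior_roi(
            counts, {"a": "r1", "b": "r1", "c": "r1", "d": "r1", "e": "lonely"}
        )
        glob = moment_match_prior(count_moments(counts))
        assert priors["lonely"].kappa == pytest.approx(glob.kappa)
        assert priors["lonely"].theta == pytest.approx(glob.theta)

    def test_empty_region_map_errors(self):
        counts = SpotCounts(["a", "b"], np.array([1, 2]))
        with pytest.raises(ValueError):
            calibrate_prior_roi(counts, {})


class TestSpotDeconvolver:
    def test_fit_sets_attributes_and_absolute_counts(self, st_instance):
        ref = ReferenceProfile(
            st_instance.genes, st_instance.cell_types, st_instance.r_gk
        )
        ns = SpotCounts(list(range(len(st_instance.n_s))), st_instance.n_s)
        est = SpotDeconvolver(reference=ref, iterations=300).fit(
            st_instance.y, nucleus_counts=ns
        )
        assert est.m_s_.shape == (st_instance.y.shape[0],)
        assert np.allclose(est.C_ks_.sum(axis=1), st_instance.n_s)
        # prior was moment-matched from the supplied counts
        mom = count_moments(ns)
        assert est.prior_.mean == pytest.approx(mom.n_bar)

    def test_get_set_params_roundtrip(self):
        est = SpotDeconvolver()
        est.set_params(**est.get_params())
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
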