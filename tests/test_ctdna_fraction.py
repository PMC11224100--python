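import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from liquidfrac.ctdna_fraction import (
    EstimatorConfig, centromere_artifact_flag, decode_states,
    estimate_ctdna, fit_fraction, initial_fraction_from_density,
    ks_two_sample, normalize_counts, residual_qc,
    _conditional_loglik, _fit_sample, _mixture_means, _nb_loglik,
)
from liquidfrac.genome_bins import BinCounts
from liquidfrac.synthetic_data import (
    DEFAULT_GC_BIAS, FLAT_GC_BIAS, simulate_cfdna_counts,
    simulate_cnv_profile, synthetic_grid,
)

from conftest import make_profile


# ---------------------------------------------------------------------------
# normalization


class TestNormalize:
    def test_uniform_counts_give_unit_ratios(self, small_grid):
        counts = BinCounts("u", np.full(small_grid.n_bins, 400))
        prof = normalize_counts(counts, small_grid)
        inc = prof.included
        assert np.allclose(prof.ratio[inc], 1.0, atol=0.02)
        assert abs(np.average(prof.ratio[inc], weights=prof.weight[inc]) - 1.0) < 1e-9

    def test_scale_invariance(self, small_grid):
        rng = np.random.default_rng(2)
        c = rng.poisson(300, small_grid.n_bins)
        a = normalize_counts(BinCounts("a", c), small_grid)
        b = normalize_counts(BinCounts("b", 2 * c), small_grid)
        assert np.allclose(a.ratio[a.included], b.ratio[b.included])

    def test_gc_bias_removed(self, medium_grid):
        # counts distorted by a known quadratic GC curve, no CNVs:
        # post-normalization ratios are uncorrelated with GC
        truth = simulate_cnv_profile(medium_grid, 0.0,
                                     altered_genome_fraction=0.0, seed=1)
        counts = simulate_cfdna_counts(medium_grid, truth, 500,
                                       DEFAULT_GC_BIAS, 1000, seed=3)
        prof = normalize_counts(counts, medium_grid)
        inc = prof.included
        rho, _ = stats.spearmanr(prof.ratio[inc], medium_grid.gc[inc])
        assert abs(rho) < 0.05

    def test_empty_sample_rejected(self, small_grid):
        with pytest.raises(ValueError, match="empty sample"):
            normalize_counts(
                BinCounts("z", np.zeros(small_grid.n_bins, dtype=int)),
                small_grid)

    def test_outlier_bins_excluded(self, medium_grid):
        rng = np.random.default_rng(4)
        c = rng.poisson(400, medium_grid.n_bins)
        c[50] = 40_000  # massive artifact spike
        prof = normalize_counts(BinCounts("o", c), medium_grid)
        assert prof.excluded[50]

    def test_excluded_superset_of_grid_mask(self, small_grid):
        counts = BinCounts("m", np.full(small_grid.n_bins, 300))
        prof = normalize_counts(counts, small_grid)
        assert np.all(prof.excluded[small_grid.mask_flag])


# ---------------------------------------------------------------------------
# density initialization


class TestDensityInit:
    def test_unimodal_returns_none(self):
        rng = np.random.default_rng(0)
        prof = make_profile(1 + rng.normal(0, 0.04, 1000))
        assert initial_fraction_from_density(prof) is None

    def test_one_copy_loss_mode_gap(self):
        # 20% of bins at ratio 0.85 (one-copy loss at tf=0.3), low noise
        rng = np.random.default_rng(1)
        ratio = np.concatenate([1 + rng.normal(0, 0.02, 800),
                                0.85 + rng.normal(0, 0.02, 200)])
        tf0 = initial_fraction_from_density(make_profile(ratio))
        assert tf0 == pytest.approx(0.3, abs=0.05)

    def test_one_copy_gain_mode_gap(self):
        rng = np.random.default_rng(2)
        ratio = np.concatenate([1 + rng.normal(0, 0.02, 800),
                                1.20 + rng.normal(0, 0.02, 200)])
        tf0 = initial_fraction_from_density(make_profile(ratio))
        assert tf0 == pytest.approx(0.40, abs=0.05)

    def test_result_clipped_or_none(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            r = 1 + np.random.default_rng(seed).normal(0, 0.1, 300)
            tf0 = initial_fraction_from_density(make_profile(r))
            assert tf0 is None or 0.01 <= tf0 <= 0.95


# ---------------------------------------------------------------------------
# HMM decoding vs exhaustive path enumeration


def enumerate_posteriors(profile, tf, stay, dispersion, states, prior=None):
    """Brute-force posterior marginals by summing over every state path."""
    inc = profile.included
    K = len(states)
    x = np.where(inc, profile.ratio * profile.weight, 0.0)
    means = np.outer(profile.weight, _mixture_means(tf, states) / 2.0)
    logem = _nb_loglik(x[:, None], means, dispersion)
    if prior is not None:
        logem = logem + np.asarray(prior)[None, :]
    logem[~inc] = 0.0
    n = len(x)
    move = (1 - stay) / (K - 1)
    logT = np.log(np.full((K, K), move) + np.eye(K) * (stay - move))
    # all K^n paths as a (K^n, n) index matrix
    paths = np.stack(np.meshgrid(*[np.arange(K)] * n, indexing="ij"),
                     axis=-1).reshape(-1, n)
    lp = -np.log(K) + logem[np.arange(n)[None, :], paths].sum(axis=1)
    lp += logT[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    z = logsumexp(lp)
    post = np.zeros((n, K))
    for t in range(n):
        for k in range(K):
            sel = paths[:, t] == k
            post[t, k] = np.exp(logsumexp(lp[sel]) - z) if sel.any() else 0.0
    return post


class TestDecode:
    def test_enumeration_oracle_12bin_3state(self):
        rng = np.random.default_rng(5)
        truth = np.array([2, 2, 2, 1, 1, 1, 2, 2, 3, 3, 3, 2])
        tf = 0.4
        ratio = ((1 - tf) * 2 + tf * truth) / 2 + rng.normal(0, 0.02, 12)
        prof = make_profile(ratio, weight=2000.0)
        states = (1, 2, 3)
        post = enumerate_posteriors(prof, tf, 0.99, 1000.0, states)
        path = decode_states(prof, tf, 0.99, 1000.0, states)
        assert np.abs(post - path.posterior).max() < 1e-9
        assert np.array_equal(path.state, np.array(states)[post.argmax(1)])
        assert np.array_equal(path.state, truth)

    def test_enumeration_oracle_8bin_5state(self):
        rng = np.random.default_rng(6)
        truth = np.array([2, 2, 0, 0, 2, 4, 4, 2])
        tf = 0.5
        ratio = ((1 - tf) * 2 + tf * truth) / 2 + rng.normal(0, 0.02, 8)
        prof = make_profile(ratio, weight=2000.0)
        states = (0, 1, 2, 3, 4)
        prior = (-0.3, -0.1, 0.0, -0.1, -0.3)
        post = enumerate_posteriors(prof, tf, 0.99, 1000.0, states, prior)
        path = decode_states(prof, tf, 0.99, 1000.0, states,
                             state_prior=prior)
        assert np.abs(post - path.posterior).max() < 1e-9
        assert np.array_equal(path.state, truth)

    def test_tf_zero_degenerate_emissions(self):
        rng = np.random.default_rng(7)
        prof = make_profile(1 + rng.normal(0, 0.05, 30))
        path = decode_states(prof, 0.0, 0.999, 500.0)
        # all state means coincide: uniform posterior, tie-broken to neutral
        assert np.allclose(path.posterior, 0.2)
        assert np.all(path.state == 2)

    def test_posterior_rows_normalized(self, medium_grid):
        truth = simulate_cnv_profile(medium_grid, 0.3, seed=8)
        counts = simulate_cfdna_counts(medium_grid, truth, 500,
                                       FLAT_GC_BIAS, 1000, seed=9)
        prof = normalize_counts(counts, medium_grid)
        path = decode_states(prof, 0.3, 0.999, 1000.0)
        assert np.allclose(path.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_chromosome_break_resets_chain(self):
        # a loss segment truncated at a chromosome boundary does not leak
        chrom = np.array(["chr1"] * 6 + ["chr2"] * 6, dtype=object)
        truth = np.array([2, 2, 2, 1, 1, 1, 2, 2, 2, 2, 2, 2])
        tf = 0.5
        ratio = ((1 - tf) * 2 + tf * truth) / 2
        prof = make_profile(ratio, weight=2000.0, chrom=chrom)
        path = decode_states(prof, tf, 0.999, 1000.0)
        assert np.array_equal(path.state, truth)
        assert len([s for s in path.segments if s[0] == "chr2"]) == 1

    def test_invalid_tf_rejected(self):
        prof = make_profile(np.ones(10))
        with pytest.raises(ValueError):
            decode_states(prof, 1.5)


# ---------------------------------------------------------------------------
# fraction fitting


class TestFitFraction:
    @pytest.fixture()
    def sim_profile_and_truth(self, medium_grid):
        truth = simulate_cnv_profile(medium_grid, 0.4, seed=10)
        counts = simulate_cfdna_counts(medium_grid, truth, 500,
                                       FLAT_GC_BIAS, 1000, seed=11)
        prof = normalize_counts(counts, medium_grid)
        return prof, truth

    def test_recovery_with_true_states(self, sim_profile_and_truth):
        prof, truth = sim_profile_and_truth
        path = decode_states(prof, 0.4, 0.999, 1000.0)
        path.state = truth.copy_number.copy()  # oracle states
        tf_hat = fit_fraction(prof, path, 1000.0)
        assert tf_hat == pytest.approx(0.4, abs=0.05)

    def test_agrees_with_grid_search(self, sim_profile_and_truth):
        prof, truth = sim_profile_and_truth
        path = decode_states(prof, 0.4, 0.999, 1000.0)
        tf_hat = fit_fraction(prof, path, 1000.0)
        grid = np.arange(0.0, 1.0001, 0.001)
        ll = [_conditional_loglik(prof, path.state, t, 1000.0) for t in grid]
        assert abs(tf_hat - grid[int(np.argmax(ll))]) <= 1e-3

    def test_all_neutral_unidentifiable(self):
        prof = make_profile(np.ones(100))
        path = decode_states(prof, 0.0, 0.999, 500.0)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_fraction(prof, path, 500.0)


# ---------------------------------------------------------------------------
# KS test


class TestKsTwoSample:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        d, p = ks_two_sample(a, a.copy())
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, p = ks_two_sample(np.arange(10.0), 100 + np.arange(10.0))
        assert d == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ks_two_sample(np.array([]), np.array([1.0]))

    def test_exact_p_matches_permutation_enumeration(self):
        # two 10-point samples: enumerate all C(20,10) label assignments
        from itertools import combinations
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.9, 1, 10)
        d_obs, p_obs = ks_two_sample(a, b)

        pooled = np.concatenate([a, b])
        order = np.argsort(pooled)
        combos = np.array(list(combinations(range(20), 10)))
        is_a = np.zeros((len(combos), 20), dtype=bool)
        np.put_along_axis(is_a, combos, True, axis=1)
        is_a = is_a[:, order]  # walk the pooled sorted order
        cdf_a = np.cumsum(is_a, axis=1) / 10.0
        cdf_b = np.cumsum(~is_a, axis=1) / 10.0
        d_all = np.abs(cdf_a - cdf_b).max(axis=1)
        p_enum = np.mean(d_all >= d_obs - 1e-12)
        assert p_obs == pytest.approx(p_enum, abs=1e-10)


# ---------------------------------------------------------------------------
# artifact flag


class TestCentromereArtifact:
    def test_no_deletions(self, small_grid):
        from liquidfrac.ctdna_fraction import StatePath
        state = np.full(small_grid.n_bins, 2)
        path = StatePath(state=state, posterior=np.zeros((len(state), 5)),
                         states=(0, 1, 2, 3, 4), segments=[],
                         log_likelihood=0.0)
        share, flag = centromere_artifact_flag(path, small_grid)
        assert share == 0.0 and flag is False

    def test_all_deletions_centromeric(self, small_grid):
        from liquidfrac.ctdna_fraction import StatePath
        state = np.full(small_grid.n_bins, 2)
        state[small_grid.centromere_flag] = 1
        path = StatePath(state=state, posterior=np.zeros((len(state), 5)),
                         states=(0, 1, 2, 3, 4), segments=[],
                         log_likelihood=0.0)
        share, flag = centromere_artifact_flag(path, small_grid)
        assert share == 1.0 and flag is True

    def test_forty_sixty_split(self, small_grid):
        # 40% of deletion bins peri-centromeric, 60% distal: no flag
        from liquidfrac.ctdna_fraction import StatePath
        state = np.full(small_grid.n_bins, 2)
        cent_idx = np.flatnonzero(small_grid.centromere_flag)[:4]
        # distal bins far from any centromere (2 Mb window = 4 bins)
        distal_idx = np.array([0, 1, 2, 3, 4, 5])
        state[cent_idx] = 1
        state[distal_idx] = 1
        path = StatePath(state=state, posterior=np.zeros((len(state), 5)),
                         states=(0, 1, 2, 3, 4), segments=[],
                         log_likelihood=0.0)
        share, flag = centromere_artifact_flag(path, small_grid)
        assert share == pytest.approx(0.4)
        assert flag is False


# ---------------------------------------------------------------------------
# residual QC


class TestResidualQc:
    def test_exchangeable_noise_not_significant(self, medium_grid):
        # pure-noise ratios: permutation changes nothing, KS p is large
        truth = simulate_cnv_profile(medium_grid, 0.0,
                                     altered_genome_fraction=0.0, seed=20)
        counts = simulate_cfdna_counts(medium_grid, truth, 500,
                                       FLAT_GC_BIAS, 1000, seed=21)
        prof = normalize_counts(counts, medium_grid)
        path = decode_states(prof, 0.0, 0.999, 1000.0)
        qc = residual_qc(prof, path, 0.0, 1000.0, EstimatorConfig(), seed=1)
        assert qc["ks_p"] > 0.05

    def test_strong_signal_significant(self, medium_grid):
        truth = simulate_cnv_profile(medium_grid, 0.4, seed=22)
        counts = simulate_cfdna_counts(medium_grid, truth, 500,
                                       FLAT_GC_BIAS, 1000, seed=23)
        est = estimate_ctdna(counts, medium_grid, EstimatorConfig(seed=5))
        assert est.qc["ks_p"] <= 0.05
        assert est.status == "detected"

    def test_deterministic_under_fixed_seed(self, medium_grid):
        truth = simulate_cnv_profile(medium_grid, 0.3, seed=24)
        counts = simulate_cfdna_counts(medium_grid, truth, 500,
                                       FLAT_GC_BIAS, 1000, seed=25)
        a = estimate_ctdna(counts, medium_grid, EstimatorConfig(seed=9))
        b = estimate_ctdna(counts, medium_grid, EstimatorConfig(seed=9))
        assert a.qc == b.qc
        assert a.tumor_fraction == b.tumor_fraction

    def test_short_profile_rejected(self):
        prof = make_profile(np.ones(30))
        path = decode_states(prof, 0.0, 0.999, 500.0)
        with pytest.raises(ValueError, match="too short"):
            residual_qc(prof, path, 0.0, 500.0, EstimatorConfig(), seed=0)


# ---------------------------------------------------------------------------
# full estimator


class TestEstimator:
    def test_null_sample_not_detected(self, medium_grid):
        truth = simulate_cnv_profile(medium_grid, 0.0,
                                     altered_genome_fraction=0.0, seed=30)
        counts = simulate_cfdna_counts(medium_grid, truth, 500,
                                       DEFAULT_GC_BIAS, 1000, seed=31)
        est = estimate_ctdna(counts, medium_grid, EstimatorConfig(seed=2))
        assert est.status == "not_detected"
        assert est.tumor_fraction == 0.0

    def test_recovery_and_status_invariants(self, medium_grid):
        truth = simulate_cnv_profile(medium_grid, 0.3, seed=32)
        counts = simulate_cfdna_counts(medium_grid, truth, 500,
                                       DEFAULT_GC_BIAS, 1000, seed=33)
        est = estimate_ctdna(counts, medium_grid, EstimatorConfig(seed=3))
        assert 0.0 <= est.tumor_fraction <= 1.0
        if est.status == "detected":
            assert est.qc["ks_p"] <= 0.05
            assert est.qc["centromere_deletion_share"] <= 0.5
            assert est.path.n_altered(est.profile.included) >= 1
        assert est.tumor_fraction == pytest.approx(0.3, abs=0.05)

    def test_rescaling_counts_leaves_estimate_invariant(self, medium_grid):
        truth = simulate_cnv_profile(medium_grid, 0.3, seed=34)
        counts = simulate_cfdna_counts(medium_grid, truth, 500,
                                       FLAT_GC_BIAS, 1000, seed=35)
        cfg = EstimatorConfig(seed=4, run_qc=False)
        a = estimate_ctdna(counts, medium_grid, cfg)
        doubled = BinCounts(counts.sample_id, counts.counts * 2)
        b = estimate_ctdna(doubled, medium_grid, cfg)
        assert a.status == b.status
        assert a.tumor_fraction == pytest.approx(b.tumor_fraction, abs=0.01)

    def test_default_reinjection_pass_logged(self):
        # density init yields a fraction, the first decode finds no CNVs:
        # the 0.05 default pass must run (visible in the iteration log)
        rng = np.random.default_rng(40)
        n = 400
        ratio = 1 + rng.normal(0, 0.05, n)
        ratio[::10] = 0.6 + rng.normal(0, 0.01, 40)  # scattered false mode
        prof = make_profile(ratio, weight=30.0)
        est = _fit_sample(prof, EstimatorConfig(), dispersion=100.0)
        stages = [h.get("stage") for h in est.history]
        assert "default_reinjection" in stages
        assert est.status == "not_detected"

    def test_objective_monotone_over_iterations(self, medium_grid):
        truth = simulate_cnv_profile(medium_grid, 0.2, seed=36)
        counts = simulate_cfdna_counts(medium_grid, truth, 500,
                                       FLAT_GC_BIAS, 1000, seed=37)
        est = estimate_ctdna(counts, medium_grid,
                             EstimatorConfig(seed=6, run_qc=False))
        objs = [h["objective"] for h in est.history
                if "objective" in h and h.get("stage") is None]
        # within each ascent the tracked objective never decreases
        # (restarts begin a new ascent; compare within the first one)
        first_run = []
        for h in est.history:
            if h.get("stage") == "alias_restart":
                break
            if "objective" in h:
                first_run.append(h["objective"])
        assert all(b >= a - 1e-6 for a, b in zip(first_run, first_run[1:]))
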