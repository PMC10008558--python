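"""Cross-entropy likelihood, priors, MAP estimation and the CRLB."""

import numpy as np
import pytest

from trackmel.localization import (
    Estimate,
    MapReconstructor,
    PhotonPattern,
    PriorConfig,
    PriorState,
    SearchConfig,
    crlb,
    fwhm_to_sigma,
    map_estimate,
    neg_log_likelihood_at,
    photon_efficiency,
    prior_c_gaussian,
    prior_efficiency_bounds,
    prior_jump,
    sigma_r_to_dmax,
    tail_average,
    update_c_ewma,
    update_r_ewma,
)
from trackmel.psf_pattern import PSFStack

from conftest import gaussian_stack


def two_slot_pattern(counts, positions=None):
    positions = positions if positions is not None else np.zeros((2, 3))
    return PhotonPattern(np.asarray(counts), positions, np.zeros(2, dtype=bool))


def pattern_from_counts(counts_illuminated, schedule, displacements_all):
    """Full 42-slot pattern with the given counts on the illuminated slots."""
    counts = np.zeros(schedule.n_slots)
    counts[schedule.illuminated] = counts_illuminated
    return PhotonPattern(counts, displacements_all, schedule.blank_mask)


def neutral_priors():
    """Prior settings that reduce the MAP estimate to the plain MLE."""
    return PriorConfig(
        gamma_c=1.0, sigma_c_rel=1e12, gamma_r=1e-12, fwhm_r_nm=(1e9, 1e9, 1e9),
        c_min=0.0, c_max=np.inf, r_tail=1.0,
    )


class TestPhotonEfficiency:
    def test_single_slot_ratio(self, flat_psf):
        pat = PhotonPattern(np.array([5]), np.zeros((1, 3)), np.array([False]))
        c, att = photon_efficiency(pat, flat_psf, np.zeros((1, 3)))
        assert att[0] and c[0] == pytest.approx(5.0)

    def test_all_zero_counts_give_zero(self, flat_psf):
        pat = two_slot_pattern([0, 0])
        c, att = photon_efficiency(pat, flat_psf, np.zeros((1, 3)))
        assert c[0] == 0.0

    def test_sum_ratio_arithmetic(self):
        # two slots with PSF values summing to 1.0 at the probe position
        stack = PSFStack(np.full((3, 3, 3), 0.5), (100.0,) * 3, (-100.0, -100.0, -100.0))
        pat = two_slot_pattern([2, 3])
        c, _ = photon_efficiency(pat, stack, np.zeros((1, 3)))
        assert c[0] == pytest.approx(5.0)


class TestNegLogLikelihood:
    def test_symmetric_two_slot_closed_form(self, flat_psf):
        # equal counts on equal PSFs: cross-entropy = 2 ln 2
        pat = two_slot_pattern([1, 1])
        grid = neg_log_likelihood_at(pat, flat_psf, np.zeros((1, 3)))
        assert grid.values[0] == pytest.approx(2.0 * np.log(2.0))

    def test_zero_total_counts_rejected(self, flat_psf):
        pat = two_slot_pattern([0, 0])
        with pytest.raises(ValueError, match="flat"):
            neg_log_likelihood_at(pat, flat_psf, np.zeros((1, 3)))

    def test_counts_proportional_to_psf_minimize_at_truth(
        self, psf, schedule, displacements_all
    ):
        # Gibbs' inequality: count ratios equal to PSF ratios pin the minimum
        r_p = np.array([100.0, -50.0, 200.0])
        disp = displacements_all[schedule.illuminated]
        lam = 100.0 * psf.value(r_p[None] - disp, outside="zero")
        pat = pattern_from_counts(lam, schedule, displacements_all)
        axes = [np.arange(-300.0, 301.0, 50.0) + o for o in r_p]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        grid = neg_log_likelihood_at(pat, psf, pts)
        best = pts[np.argmin(grid.values)]
        np.testing.assert_allclose(best, r_p, atol=1e-9)

    def test_count_scaling_preserves_argmin_and_sharpens(
        self, psf, schedule, displacements_all
    ):
        rng = np.random.default_rng(0)
        disp = displacements_all[schedule.illuminated]
        lam = 10.0 * psf.value(-disp, outside="zero")
        counts = rng.poisson(lam)
        counts[counts.sum() == 0] = 1
        pts = np.stack(
            np.meshgrid(np.arange(-200, 201, 10.0), [0.0], [0.0], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        v1 = neg_log_likelihood_at(
            pattern_from_counts(counts, schedule, displacements_all), psf, pts
        ).values
        v4 = neg_log_likelihood_at(
            pattern_from_counts(counts * 4, schedule, displacements_all), psf, pts
        ).values
        assert np.argmin(v1) == np.argmin(v4)
        curv1 = np.diff(v1, 2)
        curv4 = np.diff(v4, 2)
        np.testing.assert_allclose(curv4, 4.0 * curv1, rtol=1e-6, atol=1e-9)


class TestEfficiencyBoundPrior:
    def test_all_permissive_bounds(self, flat_psf):
        pat = two_slot_pattern([3, 4])
        t = prior_efficiency_bounds(pat, flat_psf, np.zeros((1, 3)), 0.0, np.inf)
        assert t[0] == 0.0

    def test_low_power_region_excluded(self, psf, schedule, displacements_all):
        # a corner far from every shot has negligible PSF power: with counts
        # present it cannot host the emitter
        pat = pattern_from_counts(
            np.full(39, 2.0), schedule, displacements_all
        )
        far = np.array([[3000.0, 3000.0, 3000.0]])
        t = prior_efficiency_bounds(pat, psf, far, 0.0, np.inf)
        assert np.isinf(t[0])

    def test_mask_matches_bruteforce_ratio(self, psf, schedule, displacements_all):
        rng = np.random.default_rng(1)
        disp = displacements_all[schedule.illuminated]
        counts = rng.poisson(5.0, size=39)
        pat = pattern_from_counts(counts, schedule, displacements_all)
        pts = rng.uniform(-400, 400, size=(200, 3))
        c_min, c_max = 2.0, 40.0
        t = prior_efficiency_bounds(pat, psf, pts, c_min, c_max)
        # independent recomputation of the ratio estimator per point
        for k in range(len(pts)):
            sphi = psf.value(pts[k][None] - disp, outside="zero").sum()
            if sphi <= 1e-6 * psf.max_intensity:
                assert np.isinf(t[k])
            else:
                c = counts.sum() / sphi
                assert np.isinf(t[k]) == (not (c_min < c < c_max))

    def test_invalid_bounds_rejected(self, flat_psf):
        with pytest.raises(ValueError):
            prior_efficiency_bounds(two_slot_pattern([1, 0]), flat_psf, np.zeros((1, 3)), 5.0, 1.0)


class TestEwmaPriors:
    def test_gc_zero_at_first_pattern(self, flat_psf):
        state = PriorState(PriorConfig(), j=0)
        pat = two_slot_pattern([1, 1])
        np.testing.assert_array_equal(
            prior_c_gaussian(state, pat, flat_psf, np.zeros((3, 3))), 0.0
        )

    def test_full_weight_tracks_last_value(self):
        state = PriorState(PriorConfig(gamma_c=1.0), j=1, c_hat=3.0)
        assert update_c_ewma(state, 7.0).c_hat == pytest.approx(7.0)

    def test_half_weight_averages(self):
        state = PriorState(PriorConfig(gamma_c=0.5), j=1, c_hat=0.0)
        assert update_c_ewma(state, 4.0).c_hat == pytest.approx(2.0)

    def test_r_ewma_requires_center_initialization(self):
        state = PriorState(PriorConfig(), j=0, r_hat=None)
        with pytest.raises(ValueError):
            update_r_ewma(state, np.zeros(3))

    def test_jump_penalty_zero_at_ewma(self):
        state = PriorState(PriorConfig(), j=1, r_hat=np.array([10.0, -5.0, 3.0]))
        assert prior_jump(state, state.r_hat[None, :])[0] == pytest.approx(0.0)

    def test_jump_penalty_ln2_at_half_fwhm(self):
        # Gaussian prior: at half the FWHM from the mean the penalty is ln 2
        state = PriorState(PriorConfig(fwhm_r_nm=(470.0, 470.0, 470.0)), j=1, r_hat=np.zeros(3))
        pen = prior_jump(state, np.array([[235.0, 0.0, 0.0]]))[0]
        assert pen == pytest.approx(np.log(2.0), rel=1e-12)

    def test_jump_prior_implies_24_um2s_ceiling(self):
        sigma = fwhm_to_sigma(470.0)
        assert sigma == pytest.approx(199.6, abs=0.05)
        assert sigma_r_to_dmax(sigma, 0.84e-3) == pytest.approx(24.0, abs=0.5)


class TestTailAverage:
    def test_no_tail_uses_current_only(self):
        prev = np.array([5.0, 5.0])
        cur = np.array([1.0, 2.0])
        np.testing.assert_allclose(tail_average(prev, cur, 1.0), cur)

    def test_constant_sequence_is_fixed_point(self):
        l = np.array([2.0, 3.0])
        out = l.copy()
        for _ in range(5):
            out = tail_average(out, l, 0.3)
        np.testing.assert_allclose(out, l)

    def test_half_ratio_arithmetic(self):
        l0 = np.array([2.0])
        l1 = np.array([4.0])
        t0 = tail_average(None, l0, 0.5)
        np.testing.assert_allclose(t0, l0)  # initialization: first likelihood
        np.testing.assert_allclose(tail_average(t0, l1, 0.5), [3.0])

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            tail_average(None, np.zeros(2), 0.0)


class TestMapEstimate:
    def test_proportional_counts_localize_exactly(self, psf, schedule, displacements_all):
        r_p = np.array([150.0, -100.0, 250.0])  # on the 10 nm lattice
        disp = displacements_all[schedule.illuminated]
        lam = 50.0 * psf.value(r_p[None] - disp, outside="zero")
        pat = pattern_from_counts(lam, schedule, displacements_all)
        est = map_estimate(pat, psf, priors=neutral_priors())
        np.testing.assert_allclose(est.r_tilde, r_p, atol=1e-9)

    def test_reduces_to_plain_mle_with_neutral_priors(self, psf, schedule, displacements_all):
        rng = np.random.default_rng(3)
        disp = displacements_all[schedule.illuminated]
        counts = rng.poisson(2.0 * psf.value(-disp, outside="zero"))
        pat = pattern_from_counts(counts, schedule, displacements_all)
        est = map_estimate(pat, psf, priors=neutral_priors())
        # exhaustive fine-lattice search of the bare likelihood
        axes = [np.arange(-600.0, 601.0, 10.0)] * 2 + [np.arange(-600.0, 601.0, 10.0)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = neg_log_likelihood_at(pat, psf, pts).values
        best = vals.min()
        np.testing.assert_allclose(
            neg_log_likelihood_at(pat, psf, est.r_tilde[None]).values[0], best, atol=1e-6
        )

    def test_jump_prior_pulls_outlier_toward_history(self, psf, schedule, displacements_all):
        # emitter far beyond the prior reach: the MAP estimate must sit
        # strictly between the prior mean and the prior-free optimum
        r_far = np.array([450.0, 0.0, 0.0])
        disp = displacements_all[schedule.illuminated]
        lam = 50.0 * psf.value(r_far[None] - disp, outside="zero")
        pat = pattern_from_counts(lam, schedule, displacements_all)
        priors = PriorConfig(fwhm_r_nm=(100.0, 100.0, 100.0), gamma_r=0.5)
        rec = MapReconstructor(psf, priors=priors)
        rec.state = PriorState(priors, j=1, r_hat=np.zeros(3))
        est = rec.estimate(pat)
        assert 0.0 < est.r_tilde[0] < r_far[0]

    def test_zero_photons_yield_gap(self, psf, schedule, displacements_all):
        pat = pattern_from_counts(np.zeros(39), schedule, displacements_all)
        rec = MapReconstructor(psf)
        assert rec.estimate(pat) is None
        assert rec.state.j == 1  # pattern consumed, no estimate fabricated

    def test_coarse_to_fine_matches_exhaustive_with_priors(
        self, psf, schedule, displacements_all
    ):
        rng = np.random.default_rng(7)
        disp = displacements_all[schedule.illuminated]
        lam = 1.2 * psf.value(np.array([60.0, -40.0, 90.0])[None] - disp, outside="zero")
        counts = rng.poisson(lam)
        pat = pattern_from_counts(counts, schedule, displacements_all)
        priors = PriorConfig()
        search = SearchConfig(window_halfwidth_nm=(200.0, 200.0, 200.0))
        rec = MapReconstructor(psf, priors=priors, search=search)
        rec.state = PriorState(priors, j=1, c_hat=25.0, r_hat=np.zeros(3))
        est = rec.estimate(pat)
        # exhaustive 10 nm search over the same window, recomputed from the
        # standalone prior/likelihood functions
        axes = [np.arange(-200.0, 201.0, 10.0)] * 3
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        state = PriorState(priors, j=1, c_hat=25.0, r_hat=np.zeros(3))
        obj = (
            neg_log_likelihood_at(pat, psf, pts).values
            + prior_efficiency_bounds(pat, psf, pts, priors.c_min, priors.c_max)
            + prior_c_gaussian(state, pat, psf, pts)
            + prior_jump(state, pts)
        )
        np.testing.assert_allclose(est.objective, obj.min(), rtol=1e-10)

    def test_tail_averaging_tightens_stationary_estimates(
        self, psf, schedule, displacements_all
    ):
        # exponential likelihood averaging pools photons across patterns:
        # for a stationary emitter the scatter of estimates must shrink
        rng = np.random.default_rng(11)
        disp = displacements_all[schedule.illuminated]
        # ~50 counts per pattern, the 60 kHz operating point
        lam = 25.0 * psf.value(-disp, outside="zero")

        def run(r_tail):
            rec = MapReconstructor(
                psf,
                priors=PriorConfig(r_tail=r_tail),
                search=SearchConfig(window_halfwidth_nm=(150.0, 150.0, 150.0)),
            )
            gen = np.random.default_rng(5)
            ests = []
            for j in range(60):
                counts = gen.poisson(lam)
                pat = pattern_from_counts(counts, schedule, displacements_all)
                pat.index = j
                e = rec.estimate(pat)
                if e is not None and j >= 20:  # discard the averaging transient
                    ests.append(e.r_tilde)
            return np.asarray(ests).std(axis=0).mean()

        assert run(0.2) < run(1.0)


class TestCRLB:
    def test_doubling_counts_shrinks_bound_by_sqrt2(self, psf, schedule, displacements_all):
        disp = displacements_all[schedule.illuminated]
        b1 = crlb(psf, disp, np.zeros(3), 100.0)
        b2 = crlb(psf, disp, np.zeros(3), 200.0)
        np.testing.assert_allclose(b1 / b2, np.sqrt(2.0), rtol=1e-6)

    def test_bound_finite_and_smooth_over_interior(self, psf, schedule, displacements_all):
        disp = displacements_all[schedule.illuminated]
        pts = [
            (0.0, 0.0, 0.0), (150.0, 0.0, 0.0), (0.0, 150.0, -150.0),
            (250.0, 250.0, 0.0), (0.0, 0.0, 300.0), (-250.0, 100.0, -300.0),
        ]
        bounds = np.array([crlb(psf, disp, np.array(p), 50.0) for p in pts])
        assert np.all(np.isfinite(bounds))
        # no resolution holes in the interior: bounded variation per axis
        assert np.all(bounds.max(axis=0) / bounds.min(axis=0) < 3.0)

    def test_two_beam_1d_closed_form(self):
        # quasi-1D stack: Gaussian in x, flat in y and z; two beams at +-a.
        # The cell probability is logistic in x, giving the closed form
        # I(x) = N (8a/w^2)^2 p(1-p) and CRLB = 1/sqrt(I).
        w, a, N = 300.0, 150.0, 1000.0
        nx = 801
        x = -800.0 + 2.0 * np.arange(nx)
        vals = np.tile(np.exp(-2 * x**2 / w**2), (3, 3, 1))
        stack = PSFStack(vals, (2.0, 500.0, 500.0), (-800.0, -500.0, -500.0))
        shots = np.array([[-a, 0.0, 0.0], [a, 0.0, 0.0]])
        x0 = 30.0
        p = 1.0 / (1.0 + np.exp(-8.0 * a * x0 / w**2))
        analytic = 1.0 / np.sqrt(N * (8.0 * a / w**2) ** 2 * p * (1.0 - p))
        bounds = crlb(stack, shots, np.array([x0, 0.0, 0.0]), N, delta_nm=3.0)
        assert bounds[0] == pytest.approx(analytic, rel=0.01)
        # flat axes carry no information
        assert np.isinf(bounds[1]) and np.isinf(bounds[2])

    def test_empirical_mle_sd_matches_bound(self, psf, schedule, displacements_all):
        # repeated Poisson draws at ~500 counts: the grid MLE should be
        # efficient — SD within 15% of the bound and not far below it
        disp = displacements_all[schedule.illuminated]
        r_p = np.array([40.0, -30.0, 60.0])
        c_eff = 500.0 / psf.value(r_p[None] - disp, outside="zero").sum()
        rng = np.random.default_rng(3)
        ests = []
        for _ in range(500):
            counts = rng.poisson(c_eff * psf.value(r_p[None] - disp, outside="zero"))
            pat = pattern_from_counts(counts, schedule, displacements_all)
            ests.append(map_estimate(pat, psf, priors=neutral_priors()).r_tilde)
        sd = np.asarray(ests).std(axis=0)
        bound = crlb(psf, disp, r_p, 500.0)
        np.testing.assert_allclose(sd, bound, rtol=0.15)
        assert np.all(sd > bound * 0.95)  # Monte-Carlo slack below the bound
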