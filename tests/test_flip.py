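"""FLIP normalization, one-phase-decay fitting, t75 and Barrier Index."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from budneck.flip import (
    BarrierIndex,
    DecayFit,
    FlipTrace,
    NormalizedDecay,
    analyze_flip_cohort,
    barrier_index,
    cross_run_normalize,
    fit_one_phase_decay,
    normalize_traces,
    pool_profiles,
    time_to_fraction,
)
from budneck.synthetic import FlipSimConfig, flip_latent_trajectory, gen_flip_traces

TIMES = np.arange(70) * 4.0


def decay_curve(plateau, k, times=TIMES):
    return NormalizedDecay(times=times, percent=plateau + (100 - plateau) * np.exp(-k * times))


def exact_fit(plateau, k, se_p=1.0, se_k=0.001, cov=0.0):
    return DecayFit(plateau=plateau, k=k, se_plateau=se_p, se_k=se_k, cov_pk=cov,
                    rss=0.0, n_points=70)


class TestNormalize:
    def test_perfect_correction_gives_constant_100(self):
        """A mother identical to the control mean normalizes to a flat 100%."""
        ctrl = 800.0 * 0.99 ** np.arange(70) + 50.0
        mother = FlipTrace("c1", "mother", TIMES, ctrl)
        bud = FlipTrace("c1", "bud", TIMES, ctrl * 0.5 + 25.0)
        controls = [FlipTrace(f"k{i}", "control", TIMES, ctrl) for i in range(3)]
        m, _ = normalize_traces(mother, bud, controls, background=50.0)
        np.testing.assert_allclose(m.percent, 100.0, rtol=1e-12)

    def test_background_swallowing_signal_aborts(self):
        tr = lambda cid, role: FlipTrace(cid, role, TIMES, np.full(70, 30.0))
        with pytest.raises(ValueError, match="non-positive"):
            normalize_traces(tr("c", "mother"), tr("c", "bud"),
                             [tr("k", "control")], background=30.0)

    def test_mismatched_grids_abort(self):
        mother = FlipTrace("c", "mother", TIMES, np.full(70, 500.0))
        bud = FlipTrace("c", "bud", TIMES + 1.0, np.full(70, 500.0))
        ctrl = [FlipTrace("k", "control", TIMES, np.full(70, 500.0))]
        with pytest.raises(ValueError, match="time grid"):
            normalize_traces(mother, bud, ctrl)

    def test_acquisition_decay_is_removed_by_control_correction(self):
        """Control correction on a=0.002 traces recovers the a=0 latent decay."""
        base = dict(n_cells=1, bleach_fraction=0.05, exchange_rate=0.01,
                    noise_sd=0.0, background=50.0, seed=0)
        with_a = FlipSimConfig(acquisition_decay=0.002, **base)
        no_a = FlipSimConfig(acquisition_decay=0.0, **base)
        traces = gen_flip_traces(with_a)
        mother = next(t for t in traces if t.role == "mother")
        bud = next(t for t in traces if t.role == "bud")
        controls = [t for t in traces if t.role == "control"]
        m_norm, _ = normalize_traces(mother, bud, controls, background=50.0)
        latent_m, _, _ = flip_latent_trajectory(no_a)
        np.testing.assert_allclose(m_norm.percent, 100.0 * latent_m / latent_m[0], rtol=1e-9)


class TestPooling:
    def test_single_profile_is_identity(self):
        d = decay_curve(20, 0.05)
        np.testing.assert_array_equal(pool_profiles([d]).percent, d.percent)

    def test_mirror_profiles_average_to_100(self):
        p = decay_curve(20, 0.05)
        mirror = NormalizedDecay(times=TIMES, percent=200.0 - p.percent)
        np.testing.assert_allclose(pool_profiles([p, mirror]).percent, 100.0, atol=1e-9)

    def test_pooled_mean_within_clt_bound(self):
        """50 noisy replicates pool to within 3*(sd/sqrt(50)) of truth per frame."""
        rng = np.random.default_rng(42)
        truth = decay_curve(20, 0.02).percent
        sd = 4.0
        reps = []
        for _ in range(50):
            noisy = truth + rng.normal(0, sd, truth.size)
            noisy[0] = 100.0
            reps.append(NormalizedDecay(times=TIMES, percent=noisy))
        pooled = pool_profiles(reps)
        assert np.all(np.abs(pooled.percent[1:] - truth[1:]) < 3 * sd / np.sqrt(50) + 1e-9)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            pool_profiles([])


class TestFit:
    @pytest.mark.parametrize("plateau,k", [(20.0, 0.05), (0.0, 0.05), (50.0, 0.002)])
    def test_exact_curve_recovered(self, plateau, k):
        fit = fit_one_phase_decay(decay_curve(plateau, k))
        assert fit.converged
        assert fit.plateau == pytest.approx(plateau, abs=1e-6)
        assert fit.k == pytest.approx(k, abs=1e-6)
        assert fit.rss < 1e-12

    def test_flat_trace_flagged_or_flat(self):
        fit = fit_one_phase_decay(NormalizedDecay(times=TIMES, percent=np.full(70, 100.0)))
        assert fit.rss < 1e-6
        # flat fit: either flagged, or the fitted curve stays at 100 throughout
        assert (not fit.converged) or np.max(np.abs(fit.predict(TIMES) - 100.0)) < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_one_phase_decay(NormalizedDecay(times=np.arange(5) * 4.0,
                                                percent=np.array([100, 90, 80, 70, 60.0])))


class TestTimeToFraction:
    def test_pure_exponential_closed_form(self):
        t, _, cens = time_to_fraction(exact_fit(0.0, 0.02877))
        assert not cens
        assert t == pytest.approx(math.log(4 / 3) / 0.02877, rel=1e-12)
        assert t == pytest.approx(10.0, rel=1e-3)

    def test_half_plateau_closed_form(self):
        t, _, cens = time_to_fraction(exact_fit(50.0, 0.1))
        assert not cens
        assert t == pytest.approx(10.0 * math.log(2), rel=1e-12)

    def test_plateau_above_threshold_censored(self):
        _, _, cens = time_to_fraction(exact_fit(80.0, 0.05))
        assert cens

    def test_zero_rate_censored(self):
        _, _, cens = time_to_fraction(exact_fit(0.0, 0.0))
        assert cens

    def test_closed_form_matches_numeric_root(self):
        """Closed-form t75 agrees with root-finding on the fitted curve to 1e-9."""
        for plateau, k in [(0.0, 0.05), (30.0, 0.01), (74.0, 0.2), (-50.0, 0.003)]:
            fit = exact_fit(plateau, k)
            t, _, cens = time_to_fraction(fit)
            assert not cens
            t_root = brentq(lambda x: fit.predict(x) - 75.0, 1e-12, 1e7, xtol=1e-13, rtol=1e-15)
            assert t == pytest.approx(t_root, rel=1e-9)

    def test_delta_method_matches_finite_differences(self):
        fit = exact_fit(20.0, 0.01, se_p=2.0, se_k=0.002, cov=-1e-3)
        t, se, _ = time_to_fraction(fit)
        eps = 1e-7
        dp = (time_to_fraction(exact_fit(20 + eps, 0.01))[0] - t) / eps
        dk = (time_to_fraction(exact_fit(20.0, 0.01 + eps))[0] - t) / eps
        var = dk**2 * fit.se_k**2 + dp**2 * fit.se_plateau**2 + 2 * dk * dp * fit.cov_pk
        assert se == pytest.approx(math.sqrt(var), rel=1e-5)


class TestBarrierIndex:
    def test_symmetric_fits_give_unity(self):
        fit = exact_fit(10.0, 0.03)
        bi = barrier_index(fit, fit)
        assert bi.value == pytest.approx(1.0, rel=1e-12)

    def test_tenfold_rate_difference_gives_bi_ten(self):
        bi = barrier_index(exact_fit(0.0, 0.02877), exact_fit(0.0, 0.0028768))
        assert bi.value == pytest.approx(10.0, rel=1e-3)
        assert bi.t75_bud == pytest.approx(100.0, rel=1e-2)
        assert bi.t75_mother == pytest.approx(10.0, rel=1e-3)

    def test_bud_plateau_above_threshold_censors(self):
        bi = barrier_index(exact_fit(0.0, 0.03), exact_fit(80.0, 0.03))
        assert bi.censored and math.isnan(bi.value)
        assert "n.d." in str(bi)

    def test_censored_mother_is_an_error(self):
        with pytest.raises(ValueError, match="mother"):
            barrier_index(exact_fit(80.0, 0.03), exact_fit(0.0, 0.03))

    def test_se_propagation_is_relative(self):
        fm = exact_fit(0.0, 0.03, se_k=0.003)  # 10% relative on K -> on t75
        fb = exact_fit(0.0, 0.01, se_k=0.001)
        bi = barrier_index(fm, fb)
        tm, se_tm, _ = time_to_fraction(fm)
        tb, se_tb, _ = time_to_fraction(fb)
        expect = bi.value * math.sqrt((se_tm / tm) ** 2 + (se_tb / tb) ** 2)
        assert bi.se == pytest.approx(expect, rel=1e-12)


class TestCrossRunNormalize:
    @staticmethod
    def bi(value, se=1.0):
        return BarrierIndex(value=value, se=se, censored=False, t75_mother=10, t75_bud=10 * value)

    def test_identical_references_are_identity(self):
        out = cross_run_normalize(self.bi(20.0), self.bi(30.0), self.bi(30.0))
        assert out.value == pytest.approx(20.0, rel=1e-12)

    def test_triple_ratio_arithmetic(self):
        out = cross_run_normalize(self.bi(20.0), self.bi(30.0), self.bi(42.0))
        assert out.value == pytest.approx(28.0, rel=1e-12)

    def test_censored_input_rejected(self):
        cens = BarrierIndex(float("nan"), float("nan"), True, 10.0, float("nan"))
        with pytest.raises(ValueError):
            cross_run_normalize(self.bi(20.0), cens, self.bi(42.0))


class TestCohortPipeline:
    def test_deterministic_given_seed(self):
        cfg = FlipSimConfig(n_cells=8, noise_sd=3.0, seed=77)
        a = analyze_flip_cohort(gen_flip_traces(cfg), background=cfg.background)
        b = analyze_flip_cohort(gen_flip_traces(cfg), background=cfg.background)
        assert a["barrier_index"].value == b["barrier_index"].value

    def test_no_exchange_censors_or_dominates(self):
        """x=0: the bud never decays, so its BI is censored (or huge)."""
        cfg = FlipSimConfig(n_cells=10, exchange_rate=0.0, noise_sd=1.0, seed=5)
        bi0 = analyze_flip_cohort(gen_flip_traces(cfg), background=cfg.background)["barrier_index"]
        cfg_x = FlipSimConfig(n_cells=10, exchange_rate=0.02, noise_sd=1.0, seed=5)
        bix = analyze_flip_cohort(gen_flip_traces(cfg_x), background=cfg_x.background)["barrier_index"]
        assert bi0.censored or bi0.value > bix.value
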