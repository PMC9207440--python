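import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmq.cosinor import OMEGA, fit_cosinor, noise_signal_ratio

from _oracles import gridsearch_cosinor


def sinusoid(t, mesor, amp, acro_h):
    return mesor + amp * np.cos(OMEGA * (np.asarray(t, float) - acro_h))


class TestExactFits:
    def test_noise_free_sinusoid_recovered_exactly(self, design_times):
        t = np.repeat(design_times[:-1], 3)
        y = sinusoid(t, 5.0, 2.0, 6.0)
        fit = fit_cosinor(t, y)
        assert fit.mesor == pytest.approx(5.0, abs=1e-12)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-12)
        assert fit.acrophase_h == pytest.approx(6.0, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.se_mesor == pytest.approx(0.0, abs=1e-12)
        assert fit.se_amplitude == pytest.approx(0.0, abs=1e-12)
        assert noise_signal_ratio(fit) == pytest.approx(0.0, abs=1e-12)

    def test_flat_series_has_zero_amplitude_and_undefined_acrophase(self):
        t = [3.0, 7.0, 11.0, 15.0, 19.0, 23.0]
        fit = fit_cosinor(t, np.full(6, 4.2))
        assert fit.mesor == pytest.approx(4.2)
        assert fit.amplitude == 0.0
        assert not fit.amplitude_defined
        assert np.isnan(fit.acrophase_h)
        assert np.isnan(fit.noise_signal)

    def test_follow_up_sample_at_27h_is_phase_equivalent_to_3h(self):
        t = np.array([3.0, 7.0, 11.0, 15.0, 19.0, 23.0, 27.0])
        y = sinusoid(t, 3.0, 1.5, 22.3)
        fit = fit_cosinor(t, y)
        assert fit.acrophase_h == pytest.approx(22.3, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)


class TestValidation:
    def test_rejects_fewer_than_four_observations(self):
        with pytest.raises(ValueError, match=">= 4 observations"):
            fit_cosinor([3, 7, 11], [1, 2, 3])

    def test_rejects_fewer_than_three_distinct_phases(self):
        # 3 h and 27 h collapse to one phase mod 24
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_cosinor([3, 27, 3, 27, 15, 15], [1, 2, 1, 2, 3, 3])

    def test_noise_signal_is_plain_ratio(self, design_times):
        rng = np.random.default_rng(5)
        t = np.repeat(design_times, 7)
        y = sinusoid(t, 5, 2, 12) + rng.normal(0, 0.5, t.size)
        fit = fit_cosinor(t, y)
        assert noise_signal_ratio(fit) == pytest.approx(
            fit.se_amplitude / fit.amplitude
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_linearized_solution_matches_grid_search(self, seed, design_times):
        rng = np.random.default_rng(seed)
        t = np.repeat(design_times, rng.integers(2, 5))
        y = sinusoid(t, rng.uniform(1, 10), rng.uniform(0.5, 4),
                     rng.uniform(0, 24)) + rng.normal(0, rng.uniform(0.1, 1), t.size)
        fit = fit_cosinor(t, y)
        m, a, phi, rss = gridsearch_cosinor(t, y)
        assert fit.mesor == pytest.approx(m, rel=1e-6)
        assert fit.amplitude == pytest.approx(a, rel=1e-6)
        dphi = (fit.acrophase_rad - phi + np.pi) % (2 * np.pi) - np.pi
        assert abs(dphi) < 1e-3
        assert fit.rss <= rss + 1e-9


@st.composite
def cosinor_instance(draw):
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    t = np.repeat([3.0, 7.0, 11.0, 15.0, 19.0, 23.0, 27.0], 3)
    mesor = draw(st.floats(0.5, 20))
    amp = draw(st.floats(0.1, 5))
    acro = draw(st.floats(0, 23.999))
    y = sinusoid(t, mesor, amp, acro) + rng.normal(0, 0.3, t.size)
    return t, y


class TestInvariances:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(cosinor_instance(), st.floats(-30, 30))
    def test_time_shift_equivariance(self, inst, delta):
        t, y = inst
        f0 = fit_cosinor(t, y)
        f1 = fit_cosinor(t + delta, y)
        assert f1.mesor == pytest.approx(f0.mesor, rel=1e-9)
        assert f1.amplitude == pytest.approx(f0.amplitude, rel=1e-9)
        assert f1.rss == pytest.approx(f0.rss, abs=1e-9)
        shift = (f1.acrophase_h - f0.acrophase_h - delta) % 24.0
        assert min(shift, 24 - shift) < 1e-6

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(cosinor_instance())
    def test_periodicity_t_plus_24(self, inst):
        t, y = inst
        t2 = t.copy()
        t2[::2] += 24.0
        f0, f1 = fit_cosinor(t, y), fit_cosinor(t2, y)
        assert f1.mesor == pytest.approx(f0.mesor, rel=1e-9)
        assert f1.amplitude == pytest.approx(f0.amplitude, rel=1e-9)
        assert f1.acrophase_rad == pytest.approx(f0.acrophase_rad, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(cosinor_instance())
    def test_reflection_flips_acrophase_by_half_period(self, inst):
        t, y = inst
        f0 = fit_cosinor(t, y)
        f1 = fit_cosinor(t, 2 * y.mean() - y)
        assert f1.amplitude == pytest.approx(f0.amplitude, rel=1e-9)
        dphi = (f1.acrophase_rad - f0.acrophase_rad - np.pi) % (2 * np.pi)
        assert min(dphi, 2 * np.pi - dphi) < 1e-6


class TestStandardErrors:
    def test_empirical_sd_matches_delta_method_se(self, design_times):
        """Small Monte-Carlo check of SE(A); the full-size one is in acceptance."""
        rng = np.random.default_rng(11)
        t = np.repeat(design_times, 7)
        amps, ses = [], []
        for _ in range(800):
            y = sinusoid(t, 5, 2, 12) + rng.normal(0, 0.5, t.size)
            fit = fit_cosinor(t, y)
            amps.append(fit.amplitude)
            ses.append(fit.se_amplitude)
        assert np.std(amps, ddof=1) == pytest.approx(np.mean(ses), rel=0.10)

    def test_amplitude_upward_biased_near_zero(self, design_times):
        # A-hat = |beta| is biased up when the true amplitude vanishes
        rng = np.random.default_rng(3)
        t = np.repeat(design_times, 7)
        amps = [
            fit_cosinor(t, 5 + rng.normal(0, 0.5, t.size)).amplitude
            for _ in range(400)
        ]
        assert np.mean(amps) > 0.0
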