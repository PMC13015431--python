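"""Ground-truth checks for the synthetic-data generators."""

import math

import numpy as np
import pytest
from scipy import stats as sstats
from scipy.signal import hilbert, periodogram

from edgecrit import synth
from edgecrit.synth import (
    BandComponent,
    KuramotoConfig,
    SchedulingError,
    StimulusSchedule,
    SurrogateSpec,
    generate_composite_epoch,
    generate_fgn,
    generate_mrw,
    generate_powerlaw,
    generate_rts,
    generate_schedule,
    simulate_kuramoto,
    summarize_transition,
    sweep_coupling,
    transition_demo_config,
)


class TestKuramoto:
    def test_uncoupled_network_stays_near_finite_size_floor(self):
        cfg = KuramotoConfig(coupling_K=0.0, n_oscillators=200,
                             duration=20.0, seed=1)
        tr = simulate_kuramoto(cfg)
        floor = 200 ** -0.5
        assert tr.mean_R(discard=2.0) < 4 * floor
        assert tr.mean_R(discard=2.0) > floor / 4

    def test_strong_identical_coupling_locks_phases(self):
        cfg = KuramotoConfig(coupling_K=50.0, lag_alpha=0.0,
                             n_oscillators=100, duration=10.0, seed=2,
                             natural_freq_band=(10.0, 10.0))
        tr = simulate_kuramoto(cfg, omega=np.full(100, 2 * math.pi * 10.0))
        assert tr.order_parameter_R[-1] > 0.999

    def test_order_parameter_bounded_and_phases_wrapped(self):
        tr = simulate_kuramoto(KuramotoConfig(coupling_K=2.0, duration=12.0,
                                              n_oscillators=50, seed=3))
        r = tr.order_parameter_R
        assert np.all((r >= 0.0) & (r <= 1.0))
        assert np.all((tr.phases >= 0.0) & (tr.phases < 2 * math.pi))

    def test_mean_R_nondecreasing_in_K(self):
        """Synchrony grows with coupling, averaged over a small seed bank."""
        ks = np.arange(0.5, 5.01, 0.75)
        rbars = np.zeros(ks.size)
        for seed in (11, 12, 13):
            base = transition_demo_config(seed=seed, n_oscillators=80,
                                          duration=15.0)
            traces = sweep_coupling(base, ks)
            rbars += np.array([traces[float(k)].mean_R(3.0) for k in ks])
        rbars /= 3.0
        assert np.all(np.diff(rbars) > -0.05)

    def test_sweep_matches_single_simulation_bitwise(self):
        base = transition_demo_config(2.0, seed=5, n_oscillators=40,
                                      duration=12.0)
        traces = sweep_coupling(base, [1.0, 2.0])
        single = simulate_kuramoto(base)
        assert np.array_equal(single.order_parameter_R,
                              traces[2.0].order_parameter_R)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            KuramotoConfig(n_oscillators=1)
        with pytest.raises(ValueError):
            KuramotoConfig(lag_alpha=2.0)
        with pytest.raises(ValueError):
            KuramotoConfig(duration=0.5)


class TestSummarizeTransition:
    def _fake_trace(self, rbar):
        cfg = KuramotoConfig(duration=10.0, dt=1e-2, n_oscillators=2,
                             natural_freq_band=(1.0, 1.0))
        r = np.full(1001, rbar)
        return synth.OscillatorTrace(phases=np.zeros((1, 2)),
                                     order_parameter_R=r, config=cfg)

    def test_no_crossing_returns_none(self):
        traces = {k: self._fake_trace(0.1) for k in (1, 2, 3, 4, 5)}
        assert summarize_transition(traces, 0.5, discard=1.0) is None

    def test_linear_interpolation_between_bracketing_K(self):
        traces = {1.0: self._fake_trace(0.1), 1.5: self._fake_trace(0.15),
                  2.0: self._fake_trace(0.2), 2.5: self._fake_trace(0.25),
                  3.0: self._fake_trace(0.9)}
        est = summarize_transition(traces, 0.5, discard=1.0)
        assert 2.0 < est < 3.0
        # exact interpolation: 2.5 + (0.5-0.25)/(0.9-0.25)*0.5
        assert est == pytest.approx(2.5 + 0.25 / 0.65 * 0.5)

    def test_requires_five_couplings(self):
        with pytest.raises(ValueError):
            summarize_transition({1.0: self._fake_trace(0.1)}, 0.5)


class TestPowerlaw:
    def test_white_noise_has_no_autocorrelation(self):
        x = generate_powerlaw(SurrogateSpec(kind="powerlaw", beta=0.0,
                                            n_samples=2 ** 14, seed=0))
        ac = np.correlate(x, x, "full")[x.size:] / x.size
        assert np.max(np.abs(ac[:10])) < 0.05

    def test_periodogram_slope_recovers_beta(self):
        """Log-log periodogram regression over (1 Hz, fs/2) finds beta=2."""
        spec = SurrogateSpec(kind="powerlaw", beta=2.0, n_samples=2 ** 16,
                             fs=500.0, seed=4)
        x = generate_powerlaw(spec)
        f, p = periodogram(x, fs=500.0)
        m = (f >= 1.0) & (f <= 250.0)
        slope = np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.1)

    def test_seed_reproducibility_and_unit_variance(self):
        spec = SurrogateSpec(kind="powerlaw", beta=1.0, n_samples=2 ** 12,
                             seed=9)
        x1, x2 = generate_powerlaw(spec), generate_powerlaw(spec)
        assert np.array_equal(x1, x2)
        assert x1.std() == pytest.approx(1.0)
        assert x1.mean() == pytest.approx(0.0, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(synth.InsufficientLengthError):
            generate_powerlaw(SurrogateSpec(kind="powerlaw", n_samples=512))


def _structure_function_cumulants(x, levels=(3, 10), wavelet="db1"):
    """Independent oracle: (c1, c2) from wavelet structure functions.

    zeta(q) is fit for q in {1, 2} from log2 of the mean |d|^q across
    octaves (L1 normalization); for a log-normal cascade zeta(q) =
    c1*q + c2*q^2/2, so c2 = zeta(2) - 2*zeta(1) and c1 = zeta(1) - c2/2.
    """
    import pywt

    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=levels[1])
    zetas = {}
    for q in (1.0, 2.0):
        js, ys = [], []
        for lev in range(levels[0], levels[1] + 1):
            d = np.abs(coeffs[len(coeffs) - lev]) * 2.0 ** (-lev / 2.0)
            js.append(lev)
            ys.append(np.log2(np.mean(d ** q)))
        zetas[q] = np.polyfit(js, ys, 1)[0]
    c2 = zetas[2.0] - 2.0 * zetas[1.0]
    c1 = zetas[1.0] - c2 / 2.0
    return c1, c2


class TestFgnAndMrw:
    def test_fgn_variance_and_reproducibility(self):
        spec = SurrogateSpec(kind="fgn", hurst_H=0.8, n_samples=2 ** 12,
                             seed=3)
        x = generate_fgn(spec)
        assert x.std() == pytest.approx(1.0)
        assert np.array_equal(x, generate_fgn(spec))

    def test_fgn_positive_long_range_correlation(self):
        """H > 0.5 implies positively correlated increments."""
        x = generate_fgn(SurrogateSpec(kind="fgn", hurst_H=0.85,
                                       n_samples=2 ** 14, seed=5))
        lag1 = float(np.mean(x[:-1] * x[1:]))
        assert lag1 > 0.2  # theory: 2^(2H-1) - 1 ~ 0.62 at H=0.85

    def test_mrw_cumulants_match_structure_function_oracle(self):
        spec = SurrogateSpec(kind="mrw", c1_target=0.75, c2_target=-0.05,
                             n_samples=2 ** 17, seed=21)
        x = generate_mrw(spec)
        c1, c2 = _structure_function_cumulants(x)
        assert c1 == pytest.approx(0.75, abs=0.05)
        assert c2 < 0
        assert c2 == pytest.approx(-0.05, abs=0.03)

    def test_monofractal_degenerate_when_c2_zero(self):
        spec = SurrogateSpec(kind="mrw", c1_target=0.6, c2_target=0.0,
                             n_samples=2 ** 15, seed=22)
        c1, c2 = _structure_function_cumulants(x := generate_mrw(spec),
                                               levels=(3, 9))
        assert c1 == pytest.approx(0.6, abs=0.05)
        assert abs(c2) < 0.01
        assert np.isfinite(x).all()

    def test_positive_c2_rejected(self):
        with pytest.raises(ValueError):
            SurrogateSpec(kind="mrw", c2_target=0.1)


class TestCompositeEpoch:
    def test_no_components_reduces_to_powerlaw_spectrum(self):
        spec = SurrogateSpec(kind="composite", beta=1.0, n_samples=2 ** 14,
                             seed=7)
        x = generate_composite_epoch(spec)
        f, p = periodogram(x, fs=spec.fs)
        m = (f >= 1.0) & (f <= 100.0)
        slope = np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_am_depth_raises_envelope_variability(self):
        """Hilbert-envelope CV strictly larger at AM depth 0.8 than 0.2."""
        cvs = {}
        for depth in (0.2, 0.8):
            spec = SurrogateSpec(
                kind="composite", beta=1.0, n_samples=2 ** 13, seed=8,
                band_components=(BandComponent(10.0, 4.0, 1.5, depth),))
            x = generate_composite_epoch(spec)
            from scipy.signal import butter, sosfiltfilt

            sos = butter(4, [8, 12], "bandpass", fs=spec.fs, output="sos")
            env = np.abs(hilbert(sosfiltfilt(sos, x))) ** 2
            env = env[500:-500]
            cvs[depth] = env.std() / env.mean()
        assert cvs[0.8] > cvs[0.2]

    def test_band_power_ratio_honored(self):
        spec = SurrogateSpec(
            kind="composite", beta=1.5, n_samples=2 ** 14, seed=9,
            band_components=(BandComponent(10.0, 4.0, 1.0, 0.0),))
        x = generate_composite_epoch(spec)
        bg = generate_powerlaw(SurrogateSpec(kind="powerlaw", beta=1.5,
                                             n_samples=2 ** 14, seed=9))
        f, p = periodogram(x, fs=spec.fs)
        _, pbg = periodogram(bg, fs=spec.fs)
        m = (f >= 8) & (f <= 12)
        ratio = np.trapezoid(p[m], f[m]) / np.trapezoid(pbg[m], f[m]) - 1.0
        assert math.log10(max(ratio, 1e-9)) == pytest.approx(1.0, abs=0.3)

    def test_overlapping_components_warn(self):
        spec = SurrogateSpec(
            kind="composite", n_samples=2 ** 12, seed=1,
            band_components=(BandComponent(10.0, 4.0), BandComponent(11.0, 4.0)))
        with pytest.warns(UserWarning, match="overlap"):
            generate_composite_epoch(spec)


def _check_schedule(s: StimulusSchedule):
    pooled = np.sort(s.onsets()) * 1000.0
    assert np.diff(pooled).min() >= 350.0 - 1e-9
    for stream in ("auditory", "visual"):
        on = s.onsets(stream)
        assert on.size == 25
        assert np.all(np.diff(on) > 0)
        assert on.max() < s.run_duration
        isis = np.diff(on) * 1000.0
        assert isis.min() >= 850.0 - 1e-9
        assert isis.max() <= 2300.0 + 1e-9


class TestSchedule:
    def test_constraints_hold_across_seeded_runs(self):
        for seed in range(100):
            _check_schedule(generate_schedule(seed=seed))

    def test_same_seed_same_schedule(self):
        a, b = generate_schedule(seed=42), generate_schedule(seed=42)
        assert a == b

    def test_single_stimulus_per_stream(self):
        s = generate_schedule(n_per_stream=1, seed=0)
        assert len(s.events) == 2

    def test_infeasible_parameters_raise(self):
        with pytest.raises(SchedulingError):
            generate_schedule(run_duration=5.0, n_per_stream=25, seed=0)


@pytest.fixture(scope="module")
def schedule():
    return generate_schedule(seed=1)


class TestReactionTimes:

    def test_exgaussian_mean_matches_mu_plus_tau(self, schedule):
        rts = []
        for seed in range(400):
            recs = generate_rts(schedule, (400.0, 50.0, 100.0), seed=seed)
            rts += [r.rt for r in recs]
        assert np.mean(rts) == pytest.approx(500.0, abs=5.0)

    def test_small_tau_gives_near_gaussian_skewness(self, schedule):
        rts = []
        for seed in range(200):
            recs = generate_rts(schedule, (400.0, 50.0, 1e-6), seed=seed)
            rts += [r.rt for r in recs]
        assert abs(sstats.skew(rts)) < 0.1

    def test_lapses_inflate_slow_tail(self, schedule):
        q90 = {}
        for rate in (0.0, 0.2):
            rts = []
            for seed in range(200):
                recs = generate_rts(schedule, (400.0, 50.0, 100.0),
                                    lapse_rate=rate, seed=seed)
                rts += [r.rt for r in recs]
            q90[rate] = np.quantile(rts, 0.9)
        assert q90[0.2] > q90[0.0] + 50.0

    def test_invalid_parameters_rejected(self, schedule):
        with pytest.raises(ValueError):
            generate_rts(schedule, (0.0, 50.0, 100.0))
        with pytest.raises(ValueError):
            generate_rts(schedule, lapse_rate=1.0)
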