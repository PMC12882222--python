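import numpy as np
import pytest

from phasorckm import (
    ActigraphySimSpec,
    CorrelationFunction,
    assign_quartiles,
    circular_xcorr,
    compute_phasor,
    fundamental_component,
    segment_and_qc,
    simulate_actigraphy,
)
from phasorckm.phasor import (
    DegenerateGroupingError,
    MAGNITUDE_BOUND,
    weighted_quantile,
    wrap_hours,
)
from phasorckm.preprocess import DayPair

from conftest import sinusoid_day, standardize, xcorr_bruteforce


def make_day(light, activity, idx=0):
    return DayPair(light_t=light, activity_t=activity, valid_fraction=1.0, day_index=idx)


class TestCircularXcorr:
    def test_autocorrelation_at_zero_lag_is_one(self):
        x, _ = sinusoid_day()
        assert circular_xcorr(x, x).r[0] == pytest.approx(1.0, abs=1e-12)

    def test_antiphase_is_minus_one(self):
        x, _ = sinusoid_day()
        assert circular_xcorr(x, -x).r[0] == pytest.approx(-1.0, abs=1e-12)

    def test_shift_moves_argmax(self, rng):
        x = standardize(rng.normal(size=1440))
        for k in (17, 300, 1000):
            y = standardize(np.roll(x, k))
            # y(t) = x(t - k); r is maximal where y(t+tau) aligns with x(t)
            assert np.argmax(circular_xcorr(x, y).r) == k

    @pytest.mark.parametrize("n", [24, 144, 1440])
    def test_fft_matches_bruteforce(self, n, rng):
        for _ in range(5):
            x = standardize(rng.normal(size=n))
            y = standardize(rng.normal(size=n))
            r = circular_xcorr(x, y).r
            np.testing.assert_allclose(r, xcorr_bruteforce(x, y), atol=1e-10)

    def test_rejects_unstandardized_and_mismatched(self, rng):
        x = standardize(rng.normal(size=100))
        with pytest.raises(ValueError):
            circular_xcorr(x * 3.0, x)
        with pytest.raises(ValueError):
            circular_xcorr(x, standardize(rng.normal(size=99)))


class TestFundamentalComponent:
    def test_pure_cosine_gives_unit_real_component(self):
        n = 1440
        r = np.cos(2 * np.pi * np.arange(n) / n)
        p = fundamental_component(CorrelationFunction(r=r))
        assert p == pytest.approx(1.0 + 0j, abs=1e-12)

    def test_shifted_cosine_phase(self):
        n = 1440
        for delta in (60, 240, -120):
            r = np.cos(2 * np.pi * (np.arange(n) - delta) / n)
            p = fundamental_component(CorrelationFunction(r=r))
            expected_arg = -2 * np.pi * delta / n
            assert np.angle(p) == pytest.approx(np.angle(np.exp(1j * expected_arg)), abs=1e-10)
            assert abs(p) == pytest.approx(1.0, abs=1e-12)

    def test_constant_has_no_24h_power(self):
        r = np.full(1440, 0.37)
        assert abs(fundamental_component(CorrelationFunction(r=r))) < 1e-12


class TestComputePhasor:
    def test_perfect_synchrony(self):
        light, activity = sinusoid_day(lag_minutes=0)
        days = [make_day(light, activity, i) for i in range(7)]
        res = compute_phasor(days)
        assert res.magnitude == pytest.approx(1.0, abs=1e-9)
        assert res.acrophase_hours == pytest.approx(0.0, abs=1e-9)
        assert res.n_days_used == 7

    @pytest.mark.parametrize("lag_h", [-6.0, -2.0, 2.0, 6.0, 11.0])
    def test_lag_sign_convention_activity_lagging_is_positive(self, lag_h):
        light, activity = sinusoid_day(lag_minutes=int(lag_h * 60))
        res = compute_phasor([make_day(light, activity)])
        assert res.acrophase_hours == pytest.approx(lag_h, abs=1e-6)

    def test_linearity_mean_of_per_day_phasors(self, rng):
        days = []
        for i in range(5):
            x = standardize(rng.normal(size=1440))
            y = standardize(rng.normal(size=1440))
            days.append(make_day(x, y, i))
        res = compute_phasor(days, keep_per_day=True)
        assert res.phasor == pytest.approx(np.mean(res.per_day_phasors), abs=1e-12)

    def test_time_origin_invariance(self, rng):
        light, activity = sinusoid_day(lag_minutes=120)
        res0 = compute_phasor([make_day(light, activity)])
        for shift in (13, 600):
            res = compute_phasor([make_day(np.roll(light, shift), np.roll(activity, shift))])
            assert res.magnitude == pytest.approx(res0.magnitude, abs=1e-9)
            assert res.acrophase_hours == pytest.approx(res0.acrophase_hours, abs=1e-9)

    def test_magnitude_bound_on_random_days(self, rng):
        for _ in range(20):
            x = standardize(rng.normal(size=288))
            y = standardize(rng.normal(size=288))
            res = compute_phasor([make_day(x, y)])
            assert res.magnitude <= MAGNITUDE_BOUND + 1e-9

    def test_empty_day_list_returns_none(self):
        assert compute_phasor([]) is None

    def test_concatenated_method_agrees_for_identical_days(self):
        light, activity = sinusoid_day(lag_minutes=90)
        days = [make_day(light, activity, i) for i in range(4)]
        per_day = compute_phasor(days, method="per-day-average")
        concat = compute_phasor(days, method="concatenated")
        assert concat.magnitude == pytest.approx(per_day.magnitude, abs=1e-6)
        assert concat.acrophase_hours == pytest.approx(per_day.acrophase_hours, abs=1e-6)


class TestSimulatedPhasorRecovery:
    def test_acrophase_recovered_through_full_simulation(self):
        from phasorckm.simulate import sinusoid_template

        spec = ActigraphySimSpec(
            n_days=7, coupling_rho=1.0, lag_hours=2.0,
            light_profile=sinusoid_template(),
            noise_sd_light=0.0, noise_sd_activity=0.0, seed=4,
        )
        res = compute_phasor(segment_and_qc(simulate_actigraphy(spec)))
        assert res.acrophase_hours == pytest.approx(2.0, abs=0.05)

    def test_uncoupled_recording_has_small_magnitude(self):
        mags = []
        for seed in range(25):
            spec = ActigraphySimSpec(n_days=9, coupling_rho=0.0, seed=seed)
            mags.append(compute_phasor(segment_and_qc(simulate_actigraphy(spec))).magnitude)
        assert np.median(mags) < 0.1

    def test_magnitude_increases_with_coupling(self):
        means = []
        for rho in (0.0, 0.25, 0.5, 0.75, 1.0):
            mags = []
            for seed in range(50):
                spec = ActigraphySimSpec(n_days=5, coupling_rho=rho, seed=1000 + seed)
                mags.append(
                    compute_phasor(segment_and_qc(simulate_actigraphy(spec))).magnitude
                )
            means.append(np.mean(mags))
        assert np.all(np.diff(means) > 0)


class TestWrapHours:
    @pytest.mark.parametrize(
        "h, expected",
        [(0.0, 0.0), (12.0, 12.0), (-12.0, 12.0), (13.0, -11.0), (-13.0, 11.0),
         (23.5, -0.5), (36.0, 12.0)],
    )
    def test_wrap(self, h, expected):
        assert wrap_hours(h) == pytest.approx(expected)
        assert -12.0 < wrap_hours(h) <= 12.0


class TestQuartiles:
    def test_unweighted_octet(self):
        labels, cuts = assign_quartiles(np.arange(1.0, 9.0))
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 3, 3, 4, 4])
        np.testing.assert_array_equal(cuts, [2.0, 4.0, 6.0])

    def test_tie_at_cutpoint_goes_to_lower_quartile(self):
        values = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        labels, cuts = assign_quartiles(values)
        assert all(labels[values == cuts[0]] == 1)

    def test_weights_shift_cutpoints_upward(self, rng):
        values = np.sort(rng.normal(size=200))
        w = np.ones(200)
        w[100:] = 50.0  # mass concentrated on the top half
        _, cuts_unw = assign_quartiles(values)
        _, cuts_w = assign_quartiles(values, weights=w)
        assert np.all(cuts_w > cuts_unw)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateGroupingError):
            assign_quartiles(np.full(10, 3.3))

    def test_weighted_median_two_point_hand_computation(self):
        # P(X=1)=0.8, P(X=5)=0.2 -> median 1
        assert weighted_quantile([1.0, 5.0], 0.5, [0.8, 0.2]) == 1.0
        # equal weights -> step definition picks the lower of the middle pair
        assert weighted_quantile([1.0, 5.0], 0.5, [0.5, 0.5]) == 1.0
        assert weighted_quantile([1.0, 5.0], 0.75, [0.5, 0.5]) == 5.0
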