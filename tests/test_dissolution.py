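import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vbesim import (
    DissolutionProfile,
    WeibullParams,
    compute_f2,
    f2_from_profiles,
    fit_weibull,
    weibull_fraction,
)
from vbesim.dissolution import read_dissolution_csv, write_dissolution_csv
from vbesim.errors import (
    DataError,
    GridMismatchError,
    InsufficientDataError,
    UnderdeterminedError,
)


class TestF2:
    @pytest.mark.parametrize(
        "ref, test, expected",
        [
            # identical profiles: zero squared difference -> 50*log10(100)
            ((10, 30, 50, 70, 85), (10, 30, 50, 70, 85), 100.0),
            # constant sqrt(99) offset: mean squared difference 99 -> f2 = 50
            ((10, 30, 50, 70, 85), tuple(x + math.sqrt(99) for x in (10, 30, 50, 70, 85)), 50.0),
            # hand-worked 5-point case, mean squared difference 25
            ((10, 30, 50, 70, 85), (15, 35, 55, 75, 90), 64.63),
        ],
    )
    def test_known_values(self, ref, test, expected):
        res = compute_f2(ref, test)
        assert res.f2 == pytest.approx(expected, abs=0.01)
        assert res.n_points_used == len(ref)

    def test_similarity_band(self):
        r = np.array([10.0, 30, 50, 70, 85])
        assert compute_f2(r, r).similar
        assert compute_f2(r, r + math.sqrt(98)).similar  # f2 just above 50
        assert not compute_f2(r, r + 15).similar

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            compute_f2([50.0], [55.0])
        with pytest.raises(GridMismatchError):
            compute_f2([10.0, 20, 30], [10.0, 20])
        with pytest.raises(GridMismatchError):
            compute_f2([10.0, 20], [10.0, 20], times=([1.0, 2.0], [1.0, 3.0]))

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=9),
           st.floats(0, 20))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, values, offset):
        r = np.array(values)
        t = np.clip(r + offset, 0, 110)
        assert compute_f2(r, t).f2 == pytest.approx(compute_f2(t, r).f2, abs=1e-12)

    def test_strictly_decreasing_in_offset(self):
        r = np.linspace(10, 90, 9)
        f2_vals = [compute_f2(r, r + d).f2 for d in (0.0, 1.0, 3.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(f2_vals, f2_vals[1:]))

    def test_truncate_85_keeps_one_point_above(self):
        r = np.array([20.0, 50, 80, 90, 95])
        t = np.array([25.0, 55, 85, 92, 96])
        res = compute_f2(r, t, truncate_85=True)
        assert res.n_points_used == 4  # 90/92 is first point with both >= 85
        full = compute_f2(r, t)
        assert full.n_points_used == 5


class TestWeibullFraction:
    def test_zero_at_and_before_lag(self):
        p = WeibullParams(fmax=90, lag=2.0, alpha=8, beta=1.2)
        assert weibull_fraction(p, 2.0) == 0.0
        assert weibull_fraction(p, 0.5) == 0.0

    def test_asymptote_and_e_inverse_point(self):
        p = WeibullParams(fmax=100, lag=0, alpha=8, beta=1.0)
        assert weibull_fraction(p, 8.0) == pytest.approx(63.21, abs=0.01)
        assert weibull_fraction(p, 1e6) == pytest.approx(100.0, abs=1e-6)

    @given(
        fmax=st.floats(10, 110), lag=st.floats(0, 3),
        alpha=st.floats(0.5, 20), beta=st.floats(0.2, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, fmax, lag, alpha, beta):
        p = WeibullParams(fmax=fmax, lag=lag, alpha=alpha, beta=beta)
        t = np.linspace(0, 48, 200)
        y = weibull_fraction(p, t)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(y <= fmax + 1e-9)
        assert np.all(y >= 0)

    def test_invalid_params_rejected(self):
        for kwargs in ({"fmax": 0}, {"fmax": 90, "alpha": 0},
                       {"fmax": 90, "beta": -1}, {"fmax": 90, "lag": -0.1},
                       {"fmax": float("nan")}):
            with pytest.raises(DataError):
                WeibullParams(**kwargs)


class TestFitWeibull:
    def test_noise_free_round_trip(self, usp_times):
        truth = WeibullParams(fmax=90, lag=0.5, alpha=8, beta=1.2)
        y = weibull_fraction(truth, usp_times)
        fit = fit_weibull((usp_times, y))
        for name in ("fmax", "lag", "alpha", "beta"):
            got, want = getattr(fit.params, name), getattr(truth, name)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)
        assert fit.rss < 1e-12
        # fitted curve reproduces the input to solver tolerance
        np.testing.assert_allclose(
            weibull_fraction(fit.params, usp_times), y, atol=1e-6)

    def test_e_inverse_property_of_fit(self, usp_times):
        """At t = lag + alpha the fitted curve is 63.21% of Fmax for any beta."""
        truth = WeibullParams(fmax=85, lag=1.0, alpha=6, beta=2.3)
        fit = fit_weibull((usp_times, weibull_fraction(truth, usp_times)))
        p = fit.params
        val = weibull_fraction(p, p.lag + p.alpha)
        assert val == pytest.approx(p.fmax * (1 - math.exp(-1)), rel=1e-6)

    def test_under_determined(self):
        with pytest.raises(UnderdeterminedError):
            fit_weibull((np.array([1.0, 2, 4]), np.array([10.0, 20, 40])))

    def test_noisy_recovery_single(self, usp_times):
        rng = np.random.default_rng(42)
        truth = WeibullParams(fmax=92, lag=0.5, alpha=9, beta=1.15)
        y = weibull_fraction(truth, usp_times) + rng.normal(0, 2.0, usp_times.size)
        fit = fit_weibull((usp_times, np.clip(y, 0, None)))
        assert fit.params.fmax == pytest.approx(truth.fmax, rel=0.1)
        assert fit.params.alpha == pytest.approx(truth.alpha, rel=0.2)
        assert fit.stderr  # diagnostics populated


class TestProfileIO:
    def test_csv_round_trip(self, tmp_path, usp_times):
        rng = np.random.default_rng(0)
        values = np.clip(
            weibull_fraction(WeibullParams(fmax=90, alpha=8), usp_times)
            + rng.normal(0, 1, (3, usp_times.size)), 0, 110)
        prof = DissolutionProfile("F1", usp_times, values)
        path = tmp_path / "diss.csv"
        write_dissolution_csv(prof, path)
        back = read_dissolution_csv(path)["F1"]
        np.testing.assert_allclose(back.times, prof.times)
        np.testing.assert_allclose(back.values, prof.values)

    def test_profile_invariants(self, usp_times):
        with pytest.raises(DataError):
            DissolutionProfile("x", usp_times[::-1], np.zeros((1, 9)))
        with pytest.raises(DataError):
            DissolutionProfile("x", usp_times, np.full((1, 9), 150.0))

    def test_replicate_level_f2(self, usp_times):
        base = weibull_fraction(WeibullParams(fmax=90, alpha=8), usp_times)
        a = DissolutionProfile("A", usp_times, np.vstack([base, base + 1]))
        b = DissolutionProfile("B", usp_times, np.vstack([base + 2, base + 3]))
        results = f2_from_profiles(a, b, replicate_level=True)
        assert len(results) == 4
        assert all(r.f2 > 50 for r in results)
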