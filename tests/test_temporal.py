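import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ssnpatterns.temporal import (
    CCTimeSeries,
    annual_mean_monthly_abundance,
    diversity,
    escoufier_select,
    lomb_scargle,
    rhythmic_indicators,
    rhythmic_set,
    rv_coefficient,
    seasonal_prevalence,
)


def bimonthly_dates(years=8, start=2012):
    return [
        dt.date(start + y, m, d)
        for y in range(years)
        for m in range(1, 13)
        for d in (5, 20)
    ]


def series(values, dates=None, cc_id="cc"):
    dates = dates if dates is not None else bimonthly_dates()[: len(values)]
    return CCTimeSeries(cc_id=cc_id, times=dates, values=np.asarray(values, float))


class TestDiversity:
    def test_uniform_limit(self):
        d = diversity([1, 1, 1, 1])
        assert d.richness_S == 4
        assert d.shannon_H == pytest.approx(np.log(4), abs=1e-12)
        assert d.pielou_J == pytest.approx(1.0, abs=1e-12)

    def test_single_taxon(self):
        d = diversity([5, 0, 0])
        assert (d.richness_S, d.shannon_H, d.pielou_J) == (1, 0.0, 0.0)

    def test_hand_computed(self):
        d = diversity([2, 1, 1])
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert d.shannon_H == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            diversity([0, 0])

    def test_evenness_bounded(self, rng):
        for _ in range(20):
            v = rng.uniform(0, 1, size=rng.integers(2, 10))
            d = diversity(v + 1e-9)
            assert 0 <= d.pielou_J <= 1 + 1e-12
            assert d.shannon_H <= np.log(d.richness_S) + 1e-12


class TestRV:
    def test_self_similarity_and_scale(self, rng):
        X = rng.normal(size=(20, 4))
        assert rv_coefficient(X, X) == pytest.approx(1.0)
        assert rv_coefficient(X, 3 * X) == pytest.approx(1.0)

    def test_orthogonal_blocks(self, rng):
        # Y built from residuals of projection onto X's column space
        X = rng.normal(size=(30, 3))
        Xc = X - X.mean(0)
        raw = rng.normal(size=(30, 3))
        raw = raw - raw.mean(0)
        Y = raw - Xc @ np.linalg.lstsq(Xc, raw, rcond=None)[0]
        assert rv_coefficient(Xc, Y) == pytest.approx(0.0, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(10):
            rv = rv_coefficient(rng.normal(size=(15, 3)), rng.normal(size=(15, 5)))
            assert 0 <= rv <= 1 + 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rv_coefficient(np.ones((10, 2)), np.random.default_rng(0).normal(size=(10, 2)))


class TestEscoufier:
    def _table(self, rng, p=6, n=40):
        return pd.DataFrame(
            rng.lognormal(0, 1, size=(p, n)),
            index=[f"cc{i}" for i in range(p)],
            columns=[f"d{i}" for i in range(n)],
        )

    def test_single_column(self, rng):
        t = self._table(rng, p=1)
        trace = escoufier_select(t, min_occurrence=1)
        assert trace.selected == ["cc0"]
        assert trace.cumulative_rv[-1] == pytest.approx(1.0)

    def test_level_one_returns_everything(self, rng):
        t = self._table(rng)
        trace = escoufier_select(t, level=1.0, min_occurrence=1)
        assert len(trace.selected) == len(t.index)

    def test_cumulative_rv_monotone_to_one(self, rng):
        t = self._table(rng)
        trace = escoufier_select(t, min_occurrence=1)
        diffs = np.diff(trace.cumulative_rv)
        assert (diffs >= -1e-9).all()
        assert trace.cumulative_rv[-1] == pytest.approx(1.0, abs=1e-9)

    def test_greedy_matches_exhaustive_per_step(self, rng):
        """Each greedy choice maximizes RV over all remaining candidates."""
        t = self._table(rng, p=6)
        trace = escoufier_select(t, level=1.0, min_occurrence=1)
        X = t.to_numpy().T
        Xc = X - X.mean(0)
        ids = list(t.index)
        chosen: list[int] = []
        for step, picked in enumerate(trace.order):
            best_rv, best = -1.0, None
            for j in range(len(ids)):
                if j in chosen:
                    continue
                rv = rv_coefficient(Xc[:, chosen + [j]], Xc)
                if rv > best_rv + 1e-12:
                    best_rv, best = rv, j
            assert rv_coefficient(Xc[:, chosen + [ids.index(picked)]], Xc) == pytest.approx(
                best_rv, abs=1e-9
            )
            chosen.append(ids.index(picked))

    def test_min_occurrence_excludes_sparse(self, rng):
        t = self._table(rng, p=3)
        t.iloc[2, 3:] = 0.0  # only 3 positive dates
        trace = escoufier_select(t, min_occurrence=5)
        assert "cc2" not in trace.order

    def test_invalid_level_rejected(self, rng):
        with pytest.raises(ValueError):
            escoufier_select(self._table(rng), level=1.5)


class TestLombScargle:
    def test_noiseless_period_recovery(self):
        dates = bimonthly_dates()
        t = np.array([(d - dates[0]).days for d in dates], float)
        x = np.sin(2 * np.pi * t / 365.0)
        res = lomb_scargle(series(x - x.min()))
        grid_step = res.frequency_grid[1] - res.frequency_grid[0]
        f_true = 1 / 365.0
        assert abs(1 / res.period_days - f_true) <= grid_step
        assert res.pn_max > 10

    def test_noisy_sine_strongly_rhythmic(self, rng):
        dates = bimonthly_dates()
        t = np.array([(d - dates[0]).days for d in dates], float)
        x = np.sin(2 * np.pi * t / 365.0) + rng.normal(0, 0.5, t.size)
        res = lomb_scargle(series(x - x.min()))
        assert res.pn_max > 10
        assert res.p_value < 0.01

    def test_affine_invariance(self, rng):
        x = rng.normal(1.0, 0.3, 48)
        r1 = lomb_scargle(series(x, bimonthly_dates(2)))
        r2 = lomb_scargle(series(5.0 * x + 2.0, bimonthly_dates(2)))
        assert r1.pn_max == pytest.approx(r2.pn_max, rel=1e-9)
        assert r1.period_days == r2.period_days

    def test_even_sampling_agrees_with_fft_peak(self, rng):
        # evenly sampled: the classical periodogram and LSP peak must agree
        n, step = 128, 10.0
        t = np.arange(n) * step
        x = np.sin(2 * np.pi * t / 320.0) + 0.2 * rng.normal(size=n)
        dates = [dt.date(2000, 1, 1) + dt.timedelta(days=int(ti)) for ti in t]
        res = lomb_scargle(series(x - x.min(), dates))
        xc = x - x.mean()
        fft_freqs = np.fft.rfftfreq(n, d=step)
        fft_peak = fft_freqs[np.argmax(np.abs(np.fft.rfft(xc))[1:]) + 1]
        grid_step = res.frequency_grid[1] - res.frequency_grid[0]
        assert abs(1 / res.period_days - fft_peak) <= grid_step + 1e-12

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            lomb_scargle(series(np.ones(24), bimonthly_dates(1)))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lomb_scargle(series([1, 2, 1, 2], bimonthly_dates(1)[:4]))


class TestRhythmicSets:
    def _result(self, cc_id, pn):
        from ssnpatterns.temporal import PeriodogramResult

        return PeriodogramResult(
            cc_id=cc_id, pn_max=pn, period_days=365.0, p_value=0.5,
            frequency_grid=np.array([1e-3]),
        )

    def test_threshold_strict(self):
        results = [self._result("at", 10.0), self._result("above", 10.1)]
        assert rhythmic_set(results) == {"above"}

    def test_empty(self):
        assert rhythmic_set([]) == set()

    def test_indicator_intersection(self):
        from ssnpatterns.temporal import RVTrace

        trace = RVTrace(order=["a", "b", "c"], cumulative_rv=[0.5, 0.8, 1.0],
                        selected=["a", "b"])
        assert rhythmic_indicators(trace, {"b", "c"}) == {"b"}
        assert rhythmic_indicators(trace, set()) == set()


class TestSeasonality:
    def test_prevalence_counts_distinct_seasons(self):
        dates = [dt.date(2015, m, 10) for m in (1, 2, 4, 7, 10)]
        values = [1, 1, 0, 0, 0]
        assert seasonal_prevalence(series(values, dates), 2015) == 1
        values = [1, 0, 1, 1, 1]
        assert seasonal_prevalence(series(values, dates), 2015) == 4

    def test_prevalence_zero_when_absent(self):
        dates = [dt.date(2015, m, 10) for m in (1, 4)]
        assert seasonal_prevalence(series([0, 0], dates), 2015) == 0
        assert seasonal_prevalence(series([1, 1], dates), 2014) == 0

    def test_annual_mean_of_monthly_means(self):
        dates = [dt.date(2015, 1, 5), dt.date(2015, 1, 20), dt.date(2015, 7, 5)]
        # January mean 0.2, July mean 0.4 -> annual 0.3
        value = annual_mean_monthly_abundance(series([0.1, 0.3, 0.4], dates), 2015)
        assert value == pytest.approx(0.3)

    def test_constant_year(self):
        dates = bimonthly_dates(1, start=2015)
        value = annual_mean_monthly_abundance(series(np.full(24, 0.7), dates), 2015)
        assert value == pytest.approx(0.7)

    def test_unobserved_year_is_none(self):
        dates = [dt.date(2015, 1, 5)]
        assert annual_mean_monthly_abundance(series([1.0], dates), 2016) is None
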