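import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polychamber.chamber_stats import (GroupComparison, StatsError,
                                       aggregate_metric, bin_by_birth,
                                       compare_groups, counts_from_tracks,
                                       filter_tracks, fit_density_response,
                                       fit_logistic_counts, haldane_mu,
                                       haldane_n_half, logistic_counts)


def make_tracks(rows):
    return pd.DataFrame(rows, columns=["strain", "chamber", "cell",
                                       "founder", "birth_time",
                                       "growth_rate", "departure_time"])


class TestFilterTracks:
    def test_no_negatives_passthrough(self):
        t = make_tracks([("A", 1, i, i, 0.0, 0.1 * i, np.nan)
                         for i in range(1, 6)])
        out, report = filter_tracks(t)
        assert len(out) == 5
        assert report["fraction_excluded"].iloc[0] == 0.0

    def test_two_of_ten_excluded(self):
        rates = [0.1] * 8 + [-0.1, -0.2]
        t = make_tracks([("A", 1, i, i, 0.0, r, np.nan)
                         for i, r in enumerate(rates)])
        out, report = filter_tracks(t)
        assert len(out) == 8
        assert report["fraction_excluded"].iloc[0] == pytest.approx(0.2)

    def test_per_strain_fractions_match_brute_force(self, rng):
        rows = []
        for strain, n, n_neg in (("A", 20, 5), ("B", 10, 1), ("C", 8, 0)):
            rates = [0.2] * (n - n_neg) + [-0.3] * n_neg
            rng.shuffle(rates)
            rows += [(strain, 1, i, i, 0.0, r, np.nan)
                     for i, r in enumerate(rates)]
        t = make_tracks(rows)
        _, report = filter_tracks(t)
        # independent recount
        for strain, grp in t.groupby("strain"):
            expected = float((grp["growth_rate"] < 0).mean())
            got = report.loc[report["strain"] == strain,
                             "fraction_excluded"].iloc[0]
            assert got == pytest.approx(expected)

    def test_all_excluded_errors(self):
        t = make_tracks([("A", 1, 0, 0, 0.0, -0.1, np.nan)])
        with pytest.raises(StatsError, match="all rows excluded"):
            filter_tracks(t)

    def test_empty_table_errors(self):
        with pytest.raises(StatsError, match="empty"):
            filter_tracks(make_tracks([]))


class TestBinByBirth:
    def test_persistent_cell_counts_in_every_interval(self):
        t = make_tracks([("A", 1, 0, 0, 0.0, 0.2, np.nan)])
        bins = bin_by_birth(t)
        assert len(bins) == 14
        assert (bins["n_cells"] == 1).all()

    def test_half_open_convention(self):
        t = make_tracks([("A", 1, 0, 0, 2.0, 0.2, np.nan)])
        bins = bin_by_birth(t)
        born = bins.loc[bins["n_born"] == 1]
        assert list(born["t_start"]) == [2.0]

    def test_median_of_bin(self):
        rates = [0.1, 0.2, 0.3, 0.4, 0.5]
        t = make_tracks([("A", 1, i, i, 0.5, r, np.nan)
                         for i, r in enumerate(rates)])
        bins = bin_by_birth(t)
        assert bins.loc[bins["bin"] == 0,
                        "median_growth_rate"].iloc[0] == pytest.approx(0.3)

    def test_birth_conservation(self, rng):
        t = make_tracks([("A", 1, i, i, float(rng.uniform(0, 28)),
                          0.1, np.nan) for i in range(200)])
        bins = bin_by_birth(t)
        assert bins["n_born"].sum() == 200

    def test_departed_cells_leave_counts(self):
        t = make_tracks([("A", 1, 0, 0, 0.0, 0.2, 5.0),
                         ("A", 1, 1, 0, 0.0, 0.2, np.nan)])
        bins = bin_by_birth(t)
        # departed at 5 h: still present in [4,6) (departure > start), gone
        # from [6,8) onward
        assert bins.loc[bins["bin"] == 2, "n_cells"].iloc[0] == 2
        assert bins.loc[bins["bin"] == 3, "n_cells"].iloc[0] == 1

    def test_out_of_range_birth_rejected(self):
        t = make_tracks([("A", 1, 0, 0, 30.0, 0.2, np.nan)])
        with pytest.raises(StatsError, match="birth times beyond"):
            bin_by_birth(t)


class TestHaldane:
    def test_peak_location(self):
        a, K_N, K_I = 1.0, 20.0, 500.0
        n_peak = math.sqrt(K_N * K_I)
        grid = np.linspace(1, 1000, 5000)
        vals = haldane_mu(grid, a, K_N, K_I)
        assert grid[np.argmax(vals)] == pytest.approx(n_peak, rel=1e-2)

    def test_n_half_monod_limit(self):
        # K_I -> inf reduces to Monod, where N_half = K_N
        assert haldane_n_half(1.0, 20.0, 1e12) == pytest.approx(20.0,
                                                                rel=1e-4)

    def test_n_half_is_half_max(self):
        a, K_N, K_I = 0.7, 35.0, 900.0
        n_half = haldane_n_half(a, K_N, K_I)
        peak = haldane_mu(math.sqrt(K_N * K_I), a, K_N, K_I)
        assert haldane_mu(n_half, a, K_N, K_I) == pytest.approx(peak / 2,
                                                                rel=1e-10)


class TestFitDensityResponse:
    def _bins_from_curve(self, a, K_N, K_I, N_values, noise=0.0, rng=None):
        mu = haldane_mu(np.asarray(N_values, float), a, K_N, K_I)
        if noise:
            mu = mu * rng.lognormal(0, noise, size=len(mu))
        return pd.DataFrame({
            "strain": "A", "chamber": 1,
            "bin": range(len(N_values)),
            "t_start": np.arange(len(N_values)) * 2.0,
            "t_end": (np.arange(len(N_values)) + 1) * 2.0,
            "n_cells": N_values, "n_born": 5,
            "median_growth_rate": mu,
        })

    def test_noiseless_recovery(self):
        N = [2, 5, 10, 20, 40, 80, 150, 300, 600, 1000]
        bins = self._bins_from_curve(1.0, 20.0, 500.0, N)
        fit = fit_density_response(bins)[0]
        assert fit.converged
        assert fit.a == pytest.approx(1.0, rel=1e-4)
        assert fit.K_N == pytest.approx(20.0, rel=1e-4)
        assert fit.K_I == pytest.approx(500.0, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_n_half_from_fit(self):
        N = [2, 5, 10, 20, 40, 80, 150, 300, 600, 1000]
        bins = self._bins_from_curve(1.0, 20.0, 500.0, N)
        fit = fit_density_response(bins)[0]
        assert fit.n_half == pytest.approx(haldane_n_half(1.0, 20.0, 500.0),
                                           rel=1e-4)

    def test_scale_equivariance(self):
        N = [2, 5, 10, 20, 40, 80, 150, 300, 600]
        base = self._bins_from_curve(1.0, 20.0, 500.0, N)
        scaled = base.copy()
        scaled["median_growth_rate"] *= 3.0
        f0 = fit_density_response(base)[0]
        f1 = fit_density_response(scaled)[0]
        assert f1.a == pytest.approx(3.0 * f0.a, rel=1e-6)
        assert f1.n_half == pytest.approx(f0.n_half, rel=1e-6)

    def test_too_few_bins_rejected(self):
        bins = self._bins_from_curve(1.0, 20.0, 500.0, [5, 10, 20])
        with pytest.raises(StatsError, match="non-empty bins"):
            fit_density_response(bins)


class TestFitLogisticCounts:
    def test_noiseless_recovery(self):
        t = np.arange(0, 28, 1.0)
        counts = logistic_counts(t, 100.0, 0.5, 1.0)
        fit = fit_logistic_counts(t, counts)
        assert fit.converged
        assert fit.K_max == pytest.approx(100.0, rel=1e-4)
        assert fit.k == pytest.approx(0.5, rel=1e-4)
        assert fit.N0 == pytest.approx(1.0, rel=1e-4)

    def test_constant_series_rejected(self):
        t = np.arange(0, 10, 1.0)
        with pytest.raises(StatsError, match="no growth signal"):
            fit_logistic_counts(t, np.full_like(t, 7.0))

    def test_too_short_series_rejected(self):
        with pytest.raises(StatsError, match="6 time points"):
            fit_logistic_counts(np.arange(5.0), np.arange(5.0))

    def test_noisy_recovery_within_5pct(self, rng):
        t = np.arange(0, 28, 0.5)
        counts = logistic_counts(t, 100.0, 0.5, 1.0) + rng.normal(0, 5,
                                                                  t.size)
        fit = fit_logistic_counts(t, counts)
        assert fit.K_max == pytest.approx(100.0, rel=0.05)


class TestAggregateMetric:
    def test_single_founder(self):
        t = make_tracks([("A", 1, i, 0, float(i), 0.1, np.nan)
                         for i in range(8)])
        out = aggregate_metric(t)
        assert out["max_aggregate"].iloc[0] == 8

    def test_two_founders(self):
        rows = [("A", 1, i, 0, float(i), 0.1, np.nan) for i in range(3)]
        rows += [("A", 1, 10 + i, 1, float(i), 0.1, np.nan)
                 for i in range(5)]
        out = aggregate_metric(make_tracks(rows))
        assert out["max_aggregate"].iloc[0] == 5
        assert out["founder"].iloc[0] == 1

    def test_departures_peak_before_loss(self):
        # 3 cells, one departs at t=2, two more born later: peak is 4
        rows = [("A", 1, 0, 0, 0.0, 0.1, np.nan),
                ("A", 1, 1, 0, 0.5, 0.1, 2.0),
                ("A", 1, 2, 0, 1.0, 0.1, np.nan),
                ("A", 1, 3, 0, 1.5, 0.1, np.nan),
                ("A", 1, 4, 0, 3.0, 0.1, np.nan)]
        out = aggregate_metric(make_tracks(rows))
        assert out["max_aggregate"].iloc[0] == 4

    def test_matches_brute_force_replay(self, rng):
        rows = []
        for cell in range(120):
            birth = float(rng.uniform(0, 20))
            departs = rng.random() < 0.4
            dep = birth + float(rng.uniform(0, 8)) if departs else np.nan
            rows.append(("A", 1, cell, int(rng.integers(5)), birth, 0.1,
                         dep))
        t = make_tracks(rows)
        out = aggregate_metric(t)

        # independent oracle: scan count at every event time
        def peak_for(founder):
            lin = t[t["founder"] == founder]
            times = sorted(set(lin["birth_time"]) |
                           set(lin["departure_time"].dropna()))
            best = 0
            for at in times:
                n = int(((lin["birth_time"] <= at)
                         & (lin["departure_time"].isna()
                            | (lin["departure_time"] > at))).sum())
                best = max(best, n)
            return best

        expected = max(peak_for(f) for f in t["founder"].unique())
        assert out["max_aggregate"].iloc[0] == expected

    def test_missing_founder_errors(self):
        t = make_tracks([("A", 1, 0, np.nan, 0.0, 0.1, np.nan)])
        with pytest.raises(StatsError, match="founder"):
            aggregate_metric(t)


def mwu_oracle(x, y):
    """Exhaustive enumeration oracle for the exact Mann-Whitney test."""
    from scipy.stats import rankdata
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = np.array(x + y, dtype=float)
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    stats = []
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        stats.append(u)
    stats = np.array(stats)
    has_ties = len(np.unique(pooled)) < n + m
    if has_ties:
        p = float(np.mean(np.abs(stats - center)
                          >= abs(u_obs - center) - 1e-12))
    else:
        lo = float(np.mean(stats <= u_obs))
        hi = float(np.mean(stats >= u_obs))
        p = min(1.0, 2 * min(lo, hi))
    hl = float(np.median([yy - xx for yy in y for xx in x]))
    return u_obs, p, hl


class TestCompareGroups:
    def test_separated_pairs(self):
        res = compare_groups([1, 2], [3, 4])
        assert res.U == 0
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_hl_zero(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.hodges_lehmann == 0.0

    def test_hl_enumerated(self):
        # median of the 9 pairwise differences y - x
        res = compare_groups([1, 2, 3], [2, 4, 6])
        diffs = sorted(yy - xx for yy in [2, 4, 6] for xx in [1, 2, 3])
        assert res.hodges_lehmann == pytest.approx(np.median(diffs))
        assert res.hodges_lehmann == pytest.approx(2.0)

    def test_too_small_groups(self):
        with pytest.raises(StatsError):
            compare_groups([1], [2, 3])

    @pytest.mark.parametrize("n,m", [(2, 2), (2, 5), (3, 3), (4, 4),
                                     (3, 6), (5, 5), (6, 6)])
    def test_matches_oracle_continuous(self, n, m, rng):
        for _ in range(5):
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, m)
            res = compare_groups(x, y)
            u, p, hl = mwu_oracle(x, y)
            assert res.U == pytest.approx(u)
            assert res.p_value == pytest.approx(p, abs=1e-12)
            assert res.hodges_lehmann == pytest.approx(hl)

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 4), (5, 5)])
    def test_matches_oracle_with_ties(self, n, m, rng):
        for _ in range(5):
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, m).astype(float)
            res = compare_groups(x, y)
            u, p, hl = mwu_oracle(x, y)
            assert res.U == pytest.approx(u)
            assert res.p_value == pytest.approx(p, abs=1e-12)
            assert res.hodges_lehmann == pytest.approx(hl)
            assert res.method == "permutation" or len(
                np.unique(np.concatenate([x, y]))) == n + m

    def test_large_samples_use_asymptotic(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 1, 12)
        res = compare_groups(x, y)
        assert res.method == "asymptotic"
        assert 0 <= res.p_value <= 1


class TestCountsFromTracks:
    def test_presence_intervals(self):
        t = make_tracks([("A", 1, 0, 0, 0.0, 0.1, 4.0),
                         ("A", 1, 1, 0, 2.0, 0.1, np.nan)])
        counts = counts_from_tracks(t, np.array([0.0, 1.0, 3.0, 5.0]))
        assert counts["n_cells"].tolist() == [1, 1, 2, 1]
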