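"""Single-cell chamber statistics.

Operates on tracked-cell tables (one row per cell: strain, chamber, cell,
founder lineage, birth time, growth rate, optional departure time) and
provides the filtering, 2-h birth-time binning, density-response and
logistic-count fits, the lineage aggregate-size metric, and the exact
two-sample comparison used to contrast strains.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

TRACK_COLUMNS = (
    "strain", "chamber", "cell", "founder", "birth_time", "growth_rate",
    "departure_time",
)


class StatsError(ValueError):
    """Raised for invalid inputs to the chamber statistics."""


def validate_tracks(tracks: pd.DataFrame,
                    duration: Optional[float] = None) -> pd.DataFrame:
    """Check the tracked-cell schema; returns the table with a departure
    column added (NaN = never departed) if it was absent."""
    missing = [c for c in TRACK_COLUMNS[:-1] if c not in tracks.columns]
    if missing:
        raise StatsError(f"tracked-cell table missing columns: {missing}")
    out = tracks.copy()
    if "departure_time" not in out.columns:
        out["departure_time"] = np.nan
    if out["birth_time"].min() < 0:
        raise StatsError("negative birth times")
    if duration is not None and out["birth_time"].max() > duration:
        bad = out.index[out["birth_time"] > duration].tolist()
        raise StatsError(
            f"birth times beyond the {duration} h experiment in rows {bad[:10]}"
        )
    return out


# ---------------------------------------------------------------------------
# filtering and binning


def filter_tracks(tracks: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cells with negative growth rates (tracking artifacts).

    Returns the filtered table and a per-strain exclusion report with
    columns (strain, n_total, n_excluded, fraction_excluded).
    """
    if len(tracks) == 0:
        raise StatsError("tracked-cell table is empty")
    tracks = validate_tracks(tracks)
    keep = tracks["growth_rate"] >= 0
    report = (
        tracks.assign(excluded=~keep)
        .groupby("strain", sort=True)
        .agg(n_total=("excluded", "size"), n_excluded=("excluded", "sum"))
        .reset_index()
    )
    report["fraction_excluded"] = report["n_excluded"] / report["n_total"]
    filtered = tracks.loc[keep].reset_index(drop=True)
    if len(filtered) == 0:
        raise StatsError("all rows excluded by the negative-rate filter")
    return filtered, report


def bin_by_birth(tracks: pd.DataFrame, width: float = 2.0,
                 duration: float = 28.0) -> pd.DataFrame:
    """Bin cells into birth-time intervals per chamber.

    Intervals are half-open [k*width, (k+1)*width) tiling [0, duration].
    A cell contributes its growth rate to the interval containing its
    birth time; the cell count of an interval is the number of cells
    *present* during it (born in or before it and not yet departed at its
    start).

    Returns a BinTable with columns (strain, chamber, bin, t_start, t_end,
    n_cells, n_born, median_growth_rate); bins with no births have NaN
    median.
    """
    tracks = validate_tracks(tracks, duration=duration)
    n_bins = int(math.ceil(duration / width))
    edges = np.arange(n_bins + 1) * width
    rows = []
    for (strain, chamber), grp in tracks.groupby(["strain", "chamber"],
                                                 sort=True):
        birth = grp["birth_time"].to_numpy()
        depart = grp["departure_time"].to_numpy(dtype=float)
        rate = grp["growth_rate"].to_numpy()
        for k in range(n_bins):
            t0, t1 = edges[k], edges[k + 1]
            # born in or before this interval, not yet departed at its start
            present = (birth < t1) & (np.isnan(depart) | (depart > t0))
            if k == n_bins - 1:  # duration endpoint closes the last bin
                born = (birth >= t0) & (birth <= t1)
            else:
                born = (birth >= t0) & (birth < t1)
            nb = int(born.sum())
            rows.append({
                "strain": strain,
                "chamber": chamber,
                "bin": k,
                "t_start": t0,
                "t_end": t1,
                "n_cells": int(present.sum()),
                "n_born": nb,
                "median_growth_rate": float(np.median(rate[born])) if nb else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# density response


def haldane_mu(N: np.ndarray, a: float, K_N: float, K_I: float) -> np.ndarray:
    """Unimodal growth-rate response to cell number:
    mu(N) = a*N / (K_N + N + N^2/K_I) — rises, peaks at sqrt(K_N*K_I),
    then declines."""
    N = np.asarray(N, dtype=float)
    return a * N / (K_N + N + N ** 2 / K_I)


def haldane_peak(a: float, K_N: float, K_I: float) -> Tuple[float, float]:
    """(N_peak, mu_peak) of the response curve."""
    n_peak = math.sqrt(K_N * K_I)
    return n_peak, a / (1.0 + 2.0 * math.sqrt(K_N / K_I))


def haldane_n_half(a: float, K_N: float, K_I: float) -> float:
    """Smallest cell number at which mu(N) reaches half its maximum.

    Solves mu(N) = mu_peak/2 on the rising branch; for K_I -> inf this
    reduces to K_N (the Monod half-saturation)."""
    n_peak, mu_peak = haldane_peak(a, K_N, K_I)
    target = mu_peak / 2.0
    f = lambda n: haldane_mu(n, a, K_N, K_I) - target
    # bracket the rising branch; the crossing sits at the K_N scale
    lo = max(K_N * 1e-9, 1e-300)
    return float(optimize.brentq(f, lo, n_peak, xtol=1e-12, rtol=1e-14))


@dataclass
class DensityFit:
    """Fitted density response for one chamber."""

    strain: str
    chamber: object
    a: float
    K_N: float
    K_I: float
    r_squared: float
    n_half: float
    n_points: int
    converged: bool
    message: str = ""


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_density_response(
    bins: pd.DataFrame,
    model: Callable[..., np.ndarray] = haldane_mu,
    min_bins: int = 5,
) -> List[DensityFit]:
    """Least-squares fit of the unimodal density response per chamber.

    Fits median growth rate against the number of cells present in each
    2-h interval.  Chambers with fewer than ``min_bins`` non-empty bins
    are rejected; non-converging chambers are returned flagged
    (``converged=False``) so callers can drop them from comparisons.
    """
    fits: List[DensityFit] = []
    for (strain, chamber), grp in bins.groupby(["strain", "chamber"],
                                               sort=True):
        ok = (grp["n_cells"] > 0) & grp["median_growth_rate"].notna()
        N = grp.loc[ok, "n_cells"].to_numpy(dtype=float)
        mu = grp.loc[ok, "median_growth_rate"].to_numpy(dtype=float)
        if len(N) < min_bins:
            raise StatsError(
                f"chamber {chamber!r} of strain {strain!r} has only "
                f"{len(N)} non-empty bins (need >= {min_bins})"
            )
        mu_top = float(mu.max())
        n_top = float(N[np.argmax(mu)])
        p0 = (2.0 * mu_top, max(n_top, 1.0), max(10.0 * n_top, 10.0))
        try:
            popt, _ = optimize.curve_fit(
                model, N, mu, p0=p0,
                bounds=([1e-12, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            a, K_N, K_I = (float(v) for v in popt)
            fits.append(DensityFit(
                strain=strain, chamber=chamber, a=a, K_N=K_N, K_I=K_I,
                r_squared=_r_squared(mu, model(N, a, K_N, K_I)),
                n_half=haldane_n_half(a, K_N, K_I),
                n_points=len(N), converged=True,
            ))
        except RuntimeError as exc:
            fits.append(DensityFit(
                strain=strain, chamber=chamber, a=np.nan, K_N=np.nan,
                K_I=np.nan, r_squared=np.nan, n_half=np.nan,
                n_points=len(N), converged=False, message=str(exc),
            ))
    return fits


def density_fits_frame(fits: Sequence[DensityFit]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits])


# ---------------------------------------------------------------------------
# logistic chamber counts


def logistic_counts(t: np.ndarray, K_max: float, k: float,
                    N0: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return K_max / (1.0 + ((K_max - N0) / N0) * np.exp(-k * t))


@dataclass
class LogisticFit:
    chamber: object
    K_max: float
    k: float
    N0: float
    r_squared: float
    converged: bool
    message: str = ""


def fit_logistic_counts(times: np.ndarray, counts: np.ndarray,
                        chamber: object = None) -> LogisticFit:
    """Least-squares logistic fit N(t) = K_max / (1 + ((K_max-N0)/N0) e^{-kt})
    to one chamber's cell-count time series."""
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times.size < 6:
        raise StatsError("need at least 6 time points for a logistic fit")
    if float(counts.max() - counts.min()) <= 0:
        raise StatsError("constant count series: no growth signal to fit")
    K0 = float(counts.max())
    N0_0 = max(float(counts[0]), 0.5)
    p0 = (K0, 0.3, N0_0)
    try:
        popt, _ = optimize.curve_fit(
            logistic_counts, times, counts, p0=p0,
            bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        K_max, k, N0 = (float(v) for v in popt)
        return LogisticFit(
            chamber=chamber, K_max=K_max, k=k, N0=N0,
            r_squared=_r_squared(counts, logistic_counts(times, K_max, k, N0)),
            converged=True,
        )
    except RuntimeError as exc:
        return LogisticFit(chamber=chamber, K_max=np.nan, k=np.nan, N0=np.nan,
                           r_squared=np.nan, converged=False, message=str(exc))


def counts_from_tracks(tracks: pd.DataFrame, times: np.ndarray
                       ) -> pd.DataFrame:
    """Resident-cell counts per (strain, chamber) on a time grid, derived
    from birth and departure times."""
    tracks = validate_tracks(tracks)
    times = np.asarray(times, dtype=float)
    rows = []
    for (strain, chamber), grp in tracks.groupby(["strain", "chamber"],
                                                 sort=True):
        birth = grp["birth_time"].to_numpy()[:, None]
        depart = grp["departure_time"].to_numpy(dtype=float)[:, None]
        resident = (birth <= times[None, :]) & (
            np.isnan(depart) | (depart > times[None, :]))
        for t, n in zip(times, resident.sum(axis=0)):
            rows.append({"strain": strain, "chamber": chamber,
                         "time": float(t), "n_cells": int(n)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lineage aggregation metric


def aggregate_metric(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per chamber: max over founder lineages of the peak number of that
    founder's descendants simultaneously resident.

    Computed by replaying birth (+1) and departure (-1) events in time
    order per lineage; departures at the same instant as a birth are
    applied after it (a cell born and dispersing at time t still counts
    at t).
    """
    tracks = validate_tracks(tracks)
    if tracks["founder"].isna().any():
        raise StatsError("missing founder lineage ids")
    rows = []
    for (strain, chamber), grp in tracks.groupby(["strain", "chamber"],
                                                 sort=True):
        best = 0
        best_founder = None
        for founder, lin in grp.groupby("founder"):
            events = [(t, 0, +1) for t in lin["birth_time"]]
            events += [(t, 1, -1) for t in lin["departure_time"].dropna()]
            events.sort()
            cur = peak = 0
            for _, _, delta in events:
                cur += delta
                peak = max(peak, cur)
            if peak > best:
                best, best_founder = peak, founder
        rows.append({"strain": strain, "chamber": chamber,
                     "max_aggregate": best, "founder": best_founder})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-sample comparison


@dataclass
class GroupComparison:
    U: float
    p_value: float
    hodges_lehmann: float
    n_x: int
    n_y: int
    method: str


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _u_from_ranks(ranks_x: np.ndarray, n_x: int, n_y: int) -> float:
    # U for group x: rank-sum minus its minimum
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def _exact_u_distribution(n_x: int, n_y: int) -> np.ndarray:
    """Null counts of the Mann-Whitney U statistic without ties.

    Dynamic programme over the rank-sum of ``n_x`` ranks chosen from
    ``1..n_x+n_y``; index u of the result counts labelings with U = u.
    """
    N = n_x + n_y
    max_sum = n_x * N
    # dp[j, s]: ways to pick j of the first r ranks with rank-sum s
    dp = np.zeros((n_x + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for j in range(min(r, n_x), 0, -1):
            dp[j, r:] += dp[j - 1, :-r] if r else dp[j - 1, :]
    min_sum = n_x * (n_x + 1) // 2
    return dp[n_x, min_sum:min_sum + n_x * n_y + 1]


def compare_groups(x: Sequence[float], y: Sequence[float],
                   exact_limit: int = 16) -> GroupComparison:
    """Mann-Whitney U test with the Hodges-Lehmann shift estimate.

    U is the statistic of the first group (pairs with x_i > y_j, ties
    counted 1/2, i.e. rank-sum of x minus its minimum).  The two-sided
    p-value is exact (full null enumeration) for n+m <= ``exact_limit``;
    with ties the exact path enumerates all group labelings of the
    observed data; larger samples use the normal approximation with tie
    correction.  The Hodges-Lehmann difference is the median of all
    pairwise y - x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x < 2 or n_y < 2:
        raise StatsError("need at least 2 observations per group")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    U_x = _u_from_ranks(ranks[:n_x], n_x, n_y)
    hl = float(np.median(np.subtract.outer(y, x)))
    has_ties = len(np.unique(pooled)) < n_x + n_y

    if n_x + n_y <= exact_limit:
        if not has_ties:
            counts = _exact_u_distribution(n_x, n_y)
            total = counts.sum()
            lo = counts[: int(U_x) + 1].sum() / total
            hi = counts[int(U_x):].sum() / total
            p = min(1.0, 2.0 * min(lo, hi))
            method = "exact"
        else:
            # permutation over the observed data with midranks
            stats_all = []
            idx = range(n_x + n_y)
            for combo in itertools.combinations(idx, n_x):
                sel = np.fromiter(combo, dtype=int)
                stats_all.append(_u_from_ranks(ranks[sel], n_x, n_y))
            stats_all = np.asarray(stats_all)
            center = n_x * n_y / 2.0
            p = float(np.mean(np.abs(stats_all - center)
                              >= np.abs(U_x - center) - 1e-12))
            method = "permutation"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return GroupComparison(U=U_x, p_value=float(p), hodges_lehmann=hl,
                           n_x=n_x, n_y=n_y, method=method)
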