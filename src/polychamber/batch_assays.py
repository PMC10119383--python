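"""Plate-reader growth-curve metrics and the secretion correlation.

Growth curves are blank-corrected OD600 series sampled every 30 min over
36-40 h.  The two per-curve metrics are the maximum OD within the first
36 h and the time to reach exponential phase, defined intrinsically as
the earliest time the smoothed per-capita rate d(ln OD)/dt first reaches
half of its maximum.  The definition differs from external fitting
packages, so values are comparable across strains here but only in trend
against other software.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

LOG_EPSILON = 1e-3      # OD offset inside the log transform
SMOOTH_WINDOW = 5       # centered moving-average window (samples)
MAX_OD_HORIZON = 36.0   # h; max OD taken within this span


class AssayError(ValueError):
    pass


@dataclass
class ODCurve:
    """One blank-corrected growth curve."""

    strain: str
    replicate: object
    time: np.ndarray
    od: np.ndarray
    condition: str = "plain"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.od.shape:
            raise AssayError("time and od must be equal-length 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise AssayError("time must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise AssayError("OD values must be finite")


@dataclass
class GrowthMetrics:
    max_od: float
    time_to_exponential: float
    max_rate: float
    no_growth: bool


def _moving_average(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    if window <= 1 or y.size < window:
        return y.copy()
    half = window // 2
    padded = np.concatenate([np.full(half, y[0]), y, np.full(half, y[-1])])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def growth_metrics(curve: ODCurve,
                   noise_floor: float = 0.02) -> GrowthMetrics:
    """Max OD (first 36 h, smoothed) and time to exponential phase.

    The per-capita rate is the centered finite-difference derivative of the
    moving-average-smoothed ln(OD + eps); the exponential-phase onset is
    the first upward crossing of half the maximum rate, located by linear
    interpolation between samples.  A curve whose OD range is below
    ``noise_floor`` is flagged as no-growth (NaN metrics).
    """
    if curve.time.size < 10:
        raise AssayError("need at least 10 time points")
    t, od = curve.time, curve.od
    if float(od.max() - od.min()) < noise_floor:
        return GrowthMetrics(np.nan, np.nan, np.nan, no_growth=True)
    smooth_od = _moving_average(od)
    in_horizon = t <= t[0] + MAX_OD_HORIZON
    max_od = float(smooth_od[in_horizon].max())
    log_od = _moving_average(np.log(od + LOG_EPSILON))
    rate = np.gradient(log_od, t)
    max_rate = float(rate.max())
    target = 0.5 * max_rate
    above = rate >= target
    idx = int(np.argmax(above))
    if idx == 0:
        t_exp = float(t[0])
    else:
        r0, r1 = rate[idx - 1], rate[idx]
        frac = (target - r0) / (r1 - r0) if r1 != r0 else 0.0
        t_exp = float(t[idx - 1] + frac * (t[idx] - t[idx - 1]))
    return GrowthMetrics(max_od=max_od, time_to_exponential=t_exp,
                         max_rate=max_rate, no_growth=False)


def metrics_table(curves: Sequence[ODCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        m = growth_metrics(c)
        rows.append({
            "strain": c.strain, "replicate": c.replicate,
            "condition": c.condition, "max_od": m.max_od,
            "time_to_exponential": m.time_to_exponential,
            "no_growth": m.no_growth,
        })
    return pd.DataFrame(rows)


@dataclass
class LagReduction:
    strain: str
    reduction: float       # mean(plain) - mean(supplemented), h
    ci_low: float
    ci_high: float
    n_pairs: int


def lag_reduction(plain: Sequence[ODCurve],
                  supplemented: Sequence[ODCurve]) -> List[LagReduction]:
    """Per-strain reduction in time-to-exponential under enzyme
    supplementation, with a 95% t-interval over replicate pairs.

    Replicates are paired by replicate id; if the two condition sets of a
    strain differ in replicate count they are paired by rank order of
    time-to-exponential with a warning.
    """
    def by_strain(curves: Sequence[ODCurve]) -> Dict[str, List[ODCurve]]:
        d: Dict[str, List[ODCurve]] = {}
        for c in curves:
            d.setdefault(c.strain, []).append(c)
        return d

    plain_map, supp_map = by_strain(plain), by_strain(supplemented)
    results = []
    for strain in sorted(plain_map):
        if strain not in supp_map:
            continue
        tp = np.array([growth_metrics(c).time_to_exponential
                       for c in plain_map[strain]])
        ts = np.array([growth_metrics(c).time_to_exponential
                       for c in supp_map[strain]])
        rp = [c.replicate for c in plain_map[strain]]
        rs = [c.replicate for c in supp_map[strain]]
        if len(tp) == len(ts) and sorted(map(str, rp)) == sorted(map(str, rs)):
            order_p = np.argsort([str(r) for r in rp])
            order_s = np.argsort([str(r) for r in rs])
            diffs = tp[order_p] - ts[order_s]
        else:
            warnings.warn(
                f"strain {strain!r}: unmatched replicates, pairing by rank "
                "order of time-to-exponential", RuntimeWarning, stacklevel=2)
            k = min(len(tp), len(ts))
            diffs = np.sort(tp)[:k] - np.sort(ts)[:k]
        n = len(diffs)
        mean = float(diffs.mean())
        if n > 1 and diffs.std(ddof=1) > 0:
            half = float(stats.t.ppf(0.975, n - 1)
                         * diffs.std(ddof=1) / math.sqrt(n))
        else:
            half = 0.0
        results.append(LagReduction(strain=strain, reduction=mean,
                                    ci_low=mean - half, ci_high=mean + half,
                                    n_pairs=n))
    return results


# ---------------------------------------------------------------------------
# secretion correlation


@dataclass
class SecretionCorrelation:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    spearman_r: float
    spearman_p: float
    spearman_method: str
    n: int


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho, full n! enumeration."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def _spearman_mc_p(x: np.ndarray, y: np.ndarray, r_obs: float,
                   n_perm: int = 20000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    hits = 1  # include the observed permutation
    for _ in range(n_perm):
        r = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
    return hits / (n_perm + 1)


def correlate_secretion(assays: pd.DataFrame,
                        x_col: str = "halo_diameter",
                        y_col: str = "max_od",
                        exact_limit: int = 8,
                        mc_limit: int = 12,
                        seed: int = 0) -> SecretionCorrelation:
    """OLS of max OD on halo diameter plus Spearman rank correlation.

    The Spearman p-value is exact by full permutation enumeration for
    n <= ``exact_limit``, a seeded Monte-Carlo permutation estimate up to
    ``mc_limit``, and the t approximation above that.  Raises if either
    variable has zero variance (correlation undefined).
    """
    if len(assays) < 4:
        raise AssayError("need at least 4 strains")
    x = assays[x_col].to_numpy(dtype=float)
    y = assays[y_col].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AssayError("zero variance in one variable: correlation undefined")
    ols = stats.linregress(x, y)
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n <= exact_limit:
        p = _spearman_exact_p(x, y, rho)
        method = "exact"
    elif n <= mc_limit:
        p = _spearman_mc_p(x, y, rho, seed=seed)
        method = "monte-carlo"
    else:
        p = float(stats.spearmanr(x, y).pvalue)
        method = "t-approx"
    return SecretionCorrelation(
        slope=float(ols.slope), intercept=float(ols.intercept),
        r_squared=float(ols.rvalue) ** 2, slope_stderr=float(ols.stderr),
        spearman_r=rho, spearman_p=float(p), spearman_method=method, n=n,
    )
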