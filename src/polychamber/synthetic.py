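"""Synthetic datasets with known ground truth.

Everything the analysis stages consume — tracked-cell tables from chamber
microscopy and plate-reader OD curves with halo diameters — can be
generated here with the generating parameters attached, so estimator
recovery error is always computable without the original deposit.

Tracked cells come from a birth--dispersal process: each resident cell
carries a division clock with interval ln(2)/lambda, where the intensity
lambda ties to the density-response curve mu(N) damped by a chamber
capacity so counts saturate; each daughter immediately leaves the chamber
with the dispersal probability.  With zero rate noise the division times
are deterministic.  Recorded per-cell growth rates follow mu(N at birth)
under multiplicative lognormal noise, which is what the density-response
fit recovers.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .batch_assays import ODCurve
from .chamber_stats import StatsError, haldane_mu, haldane_n_half


@dataclass(frozen=True)
class TrackGenSpec:
    """Ground truth for one strain's chamber dataset."""

    strain: str = "synthetic"
    n_chambers: int = 7
    duration: float = 28.0
    a: float = 0.45           # density-response amplitude (1/h)
    K_N: float = 80.0         # rise half-saturation (cells)
    K_I: float = 2000.0       # crowding constant (cells)
    capacity: float = 600.0   # chamber carrying capacity (cells)
    crowding_exponent: float = 4.0  # sharpness of the capacity cutoff
    founders: int = 30
    dispersal_p: float = 0.15  # probability a daughter leaves at birth
    noise_sigma: float = 0.10  # lognormal sigma on recorded rates
    measurement_window: float = 1.0  # h after birth at which the tracked
    # rate samples the density response (growth rates are measured over a
    # finite observation window, not at the instant of birth)
    artifact_fraction: float = 0.25  # extra negative-rate tracking artifacts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chambers < 1:
            raise StatsError("n_chambers must be >= 1")
        if not (0 <= self.dispersal_p <= 1):
            raise StatsError("dispersal_p must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise StatsError("noise_sigma must be >= 0")
        if not (0 <= self.artifact_fraction < 1):
            raise StatsError("artifact_fraction must lie in [0, 1)")

    @property
    def n_half(self) -> float:
        """True half-max cell number implied by (a, K_N, K_I)."""
        return haldane_n_half(self.a, self.K_N, self.K_I)


#: Qualitative strain profiles: low secretors keep daughters (large
#: aggregates, high N_half), high secretors shed them.
PROFILES: Dict[str, TrackGenSpec] = {
    "low-secretor": TrackGenSpec(strain="low-secretor", a=0.45, K_N=80.0,
                                 K_I=2000.0, capacity=600.0,
                                 dispersal_p=0.10),
    "high-secretor": TrackGenSpec(strain="high-secretor", a=0.45, K_N=16.0,
                                  K_I=400.0, capacity=200.0, founders=10,
                                  dispersal_p=0.45),
}


def _simulate_chamber(spec: TrackGenSpec, rng: np.random.Generator,
                      chamber: int) -> List[dict]:
    """Division-clock birth--dispersal process for one chamber.

    Every resident cell schedules its next division ``ln(2) / lambda``
    ahead, with intensity ``lambda = mu(N) * noise * (1 - N/capacity)``
    evaluated when the clock is set.  Daughters leave immediately with the
    dispersal probability; with ``noise_sigma = 0`` the process is fully
    deterministic.
    """

    def noisy(mu: float) -> float:
        if spec.noise_sigma == 0:
            return float(mu)
        z = rng.standard_normal()
        return float(mu) * math.exp(spec.noise_sigma * z
                                    - 0.5 * spec.noise_sigma ** 2)

    def intensity(rate: float, n: int) -> float:
        return rate * max(0.0,
                          1.0 - (n / spec.capacity) ** spec.crowding_exponent)

    rows: List[dict] = []
    # heap entries: (due time, cell id, clock start, noise factor); the due
    # time is re-derived from the *current* density when the event fires,
    # so crowding that happened after scheduling defers the division
    # instead of letting stale clocks overshoot the capacity
    heap: List[Tuple[float, int, float, float]] = []
    n_resident = spec.founders
    next_id = 0
    # resident-count timeline, for sampling the density response at
    # birth + measurement_window when assigning recorded rates
    count_times: List[float] = [0.0]
    count_values: List[int] = [spec.founders]

    def schedule(cell: int, t: float) -> None:
        noise = (1.0 if spec.noise_sigma == 0
                 else math.exp(spec.noise_sigma * rng.standard_normal()
                               - 0.5 * spec.noise_sigma ** 2))
        lam = intensity(
            noise * haldane_mu(n_resident, spec.a, spec.K_N, spec.K_I),
            n_resident)
        if lam > 0:
            heapq.heappush(heap, (t + math.log(2.0) / lam, cell, t, noise))

    def add_cell(t: float, founder: Optional[int], stays: bool) -> None:
        nonlocal next_id
        rows.append({
            "strain": spec.strain, "chamber": chamber, "cell": next_id,
            "founder": next_id if founder is None else founder,
            "birth_time": t,
            "growth_rate": np.nan,  # assigned from the timeline below
            "_rate_noise": 1.0 if spec.noise_sigma == 0 else noisy(1.0),
            "departure_time": np.nan if stays else t,
        })
        if stays:
            schedule(next_id, t)
        next_id += 1

    for _ in range(spec.founders):
        add_cell(0.0, None, stays=True)

    while heap:
        due, cell, t_set, noise = heapq.heappop(heap)
        if due >= spec.duration:
            break
        lam_now = intensity(
            noise * haldane_mu(n_resident, spec.a, spec.K_N, spec.K_I),
            n_resident)
        if lam_now <= 0:
            continue
        due_now = t_set + math.log(2.0) / lam_now
        if due_now > due + 1e-12:
            heapq.heappush(heap, (due_now, cell, t_set, noise))
            continue
        t = due
        if n_resident > 100_000:
            raise StatsError(
                "runaway population (>1e5 cells): lower the division "
                "intensity or capacity")
        daughter_stays = bool(rng.random() >= spec.dispersal_p)
        if daughter_stays:
            n_resident += 1
            count_times.append(t)
            count_values.append(n_resident)
        add_cell(t, rows[cell]["founder"], daughter_stays)
        schedule(cell, t)  # mother restarts her clock

    # recorded growth rate: density response sampled one measurement
    # window after birth, times the cell's own noise factor
    times_arr = np.asarray(count_times)
    counts_arr = np.asarray(count_values, dtype=float)
    for row in rows:
        t_meas = min(row["birth_time"] + spec.measurement_window,
                     spec.duration)
        idx = int(np.searchsorted(times_arr, t_meas, side="right")) - 1
        n_at = counts_arr[max(idx, 0)]
        row["growth_rate"] = row.pop("_rate_noise") * haldane_mu(
            n_at, spec.a, spec.K_N, spec.K_I)

    # tracking artifacts: segmentation mistakes carry negative rates and
    # are dropped by the analysis filter
    n_art = int(round(spec.artifact_fraction / (1 - spec.artifact_fraction)
                      * len(rows)))
    for _ in range(n_art):
        tb = float(rng.uniform(0, spec.duration))
        rows.append({
            "strain": spec.strain, "chamber": chamber, "cell": next_id,
            "founder": next_id, "birth_time": tb,
            "growth_rate": float(-abs(rng.normal(0.05, 0.05)) - 1e-6),
            "departure_time": tb,
        })
        next_id += 1
    return rows


def gen_tracks(spec: TrackGenSpec) -> Tuple[pd.DataFrame, dict]:
    """Generate a tracked-cell table for ``spec.n_chambers`` chambers.

    Returns the table and a truth record holding every generating
    parameter plus the implied N_half.
    """
    root = np.random.SeedSequence(spec.seed)
    rows: List[dict] = []
    for chamber, child in enumerate(root.spawn(spec.n_chambers), start=1):
        rng = np.random.default_rng(child)
        rows.extend(_simulate_chamber(spec, rng, chamber))
    tracks = pd.DataFrame(rows)
    truth = {
        "strain": spec.strain,
        "a": spec.a, "K_N": spec.K_N, "K_I": spec.K_I,
        "n_half": spec.n_half, "capacity": spec.capacity,
        "founders": spec.founders, "dispersal_p": spec.dispersal_p,
        "noise_sigma": spec.noise_sigma,
        "artifact_fraction": spec.artifact_fraction,
        "duration": spec.duration, "n_chambers": spec.n_chambers,
        "seed": spec.seed,
    }
    return tracks, truth


# ---------------------------------------------------------------------------
# plate-reader curves


@dataclass(frozen=True)
class ODGenSpec:
    """Ground truth for a batch growth-curve panel.

    Each pseudo-strain gets a halo diameter; its carrying capacity follows
    the linear link max OD = slope*halo + intercept with Gaussian scatter.
    Supplementation removes part of the lag, more for weakly secreting
    (small-halo) strains.
    """

    n_strains: int = 12
    replicates: int = 3
    t_max: float = 40.0
    sample_interval: float = 0.5     # 30-min sampling
    halo_range: Tuple[float, float] = (2.0, 18.0)
    link_slope: float = 0.05
    link_intercept: float = 0.05
    link_sigma: float = 0.12
    rate_range: Tuple[float, float] = (0.35, 0.55)
    lag_range: Tuple[float, float] = (4.0, 12.0)
    max_lag_cut: float = 4.0
    od0: float = 0.005
    od_noise: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.replicates < 1:
            raise StatsError("need at least one strain and one replicate")
        for name in ("link_sigma", "max_lag_cut", "od_noise"):
            if getattr(self, name) < 0:
                raise StatsError(f"{name} must be >= 0")
        if not (self.od0 > 0):
            raise StatsError("od0 must be > 0")


def lagged_logistic(t: np.ndarray, K: float, k: float, lag: float,
                    od0: float) -> np.ndarray:
    """Flat at od0 until ``lag``, then logistic growth to K at rate k."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, od0)
    after = t > lag
    out[after] = K / (1.0 + (K / od0 - 1.0) * np.exp(-k * (t[after] - lag)))
    return out


def gen_od_curves(spec: ODGenSpec
                  ) -> Tuple[List[ODCurve], pd.DataFrame, dict]:
    """Generate plain and lyase-supplemented OD curves plus the halo table.

    Returns (curves, assay table, truth record).  The assay table has one
    row per strain: halo diameter and the true carrying capacity; measured
    max OD should be recomputed downstream from the curves.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.t_max + 1e-9, spec.sample_interval)
    halos = np.sort(rng.uniform(*spec.halo_range, size=spec.n_strains))
    K = (spec.link_slope * halos + spec.link_intercept
         + rng.normal(0.0, spec.link_sigma, size=spec.n_strains))
    K = np.maximum(K, 0.08)
    k_rate = rng.uniform(*spec.rate_range, size=spec.n_strains)
    lag = rng.uniform(*spec.lag_range, size=spec.n_strains)
    # weak secretors benefit most from external enzyme
    halo_span = spec.halo_range[1] - spec.halo_range[0]
    lag_cut = spec.max_lag_cut * (spec.halo_range[1] - halos) / halo_span
    lag_cut = np.minimum(lag_cut, lag)

    curves: List[ODCurve] = []
    assay_rows = []
    strain_truth = []
    for i in range(spec.n_strains):
        name = f"S{i + 1:02d}"
        # one noise draw per replicate, shared across conditions, so a
        # zero lag cut yields byte-identical plain/supplemented curves
        rep_noise = [rng.normal(0.0, spec.od_noise, size=t.size)
                     for _ in range(spec.replicates)]
        for cond, this_lag in (("plain", lag[i]),
                               ("supplemented", lag[i] - lag_cut[i])):
            clean = lagged_logistic(t, K[i], k_rate[i], this_lag, spec.od0)
            for rep in range(1, spec.replicates + 1):
                od = np.maximum(clean + rep_noise[rep - 1], 0.0)
                curves.append(ODCurve(strain=name, replicate=rep, time=t,
                                      od=od, condition=cond))
        assay_rows.append({"strain": name, "halo_diameter": float(halos[i]),
                           "true_max_od": float(K[i])})
        strain_truth.append({
            "strain": name, "halo": float(halos[i]), "K": float(K[i]),
            "k": float(k_rate[i]), "lag": float(lag[i]),
            "lag_cut": float(lag_cut[i]),
        })
    assays = pd.DataFrame(assay_rows)
    truth = {
        "link_slope": spec.link_slope,
        "link_intercept": spec.link_intercept,
        "link_sigma": spec.link_sigma,
        "od0": spec.od0, "od_noise": spec.od_noise,
        "seed": spec.seed, "strains": strain_truth,
    }
    return curves, assays, truth
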