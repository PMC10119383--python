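"""Time-loop driver for one chamber and the two parameter sweeps.

One macro step applies, in order: diffusion (implicit), depolymerization,
enzyme secretion, and oligomer uptake/growth (explicit).  Sweeps run one
chamber per grid point with a per-condition seed derived from the base
seed and the condition's parameter values, so results do not depend on
grid ordering.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agents import (CellPopulation, GrowthRecord, KineticParams, place_cells,
                     secrete_step, uptake_grow_step)
from .lattice import (DepolymerizationParams, FieldError, FieldSet,
                      LatticeSpec, TransportParams, depolymerize_step,
                      diffuse_step, make_fields)


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one chamber run."""

    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    transport: TransportParams = field(default_factory=TransportParams)
    depoly: DepolymerizationParams = field(default_factory=DepolymerizationParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    rho: float = 0.3
    duration: float = 20.0
    dt: float = 0.01
    seed: int = 0
    snapshot_times: Tuple[float, ...] = ()
    boundary_mode: str = "dirichlet"
    interior_init: Optional[Mapping[str, float]] = None
    growth_rate_kind: str = "instantaneous"

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise FieldError("duration must be > 0")
        if not (self.dt > 0):
            raise FieldError("dt must be > 0")
        for t in self.snapshot_times:
            if not (0 <= t <= self.duration):
                raise FieldError(
                    f"snapshot time {t} outside [0, {self.duration}]"
                )

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class ChamberResult:
    """Everything a single chamber run produces."""

    config: SimConfig
    fields: FieldSet
    population: CellPopulation
    growth: GrowthRecord
    times: np.ndarray
    depolymerized: np.ndarray          # degraded polymer mass per step
    snapshots: Dict[float, FieldSet]
    boundary_exchange: Dict[str, float]  # cumulative net mass gained via boundary

    @property
    def total_depolymerized(self) -> float:
        return float(self.depolymerized.sum())

    @property
    def depolymerization_rate(self) -> float:
        """Cumulative degraded polymer mass divided by run duration."""
        return self.total_depolymerized / self.config.duration

    def mean_growth_rate(self) -> float:
        return self.growth.mean_mu(self.config.growth_rate_kind)

    def mass_balance_residual(self) -> float:
        """Relative closure error of the polymer/oligomer/biomass budget.

        conv * (polymer degraded) - (oligomer lost at boundary)
        - (oligomer standing stock gained) - (biomass gained)/Y  ==  0
        """
        cfg = self.config
        degraded = cfg.depoly.conv * self.total_depolymerized
        o_out = -self.boundary_exchange["O"]
        init = make_fields(cfg.lattice, cfg.interior_init)
        if cfg.boundary_mode == "reflecting":
            init.impose_boundary()  # same start as the run
        o_stock = self.fields.total_mass("O") - init.total_mass("O")
        gained = float(self.population.B.sum() - self.population.n_cells)
        consumed = gained / (cfg.kinetics.Y * cfg.kinetics.site_mass)
        residual = degraded - o_out - o_stock - consumed
        scale = max(abs(degraded), 1e-30)
        return residual / scale


def run_chamber(cfg: SimConfig, keep_history: bool = False) -> ChamberResult:
    """Run the operator-split loop from t=0 to cfg.duration.

    Deterministic for a fixed seed.  Snapshots are taken at the first step
    boundary at or after each requested time.
    """
    fields = make_fields(cfg.lattice, cfg.interior_init)
    if cfg.boundary_mode == "reflecting":
        # closed-chamber test mode: no Dirichlet ring, uniform start
        fields.impose_boundary()
    elif cfg.boundary_mode == "open-side":
        fields.impose_boundary("open-side")
    pop = place_cells(cfg.lattice, cfg.rho, cfg.seed)
    growth = GrowthRecord(pop.n_cells, keep_history=keep_history)

    n_steps = int(round(cfg.duration / cfg.dt))
    times = np.arange(1, n_steps + 1) * cfg.dt
    depoly = np.zeros(n_steps)
    exchange = {name: 0.0 for name in ("P", "E", "O")}
    pending = sorted(set(cfg.snapshot_times))
    snapshots: Dict[float, FieldSet] = {}
    if pending and pending[0] <= 0.0:
        while pending and pending[0] <= 0.0:
            snapshots[pending.pop(0)] = fields.copy()

    for i in range(n_steps):
        t = times[i]
        before = {n: fields.total_mass(n) for n in ("P", "E", "O")}
        try:
            fields = diffuse_step(fields, cfg.transport, cfg.dt,
                                  mode=cfg.boundary_mode)
        except FieldError as exc:
            raise FieldError(
                f"instability in diffuse_step at t={t:.4g} h (dt={cfg.dt}): {exc}"
            ) from exc
        for n in exchange:
            exchange[n] += fields.total_mass(n) - before[n]
        fields, dmass = depolymerize_step(fields, cfg.depoly, cfg.dt)
        depoly[i] = dmass
        fields = secrete_step(fields, pop, cfg.kinetics, cfg.dt)
        fields, pop, mu, uptake = uptake_grow_step(fields, pop, cfg.kinetics,
                                                   cfg.dt)
        growth.update(mu, uptake, cfg.dt, t)
        fields.check_finite(f"step at t={t:.4g} h")
        while pending and pending[0] <= t + 1e-12:
            snapshots[pending.pop(0)] = fields.copy()

    return ChamberResult(cfg, fields, pop, growth, times, depoly, snapshots,
                         exchange)


def default_chamber_config(seed: int = 0) -> SimConfig:
    """The tuned reference chamber configuration.

    The published model prints its parameter table only in supplementary
    material that is not available here; these values are a reconstruction
    calibrated so the simulated chamber reproduces the reported qualitative
    behaviour: growth increases with density at low enzymatic activity,
    high activity wins at low density, and oligomers accumulate in
    low-activity chambers.  The chamber is a dead-end cavity with one open
    side to the flow, initially loaded with polymer at the supply
    concentration.  Anything quantitative should be read as
    model-relative, not physical.
    """
    return SimConfig(
        lattice=LatticeSpec(),
        transport=TransportParams(D_P=30.0, D_E=2000.0, D_O=4000.0),
        depoly=DepolymerizationParams(k_cat=7.0, K_P=0.05),
        kinetics=KineticParams(K_enz=0.1, mu_max=0.5, K_m=0.002, Y=0.5,
                               site_mass=20.0),
        rho=0.3,
        duration=20.0,
        dt=0.005,
        seed=seed,
        boundary_mode="open-side",
    )


def diffusivity_sweep_config(seed: int = 0) -> SimConfig:
    """Reference configuration for the hindered-diffusion sweep.

    Starts from a flushed chamber (no interior polymer) so degradation is
    fed purely by supply through the opening, and uses weaker uptake
    kinetics.  Under this setup the depolymerization rate rises with the
    relative diffusivity while the population growth rate peaks an order
    of magnitude below free water, as reported.  With the stock-loaded
    density-sweep setup those two responses cannot hold simultaneously:
    the initial stock pins total degradation while retention feeds back
    on biomass and enzyme, inverting one trend or the other (see the
    project notes for the full analysis).
    """
    base = default_chamber_config(seed)
    return base.replace(
        transport=replace(base.transport, D_P=100.0),
        kinetics=replace(base.kinetics, mu_max=0.1, K_m=0.01),
        interior_init={"P": 0.0, "E": 0.0, "O": 0.0},
    )


# ---------------------------------------------------------------------------
# sweeps


def condition_seed(base_seed: int, *values: float) -> int:
    """Deterministic per-condition seed from the base seed and the
    condition's parameter values (reordering grid points cannot change it)."""
    words = [base_seed & 0xFFFFFFFF]
    for v in values:
        bits = struct.unpack("<Q", struct.pack("<d", float(v)))[0]
        words.append(bits & 0xFFFFFFFF)
        words.append(bits >> 32)
    return int(np.random.SeedSequence(words).generate_state(1)[0])


@dataclass
class SweepResult:
    """Tidy per-condition outcomes of a parameter sweep plus normalization.

    ``table`` has one row per condition with the axis columns, the mean
    growth rate ``mean_mu``, the depolymerization rate ``depoly_rate``
    (mass/h), and normalized variants dividing by the maximum over the
    full sweep.
    """

    axes: Dict[str, np.ndarray]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        for name, grid in self.axes.items():
            grid = np.asarray(grid, dtype=float)
            if grid.size == 0:
                raise FieldError(f"empty sweep grid {name!r}")
            if grid.size > 1 and not np.all(np.diff(grid) > 0):
                raise FieldError(f"sweep grid {name!r} must be strictly increasing")
            self.axes[name] = grid

    @staticmethod
    def _normalize(values: np.ndarray) -> np.ndarray:
        top = float(np.max(values))
        if top <= 0:
            return np.zeros_like(values)
        return values / top

    def pivot(self, value: str, index: str, columns: str) -> pd.DataFrame:
        return self.table.pivot(index=index, columns=columns, values=value)


def _finalize_sweep(axes: Dict[str, np.ndarray],
                    rows: List[dict]) -> SweepResult:
    table = pd.DataFrame(rows)
    table["mean_mu_norm"] = SweepResult._normalize(table["mean_mu"].to_numpy())
    table["depoly_rate_norm"] = SweepResult._normalize(
        table["depoly_rate"].to_numpy())
    return SweepResult(axes=axes, table=table)


def sweep_density_activity(
    base: SimConfig,
    rho_grid: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.45, 0.6),
    kenz_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
) -> SweepResult:
    """Mean growth rate at the end of the run over a (rho, K_enz) grid."""
    rho_grid = np.asarray(rho_grid, dtype=float)
    kenz_grid = np.asarray(kenz_grid, dtype=float)
    rows = []
    for rho in rho_grid:
        for kenz in kenz_grid:
            cfg = base.replace(
                rho=float(rho),
                kinetics=replace(base.kinetics, K_enz=float(kenz)),
                seed=condition_seed(base.seed, rho, kenz),
            )
            try:
                res = run_chamber(cfg)
            except FieldError as exc:
                raise FieldError(
                    f"sweep failed at rho={rho:g}, K_enz={kenz:g}: {exc}"
                ) from exc
            rows.append({
                "rho": float(rho),
                "K_enz": float(kenz),
                "n_cells": res.population.n_cells,
                "mean_mu": res.mean_growth_rate(),
                "depoly_rate": res.depolymerization_rate,
                "mean_oligomer": res.fields.interior_mean("O"),
            })
    return _finalize_sweep({"rho": rho_grid, "K_enz": kenz_grid}, rows)


def sweep_diffusivity(
    base: SimConfig,
    drel_grid: Sequence[float] = (1e-3, 1e-2, 1e-1, 1.0),
) -> SweepResult:
    """Depolymerization and growth as all diffusivities are scaled by the
    relative (free-water-normalized) coefficient."""
    drel_grid = np.asarray(drel_grid, dtype=float)
    if np.any(drel_grid <= 0) or np.any(drel_grid > 1):
        raise FieldError("d_rel grid must lie in (0, 1]")
    rows = []
    for drel in drel_grid:
        cfg = base.replace(
            transport=base.transport.with_d_rel(float(drel)),
            seed=condition_seed(base.seed, drel),
        )
        try:
            res = run_chamber(cfg)
        except FieldError as exc:
            raise FieldError(f"sweep failed at d_rel={drel:g}: {exc}") from exc
        rows.append({
            "d_rel": float(drel),
            "n_cells": res.population.n_cells,
            "mean_mu": res.mean_growth_rate(),
            "depoly_rate": res.depolymerization_rate,
            "mean_oligomer": res.fields.interior_mean("O"),
        })
    return _finalize_sweep({"d_rel": drel_grid}, rows)
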