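"""Cell agents: placement, enzyme secretion, Monod uptake and growth.

Cells are bound to single interior lattice sites (at most one per site)
and couple to the fields as sources (enzyme) and sinks (oligomer).  Cells
do not move or divide during a model run; density is a controlled initial
condition and the observable is the specific growth rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .lattice import FieldError, FieldSet, LatticeSpec


@dataclass(frozen=True)
class KineticParams:
    """Per-cell physiology.

    K_enz : enzymatic activity, enzyme secreted per unit biomass per hour.
    mu_max, K_m, Y : Monod growth parameters (max specific growth rate,
    oligomer half-saturation in mg/L, biomass yield per oligomer mass).
    site_mass : field mass units held by one site at unit concentration —
    the site-volume constant folding concentration units into biomass
    units (1.0 keeps both scales identical).
    Defaults are reconstructions, not measurements.
    """

    K_enz: float = 0.1
    mu_max: float = 0.5
    K_m: float = 0.01
    Y: float = 0.5
    site_mass: float = 1.0

    def __post_init__(self) -> None:
        if self.K_enz < 0:
            raise FieldError("K_enz must be >= 0")
        for name in ("mu_max", "K_m", "Y", "site_mass"):
            if not (getattr(self, name) > 0):
                raise FieldError(f"{name} must be > 0")


@dataclass
class CellPopulation:
    """Lattice-site-bound agents with per-cell biomass."""

    spec: LatticeSpec
    rows: np.ndarray
    cols: np.ndarray
    B: np.ndarray
    rho: float
    seed: int

    def __post_init__(self) -> None:
        if self.rows.shape != self.cols.shape or self.rows.shape != self.B.shape:
            raise FieldError("rows, cols and B must have equal length")
        if self.n_cells:
            if (
                self.rows.min() < 1
                or self.cols.min() < 1
                or self.rows.max() > self.spec.n_rows - 2
                or self.cols.max() > self.spec.n_cols - 2
            ):
                raise FieldError("cells must occupy interior sites only")
            flat = self.rows * self.spec.n_cols + self.cols
            if len(np.unique(flat)) != self.n_cells:
                raise FieldError("duplicate cell sites")

    @property
    def n_cells(self) -> int:
        return int(self.rows.size)

    def copy(self) -> "CellPopulation":
        return CellPopulation(
            self.spec, self.rows.copy(), self.cols.copy(), self.B.copy(),
            self.rho, self.seed,
        )


@dataclass
class GrowthRecord:
    """Running growth statistics for a population.

    Tracks the latest instantaneous per-cell specific growth rate, its
    time average, and cumulative oligomer uptake.  Full per-step traces
    are kept only when ``keep_history`` is set.
    """

    n_cells: int
    keep_history: bool = False
    mu_last: np.ndarray = field(init=False)
    uptake_cum: np.ndarray = field(init=False)
    _mu_time_integral: np.ndarray = field(init=False)
    _elapsed: float = field(init=False, default=0.0)
    history_times: List[float] = field(init=False, default_factory=list)
    history_mu: List[np.ndarray] = field(init=False, default_factory=list)

    def __post_init__(self) -> None:
        self.mu_last = np.zeros(self.n_cells)
        self.uptake_cum = np.zeros(self.n_cells)
        self._mu_time_integral = np.zeros(self.n_cells)

    def update(self, mu: np.ndarray, uptake: np.ndarray, dt: float,
               t: float) -> None:
        self.mu_last = mu
        self.uptake_cum += uptake
        self._mu_time_integral += mu * dt
        self._elapsed += dt
        if self.keep_history:
            self.history_times.append(t)
            self.history_mu.append(mu.copy())

    @property
    def mu_time_avg(self) -> np.ndarray:
        if self._elapsed == 0:
            return np.zeros(self.n_cells)
        return self._mu_time_integral / self._elapsed

    def mean_mu(self, kind: str = "instantaneous") -> float:
        """Population mean growth rate; ``kind`` selects the final-step
        instantaneous rate (default) or the per-cell time average."""
        if self.n_cells == 0:
            return 0.0
        if kind == "instantaneous":
            return float(self.mu_last.mean())
        if kind == "time_average":
            return float(self.mu_time_avg.mean())
        raise FieldError(f"unknown growth-rate kind {kind!r}")


def place_cells(spec: LatticeSpec, rho: float, seed: int) -> CellPopulation:
    """Scatter ``round(rho * interior_area)`` cells uniformly at random
    over distinct interior sites.  Deterministic for a fixed seed."""
    max_rho = 1.0 / spec.spacing ** 2
    if not (0 <= rho <= max_rho * (1 + 1e-12)):
        raise FieldError(
            f"rho={rho} exceeds full occupancy ({max_rho:g} per um^2)"
        )
    n_cells = int(round(rho * spec.interior_area))
    n_cells = min(n_cells, spec.n_interior)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(spec.n_interior, size=n_cells, replace=False)
    m, n = spec.interior_shape
    rows = chosen // n + 1
    cols = chosen % n + 1
    return CellPopulation(
        spec, rows.astype(np.intp), cols.astype(np.intp),
        np.ones(n_cells), rho, seed,
    )


def secrete_step(
    fields: FieldSet, pop: CellPopulation, kp: KineticParams, dt: float
) -> FieldSet:
    """First-order enzyme secretion: E at each occupied site gains
    K_enz * B * dt."""
    if not (dt > 0):
        raise FieldError("dt must be > 0")
    fields.check_finite("secrete_step")
    out = fields.copy()
    if pop.n_cells and kp.K_enz > 0:
        out.E[pop.rows, pop.cols] += kp.K_enz * pop.B * dt / kp.site_mass
    return out


def uptake_grow_step(
    fields: FieldSet,
    pop: CellPopulation,
    kp: KineticParams,
    dt: float,
    clip_warn_fraction: float = 0.10,
) -> Tuple[FieldSet, CellPopulation, np.ndarray, np.ndarray]:
    """Monod oligomer uptake and biomass growth over one explicit step.

    Per cell: demand U = (mu_max/Y) * B * O/(K_m + O) * dt (in biomass
    units; the site-volume constant converts to and from concentration),
    clipped to the oligomer available at its site; O falls by U, B rises
    by Y*U.  Returns (fields, population, mu, uptake) where mu is the
    realized instantaneous specific growth rate (Y*U)/(B*dt) per cell and
    uptake is in field (concentration) units.
    """
    if not (dt > 0):
        raise FieldError("dt must be > 0")
    fields.check_finite("uptake_grow_step")
    out = fields.copy()
    newpop = pop.copy()
    if pop.n_cells == 0:
        return out, newpop, np.zeros(0), np.zeros(0)
    O_local = out.O[pop.rows, pop.cols]
    # demand in field units: biomass demand / site mass constant
    demand = ((kp.mu_max / kp.Y) * pop.B * O_local / (kp.K_m + O_local)
              * dt / kp.site_mass)
    clipped = demand > O_local
    if int(clipped.sum()) > clip_warn_fraction * pop.n_cells:
        warnings.warn(
            "uptake_grow_step: dt too coarse, uptake clipped at "
            f">{clip_warn_fraction:.0%} of cells",
            RuntimeWarning,
            stacklevel=2,
        )
    U = np.minimum(demand, O_local)
    out.O[pop.rows, pop.cols] = O_local - U
    gain = kp.Y * U * kp.site_mass
    mu = gain / (pop.B * dt)
    newpop.B = pop.B + gain
    return out, newpop, mu, U
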