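"""Lattice domain types and the diffusion--reaction field solver.

The chamber is a rectangular lattice of square sites.  The outermost ring
of sites is the boundary: under the default ``dirichlet`` mode it is held
at fixed concentrations (flushing flow at the chamber opening), while the
``reflecting`` mode closes the chamber (zero-flux edges) and is used for
mass-conservation testing.

Three scalar concentration fields live on the lattice: polymer ``P``,
enzyme ``E`` and oligomer ``O`` (mg/L).  Diffusion is advanced with a
backward-Euler (linear-implicit) step, which is unconditionally stable and
preserves non-negativity, so free-water diffusivities (~1e5--1e6 um^2/h)
can be stepped at macroscopic dt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

FIELD_NAMES: Tuple[str, ...] = ("P", "E", "O")

#: Default fixed boundary concentrations (mg/L): polymer supplied by the
#: flow, enzyme and oligomer flushed away.
DEFAULT_BOUNDARY: Dict[str, float] = {"P": 0.1, "E": 0.0, "O": 0.0}


class FieldError(ValueError):
    """Raised for invalid field states or parameters."""


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the chamber lattice.

    Parameters
    ----------
    n_rows, n_cols
        Total lattice size in sites, including the one-site boundary ring.
    spacing
        Site edge length in micrometres.
    boundary_values
        Fixed concentration (mg/L) imposed on the boundary ring for each
        field, keyed by field name.
    """

    n_rows: int = 50
    n_cols: int = 50
    spacing: float = 1.0
    boundary_values: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDARY)
    )

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise FieldError("lattice must be at least 3x3 sites")
        if not (self.spacing > 0):
            raise FieldError("spacing must be positive")
        for name in FIELD_NAMES:
            v = float(self.boundary_values.get(name, 0.0))
            if not np.isfinite(v) or v < 0:
                raise FieldError(
                    f"boundary value for field {name!r} must be finite and >= 0"
                )

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def interior_shape(self) -> Tuple[int, int]:
        return (self.n_rows - 2, self.n_cols - 2)

    @property
    def n_interior(self) -> int:
        m, n = self.interior_shape
        return m * n

    @property
    def interior_area(self) -> float:
        """Interior area in um^2."""
        return self.n_interior * self.spacing ** 2

    def boundary_value(self, name: str) -> float:
        return float(self.boundary_values.get(name, 0.0))

    def interior_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask[1:-1, 1:-1] = True
        return mask


@dataclass(frozen=True)
class TransportParams:
    """Diffusion coefficients (um^2/h) and a relative multiplier.

    ``d_rel`` rescales the coefficients of the fields named in
    ``d_rel_scope`` (1.0 = free water); it is the knob used for the
    hindered-diffusion sweeps.  By default the multiplier applies to the
    polymer and oligomer only — the substrate species whose mobility the
    matrix hinders — while the enzyme keeps its base coefficient; include
    "E" in the scope to rescale it as well.
    """

    D_P: float = 3.6e4
    D_E: float = 1.8e5
    D_O: float = 7.2e5
    d_rel: float = 1.0
    d_rel_scope: Tuple[str, ...] = ("P", "O")

    def __post_init__(self) -> None:
        for name in ("D_P", "D_E", "D_O"):
            if getattr(self, name) < 0:
                raise FieldError(f"{name} must be >= 0")
        if not (0 < self.d_rel <= 1):
            raise FieldError("d_rel must lie in (0, 1]")
        bad = set(self.d_rel_scope) - set(FIELD_NAMES)
        if bad:
            raise FieldError(f"unknown field(s) in d_rel_scope: {sorted(bad)}")

    def coefficient(self, name: str) -> float:
        base = {"P": self.D_P, "E": self.D_E, "O": self.D_O}[name]
        return base * (self.d_rel if name in self.d_rel_scope else 1.0)

    def with_d_rel(self, d_rel: float) -> "TransportParams":
        return replace(self, d_rel=d_rel)


@dataclass(frozen=True)
class DepolymerizationParams:
    """Rate-law constants for enzymatic polymer breakdown.

    The per-site rate is ``k_cat * E * P / (K_P + P)``: Michaelis--Menten
    in polymer, first order in enzyme.  ``conv`` is the mass fraction of
    degraded polymer released as oligomer.  ``enzyme_decay`` is a
    first-order inactivation rate of the enzyme pool (1/h), applied in the
    same step.  Values are reconstructions, not measurements.
    """

    k_cat: float = 10.0
    K_P: float = 0.05
    conv: float = 1.0
    enzyme_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.k_cat < 0:
            raise FieldError("k_cat must be >= 0")
        if not (self.K_P > 0):
            raise FieldError("K_P must be > 0")
        if not (0 < self.conv <= 1):
            raise FieldError("conv must lie in (0, 1]")
        if self.enzyme_decay < 0:
            raise FieldError("enzyme_decay must be >= 0")


@dataclass
class FieldSet:
    """The three concentration fields on one lattice."""

    spec: LatticeSpec
    P: np.ndarray
    E: np.ndarray
    O: np.ndarray

    def __post_init__(self) -> None:
        for name in FIELD_NAMES:
            arr = getattr(self, name)
            if arr.shape != self.spec.shape:
                raise FieldError(f"field {name} has shape {arr.shape}, "
                                 f"expected {self.spec.shape}")

    def copy(self) -> "FieldSet":
        return FieldSet(self.spec, self.P.copy(), self.E.copy(), self.O.copy())

    def get(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def total_mass(self, name: str) -> float:
        """Summed concentration over all sites (site volume folded in)."""
        return float(self.get(name).sum())

    def interior_mean(self, name: str) -> float:
        return float(self.get(name)[1:-1, 1:-1].mean())

    def check_finite(self, context: str = "") -> None:
        for name in FIELD_NAMES:
            arr = self.get(name)
            if not np.all(np.isfinite(arr)):
                raise FieldError(
                    f"non-finite values in field {name}"
                    + (f" during {context}" if context else "")
                )

    def impose_boundary(self, mode: str = "dirichlet") -> None:
        """Re-impose the boundary ring in place.

        ``dirichlet`` clamps the whole ring to the spec's boundary values;
        ``open-side`` clamps only the first row (the chamber opening) and
        mirrors the adjacent interior onto the three wall edges.
        """
        for name in FIELD_NAMES:
            arr = self.get(name)
            bv = self.spec.boundary_value(name)
            arr[0, :] = bv
            if mode == "open-side":
                arr[-1, :] = arr[-2, :]
                arr[:, 0] = arr[:, 1]
                arr[:, -1] = arr[:, -2]
                arr[0, :] = bv  # corners belong to the opening
            else:
                arr[-1, :] = bv
                arr[:, 0] = bv
                arr[:, -1] = bv


def make_fields(
    spec: LatticeSpec,
    interior_init: Union[float, Mapping[str, float], None] = None,
) -> FieldSet:
    """Create a FieldSet with uniform interior values and the boundary ring
    at ``spec.boundary_values``.

    ``interior_init`` may be a scalar (applied to every field), a mapping
    from field name to value, or None (interior equals the boundary value,
    i.e. a fully equilibrated start).
    """
    arrays = {}
    for name in FIELD_NAMES:
        bv = spec.boundary_value(name)
        if interior_init is None:
            init = bv
        elif isinstance(interior_init, Mapping):
            init = float(interior_init.get(name, 0.0))
        else:
            init = float(interior_init)
        if not np.isfinite(init) or init < 0:
            raise FieldError(
                f"interior init for field {name!r} must be finite and >= 0"
            )
        arr = np.full(spec.shape, bv, dtype=float)
        arr[1:-1, 1:-1] = init
        arrays[name] = arr
    return FieldSet(spec, arrays["P"], arrays["E"], arrays["O"])


# ---------------------------------------------------------------------------
# implicit diffusion


def _tridiag(n: int, neumann_lo: bool, neumann_hi: bool) -> sp.csr_matrix:
    main = np.full(n, -2.0)
    if neumann_lo:
        main[0] = -1.0
    if neumann_hi:
        main[-1] = -1.0
    off = np.ones(n - 1)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def _laplacian(m: int, n: int, mode: str = "dirichlet") -> sp.csr_matrix:
    """Five-point Laplacian stencil on an m x n grid (unit spacing).

    ``dirichlet``: absorbing ring on all sides (boundary neighbours
    dropped; their contribution enters through the RHS).  ``reflecting``:
    zero-flux on all sides.  ``open-side``: absorbing along the first-row
    edge, zero-flux walls on the other three.
    """
    if mode == "dirichlet":
        Tm = _tridiag(m, False, False)
        Tn = _tridiag(n, False, False)
    elif mode == "reflecting":
        Tm = _tridiag(m, True, True)
        Tn = _tridiag(n, True, True)
    elif mode == "open-side":
        Tm = _tridiag(m, False, True)   # rows: opening above, wall below
        Tn = _tridiag(n, True, True)    # columns: walls both sides
    else:  # pragma: no cover
        raise FieldError(f"unknown boundary mode {mode!r}")
    return (sp.kron(sp.identity(m), Tn) + sp.kron(Tm, sp.identity(n))).tocsr()


def _border_multiplicity(m: int, n: int) -> np.ndarray:
    """How many boundary-ring neighbours each interior site has."""
    mult = np.zeros((m, n))
    mult[0, :] += 1
    mult[-1, :] += 1
    mult[:, 0] += 1
    mult[:, -1] += 1
    return mult


_LU_CACHE: Dict[Tuple, object] = {}


def _solver(shape: Tuple[int, int], alpha: float, mode: str):
    key = (shape, round(float(alpha), 14), mode)
    lu = _LU_CACHE.get(key)
    if lu is None:
        m, n = shape
        L = _laplacian(m, n, mode)
        A = (sp.identity(m * n, format="csr") - alpha * L).tocsc()
        lu = splu(A)
        if len(_LU_CACHE) > 64:
            _LU_CACHE.clear()
        _LU_CACHE[key] = lu
    return lu


def diffuse_step(
    fields: FieldSet,
    transport: TransportParams,
    dt: float,
    mode: str = "dirichlet",
) -> FieldSet:
    """Advance all three fields one backward-Euler diffusion step.

    ``mode='dirichlet'`` holds the whole boundary ring fixed;
    ``mode='open-side'`` clamps only the first-row edge (the chamber
    opening) and closes the other three edges as walls;
    ``mode='reflecting'`` uses zero-flux edges over the full grid (test
    mode, conserves mass).
    """
    if not (dt > 0):
        raise FieldError("dt must be > 0")
    if mode not in ("dirichlet", "open-side", "reflecting"):
        raise FieldError(f"unknown boundary mode {mode!r}")
    fields.check_finite("diffuse_step")
    spec = fields.spec
    out = fields.copy()
    h2 = spec.spacing ** 2
    m, n = spec.interior_shape
    for name in FIELD_NAMES:
        D = transport.coefficient(name)
        if D == 0.0:
            continue
        alpha = D * dt / h2
        arr = out.get(name)
        if mode == "reflecting":
            lu = _solver(spec.shape, alpha, mode)
            sol = lu.solve(arr.ravel())
            arr[:, :] = sol.reshape(spec.shape)
        else:
            lu = _solver((m, n), alpha, mode)
            rhs = arr[1:-1, 1:-1].ravel().copy()
            bv = spec.boundary_value(name)
            if bv != 0.0:
                if mode == "dirichlet":
                    rhs += alpha * bv * _border_multiplicity(m, n).ravel()
                else:  # open-side: the opening borders the first row only
                    contrib = np.zeros((m, n))
                    contrib[0, :] = alpha * bv
                    rhs += contrib.ravel()
            sol = lu.solve(rhs)
            arr[1:-1, 1:-1] = sol.reshape(m, n)
        # backward Euler on an M-matrix is positivity preserving; clip
        # solver roundoff only
        np.clip(arr, 0.0, None, out=arr)
    if mode != "reflecting":
        out.impose_boundary(mode)
    return out


def depolymerize_step(
    fields: FieldSet,
    dp: DepolymerizationParams,
    dt: float,
    clip_warn_fraction: float = 0.10,
) -> Tuple[FieldSet, float]:
    """Enzymatic polymer breakdown over one explicit step.

    Per site dP = k_cat * E * P/(K_P + P) * dt, clipped so P stays >= 0;
    the oligomer field gains conv * dP.  Returns the new fields and the
    total degraded polymer mass (summed over sites).
    """
    if not (dt > 0):
        raise FieldError("dt must be > 0")
    fields.check_finite("depolymerize_step")
    out = fields.copy()
    rate = dp.k_cat * out.E * out.P / (dp.K_P + out.P)
    dP = rate * dt
    active = rate > 0
    clipped = dP > out.P
    n_active = int(active.sum())
    if n_active and int((clipped & active).sum()) > clip_warn_fraction * n_active:
        warnings.warn(
            "depolymerize_step: dt too coarse, clipping at "
            f">{clip_warn_fraction:.0%} of active sites",
            RuntimeWarning,
            stacklevel=2,
        )
    dP = np.minimum(dP, out.P)
    out.P -= dP
    out.O += dp.conv * dP
    if dp.enzyme_decay > 0:
        out.E *= np.exp(-dp.enzyme_decay * dt)
    return out, float(dP.sum())


def steady_state_oracle(
    spec: LatticeSpec,
    transport: TransportParams,
    source: Optional[Mapping[str, np.ndarray]] = None,
) -> FieldSet:
    """Direct dense solve of the Dirichlet steady-state diffusion problem.

    For each field with a positive diffusivity, solves
    ``D * Laplacian(u) + S = 0`` on the interior with the spec's boundary
    values.  ``source`` maps field names to per-site rate arrays
    (full-lattice shape, mg/L per h; boundary entries ignored).  Intended
    as a test oracle on small grids only.
    """
    if spec.n_rows > 20 or spec.n_cols > 20:
        raise FieldError("steady_state_oracle is restricted to grids <= 20x20")
    m, n = spec.interior_shape
    L = _laplacian(m, n, "dirichlet").toarray()
    h2 = spec.spacing ** 2
    mult = _border_multiplicity(m, n).ravel()
    out = make_fields(spec, interior_init=0.0)
    for name in FIELD_NAMES:
        D = transport.coefficient(name)
        bv = spec.boundary_value(name)
        S = np.zeros((m, n))
        if source is not None and name in source:
            S_full = np.asarray(source[name], dtype=float)
            if S_full.shape != spec.shape:
                raise FieldError(
                    f"source for {name} has shape {S_full.shape}, "
                    f"expected {spec.shape}"
                )
            S = S_full[1:-1, 1:-1]
        if D == 0.0:
            if np.any(S != 0):
                raise FieldError(
                    f"no steady state: field {name} has a source but zero "
                    "diffusivity"
                )
            continue
        # D/h2 * (L u + bv*mult) + S = 0
        rhs = -(bv * mult + S.ravel() * h2 / D)
        try:
            u = np.linalg.solve(L, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FieldError(f"singular steady-state system: {exc}") from exc
        out.get(name)[1:-1, 1:-1] = u.reshape(m, n)
    out.impose_boundary()
    return out
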