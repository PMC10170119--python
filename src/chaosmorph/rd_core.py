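"""Finite-difference integration of gradient-forced reaction-diffusion systems.

The domain is a rectangular strip, periodic along ``x`` and bounded along
``y``.  Fields are advanced by an explicit method-of-lines scheme
(second-order central differences in space, RK4 in time, Euler-Maruyama
for the optional additive noise).  The module also provides two linear
oracles used throughout the package: the dispersion relation of a
homogeneous state and a sparse screened-Poisson solver.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "SpatialGrid",
    "RDSystemSpec",
    "FieldState",
    "TrajectoryRecord",
    "BlowUpError",
    "simulate_rd",
    "dispersion_growth_rates",
    "solve_screened_poisson",
    "stability_dt_bound",
    "laplacian",
]

#: any |value| above this aborts the integration
BLOWUP_THRESHOLD = 1e8


class BlowUpError(RuntimeError):
    """Raised when a field leaves the finite range during integration."""

    def __init__(self, message: str, last_time: float = float("nan")):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class SpatialGrid:
    """Rectangular strip grid: periodic in x (cell-sampled on [0, Lx)),
    bounded in y (vertex-sampled on [0, Ly])."""

    nx: int
    ny: int
    Lx: float
    Ly: float

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 3:
            raise ValueError(f"grid too small: nx={self.nx}, ny={self.ny} (need nx>=4, ny>=3)")
        if self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("domain lengths must be positive")

    @property
    def hx(self) -> float:
        return self.Lx / self.nx

    @property
    def hy(self) -> float:
        return self.Ly / (self.ny - 1)

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.nx) * self.hx

    @property
    def y(self) -> np.ndarray:
        return np.linspace(0.0, self.Ly, self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (ny, nx)."""
        return np.meshgrid(self.x, self.y)


@dataclass
class RDSystemSpec:
    """m-component reaction-diffusion system with spatial sources.

    ``reaction(*components)`` returns a tuple/list of m arrays (the reaction
    term for each component, degradation excluded).  ``sources[i]`` maps
    (X, Y) mesh arrays to the source field of component i; ``None`` means no
    source.  ``bc[i]`` is a pair of tags for y=0 and y=Ly, each
    ``"neumann0"`` or ``"dirichlet0"``; x is always periodic.
    """

    m: int
    D: Sequence[float]
    lambdas: Sequence[float]
    reaction: Optional[Callable[..., Sequence[np.ndarray]]] = None
    sources: Optional[Sequence[Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]]]] = None
    bc: Optional[Sequence[tuple[str, str]]] = None
    noise_amplitude: float = 0.0
    names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.D = tuple(float(d) for d in self.D)
        self.lambdas = tuple(float(l) for l in self.lambdas)
        if len(self.D) != self.m or len(self.lambdas) != self.m:
            raise ValueError("D and lambdas must have length m")
        if any(d <= 0 for d in self.D):
            raise ValueError("all diffusion coefficients must be > 0")
        if any(l < 0 for l in self.lambdas):
            raise ValueError("degradation rates must be >= 0")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.bc is None:
            self.bc = tuple(("neumann0", "neumann0") for _ in range(self.m))
        else:
            self.bc = tuple((str(a), str(b)) for a, b in self.bc)
            for a, b in self.bc:
                for tag in (a, b):
                    if tag not in ("neumann0", "dirichlet0"):
                        raise ValueError(f"unknown boundary tag {tag!r}")

    def source_fields(self, grid: SpatialGrid) -> np.ndarray:
        """Evaluate all sources on the grid -> (m, ny, nx) array."""
        X, Y = grid.meshgrid()
        out = np.zeros((self.m, grid.ny, grid.nx))
        if self.sources is not None:
            for i, src in enumerate(self.sources):
                if src is not None:
                    out[i] = np.broadcast_to(np.asarray(src(X, Y), dtype=float), X.shape)
        return out


@dataclass
class FieldState:
    """Concentration fields at a single time: values has shape (m, ny, nx)."""

    t: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (m, ny, nx)")

    def check_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))


@dataclass
class TrajectoryRecord:
    times: np.ndarray
    states: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def spec_hash(spec: RDSystemSpec, grid: SpatialGrid) -> str:
    """Stable short hash of the numeric content of a spec+grid pair."""
    payload = {
        "m": spec.m,
        "D": list(spec.D),
        "lambdas": list(spec.lambdas),
        "bc": [list(b) for b in spec.bc],
        "noise": spec.noise_amplitude,
        "grid": [grid.nx, grid.ny, grid.Lx, grid.Ly],
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# spatial operators


def laplacian(field2d: np.ndarray, grid: SpatialGrid, bc: tuple[str, str]) -> np.ndarray:
    """Second-order 5-point Laplacian; periodic in x, bc tags at y=0 / y=Ly.

    Neumann rows use mirrored ghost nodes; Dirichlet rows are pinned to 0
    (the returned Laplacian there is 0 and the integrator keeps them at 0).
    """
    hx2 = grid.hx * grid.hx
    hy2 = grid.hy * grid.hy
    lap = np.empty_like(field2d)
    # x direction: periodic
    lap[:] = (np.roll(field2d, -1, axis=1) - 2.0 * field2d + np.roll(field2d, 1, axis=1)) / hx2
    # y direction: interior
    lap[1:-1] += (field2d[2:] - 2.0 * field2d[1:-1] + field2d[:-2]) / hy2
    # y boundaries
    if bc[0] == "neumann0":
        lap[0] += 2.0 * (field2d[1] - field2d[0]) / hy2
    else:
        lap[0] = 0.0
    if bc[1] == "neumann0":
        lap[-1] += 2.0 * (field2d[-2] - field2d[-1]) / hy2
    else:
        lap[-1] = 0.0
    return lap


def apply_dirichlet(values: np.ndarray, spec: RDSystemSpec) -> None:
    """Pin Dirichlet rows of every component to zero, in place."""
    for i in range(spec.m):
        if spec.bc[i][0] == "dirichlet0":
            values[i, 0, :] = 0.0
        if spec.bc[i][1] == "dirichlet0":
            values[i, -1, :] = 0.0


def stability_dt_bound(spec: RDSystemSpec, grid: SpatialGrid, safety: float = 0.9) -> float:
    """Pure-diffusion CFL bound: dt <= safety * hx^2 hy^2 / (2 d (hx^2+hy^2))."""
    hx2, hy2 = grid.hx ** 2, grid.hy ** 2
    dmax = max(spec.D)
    return safety * hx2 * hy2 / (2.0 * dmax * (hx2 + hy2))


# ---------------------------------------------------------------------------
# integration


def _rhs(values: np.ndarray, spec: RDSystemSpec, grid: SpatialGrid, sources: np.ndarray) -> np.ndarray:
    out = np.empty_like(values)
    for i in range(spec.m):
        out[i] = spec.D[i] * laplacian(values[i], grid, spec.bc[i])
        out[i] -= spec.lambdas[i] * values[i]
        out[i] += sources[i]
    if spec.reaction is not None:
        rxn = spec.reaction(*values)
        for i in range(spec.m):
            out[i] += rxn[i]
    # keep Dirichlet rows frozen at zero
    for i in range(spec.m):
        if spec.bc[i][0] == "dirichlet0":
            out[i, 0, :] = 0.0
        if spec.bc[i][1] == "dirichlet0":
            out[i, -1, :] = 0.0
    return out


def simulate_rd(
    spec: RDSystemSpec,
    grid: SpatialGrid,
    init: FieldState,
    t_end: float,
    dt: float,
    save_every: int = 1,
    seed: int = 0,
) -> TrajectoryRecord:
    """Integrate the RD system from ``init`` to ``t_end``.

    Deterministic part advanced by classical RK4; when
    ``spec.noise_amplitude > 0`` an additive Euler-Maruyama increment
    ``amplitude * sqrt(dt) * N(0,1)`` is added each step (spatially white,
    independent per component).  Snapshots are stored every
    ``save_every`` steps.  Raises :class:`BlowUpError` on non-finite or
    runaway values, reporting the last finite time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bound = stability_dt_bound(spec, grid)
    if dt > bound:
        raise ValueError(f"dt={dt} violates the diffusion stability bound {bound:.3g}")
    if init.values.shape != (spec.m, grid.ny, grid.nx):
        raise ValueError("initial state shape does not match spec and grid")
    if save_every < 1:
        raise ValueError("save_every must be >= 1")

    rng = np.random.default_rng(seed)
    sources = spec.source_fields(grid)
    u = init.values.copy()
    apply_dirichlet(u, spec)
    t = float(init.t)
    n_steps = int(np.ceil((t_end - t) / dt - 1e-12))

    times = [t]
    states = [FieldState(t, u.copy())]
    for step in range(1, n_steps + 1):
        k1 = _rhs(u, spec, grid, sources)
        k2 = _rhs(u + 0.5 * dt * k1, spec, grid, sources)
        k3 = _rhs(u + 0.5 * dt * k2, spec, grid, sources)
        k4 = _rhs(u + dt * k3, spec, grid, sources)
        u = u + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if spec.noise_amplitude > 0.0:
            u = u + spec.noise_amplitude * np.sqrt(dt) * rng.standard_normal(u.shape)
            apply_dirichlet(u, spec)
        t = float(init.t) + step * dt
        if not np.all(np.isfinite(u)) or np.max(np.abs(u)) > BLOWUP_THRESHOLD:
            raise BlowUpError(
                f"field blow-up at t={t:.6g}; last finite time {times[-1]:.6g}",
                last_time=times[-1],
            )
        if step % save_every == 0 or step == n_steps:
            times.append(t)
            states.append(FieldState(t, u.copy()))

    meta = {
        "spec_hash": spec_hash(spec, grid),
        "seed": seed,
        "dt": dt,
        "save_every": save_every,
        "integrator": "rk4+euler-maruyama" if spec.noise_amplitude > 0 else "rk4",
    }
    return TrajectoryRecord(np.asarray(times), states, meta)


# ---------------------------------------------------------------------------
# linear-stability oracle


def _reaction_jacobian(spec: RDSystemSpec, u0: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Finite-difference Jacobian of the reaction terms at a homogeneous state."""
    m = spec.m
    J = np.zeros((m, m))
    if spec.reaction is None:
        return J

    def f_of(vals: np.ndarray) -> np.ndarray:
        fields = [np.full((1, 1), v) for v in vals]
        rxn = spec.reaction(*fields)
        return np.array([float(np.asarray(r).ravel()[0]) for r in rxn])

    for j in range(m):
        up = u0.copy()
        um = u0.copy()
        up[j] += eps
        um[j] -= eps
        J[:, j] = (f_of(up) - f_of(um)) / (2.0 * eps)
    return J


def dispersion_growth_rates(
    spec: RDSystemSpec,
    u0: Sequence[float],
    wavenumbers: Sequence[float],
    source_values: Optional[Sequence[float]] = None,
    equilibrium_tol: float = 1e-8,
) -> np.ndarray:
    """Growth rate max Re eig(J(u0) - k^2 D - diag(lambda)) for each wavenumber.

    ``u0`` must be an equilibrium of reaction - degradation + constant
    sources (``source_values``, default zero); the residual is checked.
    """
    u0 = np.asarray(u0, dtype=float)
    if u0.shape != (spec.m,):
        raise ValueError("u0 must have one value per component")
    src = np.zeros(spec.m) if source_values is None else np.asarray(source_values, dtype=float)

    if spec.reaction is not None:
        fields = [np.full((1, 1), v) for v in u0]
        rxn = np.array([float(np.asarray(r).ravel()[0]) for r in spec.reaction(*fields)])
    else:
        rxn = np.zeros(spec.m)
    residual = rxn - np.asarray(spec.lambdas) * u0 + src
    res_norm = float(np.max(np.abs(residual)))
    if res_norm > equilibrium_tol:
        raise ValueError(f"u0 is not an equilibrium: residual {res_norm:.3e} > {equilibrium_tol:.1e}")

    J = _reaction_jacobian(spec, u0)
    D = np.diag(spec.D)
    Lam = np.diag(spec.lambdas)
    rates = np.empty(len(wavenumbers))
    for idx, k in enumerate(wavenumbers):
        A = J - (k * k) * D - Lam
        rates[idx] = float(np.max(np.linalg.eigvals(A).real))
    return rates


# ---------------------------------------------------------------------------
# screened-Poisson solver


def _y_index_maps(grid: SpatialGrid, bc: tuple[str, str]) -> tuple[np.ndarray, int]:
    """Rows participating in the linear system (Dirichlet rows excluded)."""
    rows = np.arange(grid.ny)
    if bc[0] == "dirichlet0":
        rows = rows[1:]
    if bc[1] == "dirichlet0":
        rows = rows[:-1]
    return rows, len(rows)


def screened_poisson_operator(
    grid: SpatialGrid, d_w: float, b: float, bc: tuple[str, str] = ("neumann0", "neumann0")
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse matrix for d_w * Lap_h - b^2 on the unknown rows.

    Returns (A, rows) where ``rows`` are the y-row indices carried as
    unknowns (Dirichlet rows, pinned at 0, are eliminated).
    """
    rows, nyu = _y_index_maps(grid, bc)
    nx = grid.nx
    n = nyu * nx
    hx2, hy2 = grid.hx ** 2, grid.hy ** 2

    def idx(r: int, c: int) -> int:
        return r * nx + c

    data, ii, jj = [], [], []
    for r in range(nyu):
        yrow = rows[r]
        for c in range(nx):
            center = -2.0 * d_w / hx2 - b * b
            # x neighbours (periodic)
            for cn in ((c - 1) % nx, (c + 1) % nx):
                ii.append(idx(r, c))
                jj.append(idx(r, cn))
                data.append(d_w / hx2)
            # y neighbours
            if 0 < yrow < grid.ny - 1:
                center += -2.0 * d_w / hy2
                for rn_y in (yrow - 1, yrow + 1):
                    pos = np.searchsorted(rows, rn_y)
                    if pos < nyu and rows[pos] == rn_y:  # unknown neighbour
                        ii.append(idx(r, c))
                        jj.append(idx(pos, c))
                        data.append(d_w / hy2)
                    # Dirichlet neighbour contributes 0
            elif yrow == 0:  # Neumann bottom (mirror ghost)
                center += -2.0 * d_w / hy2
                ii.append(idx(r, c))
                jj.append(idx(r + 1, c))
                data.append(2.0 * d_w / hy2)
            else:  # Neumann top
                center += -2.0 * d_w / hy2
                ii.append(idx(r, c))
                jj.append(idx(r - 1, c))
                data.append(2.0 * d_w / hy2)
            ii.append(idx(r, c))
            jj.append(idx(r, c))
            data.append(center)
    A = sp.csr_matrix((data, (ii, jj)), shape=(n, n))
    return A, rows


def solve_screened_poisson(
    source: np.ndarray,
    d_w: float,
    b: float,
    grid: SpatialGrid,
    bc: tuple[str, str] = ("neumann0", "neumann0"),
    residual_tol: float = 1e-8,
) -> np.ndarray:
    """Solve d_w * Lap(w) - b^2 w = source on the grid.

    For b=0 with no Dirichlet side the operator has a constant nullspace:
    the source must then have zero mean and the zero-mean solution is
    selected via a Lagrange-multiplier augmentation.
    """
    if d_w <= 0:
        raise ValueError("d_w must be > 0")
    if b < 0:
        raise ValueError("b must be >= 0")
    source = np.asarray(source, dtype=float)
    if source.shape != (grid.ny, grid.nx):
        raise ValueError(f"source shape {source.shape} does not match grid ({grid.ny},{grid.nx})")

    A, rows = screened_poisson_operator(grid, d_w, b, bc)
    rhs = source[rows].ravel()
    has_dirichlet = bc[0] == "dirichlet0" or bc[1] == "dirichlet0"
    singular = (b == 0.0) and not has_dirichlet

    if singular:
        mean = float(np.mean(rhs))
        scale = float(np.max(np.abs(rhs))) or 1.0
        if abs(mean) > 1e-10 * scale:
            raise ValueError(
                "singular system: b=0 with Neumann/periodic boundaries requires a zero-mean source"
            )
        n = A.shape[0]
        ones = np.ones((n, 1))
        A_aug = sp.bmat([[A, ones], [ones.T, None]], format="csc")
        sol = spla.spsolve(A_aug, np.concatenate([rhs - mean, [0.0]]))
        w_flat = sol[:n]
    else:
        w_flat = spla.spsolve(A.tocsc(), rhs)

    w = np.zeros((grid.ny, grid.nx))
    w[rows] = w_flat.reshape(len(rows), grid.nx)

    # residual check with the same discrete operator
    lap = laplacian(w, grid, bc)
    resid = d_w * lap - b * b * w - source
    resid[np.setdiff1d(np.arange(grid.ny), rows)] = 0.0  # Dirichlet rows not part of the system
    if singular:
        resid -= np.mean(resid)
    scale = float(np.max(np.abs(source))) or 1.0
    rmax = float(np.max(np.abs(resid)))
    if rmax > residual_tol * scale:
        raise RuntimeError(f"screened-Poisson solve did not converge: residual {rmax:.3e}")
    return w
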