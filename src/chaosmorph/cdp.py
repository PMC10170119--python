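"""Cellular developmental programs (CDPs).

Discrete cell types are encoded by fixed-width binary codes, morphogen
values are classified through a partition of morphogen space, and the
morphogenetic operator reads a space-time concentration history into a
positions x times matrix of cell types.  Prescribed strings are emitted
from ergodic dynamics (tent map, thresholded Rossler coordinate) with a
stop signal once the target appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from .rd_core import SpatialGrid, TrajectoryRecord, solve_screened_poisson
from .segment_dynamics import integrate_amplitudes, AmplitudeSystem, rossler_vfield

__all__ = [
    "CellAlphabet",
    "PartitionSpec",
    "MorphogeneticOperator",
    "CDPRecord",
    "EmissionResult",
    "encode_pattern",
    "decode_pattern",
    "classify_state",
    "morphogen_field_from_u",
    "extract_cdp",
    "run_until_string",
    "tent_map_sampler",
    "rossler_coordinate_sampler",
    "two_type_alphabet",
    "four_type_alphabet",
    "halves_partition",
]


@dataclass(frozen=True)
class CellAlphabet:
    """Ordered cell-type names with fixed-width binary codes."""

    symbols: tuple
    codes: tuple

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.codes):
            raise ValueError("symbols and codes must align")
        lengths = {len(c) for c in self.codes}
        if len(lengths) != 1:
            raise ValueError("all codes must have the same length")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("codes must be distinct")
        for c in self.codes:
            if set(c) - {"0", "1"}:
                raise ValueError("codes must be binary strings")

    @property
    def bits_per_cell(self) -> int:
        return len(self.codes[0])

    def code_of(self, symbol: str) -> str:
        try:
            return self.codes[self.symbols.index(symbol)]
        except ValueError:
            raise KeyError(f"unknown symbol {symbol!r}") from None

    def symbol_of(self, code: str) -> str:
        try:
            return self.symbols[self.codes.index(code)]
        except ValueError:
            raise KeyError(f"unknown code {code!r}") from None


def four_type_alphabet() -> CellAlphabet:
    """The binary-tree encoding of the four cell types."""
    return CellAlphabet(symbols=("gr", "wr", "gb", "wb"), codes=("00", "01", "10", "11"))


def two_type_alphabet() -> CellAlphabet:
    return CellAlphabet(symbols=("r", "b"), codes=("0", "1"))


def encode_pattern(symbols: Sequence[str], alphabet: CellAlphabet) -> str:
    """Concatenated fixed-width codes of a cell pattern."""
    return "".join(alphabet.code_of(s) for s in symbols)


def decode_pattern(bits: str, alphabet: CellAlphabet) -> list:
    w = alphabet.bits_per_cell
    if len(bits) % w != 0:
        raise ValueError(f"binary string length {len(bits)} is not a multiple of {w}")
    return [alphabet.symbol_of(bits[i : i + w]) for i in range(0, len(bits), w)]


# ---------------------------------------------------------------------------
# morphogen-space partitions


@dataclass
class PartitionSpec:
    """Ordered half-open intervals [lo, hi) covering [bounds[0], bounds[1]].

    The final interval is closed at the top; a value exactly on an interior
    threshold belongs to the upper region.
    """

    edges: np.ndarray  # len(labels) + 1 increasing breakpoints
    labels: tuple

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.labels = tuple(self.labels)
        if len(self.edges) != len(self.labels) + 1:
            raise ValueError("need len(labels) + 1 edges")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("edges must be strictly increasing")

    @property
    def bounds(self) -> tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])


def halves_partition(labels: tuple = ("r", "b"), lo: float = 0.0, hi: float = 1.0) -> PartitionSpec:
    """Two equal regions of [lo, hi); the classic French-flag threshold at the midpoint."""
    return PartitionSpec(edges=np.array([lo, 0.5 * (lo + hi), hi]), labels=labels)


def classify_state(value: float, partition: PartitionSpec, clip: bool = True) -> str:
    """Label of the unique region containing ``value``.

    Out-of-box values are clipped to the bounds when ``clip`` is true,
    otherwise rejected.
    """
    lo, hi = partition.bounds
    v = float(value)
    if v < lo or v > hi:
        if not clip:
            raise ValueError(f"value {v} outside the partition box [{lo}, {hi}]")
        v = min(max(v, lo), hi)
    # half-open [lo, hi): boundary goes to the upper region; top edge closed
    idx = int(np.searchsorted(partition.edges, v, side="right")) - 1
    idx = min(max(idx, 0), len(partition.labels) - 1)
    return partition.labels[idx]


def classify_many(values: np.ndarray, partition: PartitionSpec, clip: bool = True) -> list:
    return [classify_state(v, partition, clip=clip) for v in np.asarray(values, dtype=float).ravel()]


# ---------------------------------------------------------------------------
# morphogen field


def morphogen_field_from_u(
    u_field: np.ndarray,
    u0_field: Union[np.ndarray, float, None],
    d_w: float,
    b: float,
    grid: SpatialGrid,
    bc: tuple[str, str] = ("neumann0", "neumann0"),
) -> tuple[np.ndarray, dict]:
    """Solve d_w lap(w) - b^2 w = u - u0 for the morphogen w.

    ``u0_field`` defaults to the spatial mean of u (keeps b=0 solvable).
    Returns (w, metadata) with the decay length 1/beta, beta = b / sqrt(d_w).
    """
    u_field = np.asarray(u_field, dtype=float)
    if u0_field is None:
        u0 = float(u_field.mean())
    else:
        u0 = u0_field
    source = u_field - u0
    w = solve_screened_poisson(source, d_w, b, grid, bc=bc)
    beta = b / np.sqrt(d_w)
    meta = {"beta": beta, "decay_length": (1.0 / beta) if beta > 0 else float("inf")}
    return w, meta


# ---------------------------------------------------------------------------
# the morphogenetic operator


@dataclass
class MorphogeneticOperator:
    """Reads a 1-D concentration profile into a symbol string.

    Cell averaging uses an arithmetic mean over grid nodes within
    ``cell_halfwidth`` of each sample position (default: half the minimum
    spacing between sample positions), with periodic x-distance.
    """

    partition: PartitionSpec
    sample_positions: np.ndarray
    sample_times: np.ndarray
    cell_halfwidth: Optional[float] = None

    def __post_init__(self) -> None:
        self.sample_positions = np.asarray(self.sample_positions, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if not np.all(np.diff(self.sample_positions) > 0):
            raise ValueError("sample positions must be strictly increasing")
        if len(self.sample_times) and not np.all(np.diff(self.sample_times) > 0):
            raise ValueError("sample times must be strictly increasing")
        if self.cell_halfwidth is None and len(self.sample_positions) > 1:
            self.cell_halfwidth = 0.5 * float(np.min(np.diff(self.sample_positions)))
        elif self.cell_halfwidth is None:
            self.cell_halfwidth = 0.0

    def window_average(self, profile: np.ndarray, x: np.ndarray, Lx: float, position: float) -> float:
        dist = np.abs(((x - position + Lx / 2) % Lx) - Lx / 2)
        mask = dist <= self.cell_halfwidth + 1e-12
        if not np.any(mask):
            mask = dist == dist.min()
        return float(profile[mask].mean())


@dataclass
class CDPRecord:
    """Symbols a(j, t_k): array of shape (K times, N_c positions)."""

    symbols: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    alphabet: CellAlphabet

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=object)
        if self.symbols.shape != (len(self.times), len(self.positions)):
            raise ValueError("symbol matrix shape must be (K, N_c)")
        valid = set(self.alphabet.symbols)
        for s in self.symbols.ravel():
            if s not in valid:
                raise ValueError(f"symbol {s!r} not in alphabet")

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def n_times(self) -> int:
        return len(self.times)


def _profile_at_time(times: np.ndarray, profiles: np.ndarray, t: float) -> np.ndarray:
    """Nearest snapshot, linear interpolation when t falls between samples."""
    if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
        raise ValueError(f"sample time {t} outside trajectory span [{times[0]}, {times[-1]}]")
    idx = int(np.searchsorted(times, t))
    if idx == 0:
        return profiles[0]
    if idx >= len(times):
        return profiles[-1]
    t0, t1 = times[idx - 1], times[idx]
    if abs(t - t0) < 1e-9 * max(1.0, abs(t0)):
        return profiles[idx - 1]
    if abs(t - t1) < 1e-9 * max(1.0, abs(t1)):
        return profiles[idx]
    w = (t - t0) / (t1 - t0)
    return (1 - w) * profiles[idx - 1] + w * profiles[idx]


def extract_cdp(
    trajectory: Union[TrajectoryRecord, tuple],
    op: MorphogeneticOperator,
    alphabet: CellAlphabet,
    grid: Optional[SpatialGrid] = None,
    component: int = 0,
) -> CDPRecord:
    """Apply the morphogenetic operator to a concentration history.

    ``trajectory`` is either a :class:`TrajectoryRecord` (the selected
    component is averaged over y into 1-D profiles; ``grid`` required) or
    a tuple ``(times, profiles, x, Lx)`` of precomputed 1-D profiles.
    """
    if isinstance(trajectory, TrajectoryRecord):
        if grid is None:
            raise ValueError("grid is required for a TrajectoryRecord input")
        times = trajectory.times
        profiles = np.stack([st.values[component].mean(axis=0) for st in trajectory.states])
        x, Lx = grid.x, grid.Lx
    else:
        times, profiles, x, Lx = trajectory
        times = np.asarray(times, dtype=float)
        profiles = np.asarray(profiles, dtype=float)

    missing = [t for t in op.sample_times if t < times[0] - 1e-9 or t > times[-1] + 1e-9]
    if missing:
        raise ValueError(f"sample times outside trajectory span: {missing}")

    K, Nc = len(op.sample_times), len(op.sample_positions)
    out = np.empty((K, Nc), dtype=object)
    for k, t in enumerate(op.sample_times):
        prof = _profile_at_time(times, profiles, float(t))
        for j, pos in enumerate(op.sample_positions):
            avg = op.window_average(prof, x, Lx, float(pos))
            out[k, j] = classify_state(avg, op.partition)
    return CDPRecord(symbols=out, times=np.asarray(op.sample_times), positions=op.sample_positions,
                     alphabet=alphabet)


# ---------------------------------------------------------------------------
# ergodic string emission


_TENT_BITS = 64
_TENT_MASK = (1 << _TENT_BITS) - 1


def tent_map_sampler(seed: int, x0: Optional[float] = None) -> Iterator[float]:
    """Exact tent-map orbit from a measure-typical initial condition.

    The state is kept as a 64-bit window of the binary expansion,
    lazily extended with random bits, so the orbit never collapses onto
    the dyadic fixed point the way a floating-point iteration does.  The
    emitted symbol stream under the dyadic partition is exactly
    Bernoulli(1/2).
    """
    rng = np.random.default_rng(seed)
    if x0 is not None:
        bits = int(x0 * (1 << _TENT_BITS)) & _TENT_MASK
    else:
        bits = int(rng.integers(0, 1 << 32)) << 32 | int(rng.integers(0, 1 << 32))
    while True:
        yield bits / float(1 << _TENT_BITS)
        top = bits >> (_TENT_BITS - 1)
        bits = ((bits << 1) & _TENT_MASK) | int(rng.integers(0, 2))
        if top:  # x >= 1/2: T(x) = 2(1-x) -> shifted complement
            bits = (~bits) & _TENT_MASK


def rossler_coordinate_sampler(
    seed: int,
    delta_t: float = 0.5,
    dt: float = 0.01,
    transient: float = 50.0,
    center: float = 0.0,
    scale: float = 20.0,
) -> Iterator[float]:
    """X1 coordinate of a Rossler orbit, affinely mapped into [0, 1].

    ``center`` should be near the long-run median of X1 so that the
    half-threshold partition splits the samples roughly evenly.
    """
    rng = np.random.default_rng(seed)
    system = AmplitudeSystem(n_vars=3, vfield=rossler_vfield())
    X0 = np.array([1.0, 1.0, 1.0]) + 0.1 * rng.standard_normal(3)
    _, traj = integrate_amplitudes(system, X0, transient, dt, save_every=int(round(transient / dt)))
    X = traj[-1]
    steps = max(1, int(round(delta_t / dt)))
    F = system.vfield
    while True:
        yield float(np.clip(0.5 + (X[0] - center) / scale, 0.0, 1.0))
        for _ in range(steps):
            k1 = F(X)
            k2 = F(X + 0.5 * dt * k1)
            k3 = F(X + 0.5 * dt * k2)
            k4 = F(X + dt * k3)
            X = X + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


@dataclass
class EmissionResult:
    hit_time: int  # index of the first window start matching the target; -1 if censored
    emitted: str  # symbols emitted up to and including the completed window
    censored: bool = False


def run_until_string(
    dynamics: Union[Iterable[float], Iterator[float]],
    partition: PartitionSpec,
    target: Sequence[str],
    delta_T: int = 1,
    max_steps: int = 10 ** 6,
    seed: Optional[int] = None,
) -> EmissionResult:
    """Slide a window over the emitted symbol stream until it equals ``target``.

    ``dynamics`` is an iterator of morphogen values (e.g. from
    :func:`tent_map_sampler`); every ``delta_T``-th value is sampled and
    classified.  Returns the start index of the first matching window (in
    sample counts, the value at construction time being sample 0) or a
    censored result once ``max_steps`` samples are exhausted.
    """
    if callable(dynamics):
        dynamics = dynamics(seed if seed is not None else 0)
    it = iter(dynamics)
    target = list(target)
    L = len(target)
    if L == 0:
        raise ValueError("target must be non-empty")
    for s in target:
        if s not in partition.labels:
            raise ValueError(f"target symbol {s!r} not produced by the partition")
    if delta_T < 1:
        raise ValueError("delta_T must be a positive integer stride")

    window: list = []
    emitted: list = []
    for t in range(max_steps):
        if t > 0:
            for _ in range(delta_T - 1):
                next(it)
        v = next(it)
        sym = classify_state(v, partition)
        emitted.append(sym)
        window.append(sym)
        if len(window) > L:
            window.pop(0)
        if window == target:
            return EmissionResult(hit_time=t - L + 1, emitted="".join(emitted))
    return EmissionResult(hit_time=-1, emitted="".join(emitted), censored=True)
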