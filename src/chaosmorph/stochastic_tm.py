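"""Absorbing Markov chains as stochastic Turing machines.

A target gene-expression state is declared absorbing; morphogenesis time is
the hitting time tau of that state.  The module provides Monte-Carlo
simulation, the exact fundamental-matrix oracle for E[tau] and Var[tau],
hitting-time statistics (both the mean/sd ratio and the coefficient of
variation), random-chain ensembles, the Boolean-hypercube target search
with optional staging, and the least-squares fit of E[tau] against the
number of states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "MarkovChainSpec",
    "StagePlan",
    "AbsorptionStats",
    "AbsorptionSample",
    "random_absorbing_chain",
    "simulate_absorption",
    "simulate_absorption_batch",
    "expected_absorption_exact",
    "absorption_stats",
    "hypercube_walk_chain",
    "hypercube_search",
    "fit_tau_scaling",
]

KERNEL_ROW_TOL = 1e-12


@dataclass
class MarkovChainSpec:
    """Discrete-time chain with one absorbing target state.

    ``kernel`` is row-stochastic: kernel[s, s'] = P(s -> s').  With an
    environment schedule, ``kernels`` holds one kernel per environment
    state and ``environment(t)`` returns the index used at step t.
    """

    n_states: int
    kernel: np.ndarray
    target: int
    kernels: Optional[Sequence[np.ndarray]] = None
    environment: Optional[callable] = None

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.shape != (self.n_states, self.n_states):
            raise ValueError("kernel shape must be (n_states, n_states)")
        if not (0 <= self.target < self.n_states):
            raise ValueError("target out of range")
        self.validate()

    def kernel_at(self, t: int) -> np.ndarray:
        if self.kernels is None or self.environment is None:
            return self.kernel
        return np.asarray(self.kernels[self.environment(t)], dtype=float)

    def validate(self) -> None:
        rows = self.kernel.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > KERNEL_ROW_TOL * self.n_states:
            raise ValueError("kernel rows must sum to 1")
        if np.any(self.kernel < -KERNEL_ROW_TOL):
            raise ValueError("kernel entries must be non-negative")
        trow = self.kernel[self.target]
        if abs(trow[self.target] - 1.0) > KERNEL_ROW_TOL or np.max(np.delete(trow, self.target)) > KERNEL_ROW_TOL:
            raise ValueError("target row must be absorbing")
        if not self._target_reachable():
            raise ValueError("target unreachable from some state")

    def _target_reachable(self) -> bool:
        """Reverse BFS from the target over positive-probability edges."""
        reached = np.zeros(self.n_states, dtype=bool)
        reached[self.target] = True
        frontier = [self.target]
        incoming = self.kernel.T > 0
        while frontier:
            nxt = []
            for s in frontier:
                preds = np.nonzero(incoming[s])[0]
                for p in preds:
                    if not reached[p]:
                        reached[p] = True
                        nxt.append(p)
            frontier = nxt
        return bool(reached.all())


@dataclass
class StagePlan:
    """Decomposition of a target bitstring into consecutive stage substrings."""

    target_string: str
    k: int
    substrings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        m = len(self.target_string)
        if self.k < 1 or self.k > m:
            raise ValueError("k must be in [1, len(target_string)]")
        if set(self.target_string) - {"0", "1"}:
            raise ValueError("target_string must be binary")
        if not self.substrings:
            base = m // self.k
            rem = m % self.k
            pieces, pos = [], 0
            for j in range(self.k):
                ln = base + (1 if j < rem else 0)
                pieces.append(self.target_string[pos : pos + ln])
                pos += ln
            self.substrings = pieces
        if "".join(self.substrings) != self.target_string:
            raise ValueError("substrings must concatenate to target_string")

    @property
    def stage_lengths(self) -> list:
        return [len(s) for s in self.substrings]


@dataclass
class AbsorptionSample:
    """One simulated hitting time; ``censored`` marks a max_steps cutoff."""

    tau: int
    censored: bool = False
    stage_taus: Optional[list] = None


@dataclass
class AbsorptionStats:
    n_samples: int
    mean: float
    variance: float
    sigma_paper: float  # E[tau]/sd(tau); inf when variance == 0
    cv: float  # sd(tau)/E[tau]
    se_mean: float
    se_sigma_paper: float
    se_cv: float
    n_censored: int = 0


def random_absorbing_chain(n: int, seed: int, target: Optional[int] = None) -> MarkovChainSpec:
    """Constant-transition-probability absorbing chain.

    Each transient row is drawn from a flat Dirichlet over all n states;
    the target row is absorbing.
    """
    rng = np.random.default_rng(seed)
    if target is None:
        target = int(rng.integers(n))
    W = rng.dirichlet(np.ones(n), size=n)
    W[target] = 0.0
    W[target, target] = 1.0
    return MarkovChainSpec(n_states=n, kernel=W, target=target)


def simulate_absorption(
    chain: MarkovChainSpec,
    start: int,
    seed: int,
    max_steps: int = 0,
) -> AbsorptionSample:
    """Simulate one trajectory until absorption; tau = number of steps.

    ``max_steps=0`` means the default budget 1000 * n_states.  A run that
    exhausts the budget is returned censored (tau = max_steps).
    """
    if max_steps == 0:
        max_steps = 1000 * chain.n_states
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if not (0 <= start < chain.n_states):
        raise ValueError("start out of range")
    if start == chain.target:
        return AbsorptionSample(0)
    rng = np.random.default_rng(seed)
    static = chain.kernels is None or chain.environment is None
    cum = np.cumsum(chain.kernel, axis=1) if static else None
    s = start
    for t in range(1, max_steps + 1):
        if static:
            r = rng.random()
            s = int(np.searchsorted(cum[s], r, side="right"))
            s = min(s, chain.n_states - 1)
        else:
            probs = chain.kernel_at(t - 1)[s]
            s = int(rng.choice(chain.n_states, p=probs))
        if s == chain.target:
            return AbsorptionSample(t)
    return AbsorptionSample(max_steps, censored=True)


def simulate_absorption_batch(
    chain: MarkovChainSpec,
    starts: Sequence[int],
    seed: int,
    max_steps: int = 0,
) -> list:
    """Vectorized absorption of many walkers on one static chain.

    Equivalent in distribution to repeated :func:`simulate_absorption`
    calls (not sample-path identical).  Returns AbsorptionSamples in the
    order of ``starts``.
    """
    if chain.kernels is not None and chain.environment is not None:
        raise ValueError("batch simulation supports static kernels only")
    if max_steps == 0:
        max_steps = 1000 * chain.n_states
    rng = np.random.default_rng(seed)
    cum = np.cumsum(chain.kernel, axis=1)
    states = np.asarray(starts, dtype=int).copy()
    taus = np.zeros(len(states), dtype=int)
    active = states != chain.target
    step = 0
    while np.any(active) and step < max_steps:
        step += 1
        idx = np.nonzero(active)[0]
        r = rng.random(len(idx))
        rows = cum[states[idx]]
        nxt = (rows < r[:, None]).sum(axis=1)
        np.minimum(nxt, chain.n_states - 1, out=nxt)
        states[idx] = nxt
        hit = nxt == chain.target
        taus[idx[hit]] = step
        active[idx[hit]] = False
    out = []
    for i in range(len(states)):
        if active[i]:
            out.append(AbsorptionSample(max_steps, censored=True))
        else:
            out.append(AbsorptionSample(int(taus[i])))
    return out


def expected_absorption_exact(
    chain: MarkovChainSpec,
    start: Union[int, np.ndarray],
) -> tuple[float, float]:
    """Exact (E[tau], Var[tau]) via the fundamental matrix.

    Solves (I - Q) t = 1 for the expected steps from each transient state
    and (I - Q) s = 2 Q t + 1 for the second moment, Q the
    transient-to-transient block.  ``start`` may be a state index or a
    probability distribution over all states.
    """
    n = chain.n_states
    transient = [s for s in range(n) if s != chain.target]
    Q = chain.kernel[np.ix_(transient, transient)]
    A = np.eye(len(transient)) - Q
    try:
        t_vec = np.linalg.solve(A, np.ones(len(transient)))
        second = np.linalg.solve(A, 2.0 * Q @ t_vec + np.ones(len(transient)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("target unreachable: (I - Q) is singular") from exc

    t_full = np.zeros(n)
    s_full = np.zeros(n)
    t_full[transient] = t_vec
    s_full[transient] = second

    if np.isscalar(start) or isinstance(start, (int, np.integer)):
        mean = float(t_full[int(start)])
        second_m = float(s_full[int(start)])
    else:
        p = np.asarray(start, dtype=float)
        if p.shape != (n,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("start distribution must be a probability vector over all states")
        mean = float(p @ t_full)
        second_m = float(p @ s_full)
    return mean, max(second_m - mean * mean, 0.0)


def _jackknife_se(values: np.ndarray, statistic) -> float:
    n = len(values)
    if n < 2:
        return float("nan")
    loo = np.array([statistic(np.delete(values, i)) for i in range(n)])
    loo = loo[np.isfinite(loo)]
    if len(loo) < 2:
        return float("nan")
    return float(np.sqrt((len(loo) - 1) * np.var(loo)))


def absorption_stats(samples: Sequence[Union[int, AbsorptionSample]]) -> AbsorptionStats:
    """Summary statistics of hitting times.

    ``sigma_paper`` is the mean/sd ratio; ``cv`` is its reciprocal.  Both
    are reported because the two conventions appear in the literature.
    Censored samples are excluded (their count is reported).
    """
    taus, n_censored = [], 0
    for s in samples:
        if isinstance(s, AbsorptionSample):
            if s.censored:
                n_censored += 1
            else:
                taus.append(s.tau)
        else:
            taus.append(int(s))
    if len(taus) < 2:
        raise ValueError("need at least 2 uncensored samples")
    arr = np.asarray(taus, dtype=float)
    mean = float(arr.mean())
    var = float(arr.var(ddof=1))
    sd = np.sqrt(var)
    sigma = mean / sd if sd > 0 else float("inf")
    cv = sd / mean if mean > 0 else 0.0 if sd == 0 else float("inf")

    def _sigma(x: np.ndarray) -> float:
        s = x.std(ddof=1)
        return x.mean() / s if s > 0 else float("inf")

    def _cv(x: np.ndarray) -> float:
        m = x.mean()
        return x.std(ddof=1) / m if m > 0 else float("nan")

    return AbsorptionStats(
        n_samples=len(arr),
        mean=mean,
        variance=var,
        sigma_paper=sigma,
        cv=cv,
        se_mean=float(arr.std(ddof=1) / np.sqrt(len(arr))),
        se_sigma_paper=_jackknife_se(arr, _sigma) if sd > 0 else float("nan"),
        se_cv=_jackknife_se(arr, _cv) if sd > 0 else float("nan"),
        n_censored=n_censored,
    )


# ---------------------------------------------------------------------------
# Boolean-hypercube search


def hypercube_walk_chain(m: int, target: int) -> MarkovChainSpec:
    """Explicit 2^m-state kernel of the nearest-neighbour hypercube walk
    with the target vertex made absorbing (oracle helper; m <= 12)."""
    if m > 12:
        raise ValueError("explicit kernel limited to m <= 12")
    n = 1 << m
    W = np.zeros((n, n))
    for s in range(n):
        if s == target:
            W[s, s] = 1.0
            continue
        for j in range(m):
            W[s, s ^ (1 << j)] = 1.0 / m
    return MarkovChainSpec(n_states=n, kernel=W, target=target)


def hypercube_search(
    m: int,
    seed: int,
    plan: Optional[StagePlan] = None,
    target: Optional[str] = None,
    max_steps: int = 0,
) -> AbsorptionSample:
    """Random search of a target vertex of the m-dimensional Boolean cube.

    Single stage: from a uniform random start, flip one uniformly chosen
    coordinate per step until the full target string is matched.  Staged
    (``plan`` given): run the walk on the subcube of the current stage's
    coordinates until its substring is matched, freeze those coordinates,
    move to the next stage; total tau is the sum of stage times.
    """
    if not (1 <= m <= 24):
        raise ValueError("m must be in [1, 24]")
    rng = np.random.default_rng(seed)
    if plan is not None:
        if len(plan.target_string) != m:
            raise ValueError("plan target length must equal m")
        target_bits = plan.target_string
    elif target is not None:
        if len(target) != m or set(target) - {"0", "1"}:
            raise ValueError("target must be an m-bit string")
        target_bits = target
    else:
        target_bits = "".join(rng.integers(0, 2, size=m).astype(str))

    t_int = int(target_bits, 2)
    state = int(rng.integers(1 << m))
    if max_steps == 0:
        max_steps = 1000 * (1 << min(m, 20))

    if plan is None:
        if state == t_int:
            return AbsorptionSample(0, stage_taus=[0])
        # vectorized batches: cumulative XOR of single-bit flip masks
        tau, budget = 0, max_steps
        while budget > 0:
            batch = min(budget, 65536)
            masks = (1 << rng.integers(0, m, size=batch)).astype(np.int64)
            states = state ^ np.bitwise_xor.accumulate(masks)
            hits = np.nonzero(states == t_int)[0]
            if hits.size:
                return AbsorptionSample(tau + int(hits[0]) + 1, stage_taus=[tau + int(hits[0]) + 1])
            state = int(states[-1])
            tau += batch
            budget -= batch
        return AbsorptionSample(max_steps, censored=True, stage_taus=[max_steps])

    # staged search: coordinates of stage j live in a contiguous slice
    stage_taus = []
    bits = list(format(state, f"0{m}b"))
    pos = 0
    total = 0
    for sub in plan.substrings:
        ln = len(sub)
        sub_target = sub
        sub_state = bits[pos : pos + ln]
        t_stage = 0
        while "".join(sub_state) != sub_target:
            if total >= max_steps:
                return AbsorptionSample(max_steps, censored=True, stage_taus=stage_taus)
            j = int(rng.integers(ln))
            sub_state[j] = "1" if sub_state[j] == "0" else "0"
            t_stage += 1
            total += 1
        bits[pos : pos + ln] = sub_state  # freeze matched components
        stage_taus.append(t_stage)
        pos += ln
    return AbsorptionSample(total, stage_taus=stage_taus)


def fit_tau_scaling(
    state_counts: Sequence[int],
    stats: Sequence[Union[AbsorptionStats, float]],
) -> tuple[float, float, float]:
    """OLS fit of mean tau against the state count n -> (slope, intercept, R^2)."""
    n_vals = np.asarray(state_counts, dtype=float)
    if len(set(state_counts)) < 2:
        raise ValueError("need at least 2 distinct state counts")
    if len(n_vals) < 4:
        raise ValueError("need at least 4 points")
    means = np.array([s.mean if isinstance(s, AbsorptionStats) else float(s) for s in stats])
    if len(means) != len(n_vals):
        raise ValueError("state_counts and stats must align")
    A = np.vstack([n_vals, np.ones_like(n_vals)]).T
    coef, *_ = np.linalg.lstsq(A, means, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    pred = A @ coef
    ss_res = float(np.sum((means - pred) ** 2))
    ss_tot = float(np.sum((means - means.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2
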