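"""Stochastic stepping model of synthetic myosin motor clusters.

Each enzymatic head cycles irreversibly through three chemical states:

1. unbound from the filament, ATP loaded
2. bound to the filament, post-powerstroke, ADP loaded
3. bound to the filament, nucleotide free

The 1->2 transition (rate ``k12``) requires ATP hydrolysis and binds the head
to a filament; 2->3 (rate ``k23``) releases ADP; 3->1 (rate
``k31 = k31_per_atp * [ATP]``) exchanges the nucleotide and detaches the head,
so detachment is linear in ATP concentration. Heads are independent, so a
cluster of valency ``n`` has exactly ``n`` allowed transitions at any time and
is evolved with the Gillespie algorithm.

A cluster on a filament is located by an anchor ``x(t)`` sitting half a step
length ``s/2`` ahead of the rearmost bound head on that filament. A binding
head draws its position from ``Normal(x(t) + s/2, sd=s/2)`` (the flexible
joint prefers the least strained position); with two filaments available the
target filament is chosen uniformly. Gliding velocity is the total distance
the anchor travels divided by simulation time; run length is the net anchor
displacement of one attachment episode — from the first binding event
(whose anchor reposition is part of the traveled length) to complete
detachment of the cluster.
On filament pairs, strain accumulates only while the cluster crosslinks both
filaments, giving the pair strain rate ``eps`` and the crosslinking
probability ``Pcl`` (fraction of time both filaments are bound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "RateConstants",
    "ClusterParams",
    "HeadState",
    "MotorClusterState",
    "SingleFilamentSummary",
    "TwoFilamentSummary",
    "DEFAULT_RATES",
    "DEFAULT_STEP_LENGTH",
    "TETRAMER_TARGETS",
    "gillespie_step",
    "bind_head",
    "simulate_single_filament",
    "simulate_two_filaments",
    "calibrate_rates",
    "duty_ratio",
]

#: Mean repositioning length s in µm: the scale of the forward-biased
#: relocation of the cluster anchor per binding event. This is a
#: coarse-grained quantity (lever arm + flexible linker + cluster geometry),
#: larger than a single myosin working stroke; its default comes out of the
#: same calibration as the rate constants.
DEFAULT_STEP_LENGTH = 0.40

#: Measured tetramer single-filament benchmarks: ([ATP] µM, velocity µm/s,
#: run length µm). Used to calibrate the packaged default rate constants.
TETRAMER_TARGETS = ((10.0, 0.5, 4.0), (500.0, 10.0, 0.5))


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the three-state head cycle.

    Parameters
    ----------
    k12 : float
        Hydrolysis-gated binding rate, state 1 -> 2 (1/s).
    k23 : float
        Bound-ADP to bound-apo rate, state 2 -> 3 (1/s).
    k31_per_atp : float
        Nucleotide exchange + release rate per unit ATP, so that
        ``k31 = k31_per_atp * [ATP]`` (1/(s µM)).
    """

    k12: float
    k23: float
    k31_per_atp: float

    def __post_init__(self) -> None:
        if not (self.k12 > 0 and self.k23 > 0 and self.k31_per_atp > 0):
            raise ValueError("all rate constants must be strictly positive")

    def k31(self, atp: float) -> float:
        """Detachment rate at ATP concentration `atp` (µM)."""
        return self.k31_per_atp * atp


#: Packaged default rates, calibrated with :func:`calibrate_rates` against
#: :data:`TETRAMER_TARGETS` (tetramer: ~0.5 µm/s & 4 µm at 10 µM ATP,
#: ~10 µm/s & 0.5 µm at 500 µM ATP).
DEFAULT_RATES = RateConstants(k12=6.0, k23=250.0, k31_per_atp=0.22)


@dataclass(frozen=True)
class ClusterParams:
    """A motor cluster at one experimental condition."""

    valency: int = 4
    step_length: float = DEFAULT_STEP_LENGTH
    atp: float = 100.0
    rates: RateConstants = DEFAULT_RATES

    def __post_init__(self) -> None:
        if self.valency < 1:
            raise ValueError("valency must be >= 1")
        if self.step_length < 0:
            raise ValueError("step_length must be >= 0")
        if self.atp < 0:
            raise ValueError("atp must be >= 0")


@dataclass
class HeadState:
    """Chemical and mechanical state of one head.

    ``filament_id`` is None exactly when the head is unbound (state 1);
    ``position`` is meaningful only while bound.
    """

    chem_state: int = 1
    filament_id: int | None = None
    position: float = 0.0


@dataclass
class MotorClusterState:
    """Full simulation state of a cluster on one or two filaments."""

    heads: list[HeadState]
    anchors: list[float]
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def n_filaments(self) -> int:
        return len(self.anchors)

    def bound_positions(self, filament: int) -> list[float]:
        return [
            h.position
            for h in self.heads
            if h.chem_state != 1 and h.filament_id == filament
        ]

    def is_crosslinked(self) -> bool:
        return self.n_filaments == 2 and all(
            len(self.bound_positions(f)) > 0 for f in range(2)
        )

    def update_anchors(self, step_length: float) -> None:
        """Re-evaluate every anchor: s/2 ahead of the rearmost bound head.

        A filament with no bound heads inherits the other filament's anchor
        (parallel filaments share one coordinate axis); with no heads bound
        anywhere the anchors stay frozen.
        """
        bound = [self.bound_positions(f) for f in range(self.n_filaments)]
        new = list(self.anchors)
        for f, pos in enumerate(bound):
            if pos:
                new[f] = min(pos) + step_length / 2.0
        for f, pos in enumerate(bound):
            if not pos:
                others = [new[g] for g, p in enumerate(bound) if g != f and p]
                if others:
                    new[f] = others[0]
        self.anchors = new


class StalledSystemError(RuntimeError):
    """All propensities are zero (e.g. [ATP]=0 with every head in state 3)."""


def _propensities(state: MotorClusterState, params: ClusterParams) -> np.ndarray:
    r = params.rates
    k31 = r.k31(params.atp)
    table = {1: r.k12, 2: r.k23, 3: k31}
    return np.array([table[h.chem_state] for h in state.heads])


def gillespie_step(
    state: MotorClusterState, params: ClusterParams
) -> tuple[float, int, tuple[int, int]]:
    """Advance the cluster by one Gillespie event (in place).

    Draws an exponential waiting time with rate equal to the summed
    propensities of the ``n`` allowed transitions (one per head, the cycle
    being irreversible), picks the transitioning head with probability
    proportional to its rate, applies the transition, and re-evaluates the
    anchors.

    Returns
    -------
    (waiting_time, head_index, (from_state, to_state))

    Raises
    ------
    StalledSystemError
        If the total propensity is zero, which can only happen at [ATP]=0
        with every head in state 1 or 3.
    """
    props = _propensities(state, params)
    total = props.sum()
    if total <= 0.0:
        raise StalledSystemError("zero total propensity; system is stalled")
    wait = state.rng.exponential(1.0 / total)
    head_index = int(state.rng.choice(len(props), p=props / total))
    head = state.heads[head_index]
    old = head.chem_state
    new = {1: 2, 2: 3, 3: 1}[old]
    state.time += wait
    if old == 1:
        bind_head(state, head_index, params, state.rng)
    else:
        head.chem_state = new
        if new == 1:
            head.filament_id = None
        state.update_anchors(params.step_length)
    return wait, head_index, (old, new)


def bind_head(
    state: MotorClusterState,
    head_index: int,
    params: ClusterParams,
    rng: np.random.Generator,
) -> MotorClusterState:
    """Bind an unbound head (state 1 -> 2) to a filament.

    The target filament is chosen uniformly among the available filaments
    (fast diffusion relative to binding); the binding position is drawn from
    ``Normal(anchor + s/2, sd=s/2)``. Anchors are re-evaluated afterwards.
    """
    head = state.heads[head_index]
    if head.chem_state != 1:
        raise ValueError("bind_head requires a head in state 1")
    filament = int(rng.integers(state.n_filaments))
    s = params.step_length
    head.chem_state = 2
    head.filament_id = filament
    head.position = rng.normal(state.anchors[filament] + s / 2.0, s / 2.0)
    state.update_anchors(s)
    return state


@dataclass(frozen=True)
class SingleFilamentSummary:
    """Gliding statistics of a cluster on one filament."""

    mean_velocity: float
    mean_run_length: float
    n_runs: int
    attachment_fraction: float
    total_time: float
    stalled: bool = False


@dataclass(frozen=True)
class TwoFilamentSummary:
    """Pair-sliding statistics of a cluster crosslinking two filaments."""

    strain_rate: float
    p_crosslink: float
    total_time: float
    stalled: bool = False


# ---------------------------------------------------------------------------
# Fast numba cores. Same algorithm as the pure-Python engine above; the two
# are cross-checked statistically in the test suite.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sim_single_core(
    n_heads, k12, k23, k31, s, total_time, max_episodes, seed
):  # pragma: no cover - exercised via wrappers
    """Single-filament Gillespie run; returns gliding aggregates."""
    np.random.seed(seed)
    chem = np.ones(n_heads, dtype=np.int64)
    pos = np.zeros(n_heads)
    anchor = 0.0
    rates = np.empty(n_heads)

    t = 0.0
    dist = 0.0
    bound_time = 0.0
    n_eps = 0
    run_sum = 0.0
    in_episode = False
    episode_start = 0.0
    stalled = False

    while t < total_time and (max_episodes <= 0 or n_eps < max_episodes):
        total = 0.0
        for i in range(n_heads):
            if chem[i] == 1:
                rates[i] = k12
            elif chem[i] == 2:
                rates[i] = k23
            else:
                rates[i] = k31
            total += rates[i]
        if total <= 0.0:
            stalled = True
            break
        wait = np.random.exponential(1.0 / total)
        if t + wait > total_time:
            if in_episode:
                bound_time += total_time - t
            t = total_time
            break
        if in_episode:
            bound_time += wait
        t += wait

        u = np.random.random() * total
        acc = 0.0
        head = n_heads - 1
        for i in range(n_heads):
            acc += rates[i]
            if u < acc:
                head = i
                break

        if chem[head] == 1:
            chem[head] = 2
            pos[head] = np.random.normal(anchor + s / 2.0, s / 2.0)
            if not in_episode:
                # run length counts travel from the first binding event on,
                # including the anchor reposition that binding causes
                in_episode = True
                episode_start = anchor
        elif chem[head] == 2:
            chem[head] = 3
            continue  # anchor unchanged
        else:
            chem[head] = 1

        rear = 1.0e300
        for i in range(n_heads):
            if chem[i] != 1 and pos[i] < rear:
                rear = pos[i]
        if rear < 1.0e299:
            new_anchor = rear + s / 2.0
            dist += abs(new_anchor - anchor)
            anchor = new_anchor
        else:
            # full detachment: anchor frozen, episode closes
            if in_episode:
                in_episode = False
                run_sum += abs(anchor - episode_start)
                n_eps += 1

    return t, dist, bound_time, n_eps, run_sum, stalled


@njit(cache=True)
def _sim_pair_core(
    n_heads, k12, k23, k31, s, total_time, seed
):  # pragma: no cover - exercised via wrappers
    """Two parallel filaments sharing one axis; returns strain & Pcl data."""
    np.random.seed(seed)
    chem = np.ones(n_heads, dtype=np.int64)
    fil = -np.ones(n_heads, dtype=np.int64)
    pos = np.zeros(n_heads)
    anchors = np.zeros(2)
    rates = np.empty(n_heads)

    t = 0.0
    strain = 0.0
    xl_time = 0.0
    stalled = False

    while t < total_time:
        total = 0.0
        for i in range(n_heads):
            if chem[i] == 1:
                rates[i] = k12
            elif chem[i] == 2:
                rates[i] = k23
            else:
                rates[i] = k31
            total += rates[i]
        if total <= 0.0:
            stalled = True
            break
        wait = np.random.exponential(1.0 / total)

        n0 = 0
        n1 = 0
        for i in range(n_heads):
            if chem[i] != 1:
                if fil[i] == 0:
                    n0 += 1
                else:
                    n1 += 1
        crosslinked = n0 > 0 and n1 > 0

        if t + wait > total_time:
            if crosslinked:
                xl_time += total_time - t
            t = total_time
            break
        if crosslinked:
            xl_time += wait
        t += wait

        u = np.random.random() * total
        acc = 0.0
        head = n_heads - 1
        for i in range(n_heads):
            acc += rates[i]
            if u < acc:
                head = i
                break

        if chem[head] == 1:
            f = np.random.randint(0, 2)
            chem[head] = 2
            fil[head] = f
            pos[head] = np.random.normal(anchors[f] + s / 2.0, s / 2.0)
        elif chem[head] == 2:
            chem[head] = 3
        else:
            chem[head] = 1
            fil[head] = -1

        old0 = anchors[0]
        old1 = anchors[1]
        rear0 = 1.0e300
        rear1 = 1.0e300
        for i in range(n_heads):
            if chem[i] != 1:
                if fil[i] == 0:
                    if pos[i] < rear0:
                        rear0 = pos[i]
                else:
                    if pos[i] < rear1:
                        rear1 = pos[i]
        has0 = rear0 < 1.0e299
        has1 = rear1 < 1.0e299
        if has0:
            anchors[0] = rear0 + s / 2.0
        if has1:
            anchors[1] = rear1 + s / 2.0
        if not has0 and has1:
            anchors[0] = anchors[1]
        if not has1 and has0:
            anchors[1] = anchors[0]
        # strain counts only motion generated while the pair was crosslinked
        if crosslinked:
            strain += abs(anchors[0] - old0) + abs(anchors[1] - old1)

    return t, strain, xl_time, stalled


def _python_single(params, total_time, max_episodes, seed):
    """Reference event-loop built on gillespie_step; used for cross-checks."""
    rng = np.random.default_rng(seed)
    state = MotorClusterState(
        heads=[HeadState() for _ in range(params.valency)], anchors=[0.0], rng=rng
    )
    dist = 0.0
    bound_time = 0.0
    n_eps = 0
    run_sum = 0.0
    in_episode = False
    episode_start = 0.0
    stalled = False
    while state.time < total_time and (max_episodes <= 0 or n_eps < max_episodes):
        was_bound = any(h.chem_state != 1 for h in state.heads)
        old_anchor = state.anchors[0]
        t_before = state.time
        try:
            wait, _, _ = gillespie_step(state, params)
        except StalledSystemError:
            stalled = True
            break
        if state.time > total_time:
            if was_bound:
                bound_time += total_time - t_before
            state.time = total_time
            break
        if was_bound:
            bound_time += wait
        now_bound = any(h.chem_state != 1 for h in state.heads)
        dist += abs(state.anchors[0] - old_anchor)
        if now_bound and not in_episode:
            in_episode = True
            episode_start = old_anchor
        elif in_episode and not now_bound:
            in_episode = False
            run_sum += abs(state.anchors[0] - episode_start)
            n_eps += 1
    total = state.time
    return total, dist, bound_time, n_eps, run_sum, stalled


def simulate_single_filament(
    params: ClusterParams,
    total_time: float = 1000.0,
    seed: int = 0,
    max_episodes: int = 500,
    engine: Literal["numba", "python"] = "numba",
) -> SingleFilamentSummary:
    """Simulate a cluster gliding on a single filament.

    The run stops at ``total_time`` seconds of simulated time or after
    ``max_episodes`` complete attachment episodes, whichever comes first
    (``max_episodes <= 0`` disables the episode cap). Velocity is the total
    anchor distance traveled divided by elapsed time; run length is averaged
    per attachment episode, with rebinding after complete detachment allowed.
    Identical seeds give bit-identical event sequences.
    """
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    k31 = params.rates.k31(params.atp)
    args = (
        params.valency,
        params.rates.k12,
        params.rates.k23,
        k31,
        params.step_length,
        total_time,
        max_episodes,
    )
    if engine == "numba":
        t, dist, bound_time, n_eps, run_sum, stalled = _sim_single_core(
            *args, seed
        )
    else:
        t, dist, bound_time, n_eps, run_sum, stalled = _python_single(
            params, total_time, max_episodes, seed
        )
    return SingleFilamentSummary(
        mean_velocity=dist / t if t > 0 else 0.0,
        mean_run_length=run_sum / n_eps if n_eps else 0.0,
        n_runs=int(n_eps),
        attachment_fraction=bound_time / t if t > 0 else 0.0,
        total_time=t,
        stalled=bool(stalled),
    )


def simulate_two_filaments(
    params: ClusterParams,
    total_time: float = 200.0,
    seed: int = 0,
) -> TwoFilamentSummary:
    """Simulate a cluster shared between two parallel filaments.

    Strain increments (anchor displacement magnitudes on either filament) are
    accumulated only while at least one head is bound on each filament; the
    strain rate is total strain over total time and ``Pcl`` is the fraction
    of time spent crosslinked. A single head can never bridge two filaments,
    so ``Pcl = 0`` exactly for valency 1.
    """
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    k31 = params.rates.k31(params.atp)
    t, strain, xl_time, stalled = _sim_pair_core(
        params.valency,
        params.rates.k12,
        params.rates.k23,
        k31,
        params.step_length,
        total_time,
        seed,
    )
    return TwoFilamentSummary(
        strain_rate=strain / t if t > 0 else 0.0,
        p_crosslink=xl_time / t if t > 0 else 0.0,
        total_time=t,
        stalled=bool(stalled),
    )


def duty_ratio(rates: RateConstants, atp: float) -> float:
    """Closed-form single-head duty ratio (bound fraction of the cycle).

    The cycle is a unidirectional 3-state continuous-time Markov chain, so
    occupancy of each state is proportional to its mean dwell time and the
    bound fraction is ``(1/k23 + 1/k31) / (1/k12 + 1/k23 + 1/k31)``.
    """
    k31 = rates.k31(atp)
    bound = 1.0 / rates.k23 + 1.0 / k31
    return bound / (1.0 / rates.k12 + bound)


def simulate_events(
    params: ClusterParams, n_events: int, seed: int = 0
) -> pd.DataFrame:
    """Run the Python engine recording every event (debug/event-log export).

    Returns a tidy frame with columns time, head, from_state, to_state,
    anchor, for CSV export.
    """
    rng = np.random.default_rng(seed)
    state = MotorClusterState(
        heads=[HeadState() for _ in range(params.valency)], anchors=[0.0], rng=rng
    )
    rows = []
    for _ in range(n_events):
        try:
            _, head, (a, b) = gillespie_step(state, params)
        except StalledSystemError:
            break
        rows.append(
            {
                "time": state.time,
                "head": head,
                "from_state": a,
                "to_state": b,
                "anchor": state.anchors[0],
            }
        )
    return pd.DataFrame(rows)


def calibrate_rates(
    target_table: Sequence[tuple[float, float, float]] = TETRAMER_TARGETS,
    k12_grid: Sequence[float] | None = None,
    k23_grid: Sequence[float] | None = None,
    k31_grid: Sequence[float] | None = None,
    valency: int = 4,
    step_length: float = DEFAULT_STEP_LENGTH,
    total_time: float = 200.0,
    max_episodes: int = 300,
    seed: int = 12345,
) -> tuple[RateConstants, float]:
    """Grid-scan the three rate constants against velocity/run-length targets.

    ``target_table`` rows are ``(atp_uM, velocity_um_s, run_length_um)``. For
    every grid point the cluster is simulated at each target [ATP] and scored
    by the summed squared log-space residuals of velocity and run length
    (log space weighs the ~20x velocity span and ~8x run-length span
    comparably). Returns the best grid point and its residual; if the targets
    are unreachable within the grid the best found is still returned.
    """
    targets = list(target_table)
    if not targets:
        raise ValueError("target table must not be empty")
    if k12_grid is None:
        k12_grid = np.geomspace(1, 100, 9)
    if k23_grid is None:
        k23_grid = np.geomspace(20, 3000, 9)
    if k31_grid is None:
        k31_grid = np.geomspace(0.02, 2, 9)
    if len(k12_grid) == 0 or len(k23_grid) == 0 or len(k31_grid) == 0:
        raise ValueError("rate grids must be nonempty")

    best: RateConstants | None = None
    best_res = math.inf
    for k12 in k12_grid:
        for k23 in k23_grid:
            for k31pa in k31_grid:
                rates = RateConstants(k12, k23, k31pa)
                res = 0.0
                for atp, v_t, rl_t in targets:
                    summ = simulate_single_filament(
                        ClusterParams(valency, step_length, atp, rates),
                        total_time=total_time,
                        max_episodes=max_episodes,
                        seed=seed,
                    )
                    v = max(summ.mean_velocity, 1e-12)
                    rl = max(summ.mean_run_length, 1e-12)
                    res += math.log(v / v_t) ** 2 + math.log(rl / rl_t) ** 2
                if res < best_res:
                    best_res = res
                    best = rates
    assert best is not None
    return best, best_res
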