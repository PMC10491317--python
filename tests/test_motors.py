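"""Unit and property tests of the motor-cluster Gillespie model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from actonem.motors import (
    ClusterParams,
    DEFAULT_RATES,
    DEFAULT_STEP_LENGTH,
    HeadState,
    MotorClusterState,
    RateConstants,
    StalledSystemError,
    TETRAMER_TARGETS,
    bind_head,
    calibrate_rates,
    duty_ratio,
    gillespie_step,
    simulate_events,
    simulate_single_filament,
    simulate_two_filaments,
)


# ---------------------------------------------------------------------------
# Parameter validation and plumbing
# ---------------------------------------------------------------------------


def test_rate_constant_validation():
    with pytest.raises(ValueError):
        RateConstants(k12=-1.0, k23=1.0, k31_per_atp=1.0)
    with pytest.raises(ValueError):
        RateConstants(k12=1.0, k23=0.0, k31_per_atp=1.0)


def test_k31_linear_in_atp():
    r = RateConstants(1.0, 2.0, 0.5)
    assert r.k31(10.0) == pytest.approx(5.0)
    assert r.k31(0.0) == 0.0


def test_cluster_params_validation():
    with pytest.raises(ValueError):
        ClusterParams(valency=0)
    with pytest.raises(ValueError):
        ClusterParams(atp=-1.0)
    with pytest.raises(ValueError):
        simulate_single_filament(ClusterParams(), total_time=0.0)


def test_tetramer_targets_shape():
    assert len(TETRAMER_TARGETS) == 2
    for atp, v, rl in TETRAMER_TARGETS:
        assert atp > 0 and v > 0 and rl > 0


# ---------------------------------------------------------------------------
# Single-event mechanics (pure-Python engine)
# ---------------------------------------------------------------------------


def _fresh_state(n_heads: int, n_filaments: int = 1, seed: int = 0) -> MotorClusterState:
    return MotorClusterState(
        heads=[HeadState() for _ in range(n_heads)],
        anchors=[0.0] * n_filaments,
        rng=np.random.default_rng(seed),
    )


def test_waiting_times_exponential():
    """First waiting time from an all-unbound cluster has rate n * k12."""
    params = ClusterParams(valency=4, atp=100.0)
    waits = []
    for seed in range(400):
        state = _fresh_state(4, seed=seed)
        w, _, (a, b) = gillespie_step(state, params)
        assert (a, b) == (1, 2)
        waits.append(w)
    rate = 4 * params.rates.k12
    ks = stats.kstest(waits, "expon", args=(0.0, 1.0 / rate))
    assert ks.pvalue > 1e-3


def test_binding_position_distribution():
    """Binding positions are Normal(anchor + s/2, s/2)."""
    params = ClusterParams(valency=1)
    s = params.step_length
    rng = np.random.default_rng(1)
    offsets = []
    for _ in range(4000):
        state = _fresh_state(1)
        bind_head(state, 0, params, rng)
        offsets.append(state.heads[0].position)
    offsets = np.asarray(offsets)
    assert offsets.mean() == pytest.approx(s / 2.0, abs=3 * (s / 2) / np.sqrt(len(offsets)))
    assert offsets.std() == pytest.approx(s / 2.0, rel=0.1)


def test_bind_head_rejects_bound_head():
    params = ClusterParams(valency=1)
    state = _fresh_state(1)
    bind_head(state, 0, params, np.random.default_rng(0))
    with pytest.raises(ValueError):
        bind_head(state, 0, params, np.random.default_rng(0))


def test_filament_choice_uniform():
    params = ClusterParams(valency=1)
    rng = np.random.default_rng(2)
    picks = []
    for _ in range(2000):
        state = _fresh_state(1, n_filaments=2)
        bind_head(state, 0, params, rng)
        picks.append(state.heads[0].filament_id)
    frac = np.mean(picks)
    assert frac == pytest.approx(0.5, abs=0.05)


def test_anchor_rule_tracks_rearmost_bound_head():
    params = ClusterParams(valency=2)
    state = _fresh_state(2)
    state.heads[0] = HeadState(chem_state=2, filament_id=0, position=1.0)
    state.heads[1] = HeadState(chem_state=2, filament_id=0, position=3.0)
    state.update_anchors(params.step_length)
    assert state.anchors[0] == pytest.approx(1.0 + params.step_length / 2.0)


def test_bare_filament_inherits_anchor():
    state = _fresh_state(1, n_filaments=2)
    state.heads[0] = HeadState(chem_state=2, filament_id=0, position=5.0)
    state.update_anchors(0.4)
    assert state.anchors[0] == pytest.approx(5.2)
    assert state.anchors[1] == pytest.approx(state.anchors[0])


def test_stalled_at_zero_atp():
    """At [ATP]=0, heads reach the apo state and the cycle halts."""
    params = ClusterParams(valency=2, atp=0.0)
    state = _fresh_state(2)
    with pytest.raises(StalledSystemError):
        for _ in range(100):
            gillespie_step(state, params)
    summ = simulate_single_filament(params, total_time=10.0, seed=0)
    assert summ.stalled


# ---------------------------------------------------------------------------
# Stationary statistics against closed forms
# ---------------------------------------------------------------------------


def test_duty_ratio_closed_form_values():
    r = RateConstants(k12=1.0, k23=1.0, k31_per_atp=1.0)
    # equal dwell times at atp=1: bound 2 of 3 states
    assert duty_ratio(r, 1.0) == pytest.approx(2.0 / 3.0)


@given(atp=st.floats(1.0, 1000.0))
@settings(max_examples=25, deadline=None)
def test_duty_ratio_bounds_and_monotonicity(atp):
    d = duty_ratio(DEFAULT_RATES, atp)
    assert 0.0 < d < 1.0
    # more ATP -> faster release -> lower duty ratio
    assert duty_ratio(DEFAULT_RATES, atp * 1.5) < d


def test_attachment_fraction_matches_duty_ratio():
    """For a single head the bound time fraction is the CTMC occupancy."""
    params = ClusterParams(valency=1, atp=100.0)
    expected = duty_ratio(params.rates, params.atp)
    fracs = [
        simulate_single_filament(params, total_time=2000.0, seed=s,
                                 max_episodes=0).attachment_fraction
        for s in range(3)
    ]
    assert np.mean(fracs) == pytest.approx(expected, rel=0.05)


def test_state_occupancy_from_event_log():
    """Time-weighted chemical-state occupancy matches dwell-time ratios."""
    params = ClusterParams(valency=1, atp=50.0)
    df = simulate_events(params, n_events=6000, seed=3)
    # dwell of the state *left* at each event is the inter-event gap
    gaps = np.diff(np.concatenate([[0.0], df["time"].to_numpy()]))
    occ = {s: gaps[df["from_state"].to_numpy() == s].sum() for s in (1, 2, 3)}
    total = sum(occ.values())
    r = params.rates
    expect = np.array([1 / r.k12, 1 / r.k23, 1 / r.k31(params.atp)])
    expect /= expect.sum()
    measured = np.array([occ[1], occ[2], occ[3]]) / total
    assert np.allclose(measured, expect, atol=0.03)


# ---------------------------------------------------------------------------
# Simulation-level behavior
# ---------------------------------------------------------------------------


def test_seed_determinism_and_variation():
    params = ClusterParams(atp=100.0)
    a = simulate_single_filament(params, total_time=50.0, seed=7)
    b = simulate_single_filament(params, total_time=50.0, seed=7)
    c = simulate_single_filament(params, total_time=50.0, seed=8)
    assert a == b
    assert a != c


def test_engines_agree_statistically():
    """Numba and pure-Python engines implement the same process."""
    params = ClusterParams(valency=4, atp=100.0)
    v_numba = np.mean([
        simulate_single_filament(params, total_time=300.0, seed=s).mean_velocity
        for s in range(4)
    ])
    v_python = np.mean([
        simulate_single_filament(params, total_time=300.0, seed=s,
                                 engine="python").mean_velocity
        for s in range(4)
    ])
    assert v_python == pytest.approx(v_numba, rel=0.15)


def test_velocity_increases_with_atp():
    params10 = ClusterParams(atp=10.0)
    params500 = ClusterParams(atp=500.0)
    v10 = simulate_single_filament(params10, total_time=2000.0, seed=0).mean_velocity
    v500 = simulate_single_filament(params500, total_time=2000.0, seed=0).mean_velocity
    assert v500 > 2 * v10


def test_run_length_decreases_with_atp():
    rl10 = simulate_single_filament(ClusterParams(atp=10.0), total_time=5000.0,
                                    seed=1, max_episodes=200).mean_run_length
    rl500 = simulate_single_filament(ClusterParams(atp=500.0), total_time=5000.0,
                                     seed=1, max_episodes=200).mean_run_length
    assert rl10 > 2 * rl500


def test_valency_one_never_crosslinks():
    summ = simulate_two_filaments(ClusterParams(valency=1, atp=100.0),
                                  total_time=200.0, seed=0)
    assert summ.p_crosslink == 0.0
    assert summ.strain_rate == 0.0


def test_pair_pcl_increases_with_valency():
    pcl = {
        v: np.mean([
            simulate_two_filaments(ClusterParams(valency=v, atp=100.0),
                                   total_time=400.0, seed=s).p_crosslink
            for s in range(3)
        ])
        for v in (2, 4, 8)
    }
    assert pcl[2] < pcl[4] < pcl[8]


def test_pair_summary_ranges():
    summ = simulate_two_filaments(ClusterParams(valency=4, atp=50.0),
                                  total_time=200.0, seed=5)
    assert 0.0 <= summ.p_crosslink <= 1.0
    assert summ.strain_rate >= 0.0
    assert not summ.stalled


def test_calibration_prefers_defaults_over_bad_rates():
    """Pitted against grossly wrong rate constants, the calibration score
    selects the packaged defaults (which were frozen by this procedure)."""
    best, res = calibrate_rates(
        k12_grid=[DEFAULT_RATES.k12 / 20, DEFAULT_RATES.k12],
        k23_grid=[DEFAULT_RATES.k23 / 20, DEFAULT_RATES.k23],
        k31_grid=[DEFAULT_RATES.k31_per_atp * 20, DEFAULT_RATES.k31_per_atp],
        total_time=400.0,
        max_episodes=200,
    )
    assert best == DEFAULT_RATES
    assert res < 0.5


def test_calibrate_rejects_empty_targets():
    with pytest.raises(ValueError):
        calibrate_rates(target_table=[])
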