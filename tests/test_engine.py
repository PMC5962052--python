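"""Stepwise mechanics, conservation, determinism, and dilution semantics."""

import numpy as np
import pytest

from mtarray import (
    DIMERS_PER_UM,
    DIMERS_PER_UM_UM3,
    DIParams,
    Geometry,
    NucleationSpec,
    SimState,
    StageSpec,
    apply_dilution,
    preset,
    run,
    run_stages,
    step,
)
from mtarray.engine import EMPTY, GROWING, SHORTENING

NO_NUCLEATION = NucleationSpec(rate_per_site=0.0)


def make_state(lengths, phases, n_sites=None, total=35.0, volume=1000.0):
    """A SimState with the given microtubules occupying the first sites."""
    n = n_sites or len(lengths)
    state = SimState.empty(n, total)
    for i, (length, phase) in enumerate(zip(lengths, phases)):
        state.occupied[i] = True
        state.length[i] = length
        state.phase[i] = phase
    state.free_conc = max(
        0.0, total - state.polymer_length * DIMERS_PER_UM / (DIMERS_PER_UM_UM3 * volume)
    )
    return state


def test_boundary_forced_catastrophe(kinetics, geometry, rng):
    """A growing tip that would cross the cell edge is clamped there and
    switched to shortening."""
    # pin free tubulin so that v_g * dt = 0.20 um exactly
    stage = StageSpec(
        duration=1, di=preset("setA"), nucleation=NO_NUCLEATION,
        pinned_free_conc=0.20 / kinetics.k_on,
    )
    state = make_state([24.95], [GROWING])
    state.free_conc = stage.pinned_free_conc
    step(state, stage, kinetics, geometry, rng)
    assert state.length[0] == 25.0
    assert state.phase[0] == SHORTENING


def test_complete_depolymerization_frees_site_and_returns_dimers(
    kinetics, geometry, rng
):
    stage = StageSpec(duration=1, di=preset("setB"), nucleation=NO_NUCLEATION)
    state = make_state([0.15], [SHORTENING])
    assert state.free_conc < 35.0
    step(state, stage, kinetics, geometry, rng)
    assert not state.occupied[0]
    assert state.length[0] == 0.0
    assert state.phase[0] == EMPTY
    # the 0.15 x 1624 dimers are back in the pool: the budget is all free
    assert state.free_conc == pytest.approx(35.0, rel=1e-12)


def test_empty_state_is_absorbing_without_nucleation(kinetics, geometry, rng):
    stage = StageSpec(duration=1, di=preset("setA"), nucleation=NO_NUCLEATION)
    state = SimState.empty(10, 35.0)
    before = (state.occupied.copy(), state.length.copy(), state.phase.copy())
    step(state, stage, kinetics, geometry, rng)
    assert state.t == 1.0
    assert np.array_equal(state.occupied, before[0])
    assert np.array_equal(state.length, before[1])
    assert np.array_equal(state.phase, before[2])
    assert state.free_conc == 35.0


def test_synchronous_pool_uptake(kinetics, geometry, rng):
    """All growing tips this step share one velocity computed from the
    start-of-step pool, so the uptake is n x v_g x dt worth of dimers."""
    n = 500
    poly_conc = n * 1.0 * DIMERS_PER_UM / (DIMERS_PER_UM_UM3 * 1000.0)
    total = 12.5 + poly_conc
    stage = StageSpec(
        duration=1,
        di=preset("setB").with_(k_c_mean=0.0),
        nucleation=NO_NUCLEATION,
        total_tubulin=total,
    )
    state = make_state([1.0] * n, [GROWING] * n, total=total)
    assert state.free_conc == pytest.approx(12.5, rel=1e-12)
    v_g = kinetics.k_on * 12.5  # 0.20875 um/s
    step(state, stage, kinetics, geometry, rng)
    expected_drop = n * v_g * DIMERS_PER_UM / (DIMERS_PER_UM_UM3 * 1000.0)
    assert 12.5 - state.free_conc == pytest.approx(expected_drop, rel=1e-9)
    # ~2.3% of the free pool: uptake cannot overdraw the pool in one step
    assert expected_drop / 12.5 == pytest.approx(0.0225, rel=0.01)


def test_first_increment_uses_preset_mean_velocity(kinetics, geometry, rng):
    """A newly nucleated microtubule takes exactly v_g_mean * dt in its
    birth step even though the concentration-dependent velocity is zero."""
    di = preset("setA").with_(k_c_mean=0.0)
    stage = StageSpec(
        duration=1, di=di,
        nucleation=NucleationSpec(n_sites=50, rate_per_site=50.0),  # p ~ 1
        pinned_free_conc=0.0,
    )
    state = SimState.empty(50, 35.0)
    state.free_conc = 0.0
    step(state, stage, kinetics, geometry, rng)
    newborn = state.occupied
    assert newborn.sum() > 40
    assert np.all(state.length[newborn] == di.v_g_mean)
    # next step: concentration-dependent velocity (zero here), no movement
    step(state, stage, kinetics, geometry, rng)
    assert np.all(state.length[state.occupied] == di.v_g_mean)


def test_mass_conservation_along_trajectory(kinetics, geometry):
    traj = run(
        StageSpec(duration=3000, di=preset("setB")),
        kinetics, geometry, seed=5,
    )
    total_length = np.where(
        traj.n_mt > 0, traj.n_mt * np.nan_to_num(traj.mean_length), 0.0
    )
    poly = total_length * DIMERS_PER_UM / (DIMERS_PER_UM_UM3 * geometry.volume)
    np.testing.assert_allclose(traj.free_conc + poly, 35.0, rtol=1e-9)


def test_determinism_bit_identical(kinetics, geometry):
    stage = StageSpec(duration=500, di=preset("setB"))
    a = run(stage, kinetics, geometry, seed=42)
    b = run(stage, kinetics, geometry, seed=42)
    np.testing.assert_array_equal(a.n_mt, b.n_mt)
    np.testing.assert_array_equal(a.mean_length, b.mean_length)
    np.testing.assert_array_equal(a.free_conc, b.free_conc)
    np.testing.assert_array_equal(a.final_lengths, b.final_lengths)
    c = run(stage, kinetics, geometry, seed=43)
    assert not np.array_equal(a.n_mt, c.n_mt)


def test_occupancy_bounded_and_nonincreasing_without_nucleation(
    kinetics, geometry
):
    traj = run_stages(
        [
            StageSpec(duration=2000, di=preset("setB")),
            StageSpec(duration=2000, di=preset("setB"), nucleation=NO_NUCLEATION),
        ],
        kinetics, geometry, seed=3,
    )
    assert traj.n_mt.max() <= 500
    stage2 = traj.stage_slice(1)
    assert np.all(np.diff(traj.n_mt[stage2]) <= 0)


def test_dilution_identity_and_validation(geometry):
    state = make_state([10.0], [GROWING], total=35.0)
    free_before = state.free_conc
    apply_dilution(state, 1.0, geometry)
    assert state.total_tubulin == 35.0
    assert state.free_conc == free_before
    with pytest.raises(ValueError):
        apply_dilution(state, 0.0, geometry)
    with pytest.raises(ValueError):
        apply_dilution(state, 1.5, geometry)


def test_dilution_clamps_pool_and_collapses_array(kinetics, geometry):
    """A 10x budget dilution of an assembled array zeroes the free pool
    (polymer exceeds the budget) and drives rapid depolymerization."""
    traj = run_stages(
        [
            StageSpec(duration=3000, di=preset("setB")),
            StageSpec(
                duration=600, di=preset("setB"),
                dilution_factor=0.1,
            ),
        ],
        kinetics, geometry, seed=9,
    )
    stage2 = traj.stage_slice(1)
    # the shared boundary sample holds the pre-dilution baseline; the
    # clamp shows from the first post-dilution step on
    assert traj.free_conc[stage2][0] > 10.0
    assert traj.free_conc[stage2][1] == 0.0
    n0, n_end = traj.n_mt[stage2][0], traj.n_mt[stage2][-1]
    assert n_end < 0.5 * n0
    mean0 = traj.mean_length[stage2][0]
    assert traj.mean_length[stage2][300] < 0.5 * mean0


def test_tracked_life_history_spans_site_turnover(kinetics, geometry):
    """The tracked series follows the first nucleated site, continuing
    across complete depolymerizations with restarts recorded."""
    di = DIParams(0.3, 0, 0.4, 0, 0.5, 0, 0.01, 0)  # short-lived MTs
    stage = StageSpec(
        duration=2000, di=di,
        nucleation=NucleationSpec(n_sites=1, rate_per_site=0.1),
        pinned_free_conc=18.0,
    )
    traj = run(stage, kinetics, geometry, seed=1)
    assert traj.tracked_site == 0
    assert traj.tracked_length.max() > 0
    assert len(traj.tracked_restarts) > 0
    assert np.all(np.diff(traj.tracked_restarts) > 0)


def test_trajectory_shapes_and_stage_boundaries(kinetics, geometry):
    traj = run_stages(
        [
            StageSpec(duration=100, di=preset("setA")),
            StageSpec(duration=50, di=preset("nebd")),
        ],
        kinetics, geometry, seed=0,
    )
    assert len(traj.t) == 151
    assert traj.t[0] == 0.0 and traj.t[-1] == 150.0
    assert traj.stage_boundaries == [0.0, 100.0]
    assert traj.t[traj.stage_slice(1)][0] == 100.0
    assert traj.t[traj.stage_slice(0)][-1] == 100.0  # entry sample shared


def test_state_invariants_hold_after_run(kinetics, geometry):
    stage = StageSpec(duration=1000, di=preset("setB"))
    rng = np.random.default_rng(11)
    state = SimState.empty(500, 35.0)
    for _ in range(1000):
        step(state, stage, kinetics, geometry, rng)
    state.validate(geometry)
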