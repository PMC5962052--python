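"""Per-second Monte Carlo state machine for the microtubule array.

Each simulation step represents 1 s (configurable) and follows the
sequence: (1) empty nucleation sites are tested for nucleation; (2) a
newly nucleated microtubule takes a first growth increment at the
parameter set's measured mean velocity; (3) growing microtubules add
``V_g·dt`` at the concentration-dependent velocity, undergo a forced
catastrophe on reaching the cell boundary, or a stochastic catastrophe
at the (zone-effective) frequency k_c; (4) shortening microtubules lose
``V_s·dt``, vanish when they reach zero length (freeing their site for
the next step's nucleation pass), or are rescued at frequency k_r.

Phase switches act on the *following* step (move-then-test).  The free
tubulin pool is reconciled once per step from the fixed budget and the
total polymer length, so results are independent of site iteration
order and mass conservation is structural.

Multi-stage protocols (``run_stages``) carry the full array state across
parameter switches, with optional dilution of the tubulin budget at
stage entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .params import (
    DIParams,
    NoiseSpec,
    NucleationSpec,
    growth_velocity,
    nucleation_rate,
    transition_probability,
)
from .tubulin import Geometry, KineticConstants, free_tubulin

__all__ = [
    "EMPTY",
    "GROWING",
    "SHORTENING",
    "SimState",
    "StageSpec",
    "Trajectory",
    "step",
    "run",
    "run_stages",
    "apply_dilution",
]

EMPTY = np.int8(0)
GROWING = np.int8(1)
SHORTENING = np.int8(-1)


@dataclass
class SimState:
    """Mutable array state: one record per nucleation site.

    ``free_conc`` is always derived from ``total_tubulin`` minus polymer
    (clamped at zero), never integrated independently.
    """

    t: float
    occupied: np.ndarray      # bool, (n_sites,)
    length: np.ndarray        # float μm, 0 where unoccupied
    phase: np.ndarray         # int8: GROWING / SHORTENING / EMPTY
    total_tubulin: float      # μM budget
    free_conc: float          # μM, derived
    tracked_site: int = -1    # first site ever to nucleate; -1 before that

    @classmethod
    def empty(cls, n_sites: int, total_tubulin: float) -> "SimState":
        """The initial condition: no microtubules, the whole budget free."""
        return cls(
            t=0.0,
            occupied=np.zeros(n_sites, dtype=bool),
            length=np.zeros(n_sites),
            phase=np.zeros(n_sites, dtype=np.int8),
            total_tubulin=total_tubulin,
            free_conc=total_tubulin,
        )

    @property
    def n_mt(self) -> int:
        return int(self.occupied.sum())

    @property
    def polymer_length(self) -> float:
        """Total polymer (μm) over all microtubules."""
        return float(self.length.sum())

    def mean_length(self) -> float:
        """Mean length of existing microtubules; NaN when there are none."""
        n = self.n_mt
        return float(self.length.sum() / n) if n else float("nan")

    def validate(self, geometry: Geometry, volume_conc_tol: float = 1e-9) -> None:
        """Fail fast on violated invariants (used by tests, not per step)."""
        from .tubulin import polymer_concentration

        if np.any(self.length < 0):
            raise AssertionError("negative microtubule length")
        if np.any(self.length[~self.occupied] != 0):
            raise AssertionError("unoccupied site with non-zero length")
        if np.any(self.length > geometry.radius + 1e-9):
            raise AssertionError("microtubule longer than cell radius")
        if self.free_conc < 0:
            raise AssertionError("negative free tubulin")
        poly = polymer_concentration(self.polymer_length, geometry.volume)
        if self.free_conc > 0:  # outside the dilution clamp
            total = self.free_conc + poly
            if abs(total - self.total_tubulin) > volume_conc_tol * self.total_tubulin:
                raise AssertionError(
                    f"mass balance violated: free {self.free_conc} + polymer "
                    f"{poly} != budget {self.total_tubulin}"
                )


@dataclass(frozen=True)
class StageSpec:
    """One leg of a (possibly multi-stage) protocol.

    ``total_tubulin`` sets the budget at stage entry; ``dilution_factor``
    (if given) then multiplies it, modeling dilution of the cytoplasm.
    ``pinned_free_conc`` disables the mass balance and holds the free pool
    at a constant value — a validation mode for comparing against
    constant-tubulin analytic results, not part of the cell model.
    """

    duration: float
    di: DIParams
    nucleation: NucleationSpec = NucleationSpec()
    total_tubulin: float = 35.0
    zones: Optional[object] = None          # ZoneSpec or None
    noise: NoiseSpec = NoiseSpec()
    dilution_factor: Optional[float] = None
    pinned_free_conc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError(f"duration must be >= 1 s, got {self.duration}")
        if self.total_tubulin < 0:
            raise ValueError(
                f"total_tubulin must be >= 0, got {self.total_tubulin}"
            )
        if self.dilution_factor is not None and not (
            0 < self.dilution_factor <= 1
        ):
            raise ValueError(
                f"dilution_factor must be in (0, 1], got {self.dilution_factor}"
            )


@dataclass
class Trajectory:
    """Per-step time series plus end-state snapshots for one run.

    All per-step arrays have length ``total steps + 1`` and include the
    initial state at t = 0.  ``mean_length`` is NaN wherever the array is
    empty.  The tracked series follows the first site ever to nucleate;
    if that microtubule fully depolymerizes, the same site's next
    microtubule continues the series and the restart time is recorded.
    """

    t: np.ndarray
    n_mt: np.ndarray
    mean_length: np.ndarray
    free_conc: np.ndarray
    tracked_length: np.ndarray
    tracked_site: int
    tracked_restarts: List[float]
    final_lengths: np.ndarray
    stage_boundaries: List[float] = field(default_factory=list)

    def stage_slice(self, i: int) -> slice:
        """Index slice of the per-step arrays covering stage ``i``
        (inclusive of the stage's entry sample)."""
        starts = self.stage_boundaries
        lo = int(np.searchsorted(self.t, starts[i]))
        hi = (
            int(np.searchsorted(self.t, starts[i + 1], side="right"))
            if i + 1 < len(starts)
            else len(self.t)
        )
        return slice(lo, hi)


def apply_dilution(state: SimState, factor: float, geometry: Geometry) -> SimState:
    """Dilute the tubulin budget by ``factor`` in place.

    The free pool is re-derived from the reduced budget (clamped at
    zero); depolymerized tubulin in excess of the new budget is
    discarded until polymer falls back under it.  Lengths are unchanged.
    """
    if not (0 < factor <= 1):
        raise ValueError(f"dilution factor must be in (0, 1], got {factor}")
    state.total_tubulin *= factor
    state.free_conc = free_tubulin(
        state.total_tubulin, state.polymer_length, geometry.volume
    )
    return state


def step(
    state: SimState,
    stage: StageSpec,
    kinetics: KineticConstants,
    geometry: Geometry,
    rng: np.random.Generator,
    dt: float = 1.0,
) -> SimState:
    """Advance the array by one step (in place; returns ``state``).

    Transitions are tested against the phase held at step entry; newly
    nucleated microtubules take only their fixed first increment this
    step.  The free pool is reconciled once at the end.
    """
    di = stage.di
    noise = stage.noise
    zones = stage.zones
    occupied = state.occupied
    length = state.length
    phase = state.phase
    n = occupied.size

    if noise.radius_jitter_max > 0:
        eff_radius = geometry.radius - rng.uniform(0.0, noise.radius_jitter_max)
    else:
        eff_radius = geometry.radius

    free0 = state.free_conc
    v_g = growth_velocity(free0, kinetics)

    growing0 = occupied & (phase == GROWING)
    shortening0 = occupied & (phase == SHORTENING)

    # (1) nucleation at empty sites; first increment at the measured mean
    rate = nucleation_rate(free0, stage.nucleation)
    if rate > 0:
        p_nuc = transition_probability(rate, dt)
        nuc = ~occupied & (rng.random(n) < p_nuc)
        if nuc.any():
            occupied[nuc] = True
            length[nuc] = di.v_g_mean * dt
            phase[nuc] = GROWING
            if state.tracked_site < 0:
                state.tracked_site = int(np.flatnonzero(nuc)[0])

    # (2) growth, boundary-forced catastrophe, stochastic catastrophe
    if growing0.any():
        length[growing0] += v_g * dt
        hit = growing0 & (length >= eff_radius)
        if hit.any():
            length[hit] = eff_radius
            phase[hit] = SHORTENING
        cand = growing0 & ~hit
        if cand.any():
            if noise.vary_k_c:
                k_c = rng.uniform(0.0, 2.0 * di.k_c_mean, n)
            else:
                k_c = di.k_c_mean
            if zones is not None:
                interior = length < (eff_radius - zones.peripheral_width)
                k_c = np.where(
                    interior, k_c * zones.interior_catastrophe_factor, k_c
                )
            p_c = -np.expm1(-np.asarray(k_c) * dt)
            cat = cand & (rng.random(n) < p_c)
            phase[cat] = SHORTENING

    # (3) shortening, complete depolymerization, rescue
    if shortening0.any():
        if noise.vary_v_s:
            lo = max(0.0, di.v_s_mean - di.v_s_sd)
            v_s = rng.uniform(lo, di.v_s_mean + di.v_s_sd, n)
            length[shortening0] -= v_s[shortening0] * dt
        else:
            length[shortening0] -= di.v_s_mean * dt
        gone = shortening0 & (length <= 0)
        if gone.any():
            occupied[gone] = False
            length[gone] = 0.0
            phase[gone] = EMPTY
        remain = shortening0 & ~gone
        if remain.any():
            if noise.vary_k_r:
                k_r = rng.uniform(0.0, 2.0 * di.k_r_mean, n)
                p_r = -np.expm1(-k_r * dt)
            else:
                p_r = transition_probability(di.k_r_mean, dt)
            resc = remain & (rng.random(n) < p_r)
            phase[resc] = GROWING

    # (4) a jittered-in boundary forces catastrophe on any overlong MT
    over = occupied & (length > eff_radius)
    if over.any():
        length[over] = eff_radius
        phase[over] = SHORTENING

    # (5) single pool reconciliation from the budget
    state.t += dt
    if stage.pinned_free_conc is not None:
        state.free_conc = stage.pinned_free_conc
    else:
        state.free_conc = free_tubulin(
            state.total_tubulin, float(length.sum()), geometry.volume
        )
    return state


def run_stages(
    stages: Sequence[StageSpec],
    kinetics: KineticConstants = KineticConstants(),
    geometry: Geometry = Geometry(),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    dt: float = 1.0,
) -> Trajectory:
    """Execute a staged protocol from the empty state.

    Stage 1 starts with no microtubules and the full budget free; each
    later stage inherits the complete array state, resets the budget to
    its ``total_tubulin``, and applies its ``dilution_factor`` if any.
    Fully reproducible from ``seed``.
    """
    if not stages:
        raise ValueError("at least one stage is required")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_sites = stages[0].nucleation.n_sites
    for s in stages[1:]:
        if s.nucleation.n_sites != n_sites:
            raise ValueError("n_sites must be constant across stages")

    steps_per_stage = [int(round(s.duration / dt)) for s in stages]
    total_steps = sum(steps_per_stage)

    state = SimState.empty(n_sites, stages[0].total_tubulin)
    if stages[0].pinned_free_conc is not None:
        state.free_conc = stages[0].pinned_free_conc

    t_arr = np.empty(total_steps + 1)
    n_arr = np.empty(total_steps + 1, dtype=np.int64)
    len_arr = np.empty(total_steps + 1)
    free_arr = np.empty(total_steps + 1)
    trk_arr = np.zeros(total_steps + 1)
    restarts: List[float] = []
    boundaries: List[float] = []

    def record(i: int) -> None:
        t_arr[i] = state.t
        n_arr[i] = state.n_mt
        len_arr[i] = state.mean_length()
        free_arr[i] = state.free_conc
        if state.tracked_site >= 0:
            trk_arr[i] = state.length[state.tracked_site]

    record(0)
    i = 0
    for stage, nsteps in zip(stages, steps_per_stage):
        boundaries.append(state.t)
        state.total_tubulin = stage.total_tubulin
        if stage.dilution_factor is not None:
            apply_dilution(state, stage.dilution_factor, geometry)
        elif stage.pinned_free_conc is None:
            state.free_conc = free_tubulin(
                state.total_tubulin, state.polymer_length, geometry.volume
            )
        for _ in range(nsteps):
            trk = state.tracked_site
            trk_was_empty = trk >= 0 and not state.occupied[trk]
            step(state, stage, kinetics, geometry, rng, dt)
            i += 1
            record(i)
            if trk >= 0 and trk_was_empty and state.occupied[trk]:
                restarts.append(state.t)

    return Trajectory(
        t=t_arr,
        n_mt=n_arr,
        mean_length=len_arr,
        free_conc=free_arr,
        tracked_length=trk_arr,
        tracked_site=state.tracked_site,
        tracked_restarts=restarts,
        final_lengths=state.length[state.occupied].copy(),
        stage_boundaries=boundaries,
    )


def run(
    stage: StageSpec,
    kinetics: KineticConstants = KineticConstants(),
    geometry: Geometry = Geometry(),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    dt: float = 1.0,
) -> Trajectory:
    """Single-stage convenience wrapper around :func:`run_stages`."""
    return run_stages([stage], kinetics, geometry, seed=seed, rng=rng, dt=dt)
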