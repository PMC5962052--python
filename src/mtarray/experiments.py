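"""Pre-built staged protocols as one-call recipes.

Each recipe names a simulation experiment on the interphase microtubule
array: single-state steady states for the two interphase parameter sets,
a total-tubulin scan, nucleation shutoff, 10-fold tubulin dilution,
the interphase→prophase (NEBD) switch and its single-frequency variants,
single-parameter swaps between the interphase sets, a two-zone
catastrophe scan, and parameter/boundary noise.

A recipe is a dictionary of named conditions, each a list of
:class:`~mtarray.engine.StageSpec`.  All conditions within one
experiment reuse the same replicate seed list (common random numbers),
which pairs the comparisons the experiments are designed to make.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .analysis import SteadyStateSummary, half_time, steady_state_summary
from .engine import StageSpec, Trajectory, run_stages
from .params import DIParams, NoiseSpec, NucleationSpec, ZoneSpec, preset
from .tubulin import Geometry, KineticConstants

__all__ = [
    "RECIPE_NAMES",
    "ExperimentRecipe",
    "ExperimentResult",
    "recipe",
    "run_experiment",
]

#: Steady-state assembly duration used throughout (s).
ASSEMBLY_DURATION = 10_000
#: Default prophase leg duration (s); prophase is short-lived in cells.
PROPHASE_DURATION = 1_000

_SWAP_FIELDS = {
    "v_g": ("v_g_mean", "v_g_sd"),
    "v_s": ("v_s_mean", "v_s_sd"),
    "k_c": ("k_c_mean", "k_c_sd"),
    "k_r": ("k_r_mean", "k_r_sd"),
}


@dataclass
class ExperimentRecipe:
    """A named experiment: conditions (label → stage list), replicate
    count, and the stage index (if any) at which a transition occurs and
    half-times are measured."""

    name: str
    conditions: Dict[str, List[StageSpec]]
    replicates: int = 4
    transition_stage: Optional[int] = None

    def seeds(self, base_seed: int) -> List[int]:
        """Replicate seeds: base seed plus a fixed increment of 1."""
        return [base_seed + i for i in range(self.replicates)]


@dataclass
class ExperimentResult:
    """Per-condition output of :func:`run_experiment`."""

    trajectories: List[Trajectory]
    seeds: List[int]
    summary: SteadyStateSummary
    half_times: Optional[Dict[str, float]] = None


def _stage(name_or_di, duration: float = ASSEMBLY_DURATION, **kw) -> StageSpec:
    di = preset(name_or_di) if isinstance(name_or_di, str) else name_or_di
    return StageSpec(duration=duration, di=di, **kw)


def _swapped(src: DIParams, dst: DIParams, param: str) -> DIParams:
    mean_f, sd_f = _SWAP_FIELDS[param]
    return replace(src, **{mean_f: getattr(dst, mean_f), sd_f: getattr(dst, sd_f)})


def recipe(name: str, replicates: int = 4, **overrides) -> ExperimentRecipe:
    """Build the named experiment with its published default protocol.

    Supported ``overrides`` (where applicable): ``preset_name`` for the
    nucleation-off and dilution protocols, ``stage2_duration``,
    ``total_tubulin``, ``peripheral_widths`` for the zone scan.
    """
    preset_name = overrides.pop("preset_name", None)
    stage2_duration = overrides.pop("stage2_duration", None)
    total_tubulin = overrides.pop("total_tubulin", 35.0)
    widths = overrides.pop("peripheral_widths", (25.0, 12.5, 6.25, 3.75, 1.25))
    if overrides:
        raise ValueError(f"unknown recipe overrides: {sorted(overrides)}")

    transition: Optional[int] = None

    if name in ("interphase_setA", "interphase_setB"):
        which = "setA" if name.endswith("A") else "setB"
        conditions = {which: [_stage(which, total_tubulin=total_tubulin)]}

    elif name == "tubulin_scan":
        conditions = {
            f"{which}_{conc:g}uM": [_stage(which, total_tubulin=conc)]
            for which in ("setA", "setB")
            for conc in (20.0, 25.0, 30.0, 35.0)
        }

    elif name == "nucleation_off":
        which = preset_name or "setA"
        # Set A barely loses microtubules in 48 h; Set B halves in ~10 h,
        # so its default second leg is shorter.
        duration = stage2_duration or (173_000 if which == "setA" else 80_000)
        off = NucleationSpec(rate_per_site=0.0)
        conditions = {
            which: [
                _stage(which, total_tubulin=total_tubulin),
                _stage(which, duration, nucleation=off, total_tubulin=total_tubulin),
            ]
        }
        transition = 1

    elif name == "dilution_10x":
        which = preset_name or "setB"
        duration = stage2_duration or 1_000
        conditions = {
            which: [
                _stage(which, total_tubulin=total_tubulin),
                _stage(
                    which,
                    duration,
                    total_tubulin=total_tubulin,
                    dilution_factor=0.1,
                ),
            ]
        }
        transition = 1

    elif name in (
        "prophase_switch",
        "prophase_switch_5x_nucleation",
        "prophase_keep_kc",
        "prophase_keep_kr",
    ):
        duration = stage2_duration or PROPHASE_DURATION
        di2 = preset("nebd")
        interphase = preset("setA")
        if name == "prophase_keep_kc":
            di2 = _swapped(di2, interphase, "k_c")
        elif name == "prophase_keep_kr":
            di2 = _swapped(di2, interphase, "k_r")
        nuc2 = NucleationSpec()
        if name == "prophase_switch_5x_nucleation":
            nuc2 = NucleationSpec(rate_per_site=5 * nuc2.rate_per_site)
        conditions = {
            name: [
                _stage("setA", total_tubulin=total_tubulin),
                _stage(di2, duration, nucleation=nuc2, total_tubulin=total_tubulin),
            ]
        }
        transition = 1

    elif name == "param_swap":
        set_a, set_b = preset("setA"), preset("setB")
        conditions = {
            "setA_full": [_stage(set_a, total_tubulin=total_tubulin)],
            "setB_full": [_stage(set_b, total_tubulin=total_tubulin)],
        }
        for param in _SWAP_FIELDS:
            conditions[f"setA_{param}_from_B"] = [
                _stage(_swapped(set_a, set_b, param), total_tubulin=total_tubulin)
            ]
            conditions[f"setB_{param}_from_A"] = [
                _stage(_swapped(set_b, set_a, param), total_tubulin=total_tubulin)
            ]

    elif name == "zones_scan":
        which = preset_name or "setB"
        conditions = {
            f"{which}_width_{w:g}um": [
                _stage(
                    which,
                    total_tubulin=total_tubulin,
                    zones=ZoneSpec(peripheral_width=w),
                )
            ]
            for w in widths
        }

    elif name == "noise_boundary":
        which = preset_name or "setB"
        variants = {
            "baseline": NoiseSpec(),
            "param_noise": NoiseSpec(vary_v_s=True, vary_k_c=True, vary_k_r=True),
            "radius_jitter": NoiseSpec(radius_jitter_max=3.0),
            "both": NoiseSpec(
                vary_v_s=True, vary_k_c=True, vary_k_r=True, radius_jitter_max=3.0
            ),
        }
        conditions = {
            label: [_stage(which, total_tubulin=total_tubulin, noise=noise)]
            for label, noise in variants.items()
        }

    else:
        raise ValueError(
            f"unknown recipe {name!r}; valid names: {', '.join(RECIPE_NAMES)}"
        )

    return ExperimentRecipe(
        name=name,
        conditions=conditions,
        replicates=replicates,
        transition_stage=transition,
    )


RECIPE_NAMES = (
    "interphase_setA",
    "interphase_setB",
    "tubulin_scan",
    "nucleation_off",
    "dilution_10x",
    "prophase_switch",
    "prophase_switch_5x_nucleation",
    "prophase_keep_kc",
    "prophase_keep_kr",
    "param_swap",
    "zones_scan",
    "noise_boundary",
)


def _transition_half_times(
    trajs: Sequence[Trajectory], stage_idx: int
) -> Dict[str, float]:
    """Midpoint half-times of MT count and mean length within the
    transition stage, averaged over replicates."""
    out: Dict[str, List[float]] = {"n_mt": [], "mean_length": []}
    for tr in trajs:
        sl = tr.stage_slice(stage_idx)
        t = tr.t[sl] - tr.t[sl][0]
        out["n_mt"].append(half_time(tr.n_mt[sl], t))
        out["mean_length"].append(half_time(tr.mean_length[sl], t))
    return {k: float(np.nanmean(v)) for k, v in out.items()}


def run_experiment(
    rec: ExperimentRecipe,
    kinetics: KineticConstants = KineticConstants(),
    geometry: Geometry = Geometry(),
    base_seed: int = 0,
    window_length: float = 2_000,
) -> Dict[str, ExperimentResult]:
    """Run every condition × replicate of an experiment.

    The steady-state summary window is the last ``window_length`` s of
    the assembly stage (the stage before the transition when one is
    defined, otherwise the whole run).  Half-times of MT count and mean
    length are reported for transition recipes.
    """
    seeds = rec.seeds(base_seed)
    results: Dict[str, ExperimentResult] = {}
    for label, stages in rec.conditions.items():
        trajs = [
            run_stages(stages, kinetics, geometry, seed=s) for s in seeds
        ]
        if rec.transition_stage is not None:
            t_end = trajs[0].stage_boundaries[rec.transition_stage]
        else:
            t_end = trajs[0].t[-1]
        window = (max(0.0, t_end - window_length), t_end)
        summary = steady_state_summary(trajs, window)
        halves = (
            _transition_half_times(trajs, rec.transition_stage)
            if rec.transition_stage is not None
            else None
        )
        results[label] = ExperimentResult(
            trajectories=trajs, seeds=seeds, summary=summary, half_times=halves
        )
    return results
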