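"""Run configuration: YAML round-trip, validation, and tabular outputs.

A config file is a flat YAML mapping with optional ``geometry``,
``kinetics``, ``output`` blocks and either a ``recipe`` name or an
explicit ``stages`` list.  Absent fields fill from the published
defaults (Set A, single 10,000 s stage, 35 μM total tubulin).  Unknown
keys are rejected by name so typos fail loudly.

Outputs are tab-separated tables per replicate (time series, final
length snapshot, tracked-microtubule life history) plus a YAML summary
and an echo of the fully resolved config including the replicate seeds,
so any run is independently reproducible from its own output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from .engine import StageSpec, Trajectory
from .params import (
    DIParams,
    NoiseSpec,
    NucleationSpec,
    ZoneSpec,
    preset,
)
from .tubulin import Geometry, KineticConstants

__all__ = ["RunConfig", "load_config", "dump_config", "write_outputs"]


@dataclass
class OutputOptions:
    directory: str = "mtarray_out"
    stride: int = 1
    snapshot: bool = True
    tracked: bool = True

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError(f"output stride must be >= 1, got {self.stride}")


@dataclass
class RunConfig:
    geometry: Geometry = field(default_factory=Geometry)
    kinetics: KineticConstants = field(default_factory=KineticConstants)
    stages: List[StageSpec] = field(
        default_factory=lambda: [StageSpec(duration=10_000, di=preset("setA"))]
    )
    recipe: Optional[str] = None
    replicates: int = 4
    seed: int = 0
    dt: float = 1.0
    output: OutputOptions = field(default_factory=OutputOptions)

    @property
    def replicate_seeds(self) -> List[int]:
        return [self.seed + i for i in range(self.replicates)]


def _build(cls, data: dict, context: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"{context}: unknown key(s) {sorted(unknown)}; valid: {sorted(valid)}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{context}: {exc}") from exc


def _stage_from_dict(data: dict, context: str) -> StageSpec:
    data = dict(data)
    di_spec = data.pop("preset", None)
    di_dict = data.pop("di", None)
    if di_spec is not None and di_dict is not None:
        raise ValueError(f"{context}: give either 'preset' or 'di', not both")
    if di_dict is not None:
        di = _build(DIParams, di_dict, f"{context}.di")
    else:
        di = preset(di_spec or "setA")
    kw: dict = {"di": di}
    if "nucleation" in data:
        kw["nucleation"] = _build(
            NucleationSpec, data.pop("nucleation"), f"{context}.nucleation"
        )
    if "zones" in data:
        zones = data.pop("zones")
        kw["zones"] = (
            None if zones is None else _build(ZoneSpec, zones, f"{context}.zones")
        )
    if "noise" in data:
        kw["noise"] = _build(NoiseSpec, data.pop("noise"), f"{context}.noise")
    for key in ("duration", "total_tubulin", "dilution_factor", "pinned_free_conc"):
        if key in data:
            kw[key] = data.pop(key)
    if data:
        raise ValueError(f"{context}: unknown key(s) {sorted(data)}")
    try:
        return StageSpec(**kw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{context}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full defaults.  Errors name the offending
    key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    cfg = RunConfig()
    known = {
        "geometry", "kinetics", "stages", "recipe",
        "replicates", "seed", "dt", "output",
        "resolved_replicate_seeds",  # informational echo field, ignored
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown key(s) {sorted(unknown)}")
    if "geometry" in raw:
        cfg.geometry = _build(Geometry, raw["geometry"], "geometry")
    if "kinetics" in raw:
        cfg.kinetics = _build(KineticConstants, raw["kinetics"], "kinetics")
    if "recipe" in raw and "stages" in raw:
        raise ValueError(f"{path}: give either 'recipe' or 'stages', not both")
    if "recipe" in raw:
        cfg.recipe = raw["recipe"]
    if "stages" in raw:
        stages_raw = raw["stages"]
        if not isinstance(stages_raw, list) or not stages_raw:
            raise ValueError(f"{path}: 'stages' must be a non-empty list")
        cfg.stages = [
            _stage_from_dict(s, f"stages[{i}]") for i, s in enumerate(stages_raw)
        ]
    for key in ("replicates", "seed"):
        if key in raw:
            value = raw[key]
            if not isinstance(value, int) or value < 0 or (
                key == "replicates" and value < 1
            ):
                raise ValueError(f"{path}: invalid value for {key}: {value!r}")
            setattr(cfg, key, value)
    if "dt" in raw:
        if not raw["dt"] > 0:
            raise ValueError(f"{path}: dt must be > 0, got {raw['dt']}")
        cfg.dt = float(raw["dt"])
    if "output" in raw:
        cfg.output = _build(OutputOptions, raw["output"], "output")
    return cfg


def _as_dict(obj) -> dict:
    return dataclasses.asdict(obj)


def dump_config(cfg: RunConfig, seeds: Optional[Sequence[int]] = None) -> str:
    """Serialize a config (plus resolved replicate seeds) to YAML text.

    Loading the written text reproduces the config exactly.
    """
    doc: dict = {
        "geometry": _as_dict(cfg.geometry),
        "kinetics": _as_dict(cfg.kinetics),
        "replicates": cfg.replicates,
        "seed": cfg.seed,
        "dt": cfg.dt,
        "output": _as_dict(cfg.output),
    }
    if cfg.recipe is not None:
        doc["recipe"] = cfg.recipe
    else:
        doc["stages"] = [
            {
                "duration": s.duration,
                "di": _as_dict(s.di),
                "nucleation": _as_dict(s.nucleation),
                "total_tubulin": s.total_tubulin,
                "zones": None if s.zones is None else _as_dict(s.zones),
                "noise": _as_dict(s.noise),
                "dilution_factor": s.dilution_factor,
                "pinned_free_conc": s.pinned_free_conc,
            }
            for s in cfg.stages
        ]
    if seeds is not None:
        doc["resolved_replicate_seeds"] = list(map(int, seeds))
    return yaml.safe_dump(doc, sort_keys=False)


def write_outputs(
    trajectories: Dict[str, List[Trajectory]],
    summaries: Dict[str, dict],
    cfg: RunConfig,
    outdir,
) -> List[Path]:
    """Write per-replicate tables, summaries, and the resolved config.

    ``trajectories`` maps a condition label to its replicate list (use a
    single label such as ``"run"`` for plain runs).  Returns the written
    paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    seeds = cfg.replicate_seeds
    stride = cfg.output.stride

    for label, trajs in trajectories.items():
        for seed, tr in zip(seeds, trajs):
            tag = f"{label}_seed{seed}"
            ts = pd.DataFrame(
                {
                    "t_s": tr.t[::stride],
                    "n_mt": tr.n_mt[::stride],
                    "mean_length_um": tr.mean_length[::stride],
                    "free_tubulin_uM": tr.free_conc[::stride],
                }
            )
            path = outdir / f"timeseries_{tag}.tsv"
            ts.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(path)
            if cfg.output.snapshot:
                path = outdir / f"final_lengths_{tag}.tsv"
                pd.DataFrame({"length_um": tr.final_lengths}).to_csv(
                    path, sep="\t", index=False, float_format="%.6g"
                )
                written.append(path)
            if cfg.output.tracked:
                path = outdir / f"tracked_mt_{tag}.tsv"
                pd.DataFrame(
                    {"t_s": tr.t[::stride], "length_um": tr.tracked_length[::stride]}
                ).to_csv(path, sep="\t", index=False, float_format="%.6g")
                written.append(path)

    path = outdir / "summary.yaml"
    path.write_text(yaml.safe_dump(summaries, sort_keys=False))
    written.append(path)
    path = outdir / "config_echo.yaml"
    path.write_text(dump_config(cfg, seeds=seeds))
    written.append(path)
    return written
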