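"""Dynamic-instability parameter sets, rate laws, and per-step noise.

Three published parameter sets for LLCPK1 epithelial cells ship as named
presets: two interphase measurements (``setA``, ``setB``) and one taken
around nuclear envelope breakdown (``nebd``).  Each records the mean and
standard deviation of the four plus-end dynamic-instability parameters:
growth velocity V_g, shortening velocity V_s, catastrophe frequency k_c,
and rescue frequency k_r.

Rates convert to per-step probabilities via the exponential waiting-time
form ``p = 1 − exp(−k·dt)``; at the rates in play (≤ 0.175 s⁻¹ at dt = 1 s)
this differs from the linear form ``k·dt`` by under 1% but remains a valid
probability for any rate or step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "DIParams",
    "NucleationSpec",
    "ZoneSpec",
    "NoiseSpec",
    "PRESET_NAMES",
    "preset",
    "growth_velocity",
    "transition_probability",
    "effective_catastrophe_rate",
    "nucleation_rate",
    "sample_step_params",
]


@dataclass(frozen=True)
class DIParams:
    """Mean ± sd of the four dynamic-instability parameters for one cell
    state (velocities in μm/s, frequencies in s⁻¹)."""

    v_g_mean: float
    v_g_sd: float
    v_s_mean: float
    v_s_sd: float
    k_c_mean: float
    k_c_sd: float
    k_r_mean: float
    k_r_sd: float

    def __post_init__(self) -> None:
        for name in (
            "v_g_mean", "v_g_sd", "v_s_mean", "v_s_sd",
            "k_c_mean", "k_c_sd", "k_r_mean", "k_r_sd",
        ):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    def with_(self, **changes: float) -> "DIParams":
        """Copy with selected fields replaced (for single-parameter swaps)."""
        return replace(self, **changes)


# Published plus-end dynamics for LLCPK1 cells: two interphase data sets
# and one measured around nuclear envelope breakdown (prophase).
_PRESETS = {
    "setA": DIParams(0.192, 0.123, 0.218, 0.144, 0.026, 0.024, 0.175, 0.104),
    "setB": DIParams(0.142, 0.097, 0.188, 0.132, 0.053, 0.003, 0.086, 0.005),
    "nebd": DIParams(0.178, 0.153, 0.205, 0.087, 0.075, 0.089, 0.023, 0.029),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> DIParams:
    """Return the named dynamic-instability preset.

    Raises
    ------
    ValueError
        If ``name`` is not one of :data:`PRESET_NAMES`.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None


@dataclass(frozen=True)
class NucleationSpec:
    """Nucleation from a fixed pool of central sites.

    The per-site rate is either constant (default 0.0005 s⁻¹, the measured
    centrosomal emergence rate divided over 500 sites) or linear in free
    tubulin with slope ``rate_slope``.  The default slope calibrates the
    linear law to recover 0.0005 s⁻¹ at the measured 7 μM interphase free
    tubulin concentration.
    """

    n_sites: int = 500
    rate_per_site: float = 0.0005
    concentration_dependent: bool = False
    rate_slope: float = 0.0005 / 7.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.rate_per_site < 0:
            raise ValueError(
                f"rate_per_site must be >= 0, got {self.rate_per_site}"
            )
        if self.rate_slope < 0:
            raise ValueError(f"rate_slope must be >= 0, got {self.rate_slope}")


@dataclass(frozen=True)
class ZoneSpec:
    """Two concentric catastrophe zones.

    The outer ``peripheral_width`` μm of the cell keeps the measured
    catastrophe frequency; the interior uses ``interior_catastrophe_factor``
    times that frequency (default 1/16, the reported interior reduction).
    A tip exactly at the seam takes the peripheral value.
    """

    peripheral_width: float
    interior_catastrophe_factor: float = 1.0 / 16.0

    def __post_init__(self) -> None:
        if self.peripheral_width < 0:
            raise ValueError(
                f"peripheral_width must be >= 0, got {self.peripheral_width}"
            )
        if not (0 < self.interior_catastrophe_factor <= 1):
            raise ValueError(
                "interior_catastrophe_factor must be in (0, 1], got "
                f"{self.interior_catastrophe_factor}"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Per-step random variation of parameters and of the boundary.

    * ``vary_v_s``: V_s drawn uniformly on [mean − sd, mean + sd],
      truncated at 0 (one-standard-deviation range).
    * ``vary_k_c`` / ``vary_k_r``: frequency drawn uniformly on
      [0, 2·mean] — the widest symmetric range that stays non-negative,
      matching the observation that these sds are often as large as the
      means.
    * ``radius_jitter_max``: each step the boundary radius is reduced by a
      single global draw from U(0, radius_jitter_max) μm.
    """

    vary_v_s: bool = False
    vary_k_c: bool = False
    vary_k_r: bool = False
    radius_jitter_max: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_jitter_max < 0:
            raise ValueError(
                f"radius_jitter_max must be >= 0, got {self.radius_jitter_max}"
            )


def growth_velocity(free_conc, kinetics) -> float:
    """Plus-end growth velocity (μm/s): ``k_on · [Tub]_free + c1``."""
    return kinetics.k_on * free_conc + kinetics.c1_intercept


def transition_probability(rate: float, dt: float) -> float:
    """Probability of at least one event of a Poisson rate within ``dt``."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return -math.expm1(-rate * dt)


def effective_catastrophe_rate(
    tip_radius: float,
    cell_radius: float,
    zones: Optional[ZoneSpec],
    k_c: float,
) -> float:
    """Catastrophe frequency at a tip position, honoring the zone model.

    Without zones this is simply ``k_c``.  With zones, tips strictly
    interior to ``cell_radius − peripheral_width`` see the reduced
    frequency; tips at or beyond the seam see the full one.
    """
    if not (0 <= tip_radius <= cell_radius):
        raise ValueError(
            f"tip radius {tip_radius} outside cell of radius {cell_radius}"
        )
    if zones is None:
        return k_c
    if tip_radius < cell_radius - zones.peripheral_width:
        return k_c * zones.interior_catastrophe_factor
    return k_c


def nucleation_rate(free_conc: float, spec: NucleationSpec) -> float:
    """Per-site nucleation rate (s⁻¹), constant or linear in free tubulin."""
    if free_conc < 0:
        raise ValueError(f"free_conc must be >= 0, got {free_conc}")
    if spec.concentration_dependent:
        return spec.rate_slope * free_conc
    return spec.rate_per_site


def sample_step_params(
    di: DIParams,
    noise: NoiseSpec,
    rng: np.random.Generator,
    n: int = 1,
) -> dict:
    """Draw this step's effective {v_s, k_c, k_r} for ``n`` microtubules.

    Flagged parameters are resampled independently per microtubule per
    step from their uniform ranges; unflagged parameters come back as
    arrays pinned at the mean.  All ranges are symmetric about the mean,
    so noise leaves the long-run averages unchanged.
    """
    if noise.vary_v_s:
        lo = max(0.0, di.v_s_mean - di.v_s_sd)
        v_s = rng.uniform(lo, di.v_s_mean + di.v_s_sd, n)
    else:
        v_s = np.full(n, di.v_s_mean)
    if noise.vary_k_c:
        k_c = rng.uniform(0.0, 2.0 * di.k_c_mean, n)
    else:
        k_c = np.full(n, di.k_c_mean)
    if noise.vary_k_r:
        k_r = rng.uniform(0.0, 2.0 * di.k_r_mean, n)
    else:
        k_r = np.full(n, di.k_r_mean)
    return {"v_s": v_s, "k_c": k_c, "k_r": k_r}
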