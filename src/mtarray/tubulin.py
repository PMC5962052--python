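"""Tubulin mass bookkeeping.

The simulated cell holds a fixed total tubulin budget that partitions
between a free dimer pool (μM) and microtubule polymer (μm of lattice).
Two constants bridge the units:

* 1 μm of microtubule lattice contains 1624 αβ-tubulin dimers
  (13 protofilaments, 8 nm per dimer).
* 1 μM in 1 μm³ corresponds to N_A × 10⁻²¹ ≈ 602.214 molecules.

Free tubulin is always *derived* from the budget and the instantaneous
polymer mass, so conservation is structural rather than numerically
integrated.  The only situation where the identity ``free + polymer ==
total`` does not hold is after a dilution intervention that shrinks the
budget below the standing polymer mass; the free pool is then clamped at
zero until depolymerization brings polymer back under the budget.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DIMERS_PER_UM",
    "DIMERS_PER_UM_UM3",
    "KineticConstants",
    "Geometry",
    "concentration_to_dimers",
    "dimers_to_concentration",
    "polymer_concentration",
    "polymer_length_from_concentration",
    "free_tubulin",
]

#: Dimers per μm of microtubule lattice (13 protofilaments × 125 dimers/μm).
DIMERS_PER_UM = 1624.0

#: Molecules per (μM · μm³): Avogadro's number × 10⁻²¹.
DIMERS_PER_UM_UM3 = 602.214


@dataclass(frozen=True)
class KineticConstants:
    """Rate constants for concentration-dependent plus-end growth.

    Growth velocity follows ``V_g = k_on · [Tub] + c1``, an apparent
    whole-microtubule rate law (not a per-protofilament microscopic
    constant).

    Parameters
    ----------
    k_on
        Apparent association rate constant, μm · μM⁻¹ · s⁻¹.
    c1_intercept
        Velocity intercept at zero free tubulin, μm/s.
    dimers_per_um
        Lattice packing constant; fixed at 1624.
    dimers_per_uM_um3
        Unit-bridge constant, molecules per (μM · μm³).
    """

    k_on: float = 0.0167
    c1_intercept: float = 0.0
    dimers_per_um: float = DIMERS_PER_UM
    dimers_per_uM_um3: float = DIMERS_PER_UM_UM3

    def __post_init__(self) -> None:
        if self.k_on < 0:
            raise ValueError(f"k_on must be >= 0, got {self.k_on}")
        if self.c1_intercept < 0:
            raise ValueError(
                f"c1_intercept must be >= 0, got {self.c1_intercept}"
            )
        if self.dimers_per_um != DIMERS_PER_UM:
            raise ValueError(
                "dimers_per_um is a lattice constant and must equal "
                f"{DIMERS_PER_UM}, got {self.dimers_per_um}"
            )
        if self.dimers_per_uM_um3 <= 0:
            raise ValueError("dimers_per_uM_um3 must be > 0")


@dataclass(frozen=True)
class Geometry:
    """Cell geometry: a thin cylinder mimicking the basal cell region.

    The default 25 μm radius × 0.5 μm height cylinder has a geometric
    volume of ~981.7 μm³; the working volume defaults to a round
    1000 μm³ and may be overridden independently of radius and height.
    """

    radius: float = 25.0
    height: float = 0.5
    volume: float = 1000.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.height <= 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if self.volume <= 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")


def concentration_to_dimers(conc: float, volume: float) -> float:
    """Number of dimers corresponding to ``conc`` μM in ``volume`` μm³."""
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return conc * DIMERS_PER_UM_UM3 * volume


def dimers_to_concentration(dimers: float, volume: float) -> float:
    """Concentration (μM) of ``dimers`` molecules in ``volume`` μm³."""
    if dimers < 0:
        raise ValueError(f"dimer count must be >= 0, got {dimers}")
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return dimers / (DIMERS_PER_UM_UM3 * volume)


def polymer_concentration(total_length: float, volume: float) -> float:
    """Tubulin concentration (μM) locked in ``total_length`` μm of polymer."""
    if total_length < 0:
        raise ValueError(f"polymer length must be >= 0, got {total_length}")
    return dimers_to_concentration(total_length * DIMERS_PER_UM, volume)


def polymer_length_from_concentration(conc: float, volume: float) -> float:
    """Polymer length (μm) equivalent to ``conc`` μM; inverse of
    :func:`polymer_concentration`."""
    return concentration_to_dimers(conc, volume) / DIMERS_PER_UM


def free_tubulin(
    total_conc: float, total_polymer_length: float, volume: float
) -> float:
    """Free dimer concentration (μM) given the budget and standing polymer.

    Clamped at zero when polymer exceeds the budget, which is reachable
    only after a dilution intervention.
    """
    if total_conc < 0:
        raise ValueError(f"total concentration must be >= 0, got {total_conc}")
    return max(0.0, total_conc - polymer_concentration(total_polymer_length, volume))
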