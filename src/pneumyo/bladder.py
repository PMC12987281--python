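"""Two-region isothermal muscle--bladder mechanics.

A looped air bladder worn around the thigh is approximated, when fully
inflated, as a cylinder of diameter ``D`` and axial length ``L`` (the loop
circumference), so its gas volume is ``V = pi * D**2 * L / 4``.

The bladder covers several muscle groups.  At any instant only one group is
assumed to contract; the bladder cross-section is split into a contracting
region (area ``Ab``, pressure ``Pb``) and a rest region (``Au``, ``Pu``).
Muscle and bladder share a conserved total cross-sectional area, so a muscle
area change ``dAm`` forces a bladder area change ``dAb = -dAm``.  Gas
redistribution is isothermal (the thin bladder wall sits against skin, a
constant-temperature reservoir), so per unit length the product
``pressure * area`` of the trapped gas is conserved.

First-order expansion of the isothermal balance yields the linear maps used
for sensing:

* local:  ``dAb = -(Ab / Pb) * dPb``
* total:  ``dAb = -((Ab + Au) / Pt) * dPt``
* hence   ``dPb = Pb * (Ab + Au) / (Pt * Ab) * dPt``

and, with a series-elastic tendon of stiffness ``k`` (N/mm) and muscle of
initial length ``x`` and cross-section ``Am``, the transmitted muscle force

    ``fm = k * Ab * x / (Pb * Am) * dPb = k * (Ab + Au) * x / (Pt * Am) * dPt``

so the overall bladder pressure change is a linear proxy for muscle force.
All pressures are the model's gauge-offset absolute values used
multiplicatively (no atmospheric offset is added); units are kPa, mm, N
throughout.  ``equilibrium_oracle`` provides the exact (non-linearized)
isothermal redistribution against which the first-order maps are verified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BladderGeometry",
    "RegionState",
    "SystemState",
    "MuscleTendonParams",
    "cylinder_volume",
    "local_pressure_change_to_area_change",
    "total_to_local_pressure_change",
    "muscle_force_from_local",
    "muscle_force_from_total",
    "equilibrium_oracle",
    "muscle_area_change",
]


@dataclass(frozen=True)
class BladderGeometry:
    """Inflated-bladder geometry.

    Parameters
    ----------
    diameter_D:
        Cross-sectional diameter of the inflated cylinder, mm.
    loop_length:
        Axial length of the looped cylinder around the thigh, mm.
    panel_l1, panel_l2:
        Printed rectangular panel dimensions of the flat bladder, mm.
        Carried as metadata; the volume is computed from the loop length.
    """

    diameter_D: float
    loop_length: float
    panel_l1: float = 30.0
    panel_l2: float = 40.0

    def __post_init__(self) -> None:
        if self.diameter_D <= 0:
            raise ValueError(f"diameter_D must be > 0, got {self.diameter_D}")
        if self.loop_length <= 0:
            raise ValueError(f"loop_length must be > 0, got {self.loop_length}")


@dataclass(frozen=True)
class RegionState:
    """Cross-sectional area (mm^2) and pressure (kPa) of one bladder region."""

    area: float
    pressure: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"region area must be > 0, got {self.area}")
        if self.pressure <= 0:
            raise ValueError(f"region pressure must be > 0, got {self.pressure}")


@dataclass(frozen=True)
class SystemState:
    """Two-region bladder state; at equilibrium both regions sit at ``total_pressure``."""

    region_contracting: RegionState
    region_rest: RegionState
    total_pressure: float

    def __post_init__(self) -> None:
        if self.total_pressure <= 0:
            raise ValueError("total_pressure must be > 0")

    @classmethod
    def uniform(cls, pressure: float, area_contracting: float, area_rest: float) -> "SystemState":
        """Equilibrium state with a uniform pressure in both regions."""
        return cls(
            region_contracting=RegionState(area_contracting, pressure),
            region_rest=RegionState(area_rest, pressure),
            total_pressure=pressure,
        )

    @property
    def total_area(self) -> float:
        return self.region_contracting.area + self.region_rest.area


@dataclass(frozen=True)
class MuscleTendonParams:
    """Series-elastic tendon stiffness (N/mm), muscle length (mm) and cross-section (mm^2)."""

    stiffness_k: float
    muscle_length_x: float
    muscle_area_Am: float

    def __post_init__(self) -> None:
        for name in ("stiffness_k", "muscle_length_x", "muscle_area_Am"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def cylinder_volume(geom: BladderGeometry) -> float:
    """Gas volume (mm^3) of the fully inflated looped bladder, ``pi*D^2*L/4``."""
    return math.pi * geom.diameter_D**2 * geom.loop_length / 4.0


def local_pressure_change_to_area_change(region: RegionState, dP: float) -> float:
    """First-order isothermal area change (mm^2) of a region for pressure change ``dP`` (kPa).

    ``dA = -(A / P) * dP``: raising the pressure of a fixed amount of gas
    shrinks the cross-section it occupies, and vice versa.
    """
    return -(region.area / region.pressure) * dP


def total_to_local_pressure_change(state: SystemState, dPt: float) -> float:
    """Map a total-pressure change ``dPt`` to the contracting region's ``dPb`` (kPa).

    ``dPb = Pb * (Ab + Au) / (Pt * Ab) * dPt``.  For a uniform-start state
    (``Pb == Pt``) with no rest region this reduces to the identity.
    """
    contracting = state.region_contracting
    if contracting.area <= 0:
        raise ValueError("contracting region area must be > 0")
    return (
        contracting.pressure
        * state.total_area
        / (state.total_pressure * contracting.area)
        * dPt
    )


def muscle_force_from_local(
    params: MuscleTendonParams, region: RegionState, dPb: float
) -> float:
    """Tendon-transmitted muscle force (N) from the local pressure change ``dPb``.

    ``fm = k * Ab * x / (Pb * Am) * dPb``.  The ratio form is dimensionless in
    areas and pressures, so k (N/mm) times x (mm) directly yields newtons
    (equivalently: 1 kPa * mm^2 = 1 mN, and the conversions cancel).
    """
    if region.pressure <= 0:
        raise ValueError("region pressure must be > 0")
    if params.muscle_area_Am <= 0:
        raise ValueError("muscle area must be > 0")
    return (
        params.stiffness_k
        * region.area
        * params.muscle_length_x
        / (region.pressure * params.muscle_area_Am)
        * dPb
    )


def muscle_force_from_total(
    params: MuscleTendonParams, state: SystemState, dPt: float
) -> float:
    """Tendon-transmitted muscle force (N) from the total pressure change ``dPt``.

    ``fm = k * (Ab + Au) * x / (Pt * Am) * dPt``; algebraically identical to
    composing :func:`muscle_force_from_local` with
    :func:`total_to_local_pressure_change`.
    """
    if state.total_pressure <= 0:
        raise ValueError("total pressure must be > 0")
    if params.muscle_area_Am <= 0:
        raise ValueError("muscle area must be > 0")
    return (
        params.stiffness_k
        * state.total_area
        * params.muscle_length_x
        / (state.total_pressure * params.muscle_area_Am)
        * dPt
    )


def equilibrium_oracle(state: SystemState, dAb_imposed: float) -> float:
    """Exact isothermal equilibrium pressure (kPa) after imposing ``dAb`` on the bladder.

    Per unit length the trapped-gas amount in each region is proportional to
    ``P * A``; after the contracting region's area changes by ``dAb_imposed``
    and pressures equalize, mass balance gives

        ``P_new = (Pb*Ab + Pu*Au) / (Ab + Au + dAb_imposed)``

    which conserves the ``P*A`` sum exactly.  This is the non-linearized
    reference the first-order maps approximate.
    """
    denom = state.total_area + dAb_imposed
    if denom <= 0:
        raise ValueError(
            f"area collapse: total area {state.total_area} + dAb {dAb_imposed} <= 0"
        )
    b, u = state.region_contracting, state.region_rest
    return (b.pressure * b.area + u.pressure * u.area) / denom


def muscle_area_change(dAb: float) -> float:
    """Area-conservation closure: a bladder area change implies ``dAm = -dAb``."""
    return -dAb
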