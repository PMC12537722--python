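"""Headspace-equilibration conversion of GC methane readings to porewater CH4.

A known volume of sediment is sealed in a gas-tight jar with distilled water,
leaving a headspace that equilibrates with the dissolved methane.  The GC
reports the headspace CH4 mixing ratio (ppm by volume); total methane is the
sum of the gaseous moles (ideal gas law) and the moles remaining dissolved in
the aqueous phase (Henry's law), attributed to the original porewater volume
(sediment volume x porosity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "JarGeometry",
    "LabConditions",
    "HeadspaceSample",
    "headspace_moles",
    "dissolved_moles",
    "henry_constant_at",
    "total_porewater_methane",
    "ppm_for_concentration",
]

#: Gas constant in L atm mol^-1 K^-1.
R_L_ATM = 0.082057366

# small allowance for volume bookkeeping round-off (mL)
_VOLUME_TOL = 1.0


@dataclass(frozen=True)
class JarGeometry:
    """Volumes of the incubation jar, all in mL, plus sediment porosity.

    Defaults follow the field protocol: a 600 mL gas-tight jar receives
    133 mL of sediment and 200 mL of distilled water, leaving a 200 mL
    headspace; porosity of uncompacted muddy sediment is taken as 0.8.
    """

    jar_volume: float = 600.0
    sediment_volume: float = 133.0
    water_added: float = 200.0
    headspace_volume: float = 200.0
    porosity: float = 0.8

    def __post_init__(self) -> None:
        for name in ("jar_volume", "sediment_volume", "water_added", "headspace_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError(f"porosity must be in (0, 1), got {self.porosity}")
        filled = self.sediment_volume + self.water_added + self.headspace_volume
        if filled > self.jar_volume + _VOLUME_TOL:
            raise ValueError(
                f"contents ({filled:.1f} mL) exceed jar volume ({self.jar_volume:.1f} mL)"
            )

    @property
    def porewater_volume_l(self) -> float:
        """Original porewater volume (L) the total methane is attributed to."""
        return self.sediment_volume * self.porosity / 1000.0

    @property
    def aqueous_volume_l(self) -> float:
        """Aqueous phase at equilibrium (L): added water plus porewater."""
        return (self.water_added + self.sediment_volume * self.porosity) / 1000.0


@dataclass(frozen=True)
class LabConditions:
    """Equilibration conditions and CH4 solubility constants.

    henry_constant is the CH4 solubility (mol L^-1 atm^-1) at henry_ref_temperature;
    henry_vant_hoff is the van 't Hoff temperature-dependence parameter (K), so
    K_H(T) = K_ref * exp(B * (1/T - 1/T_ref)).
    """

    temperature: float = 294.15  # K, 21 degC lab
    pressure: float = 1.0  # atm
    gas_constant: float = R_L_ATM
    henry_constant: float = 1.4e-3
    henry_ref_temperature: float = 298.15
    henry_vant_hoff: float = 1700.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.pressure <= 0:
            raise ValueError("pressure must be positive (atm)")


@dataclass(frozen=True)
class HeadspaceSample:
    """One jar: GC reading plus its geometry, conditions and provenance labels."""

    site: str
    bay: str
    season: str
    depth_interval: tuple[float, float]  # (top, bottom) cm below seafloor
    ppm: float
    geometry: JarGeometry = field(default_factory=JarGeometry)
    lab: LabConditions = field(default_factory=LabConditions)

    def __post_init__(self) -> None:
        if self.ppm < 0:
            raise ValueError(f"ppm must be non-negative, got {self.ppm}")
        top, bottom = self.depth_interval
        if bottom <= top:
            raise ValueError(f"depth interval bottom must exceed top, got {self.depth_interval}")

    @property
    def depth_midpoint(self) -> float:
        top, bottom = self.depth_interval
        return 0.5 * (top + bottom)


def henry_constant_at(lab: LabConditions) -> float:
    """CH4 Henry solubility (mol L^-1 atm^-1) at the lab temperature."""
    return lab.henry_constant * math.exp(
        lab.henry_vant_hoff * (1.0 / lab.temperature - 1.0 / lab.henry_ref_temperature)
    )


def headspace_moles(ppm: float, geometry: JarGeometry, lab: LabConditions) -> float:
    """Moles of CH4 in the jar headspace, n = x * P * V / (R * T)."""
    if ppm < 0:
        raise ValueError(f"ppm must be non-negative, got {ppm}")
    partial_pressure = ppm * 1e-6 * lab.pressure
    return partial_pressure * (geometry.headspace_volume / 1000.0) / (lab.gas_constant * lab.temperature)


def dissolved_moles(ppm: float, geometry: JarGeometry, lab: LabConditions) -> float:
    """Moles of CH4 dissolved in the jar aqueous phase at equilibrium.

    The aqueous phase is the added distilled water plus the sediment porewater;
    both equilibrate with the headspace, so n_aq = K_H(T) * p_CH4 * V_aq.
    """
    if ppm < 0:
        raise ValueError(f"ppm must be non-negative, got {ppm}")
    partial_pressure = ppm * 1e-6 * lab.pressure
    return henry_constant_at(lab) * partial_pressure * geometry.aqueous_volume_l


def total_porewater_methane(sample: HeadspaceSample, include_dissolved: bool = True) -> float:
    """Total porewater CH4 concentration (mM) for one jar.

    Sums headspace and (optionally) dissolved moles and divides by the original
    porewater volume.  ``include_dissolved=False`` gives the headspace-only
    approximation some labs use.
    """
    n = headspace_moles(sample.ppm, sample.geometry, sample.lab)
    if include_dissolved:
        n += dissolved_moles(sample.ppm, sample.geometry, sample.lab)
    return n / sample.geometry.porewater_volume_l * 1000.0  # mol/L -> mM


def ppm_for_concentration(
    concentration_mm: float,
    geometry: JarGeometry,
    lab: LabConditions,
    include_dissolved: bool = True,
) -> float:
    """Headspace mixing ratio (ppm) a jar would read for a true porewater CH4 (mM).

    Exact inverse of :func:`total_porewater_methane`; both phases are linear in
    the mixing ratio, so the inversion is a single division.
    """
    if concentration_mm < 0:
        raise ValueError("concentration must be non-negative")
    n_total = concentration_mm * 1e-3 * geometry.porewater_volume_l
    per_ppm = lab.pressure * 1e-6 * (
        geometry.headspace_volume / 1000.0 / (lab.gas_constant * lab.temperature)
        + (henry_constant_at(lab) * geometry.aqueous_volume_l if include_dissolved else 0.0)
    )
    return n_total / per_ppm
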