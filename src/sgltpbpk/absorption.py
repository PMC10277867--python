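"""Nine-compartment compartmental absorption and transit (ACAT) settings.

The gastrointestinal tract is stomach, six small-intestine segments
(duodenum, jejunum 1/2, ileum 1-3), caecum and ascending colon.  Transit is
first order per compartment; dissolution follows a lumped Noyes-Whitney
term; absorption of dissolved drug is driven by effective permeability
scaled by a per-segment absorption scale factor (ASF).

The ASF model is geometric: ASF_i = coefficient x (2 / radius_i), the
cylindrical surface-to-volume ratio, with colonic segments down-weighted.
The single coefficient is the absorption calibration parameter fitted per
compound against its lowest-dose observed pharmacokinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .compounds import CompoundRecord
from .physiology import (
    COLON,
    GI_COMPARTMENTS,
    SMALL_INTESTINE,
    SubjectPhysiology,
)

__all__ = ["AbsorptionSettings", "default_asf"]

DEFAULT_STOMACH_TRANSIT_H = 0.25  # fasted
DEFAULT_SITT_H = 3.3
DEFAULT_COLON_TRANSIT_H = 13.0
DEFAULT_COLON_DOWNWEIGHT = 0.1
#: lumped dissolution rate (Noyes-Whitney z-factor), 1/h per (mg/mL) of
#: solubility deficit.  z = 3D/(rho h r) with D ~ 5e-6 cm2/s, rho ~ 1.2
#: g/cm3, h ~ r gives ~45 for a micronised 10 um powder; the plausible
#: particle-size range 5-70 um maps to roughly 2-150.
DEFAULT_DISSOLUTION_COEFF = 45.0


@dataclass(frozen=True)
class AbsorptionSettings:
    """Per-run ACAT parameters (see module docstring for the ASF model)."""

    asf: dict[str, float]
    stomach_transit_h: float = DEFAULT_STOMACH_TRANSIT_H
    small_intestine_transit_h: float = DEFAULT_SITT_H
    colon_transit_h: float = DEFAULT_COLON_TRANSIT_H
    fraction_gut_extracted: float = 0.0
    dissolution_rate_coefficient: float = DEFAULT_DISSOLUTION_COEFF
    asf_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.asf.values()):
            raise ValueError("ASF must be non-negative")
        if not (0.0 <= self.fraction_gut_extracted < 1.0):
            raise ValueError("fraction_gut_extracted must be in [0, 1)")
        if min(
            self.stomach_transit_h,
            self.small_intestine_transit_h,
            self.colon_transit_h,
        ) <= 0:
            raise ValueError("transit times must be positive")

    def transit_times(self, subject: SubjectPhysiology) -> dict[str, float]:
        """Mean residence time per GI compartment (h)."""
        geom = subject.gi_geometry
        times = {"stomach": self.stomach_transit_h}
        for seg in SMALL_INTESTINE:
            times[seg] = float(geom.loc[seg, "transit_fraction"]) * (
                self.small_intestine_transit_h
            )
        # colon transit split between caecum and ascending colon by volume
        vols = np.array([float(geom.loc[c, "luminal_volume_ml"]) for c in COLON])
        for c, frac in zip(COLON, vols / vols.sum()):
            times[c] = self.colon_transit_h * frac
        return times

    def absorption_rate_constants(
        self, compound: CompoundRecord, subject: SubjectPhysiology
    ) -> dict[str, float]:
        """First-order absorption rate (1/h) acting on dissolved luminal drug:
        ka_i = Peff(cm/h) x ASF_i with ASF_i in 1/cm."""
        peff = compound.peff_cm_per_h
        return {seg: peff * a for seg, a in self.asf.items()}

    def with_coefficient(self, coeff: float) -> "AbsorptionSettings":
        scale = coeff / self.asf_coefficient
        return replace(
            self,
            asf={k: v * scale for k, v in self.asf.items()},
            asf_coefficient=coeff,
        )


def default_asf(
    compound: CompoundRecord,
    subject: SubjectPhysiology,
    coefficient: float = 1.0,
    colon_downweight: float = DEFAULT_COLON_DOWNWEIGHT,
) -> AbsorptionSettings:
    """Literature-standard transit times with geometric 2/r scale factors."""
    geom = subject.gi_geometry
    asf: dict[str, float] = {"stomach": 0.0}
    for seg in GI_COMPARTMENTS[1:]:
        r = float(geom.loc[seg, "radius_cm"])
        weight = colon_downweight if seg in COLON else 1.0
        asf[seg] = coefficient * weight * 2.0 / r
    return AbsorptionSettings(asf=asf, asf_coefficient=coefficient)
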