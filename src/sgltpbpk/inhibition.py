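"""Competitive-inhibition algebra and transporter inhibition time courses.

The glucose transport rate is Michaelis-Menten, V0 = Vmax S/(Km + S); a
competitive inhibitor at concentration I with constant Ki rescales the
apparent Km, Vi = Vmax S/(Km (1 + I/Ki) + S); the inhibition ratio
(1 - Vi/V0) x 100 is independent of Vmax.  Ki can be derived from an IC50
by the Cheng-Prusoff relation Ki = IC50/(1 + S'/Km').

Sites: duodenum and jejunum I (intestinal SGLT1, luminal glucose fixed),
S1S2 (renal SGLT2) and S3 (renal SGLT1).  Conventions for the inhibitor
concentration per site are documented in the methods note: intestinal sites
use the luminal drug concentration (total by default, dissolved-only
configurable); S3 uses the free filtrate concentration; S1S2 uses the
kidney tissue concentration predicted by the PBPK model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .compounds import CompoundRecord

if TYPE_CHECKING:  # pragma: no cover
    from .model import SimulationResult
    from .renal import GlucoseTransportParams

__all__ = [
    "AssayCondition",
    "InhibitionProfile",
    "ki_from_ic50",
    "mm_rate",
    "inhibited_rate",
    "inhibition_ratio",
    "inhibition_timecourse",
    "SITES",
    "LUMINAL_GLUCOSE_MM",
]

#: luminal glucose in the upper small intestine as printed in the source
#: modelling literature (mmol/L); far above physiological molarity and kept
#: only as the established convention for this calculation - overridable.
LUMINAL_GLUCOSE_MM = 1670.0

SITES = {
    "duodenum": "SGLT1",
    "jejunum1": "SGLT1",
    "S1S2": "SGLT2",
    "S3": "SGLT1",
}


@dataclass(frozen=True)
class AssayCondition:
    """IC50 assay description for Cheng-Prusoff conversion."""

    ic50: float  # nM
    substrate_conc_assay: float  # mmol/L (S')
    km_assay: float  # mmol/L (Km')

    def __post_init__(self) -> None:
        if self.ic50 <= 0 or self.substrate_conc_assay < 0 or self.km_assay <= 0:
            raise ValueError("assay condition out of range")


def ki_from_ic50(assay: AssayCondition) -> float:
    """Cheng-Prusoff: Ki = IC50 / (1 + S'/Km'), nM."""
    return assay.ic50 / (1.0 + assay.substrate_conc_assay / assay.km_assay)


def mm_rate(vmax: float, km: float, s: float | np.ndarray):
    """Michaelis-Menten rate Vmax S/(Km + S)."""
    if km <= 0:
        raise ValueError("km must be positive")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be non-negative")
    out = vmax * s / (km + s)
    return float(out) if out.ndim == 0 else out


def inhibited_rate(vmax: float, km: float, s, i, ki: float):
    """Competitive inhibition: Vmax S/(Km (1 + I/Ki) + S)."""
    if ki <= 0:
        raise ValueError("ki must be positive")
    s = np.asarray(s, dtype=float)
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise ValueError("inhibitor concentration must be non-negative")
    out = vmax * s / (km * (1.0 + i / ki) + s)
    return float(out) if out.ndim == 0 else out


def inhibition_ratio(km: float, s, i, ki: float):
    """Percent inhibition (1 - Vi/V0) x 100; Vmax cancels.

    At s = 0 with i = 0 the ratio is defined as 0 (the uninhibited limit).
    """
    if ki <= 0 or km <= 0:
        raise ValueError("km and ki must be positive")
    s = np.asarray(s, dtype=float)
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise ValueError("inhibitor concentration must be non-negative")
    out = 100.0 * (1.0 - (km + s) / (km * (1.0 + i / ki) + s))
    return float(out) if out.ndim == 0 else out


@dataclass
class InhibitionProfile:
    """Inhibitor exposure and inhibition ratio versus time at one site."""

    site: str
    transporter: str
    compound: str
    dose_mg: float
    time: np.ndarray  # h
    inhibitor_nm: np.ndarray
    ratio: np.ndarray  # percent

    @property
    def max_ratio(self) -> float:
        return float(np.max(self.ratio))

    @property
    def time_of_max(self) -> float:
        return float(self.time[int(np.argmax(self.ratio))])

    def at_time(self, t: float) -> float:
        """Linearly interpolated inhibition ratio at time t (h)."""
        return float(np.interp(t, self.time, self.ratio))


def inhibition_timecourse(
    result: "SimulationResult",
    site: str,
    compound: CompoundRecord,
    glucose: "GlucoseTransportParams | None" = None,
    luminal_glucose_mm: float = LUMINAL_GLUCOSE_MM,
    gut_basis: str = "total",
) -> InhibitionProfile:
    """Inhibition-ratio time course at one site from a simulation.

    ``gut_basis`` selects total or dissolved luminal drug for the
    intestinal sites.
    """
    from .renal import GlucoseTransportParams  # local import to avoid cycle

    if site not in SITES:
        raise KeyError(f"unknown site {site!r}; choose from {sorted(SITES)}")
    if glucose is None:
        glucose = GlucoseTransportParams()
    transporter = SITES[site]
    ki = compound.ki_sglt2 if transporter == "SGLT2" else compound.ki_sglt1

    if site in ("duodenum", "jejunum1"):
        conc_mg_l = result.gut_luminal_conc(site, basis=gut_basis)  # mg/L
        inhibitor_nm = conc_mg_l / compound.molecular_weight * 1e6
        s = luminal_glucose_mm
        km = glucose.km_sglt1
        ratio = inhibition_ratio(km, s, inhibitor_nm, ki)
    elif site == "S1S2":
        tissue_ng_ml = result.tissue["kidney"] * 1000.0  # mg/L -> ng/mL
        inhibitor_nm = compound.ng_per_ml_to_nm(tissue_ng_ml)
        s = result.subject.plasma_glucose  # filtrate glucose entering S1
        ratio = inhibition_ratio(glucose.km_sglt2, s, inhibitor_nm, ki)
    else:  # S3: free filtrate drug against SGLT1, glucose leaving S2
        inhibitor_nm = compound.ng_per_ml_to_nm(result.tubule_drug_conc[2])
        s3_glucose = result.s3_glucose_conc(glucose)
        ratio = inhibition_ratio(glucose.km_sglt1, s3_glucose, inhibitor_nm, ki)

    return InhibitionProfile(
        site=site,
        transporter=transporter,
        compound=compound.name,
        dose_mg=result.dose_mg,
        time=result.time,
        inhibitor_nm=np.asarray(inhibitor_nm, dtype=float),
        ratio=np.asarray(ratio, dtype=float),
    )
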