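"""Mechanistic proximal-tubule submodel.

The tubule is treated quasi-statically: tubular transit (minutes) is fast
against plasma kinetics (hours), so segment concentrations are algebraic
functions of the instantaneous plasma concentration and the segment fluid
flows.  Drug handling is filtration-only (renal clearance = GFR x fup, no
secretion or reabsorption of drug); as water is reabsorbed along S1 -> S3
the luminal drug concentration rises by the inverse flow ratio.

Glucose is filtered at the plasma concentration, reabsorbed by SGLT2 in
S1/S2 and by SGLT1 in S3 under competitive inhibition by luminal drug, and
any flux escaping S3 is urinary glucose excretion (UGE).  The glucose flow
into S3 is the flow-carried flux leaving S2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compounds import CompoundRecord
from .physiology import SubjectPhysiology
from .inhibition import inhibited_rate

__all__ = ["GlucoseTransportParams", "TubuleState", "tubule_concentrations", "glucose_reabsorption"]

SEGMENTS = ("S1", "S2", "S3")


@dataclass(frozen=True)
class GlucoseTransportParams:
    """SGLT transport capacities and affinities.

    Defaults: total proximal reabsorption capacity ~2.5 mmol/min split
    ~90/10 between SGLT2 (S1/S2) and SGLT1 (S3); Km(SGLT2) = 2 mmol/L,
    Km(SGLT1) = 0.4 mmol/L.  Values are configuration defaults from the
    renal systems-pharmacology literature, not fitted here.
    """

    vmax_sglt2: float = 135.0  # mmol/h, split across S1/S2
    km_sglt2: float = 2.0  # mmol/L
    vmax_sglt1: float = 15.0  # mmol/h (S3)
    km_sglt1: float = 0.4  # mmol/L
    s1_fraction: float = 0.6  # share of SGLT2 capacity sitting in S1

    def __post_init__(self) -> None:
        if min(self.vmax_sglt2, self.km_sglt2, self.vmax_sglt1, self.km_sglt1) <= 0:
            raise ValueError("glucose transport parameters must be positive")
        if not (0.0 < self.s1_fraction < 1.0):
            raise ValueError("s1_fraction must be in (0, 1)")


@dataclass
class TubuleState:
    """Per-segment snapshot (arrays are aligned with SEGMENTS)."""

    fluid_flow: np.ndarray  # L/h entering each segment
    drug_conc: np.ndarray  # ng/mL luminal
    glucose_flux_in: np.ndarray  # mmol/h
    glucose_reabsorbed: np.ndarray  # mmol/h
    uge_rate: float  # mmol/h leaving S3
    urinary_drug_rate: float  # mg/h

    def glucose_conc(self) -> np.ndarray:
        """Luminal glucose concentration per segment, mmol/L."""
        return self.glucose_flux_in / self.fluid_flow


def tubule_concentrations(
    plasma_conc_ng_ml: float | np.ndarray,
    compound: CompoundRecord,
    subject: SubjectPhysiology,
) -> np.ndarray:
    """Luminal drug concentration (ng/mL) in S1/S2/S3.

    Filtered drug flow = GFR x fup x Cp; segment concentration is that flow
    divided by the segment fluid flow (rising as water is reabsorbed).
    Accepts a scalar or an array of plasma concentrations; returns shape
    (3,) or (3, n).
    """
    cp = np.asarray(plasma_conc_ng_ml, dtype=float)
    if np.any(cp < 0):
        raise ValueError("plasma concentration must be non-negative")
    fractions = np.asarray(subject.tubule_flow_fractions)
    return compound.fup * cp / fractions[:, None] if cp.ndim else compound.fup * cp / fractions


def glucose_reabsorption(
    subject: SubjectPhysiology,
    params: GlucoseTransportParams,
    inhibitor_nm: np.ndarray | None = None,
    ki_sglt2_nm: float = np.inf,
    ki_sglt1_nm: float = np.inf,
    drug_conc_ng_ml: np.ndarray | None = None,
    urinary_drug_rate: float = 0.0,
) -> TubuleState:
    """Sequential-segment glucose balance under competitive inhibition.

    ``inhibitor_nm`` is the per-segment drug concentration presented to the
    transporter (nM); reabsorption in any segment is capped by the glucose
    flux arriving there, so the balance conserves glucose exactly.
    """
    if inhibitor_nm is None:
        inhibitor_nm = np.zeros(3)
    inhibitor_nm = np.asarray(inhibitor_nm, dtype=float)
    if np.any(inhibitor_nm < 0):
        raise ValueError("inhibitor concentration must be non-negative")
    flows = np.asarray(subject.tubule_flows())
    vmax = np.array(
        [
            params.vmax_sglt2 * params.s1_fraction,
            params.vmax_sglt2 * (1.0 - params.s1_fraction),
            params.vmax_sglt1,
        ]
    )
    km = np.array([params.km_sglt2, params.km_sglt2, params.km_sglt1])
    ki = np.array([ki_sglt2_nm, ki_sglt2_nm, ki_sglt1_nm])

    flux_in = np.empty(3)
    reabs = np.empty(3)
    flux = subject.gfr_volumetric * subject.plasma_glucose  # filtered load
    for i in range(3):
        flux_in[i] = flux
        s = flux / flows[i]
        rate = inhibited_rate(vmax[i], km[i], s, inhibitor_nm[i], ki[i])
        reabs[i] = min(rate, flux)
        flux -= reabs[i]
    drug = (
        np.zeros(3)
        if drug_conc_ng_ml is None
        else np.asarray(drug_conc_ng_ml, dtype=float)
    )
    return TubuleState(
        fluid_flow=flows,
        drug_conc=drug,
        glucose_flux_in=flux_in,
        glucose_reabsorbed=reabs,
        uge_rate=flux,
        urinary_drug_rate=urinary_drug_rate,
    )
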