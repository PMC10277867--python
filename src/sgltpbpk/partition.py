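"""Tissue-to-plasma partition coefficients by the Rodgers-Rowland
("Rodgers single", a.k.a. Lukacova) mechanistic method, neutral species.

The gliflozins carry no ionisable centre of consequence at physiological pH
(C-glycosides), so the neutral-molecule form of the Rodgers-Rowland
equations is used: partitioning into tissue water, neutral lipid and
neutral phospholipid, plus albumin-mediated binding scaled by the tissue
albumin ratio.  Adipose neutral-lipid partitioning uses the vegetable
oil:water coefficient log Pvo = 1.115 logP - 1.35.  Tissue composition
constants are pinned in ``data/tissue_composition.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .compounds import CompoundRecord
from .physiology import SubjectPhysiology

__all__ = ["PartitionSet", "compute_kp", "vss_check"]

# plasma composition (fractional volumes)
PLASMA_F_NL = 0.0023
PLASMA_F_NP = 0.0013


@dataclass(frozen=True)
class PartitionSet:
    """Per-tissue Kp (total tissue : total plasma) and derived Vss."""

    kp: dict[str, float]
    vss: float  # L/kg
    method_tag: str = "rodgers_single"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.kp.values()):
            raise ValueError("all Kp must be positive")
        if self.vss <= 0:
            raise ValueError("Vss must be positive")


def _composition() -> pd.DataFrame:
    with resources.as_file(
        resources.files("sgltpbpk.data").joinpath("tissue_composition.csv")
    ) as p:
        return pd.read_csv(p).set_index("tissue")


def _kp_one_tissue(
    row, log_p: float, fup: float, adipose: bool
) -> float:
    p_oct = 10.0**log_p
    p_tis = 10.0 ** (1.115 * log_p - 1.35) if adipose else p_oct
    # albumin association constant from the plasma mass balance
    ka_alb = max(
        1.0 / fup - 1.0 - (p_oct * PLASMA_F_NL + (0.3 * p_oct + 0.7) * PLASMA_F_NP),
        0.0,
    )
    kpu = (
        row.f_ew
        + row.f_iw
        + p_tis * row.f_nl
        + (0.3 * p_tis + 0.7) * row.f_np
        + ka_alb * row.albumin_ratio
    )
    return kpu * fup


def compute_kp(compound: CompoundRecord, subject: SubjectPhysiology) -> PartitionSet:
    """Kp for every perfused tissue of the subject, plus Vss (L/kg).

    Vss = (blood volume on a plasma-concentration basis + sum of Vt * Kp_t)
    per kg body weight.
    """
    comp = _composition()
    kp: dict[str, float] = {}
    for tissue in subject.tissue_volumes:
        if tissue in ("arterial", "venous"):
            continue
        if tissue not in comp.index:
            raise KeyError(f"no composition data for tissue {tissue!r}")
        kp[tissue] = _kp_one_tissue(
            comp.loc[tissue], compound.log_p, compound.fup, adipose=(tissue == "adipose")
        )
    v_blood = (
        subject.tissue_volumes["arterial"] + subject.tissue_volumes["venous"]
    ) * compound.rbp
    vss = (
        v_blood + sum(subject.tissue_volumes[t] * kp[t] for t in kp)
    ) / subject.body_weight
    return PartitionSet(kp=kp, vss=vss)


def vss_check(partition: PartitionSet, subject: SubjectPhysiology, rbp: float) -> float:
    """Recompute Vss from a PartitionSet; equals ``partition.vss``."""
    v_blood = (
        subject.tissue_volumes["arterial"] + subject.tissue_volumes["venous"]
    ) * rbp
    return (
        v_blood
        + sum(subject.tissue_volumes[t] * k for t, k in partition.kp.items())
    ) / subject.body_weight
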