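"""Compound parameter fixtures for the four gliflozins.

Physicochemical, disposition and transporter-affinity parameters are shipped
as versioned CSV files inside the package.  Clearances are tabulated per kg
of body weight and treated as plasma clearances (the convention of the
commercial PBPK platforms these parameter sets circulate in).

The printed solubilities carry an explicit unit tag (default mg/mL).  The
magnitudes are far below the aqueous solubilities reported elsewhere for
these molecules if read as mg/L, so the mg/mL reading is used as the
operational in-lumen reference solubility; the tag can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd

__all__ = [
    "CompoundRecord",
    "DoseRegimen",
    "ObservedPK",
    "COMPOUNDS",
    "APPROVED_DOSES",
    "HIGHEST_APPROVED_DOSE",
    "LOWEST_STUDY_DOSE",
    "load_compound",
    "load_observed_pk",
    "load_inhibition_max",
]

COMPOUNDS = ("ertugliflozin", "empagliflozin", "henagliflozin", "sotagliflozin")

#: doses (mg) at which intestinal/renal SGLT1 inhibition is tabulated
APPROVED_DOSES = {
    "ertugliflozin": (5.0, 10.0),
    "empagliflozin": (10.0, 25.0),
    "henagliflozin": (5.0, 10.0),
    "sotagliflozin": (200.0, 400.0),
}

#: highest approved dose (mg), used for the SGLT2 saturation analysis
HIGHEST_APPROVED_DOSE = {
    "ertugliflozin": 15.0,
    "empagliflozin": 25.0,
    "henagliflozin": 10.0,
    "sotagliflozin": 400.0,
}

#: lowest dose with observed PK, used for absorption calibration
LOWEST_STUDY_DOSE = {
    "ertugliflozin": 1.0,
    "empagliflozin": 1.0,
    "henagliflozin": 2.5,
    "sotagliflozin": 200.0,
}


@dataclass(frozen=True)
class CompoundRecord:
    """One gliflozin's model parameters.

    Units: molecular_weight g/mol; solubility in ``solubility_unit``
    (mg/mL or mg/L); peff 1e-4 cm/s; clearances L/h/kg of body weight
    (whole-blood basis); Ki nM.
    """

    name: str
    molecular_weight: float
    log_p: float
    solubility: float
    peff: float
    fup: float
    rbp: float
    cl_total: float
    cl_hepatic: float
    ki_sglt1: float
    ki_sglt2: float
    solubility_unit: str = "mg/mL"

    def __post_init__(self) -> None:
        if not (0.0 < self.fup <= 1.0):
            raise ValueError(f"fup must be in (0, 1], got {self.fup}")
        if self.rbp <= 0:
            raise ValueError("rbp must be positive")
        if self.cl_hepatic > self.cl_total + 1e-12:
            raise ValueError("hepatic clearance cannot exceed total clearance")
        if min(self.ki_sglt1, self.ki_sglt2) <= 0:
            raise ValueError("Ki values must be positive")
        if self.peff <= 0:
            raise ValueError("peff must be positive")
        if self.solubility_unit not in ("mg/mL", "mg/L"):
            raise ValueError(f"unknown solubility unit {self.solubility_unit!r}")

    # -- unit-normalised views (internal basis: mg, L, h) -------------

    @property
    def solubility_mg_per_ml(self) -> float:
        if self.solubility_unit == "mg/mL":
            return self.solubility
        return self.solubility / 1000.0

    @property
    def peff_cm_per_h(self) -> float:
        """Effective permeability in cm/h (input is 1e-4 cm/s)."""
        return self.peff * 1e-4 * 3600.0

    def cl_hepatic_plasma(self, body_weight_kg: float) -> float:
        """Hepatic plasma clearance, L/h (tabulated per kg of body weight)."""
        return self.cl_hepatic * body_weight_kg

    def cl_total_plasma(self, body_weight_kg: float) -> float:
        """Total plasma clearance, L/h."""
        return self.cl_total * body_weight_kg

    def ng_per_ml_to_nm(self, conc_ng_ml: float) -> float:
        """Convert a concentration in ng/mL (= ug/L) to nmol/L."""
        return conc_ng_ml / self.molecular_weight * 1000.0


@dataclass(frozen=True)
class DoseRegimen:
    """Oral dosing schedule."""

    dose_mg: float
    n_doses: int = 1
    interval_h: float = 24.0
    body_weight_kg: float = 70.0
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be non-negative (0 = null simulation)")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.n_doses > 1 and self.interval_h <= 0:
            raise ValueError("interval_h must be positive for multiple dosing")
        if self.route != "oral":
            raise ValueError("only oral dosing is modelled")


@dataclass(frozen=True)
class ObservedPK:
    """Observed non-compartmental parameters for one dose level."""

    compound: str
    dose_mg: float
    auc: float  # ng·h/mL
    cmax: float  # ng/mL
    tmax: float  # h
    population_tag: str = ""

    def __post_init__(self) -> None:
        if min(self.auc, self.cmax, self.tmax) <= 0:
            raise ValueError("observed PK parameters must be positive")


def _data_path(name: str):
    return resources.files("sgltpbpk.data").joinpath(name)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p)


def load_compound(name: str) -> CompoundRecord:
    """Load one gliflozin's parameter record from the packaged table."""
    key = name.strip().lower()
    if key not in COMPOUNDS:
        raise KeyError(
            f"unknown compound {name!r}; available: {', '.join(COMPOUNDS)}"
        )
    df = _read_csv("compounds.csv").set_index("name")
    row = df.loc[key]
    return CompoundRecord(
        name=key,
        molecular_weight=float(row.molecular_weight),
        log_p=float(row.log_p),
        solubility=float(row.solubility),
        solubility_unit=str(row.solubility_unit),
        peff=float(row.peff),
        fup=float(row.fup),
        rbp=float(row.rbp),
        cl_total=float(row.cl_total),
        cl_hepatic=float(row.cl_hepatic),
        ki_sglt1=float(row.ki_sglt1),
        ki_sglt2=float(row.ki_sglt2),
    )


def load_observed_pk(compound: str) -> list[ObservedPK]:
    """All observed dose levels for one compound, in file order."""
    key = compound.strip().lower()
    if key not in COMPOUNDS:
        raise KeyError(
            f"unknown compound {compound!r}; available: {', '.join(COMPOUNDS)}"
        )
    df = _read_csv("observed_pk.csv")
    rows = df[df["compound"] == key]
    return [
        ObservedPK(
            compound=key,
            dose_mg=float(r.dose_mg),
            auc=float(r.auc),
            cmax=float(r.cmax),
            tmax=float(r.tmax),
            population_tag=str(r.population_tag),
        )
        for r in rows.itertuples()
    ]


def load_inhibition_max() -> pd.DataFrame:
    """Published maximum SGLT1 inhibition ratios (%) per site and dose."""
    return _read_csv("inhibition_max.csv").set_index("site")


def with_overrides(compound: CompoundRecord, **overrides) -> CompoundRecord:
    """Return a copy of ``compound`` with selected fields replaced."""
    return replace(compound, **overrides)
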