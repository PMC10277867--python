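"""Virtual-subject physiology: tissue volumes, blood flows, GFR, GI and
proximal-tubule geometry, and parametric virtual-population sampling.

The reference subject is a 70 kg adult whose tissue volumes and regional
blood flows are pinned in ``data/physiology.csv`` (a standard compilation of
human physiology; regional flows balance cardiac output exactly).  Virtual
populations are sampled parametrically: body weight and height are truncated
normals, GFR is log-normal around the 127 mL/min/1.73 m2 adult mean, and
volumes/flows scale allometrically with body weight (exponent 1 for volumes,
0.75 for flows).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SubjectPhysiology",
    "PopulationSpec",
    "reference_subject",
    "sample_population",
    "GI_COMPARTMENTS",
    "SMALL_INTESTINE",
]

GI_COMPARTMENTS = (
    "stomach",
    "duodenum",
    "jejunum1",
    "jejunum2",
    "ileum1",
    "ileum2",
    "ileum3",
    "caecum",
    "ascending_colon",
)
SMALL_INTESTINE = GI_COMPARTMENTS[1:7]
COLON = GI_COMPARTMENTS[7:]

#: tissues drained directly into the venous pool
DIRECT_TO_VENOUS = (
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "rest",
    "kidney",
    "reproductive",
)
#: tissues drained into the portal vein (reach the liver first)
PORTAL_TISSUES = ("spleen", "gut_tissue")

REFERENCE_GFR = 127.0  # mL/min per 1.73 m2, healthy 20-50 y mean
REFERENCE_BSA = 1.73  # m2
REFERENCE_WEIGHT = 70.0  # kg


@dataclass(frozen=True)
class SubjectPhysiology:
    """One virtual subject.

    ``tissue_volumes`` (L) and ``blood_flows`` (L/h, whole blood) cover the
    14 circulatory compartments; ``gi_geometry`` holds per-compartment
    luminal volume (mL), radius (cm) and the small-intestine transit
    fractions; ``tubule_flow_fractions`` give luminal fluid flow entering
    S1/S2/S3 as fractions of GFR.
    """

    body_weight: float  # kg
    body_surface_area: float  # m2
    tissue_volumes: dict[str, float]
    blood_flows: dict[str, float]
    gfr: float  # mL/min per 1.73 m2
    plasma_glucose: float = 5.0  # mmol/L
    gi_geometry: pd.DataFrame | None = None
    tubule_flow_fractions: tuple[float, float, float] = (1.0, 0.6, 0.4)

    def __post_init__(self) -> None:
        if self.body_weight <= 0 or self.gfr <= 0:
            raise ValueError("body weight and GFR must be positive")
        for name, v in self.tissue_volumes.items():
            if v <= 0:
                raise ValueError(f"non-positive volume for {name}")
        for name, q in self.blood_flows.items():
            if q <= 0:
                raise ValueError(f"non-positive flow for {name}")
        f = self.tubule_flow_fractions
        if not (f[0] >= f[1] >= f[2] > 0):
            raise ValueError("tubule flows must decrease S1 -> S3")
        resid = self.venous_balance_residual()
        if abs(resid) > 1e-6:
            raise ValueError(f"venous return does not balance cardiac output ({resid:.2e})")

    # -- derived quantities --------------------------------------------

    @property
    def cardiac_output(self) -> float:
        """Cardiac blood output, L/h (lung flow)."""
        return self.blood_flows["lung"]

    @property
    def hepatic_vein_flow(self) -> float:
        """QH = hepatic artery + portal inflow, L/h."""
        return (
            self.blood_flows["liver"]
            + sum(self.blood_flows[t] for t in PORTAL_TISSUES)
        )

    def venous_balance_residual(self) -> float:
        """Relative imbalance between venous return and cardiac output."""
        venous_in = (
            sum(self.blood_flows[t] for t in DIRECT_TO_VENOUS)
            + self.hepatic_vein_flow
        )
        return (venous_in - self.cardiac_output) / self.cardiac_output

    @property
    def gfr_volumetric(self) -> float:
        """Glomerular filtration rate as a volumetric flow, L/h."""
        return self.gfr * (self.body_surface_area / REFERENCE_BSA) * 60.0 / 1000.0

    def tubule_flows(self) -> tuple[float, float, float]:
        """Luminal fluid flow entering S1, S2, S3 (L/h)."""
        g = self.gfr_volumetric
        return tuple(f * g for f in self.tubule_flow_fractions)

    def scaled(self, weight: float, gfr: float | None = None) -> "SubjectPhysiology":
        """Allometric rescale to a new body weight (volumes ~ W, flows ~ W^0.75)."""
        w = weight / self.body_weight
        return replace(
            self,
            body_weight=weight,
            body_surface_area=self.body_surface_area * w**0.5,
            tissue_volumes={k: v * w for k, v in self.tissue_volumes.items()},
            blood_flows={k: q * w**0.75 for k, q in self.blood_flows.items()},
            gfr=self.gfr if gfr is None else gfr,
        )


def _load_physiology_table() -> pd.DataFrame:
    with resources.as_file(
        resources.files("sgltpbpk.data").joinpath("physiology.csv")
    ) as p:
        return pd.read_csv(p).set_index("tissue")


def _load_gut_geometry() -> pd.DataFrame:
    with resources.as_file(
        resources.files("sgltpbpk.data").joinpath("gut_geometry.csv")
    ) as p:
        return pd.read_csv(p).set_index("compartment")


def reference_subject(
    gfr: float = REFERENCE_GFR, plasma_glucose: float = 5.0
) -> SubjectPhysiology:
    """The pinned 70 kg reference adult."""
    tab = _load_physiology_table()
    return SubjectPhysiology(
        body_weight=REFERENCE_WEIGHT,
        body_surface_area=REFERENCE_BSA,
        tissue_volumes=tab["volume_l"].to_dict(),
        blood_flows=tab["blood_flow_l_h"].to_dict(),
        gfr=gfr,
        plasma_glucose=plasma_glucose,
        gi_geometry=_load_gut_geometry(),
    )


@dataclass(frozen=True)
class PopulationSpec:
    """Parametric virtual-population description."""

    n_subjects: int = 100
    weight_mean: float = 70.0
    weight_sd: float = 10.0
    height_mean: float = 170.0
    height_sd: float = 8.0
    gfr_cv: float = 0.2
    sex_fraction_male: float = 0.5
    age_range: tuple[float, float] = (20.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.weight_sd, self.height_sd, self.gfr_cv) < 0:
            raise ValueError("spread parameters must be non-negative")


def _truncated_normal(rng, mean, sd, n, n_sigma=3.0):
    if sd == 0:
        return np.full(n, mean)
    x = rng.normal(mean, sd, size=n)
    lo, hi = mean - n_sigma * sd, mean + n_sigma * sd
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def sample_population(spec: PopulationSpec) -> list[SubjectPhysiology]:
    """Sample a deterministic (seeded) list of virtual subjects."""
    rng = np.random.default_rng(spec.seed)
    base = reference_subject()
    weights = _truncated_normal(rng, spec.weight_mean, spec.weight_sd, spec.n_subjects)
    weights = np.clip(weights, 30.0, None)
    # height currently only informs BSA via the weight scaling; sampled for
    # completeness and reproducibility of the stream layout
    _heights = _truncated_normal(rng, spec.height_mean, spec.height_sd, spec.n_subjects)
    if spec.gfr_cv > 0:
        sigma = np.sqrt(np.log(1.0 + spec.gfr_cv**2))
        gfrs = REFERENCE_GFR * np.exp(
            rng.normal(0.0, sigma, size=spec.n_subjects) - sigma**2 / 2.0
        )
    else:
        gfrs = np.full(spec.n_subjects, REFERENCE_GFR)
    return [base.scaled(w, gfr=g) for w, g in zip(weights, gfrs)]
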