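"""Whole-body PBPK model: 14 perfusion-limited circulatory compartments
coupled to the nine-compartment ACAT gut and the filtration-only kidney.

Conventions
-----------
All concentrations are plasma-referenced (mg/L internally, reported as
ng/mL); regional flows are whole-blood flows from the physiology table and
enter the transport equations as effective plasma-equivalent flows
Q_eff = Q_blood x Rbp (whole-blood drug concentration = Rbp x plasma
concentration under instantaneous red-cell equilibration).  For each
perfusion-limited tissue the exiting plasma concentration is Ct/Kp_t, so

    Vt dCt/dt = Q_eff (C_arterial - Ct / Kp_t).

The lung sits between the venous and arterial pools; the liver receives
the hepatic artery plus the portal stream (spleen and gut-wall venous
outflow and the absorbed oral dose after gut first-pass extraction).
Hepatic elimination is a linear clearance on the liver-exit plasma
concentration, capped at the hepatic plasma flow; renal elimination is
filtration only, GFR x fup on the kidney-entry (arterial) concentration,
routed through the proximal-tubule submodel into the urine accumulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .absorption import AbsorptionSettings, default_asf
from .compounds import CompoundRecord, DoseRegimen
from .nca import PKSummary, nca
from .partition import PartitionSet, compute_kp
from .physiology import (
    DIRECT_TO_VENOUS,
    GI_COMPARTMENTS,
    PORTAL_TISSUES,
    SubjectPhysiology,
    reference_subject,
)
from .renal import GlucoseTransportParams

__all__ = ["SolverSettings", "PBPKModel", "SimulationResult"]

TISSUES = (
    "lung",
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "rest",
    "spleen",
    "gut_tissue",
    "liver",
    "kidney",
    "reproductive",
)

N_GI = len(GI_COMPARTMENTS)
# state layout
I_UND = slice(0, N_GI)
I_DIS = slice(N_GI, 2 * N_GI)
I_FECAL = 2 * N_GI
I_GUTEX = 2 * N_GI + 1
I_PORTAL = 2 * N_GI + 2
I_TIS = slice(2 * N_GI + 3, 2 * N_GI + 3 + len(TISSUES))
I_ART = I_TIS.stop
I_VEN = I_ART + 1
I_URINE = I_VEN + 1
I_HEP = I_URINE + 1
N_STATE = I_HEP + 1


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    grid_step_h: float = 0.05
    t_end_h: float = 72.0

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be positive")
        if self.grid_step_h <= 0 or self.t_end_h <= 0:
            raise ValueError("output grid must be positive and increasing")


class PBPKModel:
    """A gliflozin PBPK model for one compound, subject and regimen.

    Parameters
    ----------
    compound : CompoundRecord
    regimen : DoseRegimen
    subject : SubjectPhysiology, optional (reference 70 kg adult)
    partition : PartitionSet, optional (Rodgers-single from the compound)
    absorption : AbsorptionSettings, optional (geometric ASF defaults)
    glucose : GlucoseTransportParams, optional
    solver : SolverSettings, optional
    """

    def __init__(
        self,
        compound: CompoundRecord,
        regimen: DoseRegimen,
        subject: SubjectPhysiology | None = None,
        partition: PartitionSet | None = None,
        absorption: AbsorptionSettings | None = None,
        glucose: GlucoseTransportParams | None = None,
        solver: SolverSettings | None = None,
    ) -> None:
        self.compound = compound
        self.regimen = regimen
        self.subject = subject if subject is not None else reference_subject()
        if abs(self.subject.venous_balance_residual()) > 1e-9:
            raise ValueError("subject flow imbalance")
        self.partition = (
            partition if partition is not None else compute_kp(compound, self.subject)
        )
        self.absorption = (
            absorption if absorption is not None else default_asf(compound, self.subject)
        )
        self.glucose = glucose if glucose is not None else GlucoseTransportParams()
        self.solver = solver if solver is not None else SolverSettings()

    # -- assembly -------------------------------------------------------

    def build_ode(self):
        """Return (rhs, constants) for the full state vector."""
        c = self.compound
        s = self.subject
        kp = self.partition.kp
        ab = self.absorption

        geom = s.gi_geometry
        vol_ml = geom["luminal_volume_ml"].to_numpy(dtype=float)
        times = ab.transit_times(s)
        k_transit = np.array([1.0 / times[g] for g in GI_COMPARTMENTS])
        ka = ab.absorption_rate_constants(c, s)
        ka_arr = np.array([ka.get(g, 0.0) for g in GI_COMPARTMENTS])
        sol_mg_ml = c.solubility_mg_per_ml
        kd = ab.dissolution_rate_coefficient
        g_ex = ab.fraction_gut_extracted

        rbp = c.rbp
        q_eff = {t: s.blood_flows[t] * rbp for t in TISSUES}
        co_eff = s.cardiac_output * rbp
        qh_eff = s.hepatic_vein_flow * rbp
        v_t = np.array([s.tissue_volumes[t] for t in TISSUES])
        kp_t = np.array([kp[t] for t in TISSUES])
        q_t = np.array([q_eff[t] for t in TISSUES])
        v_art = s.tissue_volumes["arterial"] * rbp
        v_ven = s.tissue_volumes["venous"] * rbp

        i_liver = TISSUES.index("liver")
        i_kidney = TISSUES.index("kidney")
        i_lung = TISSUES.index("lung")
        idx_direct = np.array([TISSUES.index(t) for t in DIRECT_TO_VENOUS])
        idx_portal = np.array([TISSUES.index(t) for t in PORTAL_TISSUES])

        cl_h = min(c.cl_hepatic_plasma(self.regimen.body_weight_kg), qh_eff)
        cl_r = s.gfr_volumetric * c.fup

        def rhs(t, y):
            dy = np.zeros(N_STATE)
            und = y[I_UND]
            dis = y[I_DIS]
            # dissolution (signed: supersaturated segments re-precipitate)
            diss = kd * und * (sol_mg_ml - dis / vol_ml)
            absorb = ka_arr * dis
            out_und = k_transit * und
            out_dis = k_transit * dis
            dy[I_UND] = -out_und - diss
            dy[I_DIS] = -out_dis + diss - absorb
            dy[I_UND.start + 1 : I_UND.stop] += out_und[:-1]
            dy[I_DIS.start + 1 : I_DIS.stop] += out_dis[:-1]
            dy[I_FECAL] = out_und[-1] + out_dis[-1]
            total_abs = absorb.sum()
            dy[I_GUTEX] = g_ex * total_abs
            portal_in = (1.0 - g_ex) * total_abs
            dy[I_PORTAL] = portal_in

            ct = y[I_TIS]
            ca = y[I_ART]
            cv = y[I_VEN]
            c_exit = ct / kp_t
            dct = q_t * (ca - c_exit) / v_t
            # lung is perfused by the whole cardiac output from the venous pool
            dct[i_lung] = co_eff * (cv - c_exit[i_lung]) / v_t[i_lung]
            # liver: hepatic artery + portal tissues + oral absorption
            liver_in = (
                q_t[i_liver] * ca
                + (q_t[idx_portal] * c_exit[idx_portal]).sum()
                + portal_in
            )
            liver_out = (qh_eff + cl_h) * c_exit[i_liver]
            dct[i_liver] = (liver_in - liver_out) / v_t[i_liver]
            # kidney: perfusion + filtration from the arterial inflow
            dct[i_kidney] = (
                q_t[i_kidney] * (ca - c_exit[i_kidney]) - cl_r * ca
            ) / v_t[i_kidney]

            dy[I_TIS] = dct
            dy[I_ART] = co_eff * (c_exit[i_lung] - ca) / v_art
            dy[I_VEN] = (
                (q_t[idx_direct] * c_exit[idx_direct]).sum()
                + qh_eff * c_exit[i_liver]
                - co_eff * cv
            ) / v_ven
            dy[I_URINE] = cl_r * ca
            dy[I_HEP] = cl_h * c_exit[i_liver]
            return dy

        constants = {
            "cl_hepatic_plasma": cl_h,
            "cl_renal_plasma": cl_r,
            "qh_eff": qh_eff,
            "vol_ml": vol_ml,
            "v_tissue": dict(zip(TISSUES, v_t)),
            "v_art_eff": v_art,
            "v_ven_eff": v_ven,
        }
        return rhs, constants

    # -- integration ----------------------------------------------------

    def simulate(
        self,
        iv_bolus: bool = False,
        t_end_h: float | None = None,
    ) -> "SimulationResult":
        """Integrate the model over the requested output grid.

        ``iv_bolus`` places each dose directly in the venous pool instead of
        the stomach (used for analytic reductions and oracle checks).
        """
        rhs, constants = self.build_ode()
        reg = self.regimen
        sol = self.solver
        t_end = sol.t_end_h if t_end_h is None else t_end_h
        dose_times = [k * reg.interval_h for k in range(reg.n_doses)]
        horizon = dose_times[-1] + t_end
        grid = np.arange(0.0, horizon + sol.grid_step_h / 2, sol.grid_step_h)

        y0 = np.zeros(N_STATE)
        ts: list[np.ndarray] = []
        ys: list[np.ndarray] = []
        segments = list(zip(dose_times, dose_times[1:] + [horizon]))
        y = y0
        for t0, t1 in segments:
            y = y.copy()
            if iv_bolus:
                y[I_VEN] += reg.dose_mg / constants["v_ven_eff"]
            else:
                y[I_UND.start] += reg.dose_mg
            t_eval = grid[(grid >= t0) & (grid <= t1)]
            if len(t_eval) == 0 or t_eval[0] > t0:
                t_eval = np.concatenate([[t0], t_eval])
            res = solve_ivp(
                rhs,
                (t0, t1),
                y,
                method="LSODA",
                t_eval=t_eval,
                rtol=sol.rtol,
                atol=sol.atol,
                max_step=sol.max_step,
            )
            if not res.success:
                raise RuntimeError(
                    f"ODE solver failed at t={res.t[-1]:.3f} h "
                    f"(|y|={np.linalg.norm(res.y[:, -1]):.3e}): {res.message}"
                )
            ts.append(res.t)
            ys.append(res.y)
            y = res.y[:, -1]
        # drop duplicated segment-boundary points
        t_all = np.concatenate(ts)
        y_all = np.concatenate(ys, axis=1)
        keep = np.concatenate([[True], np.diff(t_all) > 0])
        return SimulationResult(
            model=self,
            time=t_all[keep],
            state=y_all[:, keep],
            constants=constants,
        )

    def fit(self, observed, free_parameters, **kwargs):
        """Least-squares calibration; see :func:`sgltpbpk.calibrate.fit_parameters`."""
        from .calibrate import FitSpec, fit_parameters

        spec = observed if isinstance(observed, FitSpec) else FitSpec(
            observed=observed, free_parameters=free_parameters, **kwargs
        )
        return fit_parameters(self, spec)

    def replace(self, **kwargs) -> "PBPKModel":
        """A copy of the model with selected components replaced."""
        return PBPKModel(
            compound=kwargs.get("compound", self.compound),
            regimen=kwargs.get("regimen", self.regimen),
            subject=kwargs.get("subject", self.subject),
            partition=kwargs.get("partition", None if "compound" in kwargs else self.partition),
            absorption=kwargs.get("absorption", self.absorption),
            glucose=kwargs.get("glucose", self.glucose),
            solver=kwargs.get("solver", self.solver),
        )


class SimulationResult:
    """Trajectories plus derived quantities from one PBPK simulation."""

    def __init__(self, model: PBPKModel, time: np.ndarray, state: np.ndarray, constants: dict):
        self.model = model
        self.compound = model.compound
        self.subject = model.subject
        self.regimen = model.regimen
        self.time = time
        self.state = state
        self.constants = constants

    # -- basic views ----------------------------------------------------

    @property
    def dose_mg(self) -> float:
        return self.regimen.dose_mg

    @property
    def total_dose_mg(self) -> float:
        return self.regimen.dose_mg * self.regimen.n_doses

    @property
    def plasma_conc(self) -> np.ndarray:
        """Venous plasma concentration, ng/mL (solver round-off clipped)."""
        return np.maximum(self.state[I_VEN] * 1000.0, 0.0)

    @property
    def arterial_conc(self) -> np.ndarray:
        """Arterial plasma concentration, ng/mL."""
        return np.maximum(self.state[I_ART] * 1000.0, 0.0)

    @property
    def tissue(self) -> dict[str, np.ndarray]:
        """Total tissue concentrations, mg/L."""
        block = self.state[I_TIS]
        return {t: block[i] for i, t in enumerate(TISSUES)}

    @property
    def cumulative_urinary_mg(self) -> np.ndarray:
        return self.state[I_URINE]

    @property
    def cumulative_hepatic_mg(self) -> np.ndarray:
        return self.state[I_HEP]

    @property
    def cumulative_gut_extracted_mg(self) -> np.ndarray:
        return self.state[I_GUTEX]

    @property
    def cumulative_portal_mg(self) -> np.ndarray:
        return self.state[I_PORTAL]

    @property
    def cumulative_fecal_mg(self) -> np.ndarray:
        return self.state[I_FECAL]

    @property
    def cumulative_absorbed_mg(self) -> np.ndarray:
        """Drug removed from the lumen across the gut wall (pre first-pass)."""
        return self.state[I_PORTAL] + self.state[I_GUTEX]

    def gut_amounts(self, compartment: str, basis: str = "total") -> np.ndarray:
        i = GI_COMPARTMENTS.index(compartment)
        if basis == "total":
            amt = self.state[I_UND][i] + self.state[I_DIS][i]
        elif basis == "dissolved":
            amt = self.state[I_DIS][i]
        elif basis == "undissolved":
            amt = self.state[I_UND][i]
        else:
            raise ValueError(f"unknown basis {basis!r}")
        return np.maximum(amt, 0.0)

    def gut_luminal_conc(self, compartment: str, basis: str = "total") -> np.ndarray:
        """Luminal concentration (mg/L) in one GI compartment."""
        i = GI_COMPARTMENTS.index(compartment)
        v_l = self.constants["vol_ml"][i] / 1000.0
        return self.gut_amounts(compartment, basis) / v_l

    # -- kidney views ---------------------------------------------------

    @property
    def tubule_drug_conc(self) -> np.ndarray:
        """Luminal drug concentration in S1/S2/S3, ng/mL, shape (3, n)."""
        from .renal import tubule_concentrations

        return tubule_concentrations(self.arterial_conc, self.compound, self.subject)

    def s3_glucose_conc(self, glucose: GlucoseTransportParams | None = None) -> np.ndarray:
        """Glucose concentration entering S3 (mmol/L) along the time grid,
        with SGLT2 in S1/S2 inhibited by the simulated filtrate drug."""
        g = glucose if glucose is not None else self.model.glucose
        flux_in, _, _ = self._glucose_cascade(g)
        flows = np.asarray(self.subject.tubule_flows())
        return flux_in[2] / flows[2]

    def _glucose_cascade(self, g: GlucoseTransportParams):
        # SGLT2 (S1/S2) sees the kidney-tissue drug exposure, SGLT1 (S3)
        # the free filtrate concentration -- same conventions as the
        # inhibition-ratio sites (see methods note).
        c = self.compound
        drug_nm = c.ng_per_ml_to_nm(self.tubule_drug_conc)  # (3, n)
        kidney_nm = c.ng_per_ml_to_nm(
            np.maximum(self.tissue["kidney"], 0.0) * 1000.0
        )
        drug_nm = np.vstack([kidney_nm, kidney_nm, drug_nm[2]])
        flows = np.asarray(self.subject.tubule_flows())
        vmax = np.array(
            [g.vmax_sglt2 * g.s1_fraction, g.vmax_sglt2 * (1 - g.s1_fraction), g.vmax_sglt1]
        )
        km = np.array([g.km_sglt2, g.km_sglt2, g.km_sglt1])
        ki = np.array([c.ki_sglt2, c.ki_sglt2, c.ki_sglt1])
        n = len(self.time)
        flux_in = np.empty((3, n))
        reabs = np.empty((3, n))
        flux = np.full(n, self.subject.gfr_volumetric * self.subject.plasma_glucose)
        for i in range(3):
            flux_in[i] = flux
            s_conc = flux / flows[i]
            rate = vmax[i] * s_conc / (km[i] * (1.0 + drug_nm[i] / ki[i]) + s_conc)
            reabs[i] = np.minimum(rate, flux)
            flux = flux - reabs[i]
        return flux_in, reabs, flux

    def uge_rate(self, glucose: GlucoseTransportParams | None = None) -> np.ndarray:
        """Urinary glucose excretion rate, mmol/h, along the time grid."""
        g = glucose if glucose is not None else self.model.glucose
        return self._glucose_cascade(g)[2]

    # -- balances and summaries ----------------------------------------

    def mass_balance_residual(self) -> float:
        """Max |dose - (lumen + body + eliminated)| / dose over the grid."""
        lumen = self.state[I_UND].sum(axis=0) + self.state[I_DIS].sum(axis=0)
        v_t = np.array([self.constants["v_tissue"][t] for t in TISSUES])
        body = (self.state[I_TIS] * v_t[:, None]).sum(axis=0)
        body += self.state[I_ART] * self.constants["v_art_eff"]
        body += self.state[I_VEN] * self.constants["v_ven_eff"]
        eliminated = (
            self.state[I_URINE]
            + self.state[I_HEP]
            + self.state[I_GUTEX]
            + self.state[I_FECAL]
        )
        dosed = np.array(
            [
                self.regimen.dose_mg
                * (1 + np.floor(t / self.regimen.interval_h + 1e-12))
                if self.regimen.n_doses > 1
                else self.regimen.dose_mg
                for t in self.time
            ]
        )
        dosed = np.minimum(dosed, self.total_dose_mg)
        scale = self.total_dose_mg if self.total_dose_mg > 0 else 1.0
        resid = np.abs(dosed - lumen - body - eliminated) / scale
        return float(resid.max())

    def pk_summary(self) -> PKSummary:
        return nca(self.time, self.plasma_conc)

    def urinary_fraction(self) -> float:
        """Cumulative urinary excretion over drug reaching the circulation."""
        portal = float(self.cumulative_portal_mg[-1])
        if portal == 0:
            return 0.0
        return float(self.cumulative_urinary_mg[-1]) / portal

    def window(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.time >= t0) & (self.time <= t1)
        return self.time[m], self.plasma_conc[m]

    def plasma_at(self, t: float) -> float:
        """Interpolated plasma concentration (ng/mL) at time t (h)."""
        return float(np.interp(t, self.time, self.plasma_conc))

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, variable, value) export."""
        frames = [
            pd.DataFrame(
                {"time_h": self.time, "variable": "plasma_ng_ml", "value": self.plasma_conc}
            )
        ]
        for t, cvec in self.tissue.items():
            frames.append(
                pd.DataFrame({"time_h": self.time, "variable": f"tissue_{t}_mg_l", "value": cvec})
            )
        for g in GI_COMPARTMENTS:
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": self.time,
                        "variable": f"gut_{g}_mg_l",
                        "value": self.gut_luminal_conc(g),
                    }
                )
            )
        frames.append(
            pd.DataFrame(
                {
                    "time_h": self.time,
                    "variable": "cumulative_urine_mg",
                    "value": self.cumulative_urinary_mg,
                }
            )
        )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> dict[str, Any]:
        pk = self.pk_summary()
        return {
            "compound": self.compound.name,
            "dose_mg": self.dose_mg,
            "n_doses": self.regimen.n_doses,
            "auc_0_t_ng_h_ml": pk.auc_0_t,
            "auc_0_inf_ng_h_ml": pk.auc_0_inf,
            "cmax_ng_ml": pk.cmax,
            "tmax_h": pk.tmax,
            "urinary_fraction_of_absorbed": self.urinary_fraction(),
            "cumulative_urine_mg": float(self.cumulative_urinary_mg[-1]),
            "mass_balance_residual": self.mass_balance_residual(),
        }
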