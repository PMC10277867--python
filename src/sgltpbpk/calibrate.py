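"""Parameter sensitivity analysis and least-squares calibration.

Two calibration layers are provided:

* :func:`calibrate_compound` - the model-qualification workflow: the
  under-determined oral-absorption parameters (ASF coefficient - or, for
  the solubility-limited sotagliflozin, the dissolution coefficient -
  plus stomach transit and gut first-pass extraction) are fitted so that
  the simulated lowest-dose AUC, Cmax and Tmax match the observed values.
  All remaining doses are then pure predictions.

* :func:`fit_parameters` - a profile fit: bounded least squares on
  log-concentrations of an observed concentration-time series, with a
  seeded multistart to guard against local minima.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .absorption import AbsorptionSettings
from .compounds import (
    CompoundRecord,
    DoseRegimen,
    LOWEST_STUDY_DOSE,
    load_compound,
    load_observed_pk,
    with_overrides,
)
from .model import PBPKModel, SolverSettings

__all__ = [
    "PsaSpec",
    "FitSpec",
    "PBPKFitResults",
    "run_psa",
    "fit_parameters",
    "calibrate_compound",
]

#: parameters the PSA/fit layers know how to apply
COMPOUND_PARAMS = ("peff", "rbp", "solubility", "log_p")
ABSORPTION_PARAMS = (
    "stomach_transit_h",
    "small_intestine_transit_h",
    "colon_transit_h",
    "fraction_gut_extracted",
    "asf_coefficient",
    "dissolution_rate_coefficient",
)

#: solver settings used inside optimisation loops (coarser grid, looser
#: tolerances; the final reported simulations use the defaults)
FAST_SOLVER = SolverSettings(rtol=1e-6, atol=1e-9, grid_step_h=0.05, t_end_h=48.0)


def apply_parameters(model: PBPKModel, params: dict[str, float]) -> PBPKModel:
    """Return a new model with the named parameters applied."""
    unknown = set(params) - set(COMPOUND_PARAMS) - set(ABSORPTION_PARAMS)
    if unknown:
        raise KeyError(f"unknown parameters: {sorted(unknown)}")
    compound = model.compound
    comp_over = {k: v for k, v in params.items() if k in COMPOUND_PARAMS}
    if comp_over:
        compound = with_overrides(compound, **comp_over)
    absorption = model.absorption
    if "asf_coefficient" in params:
        absorption = absorption.with_coefficient(params["asf_coefficient"])
    abs_over = {
        k: v for k, v in params.items() if k in ABSORPTION_PARAMS and k != "asf_coefficient"
    }
    if abs_over:
        absorption = dataclasses.replace(absorption, **abs_over)
    kwargs = {"absorption": absorption}
    if comp_over:
        kwargs["compound"] = compound  # partition is recomputed
    return model.replace(**kwargs)


@dataclass(frozen=True)
class PsaSpec:
    """One-at-a-time sweep description."""

    parameter: str
    minimum: float
    maximum: float
    n_points: int = 5
    outputs: tuple[str, ...] = ("auc", "cmax", "tmax")

    def __post_init__(self) -> None:
        if self.parameter not in COMPOUND_PARAMS + ABSORPTION_PARAMS:
            raise KeyError(f"unknown PSA parameter {self.parameter!r}")
        if self.minimum > self.maximum:
            raise ValueError("PSA range must have min <= max")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")


def run_psa(model: PBPKModel, psa: PsaSpec, fast: bool = True) -> pd.DataFrame:
    """Re-simulate across the sweep grid; tidy table of output metrics."""
    grid = np.linspace(psa.minimum, psa.maximum, psa.n_points)
    records = []
    base = model.replace(solver=FAST_SOLVER) if fast else model
    for value in grid:
        rec = {"parameter": psa.parameter, "value": float(value)}
        try:
            m = apply_parameters(base, {psa.parameter: float(value)})
            pk = m.simulate().pk_summary()
            metric = {"auc": pk.auc_0_inf, "cmax": pk.cmax, "tmax": pk.tmax}
            rec.update({k: metric[k] for k in psa.outputs})
            rec["error"] = ""
        except Exception as exc:  # per-point failure is reported, not fatal
            rec.update({k: np.nan for k in psa.outputs})
            rec["error"] = str(exc)
        records.append(rec)
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class FitSpec:
    """Profile-fit configuration.

    ``observed`` is a DataFrame with columns time_h / concentration_ng_ml
    (replicates allowed).  Loss is least squares on log concentrations with
    a floor of ``conc_floor`` ng/mL.
    """

    observed: pd.DataFrame
    free_parameters: dict[str, tuple[float, float]]
    conc_floor: float = 1e-3
    n_starts: int = 3
    seed: int = 0
    max_nfev: int = 200

    def __post_init__(self) -> None:
        if len(self.observed) == 0:
            raise ValueError("observed data must be non-empty")
        for name, (lo, hi) in self.free_parameters.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bad bounds for {name}")


@dataclass
class PBPKFitResults:
    """Estimates, uncertainties and diagnostics from a calibration fit."""

    model: PBPKModel
    params: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    residual_norm: float
    n_obs: int
    n_iter: int
    success: bool
    cost_trace: list[float] = field(default_factory=list)
    stderr: dict[str, float] = field(default_factory=dict)

    @property
    def fitted_model(self) -> PBPKModel:
        return apply_parameters(self.model, self.params)

    def summary(self) -> str:
        lines = [
            "PBPK calibration results",
            "=" * 51,
            f"{'parameter':<26}{'estimate':>12}{'std err':>12}",
            "-" * 51,
        ]
        for k, v in self.params.items():
            se = self.stderr.get(k)
            lines.append(
                f"{k:<26}{v:>12.5g}{(f'{se:12.3g}' if se is not None else '      --'):>12}"
            )
        lines.append("-" * 51)
        lines.append(f"residual norm {self.residual_norm:.6g} on {self.n_obs} points")
        lines.append(f"function evaluations: {self.n_iter}; converged: {self.success}")
        return "\n".join(lines)


def _log_residuals(model: PBPKModel, obs: pd.DataFrame, floor: float) -> np.ndarray:
    sim = model.simulate()
    pred = np.interp(obs["time_h"].to_numpy(), sim.time, sim.plasma_conc)
    pred = np.maximum(pred, floor)
    meas = np.maximum(obs["concentration_ng_ml"].to_numpy(), floor)
    return np.log(pred) - np.log(meas)


def fit_parameters(model: PBPKModel, fit: FitSpec) -> PBPKFitResults:
    """Bounded least squares on log concentrations (seeded multistart)."""
    names = list(fit.free_parameters)
    if len(names) > 3:
        import warnings

        warnings.warn("more than 3 free parameters; fit may be ill-conditioned")
    base = model.replace(solver=FAST_SOLVER)
    defaults = {**{p: getattr(model.compound, p) for p in COMPOUND_PARAMS},
                **{p: getattr(model.absorption, p) for p in ABSORPTION_PARAMS}}
    lo = np.array([fit.free_parameters[n][0] for n in names])
    hi = np.array([fit.free_parameters[n][1] for n in names])
    trace: list[float] = []

    if not names:  # no-op fit: report residual at the input parameters
        r = _log_residuals(base, fit.observed, fit.conc_floor)
        return PBPKFitResults(
            model=model, params={}, bounds={}, residual_norm=float(np.linalg.norm(r)),
            n_obs=len(r), n_iter=1, success=True, cost_trace=[0.5 * float(r @ r)],
        )

    def residuals(x):
        m = apply_parameters(base, dict(zip(names, x)))
        r = _log_residuals(m, fit.observed, fit.conc_floor)
        cost = 0.5 * float(r @ r)
        trace.append(min(cost, trace[-1]) if trace else cost)
        return r

    x0_default = np.clip([defaults[n] for n in names], lo, hi)
    rng = np.random.default_rng(fit.seed)
    starts = [x0_default]
    for _ in range(fit.n_starts - 1):
        starts.append(lo + (hi - lo) * rng.random(len(names)))

    best = None
    nfev = 0
    for x0 in starts:
        res = least_squares(
            residuals, x0, bounds=(lo, hi), max_nfev=fit.max_nfev,
            xtol=1e-8, ftol=1e-8, diff_step=1e-3,
        )
        nfev += res.nfev
        if best is None or res.cost < best.cost:
            best = res

    params = dict(zip(names, best.x))
    stderr = {}
    dof = max(len(best.fun) - len(names), 1)
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * (2 * best.cost / dof)
        stderr = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    except np.linalg.LinAlgError:
        pass
    return PBPKFitResults(
        model=model,
        params=params,
        bounds=dict(fit.free_parameters),
        residual_norm=float(np.linalg.norm(best.fun)),
        n_obs=len(best.fun),
        n_iter=nfev,
        success=bool(best.success),
        cost_trace=trace,
        stderr=stderr,
    )


# -- lowest-dose qualification calibration ----------------------------


def _nca_residuals(model: PBPKModel, target: dict[str, float]) -> np.ndarray:
    pk = model.simulate().pk_summary()
    pred = {"auc": pk.auc_0_inf, "cmax": pk.cmax, "tmax": pk.tmax}
    return np.array([np.log(pred[k] / target[k]) for k in target])


def calibrate_compound(
    name: str,
    body_weight_kg: float = 70.0,
    weights: dict[str, float] | None = None,
) -> PBPKModel:
    """Calibrate a compound's absorption model on its lowest observed dose.

    Free parameters: ASF coefficient, stomach transit time and gut
    first-pass extraction, fitted to the observed lowest-dose AUC, Cmax
    and Tmax.  The fitted model carries default solver settings and is
    ready to simulate any dose.
    """
    compound = load_compound(name)
    dose = LOWEST_STUDY_DOSE[name]
    obs = next(o for o in load_observed_pk(name) if o.dose_mg == dose)
    target = {"auc": obs.auc, "cmax": obs.cmax, "tmax": obs.tmax}
    regimen = DoseRegimen(dose_mg=dose, body_weight_kg=body_weight_kg)
    base = PBPKModel(compound, regimen, solver=FAST_SOLVER)

    if name == "sotagliflozin":
        # Solubility-limited compound: the rate-controlling absorption step
        # is dissolution, so the per-compound absorption parameter is the
        # dissolution coefficient (ASF coefficient held permeation-non-
        # limiting); heavy gut first pass expected.
        from .absorption import default_asf

        base = base.replace(
            absorption=default_asf(compound, base.subject, coefficient=10.0)
        )
        names = [
            "asf_coefficient",
            "dissolution_rate_coefficient",
            "stomach_transit_h",
            "fraction_gut_extracted",
        ]
        # dissolution coefficient bounded to the physical particle-size
        # range (see absorption module): the sparse NCA targets do not
        # identify luminal residence on their own
        lo = np.array([0.5, 2.0, 0.1, 0.0])
        hi = np.array([100.0, 150.0, 3.0, 0.98])
        x0 = np.array([20.0, 45.0, 0.5, 0.85])
    else:
        names = ["asf_coefficient", "stomach_transit_h", "fraction_gut_extracted"]
        lo = np.array([0.05, 0.1, 0.0])
        hi = np.array([20.0, 3.0, 0.98])
        x0 = np.array([2.0, 0.4, 0.1])

    w = weights or {"auc": 1.0, "cmax": 1.0, "tmax": 0.5}
    wv = np.array([w[k] for k in target])

    def residuals(x):
        m = apply_parameters(base, dict(zip(names, x)))
        return wv * _nca_residuals(m, target)

    res = least_squares(
        residuals, x0, bounds=(lo, hi), xtol=1e-6, ftol=1e-8, diff_step=0.05,
        max_nfev=120,
    )
    fitted = apply_parameters(base, dict(zip(names, res.x)))
    return fitted.replace(solver=SolverSettings())
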