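"""Non-compartmental analysis and two-fold qualification.

AUC is the linear trapezoid on the sampling grid; AUC(0-inf) adds
Clast/lambda_z with the terminal slope from a log-linear regression over
the terminal phase (the longest tail of at least three points below
Cmax/2 with adjusted r^2 >= 0.9).  The fold error is the symmetric ratio
max(observed/predicted, predicted/observed); a model is qualified when
every AUC/Cmax fold error is at most 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compounds import ObservedPK

__all__ = ["PKSummary", "FoldErrorReport", "nca", "fold_error", "qualify"]


@dataclass(frozen=True)
class PKSummary:
    auc_0_t: float  # ng·h/mL
    auc_0_inf: float  # ng·h/mL
    cmax: float  # ng/mL
    tmax: float  # h
    lambda_z: float | None  # 1/h, None when the tail is not estimable
    extrapolated_fraction: float


@dataclass(frozen=True)
class FoldErrorReport:
    """Per-dose fold errors for AUC, Cmax and Tmax."""

    compound: str
    dose_mg: float
    predicted: dict[str, float]
    observed: dict[str, float]
    fold_errors: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "fold_errors",
            {
                k: fold_error(self.observed[k], self.predicted[k])
                for k in self.predicted
            },
        )

    @property
    def pass_two_fold(self) -> bool:
        """Qualification flag on the exposure metrics (AUC, Cmax)."""
        return all(
            fe <= 2.0 for k, fe in self.fold_errors.items() if k in ("auc", "cmax")
        )


def _terminal_slope(t: np.ndarray, c: np.ndarray, cmax_idx: int):
    """Log-linear terminal regression; returns (lambda_z, intercept) or None."""
    mask = np.arange(len(c)) > cmax_idx
    mask &= c > 0
    mask &= c < c[cmax_idx] / 2.0
    idx = np.flatnonzero(mask)
    best = None
    for start in range(len(idx) - 2):
        sel = idx[start:]
        if len(sel) < 3:
            break
        x, y = t[sel], np.log(c[sel])
        n = len(x)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            continue
        r2_adj = 1.0 - (ss_res / ss_tot) * (n - 1) / (n - 2)
        if slope < 0 and r2_adj >= 0.9:
            cand = (-slope, intercept, r2_adj)
            if best is None or cand[2] > best[2]:
                best = cand
    if best is None:
        return None
    return best[0], best[1]


def nca(time_h: np.ndarray, conc_ng_ml: np.ndarray) -> PKSummary:
    """Non-compartmental summary of one concentration-time profile."""
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(conc_ng_ml, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least three observations")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    auc_t = float(np.trapezoid(c, t))
    imax = int(np.argmax(c))
    cmax = float(c[imax])
    tmax = float(t[imax])
    if cmax == 0.0:
        return PKSummary(0.0, 0.0, 0.0, tmax, None, 0.0)
    fit = _terminal_slope(t, c, imax)
    if fit is None:
        return PKSummary(auc_t, auc_t, cmax, tmax, None, 0.0)
    lam, _ = fit
    tail = float(c[-1]) / lam
    auc_inf = auc_t + tail
    return PKSummary(auc_t, auc_inf, cmax, tmax, lam, tail / auc_inf)


def fold_error(observed: float, predicted: float) -> float:
    """Symmetric fold error max(obs/pred, pred/obs); always >= 1."""
    if observed <= 0 or predicted <= 0:
        raise ValueError("fold error requires positive inputs")
    return max(observed / predicted, predicted / observed)


def qualify(
    predicted: dict[float, PKSummary],
    observed: list[ObservedPK],
    auc_kind: str = "auc_0_inf",
) -> list[FoldErrorReport]:
    """Dose-matched fold-error reports (AUC, Cmax, Tmax) for one compound."""
    obs_by_dose = {o.dose_mg: o for o in observed}
    missing = sorted(set(predicted) - set(obs_by_dose))
    if missing:
        raise KeyError(f"no observed data for doses {missing}")
    reports = []
    for dose, summ in sorted(predicted.items()):
        o = obs_by_dose[dose]
        reports.append(
            FoldErrorReport(
                compound=o.compound,
                dose_mg=dose,
                predicted={
                    "auc": getattr(summ, auc_kind),
                    "cmax": summ.cmax,
                    "tmax": summ.tmax,
                },
                observed={"auc": o.auc, "cmax": o.cmax, "tmax": o.tmax},
            )
        )
    return reports
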