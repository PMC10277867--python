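"""Sensitivity sweeps and least-squares calibration."""

import numpy as np
import pandas as pd
import pytest

from sgltpbpk import DoseRegimen, PBPKModel, PsaSpec, load_compound, run_psa
from sgltpbpk.calibrate import FAST_SOLVER, FitSpec, apply_parameters, fit_parameters


@pytest.fixture(scope="module")
def hena_model():
    return PBPKModel(
        load_compound("henagliflozin"), DoseRegimen(2.5), solver=FAST_SOLVER
    )


def test_psa_peff_monotone_cmax(hena_model):
    table = run_psa(hena_model, PsaSpec("peff", 1.0, 10.0, n_points=4, outputs=("cmax",)))
    assert (table["error"] == "").all()
    assert np.all(np.diff(table["cmax"]) >= -1e-9)


def test_psa_stomach_transit_monotone_tmax(hena_model):
    table = run_psa(
        hena_model, PsaSpec("stomach_transit_h", 0.25, 2.0, n_points=4, outputs=("tmax",))
    )
    assert np.all(np.diff(table["tmax"]) >= -1e-9)


def test_psa_degenerate_sweep_identical_rows(hena_model):
    table = run_psa(hena_model, PsaSpec("rbp", 0.55, 0.55, n_points=3))
    assert table["cmax"].nunique() == 1
    assert table["auc"].nunique() == 1


def test_psa_repeatable(hena_model):
    spec = PsaSpec("peff", 2.0, 8.0, n_points=3)
    pd.testing.assert_frame_equal(run_psa(hena_model, spec), run_psa(hena_model, spec))


def test_psa_validation():
    with pytest.raises(KeyError):
        PsaSpec("nonsense", 0, 1)
    with pytest.raises(ValueError):
        PsaSpec("peff", 2.0, 1.0)
    with pytest.raises(ValueError):
        PsaSpec("peff", 1.0, 2.0, n_points=2)


def test_apply_parameters_rejects_unknown(hena_model):
    with pytest.raises(KeyError):
        apply_parameters(hena_model, {"banana": 1.0})


def test_noop_fit_returns_residual(hena_model):
    sim = hena_model.simulate()
    obs = pd.DataFrame(
        {"time_h": [1.0, 2.0, 4.0], "concentration_ng_ml": [sim.plasma_at(t) for t in (1, 2, 4)]}
    )
    res = fit_parameters(hena_model, FitSpec(observed=obs, free_parameters={}))
    assert res.params == {}
    assert res.residual_norm == pytest.approx(0.0, abs=1e-9)


def test_zero_noise_single_parameter_recovery(hena_model):
    """Noise-free data generated at a known permeability: a one-parameter
    fit must recover it to better than 1 %."""
    truth = 4.2
    truth_model = apply_parameters(hena_model, {"peff": truth})
    sim = truth_model.simulate()
    times = np.array([0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 24])
    obs = pd.DataFrame(
        {"time_h": times, "concentration_ng_ml": np.interp(times, sim.time, sim.plasma_conc)}
    )
    res = fit_parameters(
        hena_model,
        FitSpec(observed=obs, free_parameters={"peff": (1.0, 12.0)}, n_starts=2, seed=1),
    )
    assert res.params["peff"] == pytest.approx(truth, rel=0.01)
    assert np.all(np.diff(res.cost_trace) <= 1e-12)  # accepted-loss trace monotone


def test_fit_results_summary_mentions_parameters(hena_model):
    sim = hena_model.simulate()
    times = np.array([1.0, 2.0, 4.0, 8.0])
    obs = pd.DataFrame(
        {"time_h": times, "concentration_ng_ml": np.interp(times, sim.time, sim.plasma_conc)}
    )
    res = fit_parameters(
        hena_model,
        FitSpec(observed=obs, free_parameters={"rbp": (0.3, 1.0)}, n_starts=1, max_nfev=20),
    )
    text = res.summary()
    assert "rbp" in text and "residual norm" in text
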