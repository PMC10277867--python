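"""Compound/fixture loading, unit handling and validation."""

import pandas as pd
import pytest

from sgltpbpk import (
    COMPOUNDS,
    CompoundRecord,
    DoseRegimen,
    load_compound,
    load_inhibition_max,
    load_observed_pk,
)
from sgltpbpk.compounds import _read_csv


@pytest.mark.parametrize(
    "name, field, value",
    [
        ("ertugliflozin", "fup", 0.064),
        ("ertugliflozin", "rbp", 0.66),
        ("ertugliflozin", "ki_sglt2", 0.88),
        ("sotagliflozin", "ki_sglt1", 7.02),
        ("sotagliflozin", "ki_sglt2", 1.41),
        ("henagliflozin", "peff", 6.7),
        ("empagliflozin", "molecular_weight", 450.9),
    ],
)
def test_published_parameters_load(name, field, value):
    assert getattr(load_compound(name), field) == pytest.approx(value)


def test_unknown_compound_lists_available():
    with pytest.raises(KeyError) as err:
        load_compound("dapagliflozin")
    for name in COMPOUNDS:
        assert name in str(err.value)


def test_load_compound_case_insensitive():
    assert load_compound("Ertugliflozin  ").name == "ertugliflozin"


@pytest.mark.parametrize(
    "name, n_rows", [("ertugliflozin", 4), ("empagliflozin", 4), ("henagliflozin", 7), ("sotagliflozin", 2)]
)
def test_observed_pk_row_counts(name, n_rows):
    assert len(load_observed_pk(name)) == n_rows


def test_observed_pk_values():
    hena = {o.dose_mg: o for o in load_observed_pk("henagliflozin")}
    assert hena[2.5].auc == 408
    assert hena[2.5].cmax == 54.8
    assert hena[2.5].tmax == 1.5
    sota = {o.dose_mg: o for o in load_observed_pk("sotagliflozin")}
    assert sota[200].auc == pytest.approx(631.14)
    empa_doses = {o.dose_mg for o in load_observed_pk("empagliflozin")}
    assert empa_doses == {1, 10, 25, 100}


def test_unit_normalisation_is_invertible():
    c = load_compound("ertugliflozin")
    # internal views derive from, and denormalise back to, printed numbers
    assert c.peff_cm_per_h == pytest.approx(4.1 * 1e-4 * 3600)
    assert c.peff == 4.1
    assert c.solubility_mg_per_ml == pytest.approx(0.163)


def test_fixture_files_round_trip(tmp_path):
    for fname in ("compounds.csv", "observed_pk.csv", "inhibition_max.csv"):
        df = _read_csv(fname)
        out = tmp_path / fname
        df.to_csv(out, index=False)
        pd.testing.assert_frame_equal(pd.read_csv(out), df)


def test_inhibition_max_table_shape():
    tab = load_inhibition_max()
    assert list(tab.index) == ["duodenum", "jejunum1", "S3"]
    assert tab.loc["duodenum", "sotagliflozin_400"] == pytest.approx(94.47)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"fup": 0.0},
        {"fup": 1.5},
        {"rbp": -1.0},
        {"cl_hepatic": 0.2},  # exceeds cl_total
        {"ki_sglt2": 0.0},
        {"peff": -1.0},
    ],
)
def test_compound_invariants_rejected(kwargs):
    base = dict(
        name="x", molecular_weight=400.0, log_p=2.0, solubility=0.1,
        peff=1.0, fup=0.1, rbp=0.7, cl_total=0.1, cl_hepatic=0.05,
        ki_sglt1=10.0, ki_sglt2=1.0,
    )
    base.update(kwargs)
    with pytest.raises(ValueError):
        CompoundRecord(**base)


def test_regimen_validation():
    with pytest.raises(ValueError):
        DoseRegimen(-1.0)
    with pytest.raises(ValueError):
        DoseRegimen(10.0, n_doses=0)
    with pytest.raises(ValueError):
        DoseRegimen(10.0, n_doses=2, interval_h=0.0)
    assert DoseRegimen(0.0).dose_mg == 0.0  # null simulation allowed
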