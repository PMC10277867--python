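"""Competitive-inhibition algebra: exact oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from sgltpbpk import (
    AssayCondition,
    DoseRegimen,
    PBPKModel,
    inhibited_rate,
    inhibition_ratio,
    inhibition_timecourse,
    ki_from_ic50,
    load_compound,
    mm_rate,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


def test_mm_rate_half_saturation():
    assert mm_rate(10.0, 2.0, 0.0) == 0.0
    assert mm_rate(10.0, 2.0, 2.0) == pytest.approx(5.0, abs=1e-9)
    assert mm_rate(1.0, 1.0, 100.0) == pytest.approx(0.990099, abs=1e-6)


def test_inhibited_rate_oracles():
    assert inhibited_rate(10.0, 2.0, 5.0, 0.0, 1.0) == mm_rate(10.0, 2.0, 5.0)
    # s = km, i = ki: vmax/3 exactly
    assert inhibited_rate(9.0, 2.0, 2.0, 7.0, 7.0) == pytest.approx(3.0, abs=1e-9)
    assert inhibited_rate(10.0, 2.0, 5.0, 1e12, 1.0) == pytest.approx(0.0, abs=1e-9)


def test_inhibition_ratio_oracles():
    assert inhibition_ratio(2.0, 5.0, 0.0, 1.0) == 0.0
    assert inhibition_ratio(3.0, 3.0, 4.0, 4.0) == pytest.approx(100.0 / 3.0, abs=1e-9)
    # i/ki = 1000, s << km: 1 - 1/1001
    assert inhibition_ratio(1.0, 1e-9, 1000.0, 1.0) == pytest.approx(
        100.0 * (1 - 1 / 1001.0), abs=1e-6
    )


def test_ki_from_ic50_cheng_prusoff():
    assert ki_from_ic50(AssayCondition(10.0, 0.0, 1.0)) == 10.0
    assert ki_from_ic50(AssayCondition(10.0, 2.0, 2.0)) == pytest.approx(5.0)


def test_ki_round_trip_against_root_finding():
    """With Ki from the Cheng-Prusoff relation, the concentration halving
    the competitive rate at the assay substrate level must equal IC50."""
    assay = AssayCondition(ic50=12.0, substrate_conc_assay=3.0, km_assay=0.7)
    ki = ki_from_ic50(assay)
    v0 = mm_rate(1.0, assay.km_assay, assay.substrate_conc_assay)

    def half(i):
        return inhibited_rate(1.0, assay.km_assay, assay.substrate_conc_assay, i, ki) - v0 / 2

    i50 = brentq(half, 1e-9, 1e9, xtol=1e-12, rtol=1e-15)
    assert i50 == pytest.approx(assay.ic50, rel=1e-9)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(km=positive, s=positive, ki=positive, i1=positive, i2=positive)
def test_ratio_monotone_in_inhibitor(km, s, ki, i1, i2):
    lo, hi = sorted((i1, i2))
    assert inhibition_ratio(km, s, hi, ki) >= inhibition_ratio(km, s, lo, ki)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(km=positive, ki=positive, i=positive, s1=positive, s2=positive)
def test_ratio_decreasing_in_substrate(km, ki, i, s1, s2):
    lo, hi = sorted((s1, s2))
    assert inhibition_ratio(km, hi, i, ki) <= inhibition_ratio(km, lo, i, ki)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(km=positive, s=positive, ki=positive, i=positive,
       vmax=st.floats(min_value=1e-3, max_value=1e3))
def test_vmax_cancellation(km, s, ki, i, vmax):
    direct = inhibition_ratio(km, s, i, ki)
    via_rates = 100.0 * (1.0 - inhibited_rate(vmax, km, s, i, ki) / mm_rate(vmax, km, s))
    assert direct == pytest.approx(via_rates, rel=1e-9, abs=1e-9)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(km=positive, s=positive, ki=positive, i=positive)
def test_ratio_bounded(km, s, ki, i):
    r = inhibition_ratio(km, s, i, ki)
    assert 0.0 <= r <= 100.0


def test_zero_dose_profile_flat():
    c = load_compound("sotagliflozin")
    res = PBPKModel(c, DoseRegimen(0.0)).simulate()
    for site in ("duodenum", "jejunum1", "S1S2", "S3"):
        prof = inhibition_timecourse(res, site, c)
        assert prof.max_ratio == 0.0


def test_max_ratio_is_grid_maximum():
    c = load_compound("ertugliflozin")
    res = PBPKModel(c, DoseRegimen(5.0)).simulate()
    prof = inhibition_timecourse(res, "duodenum", c)
    assert prof.max_ratio == np.max(prof.ratio)
    assert prof.time[np.argmax(prof.ratio)] == prof.time_of_max


def test_unknown_site_rejected():
    c = load_compound("ertugliflozin")
    res = PBPKModel(c, DoseRegimen(5.0)).simulate()
    with pytest.raises(KeyError):
        inhibition_timecourse(res, "colon", c)


def test_gut_peak_inside_absorption_phase():
    """Peak intestinal inhibition precedes the plasma Tmax."""
    for name, dose in [("ertugliflozin", 5.0), ("empagliflozin", 10.0)]:
        c = load_compound(name)
        res = PBPKModel(c, DoseRegimen(dose)).simulate()
        prof = inhibition_timecourse(res, "duodenum", c)
        assert prof.time_of_max <= res.pk_summary().tmax
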