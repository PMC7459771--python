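"""MRC derivation: cross-multiplication, cause weighting, uncertainty factor."""

import logging

import pytest
from hypothesis import given, strategies as st

import hqdef as h

# Exact-rational oracle value for the full-precision Mg chain
# 5.66 * (sum_i w_i * HI_soft,i / HI_SR,i / 0.88) * 2 (no display rounding).
FULL_PRECISION_MG_MRC = 16.666832846140668

lv_values = st.floats(min_value=0.01, max_value=1e3, allow_nan=False)
weight_values = st.floats(min_value=0.01, max_value=10, allow_nan=False)


@pytest.mark.parametrize(
    "cw_mean, hi_group, hi_national, expected",
    [
        (21.2, 852.42, 531.05, 34.03),   # Ca, circulatory
        (5.66, 82.65, 45.83, 10.21),     # Mg, digestive
        (7.0, 123.4, 123.4, 7.0),        # group at the national average
    ],
)
def test_cross_multiplied_limit_values(cw_mean, hi_group, hi_national, expected):
    lv = h.limit_value_for_indicator(cw_mean, hi_group, hi_national)
    assert lv == pytest.approx(expected, abs=0.005)


def test_zero_national_indicator_is_an_explicit_error():
    with pytest.raises(h.InvalidParameterError, match="national"):
        h.limit_value_for_indicator(5.0, 100.0, 0.0)


def test_weighted_limit_value_calcium_row(default_weights):
    lvs = {"ReC": 28.15, "ReI": 34.03, "ReJ": 36.84, "ReK": 38.23}
    assert h.weighted_limit_value(lvs, default_weights) == pytest.approx(31.21, abs=0.005)


@given(lvs=st.lists(lv_values, min_size=4, max_size=4),
       ws=st.lists(weight_values, min_size=4, max_size=4))
def test_weighted_limit_value_matches_summation_oracle(lvs, ws):
    """sum(w_i LV_i)/sum(w_i), checked against an explicit loop, and bounded
    by the extreme limit values."""
    keys = list(h.INDICATORS)
    lv_map = dict(zip(keys, lvs))
    w = h.CauseWeights(weights=dict(zip(keys, ws)))
    got = h.weighted_limit_value(lv_map, w)
    num = den = 0.0
    for k in keys:
        num += w.weights[k] * lv_map[k]
        den += w.weights[k]
    assert got == pytest.approx(num / den, rel=1e-12)
    assert min(lvs) - 1e-9 <= got <= max(lvs) + 1e-9


def test_equal_limit_values_are_a_fixed_point(default_weights):
    assert h.weighted_limit_value(
        {k: 3.7 for k in h.INDICATORS}, default_weights) == pytest.approx(3.7)


@pytest.mark.parametrize("lv, uf, expected", [(8.33, 2.0, 16.66),
                                              (31.21, 2.0, 62.42),
                                              (5.0, 1.0, 5.0)])
def test_uncertainty_factor_scales_limit_value(lv, uf, expected):
    assert h.apply_uncertainty_factor(lv, uf) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("uf", [0.5, 0.99, 11.0, -2.0])
def test_uncertainty_factor_outside_permissible_range_rejected(uf):
    with pytest.raises(h.InvalidParameterError):
        h.apply_uncertainty_factor(10.0, uf)


def test_derive_mrc_magnesium_reproduction_mode(soft_hi, national_hi, default_weights):
    """Display rounding (round weighted LV to 2 dp, then x UF) reproduces the
    published Mg row: LV 8.33, MRC 16.66 = 2 x 8.33."""
    rec = h.derive_mrc("Mg", 5.66, soft_hi, national_hi, weights=default_weights,
                       uf=2.0, display_rounding=True)
    assert rec.weighted_lv == 8.33
    assert rec.mrc == pytest.approx(16.66, rel=1e-12)
    assert rec.provenance == "derived"
    assert min(rec.per_indicator_lv.values()) <= rec.weighted_lv <= \
        max(rec.per_indicator_lv.values())


def test_derive_mrc_full_precision_mode(soft_hi, national_hi, default_weights):
    rec = h.derive_mrc("Mg", 5.66, soft_hi, national_hi, weights=default_weights,
                       uf=2.0, display_rounding=False)
    assert rec.mrc == pytest.approx(FULL_PRECISION_MG_MRC, rel=1e-12)


def test_group_at_national_average_needs_twice_cw_under_uf2(national_hi,
                                                            default_weights):
    rec = h.derive_mrc("Mg", 9.3, national_hi, national_hi,
                       weights=default_weights, uf=2.0, display_rounding=False)
    assert rec.mrc == pytest.approx(2 * 9.3, rel=1e-12)


def test_default_weights_log_a_discrepancy_warning(soft_hi, national_hi, caplog):
    """Quoted national mortality shares contradict the table-reproducing
    weights; using the defaults must warn."""
    with caplog.at_level(logging.WARNING, logger="hqdef"):
        h.derive_mrc("Mg", 5.66, soft_hi, national_hi)
    assert any("default cause weights" in r.message for r in caplog.records)


def test_missing_indicator_weight_renormalized_with_warning(caplog):
    lvs = {"ReC": 10.0, "ReI": 20.0, "ReJ": 30.0}  # ReK absent
    with caplog.at_level(logging.WARNING, logger="hqdef"):
        got = h.weighted_limit_value(lvs, h.CauseWeights())
    expected = (0.50 * 10 + 0.25 * 20 + 0.06 * 30) / 0.81
    assert got == pytest.approx(expected, rel=1e-12)
    assert any("renormalized" in r.message for r in caplog.records)
    with pytest.raises(h.InvalidParameterError):
        h.weighted_limit_value({"LE": 70.0}, h.CauseWeights())


def test_mrc_from_standard():
    rec = h.mrc_from_standard("Mg", 20.0)
    assert rec.mrc == 20.0 and rec.provenance == "standard"
    assert rec.per_indicator_lv is None and rec.weighted_lv is None
    assert h.mrc_from_standard("Ca", 30.0).mrc == 30.0
    with pytest.raises(h.InvalidParameterError):
        h.mrc_from_standard("Mg", 0.0)


@given(k=st.lists(st.floats(0.1, 5), min_size=4, max_size=4),
       ws=st.lists(weight_values, min_size=4, max_size=4),
       cw=st.floats(0.1, 100), uf=st.floats(1, 10))
def test_mrc_recovery_from_constructed_indicator_ratios(k, ws, cw, uf,
                                                        national_hi):
    """If group indicators are national * k_i, the derived MRC (full
    precision) is exactly cw * (sum w_i k_i / sum w_i) * uf."""
    nat = national_hi.as_dict()
    group = h.HealthIndicatorSet.from_dict(
        {key: nat[key] * ki for key, ki in zip(h.INDICATORS, k)})
    w = h.CauseWeights(weights=dict(zip(h.INDICATORS, ws)))
    rec = h.derive_mrc("Mg", cw, group, national_hi, weights=w, uf=uf,
                       display_rounding=False)
    expected = cw * sum(wi * ki for wi, ki in zip(ws, k)) / sum(ws) * uf
    assert rec.mrc == pytest.approx(expected, rel=1e-9)


@given(scale=st.floats(0.1, 10))
def test_mrc_scale_equivariance_in_cw(scale, soft_hi, national_hi,
                                      default_weights):
    base = h.derive_mrc("Mg", 5.66, soft_hi, national_hi,
                        weights=default_weights, display_rounding=False)
    scaled = h.derive_mrc("Mg", 5.66 * scale, soft_hi, national_hi,
                          weights=default_weights, display_rounding=False)
    assert scaled.mrc == pytest.approx(scale * base.mrc, rel=1e-9)
    for k in h.INDICATORS:
        assert scaled.per_indicator_lv[k] == pytest.approx(
            scale * base.per_indicator_lv[k], rel=1e-9)


def test_mrc_monotone_in_group_indicators_and_uf(soft_hi, national_hi,
                                                 default_weights):
    base = h.derive_mrc("Mg", 5.66, soft_hi, national_hi,
                        weights=default_weights, display_rounding=False)
    worse = h.HealthIndicatorSet(rec=soft_hi.rec * 1.2, rei=soft_hi.rei,
                                 rej=soft_hi.rej, rek=soft_hi.rek)
    assert h.derive_mrc("Mg", 5.66, worse, national_hi, weights=default_weights,
                        display_rounding=False).mrc > base.mrc
    assert h.derive_mrc("Mg", 5.66, soft_hi, national_hi, weights=default_weights,
                        uf=3.0, display_rounding=False).mrc > base.mrc


def test_full_published_table_reproduction(tables, soft_hi, national_hi,
                                           default_weights):
    """All published per-indicator LVs, weighted LVs and MRCs for Ca, Mg and
    hardness match to +-0.01."""
    for el in h.ELEMENTS:
        cw_mean = tables["concentrations"]["soft"][el]["average"]
        rec = h.derive_mrc(el, cw_mean, soft_hi, national_hi,
                           weights=default_weights, uf=2.0,
                           display_rounding=True)
        for ind in h.INDICATORS:
            assert rec.per_indicator_lv[ind] == pytest.approx(
                tables["mrc"][el][ind], abs=0.01), (el, ind)
        assert rec.weighted_lv == pytest.approx(tables["mrc"][el]["LV"], abs=0.01)
        assert rec.mrc == pytest.approx(tables["mrc"][el]["MRC"], abs=0.01)
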