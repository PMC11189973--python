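"""Deterministic mass-balance model: worked examples and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoextract import (
    SoilCompartment,
    TissueUptake,
    extraction_potential,
    mass_at_time,
    plant_concentration,
    removal_rate,
    run_deterministic,
    soil_mass,
    time_exponential,
    time_linear,
    translocation_factor,
)
from phytoextract.core import stem_from_root

SC = SoilCompartment(c_soil_i=10.0, c_soil_f=1.0)
LIT_MEANS = TissueUptake(baf_stem=5.74, baf_leaves=0.435, bmp_stem=0.799, bmp_leaves=0.410)
SITE_MEANS = TissueUptake(baf_stem=0.89, baf_leaves=0.134, bmp_stem=0.0783, bmp_leaves=0.190)

finite_pos = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


@pytest.mark.parametrize(
    "c, expected",
    [(10.0, 5250.0), (0.0, 0.0), (2.0, 1050.0)],
)
def test_soil_mass_examples(c, expected):
    assert soil_mass(SC, c) == pytest.approx(expected)


@pytest.mark.parametrize(
    "baf, c, expected",
    [(0.89, 10.0, 8.9), (0.0, 10.0, 0.0), (5.74, 10.0, 57.4)],
)
def test_plant_concentration_examples(baf, c, expected):
    assert plant_concentration(baf, c) == pytest.approx(expected)


@pytest.mark.parametrize(
    "uptake, expected",
    [
        (LIT_MEANS, 47.6461),
        (TissueUptake(0.0, 0.0, 0.799, 0.410), 0.0),
        (SITE_MEANS, 0.95147),
    ],
)
def test_extraction_potential_examples(uptake, expected):
    assert extraction_potential(uptake, 10.0) == pytest.approx(expected, rel=1e-6)


@pytest.mark.parametrize(
    "e, m, expected",
    [(47.646, 5250.0, 0.009075), (0.0, 5250.0, 0.0), (0.9515, 5250.0, 1.8124e-4)],
)
def test_removal_rate_examples(e, m, expected):
    assert removal_rate(e, m) == pytest.approx(expected, rel=1e-3)


@pytest.mark.parametrize(
    "m_i, m_f, e, expected",
    [(5250.0, 525.0, 47.646, 99.17), (4000.0, 4000.0, 5.0, 0.0),
     (5250.0, 525.0, 0.9515, 4966.0)],
)
def test_time_linear_examples(m_i, m_f, e, expected):
    assert time_linear(m_i, m_f, e) == pytest.approx(expected, rel=1e-3)


def test_time_exponential_examples():
    assert time_exponential(5250.0, 525.0, 0.009075) == pytest.approx(253.7, rel=1e-3)
    assert time_exponential(4000.0, 4000.0, 0.02) == 0.0


def test_exponential_to_linear_ratio_is_closed_form():
    # for a 90% reduction at equal k: t_exp/t_lin = ln(10)/0.9
    k = 0.0123
    m_i, m_f = 5250.0, 525.0
    t_lin = time_linear(m_i, m_f, k * m_i)
    t_exp = time_exponential(m_i, m_f, k)
    assert t_exp / t_lin == pytest.approx(math.log(10.0) / 0.9, rel=1e-12)


@pytest.mark.parametrize(
    "t, model, expected",
    [(0.0, "exponential", 5250.0), (10.0, "exponential", 4794.6),
     (10.0, "linear", 4773.6)],
)
def test_mass_at_time_examples(t, model, expected):
    assert mass_at_time(5250.0, 0.009075, t, model) == pytest.approx(expected, rel=1e-4)


def test_translocation_factor():
    assert translocation_factor(8.9, 8.9) == 1.0
    assert translocation_factor(0.0, 4.2) == 0.0
    # round trip: imputing a stem concentration from the TF recovers it
    tf = translocation_factor(6.3, 2.1)
    assert stem_from_root(tf, 2.1) == pytest.approx(6.3)


def test_infinite_sentinels():
    assert time_linear(5250.0, 525.0, 0.0) == math.inf
    assert time_exponential(5250.0, 525.0, 0.0) == math.inf


@pytest.mark.parametrize(
    "call",
    [
        lambda: soil_mass(SC, -1.0),
        lambda: plant_concentration(0.5, 0.0),
        lambda: removal_rate(1.0, 0.0),
        lambda: time_linear(100.0, 200.0, 1.0),
        lambda: time_exponential(100.0, 0.0, 0.1),
        lambda: mass_at_time(100.0, 0.1, -1.0),
        lambda: translocation_factor(1.0, 0.0),
        lambda: extraction_potential(LIT_MEANS, 10.0, efficiency=0.0),
        lambda: SoilCompartment(c_soil_i=10.0, c_soil_f=12.0),
        lambda: SoilCompartment(c_soil_i=0.0),
        lambda: TissueUptake(-0.1, 0.1, 0.1, 0.1),
    ],
)
def test_domain_errors(call):
    with pytest.raises(ValueError):
        call()


@given(m_i=finite_pos, frac=st.floats(min_value=0.01, max_value=0.99), e=finite_pos)
def test_linear_mass_balance_closure(m_i, frac, e):
    m_f = m_i * frac
    t = time_linear(m_i, m_f, e)
    assert m_i - e * t == pytest.approx(m_f, rel=1e-9, abs=1e-9)


@given(m_i=finite_pos, frac=st.floats(min_value=0.01, max_value=0.99),
       k=st.floats(min_value=1e-6, max_value=10.0))
def test_exponential_mass_balance_closure(m_i, frac, k):
    m_f = m_i * frac
    t = time_exponential(m_i, m_f, k)
    assert mass_at_time(m_i, k, t, "exponential") == pytest.approx(m_f, rel=1e-9)


@given(m_i=finite_pos, frac=st.floats(min_value=0.01, max_value=0.99),
       k=st.floats(min_value=1e-6, max_value=10.0))
def test_fixed_rate_model_ordering(m_i, frac, k):
    # at equal k the exponential model is never faster, with a known ratio
    m_f = m_i * frac
    t_lin = time_linear(m_i, m_f, k * m_i)
    t_exp = time_exponential(m_i, m_f, k)
    assert t_exp >= t_lin
    assert t_exp / t_lin == pytest.approx(
        math.log(m_i / m_f) / (1.0 - m_f / m_i), rel=1e-9
    )


@given(m_i=finite_pos, frac=st.floats(min_value=0.01, max_value=0.99),
       e=finite_pos, factor=st.floats(min_value=1.01, max_value=100.0))
@settings(max_examples=50)
def test_times_decrease_in_rate_and_scale_with_mass(m_i, frac, e, factor):
    m_f = m_i * frac
    assert time_linear(m_i, m_f, e * factor) < time_linear(m_i, m_f, e)
    k = e / m_i
    assert time_exponential(m_i, m_f, k * factor) < time_exponential(m_i, m_f, k)
    # at a fixed reduction fraction, times depend on m_i only through
    # (m_i - m_f)/E and ln(m_i/m_f)/k
    assert time_linear(m_i * factor, m_f * factor, e) == pytest.approx(
        factor * time_linear(m_i, m_f, e), rel=1e-9
    )
    assert time_exponential(m_i * factor, m_f * factor, k) == pytest.approx(
        time_exponential(m_i, m_f, k), rel=1e-9
    )


@given(c=st.floats(min_value=0.0, max_value=1e4))
def test_default_compartment_unit_consistency(c):
    # 1500 kg/m^3 * 0.35 m^3 = 525 kg of soil per m^2: mass is 525*c mg
    assert soil_mass(SC, c) == pytest.approx(525.0 * c, rel=1e-12)


def test_run_deterministic_bundles_outputs():
    out = run_deterministic(LIT_MEANS, SC)
    assert out.e == pytest.approx(47.6461)
    assert out.k == pytest.approx(47.6461 / 5250.0)
    assert out.m_soil_i == 5250.0
    assert out.m_soil_f == 525.0
    assert out.t_linear == pytest.approx(99.17, rel=1e-3)
    assert out.t_exponential == pytest.approx(253.7, rel=1e-3)
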