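"""Exact Poisson inference and indirect standardization."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famrisk.records import CancerRecord, Person
from famrisk.risk import (
    RateTable,
    Stratum,
    assign_stratum,
    build_rate_table,
    estimate_risk,
    expected_count,
    mask_count,
    observed_count,
    poisson_exact_ci,
    poisson_one_sided_p,
    poisson_two_sided_p,
)

from conftest import minlike_oracle, upper_tail_oracle


def _person(pid, sex="F", by=1960, place="UTAH"):
    return Person(pid, sex, by, place)


def _cancer(pid, code=26000):
    return CancerRecord(pid, code, dt.date(2000, 1, 1))


# -- strata ----------------------------------------------------------------


@pytest.mark.parametrize(
    "by, expected_cohort",
    [(1962, 1960), (1960, 1960), (1959, 1955), (1964, 1960), (1965, 1965)],
)
def test_stratum_cohort_floors_to_five_year_grid(by, expected_cohort):
    s = assign_stratum(_person("x", "F", by, "UTAH"))
    assert s == Stratum("F", expected_cohort, "UTAH")


def test_unknown_birthplace_falls_back_to_non_utah(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="famrisk.risk"):
        s = assign_stratum(_person("x", "M", 1950, None))
    assert s.birthplace == "NON_UTAH"
    assert any("birthplace" in r.message for r in caplog.records)


def test_stratum_rejects_off_grid_cohort():
    with pytest.raises(ValueError):
        Stratum("F", 1962, "UTAH")


# -- rate tables and expected counts ---------------------------------------


def test_rate_table_matches_hand_computed_ratios():
    # three strata: 5/100, 2/50, 0/25
    persons = (
        [_person(f"a{i}", "F", 1950, "UTAH") for i in range(100)]
        + [_person(f"b{i}", "F", 1950, "NON_UTAH") for i in range(50)]
        + [_person(f"c{i}", "F", 1970, "UTAH") for i in range(25)]
    )
    cancers = [_cancer(f"a{i}") for i in range(5)] + [_cancer(f"b{i}") for i in range(2)]
    table = build_rate_table(persons, cancers, "breast")
    assert table.rates[Stratum("F", 1950, "UTAH")] == pytest.approx(0.05)
    assert table.rates[Stratum("F", 1950, "NON_UTAH")] == pytest.approx(0.04)
    assert table.rates[Stratum("F", 1970, "UTAH")] == 0.0
    assert table.pooled_rate == pytest.approx(7 / 175)


def test_sex_specific_site_restricts_reference():
    persons = [_person("m1", "M"), _person("m2", "M"), _person("f1", "F")]
    table = build_rate_table(persons, [_cancer("m1", 28010)], "prostate")
    assert all(s.sex == "M" for s in table.rates)
    with pytest.raises(ValueError):
        build_rate_table([_person("f1", "F")], [], "prostate")


def test_expected_count_is_additive_and_zero_on_empty():
    table = RateTable(site="breast", rates={Stratum("F", 1950, "UTAH"): 0.1, Stratum("F", 1950, "NON_UTAH"): 0.2})
    p1 = _person("x", "F", 1950, "UTAH")
    p2 = _person("y", "F", 1950, "NON_UTAH")
    assert expected_count([p1, p2], table) == pytest.approx(0.3)
    assert expected_count([], table) == 0.0


def test_unseen_stratum_contributes_pooled_rate():
    table = RateTable(site="breast", rates={Stratum("F", 1950, "UTAH"): 0.1}, pooled_rate=0.07)
    stranger = _person("z", "F", 1990, "NON_UTAH")
    assert expected_count([stranger], table) == pytest.approx(0.07)


def test_conservation_expected_equals_observed_on_reference(null_dataset):
    """Applying a rate table back to its own reference reproduces the case total."""
    for site in ("breast", "prostate", "colon"):
        table = build_rate_table(null_dataset.persons, null_dataset.cancers, site)
        E = expected_count(null_dataset.persons, table)
        O = observed_count(null_dataset.persons, null_dataset.cancers, site)
        assert E == pytest.approx(O, abs=1e-9)
        assert O == table.total_cases


# -- exact tests -----------------------------------------------------------


def test_two_sided_p_is_one_at_the_mode():
    assert poisson_two_sided_p(8, 8.19) == pytest.approx(1.0)


def test_one_sided_p_at_zero_is_whole_sample_space():
    assert poisson_one_sided_p(0, 5.0) == 1.0
    assert poisson_one_sided_p(0, 0.01) == 1.0


@pytest.mark.parametrize("fn", [poisson_two_sided_p, poisson_one_sided_p])
def test_nonpositive_expected_rejected(fn):
    with pytest.raises(ValueError):
        fn(3, 0.0)
    with pytest.raises(ValueError):
        fn(3, -1.0)


def test_ci_zero_observed_has_zero_lower_bound():
    low, high = poisson_exact_ci(0, 2.0)
    assert low == 0.0
    assert high > 0.0


@given(O=st.integers(0, 150), E=st.floats(0.05, 120.0))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_two_sided_p_matches_enumeration_oracle(O, E):
    assert poisson_two_sided_p(O, E) == pytest.approx(minlike_oracle(O, E), abs=1e-10)


@given(O=st.integers(1, 150), E=st.floats(0.05, 120.0))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_one_sided_p_matches_complement_oracle(O, E):
    assert poisson_one_sided_p(O, E) == pytest.approx(upper_tail_oracle(O, E), abs=1e-10)


@given(E=st.floats(0.5, 60.0), O=st.integers(0, 200))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_tail_relations(E, O):
    """One-sided decreases in O above E; minlike adds opposite-tail mass."""
    two = poisson_two_sided_p(O, E)
    assert 0.0 <= two <= 1.0
    if O > E:
        one = poisson_one_sided_p(O, E)
        assert one <= two + 1e-12
        assert poisson_one_sided_p(O + 1, E) <= one


@given(O=st.integers(1, 120), E=st.floats(0.2, 80.0))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_ci_brackets_the_point_estimate(O, E):
    low, high = poisson_exact_ci(O, E)
    assert low <= O / E <= high


def test_ci_width_shrinks_with_information_at_fixed_rr():
    widths = []
    for scale in (1, 2, 4, 8, 16):
        low, high = poisson_exact_ci(5 * scale, 2.5 * scale)  # RR fixed at 2
        widths.append(high - low)
    assert widths == sorted(widths, reverse=True)


# -- assembled estimates ----------------------------------------------------


def test_estimate_assembles_rr_and_bonferroni_flag():
    est = estimate_risk(18, 8.19, n_tests=4, site="breast", group="self")
    assert est.rr == 18 / 8.19
    assert est.ci_low <= est.rr <= est.ci_high
    assert est.bonferroni_alpha == pytest.approx(0.0125)
    assert est.significant  # p = .0023 < .0125


def test_zero_observed_estimate_is_null():
    est = estimate_risk(0, 3.0, n_tests=3)
    assert est.rr == 0.0
    assert not est.significant
    with pytest.raises(ValueError):
        estimate_risk(1, 2.0, n_tests=0)


def test_small_cell_masking_display_only():
    assert mask_count(0) == "<=10"
    assert mask_count(10) == "<=10"
    assert mask_count(11) == "11"
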