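"""Unit and property tests for the Mamdani inference engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzyrehab.errors import ConfigurationError, DomainError
from fuzzyrehab.fuzzy import (
    ANY,
    FISConfig,
    FuzzyRule,
    LinguisticVariable,
    MembershipFunction,
    MFShape,
    aggregate,
    centroid,
    infer,
    rule_firing_strength,
)
from fuzzyrehab.profiles import three_label_partition

from _reference import (
    ref_aggregate_at,
    ref_centroid_of_polyline,
    ref_centroid_riemann,
    ref_fuzzify,
    ref_infer_label,
)


def tri(label, a, b, c):
    return MembershipFunction(
        label=label, shape=MFShape.triangular, breakpoints=(a, b, c)
    )


def trap(label, a, b, c, d):
    return MembershipFunction(
        label=label, shape=MFShape.trapezoidal, breakpoints=(a, b, c, d)
    )


# --- membership functions -------------------------------------------------


@pytest.mark.parametrize(
    "mf, x, expected",
    [
        (tri("m", 0, 50, 100), 50, 1.0),  # peak
        (tri("m", 0, 50, 100), 25, 0.5),  # linear midpoint
        (tri("m", 0, 50, 100), 0, 0.0),
        (tri("m", 0, 50, 100), 100, 0.0),
        # descending edge of a trapezoid, value frozen from the linear
        # interpolation oracle: (40-35)/(40-30) = 0.5
        (trap("m", 10, 20, 30, 40), 35, 0.5),
        (trap("m", 10, 20, 30, 40), 25, 1.0),  # plateau
        (trap("m", 0, 0, 20, 45), 0, 1.0),  # left-shoulder vertical edge
        (trap("m", 55, 80, 100, 100), 100, 1.0),  # right-shoulder
    ],
)
def test_membership_degree_piecewise(mf, x, expected):
    assert mf.degree(x) == pytest.approx(expected)


def test_singleton_is_indicator():
    mf = MembershipFunction(
        label="Yes", shape=MFShape.crisp_singleton, breakpoints=(1.0,)
    )
    assert mf.degree(1.0) == 1.0
    assert mf.degree(0.0) == 0.0
    assert mf.degree(0.999) == 0.0


def test_membership_breakpoint_validation():
    with pytest.raises(ValueError, match="non-decreasing"):
        tri("bad", 50, 0, 100)
    with pytest.raises(ValueError, match="3 breakpoints"):
        MembershipFunction(
            label="bad", shape=MFShape.triangular, breakpoints=(0, 1, 2, 3)
        )


@given(st.floats(min_value=0, max_value=100))
@settings(max_examples=200, derandomize=True)
def test_membership_degree_matches_reference_everywhere(x):
    var = three_label_partition("v", 0, 100)
    ref = ref_fuzzify(var, x)
    for mf in var.labels:
        got = mf.degree(x)
        assert 0.0 <= got <= 1.0
        assert got == pytest.approx(ref[mf.label], abs=1e-12)


# --- fuzzification --------------------------------------------------------


def test_fuzzify_prototypes(fis4h):
    stress = fis4h.input_variable("current_stress")
    assert stress.fuzzify(0) == {"Low": 1.0, "Medium": 0.0, "High": 0.0}
    assert stress.fuzzify(100) == {"Low": 0.0, "Medium": 0.0, "High": 1.0}
    # mid-slope point, frozen from the piecewise-linear oracle:
    # Low (0,0,20,45) at 40 -> 0.2; Medium (30,50,70) at 40 -> 0.5
    assert stress.fuzzify(40) == pytest.approx(
        {"Low": 0.2, "Medium": 0.5, "High": 0.0}
    )


def test_fuzzify_clamps_out_of_universe(fis4h):
    stress = fis4h.input_variable("current_stress")
    assert stress.fuzzify(-5) == stress.fuzzify(0)
    assert stress.fuzzify(250) == stress.fuzzify(100)


def test_strict_membership_degree_raises_outside_universe(fis4h):
    stress = fis4h.input_variable("current_stress")
    with pytest.raises(DomainError, match="current_stress"):
        stress.membership_degree("Low", 101)


def test_default_partitions_cover_universe(profile):
    for fis in (profile.fis4h, profile.fis4d):
        for var in (*fis.inputs, fis.output):
            if any(mf.shape is MFShape.crisp_singleton for mf in var.labels):
                continue
            assert var.coverage_gaps(resolution=501) == []


# --- rule firing ----------------------------------------------------------


def test_firing_strength_is_min_over_non_any():
    rule = FuzzyRule(
        antecedents={"stress": "High", "time": "High", "errors": "High"},
        consequent="c",
    )
    fz = {
        "stress": {"High": 0.7},
        "time": {"High": 0.4},
        "errors": {"High": 0.9},
    }
    assert rule_firing_strength(rule, fz) == pytest.approx(0.4)


def test_firing_strength_any_contributes_one():
    rule = FuzzyRule(
        antecedents={"stress": "Low", "time": ANY, "errors": ANY},
        consequent="c",
    )
    assert rule_firing_strength(rule, {"stress": {"Low": 0.6}}) == 0.6


def test_firing_strength_zero_when_no_degree():
    rule = FuzzyRule(antecedents={"stress": "Low"}, consequent="c")
    assert rule_firing_strength(rule, {"stress": {"Low": 0.0}}) == 0.0


def test_firing_strength_missing_variable_errors():
    rule = FuzzyRule(antecedents={"stress": "Low"}, consequent="c")
    with pytest.raises(ConfigurationError, match="stress"):
        rule_firing_strength(rule, {"time": {"Low": 1.0}})


def test_all_any_rule_rejected():
    with pytest.raises(ValueError, match="at least one"):
        FuzzyRule(antecedents={"a": ANY, "b": ANY}, consequent="c")


# --- aggregation and centroid --------------------------------------------


@pytest.fixture
def out_var():
    return LinguisticVariable(
        name="out",
        universe=(0.0, 100.0),
        labels=(tri("A", 0, 25, 50), tri("B", 30, 60, 90)),
    )


def rules_for(out_var):
    return (
        FuzzyRule(antecedents={"x": "any_a"}, consequent="A"),
        FuzzyRule(antecedents={"x": "any_b"}, consequent="B"),
    )


def test_aggregate_identity_and_clip(out_var):
    rules = rules_for(out_var)
    grid, mu = aggregate([1.0, 0.0], rules, out_var, 1001)
    assert np.allclose(mu, np.asarray(out_var.label("A").degree(grid)))
    grid, mu = aggregate([0.5, 0.0], rules, out_var, 1001)
    assert mu.max() == pytest.approx(0.5)
    assert np.allclose(
        mu, np.minimum(np.asarray(out_var.label("A").degree(grid)), 0.5)
    )


def test_aggregate_is_pointwise_max_of_clipped_shapes(out_var, fis4d):
    strengths = [0.3, 0.8, 0.0, 0.55, 0.2]
    grid, mu = aggregate(
        strengths, fis4d.rules, fis4d.output, fis4d.defuzz_resolution
    )
    for i in range(0, len(grid), 97):  # spot-check against the scalar oracle
        assert mu[i] == pytest.approx(
            ref_aggregate_at(fis4d, strengths, float(grid[i])), abs=1e-12
        )


def test_centroid_symmetric_triangle_and_rectangle():
    grid = np.linspace(0, 100, 1001)
    mu = np.asarray(tri("m", 0, 50, 100).degree(grid))
    assert centroid(grid, mu) == pytest.approx(50.0, abs=1e-9)
    for h in (0.2, 0.7, 1.0):  # height-invariance of the rectangle centroid
        rect = np.where((grid >= 20) & (grid <= 40), h, 0.0)
        assert centroid(grid, rect) == pytest.approx(30.0, abs=0.2)


def test_centroid_zero_mass_is_no_activation():
    grid = np.linspace(0, 100, 1001)
    assert centroid(grid, np.zeros_like(grid)) is None


strength_lists = st.lists(
    st.one_of(st.just(0.0), st.floats(min_value=1e-6, max_value=1.0)),
    min_size=5,
    max_size=5,
)


@given(strength_lists)
@settings(max_examples=150, derandomize=True, deadline=None)
def test_centroid_matches_10x_riemann_oracle(fis4d, strengths):
    """Engine centroid vs an independent 10x-subdivided Riemann sum."""
    grid, mu = aggregate(
        strengths, fis4d.rules, fis4d.output, fis4d.defuzz_resolution
    )
    got = centroid(grid, mu)
    want = ref_centroid_of_polyline(grid.tolist(), mu.tolist(), factor=10)
    if want is None:
        assert got is None
    else:
        assert got == pytest.approx(want, rel=1e-6)


@given(strength_lists)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_centroid_within_hull_of_fired_supports(fis4d, strengths):
    grid, mu = aggregate(
        strengths, fis4d.rules, fis4d.output, fis4d.defuzz_resolution
    )
    value = centroid(grid, mu)
    fired = [
        fis4d.output.label(r.consequent).support
        for r, s in zip(fis4d.rules, strengths)
        if s > 0
    ]
    if value is None:
        assert not any(s > 0 for s in strengths)
    else:
        assert min(lo for lo, _ in fired) <= value <= max(hi for _, hi in fired)


@given(st.floats(min_value=0.05, max_value=1.0))
@settings(max_examples=50, derandomize=True)
def test_single_rule_centroid_invariant_under_strength(s):
    """Clipping a symmetric triangle at any height keeps its centroid."""
    sym = LinguisticVariable(
        name="out", universe=(0.0, 100.0), labels=(tri("A", 20, 50, 80),)
    )
    rules = (FuzzyRule(antecedents={"x": "a"}, consequent="A"),)
    grid, mu = aggregate([s], rules, sym, 2001)
    assert centroid(grid, mu) == pytest.approx(50.0, abs=1e-6)


# --- end-to-end inference -------------------------------------------------


def test_infer_requires_all_inputs(fis4h):
    with pytest.raises(ConfigurationError, match="consecutive_errors"):
        infer(fis4h, {"current_stress": 10, "time_without_interaction": 5})


def test_infer_no_rule_fired_returns_default_label(out_var):
    fis = FISConfig(
        name="toy",
        inputs=(
            LinguisticVariable(
                name="x", universe=(0.0, 1.0),
                labels=(tri("on", 0.5, 0.75, 1.0),),
            ),
        ),
        output=out_var,
        rules=(FuzzyRule(antecedents={"x": "on"}, consequent="B"),),
        default_output_label="A",
    )
    result = infer(fis, {"x": 0.0})
    assert not result.activated
    assert result.value is None
    assert result.label == "A"


def test_infer_deterministic_bit_for_bit(fis4h):
    inputs = {
        "current_stress": 63.7,
        "time_without_interaction": 21.9,
        "consecutive_errors": 4.2,
    }
    a = infer(fis4h, inputs)
    b = infer(fis4h, inputs)
    assert a == b
    assert a.value == b.value  # not approx: bit-for-bit


@pytest.mark.parametrize(
    "inputs",
    [
        {"current_stress": 70, "time_without_interaction": 45, "consecutive_errors": 3},
        {"current_stress": 30, "time_without_interaction": 50, "consecutive_errors": 6},
        {"current_stress": 90, "time_without_interaction": 10, "consecutive_errors": 1},
        {"current_stress": 50, "time_without_interaction": 35, "consecutive_errors": 5},
    ],
)
def test_infer_label_matches_straight_line_reference(fis4h, inputs):
    """End-to-end agreement with an independently coded dense-grid pipeline."""
    assert infer(fis4h, inputs).label == ref_infer_label(fis4h, inputs)


def test_misconfigured_fis_rejected_before_numeric_work(out_var):
    x = LinguisticVariable(
        name="x", universe=(0.0, 1.0), labels=(tri("on", 0.0, 0.5, 1.0),)
    )
    with pytest.raises(ValueError, match="unknown label"):
        FISConfig(
            name="bad",
            inputs=(x,),
            output=out_var,
            rules=(FuzzyRule(antecedents={"x": "Hgh"}, consequent="A"),),
            default_output_label="A",
        )
    with pytest.raises(ValueError, match="defuzz_resolution"):
        FISConfig(
            name="bad",
            inputs=(x,),
            output=out_var,
            rules=(FuzzyRule(antecedents={"x": "on"}, consequent="A"),),
            defuzz_resolution=10,
            default_output_label="A",
        )
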