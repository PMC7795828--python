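"""Mamdani inference engine against closed forms and a dense-grid oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sociability import (
    FISConfig,
    MembershipFunction,
    NoVerdictError,
    cog_defuzzify,
    default_fis,
    evaluate_rules,
    fis_assess,
    load_fis_config,
    membership,
    trapezoid,
    triangle,
)
from sociability.fuzzy import FISConfigError, LinguisticVariable, Rule

from ._oracles import mamdani_dense


class TestMembership:
    def test_triangle_apex_slope_and_support(self):
        tri = triangle(25, 50, 75)
        assert membership(tri, 50) == 1.0
        assert membership(tri, 37.5) == 0.5
        assert membership(tri, 100) == 0.0
        assert membership(tri, 0) == 0.0

    def test_trapezoid_degenerate_shoulder(self):
        trap = trapezoid(0, 0, 25, 50)
        assert membership(trap, 0) == 1.0
        assert membership(trap, 25) == 1.0
        assert membership(trap, 37.5) == 0.5
        assert membership(trap, 60) == 0.0

    def test_invalid_point_lists_rejected(self):
        with pytest.raises(FISConfigError):
            MembershipFunction(((0, 0), (0, 1)))
        with pytest.raises(FISConfigError):
            MembershipFunction(((0, 0), (10, 1.5)))

    @given(x=st.floats(-50, 150, allow_nan=False))
    def test_degrees_bounded(self, x):
        assert 0.0 <= membership(triangle(25, 50, 75), x) <= 1.0


class TestCOG:
    def test_symmetric_triangle_centroid(self):
        tri = triangle(25, 50, 75)
        assert cog_defuzzify(tri, 0, 100, 0.05) == pytest.approx(50.0, abs=0.05)

    def test_trapezoid_closed_form(self):
        # plateau 1 on [0,20] descending to 0 at 40: moment 1400/3, area 30
        trap = trapezoid(0, 0, 20, 40)
        expected = (1400 / 3) / 30
        assert cog_defuzzify(trap, 0, 100, 0.01) == pytest.approx(expected, abs=0.02)

    def test_scale_invariance_of_uniform_plateau(self):
        for c in (0.2, 0.5, 1.0):
            mf = MembershipFunction(((10.0, c), (30.0, c)))
            assert cog_defuzzify(mf, 0, 100, 0.01) == pytest.approx(20.0, abs=0.05)

    def test_zero_aggregate_raises(self):
        with pytest.raises(NoVerdictError):
            cog_defuzzify(lambda x: np.zeros_like(np.asarray(x, float)), 0, 100)

    def test_resolution_convergence(self):
        fis = default_fis()
        for sens, sim in [(70.0, 30.0), (40.0, 55.0), (90.0, 90.0)]:
            agg = evaluate_rules(fis, sens, sim)
            coarse = cog_defuzzify(agg, 0, 100, 0.5)
            fine = cog_defuzzify(agg, 0, 100, 0.25)
            assert abs(coarse - fine) < 0.5


class TestRuleEvaluation:
    def test_single_full_activation_recovers_consequent(self):
        fis = default_fis()
        # sensitivity 0 -> "low" at 1; similarity 100 -> "high" at 1;
        # only (low, high) -> no_change fires, unclipped
        agg = evaluate_rules(fis, 0.0, 100.0)
        xs = np.linspace(0, 100, 1001)
        expected = fis.output.terms["no_change"](xs)
        assert np.allclose(agg(xs), expected)

    def test_no_rule_fires_outside_all_supports(self):
        var = LinguisticVariable(
            "similarity", (0.0, 100.0), {"low": triangle(0, 10, 20)}, ("low",)
        )
        sens = LinguisticVariable(
            "sensitivity", (0.0, 100.0), {"any": trapezoid(0, 0, 100, 100)}, ("any",)
        )
        fis = FISConfig(
            inputs=(sens, var),
            output=LinguisticVariable(
                "drift", (0.0, 100.0), {"change": triangle(40, 50, 60)}, ("change",)
            ),
            rules=(Rule({"sensitivity": "any", "similarity": "low"}, "change"),),
        )
        agg = evaluate_rules(fis, 50.0, 80.0)  # similarity outside "low" support
        assert not agg(np.linspace(0, 100, 101)).any()
        with pytest.raises(NoVerdictError):
            fis_assess(fis, 50.0, 80.0)

    def test_degenerate_always_firing_rule_gives_triangle_centroid(self):
        anyv = trapezoid(0, 0, 100, 100)
        fis = FISConfig(
            inputs=(
                LinguisticVariable("sensitivity", (0, 100), {"any": anyv}, ("any",)),
                LinguisticVariable("similarity", (0, 100), {"any": anyv}, ("any",)),
            ),
            output=LinguisticVariable(
                "drift", (0, 100), {"mid": triangle(25, 50, 75)}, ("mid",)
            ),
            rules=(Rule({"sensitivity": "any", "similarity": "any"}, "mid"),),
        )
        assert fis_assess(fis, 33.0, 77.0).crisp == pytest.approx(50.0, abs=0.05)


class TestDefaultConfigAssessment:
    def test_low_sensitivity_high_similarity_is_no_change(self):
        a = fis_assess(default_fis(), 0.0, 100.0)
        # closed-form centroid of trapezoid(0,0,25,50): (729.1666/37.5)
        assert a.crisp == pytest.approx(729.1666667 / 37.5, abs=0.05)
        assert a.degrees["no_change"] == 1.0
        assert a.verdict == "no_change"

    def test_matches_dense_grid_oracle_on_random_inputs(self):
        fis = default_fis()
        in_terms = {t: fis.input("sensitivity").terms[t].points
                    for t in ("low", "moderate", "high")}
        out_terms = {t: fis.output.terms[t].points
                     for t in ("no_change", "moderate_change", "change")}
        rules = [
            (r.antecedents["sensitivity"], r.antecedents["similarity"], r.consequent)
            for r in fis.rules
        ]
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(100):
            sens, sim = rng.uniform(0, 100, size=2)
            expected = mamdani_dense(in_terms, out_terms, rules, sens, sim)
            if np.isnan(expected):
                continue
            got = fis_assess(fis, sens, sim)
            assert got.crisp == pytest.approx(expected, abs=fis.resolution)
            assert 0.0 <= got.crisp <= 100.0
            checked += 1
        assert checked >= 90  # default config covers nearly all input pairs


class TestConfigIO:
    YAML = """
variables:
  sensitivity:
    range: [0, 100]
    terms:
      low: {trapezoid: [0, 0, 25, 50]}
      high: {trapezoid: [50, 75, 100, 100]}
  similarity:
    range: [0, 100]
    terms:
      low: {trapezoid: [0, 0, 25, 50]}
      high: {trapezoid: [50, 75, 100, 100]}
  drift:
    range: [0, 100]
    terms:
      no_change: {triangle: [0, 25, 50]}
      change: {triangle: [50, 75, 100]}
rules:
  - {if: {sensitivity: high, similarity: low}, then: change}
  - {if: {sensitivity: low, similarity: high}, then: no_change}
defuzzifier: {method: cog, resolution: 0.1}
"""

    def test_yaml_round_trip_and_inference(self, tmp_path):
        path = tmp_path / "fis.yaml"
        path.write_text(self.YAML)
        fis = load_fis_config(path)
        assert {v.name for v in fis.inputs} == {"sensitivity", "similarity"}
        a = fis_assess(fis, 100.0, 0.0)
        assert a.verdict == "change"
        assert a.crisp == pytest.approx(75.0, abs=0.1)

    def test_bad_configs_rejected(self, tmp_path):
        bad_rule = self.YAML.replace("then: change}", "then: nonsense}")
        path = tmp_path / "bad.yaml"
        path.write_text(bad_rule)
        with pytest.raises(FISConfigError):
            load_fis_config(path)
        path.write_text("variables: {}")
        with pytest.raises(FISConfigError):
            load_fis_config(path)
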