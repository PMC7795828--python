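"""Minimal Mamdani fuzzy-inference system for drift assessment.

The expert's change threshold is inherently imprecise: a similarity of
59.9% against a 60% threshold should not produce a categorically
different alert than 60.1%.  The FIS replaces the crisp cut with two
inputs — *sensitivity* (how eagerly the specialist wants changes flagged,
0-100) and *similarity* (Jaccard overlap, 0-100) — and one output,
*drift* (0-100), each partitioned into overlapping linguistic terms by
piecewise-linear membership functions.

Inference is standard Mamdani: rule activation is the min of the
antecedent degrees, consequents are clipped at the activation, the
clipped sets are aggregated pointwise by max, and the aggregate is
defuzzified by center of gravity (COG) on a dense grid.  Configurations
load from YAML/JSON; a sensible three-term default ships in code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml


class NoVerdictError(ValueError):
    """No rule fired: the aggregated output set is identically zero."""


class FISConfigError(ValueError):
    """The FIS configuration is structurally invalid."""


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear membership over a variable's range.

    ``points`` are (x, mu) pairs with strictly increasing x and mu in
    [0, 1]; evaluation outside the point list is 0.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise FISConfigError("membership function needs >= 2 points")
        xs = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise FISConfigError(f"x values must be strictly increasing: {xs}")
        if any(not 0.0 <= p[1] <= 1.0 for p in self.points):
            raise FISConfigError("membership degrees must lie in [0, 1]")

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        xs = np.array([p[0] for p in self.points])
        mus = np.array([p[1] for p in self.points])
        out = np.interp(x, xs, mus)
        return np.where((np.asarray(x) < xs[0]) | (np.asarray(x) > xs[-1]), 0.0, out)


def triangle(a: float, b: float, c: float) -> MembershipFunction:
    """Triangular set: 0 at a, 1 at b, 0 at c."""
    return MembershipFunction(((a, 0.0), (b, 1.0), (c, 0.0)))


def trapezoid(a: float, b: float, c: float, d: float) -> MembershipFunction:
    """Trapezoidal set: 0 at a, plateau 1 on [b, c], 0 at d.

    Degenerate shoulders (a == b or c == d) collapse to a single point so
    the x-grid stays strictly increasing.
    """
    pts: list[tuple[float, float]] = []
    if a < b:
        pts.append((a, 0.0))
    pts.append((b, 1.0))
    if c > b:
        pts.append((c, 1.0))
    if d > c:
        pts.append((d, 0.0))
    return MembershipFunction(tuple(pts))


def membership(mf: MembershipFunction, x: float) -> float:
    """Degree of x in the set (linear interpolation, 0 outside support)."""
    return float(mf(x))


@dataclass(frozen=True)
class LinguisticVariable:
    name: str
    range: tuple[float, float]
    terms: Mapping[str, MembershipFunction]
    term_order: tuple[str, ...]  # least to most severe

    def __post_init__(self) -> None:
        if not self.terms:
            raise FISConfigError(f"variable {self.name!r} has no terms")
        if set(self.term_order) != set(self.terms):
            raise FISConfigError(f"term_order mismatch for {self.name!r}")


@dataclass(frozen=True)
class Rule:
    """IF sensitivity IS <term> AND similarity IS <term> THEN drift IS <term>."""

    antecedents: Mapping[str, str]  # variable name -> term name
    consequent: str


@dataclass(frozen=True)
class FISConfig:
    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: tuple[Rule, ...]
    resolution: float = 0.1

    def __post_init__(self) -> None:
        by_name = {v.name: v for v in self.inputs}
        for rule in self.rules:
            for var, term in rule.antecedents.items():
                if var not in by_name:
                    raise FISConfigError(f"rule references unknown input {var!r}")
                if term not in by_name[var].terms:
                    raise FISConfigError(f"unknown term {term!r} for input {var!r}")
            if rule.consequent not in self.output.terms:
                raise FISConfigError(f"unknown output term {rule.consequent!r}")

    def input(self, name: str) -> LinguisticVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass(frozen=True)
class DriftAssessment:
    """Defuzzified drift value plus the crisp value's degree in each term."""

    crisp: float
    degrees: Mapping[str, float]

    @property
    def verdict(self) -> str:
        """Output term with the highest degree; ties go to the more severe."""
        best, best_deg = None, -1.0
        for term, deg in self.degrees.items():  # insertion order = severity order
            if deg >= best_deg:
                best, best_deg = term, deg
        assert best is not None
        return best

    def to_json_dict(self) -> dict:
        return {"crisp": self.crisp, "degrees": dict(self.degrees),
                "verdict": self.verdict}


def _three_term_variable(name: str, terms: Sequence[str]) -> LinguisticVariable:
    lo, mid, hi = terms
    return LinguisticVariable(
        name=name,
        range=(0.0, 100.0),
        terms={
            lo: trapezoid(0, 0, 25, 50),
            mid: triangle(25, 50, 75),
            hi: trapezoid(50, 75, 100, 100),
        },
        term_order=(lo, mid, hi),
    )


def default_fis() -> FISConfig:
    """Three-term default configuration with a 9-rule severity table.

    High sensitivity and low similarity push toward "change"; low
    sensitivity and high similarity toward "no_change".  The terms of
    every variable overlap so that adjacent terms co-fire everywhere in
    the range: without that overlap the defuzzified value plateaus over
    mid-range similarities and the change-verdict boundary cannot be
    placed there by any sensitivity.  Fully overridable via
    :func:`load_fis_config`.
    """
    sensitivity = _three_term_variable("sensitivity", ("low", "moderate", "high"))
    similarity = _three_term_variable("similarity", ("low", "moderate", "high"))
    drift = _three_term_variable("drift", ("no_change", "moderate_change", "change"))
    table = {
        ("low", "low"): "moderate_change",
        ("low", "moderate"): "no_change",
        ("low", "high"): "no_change",
        ("moderate", "low"): "change",
        ("moderate", "moderate"): "moderate_change",
        ("moderate", "high"): "no_change",
        ("high", "low"): "change",
        ("high", "moderate"): "change",
        ("high", "high"): "moderate_change",
    }
    rules = tuple(
        Rule({"sensitivity": sens, "similarity": sim}, out)
        for (sens, sim), out in table.items()
    )
    return FISConfig(inputs=(sensitivity, similarity), output=drift, rules=rules)


def evaluate_rules(
    fis: FISConfig, sensitivity: float, similarity: float
):
    """Aggregate the rule base into one output membership function.

    Returns a callable mu(x) over the drift range: per rule the activation
    is min over antecedent degrees, the consequent is clipped at it, and
    clipped consequents combine by pointwise max.  Inputs outside a
    variable's range are clamped.
    """
    values = {"sensitivity": sensitivity, "similarity": similarity}
    activations: list[tuple[float, MembershipFunction]] = []
    for rule in fis.rules:
        act = 1.0
        for var_name, term in rule.antecedents.items():
            var = fis.input(var_name)
            x = min(max(values[var_name], var.range[0]), var.range[1])
            act = min(act, membership(var.terms[term], x))
        if act > 0.0:
            activations.append((act, fis.output.terms[rule.consequent]))

    def aggregate(x: float | np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for act, mf in activations:
            out = np.maximum(out, np.minimum(act, mf(x)))
        return out

    return aggregate


def cog_defuzzify(
    aggregate, lo: float, hi: float, resolution: float = 0.1
) -> float:
    """Center of gravity of the aggregated set on a uniform grid."""
    n = max(int(round((hi - lo) / resolution)), 1) + 1
    xs = np.linspace(lo, hi, n)
    mus = aggregate(xs)
    area = np.trapezoid(mus, xs)
    if area <= 0.0:
        raise NoVerdictError("aggregated output membership is identically zero")
    return float(np.trapezoid(xs * mus, xs) / area)


def fis_assess(fis: FISConfig, sensitivity: float, similarity: float) -> DriftAssessment:
    """Full inference: crisp drift value plus per-term degrees of it."""
    aggregate = evaluate_rules(fis, sensitivity, similarity)
    crisp = cog_defuzzify(aggregate, *fis.output.range, fis.resolution)
    degrees = {
        term: membership(fis.output.terms[term], crisp)
        for term in fis.output.term_order
    }
    return DriftAssessment(crisp=crisp, degrees=degrees)


def change_boundary(fis: FISConfig, sensitivity: float, tol: float = 1e-3) -> float:
    """Largest similarity (0-100) still judged "change" at this sensitivity.

    The verdict is monotone in similarity for severity-table rule bases,
    so the boundary is found by bisection; returns 0 when no similarity
    yields a "change" verdict.
    """
    change_term = fis.output.term_order[-1]

    def is_change(sim: float) -> bool:
        try:
            return fis_assess(fis, sensitivity, sim).verdict == change_term
        except NoVerdictError:
            return False

    lo, hi = fis.output.range
    if not is_change(lo):
        return lo
    if is_change(hi):
        return hi
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if is_change(mid):
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def calibrate_sensitivity(
    fis: FISConfig, threshold: float, tol: float = 1e-3
) -> float:
    """Sensitivity whose "change" verdict boundary sits at a crisp threshold.

    ``threshold`` is a similarity in [0, 1]; the returned sensitivity makes
    the fuzzy detector agree with a crisp below-threshold rule.  The
    boundary grows with sensitivity, so bisection applies; it may jump
    over the exact target, in which case the sensitivity with the
    smallest boundary at or above the target is returned (flagging at
    the threshold errs toward alerting, never under it).
    """
    target = threshold * 100.0
    lo, hi = fis.input("sensitivity").range
    if change_boundary(fis, hi) < target:
        return hi
    if change_boundary(fis, lo) >= target:
        return lo
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if change_boundary(fis, mid) < target:
            lo = mid
        else:
            hi = mid
    return hi


def _term_from_spec(spec) -> MembershipFunction:
    if isinstance(spec, dict):
        if "triangle" in spec:
            return triangle(*spec["triangle"])
        if "trapezoid" in spec:
            return trapezoid(*spec["trapezoid"])
        if "points" in spec:
            return MembershipFunction(tuple(tuple(p) for p in spec["points"]))
    raise FISConfigError(f"cannot interpret term shape {spec!r}")


def _variable_from_spec(name: str, spec: dict) -> LinguisticVariable:
    try:
        rng = tuple(spec["range"])
        terms_spec = spec["terms"]
    except KeyError as exc:
        raise FISConfigError(f"variable {name!r} missing key {exc}") from exc
    terms = {t: _term_from_spec(s) for t, s in terms_spec.items()}
    order = tuple(spec.get("term_order", terms_spec.keys()))
    return LinguisticVariable(name=name, range=rng, terms=terms, term_order=order)


def load_fis_config(path: str | Path) -> FISConfig:
    """Load a FIS configuration from a YAML or JSON file.

    Schema: ``variables`` maps each of sensitivity/similarity/drift to
    ``{range: [lo, hi], terms: {name: {triangle|trapezoid|points: ...}},
    term_order: [...]}``; ``rules`` is a list of
    ``{if: {sensitivity: term, similarity: term}, then: term}``;
    ``defuzzifier: {method: cog, resolution: r}``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "variables" not in data or "rules" not in data:
        raise FISConfigError("config must define 'variables' and 'rules'")
    variables = {
        name: _variable_from_spec(name, spec)
        for name, spec in data["variables"].items()
    }
    if "drift" not in variables:
        raise FISConfigError("config must define a 'drift' output variable")
    output = variables.pop("drift")
    rules = tuple(
        Rule(antecedents=dict(r["if"]), consequent=r["then"]) for r in data["rules"]
    )
    defuzz = data.get("defuzzifier", {})
    method = defuzz.get("method", "cog").lower()
    if method != "cog":
        raise FISConfigError(f"unsupported defuzzifier {method!r}; only 'cog'")
    return FISConfig(
        inputs=tuple(variables.values()),
        output=output,
        rules=rules,
        resolution=float(defuzz.get("resolution", 0.1)),
    )
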