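"""Mamdani fuzzy inference over an association rule base.

A rule fires with the minimum of its antecedent memberships at the
respondent's factor scores; its consequent WRS term is clipped at that
activation; clipped shapes are aggregated by pointwise maximum on a fixed
grid of [0, 1]; the crisp stress score is the centroid of the aggregate.  The
score maps to one of five linguistic stress levels through fixed bands.

Because the published membership-function breakpoints of the source
instrument are not numeric, the engine also provides
:func:`calibrate_breakpoints`: a deterministic coordinate-descent search over
per-variable power warps of the uniform term-peak layout that maximises the
level concordance against a reference table of profiles with known levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .fuzzy_core import (
    LinguisticVariable,
    default_variables,
    evaluate_membership,
    evaluate_membership_grid,
    fuzzify,
    uniform_variable,
    DEFAULT_TERM_SETS,
)
from .rule_mining import AssociationRule, FuzzyItem, load_rules, save_rules

__all__ = [
    "RuleBase",
    "Prediction",
    "LEVEL_BANDS",
    "fire_rule",
    "predict",
    "predict_many",
    "score_to_level",
    "load_rulebase",
    "save_rulebase",
    "reference_rulebase",
    "reference_profiles",
    "calibrate_breakpoints",
    "NoRuleFiredError",
]

GRID_POINTS = 1001

#: Stress-level bands on the defuzzified score.  Upper edges of the moderate
#: and high bands are closed (0.65 is still moderate, 0.90 still high).
LEVEL_BANDS = (
    ("very low", 0.0, 0.25),
    ("low", 0.25, 0.45),
    ("moderate", 0.45, 0.65),
    ("high", 0.65, 0.90),
    ("extremely high", 0.90, 1.0),
)


class NoRuleFiredError(RuntimeError):
    """No rule had positive activation for the given profile."""


@dataclass(frozen=True)
class RuleBase:
    rules: tuple[AssociationRule, ...]
    variables: dict[str, LinguisticVariable] = field(default_factory=default_variables)

    def __post_init__(self) -> None:
        for i, rule in enumerate(self.rules, start=1):
            for item in rule.items:
                if item.variable not in self.variables:
                    raise ValueError(f"rule {i}: unknown variable {item.variable!r}")
                if item.term not in self.variables[item.variable]:
                    raise ValueError(
                        f"rule {i}: variable {item.variable!r} has no term {item.term!r}"
                    )

    def with_variables(self, variables) -> "RuleBase":
        return RuleBase(rules=self.rules, variables=dict(variables))

    def __len__(self) -> int:
        return len(self.rules)


@dataclass(frozen=True)
class Prediction:
    score: float
    level: str
    fired: dict[int, float]


def fire_rule(rule: AssociationRule, profile, variables) -> float:
    """Min over antecedent items of the item membership at the profile's score."""
    scores = profile.as_dict() if hasattr(profile, "as_dict") else dict(profile)
    degrees = []
    for item in rule.antecedent:
        if item.variable not in scores:
            raise KeyError(
                f"rule references variable {item.variable!r} absent from the profile"
            )
        term = variables[item.variable].term(item.term)
        degrees.append(evaluate_membership(term.mf, scores[item.variable]))
    return min(degrees) if degrees else 1.0


def score_to_level(score: float) -> str:
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"stress score {score!r} outside [0, 1]")
    for label, lo, hi in LEVEL_BANDS:
        if label == "very low" and lo <= score < hi:
            return label
        if label == "low" and lo <= score < hi:
            return label
        if label == "moderate" and lo <= score <= hi:
            return label
        if label == "high" and lo < score <= hi:
            return label
        if label == "extremely high" and lo < score <= hi:
            return label
    raise AssertionError("unreachable")  # bands cover [0, 1]


def _fallback_prediction(score: float) -> Prediction:
    # NaN fallback marks "no rule fired" for callers that resample/filter
    level = "" if np.isnan(score) else score_to_level(score)
    return Prediction(score, level, {})


def predict(
    rulebase: RuleBase,
    profile,
    grid_points: int = GRID_POINTS,
    fallback_score: float | None = None,
) -> Prediction:
    """Mamdani composition: min-clip, max-aggregate, centroid defuzzify."""
    if not rulebase.rules:
        raise ValueError("empty rule base")
    out_var = rulebase.variables["WRS"]
    grid = np.linspace(0.0, 1.0, grid_points)
    aggregate = np.zeros_like(grid)
    fired: dict[int, float] = {}
    for i, rule in enumerate(rulebase.rules):
        act = fire_rule(rule, profile, rulebase.variables)
        if act <= 0.0:
            continue
        fired[i] = act
        mf = out_var.term(rule.consequent.term).mf
        shape = np.minimum(act, evaluate_membership_grid(mf, grid))
        aggregate = np.maximum(aggregate, shape)
    mass = aggregate.sum()
    if not fired or mass == 0.0:
        if fallback_score is not None:
            return _fallback_prediction(fallback_score)
        raise NoRuleFiredError("no rule fired for this profile")
    score = float((grid * aggregate).sum() / mass)
    return Prediction(score=score, level=score_to_level(score), fired=fired)


def predict_many(rulebase: RuleBase, profiles, grid_points: int = GRID_POINTS,
                 fallback_score: float | None = None) -> list[Prediction]:
    """Batch :func:`predict` with consequent shapes computed once."""
    if not rulebase.rules:
        raise ValueError("empty rule base")
    out_var = rulebase.variables["WRS"]
    grid = np.linspace(0.0, 1.0, grid_points)
    shapes = [
        evaluate_membership_grid(out_var.term(r.consequent.term).mf, grid)
        for r in rulebase.rules
    ]
    preds = []
    for p in profiles:
        aggregate = np.zeros_like(grid)
        fired: dict[int, float] = {}
        for i, rule in enumerate(rulebase.rules):
            act = fire_rule(rule, p, rulebase.variables)
            if act <= 0.0:
                continue
            fired[i] = act
            aggregate = np.maximum(aggregate, np.minimum(act, shapes[i]))
        mass = aggregate.sum()
        if not fired or mass == 0.0:
            if fallback_score is not None:
                preds.append(_fallback_prediction(fallback_score))
                continue
            raise NoRuleFiredError("no rule fired for a profile in the batch")
        score = float((grid * aggregate).sum() / mass)
        preds.append(Prediction(score, score_to_level(score), fired))
    return preds


def save_rulebase(rb: RuleBase, path) -> None:
    save_rules(rb.rules, path)


def load_rulebase(path, variables=None) -> RuleBase:
    variables = dict(variables) if variables is not None else default_variables()
    return RuleBase(rules=tuple(load_rules(path, variables)), variables=variables)


def reference_rulebase(variables=None) -> RuleBase:
    """The packaged nine-rule reference base (see data/reference_rules.frb)."""
    with resources.as_file(
        resources.files("farmstress.data") / "reference_rules.frb"
    ) as p:
        return load_rulebase(p, variables=variables)


def reference_profiles():
    """The packaged 11-respondent reference table: profiles, scores and levels.

    Returns (profiles, scores, levels) where profiles is a list of FactorProfile.
    """
    import csv

    from .survey_io import FactorProfile

    profiles, scores, levels = [], [], []
    ref = resources.files("farmstress.data") / "reference_profiles.csv"
    with resources.as_file(ref) as p, open(p, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            profiles.append(
                FactorProfile(
                    respondent_id=row["staff"],
                    pcg=float(row["PCG"]),
                    fin=float(row["FIN"]),
                    scf=float(row["SCF"]),
                    tech=float(row["TECH"]),
                )
            )
            scores.append(float(row["score"]))
            levels.append(row["level"])
    return profiles, scores, levels


# --------------------------------------------------------------------------
# breakpoint calibration
# --------------------------------------------------------------------------

def _variables_from_peaks(peaks_by_var) -> dict[str, LinguisticVariable]:
    return {
        name: uniform_variable(name, labels, peaks=peaks_by_var[name])
        for name, labels in DEFAULT_TERM_SETS.items()
    }


def calibrate_breakpoints(
    rulebase: RuleBase,
    profiles,
    target_levels,
    peak_grid=None,
    single_sweeps: int = 4,
    pair_sweeps: int = 2,
    min_gap: float = 0.05,
    grid_points: int = 201,
) -> tuple[dict[str, LinguisticVariable], int]:
    """Search interior term-peak placements maximising level concordance.

    Deterministic coordinate descent over the interior peaks of every
    variable (first/last peaks stay clamped at 0 and 1, feet always at the
    adjacent peaks, so every candidate layout remains a partition of unity):
    first single-peak moves to a local optimum, then pairwise joint moves,
    which escape the interaction traps single moves cannot (e.g. an input
    peak and an output peak that must shift together).  Candidate positions
    come from a fixed grid; peaks must stay ``min_gap`` apart and strictly
    ordered.  Returns the calibrated variable set and the concordance count.
    """
    from itertools import combinations

    profiles = list(profiles)
    target_levels = list(target_levels)
    if peak_grid is None:
        peak_grid = np.round(np.arange(0.10, 0.91, 0.05), 2)

    def concordance(state) -> int:
        rb = rulebase.with_variables(_variables_from_peaks(state))
        hits = 0
        for p, lvl in zip(profiles, target_levels):
            try:
                pred = predict(rb, p, grid_points=grid_points)
            except NoRuleFiredError:
                continue
            hits += pred.level == lvl
        return hits

    params = [
        (name, idx)
        for name, labels in DEFAULT_TERM_SETS.items()
        for idx in range(1, len(labels) - 1)
    ]

    def candidates(state, name, idx):
        lo = state[name][idx - 1] + min_gap - 1e-9
        hi = state[name][idx + 1] - min_gap + 1e-9
        return [float(v) for v in peak_grid if lo < v < hi]

    state = {
        name: [i / (len(labels) - 1) for i in range(len(labels))]
        for name, labels in DEFAULT_TERM_SETS.items()
    }
    best = concordance(state)

    for _ in range(single_sweeps):
        improved = False
        for name, idx in params:
            for v in candidates(state, name, idx):
                if v == state[name][idx]:
                    continue
                trial = {n: list(p) for n, p in state.items()}
                trial[name][idx] = v
                s = concordance(trial)
                if s > best:
                    state, best = trial, s
                    improved = True
        if not improved:
            break

    for _ in range(pair_sweeps):
        improved = False
        for (n1, i1), (n2, i2) in combinations(params, 2):
            accepted = False
            for v1 in candidates(state, n1, i1):
                for v2 in candidates(state, n2, i2):
                    trial = {n: list(p) for n, p in state.items()}
                    trial[n1][i1] = v1
                    trial[n2][i2] = v2
                    if not (
                        trial[n2][i2 - 1] + min_gap - 1e-9
                        < v2
                        < trial[n2][i2 + 1] - min_gap + 1e-9
                    ):
                        continue
                    s = concordance(trial)
                    if s > best:
                        state, best = trial, s
                        improved = accepted = True
                        break
                if accepted:
                    break
        if not improved:
            break

    return _variables_from_peaks(state), best
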