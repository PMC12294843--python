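"""Fuzzy-set primitives: triangular membership functions, linguistic variables,
fuzzification, and the min/max/complement connectives.

Every factor in the stress instrument (psychological, financial,
socio-demographic, technological impact, and the work-related-stress outcome)
lives on the unit interval and carries an ordered set of linguistic terms
("depressed", "deteriorating", "extremely high", ...).  Each term is a
triangular membership function.  The default layout for a variable with *k*
terms is the uniform triangular partition of [0, 1]: peaks at i/(k-1), each
foot at the adjacent peak, shoulder terms clamped at the interval ends.  That
layout is a partition of unity — memberships across terms sum to one at every
point — which is what makes fuzzy supports commensurate with classical ones.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import yaml

__all__ = [
    "TriangularMF",
    "LinguisticTerm",
    "LinguisticVariable",
    "evaluate_membership",
    "evaluate_membership_grid",
    "fuzzify",
    "fuzzy_connective",
    "uniform_variable",
    "default_variables",
    "load_variables",
    "save_variables",
    "slugify",
]

#: Canonical term sets per factor, in increasing order of the underlying score.
DEFAULT_TERM_SETS: dict[str, tuple[str, ...]] = {
    "PCG": ("normal mental health", "labile", "depressed", "anxious"),
    "FIN": ("deteriorating", "not changed", "improved"),
    "SCF": (
        "not associated",
        "mild association",
        "moderate association",
        "strong association",
    ),
    "TECH": ("negative impact", "no impact", "positive impact"),
    "WRS": ("very low", "low", "moderate", "high", "extremely high"),
}


def slugify(label: str) -> str:
    """Filesystem/rule-file token for a term label ("mild association" -> "mild_association")."""
    return re.sub(r"[^a-z0-9]+", "_", label.lower()).strip("_")


@dataclass(frozen=True)
class TriangularMF:
    """Triangle defined by (left foot, peak, right foot) on the factor scale.

    A degenerate triangle with ``left == peak == right`` is a crisp singleton:
    membership 1 exactly at the peak, 0 elsewhere.
    """

    left: float
    peak: float
    right: float

    def __post_init__(self) -> None:
        if not (self.left <= self.peak <= self.right):
            raise ValueError(
                f"triangular MF requires left <= peak <= right, got "
                f"({self.left}, {self.peak}, {self.right})"
            )

    def __call__(self, x: float) -> float:
        return evaluate_membership(self, x)


def evaluate_membership(mf: TriangularMF, x: float) -> float:
    """Piecewise-linear triangular membership of ``x``; zero outside the support."""
    if not math.isfinite(x):
        raise ValueError(f"membership evaluation requires a finite value, got {x!r}")
    a, b, c = mf.left, mf.peak, mf.right
    if a == b == c:
        return 1.0 if x == b else 0.0
    if x < a or x > c:
        return 0.0
    if x == b:
        return 1.0
    if x < b:
        # a < b here, else x == b was caught above
        return (x - a) / (b - a)
    if b == c:  # right shoulder: full membership up to the foot
        return 1.0
    return (c - x) / (c - b)


def evaluate_membership_grid(mf: TriangularMF, x) -> "np.ndarray":
    """Vectorised :func:`evaluate_membership` over an array of values."""
    import numpy as np

    x = np.asarray(x, dtype=float)
    a, b, c = mf.left, mf.peak, mf.right
    if a == b == c:
        return (x == b).astype(float)
    rise = (x - a) / (b - a) if b > a else np.ones_like(x)
    fall = (c - x) / (c - b) if c > b else np.ones_like(x)
    y = np.where(x < b, rise, fall)
    y = np.clip(y, 0.0, 1.0)
    y[(x < a) | (x > c)] = 0.0
    return y


@dataclass(frozen=True)
class LinguisticTerm:
    label: str
    mf: TriangularMF


@dataclass(frozen=True)
class LinguisticVariable:
    """A named factor on [0, 1] with an ordered sequence of linguistic terms."""

    name: str
    terms: tuple[LinguisticTerm, ...]
    universe: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate term labels in variable {self.name!r}")
        peaks = [t.mf.peak for t in self.terms]
        if any(b <= a for a, b in zip(peaks, peaks[1:])):
            raise ValueError(
                f"term peaks must be strictly increasing in variable {self.name!r}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    def term(self, label: str) -> LinguisticTerm:
        slug = slugify(label)
        for t in self.terms:
            if t.label == label or slugify(t.label) == slug:
                return t
        raise KeyError(f"variable {self.name!r} has no term {label!r}")

    def __contains__(self, label: str) -> bool:
        try:
            self.term(label)
            return True
        except KeyError:
            return False


def fuzzify(var: LinguisticVariable, x: float) -> dict[str, float]:
    """Membership degree of ``x`` in every term of ``var``.

    ``x`` must lie in the variable's universe.  Under the default uniform
    layout the degrees sum to 1 and at most two are nonzero.
    """
    lo, hi = var.universe
    if not (math.isfinite(x) and lo <= x <= hi):
        raise ValueError(
            f"value {x!r} outside universe [{lo}, {hi}] of variable {var.name!r}"
        )
    return {t.label: evaluate_membership(t.mf, x) for t in var.terms}


def fuzzy_connective(mode: str, degrees) -> float:
    """Combine membership degrees: ``and`` -> min, ``or`` -> max, ``not`` -> 1 - mu."""
    degrees = list(degrees)
    if not degrees:
        raise ValueError("fuzzy connective requires at least one degree")
    for d in degrees:
        if not (0.0 <= d <= 1.0):
            raise ValueError(f"membership degree {d!r} outside [0, 1]")
    if mode == "and":
        return min(degrees)
    if mode == "or":
        return max(degrees)
    if mode == "not":
        if len(degrees) != 1:
            raise ValueError("'not' takes exactly one degree")
        return 1.0 - degrees[0]
    raise ValueError(f"unknown connective {mode!r}")


def uniform_variable(
    name: str, labels, peaks=None
) -> LinguisticVariable:
    """Build a variable whose terms triangulate [0, 1].

    With the default ``peaks=None`` the peaks are equally spaced (uniform
    partition).  Explicit ``peaks`` must be strictly increasing within [0, 1];
    feet are always placed at the adjacent peaks, the first/last terms are
    shoulders clamped at 0 and 1, so any peak layout remains a partition of
    unity.
    """
    labels = tuple(labels)
    k = len(labels)
    if k < 2:
        raise ValueError("a linguistic variable needs at least two terms")
    if peaks is None:
        peaks = [i / (k - 1) for i in range(k)]
    peaks = [float(p) for p in peaks]
    if len(peaks) != k:
        raise ValueError("one peak per term required")
    terms = []
    for i, (label, p) in enumerate(zip(labels, peaks)):
        left = peaks[i - 1] if i > 0 else 0.0
        right = peaks[i + 1] if i < k - 1 else 1.0
        if i == 0:
            left = min(left, p)
        if i == k - 1:
            right = max(right, p)
        terms.append(LinguisticTerm(label, TriangularMF(left, p, right)))
    return LinguisticVariable(name=name, terms=tuple(terms))


def default_variables() -> dict[str, LinguisticVariable]:
    """The five instrument variables under the uniform default layout."""
    return {
        name: uniform_variable(name, labels)
        for name, labels in DEFAULT_TERM_SETS.items()
    }


def load_variables(path) -> dict[str, LinguisticVariable]:
    """Load linguistic-variable definitions from a YAML config.

    Schema per variable::

        PCG:
          terms: [normal mental health, labile, depressed, anxious]
          mfs:                      # optional; omit for the uniform default
            - [0.0, 0.0, 0.4]
            - ...

    An entry may also give ``peaks: [...]`` instead of full triples.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"variable config {path} must map names to definitions")
    out: dict[str, LinguisticVariable] = {}
    for name, entry in raw.items():
        labels = tuple(entry["terms"])
        if "mfs" in entry and entry["mfs"] is not None:
            triples = entry["mfs"]
            if len(triples) != len(labels):
                raise ValueError(f"variable {name!r}: one MF triple per term required")
            terms = tuple(
                LinguisticTerm(lab, TriangularMF(*map(float, tri)))
                for lab, tri in zip(labels, triples)
            )
            out[name] = LinguisticVariable(name=name, terms=terms)
        else:
            out[name] = uniform_variable(name, labels, peaks=entry.get("peaks"))
    return out


def save_variables(variables: dict[str, LinguisticVariable], path) -> None:
    doc = {
        name: {
            "terms": list(var.labels),
            "mfs": [[t.mf.left, t.mf.peak, t.mf.right] for t in var.terms],
        }
        for name, var in variables.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
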