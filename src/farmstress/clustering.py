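"""K-means clustering of factor profiles for rule-base construction.

Clustering serves two purposes in the pipeline: choosing how many fuzzy rules
the rule base needs (one rule per cluster, the count picked by mean
silhouette), and seeding candidate rule antecedents from the cluster centers
— each center coordinate is mapped to the linguistic term with maximal
membership at that coordinate, and the center's WRS coordinate supplies the
consequent term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .fuzzy_core import LinguisticVariable, fuzzify
from .rule_mining import AssociationRule, FuzzyItem

__all__ = [
    "ClusterModel",
    "FACTOR_ORDER",
    "fit_kmeans",
    "select_rule_count",
    "centers_to_rules",
]

FACTOR_ORDER = ("PCG", "FIN", "SCF", "TECH", "WRS")


@dataclass(frozen=True)
class ClusterModel:
    k: int
    centers: np.ndarray  # (k, n_features) in FACTOR_ORDER
    assignments: dict[str, int]
    inertia: float
    seed: int
    feature_names: tuple[str, ...] = FACTOR_ORDER


def _profile_matrix(profiles, with_outcome: bool = True):
    profiles = list(profiles)
    names = [n for n in FACTOR_ORDER if with_outcome or n != "WRS"]
    rows, ids = [], []
    for p in profiles:
        scores = p.as_dict()
        if "WRS" not in scores:
            names = [n for n in names if n != "WRS"]
        rows.append([scores[n] for n in names])
        ids.append(p.respondent_id)
    return np.asarray(rows, dtype=float), ids, tuple(names)


def fit_kmeans(profiles, k: int, seed: int = 0) -> ClusterModel:
    """Lloyd K-means, best of 10 restarts, deterministic given seed."""
    X, ids, names = _profile_matrix(profiles)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} available profiles")
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, tol=1e-6, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterModel(
        k=k,
        centers=km.cluster_centers_,
        assignments=dict(zip(ids, labels.tolist())),
        inertia=float(km.inertia_),
        seed=seed,
        feature_names=names,
    )


def select_rule_count(profiles, k_range, seed: int = 0, tie_margin: float = 0.01) -> int:
    """The k in ``k_range`` maximising mean Euclidean silhouette.

    Near-ties resolve to the smaller k: the smallest k whose silhouette is
    within ``tie_margin`` of the maximum wins.  On structureless data every
    split scores about the same, so the selection floors at min(k_range)
    rather than chasing silhouette noise.
    """
    ks = sorted(set(int(k) for k in k_range))
    X, _, _ = _profile_matrix(profiles)
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 2 or ks[-1] > len(X) - 1:
        raise ValueError(f"k range {ks[0]}..{ks[-1]} outside [2, n-1] for n={len(X)}")
    scores: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, max_iter=300, tol=1e-6, random_state=seed)
        labels = km.fit_predict(X)
        if len(set(labels)) < 2:
            continue
        scores[k] = silhouette_score(X, labels, metric="euclidean")
    if not scores:
        raise ValueError("silhouette undefined for every k in range")
    best = max(scores.values())
    return min(k for k, s in scores.items() if s >= best - tie_margin)


def centers_to_rules(
    model: ClusterModel, variables: dict[str, LinguisticVariable]
) -> list[AssociationRule]:
    """One candidate rule per cluster center, duplicates merged.

    Per input variable the antecedent takes the term with maximal membership
    at the center coordinate; membership ties resolve to the lower-index
    (more moderate) term.  The consequent is the analogous WRS term.
    """
    missing = [n for n in model.feature_names if n not in variables]
    if missing:
        raise KeyError(f"variables missing for cluster features {missing!r}")
    if "WRS" not in model.feature_names:
        raise ValueError("cluster model lacks a WRS coordinate; cannot form consequents")
    rules: list[AssociationRule] = []
    seen = set()
    for center in model.centers:
        items = {}
        for name, coord in zip(model.feature_names, center):
            var = variables[name]
            degrees = fuzzify(var, float(np.clip(coord, *var.universe)))
            # max membership; near-ties (within float noise of 0.5/0.5)
            # resolve to the earlier (more moderate) term
            best = max(
                var.labels,
                key=lambda lab: (round(degrees[lab], 9), -var.labels.index(lab)),
            )
            items[name] = FuzzyItem(name, best)
        rule = AssociationRule(
            antecedent=frozenset(v for k, v in items.items() if k != "WRS"),
            consequent=items["WRS"],
        )
        key = (rule.antecedent, rule.consequent)
        if key not in seen:
            seen.add(key)
            rules.append(rule)
    return rules
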