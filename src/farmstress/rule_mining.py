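"""Fuzzy association rule mining (fuzzy Apriori).

Each respondent becomes a *fuzzy transaction*: their membership degree in
every (variable, term) item, obtained by fuzzifying the factor profile.  The
fuzzy support of an itemset is the mean over transactions of the minimum
degree across its items (min t-norm, the same connective as the rule-firing
``and``); fuzzy confidence is the support ratio

    F-Conf(A -> B) = F-Supp(A u B) / F-Supp(A).

With crisp 0/1 memberships both reduce exactly to classical support and
confidence, and the min t-norm preserves downward closure, so frequent fuzzy
itemsets can be mined levelwise exactly as in classical Apriori.  Mined rules
conclude on a single WRS term, are annotated with lift and a chi-square
p-value (2x2 contingency at the 0.5 alpha-cut), and redundant specialisations
(a superset antecedent that is no more confident than a retained more general
rule with the same consequent) are pruned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy.stats import chi2_contingency

from .fuzzy_core import LinguisticVariable, fuzzify, slugify

__all__ = [
    "FuzzyItem",
    "FuzzyTransaction",
    "AssociationRule",
    "build_transactions",
    "f_support",
    "f_confidence",
    "mine_rules",
    "chi_square_filter",
    "prune_redundant",
    "format_rule",
    "parse_rule_line",
    "save_rules",
    "load_rules",
]

logger = logging.getLogger(__name__)

OUTCOME_VARIABLE = "WRS"


@dataclass(frozen=True, order=True)
class FuzzyItem:
    variable: str
    term: str

    def token(self) -> str:
        return f"{self.variable}={slugify(self.term)}"


@dataclass(frozen=True)
class FuzzyTransaction:
    respondent_id: str
    degrees: dict[FuzzyItem, float]

    def degree(self, item: FuzzyItem) -> float:
        return self.degrees.get(item, 0.0)


@dataclass(frozen=True)
class AssociationRule:
    """Antecedent items (one term per input variable at most) -> one WRS term."""

    antecedent: frozenset[FuzzyItem]
    consequent: FuzzyItem
    support: float = float("nan")
    confidence: float = float("nan")
    lift: float = float("nan")
    chi2_p: float = float("nan")

    @property
    def items(self) -> frozenset[FuzzyItem]:
        return self.antecedent | {self.consequent}

    def same_pattern(self, other: "AssociationRule") -> bool:
        return self.antecedent == other.antecedent and self.consequent == other.consequent


class MiningInputError(ValueError):
    pass


def build_transactions(profiles, variables: dict[str, LinguisticVariable],
                       require_outcome: bool = True) -> list[FuzzyTransaction]:
    """Fuzzify factor profiles into transactions over every (variable, term) item."""
    txns = []
    for p in profiles:
        scores = p.as_dict()
        if require_outcome and OUTCOME_VARIABLE not in scores:
            raise MiningInputError(
                f"respondent {p.respondent_id!r} has no observed WRS score; "
                "rule mining needs the outcome"
            )
        degrees: dict[FuzzyItem, float] = {}
        for name, var in variables.items():
            if name not in scores:
                continue
            for label, mu in fuzzify(var, scores[name]).items():
                degrees[FuzzyItem(name, label)] = mu
        txns.append(FuzzyTransaction(p.respondent_id, degrees))
    return txns


def _degree_matrix(txns, items):
    """(n_txn, n_item) degree array for vectorised support computation."""
    items = list(items)
    mat = np.empty((len(txns), len(items)))
    for j, it in enumerate(items):
        mat[:, j] = [t.degree(it) for t in txns]
    return mat


def f_support(itemset, txns) -> float:
    """Mean over transactions of the min degree across the itemset (min t-norm)."""
    itemset = list(itemset)
    if not itemset:
        raise MiningInputError("fuzzy support of an empty itemset is undefined")
    txns = list(txns)
    if not txns:
        raise MiningInputError("fuzzy support over zero transactions is undefined")
    return float(_degree_matrix(txns, itemset).min(axis=1).mean())


def f_confidence(antecedent, consequent, txns) -> float:
    """F-Supp(antecedent u consequent) / F-Supp(antecedent)."""
    antecedent = set(antecedent)
    cons = set(consequent) if not isinstance(consequent, FuzzyItem) else {consequent}
    supp_a = f_support(antecedent, txns)
    if supp_a == 0.0:
        raise MiningInputError("confidence undefined: antecedent has zero fuzzy support")
    return f_support(antecedent | cons, txns) / supp_a


def mine_rules(
    txns,
    min_support: float,
    min_confidence: float,
    max_antecedent: int = 4,
    outcome_variable: str = OUTCOME_VARIABLE,
) -> list[AssociationRule]:
    """Levelwise fuzzy Apriori restricted to rules with a single WRS consequent.

    Frequent itemsets contain at most one term per variable (terms of one
    variable are mutually exclusive alternatives, and their min-combined
    degrees are tiny by construction).  Rules are sorted by confidence desc,
    support desc, antecedent size asc, then lexically for determinism.
    """
    if not (0.0 < min_support <= 1.0):
        raise ValueError(f"min_support {min_support!r} outside (0, 1]")
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError(f"min_confidence {min_confidence!r} outside [0, 1]")
    txns = list(txns)
    if not txns:
        raise MiningInputError("no transactions to mine")

    universe = sorted({it for t in txns for it in t.degrees})
    mat = _degree_matrix(txns, universe)
    index = {it: j for j, it in enumerate(universe)}

    def supp_of(cols) -> float:
        return float(mat[:, cols].min(axis=1).mean())

    # L1
    supports: dict[frozenset[FuzzyItem], float] = {}
    frequent_prev = []
    for it in universe:
        s = supp_of([index[it]])
        if s >= min_support:
            supports[frozenset([it])] = s
            frequent_prev.append(frozenset([it]))

    outcome_items = [it for it in universe if it.variable == outcome_variable]
    if not any(frozenset([it]) in supports for it in outcome_items):
        logger.warning(
            "no %s term reaches min_support=%.3f; no rules can be generated",
            outcome_variable, min_support,
        )

    all_frequent = dict(supports)
    max_size = max_antecedent + 1  # antecedent items plus one consequent
    size = 1
    while frequent_prev and size < max_size:
        size += 1
        candidates = set()
        for a, b in combinations(frequent_prev, 2):
            union = a | b
            if len(union) != size:
                continue
            if len({it.variable for it in union}) != size:
                continue  # one term per variable
            if sum(it.variable == outcome_variable for it in union) > 1:
                continue
            # downward closure pre-check
            if any(frozenset(sub) not in all_frequent
                   for sub in combinations(union, size - 1)):
                continue
            candidates.add(union)
        frequent_prev = []
        for cand in sorted(candidates, key=lambda s: sorted(it.token() for it in s)):
            s = supp_of([index[it] for it in cand])
            if s >= min_support:
                all_frequent[cand] = s
                frequent_prev.append(cand)

    rules = []
    for itemset, supp in all_frequent.items():
        cons = [it for it in itemset if it.variable == outcome_variable]
        if len(cons) != 1 or len(itemset) < 2:
            continue
        consequent = cons[0]
        antecedent = frozenset(itemset - {consequent})
        supp_a = all_frequent[antecedent]
        conf = supp / supp_a
        if conf < min_confidence:
            continue
        supp_c = all_frequent.get(frozenset([consequent]))
        if supp_c is None:
            supp_c = supp_of([index[consequent]])
        rules.append(
            AssociationRule(
                antecedent=antecedent,
                consequent=consequent,
                support=supp,
                confidence=conf,
                lift=conf / supp_c if supp_c > 0 else float("inf"),
            )
        )
    rules.sort(
        key=lambda r: (
            -r.confidence,
            -r.support,
            len(r.antecedent),
            sorted(it.token() for it in r.antecedent),
            r.consequent.token(),
        )
    )
    return rules


def chi_square_filter(rules, txns, alpha: float = 0.05, alpha_cut: float = 0.5):
    """Keep rules whose antecedent/consequent co-occurrence is significant.

    The 2x2 contingency table counts transactions by antecedent-present vs
    consequent-present at the ``alpha_cut`` level on min-combined degrees;
    Pearson chi-square with continuity correction.  Rules with a zero margin
    are untestable and dropped with p recorded as 1.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha {alpha!r} outside (0, 1)")
    txns = list(txns)
    kept = []
    for rule in rules:
        ants = list(rule.antecedent)
        a_deg = _degree_matrix(txns, ants).min(axis=1) if ants else np.ones(len(txns))
        c_deg = np.array([t.degree(rule.consequent) for t in txns])
        a = a_deg >= alpha_cut
        c = c_deg >= alpha_cut
        table = np.array(
            [
                [np.sum(a & c), np.sum(a & ~c)],
                [np.sum(~a & c), np.sum(~a & ~c)],
            ]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p = 1.0
        else:
            p = float(chi2_contingency(table, correction=True).pvalue)
        rule = replace(rule, chi2_p=p)
        if p < alpha:
            kept.append(rule)
    return kept


def prune_redundant(rules):
    """Drop rules dominated by a retained, more general rule.

    A rule is redundant when another retained rule with the same consequent
    has a strict-subset antecedent and confidence at least as high.  Rules are
    scanned in mined order (most confident first), so a dominated
    specialisation is removed even in chains.
    """
    kept: list[AssociationRule] = []
    for rule in rules:
        dominated = any(
            k.consequent == rule.consequent
            and k.antecedent < rule.antecedent
            and k.confidence >= rule.confidence
            for k in kept
        )
        if not dominated:
            kept.append(rule)
    return kept


# --------------------------------------------------------------------------
# rule-base file format (.frb): one rule per line,
#   PCG=depressed & FIN=deteriorating => WRS=extremely_high | support=0.56 ...
# Numbers are serialised with repr() so save -> load is bit-exact.
# --------------------------------------------------------------------------

def _resolve_term(variables, var_name: str, token: str) -> str:
    if variables is None:
        return token
    if var_name not in variables:
        raise KeyError(f"unknown variable {var_name!r} in rule base")
    return variables[var_name].term(token).label


def format_rule(rule: AssociationRule) -> str:
    ants = " & ".join(it.token() for it in sorted(rule.antecedent))
    stats = (
        f"support={rule.support!r} confidence={rule.confidence!r} "
        f"lift={rule.lift!r} p={rule.chi2_p!r}"
    )
    return f"{ants} => {rule.consequent.token()} | {stats}"


def parse_rule_line(line: str, variables=None, rule_index: int | None = None):
    where = f"rule {rule_index}" if rule_index is not None else "rule"
    try:
        body, stats_part = line.split("|", 1)
        ant_part, cons_part = body.split("=>", 1)
        stats = {}
        for tok in stats_part.split():
            k, v = tok.split("=", 1)
            stats[k] = float(v)
        ants = set()
        ant_part = ant_part.strip()
        if ant_part:
            for tok in ant_part.split("&"):
                var, term = tok.strip().split("=", 1)
                ants.add(FuzzyItem(var.strip(), _resolve_term(variables, var.strip(), term.strip())))
        cvar, cterm = cons_part.strip().split("=", 1)
        consequent = FuzzyItem(cvar.strip(), _resolve_term(variables, cvar.strip(), cterm.strip()))
    except KeyError as exc:
        raise ValueError(f"{where}: {exc.args[0]}") from None
    except Exception as exc:
        raise ValueError(f"{where}: malformed rule line {line!r}: {exc}") from None
    return AssociationRule(
        antecedent=frozenset(ants),
        consequent=consequent,
        support=stats.get("support", float("nan")),
        confidence=stats.get("confidence", float("nan")),
        lift=stats.get("lift", float("nan")),
        chi2_p=stats.get("p", float("nan")),
    )


def save_rules(rules, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# farmstress rule base v1\n")
        for rule in rules:
            fh.write(format_rule(rule) + "\n")


def load_rules(path, variables=None) -> list[AssociationRule]:
    rules = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rules.append(parse_rule_line(line, variables, rule_index=len(rules) + 1))
    return rules
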