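"""Survey ingestion and factor scoring.

Reads respondent-level survey tables (CSV: demographic columns followed by
Likert item columns), validates them against an instrument schema, and reduces
each respondent to a profile of factor scores on [0, 1]:

* PCG (psychological), FIN (financial), TECH (technological) and the observed
  WRS outcome are loading-weighted means of the retained Likert items,
  normalised by answer/4 (the instrument anchors 0 = "Not at All" through
  4 = "Extremely").
* SCF (socio-demographic) is not a Likert block: it is scored as the
  equally-weighted share of risk-aligned demographic indicators (younger age
  band, single, opposes lockdown, social-media/internet news source, fewer
  than five cohabitants, little outdoor time before lockdown).

Items that failed the latent-variable weighting step of the instrument's
validation (the WRS-1..4 workload/management/support block, PCG-2, PCG-13 and
FIN-5) are excluded from scoring by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InstrumentSchema",
    "SurveyResponse",
    "FactorProfile",
    "default_schema",
    "read_survey",
    "write_survey",
    "compute_factor_scores",
    "score_survey",
    "compute_correlations",
    "SurveyFormatError",
    "SurveyValidationError",
    "UnscorableFactorError",
]

LIKERT_LEVELS = (0, 1, 2, 3, 4)

#: Standardised loadings of each retained item on its own factor.
DEFAULT_WEIGHTS: dict[str, tuple[str, float]] = {
    # financial block
    "FIN-1": ("FIN", 0.173),
    "FIN-2": ("FIN", 0.466),
    "FIN-3": ("FIN", 0.850),
    "FIN-4": ("FIN", 0.412),
    "FIN-6": ("FIN", 0.630),
    # psychological block
    "PCG-1": ("PCG", 0.590),
    "PCG-3": ("PCG", 0.632),
    "PCG-4": ("PCG", 0.393),
    "PCG-5": ("PCG", 0.628),
    "PCG-6": ("PCG", 0.482),
    "PCG-7": ("PCG", 0.350),
    "PCG-8": ("PCG", 0.606),
    "PCG-9": ("PCG", 0.464),
    "PCG-10": ("PCG", 0.848),
    "PCG-11": ("PCG", 0.810),
    "PCG-12": ("PCG", 0.390),
    "PCG-14": ("PCG", 0.238),
    "PCG-15": ("PCG", 0.346),
    # stress/anxiety outcome block (technology & teamwork items retained)
    "WRS-5": ("WRS", 0.697),
    "WRS-6": ("WRS", 0.745),
    # items dropped in the instrument validation for extremely low loadings;
    # they remain part of the survey form but never enter scoring
    "WRS-1": ("WRS", 0.0),
    "WRS-2": ("WRS", 0.0),
    "WRS-3": ("WRS", 0.0),
    "WRS-4": ("WRS", 0.0),
    "PCG-2": ("PCG", 0.0),
    "PCG-13": ("PCG", 0.0),
    "FIN-5": ("FIN", 0.0),
    # technological block placeholders; third weight is the mean of the two
    # printed technology/teamwork loadings
    "TECH-1": ("TECH", 0.697),
    "TECH-2": ("TECH", 0.745),
    "TECH-3": ("TECH", 0.721),
}

#: Items dropped for extremely low loadings in the instrument validation.
DEFAULT_EXCLUDED: frozenset[str] = frozenset(
    {"WRS-1", "WRS-2", "WRS-3", "WRS-4", "PCG-2", "PCG-13", "FIN-5"}
)

DEFAULT_DEMOGRAPHICS: dict[str, tuple[str, ...] | None] = {
    "gender": ("female", "male"),
    "age_group": ("18-29", "30-39", "40-49", "50-60"),
    "marital_status": ("single", "married"),
    "nationality": ("saudi", "non-saudi"),
    "sector": ("public", "private"),
    "occupation": (
        "nurse",
        "medical doctor",
        "health technician",
        "medical secretary",
        "dentist",
        "physiotherapist",
        "pharmacist",
        "engineer",
        "other",
    ),
    "cohabitants": None,  # numeric
    "outdoor_hours": None,  # numeric, pre-lockdown hours/day
    "lockdown_opinion": ("supports", "opposes"),
    "info_source": ("journal", "tv", "internet", "social media"),
}

#: Demographic indicators that align with higher socio-demographic stress risk.
SCF_RISK_INDICATORS = (
    "younger",  # age_group == 18-29
    "single",  # marital_status == single
    "opposes_lockdown",
    "media_news",  # internet / social media info source
    "few_cohabitants",  # < 5 people in the household
    "low_outdoor_time",  # < 2 h/day outside before lockdown
)


class SurveyFormatError(ValueError):
    """Structural problem with a survey file (missing header, unknown column)."""


class SurveyValidationError(ValueError):
    """A cell value violates the instrument schema."""


class UnscorableFactorError(ValueError):
    """Too few answered items to score a factor."""


@dataclass(frozen=True)
class InstrumentSchema:
    """Item → (factor, weight) map plus exclusions and demographic fields."""

    items: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    excluded: frozenset[str] = DEFAULT_EXCLUDED
    demographic_fields: dict[str, tuple[str, ...] | None] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS)
    )

    def __post_init__(self) -> None:
        for item, (factor, w) in self.items.items():
            if w < 0:
                raise ValueError(f"negative weight for item {item!r}")
        for factor in self.factors:
            if not any(
                f == factor and w > 0 and item not in self.excluded
                for item, (f, w) in self.items.items()
            ):
                raise ValueError(f"factor {factor!r} has no retained weighted item")

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(f for f, _ in self.items.values()))

    def retained_items(self, factor: str) -> list[str]:
        return [
            item
            for item, (f, _) in self.items.items()
            if f == factor and item not in self.excluded
        ]


@dataclass(frozen=True)
class SurveyResponse:
    respondent_id: str
    demographics: dict[str, object]
    answers: dict[str, int]


@dataclass(frozen=True)
class FactorProfile:
    """Per-respondent factor scores on [0, 1]; the fuzzy-inference input vector."""

    respondent_id: str
    pcg: float
    fin: float
    scf: float
    tech: float
    wrs_observed: float | None = None

    def __post_init__(self) -> None:
        for name in ("pcg", "fin", "scf", "tech"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score {v!r} outside [0, 1]")
        if self.wrs_observed is not None and not (0.0 <= self.wrs_observed <= 1.0):
            raise ValueError(f"wrs_observed {self.wrs_observed!r} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        d = {
            "PCG": self.pcg,
            "FIN": self.fin,
            "SCF": self.scf,
            "TECH": self.tech,
        }
        if self.wrs_observed is not None:
            d["WRS"] = self.wrs_observed
        return d


def default_schema() -> InstrumentSchema:
    return InstrumentSchema()


def load_schema(path) -> InstrumentSchema:
    """Load an instrument schema from YAML (items/excluded/demographics keys)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    items = {
        item: (str(spec["factor"]), float(spec["weight"]))
        for item, spec in raw["items"].items()
    }
    excluded = frozenset(raw.get("excluded", ()))
    demo = raw.get("demographic_fields")
    if demo is None:
        demo = dict(DEFAULT_DEMOGRAPHICS)
    else:
        demo = {k: (tuple(v) if v is not None else None) for k, v in demo.items()}
    return InstrumentSchema(items=items, excluded=excluded, demographic_fields=demo)


def save_schema(schema: InstrumentSchema, path) -> None:
    doc = {
        "items": {
            item: {"factor": f, "weight": w} for item, (f, w) in schema.items.items()
        },
        "excluded": sorted(schema.excluded),
        "demographic_fields": {
            k: (list(v) if v is not None else None)
            for k, v in schema.demographic_fields.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _parse_answer(raw: str, respondent: str, item: str, line: int) -> int | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = int(raw)
    except ValueError:
        raise SurveyValidationError(
            f"line {line}: respondent {respondent!r}, item {item}: "
            f"non-integer answer {raw!r}"
        ) from None
    if value not in LIKERT_LEVELS:
        raise SurveyValidationError(
            f"line {line}: respondent {respondent!r}, item {item}: "
            f"answer {value} outside the 0-4 Likert range"
        )
    return value


def read_survey(path, schema: InstrumentSchema | None = None) -> list[SurveyResponse]:
    """Read and validate a survey CSV; one respondent per row."""
    schema = schema or default_schema()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SurveyFormatError(f"{path}: empty file, header row required") from None
        header = [h.strip() for h in header]
        if not header or header[0] != "respondent_id":
            raise SurveyFormatError(
                f"{path}: first column must be 'respondent_id', got {header[:1]!r}"
            )
        demo_cols = [c for c in header[1:] if c in schema.demographic_fields]
        item_cols = [c for c in header[1:] if c in schema.items]
        unknown = [
            c for c in header[1:] if c not in schema.demographic_fields and c not in schema.items
        ]
        if unknown:
            raise SurveyFormatError(f"{path}: unknown columns {unknown!r}")
        idx = {c: i for i, c in enumerate(header)}
        responses: list[SurveyResponse] = []
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise SurveyFormatError(
                    f"{path}: line {line_no}: expected {len(header)} fields, got {len(row)}"
                )
            rid = row[idx["respondent_id"]].strip()
            demographics: dict[str, object] = {}
            for c in demo_cols:
                raw = row[idx[c]].strip()
                allowed = schema.demographic_fields[c]
                if allowed is None:
                    demographics[c] = float(raw) if raw != "" else None
                else:
                    if raw not in allowed:
                        raise SurveyValidationError(
                            f"line {line_no}: respondent {rid!r}, field {c}: "
                            f"category {raw!r} not in {allowed!r}"
                        )
                    demographics[c] = raw
            answers = {}
            for c in item_cols:
                val = _parse_answer(row[idx[c]], rid, c, line_no)
                if val is not None:
                    answers[c] = val
            responses.append(SurveyResponse(rid, demographics, answers))
    return responses


def write_survey(responses, path, schema: InstrumentSchema | None = None) -> None:
    """Write responses as CSV in canonical column order (round-trips read_survey)."""
    schema = schema or default_schema()
    responses = list(responses)
    demo_cols = list(schema.demographic_fields)
    item_cols = [c for c in schema.items]
    header = ["respondent_id", *demo_cols, *item_cols]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in responses:
            row = [r.respondent_id]
            for c in demo_cols:
                v = r.demographics.get(c)
                if v is None:
                    row.append("")
                elif isinstance(v, float):
                    row.append(repr(v))
                else:
                    row.append(str(v))
            for c in item_cols:
                a = r.answers.get(c)
                row.append("" if a is None else str(a))
            writer.writerow(row)


def _scf_score(demographics: dict[str, object]) -> float:
    """Equally-weighted share of risk-aligned demographic indicators."""
    flags = []
    age = demographics.get("age_group")
    if age is not None:
        flags.append(age == "18-29")
    marital = demographics.get("marital_status")
    if marital is not None:
        flags.append(marital == "single")
    lockdown = demographics.get("lockdown_opinion")
    if lockdown is not None:
        flags.append(lockdown == "opposes")
    source = demographics.get("info_source")
    if source is not None:
        flags.append(source in ("internet", "social media"))
    cohab = demographics.get("cohabitants")
    if cohab is not None:
        flags.append(float(cohab) < 5)
    outdoor = demographics.get("outdoor_hours")
    if outdoor is not None:
        flags.append(float(outdoor) < 2)
    if not flags:
        return 0.0
    return float(sum(flags)) / len(flags)


def compute_factor_scores(
    resp: SurveyResponse,
    schema: InstrumentSchema | None = None,
    min_answered: float = 0.5,
) -> FactorProfile:
    """Weighted-mean factor scores for one respondent.

    score(factor) = sum_i w_i * (answer_i / 4) / sum_i w_i over the retained,
    answered items of the factor.  A factor with fewer than ``min_answered``
    of its retained items answered is unscorable.
    """
    schema = schema or default_schema()
    scores: dict[str, float] = {}
    for factor in schema.factors:
        retained = schema.retained_items(factor)
        answered = [i for i in retained if i in resp.answers]
        if len(answered) < min_answered * len(retained) or not answered:
            raise UnscorableFactorError(
                f"respondent {resp.respondent_id!r}: factor {factor} has "
                f"{len(answered)}/{len(retained)} retained items answered"
            )
        wsum = sum(schema.items[i][1] for i in answered)
        scores[factor] = (
            sum(schema.items[i][1] * resp.answers[i] / 4.0 for i in answered) / wsum
        )
    return FactorProfile(
        respondent_id=resp.respondent_id,
        pcg=scores["PCG"],
        fin=scores["FIN"],
        scf=_scf_score(resp.demographics),
        tech=scores["TECH"],
        wrs_observed=scores.get("WRS"),
    )


def score_survey(responses, schema: InstrumentSchema | None = None) -> list[FactorProfile]:
    schema = schema or default_schema()
    return [compute_factor_scores(r, schema) for r in responses]


def profiles_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "respondent_id": p.respondent_id,
                "PCG": p.pcg,
                "FIN": p.fin,
                "SCF": p.scf,
                "TECH": p.tech,
                "WRS": p.wrs_observed,
            }
        )
    return pd.DataFrame(rows)


def compute_correlations(
    profiles, extra: dict[str, object] | pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix over factor scores and numeric covariates.

    ``extra`` maps covariate name -> per-respondent numeric sequence (e.g.
    cohabitants, outdoor hours).  Raises on constant columns, where the
    correlation is undefined.
    """
    frame = profiles_to_frame(profiles).drop(columns=["respondent_id"])
    if frame["WRS"].isna().all():
        frame = frame.drop(columns=["WRS"])
    if extra is not None:
        extra = pd.DataFrame(extra)
        extra.index = frame.index
        frame = pd.concat([frame, extra], axis=1)
    if len(frame) < 3:
        raise ValueError("correlation requires at least 3 respondents")
    stds = frame.std(ddof=0)
    constant = [c for c in frame.columns if stds[c] == 0]
    if constant:
        raise ValueError(f"correlation undefined for constant column(s) {constant!r}")
    return frame.corr(method="pearson")
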