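"""Synthetic survey cohorts with the statistical structure of the study data.

The study's respondent-level data are private, so the pipeline is exercised
on synthetic cohorts built to match the published summary structure:

* cohort size 204 with exact occupation strata (41 nurses, 21 medical
  doctors, 19 health technicians, 16 medical secretaries, 44 dentists,
  12 physiotherapists, 18 pharmacists, 11 engineers, 22 other staff);
* the published pairwise Pearson correlations among the psychological (PCG),
  financial (FIN) and stress (WRS) factor scores and the cohabitants /
  pre-lockdown outdoor-time covariates;
* the published factor-score skewness coefficients (WRS 0.0167,
  FIN -0.2898, PCG 0.9295), realised through skewness-matched Beta marginals;
* the published item-level response shares (e.g. 68% of staff at the lowest
  level of the psychiatric-complaints item, 73% reporting that workload
  affected their stress).

The generator is a Gaussian copula: each margin is a Beta quantile map solved
for its (mean, skewness) pair, and each latent correlation is solved per pair
(Nataf/Hermite expansion) so that the *post-transform* Pearson correlation
hits the printed target.  Pairwise-printed tables need not be jointly
feasible, so target and latent matrices are repaired to the nearest positive
semi-definite correlation matrix by eigenvalue clipping.

A second mechanism ("rulebase") replaces the copula draw of WRS with the
Mamdani prediction of a rule base plus truncated Gaussian noise, which gives
end-to-end parameter-recovery cohorts: rules mined from such a cohort should
recover the associations that generated it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import roots_hermitenorm

from .survey_io import (
    DEFAULT_DEMOGRAPHICS,
    FactorProfile,
    InstrumentSchema,
    SurveyResponse,
    default_schema,
)

__all__ = [
    "GeneratorConfig",
    "CORRELATION_VARIABLES",
    "DEFAULT_CORRELATION_TARGETS",
    "DEFAULT_MARGINALS",
    "DEFAULT_OCCUPATION_COUNTS",
    "DEFAULT_ITEM_MARGINALS",
    "beta_from_mean_skewness",
    "nearest_psd_correlation",
    "generate_factor_scores",
    "generate_item_responses",
    "generate_cohort",
    "generate_rulebase_cohort",
]

#: Variables entering the copula, in fixed order.
CORRELATION_VARIABLES = (
    "PCG", "FIN", "WRS", "cohabitants", "outdoor_hours", "SCF", "TECH",
)

#: Published pairwise Pearson correlations (PCG/FIN/WRS/cohabitants/outdoor
#: block).  The SCF and TECH rows are not published; modest values consistent
#: with the narrative (socio-demographic risk raises stress, technology is
#: close to neutral) complete the matrix.
DEFAULT_CORRELATION_TARGETS: dict[tuple[str, str], float] = {
    ("PCG", "FIN"): 0.344,
    ("PCG", "WRS"): 0.376,
    ("FIN", "WRS"): 0.401,
    ("PCG", "cohabitants"): -0.210,
    ("FIN", "cohabitants"): 0.337,
    ("WRS", "cohabitants"): -0.269,
    ("PCG", "outdoor_hours"): 0.255,
    ("FIN", "outdoor_hours"): 0.270,
    ("WRS", "outdoor_hours"): 0.425,
    ("cohabitants", "outdoor_hours"): -0.172,
    ("SCF", "WRS"): 0.30,
    ("SCF", "PCG"): 0.25,
    ("TECH", "WRS"): 0.10,
}

#: Marginal spec per copula variable: (mean, skewness, low, high).  Means are
#: the package's calibration choices (only skewness was published for the
#: three factor scores); low/high give the affine range of the Beta margin.
DEFAULT_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "PCG": (0.25, 0.9295, 0.0, 1.0),
    "FIN": (0.60, -0.2898, 0.0, 1.0),
    "WRS": (0.494, 0.0167, 0.0, 1.0),
    "SCF": (0.35, 0.5, 0.0, 1.0),
    "TECH": (0.60, -0.3, 0.0, 1.0),
    "cohabitants": (1.0 / 3.0, 0.5, 0.0, 12.0),
    "outdoor_hours": (0.31, 0.5, 0.0, 8.0),
}

DEFAULT_OCCUPATION_COUNTS: dict[str, int] = {
    "nurse": 41,
    "medical doctor": 21,
    "health technician": 19,
    "medical secretary": 16,
    "dentist": 44,
    "physiotherapist": 12,
    "pharmacist": 18,
    "engineer": 11,
    "other": 22,
}

#: Category-probability vectors (Likert 0..4) for the items whose response
#: shares are published; the printed shares are the pinned entries, the rest
#: of each vector is the package's unimodal completion.
DEFAULT_ITEM_MARGINALS: dict[str, tuple[float, ...]] = {
    # 68% no psychiatric complaints; 8% high+extremely high
    "PCG-1": (0.68, 0.14, 0.10, 0.05, 0.03),
    # 11% negligible worry of infection; 43% (high+extreme) concerned
    "PCG-3": (0.11, 0.21, 0.25, 0.28, 0.15),
    # 14% highly/extremely helpless
    "PCG-4": (0.40, 0.26, 0.20, 0.09, 0.05),
    # 79% not skeptical of positive news / 21% very skeptical
    "PCG-5": (0.40, 0.24, 0.15, 0.12, 0.09),
    # 85% did not share virus news
    "PCG-6": (0.85, 0.07, 0.04, 0.025, 0.015),
    # 72% not at all depressed/pessimistic, 14% a little bit
    "PCG-10": (0.72, 0.14, 0.08, 0.04, 0.02),
    # mortgage/rent capacity: 15% highly, 8% extremely affected
    "FIN-1": (0.30, 0.22, 0.25, 0.15, 0.08),
    # 40% moderately affected employment
    "FIN-2": (0.20, 0.20, 0.40, 0.12, 0.08),
    # 33% with sufficient emergency resources (lowest impact level)
    "FIN-4": (0.33, 0.25, 0.22, 0.12, 0.08),
    # 30% substantial impact on debt payments
    "FIN-6": (0.28, 0.22, 0.20, 0.18, 0.12),
    # workload affected WRS for 73% (above the lowest level)
    "WRS-1": (0.27, 0.18, 0.25, 0.20, 0.10),
    # poor management: 43% high stress, 23% strongly agreeing
    "WRS-2": (0.22, 0.15, 0.20, 0.20, 0.23),
    # >60% blamed lack of support
    "WRS-3": (0.25, 0.15, 0.25, 0.20, 0.15),
    # >70% said teamwork did not contribute negatively
    "WRS-6": (0.70, 0.12, 0.08, 0.06, 0.04),
}

#: Neutral unimodal profile for items without a published distribution.
NEUTRAL_ITEM_MARGINAL = (0.30, 0.30, 0.22, 0.12, 0.06)


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that determines a synthetic cohort (given the seed)."""

    n: int = 204
    seed: int = 0
    occupation_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPATION_COUNTS)
    )
    correlation_targets: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATION_TARGETS)
    )
    marginals: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    item_marginals: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_MARGINALS)
    )
    wrs_mechanism: str = "copula"  # "copula" | "rulebase"
    rulebase_path: str | None = None
    noise_sd: float = 0.3  # latent noise linking factor scores to item answers
    wrs_noise_sd: float = 0.05  # truncation noise on rule-base WRS
    strata_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GeneratorConfigError("cohort size must be positive")
        if self.noise_sd < 0 or self.wrs_noise_sd < 0:
            raise GeneratorConfigError("noise_sd must be nonnegative")
        if self.wrs_mechanism not in ("copula", "rulebase"):
            raise GeneratorConfigError(
                f"unknown wrs_mechanism {self.wrs_mechanism!r}"
            )
        for item, probs in self.item_marginals.items():
            if len(probs) != 5 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise GeneratorConfigError(
                    f"item {item}: category probabilities must be a 5-vector summing to 1"
                )


# --------------------------------------------------------------------------
# marginals
# --------------------------------------------------------------------------

def _beta_skewness(a: float, b: float) -> float:
    return 2.0 * (b - a) * math.sqrt(a + b + 1.0) / ((a + b + 2.0) * math.sqrt(a * b))


def beta_from_mean_skewness(mean: float, skewness: float, name: str = "factor"):
    """Solve Beta(a, b) on [0, 1] matching a mean and a skewness.

    With the mean fixed, |skewness| decreases monotonically in the
    concentration a+b, with supremum (1-2m)/sqrt(m(1-m)) as a+b -> 0; a
    target beyond that bound, or with the wrong sign for the mean, is
    infeasible.
    """
    if not (0.0 < mean < 1.0):
        raise GeneratorConfigError(f"{name}: mean {mean} outside (0, 1)")
    if abs(skewness) < 1e-12:
        if abs(mean - 0.5) > 1e-9:
            raise GeneratorConfigError(
                f"{name}: zero skewness requires mean 0.5, got {mean}"
            )
        s = 10.0
        return mean * s, (1 - mean) * s
    limit = (1.0 - 2.0 * mean) / math.sqrt(mean * (1.0 - mean))
    if skewness * limit <= 0 or abs(skewness) >= abs(limit):
        raise GeneratorConfigError(
            f"{name}: skewness {skewness} infeasible for a [0,1] Beta margin "
            f"with mean {mean} (attainable range is 0..{limit:.4f})"
        )

    def f(s: float) -> float:
        return _beta_skewness(mean * s, (1 - mean) * s) - skewness

    s = brentq(f, 1e-6, 1e6, xtol=1e-12, rtol=1e-12)
    return mean * s, (1 - mean) * s


def _margin_dists(marginals):
    dists = {}
    for name, (mean, skew, lo, hi) in marginals.items():
        a, b = beta_from_mean_skewness(mean, skew, name=name)
        dists[name] = (stats.beta(a, b), lo, hi)
    return dists


# --------------------------------------------------------------------------
# correlation machinery
# --------------------------------------------------------------------------

def nearest_psd_correlation(matrix: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clipped nearest PSD approximation with unit diagonal."""
    sym = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    vals = np.clip(vals, eps, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _target_matrix(targets, variables=CORRELATION_VARIABLES) -> np.ndarray:
    k = len(variables)
    mat = np.eye(k)
    idx = {v: i for i, v in enumerate(variables)}
    for (a, b), r in targets.items():
        if a not in idx or b not in idx:
            continue
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r
    return nearest_psd_correlation(mat)


_HERMITE_ORDER = 15
_GH_NODES = 96


def _hermite_coefficients(dist) -> np.ndarray:
    """Coefficients a_k of g(z) = F^{-1}(Phi(z)) in probabilists' Hermite basis."""
    z, w = roots_hermitenorm(_GH_NODES)
    w = w / w.sum()  # normalise to the standard normal measure
    g = dist.ppf(stats.norm.cdf(z))
    coeffs = np.empty(_HERMITE_ORDER + 1)
    he_km1 = np.zeros_like(z)
    he_k = np.ones_like(z)  # He_0
    for k in range(_HERMITE_ORDER + 1):
        coeffs[k] = np.sum(w * g * he_k) / math.factorial(k)
        he_km1, he_k = he_k, z * he_k - k * he_km1  # He_{k+1} = z He_k - k He_{k-1}
    return coeffs


def _latent_rho(coeffs_i, coeffs_j, target: float) -> float:
    """Solve the latent normal correlation giving the target Pearson correlation."""
    ks = np.arange(1, _HERMITE_ORDER + 1)
    facts = np.array([math.factorial(int(k)) for k in ks], dtype=float)
    ci = coeffs_i[1:]
    cj = coeffs_j[1:]
    var_i = float(np.sum(facts * ci * ci))
    var_j = float(np.sum(facts * cj * cj))
    denom = math.sqrt(var_i * var_j)

    def corr(rho: float) -> float:
        return float(np.sum(facts * ci * cj * rho ** ks)) / denom

    lo, hi = -0.999999, 0.999999
    c_lo, c_hi = corr(lo), corr(hi)
    if target <= c_lo:
        return lo
    if target >= c_hi:
        return hi
    return brentq(lambda r: corr(r) - target, lo, hi, xtol=1e-10)


def _latent_matrix(target_mat, dists, variables=CORRELATION_VARIABLES) -> np.ndarray:
    coeffs = {v: _hermite_coefficients(dists[v][0]) for v in variables}
    k = len(variables)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            t = target_mat[i, j]
            if t == 0.0:
                continue
            latent[i, j] = latent[j, i] = _latent_rho(
                coeffs[variables[i]], coeffs[variables[j]], t
            )
    return nearest_psd_correlation(latent)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _draw_scores_frame(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    dists = _margin_dists(cfg.marginals)
    target = _target_matrix(cfg.correlation_targets)
    latent = _latent_matrix(target, dists)
    chol = np.linalg.cholesky(latent)
    z = rng.standard_normal((cfg.n, len(CORRELATION_VARIABLES))) @ chol.T
    u = stats.norm.cdf(z)
    data = {}
    for j, name in enumerate(CORRELATION_VARIABLES):
        dist, lo, hi = dists[name]
        data[name] = lo + (hi - lo) * dist.ppf(u[:, j])
    frame = pd.DataFrame(data)
    frame.insert(0, "respondent_id", [f"S{i + 1:05d}" for i in range(cfg.n)])
    return frame


def _frame_to_profiles(frame: pd.DataFrame, with_wrs: bool = True):
    profiles = []
    for row in frame.itertuples(index=False):
        profiles.append(
            FactorProfile(
                respondent_id=row.respondent_id,
                pcg=float(row.PCG),
                fin=float(row.FIN),
                scf=float(row.SCF),
                tech=float(row.TECH),
                wrs_observed=float(row.WRS) if with_wrs else None,
            )
        )
    return profiles


def generate_factor_scores(cfg: GeneratorConfig | None = None):
    """Draw a cohort of factor profiles plus covariates.

    Returns ``(profiles, frame)``: the FactorProfile list and a DataFrame
    with columns respondent_id, PCG, FIN, WRS, cohabitants, outdoor_hours,
    SCF, TECH.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    frame = _draw_scores_frame(cfg, rng)
    return _frame_to_profiles(frame), frame


def _occupation_column(cfg: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    counts = dict(cfg.occupation_counts)
    total = sum(counts.values())
    if cfg.strata_enabled and cfg.n != total:
        # largest-remainder rescaling keeps strata exact for any n
        quotas = {k: v * cfg.n / total for k, v in counts.items()}
        counts = {k: int(math.floor(q)) for k, q in quotas.items()}
        short = cfg.n - sum(counts.values())
        for k in sorted(quotas, key=lambda k: quotas[k] - math.floor(quotas[k]),
                        reverse=True)[:short]:
            counts[k] += 1
    column = [occ for occ, c in counts.items() for _ in range(c)]
    rng.shuffle(column)
    return column


def _population_quantile_fn(factor_dist, noise_sd: float):
    """CDF of (factor score + N(0, noise_sd)) via Gauss-Legendre quadrature."""
    dist, lo, hi = factor_dist
    if noise_sd == 0.0:

        def cdf0(x):
            return dist.cdf((np.asarray(x) - lo) / (hi - lo))

        return cdf0

    nodes, weights = np.polynomial.legendre.leggauss(96)
    s = lo + (hi - lo) * (nodes + 1.0) / 2.0  # factor-score nodes
    pdf = dist.pdf((s - lo) / (hi - lo)) / (hi - lo)
    w = weights * (hi - lo) / 2.0 * pdf

    def cdf(x):
        x = np.asarray(x, dtype=float)
        return np.clip(
            (w * stats.norm.cdf((x[..., None] - s) / noise_sd)).sum(axis=-1), 0, 1
        )

    return cdf


def generate_item_responses(
    frame: pd.DataFrame,
    cfg: GeneratorConfig | None = None,
    schema: InstrumentSchema | None = None,
) -> list[SurveyResponse]:
    """Draw Likert answers and demographics for a factor-score cohort.

    Each item's answer thresholds the respondent's factor score plus
    independent Gaussian noise through the population CDF, so the
    population-level category frequencies equal the item's target marginal
    exactly (up to sampling error).  Demographics are drawn by strata
    (occupations exact) and aligned with the SCF risk score.
    """
    cfg = cfg or GeneratorConfig()
    schema = schema or default_schema()
    # child seed stream: independent of the factor-score draw
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    n = len(frame)
    dists = _margin_dists(cfg.marginals)

    # --- item answers --------------------------------------------------
    answers_by_item: dict[str, np.ndarray] = {}
    cdf_cache: dict[str, object] = {}
    for item, (factor, _w) in schema.items.items():
        probs = np.asarray(
            cfg.item_marginals.get(item, NEUTRAL_ITEM_MARGINAL), dtype=float
        )
        cum = np.cumsum(probs)[:-1]
        if factor not in cdf_cache:
            cdf_cache[factor] = _population_quantile_fn(dists[factor], cfg.noise_sd)
        latent = frame[factor].to_numpy() + (
            rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
        )
        u = cdf_cache[factor](latent)
        answers_by_item[item] = np.searchsorted(cum, u, side="left")

    # --- demographics ---------------------------------------------------
    occupation = _occupation_column(cfg, rng)
    scf = frame["SCF"].to_numpy()
    cohab = frame["cohabitants"].to_numpy()
    outdoor = frame["outdoor_hours"].to_numpy()
    younger = rng.random(n) < scf
    single = rng.random(n) < scf
    opposes = rng.random(n) < scf
    media = rng.random(n) < scf

    responses = []
    for i in range(n):
        demographics = {
            "gender": "female" if rng.random() < 0.55 else "male",
            "age_group": "18-29" if younger[i] else str(
                rng.choice(["30-39", "40-49", "50-60"], p=[0.5, 0.3, 0.2])
            ),
            "marital_status": "single" if single[i] else "married",
            "nationality": "saudi" if rng.random() < 0.8 else "non-saudi",
            "sector": "public" if rng.random() < 0.6 else "private",
            "occupation": occupation[i],
            "cohabitants": float(round(cohab[i])),
            "outdoor_hours": float(round(outdoor[i], 1)),
            "lockdown_opinion": "opposes" if opposes[i] else "supports",
            "info_source": str(
                rng.choice(["internet", "social media"]) if media[i]
                else rng.choice(["journal", "tv"])
            ),
        }
        answers = {item: int(vals[i]) for item, vals in answers_by_item.items()}
        responses.append(
            SurveyResponse(str(frame["respondent_id"].iloc[i]), demographics, answers)
        )
    return responses


def generate_cohort(cfg: GeneratorConfig | None = None, schema=None):
    """Full cohort: factor profiles, covariate frame and survey responses."""
    cfg = cfg or GeneratorConfig()
    profiles, frame = generate_factor_scores(cfg)
    responses = generate_item_responses(frame, cfg, schema)
    return profiles, frame, responses


def generate_rulebase_cohort(rulebase, cfg: GeneratorConfig | None = None,
                             max_retries: int = 20):
    """Cohort whose observed WRS is produced by the rule base itself.

    Antecedent factors and covariates are drawn by the copula; each profile's
    WRS is the Mamdani prediction plus truncated N(0, wrs_noise_sd) noise.
    Profiles for which no rule fires are resampled up to ``max_retries``
    batches; a rule base leaving holes larger than that is an error.
    """
    from .inference import NoRuleFiredError, predict_many

    cfg = cfg or GeneratorConfig(wrs_mechanism="rulebase")
    if cfg.wrs_mechanism != "rulebase":
        cfg = replace(cfg, wrs_mechanism="rulebase")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0])
    profiles, frame = generate_factor_scores(cfg)

    preds = predict_many(rulebase, [
        replace(p, wrs_observed=None) for p in profiles
    ], fallback_score=float("nan"))
    scores = np.array([pr.score for pr in preds])

    retries = 0
    while np.isnan(scores).any():
        retries += 1
        if retries > max_retries:
            raise NoRuleFiredError(
                f"{int(np.isnan(scores).sum())} profiles never fired a rule "
                f"after {max_retries} resampling rounds"
            )
        holes = np.flatnonzero(np.isnan(scores))
        resample_cfg = replace(cfg, n=len(holes), seed=cfg.seed + 100_000 + retries)
        new_profiles, new_frame = generate_factor_scores(resample_cfg)
        new_preds = predict_many(
            rulebase,
            [replace(p, wrs_observed=None) for p in new_profiles],
            fallback_score=float("nan"),
        )
        for row, (idx, pr) in enumerate(zip(holes, new_preds)):
            frame.iloc[idx, 1:] = new_frame.iloc[row, 1:]
            scores[idx] = pr.score

    if cfg.wrs_noise_sd > 0:
        scores = scores + rng.normal(0.0, cfg.wrs_noise_sd, size=len(scores))
    frame["WRS"] = np.clip(scores, 0.0, 1.0)
    profiles = _frame_to_profiles(frame)
    return profiles, frame
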