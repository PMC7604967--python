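"""Cohort tables: the printed 46-patient cohort and a simulated joint model.

The original study reports only marginal distributions of the score and its
components; the joint (score, Simpson grade, outcome) data are not printed.
``reconstruct_printed_cohort`` rebuilds a deterministic 46-row table whose
score and component marginals all equal the printed counts exactly (one
integer solution of the marginal-matching transportation problem, frozen
here). ``simulate_cohort`` draws full joint tables from a proportional-odds
model so the statistical battery can be exercised and calibrated; that
model is a testing device, not a claim about the original data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

logger = logging.getLogger(__name__)

#: Printed total-score distribution over the 46 patients.
SCORE_COUNTS = {1: 5, 2: 6, 3: 3, 4: 6, 5: 3, 6: 3, 7: 7, 8: 6, 9: 5, 10: 2}
#: Printed component marginals.
VOLUME_GRADE_COUNTS = {1: 23, 2: 14, 3: 9}
ARTERIAL_SCORE_COUNTS = {0: 7, 1: 6, 2: 8, 3: 11, 4: 14}
CS_YES = 23
BONE_YES = 10
#: Printed Simpson-grade distribution (I-IV; no grade V occurred).
SIMPSON_COUNTS = {1: 10, 2: 17, 3: 15, 4: 4}
#: Printed 4-category postoperative-outcome distribution (0 worse .. 3 excellent).
OUTCOME_COUNTS = {0: 7, 1: 27, 2: 10, 3: 2}

# One integer joint assignment (volume grade, arterial score, CS points,
# bone points) -> patient count that reproduces every printed marginal with
# per-row totals equal to the component sum. Found once by integer
# programming over the 60-cell component space; frozen for determinism.
_PRINTED_JOINT = [
    ((1, 0, 0, 0), 5),
    ((1, 0, 2, 0), 1),
    ((1, 1, 0, 0), 5),
    ((1, 2, 0, 0), 1),
    ((1, 2, 0, 1), 6),
    ((1, 2, 2, 0), 1),
    ((1, 3, 2, 0), 1),
    ((1, 4, 0, 0), 2),
    ((1, 4, 2, 1), 1),
    ((2, 0, 0, 0), 1),
    ((2, 1, 0, 0), 1),
    ((2, 3, 2, 0), 7),
    ((2, 4, 0, 0), 1),
    ((2, 4, 2, 0), 4),
    ((3, 3, 0, 0), 1),
    ((3, 3, 2, 0), 1),
    ((3, 3, 2, 1), 1),
    ((3, 4, 2, 0), 4),
    ((3, 4, 2, 1), 2),
]

COHORT_COLUMNS = [
    "volume_grade",
    "arterial_score",
    "cs_involved",
    "bone_invaded",
    "total_score",
    "simpson_grade",
    "outcome_grade",
]


@dataclass
class CohortTable:
    """Per-patient rows plus a provenance tag (printed | simulated | user).

    ``simpson_grade`` (1-4) and ``outcome_grade`` (0-3) columns may be
    wholly absent (NaN) when the provenance does not supply them.
    """

    data: pd.DataFrame
    provenance: str = "user"

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("cohort table must be non-empty")
        missing = [c for c in COHORT_COLUMNS[:5] if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        comp_total = (
            self.data["volume_grade"]
            + self.data["arterial_score"]
            + 2 * self.data["cs_involved"].astype(int)
            + self.data["bone_invaded"].astype(int)
        )
        if not (comp_total == self.data["total_score"]).all():
            raise ValueError("total_score is not the sum of the four components")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_simpson(self) -> bool:
        return "simpson_grade" in self.data.columns and self.data["simpson_grade"].notna().all()

    @property
    def has_outcome(self) -> bool:
        return "outcome_grade" in self.data.columns and self.data["outcome_grade"].notna().all()


def reconstruct_printed_cohort() -> CohortTable:
    """The deterministic 46-row cohort matching every printed marginal.

    Simpson-grade and outcome columns are absent (NaN): the joint
    distribution linking them to the score was never published.
    """
    rows = []
    for (v, a, c, b), count in _PRINTED_JOINT:
        for _ in range(count):
            rows.append(
                {
                    "volume_grade": v,
                    "arterial_score": a,
                    "cs_involved": c > 0,
                    "bone_invaded": b > 0,
                    "total_score": v + a + c + b,
                    "simpson_grade": np.nan,
                    "outcome_grade": np.nan,
                }
            )
    df = pd.DataFrame(rows).sort_values(
        ["total_score", "volume_grade", "arterial_score"], kind="stable"
    )
    df = df.reset_index(drop=True)
    return CohortTable(data=df, provenance="printed")


def _combos_by_total() -> dict[int, list[tuple[int, int, int, int]]]:
    out: dict[int, list] = {}
    for v, a, c, b in itertools.product((1, 2, 3), range(5), (0, 2), (0, 1)):
        out.setdefault(v + a + c + b, []).append((v, a, c, b))
    return out


def calibrate_thresholds(
    beta: float,
    target_counts: dict[int, int],
    score_distribution: dict[int, int] | None = None,
) -> tuple[float, ...]:
    """Cumulative-logit cutpoints matching a target ordinal marginal.

    Solves, for each cumulative split k, the monotone scalar equation
    ``sum_s p(s) * sigmoid(theta_k - beta * s) = F_k`` where ``p`` is the
    score marginal and ``F_k`` the target cumulative proportion, so that a
    proportional-odds draw at the given effect size reproduces the target
    marginal on average.
    """
    score_distribution = score_distribution or SCORE_COUNTS
    scores = np.array(sorted(score_distribution))
    p = np.array([score_distribution[s] for s in scores], dtype=float)
    p /= p.sum()
    levels = sorted(target_counts)
    n = sum(target_counts.values())
    cum = np.cumsum([target_counts[k] for k in levels])[:-1] / n
    bound = 60.0 + abs(beta) * float(np.abs(scores).max())
    thetas = []
    for f in cum:
        g = lambda th: float(np.sum(p * expit(th - beta * scores))) - f
        thetas.append(brentq(g, -bound, bound))
    return tuple(thetas)


@dataclass
class CohortModel:
    """Generative joint model: scores, Simpson grades, outcomes.

    Scores are drawn from ``score_distribution`` (default: the printed
    distribution); component combinations are drawn uniformly among those
    summing to the drawn score. The Simpson grade follows a
    proportional-odds (cumulative-logit) model with common slope
    ``beta_score`` and cutpoints ``thresholds``; the 0-3 outcome follows the
    analogous model with ``outcome_beta`` (negative: higher scores worsen
    outcomes) and ``outcome_thresholds``. Unset cutpoints are calibrated so
    that the simulated marginals match the printed Simpson (10/17/15/4) and
    outcome (7/27/10/2) distributions at the given effect sizes.
    """

    n_patients: int = 46
    score_distribution: dict[int, int] = field(default_factory=lambda: dict(SCORE_COUNTS))
    ordinal_link: str = "proportional_odds"
    beta_score: float = 1.0
    thresholds: tuple[float, float, float] | None = None
    outcome_beta: float = -0.5
    outcome_thresholds: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.ordinal_link != "proportional_odds":
            raise ValueError("only the proportional_odds link is implemented")
        if any(c < 0 for c in self.score_distribution.values()):
            raise ValueError("score counts must be non-negative")
        if sum(self.score_distribution.values()) <= 0:
            raise ValueError("score distribution must have positive mass")
        if self.thresholds is None:
            self.thresholds = calibrate_thresholds(
                self.beta_score, SIMPSON_COUNTS, self.score_distribution
            )
        if self.outcome_thresholds is None:
            self.outcome_thresholds = calibrate_thresholds(
                self.outcome_beta, OUTCOME_COUNTS, self.score_distribution
            )
        for th in (self.thresholds, self.outcome_thresholds):
            if not all(a < b for a, b in zip(th, th[1:])):
                raise ValueError("thresholds must be strictly increasing")


def _draw_ordinal(
    rng: np.random.Generator,
    scores: np.ndarray,
    beta: float,
    thresholds: tuple[float, ...],
    base_level: int,
) -> np.ndarray:
    """Draw from the cumulative-logit model P(Y <= k | s) = sigmoid(theta_k - beta*s)."""
    th = np.asarray(thresholds)
    cum = expit(th[None, :] - beta * scores[:, None])  # (n, K-1)
    u = rng.uniform(size=len(scores))
    return base_level + (u[:, None] > cum).sum(axis=1)


def simulate_cohort(model: CohortModel) -> CohortTable:
    """Draw one full joint cohort from a :class:`CohortModel`; bit-reproducible per seed."""
    rng = np.random.default_rng(model.seed)
    values = np.array(sorted(model.score_distribution))
    weights = np.array([model.score_distribution[s] for s in values], dtype=float)
    weights /= weights.sum()
    if (weights > 0).sum() == 1:
        logger.warning(
            "degenerate score distribution (single value); correlations downstream are undefined"
        )
    scores = rng.choice(values, size=model.n_patients, p=weights)

    combos = _combos_by_total()
    comp = np.empty((model.n_patients, 4), dtype=int)
    for i, s in enumerate(scores):
        options = combos[int(s)]
        comp[i] = options[int(rng.integers(len(options)))]

    simpson = _draw_ordinal(rng, scores.astype(float), model.beta_score, model.thresholds, 1)
    outcome = _draw_ordinal(
        rng, scores.astype(float), model.outcome_beta, model.outcome_thresholds, 0
    )
    df = pd.DataFrame(
        {
            "volume_grade": comp[:, 0],
            "arterial_score": comp[:, 1],
            "cs_involved": comp[:, 2] > 0,
            "bone_invaded": comp[:, 3] > 0,
            "total_score": scores,
            "simpson_grade": simpson,
            "outcome_grade": outcome,
        }
    )
    return CohortTable(data=df, provenance="simulated")
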