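"""Rank candidate offspring and evaluate listener survey responses.

Players hear sonified offspring and name the most optimal (least
detuned = lowest realised load) and least optimal (most detuned). With
k offspring presented, naming both extremes by chance succeeds with
probability 1/(k(k-1)) — 1/6 for the three-offspring game — which is
the null of the exact one-sided binomial test used to decide whether
listeners do better than guessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import pandas as pd
from scipy import stats

from .cross_engine import CrossResult


@dataclass(frozen=True)
class Ranking:
    """Crosses ordered by ascending expected offspring realised load."""

    cross_ids: List[str]
    totals: Dict[str, float]

    @property
    def most_optimal(self) -> str:
        return self.cross_ids[0]

    @property
    def least_optimal(self) -> str:
        return self.cross_ids[-1]


def rank_crosses(results: Sequence[CrossResult] | Dict[str, float]) -> Ranking:
    """Order crosses by total expected realised load, ascending; ties break
    lexicographically by cross id."""
    if isinstance(results, dict):
        totals = {str(k): float(v) for k, v in results.items()}
    else:
        totals = {r.cross_id: r.total for r in results}
    if len(totals) < 2:
        raise ValueError(f"ranking needs at least 2 crosses, got {len(totals)}")
    ordered = sorted(totals, key=lambda cid: (totals[cid], cid))
    return Ranking(cross_ids=ordered, totals=totals)


def null_probability(n_options: int) -> float:
    """Chance of naming both the most and least optimal of ``n_options``
    offspring by guessing: 1/(k(k-1))."""
    if n_options < 2:
        raise ValueError("need at least 2 options")
    return 1.0 / (n_options * (n_options - 1))


@dataclass(frozen=True)
class BinomialTestSpec:
    """Exact binomial test of x successes in n trials against pi0."""

    n: int
    x: int
    pi0: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError(f"need 0 <= x <= n, got x={self.x}, n={self.n}")
        if not 0.0 < self.pi0 < 1.0:
            raise ValueError(f"pi0 must be in (0, 1), got {self.pi0}")


def log_binomial_exact_upper(spec: BinomialTestSpec) -> float:
    """Natural log of P(X >= x) for X ~ Binomial(n, pi0), in log space so
    tails far below 1e-20 keep full precision."""
    if spec.x == 0:
        return 0.0
    return float(stats.binom.logsf(spec.x - 1, spec.n, spec.pi0))


def binomial_exact_upper(spec: BinomialTestSpec) -> float:
    """Exact upper-tail probability P(X >= x); see
    :func:`log_binomial_exact_upper` for the log-space value."""
    return math.exp(log_binomial_exact_upper(spec))


@dataclass
class SurveySummary:
    """Per-option counts/percentages for both questions, plus the number of
    respondents correct on both."""

    most_counts: pd.Series
    least_counts: pd.Series
    most_pct: pd.Series
    least_pct: pd.Series
    n: int
    n_rejected: int
    correct_most: int
    correct_least: int
    correct_both: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "most_count": self.most_counts,
                "most_pct": self.most_pct,
                "least_count": self.least_counts,
                "least_pct": self.least_pct,
            }
        )


def score_responses(
    responses: pd.DataFrame,
    truth: Ranking,
    options: Sequence[str] | None = None,
) -> SurveySummary:
    """Tally survey responses against the true ranking.

    ``responses`` needs columns most_optimal and least_optimal. Rows
    naming an unknown offspring are rejected and counted. Percentages
    are rounded to 1 decimal place.
    """
    if truth.most_optimal == truth.least_optimal:
        raise ValueError("truth must have distinct most/least optimal")
    opts = list(options) if options is not None else list(truth.cross_ids)
    valid = responses[
        responses["most_optimal"].isin(opts) & responses["least_optimal"].isin(opts)
    ]
    n_rejected = len(responses) - len(valid)
    n = len(valid)
    index = pd.Index(opts, name="offspring")
    most_counts = valid["most_optimal"].value_counts().reindex(index, fill_value=0)
    least_counts = valid["least_optimal"].value_counts().reindex(index, fill_value=0)
    if n:
        most_pct = (100.0 * most_counts / n).round(1)
        least_pct = (100.0 * least_counts / n).round(1)
    else:
        most_pct = most_counts.astype(float)
        least_pct = least_counts.astype(float)
    correct_most = int(most_counts[truth.most_optimal])
    correct_least = int(least_counts[truth.least_optimal])
    correct_both = int(
        (
            (valid["most_optimal"] == truth.most_optimal)
            & (valid["least_optimal"] == truth.least_optimal)
        ).sum()
    )
    return SurveySummary(
        most_counts=most_counts,
        least_counts=least_counts,
        most_pct=most_pct,
        least_pct=least_pct,
        n=n,
        n_rejected=n_rejected,
        correct_most=correct_most,
        correct_least=correct_least,
        correct_both=correct_both,
    )


def evaluate_survey(
    responses: pd.DataFrame,
    truth: Ranking,
    options: Sequence[str] | None = None,
) -> tuple[SurveySummary, float]:
    """Score responses and test the both-correct count against the
    guessing null 1/(k(k-1)). Returns (summary, p-value)."""
    summary = score_responses(responses, truth, options)
    k = len(options) if options is not None else len(truth.cross_ids)
    spec = BinomialTestSpec(n=summary.n, x=summary.correct_both,
                            pi0=null_probability(k))
    return summary, binomial_exact_upper(spec)


def read_responses(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"respondent_id", "most_optimal", "least_optimal"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"responses table missing columns: {sorted(missing)}")
    return frame
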