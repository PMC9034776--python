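"""Emotion reactivity and regulation task (ERRT) data model and net scores.

The task has four film-viewing conditions -- Neutral Watch, Positive Watch,
Negative Watch and Negative Regulate (reappraisal of negative clips) -- and
after every clip the participant rates, on separate 1-11 scales, how much
positive and how much negative affect they felt, plus an instruction-
compliance rating.  Condition means of the eight (condition, valence)
ratings are the observed variables for all downstream latent-variable
modelling; the three "net" scores below collapse them into the
double-difference indices used in classic emotion-regulation analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical condition names.
CONDITIONS = ("NeutralWatch", "PositiveWatch", "NegativeWatch", "NegativeRegulate")

#: Canonical (condition, valence) rating column names, in fixed order.
RATING_COLUMNS = (
    "neutral_pos",
    "neutral_neg",
    "poswatch_pos",
    "poswatch_neg",
    "negwatch_pos",
    "negwatch_neg",
    "negreg_pos",
    "negreg_neg",
)

_CONDITION_PREFIX = {
    "NeutralWatch": "neutral",
    "PositiveWatch": "poswatch",
    "NegativeWatch": "negwatch",
    "NegativeRegulate": "negreg",
}

RATING_MIN = 1.0
RATING_MAX = 11.0


class MissingConditionError(ValueError):
    """A subject has no trials (or no rating) for a required condition."""


def _check_rating(value: float, name: str) -> float:
    value = float(value)
    if not (RATING_MIN <= value <= RATING_MAX):
        raise ValueError(f"{name}={value} outside the {RATING_MIN:g}-{RATING_MAX:g} rating scale")
    return value


@dataclass(frozen=True)
class TrialRecord:
    """A single trial: one film clip, its condition, and the three ratings."""

    subject_id: str
    condition: str
    positive_rating: float
    negative_rating: float
    compliance: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        _check_rating(self.positive_rating, "positive_rating")
        _check_rating(self.negative_rating, "negative_rating")
        _check_rating(self.compliance, "compliance")


@dataclass(frozen=True)
class SubjectERRT:
    """Per-subject condition-mean ratings: eight affect means plus compliance.

    ``ratings`` maps the eight canonical column names (:data:`RATING_COLUMNS`)
    to condition-mean ratings; ``compliance`` maps condition name to the mean
    compliance rating for that condition.
    """

    subject_id: str
    ratings: Mapping[str, float]
    compliance: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RATING_COLUMNS if c not in self.ratings]
        if missing:
            raise MissingConditionError(f"subject {self.subject_id}: missing ratings {missing}")
        extra = set(self.ratings) - set(RATING_COLUMNS)
        if extra:
            raise ValueError(f"subject {self.subject_id}: unknown rating fields {sorted(extra)}")
        for name in RATING_COLUMNS:
            _check_rating(self.ratings[name], name)

    def __getitem__(self, key: str) -> float:
        return float(self.ratings[key])


@dataclass(frozen=True)
class NetScores:
    """The three double-difference net-emotionality indices (range [-20, 20])."""

    net_positive_reactivity: float
    net_negative_reactivity: float
    net_negative_regulation: float


def aggregate_trials(trials: Iterable[TrialRecord]) -> SubjectERRT:
    """Collapse one subject's trials to condition-mean ratings.

    Order-invariant arithmetic means.  Raises
    :class:`MissingConditionError` naming the condition if any of the four
    conditions has no trials, and ``ValueError`` if trials span subjects.
    """
    trials = list(trials)
    if not trials:
        raise MissingConditionError("no trials supplied")
    subject_ids = {t.subject_id for t in trials}
    if len(subject_ids) != 1:
        raise ValueError(f"trials span multiple subjects: {sorted(subject_ids)}")
    sid = trials[0].subject_id

    ratings: dict[str, float] = {}
    compliance: dict[str, float] = {}
    for cond in CONDITIONS:
        cond_trials = [t for t in trials if t.condition == cond]
        if not cond_trials:
            raise MissingConditionError(f"subject {sid}: no trials for condition {cond}")
        prefix = _CONDITION_PREFIX[cond]
        ratings[f"{prefix}_pos"] = sum(t.positive_rating for t in cond_trials) / len(cond_trials)
        ratings[f"{prefix}_neg"] = sum(t.negative_rating for t in cond_trials) / len(cond_trials)
        compliance[cond] = sum(t.compliance for t in cond_trials) / len(cond_trials)
    return SubjectERRT(subject_id=sid, ratings=ratings, compliance=compliance)


def net_positive_reactivity(s: SubjectERRT) -> float:
    """(PositiveWatch pos - PositiveWatch neg) - (NeutralWatch pos - NeutralWatch neg)."""
    return (s["poswatch_pos"] - s["poswatch_neg"]) - (s["neutral_pos"] - s["neutral_neg"])


def net_negative_reactivity(s: SubjectERRT) -> float:
    """(NegativeWatch neg - NegativeWatch pos) - (NeutralWatch neg - NeutralWatch pos)."""
    return (s["negwatch_neg"] - s["negwatch_pos"]) - (s["neutral_neg"] - s["neutral_pos"])


def net_negative_regulation(s: SubjectERRT) -> float:
    """(NegativeRegulate neg - NegativeRegulate pos) - (NegativeWatch neg - NegativeWatch pos)."""
    return (s["negreg_neg"] - s["negreg_pos"]) - (s["negwatch_neg"] - s["negwatch_pos"])


def net_scores(s: SubjectERRT) -> NetScores:
    return NetScores(
        net_positive_reactivity=net_positive_reactivity(s),
        net_negative_reactivity=net_negative_reactivity(s),
        net_negative_regulation=net_negative_regulation(s),
    )


def net_scores_frame(subjects: pd.DataFrame) -> pd.DataFrame:
    """Net scores for a subject-by-rating table.

    ``subjects`` must contain the eight canonical rating columns; rows
    failing range validation are dropped with a logged reason, and the
    returned frame has columns ``net_positive_reactivity``,
    ``net_negative_reactivity`` and ``net_negative_regulation`` indexed like
    the retained input rows.
    """
    missing = [c for c in RATING_COLUMNS if c not in subjects.columns]
    if missing:
        raise MissingConditionError(f"input table missing rating columns {missing}")
    block = subjects[list(RATING_COLUMNS)].astype(float)
    ok = block.notna().all(axis=1) & (block >= RATING_MIN).all(axis=1) & (block <= RATING_MAX).all(axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("excluding %d subject(s) with missing or out-of-range ratings", n_bad)
    block = block.loc[ok]
    out = pd.DataFrame(index=block.index)
    out["net_positive_reactivity"] = (block["poswatch_pos"] - block["poswatch_neg"]) - (
        block["neutral_pos"] - block["neutral_neg"]
    )
    out["net_negative_reactivity"] = (block["negwatch_neg"] - block["negwatch_pos"]) - (
        block["neutral_neg"] - block["neutral_pos"]
    )
    out["net_negative_regulation"] = (block["negreg_neg"] - block["negreg_pos"]) - (
        block["negwatch_neg"] - block["negwatch_pos"]
    )
    return out
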