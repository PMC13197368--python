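"""Trial-log scoring: outcome classification, the attentional-bias index,
the identification-rate exclusion rule, and questionnaire scoring.

Each dual-probe presentation shows two different probe identities, one at
the locus of the negative talking head and one at the benign locus. The
participant reports at most one identity. A report matching the
negative-locus identity is a negative-locus identification; matching the
benign-locus identity, a benign-locus identification; anything else
(including no response) counts as unidentified.

The attentional-bias index is

    I = N_neg / (N_neg + N_ben),

the proportion of correctly identified probes that appeared at the negative
locus; 0.5 means no bias. Participants who identify probes on fewer than a
threshold proportion of presentations (default 80%, boundary inclusive) are
excluded, since attentional distribution cannot be inferred from probes the
participant did not see.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .design import OUTER_KEYS

__all__ = [
    "DataError",
    "PresentationOutcome",
    "TrialRecord",
    "ParticipantSession",
    "BiasResult",
    "StateChangeScore",
    "classify_presentation",
    "score_session",
    "apply_exclusions",
    "score_stai_t",
    "score_stai_s6",
    "state_change",
    "STAI_T_REVERSE_ITEMS",
    "STAI_S6_ABSENT_ITEMS",
    "DEFAULT_THRESHOLD",
    "TRIALS_PER_SESSION",
]

DEFAULT_THRESHOLD = 0.80
TRIALS_PER_SESSION = 240  # 24 videos x 10 probe events

#: 0-based indices of the reverse-keyed (anxiety-absent) items of the
#: 20-item trait form (items 1, 3, 6, 7, 10, 13, 14, 16, 19 in 1-based
#: numbering, per the standard Form Y key).
STAI_T_REVERSE_ITEMS = frozenset({0, 2, 5, 6, 9, 12, 13, 15, 18})

#: 0-based indices of the anxiety-absent items of the six-item state short
#: form ordered (calm, tense, upset, relaxed, content, worried).
STAI_S6_ABSENT_ITEMS = frozenset({0, 3, 4})


class DataError(ValueError):
    """Malformed or inconsistent participant data."""


class PresentationOutcome(enum.Enum):
    NEG_CORRECT = "neg_correct"
    BEN_CORRECT = "ben_correct"
    UNIDENTIFIED = "unidentified"


@dataclass(frozen=True)
class TrialRecord:
    """One dual-probe presentation with ground truth and the keyed response."""

    participant_id: str
    video_id: str
    presentation_index: int  # 1..240, chronological
    negative_locus: str  # "left" | "right"
    left_identity: int
    right_identity: int
    response_identity: int | None = None

    def __post_init__(self) -> None:
        if self.negative_locus not in ("left", "right"):
            raise DataError(f"bad negative_locus {self.negative_locus!r}")
        if self.left_identity not in OUTER_KEYS or self.right_identity not in OUTER_KEYS:
            raise DataError(
                f"probe identities must be outer numpad keys, got "
                f"{self.left_identity}/{self.right_identity}"
            )
        if self.left_identity == self.right_identity:
            raise DataError("the two probe identities must differ")


@dataclass
class ParticipantSession:
    """A participant's full trial log plus questionnaire responses."""

    participant_id: str
    trials: list[TrialRecord]
    stai_t_items: list[int] | None = None  # 20 raw item responses in [1, 4]
    stai_s6_baseline: list[float] | None = None  # 6 raw items in [0, 100]
    stai_s6_post_blocks: list[list[float]] | None = None  # 6 administrations x 6 items
    demographics: dict = field(default_factory=dict)

    def sorted_trials(self) -> list[TrialRecord]:
        trials = sorted(self.trials, key=lambda t: t.presentation_index)
        idx = [t.presentation_index for t in trials]
        if len(set(idx)) != len(idx):
            raise DataError(f"{self.participant_id}: duplicate presentation_index")
        return trials


@dataclass(frozen=True)
class BiasResult:
    participant_id: str
    n_neg_correct: int
    n_ben_correct: int
    n_unidentified: int
    identification_rate: float
    ab_index: float | None  # None when no probes were identified
    retained: bool
    threshold: float = DEFAULT_THRESHOLD

    @property
    def n_trials(self) -> int:
        return self.n_neg_correct + self.n_ben_correct + self.n_unidentified


@dataclass(frozen=True)
class StateChangeScore:
    baseline: float
    post_block_scores: tuple[float, ...]
    change: float  # mean(post) - baseline; positive = elevation


def classify_presentation(trial: TrialRecord) -> PresentationOutcome:
    """Classify one presentation by which locus' identity was reported."""
    resp = trial.response_identity
    if resp is None or resp not in OUTER_KEYS:
        return PresentationOutcome.UNIDENTIFIED
    negative_identity = (
        trial.left_identity if trial.negative_locus == "left" else trial.right_identity
    )
    benign_identity = (
        trial.right_identity if trial.negative_locus == "left" else trial.left_identity
    )
    if resp == negative_identity:
        return PresentationOutcome.NEG_CORRECT
    if resp == benign_identity:
        return PresentationOutcome.BEN_CORRECT
    return PresentationOutcome.UNIDENTIFIED


def score_session(
    session: ParticipantSession,
    threshold: float = DEFAULT_THRESHOLD,
    n_trials: int = TRIALS_PER_SESSION,
) -> BiasResult:
    """Compute identification counts, the bias index, and the retention flag."""
    if len(session.trials) != n_trials:
        raise DataError(
            f"{session.participant_id}: expected {n_trials} trials, got {len(session.trials)}"
        )
    outcomes = [classify_presentation(t) for t in session.sorted_trials()]
    n_neg = sum(o is PresentationOutcome.NEG_CORRECT for o in outcomes)
    n_ben = sum(o is PresentationOutcome.BEN_CORRECT for o in outcomes)
    n_unid = n_trials - n_neg - n_ben
    rate = (n_neg + n_ben) / n_trials
    index = n_neg / (n_neg + n_ben) if (n_neg + n_ben) > 0 else None
    return BiasResult(
        participant_id=session.participant_id,
        n_neg_correct=n_neg,
        n_ben_correct=n_ben,
        n_unidentified=n_unid,
        identification_rate=rate,
        ab_index=index,
        retained=rate >= threshold,
        threshold=threshold,
    )


def apply_exclusions(results: list[BiasResult]) -> tuple[list[BiasResult], list[BiasResult]]:
    """Partition scored sessions into (retained, excluded) by the threshold rule."""
    retained = [r for r in results if r.retained]
    excluded = [r for r in results if not r.retained]
    return retained, excluded


def score_stai_t(
    items: list[int], reverse_set: frozenset[int] | set[int] = STAI_T_REVERSE_ITEMS
) -> int:
    """Sum the 20 trait items (each 1-4) after reverse-keying; range 20-80."""
    if len(items) != 20:
        raise DataError(f"trait scale requires 20 items, got {len(items)}")
    if any(not 1 <= x <= 4 for x in items):
        raise DataError("trait items must lie in [1, 4]")
    return sum(5 - x if j in reverse_set else x for j, x in enumerate(items))


def score_stai_s6(
    items: list[float], absent_set: frozenset[int] | set[int] = STAI_S6_ABSENT_ITEMS
) -> float:
    """Score one six-item state administration on the continuous 0-100 scale.

    Anxiety-absent items are reflected (x -> 100 - x); the score is the mean
    of the six transformed items, so it stays on the response scale.
    """
    if len(items) != 6:
        raise DataError(f"state short form requires 6 items, got {len(items)}")
    if len(absent_set) != 3:
        raise DataError("exactly 3 items must be flagged anxiety-absent")
    if any(not 0 <= x <= 100 for x in items):
        raise DataError("state items must lie in [0, 100]")
    transformed = [100 - x if j in absent_set else x for j, x in enumerate(items)]
    return float(np.mean(transformed))


def state_change(baseline: float, post_blocks: list[float]) -> StateChangeScore:
    """State-anxiety change: mean of the six post-block scores minus baseline."""
    if len(post_blocks) != 6:
        raise DataError(f"expected 6 post-block scores, got {len(post_blocks)}")
    posts = tuple(float(x) for x in post_blocks)
    return StateChangeScore(
        baseline=float(baseline),
        post_block_scores=posts,
        change=float(np.mean(posts) - baseline),
    )
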