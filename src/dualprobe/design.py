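"""Session-plan generation for the dual-probe attentional-bias task.

A session presents 24 one-minute "dual videos" (a negative and a benign
talking head side by side). Within each video the two heads swap sides nine
times at pseudorandom 5–7 s intervals, yielding ten arrangements; one pair
of 200-ms probes is shown per arrangement. This module generates the
counterbalanced stimulus set, per-video switch schedules and probe events,
and the constrained presentation order, all as pure functions of a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TOPICS",
    "OUTER_KEYS",
    "DualVideoSpec",
    "Arrangement",
    "ArrangementSchedule",
    "ProbeEvent",
    "SessionPlan",
    "build_stimulus_set",
    "generate_switch_schedule",
    "generate_probe_events",
    "generate_session_order",
    "build_session_plan",
    "order_satisfies_topic_spacing",
]

#: The six real-life concern topics, one negative and one benign perspective each.
TOPICS = ("security", "health", "appearance", "social", "employment", "safety")

#: Numpad keys addressing the eight outer cells of the 3x3 probe grid.
#: Key 5 is the centre cell and never holds the grey square.
OUTER_KEYS = (1, 2, 3, 4, 6, 7, 8, 9)

VIDEO_DURATION = 60.0
N_SWITCHES = 9
SWITCH_INTERVALS = (5, 6, 7)
#: Sum bounds on the nine sampled intervals so the tenth (final) arrangement
#: lasts between 5 and 10 s.
INTERVAL_SUM_RANGE = (50, 55)
PROBE_DURATION = 0.2
#: Probe onset margins within an arrangement: at least 1.0 s after the switch
#: into it and at least 1.5 s before the switch out of it.
ONSET_MARGIN_START = 1.0
ONSET_MARGIN_END = 1.5


class ConfigurationError(ValueError):
    """Invalid task configuration (topic counts, counterbalancing inputs)."""


@dataclass(frozen=True)
class DualVideoSpec:
    """One dual video: a male and a female talking head, one negative, one benign."""

    video_id: str
    topic: str
    male_head_valence: str  # "negative" | "benign"
    initial_left_gender: str  # "male" | "female"
    duration: float = VIDEO_DURATION

    def __post_init__(self) -> None:
        if self.male_head_valence not in ("negative", "benign"):
            raise ConfigurationError(f"bad male_head_valence {self.male_head_valence!r}")
        if self.initial_left_gender not in ("male", "female"):
            raise ConfigurationError(f"bad initial_left_gender {self.initial_left_gender!r}")

    @property
    def initial_left_valence(self) -> str:
        """Valence of the head initially on the left, implied by the pairing."""
        male_is_negative = self.male_head_valence == "negative"
        male_on_left = self.initial_left_gender == "male"
        return "negative" if male_is_negative == male_on_left else "benign"


@dataclass(frozen=True)
class Arrangement:
    """One positional arrangement: half-open interval [start, end) in seconds."""

    start: float
    end: float
    left_valence: str  # valence of the head on the left during this segment


@dataclass(frozen=True)
class ArrangementSchedule:
    video_id: str
    switch_times: tuple[float, ...]  # 9 ascending time points
    arrangements: tuple[Arrangement, ...]  # 10 segments tiling [0, 60]


@dataclass(frozen=True)
class ProbeEvent:
    video_id: str
    arrangement_index: int  # 0..9
    onset: float
    left_identity: int  # numpad key of the left probe's grey square
    right_identity: int
    duration: float = PROBE_DURATION


@dataclass(frozen=True)
class PlannedVideo:
    """A video with its concrete schedule and probe events for one session."""

    spec: DualVideoSpec
    schedule: ArrangementSchedule
    probes: tuple[ProbeEvent, ...]


@dataclass(frozen=True)
class SessionPlan:
    participant_id: str
    videos: tuple[PlannedVideo, ...]  # 24, in presentation order
    rng_seed: int
    block_size: int = 4

    @property
    def blocks(self) -> list[tuple[PlannedVideo, ...]]:
        """Six blocks of four consecutive videos."""
        b = self.block_size
        return [self.videos[i : i + b] for i in range(0, len(self.videos), b)]

    def to_dict(self) -> dict:
        """JSON-serializable representation: videos -> arrangements -> probes."""
        return {
            "participant_id": self.participant_id,
            "rng_seed": self.rng_seed,
            "block_size": self.block_size,
            "videos": [
                {
                    "video_id": pv.spec.video_id,
                    "topic": pv.spec.topic,
                    "male_head_valence": pv.spec.male_head_valence,
                    "initial_left_gender": pv.spec.initial_left_gender,
                    "initial_left_valence": pv.spec.initial_left_valence,
                    "duration": pv.spec.duration,
                    "switch_times": list(pv.schedule.switch_times),
                    "arrangements": [
                        {"start": a.start, "end": a.end, "left_valence": a.left_valence}
                        for a in pv.schedule.arrangements
                    ],
                    "probes": [
                        {
                            "arrangement_index": p.arrangement_index,
                            "onset": p.onset,
                            "duration": p.duration,
                            "left_identity": p.left_identity,
                            "right_identity": p.right_identity,
                        }
                        for p in pv.probes
                    ],
                }
                for pv in self.videos
            ],
        }


def build_stimulus_set(
    topics: tuple[str, ...] = TOPICS, seed: int | np.random.Generator = 0
) -> list[DualVideoSpec]:
    """Build the counterbalanced set of 24 dual-video specs (4 per topic).

    Counterbalancing: the negative script is spoken by the male head in 12
    videos and by the female head in 12; 12 videos start with the male head
    on the left and 12 with the female head, and within each of those
    subsets six start with negative content on the left and six with benign.
    Each topic contributes one video per (negative-speaker, initial-left)
    cell, which realises all three counts simultaneously.
    """
    topics = tuple(topics)
    if len(topics) != 6:
        raise ConfigurationError(f"exactly 6 topics required, got {len(topics)}")
    if len(set(topics)) != 6:
        raise ConfigurationError("topic labels must be distinct")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    cells = list(itertools.product(("negative", "benign"), ("male", "female")))
    specs: list[DualVideoSpec] = []
    for topic in topics:
        order = rng.permutation(4)
        for i, cell_idx in enumerate(order, start=1):
            male_valence, left_gender = cells[cell_idx]
            specs.append(
                DualVideoSpec(
                    video_id=f"{topic}-{i}",
                    topic=topic,
                    male_head_valence=male_valence,
                    initial_left_gender=left_gender,
                )
            )
    return specs


def generate_switch_schedule(
    spec: DualVideoSpec, seed: int | np.random.Generator = 0
) -> ArrangementSchedule:
    """Sample the nine switch times for one video.

    Inter-switch intervals are drawn i.i.d. from {5, 6, 7} s and the draw is
    rejected unless their sum lies in [50, 55], which guarantees the final
    (tenth) arrangement lasts 5-10 s. Nine draws from {5,6,7} have mean sum
    54, so acceptance is common and the loop terminates quickly.
    """
    if spec.duration != VIDEO_DURATION:
        raise ConfigurationError("switch schedules are defined for 60 s videos")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    lo, hi = INTERVAL_SUM_RANGE
    while True:
        intervals = rng.choice(SWITCH_INTERVALS, size=N_SWITCHES)
        if lo <= intervals.sum() <= hi:
            break
    switch_times = tuple(float(t) for t in np.cumsum(intervals))

    bounds = (0.0,) + switch_times + (spec.duration,)
    valences = ("negative", "benign")
    first = valences.index(spec.initial_left_valence)
    arrangements = tuple(
        Arrangement(start=bounds[i], end=bounds[i + 1], left_valence=valences[(first + i) % 2])
        for i in range(len(bounds) - 1)
    )
    return ArrangementSchedule(
        video_id=spec.video_id, switch_times=switch_times, arrangements=arrangements
    )


def generate_probe_events(
    schedule: ArrangementSchedule, seed: int | np.random.Generator = 0
) -> list[ProbeEvent]:
    """Sample one dual-probe event per arrangement (ten per video).

    The two probe identities are drawn without replacement from the eight
    outer numpad keys, so they always differ. Onsets are uniform within the
    arrangement minus the start/end margins; the shortest arrangement (5 s)
    leaves a 2.5 s window, so the margins are always satisfiable.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    events = []
    for i, arr in enumerate(schedule.arrangements):
        lo = arr.start + ONSET_MARGIN_START
        hi = arr.end - ONSET_MARGIN_END
        if hi <= lo:
            raise RuntimeError(f"arrangement {i} too short for probe margins")
        left, right = rng.choice(OUTER_KEYS, size=2, replace=False)
        events.append(
            ProbeEvent(
                video_id=schedule.video_id,
                arrangement_index=i,
                onset=float(rng.uniform(lo, hi)),
                left_identity=int(left),
                right_identity=int(right),
            )
        )
    return events


def order_satisfies_topic_spacing(topic_sequence: list[str]) -> bool:
    """Brute-force check of the topic-spacing constraint.

    A topic may not repeat before videos of all five other topics have each
    been presented once since its previous occurrence.
    """
    last: dict[str, int] = {}
    all_topics = set(topic_sequence)
    for i, t in enumerate(topic_sequence):
        if t in last:
            between = set(topic_sequence[last[t] + 1 : i])
            if not (all_topics - {t}) <= between:
                return False
        last[t] = i
    return True


def generate_session_order(
    specs: list[DualVideoSpec], seed: int | np.random.Generator = 0
) -> list[DualVideoSpec]:
    """Return a uniformly random presentation order obeying topic spacing.

    The spacing constraint is rigid: after every topic has appeared once,
    the only topic allowed to recur is the least-recently-presented one, so
    every valid order is a topic permutation repeated in four rounds, with
    the four videos of each topic in an arbitrary within-topic order.
    Sampling a random topic permutation and random within-topic orders is
    therefore exactly uniform over the valid set.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    by_topic: dict[str, list[DualVideoSpec]] = {}
    for s in specs:
        by_topic.setdefault(s.topic, []).append(s)
    counts = {t: len(v) for t, v in by_topic.items()}
    if len(counts) != 6 or any(c != 4 for c in counts.values()):
        raise ConfigurationError(f"expected 6 topics x 4 videos, got {counts}")

    topic_order = list(rng.permutation(sorted(by_topic)))
    queues = {t: [by_topic[t][i] for i in rng.permutation(4)] for t in by_topic}
    ordered = [queues[t][rnd] for rnd in range(4) for t in topic_order]
    assert order_satisfies_topic_spacing([s.topic for s in ordered])
    return ordered


def build_session_plan(
    participant_id: str,
    seed: int,
    topics: tuple[str, ...] = TOPICS,
) -> SessionPlan:
    """Assemble a full session plan: stimulus set, order, schedules, probes."""
    root = np.random.SeedSequence(seed)
    ss_set, ss_order, ss_sched = root.spawn(3)
    specs = build_stimulus_set(topics, np.random.default_rng(ss_set))
    ordered = generate_session_order(specs, np.random.default_rng(ss_order))
    rng = np.random.default_rng(ss_sched)
    videos = []
    for spec in ordered:
        schedule = generate_switch_schedule(spec, rng)
        probes = tuple(generate_probe_events(schedule, rng))
        videos.append(PlannedVideo(spec=spec, schedule=schedule, probes=probes))
    return SessionPlan(participant_id=participant_id, videos=tuple(videos), rng_seed=seed)
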