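"""Plain-text file formats: CSV trial logs and questionnaires, JSON plans
and reports, YAML configuration.

Trial logs are comma-separated with a header row, one row per dual-probe
presentation, UTF-8, and an empty ``response_identity`` field for absent
responses. The questionnaire file is one row per participant carrying the
20 trait items, the 6 baseline state items, and 6 x 6 post-block state
items. Mapping externally collected data onto these schemas is a
documented manual step; no foreign layout is guessed.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .design import OUTER_KEYS, SessionPlan
from .scoring import DataError, ParticipantSession, TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "read_trial_log",
    "write_trial_log",
    "read_questionnaires",
    "write_questionnaires",
    "write_session_plan",
    "write_report",
    "build_manifest",
    "load_yaml_config",
]

TRIAL_COLUMNS = [
    "participant_id",
    "video_id",
    "presentation_index",
    "negative_locus",
    "left_identity",
    "right_identity",
    "response_identity",
]

_QUEST_COLUMNS = (
    ["participant_id"]
    + [f"stai_t_{i}" for i in range(1, 21)]
    + [f"s6_base_{i}" for i in range(1, 7)]
    + [f"s6_block{b}_{i}" for b in range(1, 7) for i in range(1, 7)]
)


def write_trial_log(sessions: list[ParticipantSession], path: str | Path) -> None:
    rows = []
    for s in sessions:
        for t in s.sorted_trials():
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "video_id": t.video_id,
                    "presentation_index": t.presentation_index,
                    "negative_locus": t.negative_locus,
                    "left_identity": t.left_identity,
                    "right_identity": t.right_identity,
                    "response_identity": "" if t.response_identity is None else t.response_identity,
                }
            )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trial_log(path: str | Path) -> list[ParticipantSession]:
    """Parse and validate a trial-log CSV into per-participant sessions.

    Raises :class:`DataError` naming the first offending row (1-based data
    row numbers, excluding the header) for unknown key codes, equal probe
    identities, bad locus labels, or duplicate presentation indices.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "video_id": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    sessions: dict[str, list[TrialRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        resp = row.response_identity
        resp = None if pd.isna(resp) else int(resp)
        if resp is not None and resp not in OUTER_KEYS:
            raise DataError(f"{path} row {i}: invalid response key {resp}")
        try:
            rec = TrialRecord(
                participant_id=str(row.participant_id),
                video_id=str(row.video_id),
                presentation_index=int(row.presentation_index),
                negative_locus=str(row.negative_locus),
                left_identity=int(row.left_identity),
                right_identity=int(row.right_identity),
                response_identity=resp,
            )
        except (DataError, ValueError) as exc:
            raise DataError(f"{path} row {i}: {exc}") from exc
        sessions.setdefault(rec.participant_id, []).append(rec)
    out = []
    for pid, trials in sessions.items():
        seen: set[int] = set()
        for t in trials:
            if t.presentation_index in seen:
                raise DataError(
                    f"{path}: participant {pid} has duplicate "
                    f"presentation_index {t.presentation_index}"
                )
            seen.add(t.presentation_index)
        out.append(ParticipantSession(participant_id=pid, trials=trials))
    return out


def write_questionnaires(sessions: list[ParticipantSession], path: str | Path) -> None:
    rows = []
    for s in sessions:
        row: dict[str, Any] = {"participant_id": s.participant_id}
        row.update({f"stai_t_{i + 1}": s.stai_t_items[i] for i in range(20)})
        row.update({f"s6_base_{i + 1}": s.stai_s6_baseline[i] for i in range(6)})
        for b in range(6):
            row.update(
                {f"s6_block{b + 1}_{i + 1}": s.stai_s6_post_blocks[b][i] for i in range(6)}
            )
        rows.append(row)
    pd.DataFrame(rows, columns=_QUEST_COLUMNS).to_csv(path, index=False)


def read_questionnaires(path: str | Path, sessions: list[ParticipantSession]) -> None:
    """Attach questionnaire responses from CSV to matching sessions in place."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in _QUEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing[:5]}...")
    by_id = {s.participant_id: s for s in sessions}
    for _, row in df.iterrows():
        s = by_id.get(row["participant_id"])
        if s is None:
            continue
        s.stai_t_items = [int(row[f"stai_t_{i}"]) for i in range(1, 21)]
        s.stai_s6_baseline = [float(row[f"s6_base_{i}"]) for i in range(1, 7)]
        s.stai_s6_post_blocks = [
            [float(row[f"s6_block{b}_{i}"]) for i in range(1, 7)] for b in range(1, 7)
        ]


def write_session_plan(plan: SessionPlan, path: str | Path) -> None:
    Path(path).write_text(json.dumps(plan.to_dict(), indent=2))


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def build_manifest(
    command: str,
    config: dict,
    seeds: dict,
    inputs: dict,
    outputs: dict,
    extra: dict | None = None,
) -> dict:
    """Run manifest: everything needed to reproduce a CLI run exactly."""
    manifest = {
        "command": command,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds,
        "inputs": inputs,
        "outputs": outputs,
    }
    if extra:
        manifest.update(extra)
    return manifest


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DataError(f"{path}: expected a YAML mapping")
    return data
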