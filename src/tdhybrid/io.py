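"""Session and trace serialization (TSV, one row per trial/event)."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import yaml

from .task import TrialRecord

SESSION_COLUMNS = [
    "trial_index",
    "run_index",
    "block_index",
    "trial_type",
    "first_state",
    "action",
    "second_state",
    "reward",
    "error_flag",
    "rt_ms",
    "iti_s",
    "onset_iti",
    "onset_cue",
    "onset_first",
    "onset_isi1",
    "onset_second",
    "onset_isi2",
    "onset_outcome",
]

_INT_COLS = ("trial_index", "run_index", "block_index")
_FLOAT_COLS = ("rt_ms", "iti_s") + tuple(c for c in SESSION_COLUMNS if c.startswith("onset_"))


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "trial_index": r.trial_index,
            "run_index": r.run_index,
            "block_index": r.block_index,
            "trial_type": r.trial_type,
            "first_state": r.first_state,
            "action": r.action,
            "second_state": r.second_state,
            "reward": r.reward,
            "error_flag": r.error_flag,
            "rt_ms": r.rt_ms,
            "iti_s": r.iti_s,
        }
        for label in ("iti", "cue", "first", "isi1", "second", "isi2", "outcome"):
            row[f"onset_{label}"] = r.event_onsets.get(label)
        rows.append(row)
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for _, row in frame.iterrows():
        onsets = {
            label: float(row[f"onset_{label}"])
            for label in ("iti", "cue", "first", "isi1", "second", "isi2", "outcome")
            if pd.notna(row.get(f"onset_{label}"))
        }
        records.append(
            TrialRecord(
                trial_index=int(row["trial_index"]),
                run_index=int(row["run_index"]),
                block_index=int(row["block_index"]),
                trial_type=str(row["trial_type"]),
                first_state=str(row["first_state"]),
                iti_s=float(row["iti_s"]),
                action=None if pd.isna(row["action"]) else str(row["action"]),
                second_state=None if pd.isna(row["second_state"]) else str(row["second_state"]),
                reward=None if pd.isna(row["reward"]) else int(row["reward"]),
                error_flag=str(row["error_flag"]),
                rt_ms=None if pd.isna(row["rt_ms"]) else float(row["rt_ms"]),
                event_onsets=onsets,
            )
        )
    return records


def write_session(session: Union[pd.DataFrame, Sequence[TrialRecord]], path) -> None:
    """Write a session TSV; missing values serialize as empty strings."""
    frame = session if isinstance(session, pd.DataFrame) else records_to_frame(session)
    frame.to_csv(path, sep="\t", index=False, na_rep="")


def read_session(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"action": "string", "second_state": "string"})
    for c in _INT_COLS:
        frame[c] = frame[c].astype(int)
    # reward may arrive as float due to blanks on error trials
    frame["reward"] = frame["reward"].astype("Float64").astype("Int64")
    for c in _FLOAT_COLS:
        frame[c] = frame[c].astype(float)
    frame["error_flag"] = frame["error_flag"].fillna("none").astype(str)
    return frame


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=False)
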