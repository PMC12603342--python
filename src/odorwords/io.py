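"""CSV round-tripping for the pipeline's interchange tables.

All interchange is plain UTF-8 CSV with times in seconds (decimal
fractions, session-clock origin at recording start).  Floats are written
with full ``repr`` precision, so write-then-read reproduces values
exactly.  A shim for timestamp-per-line text exports is provided.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from odorwords.stimuli import TRIAL_COLUMNS
from odorwords.synthetic import SpikeTrainSet

__all__ = [
    "write_spikes",
    "read_spikes",
    "write_trials",
    "read_trials",
    "read_timestamp_lines",
]


def write_spikes(spikes: SpikeTrainSet, path) -> None:
    spikes.to_frame().to_csv(path, index=False)


def read_spikes(path, session_span_s: float | None = None) -> SpikeTrainSet:
    df = pd.read_csv(path, float_precision="round_trip")
    return SpikeTrainSet.from_frame(df, session_span_s=session_span_s)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path}: missing columns {missing}")
    for col in ("is_odor", "is_living", "is_food"):
        df[col] = df[col].astype(bool)
    if not df["onset_s"].is_monotonic_increasing:
        raise ValueError(f"trial table {path}: onsets must be increasing")
    return df


def read_timestamp_lines(path, unit_id: str, region: str) -> SpikeTrainSet:
    """Import a one-timestamp-per-line text export as a single-unit train."""
    times = np.sort(np.loadtxt(path, ndmin=1, dtype=float))
    return SpikeTrainSet(
        unit_ids=[unit_id], regions={unit_id: region}, trains={unit_id: times}
    )
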