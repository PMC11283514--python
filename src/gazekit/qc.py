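"""Dataset-level quality control and the inclusion/exclusion ledger.

Three exclusion rules are applied in a fixed order, and a recording
failing several is tallied once under the first that caught it:

1. duplicate first views — when a participant saw the same image twice,
   the earlier recording (lower ``recording_index``) is excluded, since
   an accidental first view is too short for proper inspection;
2. signal quality — recordings whose mean per-sample quality is strictly
   below the threshold (default 0.60) are excluded;
3. stimulus errors — recordings flagged by (participant, image) for a
   presentation error are excluded.

The ledger lists every input recording exactly once, so status counts
always sum to the input count, and statuses are independent of input
order (duplicates are resolved by recording_index, not list position).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GazeRecording

__all__ = [
    "STATUS_INCLUDED",
    "STATUS_DUPLICATE",
    "STATUS_QUALITY",
    "STATUS_STIMULUS_ERROR",
    "mean_signal_quality",
    "apply_exclusions",
    "funnel_counts",
]

STATUS_INCLUDED = "included"
STATUS_DUPLICATE = "excluded_duplicate"
STATUS_QUALITY = "excluded_quality"
STATUS_STIMULUS_ERROR = "excluded_stimulus_error"

LEDGER_COLUMNS = [
    "participant_id",
    "image_id",
    "condition",
    "recording_index",
    "status",
    "quality_score",
]


def mean_signal_quality(rec: GazeRecording) -> float:
    """Arithmetic (sample-weighted) mean of per-sample signal quality."""
    if rec.n_samples == 0:
        raise ValidationError("cannot compute signal quality of an empty recording")
    return float(np.mean(rec.quality))


def apply_exclusions(
    recordings: Sequence[GazeRecording],
    quality_threshold: float = 0.60,
    error_flags: Iterable[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Apply the exclusion rules and return the dataset ledger.

    Parameters
    ----------
    recordings
        All recorded datasets, in any order.
    quality_threshold
        Recordings with mean quality strictly below this are excluded;
        a recording at exactly the threshold is kept. Must be in (0, 1].
    error_flags
        ``(participant_id, image_id)`` pairs with a stimulus-presentation
        error.

    Returns
    -------
    pandas.DataFrame
        One row per input recording with columns
        participant_id, image_id, condition, recording_index, status,
        quality_score.
    """
    if not (0 < quality_threshold <= 1):
        raise ValidationError("quality_threshold must lie in (0, 1]")
    flags = {(str(p), str(i)) for p, i in error_flags}

    by_view: dict[tuple[str, str], list[GazeRecording]] = defaultdict(list)
    for rec in recordings:
        by_view[(rec.participant_id, rec.image_id)].append(rec)

    rows = []
    for rec in recordings:
        group = by_view[(rec.participant_id, rec.image_id)]
        quality = mean_signal_quality(rec)
        if len(group) > 1 and rec.recording_index < max(r.recording_index for r in group):
            status = STATUS_DUPLICATE
        elif quality < quality_threshold:
            status = STATUS_QUALITY
        elif (rec.participant_id, rec.image_id) in flags:
            status = STATUS_STIMULUS_ERROR
        else:
            status = STATUS_INCLUDED
        rows.append(
            {
                "participant_id": rec.participant_id,
                "image_id": rec.image_id,
                "condition": rec.condition.value,
                "recording_index": rec.recording_index,
                "status": status,
                "quality_score": quality,
            }
        )
    ledger = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    return ledger.sort_values(
        ["participant_id", "image_id", "recording_index"], kind="stable"
    ).reset_index(drop=True)


def funnel_counts(ledger: pd.DataFrame) -> dict[str, int]:
    """Count-funnel summary of a ledger: total, per-status, included."""
    counts = ledger["status"].value_counts().to_dict()
    return {
        "total": int(len(ledger)),
        STATUS_DUPLICATE: int(counts.get(STATUS_DUPLICATE, 0)),
        STATUS_QUALITY: int(counts.get(STATUS_QUALITY, 0)),
        STATUS_STIMULUS_ERROR: int(counts.get(STATUS_STIMULUS_ERROR, 0)),
        STATUS_INCLUDED: int(counts.get(STATUS_INCLUDED, 0)),
    }
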