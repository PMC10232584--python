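"""Event-related cardiac response: feedback-locked inter-beat intervals.

For each event the R-peak closest to the event onset is the anchor; the
interval ending at the anchor is IBI_0.  Three preceding (IBI_-3..IBI_-1)
and eight subsequent (IBI_1..IBI_8) intervals are extracted and
re-referenced to IBI_-2, giving difference scores in which negative values
mean shorter intervals, i.e. heart-rate acceleration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IBI_INDICES", "IBISeries", "align_ibis", "ibi_table", "condition_contrast_ibi"]

logger = logging.getLogger(__name__)

#: Beat indices extracted around each event.
IBI_INDICES = tuple(range(-3, 9))

REFERENCE_INDEX = -2


@dataclass(frozen=True)
class IBISeries:
    """IBIs around one event, with IBI_-2-referenced difference scores."""

    event_id: int
    condition: str
    ibi_ms: dict[int, float]
    ibi_diff_ms: dict[int, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.ibi_ms.values()):
            raise ValueError("all inter-beat intervals must be positive")
        if self.ibi_diff_ms[REFERENCE_INDEX] != 0.0:
            raise ValueError("difference score at the reference index must be exactly 0")


class InsufficientPeaksError(ValueError):
    """Raised when an event lacks the required surrounding R-peaks."""


def align_ibis(
    rpeaks_s: np.ndarray,
    event_time_s: float,
    event_id: int = 0,
    condition: str = "control",
) -> IBISeries:
    """Extract IBI_-3..IBI_8 around one event and re-reference to IBI_-2.

    The anchor is the R-peak closest to the event onset; an exact tie
    between two peaks is broken toward the earlier peak.  IBI_k is the
    interval ending at peak ``anchor + k`` (so IBI_0 is anchor minus the
    previous peak).
    """
    t = np.asarray(rpeaks_s, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need a 1-d series of at least two R-peak timestamps")
    if np.any(np.diff(t) <= 0):
        raise ValueError("R-peak timestamps must be strictly increasing")
    anchor = int(np.argmin(np.abs(t - event_time_s)))  # first minimum → earlier peak on ties
    lo = anchor + min(IBI_INDICES) - 1
    hi = anchor + max(IBI_INDICES)
    if lo < 0 or hi >= len(t):
        raise InsufficientPeaksError(
            f"event {event_id} at {event_time_s:.3f}s: needs peaks {lo}..{hi}, "
            f"series has 0..{len(t) - 1}"
        )
    ibi = {k: (t[anchor + k] - t[anchor + k - 1]) * 1000.0 for k in IBI_INDICES}
    ref = ibi[REFERENCE_INDEX]
    diff = {k: ibi[k] - ref for k in IBI_INDICES}
    return IBISeries(event_id=event_id, condition=condition, ibi_ms=ibi, ibi_diff_ms=diff)


def ibi_table(
    rpeaks_s: np.ndarray,
    events_s,
    condition: str,
    participant: str = "P00",
) -> pd.DataFrame:
    """Tidy table of IBIs and difference scores for a series of events.

    Events without enough surrounding peaks are dropped with a warning.
    """
    rows = []
    for i, ev in enumerate(np.atleast_1d(np.asarray(events_s, dtype=float))):
        try:
            series = align_ibis(rpeaks_s, ev, event_id=i, condition=condition)
        except InsufficientPeaksError as exc:
            warnings.warn(f"event dropped: {exc}", stacklevel=2)
            continue
        for k in IBI_INDICES:
            rows.append(
                {
                    "participant": participant,
                    "condition": condition,
                    "event": i,
                    "index": k,
                    "ibi_ms": series.ibi_ms[k],
                    "diff_ms": series.ibi_diff_ms[k],
                }
            )
    return pd.DataFrame(
        rows, columns=["participant", "condition", "event", "index", "ibi_ms", "diff_ms"]
    )


def condition_contrast_ibi(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-index condition means plus the model input table.

    Returns ``(means, model_input)``: ``means`` holds the per-condition
    mean difference score at each beat index; ``model_input`` holds one
    row per participant × condition × index (event-averaged difference
    score, column ``value``) — difference scores can be negative, so the
    downstream model family is linear only.

    With a single participant a random-intercept model is degenerate;
    callers should fall back to a fixed-effects (ordinary) model.
    """
    if table.empty:
        raise ValueError("empty IBI table")
    model_input = (
        table.groupby(["participant", "condition", "index"], as_index=False)["diff_ms"]
        .mean()
        .rename(columns={"diff_ms": "value"})
    )
    means = (
        table.groupby(["condition", "index"], as_index=False)["diff_ms"]
        .mean()
        .rename(columns={"diff_ms": "mean_diff_ms"})
    )
    if table["participant"].nunique() < 2:
        raise ValueError(
            "a single participant cannot support a participant random intercept; "
            "fit a fixed-effects model on the per-event table instead"
        )
    return means, model_input
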