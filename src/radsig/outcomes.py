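"""Outcome containers shared across the pipeline.

Two endpoint kinds are supported: a binary tumour-response label (1 =
responder) and a right-censored time-to-event endpoint (time in months
with an event indicator, 1 = event observed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BINARY = "binary-response"
SURVIVAL = "survival"


@dataclass
class OutcomeData:
    """Per-subject outcomes for one cohort.

    Either ``labels`` (binary endpoint) or ``times`` + ``events``
    (survival endpoint) must be present; both may be.
    """

    subject_ids: list[str]
    labels: np.ndarray | None = None
    times: np.ndarray | None = None
    events: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if self.labels is None and self.times is None:
            raise ValueError("outcome data needs labels and/or (times, events)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,) or not np.isin(self.labels, [0, 1]).all():
                raise ValueError("labels must be 0/1, one per subject")
        if self.times is not None:
            if self.events is None:
                raise ValueError("survival times need an event indicator")
            self.times = np.asarray(self.times, dtype=float)
            self.events = np.asarray(self.events, dtype=int)
            if self.times.shape != (n,) or self.events.shape != (n,):
                raise ValueError("times/events must be one per subject")
            if np.any(self.times <= 0):
                raise ValueError("survival times must be positive")
            if not np.isin(self.events, [0, 1]).all():
                raise ValueError("event indicators must be 0/1")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def endpoint(self, kind: str) -> tuple:
        """Return the arrays backing the requested endpoint kind."""
        if kind == BINARY:
            if self.labels is None:
                raise ValueError("no binary labels in this outcome set")
            return (self.labels,)
        if kind == SURVIVAL:
            if self.times is None:
                raise ValueError("no survival data in this outcome set")
            return self.times, self.events
        raise ValueError(f"unknown endpoint kind {kind!r}")

    def subset(self, idx: np.ndarray) -> "OutcomeData":
        ids = [self.subject_ids[i] for i in np.atleast_1d(idx)]
        return OutcomeData(
            ids,
            labels=None if self.labels is None else self.labels[idx],
            times=None if self.times is None else self.times[idx],
            events=None if self.events is None else self.events[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        cols: dict = {}
        if self.labels is not None:
            cols["label"] = self.labels
        if self.times is not None:
            cols["time"] = self.times
            cols["event"] = self.events
        return pd.DataFrame(cols, index=pd.Index(self.subject_ids, name="subject_id"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OutcomeData":
        return cls(
            [str(i) for i in df.index],
            labels=df["label"].to_numpy() if "label" in df else None,
            times=df["time"].to_numpy() if "time" in df else None,
            events=df["event"].to_numpy() if "event" in df else None,
        )
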