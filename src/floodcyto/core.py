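"""Core in-memory containers: event matrices and blood-sample records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelDef

#: The six sampled (day, session) combinations of the eight-day time course:
#: evenings before/after stages and mornings after overnight recovery.
TIME_POINTS = (
    (0, "evening"),
    (1, "morning"),
    (4, "evening"),
    (5, "morning"),
    (7, "evening"),
    (8, "morning"),
)

MORNING_DAYS = (1, 5, 8)
EVENING_DAYS = (0, 4, 7)


@dataclass
class EventMatrix:
    """Events-by-channels intensity table.

    ``values`` holds raw stored intensities in arbitrary units; negative
    values are legal (background subtraction / compensation can push low
    signals below zero). Optional ``labels`` carry latent per-event
    population labels — simulation ground truth used only for validation,
    never consulted by gating.
    """

    values: np.ndarray
    panel: PanelDef
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("values must be a 2-D array with >= 1 event")
        if self.values.shape[1] != self.panel.n_channels:
            raise ValueError(
                f"values has {self.values.shape[1]} columns but panel defines "
                f"{self.panel.n_channels} channels"
            )
        if np.isnan(self.values).any():
            raise ValueError("event matrix contains missing values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("labels length must equal event count")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Intensity column for one channel."""
        return self.values[:, self.panel.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.panel.channels))
        if self.labels is not None:
            df["__label__"] = self.labels
        return df


@dataclass
class SampleRecord:
    """One blood sample: its events plus acquisition metadata.

    ``counter_concentration`` is the automated haematology counter's
    leukocyte concentration (1e6 cells/ml); gated fractions are converted
    to absolute subset concentrations against it.
    """

    subject: str
    day: int
    session: str
    group: str
    events: EventMatrix
    counter_concentration: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.day, self.session) not in TIME_POINTS and self.session != "lps":
            raise ValueError(
                f"(day={self.day}, session={self.session!r}) is not a sampled "
                f"time point; expected one of {TIME_POINTS} or an 'lps' session"
            )
        if self.group not in ("control", "response"):
            raise ValueError("group must be 'control' or 'response'")
        if not self.counter_concentration > 0:
            raise ValueError("counter_concentration must be > 0")

    @property
    def time_label(self) -> str:
        return f"{self.session}_d{self.day}"
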