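"""Time-series container shared by both simulation engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Class abundances, production and (optionally) antibiotic over time.

    ``counts`` has one column per class label, one row per recorded time.
    ``production_rate`` is the instantaneous flux in units/h;
    ``cumulative_production`` is its running dt-integral and is
    non-decreasing.  ``antibiotic`` is present only for serial-batch runs
    with the antibiotic module enabled.
    """

    time: np.ndarray
    counts: np.ndarray
    labels: list[str]
    production_rate: np.ndarray
    cumulative_production: np.ndarray
    antibiotic: np.ndarray | None = None
    batch_index: np.ndarray | None = None
    clamp_events: int = 0
    clamped_mass: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.time.size, len(self.labels)):
            raise ValueError("counts must be (n_times, n_labels)")

    @property
    def total(self) -> np.ndarray:
        """Total population over time."""
        return self.counts.sum(axis=1)

    def abundance(self, label: str) -> np.ndarray:
        return self.counts[:, self.labels.index(label)]

    def grouped(self, groups: dict[str, list[str]]) -> pd.DataFrame:
        """Sum columns into named groups (e.g. producers vs non-producers)."""
        data = {name: sum((self.abundance(l) for l in labels), np.zeros(self.time.size))
                for name, labels in groups.items()}
        return pd.DataFrame({"time": self.time, **data})

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-form frame: one row per (time, class)."""
        n_t, n_c = self.counts.shape
        frame = pd.DataFrame({
            "time": np.repeat(self.time, n_c),
            "class": np.tile(np.asarray(self.labels, dtype=object), n_t),
            "abundance": self.counts.ravel(),
        })
        if self.batch_index is not None:
            frame.insert(1, "batch", np.repeat(self.batch_index, n_c))
        return frame

    def production_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "time": self.time,
            "production_rate": self.production_rate,
            "cumulative_production": self.cumulative_production,
        })
        if self.antibiotic is not None:
            frame["antibiotic"] = self.antibiotic
        if self.batch_index is not None:
            frame.insert(1, "batch", self.batch_index)
        return frame

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)
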