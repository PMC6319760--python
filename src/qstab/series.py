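"""Lightweight time-series containers shared by the Q and RMSD stages."""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

__all__ = ["TimeSeries", "QTimeSeries"]


@dataclasses.dataclass
class TimeSeries:
    """One scalar observable along one trajectory replica.

    times are in ns and strictly increasing; ``selection_label`` records what
    was measured (e.g. ``"all-all"``, ``"residue:Trp47"``, ``"rmsd_backbone"``).
    """

    times: np.ndarray
    values: np.ndarray
    selection_label: str
    replica_id: int = 0
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size == 0:
            raise ValueError("empty time series")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing within a replica")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclasses.dataclass
class QTimeSeries(TimeSeries):
    """A fraction-of-native-contacts series; values constrained to [0, 1]."""

    units: str = "fraction"

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any((self.values < 0.0) | (self.values > 1.0)):
            raise ValueError("Q values must lie in [0, 1]")
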