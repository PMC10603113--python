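"""Rectangular measurement tables: a time grid plus named channels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TimeSeriesFormatError

#: Canonical channel names and their units.
CHANNEL_UNITS = {
    "fe2_mM": "mM",
    "cells_S_od": "OD600",
    "cells_R_od": "OD600",
    "luminescence_counts": "counts",
    "absorbance_510": "AU",
}

TIME_COLUMN = "time_h"


@dataclass
class TimeSeries:
    """An observed or synthetic time course.

    ``data`` holds one ``time_h`` column (strictly increasing) plus any
    number of named channels; ``metadata`` records units, the noise
    specification, seeds and provenance of synthetic tables.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if TIME_COLUMN not in self.data.columns:
            raise TimeSeriesFormatError(f"missing required column {TIME_COLUMN!r}")
        t = self.data[TIME_COLUMN].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise TimeSeriesFormatError(
                f"times must be strictly increasing; first violation at row {bad[0] + 1}"
            )

    @property
    def times(self) -> np.ndarray:
        return self.data[TIME_COLUMN].to_numpy(dtype=float)

    @property
    def channels(self) -> list[str]:
        """Names of channels that carry at least one observation."""
        return [
            c for c in self.data.columns
            if c != TIME_COLUMN and not self.data[c].isna().all()
        ]

    def channel(self, name: str) -> np.ndarray:
        if name not in self.data.columns or self.data[name].isna().all():
            raise KeyError(f"channel {name!r} absent from this series")
        return self.data[name].to_numpy(dtype=float)

    def has_channel(self, name: str) -> bool:
        return name in self.data.columns and not self.data[name].isna().all()

    def __len__(self) -> int:
        return len(self.data)


def make_timeseries(times, metadata: dict | None = None, **channels) -> TimeSeries:
    """Build a :class:`TimeSeries` from arrays, validating lengths."""
    times = np.asarray(times, dtype=float)
    frame = {TIME_COLUMN: times}
    for name, values in channels.items():
        values = np.asarray(values, dtype=float)
        if values.shape != times.shape:
            raise TimeSeriesFormatError(
                f"channel {name!r} has length {values.size}, expected {times.size}"
            )
        frame[name] = values
    return TimeSeries(pd.DataFrame(frame), metadata or {})
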