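"""Weekly percent-of-peak search-interest series."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrendSeries"]

#: default first week (a Sunday; week-start convention of the data source)
DEFAULT_EPOCH = _dt.date(2013, 1, 6)


@dataclass
class TrendSeries:
    """Weekly search-interest observations quoted as percent of peak.

    ``values[t]`` is the interest in week ``t`` on a 0-100 scale; raw
    exports contain at least one week equal to 100.  Calendar dates are
    metadata only — model time is the week index 0..T-1.
    """

    name: str
    values: np.ndarray
    week_start_dates: list[_dt.date] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        if not self.week_start_dates:
            self.week_start_dates = [
                DEFAULT_EPOCH + _dt.timedelta(weeks=int(t))
                for t in range(self.values.size)
            ]
        if len(self.week_start_dates) != self.values.size:
            raise ValueError("week_start_dates length must match values")

    @property
    def T(self) -> int:
        return int(self.values.size)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.values > 0))

    def times(self) -> np.ndarray:
        """Week indices 0..T-1 as floats (model observation times)."""
        return np.arange(self.T, dtype=float)
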