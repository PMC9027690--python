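"""LC-MS injection-precision quality control.

The QC metric for repeated injections of a pooled quality-control sample is
the relative standard deviation, RSD% = 100 * SD / mean, computed per
monitored ion for both retention times (minutes) and peak areas (intensity
units). Sample SD (ddof=1) is used, as is conventional for replicate
injections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QCSeries", "rsd_percent", "qc_summary"]


@dataclass
class QCSeries:
    """Replicate measurements of one quantity for one monitored ion."""

    ion: str
    values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("QC series needs at least 2 replicates")
        if np.any(self.values <= 0):
            raise ValueError("QC measurements must be positive")


def rsd_percent(series: QCSeries | np.ndarray) -> float:
    """Relative standard deviation in percent: 100 * sample SD / mean."""
    values = series.values if isinstance(series, QCSeries) else np.asarray(series, float)
    if values.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(values.mean())
    if mean <= 0:
        raise ValueError("mean of QC series must be positive")
    return 100.0 * float(values.std(ddof=1)) / mean


def qc_summary(series_list: list[QCSeries]) -> pd.DataFrame:
    """Per-ion RSD% table for a batch of QC series."""
    return pd.DataFrame(
        {"ion": s.ion, "n": s.values.size, "rsd_percent": rsd_percent(s)}
        for s in series_list
    )
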