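"""Blood-pressure stage coding.

Readings are classified into five conventional groups — normal, elevated,
high stage 1, high stage 2, hypertensive — coded ordinally 1-5. The printed
band definitions (normal: systolic < 120 and diastolic < 80; elevated:
systolic 120-129 and diastolic < 80; high stage 1: systolic 130-139 and
diastolic 80-89; high stage 2: systolic 140-180 or diastolic 90-120;
hypertensive: systolic > 180 or diastolic > 120) neither cover nor partition
the plane when read as joint conditions, e.g. (125, 85) matches no band and
(150, 125) matches two.  Following the usual clinical convention of assigning
the higher category, each component is classified against its own bands and
the more severe of the two codes is returned.  This rule is total, monotone
in both components, and agrees with every band on the readings the band's
definition covers.

A 4-level display coding (normal, prehypertension, hypertension, crisis) and
a binary normal/high dichotomization are derived from the 5-level code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BPReading",
    "BPCode",
    "stage_code",
    "stage_table",
    "code_counts",
    "CODE4_MAP",
    "STAGE_NAMES",
]

STAGE_NAMES = {
    1: "normal",
    2: "elevated",
    3: "high stage 1",
    4: "high stage 2",
    5: "hypertensive",
}

#: default collapse of the 5-level code onto the 4-level display stages:
#: prehypertension conventionally spans elevated + high stage 1.
CODE4_MAP = {1: 1, 2: 2, 3: 2, 4: 3, 5: 4}


@dataclass(frozen=True)
class BPReading:
    """A single blood-pressure measurement in mmHg."""

    systolic: float
    diastolic: float

    def __post_init__(self) -> None:
        if not (self.systolic > 0 and self.diastolic > 0):
            raise ValueError("blood pressure readings must be positive")
        if self.systolic < self.diastolic:
            raise ValueError(
                f"systolic ({self.systolic}) must be >= diastolic ({self.diastolic})"
            )


@dataclass(frozen=True)
class BPCode:
    """Ordinal blood-pressure codes at three granularities."""

    code5: int
    code4: int
    binary: int  # 0 = normal, 1 = high


def _systolic_code(s: np.ndarray) -> np.ndarray:
    code = np.ones_like(s, dtype=np.int64)
    code[s >= 120] = 2
    code[s >= 130] = 3
    code[s >= 140] = 4
    code[s > 180] = 5
    return code


def _diastolic_code(d: np.ndarray) -> np.ndarray:
    # diastolic has no "elevated" band: < 80 maps to normal
    code = np.ones_like(d, dtype=np.int64)
    code[d >= 80] = 3
    code[d >= 90] = 4
    code[d > 120] = 5
    return code


def code5_array(systolic: np.ndarray, diastolic: np.ndarray) -> np.ndarray:
    """Vectorized 5-level code: the more severe of the component codes."""
    s = np.asarray(systolic, dtype=float)
    d = np.asarray(diastolic, dtype=float)
    if np.any(~(s > 0) | ~(d > 0)):
        raise ValueError("blood pressure readings must be positive")
    if np.any(s < d):
        raise ValueError("systolic must be >= diastolic for every reading")
    return np.maximum(_systolic_code(s), _diastolic_code(d))


def stage_code(reading: BPReading, code4_map: dict[int, int] | None = None) -> BPCode:
    """Classify one reading into 5-level, 4-level and binary codes."""
    c5 = int(code5_array(np.array([reading.systolic]), np.array([reading.diastolic]))[0])
    c4 = (code4_map or CODE4_MAP)[c5]
    return BPCode(code5=c5, code4=c4, binary=int(c4 >= 2))


def stage_table(
    clinical: pd.DataFrame,
    systolic_col: str = "systolic",
    diastolic_col: str = "diastolic",
    code4_map: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Add bp_code5 / bp_code4 / bp_binary columns to a clinical table.

    Returns a copy; the input is not modified.
    """
    for col in (systolic_col, diastolic_col):
        if col not in clinical.columns:
            raise ValueError(f"clinical table is missing column {col!r}")
    out = clinical.copy()
    c5 = code5_array(out[systolic_col].to_numpy(), out[diastolic_col].to_numpy())
    cmap = code4_map or CODE4_MAP
    c4 = np.vectorize(cmap.__getitem__, otypes=[np.int64])(c5) if len(c5) else c5
    out["bp_code5"] = c5
    out["bp_code4"] = c4
    out["bp_binary"] = (c4 >= 2).astype(np.int64)
    return out


def code_counts(clinical: pd.DataFrame, column: str = "bp_code5") -> pd.Series:
    """Histogram over the 5-level code; counts sum to the number of samples."""
    levels = range(1, 6)
    if clinical.empty or column not in clinical.columns:
        return pd.Series(0, index=list(levels), name=column)
    return clinical[column].value_counts().reindex(levels, fill_value=0).rename(column)
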