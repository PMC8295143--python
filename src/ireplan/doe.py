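"""Experimental designs over the five protocol factors.

The study screens five factors — active electrode length (2 levels) and
electrode distance, input voltage, pulse number and pulse width (3 levels
each) — so the full factorial holds 2·3·3·3·3 = 162 runs.  The standard
L18(2¹3⁷) orthogonal array screens the same space in 18 runs: every level
of every factor appears equally often, and the array's first five columns
carry the study factors.

Factor settings are carried both in natural units and in coded units (a
linear map of [min, max] onto [−1, +1]); with evenly spaced levels the
middle 3-level setting codes to 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "default_factors",
    "full_factorial",
    "taguchi_l18",
    "encode",
    "decode",
]

#: Standard L18(2^1 3^7) orthogonal array, levels as 0-based indices.
#: Column 0 is the 2-level column; columns 1-7 are 3-level.
L18_ARRAY = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 1, 1, 1, 1, 1, 1],
        [0, 0, 2, 2, 2, 2, 2, 2],
        [0, 1, 0, 0, 1, 1, 2, 2],
        [0, 1, 1, 1, 2, 2, 0, 0],
        [0, 1, 2, 2, 0, 0, 1, 1],
        [0, 2, 0, 1, 0, 2, 1, 2],
        [0, 2, 1, 2, 1, 0, 2, 0],
        [0, 2, 2, 0, 2, 1, 0, 1],
        [1, 0, 0, 2, 2, 1, 1, 0],
        [1, 0, 1, 0, 0, 2, 2, 1],
        [1, 0, 2, 1, 1, 0, 0, 2],
        [1, 1, 0, 1, 2, 0, 2, 1],
        [1, 1, 1, 2, 0, 1, 0, 2],
        [1, 1, 2, 0, 1, 2, 1, 0],
        [1, 2, 0, 2, 1, 2, 0, 1],
        [1, 2, 1, 0, 2, 0, 1, 2],
        [1, 2, 2, 1, 0, 1, 2, 0],
    ],
    dtype=int,
)


@dataclass
class FactorSpec:
    """A protocol factor with its tested levels.

    ``role`` distinguishes factors optimised on a continuous range (the
    levels bound the range) from genuinely discrete ones.
    """

    name: str
    levels: tuple[float, ...]
    role: str = "continuous-range"

    def __post_init__(self) -> None:
        if len(self.levels) not in (2, 3):
            raise ValueError(f"factor {self.name}: need 2 or 3 levels")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError(f"factor {self.name}: levels must be strictly increasing")
        if self.role not in ("continuous-range", "discrete-levels"):
            raise ValueError(f"factor {self.name}: unknown role {self.role!r}")

    @property
    def lo(self) -> float:
        return float(self.levels[0])

    @property
    def hi(self) -> float:
        return float(self.levels[-1])

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def default_factors() -> list[FactorSpec]:
    """The five study factors at their tested levels."""
    return [
        FactorSpec("active_length_mm", (10.0, 15.0), role="discrete-levels"),
        FactorSpec("distance_mm", (10.0, 15.0, 20.0)),
        FactorSpec("voltage_V", (1000.0, 2000.0, 3000.0)),
        FactorSpec("pulse_number", (30.0, 60.0, 90.0)),
        FactorSpec("pulse_width_us", (40.0, 70.0, 100.0)),
    ]


def encode(natural: np.ndarray, factors: list[FactorSpec]) -> np.ndarray:
    """Natural units -> coded [−1, +1] (columnwise linear map over min/max)."""
    nat = np.atleast_2d(np.asarray(natural, dtype=float))
    lo = np.array([f.lo for f in factors])
    hi = np.array([f.hi for f in factors])
    return 2.0 * (nat - lo) / (hi - lo) - 1.0


def decode(coded: np.ndarray, factors: list[FactorSpec]) -> np.ndarray:
    """Coded [−1, +1] -> natural units."""
    cod = np.atleast_2d(np.asarray(coded, dtype=float))
    lo = np.array([f.lo for f in factors])
    hi = np.array([f.hi for f in factors])
    return lo + (cod + 1.0) / 2.0 * (hi - lo)


@dataclass
class DesignTable:
    """Rows of factor settings in natural units, with coded units derived."""

    factors: list[FactorSpec]
    natural: pd.DataFrame = dc_field(repr=False, default=None)

    @property
    def coded(self) -> np.ndarray:
        return encode(self.natural.to_numpy(), self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.natural)

    def to_csv(self, path) -> None:
        df = self.natural.copy()
        df.insert(0, "run_id", np.arange(1, len(df) + 1))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors: list[FactorSpec] | None = None) -> "DesignTable":
        df = pd.read_csv(path)
        if "run_id" in df.columns:
            df = df.drop(columns=["run_id"])
        if factors is None:
            factors = default_factors()
        return cls(factors=factors, natural=df[[f.name for f in factors]])


def full_factorial(factors: list[FactorSpec]) -> DesignTable:
    """Cartesian product of all factor levels in lexicographic order."""
    if not factors or any(f.n_levels == 0 for f in factors):
        raise ValueError("every factor needs at least one level")
    rows = list(itertools.product(*(f.levels for f in factors)))
    df = pd.DataFrame(rows, columns=[f.name for f in factors], dtype=float)
    return DesignTable(factors=factors, natural=df)


def taguchi_l18(factors: list[FactorSpec]) -> DesignTable:
    """L18 orthogonal-array screening design.

    Requires exactly one 2-level factor and four 3-level factors; the
    2-level factor takes the array's 2-level column and the 3-level factors
    take the next four columns in the order given.
    """
    two = [f for f in factors if f.n_levels == 2]
    three = [f for f in factors if f.n_levels == 3]
    if len(factors) != 5 or len(two) != 1 or len(three) != 4:
        raise ValueError("L18 layout here requires one 2-level and four 3-level factors")
    ordered = sorted(factors, key=lambda f: f.n_levels != 2)  # 2-level first
    levels = L18_ARRAY[:, : len(ordered)]
    data = {
        f.name: np.array([f.levels[i] for i in levels[:, j]], dtype=float)
        for j, f in enumerate(ordered)
    }
    df = pd.DataFrame(data)[[f.name for f in factors]]
    return DesignTable(factors=factors, natural=df)
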