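"""EQ-5D-5L health states and utility-index scoring.

A health state is a profile of five levels (1 = no problems .. 5 = extreme
problems) on mobility, self-care, usual activities, pain/discomfort and
anxiety/depression. A country-specific tariff (value set) maps each of the
5^5 = 3125 states to a utility index anchored at 1 (full health) and 0
(death); negative indices denote states valued worse than death. The Dutch
tariff spans -0.446 to 1.

Scoring is tariff-agnostic: a :class:`Tariff` is an additive decrement table
loaded from a plain CSV, so other value sets can be plugged in.
"""
from __future__ import annotations

import dataclasses
import itertools
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import ValidationError

DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")
_TARIFF_FILES = {"dutch": "eq5d5l_nl.csv"}


@dataclasses.dataclass(frozen=True)
class EQ5DState:
    """One EQ-5D-5L health state; e.g. ``EQ5DState.from_string("21345")``."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self):
        for dim, lvl in zip(DIMENSIONS, self.levels):
            if lvl not in (1, 2, 3, 4, 5):
                raise ValidationError(f"{dim} level must be 1..5, got {lvl}")

    @property
    def levels(self) -> tuple[int, ...]:
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )

    @classmethod
    def from_string(cls, s: str) -> "EQ5DState":
        if len(s) != 5 or not s.isdigit():
            raise ValidationError(f"state string must be 5 digits, got {s!r}")
        return cls(*(int(c) for c in s))

    def __str__(self) -> str:
        return "".join(str(l) for l in self.levels)


@dataclasses.dataclass
class Tariff:
    """Additive value set: index = 1 - constant - sum of decrements."""

    name: str
    decrements: dict          # (dimension, level) -> decrement
    constant: float = 0.0     # subtracted for any state != 11111

    def __post_init__(self):
        for dim in DIMENSIONS:
            prev = -np.inf
            for lvl in range(1, 6):
                d = self.decrements.get((dim, lvl))
                if d is None:
                    raise ValidationError(f"tariff {self.name} lacks ({dim}, {lvl})")
                if lvl == 1 and d != 0.0:
                    raise ValidationError("level 1 must carry a zero decrement")
                if d < prev:
                    raise ValidationError(
                        f"decrements must be non-decreasing in level ({dim})"
                    )
                prev = d

    def index(self, state: EQ5DState) -> float:
        total = sum(self.decrements[(dim, lvl)] for dim, lvl in zip(DIMENSIONS, state.levels))
        if total == 0.0:
            return 1.0
        return 1.0 - self.constant - total


def load_tariff(name: str = "dutch") -> Tariff:
    """Load a vendored value set; currently only ``dutch``."""
    key = name.lower()
    if key not in _TARIFF_FILES:
        raise ValidationError(
            f"unknown tariff {name!r}; available: {sorted(_TARIFF_FILES)}"
        )
    with resources.files("hemoqol.data").joinpath(_TARIFF_FILES[key]).open() as fh:
        df = pd.read_csv(fh, comment="#")
    dec = {(r.dimension, int(r.level)): float(r.decrement) for r in df.itertuples()}
    return Tariff(name=key, decrements=dec)


def score_eq5d(state: EQ5DState, tariff: Tariff) -> float:
    """Utility index of ``state`` under ``tariff``."""
    return tariff.index(state)


def all_states():
    """Iterate over all 3125 EQ-5D-5L states."""
    for levels in itertools.product(range(1, 6), repeat=5):
        yield EQ5DState(*levels)


def attainable_indices(tariff: Tariff) -> pd.DataFrame:
    """All states with their indices, sorted ascending by index.

    Used by the synthetic cohort generator to map a latent utility to the
    nearest attainable health state.
    """
    rows = [(str(s), tariff.index(s)) for s in all_states()]
    df = pd.DataFrame(rows, columns=["state", "index"]).sort_values("index", kind="stable")
    return df.reset_index(drop=True)


def nearest_state(target: float | np.ndarray, table: pd.DataFrame) -> pd.DataFrame:
    """Nearest attainable state(s) for latent utility value(s).

    ``table`` comes from :func:`attainable_indices`. Ties go to the lower
    index. Returns a DataFrame with columns ``state`` and ``index``.
    """
    vals = table["index"].to_numpy()
    t = np.atleast_1d(np.asarray(target, float))
    pos = np.searchsorted(vals, t)
    pos = np.clip(pos, 1, len(vals) - 1)
    lower, upper = vals[pos - 1], vals[pos]
    choose_lower = (t - lower) <= (upper - t)
    idx = np.where(choose_lower, pos - 1, pos)
    return table.iloc[idx].reset_index(drop=True)
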