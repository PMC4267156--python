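"""EQ-5D-5L health states, value sets and the bounded-outcome transform.

The EQ-5D-5L describes a health state by five dimensions — mobility (MO),
self-care (SC), usual activities (UA), pain/discomfort (PD) and
anxiety/depression (AD) — each at one of five levels (1 = no problems,
5 = unable/extreme). A country-specific *value set* assigns each of the
5^5 = 3125 states a utility on a scale anchored at 1 (full health, state
11111) and 0 (death); states worse than death take negative values. Interim
crosswalk value sets give a floor of −0.111 (Japanese) or −0.594 (UK).

The actual crosswalk tables are licensed artifacts and are not bundled. Any
user-supplied table can be loaded from CSV; for tests and examples the
package builds clearly-labelled *synthetic* stub value sets that share the
real sets' anchors (full health = 1, configurable floor) and monotonicity.

This module also owns the logistic transform used by logistic quantile
regression for bounded outcomes:

    h(y) = log((y - y_min) / (y_max - y)),

defined on the open interval (y_min, y_max). In practice y_min is set to
half the smallest observed utility increment below the smallest observed
utility, and y_max slightly above 1 (default 1.001).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidBoundsError, MissingStateError, SchemaError, TransformDomainError

DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")

#: y_min constants used with the interim crosswalk value sets; y_max = 1.001
#: for both. The increments behind them are not recoverable from the printed
#: constants, so the presets store the numbers directly.
BOUNDS_PRESETS = {
    "japanese": (0.17885, 1.001),
    "uk": (-0.28265, 1.001),
}


@dataclass(frozen=True)
class EQ5DState:
    """One EQ-5D-5L response: five dimension levels, each in 1..5."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self):
        for name, lev in zip(DIMENSIONS, self.levels):
            if lev not in (1, 2, 3, 4, 5):
                raise SchemaError(f"dimension {name}: level {lev!r} not in 1..5")

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )

    @classmethod
    def from_levels(cls, levels: Iterable[int]) -> "EQ5DState":
        return cls(*map(int, levels))


FULL_HEALTH = (1, 1, 1, 1, 1)
WORST_STATE = (5, 5, 5, 5, 5)


class ValueSet:
    """Health-state → utility lookup with ceiling 1 and floor ``u_min``."""

    def __init__(self, name: str, entries: dict[tuple[int, ...], float], smallest_increment: float | None = None):
        if FULL_HEALTH not in entries:
            raise SchemaError("value set must cover the full-health state 11111")
        if abs(entries[FULL_HEALTH] - 1.0) > 1e-12:
            raise SchemaError(f"full health must map to exactly 1, got {entries[FULL_HEALTH]}")
        self.name = name
        self.entries = dict(entries)
        self.u_min = min(self.entries.values())
        self.u_max = 1.0
        if smallest_increment is not None and smallest_increment <= 0:
            raise SchemaError("smallest_increment must be > 0")
        self.smallest_increment = smallest_increment

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def complete(self) -> bool:
        return len(self.entries) == 5**5

    def utility_of(self, state: EQ5DState | tuple[int, ...]) -> float:
        levels = state.levels if isinstance(state, EQ5DState) else tuple(int(v) for v in state)
        try:
            return self.entries[levels]
        except KeyError:
            raise MissingStateError(f"state {levels} not covered by value set {self.name!r}") from None

    def observed_smallest_increment(self) -> float:
        """Smallest positive gap between distinct utilities in the table."""
        u = np.unique(np.fromiter(self.entries.values(), float))
        if len(u) < 2:
            raise SchemaError("value set has a single utility level")
        return float(np.min(np.diff(u)))

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "ValueSet":
        """Load a full table (MO,SC,UA,PD,AD,utility; 3125 rows) or an
        additive-decrement table (dimension,level,decrement) expanded at load."""
        df = pd.read_csv(path)
        cols = set(df.columns)
        if {"MO", "SC", "UA", "PD", "AD", "utility"}.issubset(cols):
            if len(df) != 5**5:
                raise SchemaError(f"full value-set table must have 3125 rows, got {len(df)}")
            entries = {
                tuple(int(r[d]) for d in DIMENSIONS): float(r["utility"]) for _, r in df.iterrows()
            }
            if len(entries) != 5**5:
                raise SchemaError("duplicate states in value-set table")
            return cls(name or str(path), entries)
        if {"dimension", "level", "decrement"}.issubset(cols):
            dec: dict[str, dict[int, float]] = {d: {} for d in DIMENSIONS}
            for _, r in df.iterrows():
                d = str(r["dimension"])
                if d not in dec:
                    raise SchemaError(f"unknown dimension {d!r}")
                dec[d][int(r["level"])] = float(r["decrement"])
            for d in DIMENSIONS:
                for lev in range(1, 6):
                    if lev not in dec[d]:
                        raise SchemaError(f"decrement table missing {d} level {lev}")
                if abs(dec[d][1]) > 1e-12:
                    raise SchemaError(f"{d} level 1 decrement must be 0")
            entries = {
                levels: 1.0 - sum(dec[d][l] for d, l in zip(DIMENSIONS, levels))
                for levels in product(range(1, 6), repeat=5)
            }
            return cls(name or str(path), entries)
        raise SchemaError(
            "value-set CSV must have columns MO,SC,UA,PD,AD,utility or dimension,level,decrement"
        )

    def to_frame(self) -> pd.DataFrame:
        recs = [dict(zip(DIMENSIONS, k), utility=v) for k, v in sorted(self.entries.items())]
        return pd.DataFrame(recs)


# relative severity of the five dimensions in the synthetic stubs; pain and
# mobility weigh most, loosely echoing published crosswalk tariffs
_STUB_WEIGHTS = {"MO": 0.24, "SC": 0.18, "UA": 0.17, "PD": 0.23, "AD": 0.18}
_STUB_LEVEL_STEPS = {1: 0.0, 2: 0.18, 3: 0.40, 4: 0.72, 5: 1.0}


def make_stub_value_set(name: str = "japanese-stub", u_min: float = -0.111) -> ValueSet:
    """Build a synthetic value set: monotone in every dimension, full health
    exactly 1, worst state exactly ``u_min``.

    This is a stand-in for the licensed crosswalk tables; it reproduces their
    anchors and ordering structure, not their tariffs.
    """
    if u_min >= 1:
        raise SchemaError("u_min must be < 1")
    total = 1.0 - u_min
    entries = {}
    for levels in product(range(1, 6), repeat=5):
        dec = sum(
            total * _STUB_WEIGHTS[d] * _STUB_LEVEL_STEPS[l] for d, l in zip(DIMENSIONS, levels)
        )
        entries[levels] = 1.0 - dec
    entries[FULL_HEALTH] = 1.0
    entries[WORST_STATE] = u_min  # pin anchors against float round-off
    return ValueSet(name, entries)


def japanese_stub() -> ValueSet:
    """Synthetic stand-in with the Japanese crosswalk range −0.111..1."""
    return make_stub_value_set("japanese-stub", u_min=-0.111)


def uk_stub() -> ValueSet:
    """Synthetic stand-in with the UK crosswalk range −0.594..1."""
    return make_stub_value_set("uk-stub", u_min=-0.594)


def utility_of(state: EQ5DState | tuple[int, ...], value_set: ValueSet) -> float:
    """Utility of ``state`` under ``value_set`` (module-level convenience)."""
    return value_set.utility_of(state)


def utilities_from_csv(path, value_set: ValueSet) -> pd.Series:
    """Convert an EQ-5D-5L response CSV (columns MO,SC,UA,PD,AD) to utilities."""
    df = pd.read_csv(path)
    missing = [c for c in DIMENSIONS if c not in df.columns]
    if missing:
        raise SchemaError(f"response CSV missing columns {missing}")
    return df[list(DIMENSIONS)].apply(
        lambda r: value_set.utility_of(tuple(int(v) for v in r)), axis=1
    )


@dataclass(frozen=True)
class TransformBounds:
    """Open support (y_min, y_max) of the logistic transform."""

    y_min: float
    y_max: float

    def __post_init__(self):
        if not self.y_min < self.y_max:
            raise InvalidBoundsError(f"need y_min < y_max, got ({self.y_min}, {self.y_max})")

    def contains(self, y) -> np.ndarray:
        y = np.asarray(y, float)
        return (y > self.y_min) & (y < self.y_max)


def bounds_preset(name: str) -> TransformBounds:
    """Named bounds used with the crosswalk value sets ('japanese', 'uk')."""
    try:
        y_min, y_max = BOUNDS_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown bounds preset {name!r}; have {sorted(BOUNDS_PRESETS)}") from None
    return TransformBounds(y_min, y_max)


def derive_bounds(
    observed_min: float, smallest_increment: float, y_max_override: float = 1.001
) -> TransformBounds:
    """y_min = observed_min − increment/2; y_max from the override (default 1.001)."""
    if smallest_increment <= 0:
        raise InvalidBoundsError("smallest_increment must be > 0")
    y_min = observed_min - smallest_increment / 2.0
    if y_min >= observed_min:
        raise InvalidBoundsError("derived y_min does not lie below the observed minimum")
    return TransformBounds(y_min, y_max_override)


def logit_transform(y, bounds: TransformBounds) -> np.ndarray | float:
    """h(y) = log((y − y_min)/(y_max − y)); y must lie strictly inside the bounds."""
    arr = np.asarray(y, float)
    if not np.all(bounds.contains(arr)):
        bad = np.asarray(arr)[~bounds.contains(arr)]
        raise TransformDomainError(
            f"{bad.size} value(s) on or outside ({bounds.y_min}, {bounds.y_max}); first: {bad.flat[0]}"
        )
    out = np.log((arr - bounds.y_min) / (bounds.y_max - arr))
    return float(out) if np.isscalar(y) else out


def inverse_logit_transform(h, bounds: TransformBounds) -> np.ndarray | float:
    """Inverse of :func:`logit_transform`; output strictly inside (y_min, y_max)."""
    arr = np.asarray(h, float)
    # expit-style stable evaluation
    with np.errstate(over="ignore"):
        e = np.where(arr >= 0, np.exp(-arr), np.exp(arr))
    p = np.where(arr >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    out = bounds.y_min + (bounds.y_max - bounds.y_min) * p
    # the codomain is the OPEN interval; for |h| beyond ~36 the float result
    # would round onto a bound, so clamp to the nearest interior values
    out = np.clip(
        out,
        np.nextafter(bounds.y_min, np.inf),
        np.nextafter(bounds.y_max, -np.inf),
    )
    return float(out) if np.isscalar(h) else out
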