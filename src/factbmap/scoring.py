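"""FACT-B instrument scoring.

The FACT-B (Functional Assessment of Cancer Therapy - Breast, version 4) is a
37-item breast-cancer quality-of-life questionnaire. Items are answered on a
0-4 Likert scale and grouped into five subscales:

========  ===========================  =====  ===========
subscale  meaning                      items  score range
========  ===========================  =====  ===========
PWB       physical well-being              7  0-28
SWB       social/family well-being         7  0-28
EWB       emotional well-being             6  0-24
FWB       functional well-being            7  0-28
BCS       breast cancer subscale          10  0-40
========  ===========================  =====  ===========

Negatively worded items are reverse-scored (``4 - raw``) so that higher always
means better. Missing items are prorated by the FACIT "half-rule": a subscale
score is defined only when strictly more than half of its items are answered,
in which case each missing item is imputed with the mean of the answered ones
(equivalently, score = answered_sum * n_items / n_answered). Composites:

* FACT-G       = PWB + SWB + EWB + FWB            (0-108)
* TOI          = PWB + FWB + BCS                  (0-96)
* FACT-B total = PWB + SWB + EWB + FWB + BCS      (0-148)

The official FACIT item texts and IDs are licensed; the default manifest
shipped here uses placeholder IDs (PWB1..PWB7, ..., BCS1..BCS10) with a
reverse-scoring pattern resembling the FACIT convention. Supply the real
manifest as a CSV (columns ``item_id,subscale,negatively_worded``) for use
with actual questionnaires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import InvalidResponseError, ManifestError, SchemaError

SUBSCALES = ("PWB", "SWB", "EWB", "FWB", "BCS")

#: number of items per subscale; fixed by the instrument
SUBSCALE_SIZES = {"PWB": 7, "SWB": 7, "EWB": 6, "FWB": 7, "BCS": 10}

#: maximum attainable score per subscale (n_items * 4)
SUBSCALE_MAXIMA = {s: 4 * n for s, n in SUBSCALE_SIZES.items()}


@dataclass(frozen=True)
class ManifestItem:
    item_id: str
    subscale: str
    negatively_worded: bool


@dataclass(frozen=True)
class ItemManifest:
    """The 37-item FACT-B structure: item ids, subscale membership, polarity."""

    items: tuple[ManifestItem, ...]

    def __post_init__(self):
        if len(self.items) != 37:
            raise ManifestError(f"FACT-B manifest must have 37 items, got {len(self.items)}")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ManifestError("duplicate item_id in manifest")
        counts: dict[str, int] = {}
        for it in self.items:
            if it.subscale not in SUBSCALE_SIZES:
                raise ManifestError(f"unknown subscale {it.subscale!r} for item {it.item_id}")
            counts[it.subscale] = counts.get(it.subscale, 0) + 1
        if counts != SUBSCALE_SIZES:
            raise ManifestError(f"subscale sizes {counts} != required {SUBSCALE_SIZES}")

    def item_ids(self, subscale: str | None = None) -> list[str]:
        return [it.item_id for it in self.items if subscale is None or it.subscale == subscale]

    def __getitem__(self, item_id: str) -> ManifestItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @classmethod
    def from_csv(cls, path) -> "ItemManifest":
        df = pd.read_csv(path)
        required = {"item_id", "subscale", "negatively_worded"}
        if not required.issubset(df.columns):
            raise SchemaError(f"manifest CSV needs columns {sorted(required)}, got {list(df.columns)}")
        items = tuple(
            ManifestItem(str(r.item_id), str(r.subscale), _as_bool(r.negatively_worded))
            for r in df.itertuples()
        )
        return cls(items)


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"1", "true", "yes", "y"}
    return bool(x)


def default_manifest() -> ItemManifest:
    """Placeholder manifest shipped with the package (see module docstring)."""
    with resources.files("factbmap.data").joinpath("default_manifest.csv").open("rb") as fh:
        return ItemManifest.from_csv(fh)


@dataclass
class FactBForm:
    """One respondent's raw item responses; absent keys are missing answers."""

    responses: dict[str, int] = field(default_factory=dict)

    def validate(self, manifest: ItemManifest) -> None:
        known = set(manifest.item_ids())
        for item_id, value in self.responses.items():
            if item_id not in known:
                raise SchemaError(f"response for unknown item {item_id!r}")
            if value not in (0, 1, 2, 3, 4):
                raise InvalidResponseError(f"item {item_id}: response {value!r} not in 0..4")


@dataclass
class SubscaleProfile:
    """Subscale scores; ``None`` marks a subscale the half-rule left undefined."""

    pwb: Optional[float] = None
    swb: Optional[float] = None
    ewb: Optional[float] = None
    fwb: Optional[float] = None
    bcs: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {"PWB": self.pwb, "SWB": self.swb, "EWB": self.ewb, "FWB": self.fwb, "BCS": self.bcs}

    def get(self, subscale: str) -> Optional[float]:
        return self.as_dict()[subscale]

    @property
    def fact_g(self) -> Optional[float]:
        vals = (self.pwb, self.swb, self.ewb, self.fwb)
        return None if any(v is None for v in vals) else float(sum(vals))

    @property
    def toi(self) -> Optional[float]:
        vals = (self.pwb, self.fwb, self.bcs)
        return None if any(v is None for v in vals) else float(sum(vals))

    @property
    def fact_b_total(self) -> Optional[float]:
        vals = (self.pwb, self.swb, self.ewb, self.fwb, self.bcs)
        return None if any(v is None for v in vals) else float(sum(vals))


def recode_item(raw: int, negatively_worded: bool) -> int:
    """Reverse-score a negatively worded item so higher = better HRQoL.

    The reversal on the 0-4 scale is ``4 - raw`` and is an involution.
    """
    if raw not in (0, 1, 2, 3, 4):
        raise InvalidResponseError(f"response {raw!r} not in 0..4")
    return 4 - raw if negatively_worded else raw


def score_subscale(items: Sequence[Optional[float]], n_items: int | None = None) -> Optional[float]:
    """Prorated subscale score under the half-rule; ``None`` when undefined.

    ``items`` are already-recoded responses with ``None`` for missing. The
    score is defined when strictly more than half the items are answered:
    ``sum(answered) * n_items / n_answered``, i.e. mean-imputation of the
    missing items. Kept at full float precision (no rounding).
    """
    if n_items is None:
        n_items = len(items)
    if len(items) != n_items:
        raise SchemaError(f"expected {n_items} item values, got {len(items)}")
    answered = [v for v in items if v is not None and not (isinstance(v, float) and math.isnan(v))]
    for v in answered:
        if v not in (0, 1, 2, 3, 4):
            raise InvalidResponseError(f"recoded response {v!r} not in 0..4")
    if len(answered) * 2 <= n_items:  # "more than half" is strict
        return None
    return float(sum(answered)) * n_items / len(answered)


def score_form(form: FactBForm | Mapping[str, int], manifest: ItemManifest | None = None) -> SubscaleProfile:
    """Recode and score one FACT-B form into a :class:`SubscaleProfile`."""
    if manifest is None:
        manifest = default_manifest()
    if not isinstance(form, FactBForm):
        form = FactBForm(dict(form))
    form.validate(manifest)
    scores: dict[str, Optional[float]] = {}
    for sub in SUBSCALES:
        vals = [
            None
            if it.item_id not in form.responses
            else recode_item(form.responses[it.item_id], it.negatively_worded)
            for it in manifest.items
            if it.subscale == sub
        ]
        scores[sub] = score_subscale(vals, SUBSCALE_SIZES[sub])
    return SubscaleProfile(
        pwb=scores["PWB"], swb=scores["SWB"], ewb=scores["EWB"], fwb=scores["FWB"], bcs=scores["BCS"]
    )


def compute_composites(profile: SubscaleProfile) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Return ``(fact_g, toi, fact_b_total)``; a composite with any undefined
    component is itself ``None``."""
    return profile.fact_g, profile.toi, profile.fact_b_total


def score_items_csv(path, manifest: ItemManifest | None = None) -> pd.DataFrame:
    """Score an item-level CSV (one row per subject, one column per item id,
    blank = missing) into a subscale/composite table."""
    if manifest is None:
        manifest = default_manifest()
    df = pd.read_csv(path)
    missing_cols = [i for i in manifest.item_ids() if i not in df.columns]
    if missing_cols:
        raise SchemaError(f"item CSV missing columns: {missing_cols[:5]}{'...' if len(missing_cols) > 5 else ''}")
    rows = []
    for _, row in df.iterrows():
        responses = {}
        for item_id in manifest.item_ids():
            v = row[item_id]
            if pd.isna(v):
                continue
            fv = float(v)
            if not fv.is_integer():
                raise InvalidResponseError(f"non-integer response {v!r} for item {item_id}")
            responses[item_id] = int(fv)
        prof = score_form(FactBForm(responses), manifest)
        rows.append(
            {
                "PWB": prof.pwb,
                "SWB": prof.swb,
                "EWB": prof.ewb,
                "FWB": prof.fwb,
                "BCS": prof.bcs,
                "FACT_G": prof.fact_g,
                "TOI": prof.toi,
                "FACT_B_TOTAL": prof.fact_b_total,
            }
        )
    return pd.DataFrame(rows, columns=["PWB", "SWB", "EWB", "FWB", "BCS", "FACT_G", "TOI", "FACT_B_TOTAL"])


def profiles_from_subscale_csv(path) -> pd.DataFrame:
    """Load a pre-scored subscale CSV (columns PWB,SWB,EWB,FWB,BCS)."""
    df = pd.read_csv(path)
    missing = [c for c in SUBSCALES if c not in df.columns]
    if missing:
        raise SchemaError(f"subscale CSV missing columns {missing}")
    return df
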