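"""Data model and deterministic scoring for the questionnaire instruments.

Covers the five 5-item behaviour subscales rated 0-2 by two reporters, the
6-item parent distress screen rated 0-4 (summed 0-24, 'high' at >= 5), and
recoding of the parental education level (high iff NVQ-equivalent level >= 4).

Scoring here is complete-case: any missing item makes the sum score missing.
Latent-variable stages, not pro-rating, are the missing-data strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

CONSTRUCTS = ("conduct", "emotion", "peer", "prosocial", "hyperactivity")
REPORTERS = ("self", "parent")
SDQ_MAX = 2
K6_MAX = 4
K6_ITEMS = 6
K6_HIGH_CUTOFF = 5
EDUCATION_HIGH_MIN = 4

MISSING = float("nan")


class ItemValidationError(ValueError):
    """An item value outside its declared range, named for diagnosis."""


def _load_item_dictionary() -> dict:
    with resources.files("dyadlds.data").joinpath("items_sdq.yaml").open() as fh:
        return yaml.safe_load(fh)


_ITEMS = _load_item_dictionary()


@dataclass(frozen=True)
class SubscaleDefinition:
    """One 5-item subscale for one reporter."""

    name: str
    item_ids: tuple[int, ...]
    reverse_mask: tuple[bool, ...]
    reporter: str
    text: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in CONSTRUCTS:
            raise ValueError(f"unknown construct {self.name!r}")
        if self.reporter not in REPORTERS:
            raise ValueError(f"unknown reporter {self.reporter!r}")
        if len(self.item_ids) != 5 or len(set(self.item_ids)) != 5:
            raise ValueError(f"{self.name}: exactly 5 unique items required")
        if len(self.reverse_mask) != 5:
            raise ValueError(f"{self.name}: reverse mask must have 5 entries")


def subscale_definition(name: str, reporter: str) -> SubscaleDefinition:
    """Look up a subscale from the packaged item dictionary."""
    try:
        entry = _ITEMS["subscales"][name]
    except KeyError as exc:
        raise ValueError(f"unknown construct {name!r}") from exc
    items = tuple(entry["items"])
    rev = tuple(i in set(entry["reverse"]) for i in items)
    text = dict(entry[reporter]["text"])
    return SubscaleDefinition(name, items, rev, reporter, text)


def reference_item_moments(name: str, reporter: str) -> tuple[np.ndarray, np.ndarray]:
    """Published item means and SDs used as default calibration targets."""
    entry = _ITEMS["subscales"][name][reporter]
    items = _ITEMS["subscales"][name]["items"]
    mean = np.array([entry["reference_mean"][i] for i in items], dtype=float)
    sd = np.array([entry["reference_sd"][i] for i in items], dtype=float)
    return mean, sd


def is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def reverse_score(value, max_value: int):
    """Reflect a rating: 0 <-> max.  Missing propagates."""
    if is_missing(value):
        return MISSING
    if not float(value).is_integer() or not 0 <= value <= max_value:
        raise ItemValidationError(
            f"value {value!r} outside 0..{max_value}"
        )
    return max_value - int(value)


def score_subscale(items, definition: SubscaleDefinition):
    """Sum score 0-10 after reversing masked items; missing if any item is.

    ``items`` must align positionally with ``definition.item_ids``; a mapping
    keyed by item id is also accepted (and is the safe way to pass data whose
    order is not guaranteed).
    """
    if isinstance(items, dict):
        missing_ids = [i for i in definition.item_ids if i not in items]
        if missing_ids:
            raise ItemValidationError(
                f"{definition.name}/{definition.reporter}: items {missing_ids} absent"
            )
        values = [items[i] for i in definition.item_ids]
    else:
        values = list(items)
    if len(values) != 5:
        raise ItemValidationError(
            f"{definition.name}: expected 5 items, got {len(values)}"
        )
    total = 0
    for item_id, v, rev in zip(definition.item_ids, values, definition.reverse_mask):
        if is_missing(v):
            return MISSING
        if not float(v).is_integer() or not 0 <= v <= SDQ_MAX:
            raise ItemValidationError(
                f"{definition.name} item {item_id}: value {v!r} outside 0..{SDQ_MAX}"
            )
        total += SDQ_MAX - int(v) if rev else int(v)
    return total


def score_kessler6(items):
    """(total 0-24, 'low'/'high') for the distress screen; missing propagates."""
    values = list(items)
    if len(values) != K6_ITEMS:
        raise ItemValidationError(f"distress screen needs {K6_ITEMS} items")
    total = 0
    for j, v in enumerate(values, start=1):
        if is_missing(v):
            return MISSING, MISSING
        if not float(v).is_integer() or not 0 <= v <= K6_MAX:
            raise ItemValidationError(f"distress item {j}: value {v!r} outside 0..{K6_MAX}")
        total += int(v)
    return total, ("high" if total >= K6_HIGH_CUTOFF else "low")


def binarize_education(level):
    """'high' iff qualification level >= 4; no qualification counts as low."""
    if is_missing(level):
        return "low"
    if not float(level).is_integer() or not 1 <= level <= 5:
        raise ItemValidationError(f"education level {level!r} outside 1..5")
    return "high" if level >= EDUCATION_HIGH_MIN else "low"


# ---------------------------------------------------------------------------
# dyad-level data
# ---------------------------------------------------------------------------


@dataclass
class DyadRecord:
    """One parent-adolescent pair.

    sex: 1 = male, 0 = female (reference).  education: 1 = high, 0 = low
    (reference).  distress_high: 1 = above cutoff, 0 = at/below (reference).
    """

    dyad_id: int
    self_items: dict[str, list[float]]
    parent_items: dict[str, list[float]]
    distress_items: list[float]
    sex: int
    education: int
    survey_weight: float
    complete: bool

    def __post_init__(self):
        if self.survey_weight < 0:
            raise ValueError(f"dyad {self.dyad_id}: negative survey weight")
        for name, val in (("sex", self.sex), ("education", self.education)):
            if val not in (0, 1):
                raise ValueError(f"dyad {self.dyad_id}: {name} must be 0/1")


def item_column(construct: str, reporter: str, position: int) -> str:
    """CSV column name for one item (position is 1-based within the subscale)."""
    return f"{construct}_{reporter}_i{position}"


def item_columns(construct: str, reporter: str) -> list[str]:
    return [item_column(construct, reporter, k) for k in range(1, 6)]


def k6_columns() -> list[str]:
    return [f"k6_i{k}" for k in range(1, 7)]


def expected_columns(constructs=CONSTRUCTS) -> list[str]:
    cols: list[str] = []
    for c in constructs:
        for r in REPORTERS:
            cols.extend(item_columns(c, r))
    cols += k6_columns() + ["sex", "edu", "svywt", "complete"]
    return cols


def read_dyads_csv(path, constructs=CONSTRUCTS) -> pd.DataFrame:
    """Read the one-row-per-dyad CSV dialect; blank cells become NaN."""
    frame = pd.read_csv(path)
    missing = [c for c in expected_columns(constructs) if c not in frame.columns]
    if missing:
        raise ValueError(f"input CSV lacks columns: {missing}")
    for c in ("sex", "edu"):
        bad = ~frame[c].dropna().isin((0, 1))
        if bad.any():
            raise ValueError(f"column {c} must be coded 0/1")
    if (frame["svywt"].fillna(0) < 0).any():
        raise ValueError("survey weights must be nonnegative")
    return frame


def add_sum_scores(frame: pd.DataFrame, constructs=CONSTRUCTS) -> pd.DataFrame:
    """Append complete-case sum-score and distress columns to a dyad frame."""
    out = frame.copy()
    for c in constructs:
        for r in REPORTERS:
            definition = subscale_definition(c, r)
            block = frame[item_columns(c, r)].to_numpy(dtype=float)
            rev = np.array(definition.reverse_mask)
            scored = np.where(rev, SDQ_MAX - block, block)
            sums = scored.sum(axis=1)
            sums[np.isnan(block).any(axis=1)] = np.nan
            out[f"{c}_{r}_sum"] = sums
    k6 = frame[k6_columns()].to_numpy(dtype=float)
    total = k6.sum(axis=1)
    total[np.isnan(k6).any(axis=1)] = np.nan
    out["k6_total"] = total
    out["distress_high"] = np.where(
        np.isnan(total), np.nan, (total >= K6_HIGH_CUTOFF).astype(float)
    )
    return out


def scored_item_frame(frame: pd.DataFrame, construct: str, reporter: str) -> pd.DataFrame:
    """Item columns for one subscale on the scored metric (reverse applied).

    The CSV stores raw ratings; every analysis stage works on this scored
    view so reverse-flagged items load positively on their factor.
    """
    definition = subscale_definition(construct, reporter)
    cols = item_columns(construct, reporter)
    block = frame[cols].astype(float).copy()
    for col, rev in zip(cols, definition.reverse_mask):
        if rev:
            block[col] = SDQ_MAX - block[col]
    return block


def item_descriptives(frame: pd.DataFrame, constructs=CONSTRUCTS) -> pd.DataFrame:
    """Item-level mean/SD by construct and reporter on the scored metric."""
    rows = []
    for c in constructs:
        for r in REPORTERS:
            definition = subscale_definition(c, r)
            block = scored_item_frame(frame, c, r)
            for pos, item_id in enumerate(definition.item_ids, start=1):
                vals = block[item_column(c, r, pos)].dropna()
                rows.append({
                    "construct": c, "reporter": r, "item": item_id,
                    "reversed": definition.reverse_mask[pos - 1],
                    "text": definition.text.get(item_id, ""),
                    "mean": vals.mean(), "sd": vals.std(ddof=1), "n": len(vals),
                })
    return pd.DataFrame(rows)
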