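"""Scoring of the EPOCH adolescent-wellbeing questionnaire.

EPOCH measures five domains of positive psychological functioning —
Engagement, Perseverance, Optimism, Connectedness, Happiness — with 20
positively-worded items (4 per domain) rated on a 5-point frequency scale
("Almost never" = 1 ... "Almost always" = 5). Each domain score is the
arithmetic mean of its four items; no item is reverse-coded.

The item-to-domain mapping is configuration: instruments are licensed and
item order varies across administrations, so the shipped default is a
synthetic placeholder that assigns items 1-4 to engagement, 5-8 to
perseverance, and so on. Supply the real mapping as a two-column table
(item, domain) when scoring real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "N_ITEMS",
    "SCALE_MIN",
    "SCALE_MAX",
    "DEFAULT_ITEM_MAPPING",
    "EpochResponse",
    "EpochScores",
    "InvalidResponseError",
    "score_epoch",
    "validate_epoch",
    "read_item_mapping",
]

DOMAINS: tuple[str, ...] = (
    "engagement",
    "perseverance",
    "optimism",
    "connectedness",
    "happiness",
)
N_ITEMS = 20
ITEMS_PER_DOMAIN = 4
SCALE_MIN, SCALE_MAX = 1, 5

#: Synthetic placeholder mapping (blocks of four in domain order); real
#: administrations should load their instrument's mapping instead.
DEFAULT_ITEM_MAPPING: dict[int, str] = {
    i + 1: DOMAINS[i // ITEMS_PER_DOMAIN] for i in range(N_ITEMS)
}


class InvalidResponseError(ValueError):
    """A response sheet is incomplete or has out-of-range items."""


@dataclass(frozen=True)
class EpochResponse:
    """One participant's 20 raw item responses (1..5; None marks missing)."""

    participant_id: str
    items: tuple[int | None, ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(
                f"{self.participant_id}: expected {N_ITEMS} items, got {len(self.items)}"
            )
        object.__setattr__(self, "items", tuple(self.items))

    def problems(self) -> list[str]:
        out = []
        for i, v in enumerate(self.items, start=1):
            if v is None:
                out.append(f"item_{i:02d} missing")
            elif not (SCALE_MIN <= v <= SCALE_MAX) or int(v) != v:
                out.append(f"item_{i:02d} out of range ({v!r})")
        return out

    @property
    def is_valid(self) -> bool:
        return not self.problems()


@dataclass(frozen=True)
class EpochScores:
    """Five domain scores, each the mean of four items, in [1, 5]."""

    engagement: float
    perseverance: float
    optimism: float
    connectedness: float
    happiness: float

    def as_dict(self) -> dict[str, float]:
        return {d: getattr(self, d) for d in DOMAINS}

    def __getitem__(self, domain: str) -> float:
        if domain not in DOMAINS:
            raise KeyError(domain)
        return getattr(self, domain)


def _check_mapping(mapping: Mapping[int, str]) -> None:
    if set(mapping.keys()) != set(range(1, N_ITEMS + 1)):
        raise ValueError("mapping must cover items 1..20 exactly once")
    counts = pd.Series(list(mapping.values())).value_counts()
    if set(counts.index) != set(DOMAINS) or not (counts == ITEMS_PER_DOMAIN).all():
        raise ValueError("mapping must assign exactly 4 items to each of the 5 domains")


def score_epoch(
    response: EpochResponse, mapping: Mapping[int, str] | None = None
) -> EpochScores:
    """Score a complete response sheet into the five domain means.

    Raises :class:`InvalidResponseError` for missing or out-of-range items;
    such participants are excluded, not imputed.
    """
    mapping = dict(mapping) if mapping is not None else DEFAULT_ITEM_MAPPING
    _check_mapping(mapping)
    problems = response.problems()
    if problems:
        raise InvalidResponseError(
            f"{response.participant_id}: {'; '.join(problems)}"
        )
    sums: dict[str, list[int]] = {d: [] for d in DOMAINS}
    for item, value in enumerate(response.items, start=1):
        sums[mapping[item]].append(int(value))
    return EpochScores(**{d: float(np.mean(v)) for d, v in sums.items()})


def validate_epoch(
    responses: Iterable[EpochResponse], mapping: Mapping[int, str] | None = None
) -> tuple[list[tuple[EpochResponse, EpochScores]], list[EpochResponse]]:
    """Split responses into scored valid ones and excluded invalid ones."""
    valid: list[tuple[EpochResponse, EpochScores]] = []
    excluded: list[EpochResponse] = []
    for r in responses:
        try:
            valid.append((r, score_epoch(r, mapping)))
        except InvalidResponseError:
            excluded.append(r)
    return valid, excluded


def read_item_mapping(path) -> dict[int, str]:
    """Load an (item, domain) mapping table from delimited text."""
    df = pd.read_csv(path)
    if not {"item", "domain"} <= set(df.columns):
        raise ValueError("mapping table needs 'item' and 'domain' columns")
    mapping = {int(r.item): str(r.domain) for r in df.itertuples(index=False)}
    _check_mapping(mapping)
    return mapping


def read_responses(path) -> list[EpochResponse]:
    """Read wide response sheets (columns item_01..item_20; blanks = missing)."""
    df = pd.read_csv(path)
    cols = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        items = tuple(
            None if pd.isna(row[c]) else int(row[c]) for c in cols
        )
        out.append(EpochResponse(str(row["participant_id"]), items))
    return out
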