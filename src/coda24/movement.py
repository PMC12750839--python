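"""From accelerometer summaries to valid daily 4-part compositions.

Raw-acceleration processing (autocalibration, non-wear detection, sleep
algorithms) is out of scope; this module starts from per-epoch ENMO values
or per-day minute summaries and applies the study's classification and
inclusion rules:

* ENMO (milli-g) cut-points for adolescents: sedentary < 35.6,
  LPA [35.6, 201.4), MPA [201.4, 707.0), VPA >= 707.0. Intervals are
  left-closed on the upper side; MVPA = MPA + VPA.
* A day is valid iff wear time >= 16 h and sleep > 0 min; a participant is
  included iff they have >= 3 valid days.
* The analysed composition is the arithmetic mean of minutes per behaviour
  across valid days, closed to 1440.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coda import Composition, ZeroPartError, close

__all__ = [
    "IntensityClass",
    "EpochRecord",
    "DaySummary",
    "InclusionFlow",
    "classify_epoch",
    "classify_epochs",
    "summarise_day",
    "filter_valid",
    "participant_composition",
    "inclusion_flow",
    "multiplicative_replacement",
    "read_day_summaries",
]

# ENMO cut-points in milli-g (lower edges of LPA, MPA, VPA).
SED_LPA_CUT = 35.6
LPA_MPA_CUT = 201.4
MPA_VPA_CUT = 707.0

MIN_WEAR_HOURS = 16.0
MIN_VALID_DAYS = 3


class IntensityClass(str, Enum):
    SED = "sed"
    LPA = "lpa"
    MPA = "mpa"
    VPA = "vpa"


@dataclass(frozen=True)
class EpochRecord:
    participant_id: str
    day_index: int
    enmo: float  # milli-g
    epoch_length: float = 30.0  # seconds

    def __post_init__(self) -> None:
        if self.enmo < 0:
            raise ValueError(f"negative ENMO {self.enmo} for {self.participant_id}")
        if self.epoch_length <= 0:
            raise ValueError("epoch length must be > 0 seconds")


@dataclass(frozen=True)
class DaySummary:
    """Minutes per intensity class plus sleep and wear time for one day."""

    participant_id: str
    day_index: int
    sed_min: float
    lpa_min: float
    mpa_min: float
    vpa_min: float
    sleep_min: float
    wear_hours: float
    non_wear: bool = False

    def __post_init__(self) -> None:
        for name in ("sed_min", "lpa_min", "mpa_min", "vpa_min", "sleep_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} for {self.participant_id}")
        if not 0 <= self.wear_hours <= 24:
            raise ValueError(f"wear_hours {self.wear_hours} outside [0, 24]")

    @property
    def mvpa_min(self) -> float:
        return self.mpa_min + self.vpa_min

    @property
    def is_valid(self) -> bool:
        """Valid day: >= 16 h wear and > 0 min sleep."""
        return self.wear_hours >= MIN_WEAR_HOURS and self.sleep_min > 0


def classify_epoch(enmo: float) -> IntensityClass:
    """Classify one epoch's ENMO (milli-g) into an intensity class."""
    if enmo < 0:
        raise ValueError(f"ENMO must be non-negative, got {enmo}")
    if enmo < SED_LPA_CUT:
        return IntensityClass.SED
    if enmo < LPA_MPA_CUT:
        return IntensityClass.LPA
    if enmo < MPA_VPA_CUT:
        return IntensityClass.MPA
    return IntensityClass.VPA


def classify_epochs(enmo: np.ndarray) -> np.ndarray:
    """Vectorised cut-point classification; returns class codes 0..3 (SED..VPA)."""
    enmo = np.asarray(enmo, dtype=float)
    if np.any(enmo < 0):
        raise ValueError("ENMO must be non-negative")
    return np.digitize(enmo, [SED_LPA_CUT, LPA_MPA_CUT, MPA_VPA_CUT])


def summarise_day(
    epochs: Sequence[EpochRecord], sleep_minutes: float, wear_hours: float | None = None
) -> DaySummary:
    """Tally a day's epochs into minutes per intensity class.

    Minutes per class = epoch count x epoch_length / 60, so class minutes sum
    exactly to the recorded wear span. An empty epoch list is flagged as
    non-wear. When ``wear_hours`` is not given it is taken as the epoch
    coverage itself.
    """
    if not epochs:
        pid = "?"
        return DaySummary(pid, -1, 0, 0, 0, 0, sleep_minutes, 0.0, non_wear=True)
    pid = epochs[0].participant_id
    day = epochs[0].day_index
    seen: set[tuple[int, int]] = set()
    minutes = Counter()
    total_min = 0.0
    for i, e in enumerate(epochs):
        if (e.participant_id, e.day_index) != (pid, day):
            raise ValueError("epochs span multiple participants/days")
        m = e.epoch_length / 60.0
        minutes[classify_epoch(e.enmo)] += m
        total_min += m
    if wear_hours is None:
        wear_hours = min(total_min / 60.0, 24.0)
    return DaySummary(
        pid,
        day,
        sed_min=minutes[IntensityClass.SED],
        lpa_min=minutes[IntensityClass.LPA],
        mpa_min=minutes[IntensityClass.MPA],
        vpa_min=minutes[IntensityClass.VPA],
        sleep_min=sleep_minutes,
        wear_hours=wear_hours,
    )


@dataclass
class ValidityResult:
    included: bool
    valid_days: list[DaySummary]
    reason: str | None  # None when included

    @property
    def n_valid(self) -> int:
        return len(self.valid_days)


def filter_valid(
    days: Iterable[DaySummary],
    min_hours: float = MIN_WEAR_HOURS,
    min_days: int = MIN_VALID_DAYS,
) -> ValidityResult:
    """Apply the valid-day and valid-participant rules to one participant's days.

    A day is valid iff wear >= ``min_hours`` and sleep > 0; the participant is
    included iff at least ``min_days`` days are valid. The exclusion reason
    distinguishes "too few recorded days" from "days recorded but under the
    wear threshold", mirroring the study's exclusion-flow split.
    """
    days = list(days)
    valid = [d for d in days if d.wear_hours >= min_hours and d.sleep_min > 0]
    if len(valid) >= min_days:
        return ValidityResult(True, valid, None)
    # Two exclusion arms: a blanket wear-time failure (every recorded day
    # under the wear threshold) vs simply too few valid days.
    if days and all(d.wear_hours < min_hours for d in days):
        reason = "under_16h_wear"
    else:
        reason = "fewer_than_3_valid_days"
    return ValidityResult(False, valid, reason)


def participant_composition(valid_days: Sequence[DaySummary]) -> Composition:
    """Average minutes per behaviour over valid days, closed to 1440.

    Averaging precedes closure so the arithmetic means stay on the raw-minute
    scale reported descriptively; closure then restores the 1440-min total.
    """
    if not valid_days:
        raise ValueError("no valid days to average")
    sleep = float(np.mean([d.sleep_min for d in valid_days]))
    sed = float(np.mean([d.sed_min for d in valid_days]))
    lpa = float(np.mean([d.lpa_min for d in valid_days]))
    mvpa = float(np.mean([d.mvpa_min for d in valid_days]))
    try:
        return close([sleep, sed, lpa, mvpa])
    except ZeroPartError as err:
        raise ZeroPartError(
            f"{err}; consider the optional multiplicative_replacement pre-step"
        ) from None


def multiplicative_replacement(
    values: Sequence[float], minimum: float = 1.0, total: float = 1440.0
) -> np.ndarray:
    """Replace zero parts with ``minimum`` minutes, shrinking the rest to keep the total.

    Opt-in pre-step for datasets with structural zeros; the reference study
    had none.
    """
    vals = np.asarray(values, dtype=float)
    if np.any(vals < 0):
        raise ValueError("parts must be non-negative")
    zeros = vals == 0
    if not zeros.any():
        return vals.copy()
    replaced = vals.copy()
    replaced[zeros] = minimum
    replaced[~zeros] *= (total - minimum * zeros.sum()) / vals[~zeros].sum()
    return replaced


@dataclass(frozen=True)
class InclusionFlow:
    """Participant counts at each exclusion step of the study flow."""

    enrolled: int
    device_missing: int
    fewer_than_3_valid_days: int
    under_16h_wear: int
    invalid_wellbeing: int

    def __post_init__(self) -> None:
        for f in (
            self.enrolled,
            self.device_missing,
            self.fewer_than_3_valid_days,
            self.under_16h_wear,
            self.invalid_wellbeing,
        ):
            if f < 0:
                raise ValueError("flow counts must be non-negative")
        if self.final < 0:
            raise ValueError("exclusions exceed enrolment")

    @property
    def insufficient_accelerometer(self) -> int:
        return self.fewer_than_3_valid_days + self.under_16h_wear

    @property
    def final(self) -> int:
        return (
            self.enrolled
            - self.device_missing
            - self.insufficient_accelerometer
            - self.invalid_wellbeing
        )

    @property
    def retention_pct(self) -> float:
        return 100.0 * self.final / self.enrolled

    def pct(self, count: int) -> float:
        """A step count as a percentage of enrolment."""
        return 100.0 * count / self.enrolled

    def as_dict(self) -> dict[str, float]:
        return {
            "enrolled": self.enrolled,
            "device_missing": self.device_missing,
            "fewer_than_3_valid_days": self.fewer_than_3_valid_days,
            "under_16h_wear": self.under_16h_wear,
            "insufficient_accelerometer": self.insufficient_accelerometer,
            "invalid_wellbeing": self.invalid_wellbeing,
            "final": self.final,
            "retention_pct": round(self.retention_pct, 1),
        }


def inclusion_flow(roster: pd.DataFrame) -> InclusionFlow:
    """Tally the exclusion flow from a roster with one row per enrolled participant.

    ``roster`` needs a ``status`` column with values ``included``,
    ``device_missing``, ``fewer_than_3_valid_days``, ``under_16h_wear`` or
    ``invalid_wellbeing``.
    """
    counts = roster["status"].value_counts().to_dict()
    known = {
        "included",
        "device_missing",
        "fewer_than_3_valid_days",
        "under_16h_wear",
        "invalid_wellbeing",
    }
    unknown = set(counts) - known
    if unknown:
        raise ValueError(f"unknown roster status values: {sorted(unknown)}")
    flow = InclusionFlow(
        enrolled=len(roster),
        device_missing=counts.get("device_missing", 0),
        fewer_than_3_valid_days=counts.get("fewer_than_3_valid_days", 0),
        under_16h_wear=counts.get("under_16h_wear", 0),
        invalid_wellbeing=counts.get("invalid_wellbeing", 0),
    )
    assert flow.final == counts.get("included", 0)
    return flow


DAY_COLUMNS = [
    "participant_id",
    "day",
    "sleep_min",
    "sed_min",
    "lpa_min",
    "mvpa_min",
    "wear_hours",
]


def read_day_summaries(path) -> list[DaySummary]:
    """Read one-row-per-day summaries from delimited text (header required)."""
    df = pd.read_csv(path)
    missing = set(DAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"day-summary table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DaySummary(
                participant_id=str(row.participant_id),
                day_index=int(row.day),
                sed_min=float(row.sed_min),
                lpa_min=float(row.lpa_min),
                mpa_min=float(row.mvpa_min),  # day files carry MVPA already merged
                vpa_min=0.0,
                sleep_min=float(row.sleep_min),
                wear_hours=float(row.wear_hours),
            )
        )
    return out
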