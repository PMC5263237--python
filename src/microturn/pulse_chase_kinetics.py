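"""Closed-form labeling-kinetics calculations.

Converts a single-pulse labeling index into a cycling fraction, estimates
the cell-cycle length from the pulse-to-doubling interval, derives the
whole-population renewal time and lifetime renewal cycles, and converts an
instantaneous apoptotic fraction plus a clearance time into a
population-depletion time.

Conventions
-----------
* Printed-style values are *truncated* (floor) to whole hours/days; raw
  quotients are always reported alongside.
* The depletion formula is linear (constant absolute removal rate).  An
  exponential-decay variant is provided for comparison only.
* G2/M duration is ignored when reading the cell-cycle length off the
  doubling onset, a small positive bias on the estimate.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PulseChaseCurve",
    "KineticEstimates",
    "DepletionEstimate",
    "OnsetResult",
    "cycling_fraction",
    "estimate_cycle_length",
    "detect_doubling_onset",
    "renewal_time",
    "renewal_cycles",
    "depletion_time",
    "depletion_time_exponential",
    "ki67_to_brdu_index",
    "species_rate_ratio",
    "hours_to_days",
    "days_to_hours",
    "minutes_to_hours",
]

DAYS_PER_MONTH = 30.44


def hours_to_days(hours: float) -> float:
    return hours / 24.0


def days_to_hours(days: float) -> float:
    return days * 24.0


def minutes_to_hours(minutes: float) -> float:
    return minutes / 60.0


@dataclasses.dataclass
class PulseChaseCurve:
    """Labeled-fraction time course after a label pulse.

    ``times`` are hours post pulse (strictly increasing), ``labeled_fraction``
    is the percent of the population labeled at each time.
    """

    times: np.ndarray
    labeled_fraction: np.ndarray
    region: str = ""
    n_animals: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labeled_fraction = np.asarray(self.labeled_fraction, dtype=float)
        if self.times.shape != self.labeled_fraction.shape or self.times.ndim != 1:
            raise ValueError("times and labeled_fraction must be 1-D and equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.labeled_fraction < 0) or np.any(self.labeled_fraction > 100):
            raise ValueError("labeled_fraction values must lie in [0, 100]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_hr": self.times,
                "labeled_fraction_pct": self.labeled_fraction,
                "region": self.region,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PulseChaseCurve":
        df = pd.read_csv(path)
        region = str(df["region"].iloc[0]) if "region" in df and len(df) else ""
        return cls(
            times=df["time_hr"].to_numpy(float),
            labeled_fraction=df["labeled_fraction_pct"].to_numpy(float),
            region=region,
        )


@dataclasses.dataclass
class KineticEstimates:
    """Container for the renewal-equation quantities."""

    labeling_index: float | None = None
    s_fraction: float = 0.5
    cycle_length_hr: float | None = None
    cycling_fraction: float | None = None
    renewal_time_hr: float | None = None
    renewal_time_hr_trunc: int | None = None
    renewal_time_days: float | None = None
    renewal_time_days_trunc: int | None = None
    renewal_cycles: int | None = None
    lifespan_months: float | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclasses.dataclass
class DepletionEstimate:
    """Time to remove a whole population by constant-rate apoptosis."""

    clearance_min: float
    apoptotic_fraction: float
    depletion_hr: float
    depletion_hr_trunc: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclasses.dataclass
class OnsetResult:
    onset_hr: float | None
    baseline_return_hr: float | None


def cycling_fraction(labeling_index: float, s_fraction: float = 0.5) -> float:
    """Percent of the population in cycle, given the percent labeled by a
    single S-phase pulse: ``labeling_index / s_fraction``, capped at 100."""
    if s_fraction <= 0 or s_fraction > 1:
        raise ValueError(f"s_fraction must lie in (0, 1], got {s_fraction}")
    if not 0 <= labeling_index <= 100:
        raise ValueError(f"labeling_index must lie in [0, 100], got {labeling_index}")
    value = labeling_index / s_fraction
    if value > 100.0:
        warnings.warn(
            f"cycling fraction {value:.3g}% exceeds 100%; capped",
            RuntimeWarning,
            stacklevel=2,
        )
        return 100.0
    return value


def estimate_cycle_length(doubling_onset_hr: float, s_fraction: float = 0.5) -> float:
    """Cell-cycle length from the pulse-to-doubling interval, which is read
    as the S-phase duration: ``doubling_onset_hr / s_fraction``."""
    if s_fraction <= 0 or s_fraction > 1:
        raise ValueError(f"s_fraction must lie in (0, 1], got {s_fraction}")
    if doubling_onset_hr <= 0:
        raise ValueError("doubling_onset_hr must be positive")
    return doubling_onset_hr / s_fraction


def detect_doubling_onset(
    curve: PulseChaseCurve, tolerance: float = 0.05
) -> OnsetResult:
    """Earliest sampled time at which the labeled fraction has doubled
    (within ``tolerance``), plus the earliest later time back at baseline.

    No interpolation: onsets are read directly off sampled time points.
    """
    if curve.times.size < 2:
        raise ValueError("need at least 2 time points to detect a doubling onset")
    f0 = curve.labeled_fraction[0]
    onset = None
    baseline = None
    threshold = (2.0 - tolerance) * f0
    for t, f in zip(curve.times[1:], curve.labeled_fraction[1:]):
        if onset is None:
            if f0 > 0 and f >= threshold:
                onset = float(t)
        elif abs(f - f0) <= tolerance * f0:
            baseline = float(t)
            break
    return OnsetResult(onset_hr=onset, baseline_return_hr=baseline)


def renewal_time(cycle_length_hr: float, cycling_fraction: float) -> KineticEstimates:
    """Whole-population renewal time: ``100 * Tc / F`` hours.

    ``renewal_time_hr * cycling_fraction == 100 * cycle_length_hr`` holds
    exactly before rounding; truncated values mirror printed conventions.
    """
    if cycle_length_hr <= 0:
        raise ValueError("cycle_length_hr must be positive")
    if cycling_fraction <= 0:
        raise ValueError(
            "cycling_fraction must be positive (a population with no cycling "
            "cells never renews)"
        )
    raw_hr = 100.0 * cycle_length_hr / cycling_fraction
    trunc_hr = math.floor(raw_hr)
    return KineticEstimates(
        cycle_length_hr=cycle_length_hr,
        cycling_fraction=cycling_fraction,
        renewal_time_hr=raw_hr,
        renewal_time_hr_trunc=trunc_hr,
        renewal_time_days=trunc_hr / 24.0,
        renewal_time_days_trunc=trunc_hr // 24,
    )


def renewal_cycles(
    lifespan_months: float,
    renewal_time_hr: float,
    days_per_month: float = DAYS_PER_MONTH,
) -> int:
    """Whole renewals of the population that fit in a lifespan."""
    if lifespan_months <= 0 or renewal_time_hr <= 0 or days_per_month <= 0:
        raise ValueError("lifespan, renewal time and days_per_month must be positive")
    return math.floor(lifespan_months * days_per_month * 24.0 / renewal_time_hr)


def depletion_time(
    clearance_min: float = 80.0, apoptotic_fraction: float = 1.0
) -> DepletionEstimate:
    """Hours to remove a whole population when a constant
    ``apoptotic_fraction`` percent of it is visibly apoptotic at any instant
    and each apoptotic cell is cleared in ``clearance_min`` minutes."""
    if clearance_min <= 0:
        raise ValueError("clearance_min must be positive")
    if apoptotic_fraction <= 0:
        raise ValueError("apoptotic_fraction must be positive")
    raw_hr = clearance_min / (apoptotic_fraction / 100.0) / 60.0
    return DepletionEstimate(
        clearance_min=clearance_min,
        apoptotic_fraction=apoptotic_fraction,
        depletion_hr=raw_hr,
        depletion_hr_trunc=math.floor(raw_hr),
    )


def depletion_time_exponential(
    clearance_min: float = 80.0,
    apoptotic_fraction: float = 1.0,
    remaining_fraction: float = 0.01,
) -> float:
    """Exponential-decay variant: hours until only ``remaining_fraction`` of
    the population is left, with per-hour removal rate
    ``apoptotic_fraction% / clearance``.  For comparison only; the linear
    form is the headline."""
    if not 0 < remaining_fraction < 1:
        raise ValueError("remaining_fraction must lie in (0, 1)")
    rate_per_hr = (apoptotic_fraction / 100.0) / (clearance_min / 60.0)
    return -math.log(remaining_fraction) / rate_per_hr


def ki67_to_brdu_index(ki67_index: float) -> float:
    """Convert a Ki67 labeling index (all cycle phases except G0, roughly
    twice a single S-phase pulse) into the equivalent S-phase index."""
    if not 0 <= ki67_index <= 100:
        raise ValueError(f"ki67_index must lie in [0, 100], got {ki67_index}")
    return ki67_index / 2.0


def species_rate_ratio(rate_a: float, rate_b: float, decimals: int = 1) -> float:
    """``rate_a / rate_b`` rounded half-up to ``decimals`` places."""
    if rate_b <= 0:
        raise ValueError("rate_b must be positive")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    q = Decimal(rate_a) / Decimal(rate_b)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))
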