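"""Rate and spacing estimators for longitudinal cell-track tables.

Operates on the long-format snapshot tables produced by
:mod:`microturn.synthetic_population` (or equivalently formatted imaging
exports).  Rates use a cell-days-at-risk denominator: a cell present on day
``t`` contributes one risk day for the transition out of ``t`` for every
``t`` strictly before the last snapshot day, and a ``divided``/``died``
event on its day-``t`` row counts one event against that denominator.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import spatial, stats

from .synthetic_population import EVENT_DIED, EVENT_DIVIDED

logger = logging.getLogger(__name__)

__all__ = [
    "RateEstimate",
    "TwinPairProfile",
    "TwinDispersionResult",
    "proliferation_rate",
    "death_rate",
    "twin_dispersion",
    "nearest_neighbor_distances",
    "nn_summary",
]

STRATA = ("all", "resident", "newborn", "newborn_first5")


@dataclasses.dataclass
class RateEstimate:
    """Per-day event rate with per-field-of-view dispersion.

    ``rate_pct_per_day`` pools events over all cell-days; the median/IQR
    summarize the per-FOV rates (the headline presentation for imaging
    data).
    """

    rate_pct_per_day: float
    median_pct_per_day: float
    iqr_pct_per_day: float
    per_fov_rates: list[float]
    n_cells: int
    n_fov: int
    n_events: int
    n_cell_days: int
    stratum: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class TwinPairProfile:
    """Distance between the two daughters of one division, by day of age."""

    pair_id: str
    distances_by_age: dict[int, float]
    reference_nn_distance: float


@dataclasses.dataclass
class TwinDispersionResult:
    profiles: list[TwinPairProfile]
    median_by_age: dict[int, float]
    twin_day1_mean: float
    resident_nn_mean: float
    resident_nn_median: float
    crossing_age: int | None
    rank_statistic: float
    rank_pvalue: float
    t_statistic: float
    t_pvalue: float


def _iter_fovs(df: pd.DataFrame) -> Iterator[tuple[str, pd.DataFrame]]:
    if "fov" in df.columns:
        for fov, sub in df.groupby("fov", sort=True):
            yield str(fov), sub
    else:
        yield "fov0", df


def _is_newborn(sub: pd.DataFrame) -> pd.Series:
    parent = sub["parent_id"].fillna("").astype(str)
    return parent != ""


def _event_rate(
    df: pd.DataFrame, event: str, stratification: str, first5: int = 5
) -> RateEstimate:
    if stratification not in STRATA:
        raise ValueError(f"unknown stratum {stratification!r}; expected one of {STRATA}")
    if df["day"].nunique() < 2:
        raise ValueError("need at least 2 days of snapshots to estimate a rate")

    per_fov: list[float] = []
    total_events = total_days = 0
    cells: set[tuple[str, str]] = set()
    n_fov = 0
    for fov, sub in _iter_fovs(df):
        n_fov += 1
        last_day = sub["day"].max()
        at_risk = sub[sub["day"] < last_day].copy()
        if stratification != "all":
            newborn = _is_newborn(at_risk)
            if stratification == "resident":
                at_risk = at_risk[~newborn]
            else:
                at_risk = at_risk[newborn]
                if stratification == "newborn_first5":
                    birth = at_risk.groupby("cell_id")["day"].transform("min")
                    at_risk = at_risk[at_risk["day"] - birth < first5]
        n_days_at_risk = len(at_risk)
        n_events = int((at_risk["event"] == event).sum())
        if n_days_at_risk == 0:
            warnings.warn(
                f"field of view {fov}: no cell-days at risk in stratum "
                f"{stratification!r}; excluded",
                RuntimeWarning,
                stacklevel=3,
            )
            continue
        per_fov.append(100.0 * n_events / n_days_at_risk)
        total_events += n_events
        total_days += n_days_at_risk
        cells.update((fov, c) for c in at_risk["cell_id"].unique())

    if total_days == 0:
        raise ValueError(f"no cell-days at risk in stratum {stratification!r}")
    arr = np.asarray(per_fov)
    est = RateEstimate(
        rate_pct_per_day=100.0 * total_events / total_days,
        median_pct_per_day=float(np.median(arr)),
        iqr_pct_per_day=float(np.percentile(arr, 75) - np.percentile(arr, 25)),
        per_fov_rates=sorted(per_fov),
        n_cells=len(cells),
        n_fov=n_fov,
        n_events=total_events,
        n_cell_days=total_days,
        stratum=stratification,
    )
    logger.info(
        "%s rate [%s]: %.4f %%/day (%d events / %d cell-days, %d FOVs)",
        event,
        stratification,
        est.rate_pct_per_day,
        total_events,
        total_days,
        n_fov,
    )
    return est


def proliferation_rate(
    snapshots: pd.DataFrame, stratification: str = "all"
) -> RateEstimate:
    """Percent of cells dividing per day (one event per division)."""
    return _event_rate(snapshots, EVENT_DIVIDED, stratification)


def death_rate(snapshots: pd.DataFrame, stratification: str = "all") -> RateEstimate:
    """Percent of cells dying per day.  ``newborn`` restricts to cells whose
    birth was observed (non-empty ``parent_id``); ``newborn_first5`` further
    restricts risk days to the first 5 days of life."""
    return _event_rate(snapshots, EVENT_DIED, stratification)


# ---------------------------------------------------------------------------
# spacing
# ---------------------------------------------------------------------------

def nearest_neighbor_distances(positions: np.ndarray) -> np.ndarray:
    """Euclidean nearest-neighbor distance for every point (n >= 2)."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] < 2:
        raise ValueError("need at least 2 positions of equal dimension")
    tree = spatial.cKDTree(positions)
    dists, _ = tree.query(positions, k=2)
    nn = dists[:, 1]
    if np.any(nn == 0):
        warnings.warn(
            "duplicate coordinates found (nearest-neighbor distance 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    return nn


def nn_summary(distances: np.ndarray) -> dict:
    d = np.asarray(distances, dtype=float)
    return {
        "mean": float(d.mean()),
        "sem": float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0,
        "median": float(np.median(d)),
        "iqr": float(np.percentile(d, 75) - np.percentile(d, 25)),
        "n": int(d.size),
    }


def _positions(sub: pd.DataFrame) -> np.ndarray:
    return sub[["x_um", "y_um", "z_um"]].to_numpy(float)


def twin_dispersion(snapshots: pd.DataFrame, reference_day: int = 0) -> TwinDispersionResult:
    """Distance between twin daughters as a function of their age.

    Age 1 is the first day the pair is visible (its first 24 h of life).
    The resident nearest-neighbor spacing on ``reference_day`` (cells with
    no recorded parent) provides the comparison baseline; ``crossing_age``
    is the first age at which the median twin distance reaches the resident
    nearest-neighbor median.
    """
    profiles: list[TwinPairProfile] = []
    resident_nn: list[np.ndarray] = []
    for fov, sub in _iter_fovs(snapshots):
        residents = sub[(sub["day"] == reference_day) & ~_is_newborn(sub)]
        ref_median = np.nan
        if len(residents) >= 2:
            nn = nearest_neighbor_distances(_positions(residents))
            resident_nn.append(nn)
            ref_median = float(np.median(nn))
        newborn = sub[_is_newborn(sub)]
        for parent, pair in newborn.groupby("parent_id"):
            ids = sorted(pair["cell_id"].unique())
            if len(ids) != 2:
                warnings.warn(
                    f"parent {parent}: expected 2 daughters, found {len(ids)}; skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            a = pair[pair["cell_id"] == ids[0]].set_index("day")
            b = pair[pair["cell_id"] == ids[1]].set_index("day")
            common = a.index.intersection(b.index).sort_values()
            if common.empty:
                warnings.warn(
                    f"daughters of {parent} never co-observed; pair skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            birth = int(common.min())
            pa = a.loc[common, ["x_um", "y_um", "z_um"]].to_numpy(float)
            pb = b.loc[common, ["x_um", "y_um", "z_um"]].to_numpy(float)
            d = np.linalg.norm(pa - pb, axis=1)
            profile = {
                int(day) - birth + 1: float(dist) for day, dist in zip(common, d)
            }
            profiles.append(
                TwinPairProfile(
                    pair_id=f"{fov}:{parent}",
                    distances_by_age=profile,
                    reference_nn_distance=ref_median,
                )
            )

    by_age: dict[int, list[float]] = {}
    for p in profiles:
        for age, d in p.distances_by_age.items():
            by_age.setdefault(age, []).append(d)
    median_by_age = {age: float(np.median(v)) for age, v in sorted(by_age.items())}

    nn_all = np.concatenate(resident_nn) if resident_nn else np.array([])
    day1 = np.array(by_age.get(1, []), dtype=float)
    crossing = None
    if nn_all.size:
        ref = float(np.median(nn_all))
        for age in sorted(median_by_age):
            if median_by_age[age] >= ref:
                crossing = age
                break
    if day1.size and nn_all.size:
        rank = stats.mannwhitneyu(day1, nn_all, alternative="two-sided")
        tt = stats.ttest_ind(day1, nn_all, equal_var=False)
        rank_stat, rank_p = float(rank.statistic), float(rank.pvalue)
        t_stat, t_p = float(tt.statistic), float(tt.pvalue)
    else:
        rank_stat = rank_p = t_stat = t_p = float("nan")
    return TwinDispersionResult(
        profiles=profiles,
        median_by_age=median_by_age,
        twin_day1_mean=float(day1.mean()) if day1.size else float("nan"),
        resident_nn_mean=float(nn_all.mean()) if nn_all.size else float("nan"),
        resident_nn_median=float(np.median(nn_all)) if nn_all.size else float("nan"),
        crossing_age=crossing,
        rank_statistic=rank_stat,
        rank_pvalue=rank_p,
        t_statistic=t_stat,
        t_pvalue=t_p,
    )
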