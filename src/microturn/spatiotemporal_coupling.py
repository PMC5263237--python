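"""Spatial and temporal coupling between death and division events.

Given a longitudinal snapshot table, extracts death and division events and
quantifies how divisions cluster around deaths: counts of divisions within a
radius in the days before/during/after each death, nearest-division and
nearest-resident distances per death, the neighbor rank of the nearest
division, a permutation null for the temporal asymmetry, and an exact
Wilcoxon signed-rank test for the paired distance comparison.

All distances are plain Euclidean within one field of view; events from
different fields of view are never matched to each other.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_population import (
    ConfigurationError,
    EVENT_DIED,
    EVENT_DIVIDED,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingConfig",
    "TemporalCoupling",
    "CouplingDistances",
    "PermutationNull",
    "WilcoxonResult",
    "annotate_events",
    "temporal_coupling",
    "nearest_event_distances",
    "permutation_null",
    "wilcoxon_signed_rank",
]

EVENT_COLUMNS = ["fov", "cell_id", "parent_id", "day", "x_um", "y_um", "z_um"]


@dataclasses.dataclass
class CouplingConfig:
    radius_um: float = 200.0
    window_days: int = 4
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ConfigurationError("radius_um must be positive")
        if self.window_days < 1:
            raise ConfigurationError("window_days must be >= 1")
        if self.n_permutations < 100:
            raise ConfigurationError("n_permutations must be >= 100")


@dataclasses.dataclass
class TemporalCoupling:
    """Counts and fractions of vicinity divisions around death events."""

    n_before: int
    n_during: int
    n_after: int
    frac_before: float | None
    frac_during: float | None
    frac_after: float | None
    asymmetry: float | None
    n_deaths: int
    empty: bool

    @property
    def total(self) -> int:
        return self.n_before + self.n_during + self.n_after


@dataclasses.dataclass
class CouplingDistances:
    """Per-death nearest-division / nearest-resident distance block."""

    records: pd.DataFrame  # death_id, day, nearest_proliferating_um, ...
    median_proliferating: float
    iqr_proliferating: float
    median_resident: float
    iqr_resident: float
    median_rank: float
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    n_pairs: int


@dataclasses.dataclass
class PermutationNull:
    observed_asymmetry: float
    null_asymmetry: np.ndarray
    p_value: float
    n_permutations: int


@dataclasses.dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int
    method: str  # "exact" | "normal" | "degenerate"
    all_zero: bool = False


def _frame_positions(df: pd.DataFrame) -> np.ndarray:
    return df[["x_um", "y_um", "z_um"]].to_numpy(float)


def annotate_events(snapshots: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract death and division event lists from a snapshot table.

    The death position is the cell's last observed position; the division
    position is the mother's position on its division day.  A cell observed
    again after its ``died`` row is a validation error.
    """
    df = snapshots.copy()
    if "fov" not in df.columns:
        df.insert(0, "fov", "fov0")
    for key, sub in df[df["event"] == EVENT_DIED].groupby(["fov", "cell_id"]):
        fov, cell = key
        death_day = sub["day"].max()
        later = df[
            (df["fov"] == fov) & (df["cell_id"] == cell) & (df["day"] > death_day)
        ]
        if len(later):
            raise ValueError(
                f"cell {cell} (fov {fov}) reappears on day "
                f"{int(later['day'].min())} after dying on day {int(death_day)}"
            )
    deaths = df[df["event"] == EVENT_DIED][EVENT_COLUMNS].reset_index(drop=True)
    divisions = df[df["event"] == EVENT_DIVIDED][EVENT_COLUMNS].reset_index(drop=True)
    logger.info("annotated %d deaths and %d divisions", len(deaths), len(divisions))
    return deaths, divisions


def _vicinity_pairs(
    deaths: pd.DataFrame, divisions: pd.DataFrame, radius_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (death i, division j) in the same FOV within the radius.

    Pairs sharing a direct lineage are excluded (a dying daughter is one
    snapshot away from her own mother's division row, which would otherwise
    fabricate a before-death proliferation signal).
    """
    di, dj = [], []
    death_pos = _frame_positions(deaths)
    div_pos = _frame_positions(divisions)
    death_fov = deaths["fov"].to_numpy()
    div_fov = divisions["fov"].to_numpy()
    death_id = deaths["cell_id"].astype(str).to_numpy()
    death_parent = deaths["parent_id"].fillna("").astype(str).to_numpy()
    div_id = divisions["cell_id"].astype(str).to_numpy()
    div_parent = divisions["parent_id"].fillna("").astype(str).to_numpy()
    for i in range(len(deaths)):
        same = np.flatnonzero(div_fov == death_fov[i])
        if same.size == 0:
            continue
        d = np.linalg.norm(div_pos[same] - death_pos[i], axis=1)
        related = (
            (div_id[same] == death_id[i])
            | ((death_parent[i] != "") & (div_id[same] == death_parent[i]))
            | (div_parent[same] == death_id[i])
        )
        close = same[(d <= radius_um) & ~related]
        di.extend([i] * close.size)
        dj.extend(close.tolist())
    return np.asarray(di, dtype=int), np.asarray(dj, dtype=int)


def temporal_coupling(
    deaths: pd.DataFrame, divisions: pd.DataFrame, config: CouplingConfig
) -> TemporalCoupling:
    """Bin vicinity divisions as before / during / after each death.

    Division events within ``radius_um`` of a death and within
    ``window_days`` on either side are counted; ``during`` means the same
    snapshot day.  Asymmetry = (after - before) / (after + before).
    """
    if len(deaths) == 0 or len(divisions) == 0:
        raise ValueError("need at least one death and one division event")
    di, dj = _vicinity_pairs(deaths, divisions, config.radius_um)
    delta = divisions["day"].to_numpy()[dj] - deaths["day"].to_numpy()[di]
    in_window = np.abs(delta) <= config.window_days
    delta = delta[in_window]
    n_before = int((delta < 0).sum())
    n_during = int((delta == 0).sum())
    n_after = int((delta > 0).sum())
    total = n_before + n_during + n_after
    if total == 0:
        return TemporalCoupling(
            0, 0, 0, None, None, None, None, n_deaths=len(deaths), empty=True
        )
    asym = (
        (n_after - n_before) / (n_after + n_before)
        if (n_after + n_before) > 0
        else 0.0
    )
    return TemporalCoupling(
        n_before=n_before,
        n_during=n_during,
        n_after=n_after,
        frac_before=n_before / total,
        frac_during=n_during / total,
        frac_after=n_after / total,
        asymmetry=asym,
        n_deaths=len(deaths),
        empty=False,
    )


def _lineage_exclusions(death: pd.Series, parent_of: dict[str, str]) -> set[str]:
    """The dying cell plus cells sharing its lineage within one generation."""
    out = {death["cell_id"]}
    parent = parent_of.get(death["cell_id"], "")
    if parent:
        out.add(parent)
    for child, p in parent_of.items():
        if p == death["cell_id"]:
            out.add(child)
    return out


def nearest_event_distances(
    deaths: pd.DataFrame,
    divisions: pd.DataFrame,
    residents: pd.DataFrame,
    config: CouplingConfig,
) -> CouplingDistances:
    """Per death: distance to the nearest division within the temporal
    window, distance to the nearest resident cell on the death day, and the
    neighbor rank of that nearest division among all cells present on the
    death day.  The dying cell and its one-generation lineage are excluded
    from both candidate sets.
    """
    if len(deaths) == 0:
        raise ValueError("no death events")
    df = residents.copy()
    if "fov" not in df.columns:
        df.insert(0, "fov", "fov0")
    parent_of = {}
    for _, row in df.drop_duplicates("cell_id").iterrows():
        p = str(row.get("parent_id", "") or "")
        if p:
            parent_of[str(row["cell_id"])] = p

    div_day = divisions["day"].to_numpy() if len(divisions) else np.array([])
    div_pos = _frame_positions(divisions) if len(divisions) else np.empty((0, 3))
    records = []
    for _, death in deaths.iterrows():
        excluded = _lineage_exclusions(death, parent_of)
        day = death["day"]
        pos = np.array([death["x_um"], death["y_um"], death["z_um"]])

        same_day = df[
            (df["fov"] == death["fov"])
            & (df["day"] == day)
            & ~df["cell_id"].isin(excluded)
        ]
        if len(same_day) == 0:
            warnings.warn(
                f"death {death['cell_id']}: no resident cells on day {day}; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        neighbor_d = np.sort(
            np.linalg.norm(_frame_positions(same_day) - pos, axis=1)
        )
        nearest_resident = float(neighbor_d[0])

        nearest_prolif = np.nan
        rank = np.nan
        if len(divisions):
            ok = (
                (divisions["fov"].to_numpy() == death["fov"])
                & (np.abs(div_day - day) <= config.window_days)
                & ~divisions["cell_id"].isin(excluded).to_numpy()
            )
            if ok.any():
                d = np.linalg.norm(div_pos[ok] - pos, axis=1)
                nearest_prolif = float(d.min())
                rank = int(1 + np.searchsorted(neighbor_d, nearest_prolif, "left"))

        delta = div_day[ok] - day if len(divisions) and ok.any() else np.array([])
        records.append(
            {
                "death_id": death["cell_id"],
                "fov": death["fov"],
                "day": int(day),
                "nearest_proliferating_um": nearest_prolif,
                "nearest_resident_um": nearest_resident,
                "rank_of_nearest_proliferating": rank,
                "n_prolif_before": int((delta < 0).sum()),
                "n_prolif_during": int((delta == 0).sum()),
                "n_prolif_after": int((delta > 0).sum()),
            }
        )
    rec = pd.DataFrame.from_records(records)
    if rec.empty:
        raise ValueError("no death event had resident cells on its death day")
    paired = rec.dropna(subset=["nearest_proliferating_um"])
    if len(paired) >= 5:
        w = wilcoxon_signed_rank(
            paired["nearest_proliferating_um"].to_numpy(),
            paired["nearest_resident_um"].to_numpy(),
        )
        w_stat, w_p = w.statistic, w.p_value
    else:
        w_stat = w_p = float("nan")
    np_vals = paired["nearest_proliferating_um"].to_numpy()
    nr_vals = rec["nearest_resident_um"].to_numpy()
    return CouplingDistances(
        records=rec,
        median_proliferating=float(np.median(np_vals)) if np_vals.size else np.nan,
        iqr_proliferating=(
            float(np.percentile(np_vals, 75) - np.percentile(np_vals, 25))
            if np_vals.size
            else np.nan
        ),
        median_resident=float(np.median(nr_vals)),
        iqr_resident=float(np.percentile(nr_vals, 75) - np.percentile(nr_vals, 25)),
        median_rank=(
            float(paired["rank_of_nearest_proliferating"].median())
            if len(paired)
            else np.nan
        ),
        wilcoxon_statistic=w_stat,
        wilcoxon_pvalue=w_p,
        n_pairs=len(paired),
    )


def permutation_null(
    deaths: pd.DataFrame,
    divisions: pd.DataFrame,
    config: CouplingConfig,
) -> PermutationNull:
    """Null distribution of the temporal asymmetry obtained by permuting
    division days within the observation window (positions and fields of
    view fixed, so the spatial point pattern and the day-marginal of
    division activity are preserved; only the death-division temporal
    alignment is destroyed).

    p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if len(deaths) < 5 or len(divisions) < 5:
        raise ValueError(
            "permutation null needs at least 5 deaths and 5 divisions; "
            "simulate more data"
        )
    observed = temporal_coupling(deaths, divisions, config)
    if observed.empty or observed.asymmetry is None:
        raise ValueError("no vicinity divisions observed; nothing to test")
    rng = np.random.default_rng(config.seed)
    di, dj = _vicinity_pairs(deaths, divisions, config.radius_um)
    death_days = deaths["day"].to_numpy()[di]
    observed_div_days = divisions["day"].to_numpy()

    null = np.empty(config.n_permutations)
    chunk = 200
    for start in range(0, config.n_permutations, chunk):
        size = min(chunk, config.n_permutations - start)
        perm_days = np.stack(
            [rng.permutation(observed_div_days) for _ in range(size)]
        )
        delta = perm_days[:, dj] - death_days[None, :]
        in_win = np.abs(delta) <= config.window_days
        after = ((delta > 0) & in_win).sum(axis=1)
        before = ((delta < 0) & in_win).sum(axis=1)
        denom = after + before
        with np.errstate(invalid="ignore"):
            a = np.where(denom > 0, (after - before) / np.maximum(denom, 1), np.nan)
        null[start : start + size] = a
    exceed = np.nansum(null >= observed.asymmetry)
    p = (1.0 + exceed) / (1.0 + config.n_permutations)
    return PermutationNull(
        observed_asymmetry=observed.asymmetry,
        null_asymmetry=null,
        p_value=float(p),
        n_permutations=config.n_permutations,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _exact_sf_table(doubled_ranks: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ over all sign assignments, by convolution.

    ``doubled_ranks`` are the (mid-)ranks times two, so all achievable sums
    are integers.  Returns counts indexed by the value of 2*W+.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties receive mid-ranks.  The null
    distribution of W+ (sum of positive-difference ranks) is enumerated
    exactly for n <= 25 and approximated by a tie-corrected normal with
    continuity correction above.  All differences zero returns p = 1 by
    convention, flagged via ``all_zero``.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(
            statistic=0.0, p_value=1.0, n_used=0, method="degenerate", all_zero=True
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= 25:
        doubled = np.round(2 * ranks).astype(int)
        counts = _exact_sf_table(doubled)
        total = counts.sum()  # 2**n
        w2 = int(round(2 * w_plus))
        cdf_le = counts[: w2 + 1].sum() / total
        cdf_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(cdf_le, cdf_ge))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if sigma == 0:
            p, method = 1.0, "degenerate"
        else:
            z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
            p = float(2.0 * stats.norm.sf(abs(z)))
            p = min(1.0, p)
            method = "normal"
    return WilcoxonResult(
        statistic=w_plus, p_value=float(p), n_used=n, method=method, all_zero=False
    )
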