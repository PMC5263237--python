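"""Spatial birth-death simulation of a tissue-resident cell population.

The model mimics daily two-photon snapshots of a fixed imaging volume: cells
occupy fixed positions, divide into two adjacent daughters that disperse by a
random walk, and die with hazards that differ between resident and newborn
cells.  Division can optionally be coupled to recent nearby deaths
("local replacement"), which redistributes the division hazard toward the
neighborhood of a death without changing its population mean.

Time is discretized to one step per imaging day.  On the transition out of
day ``t`` each alive cell draws a single uniform variate and either divides
(probability ``p_div``), dies (probability ``p_death``), or survives.  Using
one variate keeps the marginal event probabilities exactly equal to the
configured hazards, so downstream rate estimators are unbiased.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "CellTrack",
    "TrackSet",
    "simulate",
    "simulate_apoptosis_blocked",
    "apply_label_pulse",
    "labeled_fraction_curve",
    "render_snapshots",
    "render_all",
    "write_snapshots",
    "read_snapshots",
    "monocyte_wave_config",
    "SNAPSHOT_COLUMNS",
]

SNAPSHOT_COLUMNS = [
    "day",
    "cell_id",
    "parent_id",
    "x_um",
    "y_um",
    "z_um",
    "event",
    "labels",
]

EVENT_NONE = "none"
EVENT_DIVIDED = "divided"
EVENT_DIED = "died"
EVENT_APPEARED = "appeared"

LABEL_BRDU = "brdu_positive"
LABEL_NEWBORN = "newborn"
LABEL_MONOCYTE = "monocyte"


class ConfigurationError(ValueError):
    """Raised for invalid simulation or analysis configuration."""


@dataclasses.dataclass
class SimulationConfig:
    """All geometry, hazard, coupling and labeling parameters of a run.

    Hazards are per-cell per-day probabilities.  ``newborn_hazard_profile``
    selects how the elevated death hazard of recently divided cells is
    shaped: ``"flat"`` applies ``newborn_death_hazard`` for the first
    ``newborn_window`` days of life, ``"early5"`` applies
    ``early_death_hazard`` for the first 5 days and the resident hazard
    afterwards.
    """

    volume_dims: tuple[float, float, float] = (317.0, 317.0, 160.0)
    n_fov: int = 9
    initial_cells_per_fov: int = 74
    division_hazard: float = 0.0079
    resident_death_hazard: float = 0.0123
    newborn_death_hazard: float = 0.024
    newborn_hazard_profile: str = "flat"
    early_death_hazard: float = 0.05
    newborn_window: int = 10
    coupling_mode: str = "local_replacement"
    coupling_radius: float = 200.0
    # each death deposits a division trigger within coupling_radius whose
    # intensity halves every day and expires after coupling_lag days;
    # coupling_fraction is the share of the division budget delivered via
    # these triggers (the rest is a spatially uniform base hazard).  The
    # per-death trigger budget is calibrated against the expected death
    # rate so the population-mean division hazard stays at division_hazard.
    coupling_lag: int = 4
    coupling_fraction: float = 0.9
    coupling_kernel_um: float = 30.0
    # 16.5 um/day makes the median twin separation cross the resident
    # nearest-neighbor spacing (~34 um at default density) 3-4 days after
    # division: median d(age) ~ 0.89 * sqrt((2*offset)^2
    # + 2*(age-1)*step^2), with age 1 = the pair's first 24 h.
    dispersion_step: float = 16.5
    daughter_offset_um: float = 5.0
    crowding_capacity: float | None = None
    apoptotic_clearance_min: float = 80.0
    n_days: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_dims = tuple(float(v) for v in self.volume_dims)
        if len(self.volume_dims) != 3 or any(
            not np.isfinite(v) or v <= 0 for v in self.volume_dims
        ):
            raise ConfigurationError(
                f"volume_dims must be 3 strictly positive lengths, got {self.volume_dims}"
            )
        for name in (
            "division_hazard",
            "resident_death_hazard",
            "newborn_death_hazard",
            "early_death_hazard",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.newborn_hazard_profile not in ("flat", "early5"):
            raise ConfigurationError(
                f"newborn_hazard_profile must be 'flat' or 'early5', "
                f"got {self.newborn_hazard_profile!r}"
            )
        if self.coupling_mode not in ("uncoupled", "local_replacement"):
            raise ConfigurationError(
                f"coupling_mode must be 'uncoupled' or 'local_replacement', "
                f"got {self.coupling_mode!r}"
            )
        if self.coupling_radius <= 0:
            raise ConfigurationError("coupling_radius must be positive")
        if self.coupling_lag < 1:
            raise ConfigurationError("coupling_lag must be >= 1 day")
        if not 0.0 <= self.coupling_fraction <= 1.0:
            raise ConfigurationError("coupling_fraction must lie in [0, 1]")
        if self.coupling_kernel_um <= 0:
            raise ConfigurationError("coupling_kernel_um must be positive")
        if self.dispersion_step < 0 or self.daughter_offset_um < 0:
            raise ConfigurationError("dispersion parameters must be non-negative")
        if self.crowding_capacity is not None and self.crowding_capacity < 1.0:
            raise ConfigurationError(
                f"crowding_capacity must be >= 1.0, got {self.crowding_capacity}"
            )
        if self.n_days < 2:
            raise ConfigurationError("n_days must be >= 2 (need at least one transition)")
        if self.n_fov < 1 or self.initial_cells_per_fov < 0:
            raise ConfigurationError("n_fov must be >= 1 and initial cell count >= 0")
        if self.newborn_window < 0:
            raise ConfigurationError("newborn_window must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["volume_dims"] = list(self.volume_dims)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {unknown}")
        return cls(**dict(data))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


def monocyte_wave_config(
    apoptotic_fraction_pct: float = 3.17, **overrides
) -> SimulationConfig:
    """Preset for a non-proliferating labeled population that is cleared
    by a constant apoptotic fraction (used to exercise depletion-time
    estimates)."""
    if not 0 < apoptotic_fraction_pct <= 100:
        raise ConfigurationError("apoptotic_fraction_pct must lie in (0, 100]")
    params = dict(
        division_hazard=0.0,
        resident_death_hazard=apoptotic_fraction_pct / 100.0,
        newborn_death_hazard=apoptotic_fraction_pct / 100.0,
        coupling_mode="uncoupled",
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclasses.dataclass
class CellTrack:
    """One cell's lifetime within a field of view.

    ``birth_day`` is ``None`` for cells present before observation started.
    ``death_day`` / ``divided_day`` are the last day the cell was observed
    (the event happened on the transition out of that day).  ``positions``
    maps day index to a 3-vector in micrometers.
    """

    cell_id: str
    parent_id: str | None = None
    birth_day: int | None = None
    death_day: int | None = None
    divided_day: int | None = None
    positions: dict[int, np.ndarray] = dataclasses.field(default_factory=dict)
    labels: set[str] = dataclasses.field(default_factory=set)

    @property
    def first_day(self) -> int:
        return min(self.positions)

    @property
    def last_day(self) -> int:
        return max(self.positions)


@dataclasses.dataclass
class TrackSet:
    """All tracks of one field of view plus the generating configuration."""

    tracks: list[CellTrack]
    config: SimulationConfig
    fov_id: str
    extinct: bool = False
    n_division_events: int = 0
    n_death_events: int = 0

    def alive_on(self, day: int) -> list[CellTrack]:
        return [t for t in self.tracks if day in t.positions]

    def validate(self) -> None:
        ids = [t.cell_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate cell ids in field of view {self.fov_id}")
        dims = np.asarray(self.config.volume_dims)
        children: dict[str, int] = {}
        for t in self.tracks:
            if t.birth_day is not None and t.death_day is not None:
                if t.death_day < t.birth_day:
                    raise ValueError(f"cell {t.cell_id}: death before birth")
            days = sorted(t.positions)
            if days != list(range(days[0], days[-1] + 1)):
                raise ValueError(f"cell {t.cell_id}: non-contiguous observation days")
            for p in t.positions.values():
                if np.any(p < 0) or np.any(p > dims):
                    raise ValueError(f"cell {t.cell_id}: position outside the volume")
            if t.parent_id is not None:
                children[t.parent_id] = children.get(t.parent_id, 0) + 1
        for parent, n in children.items():
            if n != 2:
                raise ValueError(f"division of {parent} yielded {n} daughters, not 2")
        if not self.extinct:
            n0 = len(self.alive_on(0))
            if n0 != self.config.initial_cells_per_fov:
                raise ValueError(
                    f"day-0 count {n0} != initial_cells_per_fov "
                    f"{self.config.initial_cells_per_fov}"
                )


def _reflect(points: np.ndarray, dims: np.ndarray) -> np.ndarray:
    """Fold coordinates back into [0, L] by mirror reflection."""
    period = 2.0 * dims
    m = np.mod(points, period)
    return np.where(m > dims, period - m, m)


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return v / norms


def _death_hazards(cfg: SimulationConfig, ages: np.ndarray) -> np.ndarray:
    """Per-cell death probability given days since birth (-1 = pre-existing)."""
    h = np.full(ages.shape, cfg.resident_death_hazard)
    newborn = ages >= 0
    if cfg.newborn_hazard_profile == "flat":
        h[newborn & (ages < cfg.newborn_window)] = cfg.newborn_death_hazard
    else:  # early5: elevated hazard on the first 5 days of life only
        h[newborn & (ages < 5)] = cfg.early_death_hazard
    return h


def _age_hazard(cfg: SimulationConfig, age: int) -> float:
    return float(_death_hazards(cfg, np.array([age]))[0])


def _expected_death_hazard_mix(cfg: SimulationConfig) -> float:
    """Expected deaths per cell-day over the run, from the deterministic
    age-structure recursion (newborn pools age into the resident pool).

    Used to calibrate the per-death trigger budget of the coupled mode so
    the population-mean division hazard stays at ``division_hazard``.
    """
    window = max(cfg.newborn_window, 5 if cfg.newborn_hazard_profile == "early5" else 0)
    mature = float(cfg.initial_cells_per_fov)
    newborn = [0.0] * max(window, 1)
    h_div = cfg.division_hazard
    deaths = cell_days = 0.0
    for _ in range(cfg.n_days - 1):
        total = mature + sum(newborn)
        if total <= 0:
            break
        cell_days += total
        day_deaths = mature * cfg.resident_death_hazard + sum(
            newborn[a] * _age_hazard(cfg, a) for a in range(len(newborn))
        )
        deaths += day_deaths
        divisions = total * h_div
        nxt = [0.0] * len(newborn)
        nxt[0] = 2.0 * divisions
        for a in range(len(newborn) - 1):
            surv = max(0.0, 1.0 - h_div - _age_hazard(cfg, a))
            nxt[a + 1] += newborn[a] * surv
        graduating = newborn[-1] * max(
            0.0, 1.0 - h_div - _age_hazard(cfg, len(newborn) - 1)
        )
        mature = mature * max(0.0, 1.0 - h_div - cfg.resident_death_hazard) + graduating
        newborn = nxt
    return deaths / cell_days if cell_days > 0 else 0.0


def _coupling_calibration(cfg: SimulationConfig) -> float:
    """Trigger budget per death for the coupled mode.

    The budget ``c`` makes E[triggered divisions] = coupling_fraction x
    division_hazard x cell-days, given the expected death rate: every death
    begets on average ``c`` local divisions over the lag window.
    """
    h_mix = _expected_death_hazard_mix(cfg)
    if h_mix <= 0:
        return 0.0
    return cfg.coupling_fraction * cfg.division_hazard / h_mix


def _simulate_fov(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    fov_id: str,
    initial_labels: Iterable[str] = (),
    block_apoptosis: bool = False,
    calibration: float | None = None,
) -> TrackSet:
    dims = np.asarray(cfg.volume_dims, dtype=float)
    coupled = (
        cfg.coupling_mode == "local_replacement"
        and cfg.division_hazard > 0
        and not block_apoptosis
    )
    if coupled:
        trigger_budget = (
            calibration if calibration is not None else _coupling_calibration(cfg)
        )
        coupled = trigger_budget > 0
    decay_weights = 0.5 ** np.arange(cfg.coupling_lag)
    decay_weights = decay_weights / decay_weights.sum()
    initial_labels = set(initial_labels)

    tracks: list[CellTrack] = []
    counter = 0

    def new_track(parent_id, birth_day, pos, labels) -> CellTrack:
        nonlocal counter
        t = CellTrack(
            cell_id=f"{fov_id}c{counter:05d}",
            parent_id=parent_id,
            birth_day=birth_day,
            labels=set(labels),
        )
        t.positions[birth_day if birth_day is not None else 0] = np.asarray(pos, float)
        counter += 1
        tracks.append(t)
        return t

    alive: list[CellTrack] = []
    init_pos = rng.random((cfg.initial_cells_per_fov, 3)) * dims
    for i in range(cfg.initial_cells_per_fov):
        alive.append(new_track(None, None, init_pos[i], initial_labels))

    # (day, position) of recent deaths, consumed by the coupling boost
    recent_deaths: list[tuple[int, np.ndarray]] = []
    if coupled:
        # stationary warm-up: pre-observation deaths supply trigger inflow
        # to the first days, balancing the budget that deaths near the end
        # of the run carry beyond the observation window
        h_mix = _expected_death_hazard_mix(cfg)
        for dday in range(-cfg.coupling_lag, 0):
            for _ in range(rng.poisson(cfg.initial_cells_per_fov * h_mix)):
                recent_deaths.append((dday, rng.random(3) * dims))
    n_div = n_death = 0
    extinct = False

    for day in range(cfg.n_days - 1):
        n = len(alive)
        if n == 0:
            extinct = True
            break
        pos = np.array([t.positions[day] for t in alive])

        # --- division probabilities -------------------------------------
        if coupled:
            # base hazard plus death-triggered local-replacement intensity;
            # each death spends exactly an expected `trigger_budget`
            # divisions over the lag window (its kernel is normalized by
            # the realized kernel mass, so the budget holds at any local
            # density or boundary truncation)
            p_div = np.full(n, (1.0 - cfg.coupling_fraction) * cfg.division_hazard)
            for dday, dpos in recent_deaths:
                lag = day - dday
                if 1 <= lag <= cfg.coupling_lag:
                    d = np.linalg.norm(pos - dpos, axis=1)
                    kern = np.exp(-0.5 * (d / cfg.coupling_kernel_um) ** 2)
                    kern *= d <= cfg.coupling_radius
                    mass = kern.sum()
                    if mass > 0:
                        p_div += (
                            trigger_budget * decay_weights[lag - 1] * kern / mass
                        )
        else:
            p_div = np.full(n, cfg.division_hazard)
        if cfg.crowding_capacity is not None:
            ratio = n / max(cfg.initial_cells_per_fov, 1)
            cap = cfg.crowding_capacity
            if cap == 1.0:
                factor = 0.0
            else:
                factor = min(1.0, max(0.0, (cap - ratio) / (cap - 1.0)))
            p_div = p_div * factor
        # --- death probabilities ----------------------------------------
        if block_apoptosis:
            p_death = np.zeros(n)
        else:
            ages = np.array(
                [-1 if t.birth_day is None else day - t.birth_day for t in alive]
            )
            p_death = _death_hazards(cfg, ages)
        if cfg.division_hazard + p_death.max() > 1.0:
            raise ConfigurationError(
                "division and death hazards sum above 1 for at least one cell"
            )
        # trigger stacking can locally exceed the admissible range; cap it
        p_div = np.minimum(np.clip(p_div, 0.0, 0.95), 1.0 - p_death)

        # single uniform draw -> exact marginal event probabilities
        u = rng.random(n)
        divide = u < p_div
        die = ~divide & (u < p_div + p_death)

        survivors: list[CellTrack] = []
        for i, t in enumerate(alive):
            if divide[i]:
                t.divided_day = day
                n_div += 1
                offset = cfg.daughter_offset_um * _unit_vectors(rng, 1)[0]
                inherited = {LABEL_NEWBORN}
                if LABEL_BRDU in t.labels:
                    inherited.add(LABEL_BRDU)
                if LABEL_MONOCYTE in t.labels:
                    inherited.add(LABEL_MONOCYTE)
                for sign in (+1.0, -1.0):
                    daughter_pos = _reflect(t.positions[day] + sign * offset, dims)
                    survivors.append(
                        new_track(t.cell_id, day + 1, daughter_pos, inherited)
                    )
            elif die[i]:
                t.death_day = day
                n_death += 1
                recent_deaths.append((day, t.positions[day].copy()))
            else:
                survivors.append(t)

        # --- movement: newborn cells random-walk until they settle -------
        for t in survivors:
            if t.birth_day == day + 1:
                continue  # placed this step; first step happens next day
            p = t.positions[day]
            if (
                t.birth_day is not None
                and (day + 1 - t.birth_day) <= cfg.newborn_window
                and cfg.dispersion_step > 0
            ):
                step = cfg.dispersion_step * _unit_vectors(rng, 1)[0]
                p = _reflect(p + step, dims)
            t.positions[day + 1] = p.copy()

        recent_deaths = [
            (d, p) for d, p in recent_deaths if day + 1 - d <= cfg.coupling_lag
        ]
        alive = survivors

    ts = TrackSet(
        tracks=tracks,
        config=cfg,
        fov_id=fov_id,
        extinct=extinct,
        n_division_events=n_div,
        n_death_events=n_death,
    )
    logger.info(
        "fov %s: %d tracks, %d divisions, %d deaths%s",
        fov_id,
        len(tracks),
        n_div,
        n_death,
        " (EXTINCT)" if extinct else "",
    )
    return ts


def simulate(
    config: SimulationConfig,
    initial_labels: Iterable[str] = (),
    block_apoptosis: bool = False,
) -> list[TrackSet]:
    """Run the birth-death model, one :class:`TrackSet` per field of view.

    Reproducible for a fixed ``config.seed``: each field of view receives an
    independent child stream of the top-level seed.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_fov)
    calibration = None
    if config.coupling_mode == "local_replacement" and not block_apoptosis:
        calibration = _coupling_calibration(config)
    tracksets = []
    for k, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        tracksets.append(
            _simulate_fov(
                config,
                rng,
                fov_id=f"f{k}",
                initial_labels=initial_labels,
                block_apoptosis=block_apoptosis,
                calibration=calibration,
            )
        )
    return tracksets


def simulate_apoptosis_blocked(config: SimulationConfig) -> list[TrackSet]:
    """Apoptosis-deficient scenario: death hazards are zeroed and division is
    attenuated by crowding, so density rises and then plateaus below
    ``crowding_capacity`` times the baseline."""
    if config.crowding_capacity is None:
        raise ConfigurationError(
            "simulate_apoptosis_blocked requires crowding_capacity to be set"
        )
    return simulate(config, block_apoptosis=True)


# ---------------------------------------------------------------------------
# label pulse
# ---------------------------------------------------------------------------

def apply_label_pulse(
    tracks: TrackSet,
    pulse_day: int,
    s_fraction: float = 0.5,
    cycle_length_hr: float = 32.0,
    cycling_fraction_pct: float | None = None,
    seed: int | None = None,
) -> TrackSet:
    """Mark cells that are in S phase at ``pulse_day`` and propagate the
    label to their descendants.

    On the daily snapshot grid, cells in S phase at the pulse are the cells
    that divide on the transition out of ``pulse_day``; each is labeled with
    probability ``min(1, s_fraction * cycle_length_hr / 24)``, the fraction
    of the next snapshot interval covered by S phase.  If
    ``cycling_fraction_pct`` is given (an instantaneous percent of the
    population in cycle, not observable from daily divisions alone), every
    alive cell is instead labeled independently with probability
    ``cycling_fraction_pct/100 * s_fraction``, so the expected labeling
    index equals cycling fraction x S fraction.

    The input TrackSet is modified in place and returned.
    """
    if not 0 < s_fraction <= 1:
        raise ValueError(f"s_fraction must lie in (0, 1], got {s_fraction}")
    if not 0 <= pulse_day <= tracks.config.n_days - 1:
        raise ValueError(
            f"pulse_day {pulse_day} outside the simulated window "
            f"[0, {tracks.config.n_days - 1}]"
        )
    rng = np.random.default_rng(tracks.config.seed if seed is None else seed)
    alive = tracks.alive_on(pulse_day)

    newly_labeled: list[CellTrack] = []
    if cycling_fraction_pct is None:
        p_s = min(1.0, s_fraction * cycle_length_hr / 24.0)
        for t in alive:
            if t.divided_day == pulse_day and rng.random() < p_s:
                newly_labeled.append(t)
    else:
        if not 0 <= cycling_fraction_pct <= 100:
            raise ValueError("cycling_fraction_pct must lie in [0, 100]")
        p_label = cycling_fraction_pct / 100.0 * s_fraction
        draws = rng.random(len(alive))
        for t, u in zip(alive, draws):
            if u < p_label:
                newly_labeled.append(t)

    for t in newly_labeled:
        t.labels.add(LABEL_BRDU)

    # heritable: breadth-first propagation to descendants born after the pulse
    children: dict[str, list[CellTrack]] = {}
    for t in tracks.tracks:
        if t.parent_id is not None:
            children.setdefault(t.parent_id, []).append(t)
    frontier = list(newly_labeled)
    while frontier:
        t = frontier.pop()
        for child in children.get(t.cell_id, []):
            if child.birth_day is not None and child.birth_day > pulse_day:
                child.labels.add(LABEL_BRDU)
                frontier.append(child)

    logger.info(
        "label pulse day %d: %d cells labeled of %d alive",
        pulse_day,
        len(newly_labeled),
        len(alive),
    )
    return tracks


def labeled_fraction_curve(tracksets: "TrackSet | Sequence[TrackSet]", pulse_day: int):
    """Labeled-percent time course (hours post pulse) pooled over fields of
    view; returns a :class:`~microturn.pulse_chase_kinetics.PulseChaseCurve`."""
    from .pulse_chase_kinetics import PulseChaseCurve

    if isinstance(tracksets, TrackSet):
        tracksets = [tracksets]
    n_days = tracksets[0].config.n_days
    times, fractions = [], []
    for day in range(pulse_day, n_days):
        total = labeled = 0
        for ts in tracksets:
            for t in ts.alive_on(day):
                total += 1
                labeled += LABEL_BRDU in t.labels
        if total == 0:
            break
        times.append((day - pulse_day) * 24.0)
        fractions.append(100.0 * labeled / total)
    return PulseChaseCurve(
        times=np.array(times), labeled_fraction=np.array(fractions), region="synthetic"
    )


# ---------------------------------------------------------------------------
# snapshot tables
# ---------------------------------------------------------------------------

def render_snapshots(tracks: TrackSet) -> pd.DataFrame:
    """Long-format daily snapshot table, lossless with respect to events.

    One row per cell per observed day.  The ``event`` column tags the last
    row of a dying cell ``died``, the last row of a dividing mother
    ``divided`` and the first row of a daughter ``appeared`` (terminal
    events take precedence if they coincide; lineage stays recoverable from
    ``parent_id``).
    """
    rows = []
    for t in tracks.tracks:
        for day in sorted(t.positions):
            if day == t.death_day:
                event = EVENT_DIED
            elif day == t.divided_day:
                event = EVENT_DIVIDED
            elif t.birth_day is not None and day == t.birth_day:
                event = EVENT_APPEARED
            else:
                event = EVENT_NONE
            p = t.positions[day]
            rows.append(
                (
                    day,
                    t.cell_id,
                    t.parent_id if t.parent_id is not None else "",
                    float(p[0]),
                    float(p[1]),
                    float(p[2]),
                    event,
                    ";".join(sorted(t.labels)),
                )
            )
    df = pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)
    df = df.sort_values(["day", "cell_id"], kind="stable").reset_index(drop=True)
    return df


def render_all(tracksets: Sequence[TrackSet]) -> pd.DataFrame:
    """Concatenate per-FOV snapshot tables, adding a leading ``fov`` column."""
    frames = []
    for ts in tracksets:
        df = render_snapshots(ts)
        df.insert(0, "fov", ts.fov_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_snapshots(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_snapshots(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    df["day"] = df["day"].astype(int)
    for c in ("x_um", "y_um", "z_um"):
        df[c] = df[c].astype(float)
    for c in ("cell_id", "parent_id", "event", "labels"):
        df[c] = df[c].astype(str)
    if "fov" in df.columns:
        df["fov"] = df["fov"].astype(str)
    return df
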