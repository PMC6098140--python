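"""Synthetic flock simulator.

Generates per-hen 1 Hz zone-registration logs with the statistical
structure real aviary tracking data shows: hen-specific zone preferences
and transition rates, diurnal activity modulation, quasi-daily nestbox
visits (24.0 h or 25.5 h oviposition cycles), wintergarden access gated by
a pophole schedule, zone avoidance, and day-to-day variability.

The generative model is an inhomogeneous semi-Markov process: while the
lights are on the hen occupies one zone at a time, dwell times are drawn
from a per-zone log-normal whose median depends on hour of day, and the
next zone is drawn from a per-hen categorical destination matrix.
Deterministic scheduled events (a nestbox visit per oviposition cycle, an
optional end-of-day wintergarden bout) are overlaid on the stochastic
trajectory.  Outside the lit period the hen is stationary on her roost
zone.  Optional i.i.d. per-sample misreads emulate receiver zone-assignment
error.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .core import (
    N_ZONES,
    SECONDS_PER_DAY,
    ZONES,
    RegistrationLog,
    seconds_of_day,
)

__all__ = [
    "ScheduleConfig",
    "HenProfile",
    "ARCHETYPES",
    "DEFAULT_FLOCK",
    "make_profile",
    "default_profiles",
    "simulate_day",
    "simulate_flock",
    "henday_rng",
    "write_log",
    "load_flock_config",
    "default_flock_config",
]


# --------------------------------------------------------------------------
# schedule


@dataclass(frozen=True)
class ScheduleConfig:
    """Barn light and pophole schedule, in seconds-of-day.

    Defaults: artificial light 02:00:00-17:00:00; pophole (wintergarden
    access) open 10:00:00-16:45:00, within the lit period.
    """

    lights_on_s: int = seconds_of_day(2)
    lights_off_s: int = seconds_of_day(17)
    pophole_open_s: int = seconds_of_day(10)
    pophole_close_s: int = seconds_of_day(16, 45)
    sample_hz: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.lights_on_s < self.lights_off_s <= SECONDS_PER_DAY):
            raise ValueError("lights_on must precede lights_off within the day")
        if not (
            self.lights_on_s <= self.pophole_open_s
            < self.pophole_close_s
            <= self.lights_off_s
        ):
            raise ValueError("pophole interval must lie within the lit interval")
        if self.sample_hz != 1:
            raise ValueError("only 1 Hz sampling is supported")


DEFAULT_SCHEDULE = ScheduleConfig()


# --------------------------------------------------------------------------
# hen profiles


@dataclass
class HenProfile:
    """Behavioural parameters of one simulated hen.

    dwell_params has shape (5 zones, 24 hours, 2): log-median dwell (log
    seconds) and log-normal sigma, per zone and hour of day.  dest_matrix
    rows are categorical next-zone distributions with zero diagonal and
    zero mass on forbidden zones.  day_noise scales day-to-day jitter of
    dwell medians, destination weights and the nest-visit anchor;
    misread_rate injects i.i.d. wrong-zone registrations.
    """

    hen_id: str
    dwell_params: np.ndarray
    dest_matrix: np.ndarray
    roost_zone: int = 5
    start_zone: int | None = None  # zone at lights-on; default roost
    nest_cycle_h: float | None = None
    nest_visit_duration_s: int = 1800
    nest_anchor_s: int = seconds_of_day(6)
    wintergarden_evening_s: int = 0  # end-of-day wintergarden bout length
    forbidden_zones: frozenset[int] = frozenset()
    day_noise: float = 0.25
    misread_rate: float = 0.0
    dwell_dist: str = "lognormal"  # or "exponential" (constant hazard)
    archetype: str = ""

    def __post_init__(self) -> None:
        self.dwell_params = np.asarray(self.dwell_params, dtype=float)
        if self.dwell_params.shape != (N_ZONES, 24, 2):
            raise ValueError("dwell_params must have shape (5, 24, 2)")
        if np.any(self.dwell_params[:, :, 1] < 0):
            raise ValueError("dwell sigma must be non-negative")
        self.dest_matrix = np.asarray(self.dest_matrix, dtype=float)
        if self.dest_matrix.shape != (N_ZONES, N_ZONES):
            raise ValueError("dest_matrix must be 5x5")
        if np.any(self.dest_matrix < 0):
            raise ValueError("dest_matrix entries must be non-negative")
        if np.any(np.abs(np.diag(self.dest_matrix)) > 1e-12):
            raise ValueError("dest_matrix diagonal must be zero")
        self.forbidden_zones = frozenset(int(z) for z in self.forbidden_zones)
        for z in self.forbidden_zones:
            if z not in ZONES:
                raise ValueError(f"forbidden zone {z} outside 1..5")
            if np.any(self.dest_matrix[:, z - 1] > 1e-12):
                raise ValueError(f"dest_matrix has mass on forbidden zone {z}")
        rows = self.dest_matrix.sum(axis=1)
        live = [z for z in ZONES if z not in self.forbidden_zones]
        for z in live:
            if not math.isclose(rows[z - 1], 1.0, abs_tol=1e-9):
                raise ValueError(f"dest_matrix row for zone {z} must sum to 1")
        if self.roost_zone in self.forbidden_zones or self.roost_zone not in ZONES:
            raise ValueError("invalid roost zone")
        if not (0.0 <= self.misread_rate < 1.0):
            raise ValueError("misread_rate must be in [0, 1)")
        if self.day_noise < 0:
            raise ValueError("day_noise must be non-negative")
        if self.dwell_dist not in ("lognormal", "exponential"):
            raise ValueError("dwell_dist must be 'lognormal' or 'exponential'")


# Archetype parameter ranges.  total: expected transitions/day; zone_mult:
# multiplicative tilt on the flock-level zone attractiveness; the contrasts
# mirror the extremes real flocks show (very active hens, near-sedentary
# hens, upper-tier avoiders, strongly rhythmic nest visitors).
ARCHETYPES: dict[str, dict] = {
    "high-transitioner": dict(
        total=(110.0, 150.0),
        zone_mult={5: (0.4, 2.5), 1: (1.0, 2.0)},
        nest=("maybe", 24.0),
    ),
    "low-transitioner": dict(
        total=(18.0, 32.0),
        zone_mult={},
        nest=("maybe", 24.0),
    ),
    "zone5-avoider": dict(
        total=(35.0, 55.0),
        zone_mult={2: (1.3, 2.2)},
        forbidden=(5,),
        wintergarden_evening=(1800, 3600),
        nest=("always", 24.0),
    ),
    "nest-cycler": dict(
        total=(55.0, 90.0),
        zone_mult={4: (1.1, 1.8)},
        nest=("always", None),  # cycle drawn: 24.0 or 25.5 h
    ),
    "uniform": dict(
        total=(60.0, 95.0),
        zone_mult={},
        nest=("maybe", 24.0),
    ),
}

# Flock-level zone attractiveness, tuned so that flock-mean visit shares
# resemble a commercial aviary (litter and lower tier dominate, upper tier
# and wintergarden rare); zones are ordered along the house's physical
# axis, so destination choice decays with zone distance.
_BASE_ZONE_WEIGHT = np.array([2.4, 2.8, 2.4, 0.9, 0.5])
_ZONE_DISTANCE_SCALE = 1.3
# Relative dwell medians per zone (dimensionless; rescaled per hen so the
# expected transition total matches the archetype draw).
_REL_DWELL = np.array([1.0, 1.3, 1.0, 0.9, 0.7])
_DWELL_SIGMA = 0.45

# 13-hen default flock; ids follow the focal hens of an 11-day commercial
# observation (1 and 37 highly active, 9 an upper-tier avoider, 7 and 39 on
# a 25.5 h oviposition cycle, 2/18/35/36 on 24.0 h cycles).
DEFAULT_FLOCK: tuple[tuple[str, str], ...] = (
    ("1", "high-transitioner"),
    ("2", "nest-cycler"),
    ("3", "uniform"),
    ("7", "nest-cycler"),
    ("9", "zone5-avoider"),
    ("17", "uniform"),
    ("18", "nest-cycler"),
    ("35", "nest-cycler"),
    ("36", "nest-cycler"),
    ("37", "high-transitioner"),
    ("38", "low-transitioner"),
    ("39", "nest-cycler"),
    ("58", "uniform"),
)


def _stable_hash(hen_id: str) -> int:
    return zlib.crc32(str(hen_id).encode("utf-8"))


def _dest_matrix(weights: np.ndarray, forbidden: frozenset[int]) -> np.ndarray:
    """Destination matrix: next-zone mass ~ attractiveness x proximity."""
    P = np.zeros((N_ZONES, N_ZONES))
    for i in range(N_ZONES):
        if (i + 1) in forbidden:
            continue
        for j in range(N_ZONES):
            if j == i or (j + 1) in forbidden:
                continue
            P[i, j] = weights[j] * math.exp(-abs(i - j) / _ZONE_DISTANCE_SCALE)
        P[i] /= P[i].sum()
    return P


def _visit_shares(P: np.ndarray, forbidden: frozenset[int]) -> np.ndarray:
    """Stationary visit shares of the destination chain (power iteration)."""
    live = np.array([z - 1 for z in ZONES if z not in forbidden])
    pi = np.zeros(N_ZONES)
    pi[live] = 1.0 / live.size
    for _ in range(300):
        pi = pi @ P
        pi /= pi.sum()
    return pi


def make_profile(hen_id: str, archetype: str, rng_seed: int) -> HenProfile:
    """Draw a hen profile from the named archetype's parameter ranges.

    Deterministic for a fixed (hen_id, archetype, rng_seed).
    """
    if archetype not in ARCHETYPES:
        raise ValueError(
            f"unknown archetype {archetype!r}; expected one of {sorted(ARCHETYPES)}"
        )
    spec = ARCHETYPES[archetype]
    rng = np.random.default_rng(
        np.random.SeedSequence([int(rng_seed), _stable_hash(hen_id)])
    )

    forbidden = frozenset(spec.get("forbidden", ()))
    total_rate = rng.uniform(*spec["total"])

    # per-hen zone attractiveness: flock baseline x lognormal jitter x
    # archetype tilts x one extra "home zone" bias.
    weights = _BASE_ZONE_WEIGHT * np.exp(rng.normal(0.0, 0.85, N_ZONES))
    for z, (lo, hi) in spec.get("zone_mult", {}).items():
        weights[z - 1] *= rng.uniform(lo, hi)
    live = [z for z in ZONES if z not in forbidden]
    home = int(rng.choice(live))
    weights[home - 1] *= rng.uniform(2.5, 5.0)
    weights[[z - 1 for z in forbidden]] = 0.0

    P = _dest_matrix(weights, forbidden)
    shares = _visit_shares(P, forbidden)

    # hour-of-day activity: smooth per-hen curve; dwell medians scale with
    # its inverse so active hours mean shorter stays.
    hours = np.arange(24)
    a, b = rng.normal(0.0, 0.35, 2)
    phase = rng.uniform(0, 2 * math.pi)
    act = np.exp(a * np.sin(2 * math.pi * hours / 24 + phase)
                 + b * np.cos(2 * math.pi * hours / 24 + phase))
    inv_act = 1.0 / act
    inv_act /= inv_act.mean()

    # scale dwell medians so expected visits over the 15 h lit window match
    # the archetype's transition total: mean dwell = lit_seconds / total.
    lit = DEFAULT_SCHEDULE.lights_off_s - DEFAULT_SCHEDULE.lights_on_s
    lognorm_mean_factor = math.exp(_DWELL_SIGMA**2 / 2)
    mean_rel = float(np.dot(shares, _REL_DWELL))
    scale = (lit / total_rate) / (mean_rel * lognorm_mean_factor)

    dwell = np.zeros((N_ZONES, 24, 2))
    for z in range(N_ZONES):
        dwell[z, :, 0] = np.log(scale * _REL_DWELL[z] * inv_act)
        dwell[z, :, 1] = _DWELL_SIGMA

    # nest rhythm
    nest_mode, fixed_cycle = spec["nest"]
    nest_cycle = None
    if nest_mode == "always" or (nest_mode == "maybe" and rng.random() < 0.5):
        if fixed_cycle is None:
            nest_cycle = float(rng.choice([24.0, 25.5]))
        else:
            nest_cycle = float(fixed_cycle)
    nest_anchor = int(rng.uniform(seconds_of_day(4), seconds_of_day(9)))
    nest_dur = int(rng.uniform(1500, 2700))

    wg_lo, wg_hi = spec.get("wintergarden_evening", (0, 0))
    wg = int(rng.uniform(wg_lo, wg_hi)) if wg_hi else 0

    roost_choices = [z for z in (5, 4, 3) if z not in forbidden]
    roost = int(rng.choice(roost_choices[:2] if len(roost_choices) > 1 else roost_choices))

    return HenProfile(
        hen_id=str(hen_id),
        dwell_params=dwell,
        dest_matrix=P,
        roost_zone=roost,
        nest_cycle_h=nest_cycle,
        nest_visit_duration_s=nest_dur,
        nest_anchor_s=nest_anchor,
        wintergarden_evening_s=wg,
        forbidden_zones=forbidden,
        archetype=archetype,
    )


def default_profiles(
    rng_seed: int,
    flock: tuple[tuple[str, str], ...] = DEFAULT_FLOCK,
    day_noise: float | None = None,
    misread_rate: float | None = None,
) -> list[HenProfile]:
    """Profiles for the default 13-hen archetype-assigned flock."""
    profiles = []
    for hen_id, archetype in flock:
        p = make_profile(hen_id, archetype, rng_seed)
        if day_noise is not None:
            p = replace(p, day_noise=day_noise)
        if misread_rate is not None:
            p = replace(p, misread_rate=misread_rate)
        profiles.append(p)
    return profiles


# --------------------------------------------------------------------------
# one-day simulation


def nest_anchor_for_day(
    profile: HenProfile, schedule: ScheduleConfig, day_index: int
) -> int | None:
    """Scheduled nest-visit start for a day, following the cycle's drift.

    The phase advances by (cycle - 24 h) per day; when it would leave the
    lit window the visit is skipped and the phase resets to the base
    anchor (the pause lets the hen reset her laying rhythm).  Returns None
    when no visit is scheduled that day.
    """
    if profile.nest_cycle_h is None:
        return None
    drift = (profile.nest_cycle_h - 24.0) * 3600.0
    phase = float(profile.nest_anchor_s)
    for d in range(1, day_index + 1):
        ok = (
            schedule.lights_on_s <= phase
            and phase + profile.nest_visit_duration_s <= schedule.lights_off_s
        )
        if d == day_index:
            return int(phase) if ok else None
        phase = phase + drift if ok else float(profile.nest_anchor_s)
    raise AssertionError("unreachable")


def _draw_dwell(rng, profile: HenProfile, zone: int, hour: int, jitter: float) -> int:
    logm, sigma = profile.dwell_params[zone - 1, hour]
    if profile.dwell_dist == "exponential":
        d = rng.exponential(math.exp(logm + jitter))
    else:
        d = rng.lognormal(logm + jitter, sigma)
    return max(1, int(round(d)))


def simulate_day(
    profile: HenProfile,
    schedule: ScheduleConfig,
    day_index: int,
    rng: np.random.Generator,
) -> RegistrationLog:
    """Simulate one full day (00:00-24:00) of 1 Hz registrations.

    Dark-period samples are emitted with the hen stationary on her roost
    zone.  Zone 1 (wintergarden) is only enterable inside the pophole
    window and is vacated when the pophole closes.  Scheduled overlays
    (nest visit, evening wintergarden bout) are applied before misread
    noise.
    """
    nu = profile.day_noise
    dwell_jitter = float(rng.normal(0.0, 0.20 * nu)) if nu > 0 else 0.0
    if nu > 0:
        wj = np.exp(rng.normal(0.0, 0.25 * nu, N_ZONES))
    else:
        wj = np.ones(N_ZONES)
    anchor_jitter = int(round(rng.normal(0.0, 900.0 * nu))) if nu > 0 else 0

    on, off = schedule.lights_on_s, schedule.lights_off_s
    p_open, p_close = schedule.pophole_open_s, schedule.pophole_close_s
    forbidden_idx = [z - 1 for z in profile.forbidden_zones]

    zones = np.empty(SECONDS_PER_DAY, dtype=np.int8)
    zones[:on] = profile.roost_zone
    zones[off:] = profile.roost_zone

    cur = profile.start_zone or profile.roost_zone
    t = on
    while t < off:
        d = _draw_dwell(rng, profile, cur, t // 3600, dwell_jitter)
        end = min(t + d, off)
        if cur == 1:
            end = min(end, p_close)  # pophole closes: wintergarden vacated
            end = max(end, t + 1)
        zones[t:end] = cur
        t = end
        if t >= off:
            break
        w = profile.dest_matrix[cur - 1] * wj
        w[cur - 1] = 0.0
        if forbidden_idx:
            w[forbidden_idx] = 0.0
        if not (p_open <= t < p_close):
            w[0] = 0.0
        s = w.sum()
        if s <= 0:  # gated into a corner: any allowed zone but the current
            w = np.ones(N_ZONES)
            w[cur - 1] = 0.0
            if forbidden_idx:
                w[forbidden_idx] = 0.0
            if not (p_open <= t < p_close):
                w[0] = 0.0
            s = w.sum()
        cur = int(rng.choice(N_ZONES, p=w / s)) + 1

    # scheduled nest visit
    anchor = nest_anchor_for_day(profile, schedule, day_index)
    if anchor is not None and 4 not in profile.forbidden_zones:
        a = anchor + anchor_jitter
        a = max(on, min(a, off - profile.nest_visit_duration_s))
        zones[a : a + profile.nest_visit_duration_s] = 4

    # end-of-day wintergarden bout, ending at pophole close
    if profile.wintergarden_evening_s > 0 and 1 not in profile.forbidden_zones:
        start = max(p_open, p_close - profile.wintergarden_evening_s)
        zones[start:p_close] = 1

    # receiver misreads: i.i.d. wrong-zone substitutions
    if profile.misread_rate > 0:
        mask = rng.random(SECONDS_PER_DAY) < profile.misread_rate
        n_bad = int(mask.sum())
        if n_bad:
            offsets = rng.integers(1, N_ZONES, size=n_bad)
            zones[mask] = ((zones[mask] - 1 + offsets) % N_ZONES + 1).astype(np.int8)

    log = RegistrationLog(hen_id=profile.hen_id)
    log.add_day(day_index, np.arange(SECONDS_PER_DAY, dtype=np.int32), zones)
    return log


# --------------------------------------------------------------------------
# flock simulation


def henday_rng(master_seed: int, hen_id: str, day_index: int) -> np.random.Generator:
    """Independent substream for one hen-day, reproducible in isolation."""
    ss = np.random.SeedSequence(
        [int(master_seed), _stable_hash(hen_id), int(day_index)]
    )
    return np.random.default_rng(ss)


def simulate_flock(
    profiles: list[HenProfile],
    schedule: ScheduleConfig = DEFAULT_SCHEDULE,
    n_days: int = 7,
    master_seed: int = 0,
) -> list[RegistrationLog]:
    """Simulate ``n_days`` for every profile; one multi-day log per hen."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    ids = [p.hen_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate hen_ids in flock")
    logs = []
    for profile in profiles:
        log = RegistrationLog(hen_id=profile.hen_id)
        for day in range(1, n_days + 1):
            rng = henday_rng(master_seed, profile.hen_id, day)
            day_log = simulate_day(profile, schedule, day, rng)
            sec, zon = day_log.days[day]
            log.add_day(day, sec, zon)
        logs.append(log)
    return logs


# --------------------------------------------------------------------------
# log writer and flock config files

BASE_DATE = np.datetime64("2017-08-23")  # date mapped to day_index 1


def write_log(log: RegistrationLog, path) -> None:
    """Write one hen's registrations as the receiver's CSV dialect.

    Columns: date (ISO 8601), time (HH:MM:SS), zone (1-5).
    """
    import pandas as pd

    frames = []
    for day in log.day_indices:
        sec, zon = log.days[day]
        ts = pd.to_datetime(BASE_DATE + np.timedelta64(day - 1, "D")) + pd.to_timedelta(
            sec, unit="s"
        )
        frames.append(
            pd.DataFrame(
                {
                    "date": ts.strftime("%Y-%m-%d"),
                    "time": ts.strftime("%H:%M:%S"),
                    "zone": zon,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def default_flock_config() -> dict:
    """Config dict reproducing the default 13-hen archetype flock."""
    return {
        "seed": 0,
        "n_days": 7,
        "schedule": {
            "lights_on": "02:00:00",
            "lights_off": "17:00:00",
            "pophole_open": "10:00:00",
            "pophole_close": "16:45:00",
        },
        "day_noise": None,  # per-archetype default when null
        "misread_rate": None,
        "hens": [
            {"hen_id": hen_id, "archetype": archetype}
            for hen_id, archetype in DEFAULT_FLOCK
        ],
    }


def _parse_clock(text: str) -> int:
    h, m, s = (int(x) for x in str(text).split(":"))
    return seconds_of_day(h, m, s)


def load_flock_config(path) -> tuple[list[HenProfile], ScheduleConfig, int, int]:
    """Load (profiles, schedule, n_days, seed) from a YAML flock config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    known = {"seed", "n_days", "schedule", "day_noise", "misread_rate", "hens"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown flock config keys: {sorted(unknown)}")
    sched_cfg = cfg.get("schedule", {})
    schedule = ScheduleConfig(
        lights_on_s=_parse_clock(sched_cfg.get("lights_on", "02:00:00")),
        lights_off_s=_parse_clock(sched_cfg.get("lights_off", "17:00:00")),
        pophole_open_s=_parse_clock(sched_cfg.get("pophole_open", "10:00:00")),
        pophole_close_s=_parse_clock(sched_cfg.get("pophole_close", "16:45:00")),
    )
    seed = int(cfg.get("seed", 0))
    flock = tuple((str(h["hen_id"]), h["archetype"]) for h in cfg["hens"])
    profiles = default_profiles(
        seed,
        flock=flock,
        day_noise=cfg.get("day_noise"),
        misread_rate=cfg.get("misread_rate"),
    )
    return profiles, schedule, int(cfg.get("n_days", 7)), seed
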