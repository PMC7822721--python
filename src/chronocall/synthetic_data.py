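"""Synthetic call-detail-record cohorts with known circadian ground truth.

Real CDR datasets of this kind are private, so every downstream stage is
exercised on simulated cohorts whose true structure is known.  Each
person's time-of-day call distribution is a two-component wrapped
Gaussian mixture on the 24-hour circle (one morning and one evening
activity period, with a configurable dominant component), and daily
outgoing-call counts are Poisson.  "Partial" persons enroll one or more
months late, guaranteeing at least one fully silent calendar month
inside the observation window so that the full-period activity filter
must drop them.

Default cohort: 11 morning-dominant + 10 evening-dominant always-active
persons and 5 partial persons over 12 months — 26 before preprocessing,
21 after.  Default mixture peaks sit at 10:00 and 18:00 (the midmorning
/ early-evening bimodality typical of older adults' call activity), with
the dominant component holding 70% of the mass, and about two outgoing
calls per day (~730/year, near the reported per-person median).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cdr_io import COLUMNS, CallRecordSet

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class ChronotypeProfile:
    """Ground-truth circadian parameters of one simulated person.

    ``peaks`` are the two component means in hours-of-day, ``spreads``
    the component standard deviations in hours, ``weight`` the mixing
    proportion of the first component, ``daily_rate`` the Poisson mean
    of outgoing calls per day.
    """

    peaks: tuple[float, float]
    spreads: tuple[float, float]
    weight: float
    daily_rate: float

    def __post_init__(self) -> None:
        if not all(0.0 <= m < HOURS_PER_DAY for m in self.peaks):
            raise ValueError(f"peaks must lie in [0, 24), got {self.peaks}")
        if not all(s > 0 for s in self.spreads):
            raise ValueError("spreads must be positive")
        if not 0.0 < self.weight < 1.0:
            raise ValueError("weight must lie strictly in (0, 1)")
        if self.daily_rate <= 0:
            raise ValueError("daily_rate must be positive")


MORNING_PROFILE = ChronotypeProfile(peaks=(10.0, 18.0), spreads=(1.5, 1.5), weight=0.7, daily_rate=2.0)
EVENING_PROFILE = ChronotypeProfile(peaks=(10.0, 18.0), spreads=(1.5, 1.5), weight=0.3, daily_rate=2.0)


@dataclass
class PopulationConfig:
    """Scenario definition for one simulated cohort."""

    n_morning: int = 11
    n_evening: int = 10
    n_partial: int = 5
    months: int = 12
    start_date: str = "2015-01-01"
    seed: int | None = None
    morning_profile: ChronotypeProfile = MORNING_PROFILE
    evening_profile: ChronotypeProfile = EVENING_PROFILE
    #: partial persons enroll 1..enrollment_jitter months late
    enrollment_jitter: int = 3
    #: expected incoming calls per outgoing call (token traffic so that
    #: the outgoing-only filter has something to remove)
    incoming_ratio: float = 0.1
    #: log-normal sigma of per-person multiplicative jitter on
    #: daily_rate; real cohorts show a wide spread of calls per person
    rate_dispersion: float = 0.4

    def __post_init__(self) -> None:
        if min(self.n_morning, self.n_evening, self.n_partial) < 0:
            raise ValueError("person counts must be >= 0")
        if self.months < 1:
            raise ValueError("months must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory (determinism is enforced)")
        if self.n_partial > 0 and not 1 <= self.enrollment_jitter < self.months:
            raise ValueError("enrollment_jitter must be in [1, months) when partials exist")


@dataclass
class GroundTruth:
    """Per-person truth: profile, archetype label, enrollment interval."""

    profiles: dict[str, ChronotypeProfile] = field(default_factory=dict)
    archetypes: dict[str, str] = field(default_factory=dict)  # morningness/eveningness
    partial: dict[str, bool] = field(default_factory=dict)
    enrollment: dict[str, tuple[pd.Period, pd.Period]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, prof in self.profiles.items():
            lo, hi = self.enrollment[pid]
            rows.append(
                {
                    "person_id": pid,
                    "archetype": self.archetypes[pid],
                    "partial": self.partial[pid],
                    "mu1": prof.peaks[0],
                    "sigma1": prof.spreads[0],
                    "mu2": prof.peaks[1],
                    "sigma2": prof.spreads[1],
                    "pi1": prof.weight,
                    "daily_rate": prof.daily_rate,
                    "enroll_start": str(lo),
                    "enroll_end": str(hi),
                }
            )
        return pd.DataFrame(rows)


def sample_call_times(
    profile: ChronotypeProfile, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` hour-of-day values from the wrapped Gaussian mixture.

    Component 1 is chosen with probability ``profile.weight``; the
    Gaussian draw is reduced modulo 24, so mass near midnight wraps
    around the day boundary (a 2 AM peak is representable).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    comp = rng.random(n) >= profile.weight  # False -> component 1
    mu = np.where(comp, profile.peaks[1], profile.peaks[0])
    sigma = np.where(comp, profile.spreads[1], profile.spreads[0])
    return np.mod(rng.normal(mu, sigma), HOURS_PER_DAY)


def _hours_to_timedelta(hours: np.ndarray) -> pd.TimedeltaIndex:
    # floor to whole seconds so written timestamps round-trip exactly
    return pd.to_timedelta(np.floor(hours * 3600.0).astype(np.int64), unit="s")


def generate_population(config: PopulationConfig) -> tuple[CallRecordSet, GroundTruth]:
    """Simulate a cohort of CDRs plus its ground truth.

    Per person and per enrolled day the outgoing-call count is
    Poisson(``daily_rate``) and each call time comes from
    :func:`sample_call_times`.  Always-active persons are guaranteed at
    least one outgoing call in every month of the window (a silent
    month is back-filled with a single call) so that the activity
    filter retains exactly the non-partial persons by construction.
    Output is deterministic given the config and its seed.
    """
    root = np.random.SeedSequence(config.seed)
    months = pd.period_range(config.start_date, periods=config.months, freq="M")

    roster: list[tuple[str, ChronotypeProfile, str, bool]] = []
    for i in range(config.n_morning):
        roster.append((f"m{i + 1:02d}", config.morning_profile, "morningness", None))
    for i in range(config.n_evening):
        roster.append((f"e{i + 1:02d}", config.evening_profile, "eveningness", None))
    for i in range(config.n_partial):
        prof = config.morning_profile if i % 2 == 0 else config.evening_profile
        arch = "morningness" if i % 2 == 0 else "eveningness"
        # alternate dropout mechanisms: an interior silent month ("gap")
        # vs staggered late enrollment ("late")
        mode = "gap" if (i % 2 == 0 and config.months >= 3) else "late"
        roster.append((f"x{i + 1:02d}", prof, arch, mode))

    truth = GroundTruth()
    frames: list[pd.DataFrame] = []
    child_seeds = root.spawn(len(roster))
    for (pid, prof, arch, mode), seq in zip(roster, child_seeds):
        rng = np.random.default_rng(seq)
        is_partial = mode is not None
        if config.rate_dispersion > 0:
            rate = prof.daily_rate * float(rng.lognormal(0.0, config.rate_dispersion))
            prof = replace(prof, daily_rate=rate)
        silent: set[pd.Period] = set()
        if mode == "late":
            offset = int(rng.integers(1, config.enrollment_jitter + 1))
            enrolled = months[offset:]
        elif mode == "gap":
            enrolled = months
            silent = {months[int(rng.integers(1, config.months - 1))]}
        else:
            enrolled = months
        truth.profiles[pid] = prof
        truth.archetypes[pid] = arch
        truth.partial[pid] = is_partial
        truth.enrollment[pid] = (enrolled[0], enrolled[-1])

        stamps: list[pd.Timestamp] = []
        for month in enrolled:
            if month in silent:
                continue
            days = pd.date_range(month.start_time, month.end_time.normalize(), freq="D")
            counts = rng.poisson(prof.daily_rate, size=len(days))
            if not is_partial and counts.sum() == 0:
                counts[rng.integers(len(days))] = 1  # keep the person active
            n_calls = int(counts.sum())
            hours = sample_call_times(prof, n_calls, rng)
            day_of_call = np.repeat(days, counts)
            stamps.extend(day_of_call + _hours_to_timedelta(hours))
        n_out = len(stamps)
        n_in = rng.poisson(config.incoming_ratio * n_out) if n_out else 0
        if n_in:
            # silent months stay fully silent (no incoming either)
            active = pd.PeriodIndex([m for m in enrolled if m not in silent])
            in_days = active.to_timestamp()[rng.integers(0, len(active), n_in)]
            in_offsets = rng.integers(0, 28, n_in)  # uniform day within month
            in_hours = rng.uniform(0, HOURS_PER_DAY, n_in)
            stamps_in = in_days + pd.to_timedelta(in_offsets, unit="D") + _hours_to_timedelta(in_hours)
        else:
            stamps_in = pd.DatetimeIndex([])

        directions = ["out"] * n_out + ["in"] * n_in
        all_stamps = pd.DatetimeIndex(stamps).append(pd.DatetimeIndex(stamps_in))
        n_total = len(all_stamps)
        frames.append(
            pd.DataFrame(
                {
                    "person_id": pid,
                    "timestamp": all_stamps,
                    "recipient_id": [f"c{j}" for j in rng.integers(1, 16, n_total)],
                    "direction": directions,
                    "duration_s": np.round(rng.lognormal(4.0, 1.0, n_total), 1),
                    "device_id": np.where(rng.random(n_total) < 0.2, "d2", "d1"),
                }
            ).sort_values("timestamp", kind="stable")
        )

    if frames:
        frame = pd.concat(frames, ignore_index=True)
    else:
        frame = pd.DataFrame(
            {
                "person_id": pd.Series(dtype=str),
                "timestamp": pd.Series(dtype="datetime64[ns]"),
                "recipient_id": pd.Series(dtype=str),
                "direction": pd.Series(dtype=str),
                "duration_s": pd.Series(dtype=float),
                "device_id": pd.Series(dtype=str),
            }
        )
    return CallRecordSet(frame[COLUMNS]), truth


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------

_PROFILE_KEYS = ("mu1", "mu2", "sigma1", "sigma2", "weight", "daily_rate")


def _profile_from_flat(d: dict, prefix: str, default: ChronotypeProfile) -> ChronotypeProfile:
    vals = {k: d.get(f"{prefix}_{k}") for k in _PROFILE_KEYS}
    if all(v is None for v in vals.values()):
        return default
    return ChronotypeProfile(
        peaks=(
            float(vals["mu1"] if vals["mu1"] is not None else default.peaks[0]),
            float(vals["mu2"] if vals["mu2"] is not None else default.peaks[1]),
        ),
        spreads=(
            float(vals["sigma1"] if vals["sigma1"] is not None else default.spreads[0]),
            float(vals["sigma2"] if vals["sigma2"] is not None else default.spreads[1]),
        ),
        weight=float(vals["weight"] if vals["weight"] is not None else default.weight),
        daily_rate=float(vals["daily_rate"] if vals["daily_rate"] is not None else default.daily_rate),
    )


def load_scenario(path: str | Path, seed: int | None = None) -> PopulationConfig:
    """Load a flat key:value scenario file (YAML).

    Recognized keys mirror :class:`PopulationConfig`; archetype
    parameters are flattened as ``morning_mu1``, ``evening_weight``,
    etc.  A seed must be present in the file or passed explicitly.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("scenario file must be a flat mapping")
    known = {"n_morning", "n_evening", "n_partial", "months", "start_date",
             "seed", "enrollment_jitter", "incoming_ratio", "rate_dispersion"}
    prefixed = {f"{p}_{k}" for p in ("morning", "evening") for k in _PROFILE_KEYS}
    unknown = set(data) - known - prefixed
    if unknown:
        raise ValueError(f"unknown scenario key(s): {sorted(unknown)}")
    kwargs = {k: data[k] for k in known if k in data}
    if seed is not None:
        kwargs["seed"] = seed
    return PopulationConfig(
        **kwargs,
        morning_profile=_profile_from_flat(data, "morning", MORNING_PROFILE),
        evening_profile=_profile_from_flat(data, "evening", EVENING_PROFILE),
    )
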