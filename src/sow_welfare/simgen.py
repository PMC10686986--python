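"""Synthetic generator for group-housed gestating-sow behavior data.

Each sow-period carries one of three latent behavioral states —
``gentle``, ``aggressive`` or ``scapegoat`` — drawn from week-type
dependent probabilities (event weeks shift sows away from ``gentle``
toward ``aggressive``). Conditional on the state, the generator emits
the four observable streams a precision-livestock setup records:

* per-visit electronic-feeder logs (nutritive / non-nutritive visits),
* per-sow-period ethogram tallies (active/passive minutes, four
  interaction counts) from which the behavior indices derive,
* per-group-period posture summaries (six posture percentages),
* a sow registry and a control/event period schedule.

Interaction counts are Poisson with rate ratios chosen so each derived
index ``(pos − neg)/(pos + neg)`` matches the state's configured center
in expectation; feeder counts are Poisson at the state's per-period
mean and visit durations are Gamma so that total visit time also hits
its per-state mean. A single ``dispersion_scale`` multiplies every
continuous dispersion, controlling how separable the states are in the
automatically recorded features.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STATES = ("gentle", "aggressive", "scapegoat")
WEEK_TYPES = ("control", "event")
EVENT_TYPES = (
    "feed_competition",
    "sound",
    "cold",
    "hot",
    "enrichment",
    "impoverishment",
)
POSTURES = ("side_lying", "ventral_lying", "standing", "sitting", "eating", "drinking")

# (index_activity, index_giving, index_receiving) targets per latent state.
DEFAULT_INDEX_CENTERS: dict[str, tuple[float, float, float]] = {
    "scapegoat": (-0.14, 0.08, -0.75),
    "aggressive": (0.07, -0.80, -0.67),
    "gentle": (-0.18, 0.50, 0.00),
}

# Per-2-day-period feeder means per state: visit counts and total minutes.
DEFAULT_FEEDER_PARAMS: dict[str, dict[str, float]] = {
    "scapegoat": {"nb_nv": 2.48, "nb_nnv": 10.40, "time_nv": 90.40, "time_nnv": 61.40},
    "aggressive": {"nb_nv": 3.11, "nb_nnv": 15.40, "time_nv": 105.00, "time_nnv": 88.20},
    "gentle": {"nb_nv": 2.39, "nb_nnv": 11.10, "time_nv": 80.60, "time_nnv": 63.50},
}

# Individual posture time budgets (%) per state; they sum to ~96.3 and the
# deficit is an explicit "undetected" fraction (animals the detector misses).
DEFAULT_POSTURE_PARAMS: dict[str, dict[str, float]] = {
    "scapegoat": {
        "side_lying": 51.00, "ventral_lying": 21.30, "standing": 19.20,
        "sitting": 1.13, "eating": 3.20, "drinking": 0.58,
    },
    "aggressive": {
        "side_lying": 50.10, "ventral_lying": 22.00, "standing": 18.60,
        "sitting": 0.93, "eating": 3.93, "drinking": 0.66,
    },
    "gentle": {
        "side_lying": 50.20, "ventral_lying": 21.20, "standing": 20.40,
        "sitting": 0.93, "eating": 2.97, "drinking": 0.60,
    },
}

# Mean minutes-after-midnight of the first nutritive visit of the day.
# More dominant (aggressive) sows reach the feeder earlier; scapegoats last.
DEFAULT_FIRST_VISIT_MEAN: dict[str, float] = {
    "aggressive": 300.0,
    "gentle": 330.0,
    "scapegoat": 390.0,
}

#: Default multiplier on all continuous dispersions; calibrated once (grid
#: search during development) so the end-to-end tree accuracy lands in a
#: realistic 72–80 % band given the irreducible Poisson count overlap.
DEFAULT_DISPERSION_SCALE = 0.05


class SimConfigError(ValueError):
    """Invalid simulation configuration (probabilities, rates, names)."""


def _copy(mapping):
    return {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in mapping.items()}


@dataclass
class SimConfig:
    """Parameters of the synthetic herd.

    Defaults describe a typical experimental herd: 4 groups of 17
    sows followed over 6 two-day periods alternating control and event
    weeks, control state probabilities (gentle/aggressive/scapegoat) =
    0.53/0.25/0.22 shifting to 0.35/0.39/0.26 in event weeks, index
    centers at the canonical behavioral archetypes, and feeder/posture
    means at the per-state values in the module defaults above.
    """

    n_groups: int = 4
    sows_per_group: int = 17
    n_periods: int = 6
    week_types: tuple[str, ...] | None = None  # default: alternate control/event
    event_types: tuple[str, ...] = EVENT_TYPES
    days_per_period: int = 2

    state_probs_control: dict[str, float] = field(
        default_factory=lambda: {"gentle": 0.53, "aggressive": 0.25, "scapegoat": 0.22}
    )
    state_probs_event: dict[str, float] = field(
        default_factory=lambda: {"gentle": 0.35, "aggressive": 0.39, "scapegoat": 0.26}
    )
    event_modifiers: dict[str, dict[str, float]] = field(default_factory=dict)
    stickiness: float = 0.0  # P(keep previous period's state)

    index_centers: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: _copy(DEFAULT_INDEX_CENTERS)
    )
    interaction_total_rate: float = 20.0  # expected interactions per period, each axis
    observed_minutes: float = 1200.0  # 2 days x two 5-h observation windows
    activity_cv: float = 0.5

    feeder_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: _copy(DEFAULT_FEEDER_PARAMS)
    )
    visit_duration_cv: float = 0.6
    first_visit_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIRST_VISIT_MEAN)
    )
    first_visit_sd: float = 240.0
    feed_per_nv_g: float = 900.0
    feed_cv: float = 0.3

    posture_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: _copy(DEFAULT_POSTURE_PARAMS)
    )
    posture_noise_sd: float = 0.8  # percentage points, on the group summary

    dispersion_scale: float = DEFAULT_DISPERSION_SCALE
    unhealthy_prob: float = 0.2
    health_aggressive_bias: float = 0.0  # extra aggressive odds for unhealthy sows
    seed: int = 42

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, probs in (
            ("state_probs_control", self.state_probs_control),
            ("state_probs_event", self.state_probs_event),
            *((f"event_modifiers[{k}]", v) for k, v in self.event_modifiers.items()),
        ):
            if set(probs) != set(STATES):
                raise SimConfigError(f"{name} must have keys {STATES}")
            vals = np.array([probs[s] for s in STATES], dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise SimConfigError(f"{name} must be a probability simplex over {STATES}")
        for k in self.event_modifiers:
            if k not in EVENT_TYPES:
                raise SimConfigError(f"unknown event type in event_modifiers: {k!r}")
        for state in STATES:
            center = self.index_centers[state]
            if len(center) != 3 or any(abs(c) > 1 for c in center):
                raise SimConfigError("index centers must be triples within [-1, 1]")
            fp = self.feeder_params[state]
            if any(fp[k] < 0 for k in ("nb_nv", "nb_nnv", "time_nv", "time_nnv")):
                raise SimConfigError("feeder params must be non-negative")
            budget = self.posture_params[state]
            if any(budget[p] < 0 for p in POSTURES):
                raise SimConfigError("posture budgets must be non-negative")
            if sum(budget[p] for p in POSTURES) > 100.0 + 1e-9:
                raise SimConfigError("posture budgets must sum to at most 100%")
        if self.interaction_total_rate < 0 or self.dispersion_scale < 0:
            raise SimConfigError("rates and dispersions must be non-negative")
        if not 0.0 <= self.stickiness <= 1.0:
            raise SimConfigError("stickiness must be in [0, 1]")

    def resolved_week_types(self) -> tuple[str, ...]:
        """Per-period week types; default alternates control, event, ..."""
        if self.week_types is not None:
            if len(self.week_types) != self.n_periods:
                raise SimConfigError("week_types length must equal n_periods")
            if any(w not in WEEK_TYPES for w in self.week_types):
                raise SimConfigError(f"week types must be in {WEEK_TYPES}")
            return tuple(self.week_types)
        return tuple(WEEK_TYPES[i % 2] for i in range(self.n_periods))

    def interaction_rates(self, state: str) -> dict[str, float]:
        """Poisson rates for the four interaction counts of one period.

        Rates are scaled so (pos − neg)/(pos + neg) equals the state's
        index center in expectation: λ_pos = R(1+c)/2, λ_neg = R(1−c)/2.
        """
        _, c_giv, c_rec = self.index_centers[state]
        half = self.interaction_total_rate / 2.0
        return {
            "giv_pos": half * (1 + c_giv),
            "giv_neg": half * (1 - c_giv),
            "rec_pos": half * (1 + c_rec),
            "rec_neg": half * (1 - c_rec),
        }


@dataclass(frozen=True)
class FeederVisit:
    """One raw visit event at the electronic feeder."""

    sow_id: str
    group_id: str
    period: int
    day: int
    start_time: float  # minutes since midnight (feeding day starts at midnight)
    duration_min: float
    feed_g: float

    @property
    def nutritive(self) -> bool:
        return self.feed_g > 0


@dataclass(frozen=True)
class EthogramTally:
    """Active/passive minutes and the four interaction counts of one period."""

    active_min: float
    passive_min: float
    giv_pos: int
    giv_neg: int
    rec_pos: int
    rec_neg: int


@dataclass
class SimDataset:
    """The five observable streams plus the latent-state ground truth."""

    visits: pd.DataFrame
    ethogram: pd.DataFrame
    postures: pd.DataFrame
    registry: pd.DataFrame
    schedule: pd.DataFrame
    truth: pd.DataFrame


def child_rng(root_seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named stream of one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed) % 2**31, zlib.crc32(stream.encode())])
    )


def _gamma(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Gamma draws with a given mean and coefficient of variation."""
    if mean <= 0:
        return np.zeros(size) if size is not None else 0.0
    if cv <= 0:
        return np.full(size, mean) if size is not None else mean
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=size)


def sample_state(
    week_type: str,
    event_type: str | None,
    config: SimConfig,
    rng: np.random.Generator,
) -> str:
    """Draw one latent state for a sow-period given its week type."""
    if week_type not in WEEK_TYPES:
        raise SimConfigError(f"unknown week type {week_type!r}")
    if week_type == "control":
        if event_type is not None:
            raise SimConfigError("control weeks carry no event type")
        probs = config.state_probs_control
    else:
        if event_type is not None and event_type not in config.event_types:
            raise SimConfigError(f"unknown event type {event_type!r}")
        probs = config.state_probs_event
        if event_type is not None and event_type in config.event_modifiers:
            probs = config.event_modifiers[event_type]
    p = np.array([probs[s] for s in STATES], dtype=float)
    return STATES[rng.choice(len(STATES), p=p)]


def simulate_ethogram(
    state: str, config: SimConfig, rng: np.random.Generator
) -> EthogramTally:
    """One period of manually coded behavior for a sow in `state`.

    Active/passive minutes are Gamma around T(1±c)/2 with T the total
    observed time, so the activity index has expectation ≈ c; the four
    interaction counts are Poisson at the state's configured rates.
    """
    if state not in STATES:
        raise SimConfigError(f"unknown state {state!r}")
    c_act = config.index_centers[state][0]
    cv = config.activity_cv * config.dispersion_scale
    total = config.observed_minutes
    active = float(_gamma(rng, total * (1 + c_act) / 2.0, cv))
    passive = float(_gamma(rng, total * (1 - c_act) / 2.0, cv))
    rates = config.interaction_rates(state)
    return EthogramTally(
        active_min=active,
        passive_min=passive,
        giv_pos=int(rng.poisson(rates["giv_pos"])),
        giv_neg=int(rng.poisson(rates["giv_neg"])),
        rec_pos=int(rng.poisson(rates["rec_pos"])),
        rec_neg=int(rng.poisson(rates["rec_neg"])),
    )


def simulate_feeder_visits(
    state: str,
    sow_id: str,
    n_days: int,
    config: SimConfig,
    rng: np.random.Generator,
    group_id: str = "A",
    period: int = 1,
    first_day: int = 1,
) -> list[FeederVisit]:
    """Feeder visits of one sow over `n_days` feeding days.

    Daily nutritive/non-nutritive visit counts are Poisson at the
    per-period state mean divided by the period length, so per-period
    totals match the configured means in expectation. The first
    nutritive visit of the day is centered at a state-dependent hour
    (dominant sows feed earlier), which induces the feeder-rank signal.
    """
    if state not in STATES:
        raise SimConfigError(f"unknown state {state!r}")
    if n_days < 1:
        raise SimConfigError("n_days must be >= 1")
    fp = config.feeder_params[state]
    delta = config.dispersion_scale
    dur_cv = config.visit_duration_cv * delta
    mean_dur_nv = fp["time_nv"] / fp["nb_nv"] if fp["nb_nv"] > 0 else 0.0
    mean_dur_nnv = fp["time_nnv"] / fp["nb_nnv"] if fp["nb_nnv"] > 0 else 0.0
    per_day = config.days_per_period
    visits: list[FeederVisit] = []
    for day in range(first_day, first_day + n_days):
        n_nv = rng.poisson(fp["nb_nv"] / per_day)
        if n_nv > 0:
            first = float(
                np.clip(
                    rng.normal(config.first_visit_mean[state], config.first_visit_sd * delta),
                    0.0,
                    1380.0,
                )
            )
            later = np.sort(rng.uniform(first, 1439.0, size=n_nv - 1))
            times = np.concatenate([[first], later])
            durs = _gamma(rng, mean_dur_nv, dur_cv, size=n_nv)
            feeds = np.maximum(_gamma(rng, config.feed_per_nv_g, config.feed_cv * delta, size=n_nv), 1.0)
            for t, d, f in zip(times, durs, feeds):
                visits.append(
                    FeederVisit(sow_id, group_id, period, day, float(t), float(d), float(f))
                )
        n_nnv = rng.poisson(fp["nb_nnv"] / per_day)
        if n_nnv > 0:
            times = np.sort(rng.uniform(0.0, 1439.0, size=n_nnv))
            durs = _gamma(rng, mean_dur_nnv, dur_cv, size=n_nnv)
            for t, d in zip(times, durs):
                visits.append(
                    FeederVisit(sow_id, group_id, period, day, float(t), float(d), 0.0)
                )
    return visits


def simulate_postures(
    group_states: Sequence[str], config: SimConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Group posture summary (six percentages) for one period.

    The group percentage of each posture is the mean over sows of the
    state-conditional individual time budgets plus Gaussian detector
    noise, clipped to [0, 100] and rescaled if the sum exceeds 100.
    """
    if len(group_states) == 0:
        raise SimConfigError("group_states must be non-empty")
    for s in group_states:
        if s not in STATES:
            raise SimConfigError(f"unknown state {s!r}")
    sd = config.posture_noise_sd * config.dispersion_scale
    out: dict[str, float] = {}
    for posture in POSTURES:
        mean = float(np.mean([config.posture_params[s][posture] for s in group_states]))
        out[posture] = float(np.clip(mean + rng.normal(0.0, sd) if sd > 0 else mean, 0.0, 100.0))
    total = sum(out.values())
    if total > 100.0:
        out = {k: v * 100.0 / total for k, v in out.items()}
    return out


def _sow_ids(config: SimConfig) -> dict[str, list[str]]:
    groups = [chr(ord("A") + i) for i in range(config.n_groups)]
    return {g: [f"{g}{i + 1:02d}" for i in range(config.sows_per_group)] for g in groups}


def _event_assignment(config: SimConfig) -> dict[tuple[str, int], str | None]:
    """Event type per (group, period); groups rotate through the event pool."""
    week_types = config.resolved_week_types()
    out: dict[tuple[str, int], str | None] = {}
    for gi, group in enumerate(_sow_ids(config)):
        j = 0
        for p, wt in enumerate(week_types, start=1):
            if wt == "event":
                out[(group, p)] = config.event_types[(gi + j) % len(config.event_types)]
                j += 1
            else:
                out[(group, p)] = None
    return out


def generate_dataset(config: SimConfig) -> SimDataset:
    """Simulate the full herd; bit-identical for identical configs."""
    config.validate()
    rng_state = child_rng(config.seed, "states")
    rng_eth = child_rng(config.seed, "ethogram")
    rng_feed = child_rng(config.seed, "feeder")
    rng_post = child_rng(config.seed, "postures")
    rng_reg = child_rng(config.seed, "registry")

    week_types = config.resolved_week_types()
    events = _event_assignment(config)
    sow_ids = _sow_ids(config)

    registry_rows = []
    healthy: dict[str, bool] = {}
    for group, sows in sow_ids.items():
        parities = [1] * min(4, len(sows)) + list(
            rng_reg.integers(2, 11, size=max(len(sows) - 4, 0))
        )
        for sow, parity in zip(sows, parities):
            healthy[sow] = bool(rng_reg.random() >= config.unhealthy_prob)
            registry_rows.append(
                {
                    "sow_id": sow,
                    "group_id": group,
                    "parity": int(parity),
                    "body_weight_kg": round(float(rng_reg.normal(230.0, 25.0)), 1),
                    "backfat_mm": round(float(np.clip(rng_reg.normal(16.0, 3.0), 5.0, 35.0)), 1),
                    "healthy": healthy[sow],
                }
            )

    truth_rows, eth_rows, post_rows, sched_rows = [], [], [], []
    all_visits: list[FeederVisit] = []
    prev_state: dict[str, str] = {}
    for group, sows in sow_ids.items():
        for p, wt in enumerate(week_types, start=1):
            ev = events[(group, p)]
            sched_rows.append(
                {"group_id": group, "period": p, "week_type": wt, "event_type": ev or ""}
            )
            states = []
            for sow in sows:
                if sow in prev_state and rng_state.random() < config.stickiness:
                    state = prev_state[sow]
                else:
                    cfg = config
                    if config.health_aggressive_bias > 0 and not healthy[sow]:
                        base = (
                            config.state_probs_control
                            if wt == "control"
                            else config.state_probs_event
                        )
                        boosted = dict(base)
                        boosted["aggressive"] = min(
                            1.0, base["aggressive"] * (1 + config.health_aggressive_bias)
                        )
                        norm = sum(boosted.values())
                        boosted = {k: v / norm for k, v in boosted.items()}
                        state = STATES[
                            rng_state.choice(
                                len(STATES), p=[boosted[s] for s in STATES]
                            )
                        ]
                        prev_state[sow] = state
                        states.append(state)
                        continue
                    state = sample_state(wt, ev, cfg, rng_state)
                prev_state[sow] = state
                states.append(state)
            for sow, state in zip(sows, states):
                truth_rows.append(
                    {
                        "sow_id": sow,
                        "group_id": group,
                        "period": p,
                        "week_type": wt,
                        "event_type": ev or "",
                        "state": state,
                    }
                )
                tally = simulate_ethogram(state, config, rng_eth)
                eth_rows.append(
                    {
                        "sow_id": sow,
                        "period": p,
                        "active_min": round(tally.active_min, 4),
                        "passive_min": round(tally.passive_min, 4),
                        "giv_pos": tally.giv_pos,
                        "giv_neg": tally.giv_neg,
                        "rec_pos": tally.rec_pos,
                        "rec_neg": tally.rec_neg,
                    }
                )
                all_visits.extend(
                    simulate_feeder_visits(
                        state,
                        sow,
                        config.days_per_period,
                        config,
                        rng_feed,
                        group_id=group,
                        period=p,
                    )
                )
            summary = simulate_postures(states, config, rng_post)
            post_rows.append({"group_id": group, "period": p, **{k: round(v, 4) for k, v in summary.items()}})

    visits = pd.DataFrame(
        [
            {
                "sow_id": v.sow_id,
                "group_id": v.group_id,
                "period": v.period,
                "day": v.day,
                "start_time": round(v.start_time, 4),
                "duration_min": round(v.duration_min, 4),
                "feed_g": round(v.feed_g, 1),
                "nutritive": v.nutritive,
            }
            for v in all_visits
        ],
        columns=[
            "sow_id", "group_id", "period", "day",
            "start_time", "duration_min", "feed_g", "nutritive",
        ],
    )
    return SimDataset(
        visits=visits,
        ethogram=pd.DataFrame(eth_rows),
        postures=pd.DataFrame(post_rows),
        registry=pd.DataFrame(registry_rows),
        schedule=pd.DataFrame(sched_rows),
        truth=pd.DataFrame(truth_rows),
    )
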