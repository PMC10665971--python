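"""Synthetic regular seasons with the structure the binomial model assumes.

Each game independently produces at most one concussion event (Bernoulli at
a configured per-game incidence, matching the intercept-only binomial-logit
model exactly; a Poisson-per-game variant exists for misspecification
stress tests).  Each event draws its characteristics independently from
per-group categorical mixtures — rink location, zone, period, body-check
mechanism chain (body check? to the head? by shoulder/glove/arm? lateral?),
position, puck possession, penalty — and a video-availability flag.  Events
without video are excluded from proportion numerators and denominators,
mirroring how real events without usable footage go uncoded; incidence
denominators use all games.

A paper-calibrated pair of season configs reproduces the two cohorts'
marginal structure from the bundled count fixture, so the full pipeline is
exercisable end to end, and interval calibration is measurable, without any
real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .cohort_data import (
    DEFAULT_TAXONOMY,
    CharacteristicCount,
    CohortSpec,
    DenominatorKind,
    Taxonomy,
    load_paper_fixture,
)
from .contrast import make_contrast
from .posterior_engine import posterior_quadrature
from .prior_builder import continuity_adjusted_center, tune_sigma

__all__ = [
    "SeasonConfig",
    "simulate_season",
    "aggregate",
    "paper_calibrated_configs",
    "CalibrationReport",
    "calibration_study",
]

LOCATIONS = ("open ice", "perimeter")
ZONES = ("offensive", "neutral", "defensive")
PERIODS = ("first", "later")
#: Mechanism chain: not a body check at all; a body check not to the head;
#: or a body check to the head initiated by shoulder, glove, or arm.
MECHANISMS = ("none", "body check body", "shoulder", "glove", "arm")
HEAD_MECHANISMS = ("shoulder", "glove", "arm")
POSITIONS = ("forward", "defense", "goalie")

_GROUP_CATEGORIES: dict[str, tuple[str, ...]] = {
    "location": LOCATIONS,
    "zone": ZONES,
    "period": PERIODS,
    "mechanism": MECHANISMS,
    "position": POSITIONS,
}


class SeasonConfig(BaseModel):
    """Generating process for one cohort's regular seasons.

    ``characteristic_mixtures`` maps each group to a categorical probability
    vector over that group's categories; ``lateral_given_head`` is the
    probability that a hit to the head contacts the lateral aspect;
    ``puck_possession_rate`` / ``penalty_rate`` are per-event Bernoulli
    probabilities.
    """

    label: str
    n_games: int = Field(gt=0)
    incidence_per_game: float = Field(ge=0.0, le=1.0)
    characteristic_mixtures: dict[str, dict[str, float]]
    lateral_given_head: float = Field(ge=0.0, le=1.0)
    puck_possession_rate: float = Field(ge=0.0, le=1.0)
    penalty_rate: float = Field(ge=0.0, le=1.0)
    video_rate: float = Field(ge=0.0, le=1.0)
    seed: int = 0
    poisson_per_game: bool = False

    @field_validator("characteristic_mixtures")
    @classmethod
    def _check_mixtures(cls, mixtures: dict[str, dict[str, float]]):
        for group, categories in _GROUP_CATEGORIES.items():
            if group not in mixtures:
                raise ValueError(f"missing mixture for group {group!r}")
            mix = mixtures[group]
            unknown = set(mix) - set(categories)
            if unknown:
                raise ValueError(f"unknown categories {unknown} in group {group!r}")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture for {group!r} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"negative probability in group {group!r}")
        return mixtures

    def mixture_vector(self, group: str) -> np.ndarray:
        categories = _GROUP_CATEGORIES[group]
        return np.array([self.characteristic_mixtures[group].get(c, 0.0) for c in categories])


_EVENT_COLUMNS = [
    "game",
    "cohort",
    "event",
    "video",
    "location",
    "zone",
    "period",
    "mechanism",
    "lateral",
    "position",
    "puck_possession",
    "penalty",
]


def simulate_season(config: SeasonConfig) -> pd.DataFrame:
    """Simulate one cohort; one row per game, characteristic columns per event.

    Bit-identical for identical configs (all randomness flows from
    ``config.seed``).  ``DataFrame.attrs`` carries ``label`` and ``n_games``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_games
    if config.poisson_per_game:
        counts = rng.poisson(config.incidence_per_game, size=n)
        game_idx = np.repeat(np.arange(n), counts)
    else:
        event = rng.random(n) < config.incidence_per_game
        game_idx = np.flatnonzero(event)
    m = game_idx.size

    def draw(group: str) -> np.ndarray:
        categories = np.array(_GROUP_CATEGORIES[group], dtype=object)
        return rng.choice(categories, size=m, p=config.mixture_vector(group))

    mechanism = draw("mechanism")
    head = np.isin(mechanism, HEAD_MECHANISMS)
    lateral = np.zeros(m, dtype=bool)
    lateral[head] = rng.random(int(head.sum())) < config.lateral_given_head

    events = pd.DataFrame(
        {
            "game": game_idx,
            "cohort": config.label,
            "event": True,
            "video": rng.random(m) < config.video_rate,
            "location": draw("location"),
            "zone": draw("zone"),
            "period": draw("period"),
            "mechanism": mechanism,
            "lateral": lateral,
            "position": draw("position"),
            "puck_possession": rng.random(m) < config.puck_possession_rate,
            "penalty": rng.random(m) < config.penalty_rate,
        }
    )
    quiet_games = np.setdiff1d(np.arange(n), game_idx, assume_unique=False)
    quiet = pd.DataFrame({"game": quiet_games, "cohort": config.label, "event": False})
    table = (
        pd.concat([events, quiet], ignore_index=True)
        .reindex(columns=_EVENT_COLUMNS)
        .sort_values(["game"], kind="stable")
        .reset_index(drop=True)
    )
    table.attrs["label"] = config.label
    table.attrs["n_games"] = n
    return table


def aggregate(
    events: pd.DataFrame, taxonomy: Taxonomy = DEFAULT_TAXONOMY
) -> tuple[list[CharacteristicCount], CohortSpec]:
    """Reduce a game-event table to characteristic counts plus cohort totals.

    Proportion records count only events with video (uncoded events drop out
    of both numerator and denominator); the cohort spec retains all events
    and all games so incidence arithmetic stays exposure-based.
    """
    if events.empty:
        raise ValueError("cannot aggregate an empty event table")
    label = events.attrs.get("label", str(events["cohort"].iloc[0]))
    n_games = int(events.attrs.get("n_games", events["game"].max() + 1))
    ev = events[events["event"].astype(bool)]
    vid = ev[ev["video"].astype(bool)]

    for column, allowed in (
        ("location", LOCATIONS),
        ("zone", ZONES),
        ("period", PERIODS),
        ("mechanism", MECHANISMS),
        ("position", POSITIONS),
    ):
        values = set(vid[column].dropna().unique())
        if not values <= set(allowed):
            raise ValueError(f"unknown {column} label(s): {values - set(allowed)}")

    cohort = CohortSpec(
        label=label,
        n_games=n_games,
        n_concussions_total=int(len(ev)),
        n_concussions_video=int(len(vid)),
    )
    n_vid = len(vid)
    if n_vid == 0:
        warnings.warn(
            f"cohort {label!r}: no events with video; proportion records dropped",
            stacklevel=2,
        )
        return [], cohort

    head = vid["mechanism"].isin(HEAD_MECHANISMS)
    numerators = {
        "open ice": (vid["location"] == "open ice").sum(),
        "offensive": (vid["zone"] == "offensive").sum(),
        "neutral": (vid["zone"] == "neutral").sum(),
        "defensive": (vid["zone"] == "defensive").sum(),
        "all body checks": (vid["mechanism"] != "none").sum(),
        "body checks to head": head.sum(),
        "shoulder": (vid["mechanism"] == "shoulder").sum(),
        "glove": (vid["mechanism"] == "glove").sum(),
        "arm": (vid["mechanism"] == "arm").sum(),
        "lateral hit to head": vid["lateral"].astype(bool).sum(),
        "first period": (vid["period"] == "first").sum(),
        "puck possession": vid["puck_possession"].astype(bool).sum(),
        "penalty called": vid["penalty"].astype(bool).sum(),
        "forward": (vid["position"] == "forward").sum(),
        "defense": (vid["position"] == "defense").sum(),
        "goalie": (vid["position"] == "goalie").sum(),
    }
    counts = [
        CharacteristicCount(
            cohort=label,
            variable=variable,
            numerator=int(numerators[variable]),
            denominator=n_vid,
            denominator_kind=DenominatorKind.EVENTS_WITH_VIDEO,
        )
        for variable in taxonomy.variables
        if variable in numerators
    ]
    return counts, cohort


def paper_calibrated_configs(seed: int = 0) -> tuple[SeasonConfig, SeasonConfig]:
    """Season configs reproducing the two cohorts' published marginal structure.

    Incidence, video rate and characteristic mixtures are derived from the
    bundled fixture: the pre cohort emulates 2006-2010 (301 concussions in
    4920 games, 76.7% with video), the post cohort 2014-2019 (516 in 6232,
    88.6% with video).  Mixtures normalize the printed per-variable counts;
    the position mixture normalizes (forward, defense, goalie) counts since
    their printed denominators are not mutually consistent.
    """
    counts, cohorts = load_paper_fixture()
    by = {(c.cohort, c.variable): c for c in counts}
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    configs = []
    for cohort, cfg_seed in zip(cohorts, seeds):
        lab = cohort.label

        def y(variable: str) -> int:
            return by[(lab, variable)].numerator

        def frac(variable: str) -> float:
            record = by[(lab, variable)]
            return record.numerator / record.denominator

        n_events = by[(lab, "open ice")].denominator  # cohort video total
        zone_total = by[(lab, "offensive")].denominator
        pos = np.array([y("forward"), y("defense"), y("goalie")], dtype=float)
        pos /= pos.sum()
        p_open = frac("open ice")
        bc, head = y("all body checks"), y("body checks to head")
        mech = {
            "none": (n_events - bc) / n_events,
            "body check body": (bc - head) / n_events,
            "shoulder": y("shoulder") / n_events,
            "glove": y("glove") / n_events,
            "arm": y("arm") / n_events,
        }
        configs.append(
            SeasonConfig(
                label=lab,
                n_games=cohort.n_games,
                incidence_per_game=cohort.n_concussions_total / cohort.n_games,
                characteristic_mixtures={
                    "location": {"open ice": p_open, "perimeter": 1.0 - p_open},
                    "zone": {
                        "offensive": y("offensive") / zone_total,
                        "neutral": y("neutral") / zone_total,
                        "defensive": y("defensive") / zone_total,
                    },
                    "period": {
                        "first": frac("first period"),
                        "later": 1.0 - frac("first period"),
                    },
                    "mechanism": mech,
                    "position": dict(zip(POSITIONS, pos)),
                },
                lateral_given_head=y("lateral hit to head") / head,
                puck_possession_rate=frac("puck possession"),
                penalty_rate=frac("penalty called"),
                video_rate=cohort.n_concussions_video / cohort.n_concussions_total,
                seed=cfg_seed,
            )
        )
    return configs[0], configs[1]


@dataclass(frozen=True)
class CalibrationReport:
    """Frequentist operating characteristics of the Bayesian pipeline."""

    variable: str
    true_diff: float
    n_reps: int
    coverage_90: float
    mean_bias: float
    estimates: np.ndarray
    covered: np.ndarray


def calibration_study(
    config_pre: SeasonConfig,
    config_post: SeasonConfig,
    true_diff: float,
    n_reps: int,
    seed: int = 0,
    variable: str = "lateral hit to head",
    target_sd_diff: float = 10.0,
) -> CalibrationReport:
    """Simulate, fit, contrast — repeatedly — and score interval coverage.

    Each replicate simulates both cohorts afresh, reruns the whole
    prior-tuning -> posterior (quadrature) -> contrast pipeline for one
    focal proportion variable, and records whether the 90% credible
    interval covers ``true_diff`` (in pp) and the estimate's bias.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(n_reps, 4))
    estimates = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    for r in range(n_reps):
        draws_by_cohort = []
        for config, s in ((config_pre, rep_seeds[r, 0]), (config_post, rep_seeds[r, 1])):
            replicate = config.model_copy(update={"seed": int(s)})
            counts, _ = aggregate(simulate_season(replicate))
            record = next(c for c in counts if c.variable == variable)
            draws_by_cohort.append((record.numerator, record.denominator))
        (y_pre, n_pre), (y_post, n_post) = draws_by_cohort
        center = (
            y_pre / n_pre
            if 0 < y_pre < n_pre
            else continuity_adjusted_center(y_pre, n_pre)
        )
        prior = tune_sigma(center, target_sd_diff, seed=int(rep_seeds[r, 2]))
        pre = posterior_quadrature(y_pre, n_pre, prior, variable=variable, cohort="pre")
        post = posterior_quadrature(y_post, n_post, prior, variable=variable, cohort="post")
        result, _ = make_contrast(pre, post, scale="pp", seed=int(rep_seeds[r, 3]))
        estimates[r] = result.mean_diff
        lo, hi = result.cri90
        covered[r] = lo <= true_diff <= hi
    return CalibrationReport(
        variable=variable,
        true_diff=true_diff,
        n_reps=n_reps,
        coverage_90=float(covered.mean()),
        mean_bias=float(estimates.mean() - true_diff),
        estimates=estimates,
        covered=covered,
    )
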