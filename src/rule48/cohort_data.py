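"""Count tables, cohort metadata, and the raw-rate arithmetic that precedes modeling.

The unit of analysis is a *characteristic count*: for one cohort (an era of
regular seasons) and one injury characteristic (e.g. "lateral hit to head"),
the number of video-documented concussion events bearing that characteristic
out of a per-variable denominator.  Proportions are shares of events with
video; incidences are events per 100 regular-season games.

Per-variable denominators are stored explicitly rather than inherited from
the cohort, because missing data can shrink the denominator for individual
variables (e.g. zone or penalty information absent for a handful of events).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "DenominatorKind",
    "Taxonomy",
    "DEFAULT_TAXONOMY",
    "CohortSpec",
    "CharacteristicCount",
    "CountsError",
    "CountsParseError",
    "CountsValidationError",
    "read_counts",
    "write_counts",
    "load_paper_fixture",
    "video_coverage",
    "raw_incidence_per_100",
    "raw_proportion",
    "round_half_up",
]


class CountsError(ValueError):
    """Base class for count-table errors."""


class CountsParseError(CountsError):
    """A row could not be parsed; the message names the offending line."""


class CountsValidationError(CountsError):
    """A parsed record violates an invariant (e.g. numerator > denominator)."""


class DenominatorKind(str, Enum):
    """What the denominator of a characteristic count refers to."""

    EVENTS_WITH_VIDEO = "events_with_video"
    GAMES = "games"


@dataclass(frozen=True)
class Taxonomy:
    """Ordered vocabulary of characteristic variables, grouped by theme.

    ``groups`` maps a group name (location, mechanism, game situation,
    position) to the ordered category names within it.  Every
    :class:`CharacteristicCount` variable must resolve to exactly one entry.
    """

    groups: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group, names in self.groups:
            for name in names:
                if name in seen:
                    raise ValueError(f"duplicate category {name!r} in taxonomy")
                seen.add(name)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(n for _, names in self.groups for n in names)

    def group_of(self, variable: str) -> str:
        for group, names in self.groups:
            if variable in names:
                return group
        raise KeyError(variable)

    def __contains__(self, variable: object) -> bool:
        return any(variable in names for _, names in self.groups)


#: The characteristic vocabulary used throughout: rink location (open ice is
#: the interior of the ice away from the boards; offensive/neutral/defensive
#: are zones relative to the injured player's team), body-check mechanism
#: (hits to the head are body checks where the shoulder, arm, or glove/fist
#: contacts the head; lateral hits contact the side of the head), game
#: situation, and the injured player's position.
DEFAULT_TAXONOMY = Taxonomy(
    groups=(
        ("location", ("open ice", "offensive", "neutral", "defensive")),
        (
            "mechanism",
            (
                "all body checks",
                "body checks to head",
                "shoulder",
                "glove",
                "arm",
                "lateral hit to head",
            ),
        ),
        ("game situation", ("first period", "puck possession", "penalty called")),
        ("position", ("forward", "defense", "goalie")),
    )
)


@dataclass(frozen=True)
class CohortSpec:
    """One era of regular seasons: exposure and event totals."""

    label: str
    n_games: int
    n_concussions_total: int
    n_concussions_video: int

    def __post_init__(self) -> None:
        for field in ("n_games", "n_concussions_total", "n_concussions_video"):
            if getattr(self, field) < 0:
                raise CountsValidationError(f"{field} must be nonnegative")
        if self.n_concussions_video > self.n_concussions_total:
            raise CountsValidationError(
                f"cohort {self.label!r}: events with video "
                f"({self.n_concussions_video}) exceed total concussions "
                f"({self.n_concussions_total})"
            )


@dataclass(frozen=True)
class CharacteristicCount:
    """One (cohort, variable) cell: numerator y out of denominator n."""

    cohort: str
    variable: str
    numerator: int
    denominator: int
    denominator_kind: DenominatorKind

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise CountsValidationError(
                f"{self.cohort}/{self.variable}: denominator must be positive"
            )
        if not 0 <= self.numerator <= self.denominator:
            raise CountsValidationError(
                f"{self.cohort}/{self.variable}: numerator {self.numerator} "
                f"outside [0, {self.denominator}]"
            )


def _normalize(text: str) -> str:
    # Published tables use the Unicode minus / en dash in era labels.
    return text.strip().replace("−", "-").replace("–", "-")


_COUNT_COLUMNS = ("cohort", "variable", "numerator", "denominator", "denominator_kind")
_COHORT_COLUMNS = ("label", "n_games", "n_concussions_total", "n_concussions_video")


def read_counts(
    path: Union[str, Path],
    schema: Taxonomy = DEFAULT_TAXONOMY,
    cohorts_path: Union[str, Path, None] = None,
) -> tuple[list[CharacteristicCount], list[CohortSpec]]:
    """Read a characteristic-count CSV (and an optional cohort CSV).

    The counts CSV has columns ``cohort, variable, numerator, denominator,
    denominator_kind``.  Cohort totals live in a companion CSV with columns
    ``label, n_games, n_concussions_total, n_concussions_video``; when
    ``cohorts_path`` is omitted, a sibling file named ``<stem>_cohorts.csv``
    is used if present.  When cohort totals are available, per-variable
    event denominators are cross-checked against the cohort's video total.

    Raises :class:`CountsParseError` naming the line for malformed rows and
    :class:`CountsValidationError` for records violating invariants.
    """
    path = Path(path)
    counts: list[CharacteristicCount] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _COUNT_COLUMNS:
            raise CountsParseError(
                f"{path}: expected header {','.join(_COUNT_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            line = reader.line_num
            if any(row.get(c) in (None, "") for c in _COUNT_COLUMNS):
                raise CountsParseError(f"{path}:{line}: missing field(s)")
            try:
                numerator = int(row["numerator"])
                denominator = int(row["denominator"])
            except ValueError as exc:
                raise CountsParseError(f"{path}:{line}: non-integer count: {exc}") from exc
            try:
                kind = DenominatorKind(_normalize(row["denominator_kind"]))
            except ValueError as exc:
                raise CountsParseError(
                    f"{path}:{line}: unknown denominator_kind "
                    f"{row['denominator_kind']!r}"
                ) from exc
            variable = _normalize(row["variable"])
            if variable not in schema:
                raise CountsValidationError(
                    f"{path}:{line}: unknown variable {variable!r}"
                )
            try:
                record = CharacteristicCount(
                    cohort=_normalize(row["cohort"]),
                    variable=variable,
                    numerator=numerator,
                    denominator=denominator,
                    denominator_kind=kind,
                )
            except CountsValidationError as exc:
                raise CountsValidationError(f"{path}:{line}: {exc}") from exc
            counts.append(record)

    if cohorts_path is None:
        candidate = path.with_name(path.stem + "_cohorts.csv")
        cohorts_path = candidate if candidate.exists() else None
    cohorts: list[CohortSpec] = []
    if cohorts_path is not None:
        cohorts = _read_cohorts(Path(cohorts_path))
        by_label = {c.label: c for c in cohorts}
        for record in counts:
            cohort = by_label.get(record.cohort)
            if cohort is None:
                continue
            if (
                record.denominator_kind is DenominatorKind.EVENTS_WITH_VIDEO
                and record.denominator > cohort.n_concussions_video
            ):
                raise CountsValidationError(
                    f"{record.cohort}/{record.variable}: denominator "
                    f"{record.denominator} exceeds cohort video total "
                    f"{cohort.n_concussions_video}"
                )
            if (
                record.denominator_kind is DenominatorKind.GAMES
                and record.denominator != cohort.n_games
            ):
                raise CountsValidationError(
                    f"{record.cohort}/{record.variable}: games denominator "
                    f"{record.denominator} != cohort games {cohort.n_games}"
                )
    return counts, cohorts


def _read_cohorts(path: Path) -> list[CohortSpec]:
    cohorts: list[CohortSpec] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _COHORT_COLUMNS:
            raise CountsParseError(
                f"{path}: expected header {','.join(_COHORT_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            line = reader.line_num
            try:
                cohorts.append(
                    CohortSpec(
                        label=_normalize(row["label"]),
                        n_games=int(row["n_games"]),
                        n_concussions_total=int(row["n_concussions_total"]),
                        n_concussions_video=int(row["n_concussions_video"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                if isinstance(exc, CountsValidationError):
                    raise
                raise CountsParseError(f"{path}:{line}: {exc}") from exc
    return cohorts


def write_counts(counts: Iterable[CharacteristicCount], path: Union[str, Path]) -> None:
    """Write characteristic counts back to CSV (inverse of :func:`read_counts`)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COUNT_COLUMNS)
        for c in counts:
            writer.writerow(
                [c.cohort, c.variable, c.numerator, c.denominator, c.denominator_kind.value]
            )


def load_paper_fixture() -> tuple[list[CharacteristicCount], list[CohortSpec]]:
    """Load the bundled published count tables (two cohorts, 16 variables).

    Pre-era cohort: 301 concussions in 4920 games, 231 with video; post-era:
    516 concussions in 6232 games, 457 with video.  Per-variable proportion
    denominators follow the printed tables (missing data shrink some of them).
    """
    data = resources.files("rule48") / "data"
    with resources.as_file(data / "paper_counts.csv") as counts_path, resources.as_file(
        data / "paper_counts_cohorts.csv"
    ) as cohorts_path:
        return read_counts(counts_path, cohorts_path=cohorts_path)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention).

    Python's builtin ``round`` is banker's rounding; published rates use
    conventional half-up (e.g. 301/4920*100 = 6.118 -> 6.1, 84.21 -> 84.2).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def video_coverage(
    cohorts: Union[CohortSpec, Sequence[CohortSpec]],
) -> float:
    """Percentage of diagnosed concussions with usable video, pooled over cohorts.

    Returns the full-precision percentage; apply :func:`round_half_up` for
    display (e.g. pooled 688/817 -> 84.2).
    """
    if isinstance(cohorts, CohortSpec):
        cohorts = [cohorts]
    total = sum(c.n_concussions_total for c in cohorts)
    video = sum(c.n_concussions_video for c in cohorts)
    if total == 0:
        raise CountsValidationError("video coverage undefined: no concussions")
    return 100.0 * video / total


def raw_incidence_per_100(numerator: int, n_games: int) -> float:
    """Events per 100 regular-season games, full precision."""
    if n_games <= 0:
        raise CountsValidationError("incidence undefined: n_games must be positive")
    return 100.0 * numerator / n_games


def raw_proportion(numerator: int, denominator: int) -> float:
    """Percentage of events bearing a characteristic, full precision."""
    if denominator <= 0:
        raise CountsValidationError("proportion undefined: denominator must be positive")
    return 100.0 * numerator / denominator
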