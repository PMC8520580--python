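"""Domain types, validation and CSV I/O for interval-valued grouped data.

A neutrosophic observation is an interval ``[X_L, X_U]`` whose lower
endpoint is the determinate (certain) part of the measurement and whose
upper endpoint incorporates the indeterminate part.  A degenerate interval
(``lower == upper``) is an ordinary classical observation.

The module also ships the embedded reference dataset: daily ICU occupancy
of Covid-19 patients in Pakistan during December 2020, recorded as
indeterminacy intervals for three age groups over 20 days.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence, TextIO

import pandas as pd

__all__ = [
    "NeutrosophicObservation",
    "GroupedNeutrosophicData",
    "ComponentPair",
    "parse_csv",
    "render_csv",
    "table1_fixture",
    "validate",
]


class DataError(ValueError):
    """Invalid interval data (bad CSV, violated invariant)."""


@dataclass(frozen=True)
class NeutrosophicObservation:
    """One interval datum: determinate lower and indeterminate upper part."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise DataError(
                f"observation components must be finite, got [{self.lower}, {self.upper}]"
            )
        if self.lower > self.upper:
            raise DataError(
                f"observation lower endpoint exceeds upper: [{self.lower}, {self.upper}]"
            )

    @property
    def is_degenerate(self) -> bool:
        """True when the interval carries no indeterminacy (lower == upper)."""
        return self.lower == self.upper


@dataclass(frozen=True)
class ComponentPair:
    """(lower-component, upper-component) value of a derived statistic.

    Unlike an input observation, a derived pair need not be an ordered
    interval: with ties the upper-component sum of squared ranks can fall
    below the lower-component one, so no ordering is enforced.
    """

    lower_component: float
    upper_component: float

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.lower_component) and math.isfinite(self.upper_component)
        ):
            raise DataError("component pair must be finite")

    def as_tuple(self) -> tuple[float, float]:
        return (self.lower_component, self.upper_component)


@dataclass(frozen=True)
class GroupedNeutrosophicData:
    """k labeled independent samples of interval observations."""

    groups: tuple[tuple[str, tuple[NeutrosophicObservation, ...]], ...]

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.groups]
        if len(self.groups) < 2:
            raise DataError(f"need at least 2 groups, got {len(self.groups)}")
        if len(set(labels)) != len(labels):
            raise DataError(f"group labels must be unique, got {labels}")
        for label, obs in self.groups:
            if len(obs) == 0:
                raise DataError(f"group {label!r} is empty")

    @property
    def k(self) -> int:
        """Number of groups."""
        return len(self.groups)

    @property
    def n(self) -> int:
        """Total number of observations across groups."""
        return sum(len(obs) for _, obs in self.groups)

    @property
    def group_sizes(self) -> tuple[int, ...]:
        return tuple(len(obs) for _, obs in self.groups)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.groups)

    def observations(self) -> Iterable[NeutrosophicObservation]:
        """All observations in group order, then within-group order."""
        for _, obs in self.groups:
            yield from obs

    def component_values(self, component: str) -> list[float]:
        """Pooled values of one component ('lower' or 'upper'), data order."""
        if component not in ("lower", "upper"):
            raise ValueError(f"component must be 'lower' or 'upper', got {component!r}")
        return [getattr(o, component) for o in self.observations()]

    @classmethod
    def from_items(
        cls, items: Sequence[tuple[str, Sequence[tuple[float, float]]]]
    ) -> "GroupedNeutrosophicData":
        """Build from ``[(label, [(lower, upper), ...]), ...]``."""
        return cls(
            tuple(
                (label, tuple(NeutrosophicObservation(lo, up) for lo, up in obs))
                for label, obs in items
            )
        )


def parse_csv(source: TextIO | str) -> GroupedNeutrosophicData:
    """Parse grouped interval data from CSV.

    Two dialects are accepted: ``group,lower,upper`` for interval data and
    ``group,value`` for all-degenerate (classical) data.  Group order is
    first appearance; row order within groups is preserved.

    Raises :class:`DataError` on missing/unknown columns, non-numeric
    cells, reversed intervals (with the offending data row number), fewer
    than two groups, or an empty file.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    try:
        frame = pd.read_csv(source, dtype={"group": str}, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise DataError("empty CSV input") from None
    cols = list(frame.columns)
    if cols == ["group", "value"]:
        lower_col, upper_col = "value", "value"
    elif cols == ["group", "lower", "upper"]:
        lower_col, upper_col = "lower", "upper"
    else:
        raise DataError(
            f"expected columns group,lower,upper or group,value; got {cols}"
        )
    if len(frame) == 0:
        raise DataError("CSV contains a header but no data rows")

    groups: dict[str, list[NeutrosophicObservation]] = {}
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        label = getattr(row, "group")
        if pd.isna(label):
            raise DataError(f"row {row_number}: missing group label")
        raw_lo, raw_up = getattr(row, lower_col), getattr(row, upper_col)
        try:
            lo, up = float(raw_lo), float(raw_up)
        except (TypeError, ValueError):
            raise DataError(
                f"row {row_number}: non-numeric value ({raw_lo!r}, {raw_up!r})"
            ) from None
        if math.isnan(lo) or math.isnan(up):
            raise DataError(f"row {row_number}: missing value")
        try:
            obs = NeutrosophicObservation(lo, up)
        except DataError as exc:
            raise DataError(f"row {row_number}: {exc}") from None
        groups.setdefault(str(label), []).append(obs)

    if len(groups) < 2:
        raise DataError(f"need at least 2 groups, found {len(groups)}")
    return GroupedNeutrosophicData(
        tuple((label, tuple(obs)) for label, obs in groups.items())
    )


def render_csv(data: GroupedNeutrosophicData) -> str:
    """Serialize to the ``group,lower,upper`` dialect (round-trips parse_csv).

    Integral endpoints are written without a decimal point so the packaged
    fixture stays byte-stable.
    """

    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else repr(x)

    lines = ["group,lower,upper"]
    for label, obs in data.groups:
        for o in obs:
            lines.append(f"{label},{fmt(o.lower)},{fmt(o.upper)}")
    return "\n".join(lines) + "\n"


# Daily ICU occupancy of Covid-19 patients in Pakistan, December 2020,
# by age group (20 days x 3 groups).  Single published values are
# degenerate intervals: the source logged no indeterminacy that day.
_TABLE1_ROWS: tuple[
    tuple[tuple[float, float], tuple[float, float], tuple[float, float]], ...
] = (
    ((443, 450), (359, 361), (460, 465)),
    ((421, 426), (352, 365), (427, 429)),
    ((436, 450), (445, 455), (407, 410)),
    ((376, 385), (410, 410), (378, 380)),
    ((458, 458), (458, 464), (364, 368)),
    ((408, 420), (410, 415), (345, 349)),
    ((422, 425), (463, 470), (342, 346)),
    ((431, 440), (580, 584), (345, 345)),
    ((459, 462), (432, 440), (313, 318)),
    ((369, 369), (379, 379), (277, 280)),
    ((360, 360), (370, 370), (268, 271)),
    ((431, 445), (584, 589), (259, 262)),
    ((403, 415), (410, 416), (256, 260)),
    ((436, 445), (587, 590), (251, 251)),
    ((376, 376), (415, 415), (249, 249)),
    ((370, 370), (419, 422), (223, 227)),
    ((443, 443), (357, 357), (209, 211)),
    ((445, 445), (467, 472), (187, 191)),
    ((355, 365), (415, 418), (173, 175)),
    ((450, 450), (358, 358), (168, 168)),
)

TABLE1_GROUP_LABELS = ("55 and above", "35-55", "35 and below")


def table1_fixture() -> GroupedNeutrosophicData:
    """The embedded Covid-19 ICU occupancy dataset (3 age groups x 20 days)."""
    return GroupedNeutrosophicData.from_items(
        [
            (label, [row[g] for row in _TABLE1_ROWS])
            for g, label in enumerate(TABLE1_GROUP_LABELS)
        ]
    )


def table1_csv_text() -> str:
    """The packaged CSV copy of the embedded dataset, as text."""
    return (
        resources.files("neutrokw").joinpath("data/table1.csv").read_text("utf-8")
    )


SMALL_GROUP_THRESHOLD = 5
HEAVY_TIE_FRACTION = 0.5


@dataclass(frozen=True)
class Diagnostic:
    """A non-fatal data-quality warning."""

    code: str
    message: str


def validate(data: GroupedNeutrosophicData) -> list[Diagnostic]:
    """Check soft assumptions of the rank test; return warnings.

    Hard invariants (k >= 2, nonempty groups) are enforced by the type and
    raise on construction.  Warnings cover: any group with five or fewer
    observations (chi-square null is then a poor approximation — use the
    permutation p-value), and heavy ties, i.e. more than half of one
    component's pooled values involved in ties (the test is robust to
    scattered ties but not to concentrated ones).
    """
    out: list[Diagnostic] = []
    small = [label for label, obs in data.groups if len(obs) <= SMALL_GROUP_THRESHOLD]
    if small:
        out.append(
            Diagnostic(
                "small_groups",
                f"groups with <= {SMALL_GROUP_THRESHOLD} observations: {small}; "
                "chi-square p-values are unreliable, prefer p_method='permutation'",
            )
        )
    for component in ("lower", "upper"):
        values = data.component_values(component)
        counts: dict[float, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        tied = sum(c for c in counts.values() if c > 1)
        if tied > 0:
            frac = tied / len(values)
            msg = (
                f"{component} component: {tied}/{len(values)} observations tied "
                f"({frac:.0%})"
            )
            if frac > HEAVY_TIE_FRACTION:
                out.append(Diagnostic("heavy_ties", msg + "; ties are concentrated"))
            else:
                out.append(Diagnostic("ties", msg))
    return out
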