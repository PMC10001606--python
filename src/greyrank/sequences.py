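"""Annual series containers and the image operators feeding grey incidence.

The unit of data in grey relational analysis is a short annual series: a
reference sequence (the outcome, e.g. circulatory-disease mortality per
100,000) and one comparison sequence per candidate factor (income per capita,
physician density, smoking rate, ...).  All incidence variants consume one of
three *images* of a sequence:

``mean_image``
    values divided by their arithmetic mean — the standardization used before
    Deng's degree, removing units of measurement.
``initial_image``
    values divided by the first value — the normalization behind the relative
    (rate-of-change) degree.
``zero_start_image``
    first value subtracted — the translation underlying the absolute
    (area-based) degree.

Sequences are plain frozen containers over numpy arrays with a calendar-year
index; groups (male/female/total) are separate sequences sharing a year axis,
which keeps every incidence operator strictly one-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    ConfigurationError,
    DegenerateSequenceError,
    LengthError,
    PanelParseError,
)

__all__ = [
    "Sequence",
    "PanelGroup",
    "load_panel",
    "panel_from_frame",
    "mean_image",
    "initial_image",
    "zero_start_image",
    "lag_align",
]

#: Minimum admissible series length; the absolute degree's area construction
#: needs at least one interior point.
MIN_LENGTH = 3


@dataclass(frozen=True)
class Sequence:
    """One named annual series.

    Parameters
    ----------
    name:
        Variable label (e.g. ``"smoking_f"``).
    years:
        Strictly increasing integer calendar years, one per value.
    values:
        Finite real observations.  Units depend on the variable (per-100k
        mortality, %, physicians per 1k, currency units).
    """

    name: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1 or len(years) != len(values):
            raise AlignmentError(
                f"sequence {self.name!r}: years and values must be 1-D and equal length"
            )
        if len(values) < MIN_LENGTH:
            raise LengthError(
                f"sequence {self.name!r}: need at least {MIN_LENGTH} observations, "
                f"got {len(values)}"
            )
        if np.any(np.diff(years) <= 0):
            raise AlignmentError(
                f"sequence {self.name!r}: years must be strictly increasing"
            )
        if not np.all(np.isfinite(values)):
            raise PanelParseError(f"sequence {self.name!r}: values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray, suffix: str = "") -> "Sequence":
        """Return a sequence with the same year axis and new values."""
        name = self.name + suffix if suffix else self.name
        return Sequence(name, self.years, np.asarray(values, dtype=np.float64))

    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.years) != 1))


@dataclass(frozen=True)
class PanelGroup:
    """Reference sequence plus its comparison sequences for one group."""

    reference: Sequence
    factors: tuple[Sequence, ...] = field(default_factory=tuple)


def mean_image(s: Sequence) -> Sequence:
    """Divide a sequence by its arithmetic mean.

    The output has mean exactly 1 and is invariant to positive rescaling of
    the input — this is the unit-removing standardization applied before
    Deng's degree.
    """
    mean = float(np.mean(s.values))
    if mean == 0.0:
        raise DegenerateSequenceError(
            f"sequence {s.name!r}: mean is zero, mean image undefined"
        )
    return s.with_values(s.values / mean)


def initial_image(s: Sequence) -> Sequence:
    """Divide a sequence by its first value; the output starts at 1."""
    first = float(s.values[0])
    if first == 0.0:
        raise DegenerateSequenceError(
            f"sequence {s.name!r}: first value is zero, initial image undefined"
        )
    return s.with_values(s.values / first)


def zero_start_image(s: Sequence) -> Sequence:
    """Subtract the first value; the output starts at 0.

    Removes translation: ``zero_start_image(s + c) == zero_start_image(s)``.
    """
    return s.with_values(s.values - s.values[0])


def lag_align(
    reference: Sequence,
    comparisons: Iterable[Sequence],
    lag: int = 0,
) -> tuple[Sequence, tuple[Sequence, ...]]:
    """Pair the reference at year *t* with each comparison at year *t − lag*.

    A lag of 1 realizes the robustness convention where the outcome at year t
    is explained by the factors at year t − 1.  Pairing is by year value, so
    gappy (explicitly permitted) series align correctly rather than by
    position.  Aligned comparisons are re-indexed to the reference years they
    are paired with, so all outputs share one year axis and equal length.

    Raises
    ------
    LengthError
        If ``lag >= len(reference) - 2`` or fewer than three pairs survive.
    """
    comparisons = tuple(comparisons)
    if lag < 0:
        raise ConfigurationError(f"lag must be non-negative, got {lag}")
    if lag >= len(reference) - 2:
        raise LengthError(
            f"lag {lag} too large for a series of length {len(reference)}"
        )
    ref_years = reference.years
    keep = np.ones(len(ref_years), dtype=bool)
    comp_positions = []
    for comp in comparisons:
        # position of year t - lag in the comparison, or -1 if absent
        lookup = {int(y): i for i, y in enumerate(comp.years)}
        pos = np.array([lookup.get(int(t) - lag, -1) for t in ref_years])
        keep &= pos >= 0
        comp_positions.append(pos)
    if keep.sum() < MIN_LENGTH:
        raise LengthError(
            f"only {int(keep.sum())} aligned pairs at lag {lag}; need {MIN_LENGTH}"
        )
    years = ref_years[keep]
    aligned_ref = Sequence(reference.name, years, reference.values[keep])
    aligned_comps = tuple(
        Sequence(comp.name, years, comp.values[pos[keep]])
        for comp, pos in zip(comparisons, comp_positions)
    )
    return aligned_ref, aligned_comps


def _column_to_array(df: pd.DataFrame, column: str, path: str) -> np.ndarray:
    parsed = pd.to_numeric(df[column], errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise PanelParseError(
            f"{path}: non-numeric value {df.loc[row, column]!r} "
            f"in column {column!r}, row {row}"
        )
    if parsed.isna().any():
        row = int(parsed.isna().idxmax())
        raise PanelParseError(f"{path}: missing value in column {column!r}, row {row}")
    return parsed.to_numpy(dtype=np.float64)


def _check_years(years: np.ndarray, where: str, allow_gaps: bool) -> None:
    if len(np.unique(years)) != len(years):
        raise AlignmentError(f"{where}: repeated year in panel")
    if np.any(np.diff(years) <= 0):
        raise AlignmentError(f"{where}: years must be strictly increasing")
    if not allow_gaps and np.any(np.diff(years) != 1):
        raise AlignmentError(
            f"{where}: year gaps present; pass allow_gaps=True to permit them"
        )


def load_panel(
    path: str,
    reference: str,
    factors: TypingSequence[str],
    group: str | None = None,
    allow_gaps: bool = False,
) -> Mapping[str, PanelGroup]:
    """Load a tidy annual panel CSV into per-group sequences.

    Two dialects are supported.  *Wide*: one row per year, variables as
    columns (``group=None``); the result has the single key ``""``.  *Long*:
    a ``group`` column names the stratum of each row; the result has one
    :class:`PanelGroup` per group, all sharing the same year axis.

    Missing years are rejected unless ``allow_gaps`` — interpolating an
    annual health panel would fabricate observations.
    """
    return panel_from_frame(
        pd.read_csv(path), reference, factors,
        group=group, allow_gaps=allow_gaps, path=path,
    )


def panel_from_frame(
    df: pd.DataFrame,
    reference: str,
    factors: TypingSequence[str],
    group: str | None = None,
    allow_gaps: bool = False,
    path: str = "<frame>",
) -> Mapping[str, PanelGroup]:
    """In-memory counterpart of :func:`load_panel` for an existing DataFrame."""
    needed = ["year", reference, *factors] + ([group] if group else [])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing column(s) {missing}")

    def build(sub: pd.DataFrame, label: str) -> PanelGroup:
        sub = sub.sort_values("year").reset_index(drop=True)
        years = _column_to_array(sub, "year", path).astype(np.int64)
        _check_years(years, f"{path} [{label}]" if label else path, allow_gaps)
        ref = Sequence(reference, years, _column_to_array(sub, reference, path))
        if np.mean(ref.values) == 0.0:
            raise DegenerateSequenceError(
                f"{path}: reference column {reference!r} has zero mean"
            )
        comps = tuple(
            Sequence(f, years, _column_to_array(sub, f, path)) for f in factors
        )
        return PanelGroup(ref, comps)

    if group is None:
        return {"": build(df, "")}
    groups: dict[str, PanelGroup] = {}
    for label, sub in df.groupby(group, sort=False):
        groups[str(label)] = build(sub, str(label))
    year_sets = {g: tuple(pg.reference.years.tolist()) for g, pg in groups.items()}
    if len(set(year_sets.values())) > 1:
        raise AlignmentError(f"{path}: groups cover different year ranges {year_sets}")
    return groups
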