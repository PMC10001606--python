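"""Degrees of grey incidence and per-model factor ranking.

Grey relational analysis scores how geometrically similar a comparison curve
is to a reference curve.  Five degrees are implemented:

Deng's degree
    Mean of the pointwise grey relational coefficients

    .. math::

        \\gamma_i(k) = \\frac{\\min_i \\min_k |\\Delta_i(k)|
                             + \\varepsilon \\max_i \\max_k |\\Delta_i(k)|}
                            {|\\Delta_i(k)|
                             + \\varepsilon \\max_i \\max_k |\\Delta_i(k)|},

    with :math:`\\Delta_i(k)` the deviation between the *mean images* of the
    reference and comparison and :math:`\\varepsilon \\in (0, 1]` the
    resolution coefficient (conventionally 0.5).  The two-level min/max runs
    over all observations *and* all comparison sequences in the run.

absolute degree
    Area-based incidence on zero-start images of the raw sequences, using the
    signed area signature :math:`s = \\sum_{k=2}^{m-1} X(k) + X(m)/2`:

    .. math::

        \\epsilon = \\frac{1 + |s_0| + |s_i|}{1 + |s_0| + |s_i| + |s_i - s_0|}.

    Sensitive to the absolute magnitudes of change: when the two series carry
    wildly different scales the degree is pinned near 0.5.

relative degree
    The same area construction applied to initial-value images — scale-free,
    sensitive to rates of change; equals 1 for proportional sequences.

SDGRA
    Synthetic degree, the θ-weighted mean of absolute and relative degrees
    (θ = 0.5 by default).

SSGRA
    Second synthetic degree, the plain mean of Deng's and absolute degrees —
    mixing pointwise and integral similarity.

Higher degree means stronger incidence; ranks are assigned per model in
descending order of degree, with ties detected at the reporting precision and
shown in shared-rank notation (``"3(4)"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError, DomainError
from .sequences import (
    Sequence,
    initial_image,
    lag_align,
    mean_image,
    zero_start_image,
)

__all__ = [
    "GreyConfig",
    "DegreeTable",
    "grey_coefficients",
    "deng_degree",
    "absolute_degree",
    "relative_degree",
    "sdgra",
    "ssgra",
    "rank_factors",
    "run_all_models",
]

MODELS = ("deng", "sdgra", "ssgra", "absolute", "relative")


@dataclass(frozen=True)
class GreyConfig:
    """Tunable parameters of a grey incidence run.

    epsilon : resolution coefficient in (0, 1]; damps the influence of the
        maximum deviation.  0.5 is the conventional middle value.
    theta : weight of the absolute degree inside SDGRA, in [0, 1].
    rounding : decimal places used for reported degrees and for tie
        detection; ranks themselves are computed on unrounded values first,
        then ties are merged at this precision.
    """

    epsilon: float = 0.5
    theta: float = 0.5
    rounding: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon <= 1.0:
            raise DomainError(f"epsilon must be in (0, 1], got {self.epsilon}")
        if not 0.0 <= self.theta <= 1.0:
            raise DomainError(f"theta must be in [0, 1], got {self.theta}")
        if self.rounding < 0:
            raise DomainError(f"rounding must be non-negative, got {self.rounding}")


def _check_aligned(reference: Sequence, comparison: Sequence) -> None:
    if len(reference) != len(comparison) or np.any(
        reference.years != comparison.years
    ):
        raise AlignmentError(
            f"{reference.name!r} and {comparison.name!r} are not aligned"
        )


def _deviations(reference: Sequence, comparisons: Iterable[Sequence]) -> list[np.ndarray]:
    ref_img = mean_image(reference).values
    return [np.abs(ref_img - mean_image(c).values) for c in comparisons]


def grey_coefficients(
    reference: Sequence,
    comparison: Sequence,
    epsilon: float = 0.5,
    pool: Iterable[Sequence] | None = None,
) -> np.ndarray:
    """Pointwise grey relational coefficients of one comparison sequence.

    ``pool`` supplies the full set of comparison sequences of the run over
    which the two-level min/max is taken; by default the single comparison is
    its own pool (the two scopes then coincide).  Coefficients lie in (0, 1]
    and equal 1 exactly where the deviation attains the global minimum.  If
    every deviation is zero (identical mean images) all coefficients are 1 by
    the limiting convention.
    """
    _check_aligned(reference, comparison)
    pool_seqs = [comparison] if pool is None else list(pool)
    for p in pool_seqs:
        _check_aligned(reference, p)
    deltas = _deviations(reference, pool_seqs)
    delta_min = min(float(d.min()) for d in deltas)
    delta_max = max(float(d.max()) for d in deltas)
    delta_self = np.abs(mean_image(reference).values - mean_image(comparison).values)
    # Mean images live on a unit scale, so deviations below 1e-12 are pure
    # roundoff; without this guard the coefficients become ratios of noise
    # when every pooled comparison is (numerically) proportional to the
    # reference.  Limiting value: perfect incidence, all coefficients 1.
    if delta_max < 1e-12:
        return np.ones_like(delta_self)
    return (delta_min + epsilon * delta_max) / (delta_self + epsilon * delta_max)


def deng_degree(
    reference: Sequence,
    comparison: Sequence,
    config: GreyConfig = GreyConfig(),
    pool: Iterable[Sequence] | None = None,
) -> float:
    """Deng's degree of grey incidence: the mean pointwise coefficient.

    Lies in (0, 1]; equals 1 iff the mean images coincide, hence invariant
    under positive rescaling of either sequence.
    """
    return float(np.mean(grey_coefficients(reference, comparison, config.epsilon, pool)))


def _area_signature(zero_start_values: np.ndarray) -> float:
    # s = sum of interior points + half the final point, on a zero-start image
    return float(np.sum(zero_start_values[1:-1]) + 0.5 * zero_start_values[-1])


def absolute_degree(reference: Sequence, comparison: Sequence) -> float:
    """Absolute degree of grey incidence (area-based, scale-sensitive).

    Computed on zero-start images of the inputs as received; run_all_models
    passes the raw sequences, so series with very different magnitudes of
    change score near 0.5.
    """
    _check_aligned(reference, comparison)
    s0 = _area_signature(zero_start_image(reference).values)
    si = _area_signature(zero_start_image(comparison).values)
    return (1.0 + abs(s0) + abs(si)) / (1.0 + abs(s0) + abs(si) + abs(si - s0))


def relative_degree(reference: Sequence, comparison: Sequence) -> float:
    """Relative degree: the absolute construction on initial-value images.

    Scale-free; equals 1 for proportional sequences (same rates of change).
    """
    return absolute_degree(initial_image(reference), initial_image(comparison))


def _check_degree(value: float, label: str) -> None:
    if not 0.0 < value <= 1.0:
        raise DomainError(f"{label} must lie in (0, 1], got {value}")


def sdgra(absolute: float, relative: float, theta: float = 0.5) -> float:
    """Synthetic degree: theta·absolute + (1−theta)·relative."""
    _check_degree(absolute, "absolute degree")
    _check_degree(relative, "relative degree")
    if not 0.0 <= theta <= 1.0:
        raise DomainError(f"theta must be in [0, 1], got {theta}")
    return theta * absolute + (1.0 - theta) * relative


def ssgra(deng: float, absolute: float) -> float:
    """Second synthetic degree: mean of Deng's and absolute degrees."""
    _check_degree(deng, "Deng's degree")
    _check_degree(absolute, "absolute degree")
    return 0.5 * (deng + absolute)


def rank_factors(
    degrees: Mapping[str, float],
    rounding: int = 3,
) -> dict[str, str]:
    """Rank factors by descending degree, sharing ranks for rounded ties.

    Degrees equal after rounding to ``rounding`` decimals occupy consecutive
    sort positions and share the notation ``"r(r+1)"`` (extended as
    ``"r(r+1)(r+2)"`` for larger tie groups).  Distinct values get plain
    ``"1"``, ``"2"``, ...
    """
    if not degrees:
        raise ConfigurationError("rank_factors needs at least one degree")
    rounded = {f: round(v, rounding) for f, v in degrees.items()}
    order = sorted(degrees, key=lambda f: -degrees[f])
    position = {f: i + 1 for i, f in enumerate(order)}
    ranks: dict[str, str] = {}
    for f in order:
        tied = sorted(position[g] for g in order if rounded[g] == rounded[f])
        ranks[f] = str(tied[0]) + "".join(f"({p})" for p in tied[1:])
    return ranks


@dataclass(frozen=True)
class DegreeTable:
    """Per-factor degrees under the five incidence models, plus ranks.

    ``degrees`` holds unrounded values (factors × models); ``ranks`` holds
    the shared-rank strings computed at the config's reporting precision.
    The identities ``sdgra = θ·absolute + (1−θ)·relative`` and
    ``ssgra = (deng + absolute)/2`` hold exactly on the unrounded values.
    """

    degrees: pd.DataFrame
    ranks: pd.DataFrame
    config: GreyConfig
    lag: int = 0

    def rounded(self) -> pd.DataFrame:
        """Reporting view: degree and rank column per model, degrees rounded."""
        out = pd.DataFrame(index=self.degrees.index)
        for model in MODELS:
            out[model] = self.degrees[model].round(self.config.rounding)
            out[f"{model}_rank"] = self.ranks[model]
        return out

    def to_csv(self, path: str) -> None:
        fmt = f"%.{self.config.rounding}f"
        self.rounded().to_csv(path, float_format=fmt, index_label="factor")


def run_all_models(
    reference: Sequence,
    comparisons: Iterable[Sequence],
    config: GreyConfig = GreyConfig(),
    lag: int = 0,
) -> DegreeTable:
    """Compute all five degrees and per-model ranks for a factor set.

    Preprocessing per variant: Deng's degree consumes mean images (computed
    inside :func:`grey_coefficients`), the absolute degree consumes the raw
    aligned sequences (zero-start applied internally), and the relative
    degree consumes initial-value images.  The synthetic degrees are exact
    combinations of the other three, computed on unrounded values.
    """
    comparisons = tuple(comparisons)
    if not comparisons:
        raise ConfigurationError("run_all_models needs at least one comparison")
    ref, comps = lag_align(reference, comparisons, lag)
    rows = {}
    for comp in comps:
        deng = deng_degree(ref, comp, config, pool=comps)
        absolute = absolute_degree(ref, comp)
        relative = relative_degree(ref, comp)
        rows[comp.name] = {
            "deng": deng,
            "sdgra": sdgra(absolute, relative, config.theta),
            "ssgra": ssgra(deng, absolute),
            "absolute": absolute,
            "relative": relative,
        }
    degrees = pd.DataFrame.from_dict(rows, orient="index")[list(MODELS)]
    ranks = pd.DataFrame(
        {
            model: pd.Series(rank_factors(degrees[model].to_dict(), config.rounding))
            for model in MODELS
        }
    ).loc[degrees.index]
    return DegreeTable(degrees=degrees, ranks=ranks, config=config, lag=lag)
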