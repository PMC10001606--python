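"""Seed-reproducible synthetic annual panels for the Macao-style analysis.

The generator emulates the statistical structure of a 20-year (2001–2020)
two-group (male/female) annual panel of circulatory-system-disease mortality
and its candidate factors:

* physician density: a rising linear trend around 2.4 per 1,000 with small
  Gaussian jitter;
* income per capita: smooth exponential growth (strictly increasing);
* smoking rate: piecewise-linear per group — near-flat around 33% for men,
  a low (~2%) series for women with a kink at the ban year after which it
  roughly halves by the end of the panel;
* mortality: a linear function of physician density plus a group-specific
  post-ban shift plus Gaussian noise,

  mortality(g, t) = α + β_physician·physician(t)
                    + β_ban·1[g = ban group, t ≥ ban year] + ε,  ε ~ N(0, σ²).

The defaults mirror the magnitudes of the study population (group mortality
≈ 43–44 per 100k, physician density ≈ 2.4, β_physician = −9, β_ban = −5) and
σ is fixed so that the default full regression's R² lands near 0.28.  A
:class:`SyntheticPanel` carries the exact :class:`SyntheticSpec` that
generated it, so any panel is regenerable bit-exactly from its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "TrendPath",
    "SyntheticSpec",
    "SyntheticPanel",
    "simulate_panel",
    "planted_rank_scenario",
]


@dataclass(frozen=True)
class TrendPath:
    """Piecewise-linear path: baseline at the first year, a slope before the
    kink year and another after it (equal slopes = plain linear)."""

    baseline: float
    pre_slope: float = 0.0
    post_slope: float = 0.0

    def values(self, years: np.ndarray, kink_year: int) -> np.ndarray:
        t = np.asarray(years, dtype=float)
        y0 = t[0]
        pre = self.baseline + self.pre_slope * (t - y0)
        level_at_kink = self.baseline + self.pre_slope * (kink_year - 1 - y0)
        post = level_at_kink + self.post_slope * (t - (kink_year - 1))
        return np.where(t < kink_year, pre, post)


DEFAULT_SMOKING_PATHS: Mapping[str, TrendPath] = {
    "male": TrendPath(baseline=33.8, pre_slope=-0.05, post_slope=-0.05),
    "female": TrendPath(baseline=2.6, pre_slope=-0.02, post_slope=-0.16),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of a synthetic panel.

    Units: mortality per 100,000; physician density per 1,000 people;
    smoking/alcohol/overweight rates in %; income in 1,000 MOP.
    """

    start_year: int = 2001
    end_year: int = 2020
    groups: tuple[str, ...] = ("male", "female")
    ban_year: int = 2012
    ban_group: str = "female"
    alpha: float = 67.9
    beta_physician: float = -9.0
    beta_ban: float = -5.0
    noise_sd: float = 7.5
    smoking_paths: Mapping[str, TrendPath] = field(
        default_factory=lambda: dict(DEFAULT_SMOKING_PATHS)
    )
    physician_baseline: float = 2.0
    physician_slope: float = 0.047
    physician_jitter_sd: float = 0.02
    income_baseline: float = 150.0
    income_growth: float = 0.07
    include_extra_factors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year - self.start_year + 1 < 3:
            raise DomainError("need at least 3 years")
        if not self.start_year <= self.ban_year <= self.end_year:
            raise DomainError(
                f"ban year {self.ban_year} outside panel years "
                f"{self.start_year}-{self.end_year}"
            )
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.ban_group not in self.groups:
            raise DomainError(f"ban group {self.ban_group!r} not among groups")
        missing = [g for g in self.groups if g not in self.smoking_paths]
        if missing:
            raise DomainError(f"no smoking path for group(s) {missing}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1, dtype=np.int64)


@dataclass(frozen=True)
class SyntheticPanel:
    """Tidy generated panel plus the ground truth that produced it."""

    frame: pd.DataFrame
    ground_truth: SyntheticSpec


# Extra-factor anchors for the robustness scenario (four-wave style variables
# extended to annual paths): male alcohol high and flat, female alcohol slowly
# rising; male overweight rising steeply, female flat.
_EXTRA_PATHS: Mapping[str, Mapping[str, TrendPath]] = {
    "alcohol": {
        "male": TrendPath(baseline=44.5, pre_slope=0.2, post_slope=0.05),
        "female": TrendPath(baseline=10.2, pre_slope=0.45, post_slope=0.45),
    },
    "overweight": {
        "male": TrendPath(baseline=29.1, pre_slope=1.4, post_slope=0.4),
        "female": TrendPath(baseline=38.6, pre_slope=-0.1, post_slope=0.35),
    },
}


def _covariate_paths(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    years = spec.years
    t = (years - spec.start_year).astype(float)
    physician = (
        spec.physician_baseline
        + spec.physician_slope * t
        + rng.normal(0.0, spec.physician_jitter_sd, size=len(years))
    )
    income = spec.income_baseline * np.exp(spec.income_growth * t)
    smoking = {
        g: np.clip(spec.smoking_paths[g].values(years, spec.ban_year), 0.0, 100.0)
        for g in spec.groups
    }
    return physician, income, smoking


def _assemble(
    spec: SyntheticSpec,
    physician: np.ndarray,
    income: np.ndarray,
    smoking: Mapping[str, np.ndarray],
    mortality: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    years = spec.years
    records = []
    for g in spec.groups:
        block = pd.DataFrame(
            {
                "year": years,
                "group": g,
                "mortality": mortality[g],
                "income": income,
                "physician": physician,
                "smoking": smoking[g],
            }
        )
        if spec.include_extra_factors:
            for name, paths in _EXTRA_PATHS.items():
                path = paths.get(g, TrendPath(baseline=30.0))
                block[name] = np.clip(path.values(years, spec.ban_year), 0.0, 100.0)
        records.append(block)
    return pd.concat(records, ignore_index=True)


def simulate_panel(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticPanel:
    """Generate one panel under the default mortality model.

    Same spec (including seed) ⇒ bit-identical panel.  With ``noise_sd = 0``
    the female-minus-male mortality gap changes by exactly ``beta_ban``
    between pre- and post-ban periods, since all other terms are shared.
    """
    rng = np.random.default_rng(spec.seed)
    physician, income, smoking = _covariate_paths(spec, rng)
    years = spec.years
    ban = (years >= spec.ban_year).astype(float)
    mortality = {}
    for g in spec.groups:
        signal = spec.alpha + spec.beta_physician * physician
        if g == spec.ban_group:
            signal = signal + spec.beta_ban * ban
        mortality[g] = signal + rng.normal(0.0, spec.noise_sd, size=len(years))
    return SyntheticPanel(
        frame=_assemble(spec, physician, income, smoking, mortality),
        ground_truth=spec,
    )


def planted_rank_scenario(
    dominant_factor: str,
    spec: SyntheticSpec = SyntheticSpec(),
    mortality_scale: float = 43.5,
) -> SyntheticPanel:
    """Generate a panel whose mortality co-moves with one chosen factor.

    Per group, mortality is a positive multiple of the dominant factor's
    series (rescaled to the mortality level) perturbed by *multiplicative*
    Gaussian noise with relative sd ``noise_sd / alpha`` — so the co-movement
    is in mean-image geometry, which is what the incidence degrees measure.
    The remaining factors keep their independent trends.  With zero noise the
    dominant factor is exactly proportional to mortality, so its Deng and
    relative degrees equal 1.
    """
    rng = np.random.default_rng(spec.seed)
    physician, income, smoking = _covariate_paths(spec, rng)
    factor_series: dict[str, Mapping[str, np.ndarray] | np.ndarray] = {
        "income": income,
        "physician": physician,
        "smoking": smoking,
    }
    if dominant_factor not in factor_series:
        raise ConfigurationError(
            f"unknown dominant factor {dominant_factor!r}; "
            f"choose from {sorted(factor_series)}"
        )
    rel_sd = spec.noise_sd / spec.alpha
    mortality = {}
    for g in spec.groups:
        series = factor_series[dominant_factor]
        base = series[g] if isinstance(series, Mapping) else series
        scale = mortality_scale / float(np.mean(base))
        noise = rng.normal(0.0, rel_sd, size=len(base)) if rel_sd > 0 else 0.0
        mortality[g] = scale * base * (1.0 + noise)
    return SyntheticPanel(
        frame=_assemble(spec, physician, income, smoking, mortality),
        ground_truth=spec,
    )


def wide_frame(panel: SyntheticPanel) -> pd.DataFrame:
    """Pivot a tidy panel to the loader's wide dialect (``mortality_male``...)."""
    df = panel.frame
    value_cols = [c for c in df.columns if c not in ("year", "group")]
    wide = df.pivot(index="year", columns="group", values=value_cols)
    wide.columns = [f"{var}_{grp}" for var, grp in wide.columns]
    return wide.reset_index()


def spec_to_dict(spec: SyntheticSpec) -> dict:
    """Flatten a spec to plain scalars for the ground-truth sidecar file."""
    out: dict = {
        "start_year": spec.start_year,
        "end_year": spec.end_year,
        "groups": list(spec.groups),
        "ban_year": spec.ban_year,
        "ban_group": spec.ban_group,
        "alpha": spec.alpha,
        "beta_physician": spec.beta_physician,
        "beta_ban": spec.beta_ban,
        "noise_sd": spec.noise_sd,
        "physician_baseline": spec.physician_baseline,
        "physician_slope": spec.physician_slope,
        "physician_jitter_sd": spec.physician_jitter_sd,
        "income_baseline": spec.income_baseline,
        "income_growth": spec.income_growth,
        "include_extra_factors": spec.include_extra_factors,
        "seed": spec.seed,
    }
    for g, p in spec.smoking_paths.items():
        out[f"smoking_{g}"] = [p.baseline, p.pre_slope, p.post_slope]
    return out


def spec_from_dict(data: Mapping) -> SyntheticSpec:
    """Rebuild a spec from the flat ground-truth mapping."""
    paths = {
        key.removeprefix("smoking_"): TrendPath(*value)
        for key, value in data.items()
        if key.startswith("smoking_")
    }
    kwargs = {
        k: v
        for k, v in data.items()
        if not k.startswith("smoking_")
    }
    kwargs["groups"] = tuple(kwargs.get("groups", ("male", "female")))
    return replace(SyntheticSpec(**kwargs), smoking_paths=paths)
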