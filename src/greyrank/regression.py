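"""OLS stage: intervention-dummy regression with bootstrap SEs and RESET.

The regression estimates the size of the association that the grey incidence
ranking only orders: annual CSD mortality per 100,000 (stacked male + female
rows) on smoking rate and physician density, plus a "female after ban" dummy
equal to 1 for female observations from the ban year (2012, inclusive)
onward.  The dummy's coefficient is the excess post-ban change in female
mortality.

Because the stacked panel is small (n = 40), standard errors come from a
nonparametric case-resampling bootstrap — whole (year, group) rows resampled
with replacement — rather than the asymptotic covariance.  The Ramsey RESET
test (powers 2–4 of the fitted values, so 3 added regressors) serves as the
specification diagnostic.  No autocorrelation correction is applied; see the
methods note for why this is a known limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import linear_reset

from .exceptions import ConfigurationError, DomainError, ResamplingError

__all__ = [
    "RegressionSpec",
    "RegressionResult",
    "build_design",
    "fit_ols",
    "bootstrap_se",
    "reset_test",
    "describe",
    "run_regression",
    "annual_reduction_share",
]

#: p-value thresholds for the significance stars in formatted output.
STAR_LEVELS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))

_RESET_POWERS = 4  # powers 2..4 of fitted values -> 3 added regressors
_MAX_REDRAW_FACTOR = 100


@dataclass(frozen=True)
class RegressionSpec:
    """Configuration of one regression specification."""

    outcome: str = "mortality"
    covariates: tuple[str, ...] = ("smoking", "physician")
    ban_year: int = 2012
    ban_group: str = "female"
    include_dummy: bool = True
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise DomainError(
                f"bootstrap_reps must be >= 1, got {self.bootstrap_reps}"
            )


@dataclass(frozen=True)
class RegressionResult:
    """Coefficients, bootstrap SEs, fit quality and RESET diagnostic."""

    coefficients: "pd.Series[float]"
    bootstrap_se: "pd.Series[float]"
    r_squared: float
    n_obs: int
    reset_F: float
    reset_df: tuple[int, int]
    reset_p: float
    degenerate_resamples: int = 0

    def stars(self) -> dict[str, str]:
        """Significance stars from normal-approximation bootstrap z-tests."""
        out = {}
        for term in self.coefficients.index:
            se = self.bootstrap_se[term]
            if se == 0:
                out[term] = ""
                continue
            z = self.coefficients[term] / se
            p = 2.0 * scipy.stats.norm.sf(abs(z))
            out[term] = next((s for thr, s in STAR_LEVELS if p < thr), "")
        return out

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "bootstrap_se": self.bootstrap_se.to_dict(),
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
            "reset_F": self.reset_F,
            "reset_df": list(self.reset_df),
            "reset_p": self.reset_p,
            "degenerate_resamples": self.degenerate_resamples,
        }


def build_design(
    panel: pd.DataFrame,
    spec: RegressionSpec,
    dummy_name: str = "female_after_ban",
) -> tuple[pd.DataFrame, pd.Series]:
    """Stack (year, group) rows into a design matrix and outcome vector.

    ``panel`` is tidy/long: columns ``year``, ``group``, the outcome, and the
    covariates.  The intervention dummy is 1 iff ``group == spec.ban_group``
    and ``year >= spec.ban_year`` (the ban year itself counts as treated).
    An intercept column ``const`` is always included.
    """
    needed = ["year", "group", spec.outcome, *spec.covariates]
    missing = [c for c in needed if c not in panel.columns]
    if missing:
        raise ConfigurationError(f"panel missing column(s) {missing}")
    if spec.include_dummy and spec.ban_group not in set(panel["group"]):
        raise ConfigurationError(
            f"ban group {spec.ban_group!r} absent from panel groups"
        )
    panel = panel.sort_values(["group", "year"]).reset_index(drop=True)
    X = panel[list(spec.covariates)].astype(float).copy()
    if spec.include_dummy:
        X[dummy_name] = (
            (panel["group"] == spec.ban_group) & (panel["year"] >= spec.ban_year)
        ).astype(float)
    X = sm.add_constant(X, prepend=False)
    y = panel[spec.outcome].astype(float)
    return X, y


def fit_ols(design: pd.DataFrame, outcome: pd.Series):
    """Ordinary least squares via statsmodels; errors on rank deficiency."""
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ConfigurationError("design matrix is rank deficient")
    if len(outcome) <= design.shape[1]:
        raise ConfigurationError("need more observations than parameters")
    return sm.OLS(outcome.to_numpy(), design).fit()


def bootstrap_se(
    design: pd.DataFrame,
    outcome: pd.Series,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[pd.Series, int]:
    """Case-resampling bootstrap standard errors of the OLS coefficients.

    Rows are resampled with replacement (size n) and the model refit; the SE
    of each term is the standard deviation of its estimates across the
    ``reps`` refits.  Rank-deficient resamples are redrawn (their count is
    returned); if redraws keep failing a :class:`ResamplingError` is raised.
    Identical seeds give bit-identical output.
    """
    if reps < 2:
        raise DomainError(f"bootstrap reps must be >= 2, got {reps}")
    X = design.to_numpy(dtype=np.float64)
    y = outcome.to_numpy(dtype=np.float64)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    estimates = np.empty((reps, p))
    degenerate = 0
    max_draws = _MAX_REDRAW_FACTOR * reps
    draws = 0
    done = 0
    while done < reps:
        if draws >= max_draws:
            raise ResamplingError(
                f"{degenerate} rank-deficient resamples; giving up after "
                f"{draws} draws"
            )
        idx = rng.integers(0, n, size=n)
        draws += 1
        Xb = X[idx]
        if np.linalg.matrix_rank(Xb) < p:
            degenerate += 1
            continue
        estimates[done] = np.linalg.lstsq(Xb, y[idx], rcond=None)[0]
        done += 1
    se = pd.Series(estimates.std(axis=0, ddof=1), index=design.columns)
    return se, degenerate


def reset_test(
    design: pd.DataFrame, outcome: pd.Series
) -> tuple[float, tuple[int, int], float]:
    """Ramsey RESET: F-test of powers 2–4 of the fitted values.

    Returns ``(F, (df_num, df_denom), p)`` with ``df_num = 3`` and
    ``df_denom = n − p − 3``.  A numerically perfect fit (zero residual
    variance) makes the test degenerate; it is then reported as no evidence
    of misspecification (F = 0, p = 1).
    """
    n, p = design.shape
    df_num = _RESET_POWERS - 1
    df_denom = n - p - df_num
    if df_denom < 1:
        raise DomainError(
            f"insufficient denominator df ({df_denom}) for RESET at n={n}, p={p}"
        )
    res = fit_ols(design, outcome)
    ssr_scale = float(np.mean(res.fittedvalues**2)) + 1.0
    if res.ssr <= 1e-10 * ssr_scale * n:
        return 0.0, (df_num, df_denom), 1.0
    with warnings.catch_warnings():
        # powers 2-4 of fitted values are often near-collinear on short
        # annual panels; statsmodels warns but the F statistic is well defined
        warnings.simplefilter("ignore")
        out = linear_reset(res, power=_RESET_POWERS, test_type="fitted", use_f=True)
    return float(out.fvalue), (df_num, df_denom), float(out.pvalue)


def describe(
    panel: pd.DataFrame | Mapping[str, TypingSequence[float]],
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-variable mean, standard error, and t-based confidence interval.

    SE = sd/√n with the sample sd (ddof 1); the interval is
    mean ± t(1−α/2, n−1)·SE.  Constant series collapse to the point.
    """
    df = pd.DataFrame(panel)
    rows = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=np.float64)
        n = len(x)
        if n < 2:
            raise DomainError(f"variable {col!r}: need >= 2 observations")
        mean = float(np.mean(x))
        se = float(np.std(x, ddof=1) / np.sqrt(n))
        half = float(scipy.stats.t.ppf(0.5 + level / 2.0, n - 1) * se)
        rows[col] = {
            "mean": mean,
            "std_err": se,
            "ci_low": mean - half,
            "ci_high": mean + half,
            "n": n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def run_regression(panel: pd.DataFrame, spec: RegressionSpec) -> RegressionResult:
    """Fit one specification end to end: OLS, bootstrap SEs, RESET."""
    X, y = build_design(panel, spec)
    res = fit_ols(X, y)
    se, degenerate = bootstrap_se(X, y, spec.bootstrap_reps, spec.seed)
    F, df, pval = reset_test(X, y)
    return RegressionResult(
        coefficients=pd.Series(res.params, index=X.columns),
        bootstrap_se=se,
        r_squared=float(res.rsquared),
        n_obs=len(y),
        reset_F=F,
        reset_df=df,
        reset_p=pval,
        degenerate_resamples=degenerate,
    )


def annual_reduction_share(deaths_avoided: float, mean_mortality: float) -> float:
    """Avoided deaths as a percentage of the mean annual mortality rate.

    Both arguments are per-100,000 rates; e.g. 5 avoided deaths against a
    mean female CSD mortality of 43.66 is 11.45%.
    """
    if mean_mortality <= 0:
        raise DomainError("mean mortality must be positive")
    return 100.0 * deaths_avoided / mean_mortality
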