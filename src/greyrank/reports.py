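"""Report writers and the end-to-end pipeline.

The pipeline reproduces the study workflow on one tidy panel: descriptive
statistics, the five-model degree table per group at lag 0 and lag 1, an
extended-factor robustness table when alcohol/overweight columns are
present, and the three regression specifications (baseline, full with the
female-after-ban dummy, and dummy-without-smoking).  Every table is written
both as CSV and as a human-readable text rendering; numbers in the text
rendering equal their CSV counterparts after the declared rounding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import GreyRankError
from .incidence import MODELS, DegreeTable, GreyConfig, run_all_models
from .regression import (
    RegressionResult,
    RegressionSpec,
    describe,
    run_regression,
)
from .sequences import PanelGroup, load_panel

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "format_degree_table",
           "format_regression"]

log = logging.getLogger("greyrank")

BASE_FACTORS = ("income", "physician", "smoking")
EXTRA_FACTORS = ("alcohol", "overweight")


class PipelineError(GreyRankError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run."""

    input_path: str
    outdir: str
    reference: str = "mortality"
    factors: tuple[str, ...] = BASE_FACTORS
    extra_factors: tuple[str, ...] = EXTRA_FACTORS
    group: str | None = "group"
    ban_year: int = 2012
    ban_group: str = "female"
    epsilon: float = 0.5
    theta: float = 0.5
    rounding: int = 3
    bootstrap_reps: int = 1000
    seed: int = 0
    lags: tuple[int, ...] = (0, 1)


def format_degree_table(table: DegreeTable, title: str) -> str:
    """Fixed-width text rendering of a degree table, Tables 2–4 style."""
    r = table.config.rounding
    width = max(12, r + 4)
    header = [f"{'factor':<24}"] + [
        f"{m:>{width}} {'rank':>6}" for m in MODELS
    ]
    lines = [title, "".join(header)]
    view = table.rounded()
    for factor, row in view.iterrows():
        cells = [f"{factor:<24}"]
        for m in MODELS:
            cells.append(f"{row[m]:>{width}.{r}f} {row[f'{m}_rank']:>6}")
        lines.append("".join(cells))
    return "\n".join(lines) + "\n"


def format_regression(results: dict[str, RegressionResult], rounding: int = 3) -> str:
    """Side-by-side text rendering of regression columns, Table 5 style."""
    terms: list[str] = []
    for res in results.values():
        for t in res.coefficients.index:
            if t not in terms:
                terms.append(t)
    # constant goes last, as in the published layout
    terms.sort(key=lambda t: t == "const")
    lines = [f"{'variable':<20}" + "".join(f"{name:>18}" for name in results)]
    for t in terms:
        coefs, ses = [], []
        for res in results.values():
            if t in res.coefficients.index:
                star = res.stars()[t]
                coefs.append(f"{res.coefficients[t]:.{rounding}f}{star}")
                ses.append(f"({res.bootstrap_se[t]:.{rounding}f})")
            else:
                coefs.append("")
                ses.append("")
        lines.append(f"{t:<20}" + "".join(f"{c:>18}" for c in coefs))
        lines.append(f"{'':<20}" + "".join(f"{s:>18}" for s in ses))
    lines.append(
        f"{'observations':<20}"
        + "".join(f"{res.n_obs:>18d}" for res in results.values())
    )
    lines.append(
        f"{'r_squared':<20}"
        + "".join(f"{res.r_squared:>18.{rounding}f}" for res in results.values())
    )
    lines.append(
        f"{'RESET':<20}"
        + "".join(
            f"{'F(%d, %d)=%.2f' % (*res.reset_df, res.reset_F):>18}"
            for res in results.values()
        )
    )
    lines.append(
        f"{'RESET p':<20}"
        + "".join(f"{res.reset_p:>18.{rounding}f}" for res in results.values())
    )
    lines.append("bootstrap SEs in parentheses; *** p<0.01, ** p<0.05, * p<0.1")
    return "\n".join(lines) + "\n"


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except GreyRankError as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("load_panel")
def _load(config: RunConfig, factors: tuple[str, ...]):
    return load_panel(
        config.input_path, config.reference, list(factors), group=config.group
    )


@_stage("rank")
def _rank(groups: dict[str, PanelGroup], grey: GreyConfig, lag: int):
    return {
        name: run_all_models(pg.reference, pg.factors, grey, lag=lag)
        for name, pg in groups.items()
    }


@_stage("regress")
def _regress(frame: pd.DataFrame, config: RunConfig) -> dict[str, RegressionResult]:
    common = dict(
        outcome=config.reference,
        ban_year=config.ban_year,
        ban_group=config.ban_group,
        bootstrap_reps=config.bootstrap_reps,
    )
    specs = {
        "baseline": RegressionSpec(
            covariates=("smoking", "physician"), include_dummy=False,
            seed=config.seed, **common,
        ),
        "full": RegressionSpec(
            covariates=("smoking", "physician"), include_dummy=True,
            seed=config.seed + 1, **common,
        ),
        "no_smoking": RegressionSpec(
            covariates=("physician",), include_dummy=True,
            seed=config.seed + 2, **common,
        ),
    }
    return {name: run_regression(frame, spec) for name, spec in specs.items()}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run describe → rank (per lag) → robustness rank → regress.

    Returns a mapping from artifact name to written path.  Two runs with the
    same config and seed produce byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grey = GreyConfig(config.epsilon, config.theta, config.rounding)
    log.info(
        "pipeline: input=%s seed=%d epsilon=%g theta=%g reps=%d",
        config.input_path, config.seed, config.epsilon, config.theta,
        config.bootstrap_reps,
    )
    artifacts: dict[str, Path] = {}

    frame = pd.read_csv(config.input_path)
    groups = _load(config, config.factors)

    # descriptive statistics per group
    desc_frames = []
    for name, sub in (frame.groupby(config.group) if config.group else [("", frame)]):
        numeric = sub.drop(columns=[config.group] if config.group else [])
        numeric = numeric.drop(columns=["year"], errors="ignore")
        d = describe(numeric.select_dtypes("number"))
        d.insert(0, "group", name)
        desc_frames.append(d)
    desc = pd.concat(desc_frames)
    path = outdir / "describe.csv"
    desc.to_csv(path, float_format="%.4f", index_label="variable")
    artifacts["describe"] = path

    # degree tables per lag
    text_chunks = []
    for lag in config.lags:
        tables = _rank(groups, grey, lag)
        for gname, table in tables.items():
            tag = f"rank_lag{lag}" + (f"_{gname}" if gname else "")
            p = outdir / f"{tag}.csv"
            table.to_csv(str(p))
            artifacts[tag] = p
            text_chunks.append(
                format_degree_table(table, f"== degrees (group={gname or 'all'}, lag={lag}) ==")
            )

    # robustness table with extended factors, when present
    extra_present = [c for c in config.extra_factors if c in frame.columns]
    if len(extra_present) == len(config.extra_factors):
        extended = _load(config, config.factors + tuple(extra_present))
        tables = _rank(extended, grey, 0)
        for gname, table in tables.items():
            tag = "rank_extended" + (f"_{gname}" if gname else "")
            p = outdir / f"{tag}.csv"
            table.to_csv(str(p))
            artifacts[tag] = p
            text_chunks.append(
                format_degree_table(table, f"== extended degrees (group={gname or 'all'}) ==")
            )
    else:
        log.info("robustness table skipped: columns %s not all present",
                 list(config.extra_factors))

    # regressions (need both sexes stacked)
    results = _regress(frame, config)
    path = outdir / "regression.json"
    path.write_text(
        json.dumps({k: v.to_dict() for k, v in results.items()}, indent=2,
                   sort_keys=True)
        + "\n"
    )
    artifacts["regression"] = path
    text_chunks.append(format_regression(results, config.rounding))

    report = outdir / "report.txt"
    report.write_text("\n".join(text_chunks))
    artifacts["report"] = report
    return artifacts
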