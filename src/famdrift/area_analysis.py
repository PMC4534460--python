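"""Log-linear analysis of the estimated counts, and the pipeline driver.

Once every family has an estimated bias direction, the per-area counts of
A-biased vs E-biased families (families with no bias signal are excluded:
they argue neither for nor against a directed preference) form a
5 x 2 contingency table.  Poisson log-linear models test

* the area x direction interaction: deviance difference between the
  saturated model and {area + direction}, chi-square with 4 df, and
* the direction term: deviance difference between the saturated model and
  {area} alone, chi-square with 5 df,

and one-sided exact binomial tests within each area resolve the
interaction.  Mean counts are rounded half-up to integers before testing;
a flag lets the non-integer means enter the deviance directly instead.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import binomtest, chi2

from . import __version__
from .corpus import group_families, read_database
from .extrapolation import (
    AreaBiasSummary,
    combine_counts,
    estimate_area_model,
    extrapolate,
)
from .setbias import AGAINST, TOWARD, classify_large_families
from .treebias import classify_large_families_tree


@dataclass
class TestResult:
    name: str
    statistic: float
    df: int
    p_value: float


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def _direction_table(counts: AreaBiasSummary, round_counts: bool) -> pd.DataFrame:
    tab = counts.mean[[AGAINST, TOWARD]].copy()
    if round_counts:
        tab.loc[:, :] = _round_half_up(tab.values)
    return tab


def loglinear_tests(
    counts: AreaBiasSummary, round_counts: bool = True
) -> tuple[TestResult, TestResult]:
    """LR tests of the area x direction interaction and of the direction term.

    Fits Poisson log-linear models to the (area x {A, E}) count table via
    iteratively reweighted least squares and compares deviances of the
    nested models {area} < {area + direction} < {area x direction}.
    """
    tab = _direction_table(counts, round_counts)
    if (tab.sum(axis=1) == 0).any():
        warnings.warn("an area has zero A+E count; tests run on zero cells")
    long = tab.stack().rename("count").reset_index()
    long.columns = ["area", "direction", "count"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-count cells trigger benign domain warnings
        dev_add = smf.glm("count ~ C(area) + C(direction)", data=long,
                          family=sm.families.Poisson()).fit().deviance
        dev_area = smf.glm("count ~ C(area)", data=long,
                           family=sm.families.Poisson()).fit().deviance
    # the saturated model reproduces the table exactly: deviance 0
    n_area = tab.shape[0]
    df_int = n_area - 1
    df_bias = n_area
    interaction = TestResult("LR interaction area x direction", float(dev_add),
                             df_int, float(chi2.sf(dev_add, df_int)))
    bias = TestResult("LR bias direction", float(dev_area),
                      df_bias, float(chi2.sf(dev_area, df_bias)))
    return interaction, bias


def binomial_per_area(
    counts: AreaBiasSummary,
    alternative: str = "one-sided",
    round_counts: bool = True,
) -> list[TestResult]:
    """Exact binomial test of A vs E counts within each area.

    Counts are rounded half-up to integers.  ``alternative="one-sided"``
    (default) takes the minority direction's lower tail — the probability of
    a split at least as lopsided toward the observed majority; "two-sided"
    is the symmetric test.  ``df`` reports the number of trials (A+E).
    """
    tab = _direction_table(counts, round_counts)
    out = []
    for area, row in tab.iterrows():
        a, e = int(row[AGAINST]), int(row[TOWARD])
        n = a + e
        if n == 0:
            warnings.warn(f"area {area!r}: A+E rounds to 0; test skipped")
            continue
        k_min = min(a, e)
        if alternative == "one-sided":
            p = binomtest(k_min, n, 0.5, alternative="less").pvalue
        else:
            p = binomtest(k_min, n, 0.5).pvalue
        dominant = AGAINST if a >= e else TOWARD
        out.append(TestResult(f"binomial[{area}] {dominant}-dominant",
                              float(k_min), n, float(p)))
    return out


@dataclass
class PipelineConfig:
    db_path: str
    taxonomy: str = "autotyp"
    engine: str = "set"  # set | ml | mcmc
    cutoff: int = 5
    n_reps: int = 10_000
    seed: int = 0
    out_dir: str | None = None
    alpha: float = 0.05
    strict: bool = True
    round_counts: bool = True
    binomial_alternative: str = "one-sided"
    mcmc_kwargs: dict = field(default_factory=dict)


@dataclass
class PipelineReport:
    config: PipelineConfig
    summary: dict
    large_estimates: list
    area_models: dict
    small_summary: AreaBiasSummary
    totals: AreaBiasSummary
    interaction: TestResult
    bias: TestResult
    per_area: list[TestResult]


def _estimates_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": e.family_id, "taxonomy": e.taxonomy, "area": e.area,
                "method": e.method, "direction": e.direction,
                "strength": e.strength, "evidence": e.evidence,
                "n_trials": e.n_trials,
            }
            for e in estimates
        ]
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the whole analysis: read, classify, extrapolate, test, report.

    Deterministic given the seed.  When ``config.out_dir`` is set, writes the
    per-family estimates (TSV), area models (JSON), the count table and test
    results (TSV/JSON) and a run manifest with every setting.
    """
    from .corpus import database_summary

    stage = "read"
    try:
        records = read_database(config.db_path, strict=config.strict)
        summary = database_summary(records)
        stage = "group"
        families = group_families(records, config.taxonomy, cutoff=config.cutoff)
        large = [f for f in families if f.is_large]
        small = [f for f in families if not f.is_large]
        stage = "classify-large"
        if config.engine == "set":
            large_est = classify_large_families(large, alpha=config.alpha)
        else:
            large_est = classify_large_families_tree(
                large, engine=config.engine, alpha=config.alpha,
                seed=config.seed, mcmc_kwargs=config.mcmc_kwargs,
            )
        stage = "area-models"
        areas = sorted({f.area for f in families})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            area_models = {
                a: estimate_area_model(
                    [e for e in large_est if e.area == a], a)
                for a in areas
            }
        stage = "extrapolate"
        small_summary = extrapolate(
            small, area_models, n_reps=config.n_reps, seed=config.seed)
        totals = combine_counts(large_est, small_summary)
        stage = "tests"
        interaction, bias = loglinear_tests(totals, config.round_counts)
        per_area = binomial_per_area(
            totals, alternative=config.binomial_alternative,
            round_counts=config.round_counts)
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineError(f"[{stage}] {exc}") from exc

    report = PipelineReport(
        config=config, summary=summary, large_estimates=large_est,
        area_models=area_models, small_summary=small_summary, totals=totals,
        interaction=interaction, bias=bias, per_area=per_area,
    )
    if config.out_dir is not None:
        _write_report(report, Path(config.out_dir))
    return report


def counts_long(summary: AreaBiasSummary, **extra) -> pd.DataFrame:
    rows = []
    for area in summary.areas:
        for d in summary.mean.columns:
            rows.append({"area": area, "bias": d,
                         "mean": summary.mean.loc[area, d],
                         "se": summary.se.loc[area, d],
                         "n_reps": summary.n_reps, **extra})
    return pd.DataFrame(rows)


def _write_report(report: PipelineReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    _estimates_frame(report.large_estimates).to_csv(
        out / "large_family_estimates.tsv", sep="\t", index=False)
    counts_long(report.totals, method=cfg.engine, taxonomy=cfg.taxonomy,
                seed=cfg.seed).to_csv(out / "area_counts.tsv", sep="\t", index=False)
    (out / "area_models.json").write_text(json.dumps(
        {a: dataclasses.asdict(m) for a, m in report.area_models.items()},
        indent=2))
    tests = {
        "interaction": dataclasses.asdict(report.interaction),
        "bias": dataclasses.asdict(report.bias),
        "per_area": [dataclasses.asdict(t) for t in report.per_area],
    }
    (out / "tests.json").write_text(json.dumps(tests, indent=2))
    manifest = dataclasses.asdict(cfg)
    manifest["famdrift_version"] = __version__
    manifest["database_summary"] = report.summary
    manifest["conventions"] = {
        "binomial_alternative": cfg.binomial_alternative,
        "counts_rounded_half_up": cfg.round_counts,
        "set_test": "two-sided exact binomial vs p0=0.5 on trials",
        "small_family_strength_unit": "trials",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
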