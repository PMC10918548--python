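"""Presentation artifacts and pipeline orchestration.

Produces the study-style outputs: a cohort/outcome characteristics table
(per-period counts and percentages plus outcome summaries), a segmented-
regression coefficient table for the four outcomes, and a four-panel figure
with observed monthly values, fitted segment lines, counterfactual dot-dash
extensions and vertical markers at the interruption months.
:func:`run_pipeline` chains simulate -> cohort -> indicators -> fit x4 ->
tables + figure and writes a reproducibility manifest.
"""

from __future__ import annotations

import datetime
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import claims_data, indicators, its_model, synthetic
from .claims_data import Cohort, OpioidCatalog, assign_age_group, morbidity_class
from .indicators import INDICATORS, IndicatorConfig, MonthlyIndicatorSeries, percentage
from .its_model import ITSFit, TERM_LABELS, fit_its, predict_lines

log = logging.getLogger("opioid_its.reporting")

OUTCOME_LABELS = {
    "high_dose": "Proportion of patients on high-dose opioid treatment",
    "multi_provider": ("Proportion of patients receiving opioid prescriptions "
                       "from multiple providers"),
    "overlap": "Overlap rate of opioid prescriptions per patient",
    "naloxone": "Naloxone use rate among opioid users",
}


@dataclass(frozen=True)
class PeriodDefinition:
    """Labeled calendar periods partitioning the study window.

    Defaults to pre-NIMS (Jan 2016 - Apr 2018, months 1-28), post-NIMS
    pre-COVID (May 2018 - Jan 2020, months 29-49) and post-COVID (Feb 2020 -
    Dec 2020, months 50-60).  The interruption months themselves belong to
    the post periods.
    """

    labels: tuple[str, ...] = ("pre_nims", "post_nims_pre_covid", "post_covid")
    month_ranges: tuple[tuple[int, int], ...] = ((1, 28), (29, 49), (50, 60))

    def __post_init__(self):
        if len(self.labels) != len(self.month_ranges):
            raise ValueError("labels and month_ranges must align")
        expected = 1
        for lo, hi in self.month_ranges:
            if lo != expected or hi < lo:
                raise ValueError("month ranges must partition 1..n gaplessly")
            expected = hi + 1

    @property
    def n_months(self) -> int:
        return self.month_ranges[-1][1]

    def period_of(self, month_index: int) -> str:
        for label, (lo, hi) in zip(self.labels, self.month_ranges):
            if lo <= month_index <= hi:
                return label
        raise ValueError(f"month index {month_index} outside the study window")


@dataclass
class Table1:
    """Characteristics table: formatted presentation plus raw numerics."""

    formatted: pd.DataFrame
    counts: pd.DataFrame          # tidy: block, level, period, n
    outcome_summary: pd.DataFrame


def _month_index_of(date: datetime.date, grid: Sequence[tuple[int, int]]) -> int | None:
    try:
        return grid.index((date.year, date.month)) + 1
    except ValueError:
        return None


def make_table1(cohort: Cohort, series: MonthlyIndicatorSeries,
                periods: PeriodDefinition | None = None,
                config: IndicatorConfig | None = None) -> Table1:
    """Per-period cohort characteristics and outcome summaries.

    Each patient is assigned to the period of their first in-window opioid
    fill (so the period columns partition the total).  The outcome block
    reports both the mean (SD) of monthly percentage values within the period
    and the pooled numerator/denominator proportion, since the two summaries
    need not agree.
    """
    periods = periods or PeriodDefinition()
    config = config or IndicatorConfig()
    grid = list(config.month_grid)

    first_fill: dict[str, datetime.date] = {}
    for f in cohort.opioid_fills:
        cur = first_fill.get(f.patient_id)
        if cur is None or f.start_date < cur:
            first_fill[f.patient_id] = f.start_date

    rows = []
    for p in cohort.patients:
        start = first_fill.get(p.patient_id)
        if start is None:
            continue
        mi = _month_index_of(start, grid)
        if mi is None:
            continue
        rows.append({
            "patient_id": p.patient_id,
            "period": periods.period_of(mi),
            "sex": p.sex,
            "age_group": assign_age_group(p, start.year),
            "insurance": ("NHI" if p.insurance == "NHI" else "MedAid_or_PVI"),
            "morbidity": morbidity_class(p.diagnoses) or "others",
        })
    pat = pd.DataFrame(rows, columns=["patient_id", "period", "sex", "age_group",
                                      "insurance", "morbidity"])

    blocks = {
        "sex": ("male", "female"),
        "age_group": claims_data.AGE_GROUPS,
        "insurance": ("NHI", "MedAid_or_PVI"),
        "morbidity": claims_data.MORBIDITY_LABELS,
    }
    period_cols = ("total",) + periods.labels
    count_rows = []
    for block, levels in blocks.items():
        for level in levels:
            for col in period_cols:
                sub = pat if col == "total" else pat[pat["period"] == col]
                count_rows.append({
                    "block": block, "level": level, "period": col,
                    "n": int((sub[block] == level).sum()),
                    "N": len(sub),
                })
    counts = pd.DataFrame(count_rows)

    fmt_rows = []
    for block, levels in blocks.items():
        for level in levels:
            row = {"block": block, "level": level}
            for col in period_cols:
                c = counts[(counts["block"] == block) & (counts["level"] == level)
                           & (counts["period"] == col)].iloc[0]
                pct = percentage(c["n"], c["N"], 1) if c["N"] else float("nan")
                row[col] = f"{c['n']:,} ({pct})" if c["N"] else "-"
            fmt_rows.append(row)

    # outcome block: per-period mean (SD) of monthly values + pooled proportion
    sf = series.frame
    out_rows = []
    for name in INDICATORS:
        for label, (lo, hi) in zip(periods.labels, periods.month_ranges):
            sub = sf[(sf["month_index"] >= lo) & (sf["month_index"] <= hi)]
            vals = sub[f"{name}_value"].dropna()
            num = int(sub[f"{name}_num"].sum())
            den = int(sub["n_users"].sum())
            out_rows.append({
                "indicator": name, "period": label,
                "monthly_mean": float(vals.mean()) if len(vals) else float("nan"),
                "monthly_sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "pooled_num": num, "pooled_den": den,
                "pooled_pct": percentage(num, den) if den else float("nan"),
            })
    outcome_summary = pd.DataFrame(out_rows)

    for name in INDICATORS:
        row = {"block": "outcome", "level": OUTCOME_LABELS[name], "total": "N/A"}
        for label in periods.labels:
            c = outcome_summary[(outcome_summary["indicator"] == name)
                                & (outcome_summary["period"] == label)].iloc[0]
            row[label] = (f"{c['monthly_mean']:.2f} ({c['monthly_sd']:.2f})"
                          if np.isfinite(c["monthly_mean"]) else "-")
        fmt_rows.append(row)

    formatted = pd.DataFrame(fmt_rows, columns=["block", "level", *period_cols])
    return Table1(formatted=formatted, counts=counts, outcome_summary=outcome_summary)


def _format_pvalue(p: float) -> str:
    if not np.isfinite(p):
        return "-"
    if p < 0.001:
        return "<.001"
    if p > 0.99:
        return ">.99"
    s = f"{p:.3f}" if p < 0.01 else f"{p:.2f}"
    return s.lstrip("0")


def make_table2(fits: Mapping[str, ITSFit]) -> pd.DataFrame:
    """Coefficient table for the four outcomes in publication layout.

    One row per coefficient per outcome: label, estimate (4 dp), formatted
    p-value; the outcome's Durbin-Watson statistic and estimator are repeated
    on its rows.  Single-interruption fits simply omit the second-interruption
    rows.
    """
    rows = []
    for name, fit in fits.items():
        for term in fit.design.terms:
            rows.append({
                "outcome": OUTCOME_LABELS.get(name, name),
                "term": TERM_LABELS[term],
                "coefficient": f"{fit.params[term]:.4f}",
                "p_value": _format_pvalue(float(fit.pvalues[term])),
                "dw": f"{fit.dw:.4f}" if np.isfinite(fit.dw) else "-",
                "estimator": fit.estimator,
            })
    return pd.DataFrame(rows, columns=["outcome", "term", "coefficient",
                                       "p_value", "dw", "estimator"])


def plot_series(series: MonthlyIndicatorSeries, fits: Mapping[str, ITSFit],
                periods: PeriodDefinition | None = None,
                path: str | Path = "figure2.svg") -> list[Path]:
    """Four-panel observed/fitted/counterfactual figure.

    Observed monthly values as a solid line (gaps left unplotted), fitted
    segment lines, dot-dash counterfactual extensions past each interruption,
    and dashed vertical markers at the interruption months.  Writes the given
    path plus a .png sibling; output is byte-stable for fixed inputs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "opioid-its"
    path = Path(path)
    names = [n for n in INDICATORS if n in fits]
    fig, axes = plt.subplots(2, 2, figsize=(11, 7), sharex=True)
    for ax, name in zip(axes.ravel(), names):
        fit = fits[name]
        lines = predict_lines(fit)
        obs = series.values(name)
        ax.plot(obs.index, obs.to_numpy(), color="tab:blue", lw=1.2,
                label="observed")
        m1, m2 = fit.design.m1, fit.design.m2
        t = lines.index.to_numpy()
        ax.plot(t, lines["fitted"], color="black", lw=1.0, label="fitted")
        cf1 = lines["counterfactual_pre"]
        ax.plot(t[t >= m1], cf1[t >= m1], color="tab:orange", ls="-.",
                lw=1.0, label="pre-interruption model extended")
        if m2 is not None and "counterfactual_mid" in lines:
            cf2 = lines["counterfactual_mid"]
            ax.plot(t[t >= m2], cf2[t >= m2], color="tab:green", ls="-.",
                    lw=1.0, label="between-interruptions model extended")
        ax.axvline(m1, color="gray", ls="--", lw=0.8)
        if m2 is not None:
            ax.axvline(m2, color="gray", ls="--", lw=0.8)
        ax.set_title(OUTCOME_LABELS.get(name, name), fontsize=8)
        ax.set_ylabel("% of opioid users", fontsize=8)
        ax.tick_params(labelsize=7)
    axes[0, 0].legend(fontsize=6)
    for ax in axes[1]:
        ax.set_xlabel("month index", fontsize=8)
    fig.tight_layout()

    written = []
    for target in (path, path.with_suffix(".png")):
        fig.savefig(target, metadata=_stable_metadata(target.suffix), dpi=150)
        written.append(target)
    plt.close(fig)
    return written


def _stable_metadata(suffix: str):
    if suffix == ".svg":
        return {"Date": None, "Creator": None}
    if suffix == ".png":
        return {"Software": None}
    return None


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "n_months": 60,
    "interruption_months": [29, 50],
    "patients_per_month": 800,
    "decoys_per_month": 0,
    "noise_sd": 0.25,
    "ar1_rho": 0.0,
    "alpha": 0.05,
    "estimator": "auto",
    "high_dose_mme_threshold": 100.0,
    "multi_provider_min": 2,
    "overlap_mode": "mean_ratio",
    "start": [2016, 1],
}


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_PIPELINE_CONFIG) - {"true_betas"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(user)
    if len(cfg["interruption_months"]) not in (1, 2):
        raise ValueError("interruption_months must list one or two month indices")
    return cfg


def run_pipeline(config: str | Path | Mapping, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Execute simulate -> cohort -> indicators -> fit x4 -> tables + figure.

    ``config`` is a mapping or a YAML path with the keys of
    ``DEFAULT_PIPELINE_CONFIG`` (plus optional per-indicator ``true_betas``).
    All outputs land in ``outdir`` together with ``manifest.json``; on any
    stage failure the partially written outputs are removed and a
    :class:`PipelineError` names the stage.  Returns the in-memory results.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else {
        **DEFAULT_PIPELINE_CONFIG, **dict(config)}
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "configure"
    try:
        syn_cfg = synthetic.SyntheticConfig(
            n_months=int(cfg["n_months"]),
            interruption_months=tuple(cfg["interruption_months"]),
            patients_per_month=int(cfg["patients_per_month"]),
            decoys_per_month=int(cfg["decoys_per_month"]),
            true_betas=cfg.get("true_betas", synthetic.DEFAULT_TRUE_BETAS),
            noise_sd=cfg["noise_sd"],
            ar1_rho=float(cfg["ar1_rho"]),
            seed=int(cfg["seed"]),
            start=tuple(cfg["start"]),
        )
        catalog = OpioidCatalog.default()

        stage = "simulate"
        patients, fills, truth = synthetic.simulate_claims(syn_cfg, outdir=outdir)
        written += [outdir / "patients.csv", outdir / "prescriptions.csv",
                    outdir / "truth.json"]

        stage = "cohort"
        start = datetime.date(syn_cfg.start[0], syn_cfg.start[1], 1)
        grid = indicators.month_grid(syn_cfg.start, syn_cfg.n_months)
        last_y, last_m = grid[-1]
        import calendar as _cal
        window = (start, datetime.date(last_y, last_m,
                                       _cal.monthrange(last_y, last_m)[1]))
        criteria = claims_data.CohortCriteria(study_window=window)
        cohort = claims_data.select_cohort(patients, fills, criteria, catalog)

        stage = "indicators"
        ind_cfg = IndicatorConfig(
            high_dose_mme_threshold=float(cfg["high_dose_mme_threshold"]),
            multi_provider_min=int(cfg["multi_provider_min"]),
            month_grid=tuple(grid),
            overlap_mode=cfg["overlap_mode"],
        )
        series = indicators.build_series(cohort, ind_cfg, catalog)
        series.to_csv(outdir / "series.csv")
        written.append(outdir / "series.csv")

        stage = "fit"
        design = syn_cfg.design()
        fits: dict[str, ITSFit] = {}
        (outdir / "fits").mkdir(exist_ok=True)
        for name in INDICATORS:
            fit = fit_its(design, series.values(name).to_numpy(),
                          alpha=float(cfg["alpha"]), estimator=cfg["estimator"])
            fits[name] = fit
            payload = {
                "estimator": fit.estimator,
                "coefficients": fit.params.round(10).to_dict(),
                "standard_errors": fit.bse.round(10).to_dict(),
                "p_values": fit.pvalues.round(10).to_dict(),
                "rho_hat": fit.rho_hat,
                "sigma_hat": fit.sigma_hat,
                "dw": fit.dw,
                "dw_p": fit.dw_p,
                "loglik": fit.loglik,
                "post_slope_after_first": its_model.post_slope(fit, "after_first"),
            }
            if design.m2 is not None:
                payload["post_slope_after_second"] = its_model.post_slope(
                    fit, "after_second")
            p = outdir / "fits" / f"{name}.json"
            p.write_text(json.dumps(payload, indent=2))
            written.append(p)

        stage = "report"
        n_ranges = _period_ranges(syn_cfg)
        periods = PeriodDefinition(month_ranges=n_ranges[0], labels=n_ranges[1])
        t1 = make_table1(cohort, series, periods, ind_cfg)
        t1.formatted.to_csv(outdir / "table1.csv", index=False)
        t1.outcome_summary.to_csv(outdir / "table1_outcomes.csv", index=False)
        t2 = make_table2(fits)
        t2.to_csv(outdir / "table2.csv", index=False)
        figs = plot_series(series, fits, periods, outdir / "figure2.svg")
        written += [outdir / "table1.csv", outdir / "table1_outcomes.csv",
                    outdir / "table2.csv", *figs]

        stage = "manifest"
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in cfg.items() if k != "true_betas"},
            "true_betas": {k: list(v) for k, v in syn_cfg.true_betas.items()},
            "seed": syn_cfg.seed,
            "versions": _versions(),
            "outputs": sorted(str(p.relative_to(outdir)) for p in written),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    return {"cohort": cohort, "series": series, "fits": fits,
            "table1": t1, "table2": t2, "truth": truth, "manifest": manifest}


def _period_ranges(syn_cfg) -> tuple[tuple, tuple]:
    ms = list(syn_cfg.interruption_months)
    n = syn_cfg.n_months
    if len(ms) == 2:
        return (((1, ms[0] - 1), (ms[0], ms[1] - 1), (ms[1], n)),
                ("pre_nims", "post_nims_pre_covid", "post_covid"))
    return (((1, ms[0] - 1), (ms[0], n)), ("pre_nims", "post_nims"))


def _versions() -> dict:
    import matplotlib
    import scipy
    import statsmodels

    from . import __version__

    return {
        "opioid_its": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
    }
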