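"""Monthly inappropriate-opioid-use indicators computed from cohort claims.

Four indicators are computed per calendar month among that month's opioid
users (patients with at least one catalog-opioid fill starting in the month):

* **high_dose** — patients whose summed daily dose reaches the high-dose
  threshold (default 100 MME/day) on at least one day of the month;
* **multi_provider** — patients filling opioids from >= 2 distinct prescriber
  ids that month, irrespective of institutional affiliation;
* **overlap** — per-patient ratio of days covered by >= 2 concurrent fills to
  days covered by >= 1 fill (clipped to the month), averaged over patients;
  an alternative "any overlap" patient-proportion mode is emitted alongside;
* **naloxone** — opioid users with a naloxone record that month, a proxy for
  overdose events.

Daily dose is morphine milligram equivalents:
``units_per_day x unit_strength_mg x mme_factor`` summed over fills covering
the day.  A fill's covered interval is the closed day range
``[start, start + days_supplied - 1]``; fills that started in an earlier month
still contribute to dose and overlap on the days they cover.
"""

from __future__ import annotations

import calendar
import datetime
import decimal
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .claims_data import (
    Cohort,
    NALOXONE_CODE,
    OpioidCatalog,
    PrescriptionRecord,
    UnknownDrugError,
)

INDICATORS = ("high_dose", "multi_provider", "overlap", "naloxone")


def month_grid(start: tuple[int, int] = (2016, 1), n_months: int = 60) -> list[tuple[int, int]]:
    """A gapless list of (year, month) pairs; default Jan 2016 - Dec 2020."""
    y, m = start
    out = []
    for _ in range(n_months):
        out.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def percentage(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places.

    This is the presentation rounding used throughout the reported tables.
    """
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    q = decimal.Decimal(100) * decimal.Decimal(str(numerator)) / decimal.Decimal(str(denominator))
    exp = decimal.Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class IndicatorConfig:
    high_dose_mme_threshold: float = 100.0
    multi_provider_min: int = 2
    month_grid: tuple[tuple[int, int], ...] = tuple(month_grid())
    high_dose_stat: str = "max"          # or "mean" (over covered days)
    overlap_mode: str = "mean_ratio"     # or "any_overlap"

    def __post_init__(self):
        if self.high_dose_mme_threshold <= 0:
            raise ValueError("high_dose_mme_threshold must be > 0")
        if self.multi_provider_min < 2:
            raise ValueError("multi_provider_min must be >= 2")
        if self.high_dose_stat not in ("max", "mean"):
            raise ValueError("high_dose_stat must be 'max' or 'mean'")
        if self.overlap_mode not in ("mean_ratio", "any_overlap"):
            raise ValueError("overlap_mode must be 'mean_ratio' or 'any_overlap'")
        mg = list(self.month_grid)
        for (y0, m0), (y1, m1) in zip(mg, mg[1:]):
            if (y1, m1) != ((y0 + 1, 1) if m0 == 12 else (y0, m0 + 1)):
                raise ValueError("month_grid must be gapless and increasing")


@dataclass
class MonthlyIndicatorSeries:
    """Gapless monthly series of the four indicators with denominators.

    ``frame`` columns: month_index (1-based), year, month, n_users, and per
    indicator a numerator and a value column.  Values are exact percentages
    (no presentation rounding); months with zero opioid users carry NaN
    values.  For the overlap indicator the numerator counts patients with any
    overlapping day; ``overlap_value`` follows the configured mode and
    ``overlap_alt_value`` the other mode.
    """

    frame: pd.DataFrame
    overlap_mode: str = "mean_ratio"

    def __post_init__(self):
        f = self.frame
        mi = f["month_index"].to_numpy()
        if not (np.diff(mi) == 1).all() or mi[0] != 1:
            raise ValueError("month_index must be 1-based, increasing and gapless")
        for name in INDICATORS:
            num = f[f"{name}_num"].to_numpy(dtype=float)
            den = f["n_users"].to_numpy(dtype=float)
            if (num > den).any():
                raise ValueError(f"{name} numerator exceeds denominator")
            val = f[f"{name}_value"].to_numpy(dtype=float)
            ok = np.isnan(val) | ((val >= 0) & (val <= 100))
            if not ok.all():
                raise ValueError(f"{name} value outside [0, 100]")
            if name != "overlap" or self.overlap_mode == "any_overlap":
                has = den > 0
                if not np.allclose(val[has], 100 * num[has] / den[has]):
                    raise ValueError(f"{name} value != 100*num/den")

    def values(self, indicator: str) -> pd.Series:
        return self.frame.set_index("month_index")[f"{indicator}_value"]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, overlap_mode: str = "mean_ratio") -> "MonthlyIndicatorSeries":
        return cls(pd.read_csv(path), overlap_mode=overlap_mode)


# ---------------------------------------------------------------------------
# per-day dose arithmetic
# ---------------------------------------------------------------------------

def daily_mme(fills: Iterable[PrescriptionRecord], day: datetime.date,
              catalog: OpioidCatalog) -> float:
    """Summed MME/day for one patient's fills active on ``day``."""
    total = 0.0
    for f in fills:
        if f.drug_code == NALOXONE_CODE:
            raise UnknownDrugError("NALOXONE has no MME; pass opioid fills only")
        if f.covers(day):
            total += f.units_per_day * f.unit_strength_mg * catalog.mme_factor(f.drug_code)
    return total


def _month_span(year: int, month: int) -> tuple[datetime.date, int]:
    return datetime.date(year, month, 1), calendar.monthrange(year, month)[1]


def _clip_offsets(f: PrescriptionRecord, first: datetime.date, dim: int):
    """Day offsets (0-based, within the month) covered by the fill, or None."""
    a = (f.start_date - first).days
    b = (f.end_date - first).days
    a, b = max(a, 0), min(b, dim - 1)
    if a > b:
        return None
    return a, b


def _patient_day_arrays(fills: Sequence[PrescriptionRecord], year: int, month: int,
                        catalog: OpioidCatalog):
    """(mme_per_day, coverage_count) arrays over the days of the month."""
    first, dim = _month_span(year, month)
    mme = np.zeros(dim)
    cnt = np.zeros(dim, dtype=int)
    for f in fills:
        off = _clip_offsets(f, first, dim)
        if off is None:
            continue
        a, b = off
        mme[a:b + 1] += f.units_per_day * f.unit_strength_mg * catalog.mme_factor(f.drug_code)
        cnt[a:b + 1] += 1
    return mme, cnt


# ---------------------------------------------------------------------------
# monthly indicator operations
# ---------------------------------------------------------------------------

def _month_users(fills: Iterable[PrescriptionRecord], year: int, month: int) -> set[str]:
    """Denominator: patients with >= 1 opioid fill starting in the month."""
    return {f.patient_id for f in fills
            if f.drug_code != NALOXONE_CODE and f.month == (year, month)}


def _fills_touching(fills: Iterable[PrescriptionRecord], year: int, month: int,
                    patients: set[str]) -> dict[str, list[PrescriptionRecord]]:
    first, dim = _month_span(year, month)
    last = first + datetime.timedelta(days=dim - 1)
    by_patient: dict[str, list[PrescriptionRecord]] = {p: [] for p in patients}
    for f in fills:
        if f.drug_code == NALOXONE_CODE or f.patient_id not in patients:
            continue
        if f.start_date <= last and f.end_date >= first:
            by_patient[f.patient_id].append(f)
    return by_patient


def high_dose_proportion(fills: Sequence[PrescriptionRecord], year: int, month: int,
                         config: IndicatorConfig, catalog: OpioidCatalog) -> float:
    """Percent of the month's opioid users at/above the MME threshold.

    A patient qualifies when the summed daily MME over their fills reaches the
    threshold on at least one day of the month ("max" statistic; the "mean"
    option averages over the patient's covered days instead).  Returns NaN
    when the month has no opioid users.
    """
    users = _month_users(fills, year, month)
    if not users:
        return float("nan")
    by_patient = _fills_touching(fills, year, month, users)
    num = 0
    for pid in users:
        mme, cnt = _patient_day_arrays(by_patient[pid], year, month, catalog)
        stat = mme.max() if config.high_dose_stat == "max" else mme[cnt > 0].mean()
        if stat >= config.high_dose_mme_threshold:
            num += 1
    return 100.0 * num / len(users)


def multi_provider_proportion(fills: Sequence[PrescriptionRecord], year: int,
                              month: int, config: IndicatorConfig) -> float:
    """Percent of the month's opioid users with >= 2 distinct prescribers."""
    users = _month_users(fills, year, month)
    if not users:
        return float("nan")
    providers: dict[str, set[str]] = {p: set() for p in users}
    for f in fills:
        if f.drug_code != NALOXONE_CODE and f.month == (year, month):
            providers[f.patient_id].add(f.provider_id)
    num = sum(len(v) >= config.multi_provider_min for v in providers.values())
    return 100.0 * num / len(users)


def overlap_ratio(fills: Sequence[PrescriptionRecord],
                  year: int | None = None, month: int | None = None) -> float:
    """One patient's overlapping-to-total covered-day ratio, in [0, 1].

    Days covered by >= 2 fills divided by days covered by >= 1 fill; with a
    (year, month) given, fill intervals are clipped to that month first.
    """
    fills = list(fills)
    if not fills:
        raise ValueError("need at least one fill")
    if len({f.patient_id for f in fills}) > 1:
        raise ValueError("fills must belong to a single patient")
    if year is not None and month is not None:
        first, dim = _month_span(year, month)
    else:
        first = min(f.start_date for f in fills)
        dim = (max(f.end_date for f in fills) - first).days + 1
    cnt = np.zeros(dim, dtype=int)
    for f in fills:
        off = _clip_offsets(f, first, dim)
        if off is None:
            continue
        a, b = off
        cnt[a:b + 1] += 1
    total = int((cnt >= 1).sum())
    if total == 0:
        return 0.0
    return int((cnt >= 2).sum()) / total


def overlap_rate_monthly(fills: Sequence[PrescriptionRecord], year: int, month: int,
                         mode: str = "mean_ratio") -> float:
    """Monthly overlap indicator as a percentage.

    ``mean_ratio`` (primary): mean per-patient overlap_ratio x 100 across the
    month's opioid users.  ``any_overlap``: percent of users with any
    double-covered day.
    """
    users = _month_users(fills, year, month)
    if not users:
        return float("nan")
    by_patient = _fills_touching(fills, year, month, users)
    ratios = [overlap_ratio(by_patient[p], year, month) for p in users]
    if mode == "mean_ratio":
        return 100.0 * float(np.mean(ratios))
    if mode == "any_overlap":
        return 100.0 * sum(r > 0 for r in ratios) / len(users)
    raise ValueError(f"unknown overlap mode {mode!r}")


def naloxone_rate(opioid_fills: Sequence[PrescriptionRecord],
                  naloxone_fills: Sequence[PrescriptionRecord],
                  year: int, month: int) -> float:
    """Percent of the month's opioid users with a naloxone record that month."""
    users = _month_users(opioid_fills, year, month)
    if not users:
        return float("nan")
    recipients = {f.patient_id for f in naloxone_fills
                  if f.month == (year, month) and f.patient_id in users}
    return 100.0 * len(recipients) / len(users)


# ---------------------------------------------------------------------------
# series construction
# ---------------------------------------------------------------------------

def build_series(cohort: Cohort, config: IndicatorConfig | None = None,
                 catalog: OpioidCatalog | None = None) -> MonthlyIndicatorSeries:
    """Aggregate cohort claims into the gapless monthly indicator series.

    One row per month on the configured grid; months with zero opioid users
    are flagged missing (NaN values) with a warning and the run continues.
    """
    config = config or IndicatorConfig()
    catalog = catalog or OpioidCatalog.default()

    # Bucket fills by the months their covered interval touches (for dose and
    # overlap) and by start month (for denominators and provider counts).
    touching: dict[tuple[int, int], dict[str, list[PrescriptionRecord]]] = {
        ym: {} for ym in config.month_grid}
    starting: dict[tuple[int, int], list[PrescriptionRecord]] = {
        ym: [] for ym in config.month_grid}
    grid_set = set(config.month_grid)
    for f in cohort.opioid_fills:
        if f.month in grid_set:
            starting[f.month].append(f)
        y, m = f.month
        d = f.start_date
        while d <= f.end_date:
            if (y, m) in grid_set:
                touching[(y, m)].setdefault(f.patient_id, []).append(f)
            m += 1
            if m == 13:
                y, m = y + 1, 1
            if (y, m) not in grid_set and (y, m) > max(grid_set):
                break
            d = datetime.date(y, m, 1)

    naloxone_by_month: dict[tuple[int, int], set[str]] = {}
    for f in cohort.naloxone_fills:
        naloxone_by_month.setdefault(f.month, set()).add(f.patient_id)

    rows = []
    empty_months = 0
    for t, (y, m) in enumerate(config.month_grid, start=1):
        users = {f.patient_id for f in starting[(y, m)]}
        den = len(users)
        row = {"month_index": t, "year": y, "month": m, "n_users": den}
        if den == 0:
            empty_months += 1
            for name in INDICATORS:
                row[f"{name}_num"] = 0
                row[f"{name}_value"] = np.nan
            row["overlap_alt_value"] = np.nan
            rows.append(row)
            continue

        providers: dict[str, set[str]] = {p: set() for p in users}
        for f in starting[(y, m)]:
            providers[f.patient_id].add(f.provider_id)

        hd_num = ov_any = 0
        ratios = []
        for pid in users:
            pf = touching[(y, m)].get(pid, [])
            mme, cnt = _patient_day_arrays(pf, y, m, catalog)
            covered = cnt > 0
            stat = mme.max() if config.high_dose_stat == "max" else (
                mme[covered].mean() if covered.any() else 0.0)
            if stat >= config.high_dose_mme_threshold:
                hd_num += 1
            total = int(covered.sum())
            ratio = int((cnt >= 2).sum()) / total if total else 0.0
            ratios.append(ratio)
            if ratio > 0:
                ov_any += 1

        mp_num = sum(len(v) >= config.multi_provider_min for v in providers.values())
        nx_num = len(naloxone_by_month.get((y, m), set()) & users)
        mean_ratio_pct = 100.0 * float(np.mean(ratios))
        any_pct = 100.0 * ov_any / den
        primary, alt = ((mean_ratio_pct, any_pct)
                        if config.overlap_mode == "mean_ratio"
                        else (any_pct, mean_ratio_pct))

        row.update({
            "high_dose_num": hd_num, "high_dose_value": 100.0 * hd_num / den,
            "multi_provider_num": mp_num, "multi_provider_value": 100.0 * mp_num / den,
            "overlap_num": ov_any, "overlap_value": primary,
            "overlap_alt_value": alt,
            "naloxone_num": nx_num, "naloxone_value": 100.0 * nx_num / den,
        })
        rows.append(row)

    if empty_months:
        warnings.warn(f"{empty_months} month(s) with zero opioid users flagged "
                      "missing", UserWarning, stacklevel=2)
    cols = ["month_index", "year", "month", "n_users"]
    for name in INDICATORS:
        cols += [f"{name}_num", f"{name}_value"]
    cols.insert(cols.index("overlap_value") + 1, "overlap_alt_value")
    frame = pd.DataFrame(rows)[cols]
    return MonthlyIndicatorSeries(frame, overlap_mode=config.overlap_mode)
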