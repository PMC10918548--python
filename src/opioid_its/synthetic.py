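"""Synthetic claims generator with the segmented statistical structure.

Two tiers:

* **series tier** (:func:`simulate_series`) draws a 60-month indicator series
  directly from the segmented linear model plus stationary AR(1) Gaussian
  noise — the exact error structure the regression estimators assume;
* **record tier** (:func:`simulate_claims`) emits patient/prescription tables
  that pass schema validation and cohort selection, in which each monthly
  cohort member is independently made high-dose, multi-provider, overlapping
  or a naloxone recipient with the month's model-implied probability, so the
  noise around the segmented mean is binomial rather than Gaussian.

Generator defaults mirror the study conditions: 60 months (Jan 2016 -
Dec 2020), interruptions at months 29 and 50, per-indicator true coefficients
equal to the published two-interruption fits, and a demographic mix matching
the study population totals (60.9% female; age groups 12.5/33.1/34.6/19.8%;
9.1% MedAid-or-PVI; morbidity 26.1/46.6/26.1/1.2%).
"""

from __future__ import annotations

import calendar
import datetime
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .claims_data import PatientRecord, PrescriptionRecord, write_claims
from .indicators import month_grid
from .its_model import build_design

# Per-indicator true coefficients (percentage scale): b0, b1, b2, b3, b4, b5.
DEFAULT_TRUE_BETAS: dict[str, tuple[float, ...]] = {
    "high_dose": (0.7947, 0.0040, 0.1743, 0.0271, 0.0484, 0.0309),
    "multi_provider": (0.8141, -0.0076, 0.6252, -0.0067, 0.3969, 0.0323),
    "overlap": (1.4828, -0.0113, 0.3349, 0.0101, 0.3709, -0.0442),
    "naloxone": (0.3685, 0.0156, -0.2968, -0.0117, 0.0652, -0.0324),
}


@dataclass(frozen=True)
class DemographicMix:
    """Target population fractions for sampled patient attributes."""

    female: float = 0.609
    age_group_probs: tuple[float, ...] = (0.125, 0.331, 0.346, 0.198)
    medaid_pvi: float = 0.091
    morbidity_probs: tuple[float, ...] = (0.261, 0.466, 0.261, 0.012)

    def __post_init__(self):
        if not 0 <= self.female <= 1 or not 0 <= self.medaid_pvi <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        for probs in (self.age_group_probs, self.morbidity_probs):
            if len(probs) != 4 or abs(sum(probs) - 1) > 1e-9:
                raise ValueError("probability vectors must have 4 entries summing to 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the study conditions."""

    n_months: int = 60
    interruption_months: tuple[int, ...] = (29, 50)
    patients_per_month: int = 800
    decoys_per_month: int = 0
    true_betas: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETAS))
    noise_sd: float | Mapping[str, float] = 0.25
    ar1_rho: float = 0.0
    demographic_mix: DemographicMix = field(default_factory=DemographicMix)
    seed: int = 0
    start: tuple[int, int] = (2016, 1)

    def __post_init__(self):
        if len(self.interruption_months) == 2 and self.n_months < 24:
            raise ValueError("two interruptions require n_months >= 24 "
                             "(at least 12 months before and after)")
        if not -0.99 <= self.ar1_rho <= 0.99:
            raise ValueError("ar1_rho must lie in [-0.99, 0.99]")
        if self.patients_per_month < 0 or self.decoys_per_month < 0:
            raise ValueError("cohort sizes must be non-negative")
        for name, betas in self.true_betas.items():
            if len(betas) not in (4, 6):
                raise ValueError(f"{name}: need 4 or 6 coefficients, got {len(betas)}")
            mu = self.segmented_mean(name)
            if (mu < 0).any() or (mu > 100).any():
                raise ValueError(
                    f"{name}: implied monthly mean leaves [0, 100] "
                    f"(range {mu.min():.3g}..{mu.max():.3g})")

    def sd_for(self, indicator: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd[indicator])
        return float(self.noise_sd)

    def design(self):
        # the short-segment advisory is about user-supplied designs; the
        # generator's own window is fixed by construction, so silence it here
        import warnings
        m = list(self.interruption_months)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return build_design(self.n_months, m[0], m[1] if len(m) > 1 else None)

    def segmented_mean(self, indicator: str) -> np.ndarray:
        """Deterministic monthly mean implied by the indicator's coefficients."""
        betas = np.asarray(self.true_betas[indicator], dtype=float)
        X = self.design().X.to_numpy()
        if X.shape[1] != len(betas):
            raise ValueError(
                f"{indicator}: {len(betas)} coefficients but design has "
                f"{X.shape[1]} columns")
        return X @ betas


# ---------------------------------------------------------------------------
# series tier
# ---------------------------------------------------------------------------

def _indicator_rng(config: SyntheticConfig, indicator: str) -> np.random.Generator:
    # stable per-indicator stream, independent of the set of indicators
    tag = zlib.crc32(indicator.encode())
    return np.random.default_rng([config.seed, tag])


def simulate_series(config: SyntheticConfig, indicator: str) -> pd.Series:
    """Segmented mean plus stationary AR(1) Gaussian noise, one value per month.

    The AR(1) residual is initialized from its stationary marginal
    N(0, sd^2), so every month has the same marginal variance; the same seed
    yields a bit-identical series.  Values are not clipped to [0, 100] — the
    Gaussian structure is what the regression tests rely on.
    """
    mu = config.segmented_mean(indicator)
    sd = config.sd_for(indicator)
    rho = config.ar1_rho
    rng = _indicator_rng(config, indicator)
    eps = np.empty(config.n_months)
    if sd == 0:
        eps[:] = 0.0
    else:
        eps[0] = rng.normal(0.0, sd)
        innov_sd = sd * np.sqrt(1.0 - rho * rho)
        shocks = rng.normal(0.0, innov_sd, size=config.n_months - 1)
        for t in range(1, config.n_months):
            eps[t] = rho * eps[t - 1] + shocks[t - 1]
    idx = pd.Index(np.arange(1, config.n_months + 1), name="month_index")
    return pd.Series(mu + eps, index=idx, name=indicator)


# ---------------------------------------------------------------------------
# record tier
# ---------------------------------------------------------------------------

# Fill templates kept below 50 MME/day so that even a duplicated (overlapping)
# base fill stays under the 100 MME/day threshold; the high-dose template
# alone reaches it.
_BASE_TEMPLATES = (
    # (drug_code, unit_strength_mg, units_per_day)  -> MME/day
    ("oxycodone", 10.0, 3.0),      # 45
    ("codeine", 20.0, 3.0),        # 9
    ("hydrocodone", 10.0, 3.0),    # 30
    ("tapentadol", 50.0, 2.0),     # 40
)
_HIGH_DOSE_TEMPLATE = ("morphine", 30.0, 4.0)   # 120 MME/day
_SECOND_PROVIDER_TEMPLATE = ("oxycodone", 5.0, 2.0)  # 15 MME/day, disjoint days

_AGE_RANGES = ((20, 39), (40, 59), (60, 74), (75, 90))
_MORBIDITY_CODE_RANGES = (("M00", 26), ("M40", 15), ("M60", 20), ("M80", 17))


def simulate_claims(
    config: SyntheticConfig,
    outdir: str | Path | None = None,
) -> tuple[list[PatientRecord], list[PrescriptionRecord], dict]:
    """Generate record-level claims with planted monthly indicator flags.

    Each month gets a fresh cohort of ``patients_per_month`` adult outpatients
    with a musculoskeletal diagnosis; every patient receives a base opioid
    fill fully inside the month, and is independently flagged high-dose
    (a >= 100 MME/day fill), multi-provider (a second fill from a distinct
    prescriber on disjoint days), overlapping (an exact duplicate of the base
    fill, giving overlap ratio 1) or a naloxone recipient, with probabilities
    given by the segmented model for that month.  ``decoys_per_month`` adds
    patients that cohort selection must drop (under-age, cancer or inpatient).

    Returns (patients, prescriptions, truth) where ``truth`` records the
    generating parameters and the planted per-month numerators; with
    ``outdir`` set, writes patients.csv, prescriptions.csv and truth.json.
    """
    rng = np.random.default_rng([config.seed, 1000])
    grid = month_grid(config.start, config.n_months)
    means = {name: config.segmented_mean(name) / 100.0
             for name in config.true_betas}
    mix = config.demographic_mix

    patients: list[PatientRecord] = []
    fills: list[PrescriptionRecord] = []
    planted = {name: [] for name in config.true_betas}
    denominators = []
    rx_counter = 0

    def next_rx() -> str:
        nonlocal rx_counter
        rx_counter += 1
        return f"R{rx_counter:07d}"

    for t, (year, month) in enumerate(grid, start=1):
        n = config.patients_per_month
        denominators.append(n)
        dim = calendar.monthrange(year, month)[1]
        flags = {name: rng.random(n) < means[name][t - 1]
                 for name in config.true_betas}
        for name in config.true_betas:
            planted[name].append(int(flags[name].sum()))
        if n == 0:
            continue

        # vectorized attribute sampling for the month's cohort
        groups = rng.choice(4, size=n, p=mix.age_group_probs)
        ages = np.empty(n, dtype=int)
        for g, (lo, hi) in enumerate(_AGE_RANGES):
            m_g = groups == g
            ages[m_g] = rng.integers(lo, hi + 1, size=int(m_g.sum()))
        female = rng.random(n) < mix.female
        medaid = rng.random(n) < mix.medaid_pvi
        pvi = rng.random(n) < 0.2
        dx_cls = rng.choice(4, size=n, p=mix.morbidity_probs)
        dx_off = np.empty(n, dtype=int)
        for c, (base, span) in enumerate(_MORBIDITY_CODE_RANGES):
            m_c = dx_cls == c
            dx_off[m_c] = int(base[1:]) + rng.integers(span, size=int(m_c.sum()))
        providers = rng.integers(1, 500, size=n)
        institutions = rng.integers(1, 100, size=n)
        templates = rng.integers(len(_BASE_TEMPLATES), size=n)
        start_days = rng.integers(1, 11, size=n)      # base fill spans <= day 19
        other_providers = rng.integers(500, 999, size=n)
        naloxone_days = rng.integers(1, dim + 1, size=n)

        hd = flags.get("high_dose", np.zeros(n, bool))
        ov = flags.get("overlap", np.zeros(n, bool))
        mp = flags.get("multi_provider", np.zeros(n, bool))
        nx = flags.get("naloxone", np.zeros(n, bool))

        for i in range(n):
            pid = f"P{t:02d}{i:05d}"
            insurance = ("MedAid" if not pvi[i] else "PVI") if medaid[i] else "NHI"
            patients.append(PatientRecord(
                pid, "female" if female[i] else "male", year - int(ages[i]),
                insurance, frozenset({f"M{dx_off[i]:02d}"})))

            provider = f"D{providers[i]:04d}"
            institution = f"H{institutions[i]:03d}"
            drug, mg, upd = (_HIGH_DOSE_TEMPLATE if hd[i]
                             else _BASE_TEMPLATES[templates[i]])
            base_start = datetime.date(year, month, int(start_days[i]))
            fills.append(PrescriptionRecord(
                next_rx(), pid, provider, institution, drug,
                base_start, 10, upd, mg, "outpatient"))

            if ov[i]:
                # exact duplicate interval -> per-patient overlap ratio 1
                fills.append(PrescriptionRecord(
                    next_rx(), pid, provider, institution, drug,
                    base_start, 10, upd, mg, "outpatient"))
            if mp[i]:
                drug2, mg2, upd2 = _SECOND_PROVIDER_TEMPLATE
                fills.append(PrescriptionRecord(
                    next_rx(), pid, f"D{other_providers[i]:04d}", institution,
                    drug2, datetime.date(year, month, 20), 5, upd2, mg2,
                    "outpatient"))
            if nx[i]:
                fills.append(PrescriptionRecord(
                    next_rx(), pid, provider, institution, "NALOXONE",
                    datetime.date(year, month, int(naloxone_days[i])),
                    1, 1.0, 0.4, "outpatient"))

        for j in range(config.decoys_per_month):
            kind = j % 3
            pid = f"X{t:02d}{j:05d}"
            if kind == 0:       # under-age
                patients.append(PatientRecord(
                    pid, "male", year - 15, "NHI", frozenset({"M54"})))
            elif kind == 1:     # cancer diagnosis
                patients.append(PatientRecord(
                    pid, "female", year - 50, "NHI", frozenset({"M54", "C50"})))
            else:               # inpatient-only fill
                patients.append(PatientRecord(
                    pid, "female", year - 50, "NHI", frozenset({"M17"})))
            fills.append(PrescriptionRecord(
                next_rx(), pid, "D0001", "H001", "morphine",
                datetime.date(year, month, 1), 5, 2.0, 10.0,
                "inpatient" if kind == 2 else "outpatient"))

    truth = {
        "config": {
            "n_months": config.n_months,
            "interruption_months": list(config.interruption_months),
            "patients_per_month": config.patients_per_month,
            "decoys_per_month": config.decoys_per_month,
            "true_betas": {k: list(v) for k, v in config.true_betas.items()},
            "ar1_rho": config.ar1_rho,
            "seed": config.seed,
            "start": list(config.start),
        },
        "denominators": denominators,
        "planted_numerators": planted,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_claims(patients, fills, outdir / "patients.csv",
                     outdir / "prescriptions.csv")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return patients, fills, truth
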