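"""Outpatient claims schema, delimited-text I/O, and study-cohort selection.

The pipeline consumes two flat tables: a patient table (one row per patient,
with sex, birth year, insurance type and a semicolon-separated list of dot-free
ICD-10 diagnosis codes) and a prescription table (one row per dispensing event,
with prescriber and institution ids, drug code, start date, days supplied, dose
units per day and unit strength in mg).  Drug codes resolve against an
:class:`OpioidCatalog` mapping each study opioid to its route and its morphine
milligram equivalent (MME) conversion factor; the reserved code ``NALOXONE``
marks naloxone administrations and is carried through cohort selection for the
overdose-proxy indicator.

Cohort selection keeps adult (>=20 years) outpatients with at least one
musculoskeletal/connective-tissue diagnosis (ICD-10 chapter M), no cancer
diagnosis (C chapter), and at least one in-window outpatient fill of a catalog
opioid.  Age is computed in completed years at the year of the first in-window
opioid fill, because claims carry birth year only.
"""

from __future__ import annotations

import csv
import datetime
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger("opioid_its.claims")

ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")
SEXES = ("male", "female")
INSURANCE_TYPES = ("NHI", "MedAid", "PVI")
SETTINGS = ("outpatient", "inpatient")
NALOXONE_CODE = "NALOXONE"
AGE_GROUPS = ("20-39", "40-59", "60-74", "75+")

PATIENT_COLUMNS = ("patient_id", "sex", "birth_year", "insurance", "diagnoses")
PRESCRIPTION_COLUMNS = (
    "rx_id", "patient_id", "provider_id", "institution_id", "drug_code",
    "start_date", "days_supplied", "units_per_day", "unit_strength_mg",
    "setting",
)
CATALOG_COLUMNS = ("drug_code", "molecule", "route", "mme_factor")

# Morbidity classes within the M chapter; any other M code falls in "others".
MORBIDITY_CLASSES = (
    ("arthropathies", "M00", "M25"),
    ("dorsopathies", "M40", "M54"),
    ("soft_tissue", "M60", "M79"),
)
MORBIDITY_LABELS = ("arthropathies", "dorsopathies", "soft_tissue", "others")


class ClaimsError(ValueError):
    """Base class for claims-data validation failures."""


class SchemaError(ClaimsError):
    """A required column is missing or the header does not match the schema."""


class RowValidationError(ClaimsError):
    """A row violates a field invariant; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class ReferentialError(ClaimsError):
    """A prescription references a patient id absent from the patient table."""


class UnknownDrugError(ClaimsError):
    """A drug code does not resolve against the opioid catalog."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    birth_year: int
    insurance: str
    diagnoses: frozenset[str]

    def __post_init__(self):
        if not self.patient_id:
            raise ClaimsError("patient_id must be non-empty")
        if self.sex not in SEXES:
            raise ClaimsError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.insurance not in INSURANCE_TYPES:
            raise ClaimsError(
                f"insurance must be one of {INSURANCE_TYPES}, got {self.insurance!r}")
        object.__setattr__(self, "diagnoses", frozenset(self.diagnoses))
        for dx in self.diagnoses:
            if not ICD10_RE.match(dx):
                raise ClaimsError(f"invalid ICD-10 code {dx!r} (dot-free codes expected)")


@dataclass(frozen=True)
class PrescriptionRecord:
    rx_id: str
    patient_id: str
    provider_id: str
    institution_id: str
    drug_code: str
    start_date: datetime.date
    days_supplied: int
    units_per_day: float
    unit_strength_mg: float
    setting: str

    def __post_init__(self):
        if self.days_supplied < 1:
            raise ClaimsError(f"days_supplied must be >= 1, got {self.days_supplied}")
        if self.units_per_day <= 0:
            raise ClaimsError(f"units_per_day must be > 0, got {self.units_per_day}")
        if self.unit_strength_mg <= 0:
            raise ClaimsError(f"unit_strength_mg must be > 0, got {self.unit_strength_mg}")
        if self.setting not in SETTINGS:
            raise ClaimsError(f"setting must be one of {SETTINGS}, got {self.setting!r}")

    @property
    def end_date(self) -> datetime.date:
        """Last covered day (covered interval is the closed range start..end)."""
        return self.start_date + datetime.timedelta(days=self.days_supplied - 1)

    def covers(self, day: datetime.date) -> bool:
        return self.start_date <= day <= self.end_date

    @property
    def month(self) -> tuple[int, int]:
        """(year, month) of the dispensing event; a fill belongs to its start month."""
        return (self.start_date.year, self.start_date.month)


@dataclass(frozen=True)
class CatalogEntry:
    drug_code: str
    molecule: str
    route: str
    mme_factor: float

    def __post_init__(self):
        if self.route not in ("oral", "transdermal"):
            raise ClaimsError(f"route must be oral or transdermal, got {self.route!r}")
        if self.mme_factor <= 0:
            raise ClaimsError("mme_factor must be > 0")


# Default conversion factors follow the CDC 2018 oral-MME table.  For the two
# transdermal products the published factors are per mcg/hr of labeled patch
# delivery rate, so catalog users record patch strength in mcg/hr in the
# unit_strength_mg column; for oral products the factor is MME per mg.
_DEFAULT_CATALOG_ROWS = (
    ("buprenorphine_td", "buprenorphine", "transdermal", 12.6),
    ("codeine", "codeine", "oral", 0.15),
    ("dihydrocodeine", "dihydrocodeine", "oral", 0.25),
    ("fentanyl_td", "fentanyl", "transdermal", 2.4),
    ("hydrocodone", "hydrocodone", "oral", 1.0),
    ("hydromorphone", "hydromorphone", "oral", 4.0),
    ("morphine", "morphine", "oral", 1.0),
    ("oxycodone", "oxycodone", "oral", 1.5),
    ("tapentadol", "tapentadol", "oral", 0.4),
)


class OpioidCatalog:
    """Drug-code registry mapping each study opioid to route and MME factor.

    The default catalog holds exactly the nine study molecules (oral codeine,
    dihydrocodeine, hydrocodone, hydromorphone, morphine, oxycodone and
    tapentadol; transdermal buprenorphine and fentanyl).  Users may load a
    replacement table from ``opioid_catalog.csv`` to change codes or factors.
    """

    def __init__(self, entries: Iterable[CatalogEntry]):
        self.entries: dict[str, CatalogEntry] = {}
        for e in entries:
            if e.drug_code in self.entries:
                raise ClaimsError(f"duplicate drug_code {e.drug_code!r}")
            if e.drug_code == NALOXONE_CODE:
                raise ClaimsError("NALOXONE is a reserved code, not a catalog opioid")
            self.entries[e.drug_code] = e
        morphine = [e for e in self.entries.values()
                    if e.molecule == "morphine" and e.route == "oral"]
        if morphine and any(e.mme_factor != 1.0 for e in morphine):
            raise ClaimsError("oral morphine must have mme_factor exactly 1")

    @classmethod
    def default(cls) -> "OpioidCatalog":
        return cls(CatalogEntry(*row) for row in _DEFAULT_CATALOG_ROWS)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OpioidCatalog":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            _check_header(reader.fieldnames, CATALOG_COLUMNS, path)
            entries = []
            for i, row in enumerate(reader, start=2):
                try:
                    entries.append(CatalogEntry(
                        row["drug_code"], row["molecule"], row["route"],
                        float(row["mme_factor"])))
                except (ClaimsError, ValueError) as exc:
                    raise RowValidationError(str(exc), line=i) from exc
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(CATALOG_COLUMNS)
            for e in sorted(self.entries.values(), key=lambda e: e.drug_code):
                w.writerow([e.drug_code, e.molecule, e.route, _fmt_num(e.mme_factor)])

    def __contains__(self, drug_code: str) -> bool:
        return drug_code in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def mme_factor(self, drug_code: str) -> float:
        try:
            return self.entries[drug_code].mme_factor
        except KeyError:
            raise UnknownDrugError(f"drug code {drug_code!r} not in catalog") from None


@dataclass(frozen=True)
class CohortCriteria:
    """Inclusion/exclusion rules for the study cohort.

    Prefix matching is on dot-free ICD-10 codes: the default include prefix
    ``M`` covers the musculoskeletal chapter M00-M99; the default exclude
    prefix ``C`` covers the cancer chapter C00-C97.  A cancer code at any time
    in the window excludes the patient (conservative reading).
    """

    min_age: int = 20
    include_dx_prefixes: tuple[str, ...] = ("M",)
    exclude_dx_prefixes: tuple[str, ...] = ("C",)
    setting: str = "outpatient"
    study_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2016, 1, 1), datetime.date(2020, 12, 31))

    def __post_init__(self):
        for inc in self.include_dx_prefixes:
            for exc in self.exclude_dx_prefixes:
                if inc.startswith(exc) or exc.startswith(inc):
                    raise ClaimsError(
                        f"include prefix {inc!r} and exclude prefix {exc!r} overlap")
        if self.study_window[0] > self.study_window[1]:
            raise ClaimsError("study_window start after end")


@dataclass
class Cohort:
    """Result of cohort selection: retained patients and their fills.

    ``naloxone_fills`` are the retained patients' NALOXONE records, carried
    alongside for the naloxone indicator; ``attrition`` holds the selection
    counts (flowchart-style).
    """

    patients: list[PatientRecord]
    opioid_fills: list[PrescriptionRecord]
    naloxone_fills: list[PrescriptionRecord]
    attrition: dict[str, int] = field(default_factory=dict)
    reference_years: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _check_header(fieldnames, expected, path):
    if fieldnames is None:
        raise SchemaError(f"{path}: empty file, header required")
    missing = [c for c in expected if c not in fieldnames]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _fmt_num(x: float) -> str:
    """Canonical numeric formatting: integers bare, floats minimal."""
    if float(x) == int(x):
        return str(int(x))
    return format(float(x), ".10g")


def read_claims(
    patients_path: str | Path,
    prescriptions_path: str | Path,
    catalog: OpioidCatalog | None = None,
) -> tuple[list[PatientRecord], list[PrescriptionRecord]]:
    """Read and validate the two claims tables.

    Every row is validated against the record invariants; prescriptions must
    reference a known patient, and drug codes must be catalog opioids or the
    reserved ``NALOXONE`` code.
    """
    catalog = catalog or OpioidCatalog.default()
    patients: list[PatientRecord] = []
    seen_ids: set[str] = set()
    with open(patients_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, PATIENT_COLUMNS, patients_path)
        for i, row in enumerate(reader, start=2):
            try:
                pid = row["patient_id"]
                if pid in seen_ids:
                    raise ClaimsError(f"duplicate patient_id {pid!r}")
                dx = frozenset(d for d in row["diagnoses"].split(";") if d)
                patients.append(PatientRecord(
                    pid, row["sex"], int(row["birth_year"]), row["insurance"], dx))
                seen_ids.add(pid)
            except (ClaimsError, ValueError) as exc:
                raise RowValidationError(str(exc), line=i) from exc

    prescriptions: list[PrescriptionRecord] = []
    with open(prescriptions_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, PRESCRIPTION_COLUMNS, prescriptions_path)
        for i, row in enumerate(reader, start=2):
            try:
                code = row["drug_code"]
                if code != NALOXONE_CODE and code not in catalog:
                    raise ClaimsError(f"drug code {code!r} not in catalog")
                rec = PrescriptionRecord(
                    row["rx_id"], row["patient_id"], row["provider_id"],
                    row["institution_id"], code,
                    datetime.date.fromisoformat(row["start_date"]),
                    int(row["days_supplied"]), float(row["units_per_day"]),
                    float(row["unit_strength_mg"]), row["setting"])
            except (ClaimsError, ValueError) as exc:
                raise RowValidationError(str(exc), line=i) from exc
            if rec.patient_id not in seen_ids:
                raise ReferentialError(
                    f"line {i}: prescription {rec.rx_id!r} references unknown "
                    f"patient {rec.patient_id!r}")
            prescriptions.append(rec)
    return patients, prescriptions


def write_claims(
    patients: Sequence[PatientRecord],
    prescriptions: Sequence[PrescriptionRecord],
    patients_path: str | Path,
    prescriptions_path: str | Path,
) -> None:
    """Write the two tables in canonical form (sorted diagnoses, minimal numerics).

    Reading a canonically written pair back and rewriting it reproduces the
    files byte-for-byte.
    """
    with open(patients_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_COLUMNS)
        for p in patients:
            w.writerow([p.patient_id, p.sex, p.birth_year, p.insurance,
                        ";".join(sorted(p.diagnoses))])
    with open(prescriptions_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PRESCRIPTION_COLUMNS)
        for r in prescriptions:
            w.writerow([r.rx_id, r.patient_id, r.provider_id, r.institution_id,
                        r.drug_code, r.start_date.isoformat(), r.days_supplied,
                        _fmt_num(r.units_per_day), _fmt_num(r.unit_strength_mg),
                        r.setting])


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------

def _matches_any(dx: str, prefixes: Sequence[str]) -> bool:
    return any(dx.startswith(p) for p in prefixes)


def select_cohort(
    patients: Sequence[PatientRecord],
    prescriptions: Sequence[PrescriptionRecord],
    criteria: CohortCriteria | None = None,
    catalog: OpioidCatalog | None = None,
) -> Cohort:
    """Select the study cohort.

    A patient is retained when they have (a) at least one diagnosis matching an
    include prefix, (b) no diagnosis matching an exclude prefix, (c) age >=
    ``min_age`` in the year of their first in-window outpatient opioid fill,
    and (d) at least one such fill.  Retained prescriptions are the outpatient
    catalog-opioid fills of retained patients within the window; NALOXONE rows
    of retained patients are carried alongside.  Selection is idempotent.
    """
    criteria = criteria or CohortCriteria()
    catalog = catalog or OpioidCatalog.default()
    lo, hi = criteria.study_window

    fills_by_patient: dict[str, list[PrescriptionRecord]] = {}
    naloxone_by_patient: dict[str, list[PrescriptionRecord]] = {}
    for r in prescriptions:
        if not (lo <= r.start_date <= hi) or r.setting != criteria.setting:
            continue
        if r.drug_code == NALOXONE_CODE:
            naloxone_by_patient.setdefault(r.patient_id, []).append(r)
        elif r.drug_code in catalog:
            fills_by_patient.setdefault(r.patient_id, []).append(r)

    attrition = {
        "total_patients": len(patients),
        "with_include_dx": 0,
        "after_cancer_exclusion": 0,
        "with_outpatient_opioid_fill": 0,
        "age_eligible": 0,
    }
    kept: list[PatientRecord] = []
    reference_years: dict[str, int] = {}
    for p in patients:
        if not any(_matches_any(dx, criteria.include_dx_prefixes) for dx in p.diagnoses):
            continue
        attrition["with_include_dx"] += 1
        if any(_matches_any(dx, criteria.exclude_dx_prefixes) for dx in p.diagnoses):
            continue
        attrition["after_cancer_exclusion"] += 1
        fills = fills_by_patient.get(p.patient_id)
        if not fills:
            continue
        attrition["with_outpatient_opioid_fill"] += 1
        ref_year = min(f.start_date for f in fills).year
        if ref_year - p.birth_year < criteria.min_age:
            continue
        attrition["age_eligible"] += 1
        kept.append(p)
        reference_years[p.patient_id] = ref_year

    kept_ids = {p.patient_id for p in kept}
    opioid_fills = [r for pid in kept_ids for r in fills_by_patient.get(pid, ())]
    opioid_fills.sort(key=lambda r: (r.start_date, r.rx_id))
    naloxone_fills = [r for pid in kept_ids for r in naloxone_by_patient.get(pid, ())]
    naloxone_fills.sort(key=lambda r: (r.start_date, r.rx_id))

    log.info("cohort attrition: %s", attrition)
    return Cohort(kept, opioid_fills, naloxone_fills, attrition, reference_years)


def assign_age_group(patient: PatientRecord, reference_year: int) -> str:
    """Bucket a patient by completed years at ``reference_year``.

    Buckets are 20-39, 40-59, 60-74 and 75+; ages below 20 should have been
    filtered by cohort selection and raise.
    """
    age = reference_year - patient.birth_year
    if age < 20:
        raise ClaimsError(f"patient {patient.patient_id!r} is under 20 (age {age})")
    if age <= 39:
        return "20-39"
    if age <= 59:
        return "40-59"
    if age <= 74:
        return "60-74"
    return "75+"


def morbidity_class(diagnoses: Iterable[str]) -> str | None:
    """Classify a patient's musculoskeletal morbidity.

    Arthropathies M00-M25, dorsopathies M40-M54, soft-tissue M60-M79; any other
    M code is "others".  A patient with several M codes is classified by the
    lexicographically first one (deterministic tie-break).  Returns None when
    no M code is present.
    """
    m_codes = sorted(d for d in diagnoses if d.startswith("M"))
    if not m_codes:
        return None
    head = m_codes[0][:3]
    for name, lo_code, hi_code in MORBIDITY_CLASSES:
        if lo_code <= head <= hi_code:
            return name
    return "others"
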