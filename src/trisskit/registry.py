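"""Trauma-registry schema, CSV I/O, cohort inclusion filtering, and missing-data accounting.

A registry is a flat table, one row per patient: demographics, per-region AIS
severities, arrival physiology (GCS total, systolic BP, respiratory rate) and
survival to discharge.  Any field may be missing (empty cell or a configurable
sentinel).  The study cohort is obtained by a fixed, ordered filter chain
mirroring a disposition flow diagram:

1. age 18 years or less,
2. blunt mechanism only (burns and penetrating trauma excluded),
3. no cardiac arrest on hospital arrival,
4. survival outcome known,
5. TRISS prediction computable (age, all six AIS regions, GCS, sBP, RR present).

Each excluded record is attributed to the *first* rule it fails, so exclusion
buckets partition the excluded set and stage counts are non-increasing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .scoring import ISS_REGIONS

__all__ = [
    "MECHANISMS",
    "PatientRecord",
    "RowIssue",
    "ReadResult",
    "CohortAccounting",
    "MissingnessReport",
    "RegistryError",
    "read_registry",
    "write_registry",
    "records_to_dataframe",
    "dataframe_to_records",
    "apply_inclusion",
    "missingness_report",
]

MECHANISMS = ("blunt", "penetrating", "burn")

#: Cell values treated as missing on read.
MISSING_SENTINELS = frozenset({"", "na", "nan", "none", "null", "."})

#: Predictor fields whose absence makes the TRISS Ps non-computable.
PREDICTOR_FIELDS = ("age", "ais", "gcs", "sbp", "rr")

#: Canonical CSV column names, logical field -> column.
DEFAULT_SCHEMA = {
    "patient_id": "patient_id",
    "age_years": "age_years",
    "sex": "sex",
    "mechanism": "mechanism",
    "arrest_on_arrival": "arrest_on_arrival",
    "gcs_total": "gcs_total",
    "sbp_mmhg": "sbp_mmhg",
    "rr_per_min": "rr_per_min",
    "survived": "survived",
    **{f"ais_{r}": f"ais_{r}" for r in ISS_REGIONS},
}


class RegistryError(ValueError):
    """Raised for unreadable or structurally invalid registry files."""


@dataclass
class PatientRecord:
    """One registry row; ``None`` marks a missing field."""

    patient_id: str
    age_years: Optional[int] = None
    sex: Optional[str] = None
    mechanism: Optional[str] = None
    arrest_on_arrival: Optional[bool] = None
    ais: dict = field(default_factory=lambda: {r: None for r in ISS_REGIONS})
    gcs_total: Optional[int] = None
    sbp_mmhg: Optional[float] = None
    rr_per_min: Optional[float] = None
    survived: Optional[bool] = None

    def ais_complete(self) -> bool:
        return all(self.ais.get(r) is not None for r in ISS_REGIONS)

    def predictor_missing_fields(self) -> list[str]:
        """Predictor fields (TRISS inputs) missing on this record."""
        out = []
        if self.age_years is None:
            out.append("age")
        if not self.ais_complete():
            out.append("ais")
        if self.gcs_total is None:
            out.append("gcs")
        if self.sbp_mmhg is None:
            out.append("sbp")
        if self.rr_per_min is None:
            out.append("rr")
        return out


@dataclass(frozen=True)
class RowIssue:
    """A row-numbered diagnostic produced while reading a registry CSV."""

    row: int  # 1-based data-row number (header excluded)
    fields: str
    message: str


@dataclass
class ReadResult:
    records: list[PatientRecord]
    issues: list[RowIssue]


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------


def _parse_missing(raw: Optional[str]) -> Optional[str]:
    if raw is None or raw.strip().lower() in MISSING_SENTINELS:
        return None
    return raw.strip()


def _parse_bool(raw: str) -> bool:
    low = raw.lower()
    if low in ("1", "true", "yes", "y", "t"):
        return True
    if low in ("0", "false", "no", "n", "f"):
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def _parse_row(row: Mapping[str, str], schema: Mapping[str, str], rownum: int):
    errors: list[RowIssue] = []

    def get(fieldname: str) -> Optional[str]:
        return _parse_missing(row.get(schema[fieldname]))

    def fail(fieldname: str, msg: str) -> None:
        errors.append(RowIssue(rownum, fieldname, msg))

    pid = get("patient_id") or f"row{rownum}"
    rec = PatientRecord(patient_id=pid)

    raw = get("age_years")
    if raw is not None:
        try:
            age = int(float(raw))
            if not (0 <= age <= 120):
                raise ValueError
            rec.age_years = age
        except ValueError:
            fail("age_years", f"age out of range 0..120: {raw!r}")

    raw = get("sex")
    if raw is not None:
        if raw.lower() in ("male", "female", "m", "f"):
            rec.sex = "male" if raw.lower().startswith("m") else "female"
        else:
            fail("sex", f"unknown sex code: {raw!r}")

    raw = get("mechanism")
    if raw is not None:
        if raw.lower() in MECHANISMS:
            rec.mechanism = raw.lower()
        else:
            fail("mechanism", f"unknown mechanism code: {raw!r}")

    raw = get("arrest_on_arrival")
    if raw is not None:
        try:
            rec.arrest_on_arrival = _parse_bool(raw)
        except ValueError:
            fail("arrest_on_arrival", f"not a boolean: {raw!r}")

    for region in ISS_REGIONS:
        raw = get(f"ais_{region}")
        if raw is not None:
            try:
                sev = int(float(raw))
                if not (0 <= sev <= 6):
                    raise ValueError
                rec.ais[region] = sev
            except ValueError:
                fail(f"ais_{region}", f"AIS severity out of range 0..6: {raw!r}")

    raw = get("gcs_total")
    if raw is not None:
        try:
            gcs = int(float(raw))
            if not (3 <= gcs <= 15):
                raise ValueError
            rec.gcs_total = gcs
        except ValueError:
            fail("gcs_total", f"GCS out of range 3..15: {raw!r}")

    raw = get("sbp_mmhg")
    if raw is not None:
        try:
            sbp = float(raw)
            if not (0 <= sbp <= 400):
                raise ValueError
            rec.sbp_mmhg = sbp
        except ValueError:
            fail("sbp_mmhg", f"systolic BP out of range 0..400: {raw!r}")

    raw = get("rr_per_min")
    if raw is not None:
        try:
            rr = float(raw)
            if not (0 <= rr <= 150):
                raise ValueError
            rec.rr_per_min = rr
        except ValueError:
            fail("rr_per_min", f"respiratory rate out of range 0..150: {raw!r}")

    raw = get("survived")
    if raw is not None:
        try:
            rec.survived = _parse_bool(raw)
        except ValueError:
            fail("survived", f"not a boolean: {raw!r}")

    return rec, errors


def read_registry(path, schema_config: Optional[Mapping[str, str]] = None) -> ReadResult:
    """Read a registry CSV into validated :class:`PatientRecord` objects.

    Malformed rows are rejected with row-numbered diagnostics collected in
    :attr:`ReadResult.issues` (never silently dropped); well-formed rows are
    kept.  ``schema_config`` remaps logical field names to CSV column names.
    """
    schema = dict(DEFAULT_SCHEMA)
    if schema_config:
        schema.update(schema_config)
    records: list[PatientRecord] = []
    issues: list[RowIssue] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise RegistryError(f"{path}: empty file, header required")
        for i, row in enumerate(reader, start=1):
            rec, errors = _parse_row(row, schema, i)
            if errors:
                issues.extend(errors)
            else:
                records.append(rec)
    seen: set[str] = set()
    for rec in records:
        if rec.patient_id in seen:
            raise RegistryError(f"duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)
    return ReadResult(records=records, issues=issues)


def records_to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age_years": r.age_years,
            "sex": r.sex,
            "mechanism": r.mechanism,
            "arrest_on_arrival": r.arrest_on_arrival,
            "gcs_total": r.gcs_total,
            "sbp_mmhg": r.sbp_mmhg,
            "rr_per_min": r.rr_per_min,
            "survived": r.survived,
        }
        for region in ISS_REGIONS:
            row[f"ais_{region}"] = r.ais.get(region)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA))


def dataframe_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def val(k, cast=None):
            v = d.get(k)
            if v is None or (isinstance(v, float) and pd.isna(v)) or pd.isna(v):
                return None
            return cast(v) if cast else v

        records.append(
            PatientRecord(
                patient_id=str(d["patient_id"]),
                age_years=val("age_years", int),
                sex=val("sex"),
                mechanism=val("mechanism"),
                arrest_on_arrival=val("arrest_on_arrival", bool),
                ais={r: val(f"ais_{r}", int) for r in ISS_REGIONS},
                gcs_total=val("gcs_total", int),
                sbp_mmhg=val("sbp_mmhg", float),
                rr_per_min=val("rr_per_min", float),
                survived=val("survived", bool),
            )
        )
    return records


def write_registry(records_or_df, path) -> None:
    """Write records (or an equivalent DataFrame) as a canonical registry CSV."""
    df = records_or_df if isinstance(records_or_df, pd.DataFrame) else records_to_dataframe(records_or_df)
    out = df.copy()
    for col in ("arrest_on_arrival", "survived"):
        if col in out:
            out[col] = out[col].map(lambda v: "" if v is None or pd.isna(v) else str(int(bool(v))))
    out.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Cohort filtering (flow-diagram order) and accounting
# ---------------------------------------------------------------------------

FILTER_STAGES = (
    "initial",
    "age_eligible",
    "blunt_only",
    "non_arrest",
    "outcome_known",
    "predictor_complete",
)


@dataclass
class CohortAccounting:
    """Stage counts along the inclusion filter chain plus exclusion buckets.

    ``stage_counts`` gives the number of records surviving after each stage in
    flow-diagram order; ``excluded`` attributes every excluded record to the
    first rule it failed, so the buckets partition the excluded set.
    """

    stage_counts: dict
    excluded: dict

    def to_json(self) -> str:
        return json.dumps({"stages": self.stage_counts, "excluded": self.excluded}, indent=2)

    def to_text(self) -> str:
        lines = ["Cohort disposition"]
        reasons = {
            "age_eligible": "aged 19+",
            "blunt_only": "burn or penetrating",
            "non_arrest": "cardiac arrest on arrival",
            "outcome_known": "missing survival outcome",
            "predictor_complete": "missing TRISS predictor",
        }
        lines.append(f"  initial registry              n = {self.stage_counts['initial']}")
        for stage in FILTER_STAGES[1:]:
            n_excl = self.excluded[stage]
            lines.append(f"  - excluded {reasons[stage]:<27s} {n_excl}")
            lines.append(f"    remaining                   n = {self.stage_counts[stage]}")
        return "\n".join(lines)


def apply_inclusion(records: Sequence[PatientRecord], max_age: int = 18):
    """Apply the ordered cohort filter; return ``(cohort, CohortAccounting)``.

    Order: age eligibility, blunt mechanism, no arrest on arrival, outcome
    known, TRISS predictors complete.  An empty cohort is allowed (reported,
    not raised).  Stage counts are invariant to record order.
    """
    stage_counts = {"initial": len(records)}
    excluded = {}
    current = list(records)

    def run_stage(name: str, keep) -> None:
        nonlocal current
        kept = [r for r in current if keep(r)]
        excluded[name] = len(current) - len(kept)
        stage_counts[name] = len(kept)
        current = kept

    run_stage("age_eligible", lambda r: r.age_years is None or r.age_years <= max_age)
    run_stage("blunt_only", lambda r: r.mechanism == "blunt")
    run_stage("non_arrest", lambda r: r.arrest_on_arrival is not True)
    run_stage("outcome_known", lambda r: r.survived is not None)
    run_stage("predictor_complete", lambda r: not r.predictor_missing_fields())

    return current, CohortAccounting(stage_counts=stage_counts, excluded=excluded)


# ---------------------------------------------------------------------------
# Missingness accounting
# ---------------------------------------------------------------------------


@dataclass
class MissingnessReport:
    """Per-field missing counts by age group with display-ready percentages."""

    counts: pd.DataFrame  # fields x groups, missing counts
    denominators: pd.Series  # group -> n records

    def percents(self) -> pd.DataFrame:
        """Missing fractions as percentages at 1 decimal; NaN where a group is empty."""
        from .scoring import round_half_up

        pct = self.counts.astype(float).copy()
        for g in pct.columns:
            n = self.denominators[g]
            if n == 0:
                pct[g] = float("nan")
            else:
                pct[g] = [round_half_up(100.0 * c / n, 1) for c in self.counts[g]]
        return pct

    def to_text(self) -> str:
        pct = self.percents()
        disp = pct.map(lambda v: "—" if pd.isna(v) else f"{v:.1f}%")
        disp.loc["n"] = [str(int(self.denominators[g])) for g in pct.columns]
        return disp.to_string()


def missingness_report(records: Sequence[PatientRecord], age_groups=None) -> MissingnessReport:
    """Count missing values per field, stratified by age group.

    Fields: survival outcome, each TRISS predictor, and the any-predictor
    composite.  Records with missing age go to an ``unknown`` group.
    Fractions use the supplied record set as denominator (stage n).
    """
    from .validation import AGE_GROUPS, age_group_label

    if age_groups is None:
        age_groups = AGE_GROUPS
    group_labels = [g.label for g in age_groups] + ["unknown", "total"]
    fields = ["survived", "any_predictor", "ais", "gcs", "sbp", "rr", "age"]
    counts = pd.DataFrame(0, index=fields, columns=group_labels)
    denom = pd.Series(0, index=group_labels)

    for rec in records:
        if rec.age_years is None:
            label = "unknown"
        else:
            label = age_group_label(rec.age_years, age_groups) or "unknown"
        for g in (label, "total"):
            denom[g] += 1
            missing = rec.predictor_missing_fields()
            if rec.survived is None:
                counts.loc["survived", g] += 1
            if missing:
                counts.loc["any_predictor", g] += 1
            for f in ("ais", "gcs", "sbp", "rr", "age"):
                if f in missing:
                    counts.loc[f, g] += 1
    return MissingnessReport(counts=counts, denominators=denom)
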