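"""Domain types, CSV ingestion, record validation, and transaction building.

The mining pipeline works on per-patient *sets*: the set of active-ingredient
drug codes a patient was exposed to, and the set of adverse-event terms graded
for that patient. This module turns long-format CSV tables into that
representation (:class:`ItemsetDB`) and applies case-deletion cleaning to the
raw laboratory table beforehand.

Expected CSV layouts (comma-separated, UTF-8, header required):

* exposures:       ``patient_id,drug_code``
* lab results:     ``patient_id,test_code,value,ref_low,ref_high``
* adverse events:  ``patient_id,ae_term,soc,grade``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPOSURE_COLUMNS = ("patient_id", "drug_code")
LAB_COLUMNS = ("patient_id", "test_code", "value", "ref_low", "ref_high")
AE_COLUMNS = ("patient_id", "ae_term", "soc", "grade")


class ConfigurationError(ValueError):
    """Raised for malformed inputs: missing columns, unsupported options."""


@dataclass(frozen=True)
class DrugExposure:
    """One patient-drug exposure; drug_code is active-ingredient normalized."""

    patient_id: str
    drug_code: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.drug_code:
            raise ValueError("drug_code must be non-empty")


@dataclass(frozen=True)
class LabResult:
    """A single laboratory measurement with its reference interval.

    ``ref_low``/``ref_high`` may be ``None`` when the laboratory did not
    report a bound; when both are present ``ref_low < ref_high`` must hold
    (violations are dropped by :func:`validate_records`, not raised).
    """

    patient_id: str
    test_code: str
    value: float
    ref_low: float | None = None
    ref_high: float | None = None


@dataclass(frozen=True)
class AERecord:
    """A graded adverse event for one patient (worst grade after rollup)."""

    patient_id: str
    ae_term: str
    soc: str
    grade: int

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise ValueError(f"grade must be in 1..4, got {self.grade}")


@dataclass
class ItemsetDB:
    """Per-patient drug and adverse-event sets — the transaction database.

    Patients are kept in insertion order of first appearance so every
    downstream computation is deterministic. Patients may have an empty drug
    set or an empty AE set (they still count in the denominator ``n``).
    """

    patients: list[str] = field(default_factory=list)
    drug_sets: dict[str, set[str]] = field(default_factory=dict)
    ae_sets: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.patients)

    def drug_vocabulary(self) -> list[str]:
        vocab: set[str] = set()
        for s in self.drug_sets.values():
            vocab |= s
        return sorted(vocab)

    def ae_vocabulary(self) -> list[str]:
        vocab: set[str] = set()
        for s in self.ae_sets.values():
            vocab |= s
        return sorted(vocab)

    def matrices(self) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
        """Boolean patient x drug and patient x AE membership matrices.

        Row order follows ``patients``; column order is the sorted
        vocabulary. Used internally for fast support counting.
        """
        drugs = self.drug_vocabulary()
        aes = self.ae_vocabulary()
        didx = {d: j for j, d in enumerate(drugs)}
        aidx = {a: j for j, a in enumerate(aes)}
        X = np.zeros((self.n, len(drugs)), dtype=bool)
        Y = np.zeros((self.n, len(aes)), dtype=bool)
        for i, pid in enumerate(self.patients):
            for d in self.drug_sets.get(pid, ()):
                X[i, didx[d]] = True
            for a in self.ae_sets.get(pid, ()):
                Y[i, aidx[a]] = True
        return X, drugs, Y, aes


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )


def read_exposures(path: str) -> list[DrugExposure]:
    """Read a patient-drug exposure CSV, deduplicating (patient, drug) pairs.

    drug_code is lower-cased and whitespace-stripped; dose/form normalization
    to active ingredient is assumed done upstream.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _require_columns(df, EXPOSURE_COLUMNS, str(path))
    n_rows = len(df)
    if n_rows == 0:
        logger.warning("%s: no exposure rows", path)
        return []
    seen: set[tuple[str, str]] = set()
    out: list[DrugExposure] = []
    for pid, code in zip(df["patient_id"], df["drug_code"]):
        pid = pid.strip()
        code = code.strip().lower()
        if not pid or not code:
            continue
        key = (pid, code)
        if key in seen:
            continue
        seen.add(key)
        out.append(DrugExposure(pid, code))
    logger.info("read %d exposure rows, %d after dedup", n_rows, len(out))
    return out


def write_exposures(exposures: Iterable[DrugExposure], path: str) -> None:
    """Write exposures back to CSV in the canonical dialect."""
    df = pd.DataFrame(
        [(e.patient_id, e.drug_code) for e in exposures],
        columns=list(EXPOSURE_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_labs(path: str) -> pd.DataFrame:
    """Read a laboratory-result CSV into a raw DataFrame.

    Numeric parsing is deliberately lenient (non-numeric values become NaN)
    so that :func:`validate_records` can report, rather than crash on, dirty
    rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _require_columns(df, LAB_COLUMNS, str(path))
    for col in ("value", "ref_low", "ref_high"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["patient_id"] = df["patient_id"].str.strip()
    df["test_code"] = df["test_code"].str.strip()
    return df


def read_ae_records(path: str) -> list[AERecord]:
    """Read a pre-graded adverse-event CSV, keeping the worst grade per
    (patient, term)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _require_columns(df, AE_COLUMNS, str(path))
    worst: dict[tuple[str, str], AERecord] = {}
    for pid, term, soc, grade in zip(
        df["patient_id"], df["ae_term"], df["soc"], df["grade"]
    ):
        pid = pid.strip()
        term = term.strip()
        if not pid or not term:
            continue
        g = int(grade)
        key = (pid, term)
        if key not in worst or g > worst[key].grade:
            worst[key] = AERecord(pid, term, soc.strip(), g)
    return list(worst.values())


# ---------------------------------------------------------------------------
# validation

#: the only missing-data remedy implemented; others are rejected.
SUPPORTED_DELETION_STRATEGIES = ("case",)


def validate_records(
    exposures: list[DrugExposure],
    labs: pd.DataFrame,
    *,
    strategy: str = "case",
) -> tuple[list[DrugExposure], list[LabResult], dict[str, int]]:
    """Case-deletion cleaning of exposure and laboratory tables.

    Rows violating a consistency rule are dropped and tallied, never raised:

    * ``missing id`` — empty patient_id (either table) or empty test_code
    * ``non-numeric value`` — lab value absent or unparseable
    * ``ref_low >= ref_high`` — inverted reference interval

    Returns the cleaned exposures, the cleaned labs as typed records, and the
    exclusion report mapping rule name to dropped-row count. Output rows are
    always a subset of input rows.
    """
    if strategy not in SUPPORTED_DELETION_STRATEGIES:
        raise ConfigurationError(
            f"deletion strategy {strategy!r} is not supported; only 'case' "
            "deletion is implemented (estimation, variable and pairwise "
            "deletion require manual review)"
        )
    report = {"missing id": 0, "non-numeric value": 0, "ref_low >= ref_high": 0}

    clean_exp: list[DrugExposure] = []
    for e in exposures:
        if not e.patient_id or not e.drug_code:
            report["missing id"] += 1
            continue
        clean_exp.append(e)

    clean_labs: list[LabResult] = []
    for row in labs.itertuples(index=False):
        if not row.patient_id or not row.test_code:
            report["missing id"] += 1
            continue
        if pd.isna(row.value) or not np.isfinite(row.value):
            report["non-numeric value"] += 1
            continue
        lo = None if pd.isna(row.ref_low) else float(row.ref_low)
        hi = None if pd.isna(row.ref_high) else float(row.ref_high)
        if lo is not None and hi is not None and lo >= hi:
            report["ref_low >= ref_high"] += 1
            continue
        clean_labs.append(
            LabResult(row.patient_id, row.test_code, float(row.value), lo, hi)
        )

    dropped = sum(report.values())
    if dropped:
        logger.info("validate_records dropped %d rows: %s", dropped, report)
    return clean_exp, clean_labs, report


# ---------------------------------------------------------------------------
# transaction building


def build_itemset_db(
    exposures: Iterable[DrugExposure], ae_records: Iterable[AERecord]
) -> ItemsetDB:
    """Assemble the transaction database from cleaned exposures and AEs.

    The patient universe is the union of ids across both tables: a patient
    with drugs but no graded AEs keeps an empty AE set (and vice versa) and
    still counts in ``n``. Iteration order is first appearance, exposures
    first.
    """
    db = ItemsetDB()

    def _ensure(pid: str) -> None:
        if pid not in db.drug_sets:
            db.patients.append(pid)
            db.drug_sets[pid] = set()
            db.ae_sets[pid] = set()

    for e in exposures:
        _ensure(e.patient_id)
        db.drug_sets[e.patient_id].add(e.drug_code)
    for r in ae_records:
        _ensure(r.patient_id)
        db.ae_sets[r.patient_id].add(r.ae_term)
    return db


def itemset_db_from_frames(
    exposures: pd.DataFrame, adverse_events: pd.DataFrame
) -> ItemsetDB:
    """Fast-path :func:`build_itemset_db` for long-format DataFrames
    (``patient_id,drug_code`` and ``patient_id,ae_term``)."""
    db = ItemsetDB()
    for pid, code in zip(exposures["patient_id"], exposures["drug_code"]):
        if pid not in db.drug_sets:
            db.patients.append(pid)
            db.drug_sets[pid] = set()
            db.ae_sets[pid] = set()
        db.drug_sets[pid].add(code)
    for pid, term in zip(adverse_events["patient_id"], adverse_events["ae_term"]):
        if pid not in db.drug_sets:
            db.patients.append(pid)
            db.drug_sets[pid] = set()
            db.ae_sets[pid] = set()
        db.ae_sets[pid].add(term)
    return db
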