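"""Grade laboratory abnormalities into adverse events and tabulate incidence.

Laboratory values are mapped onto severity grades 1-4 in the style of the
Common Terminology Criteria for Adverse Events (CTCAE): each adverse-event
term carries an ordered list of boundaries that the value must cross in the
rule's severity direction (``below`` for e.g. anemia, ``above`` for e.g.
hyperglycemia). The threshold table itself is user-supplied configuration —
an illustrative example ships in ``data/example_grading.yaml`` — because the
official CTCAE values are maintained externally and many sites adapt them.

Conventions fixed here:

* a value inside the reported reference interval is always grade 0;
* a value exactly on a boundary takes the more severe grade;
* a patient's grade for a term is the worst grade over all measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
import yaml

from .io_model import AERecord, LabResult

#: how rule boundaries are expressed
BOUNDARY_KINDS = ("absolute", "ratio", "offset")


@dataclass(frozen=True)
class GradeRule:
    """Severity boundaries for one (adverse event, lab test) pair.

    ``boundaries`` holds up to four cut points for grades 1..4; ``None``
    means the grade is not laboratory-defined (common for grade 4). With
    ``kind='absolute'`` boundaries are in the test's native unit; with
    ``'ratio'`` they multiply the relevant reference limit (upper limit for
    ``above`` rules, lower limit for ``below``); with ``'offset'`` they are
    added to it (use signed offsets).
    """

    ae_term: str
    soc: str
    test_code: str
    direction: str  # "above" | "below"
    boundaries: tuple[float | None, float | None, float | None, float | None]
    kind: str = "absolute"

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError(f"direction must be 'above' or 'below', got {self.direction!r}")
        if self.kind not in BOUNDARY_KINDS:
            raise ValueError(f"kind must be one of {BOUNDARY_KINDS}, got {self.kind!r}")
        present = [b for b in self.boundaries if b is not None]
        if not present:
            raise ValueError("at least one boundary must be present")
        # successive grades must be at least as extreme in the severity direction
        if self.direction == "below":
            ordered = all(x >= y for x, y in zip(present, present[1:]))
        else:
            ordered = all(x <= y for x, y in zip(present, present[1:]))
        if not ordered:
            raise ValueError(
                f"boundaries {self.boundaries} are not monotone toward severity "
                f"for a {self.direction!r} rule"
            )


def _absolute_boundaries(rule: GradeRule, lab: LabResult) -> list[float | None] | None:
    """Resolve rule boundaries to the lab's native unit; None if ungradeable
    (relative rule but the needed reference limit is missing)."""
    if rule.kind == "absolute":
        return list(rule.boundaries)
    ref = lab.ref_high if rule.direction == "above" else lab.ref_low
    if ref is None:
        return None
    if rule.kind == "ratio":
        return [None if b is None else b * ref for b in rule.boundaries]
    return [None if b is None else ref + b for b in rule.boundaries]


def grade_value(rule: GradeRule, lab: LabResult) -> int:
    """Grade one measurement against one rule; 0 means within normal limits.

    Returns the highest grade whose boundary the value meets; boundaries are
    inclusive toward the more severe grade. A relative rule applied to a lab
    row missing its reference limit returns 0 (callers tally these as
    ungradeable via :func:`derive_ae_records`).
    """
    if lab.test_code != rule.test_code:
        raise ValueError(
            f"rule is for test {rule.test_code!r}, lab row is {lab.test_code!r}"
        )
    if (
        lab.ref_low is not None
        and lab.ref_high is not None
        and lab.ref_low <= lab.value <= lab.ref_high
    ):
        return 0
    bounds = _absolute_boundaries(rule, lab)
    if bounds is None:
        return 0
    for g in (4, 3, 2, 1):
        b = bounds[g - 1]
        if b is None:
            continue
        if rule.direction == "below" and lab.value <= b:
            return g
        if rule.direction == "above" and lab.value >= b:
            return g
    return 0


def derive_ae_records(
    labs: list[LabResult],
    rules: list[GradeRule],
    *,
    report: dict[str, int] | None = None,
) -> list[AERecord]:
    """Apply every matching rule to every measurement; worst grade wins.

    One :class:`AERecord` is emitted per (patient, ae_term) whose worst grade
    is at least 1. Measurements a relative rule cannot grade (missing
    reference limit) are counted under ``report['ungradeable']`` when a
    report dict is passed.
    """
    by_test: dict[str, list[GradeRule]] = {}
    for r in rules:
        by_test.setdefault(r.test_code, []).append(r)

    worst: dict[tuple[str, str], tuple[int, str]] = {}
    order: list[tuple[str, str]] = []
    ungradeable = 0
    for lab in labs:
        for rule in by_test.get(lab.test_code, ()):
            if rule.kind != "absolute":
                ref = lab.ref_high if rule.direction == "above" else lab.ref_low
                if ref is None:
                    ungradeable += 1
                    continue
            g = grade_value(rule, lab)
            if g == 0:
                continue
            key = (lab.patient_id, rule.ae_term)
            if key not in worst:
                worst[key] = (g, rule.soc)
                order.append(key)
            elif g > worst[key][0]:
                worst[key] = (g, rule.soc)
    if report is not None:
        report["ungradeable"] = report.get("ungradeable", 0) + ungradeable
    return [
        AERecord(pid, term, worst[(pid, term)][1], worst[(pid, term)][0])
        for pid, term in order
    ]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of clinical tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, n: int) -> float:
    """Incidence percentage of ``count`` out of cohort size ``n``, rounded
    half-up to two decimals (e.g. 6426 of 16527 -> 38.88)."""
    if n < 1:
        raise ValueError("cohort size n must be >= 1")
    return round_half_up(100.0 * count / n)


INCIDENCE_COLUMNS = [
    "soc",
    "ae_term",
    "grade_1",
    "grade_2",
    "grade_3",
    "grade_4",
    "grand_total",
    "percentage",
]


def incidence_table(ae_records: list[AERecord], n: int) -> pd.DataFrame:
    """Tabulate per-term incidence by worst grade.

    Rows are keyed by (soc, ae_term); the grade columns count patients whose
    worst grade is that grade, so they sum to ``grand_total`` (distinct
    patients with the event at any grade); ``percentage`` is grand_total/n.
    """
    if n < 1:
        raise ValueError("cohort size n must be >= 1")
    if not ae_records:
        return pd.DataFrame(columns=INCIDENCE_COLUMNS)
    rows: dict[tuple[str, str], list[int]] = {}
    for r in ae_records:
        key = (r.soc, r.ae_term)
        rows.setdefault(key, [0, 0, 0, 0])[r.grade - 1] += 1
    out = []
    for (soc, term) in sorted(rows):
        g = rows[(soc, term)]
        total = sum(g)
        out.append([soc, term, g[0], g[1], g[2], g[3], total, percentage(total, n)])
    return pd.DataFrame(out, columns=INCIDENCE_COLUMNS)


def write_incidence_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_grading_config(path: str) -> list[GradeRule]:
    """Load grading rules from a YAML file.

    Each entry maps ``ae_term, soc, test_code, direction, kind, boundaries``;
    boundaries shorter than four entries are padded with nulls.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: grading config must be a list of rules")
    rules = []
    for entry in raw:
        bounds = list(entry["boundaries"])
        if len(bounds) > 4:
            raise ValueError(f"{path}: rule {entry.get('ae_term')}: more than 4 boundaries")
        bounds += [None] * (4 - len(bounds))
        rules.append(
            GradeRule(
                ae_term=entry["ae_term"],
                soc=entry.get("soc", ""),
                test_code=entry["test_code"],
                direction=entry["direction"],
                boundaries=tuple(bounds),
                kind=entry.get("kind", "absolute"),
            )
        )
    return rules
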