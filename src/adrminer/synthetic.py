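"""Synthetic cohorts with planted drug - adverse-event associations.

Real pharmacovigilance EHR extracts are rarely shareable, so the miners are
exercised on generated cohorts whose ground truth is known exactly. Each
patient's drug exposures are independent Bernoulli draws (optionally with
pairwise co-prescription boosts to create regimen-like two-drug antecedents);
each adverse event then occurs with probability given by a logistic model:

    logit p(ae | exposures) = logit(baseline) + sum_exposed log OR(drug, ae)

so an odds ratio of 1 is a null pair, OR > 1 plants a positive association
and OR < 1 a protective (negative) one. Occurring events receive a severity
grade drawn from a per-event grade distribution. The generator emits the
same long-format CSV tables the readers in :mod:`adrminer.io_model` consume,
plus a truth record of every non-unit odds ratio for evaluation.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssociationRule
from .io_model import ItemsetDB, itemset_db_from_frames

#: default severity distribution over grades 1..4 (mild events dominate,
#: matching the shape of routine laboratory AE tables)
DEFAULT_GRADE_PROBS = (0.60, 0.25, 0.10, 0.05)


@dataclass
class SyntheticSpec:
    """Generative parameters of a synthetic cohort.

    drugs: list of (drug_code, exposure prevalence in (0,1)).
    aes: list of (ae_term, baseline event rate in (0,1)).
    effects: mapping (drug_code, ae_term) -> odds ratio (> 0; 1 is null).
    co_rx: (drug_i, drug_j, boost >= 1): patients exposed to drug_i have
        their drug_j exposure redrawn at min(1, prevalence_j * boost).
    grade_probs: per-AE distribution over grades 1..4 (defaulted).
    """

    n_patients: int
    drugs: list[tuple[str, float]]
    aes: list[tuple[str, float]]
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    co_rx: list[tuple[str, str, float]] = field(default_factory=list)
    grade_probs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        drug_names = [d for d, _ in self.drugs]
        ae_names = [a for a, _ in self.aes]
        if len(set(drug_names)) != len(drug_names):
            raise ValueError("drugs: duplicate drug_code")
        if len(set(ae_names)) != len(ae_names):
            raise ValueError("aes: duplicate ae_term")
        for d, p in self.drugs:
            if not 0 < p < 1:
                raise ValueError(f"drugs: prevalence of {d!r} must be in (0,1)")
        for a, p in self.aes:
            if not 0 < p < 1:
                raise ValueError(f"aes: baseline rate of {a!r} must be in (0,1)")
        for (d, a), orr in self.effects.items():
            if orr <= 0:
                raise ValueError(f"effects: OR({d},{a}) must be > 0")
            if d not in drug_names:
                raise ValueError(f"effects: unknown drug {d!r}")
            if a not in ae_names:
                raise ValueError(f"effects: unknown ae_term {a!r}")
        for d1, d2, boost in self.co_rx:
            if boost < 1:
                raise ValueError(f"co_rx: boost for ({d1},{d2}) must be >= 1")
            if d1 not in drug_names or d2 not in drug_names:
                raise ValueError(f"co_rx: unknown drug in ({d1},{d2})")
        for a, probs in self.grade_probs.items():
            if a not in ae_names:
                raise ValueError(f"grade_probs: unknown ae_term {a!r}")
            if len(probs) != 4 or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"grade_probs: {a!r} must give 4 probs summing to 1")


def null_spec(
    n_patients: int = 2000,
    n_drugs: int = 20,
    n_aes: int = 10,
    prevalence: float = 0.2,
    base_rate: float = 0.2,
    seed: int = 0,
) -> SyntheticSpec:
    """A fully null cohort: every drug-AE odds ratio is 1."""
    return SyntheticSpec(
        n_patients=n_patients,
        drugs=[(f"drug{i:02d}", prevalence) for i in range(n_drugs)],
        aes=[(f"ae{j:02d}", base_rate) for j in range(n_aes)],
        seed=seed,
    )


def planted_spec(
    n_patients: int = 5000,
    n_drugs: int = 10,
    n_aes: int = 6,
    prevalence: float = 0.2,
    base_rate: float = 0.2,
    or_positive: float = 3.0,
    or_negative: float = 1 / 3.0,
    seed: int = 0,
) -> SyntheticSpec:
    """A cohort with one planted positive and one planted negative pair,
    one co-prescribed drug pair, and all remaining pairs null."""
    spec = null_spec(n_patients, n_drugs, n_aes, prevalence, base_rate, seed)
    spec.effects = {
        ("drug00", "ae00"): or_positive,
        ("drug01", "ae01"): or_negative,
    }
    spec.co_rx = [("drug02", "drug03", 2.0)]
    return spec


@dataclass
class Cohort:
    """Generated tables plus the generative truth."""

    exposures: pd.DataFrame  # patient_id, drug_code
    adverse_events: pd.DataFrame  # patient_id, ae_term, soc, grade
    truth: dict

    def itemset_db(self) -> ItemsetDB:
        db = itemset_db_from_frames(self.exposures, self.adverse_events)
        # patients with neither exposures nor events still belong to the cohort
        for pid in self.truth["patients"]:
            if pid not in db.drug_sets:
                db.patients.append(pid)
                db.drug_sets[pid] = set()
                db.ae_sets[pid] = set()
        return db


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Draw one cohort from the generative model; reproducible from seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    drug_names = [d for d, _ in spec.drugs]
    ae_names = [a for a, _ in spec.aes]
    prev = np.array([p for _, p in spec.drugs])
    base = np.array([p for _, p in spec.aes])
    didx = {d: j for j, d in enumerate(drug_names)}
    aidx = {a: j for j, a in enumerate(ae_names)}
    pids = [f"P{i+1:06d}" for i in range(n)]

    X = rng.random((n, len(drug_names))) < prev[None, :]
    for d1, d2, boost in spec.co_rx:
        j1, j2 = didx[d1], didx[d2]
        p2 = min(1.0, prev[j2] * boost)
        redraw = rng.random(n) < p2
        X[X[:, j1], j2] = redraw[X[:, j1]]

    # log-odds: baseline plus additive exposure effects
    logit = np.tile(np.log(base / (1 - base)), (n, 1))
    for (d, a), orr in spec.effects.items():
        logit[:, aidx[a]] += X[:, didx[d]] * math.log(orr)
    p_ae = 1.0 / (1.0 + np.exp(-logit))
    Y = rng.random((n, len(ae_names))) < p_ae

    grade_mat = np.zeros_like(Y, dtype=int)
    for j, a in enumerate(ae_names):
        probs = spec.grade_probs.get(a, DEFAULT_GRADE_PROBS)
        grade_mat[:, j] = rng.choice(4, size=n, p=probs) + 1

    ii, jj = np.nonzero(X)
    exposures = pd.DataFrame(
        {"patient_id": [pids[i] for i in ii], "drug_code": [drug_names[j] for j in jj]}
    )
    ii, jj = np.nonzero(Y)
    adverse_events = pd.DataFrame(
        {
            "patient_id": [pids[i] for i in ii],
            "ae_term": [ae_names[j] for j in jj],
            "soc": "Synthetic",
            "grade": grade_mat[ii, jj],
        }
    )
    truth = {
        "seed": spec.seed,
        "n_patients": n,
        "patients": pids,
        "drugs": {d: float(p) for d, p in spec.drugs},
        "aes": {a: float(p) for a, p in spec.aes},
        "effects": [
            {"drug": d, "ae_term": a, "odds_ratio": float(orr)}
            for (d, a), orr in sorted(spec.effects.items())
            if orr != 1.0
        ],
    }
    return Cohort(exposures, adverse_events, truth)


def write_cohort(cohort: Cohort, outdir: str) -> dict[str, str]:
    """Write exposures.csv, adverse_events.csv, truth.json under outdir."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "exposures": os.path.join(outdir, "exposures.csv"),
        "adverse_events": os.path.join(outdir, "adverse_events.csv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    cohort.exposures.to_csv(paths["exposures"], index=False)
    cohort.adverse_events.to_csv(paths["adverse_events"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
    return paths


def evaluate_against_truth(
    rules: list[AssociationRule],
    truth: dict,
    *,
    two_drug_rule: str = "all",
) -> dict:
    """Score mined rules against planted effects.

    A truth pair (drug, ae, OR) is *recalled* when some rule's antecedent
    contains the drug, its consequent is the ae, and the rule's direction
    matches the OR side of 1. A rule is a *true positive* (for precision)
    when its consequent has planted effects covering its antecedent: with
    ``two_drug_rule='all'`` every antecedent drug must carry a non-unit OR
    for that AE; with ``'any'`` one suffices. Sign accuracy is the fraction
    of true-positive rules whose direction matches. With no rules, precision
    is reported as 1.0 with ``precision_defined=False``.
    """
    if two_drug_rule not in ("all", "any"):
        raise ValueError(f"two_drug_rule must be 'all' or 'any', got {two_drug_rule!r}")
    effects = {(e["drug"], e["ae_term"]): e["odds_ratio"] for e in truth["effects"]}

    def sign_ok(direction: str, orr: float) -> bool:
        return (direction == "positive" and orr > 1) or (
            direction == "negative" and orr < 1
        )

    recalled = 0
    for (d, a), orr in effects.items():
        if any(
            d in r.antecedent and r.consequent == a and sign_ok(r.direction, orr)
            for r in rules
        ):
            recalled += 1

    tp = sign_hits = 0
    for r in rules:
        keys = [(d, r.consequent) for d in r.antecedent]
        hit = [k for k in keys if k in effects]
        matched = len(hit) == len(keys) if two_drug_rule == "all" else bool(hit)
        if matched:
            tp += 1
            if all(sign_ok(r.direction, effects[k]) for k in hit):
                sign_hits += 1

    out = {
        "n_rules": len(rules),
        "n_truth": len(effects),
        "recall": recalled / len(effects) if effects else float("nan"),
        "precision": tp / len(rules) if rules else 1.0,
        "precision_defined": bool(rules),
        "sign_accuracy": sign_hits / tp if tp else float("nan"),
    }
    return out
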