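"""Conventional support/confidence mining and the two-miner comparison.

The conventional Apriori rule miner keeps every (frequent itemset, AE) pair
whose confidence clears min_cof — no chi-square screen — so its rule set
always contains the modified miner's rule set at equal parameters. comp is
still computed and attached so the two rule sets can be compared
statistically, and each conventional rule is labelled positive/negative post
hoc by the sign of comp (the conventional algorithm itself cannot make that
distinction; the labelling only serves the comparison).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .apriori import mine_frequent_itemsets
from .association import (
    AssociationRule,
    MiningParams,
    _rows_to_rules,
    _score_pairs,
    mine_rules,
)
from .io_model import ItemsetDB


def mine_rules_conventional(
    db: ItemsetDB,
    min_sup: int | float,
    min_cof: float,
    max_antecedent: int = 2,
    support_def: str = "antecedent",
) -> list[AssociationRule]:
    """Support/confidence-only mining: retain every pair with confidence >=
    min_cof. Direction is the post-hoc sign of comp; validity is flagged."""
    itemsets = mine_frequent_itemsets(db, min_sup, max_antecedent)
    scored = _score_pairs(db, itemsets, support_def)
    if scored.empty:
        return []
    scored = scored[(scored["confidence"] >= min_cof).fillna(False)]

    def direction(compv: float) -> str:
        if np.isfinite(compv) and compv > 0:
            return "positive"
        if np.isfinite(compv) and compv < 0:
            return "negative"
        return "none"

    return _rows_to_rules(scored, direction)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact enumeration when the pooled sample has at most 12 observations and
    no ties; otherwise the normal approximation with tie and continuity
    corrections. Returns (U statistic of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 12 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonReport:
    """Side-by-side statistics of the conventional and modified rule sets.

    ``strata`` has one row per (antecedent size, direction) with each
    algorithm's rule count and mean comp/support/confidence, plus the
    rank-sum p-value comparing the two comp distributions (NaN when either
    side of a stratum is empty). Runtimes are wall-clock seconds and are
    informational only.
    """

    n_patients: int
    params: MiningParams
    conventional_total: int
    modified_total: int
    conventional_runtime_s: float
    modified_runtime_s: float
    strata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path: str) -> None:
        self.strata.to_csv(path, sep="\t", index=False, na_rep="NA")

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "n_patients": self.n_patients,
            "conventional_total": self.conventional_total,
            "modified_total": self.modified_total,
            "conventional_runtime_s": self.conventional_runtime_s,
            "modified_runtime_s": self.modified_runtime_s,
            "strata": json.loads(self.strata.to_json(orient="records")),
        }
        text = json.dumps(payload, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _stratum_stats(rules: list[AssociationRule], size: int, direction: str):
    sel = [r for r in rules if len(r.antecedent) == size and r.direction == direction]
    comps = np.array([r.comp for r in sel], dtype=float)
    if not sel:
        return 0, float("nan"), float("nan"), float("nan"), comps
    return (
        len(sel),
        float(np.nanmean(comps)),
        float(np.mean([r.support for r in sel])),
        float(np.mean([r.confidence for r in sel])),
        comps,
    )


def compare_algorithms(db: ItemsetDB, params: MiningParams) -> ComparisonReport:
    """Run both miners at identical parameters and compare them per stratum.

    Strata are (antecedent size in 1..max_antecedent) x (positive, negative).
    The rank-sum p compares the comp values of the two algorithms' rules in
    the stratum; it is NaN whenever either rule set is empty there.
    """
    t0 = time.perf_counter()
    conventional = mine_rules_conventional(
        db, params.min_sup, params.min_cof, params.max_antecedent, params.support_def
    )
    t1 = time.perf_counter()
    modified = mine_rules(db, params)
    t2 = time.perf_counter()

    rows = []
    for size in range(1, params.max_antecedent + 1):
        for direction in ("positive", "negative"):
            cn, c_comp, c_sup, c_conf, c_vals = _stratum_stats(
                conventional, size, direction
            )
            mn, m_comp, m_sup, m_conf, m_vals = _stratum_stats(
                modified, size, direction
            )
            c_vals = c_vals[np.isfinite(c_vals)]
            m_vals = m_vals[np.isfinite(m_vals)]
            if c_vals.size and m_vals.size:
                _, p = rank_sum_test(c_vals, m_vals)
            else:
                p = float("nan")
            rows.append(
                {
                    "antecedent_size": size,
                    "direction": direction,
                    "conventional_n": cn,
                    "conventional_comp_mean": c_comp,
                    "conventional_support_mean": c_sup,
                    "conventional_confidence_mean": c_conf,
                    "modified_n": mn,
                    "modified_comp_mean": m_comp,
                    "modified_support_mean": m_sup,
                    "modified_confidence_mean": m_conf,
                    "rank_sum_p": p,
                }
            )
    return ComparisonReport(
        n_patients=db.n,
        params=params,
        conventional_total=len(conventional),
        modified_total=len(modified),
        conventional_runtime_s=t1 - t0,
        modified_runtime_s=t2 - t1,
        strata=pd.DataFrame(rows),
    )
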