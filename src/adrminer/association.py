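"""Signed chi-square screening of (drug itemset -> adverse event) rules.

For each frequent drug combination X and adverse-event term Y, the 2x2 table

    =============  ==========  ==========
                   Y present   Y absent
    X present      a           b
    X absent       c           d
    =============  ==========  ==========

yields the Pearson statistic (df = 1)

    chi2 = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)],   n = a+b+c+d,

and the screening statistic ``comp``, the signed square root of chi2:

    comp = sign(ad - bc) * sqrt(chi2) = sqrt(n) * phi,

where phi is the phi coefficient of the two binary variables. A rule is kept
when its confidence a/(a+b) clears ``min_cof`` and |comp| exceeds the minimum
test value ``min_tev`` derived from the chi-square critical value at level
alpha; the sign of comp classifies the rule as a positive association (the
drug combination raises the event frequency) or a negative one (it lowers
it). Rule strength is ranked by |comp|.

``threshold_mode`` controls the scale of min_tev. Mode ``'paper'`` compares
comp directly against the chi-square critical value itself (3.841 at
alpha=0.05) — a deliberately conservative screen; mode ``'sqrt_scale'``
compares against its square root (1.960 at 0.05), which puts the threshold
on the same scale as comp and makes the two-sided screen an exact
alpha-level test. Both are offered because each is defensible; see
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .apriori import Itemset, mine_frequent_itemsets, resolve_min_sup
from .io_model import ItemsetDB


class UndefinedStatisticError(ValueError):
    """A 2x2 margin is zero, so chi-square (and comp) are undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 counts a, b, c, d (see module docstring for orientation)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cell counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) marginal totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def expected(self) -> tuple[float, float, float, float]:
        """Expected cell counts under independence (row*col/n)."""
        r1, r2, c1, c2 = self.margins()
        n = self.n
        if n == 0:
            raise UndefinedStatisticError("empty table")
        return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


def chi_square(t: ContingencyTable) -> float:
    """Pearson chi-square (df=1) by the shortcut determinant formula."""
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        raise UndefinedStatisticError(f"zero margin in table {t}")
    det = t.a * t.d - t.b * t.c
    return t.n * det * det / (r1 * r2 * c1 * c2)


def comp(t: ContingencyTable) -> float:
    """Signed square root of chi-square; sign follows ad - bc.

    Positive when the antecedent raises the event frequency, negative when
    it lowers it, zero exactly when ad = bc (independence).
    """
    det = t.a * t.d - t.b * t.c
    return math.copysign(math.sqrt(chi_square(t)), det) if det else 0.0


def min_tev(alpha: float = 0.05, mode: str = "paper") -> float:
    """Minimum test value: the screening threshold for |comp|.

    ``'paper'`` returns the chi-square(1) upper-alpha critical value
    (3.841 at alpha=0.05); ``'sqrt_scale'`` its square root (1.960), the
    standard-normal two-sided critical value matching comp's scale.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    crit = float(stats.chi2.ppf(1 - alpha, df=1))
    if mode == "paper":
        return crit
    if mode == "sqrt_scale":
        return math.sqrt(crit)
    raise ValueError(f"unknown threshold mode {mode!r}")


def validity_check(t: ContingencyTable) -> bool:
    """Chi-square applicability: n > 40 and every expected count >= 5."""
    if t.n == 0:
        return False
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        return False
    return t.n > 40 and min(t.expected()) >= 5


def build_table(
    db: ItemsetDB, antecedent: Itemset | Sequence[str], consequent: str
) -> ContingencyTable:
    """Count the 2x2 table for a drug combination vs one AE term.

    A patient is antecedent-positive only with ALL the drugs in the itemset,
    and event-positive with the AE at any grade >= 1. The denominator is the
    full cohort n.
    """
    items = antecedent.items if isinstance(antecedent, Itemset) else tuple(antecedent)
    if not items:
        raise ValueError("antecedent must be non-empty")
    need = set(items)
    a = b = c = d = 0
    for pid in db.patients:
        exposed = need <= db.drug_sets.get(pid, set())
        event = consequent in db.ae_sets.get(pid, set())
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def reconstruct_table(
    n: int, support: float, confidence_pct: float, ae_total: int
) -> ContingencyTable:
    """Rebuild a 2x2 table from published rule marginals.

    Given the cohort size, the rule's antecedent support fraction, its
    confidence in percent, and the event's total incidence count:
    a+b = round(support*n), a = round(confidence*(a+b)), a+c = ae_total.
    """
    row1 = round(support * n)
    a = round(confidence_pct / 100.0 * row1)
    b = row1 - a
    c = ae_total - a
    d = n - a - b - c
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# rule mining


@dataclass(frozen=True)
class MiningParams:
    """Knobs of the rule-mining run.

    min_sup: absolute support count, or fraction of the cohort in (0,1).
    min_cof: minimum confidence in percent.
    alpha: significance level feeding min_tev.
    threshold_mode: 'paper' (chi-square critical value) or 'sqrt_scale'.
    max_antecedent: largest drug-combination size mined.
    support_def: 'antecedent' reports the antecedent itemset's support as the
        rule's support; 'joint' reports a/n instead.
    bh_correct: additionally require a Benjamini-Hochberg adjusted two-sided
        p-value <= alpha across all candidate pairs.
    """

    min_sup: int | float = 165
    min_cof: float = 10.0
    alpha: float = 0.05
    threshold_mode: Literal["paper", "sqrt_scale"] = "paper"
    max_antecedent: int = 2
    support_def: Literal["antecedent", "joint"] = "antecedent"
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.min_cof <= 100:
            raise ValueError(f"min_cof must be in (0,100], got {self.min_cof}")
        if self.max_antecedent < 1:
            raise ValueError("max_antecedent must be >= 1")
        if self.threshold_mode not in ("paper", "sqrt_scale"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.support_def not in ("antecedent", "joint"):
            raise ValueError(f"unknown support_def {self.support_def!r}")


@dataclass(frozen=True)
class AssociationRule:
    """One mined (drug itemset -> adverse event) rule with its statistics."""

    antecedent: tuple[str, ...]
    consequent: str
    table: ContingencyTable
    support: float
    confidence: float  # percent
    chi2: float  # nan when a margin is zero
    comp: float  # nan when a margin is zero
    direction: Literal["positive", "negative", "none"]
    valid: bool
    p_value: float = float("nan")


def _score_pairs(
    db: ItemsetDB, itemsets: Sequence[Itemset], support_def: str
) -> pd.DataFrame:
    """Vectorized statistics for every (frequent itemset, AE term) pair."""
    X, drugs, Y, aes = db.matrices()
    if not itemsets or not aes:
        return pd.DataFrame(
            columns=["antecedent", "consequent", "a", "b", "c", "d",
                     "support", "confidence", "chi2", "comp", "valid"]
        )
    col = {dname: j for j, dname in enumerate(drugs)}
    expo = np.stack(
        [X[:, [col[d] for d in it.items]].all(axis=1) for it in itemsets]
    ).astype(np.float64)  # m x n
    Yf = Y.astype(np.float64)
    n = float(db.n)

    a = expo @ Yf  # m x n_ae
    row1 = expo.sum(axis=1)[:, None]
    col1 = Yf.sum(axis=0)[None, :]
    b = row1 - a
    c = col1 - a
    d = n - a - b - c
    det = a * d - b * c
    denom = row1 * (n - row1) * col1 * (n - col1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * det**2 / denom, np.nan)
        comp_ = np.sign(det) * np.sqrt(chi2)
        conf = np.where(row1 > 0, 100.0 * a / row1, np.nan)
    # validity: n>40 and all expected counts >= 5
    e_min = np.minimum.reduce(
        [row1 * col1 / n, row1 * (n - col1) / n, (n - row1) * col1 / n,
         (n - row1) * (n - col1) / n]
    )
    valid = (n > 40) & (e_min >= 5) & (denom > 0)

    rows = []
    for i, it in enumerate(itemsets):
        sup_ant = it.support_count / n
        for j, ae in enumerate(aes):
            sup = sup_ant if support_def == "antecedent" else a[i, j] / n
            rows.append(
                (it.items, ae, int(a[i, j]), int(b[i, j]), int(c[i, j]),
                 int(d[i, j]), sup, conf[i, j], chi2[i, j], comp_[i, j],
                 bool(valid[i, j]))
            )
    return pd.DataFrame(
        rows,
        columns=["antecedent", "consequent", "a", "b", "c", "d",
                 "support", "confidence", "chi2", "comp", "valid"],
    )


def _rows_to_rules(
    scored: pd.DataFrame, direction_fn
) -> list[AssociationRule]:
    rules = []
    for r in scored.itertuples(index=False):
        chi2v = float(r.chi2) if not pd.isna(r.chi2) else float("nan")
        compv = float(r.comp) if not pd.isna(r.comp) else float("nan")
        p = float(stats.chi2.sf(chi2v, df=1)) if np.isfinite(chi2v) else float("nan")
        rules.append(
            AssociationRule(
                antecedent=tuple(r.antecedent),
                consequent=r.consequent,
                table=ContingencyTable(r.a, r.b, r.c, r.d),
                support=float(r.support),
                confidence=float(r.confidence),
                chi2=chi2v,
                comp=compv,
                direction=direction_fn(compv),
                valid=bool(r.valid),
                p_value=p,
            )
        )
    return rule_strength_rank(rules)


def rule_strength_rank(rules: Sequence[AssociationRule]) -> list[AssociationRule]:
    """Stable sort by |comp| descending; ties break lexicographically by
    antecedent then consequent. Rules with undefined comp sort last."""
    def key(r: AssociationRule):
        mag = abs(r.comp) if np.isfinite(r.comp) else -math.inf
        return (-mag, r.antecedent, r.consequent)

    return sorted(rules, key=key)


def _bh_keep(scored: pd.DataFrame, alpha: float) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    p = stats.chi2.sf(scored["chi2"].to_numpy(dtype=float), df=1)
    keep = np.zeros(len(scored), dtype=bool)
    finite = np.isfinite(p)
    if finite.any():
        keep[finite] = multipletests(p[finite], alpha=alpha, method="fdr_bh")[0]
    return keep


def mine_rules(db: ItemsetDB, params: MiningParams) -> list[AssociationRule]:
    """The modified miner: frequent itemsets, then the comp/min_tev screen.

    Step 1 mines frequent drug itemsets at min_sup; Step 2 scores every
    (itemset, AE) pair and retains those with confidence >= min_cof and
    |comp| > min_tev(alpha, threshold_mode). Rules are returned strongest
    first (by |comp|). Rules failing the chi-square validity condition are
    retained but flagged ``valid=False``.
    """
    itemsets = mine_frequent_itemsets(db, params.min_sup, params.max_antecedent)
    scored = _score_pairs(db, itemsets, params.support_def)
    if scored.empty:
        return []
    thr = min_tev(params.alpha, params.threshold_mode)
    keep = (scored["confidence"] >= params.min_cof) & (
        scored["comp"].abs() > thr
    )
    if params.bh_correct:
        keep &= _bh_keep(scored, params.alpha)
    scored = scored[keep.fillna(False)]

    def direction(compv: float) -> str:
        if np.isfinite(compv) and compv > thr:
            return "positive"
        if np.isfinite(compv) and compv < -thr:
            return "negative"
        return "none"

    return _rows_to_rules(scored, direction)


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Flatten rules for TSV/JSON output."""
    return pd.DataFrame(
        [
            {
                "antecedent": ";".join(r.antecedent),
                "consequent": r.consequent,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "n": r.table.n,
                "support": r.support,
                "confidence": r.confidence,
                "chi2": r.chi2,
                "comp": r.comp,
                "p_value": r.p_value,
                "direction": r.direction,
                "valid": r.valid,
            }
            for r in rules
        ]
    )
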