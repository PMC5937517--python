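"""Level-wise (Apriori) frequent-itemset mining over patient drug sets.

Classic Agrawal-Srikant candidate generation: frequent (k-1)-itemsets are
joined on their first k-2 items, candidates any of whose (k-1)-subsets are
infrequent are pruned, and survivors are support-counted against the
transaction database. Support counting is per patient: a patient contributes
at most one to an itemset's count no matter how often a drug was prescribed.

Itemsets are plain sorted tuples of drug codes throughout; the public result
type :class:`Itemset` pairs the tuple with its exact support count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .io_model import ItemsetDB


@dataclass(frozen=True, order=True)
class Itemset:
    items: tuple[str, ...]
    support_count: int

    def __post_init__(self) -> None:
        if tuple(sorted(set(self.items))) != self.items:
            raise ValueError(f"items must be sorted and duplicate-free: {self.items}")
        if self.support_count < 0:
            raise ValueError("support_count must be >= 0")

    @property
    def size(self) -> int:
        return len(self.items)


def resolve_min_sup(min_sup: int | float, n: int) -> int:
    """Normalize the minimum support to an absolute count.

    An integer is taken as a count; a float in (0, 1) as a fraction of the
    cohort, converted by flooring (1% of 16,527 patients -> 165).
    """
    if isinstance(min_sup, float) and 0 < min_sup < 1:
        count = math.floor(min_sup * n)
    else:
        count = int(min_sup)
    if count < 1:
        raise ValueError(f"min_sup must resolve to a count >= 1, got {count}")
    return count


def _as_tuples(itemsets: Sequence) -> list[tuple[str, ...]]:
    return [it.items if isinstance(it, Itemset) else tuple(it) for it in itemsets]


def find_frequent_1_itemsets(db: ItemsetDB, min_sup: int | float) -> list[Itemset]:
    """First pass: single drugs with support count >= min_sup, sorted."""
    min_count = resolve_min_sup(min_sup, db.n) if db.n else int(min_sup)
    counts: dict[str, int] = {}
    for s in db.drug_sets.values():
        for d in s:
            counts[d] = counts.get(d, 0) + 1
    return [
        Itemset((d,), c) for d, c in sorted(counts.items()) if c >= min_count
    ]


def apriori_join(L_prev: Sequence) -> list[tuple[str, ...]]:
    """Join frequent (k-1)-itemsets sharing their first k-2 items into
    k-candidates. Output is sorted and duplicate-free."""
    prev = sorted(set(_as_tuples(L_prev)))
    if not prev:
        return []
    sizes = {len(t) for t in prev}
    if len(sizes) != 1:
        raise ValueError(f"mixed itemset sizes in join input: {sorted(sizes)}")
    k = sizes.pop() + 1
    out: list[tuple[str, ...]] = []
    for i, p in enumerate(prev):
        for q in prev[i + 1 :]:
            if p[: k - 2] != q[: k - 2]:
                break  # sorted order: later q cannot share the prefix either
            out.append(p + (q[-1],))
    return out


def apriori_prune(
    candidates: Sequence[tuple[str, ...]], L_prev: Sequence
) -> list[tuple[str, ...]]:
    """Drop candidates with any infrequent (k-1)-subset (anti-monotonicity)."""
    prev = set(_as_tuples(L_prev))
    kept = []
    for c in _as_tuples(candidates):
        if all(sub in prev for sub in combinations(c, len(c) - 1)):
            kept.append(c)
    return kept


def mine_frequent_itemsets(
    db: ItemsetDB, min_sup: int | float, max_k: int = 2
) -> list[Itemset]:
    """All itemsets with support >= min_sup and size <= max_k.

    Equivalent to exhaustive enumeration; ordering is (size, lexicographic)
    and therefore deterministic.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    if db.n == 0:
        return []
    min_count = resolve_min_sup(min_sup, db.n)

    X, drugs, _, _ = db.matrices()
    col = {d: j for j, d in enumerate(drugs)}

    result = find_frequent_1_itemsets(db, min_count)
    L_prev = [it.items for it in result]
    k = 2
    while L_prev and k <= max_k:
        candidates = apriori_prune(apriori_join(L_prev), L_prev)
        Lk: list[Itemset] = []
        for c in candidates:
            count = int(X[:, [col[d] for d in c]].all(axis=1).sum())
            if count >= min_count:
                Lk.append(Itemset(c, count))
        result.extend(Lk)
        L_prev = [it.items for it in Lk]
        k += 1
    return result


def itemsets_to_rows(itemsets: Sequence[Itemset], n: int) -> list[dict]:
    """TSV-friendly rows: items (semicolon-joined), size, count, fraction."""
    return [
        {
            "items": ";".join(it.items),
            "size": it.size,
            "support_count": it.support_count,
            "support_fraction": it.support_count / n if n else float("nan"),
        }
        for it in itemsets
    ]
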