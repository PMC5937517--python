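import numpy as np
import pytest

from adrminer.io_model import ItemsetDB


def make_db(drug_sets: dict, ae_sets: dict | None = None) -> ItemsetDB:
    """Assemble an ItemsetDB from plain dicts (patients in dict order)."""
    ae_sets = ae_sets or {}
    db = ItemsetDB()
    for pid in list(drug_sets) + [p for p in ae_sets if p not in drug_sets]:
        db.patients.append(pid)
        db.drug_sets[pid] = set(drug_sets.get(pid, ()))
        db.ae_sets[pid] = set(ae_sets.get(pid, ()))
    return db


def random_db(rng: np.random.Generator, n_items: int = 8, n_trans: int = 50,
              density: float = 0.3) -> ItemsetDB:
    """A random transaction database over items a, b, c, ..."""
    items = [chr(ord("a") + i) for i in range(n_items)]
    X = rng.random((n_trans, n_items)) < density
    return make_db(
        {f"P{i}": {items[j] for j in np.nonzero(X[i])[0]} for i in range(n_trans)}
    )


@pytest.fixture
def tiny_db() -> ItemsetDB:
    """Five transactions {ABC, AB, AC, B, ABC} with a couple of AEs."""
    return make_db(
        {
            "P1": "abc",
            "P2": "ab",
            "P3": "ac",
            "P4": "b",
            "P5": "abc",
        },
        {"P1": {"rash"}, "P2": {"rash"}, "P4": {"fever"}},
    )
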