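import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netarm import (CohortConfig, GroupParams, Transaction, TransactionDB,
                    sinet_config)

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def tiny_config(seed=0, n_patients=40, pd_fraction=0.5, n_controls=30,
                **overrides) -> CohortConfig:
    """Small, fast cohort configuration: four proteins, small cohorts."""
    markers = {
        "CPE": {"control": GroupParams(mean=3.09, sd=0.34),
                "SD": GroupParams(mean=2.96, sd=0.33),
                "PD": GroupParams(mean=3.32, sd=0.74)},
        "WISP-1": {"control": GroupParams(mean=3.0, sd=0.5),
                   "SD": GroupParams(mean=3.0, sd=0.5),
                   "PD": GroupParams(mean=3.4, sd=0.5)},
        "CD160": {"control": GroupParams(mean=4.0, sd=0.5),
                  "SD": GroupParams(mean=4.4, sd=0.5),
                  "PD": GroupParams(mean=4.0, sd=0.5)},
        "TRAIL": {"control": GroupParams(mean=7.0, sd=0.6),
                  "SD": GroupParams(mean=7.0, sd=0.6),
                  "PD": GroupParams(mean=7.0, sd=0.6)},
    }
    return sinet_config(seed=seed, n_patients=n_patients,
                        pd_fraction=pd_fraction, n_controls=n_controls,
                        biomarker_params=markers, **overrides)


@pytest.fixture
def tiny_cfg():
    return tiny_config()


def make_db(itemsets, outcomes=None) -> TransactionDB:
    """Build a TransactionDB from raw item collections.

    The outcome item of each transaction is taken from its items if present,
    else from ``outcomes``, else defaults to "SD" (kept out of the item set).
    """
    txs = []
    for i, items in enumerate(itemsets):
        items = frozenset(items)
        if outcomes is not None:
            oc = outcomes[i]
        elif "PD" in items:
            oc = "PD"
        else:
            oc = "SD"
        txs.append(Transaction(f"T{i:03d}", items, oc))
    return TransactionDB(txs)


def random_db(rng: np.random.Generator, max_tx=12, max_items=8) -> TransactionDB:
    """Random small database over letter items plus SD/PD outcome items."""
    n_tx = int(rng.integers(1, max_tx + 1))
    n_items = int(rng.integers(2, max_items - 1))
    alphabet = [chr(ord("A") + j) for j in range(n_items)]
    txs = []
    for i in range(n_tx):
        items = {a for a in alphabet if rng.random() < 0.45}
        oc = "PD" if rng.random() < 0.5 else "SD"
        items.add(oc)
        txs.append(Transaction(f"T{i:03d}", frozenset(items), oc))
    return TransactionDB(txs)
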