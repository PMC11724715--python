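"""Shared fixtures: toy networks, and the seeded random-network verification
suite (oracle + all three engines at K = inf, with elementarity audit) that
several test modules interrogate."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pytest

from eprays import (
    EPSet,
    FilterConfig,
    augment,
    brute_force_rays,
    fixtures,
    generate_random_network,
    run_cba,
    run_nsa,
)

N_RANDOM_NETWORKS = 50


@pytest.fixture(scope="session")
def toy():
    return fixtures()


@dataclass
class SuiteRecord:
    seed: int
    net: object
    aug: object
    oracle: EPSet
    cba_pd: EPSet
    cba_nullity: EPSet
    nsa: EPSet
    audit: list


@pytest.fixture(scope="session")
def random_suite() -> list[SuiteRecord]:
    """Oracle + CBA(pd)/CBA(nullity)/NSA at K = inf over seeded random
    networks (m in [3,8], r in [4,12]), with per-candidate audit records."""
    records = []
    for seed in range(N_RANDOM_NETWORKS):
        rng = np.random.default_rng(seed + 1000)
        m = int(rng.integers(3, 9))
        r = int(rng.integers(4, 13))
        net = generate_random_network(
            m, r, density=0.4, rev_frac=0.3, exch_frac=0.2, coeff_range=3, seed=seed
        )
        aug = augment(net)
        orc = brute_force_rays(aug)
        cfg = FilterConfig(K=math.inf, seed=seed)
        audit: list = []
        pd = run_cba(net, cfg, test="pd", drop_futile=False, audit=audit)
        nl = run_cba(net, cfg, test="nullity", drop_futile=False)
        ns = run_nsa(net, cfg, drop_futile=False)
        records.append(SuiteRecord(seed, net, aug, orc, pd, nl, ns, audit))
    return records


@pytest.fixture(scope="session")
def medium_network():
    """A fixed random network rich enough (13 extreme pathways, candidate
    counts in the hundreds) for the stochastic-filter behaviour to show."""
    return generate_random_network(
        7, 12, density=0.45, rev_frac=0.25, exch_frac=0.2, coeff_range=2, seed=3
    )
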