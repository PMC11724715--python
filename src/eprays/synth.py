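"""Synthetic random metabolic networks and hand-built fixture networks.

The generator draws integer stoichiometries at a given density, requiring
every metabolite to have at least one producer and one consumer (so no row is
trivially infeasible) and every reaction to touch at least one metabolite.
Fixtures are four tiny textbook topologies whose extreme pathways are known
by exhaustive inspection and embedded for regression testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import MetabolicNetwork

__all__ = ["generate_random_network", "fixtures", "Fixture"]


def generate_random_network(
    m: int,
    r: int,
    density: float = 0.4,
    rev_frac: float = 0.3,
    exch_frac: float = 0.2,
    coeff_range: int = 3,
    seed: int = 0,
    max_tries: int = 1000,
) -> MetabolicNetwork:
    """Random integer stoichiometric network (deterministic per seed).

    Entries are drawn uniformly from [-coeff_range, coeff_range] \\ {0} with
    the given density; the matrix is redrawn (bounded retries) until every
    metabolite has a producer and a consumer and no reaction column is
    all-zero. Reversibility and exchange flags are Bernoulli draws at the
    stated fractions.
    """
    if m < 1 or r < 2:
        raise ValueError("need m >= 1 and r >= 2")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        # place one producer and one consumer per metabolite, then fill the
        # remaining cells at the requested density
        S = np.zeros((m, r), dtype=int)
        for i in range(m):
            jp, jm = rng.choice(r, size=2, replace=False)
            S[i, jp] = int(rng.integers(1, coeff_range + 1))
            S[i, jm] = -int(rng.integers(1, coeff_range + 1))
        fill = (rng.random((m, r)) < density) & (S == 0)
        mags = rng.integers(1, coeff_range + 1, size=(m, r))
        signs = rng.choice([-1, 1], size=(m, r))
        S = S + fill * mags * signs
        ok_rows = all((S[i] > 0).any() and (S[i] < 0).any() for i in range(m))
        ok_cols = all((S[:, j] != 0).any() for j in range(r))
        if ok_rows and ok_cols:
            break
    else:
        raise RuntimeError(
            f"could not draw a connected network in {max_tries} tries "
            f"(m={m}, r={r}, density={density})"
        )
    reversible = rng.random(r) < rev_frac
    exchange = rng.random(r) < exch_frac
    S_obj = np.array([[int(x) for x in row] for row in S.tolist()], dtype=object)
    return MetabolicNetwork(
        [f"M{i}" for i in range(m)],
        [f"R{j}" for j in range(r)],
        S_obj,
        reversible,
        exchange,
    )


@dataclass(frozen=True)
class Fixture:
    """A fixture network plus its known extreme rays (augmented coordinates,
    internal-reversible split, futile cycles included)."""

    network: MetabolicNetwork
    expected_rays_aug: tuple[tuple[int, ...], ...]


def _net(mets, rxns, S, reversible, exchange) -> MetabolicNetwork:
    S_obj = np.array([[int(x) for x in row] for row in S], dtype=object)
    return MetabolicNetwork(list(mets), list(rxns), S_obj, list(reversible), list(exchange))


def fixtures() -> dict[str, Fixture]:
    """Chain, split-chain, branched and diamond fixture networks."""
    chain = _net(
        "AB",
        ["R1", "R2", "R3"],
        [[1, -1, 0], [0, 1, -1]],
        [False, False, False],
        [True, False, True],
    )
    # same chain with the internal step reversible: augmenting adds its
    # backward column, so the augmented cone gains the futile 2-cycle
    split_chain = _net(
        "AB",
        ["R1", "R2", "R3"],
        [[1, -1, 0], [0, 1, -1]],
        [False, True, False],
        [True, False, True],
    )
    branched = _net(
        "AB",
        ["R1", "R2", "R3", "R4"],
        [[1, -1, 0, -1], [0, 1, -1, 0]],
        [False] * 4,
        [True, False, True, True],
    )
    diamond = _net(
        "ABCD",
        ["R1", "R2", "R3", "R4", "R5", "R6"],
        [
            [1, -1, -1, 0, 0, 0],
            [0, 1, 0, -1, 0, 0],
            [0, 0, 1, 0, -1, 0],
            [0, 0, 0, 1, 1, -1],
        ],
        [False] * 6,
        [True, False, False, False, False, True],
    )
    return {
        "chain": Fixture(chain, ((1, 1, 1),)),
        "split_chain": Fixture(split_chain, ((1, 1, 1, 0), (0, 1, 0, 1))),
        "branched": Fixture(branched, ((1, 1, 1, 0), (1, 0, 0, 1))),
        "diamond": Fixture(diamond, ((1, 1, 0, 1, 0, 1), (1, 0, 1, 0, 1, 1))),
    }
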