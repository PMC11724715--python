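"""Brute-force extreme-ray oracle for desk-scale networks.

An extreme ray of the pointed cone {v >= 0, S'v = 0} is exactly a support
whose column submatrix has a one-dimensional nullspace spanned by a vector of
one strict sign over that support. The oracle enumerates supports in
increasing cardinality (2^r' of them, so r' is guarded) and is deliberately
built on numpy's SVD rank/nullspace path — fully independent of the exact
rational tableau machinery it verifies.
"""

from __future__ import annotations

import itertools

import numpy as np

from .epset import EPSet, dedupe_rays, normalize_ray
from .network import AugmentedNetwork, project_to_original

__all__ = ["brute_force_rays"]

_RANK_RTOL = 1e-12
_SIGN_TOL = 1e-9


def _rank_and_null(A: np.ndarray) -> tuple[int, np.ndarray | None]:
    """(rank, nullspace vector if nullity is exactly 1 else None)."""
    U, s, Vt = np.linalg.svd(A)
    if s.size == 0:
        rank = 0
    else:
        rank = int(np.sum(s > max(A.shape) * s[0] * _RANK_RTOL))
    if A.shape[1] - rank != 1:
        return rank, None
    return rank, Vt[-1]


def brute_force_rays(
    aug: AugmentedNetwork,
    max_r_prime: int = 20,
    force: bool = False,
    prune: bool = True,
) -> EPSet:
    """Enumerate every extreme ray of {v >= 0, S'v = 0} by support search.

    ``prune`` skips supports that strictly contain an already accepted one
    (supersets can never be support-minimal); disabling it reproduces the
    same set by sheer enumeration and exists for self-verification.
    """
    rp = aug.r_prime
    if rp > max_r_prime and not force:
        raise ValueError(
            f"r' = {rp} exceeds the brute-force guard ({max_r_prime}); pass force=True to override"
        )
    S = np.asarray(aug.S_aug, dtype=float)
    accepted_supports: list[frozenset[int]] = []
    rays: list[np.ndarray] = []
    cols = range(rp)
    for size in range(1, rp + 1):
        for comb in itertools.combinations(cols, size):
            supp = frozenset(comb)
            if prune and any(acc < supp for acc in accepted_supports):
                continue
            sub = S[:, list(comb)]
            _, nv = _rank_and_null(sub)
            if nv is None:
                continue
            scale = float(np.max(np.abs(nv)))
            if scale == 0.0:
                continue
            nv = nv / scale
            if np.any(np.abs(nv) <= _SIGN_TOL):
                continue  # a zero inside the support: true support is smaller
            if np.all(nv < 0):
                nv = -nv
            if not np.all(nv > 0):
                continue
            v = np.zeros(rp)
            v[list(comb)] = nv
            accepted_supports.append(supp)
            rays.append(normalize_ray(v))
    rays = dedupe_rays(rays)
    meta = {"method": "oracle", "K": "inf", "seed": None, "arithmetic": "float"}
    return EPSet(rays, [project_to_original(v, aug) for v in rays], meta)
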