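"""Elementarity tests for extreme-pathway candidates.

A candidate flux vector v (nonnegative, steady-state over the metabolite rows
processed so far) is *elementary* when the columns of S' over its support
carry a one-dimensional nullspace — the classical nullity test. Two cheaper
equivalents are provided:

* the positive-definite (Gramian) test: because the canonical-basis tableau
  maintains v >= 0 throughout, Gordan's theorem guarantees that appending a
  strictly positive row to the support submatrix absorbs exactly the
  candidate's nullspace direction, so elementarity is equivalent to the
  Gramian of the extended submatrix being positive definite. The full-width
  Gramian (S*)^T S* is built once per iteration and each candidate merely
  slices its rows and columns by the support.
* the kernel-structured reduced test used by the nullspace approach, which
  exploits the permutation-identity block of the kernel matrix to shrink the
  rank computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import (
    cholesky_pd,
    is_exact_array,
    leading_minors_positive,
    rank_exact,
    rank_float,
)

__all__ = [
    "SupportSet",
    "GramianContext",
    "support",
    "nullity",
    "nullity_test",
    "build_gramian",
    "pd_test",
    "nsa_reduced_test",
    "KernelStructureError",
]


class KernelStructureError(ValueError):
    """Kernel matrix lacks the permutation-identity block the reduced test needs."""


@dataclass(frozen=True)
class SupportSet:
    """Zero set Z and support (complement) of a flux vector of length n."""

    Z: tuple[int, ...]
    Z_bar: tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        if set(self.Z) | set(self.Z_bar) != set(range(self.n)) or set(self.Z) & set(self.Z_bar):
            raise ValueError("Z and Z_bar must partition 0..n-1")


def support(v, zero_tol: float = 0.0) -> SupportSet:
    """Classify entries of ``v`` as zero/nonzero.

    In float mode an entry is zero when |v[i]| <= zero_tol * max(1, max|v|);
    exact (object-dtype) vectors use literal comparison.
    """
    v = np.asarray(v)
    if v.size == 0:
        raise ValueError("empty flux vector has no support")
    if is_exact_array(v) or zero_tol == 0.0:
        zmask = np.array([x == 0 for x in v.tolist()], dtype=bool)
    else:
        scale = max(1.0, float(np.max(np.abs(v.astype(float)))))
        zmask = np.abs(v.astype(float)) <= zero_tol * scale
    idx = np.arange(v.size)
    return SupportSet(tuple(idx[zmask].tolist()), tuple(idx[~zmask].tolist()), int(v.size))


def nullity(M) -> int:
    """Columns minus rank; a 0-row matrix has nullity equal to its width."""
    M = np.asarray(M)
    if M.ndim != 2:
        raise ValueError("nullity expects a 2-D matrix")
    nrows, ncols = M.shape
    if nrows == 0:
        return ncols
    rank = rank_exact(M) if is_exact_array(M) else rank_float(M)
    return ncols - rank


def nullity_test(S_aug: np.ndarray, Z_bar: SupportSet | tuple[int, ...], k: int) -> bool:
    """Classical test at iteration k: nullity of the first k metabolite rows
    restricted to the support columns equals 1."""
    cols = Z_bar.Z_bar if isinstance(Z_bar, SupportSet) else tuple(Z_bar)
    if len(cols) == 0:
        raise ValueError("empty support: candidate is the zero vector")
    sub = S_aug[:k, :][:, list(cols)]
    return nullity(sub) == 1


@dataclass
class GramianContext:
    """Precomputed (S*)^T S* for iteration k, S* = first k rows of S' plus a
    strictly positive row ``a``."""

    k: int
    G: np.ndarray  # (r', r'), symmetric
    a: np.ndarray

    def updated(self, s_row: np.ndarray) -> "GramianContext":
        """Context for k+1 via the rank-1 update with metabolite row k."""
        s = np.asarray(s_row)
        return GramianContext(self.k + 1, self.G + np.outer(s, s), self.a)


def build_gramian(S_aug: np.ndarray, k: int, a=None) -> GramianContext:
    """Gramian of the first ``k`` rows of S' extended by positive row ``a``
    (default all-ones, which keeps G integer for integer S)."""
    n = S_aug.shape[1]
    exact = is_exact_array(S_aug)
    if a is None:
        a = np.ones(n, dtype=object if exact else float)
        if exact:
            a[:] = 1
    else:
        a = np.asarray(a, dtype=object if exact else float)
        if any(x <= 0 for x in np.asarray(a, dtype=float).tolist()):
            raise ValueError("the appended row must be strictly positive")
    G = np.outer(a, a)
    for i in range(k):
        s = S_aug[i, :]
        G = G + np.outer(s, s)
    return GramianContext(k, G, a)


def pd_test(ctx: GramianContext, Z_bar: SupportSet | tuple[int, ...]) -> bool:
    """Gramian elementarity test: G sliced to the support is positive definite.

    Caller contract: the candidate is nonnegative, strictly positive on the
    support, and at steady state over the first ``ctx.k`` metabolite rows.
    """
    cols = list(Z_bar.Z_bar if isinstance(Z_bar, SupportSet) else Z_bar)
    if not cols:
        raise ValueError("empty support: candidate is the zero vector")
    sub = ctx.G[np.ix_(cols, cols)]
    if is_exact_array(ctx.G):
        return leading_minors_positive(sub)
    return cholesky_pd(sub)


def nsa_reduced_test(
    kernel: np.ndarray,
    identity_cols: list[int],
    processed: set[int] | frozenset[int],
    Z: set[int] | frozenset[int] | tuple[int, ...],
) -> bool:
    """Kernel-structured elementarity test for the nullspace approach.

    With q kernel rows whose restriction to ``identity_cols`` is a
    (row-scaled) permutation identity, a candidate with zero set Z is
    elementary over the processed columns iff
    ``rank(kernel[:, Z & processed]) == q - 1``. The rank is computed in
    reduced form: identity columns inside the zero set contribute one
    independent column each, leaving a rank computation on the remaining rows
    and non-identity columns only.
    """
    kernel = np.asarray(kernel)
    q = kernel.shape[0]
    processed = set(processed)
    if not processed.issuperset(identity_cols):
        raise KernelStructureError("identity columns must all be processed")
    if len(identity_cols) != q:
        raise KernelStructureError("need one identity column per kernel row")
    for i, c in enumerate(identity_cols):
        col = kernel[:, c]
        ok = col[i] != 0 and all(col[j] == 0 for j in range(q) if j != i)
        if not ok:
            raise KernelStructureError(f"column {c} is not a unit column for row {i}")
    Zk = sorted(set(Z) & processed)
    if q == 1:
        # a single kernel row is the whole (1-dim) nullspace: always elementary
        return True
    id_set = set(identity_cols)
    Z_id = [c for c in Zk if c in id_set]
    rows_R = [i for i, c in enumerate(identity_cols) if c not in Z_id]
    other_cols = [c for c in Zk if c not in id_set]
    sub = kernel[np.ix_(rows_R, other_cols)] if rows_R and other_cols else None
    if sub is None or sub.size == 0:
        r_sub = 0
    else:
        r_sub = rank_exact(sub) if is_exact_array(kernel) else rank_float(sub)
    return len(Z_id) + r_sub == q - 1
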