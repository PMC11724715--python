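"""Low-level linear algebra in two arithmetic modes.

Exact mode works on Python ``Fraction``/``int`` entries (kept in numpy object
arrays by the callers); float mode defers to numpy/scipy. Rank in float mode is
decided by singular-value thresholding, in exact mode by fraction-free row
reduction, and positive definiteness by Cholesky (float) or leading principal
minors (exact).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

__all__ = [
    "rref_exact",
    "rank_exact",
    "rank_float",
    "nullspace_exact",
    "leading_minors_positive",
    "cholesky_pd",
    "is_exact_array",
    "gcd_reduce",
]

_FLOAT_RANK_RTOL = 1e-12


def is_exact_array(a: np.ndarray) -> bool:
    """True if ``a`` holds exact entries (object dtype: int/Fraction)."""
    return a.dtype == object


def _as_fraction_rows(M) -> list[list[Fraction]]:
    return [[x if isinstance(x, Fraction) else Fraction(x) for x in row] for row in M]


def rref_exact(M) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row-echelon form over the rationals.

    Returns (rows, pivot_columns). ``M`` is any 2-D structure of rational
    entries; zero-row inputs are allowed.
    """
    R = _as_fraction_rows(M)
    nrows = len(R)
    ncols = len(R[0]) if nrows else 0
    pivots: list[int] = []
    row = 0
    for col in range(ncols):
        if row >= nrows:
            break
        piv = next((i for i in range(row, nrows) if R[i][col] != 0), None)
        if piv is None:
            continue
        R[row], R[piv] = R[piv], R[row]
        pv = R[row][col]
        R[row] = [x / pv for x in R[row]]
        for i in range(nrows):
            if i != row and R[i][col] != 0:
                f = R[i][col]
                R[i] = [a - f * b for a, b in zip(R[i], R[row])]
        pivots.append(col)
        row += 1
    return R, pivots


def rank_exact(M) -> int:
    M = np.asarray(M, dtype=object)
    if M.size == 0:
        return 0
    _, pivots = rref_exact(M.tolist())
    return len(pivots)


def rank_float(M) -> int:
    A = np.asarray(M, dtype=float)
    if A.size == 0:
        return 0
    s = np.linalg.svd(A, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    tol = max(A.shape) * s[0] * _FLOAT_RANK_RTOL
    return int(np.sum(s > tol))


def nullspace_exact(M) -> tuple[list[list[Fraction]], list[int]]:
    """Rational nullspace basis of ``M`` with an identity sub-block.

    Returns (basis_rows, free_columns). Basis row ``i`` has entry 1 at
    ``free_columns[i]`` and 0 at every other free column, so the basis matrix
    restricted to the free columns is a permutation identity.
    """
    M = np.asarray(M, dtype=object)
    nrows, ncols = (M.shape if M.ndim == 2 else (0, int(M.shape[0])))
    if nrows == 0:
        return [[Fraction(int(i == j)) for j in range(ncols)] for i in range(ncols)], list(range(ncols))
    R, pivots = rref_exact(M.tolist())
    free = [j for j in range(ncols) if j not in pivots]
    basis = []
    for f in free:
        v = [Fraction(0)] * ncols
        v[f] = Fraction(1)
        for i, p in enumerate(pivots):
            v[p] = -R[i][f]
        basis.append(v)
    return basis, free


def leading_minors_positive(A) -> bool:
    """Sylvester test: every leading principal minor of symmetric ``A`` > 0.

    Fraction-free (Bareiss) elimination without pivoting: after step k the
    (k,k) entry equals the order-(k+1) leading minor, so a nonpositive pivot
    decides immediately.
    """
    M = _as_fraction_rows(np.asarray(A, dtype=object).tolist())
    n = len(M)
    prev = Fraction(1)
    for k in range(n):
        piv = M[k][k]
        if piv <= 0:
            return False
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                M[i][j] = (M[i][j] * piv - M[i][k] * M[k][j]) / prev
            M[i][k] = Fraction(0)
        prev = piv
    return True


def cholesky_pd(A: np.ndarray, *, eps: float = 2.0**-26) -> bool:
    """Positive definiteness by attempted Cholesky factorization.

    A pivot is accepted when it exceeds ``n * eps * max(diag)``; a rejected
    pivot means the matrix is (numerically) not positive definite. The
    default tolerance is sqrt(machine epsilon): Cholesky roundoff on an
    exactly singular Gramian leaves pivot residue well above machine epsilon
    (but far below sqrt(eps)), while genuinely positive-definite support
    Gramians of small-integer networks keep pivots orders of magnitude above
    it.
    """
    A = np.array(A, dtype=float)
    n = A.shape[0]
    if n == 0:
        return True
    thresh = n * eps * float(np.max(np.diag(A)))
    L = np.zeros_like(A)
    for j in range(n):
        d = A[j, j] - L[j, :j] @ L[j, :j]
        if d <= thresh:
            return False
        L[j, j] = np.sqrt(d)
        if j + 1 < n:
            L[j + 1 :, j] = (A[j + 1 :, j] - L[j + 1 :, :j] @ L[j, :j]) / L[j, j]
    return True


def gcd_reduce(v: np.ndarray) -> np.ndarray:
    """Scale an exact row to coprime integers (object array in, object out).

    Rational entries are cleared to integers via the LCM of denominators, then
    divided by the collective GCD. All-zero rows are returned unchanged.
    """
    import math

    fr = [x if isinstance(x, Fraction) else Fraction(x) for x in v.tolist()]
    denoms = [f.denominator for f in fr]
    lcm = 1
    for d in denoms:
        lcm = lcm * d // math.gcd(lcm, d)
    ints = [int(f * lcm) for f in fr]
    g = 0
    for x in ints:
        g = math.gcd(g, abs(x))
    if g > 1:
        ints = [x // g for x in ints]
    return np.array(ints, dtype=object)
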