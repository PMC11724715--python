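"""Shared double-description tableau machinery.

Rows are candidate generators of the flux cone: a nonnegative flux part of
width r' and, for the canonical basis approach, a tail of metabolite
accumulation values. Constraints are imposed one column at a time by
partitioning rows on the sign of that column and replacing the (+,-) pairs
with nonnegative combinations that zero it.

The stochastic candidate filter keeps each (+,-) pair with probability
P = K / (N + K), where N is the number of pairs in the iteration and K is the
user's filter setting. Gating verdicts are drawn from per-candidate RNG
substreams keyed by (seed, iteration, candidate index), so the outcome is
independent of evaluation order and worker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._linalg import gcd_reduce, is_exact_array
from .elementarity import SupportSet, support

__all__ = [
    "FilterConfig",
    "TableauRow",
    "Tableau",
    "partition",
    "combine",
    "selection_probability",
    "sample_gate",
]

DEFAULT_ZERO_TOL = 1e-9
DEFAULT_SPARSE_THRESHOLD = 200


@dataclass(frozen=True)
class FilterConfig:
    """Filter setting K (finite > 0 or math.inf) and the base RNG seed."""

    K: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.K > 0):
            raise ValueError("filter setting K must be positive (use math.inf for no filtering)")


def _dense(vec) -> np.ndarray:
    if sp.issparse(vec):
        return np.asarray(vec.todense()).ravel()
    return np.asarray(vec)


@dataclass
class TableauRow:
    """One candidate generator: flux part, constraint tail, cached support."""

    flux: object  # ndarray (object/float) or 1 x r' sparse matrix
    tail: object  # ndarray or 1 x m sparse matrix (width 0 for NSA)
    support: SupportSet | None = None
    tested: bool = False  # whether an elementarity test ever vouched for this row

    def flux_dense(self) -> np.ndarray:
        return _dense(self.flux)

    def tail_dense(self) -> np.ndarray:
        return _dense(self.tail)

    def value(self, col: int, flux_width: int):
        """Entry of the concatenated (flux | tail) row at global column col."""
        if col < flux_width:
            v = self.flux
            j = col
        else:
            v = self.tail
            j = col - flux_width
        if sp.issparse(v):
            return v[0, j]
        return v[j]


@dataclass
class Tableau:
    """A set of candidate rows plus the arithmetic and tolerance they share."""

    rows: list[TableauRow]
    flux_width: int
    constraint_width: int
    arithmetic: str = "exact"  # "exact" | "float"
    zero_tol: float = DEFAULT_ZERO_TOL
    sparse: bool = False

    def row_support(self, row: TableauRow) -> SupportSet:
        if row.support is None:
            tol = 0.0 if self.arithmetic == "exact" else self.zero_tol
            row.support = support(row.flux_dense(), tol)
        return row.support


def partition(t: Tableau, col: int) -> tuple[list[int], list[int], list[int]]:
    """Split row indices by the sign of the selected column (zero under the
    tableau tolerance counts as zero)."""
    vals = [row.value(col, t.flux_width) for row in t.rows]
    if t.arithmetic == "exact":
        thresh = 0
    else:
        scale = max([1.0] + [abs(float(v)) for v in vals])
        thresh = t.zero_tol * scale
    T0, Tp, Tm = [], [], []
    for i, v in enumerate(vals):
        if abs(v) <= thresh:
            T0.append(i)
        elif v > 0:
            Tp.append(i)
        else:
            Tm.append(i)
    return T0, Tp, Tm


def _axpy(a, x, b, y):
    """a*x + b*y for dense/sparse row storage."""
    if sp.issparse(x) or sp.issparse(y):
        return (x * a + y * b).tocsr()
    return a * x + b * y


def combine(row_plus: TableauRow, row_minus: TableauRow, col: int, t: Tableau) -> TableauRow:
    """Nonnegative combination of a (+,-) row pair that zeroes column ``col``.

    c = v_plus(col) * row_minus - v_minus(col) * row_plus; both coefficients
    are positive, so the flux part stays nonnegative. Exact rows are
    GCD-reduced to coprime integers afterwards.
    """
    vp = row_plus.value(col, t.flux_width)
    vm = row_minus.value(col, t.flux_width)
    if not (vp > 0 and vm < 0):
        raise ValueError("combine needs a strictly positive and a strictly negative row")
    flux = _axpy(-vm, row_plus.flux, vp, row_minus.flux)
    tail = _axpy(-vm, row_plus.tail, vp, row_minus.tail)
    if t.arithmetic == "exact":
        n_flux = t.flux_width
        joint = np.concatenate([np.asarray(flux, dtype=object), np.asarray(tail, dtype=object)])
        joint = gcd_reduce(joint)
        flux, tail = joint[:n_flux], joint[n_flux:]
    else:
        # float rows are rescaled to unit max entry (the analogue of exact
        # GCD reduction) and roundoff below the relative tolerance is
        # clamped: the processed column and the flux part are exact
        # nonnegative combinations, only float error can make them stray
        fd = _dense(flux).astype(float)
        td = _dense(tail).astype(float)
        if col >= t.flux_width:
            td[col - t.flux_width] = 0.0
        scale = max(
            float(np.max(np.abs(fd), initial=0.0)), float(np.max(np.abs(td), initial=0.0))
        )
        if scale > 0:
            fd /= scale
            td /= scale
        fd[np.abs(fd) <= t.zero_tol] = 0.0
        np.maximum(fd, 0.0, out=fd)
        td[np.abs(td) <= t.zero_tol] = 0.0
        flux = sp.csr_matrix(fd) if t.sparse else fd
        tail = sp.csr_matrix(td) if t.sparse else td
    return TableauRow(flux=flux, tail=tail)


def selection_probability(K: float, N: int) -> float:
    """P = K / (N + K); 1 when there is nothing to filter (N = 0) or K = inf."""
    if K < 0 or N < 0:
        raise ValueError("K and N must be nonnegative")
    if N == 0:
        return 1.0
    if math.isinf(K):
        return 1.0
    if K == 0:
        return 0.0
    return K / (N + K)


def sample_gate(p: float, iteration: int, candidate_index: int, cfg: FilterConfig) -> bool:
    """Deterministic per-candidate uniform draw compared against p.

    The substream is keyed by (seed, iteration, candidate index), so repeated
    runs and any parallel schedule reach the same verdict.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("probability out of range")
    if p >= 1.0:
        return True
    if p <= 0.0:
        return False
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(iteration, candidate_index))
    return float(np.random.default_rng(ss).uniform()) <= p
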