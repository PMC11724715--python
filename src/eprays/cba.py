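"""Sampling-based canonical basis approach (CBA).

The tableau starts from the identity over the augmented reactions (every unit
flux vector trivially satisfies nonnegativity) with each row's tail holding
the accumulation of every metabolite under that row's flux. Metabolite
steady-state constraints are imposed one at a time; new candidate rows are
admitted only after passing an elementarity test at the current iteration
depth — either the classical nullity test over the processed metabolite rows,
or the positive-definite Gramian test, whose full-width Gramian is maintained
incrementally across iterations by rank-1 updates.
"""

from __future__ import annotations

import math
import time

import numpy as np

from ._engine import process_column
from .elementarity import GramianContext, build_gramian, nullity, nullity_test, pd_test
from .epset import EPSet, finalize_epset
from .network import AugmentedNetwork, MetabolicNetwork, augment
from .tableau import (
    DEFAULT_SPARSE_THRESHOLD,
    DEFAULT_ZERO_TOL,
    FilterConfig,
    Tableau,
    TableauRow,
    partition,
)

__all__ = ["init_cba_tableau", "cba_iteration", "run_cba"]


def _aug_matrix(aug: AugmentedNetwork, arithmetic: str) -> np.ndarray:
    if arithmetic == "float":
        return np.asarray(aug.S_aug, dtype=float)
    return aug.S_aug


def _resolve_arithmetic(arithmetic: str) -> str:
    # model coefficients are stored exactly, so "auto" resolves to exact
    if arithmetic not in ("auto", "exact", "float"):
        raise ValueError(f"unknown arithmetic mode {arithmetic!r}")
    return "exact" if arithmetic == "auto" else arithmetic


def init_cba_tableau(
    aug: AugmentedNetwork,
    arithmetic: str = "exact",
    zero_tol: float = DEFAULT_ZERO_TOL,
    sparse_threshold: int = DEFAULT_SPARSE_THRESHOLD,
) -> Tableau:
    """Identity flux block with tails = columns of S' (metabolite accumulations)."""
    import scipy.sparse as sp

    arithmetic = _resolve_arithmetic(arithmetic)
    S = _aug_matrix(aug, arithmetic)
    rp, m = aug.r_prime, aug.m
    sparse = arithmetic == "float" and (rp + m) > sparse_threshold
    from ._linalg import gcd_reduce

    rows = []
    for i in range(rp):
        if arithmetic == "exact":
            flux = np.zeros(rp, dtype=object)
            flux[:] = 0
            flux[i] = 1
            tail = np.array([S[j, i] for j in range(m)], dtype=object)
            # rational models: clear denominators so rows stay integer
            joint = gcd_reduce(np.concatenate([flux, tail]))
            flux, tail = joint[:rp], joint[rp:]
        else:
            flux = np.zeros(rp)
            flux[i] = 1.0
            tail = S[:, i].astype(float).copy()
            if sparse:
                flux = sp.csr_matrix(flux)
                tail = sp.csr_matrix(tail)
        rows.append(TableauRow(flux=flux, tail=tail))
    return Tableau(rows, rp, m, arithmetic, zero_tol, sparse)


def _make_tester(
    S_proc: np.ndarray,
    ctx: GramianContext,
    t: Tableau,
    test: str,
    audit_wanted: bool,
):
    """Elementarity tester at the current iteration depth k = S_proc rows."""
    k = S_proc.shape[0]

    def tester(row):
        supp = t.row_support(row)
        if test == "pd":
            verdict = pd_test(ctx, supp)
        else:
            verdict = nullity_test(S_proc, supp, k)
        if not audit_wanted:
            return verdict, None
        nv = nullity_test(S_proc, supp, k)
        pv = pd_test(ctx, supp)
        cols = list(supp.Z_bar)
        null_plain = nullity(S_proc[:, cols])
        a_row = np.asarray(ctx.a, dtype=object if S_proc.dtype == object else float)
        star = np.vstack([S_proc[:, cols], a_row[cols].reshape(1, -1)])
        null_star = nullity(star)
        rec = {
            "iteration_k": k,
            "support": ",".join(map(str, cols)),
            "nullity_verdict": nv,
            "pd_verdict": pv,
            "nullity_plain": null_plain,
            "nullity_star": null_star,
        }
        return verdict, rec

    return tester


def cba_iteration(
    t: Tableau,
    S_aug: np.ndarray,
    processed_rows: list[int],
    ctx: GramianContext,
    iteration: int,
    cfg: FilterConfig,
    test: str = "pd",
    workers: int = 1,
    audit: list | None = None,
) -> tuple[Tableau, dict]:
    """One CBA step: impose steady state for the last row in ``processed_rows``.

    ``ctx`` must already include that row (the per-iteration Gramian). Pure
    in (t, cfg): identical inputs give identical outputs regardless of
    ``workers``.
    """
    met_row = processed_rows[-1]
    S_proc = S_aug[processed_rows, :]
    tester = _make_tester(S_proc, ctx, t, test, audit is not None)
    col = t.flux_width + met_row
    return process_column(
        t, col, iteration, cfg, tester, keep_plus=False, workers=workers, audit=audit
    )


def run_cba(
    net: MetabolicNetwork,
    cfg: FilterConfig,
    test: str = "pd",
    order: str = "natural",
    split_policy: str = "internal-reversible",
    drop_futile: bool = True,
    arithmetic: str = "auto",
    zero_tol: float = DEFAULT_ZERO_TOL,
    workers: int = 1,
    audit: list | None = None,
    sparse_threshold: int = DEFAULT_SPARSE_THRESHOLD,
) -> EPSet:
    """Enumerate (a sample of) the extreme pathways by sampling-based CBA.

    Parameters
    ----------
    test : {"pd", "nullity"}
        Elementarity test applied to each combined candidate.
    order : {"natural", "min-product"}
        Metabolite processing order; "min-product" greedily processes the
        metabolite with the fewest (+,-) candidate pairs next.
    audit : list, optional
        When given, every tested candidate appends a record holding both
        test verdicts and the plain/extended nullities.
    """
    if test not in ("pd", "nullity"):
        raise ValueError(f"unknown elementarity test {test!r}")
    arithmetic = _resolve_arithmetic(arithmetic)
    aug = augment(net, split_policy)
    S = _aug_matrix(aug, arithmetic)
    t = init_cba_tableau(aug, arithmetic, zero_tol, sparse_threshold)
    ctx = build_gramian(S, 0)
    remaining = list(range(aug.m))
    processed: list[int] = []
    iteration_log: list[dict] = []
    t0 = time.perf_counter()
    iteration = 0
    while remaining:
        if order == "min-product":
            costs = []
            for i in remaining:
                _, Tp, Tm = partition(t, t.flux_width + i)
                costs.append(len(Tp) * len(Tm))
            met_row = remaining.pop(int(np.argmin(costs)))
        elif order == "natural":
            met_row = remaining.pop(0)
        else:
            raise ValueError(f"unknown processing order {order!r}")
        processed.append(met_row)
        ctx = ctx.updated(S[met_row, :])
        t, stats = cba_iteration(t, S, processed, ctx, iteration, cfg, test, workers, audit)
        stats = {
            "k": len(processed),
            "metabolite": net.metabolite_ids[met_row],
            **stats,
        }
        iteration_log.append(stats)
        iteration += 1
    meta = {
        "method": f"cba-{test}",
        "K": "inf" if math.isinf(cfg.K) else repr(cfg.K),
        "seed": cfg.seed,
        "arithmetic": arithmetic,
        "split_policy": split_policy,
        "order": order,
        "runtime_s": time.perf_counter() - t0,
    }
    return finalize_epset(
        [row.flux_dense() for row in t.rows], aug, meta, iteration_log, drop_futile, zero_tol
    )
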