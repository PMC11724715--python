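"""Column-processing step shared by the canonical-basis and nullspace engines.

One step imposes a single constraint column: rows already at zero are carried,
(+,-) row pairs are enumerated in lexicographic order, each pair passes the
stochastic gate independently (per-candidate RNG substream), survivors are
combined and kept only if the elementarity tester vouches for them. The
nullspace engine additionally carries the + rows (a one-sided constraint);
the canonical-basis engine consumes both sides (an equality constraint).

Candidates are independent, so they may be dispatched to worker threads; the
gate verdicts and the lexicographic collection order make the result
identical for any worker count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from typing import Callable

from .tableau import FilterConfig, Tableau, TableauRow, combine, partition, sample_gate, selection_probability

Tester = Callable[[TableauRow], tuple[bool, dict | None]]


def process_column(
    t: Tableau,
    col: int,
    iteration: int,
    cfg: FilterConfig,
    tester: Tester,
    *,
    keep_plus: bool,
    workers: int = 1,
    audit: list | None = None,
) -> tuple[Tableau, dict]:
    """Impose one constraint column on the tableau; returns (new tableau, stats)."""
    T0, Tp, Tm = partition(t, col)
    N = len(Tp) * len(Tm)
    P = selection_probability(cfg.K, N)
    kept_rows = [t.rows[i] for i in T0]
    if keep_plus:
        kept_rows += [t.rows[i] for i in Tp]
    pairs = [(ip, im) for ip in sorted(Tp) for im in sorted(Tm)]

    def handle(args: tuple[int, tuple[int, int]]):
        ci, (ip, im) = args
        if not sample_gate(P, iteration, ci, cfg):
            return None
        row = combine(t.rows[ip], t.rows[im], col, t)
        supp = t.row_support(row)
        if len(supp.Z_bar) == 0:
            return (row, False, None)
        verdict, audit_rec = tester(row)
        return (row, verdict, audit_rec)

    tasks = list(enumerate(pairs))
    if workers > 1 and tasks:
        with ThreadPoolExecutor(max_workers=workers) as ex:
            results = list(ex.map(handle, tasks))
    else:
        results = [handle(a) for a in tasks]

    gated = sum(1 for res in results if res is not None)
    elementary = 0
    for res in results:
        if res is None:
            continue
        row, verdict, audit_rec = res
        if audit is not None and audit_rec is not None:
            audit.append(audit_rec)
        if verdict:
            row.tested = True
            elementary += 1
            kept_rows.append(row)
    stats = {
        "T0": len(T0),
        "T_plus": len(Tp),
        "T_minus": len(Tm),
        "N": N,
        "P": P,
        "gated": gated,
        "elementary": elementary,
    }
    new_t = Tableau(
        rows=kept_rows,
        flux_width=t.flux_width,
        constraint_width=t.constraint_width,
        arithmetic=t.arithmetic,
        zero_tol=t.zero_tol,
        sparse=t.sparse,
    )
    return new_t, stats


def write_audit_tsv(audit: list[dict], path) -> None:
    """Dump per-candidate elementarity audit records to TSV."""
    if not audit:
        cols: list[str] = ["iteration_k", "support"]
    else:
        cols = list(audit[0].keys())
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in audit:
            fh.write("\t".join(str(rec.get(c, "")) for c in cols) + "\n")
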