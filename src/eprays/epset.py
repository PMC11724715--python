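"""Extreme-pathway sets: normalization, deduplication, validation and I/O.

Rays are scale-free; exact-mode rays are normalized to coprime integers and
float-mode rays to a maximum entry of 1, then deduplicated by value. Futile
two-cycles — the zero-net-flux rays spanned by the forward and backward
columns of one split reversible reaction — are genuine extreme rays of the
augmented cone but pure augmentation artifacts, so engines drop them from the
output by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._linalg import gcd_reduce, is_exact_array
from .elementarity import nullity, support
from .network import AugmentedNetwork, project_to_original

__all__ = [
    "EPSet",
    "normalize_ray",
    "dedupe_rays",
    "is_futile_ray",
    "same_ray",
    "same_ray_set",
    "check_epset",
    "ValidationReport",
    "write_ep_tsv",
    "read_ep_tsv",
    "write_ep_mtx",
]


def normalize_ray(v: np.ndarray) -> np.ndarray:
    """Scale-normalize a ray: coprime integers (exact) or max entry 1 (float)."""
    v = np.asarray(v)
    if is_exact_array(v):
        return gcd_reduce(v)
    mx = float(np.max(np.abs(v)))
    return v / mx if mx > 0 else v


def dedupe_rays(rays: list[np.ndarray]) -> list[np.ndarray]:
    """Drop duplicate normalized rays, keeping first-seen order."""
    seen: set[tuple] = set()
    out = []
    for v in rays:
        key = tuple(v.tolist()) if is_exact_array(v) else tuple(np.round(v, 9).tolist())
        if key not in seen:
            seen.add(key)
            out.append(v)
    return out


def is_futile_ray(v: np.ndarray, aug: AugmentedNetwork, zero_tol: float = 0.0) -> bool:
    """True when the ray's support is exactly one split forward/backward pair."""
    supp = set(support(v, zero_tol).Z_bar)
    return any(supp == {f, b} for f, b in aug.split_columns)


def same_ray(u, v, tol: float = 1e-8) -> bool:
    """Proportionality of two nonnegative rays up to positive scaling."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        return False
    mu, mv = np.max(np.abs(u)), np.max(np.abs(v))
    if mu == 0 or mv == 0:
        return mu == mv
    return bool(np.allclose(u / mu, v / mv, atol=tol))


def same_ray_set(a: list, b: list, tol: float = 1e-8) -> bool:
    """Set equality up to positive scaling (each ray matched exactly once)."""
    if len(a) != len(b):
        return False
    unmatched = list(b)
    for u in a:
        for i, v in enumerate(unmatched):
            if same_ray(u, v, tol):
                unmatched.pop(i)
                break
        else:
            return False
    return True


@dataclass
class EPSet:
    """Extreme pathways in augmented and original coordinates plus run metadata."""

    rays_aug: list[np.ndarray]
    rays_orig: list[np.ndarray]
    meta: dict = field(default_factory=dict)
    iteration_log: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rays_aug)


@dataclass
class ValidationReport:
    per_ray: list[dict]
    pairwise_proportional: list[tuple[int, int]]

    @property
    def ok(self) -> bool:
        return not self.pairwise_proportional and all(
            all(v for v in d.values()) for d in self.per_ray
        )

    def failures(self) -> list[str]:
        msgs = []
        for i, d in enumerate(self.per_ray):
            for name, passed in d.items():
                if not passed:
                    msgs.append(f"ray {i}: {name}")
        for i, j in self.pairwise_proportional:
            msgs.append(f"rays {i} and {j} are proportional")
        return msgs


def check_epset(eps: EPSet, aug: AugmentedNetwork, zero_tol: float = 1e-9) -> ValidationReport:
    """Validate every ray: steady state, nonnegativity, nonzero, elementarity
    (full nullity test), no mixed use of a split pair, pairwise independence."""
    S = np.asarray(aug.S_aug, dtype=float)
    scale = max(1.0, float(np.max(np.abs(S))))
    per_ray = []
    for v in eps.rays_aug:
        vf = np.asarray(v, dtype=float)
        if vf.shape[0] != aug.r_prime:
            raise ValueError("ray length does not match the augmented network")
        vmax = max(1.0, float(np.max(np.abs(vf))))
        supp = support(v, 0.0 if is_exact_array(np.asarray(v)) else zero_tol)
        checks = {
            "steady_state": bool(np.all(np.abs(S @ vf) <= 1e-9 * scale * vmax)),
            "nonnegative": bool(np.all(vf >= -1e-9 * vmax)),
            "nonzero": len(supp.Z_bar) > 0,
            "elementary": (
                len(supp.Z_bar) > 0
                and nullity(aug.S_aug[:, list(supp.Z_bar)]) == 1
            ),
            # both directions of one split pair only ever appear together in
            # the futile 2-cycle itself (support exactly the pair)
            "no_double_direction": all(
                not (f in supp.Z_bar and b in supp.Z_bar) or set(supp.Z_bar) == {f, b}
                for f, b in aug.split_columns
            ),
        }
        per_ray.append(checks)
    prop = [
        (i, j)
        for i in range(len(eps.rays_aug))
        for j in range(i + 1, len(eps.rays_aug))
        if same_ray(eps.rays_aug[i], eps.rays_aug[j])
    ]
    return ValidationReport(per_ray, prop)


def _fmt_entry(x) -> str:
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, Fraction):
        return str(x.numerator) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"
    return repr(float(x))


def write_ep_tsv(eps: EPSet, path, aug: AugmentedNetwork, augmented: bool = False) -> None:
    """EP table: '#' metadata header lines, a column per original reaction
    (net flux), optionally followed by the augmented-coordinate block."""
    rids = aug.base.reaction_ids
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#method\t{eps.meta.get('method', '?')}\n")
        fh.write(f"#K\t{eps.meta.get('K', 'inf')}\n")
        fh.write(f"#seed\t{eps.meta.get('seed', '')}\n")
        cols = list(rids)
        if augmented:
            cols += [f"aug:{c}" for c in range(aug.r_prime)]
        fh.write("\t".join(cols) + "\n")
        for v_orig, v_aug in zip(eps.rays_orig, eps.rays_aug):
            row = [_fmt_entry(x) for x in np.asarray(v_orig).tolist()]
            if augmented:
                row += [_fmt_entry(x) for x in np.asarray(v_aug).tolist()]
            fh.write("\t".join(row) + "\n")


def read_ep_tsv(path) -> tuple[list[np.ndarray], dict]:
    """Read an EP table; returns (original-coordinate rays, metadata)."""
    meta: dict = {}
    rays: list[np.ndarray] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            if ln.startswith("#"):
                parts = ln[1:].split("\t")
                meta[parts[0]] = parts[1] if len(parts) > 1 else ""
                continue
            if header is None:
                header = ln.split("\t")
                n_orig = len([c for c in header if not c.startswith("aug:")])
                continue
            toks = ln.split("\t")
            vals = [Fraction(t) for t in toks[:n_orig]]
            rays.append(
                np.array(
                    [int(v) if v.denominator == 1 else v for v in vals], dtype=object
                )
            )
    if header is None:
        raise ValueError(f"{path}: no column header found")
    meta["reaction_ids"] = [c for c in header if not c.startswith("aug:")]
    return rays, meta


def write_ep_mtx(eps: EPSet, path) -> None:
    """Sparse MatrixMarket export of the EP x reaction (original) matrix."""
    import scipy.io
    import scipy.sparse as sp

    M = np.array([np.asarray(v, dtype=float) for v in eps.rays_orig])
    scipy.io.mmwrite(str(path), sp.csr_matrix(M))


def finalize_epset(
    flux_rows: list[np.ndarray],
    aug: AugmentedNetwork,
    meta: dict,
    iteration_log: list[dict],
    drop_futile: bool = True,
    zero_tol: float = 1e-9,
) -> EPSet:
    """Normalize, deduplicate, optionally drop futile 2-cycles, and project."""
    rays = dedupe_rays([normalize_ray(v) for v in flux_rows])
    exact = bool(rays) and is_exact_array(rays[0])
    tol = 0.0 if exact else zero_tol
    for v in rays:
        supp = set(support(v, tol).Z_bar)
        for f, b in aug.split_columns:
            if f in supp and b in supp and supp != {f, b}:
                raise RuntimeError(
                    "internal error: an output ray uses both directions of a split "
                    "reaction beyond the futile 2-cycle"
                )
    if drop_futile:
        rays = [v for v in rays if not is_futile_ray(v, aug, tol)]
    rays_orig = [project_to_original(v, aug) for v in rays]
    return EPSet(rays, rays_orig, meta, iteration_log)
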