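"""Metabolic network containers and model I/O.

A :class:`MetabolicNetwork` is the stoichiometric matrix S (metabolites x
reactions) plus per-reaction reversibility and exchange flags. Enumerating
extreme pathways requires a pointed flux cone, so reversible internal
reactions are split into forward/backward columns, giving the augmented
matrix S' = [S | -S[:, R_R]] held by :class:`AugmentedNetwork`.

Models are read either from SBML (delegated to cobra) or from a plain TSV
dialect: a header row of reaction ids, one row per metabolite with its
coefficients (decimal or "p/q"), then ``#reversible`` and ``#exchange`` flag
lines of 0/1 values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicNetwork",
    "AugmentedNetwork",
    "NetworkFormatError",
    "load_sbml",
    "load_tsv",
    "write_tsv",
    "augment",
    "project_to_original",
]


class NetworkFormatError(ValueError):
    """Malformed model file or inconsistent network definition."""


@dataclass
class MetabolicNetwork:
    """Stoichiometric model: S is m x r with exact rational entries."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray  # object array of Fraction/int, shape (m, r)
    reversible: np.ndarray  # bool, length r
    exchange: np.ndarray  # bool, length r
    allow_empty_exchange: bool = False

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=object)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.exchange = np.asarray(self.exchange, dtype=bool)
        m, r = self.S.shape
        if m < 1 or r < 1:
            raise NetworkFormatError("network must have at least one metabolite and one reaction")
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != r:
            raise NetworkFormatError("id lists do not match matrix dimensions")
        if len(set(self.metabolite_ids)) != m:
            raise NetworkFormatError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != r:
            raise NetworkFormatError("duplicate reaction ids")
        if self.reversible.shape != (r,) or self.exchange.shape != (r,):
            raise NetworkFormatError("flag vectors must have one entry per reaction")
        for j in range(r):
            if all(self.S[i, j] == 0 for i in range(m)):
                if not (self.allow_empty_exchange and self.exchange[j]):
                    raise NetworkFormatError(
                        f"reaction {self.reaction_ids[j]!r} has an all-zero stoichiometry column"
                    )

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def r(self) -> int:
        return self.S.shape[1]


@dataclass
class AugmentedNetwork:
    """S' = [S | -S[:, R_R]] with a map from split columns back to reactions."""

    base: MetabolicNetwork
    S_aug: np.ndarray  # object array, shape (m, r')
    split_columns: list[tuple[int, int]]  # (forward original index, backward augmented index)
    origin: dict[int, tuple[int, int]] = field(default_factory=dict)  # col -> (reaction, +/-1)

    @property
    def r_prime(self) -> int:
        return self.S_aug.shape[1]

    @property
    def m(self) -> int:
        return self.S_aug.shape[0]

    def backward_of(self) -> dict[int, int]:
        return {f: b for f, b in self.split_columns}


def _parse_coeff(tok: str, lineno: int) -> Fraction:
    try:
        return Fraction(tok)
    except (ValueError, ZeroDivisionError) as exc:
        raise NetworkFormatError(f"line {lineno}: cannot parse coefficient {tok!r}") from exc


def load_tsv(path) -> MetabolicNetwork:
    """Read the TSV model dialect (see module docstring)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise NetworkFormatError("empty model file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise NetworkFormatError("line 1: header must list at least one reaction id")
    reaction_ids = header[1:]
    r = len(reaction_ids)
    metabolite_ids: list[str] = []
    rows: list[list[Fraction]] = []
    flags: dict[str, list[bool]] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        toks = ln.split("\t")
        if toks[0] in ("#reversible", "#exchange"):
            if len(toks) != r + 1:
                raise NetworkFormatError(f"line {lineno}: expected {r} flag values")
            flags[toks[0][1:]] = [t == "1" for t in toks[1:]]
            continue
        if len(toks) != r + 1:
            raise NetworkFormatError(f"line {lineno}: expected {r} coefficients, got {len(toks) - 1}")
        metabolite_ids.append(toks[0])
        rows.append([_parse_coeff(t, lineno) for t in toks[1:]])
    for name in ("reversible", "exchange"):
        if name not in flags:
            raise NetworkFormatError(f"missing #{name} flag line")
    S = np.array(rows, dtype=object)
    S = np.array([[int(x) if x.denominator == 1 else x for x in row] for row in S.tolist()], dtype=object)
    return MetabolicNetwork(metabolite_ids, reaction_ids, S, flags["reversible"], flags["exchange"])


def write_tsv(net: MetabolicNetwork, path) -> None:
    """Write the TSV model dialect; exact round-trip partner of load_tsv."""

    def fmt(x) -> str:
        f = Fraction(x)
        return str(f.numerator) if f.denominator == 1 else f"{f.numerator}/{f.denominator}"

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("metabolite\t" + "\t".join(net.reaction_ids) + "\n")
        for i, mid in enumerate(net.metabolite_ids):
            fh.write(mid + "\t" + "\t".join(fmt(net.S[i, j]) for j in range(net.r)) + "\n")
        fh.write("#reversible\t" + "\t".join("1" if b else "0" for b in net.reversible) + "\n")
        fh.write("#exchange\t" + "\t".join("1" if b else "0" for b in net.exchange) + "\n")


def load_sbml(path, *, exchange_prefix: str = "EX_") -> MetabolicNetwork:
    """Read an SBML (Level 3 / FBC accepted) model.

    Only stoichiometry, reversibility and boundary information are used; flux
    bounds, objectives and GPR rules are ignored. A reaction is flagged as
    exchange when it is a boundary reaction (single-sided) or its id starts
    with ``exchange_prefix``. Boundary-condition species are excluded by the
    reader.
    """
    import cobra.io

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several parser exception types
        raise NetworkFormatError(f"cannot parse SBML file {path}: {exc}") from exc
    if len(model.reactions) == 0:
        raise NetworkFormatError("SBML model contains no reactions")
    metabolite_ids = [m.id for m in model.metabolites]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    reaction_ids = [rx.id for rx in model.reactions]
    S = np.zeros((len(metabolite_ids), len(reaction_ids)), dtype=object)
    S[:] = 0
    reversible = np.zeros(len(reaction_ids), dtype=bool)
    exchange = np.zeros(len(reaction_ids), dtype=bool)
    for j, rx in enumerate(model.reactions):
        reversible[j] = rx.reversibility
        exchange[j] = rx.boundary or rx.id.startswith(exchange_prefix)
        for met, coeff in rx.metabolites.items():
            # SBML stoichiometries are decimal; keep them exact via the
            # decimal string form (0.5 -> 1/2).
            f = Fraction(str(coeff))
            S[met_index[met.id], j] = int(f) if f.denominator == 1 else f
    return MetabolicNetwork(
        metabolite_ids, reaction_ids, S, reversible, exchange, allow_empty_exchange=True
    )


def augment(net: MetabolicNetwork, split_policy: str = "internal-reversible") -> AugmentedNetwork:
    """Split reversible reactions into forward + negated backward columns.

    ``internal-reversible`` (default) splits reversible non-exchange reactions
    only; ``all-reversible`` splits every reversible reaction. With the
    default policy a reversible exchange reaction remains a single
    nonnegative column, which restricts the cone; this is logged.
    """
    if split_policy == "internal-reversible":
        rr = [j for j in range(net.r) if net.reversible[j] and not net.exchange[j]]
        n_rev_exch = int(np.sum(net.reversible & net.exchange))
        if n_rev_exch:
            logger.info(
                "model has %d reversible exchange reactions left unsplit under the "
                "internal-reversible policy; their backward direction is excluded "
                "from the cone (use all-reversible to split them too)",
                n_rev_exch,
            )
    elif split_policy == "all-reversible":
        rr = [j for j in range(net.r) if net.reversible[j]]
    else:
        raise ValueError(f"unknown split policy {split_policy!r}")
    r = net.r
    S_aug = np.empty((net.m, r + len(rr)), dtype=object)
    S_aug[:, :r] = net.S
    split_columns = []
    origin = {j: (j, +1) for j in range(r)}
    for k, j in enumerate(rr):
        col = r + k
        for i in range(net.m):
            S_aug[i, col] = -net.S[i, j]
        split_columns.append((j, col))
        origin[col] = (j, -1)
    return AugmentedNetwork(net, S_aug, split_columns, origin)


def project_to_original(v_aug, aug: AugmentedNetwork) -> np.ndarray:
    """Net flux in original reaction space: forward minus backward columns."""
    v_aug = np.asarray(v_aug)
    if v_aug.shape[0] != aug.r_prime:
        raise ValueError(f"flux vector has length {v_aug.shape[0]}, expected {aug.r_prime}")
    v = np.array(v_aug[: aug.base.r], dtype=v_aug.dtype)
    for f, b in aug.split_columns:
        v[f] = v[f] - v_aug[b]
    return v
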