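"""Canonical base-pair annotation.

Stems are built from canonical pairs (Watson-Crick A-U / G-C and the G-U
wobble).  Two routes produce the pair list consumed by the GSSU
decomposition:

* :func:`detect_pairs` — a purely geometric detector that requires, for a
  candidate pair, (i) complementary bases, (ii) a C1'-C1' distance in the
  A-form window, (iii) a short glycosidic-face donor-acceptor contact
  (purine N1 to pyrimidine N3), and (iv) roughly coplanar bases.
* :func:`read_pair_annotation` — import of an externally computed pair
  list (e.g. 3DNA/DSSR output reformatted to a simple flat file), for
  users who prefer an established hydrogen-bond annotator.

:func:`remove_pseudoknots` reduces an arbitrary pair set to its maximum
nested (crossing-free) subset, the prerequisite for stem finding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import RnaStructure

logger = logging.getLogger(__name__)

#: complementary base combinations (canonical + wobble)
CANONICAL = {frozenset("AU"): "WC", frozenset("GC"): "WC",
             frozenset("GU"): "wobble"}
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}


class PairingError(Exception):
    """Raised for malformed or conflicting pair annotations."""


@dataclass(frozen=True, order=True)
class BasePair:
    """A canonical pair between residues ``i < j`` (0-based indices)."""

    i: int
    j: int
    kind: str = "WC"

    def __post_init__(self):
        if self.i >= self.j:
            raise PairingError(f"pair indices must satisfy i < j: {self}")


@dataclass
class PairParams:
    """Geometric thresholds for :func:`detect_pairs` (Angstrom/degrees)."""

    c1_min: float = 8.0
    c1_max: float = 12.0
    donor_acceptor_max: float = 3.6
    plane_angle_max: float = 65.0
    min_loop_sep: int = 3


def _face_atom(res) -> np.ndarray | None:
    """Glycosidic-face donor/acceptor: purine N1, pyrimidine N3."""
    name = "N1" if res.base in PURINES else "N3"
    return res.atoms.get(name)


def _plane_normal(res) -> np.ndarray | None:
    """Base-plane normal from C1', the face atom and C2 (both base types
    carry a C2).  Returns None if atoms are missing or degenerate."""
    c1 = res.atoms.get("C1'")
    face = _face_atom(res)
    c2 = res.atoms.get("C2")
    if c1 is None or face is None or c2 is None:
        return None
    n = np.cross(face - c1, c2 - c1)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        return None
    return n / norm


def detect_pairs(s: RnaStructure,
                 params: PairParams | None = None) -> list[BasePair]:
    """Detect canonical base pairs from geometry alone.

    One pair per residue is enforced: conflicting candidates are resolved
    by keeping the pair with the smallest donor-acceptor distance.
    Residues lacking base atoms are skipped with a log entry.
    """
    params = params or PairParams()
    res = s.residues
    n = len(res)
    c1 = np.full((n, 3), np.nan)
    face = np.full((n, 3), np.nan)
    usable = np.zeros(n, dtype=bool)
    normals: list[np.ndarray | None] = [None] * n
    for k, r in enumerate(res):
        a = r.atoms.get("C1'")
        f = _face_atom(r)
        if a is None or f is None or r.base == "N":
            logger.debug("residue %s lacks base atoms; skipped in pairing", r.key)
            continue
        c1[k] = a
        face[k] = f
        usable[k] = True
        normals[k] = _plane_normal(r)

    candidates: list[tuple[float, int, int, str]] = []
    idx = np.flatnonzero(usable)
    for ai in range(len(idx)):
        i = idx[ai]
        for bj in range(ai + 1, len(idx)):
            j = idx[bj]
            kind = CANONICAL.get(frozenset((res[i].base, res[j].base)))
            if kind is None:
                continue
            if res[i].chain_id == res[j].chain_id and j - i < params.min_loop_sep:
                continue
            d_c1 = float(np.linalg.norm(c1[i] - c1[j]))
            if not (params.c1_min <= d_c1 <= params.c1_max):
                continue
            d_da = float(np.linalg.norm(face[i] - face[j]))
            if d_da > params.donor_acceptor_max:
                continue
            ni, nj = normals[i], normals[j]
            if ni is not None and nj is not None:
                cosang = abs(float(np.dot(ni, nj)))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang > params.plane_angle_max:
                    continue
            candidates.append((d_da, int(i), int(j), kind))

    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[int] = set()
    pairs: list[BasePair] = []
    for d_da, i, j, kind in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append(BasePair(i, j, kind))
    pairs.sort()
    return pairs


def read_pair_annotation(path: str | Path, s: RnaStructure) -> list[BasePair]:
    """Read a flat-file pair annotation and map it onto ``s``.

    Format: whitespace-delimited, one pair per line::

        chain seq_num icode chain seq_num icode

    with ``.`` (or ``-``) standing for an empty insertion code and
    ``#``-prefixed comment lines allowed.
    """
    path = Path(path)
    index = {r.key: k for k, r in enumerate(s.residues)}

    def lookup(chain: str, num: str, icode: str, lineno: int) -> int:
        ic = "" if icode in (".", "-") else icode
        try:
            key = (chain, int(num), ic)
        except ValueError:
            raise PairingError(f"{path}:{lineno}: bad residue number {num!r}")
        if key not in index:
            raise PairingError(
                f"{path}:{lineno}: residue {key} not present in structure "
                f"{s.id!r}")
        return index[key]

    pairs: list[BasePair] = []
    used: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 6:
                raise PairingError(
                    f"{path}:{lineno}: expected 6 fields, got {len(tokens)}")
            i = lookup(tokens[0], tokens[1], tokens[2], lineno)
            j = lookup(tokens[3], tokens[4], tokens[5], lineno)
            if i == j:
                raise PairingError(f"{path}:{lineno}: residue paired with itself")
            if i > j:
                i, j = j, i
            if i in used or j in used:
                raise PairingError(
                    f"{path}:{lineno}: residue appears in more than one pair")
            used.update((i, j))
            bases = frozenset((s.residues[i].base, s.residues[j].base))
            pairs.append(BasePair(i, j, CANONICAL.get(bases, "WC")))
    pairs.sort()
    return pairs


def write_pair_annotation(path: str | Path, pairs: Sequence[BasePair],
                          s: RnaStructure) -> None:
    """Write pairs in the flat format accepted by :func:`read_pair_annotation`."""
    with open(path, "w") as fh:
        fh.write(f"# base pairs for {s.id}\n")
        for p in pairs:
            a, b = s.residues[p.i], s.residues[p.j]
            fh.write(f"{a.chain_id} {a.seq_num} {a.icode or '.'} "
                     f"{b.chain_id} {b.seq_num} {b.icode or '.'}\n")


def crossing(p: BasePair, q: BasePair) -> bool:
    """True if the two pairs cross (pseudoknot): i < k < j < l."""
    a, b = (p, q) if p.i <= q.i else (q, p)
    return a.i < b.i < a.j < b.j


def remove_pseudoknots(pairs: Sequence[BasePair]) -> list[BasePair]:
    """Return a maximum-cardinality nested (crossing-free) subset.

    Assumes each residue occurs in at most one pair (the output contract
    of :func:`detect_pairs` / :func:`read_pair_annotation`).  Solved by
    interval dynamic programming; ties between including and excluding an
    arc are broken toward inclusion of the arc with the smaller 5' index.
    """
    if not pairs:
        return []
    arcs = sorted(pairs)
    left = {p.i: p for p in arcs}
    positions = sorted({x for p in arcs for x in (p.i, p.j)})
    pos_index = {x: k for k, x in enumerate(positions)}

    @lru_cache(maxsize=None)
    def best(lo: int, hi: int) -> tuple[int, frozenset]:
        """Max nested subset among arcs with both endpoints in
        positions[lo:hi+1]."""
        if lo > hi:
            return 0, frozenset()
        x = positions[lo]
        arc = left.get(x)
        if arc is None or pos_index[arc.j] > hi:
            return best(lo + 1, hi)
        skip = best(lo + 1, hi)
        jn = pos_index[arc.j]
        inside = best(lo + 1, jn - 1)
        after = best(jn + 1, hi)
        take = (1 + inside[0] + after[0],
                inside[1] | after[1] | {arc})
        return take if take[0] >= skip[0] else skip

    _, kept = best(0, len(positions) - 1)
    best.cache_clear()
    return sorted(kept)
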