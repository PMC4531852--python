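"""Decomposition of an RNA structure into generalized secondary
structure units (GSSUs).

A GSSU is a hairpin-like fragment: a *stem* (helix of nested canonical
pairs), a *neck* (the innermost stem pair, closing the loop) and a *loop*
(the unpaired residues enclosed by the neck).  Helices that close no
hairpin — e.g. the stem closing a multiloop — form loop-less GSSUs with
no neck.  Every residue of the structure belongs to exactly one GSSU:
unpaired residues between units (junctions, external single strands) are
attached to the flanks of the 5'-adjacent unit.

Rules the decomposition applies, in order:

1. Helices are maximal runs of nested pairs in which consecutive pairs
   leave at most 2 unpaired (bulge) residues on either strand.
2. Helices shorter than ``min_stem`` pairs (default 2) are dissolved:
   their residues are treated as unpaired.
3. A helix whose innermost pair encloses no remaining pair becomes a
   hairpin GSSU (neck = innermost pair, loop = enclosed residues);
   otherwise it becomes a loop-less GSSU.
4. GSSUs are ordered 5'->3' by their outermost pair; each remaining
   unpaired residue joins the flank3 of the unit owning the nearest
   preceding paired residue, or the first unit's flank5 if there is none.
5. A structure with no pairs at all is a single all-loop GSSU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .base_pairing import BasePair
from .structure_io import RnaStructure


class DecompositionError(Exception):
    pass


@dataclass
class Gssu:
    """One stem/neck/loop unit; residue indices are 0-based positions in
    the parent structure's residue list."""

    stem_pairs: list[BasePair] = field(default_factory=list)
    neck: BasePair | None = None
    loop: list[int] = field(default_factory=list)
    flank5: list[int] = field(default_factory=list)
    flank3: list[int] = field(default_factory=list)
    index: int = 0

    @property
    def stem_len(self) -> int:
        return len(self.stem_pairs)

    def residue_indices(self) -> list[int]:
        """All residue indices of the unit (stem + loop + flanks)."""
        out = list(self.flank5)
        for p in self.stem_pairs:
            out.extend((p.i, p.j))
        out.extend(self.loop)
        out.extend(self.flank3)
        return sorted(out)


def _build_helices(pairs: Sequence[BasePair], max_bulge: int) -> list[list[BasePair]]:
    """Chain nested pairs into helices allowing small interior bulges."""
    arcs = sorted(pairs)
    # containment forest via stack (input must be crossing-free)
    parent: dict[BasePair, BasePair | None] = {}
    children: dict[BasePair, list[BasePair]] = {p: [] for p in arcs}
    stack: list[BasePair] = []
    for p in arcs:
        while stack and not (stack[-1].i < p.i and p.j < stack[-1].j):
            stack.pop()
        parent[p] = stack[-1] if stack else None
        if stack:
            children[stack[-1]].append(p)
        stack.append(p)

    def continues(outer: BasePair, inner: BasePair) -> bool:
        return (len(children[outer]) == 1
                and 0 <= inner.i - outer.i - 1 <= max_bulge
                and 0 <= outer.j - inner.j - 1 <= max_bulge)

    helices: list[list[BasePair]] = []
    for p in arcs:
        par = parent[p]
        if par is not None and continues(par, p):
            continue  # p extends an existing helix, not a helix start
        helix = [p]
        while children[helix[-1]] and continues(helix[-1], children[helix[-1]][0]):
            helix.append(children[helix[-1]][0])
        helices.append(helix)
    return helices


def decompose(s: RnaStructure, pairs: Sequence[BasePair],
              min_stem: int = 2, max_bulge: int = 2) -> list[Gssu]:
    """Split ``s`` (with nested pair annotation) into GSSUs.

    The decomposition depends only on the pair list and the residue
    order, never on coordinates.
    """
    n = len(s)
    if n == 0:
        raise DecompositionError("cannot decompose an empty structure")
    if min_stem < 1:
        raise DecompositionError("min_stem must be >= 1")
    for p in pairs:
        if p.j >= n:
            raise DecompositionError(f"pair {p} outside structure of length {n}")

    helices = [h for h in _build_helices(pairs, max_bulge) if len(h) >= min_stem]
    if not helices:
        return [Gssu(loop=list(range(n)), index=0)]

    paired: dict[int, int] = {}  # residue index -> helix ordinal
    helices.sort(key=lambda h: h[0].i)
    for hidx, helix in enumerate(helices):
        for p in helix:
            paired[p.i] = hidx
            paired[p.j] = hidx

    units: list[Gssu] = []
    for hidx, helix in enumerate(helices):
        inner = helix[-1]
        enclosed = list(range(inner.i + 1, inner.j))
        if not enclosed or any(r in paired for r in enclosed):
            units.append(Gssu(stem_pairs=list(helix)))  # loop-less
        else:
            units.append(Gssu(stem_pairs=list(helix), neck=inner, loop=enclosed))

    in_loop = {r for g in units for r in g.loop}
    # nearest preceding paired residue, per position
    owner_before = [-1] * n
    last = -1
    for r in range(n):
        owner_before[r] = last
        if r in paired:
            last = r
    for r in range(n):
        if r in paired or r in in_loop:
            continue
        prev = owner_before[r]
        if prev < 0:
            units[0].flank5.append(r)
        else:
            units[paired[prev]].flank3.append(r)

    for k, g in enumerate(units):
        g.index = k
        g.flank5.sort()
        g.flank3.sort()
    return units


def gssu_summary(gssus: Sequence[Gssu], s: RnaStructure) -> pd.DataFrame:
    """Per-GSSU summary table (one row per unit).

    Columns: structure id, total GSSU and nucleotide counts, and the
    stem/loop/flank lengths of each unit.  Export with
    ``df.to_csv(sep="\\t")`` or ``df.to_json(orient="records")``.
    """
    rows = []
    for g in gssus:
        rows.append({
            "structure_id": s.id,
            "n_gssus": len(gssus),
            "n_nucleotides": len(s),
            "gssu_index": g.index,
            "stem_bp": g.stem_len,
            "loop_nt": len(g.loop),
            "flank5_nt": len(g.flank5),
            "flank3_nt": len(g.flank3),
            "has_neck": g.neck is not None,
        })
    return pd.DataFrame(rows)
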