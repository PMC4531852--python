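"""Multiple RNA structure alignment.

Pipeline (the Clustal-style progressive strategy, driven by structure
rather than sequence distances):

1. all ``n (n - 1) / 2`` pairwise S-distances form a distance matrix;
2. a guide tree is built by neighbor joining (Q-criterion join
   selection, standard branch-length formulas, negative lengths clamped
   to zero, ties broken toward the smallest cluster index pair);
3. structures are merged in the tree's join order starting from the
   closest pair, each merge producing a weighted *average structure*
   (matched residues' coordinates averaged by cluster weight, unmatched
   residues inherited from the heavier cluster);
4. every input is finally re-aligned against the root average, and the
   per-member results are reported in descending S-distance order.

Parallelism over independent pairwise alignments is supported through a
thread pool; scheduling never changes floating-point summation order
within a single alignment, so every output is bit-identical for any
thread count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio.tree import TreeNode

from .base_pairing import BasePair, detect_pairs, remove_pseudoknots
from .gssu import Gssu, decompose
from .structure_io import RnaStructure
from .superpose import AlignParams, DEFAULT_PARAMS, PairResult, align_structures


class MultiAlignError(Exception):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric S-distance matrix over labelled structures."""

    ids: list[str]
    d: np.ndarray
    n_alignments: int = 0

    def to_phylip(self) -> str:
        """PHYLIP square-matrix format."""
        lines = [f"{len(self.ids)}"]
        for i, name in enumerate(self.ids):
            row = " ".join(f"{x:.6f}" for x in self.d[i])
            lines.append(f"{name[:10]:<10} {row}")
        return "\n".join(lines) + "\n"


@dataclass
class GuideTree:
    """NJ guide tree plus the cluster merge order it induces."""

    root: TreeNode
    ids: list[str]
    #: ordered joins, each a pair of leaf-label frozensets
    merge_order: list[tuple[frozenset, frozenset]]

    def to_newick(self) -> str:
        return str(self.root).strip() + ("\n" if not str(self.root).endswith("\n") else "")


@dataclass
class AverageStructure:
    """Running consensus of one or more structures."""

    structure: RnaStructure
    pairs: list[BasePair]
    weight: int = 1
    provenance: list[list[tuple[str, int]]] = field(default_factory=list)

    @classmethod
    def from_structure(cls, s: RnaStructure,
                       pairs: Sequence[BasePair]) -> "AverageStructure":
        return cls(s.copy(), list(pairs), 1,
                   [[(s.id, k)] for k in range(len(s))])


@dataclass
class MultiResult:
    tree: GuideTree
    average: AverageStructure
    distance_matrix: DistanceMatrix
    #: (structure id, result vs the final average), descending S-distance
    per_member: list[tuple[str, PairResult]]


def _structure_pairs(s: RnaStructure,
                     pairs: Sequence[BasePair] | None) -> list[BasePair]:
    if pairs is not None:
        return list(pairs)
    return remove_pseudoknots(detect_pairs(s))


def distance_matrix(structures: Sequence[RnaStructure],
                    params: AlignParams = DEFAULT_PARAMS,
                    threads: int = 1,
                    pairs_list: Sequence[Sequence[BasePair]] | None = None
                    ) -> DistanceMatrix:
    """All-to-all S-distance matrix from ``n (n - 1) / 2`` pairwise
    alignments; any failing pair raises an error naming the pair."""
    n = len(structures)
    if n < 2:
        raise MultiAlignError("need at least 2 structures")
    ids = [s.id for s in structures]
    if len(set(ids)) != n:
        raise MultiAlignError("structure ids must be unique")
    pair_sets = [_structure_pairs(s, pairs_list[k] if pairs_list else None)
                 for k, s in enumerate(structures)]
    decomps = [decompose(s, pair_sets[k], min_stem=params.min_stem)
               for k, s in enumerate(structures)]
    tasks = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def run(task: tuple[int, int]) -> tuple[int, int, float]:
        i, j = task
        try:
            res = align_structures(structures[i], structures[j],
                                   decomps[i], decomps[j], params)
        except Exception as exc:
            raise MultiAlignError(
                f"alignment failed for pair ({ids[i]}, {ids[j]}): {exc}"
            ) from exc
        return i, j, res.s_distance

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(run, tasks))
    else:
        results = [run(t) for t in tasks]

    d = np.zeros((n, n))
    for i, j, s_dist in results:
        d[i, j] = d[j, i] = s_dist
    return DistanceMatrix(ids, d, n_alignments=len(results))


def nj_tree(dm: DistanceMatrix) -> GuideTree:
    """Neighbor-joining guide tree.

    Deterministic: the Q-minimal pair is selected with lexicographic
    tie-breaking on cluster indices (creation order), and negative branch
    lengths are clamped to zero.
    """
    d = np.asarray(dm.d, dtype=float)
    n = len(dm.ids)
    if d.shape != (n, n):
        raise MultiAlignError("distance matrix shape mismatch")
    if not np.allclose(d, d.T, atol=1e-12):
        raise MultiAlignError("distance matrix must be symmetric")
    if np.any(d < 0) or np.any(np.diag(d) != 0):
        raise MultiAlignError("distances must be nonnegative with zero diagonal")
    if n < 2:
        raise MultiAlignError("need at least 2 leaves")

    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    leafsets: list[frozenset] = [frozenset([name]) for name in dm.ids]
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    merge_order: list[tuple[frozenset, frozenset]] = []

    while len(active) > 2:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length = li
        nodes[j].length = lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        merge_order.append((leafsets[i], leafsets[j]))
        new_idx = len(nodes)
        nodes.append(new)
        leafsets.append(leafsets[i] | leafsets[j])
        for k in active:
            if k in (i, j):
                continue
            dist[(k, new_idx) if k < new_idx else (new_idx, k)] = \
                0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j = active
    dij = get(i, j)
    nodes[i].length = 0.5 * dij
    nodes[j].length = 0.5 * dij
    root = TreeNode(children=[nodes[i], nodes[j]])
    merge_order.append((leafsets[i], leafsets[j]))
    return GuideTree(root, list(dm.ids), merge_order)


def _wavg(wa: int, pa: np.ndarray, wb: int, pb: np.ndarray) -> np.ndarray:
    if np.array_equal(pa, pb):  # exact consensus stays exact
        return pa.copy()
    return (wa * pa + wb * pb) / (wa + wb)


def merge_structures(a: AverageStructure, b: AverageStructure,
                     params: AlignParams = DEFAULT_PARAMS) -> AverageStructure:
    """Merge two averages into one.

    The lighter cluster is aligned onto the heavier one (ties: onto
    ``a``); matched residues' representative points (and, for identical
    bases, all shared atoms) are replaced by the weight-weighted mean,
    unmatched residues are inherited from the heavier cluster.
    """
    host, guest = (a, b) if a.weight >= b.weight else (b, a)
    hs, gs = host.structure, guest.structure
    host_g = decompose(hs, host.pairs, min_stem=params.min_stem)
    guest_g = decompose(gs, guest.pairs, min_stem=params.min_stem)
    res = align_structures(hs, gs, host_g, guest_g, params)
    sup = res.superposition
    guest_t = gs.transformed(sup.rotation, sup.translation)

    merged = hs.copy(f"({a.structure.id}+{b.structure.id})")
    provenance = [list(p) for p in host.provenance]
    wh, wg = host.weight, guest.weight
    for i, j in sup.pairs:
        rh = merged.residues[i]
        rg = guest_t.residues[j]
        rh.rep_point = _wavg(wh, rh.rep_point, wg, rg.rep_point)
        if rh.base == rg.base:
            for name in rh.atoms:
                if name in rg.atoms:
                    rh.atoms[name] = _wavg(wh, rh.atoms[name], wg, rg.atoms[name])
        else:
            for name in ("P", "O5'", "C5'", "C1'"):
                if name in rh.atoms and name in rg.atoms:
                    rh.atoms[name] = _wavg(wh, rh.atoms[name], wg, rg.atoms[name])
        provenance[i] = provenance[i] + guest.provenance[j]
    return AverageStructure(merged, list(host.pairs), wh + wg, provenance)


def progressive_align(structures: Sequence[RnaStructure],
                      params: AlignParams = DEFAULT_PARAMS,
                      threads: int = 1,
                      pairs_list: Sequence[Sequence[BasePair]] | None = None
                      ) -> MultiResult:
    """Guide-tree-driven progressive multiple structure alignment.

    Merging follows the NJ join order (the first join is the Q-minimal,
    i.e. most related, pair); the final average is the reference against
    which every input is re-aligned for reporting.
    """
    n = len(structures)
    if n < 2:
        raise MultiAlignError("need at least 2 structures")
    pair_sets = [_structure_pairs(s, pairs_list[k] if pairs_list else None)
                 for k, s in enumerate(structures)]
    decomps = [decompose(s, pair_sets[k], min_stem=params.min_stem)
               for k, s in enumerate(structures)]
    dm = distance_matrix(structures, params, threads, pair_sets)
    tree = nj_tree(dm)

    averages: dict[frozenset, AverageStructure] = {
        frozenset([s.id]): AverageStructure.from_structure(s, pair_sets[k])
        for k, s in enumerate(structures)
    }
    for set_a, set_b in tree.merge_order:
        merged = merge_structures(averages.pop(set_a), averages.pop(set_b),
                                  params)
        averages[set_a | set_b] = merged
    (final,) = averages.values()
    final.structure.id = "average"
    final_gssus = decompose(final.structure, final.pairs,
                            min_stem=params.min_stem)

    def member_result(k: int) -> tuple[str, PairResult]:
        res = align_structures(structures[k], final.structure,
                               decomps[k], final_gssus, params)
        return structures[k].id, res

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            per_member = list(pool.map(member_result, range(n)))
    else:
        per_member = [member_result(k) for k in range(n)]
    order = sorted(range(n), key=lambda k: (-per_member[k][1].s_distance, k))
    per_member = [per_member[k] for k in order]
    return MultiResult(tree, final, dm, per_member)
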