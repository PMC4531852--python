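"""Alignment quality measures and empirical significance.

Measures reported for every pairwise alignment, all relative to the
length of the shorter structure where a denominator is needed:

* RMSD over the phosphate representative points of matched residues;
* PSI — percentage of matched residues superimposed within a cutoff
  (default 4.0 A) of their partner;
* PID — percentage of matched residues whose bases are identical
  (unknown N bases never count as identical);
* the number of aligned residues and of exact base matches.

Significance of an S-distance is estimated with an add-one permutation
p-value against an explicit null: copies of the second structure whose
base identities are shuffled and whose GSSUs are independently re-posed
by uniformly random rotations (geometry *within* each unit preserved),
so the null reflects the chance compatibility of the units' shapes
rather than their actual spatial arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import RnaStructure

if TYPE_CHECKING:  # pragma: no cover
    from .base_pairing import BasePair
    from .superpose import AlignParams, Superposition


class ScoringError(Exception):
    pass


@dataclass
class QualityMeasures:
    rmsd_phosphate: float
    psi: float
    pid: float
    n_aligned: int
    n_exact: int

    def as_dict(self) -> dict:
        return {
            "rmsd_phosphate": self.rmsd_phosphate,
            "psi": self.psi,
            "pid": self.pid,
            "n_aligned": self.n_aligned,
            "n_exact": self.n_exact,
        }


def rmsd_points(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between two equally-sized coordinate arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ScoringError("RMSD needs two non-empty arrays of equal shape")
    d = a - b
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def _matched_coords(pairs, sa, sb, sup):
    idx_a = [i for i, _ in pairs]
    idx_b = [j for _, j in pairs]
    pa = sa.rep_points()[idx_a]
    pb = sup.apply(sb.rep_points()[idx_b])
    return pa, pb


def rmsd_phosphate(pairs: Sequence[tuple[int, int]],
                   sa: RnaStructure, sb: RnaStructure,
                   sup: "Superposition") -> float:
    """RMSD (A) over representative points of matched residue pairs,
    after transforming ``sb``."""
    if not pairs:
        raise ScoringError("rmsd_phosphate needs at least one matched pair")
    pa, pb = _matched_coords(pairs, sa, sb, sup)
    return rmsd_points(pa, pb)


def psi(pairs: Sequence[tuple[int, int]],
        sa: RnaStructure, sb: RnaStructure,
        sup: "Superposition", cutoff: float = 4.0) -> float:
    """Percentage of superimposed residues within ``cutoff`` Angstrom,
    relative to the shorter structure's length."""
    if cutoff <= 0:
        raise ScoringError("PSI cutoff must be positive")
    if not pairs:
        return 0.0
    pa, pb = _matched_coords(pairs, sa, sb, sup)
    within = int(np.sum(np.linalg.norm(pa - pb, axis=1) <= cutoff))
    return 100.0 * within / min(len(sa), len(sb))


def pid(pairs: Sequence[tuple[int, int]],
        sa: RnaStructure, sb: RnaStructure) -> float:
    """Percentage of aligned nucleotides of identical type, relative to
    the shorter structure's length.  N bases are never identical."""
    same = sum(1 for i, j in pairs
               if sa.residues[i].base == sb.residues[j].base
               and sa.residues[i].base != "N")
    return 100.0 * same / min(len(sa), len(sb))


def _null_copy(sb: RnaStructure, gssus, rng: np.random.Generator) -> RnaStructure:
    """Base-shuffled copy of ``sb`` with each GSSU independently re-posed
    by a uniformly random proper rotation about its centroid."""
    out = sb.copy(sb.id + "~null")
    perm = rng.permutation(len(out))
    bases = out.bases()
    for k, res in enumerate(out.residues):
        res.base = bases[perm[k]]
    for g in gssus:
        idx = g.residue_indices()
        centroid = np.mean([out.residues[r].rep_point for r in idx], axis=0)
        R = Rotation.random(rng=rng).as_matrix()
        for r in idx:
            res = out.residues[r]
            for name in res.atoms:
                res.atoms[name] = R @ (res.atoms[name] - centroid) + centroid
            res.rep_point = R @ (res.rep_point - centroid) + centroid
    # one global re-orientation about the overall centroid
    centroid = out.rep_points().mean(axis=0)
    R = Rotation.random(rng=rng).as_matrix()
    for res in out.residues:
        for name in res.atoms:
            res.atoms[name] = R @ (res.atoms[name] - centroid) + centroid
        res.rep_point = R @ (res.rep_point - centroid) + centroid
    return out


def empirical_p_value(observed: float,
                      sa: RnaStructure, sb: RnaStructure,
                      n_null: int, seed: int,
                      params: "AlignParams | None" = None,
                      pairs_a: "Sequence[BasePair] | None" = None,
                      pairs_b: "Sequence[BasePair] | None" = None) -> float:
    """Add-one permutation p-value for an observed S-distance.

    ``p = (1 + #{null S-distances <= observed}) / (n_null + 1)`` with the
    null described in the module docstring.  The estimator is bounded in
    ``[1/(n_null+1), 1]``.  A seed is mandatory; results are reproducible
    for a fixed seed.
    """
    from .base_pairing import detect_pairs, remove_pseudoknots
    from .gssu import decompose
    from .superpose import DEFAULT_PARAMS, align_structures

    if n_null < 19:
        raise ScoringError("n_null must be >= 19 for a meaningful p-value")
    if len(sa) < 4 or len(sb) < 4:
        raise ScoringError("structures too small to shuffle meaningfully")
    params = params or DEFAULT_PARAMS
    if pairs_a is None:
        pairs_a = remove_pseudoknots(detect_pairs(sa))
    if pairs_b is None:
        pairs_b = remove_pseudoknots(detect_pairs(sb))
    gssus_a = decompose(sa, pairs_a, min_stem=params.min_stem)
    gssus_b = decompose(sb, pairs_b, min_stem=params.min_stem)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_null):
        null = _null_copy(sb, gssus_b, rng)
        gssus_null = decompose(null, pairs_b, min_stem=params.min_stem)
        res = align_structures(sa, null, gssus_a, gssus_null, params)
        if res.s_distance <= observed:
            hits += 1
    return (1 + hits) / (n_null + 1)
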