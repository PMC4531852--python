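"""Idealized RNA-like 3D structure generators.

Every other module is testable offline against these generators: they
build A-form-like duplexes, hairpins, multi-hairpin chains, random coils
and noise-perturbed structure families with *known* topology, so the
base-pair detector, the GSSU decomposition and the aligners can be
checked against ground truth.

The geometry is idealized, not crystallographic: each residue carries
only the atoms the pipeline consumes — P, O5', C5', C1', the glycosidic
nitrogen (N9 for purines, N1 for pyrimidines), the pairing-face nitrogen
(N1 purines, N3 pyrimidines) and C2 as base-plane helper.  The helical
constants (rise 2.8 A per step, twist 32.7 deg, 10.4 A C1'-C1' across a
pair) sit inside the geometric detector's acceptance windows by
construction, and pairing-face atoms of a true pair are placed exactly
3.0 A apart while every other face-face contact exceeds the 3.6 A
donor-acceptor threshold.  Loop and linker bases are drawn from {A, G}
only, which admits no canonical combination, so at zero noise the
detector recovers exactly the constructed pairs and nothing else.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base_pairing import BasePair
from .structure_io import Residue, RnaStructure

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
PURINES = {"A", "G"}

#: default helical constants (Angstrom / degrees)
RISE = 2.8
TWIST = 32.7
PAIR_WIDTH = 10.4


class SynthError(Exception):
    pass


@dataclass
class HairpinSpec:
    stem_bp: int
    loop_nt: int


@dataclass
class SynthSpec:
    """Topology + geometry of a synthetic multi-hairpin chain."""

    topology: list[HairpinSpec]
    linker_nt: list[int] = field(default_factory=list)
    rise: float = RISE
    twist: float = TWIST
    pair_width: float = PAIR_WIDTH
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self):
        for h in self.topology:
            if h.stem_bp < 1:
                raise SynthError("stem_bp must be >= 1")
            if h.loop_nt in (1, 2):
                raise SynthError(
                    "loop_nt 1 or 2 is geometrically unclosable; use 0 or >= 3")
        if self.noise_sigma < 0:
            raise SynthError("noise_sigma must be >= 0")
        if len(self.linker_nt) not in (0, max(len(self.topology) - 1, 0)):
            raise SynthError("need one linker length per hairpin junction")


def _residue(chain: str, num: int, base: str, c1: np.ndarray, p: np.ndarray,
             gly: np.ndarray, face: np.ndarray, c2: np.ndarray,
             o5: np.ndarray, c5: np.ndarray) -> Residue:
    gly_name = "N9" if base in PURINES else "N1"
    face_name = "N1" if base in PURINES else "N3"
    atoms = {"P": p, "O5'": o5, "C5'": c5, "C1'": c1,
             gly_name: gly, face_name: face, "C2": c2}
    return Residue(chain, num, "", base, atoms, atoms["P"].copy())


def _stem_residue(base: str, step: int, side: int, spec: SynthSpec,
                  origin: np.ndarray, chain: str, num: int) -> Residue:
    """One paired residue; ``side`` is -1 (5' strand) or +1 (3' strand)."""
    theta = np.radians(spec.twist) * step
    u = np.array([np.cos(theta), np.sin(theta), 0.0])
    v = np.array([-np.sin(theta), np.cos(theta), 0.0])
    z = np.array([0.0, 0.0, spec.rise * step])
    half = spec.pair_width / 2.0
    c1 = origin + side * half * u + z
    gly = origin + side * (half - 1.5) * u + z
    face = origin + side * 1.5 * u + z
    c2 = face + 1.2 * v
    p = origin + side * (half + 2.0) * u + 1.0 * v + z + np.array([0, 0, 0.5])
    o5 = p + 0.3 * (c1 - p) + 0.4 * v
    c5 = p + 0.6 * (c1 - p) - 0.4 * v
    return _residue(chain, num, base, c1, p, gly, face, c2, o5, c5)


def _loop_residue(base: str, alpha: float, spec: SynthSpec, n_bp: int,
                  origin: np.ndarray, chain: str, num: int) -> Residue:
    """Loop residue on a semicircle bridging the innermost pair, base
    face pointing outward."""
    step = n_bp - 1
    theta = np.radians(spec.twist) * step
    u = np.array([np.cos(theta), np.sin(theta), 0.0])
    m = origin + np.array([0.0, 0.0, spec.rise * step])
    w = np.cos(alpha) * (-u) + np.sin(alpha) * np.array([0.0, 0.0, 1.0])
    t = np.sin(alpha) * u + np.cos(alpha) * np.array([0.0, 0.0, 1.0])
    r = spec.pair_width / 2.0
    c1 = m + r * w
    gly = c1 + 1.0 * w
    face = c1 + 2.5 * w
    c2 = face + 1.2 * t
    p = c1 + 0.8 * w + 2.0 * t + np.array([0.3, 0.0, 0.0])
    o5 = p + 0.3 * (c1 - p)
    c5 = p + 0.6 * (c1 - p)
    return _residue(chain, num, base, c1, p, gly, face, c2, o5, c5)


def _linker_residue(base: str, pos: np.ndarray, chain: str, num: int) -> Residue:
    c1 = pos
    gly = c1 + np.array([0.0, -1.0, 0.0])
    face = c1 + np.array([0.0, -2.5, 0.0])
    c2 = face + np.array([1.2, 0.0, 0.0])
    p = c1 + np.array([0.0, 2.0, 0.5])
    o5 = p + 0.3 * (c1 - p)
    c5 = p + 0.6 * (c1 - p)
    return _residue(chain, num, base, c1, p, gly, face, c2, o5, c5)


def _stem_sequence(n: int, offset: int = 0) -> list[str]:
    cycle = "GACU"
    return [cycle[(offset + k) % 4] for k in range(n)]


def _apply_noise(s: RnaStructure, sigma: float, seed: int) -> None:
    rng = np.random.default_rng(seed)
    for res in s.residues:
        for name in sorted(res.atoms):
            res.atoms[name] = res.atoms[name] + rng.normal(0.0, sigma, size=3)
        res.rep_point = res.atoms["P"].copy()


def make_helix(stem_bp: int = 5, spec: SynthSpec | None = None,
               seed: int = 0, noise_sigma: float = 0.0,
               structure_id: str = "helix") -> tuple[RnaStructure, list[BasePair]]:
    """Blunt two-chain duplex of ``stem_bp`` complementary pairs.

    Returns the structure and its ground-truth pair list; pair ``t``
    joins residue ``t`` (chain A) with residue ``2*stem_bp - 1 - t``
    (chain B).
    """
    spec = spec or SynthSpec([HairpinSpec(stem_bp, 0)],
                             seed=seed, noise_sigma=noise_sigma)
    n = stem_bp
    origin = np.zeros(3)
    seq = _stem_sequence(n)
    strand1 = [_stem_residue(seq[t], t, -1, spec, origin, "A", t + 1)
               for t in range(n)]
    strand2 = [_stem_residue(COMPLEMENT[seq[t]], t, +1, spec, origin, "B", n - t)
               for t in range(n - 1, -1, -1)]
    s = RnaStructure(structure_id, strand1 + strand2, ["A", "B"])
    pairs = [BasePair(t, 2 * n - 1 - t,
                      "wobble" if {seq[t], COMPLEMENT[seq[t]]} == {"G", "U"}
                      else "WC")
             for t in range(n)]
    if spec.noise_sigma > 0:
        _apply_noise(s, spec.noise_sigma, spec.seed)
    return s, sorted(pairs)


def _build_hairpin_residues(h: HairpinSpec, spec: SynthSpec,
                            origin: np.ndarray, chain: str, num0: int,
                            seq_offset: int
                            ) -> tuple[list[Residue], list[tuple[int, int]]]:
    """Residues of one hairpin (local indices) and its local pair list."""
    n, L = h.stem_bp, h.loop_nt
    seq = _stem_sequence(n, seq_offset)
    out: list[Residue] = []
    for t in range(n):
        out.append(_stem_residue(seq[t], t, -1, spec, origin, chain, num0 + t))
    loop_bases = ["A" if k % 2 == 0 else "G" for k in range(L)]
    for k in range(L):
        alpha = np.pi * (k + 1) / (L + 1)
        out.append(_loop_residue(loop_bases[k], alpha, spec, n, origin,
                                 chain, num0 + n + k))
    for t in range(n - 1, -1, -1):
        out.append(_stem_residue(COMPLEMENT[seq[t]], t, +1, spec, origin,
                                 chain, num0 + n + L + (n - 1 - t)))
    pairs = [(t, 2 * n + L - 1 - t) for t in range(n)]
    return out, pairs


def make_hairpin(stem_bp: int = 5, loop_nt: int = 4,
                 spec: SynthSpec | None = None, seed: int = 0,
                 noise_sigma: float = 0.0,
                 structure_id: str = "hairpin"
                 ) -> tuple[RnaStructure, list[BasePair]]:
    """Single-chain hairpin: stem of ``stem_bp`` pairs closed by a
    semicircular loop of ``loop_nt`` residues (``loop_nt >= 3``)."""
    if loop_nt < 3:
        raise SynthError("a hairpin loop needs at least 3 residues")
    spec = spec or SynthSpec([HairpinSpec(stem_bp, loop_nt)],
                             seed=seed, noise_sigma=noise_sigma)
    residues, local_pairs = _build_hairpin_residues(
        spec.topology[0], spec, np.zeros(3), "A", 1, 0)
    s = RnaStructure(structure_id, residues, ["A"])
    pairs = sorted(BasePair(i, j) for i, j in local_pairs)
    if spec.noise_sigma > 0:
        _apply_noise(s, spec.noise_sigma, spec.seed)
    return s, pairs


def make_multi_hairpin(spec: SynthSpec, structure_id: str = "multi"
                       ) -> tuple[RnaStructure, list[BasePair]]:
    """Chain of hairpins joined by single-stranded linkers (one chain).

    Hairpin ``h`` sits at x-offset ``h * 30`` A so units are far outside
    the detector's distance windows from each other; linker residues run
    in a straight line between consecutive hairpins and use non-pairable
    bases.
    """
    if not spec.topology:
        raise SynthError("need at least one hairpin")
    spacing = 30.0
    linkers = spec.linker_nt or [4] * (len(spec.topology) - 1)
    residues: list[Residue] = []
    pairs: list[BasePair] = []
    num = 1
    for h_idx, h in enumerate(spec.topology):
        if h.loop_nt < 3:
            raise SynthError("hairpins inside a chain need loop_nt >= 3")
        origin = np.array([h_idx * spacing, 0.0, 0.0])
        offset = len(residues)
        hp_res, hp_pairs = _build_hairpin_residues(
            h, spec, origin, "A", num, seq_offset=h_idx)
        residues.extend(hp_res)
        num += len(hp_res)
        pairs.extend(BasePair(offset + i, offset + j) for i, j in hp_pairs)
        if h_idx < len(spec.topology) - 1:
            n_link = linkers[h_idx]
            start = np.array([h_idx * spacing + spec.pair_width / 2.0, 0.0, 0.0])
            end = np.array([(h_idx + 1) * spacing - spec.pair_width / 2.0, 0.0, 0.0])
            for k in range(n_link):
                frac = (k + 1) / (n_link + 1)
                pos = start + frac * (end - start)
                residues.append(_linker_residue("A", pos, "A", num))
                num += 1
    s = RnaStructure(structure_id, residues, ["A"])
    if spec.noise_sigma > 0:
        _apply_noise(s, spec.noise_sigma, spec.seed)
    return s, sorted(pairs)


def make_coil(n_nt: int = 12, seed: int = 0, step: float = 5.9,
              structure_id: str = "coil") -> RnaStructure:
    """Unstructured single strand: a self-avoiding-ish random walk of
    phosphates with randomly oriented bases (no designed pairs)."""
    if n_nt < 3:
        raise SynthError("a coil needs at least 3 residues")
    rng = np.random.default_rng(seed)
    bases = [str(b) for b in rng.choice(list("AUGC"), size=n_nt)]
    pos = np.zeros(3)
    residues = []
    for k in range(n_nt):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pos = pos + step * d
        e1 = rng.normal(size=3)
        e1 -= e1.dot(d) * d
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        c1 = pos + 2.0 * e1
        gly = c1 + 1.0 * e1
        face = c1 + 2.5 * e1
        c2 = face + 1.2 * e2
        p = pos
        o5 = p + 0.3 * (c1 - p)
        c5 = p + 0.6 * (c1 - p)
        residues.append(_residue("A", k + 1, bases[k], c1, p, gly, face, c2,
                                 o5, c5))
    return RnaStructure(structure_id, residues, ["A"])


def make_family(base: RnaStructure, noise_sigma: float,
                seeds: list[int], keep_first_noise_free: bool = False
                ) -> list[RnaStructure]:
    """Noise-perturbed copies of ``base``, one per seed.

    Member ``k`` displaces every atom of ``base`` independently by
    isotropic Gaussian noise of standard deviation ``noise_sigma`` per
    coordinate, seeded by ``seeds[k]``; topology is unchanged, so the
    base structure's pair list remains the ground truth for all members.
    """
    if len(seeds) < 2:
        raise SynthError("a family needs at least 2 members")
    if len(set(seeds)) != len(seeds):
        raise SynthError("family seeds must be distinct")
    members = []
    for k, seed in enumerate(seeds):
        m = base.copy(f"{base.id}_m{k}")
        if noise_sigma > 0 and not (keep_first_noise_free and k == 0):
            _apply_noise(m, noise_sigma, seed)
        members.append(m)
    return members
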