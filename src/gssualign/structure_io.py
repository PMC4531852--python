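"""Reading, writing and in-memory representation of RNA 3D structures.

The central container is :class:`RnaStructure`, an ordered list of
:class:`Residue` objects.  Each residue carries its atoms (name -> Cartesian
coordinate in Angstrom) and a single representative point used by all
superposition code: the backbone phosphate ``P`` when present, with a
documented fallback chain (``O5'``, ``C5'``, ``C1'``) for 5'-terminal
residues that lack a phosphate.

Input formats are PDB and mmCIF (parsed with gemmi); output is PDB only.
Only nucleic-acid residues are retained: a residue must carry a ``C1'``
atom and map to one of the bases A, U, G, C or N.  A small built-in table
maps common modified nucleotides to their parent base; unknown residues
with a ribose C1' become N.  DNA residues are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: modified-nucleotide names mapped to their parent base
MODIFIED_BASES = {
    "PSU": "U", "H2U": "U", "4SU": "U", "5MU": "U", "OMU": "U", "UR3": "U",
    "1MA": "A", "2MA": "A", "6MA": "A", "MIA": "A", "OMA": "A", "A2M": "A",
    "5MC": "C", "OMC": "C", "4OC": "C", "M4C": "C",
    "1MG": "G", "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "G7M": "G",
}

_DNA_NAMES = {"DA", "DC", "DG", "DT", "DU", "DI"}
_STANDARD = {"A", "U", "G", "C", "N"}

#: representative-point preference order
REP_ATOM_ORDER = ("P", "O5'", "C5'", "C1'")


class StructureError(Exception):
    """Raised for unreadable files, missing chains or empty structures."""


@dataclass
class Residue:
    """One nucleotide with its atoms and representative point."""

    chain_id: str
    seq_num: int
    icode: str
    base: str
    atoms: dict[str, np.ndarray]
    rep_point: np.ndarray

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id, self.seq_num, self.icode, self.base,
            {k: v.copy() for k, v in self.atoms.items()},
            self.rep_point.copy(),
        )


@dataclass
class RnaStructure:
    """An ordered chain (or set of chains) of RNA residues."""

    id: str
    residues: list[Residue]
    source_chains: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def rep_points(self) -> np.ndarray:
        """(n, 3) array of representative points (phosphate trace)."""
        return np.array([r.rep_point for r in self.residues], dtype=float)

    def bases(self) -> list[str]:
        return [r.base for r in self.residues]

    def sequence(self) -> str:
        return "".join(self.bases())

    def copy(self, new_id: str | None = None) -> "RnaStructure":
        return RnaStructure(
            new_id if new_id is not None else self.id,
            [r.copy() for r in self.residues],
            list(self.source_chains),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    new_id: str | None = None) -> "RnaStructure":
        """Return a rigidly moved copy: x -> R x + t for every atom."""
        out = self.copy(new_id)
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for res in out.residues:
            for name in res.atoms:
                res.atoms[name] = R @ res.atoms[name] + t
            res.rep_point = R @ res.rep_point + t
        return out


def _base_of(resname: str) -> str | None:
    name = resname.strip().upper()
    if name in _DNA_NAMES:
        return None
    if name in _STANDARD:
        return name
    if name in MODIFIED_BASES:
        return MODIFIED_BASES[name]
    return "N"  # unknown hetero nucleotide with a C1' atom


def _convert_residue(res: gemmi.Residue, chain_id: str) -> Residue | None:
    atoms: dict[str, np.ndarray] = {}
    for atom in res:
        if atom.altloc not in ("\0", "", "A"):
            continue
        if atom.name not in atoms:
            atoms[atom.name] = np.array(
                [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
    if "C1'" not in atoms:
        return None
    base = _base_of(res.name)
    if base is None:
        return None
    rep = None
    for name in REP_ATOM_ORDER:
        if name in atoms:
            rep = atoms[name]
            break
    if rep is None or not np.all(np.isfinite(rep)):
        logger.warning("dropping residue %s %s%s: no usable representative atom",
                       res.name, res.seqid.num, res.seqid.icode)
        return None
    icode = res.seqid.icode
    if icode in (" ", "\0"):
        icode = ""
    return Residue(chain_id, res.seqid.num, icode, base, atoms, rep)


def read_structure(path: str | Path,
                   chains: Sequence[str] | None = None,
                   model: int | None = None,
                   fmt: str = "auto") -> RnaStructure:
    """Read a PDB or mmCIF file into an :class:`RnaStructure`.

    Parameters
    ----------
    path:
        File path; the format is detected from the extension unless
        ``fmt`` is ``"pdb"`` or ``"cif"``.
    chains:
        Chain identifiers to keep, in the order given.  When absent every
        chain containing RNA residues is included in file order.
    model:
        1-based model index for multi-model (e.g. NMR) files; defaults to
        the first model.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        elif fmt == "cif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError with line info
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")
    midx = (model - 1) if model is not None else 0
    if midx < 0 or midx >= len(st):
        raise StructureError(
            f"{path}: model {model} not present ({len(st)} models)")
    gmodel = st[midx]

    by_chain: dict[str, list[Residue]] = {}
    chain_order: list[str] = []
    for chain in gmodel:
        converted = []
        for res in chain:
            r = _convert_residue(res, chain.name)
            if r is not None:
                converted.append(r)
        if converted:
            converted.sort(key=lambda r: (r.seq_num, r.icode))
            by_chain.setdefault(chain.name, []).extend(converted)
            if chain.name not in chain_order:
                chain_order.append(chain.name)

    if chains is not None:
        missing = [c for c in chains if c not in by_chain]
        if missing:
            raise StructureError(
                f"{path}: chain(s) {missing} not found; available RNA chains: "
                f"{chain_order}")
        selected = list(chains)
    else:
        selected = chain_order

    residues = [r for c in selected for r in by_chain.get(c, [])]
    if not residues:
        raise StructureError(f"{path}: no RNA residues after filtering")
    return RnaStructure(path.stem, residues, selected)


_ELEMENT_GUESS = {"P": "P", "O": "O", "C": "C", "N": "N", "S": "S", "H": "H"}


def _element_for(atom_name: str) -> gemmi.Element:
    for ch in atom_name:
        if ch.isalpha():
            return gemmi.Element(_ELEMENT_GUESS.get(ch.upper(), "C"))
    return gemmi.Element("C")


def write_structure(s: RnaStructure, path: str | Path,
                    transform: "object | None" = None) -> None:
    """Write an :class:`RnaStructure` as a PDB file.

    ``transform`` may be a :class:`~gssualign.superpose.Superposition`
    (or any object with ``rotation`` and ``translation`` attributes);
    all atom coordinates are transformed before writing.
    """
    if len(s) == 0:
        raise StructureError("cannot write an empty structure")
    if transform is not None:
        s = s.transformed(transform.rotation, transform.translation)
    st = gemmi.Structure()
    st.name = s.id[:78] if s.id else "RNA"
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    order: list[str] = []
    for res in s.residues:
        if res.chain_id not in chains:
            chains[res.chain_id] = gemmi.Chain(res.chain_id)
            order.append(res.chain_id)
        gres = gemmi.Residue()
        gres.name = res.base
        gres.seqid = gemmi.SeqId(res.seq_num, res.icode if res.icode else " ")
        gres.het_flag = "A"
        for name, xyz in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.pos = gemmi.Position(float(xyz[0]), float(xyz[1]), float(xyz[2]))
            atom.element = _element_for(name)
            atom.occ = 1.0
            atom.b_iso = 0.0
            gres.add_atom(atom)
        chains[res.chain_id].add_residue(gres)
    for name in order:
        gmodel.add_chain(chains[name])
    st.add_model(gmodel)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except Exception as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc


def concatenate(structures: Sequence[RnaStructure], id: str) -> RnaStructure:
    """Concatenate several structures into one, preserving chain identifiers.

    Raises :class:`StructureError` if the same (chain, residue number,
    insertion code) triple occurs in more than one input.
    """
    if not structures:
        raise StructureError("concatenate requires at least one structure")
    seen: set[tuple[str, int, str]] = set()
    residues: list[Residue] = []
    chains: list[str] = []
    for s in structures:
        for r in s.residues:
            if r.key in seen:
                raise StructureError(
                    f"ambiguous residue identity {r.key} appears in more "
                    f"than one input")
            seen.add(r.key)
            residues.append(r.copy())
        for c in s.source_chains:
            if c not in chains:
                chains.append(c)
    return RnaStructure(id, residues, chains)
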