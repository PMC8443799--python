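"""Macromolecular coordinate I/O and amide bond-vector extraction.

Reads PDB/mmCIF through gemmi into a light-weight chain/residue/atom model
that the geometry modules consume, writes fixed-column PDB (single- or
multi-model), and derives backbone amide N-H unit vectors, reconstructing
the proton geometrically for X-ray entries that lack hydrogens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("coilreg")

N_H_BOND_LENGTH = 1.02  # Angstrom, standard amide geometry

WATER_NAMES = {"HOH", "WAT", "DOD"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}


class FormatError(Exception):
    """Raised when a coordinate file cannot be read."""


class EmptyStructureError(Exception):
    """Raised when the requested model contains no residues."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coords

    def backbone(self) -> dict[str, np.ndarray]:
        """Coordinates of N, CA, C, O where present."""
        return {n: a.coords for n in ("N", "CA", "C", "O")
                if (a := self.atom(n)) is not None}

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class Structure:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_id: str = ""

    def chain(self, chain_id: str) -> list[Residue]:
        return self.chains[chain_id]

    def chain_ids(self) -> list[str]:
        return list(self.chains.keys())

    def residue(self, chain_id: str, number: int) -> Residue | None:
        for r in self.chains[chain_id]:
            if r.number == number:
                return r
        return None

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id])


@dataclass
class AmideVector:
    chain_id: str
    residue: Residue
    vector: np.ndarray
    provenance: str  # "measured-H" | "reconstructed-H"

    @property
    def residue_number(self) -> int:
        return self.residue.number


def _resolve_altlocs(raw_atoms: Iterable[Atom]) -> list[Atom]:
    """Keep the highest-occupancy altloc per atom name; ties go to 'A'."""
    by_name: dict[str, list[Atom]] = {}
    for a in raw_atoms:
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occupancy, a.altloc or "A"))
        resolved.append(group[0])
    return resolved


def read_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Read a PDB or mmCIF file into a Structure.

    Altlocs are resolved to the highest-occupancy conformer (ties broken in
    favour of altloc 'A'), waters are dropped, heteroatom residues are kept
    so they can be inspected but carry no special treatment downstream.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read coordinate file {path}: {exc}") from exc
    if model_index >= len(st):
        raise FormatError(
            f"model index {model_index} out of range ({len(st)} models in {path})")
    model = st[model_index]
    out = Structure(source_id=st.name or path.stem)
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.name in WATER_NAMES:
                continue
            raw = [Atom(name=a.name, element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=a.occ, b_factor=a.b_iso,
                        altloc=a.altloc or "")
                   for a in res]
            if not raw:
                continue
            residues.append(Residue(number=res.seqid.num, name=res.name,
                                    atoms=_resolve_altlocs(raw),
                                    insertion_code=res.seqid.icode.strip()))
        if residues:
            numbers = [r.number for r in residues]
            if any(b <= a for a, b in zip(numbers, numbers[1:])):
                logger.warning("chain %s of %s: residue numbers not strictly "
                               "increasing", chain.name, path.name)
            out.chains[chain.name] = residues
    if not out.chains:
        raise EmptyStructureError(f"model {model_index} of {path} has no residues")
    return out


def _to_gemmi(structures: Sequence[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structures[0].source_id or "model"
    for idx, s in enumerate(structures, start=1):
        model = gemmi.Model(idx)
        for chain_id, residues in s.chains.items():
            chain = gemmi.Chain(chain_id)
            for r in residues:
                gr = gemmi.Residue()
                gr.name = r.name
                gr.seqid = gemmi.SeqId(r.number, r.insertion_code or " ")
                for a in r.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element or a.name[0])
                    ga.pos = gemmi.Position(*a.coords)
                    ga.occ = a.occupancy
                    ga.b_iso = a.b_factor
                    ga.altloc = a.altloc[:1] if a.altloc else "\0"
                    gr.add_atom(ga)
                chain.add_residue(gr)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structures: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write one Structure (or a sequence, as a multi-model file) as PDB."""
    if isinstance(structures, Structure):
        structures = [structures]
    st = _to_gemmi(list(structures))
    st.write_pdb(str(path))


def reconstruct_amide_h(n: np.ndarray, ca: np.ndarray,
                        c_prev: np.ndarray) -> np.ndarray:
    """Place the amide proton in the C(prev)-N-CA plane on the external
    bisector of that angle, 1.02 A from N."""
    u1 = c_prev - n
    u2 = ca - n
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    bis = u1 + u2
    nrm = np.linalg.norm(bis)
    if nrm < 1e-8:
        raise ValueError("degenerate C(prev)-N-CA geometry")
    return n - N_H_BOND_LENGTH * bis / nrm


def amide_vectors(structure: Structure,
                  chain_ids: Sequence[str] | None = None) -> list[AmideVector]:
    """One unit N->H vector per non-proline residue with sufficient atoms.

    Uses the measured proton when present; otherwise reconstructs it from
    the preceding residue's carbonyl carbon. The first residue of a chain
    (or after a break) is skipped when no preceding C exists.
    """
    out: list[AmideVector] = []
    for chain_id, residues in structure.chains.items():
        if chain_ids is not None and chain_id not in chain_ids:
            continue
        prev: Residue | None = None
        for res in residues:
            if res.name == "PRO":
                prev = res
                continue
            n = res.coords("N")
            ca = res.coords("CA")
            if n is None or ca is None:
                logger.warning("residue %s%d %s: missing N or CA, no amide vector",
                               chain_id, res.number, res.name)
                prev = res
                continue
            h = res.coords("H")
            if h is None:
                h = res.coords("HN")
            if h is not None:
                vec = h - n
                provenance = "measured-H"
            else:
                c_prev = prev.coords("C") if prev is not None else None
                sequential = (prev is not None and c_prev is not None
                              and np.linalg.norm(c_prev - n) < 2.5)
                if not sequential:
                    prev = res
                    continue
                vec = reconstruct_amide_h(n, ca, c_prev) - n
                provenance = "reconstructed-H"
            vec = vec / np.linalg.norm(vec)
            out.append(AmideVector(chain_id=chain_id, residue=res,
                                   vector=vec, provenance=provenance))
            prev = res
    return out
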