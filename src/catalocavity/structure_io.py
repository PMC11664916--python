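"""Protein structure I/O and active-site bookkeeping.

Reads and writes PDB files (via gemmi), locates the flavin cofactor and
derives its reference frame (N5 position, isoalloxazine centroid and ring
normal), and truncates long-chain carboxylic-acid ligands to a fixed number
of chain carbons so that the cavity computed around the ligand emphasises
the carboxylate-binding region rather than a long apolar tunnel.

Coordinates are in Angstrom throughout.  Hydrogens are read but ignored by
all downstream geometry (most crystal structures lack them).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "FlavinFrame",
    "LigandSpec",
    "StructureError",
    "CofactorNotFoundError",
    "LigandNotFoundError",
    "read_structure",
    "write_structure",
    "locate_flavin",
    "flavin_frame_axes",
    "truncate_ligand",
]

# Isoalloxazine atoms used for the least-squares ring plane; at least
# MIN_RING_ATOMS of these must be present.
ISOALLOXAZINE_ATOMS = ("N5", "N10", "C4A", "C5A", "C9A", "C10")
MIN_RING_ATOMS = 4


class StructureError(ValueError):
    """Malformed or unusable structure input."""


class CofactorNotFoundError(StructureError):
    """The requested flavin residue (or its ring atoms) is missing."""


class LigandNotFoundError(StructureError):
    """The ligand named by a LigandSpec is not in the structure."""


@dataclass(frozen=True)
class Atom:
    """One atom record; residue_number is preserved verbatim from the file."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_number: int
    coords: np.ndarray  # shape (3,), Angstrom
    is_hetero: bool

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            raise StructureError(f"atom {self.serial}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """An ordered list of atoms with a structure id."""

    atoms: list[Atom]
    id: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("duplicate atom serials in structure")

    def __len__(self) -> int:
        return len(self.atoms)

    def select(self, *, hetero: Optional[bool] = None,
               residue_name: Optional[str] = None,
               heavy_only: bool = False) -> list[Atom]:
        out = []
        for a in self.atoms:
            if hetero is not None and a.is_hetero != hetero:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            out.append(a)
        return out

    def protein_heavy_atoms(self) -> list[Atom]:
        """Non-hetero, non-hydrogen atoms (the cavity-blocking set)."""
        return self.select(hetero=False, heavy_only=True)

    def coords_of(self, atoms: Sequence[Atom]) -> np.ndarray:
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.coords for a in atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [dataclasses.replace(a, coords=R @ a.coords + t) for a in self.atoms]
        return Structure(atoms, id=self.id)


@dataclass(frozen=True)
class FlavinFrame:
    """Reference frame of the flavin: N5 atom, ring centroid, unit ring normal."""

    n5: np.ndarray
    ring_centroid: np.ndarray
    ring_normal: np.ndarray

    def __post_init__(self) -> None:
        for name in ("n5", "ring_centroid", "ring_normal"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if abs(np.linalg.norm(self.ring_normal) - 1.0) > 1e-9:
            raise StructureError("ring_normal must be a unit vector")
        if np.linalg.norm(self.n5 - self.ring_centroid) > 3.0:
            raise StructureError("N5 implausibly far from the ring centroid")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FlavinFrame":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return FlavinFrame(R @ self.n5 + t, R @ self.ring_centroid + t,
                           R @ self.ring_normal)


@dataclass(frozen=True)
class LigandSpec:
    """Identifies the bound carboxylic acid and orders its chain carbons.

    ``chain_carbons`` runs from the carboxyl carbon outward along the alkyl
    chain; truncation keeps a prefix of this list.
    """

    residue_name: str
    chain: str
    residue_number: int
    carboxyl_carbon: str = "C1"
    chain_carbons: tuple[str, ...] = ()
    carboxylate_oxygens: tuple[str, ...] = ("O1", "O2")

    def __post_init__(self) -> None:
        if self.chain_carbons and self.chain_carbons[0] != self.carboxyl_carbon:
            raise StructureError("chain_carbons[0] must be the carboxyl carbon")
        if len(set(self.chain_carbons)) != len(self.chain_carbons):
            raise StructureError("duplicate names in chain_carbons")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_structure(path: str | os.PathLike, *, drop_waters: bool = True,
                   structure_id: Optional[str] = None) -> Structure:
    """Parse a PDB file into a Structure.

    Altloc handling follows the common convention: keep the highest-occupancy
    alternative, ties resolved in favour of altloc 'A'.  Waters (HOH/WAT/DOD)
    are dropped by default.
    """
    path = os.fspath(path)
    try:
        st = gemmi.read_pdb(path)
    except OSError:
        raise
    except RuntimeError as exc:
        raise StructureError(f"cannot parse PDB file {path!r}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no atoms parsed from {path!r}")
    st.setup_entities()
    model = st[0]
    atoms: list[Atom] = []
    serial = 0
    waters = {"HOH", "WAT", "DOD"}
    for chain in model:
        for residue in chain:
            if drop_waters and residue.name in waters:
                continue
            is_het = residue.het_flag == "H"
            # altloc: group by atom name, keep best occupancy (tie -> 'A').
            by_name: dict[str, gemmi.Atom] = {}
            for at in residue:
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                    continue
                key_new = (at.occ, -ord(at.altloc or "A"))
                key_old = (prev.occ, -ord(prev.altloc or "A"))
                if key_new > key_old:
                    by_name[at.name] = at
            for at in residue:  # preserve file order of first occurrences
                chosen = by_name.pop(at.name, None)
                if chosen is None:
                    continue
                serial += 1
                atoms.append(Atom(
                    serial=serial,
                    name=chosen.name,
                    element=chosen.element.name or "X",
                    residue_name=residue.name,
                    chain=(chain.name or "A")[:1] or "A",
                    residue_number=residue.seqid.num,
                    coords=np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z]),
                    is_hetero=is_het,
                ))
    if not atoms:
        raise StructureError(f"no atoms parsed from {path!r}")
    sid = structure_id if structure_id is not None else os.path.splitext(
        os.path.basename(path))[0]
    return Structure(atoms, id=sid)


def write_structure(s: Structure, path: str | os.PathLike) -> None:
    """Write a Structure back to a fixed-column PDB file."""
    st = gemmi.Structure()
    st.name = s.id or "XXXX"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int, str], gemmi.Residue] = {}
    for a in s.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chains[a.chain] = ch
        rkey = (a.chain, a.residue_number, a.residue_name)
        res = residues.get(rkey)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.is_hetero else "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
            residues[rkey] = res
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        at.occ = 1.0
        at.b_iso = 0.0
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(os.fspath(path))


# ---------------------------------------------------------------------------
# Flavin frame
# ---------------------------------------------------------------------------

def _ring_plane_normal(coords: np.ndarray) -> np.ndarray:
    """Least-squares plane normal through points (smallest singular vector)."""
    centered = coords - coords.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[-2] < 1e-6:  # collinear/degenerate ring atoms
        raise CofactorNotFoundError("isoalloxazine ring atoms are degenerate")
    return vt[-1]


def flavin_frame_axes(frame: FlavinFrame) -> np.ndarray:
    """Right-handed orthonormal axes (rows) derived from a flavin frame.

    e3 is the ring normal; e1 is the in-plane direction from the ring
    centroid toward N5; e2 completes the frame.  The axes are equivariant
    under rigid motions, which makes them usable as a structure-intrinsic
    coordinate system for grids and alignments.
    """
    e3 = frame.ring_normal / np.linalg.norm(frame.ring_normal)
    v = frame.n5 - frame.ring_centroid
    v = v - np.dot(v, e3) * e3
    nv = np.linalg.norm(v)
    if nv < 1e-6:
        raise StructureError("N5 coincides with the ring centroid; frame axes undefined")
    e1 = v / nv
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3])


def locate_flavin(s: Structure, residue_name: str = "FAD",
                  ligand_spec: Optional[LigandSpec] = None) -> FlavinFrame:
    """Locate the flavin and build its reference frame.

    The ring normal comes from a least-squares plane through the
    isoalloxazine core atoms.  Its sign is fixed so that, when a ligand is
    given, the normal points toward the ligand's carboxyl carbon (the
    substrate side of the ring); without a ligand the sign follows the
    ordered ring-atom convention (N10-N5) x (C4A-N5), which is equivariant
    under rotations.
    """
    flavin_atoms = {a.name: a for a in s.select(residue_name=residue_name)}
    if not flavin_atoms:
        raise CofactorNotFoundError(f"no residue named {residue_name!r} in {s.id!r}")
    ring = [flavin_atoms[n] for n in ISOALLOXAZINE_ATOMS if n in flavin_atoms]
    if len(ring) < MIN_RING_ATOMS or "N5" not in flavin_atoms:
        raise CofactorNotFoundError(
            f"isoalloxazine core incomplete in {residue_name!r}: found "
            f"{sorted(a.name for a in ring)}")
    coords = np.stack([a.coords for a in ring])
    centroid = coords.mean(axis=0)
    normal = _ring_plane_normal(coords)
    n5 = flavin_atoms["N5"].coords

    reference = None
    if ligand_spec is not None:
        lig = _ligand_atoms(s, ligand_spec)
        carboxyl = next((a for a in lig if a.name == ligand_spec.carboxyl_carbon), None)
        if carboxyl is not None:
            reference = carboxyl.coords - centroid
            if abs(np.dot(normal, reference)) < 1e-9:
                reference = None  # carboxyl in the ring plane: no side defined
    if reference is None and {"N10", "C4A"} <= flavin_atoms.keys():
        v1 = flavin_atoms["N10"].coords - n5
        v2 = flavin_atoms["C4A"].coords - n5
        reference = np.cross(v1, v2)
    if reference is not None and np.dot(normal, reference) < 0:
        normal = -normal
    return FlavinFrame(n5=n5, ring_centroid=centroid, ring_normal=normal)


# ---------------------------------------------------------------------------
# Ligand truncation
# ---------------------------------------------------------------------------

def _ligand_atoms(s: Structure, spec: LigandSpec) -> list[Atom]:
    atoms = [a for a in s.atoms
             if a.residue_name == spec.residue_name
             and a.chain == spec.chain
             and a.residue_number == spec.residue_number]
    if not atoms:
        raise LigandNotFoundError(
            f"ligand {spec.residue_name}:{spec.chain}:{spec.residue_number} "
            f"not found in {s.id!r}")
    return atoms


def ligand_heavy_atoms(s: Structure, spec: LigandSpec) -> list[Atom]:
    """Heavy atoms of the (possibly truncated) ligand residue."""
    return [a for a in _ligand_atoms(s, spec) if not a.is_hydrogen]


def infer_ligand_spec(s: Structure, ligand: str) -> LigandSpec:
    """Build a LigandSpec from a "RES:CHAIN:NUM" selector.

    Chain carbons are the ligand atoms named C1, C2, ... ordered by index
    (C1 taken as the carboxyl carbon, the usual convention for fatty-acid
    ligands); carboxylate oxygens are the atoms named O1, O2, ...
    """
    try:
        resname, chain, num = ligand.split(":")
        resnum = int(num)
    except ValueError as exc:
        raise ValueError(f"ligand selector {ligand!r} is not RES:CHAIN:NUM") from exc
    spec0 = LigandSpec(resname, chain, resnum)
    atoms = _ligand_atoms(s, spec0)
    carbons = sorted((a.name for a in atoms
                      if a.name.startswith("C") and a.name[1:].isdigit()),
                     key=lambda n: int(n[1:]))
    oxygens = sorted((a.name for a in atoms
                      if a.name.startswith("O") and a.name[1:].isdigit()),
                     key=lambda n: int(n[1:]))
    if not carbons:
        raise LigandNotFoundError(f"ligand {ligand!r} has no numbered carbons")
    return LigandSpec(resname, chain, resnum, carboxyl_carbon=carbons[0],
                      chain_carbons=tuple(carbons),
                      carboxylate_oxygens=tuple(oxygens))


def truncate_ligand(s: Structure, spec: LigandSpec, keep_carbons: int = 8) -> Structure:
    """Trim the ligand's alkyl chain to ``keep_carbons`` carbons.

    Keeps the carboxylate oxygens, the first ``keep_carbons`` chain carbons
    (counted from the carboxyl carbon outward) and any hydrogens attached by
    name suffix; removes all later chain atoms.  Protein atoms are untouched
    and no geometry is re-optimised.
    """
    if keep_carbons < 2:
        raise ValueError("keep_carbons must be >= 2")
    if not spec.chain_carbons:
        raise ValueError("LigandSpec.chain_carbons is empty; nothing to truncate")
    if keep_carbons > len(spec.chain_carbons):
        raise ValueError(
            f"keep_carbons={keep_carbons} exceeds chain length "
            f"{len(spec.chain_carbons)}")
    lig = _ligand_atoms(s, spec)  # raises LigandNotFoundError if absent
    kept_names = set(spec.chain_carbons[:keep_carbons]) | set(spec.carboxylate_oxygens)
    kept_heavy = [a for a in lig if a.name in kept_names]

    def keep(a: Atom) -> bool:
        if not (a.residue_name == spec.residue_name and a.chain == spec.chain
                and a.residue_number == spec.residue_number):
            return True
        if a.name in kept_names:
            return True
        if a.is_hydrogen:
            # hydrogens follow their parent heavy atom (bond-distance rule;
            # atom-name conventions for fatty-acid hydrogens vary too much)
            return any(np.linalg.norm(a.coords - h.coords) <= 1.3 for h in kept_heavy)
        return False

    return Structure([a for a in s.atoms if keep(a)], id=s.id)
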