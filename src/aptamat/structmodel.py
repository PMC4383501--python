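"""Structures, docking poses, and binding-interface analysis.

A :class:`Structure` is a flat list of atoms with chain/residue bookkeeping
preserved verbatim from the source PDB file; a :class:`Pose` is one rigid
placement of an RNA ligand relative to a protein receptor, with the rigid
transform stored explicitly (never baked into the ligand coordinates) so that
rescoring and interface analysis always agree on the geometry.

Interface analysis finds all receptor-residue / ligand-nucleotide pairs whose
minimum heavy-atom distance is within a cutoff (default 5 angstrom, a
conventional contact threshold) and can check the recovered receptor residues
against a named epitope — by default the five Ang2 residues that contact Tie2
(K468, F469, K473, Y475, Y476), so that a pose can be classified as binding
on or off the receptor-blocking site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .panels import TIE2_EPITOPE_RESIDUES

#: Default heavy-atom contact cutoff, angstrom.
DEFAULT_CONTACT_CUTOFF = 5.0

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_RNA_RESNAMES = {"A", "C", "G", "U", "RA", "RC", "RG", "RU"}


class PDBParseError(ValueError):
    """Unreadable or malformed PDB content (carries a line number if known)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    res_name: str
    name: str
    element: str
    pos: tuple[float, float, float]

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass(frozen=True)
class Structure:
    """A molecule (or chain selection) as a flat atom list."""

    atoms: tuple[Atom, ...]
    molecule_kind: str = "protein"  # "protein" | "rna"

    def __post_init__(self) -> None:
        if self.molecule_kind not in ("protein", "rna"):
            raise ValueError(f"unknown molecule_kind {self.molecule_kind!r}")
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.pos):
                raise ValueError(f"non-finite coordinate on atom {a.name}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return tuple(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float).reshape(-1, 3)

    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if not a.is_hydrogen)

    def heavy_coords(self) -> np.ndarray:
        return np.array(
            [a.pos for a in self.atoms if not a.is_hydrogen], dtype=float
        ).reshape(-1, 3)

    @property
    def residue_ids(self) -> tuple[tuple[str, int, str], ...]:
        """(chain, res_seq, res_name) triples in first-appearance order."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.res_seq, a.res_name), None)
        return tuple(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


def _infer_kind(res_names: Iterable[str]) -> str:
    names = set(res_names)
    return "rna" if names and names <= _RNA_RESNAMES else "protein"


def read_pdb(
    path: str | Path,
    include_hetero: bool = False,
    molecule_kind: str | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model only).

    Waters and, unless ``include_hetero`` is set, other hetero groups are
    excluded. Altloc variants beyond the first are dropped. Parse failures
    raise :class:`PDBParseError` with the offending line number when it can be
    located.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(str(exc), _find_bad_line(path)) from exc
    bad = _find_bad_line(path)
    if bad is not None:
        raise PDBParseError("malformed ATOM/HETATM coordinate field", bad)
    st.setup_entities()
    st.remove_alternative_conformations()
    atoms: list[Atom] = []
    if len(st) == 0:
        raise PDBParseError("no models in file")
    for chain in st[0]:
        for res in chain:
            if res.is_water():
                continue
            if res.het_flag == "H" and not include_hetero:
                continue
            for at in res:
                atoms.append(
                    Atom(
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        res_name=res.name.strip(),
                        name=at.name,
                        element=at.element.name,
                        pos=(at.pos.x, at.pos.y, at.pos.z),
                    )
                )
    kind = molecule_kind or _infer_kind(a.res_name for a in atoms)
    return Structure(atoms=tuple(atoms), molecule_kind=kind)


def _find_bad_line(path: Path) -> int | None:
    """Locate the first ATOM/HETATM record with an unparseable coordinate."""
    try:
        text = path.read_text()
    except OSError:
        return None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            fld = line[lo:hi].strip()
            try:
                float(fld)
            except ValueError:
                return lineno
    return None


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = "aptamat"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int, str], gemmi.Residue] = {}
    for a in structure.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        key = (a.chain, a.res_seq, a.res_name)
        if key not in residues:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, " ")
            chains[a.chain].add_residue(res)
            residues[key] = chains[a.chain][-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.pos)
        residues[key].add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def extract_receptor(structure: Structure, drop_chains: Sequence[str]) -> Structure:
    """Remove chains (e.g. the Tie2 chain of an Ang2/Tie2 complex).

    Atom order is preserved; asking to drop an absent chain is an error.
    """
    present = set(structure.chains)
    missing = [c for c in drop_chains if c not in present]
    if missing:
        raise KeyError(f"chain(s) not in structure: {missing}")
    dropped = set(drop_chains)
    kept = tuple(a for a in structure.atoms if a.chain not in dropped)
    return replace(structure, atoms=kept)


def transform_structure(
    structure: Structure, rotation: np.ndarray, translation: np.ndarray
) -> Structure:
    """Apply a rigid transform (x -> R x + t) to every atom."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    atoms = tuple(
        replace(a, pos=tuple(R @ np.asarray(a.pos) + t)) for a in structure.atoms
    )
    return replace(structure, atoms=atoms)


@dataclass(frozen=True)
class Pose:
    """A candidate rigid placement of a ligand against a receptor.

    The transform (rotation + translation, applied as x -> R x + t to the
    ligand's stored coordinates) brings the ligand into the receptor's frame.
    """

    receptor: Structure
    ligand: Structure
    pose_id: int = 0
    rotation: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0),
    )
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        return np.array(self.rotation, dtype=float)

    def translation_vector(self) -> np.ndarray:
        return np.array(self.translation, dtype=float)

    def ligand_heavy_coords(self) -> np.ndarray:
        xyz = self.ligand.heavy_coords()
        return xyz @ self.rotation_matrix().T + self.translation_vector()

    def transformed_ligand(self) -> Structure:
        return transform_structure(
            self.ligand, self.rotation_matrix(), self.translation_vector()
        )


@dataclass(frozen=True)
class Contact:
    """One receptor-residue / ligand-nucleotide contact pair."""

    receptor_residue: tuple[str, int, str]  # chain, number, name
    ligand_nucleotide: tuple[str, int, str]
    min_distance: float


@dataclass(frozen=True)
class InterfaceReport:
    """All contacts of a pose within a cutoff, plus the interface centroid."""

    contacts: tuple[Contact, ...]
    cutoff: float
    center: tuple[float, float, float] | None

    @property
    def receptor_residues(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(c.receptor_residue for c in self.contacts)

    @property
    def ligand_nucleotides(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(c.ligand_nucleotide for c in self.contacts)

    def is_empty(self) -> bool:
        return not self.contacts

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "receptor_chain": [c.receptor_residue[0] for c in self.contacts],
                "receptor_resnum": [c.receptor_residue[1] for c in self.contacts],
                "receptor_resname": [c.receptor_residue[2] for c in self.contacts],
                "ligand_chain": [c.ligand_nucleotide[0] for c in self.contacts],
                "ligand_ntnum": [c.ligand_nucleotide[1] for c in self.contacts],
                "ligand_ntname": [c.ligand_nucleotide[2] for c in self.contacts],
                "min_distance": [c.min_distance for c in self.contacts],
            }
        )


def interface_residues(
    pose: Pose, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> InterfaceReport:
    """Find all residue/nucleotide contact pairs within ``cutoff`` angstrom.

    Heavy atoms only (the crystal structures of interest lack hydrogens). The
    reported distance per pair is the minimum over its heavy-atom pairs; the
    interface center is the centroid of all heavy atoms, on both partners,
    that participate in at least one contact.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec_atoms = pose.receptor.heavy_atoms()
    lig_atoms = pose.ligand.heavy_atoms()
    if not rec_atoms or not lig_atoms:
        raise ValueError("receptor and ligand must both contain heavy atoms")
    rec_xyz = pose.receptor.heavy_coords()
    lig_xyz = pose.ligand_heavy_coords()

    tree = cKDTree(rec_xyz)
    neighbor_lists = tree.query_ball_point(lig_xyz, r=cutoff)

    best: dict[tuple, float] = {}
    touched_rec: set[int] = set()
    touched_lig: set[int] = set()
    for j, neighbors in enumerate(neighbor_lists):
        if not neighbors:
            continue
        lj = lig_atoms[j]
        lig_key = (lj.chain, lj.res_seq, lj.res_name)
        for i in neighbors:
            ri = rec_atoms[i]
            d = float(np.linalg.norm(rec_xyz[i] - lig_xyz[j]))
            if d > cutoff:
                continue
            key = ((ri.chain, ri.res_seq, ri.res_name), lig_key)
            if d < best.get(key, np.inf):
                best[key] = d
            touched_rec.add(i)
            touched_lig.add(j)

    contacts = tuple(
        Contact(receptor_residue=rk, ligand_nucleotide=lk, min_distance=d)
        for (rk, lk), d in sorted(best.items(), key=lambda kv: kv[0])
    )
    center = None
    if contacts:
        pts = np.vstack(
            [rec_xyz[sorted(touched_rec)], lig_xyz[sorted(touched_lig)]]
        )
        center = tuple(float(v) for v in pts.mean(axis=0))
    return InterfaceReport(contacts=contacts, cutoff=cutoff, center=center)


@dataclass(frozen=True)
class Epitope:
    """A named set of receptor residues, e.g. the Tie2-binding site of Ang2."""

    name: str = "Tie2-binding epitope"
    residues: tuple[str, ...] = TIE2_EPITOPE_RESIDUES

    def parsed(self) -> tuple[tuple[str, int], ...]:
        out = []
        for label in self.residues:
            out.append((label[0].upper(), int(label[1:])))
        return tuple(out)


@dataclass(frozen=True)
class EpitopeOverlap:
    """Epitope residues confirmed at an interface, plus any identity clashes.

    ``mismatches`` lists epitope residue numbers found at the interface whose
    residue name does not match the epitope's expectation; these are flagged,
    never silently counted as overlap.
    """

    residues: tuple[str, ...]
    mismatches: tuple[str, ...] = ()

    @property
    def count(self) -> int:
        return len(self.residues)


def epitope_overlap(
    report: InterfaceReport, epitope: Epitope | None = None
) -> EpitopeOverlap:
    """Which epitope residues appear among a report's receptor residues.

    Residues match on (one-letter name, number); a residue at an epitope
    number whose name disagrees is reported in ``mismatches``.
    """
    epitope = epitope or Epitope()
    at_interface: dict[int, set[str]] = {}
    for chain, num, resname in report.receptor_residues:
        one = _THREE_TO_ONE.get(resname.upper(), resname[:1].upper())
        at_interface.setdefault(num, set()).add(one)
    hits: list[str] = []
    mismatches: list[str] = []
    for letter, num in epitope.parsed():
        names = at_interface.get(num)
        if names is None:
            continue
        if letter in names:
            hits.append(f"{letter}{num}")
        else:
            mismatches.append(f"{'/'.join(sorted(names))}{num}!={letter}{num}")
    return EpitopeOverlap(residues=tuple(hits), mismatches=tuple(mismatches))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def toy_pose_sampler(
    receptor: Structure,
    ligand: Structure,
    n_poses: int,
    seed: int,
    clash_distance: float = 2.0,
    max_attempts_per_pose: int = 500,
) -> list[Pose]:
    """Seeded rigid pose generator standing in for an external docking search.

    Each pose applies a uniform random rotation to the ligand and anchors a
    random ligand atom a few angstrom from a random receptor atom (so poses
    actually touch the receptor surface); placements with any heavy-atom pair
    closer than ``clash_distance`` are rejected and resampled.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    rec_xyz = receptor.heavy_coords()
    lig_xyz = ligand.heavy_coords()
    tree = cKDTree(rec_xyz)

    poses: list[Pose] = []
    for pose_id in range(n_poses):
        for _ in range(max_attempts_per_pose):
            R = _random_rotation(rng)
            anchor_rec = rec_xyz[rng.integers(len(rec_xyz))]
            anchor_lig = lig_xyz[rng.integers(len(lig_xyz))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            gap = rng.uniform(clash_distance + 0.5, 6.0)
            t = anchor_rec + direction * gap - R @ anchor_lig
            placed = lig_xyz @ R.T + t
            dmin, _ = tree.query(placed, k=1)
            if float(np.min(dmin)) >= clash_distance:
                poses.append(
                    Pose(
                        receptor=receptor,
                        ligand=ligand,
                        pose_id=pose_id,
                        rotation=tuple(tuple(float(v) for v in row) for row in R),
                        translation=tuple(float(v) for v in t),
                    )
                )
                break
        else:
            raise RuntimeError(
                f"could not place pose {pose_id} without clashes after "
                f"{max_attempts_per_pose} attempts"
            )
    return poses
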