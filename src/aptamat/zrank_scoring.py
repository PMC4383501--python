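"""Energetic rescoring of docking poses.

A geometric docking search ranks candidate placements by shape
complementarity, which is a weak discriminator for long, structurally complex
RNA ligands. This module reranks poses with a seven-term pairwise energy in
the style of the ZRANK rescoring function: van der Waals attraction and
repulsion, Coulomb electrostatics split by distance range (short vs long) and
by sign (attractive vs repulsive), and a pairwise atom-type desolvation
contact potential. The total is a weighted sum; more negative is better.

Only intermolecular (receptor heavy atom x ligand heavy atom) pairs are
summed — never intramolecular ones — so the score of two infinitely separated
partners is exactly zero.

Functional forms
----------------
van der Waals uses a 6-12 potential with ``rmin = r_i + r_j`` and
``eps = sqrt(eps_i * eps_j)``; for ``r >= rmin`` the full (negative) value is
attractive, while for ``r < rmin`` the attraction is floored at ``-eps`` and
the excess is booked as repulsion, so shrinking a clash distance can only
increase the repulsive term. Electrostatics is Coulomb's law
``332.0716 q_i q_j / r`` (kcal/mol with charges in e and r in angstrom),
binned short/long at a configurable boundary. Desolvation sums a small
symmetric atom-class contact matrix over pairs within its own cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structmodel import Pose, Structure

#: Coulomb conversion constant, kcal*angstrom/(mol*e^2).
COULOMB_CONSTANT = 332.0716

#: Term order used everywhere a 7-vector appears.
TERM_NAMES = (
    "vdw_attractive",
    "vdw_repulsive",
    "elec_short_attractive",
    "elec_short_repulsive",
    "elec_long_attractive",
    "elec_long_repulsive",
    "desolvation",
)

#: Default term weights, following the weighting published for the original
#: ZRANK rescoring function (van der Waals attraction fixed at 1).
DEFAULT_WEIGHTS = (1.0, 0.009, 0.31, 0.34, 0.44, 0.50, 1.02)


class ParameterizationError(ValueError):
    """One or more atoms could not be assigned energy parameters."""

    def __init__(self, unresolved: Sequence[tuple[str, str, str]]):
        self.unresolved = tuple(unresolved)
        preview = ", ".join(f"{r}/{a} ({e})" for r, a, e in self.unresolved[:5])
        more = "" if len(self.unresolved) <= 5 else f" (+{len(self.unresolved) - 5} more)"
        super().__init__(f"unparameterizable atoms: {preview}{more}")


@dataclass(frozen=True)
class AtomParams:
    """Nonbonded parameters of one atom."""

    charge: float       # partial charge, e
    radius: float       # van der Waals radius, angstrom
    well_depth: float   # 6-12 well depth, kcal/mol
    desolv_type: str    # class key into the desolvation contact matrix


class ParameterSet:
    """Lookup tables mapping atoms to :class:`AtomParams`.

    Resolution order: exact (residue, atom name) entry, then wildcard
    ("*", atom name) entry, then — if fallback is allowed — an element
    default. Tables are loaded from the package's versioned CSV data files.
    """

    def __init__(
        self,
        protein: Mapping[tuple[str, str], AtomParams],
        rna: Mapping[tuple[str, str], AtomParams],
        element_defaults: Mapping[str, AtomParams],
        ace: pd.DataFrame,
    ):
        self._tables = {"protein": dict(protein), "rna": dict(rna)}
        self._element_defaults = dict(element_defaults)
        self._ace = ace
        self._ace_index = {t: i for i, t in enumerate(ace.index)}

    @classmethod
    def default(cls) -> "ParameterSet":
        def load(name: str) -> pd.DataFrame:
            with resources.files("aptamat.data").joinpath(name).open() as fh:
                return pd.read_csv(fh)

        def table(df: pd.DataFrame) -> dict[tuple[str, str], AtomParams]:
            return {
                (row.res_name, row.atom_name): AtomParams(
                    row.charge, row.radius, row.well_depth, row.desolv_type
                )
                for row in df.itertuples()
            }

        elements = {
            row.element: AtomParams(
                row.charge, row.radius, row.well_depth, row.desolv_type
            )
            for row in load("element_defaults.csv").itertuples()
        }
        with resources.files("aptamat.data").joinpath(
            "desolvation_ace.csv"
        ).open() as fh:
            ace = pd.read_csv(fh, index_col="type")
        return cls(
            protein=table(load("protein_atoms.csv")),
            rna=table(load("rna_atoms.csv")),
            element_defaults=elements,
            ace=ace,
        )

    @property
    def ace_matrix(self) -> np.ndarray:
        return self._ace.to_numpy(dtype=float)

    def ace_type_index(self, desolv_type: str) -> int:
        try:
            return self._ace_index[desolv_type]
        except KeyError:
            return self._ace_index["NONE"]

    def lookup(
        self,
        molecule_kind: str,
        res_name: str,
        atom_name: str,
        element: str,
        allow_element_fallback: bool = True,
    ) -> tuple[AtomParams, bool]:
        """Resolve one atom's parameters; returns (params, used_fallback)."""
        table = self._tables[molecule_kind]
        hit = table.get((res_name, atom_name)) or table.get(("*", atom_name))
        if hit is not None:
            return hit, False
        if allow_element_fallback:
            default = self._element_defaults.get(element.upper())
            if default is not None:
                return default, True
        raise KeyError((res_name, atom_name, element))


@dataclass(frozen=True, eq=False)
class ParameterizedStructure:
    """A structure's heavy atoms with per-atom nonbonded parameter arrays."""

    structure: Structure
    charges: np.ndarray
    radii: np.ndarray
    well_depths: np.ndarray
    ace_types: np.ndarray        # int indices into the ACE matrix
    ace_matrix: np.ndarray       # the contact matrix those indices refer to
    fallback_atoms: tuple[tuple[str, str, str], ...]  # (res, atom, element)

    def __len__(self) -> int:
        return len(self.charges)


def assign_params(
    structure: Structure,
    parameter_set: ParameterSet | None = None,
    allow_element_fallback: bool = True,
) -> ParameterizedStructure:
    """Assign nonbonded parameters to every heavy atom of ``structure``.

    Atoms missing from the per-residue tables fall back to element defaults
    (recorded in ``fallback_atoms``); with fallback disabled, any unresolved
    atom raises :class:`ParameterizationError` listing the offenders.
    """
    pset = parameter_set or ParameterSet.default()
    heavy = structure.heavy_atoms()
    charges = np.empty(len(heavy))
    radii = np.empty(len(heavy))
    depths = np.empty(len(heavy))
    types = np.empty(len(heavy), dtype=int)
    fallbacks: list[tuple[str, str, str]] = []
    unresolved: list[tuple[str, str, str]] = []
    for i, atom in enumerate(heavy):
        try:
            params, used_fallback = pset.lookup(
                structure.molecule_kind,
                atom.res_name,
                atom.name,
                atom.element,
                allow_element_fallback=allow_element_fallback,
            )
        except KeyError:
            unresolved.append((atom.res_name, atom.name, atom.element))
            continue
        charges[i] = params.charge
        radii[i] = params.radius
        depths[i] = params.well_depth
        types[i] = pset.ace_type_index(params.desolv_type)
        if used_fallback:
            fallbacks.append((atom.res_name, atom.name, atom.element))
    if unresolved:
        raise ParameterizationError(unresolved)
    return ParameterizedStructure(
        structure=structure,
        charges=charges,
        radii=radii,
        well_depths=depths,
        ace_types=types,
        ace_matrix=pset.ace_matrix,
        fallback_atoms=tuple(fallbacks),
    )


@dataclass(frozen=True)
class ScoringConfig:
    """Cutoffs and weights for the seven-term rescoring energy."""

    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    nonbonded_cutoff: float = 12.0   # angstrom; pairs beyond contribute nothing
    short_range_boundary: float = 5.0  # angstrom; elec short/long split
    desolvation_cutoff: float = 6.0  # angstrom; ACE contact range

    def __post_init__(self) -> None:
        if len(self.weights) != len(TERM_NAMES):
            raise ValueError(f"weights must have length {len(TERM_NAMES)}")
        if not 0 < self.short_range_boundary <= self.nonbonded_cutoff:
            raise ValueError("need 0 < short_range_boundary <= nonbonded_cutoff")


@dataclass(frozen=True)
class EnergyTerms:
    """The seven-term energetic decomposition of one pose."""

    vdw_attractive: float = 0.0
    vdw_repulsive: float = 0.0
    elec_short_attractive: float = 0.0
    elec_short_repulsive: float = 0.0
    elec_long_attractive: float = 0.0
    elec_long_repulsive: float = 0.0
    desolvation: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TERM_NAMES], dtype=float)


@dataclass(frozen=True)
class ZrankScore:
    """A pose's energy terms, the weights applied, and the weighted total."""

    pose_id: int
    terms: EnergyTerms
    weights: tuple[float, ...]
    total: float


def _pairwise_terms(
    dist: np.ndarray,
    qq: np.ndarray,
    rmin: np.ndarray,
    eps: np.ndarray,
    ace: np.ndarray,
    config: ScoringConfig,
) -> EnergyTerms:
    """Accumulate the seven terms over pre-gathered pair arrays."""
    within = dist <= config.nonbonded_cutoff
    dist, qq, rmin, eps, ace = (
        a[within] for a in (dist, qq, rmin, eps, ace)
    )
    if dist.size == 0:
        return EnergyTerms()

    # 6-12 van der Waals split at the minimum
    ratio6 = (rmin / dist) ** 6
    lj = eps * (ratio6 * ratio6 - 2.0 * ratio6)
    clashing = dist < rmin
    vdw_att = float(np.where(clashing, -eps, lj).sum())
    vdw_rep = float(np.where(clashing, lj + eps, 0.0).sum())

    # Coulomb, split by range and sign
    coul = COULOMB_CONSTANT * qq / dist
    short = dist <= config.short_range_boundary
    es_att = float(coul[short & (coul < 0)].sum())
    es_rep = float(coul[short & (coul > 0)].sum())
    el_att = float(coul[~short & (coul < 0)].sum())
    el_rep = float(coul[~short & (coul > 0)].sum())

    desolv = float(ace[dist <= config.desolvation_cutoff].sum())

    return EnergyTerms(
        vdw_attractive=vdw_att,
        vdw_repulsive=vdw_rep,
        elec_short_attractive=es_att,
        elec_short_repulsive=es_rep,
        elec_long_attractive=el_att,
        elec_long_repulsive=el_rep,
        desolvation=desolv,
    )


def energy_terms(
    pose: Pose,
    receptor_params: ParameterizedStructure,
    ligand_params: ParameterizedStructure,
    config: ScoringConfig | None = None,
) -> EnergyTerms:
    """Seven-term intermolecular energy of one pose.

    Sums run over receptor-ligand heavy-atom pairs within the nonbonded
    cutoff, gathered with a k-d tree; the ligand coordinates are taken after
    applying the pose's rigid transform.
    """
    config = config or ScoringConfig()
    if receptor_params.structure is not pose.receptor:
        if receptor_params.structure != pose.receptor:
            raise ValueError("receptor parameters do not match the pose receptor")
    if ligand_params.structure is not pose.ligand:
        if ligand_params.structure != pose.ligand:
            raise ValueError("ligand parameters do not match the pose ligand")
    rec_xyz = pose.receptor.heavy_coords()
    lig_xyz = pose.ligand_heavy_coords()
    if len(rec_xyz) != len(receptor_params) or len(lig_xyz) != len(ligand_params):
        raise ValueError("parameter arrays do not cover all heavy atoms")

    tree = cKDTree(rec_xyz)
    neighbor_lists = tree.query_ball_point(lig_xyz, r=config.nonbonded_cutoff)
    pair_i: list[int] = []
    pair_j: list[int] = []
    for j, neigh in enumerate(neighbor_lists):
        pair_i.extend(neigh)
        pair_j.extend([j] * len(neigh))
    if not pair_i:
        return EnergyTerms()
    ii = np.asarray(pair_i)
    jj = np.asarray(pair_j)
    dist = np.linalg.norm(rec_xyz[ii] - lig_xyz[jj], axis=1)
    qq = receptor_params.charges[ii] * ligand_params.charges[jj]
    rmin = receptor_params.radii[ii] + ligand_params.radii[jj]
    eps = np.sqrt(receptor_params.well_depths[ii] * ligand_params.well_depths[jj])
    ace = receptor_params.ace_matrix[
        receptor_params.ace_types[ii], ligand_params.ace_types[jj]
    ]
    return _pairwise_terms(dist, qq, rmin, eps, ace, config)


def zrank_score(
    terms: EnergyTerms,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    pose_id: int = 0,
) -> ZrankScore:
    """Weighted scalar score of a term decomposition (more negative = better)."""
    w = tuple(float(x) for x in weights)
    if len(w) != len(TERM_NAMES):
        raise ValueError(f"weights must have length {len(TERM_NAMES)}")
    total = float(np.dot(np.asarray(w), terms.as_vector()))
    return ZrankScore(pose_id=pose_id, terms=terms, weights=w, total=total)


def rerank_poses(
    poses: Sequence[Pose],
    parameter_set: ParameterSet | None = None,
    config: ScoringConfig | None = None,
) -> list[ZrankScore]:
    """Score and sort poses best (most negative) first.

    All poses must share one receptor and one ligand structure (the usual
    docking-output layout); parameters are assigned once. Ties in total are
    broken by pose_id, keeping the original order among equals.
    """
    if not poses:
        raise ValueError("need at least one pose")
    config = config or ScoringConfig()
    pset = parameter_set or ParameterSet.default()
    rec_params = assign_params(poses[0].receptor, pset)
    lig_params = assign_params(poses[0].ligand, pset)
    scores = []
    for pose in poses:
        terms = energy_terms(pose, rec_params, lig_params, config)
        scores.append(zrank_score(terms, config.weights, pose_id=pose.pose_id))
    return sorted(scores, key=lambda s: (s.total, s.pose_id))


def scores_to_frame(scores: Sequence[ZrankScore]) -> pd.DataFrame:
    """Per-pose score table: pose_id, the seven terms, and the total."""
    rows = {"pose_id": [s.pose_id for s in scores]}
    for name in TERM_NAMES:
        rows[name] = [getattr(s.terms, name) for s in scores]
    rows["total"] = [s.total for s in scores]
    return pd.DataFrame(rows)
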