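"""Seeded generators for every input the pipeline consumes.

Three families of synthetic inputs, each emitted together with its ground
truth so recovery tests never have to re-derive it:

* toy protein-RNA complexes with an exactly planted contact interface
  (coarse one-atom-per-residue geometry, so brute-force oracles stay fast);
* SPR sensorgrams simulated from the 1:1 Langmuir model with additive
  Gaussian noise and recorded true (k_a, k_d, R_max);
* random RNA aptamer libraries over {A, C, G, U}.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqlib import AptamerSequence
from .spr_kinetics import (
    PHASE_ASSOCIATION,
    PHASE_DISSOCIATION,
    Sensorgram,
    model_association,
    model_dissociation,
)
from .structmodel import (
    Atom,
    Contact,
    DEFAULT_CONTACT_CUTOFF,
    InterfaceReport,
    Pose,
    Structure,
)


class GenerationError(ValueError):
    """A synthetic spec cannot be realized (e.g. contradictory contacts)."""


@dataclass(frozen=True)
class ComplexSpec:
    """Blueprint for a toy complex with planted interface contacts.

    ``planted_contacts`` lists (receptor residue number, ligand nucleotide
    number) pairs that must fall within ``cutoff``; every other pair ends up
    farther than ``cutoff + margin``. ``receptor_residues`` optionally fixes
    residue numbers and 3-letter names (e.g. epitope residues); by default
    residues are ALA numbered 1..n.
    """

    n_receptor_residues: int = 20
    n_ligand_nt: int = 10
    planted_contacts: tuple[tuple[int, int], ...] = ()
    contact_distance: float = 4.0
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    margin: float = 2.0
    clash_min: float = 2.5
    receptor_residues: tuple[tuple[int, str], ...] | None = None
    ligand_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.n_receptor_residues < 1 or self.n_ligand_nt < 1:
            raise ValueError("counts must be >= 1")
        if not self.clash_min <= self.contact_distance <= self.cutoff:
            raise GenerationError(
                "need clash_min <= contact_distance <= cutoff"
            )


@dataclass(frozen=True)
class SensorgramSpec:
    """Blueprint for a simulated 1:1 Langmuir sensorgram.

    Defaults mirror the bench protocol: 0.5 uM analyte, 9 min association,
    6 min rinse, 1 Hz sampling, noise SD 1% of the association plateau.
    """

    ka: float = 6.03e3
    kd: float = 0.61e-3
    conc: float = 0.5e-6
    rmax: float = 100.0
    noise_sd: float | None = None  # None -> 1% of plateau
    t_association: float = 540.0
    t_dissociation: float = 360.0
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        if min(self.ka, self.kd, self.conc, self.rmax, self.rate_hz) <= 0:
            raise ValueError("ka, kd, conc, rmax and rate_hz must be positive")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LibrarySpec:
    """Blueprint for a random RNA library."""

    n_sequences: int = 10
    length: int = 40
    alphabet: str = "ACGU"

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class SynthSpec:
    """Bundle of all three generator blueprints plus the master seed."""

    seed: int = 0
    complex: ComplexSpec = field(default_factory=ComplexSpec)
    sensorgram: SensorgramSpec = field(default_factory=SensorgramSpec)
    library: LibrarySpec = field(default_factory=LibrarySpec)


def _grid_positions(n: int, spacing: float, origin: np.ndarray) -> np.ndarray:
    """n points on a cubic grid with the given spacing, row-major."""
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for idx in range(n):
        i, rem = divmod(idx, side * side)
        j, k = divmod(rem, side)
        pts.append(origin + spacing * np.array([i, j, k], dtype=float))
    return np.asarray(pts)


def make_toy_complex(
    spec: ComplexSpec, seed: int = 0
) -> tuple[Structure, Structure, Pose, InterfaceReport]:
    """Build a coarse receptor/ligand pair realizing exactly the planted contacts.

    The receptor is a one-CA-per-residue protein on a grid spaced so that a
    nucleotide planted near one residue cannot accidentally contact another;
    non-contacting nucleotides are parked far from the receptor. Returns the
    receptor, the ligand, an identity-transform pose, and the planted
    interface report computed from the realized geometry.
    """
    rng = np.random.default_rng(seed)
    if spec.receptor_residues is not None:
        residues = list(spec.receptor_residues)
    else:
        residues = [(i + 1, "ALA") for i in range(spec.n_receptor_residues)]
    res_numbers = [num for num, _ in residues]
    if len(set(res_numbers)) != len(res_numbers):
        raise GenerationError("duplicate receptor residue numbers")

    for res_num, nt_num in spec.planted_contacts:
        if res_num not in res_numbers:
            raise GenerationError(f"planted contact names unknown residue {res_num}")
        if not 1 <= nt_num <= spec.n_ligand_nt:
            raise GenerationError(f"planted contact names unknown nucleotide {nt_num}")

    # Grid spacing guarantees separation between distinct planted sites.
    spacing = 2.0 * spec.cutoff + spec.margin + spec.contact_distance
    rec_xyz = _grid_positions(len(residues), spacing, np.zeros(3))
    rec_atoms = tuple(
        Atom(chain="A", res_seq=num, res_name=name, name="CA", element="C",
             pos=tuple(rec_xyz[i]))
        for i, (num, name) in enumerate(residues)
    )
    receptor = Structure(atoms=rec_atoms, molecule_kind="protein")
    rec_by_num = {num: rec_xyz[i] for i, (num, _) in enumerate(residues)}

    if spec.ligand_sequence is not None:
        if len(spec.ligand_sequence) != spec.n_ligand_nt:
            raise GenerationError("ligand_sequence length must equal n_ligand_nt")
        nt_names = list(spec.ligand_sequence)
    else:
        nt_names = [str(rng.choice(list("ACGU"))) for _ in range(spec.n_ligand_nt)]

    # Park every nucleotide far away, then pull planted ones onto their sites.
    far_origin = rec_xyz.max(axis=0) + 10.0 * (spec.cutoff + spec.margin)
    lig_xyz = _grid_positions(spec.n_ligand_nt, spacing, far_origin)

    by_nt: dict[int, list[int]] = {}
    for res_num, nt_num in spec.planted_contacts:
        by_nt.setdefault(nt_num, []).append(res_num)
    for nt_num, partners in by_nt.items():
        sites = np.asarray([rec_by_num[r] for r in partners])
        if len(partners) == 1:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = sites[0] + direction * spec.contact_distance
        else:
            pos = sites.mean(axis=0)
            dists = np.linalg.norm(sites - pos, axis=1)
            if np.any(dists > spec.cutoff) or np.any(dists < spec.clash_min):
                raise GenerationError(
                    f"nucleotide {nt_num} cannot simultaneously contact "
                    f"residues {partners} within the cutoff without clashing"
                )
        lig_xyz[nt_num - 1] = pos

    # "BB" is the coarse one-bead-per-nucleotide type carrying the net
    # nucleotide charge (see the RNA parameter table).
    lig_atoms = tuple(
        Atom(chain="B", res_seq=i + 1, res_name=nt_names[i], name="BB",
             element="P", pos=tuple(lig_xyz[i]))
        for i in range(spec.n_ligand_nt)
    )
    ligand = Structure(atoms=lig_atoms, molecule_kind="rna")
    pose = Pose(receptor=receptor, ligand=ligand, pose_id=0)

    # Verify the realized geometry plants exactly the requested interface.
    planted = set(spec.planted_contacts)
    diff = rec_xyz[:, None, :] - lig_xyz[None, :, :]
    dmat = np.linalg.norm(diff, axis=2)
    contacts = []
    for i, (num, name) in enumerate(residues):
        for j in range(spec.n_ligand_nt):
            d = float(dmat[i, j])
            if (num, j + 1) in planted:
                if d > spec.cutoff or d < spec.clash_min:
                    raise GenerationError(
                        f"planted contact ({num}, {j + 1}) realized at {d:.2f} A"
                    )
                contacts.append(
                    Contact(
                        receptor_residue=("A", num, name),
                        ligand_nucleotide=("B", j + 1, nt_names[j]),
                        min_distance=d,
                    )
                )
            elif d <= spec.cutoff + spec.margin:
                raise GenerationError(
                    f"unplanted pair ({num}, {j + 1}) landed at {d:.2f} A"
                )
    center = None
    if contacts:
        involved_rec = {c.receptor_residue[1] for c in contacts}
        involved_nt = {c.ligand_nucleotide[1] for c in contacts}
        pts = np.vstack(
            [rec_by_num[n] for n in sorted(involved_rec)]
            + [lig_xyz[n - 1] for n in sorted(involved_nt)]
        )
        center = tuple(float(v) for v in pts.mean(axis=0))
    report = InterfaceReport(
        contacts=tuple(sorted(contacts, key=lambda c: (c.receptor_residue, c.ligand_nucleotide))),
        cutoff=spec.cutoff,
        center=center,
    )
    return receptor, ligand, pose, report


def make_sensorgram(
    spec: SensorgramSpec, seed: int = 0
) -> tuple[Sensorgram, dict[str, float]]:
    """Simulate a sensorgram and return it with its ground truth.

    The association phase follows the Langmuir association equation from
    t = 0; the dissociation phase decays exponentially from the noiseless
    association endpoint. Gaussian noise of the requested SD is added to both
    phases.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / spec.rate_hz
    t_assoc = np.arange(0.0, spec.t_association + dt / 2, dt)
    t0 = float(t_assoc[-1])
    t_diss = np.arange(t0 + dt, t0 + spec.t_dissociation + dt / 2, dt)

    r_assoc = model_association(spec.ka, spec.kd, spec.conc, spec.rmax, t_assoc)
    r0 = float(r_assoc[-1])
    r_diss = model_dissociation(r0, spec.kd, t_diss, t0=t0)

    plateau = spec.ka * spec.conc * spec.rmax / (spec.ka * spec.conc + spec.kd)
    noise_sd = spec.noise_sd if spec.noise_sd is not None else 0.01 * plateau
    time = np.concatenate([t_assoc, t_diss])
    response = np.concatenate([r_assoc, r_diss])
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=len(response))
    phase = np.concatenate(
        [
            np.full(len(t_assoc), PHASE_ASSOCIATION),
            np.full(len(t_diss), PHASE_DISSOCIATION),
        ]
    )
    sg = Sensorgram(time=time, response=response, phase=phase, conc=spec.conc, t0=t0)
    truth = {
        "ka": spec.ka,
        "kd": spec.kd,
        "Rmax": spec.rmax,
        "R0": r0,
        "conc": spec.conc,
        "noise_sd": float(noise_sd),
        "plateau": float(plateau),
    }
    return sg, truth


def make_random_library(spec: LibrarySpec, seed: int = 0) -> list[AptamerSequence]:
    """Seeded uniform random RNA sequences, named rand001, rand002, ..."""
    rng = np.random.default_rng(seed)
    letters = list(spec.alphabet)
    out = []
    for i in range(spec.n_sequences):
        bases = "".join(rng.choice(letters, size=spec.length))
        out.append(AptamerSequence(name=f"rand{i + 1:03d}", bases=bases))
    return out


def make_toy_rna_structure(seq: AptamerSequence, seed: int = 0) -> Structure:
    """Coarse random-walk 3D stand-in for an RNA tertiary model.

    One backbone bead per nucleotide (phosphate-sized, carrying the net
    nucleotide charge) on a seeded random walk with a 6 angstrom step. This is
    the shipped toy backend for the external 2D-prediction + 3D-modelling
    stages of the pipeline.
    """
    rng = np.random.default_rng(seed)
    step = 6.0
    pos = np.zeros(3)
    atoms = []
    for i, base in enumerate(seq.bases, start=1):
        if i > 1:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + step * direction
        atoms.append(
            Atom(chain="B", res_seq=i, res_name=base, name="BB", element="P",
                 pos=tuple(pos))
        )
    return Structure(atoms=tuple(atoms), molecule_kind="rna")


def make_toy_receptor(
    n_residues: int = 24, seed: int = 0, epitope_numbers: Sequence[int] = ()
) -> Structure:
    """Compact globular toy receptor; optional residues renumbered to an epitope.

    Residues are CA pseudo-atoms packed on a 6 angstrom grid. If
    ``epitope_numbers`` is given, the first ``len(epitope_numbers)`` residues
    take those numbers (useful for epitope-overlap exercises); names stay ALA
    except K/F/Y epitope conventions are not imposed here.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    xyz = _grid_positions(n_residues, 6.0, np.zeros(3))
    rng = np.random.default_rng(seed)
    xyz = xyz + rng.normal(0.0, 0.3, size=xyz.shape)  # break grid degeneracy
    numbers = list(range(1, n_residues + 1))
    for i, num in enumerate(epitope_numbers):
        if i < n_residues:
            numbers[i] = int(num)
    atoms = tuple(
        Atom(chain="A", res_seq=numbers[i], res_name="ALA", name="CA",
             element="C", pos=tuple(xyz[i]))
        for i in range(n_residues)
    )
    return Structure(atoms=atoms, molecule_kind="protein")
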