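import math

import numpy as np
import pytest

from aptamat.panels import panel_sequence
from aptamat.structmodel import Pose
from aptamat.zrank_scoring import (
    COULOMB_CONSTANT,
    EnergyTerms,
    ParameterSet,
    ParameterizedStructure,
    ScoringConfig,
)


@pytest.fixture(scope="session")
def param_set() -> ParameterSet:
    return ParameterSet.default()


@pytest.fixture(scope="session")
def seq1():
    return panel_sequence("Seq1")


@pytest.fixture(scope="session")
def seq2():
    return panel_sequence("Seq2")


@pytest.fixture(scope="session")
def seq15():
    return panel_sequence("Seq15")


def brute_force_interface(pose: Pose, cutoff: float):
    """All-pairs reference for interface detection.

    Returns {(receptor residue id, ligand nucleotide id): min distance} using
    plain double loops over heavy atoms.
    """
    rec_atoms = pose.receptor.heavy_atoms()
    lig_atoms = pose.ligand.heavy_atoms()
    rec_xyz = pose.receptor.heavy_coords()
    lig_xyz = pose.ligand_heavy_coords()
    best: dict[tuple, float] = {}
    for i, ra in enumerate(rec_atoms):
        for j, la in enumerate(lig_atoms):
            d = math.dist(rec_xyz[i], lig_xyz[j])
            if d <= cutoff:
                key = (
                    (ra.chain, ra.res_seq, ra.res_name),
                    (la.chain, la.res_seq, la.res_name),
                )
                if d < best.get(key, math.inf):
                    best[key] = d
    return best


def brute_force_energy_terms(
    pose: Pose,
    rec_params: ParameterizedStructure,
    lig_params: ParameterizedStructure,
    config: ScoringConfig,
) -> EnergyTerms:
    """All-pairs double-loop reference for the seven energy terms."""
    rec_xyz = pose.receptor.heavy_coords()
    lig_xyz = pose.ligand_heavy_coords()
    vdw_att = vdw_rep = 0.0
    es_att = es_rep = el_att = el_rep = desolv = 0.0
    for i in range(len(rec_xyz)):
        for j in range(len(lig_xyz)):
            d = math.dist(rec_xyz[i], lig_xyz[j])
            if d > config.nonbonded_cutoff:
                continue
            rmin = rec_params.radii[i] + lig_params.radii[j]
            eps = math.sqrt(
                rec_params.well_depths[i] * lig_params.well_depths[j]
            )
            ratio6 = (rmin / d) ** 6
            lj = eps * (ratio6 * ratio6 - 2.0 * ratio6)
            if d < rmin:
                vdw_att += -eps
                vdw_rep += lj + eps
            else:
                vdw_att += lj
            coul = (
                COULOMB_CONSTANT
                * rec_params.charges[i]
                * lig_params.charges[j]
                / d
            )
            if d <= config.short_range_boundary:
                if coul < 0:
                    es_att += coul
                elif coul > 0:
                    es_rep += coul
            else:
                if coul < 0:
                    el_att += coul
                elif coul > 0:
                    el_rep += coul
            if d <= config.desolvation_cutoff:
                desolv += rec_params.ace_matrix[
                    rec_params.ace_types[i], lig_params.ace_types[j]
                ]
    return EnergyTerms(
        vdw_attractive=vdw_att,
        vdw_repulsive=vdw_rep,
        elec_short_attractive=es_att,
        elec_short_repulsive=es_rep,
        elec_long_attractive=el_att,
        elec_long_repulsive=el_rep,
        desolvation=desolv,
    )


def assert_terms_close(a: EnergyTerms, b: EnergyTerms, rtol: float = 1e-9):
    va, vb = a.as_vector(), b.as_vector()
    np.testing.assert_allclose(va, vb, rtol=rtol, atol=1e-12)
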