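"""Seven-term pose rescoring: parameter assignment, terms, reranking."""

import numpy as np
import pandas as pd
import pytest

from aptamat.structmodel import Atom, Pose, Structure, toy_pose_sampler, transform_structure
from aptamat.synth_data import ComplexSpec, make_toy_complex, make_toy_rna_structure
from aptamat.seqlib import AptamerSequence
from aptamat.zrank_scoring import (
    COULOMB_CONSTANT,
    DEFAULT_WEIGHTS,
    AtomParams,
    EnergyTerms,
    ParameterSet,
    ParameterizationError,
    ScoringConfig,
    assign_params,
    energy_terms,
    rerank_poses,
    scores_to_frame,
    zrank_score,
)

from conftest import assert_terms_close, brute_force_energy_terms


def _custom_pset(protein, rna):
    """Two-sided parameter set with a trivial desolvation matrix."""
    ace = pd.DataFrame(
        [[0.5, 0.0], [0.0, 0.0]],
        index=["X", "NONE"],
        columns=["X", "NONE"],
    )
    elements = {
        "C": AtomParams(0.0, 1.9, 0.07, "NONE"),
        "P": AtomParams(0.0, 2.1, 0.20, "NONE"),
    }
    return ParameterSet(protein=protein, rna=rna, element_defaults=elements, ace=ace)


def _pair_pose(distance: float) -> Pose:
    receptor = Structure(
        atoms=(Atom("A", 1, "ALA", "QP", "C", (0.0, 0.0, 0.0)),),
        molecule_kind="protein",
    )
    ligand = Structure(
        atoms=(Atom("B", 1, "U", "QM", "P", (distance, 0.0, 0.0)),),
        molecule_kind="rna",
    )
    return Pose(receptor=receptor, ligand=ligand)


class TestAssignParams:
    def test_explicit_params_used(self):
        pset = _custom_pset(
            protein={("ALA", "QP"): AtomParams(1.0, 1.5, 0.1, "X")},
            rna={("U", "QM"): AtomParams(-1.0, 1.5, 0.1, "X")},
        )
        pose = _pair_pose(3.0)
        rp = assign_params(pose.receptor, pset)
        lp = assign_params(pose.ligand, pset)
        assert rp.charges[0] == 1.0 and lp.charges[0] == -1.0
        assert rp.fallback_atoms == ()

    def test_element_fallback_reported(self):
        pset = _custom_pset(protein={}, rna={})
        pose = _pair_pose(3.0)
        rp = assign_params(pose.receptor, pset)
        assert rp.radii[0] == 1.9  # carbon default
        assert rp.fallback_atoms == (("ALA", "QP", "C"),)

    def test_fallback_disabled_errors(self):
        pset = _custom_pset(protein={}, rna={})
        pose = _pair_pose(3.0)
        with pytest.raises(ParameterizationError) as err:
            assign_params(pose.receptor, pset, allow_element_fallback=False)
        assert ("ALA", "QP", "C") in err.value.unresolved

    def test_default_tables_cover_coarse_beads(self, param_set):
        rna = make_toy_rna_structure(AptamerSequence("x", "ACGU" * 10), seed=0)
        lp = assign_params(rna, param_set)
        assert len(lp) == 40
        assert np.all(lp.charges == -1.0)  # net nucleotide charge


class TestEnergyTerms:
    def test_separated_pose_all_zero(self):
        pset = _custom_pset(
            protein={("ALA", "QP"): AtomParams(1.0, 1.5, 0.1, "X")},
            rna={("U", "QM"): AtomParams(-1.0, 1.5, 0.1, "X")},
        )
        pose = _pair_pose(50.0)
        terms = energy_terms(
            pose,
            assign_params(pose.receptor, pset),
            assign_params(pose.ligand, pset),
        )
        assert terms == EnergyTerms()

    def test_unit_charges_give_hand_computed_coulomb(self):
        # +1e / -1e at 3 angstrom, zero well depth, inert desolvation class:
        # the only nonzero term is short-range attraction, 332.0716*(-1)/3.
        pset = _custom_pset(
            protein={("ALA", "QP"): AtomParams(+1.0, 1.0, 0.0, "NONE")},
            rna={("U", "QM"): AtomParams(-1.0, 1.0, 0.0, "NONE")},
        )
        pose = _pair_pose(3.0)
        terms = energy_terms(
            pose,
            assign_params(pose.receptor, pset),
            assign_params(pose.ligand, pset),
        )
        assert terms.elec_short_attractive == pytest.approx(
            COULOMB_CONSTANT * (-1.0) / 3.0, rel=1e-12
        )
        for name in (
            "elec_short_repulsive", "elec_long_attractive",
            "elec_long_repulsive", "vdw_attractive", "vdw_repulsive",
            "desolvation",
        ):
            assert getattr(terms, name) == 0.0

    def test_long_range_bucket(self):
        pset = _custom_pset(
            protein={("ALA", "QP"): AtomParams(+1.0, 1.0, 0.0, "NONE")},
            rna={("U", "QM"): AtomParams(+1.0, 1.0, 0.0, "NONE")},
        )
        pose = _pair_pose(8.0)  # between the 5 A boundary and 12 A cutoff
        terms = energy_terms(
            pose,
            assign_params(pose.receptor, pset),
            assign_params(pose.ligand, pset),
        )
        assert terms.elec_long_repulsive == pytest.approx(
            COULOMB_CONSTANT / 8.0, rel=1e-12
        )
        assert terms.elec_short_repulsive == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed, param_set):
        spec = ComplexSpec(
            n_receptor_residues=20,
            n_ligand_nt=12,
            planted_contacts=((2, 1), (9, 6)),
        )
        receptor, ligand, _, _ = make_toy_complex(spec, seed=seed)
        rp = assign_params(receptor, param_set)
        lp = assign_params(ligand, param_set)
        config = ScoringConfig()
        for pose in toy_pose_sampler(receptor, ligand, 4, seed=seed):
            fast = energy_terms(pose, rp, lp, config)
            slow = brute_force_energy_terms(pose, rp, lp, config)
            assert_terms_close(fast, slow, rtol=1e-9)

    def test_clash_monotonicity(self):
        """Shrinking a clashing distance never decreases vdW repulsion."""
        pset = _custom_pset(
            protein={("ALA", "QP"): AtomParams(0.0, 1.5, 0.2, "NONE")},
            rna={("U", "QM"): AtomParams(0.0, 1.5, 0.2, "NONE")},
        )
        reps = []
        for d in (2.9, 2.5, 2.0, 1.5, 1.0):  # rmin = 3.0
            pose = _pair_pose(d)
            terms = energy_terms(
                pose,
                assign_params(pose.receptor, pset),
                assign_params(pose.ligand, pset),
            )
            reps.append(terms.vdw_repulsive)
        assert all(b >= a for a, b in zip(reps, reps[1:]))
        assert all(r >= 0 for r in reps)

    def test_sign_conventions_on_random_poses(self, param_set):
        spec = ComplexSpec(n_receptor_residues=15, n_ligand_nt=8)
        receptor, ligand, _, _ = make_toy_complex(spec, seed=4)
        rp = assign_params(receptor, param_set)
        lp = assign_params(ligand, param_set)
        for pose in toy_pose_sampler(receptor, ligand, 6, seed=4):
            terms = energy_terms(pose, rp, lp)
            assert terms.vdw_attractive <= 0
            assert terms.vdw_repulsive >= 0
            assert terms.elec_short_attractive <= 0
            assert terms.elec_short_repulsive >= 0
            assert terms.elec_long_attractive <= 0
            assert terms.elec_long_repulsive >= 0
            assert np.all(np.isfinite(terms.as_vector()))

    def test_rigid_motion_invariance(self, param_set):
        spec = ComplexSpec(
            n_receptor_residues=12, n_ligand_nt=8,
            planted_contacts=((1, 1), (5, 4)),
        )
        receptor, ligand, pose, _ = make_toy_complex(spec, seed=8)
        rp = assign_params(receptor, param_set)
        lp = assign_params(ligand, param_set)
        before = energy_terms(pose, rp, lp)

        rng = np.random.default_rng(21)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        t = np.array([-30.0, 12.0, 99.0])
        rec2 = transform_structure(receptor, R, t)
        lig2 = transform_structure(ligand, R, t)
        after = energy_terms(
            Pose(receptor=rec2, ligand=lig2),
            assign_params(rec2, param_set),
            assign_params(lig2, param_set),
        )
        assert_terms_close(after, before, rtol=1e-9)


class TestZrankScore:
    def test_zero_terms_zero_total(self):
        assert zrank_score(EnergyTerms()).total == 0.0

    def test_one_hot_weight_extracts_term(self):
        terms = EnergyTerms(vdw_attractive=-3.5, desolvation=1.0)
        score = zrank_score(terms, weights=(1, 0, 0, 0, 0, 0, 0))
        assert score.total == -3.5

    def test_linearity_in_weights(self):
        terms = EnergyTerms(
            vdw_attractive=-2.0, vdw_repulsive=1.0,
            elec_short_attractive=-0.5, desolvation=0.25,
        )
        single = zrank_score(terms, DEFAULT_WEIGHTS).total
        double = zrank_score(
            terms, tuple(2 * w for w in DEFAULT_WEIGHTS)
        ).total
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_total_is_exact_dot_product(self):
        terms = EnergyTerms(*(float(i + 1) for i in range(7)))
        score = zrank_score(terms, DEFAULT_WEIGHTS)
        assert score.total == float(
            np.dot(np.array(DEFAULT_WEIGHTS), terms.as_vector())
        )


class TestRerankPoses:
    def test_ascending_order(self, param_set):
        spec = ComplexSpec(n_receptor_residues=10, n_ligand_nt=6)
        receptor, ligand, _, _ = make_toy_complex(spec, seed=2)
        poses = toy_pose_sampler(receptor, ligand, 8, seed=2)
        scores = rerank_poses(poses, param_set)
        totals = [s.total for s in scores]
        assert totals == sorted(totals)

    def test_stable_tie_break_by_pose_id(self):
        ties = [
            zrank_score(EnergyTerms(), pose_id=i) for i in (3, 1, 2)
        ]
        ordered = sorted(ties, key=lambda s: (s.total, s.pose_id))
        assert [s.pose_id for s in ordered] == [1, 2, 3]

    def test_planted_optimum_ranks_first(self, param_set):
        spec = ComplexSpec(
            n_receptor_residues=12, n_ligand_nt=8,
            planted_contacts=((1, 1), (4, 3), (8, 6)),
        )
        receptor, ligand, contact_pose, _ = make_toy_complex(spec, seed=6)
        # Decoys: same partners pushed far along x, out of every cutoff.
        decoys = [
            Pose(receptor=receptor, ligand=ligand, pose_id=i,
                 translation=(500.0 + 30.0 * i, 0.0, 0.0))
            for i in range(1, 6)
        ]
        planted = Pose(receptor=receptor, ligand=ligand, pose_id=0)
        scores = rerank_poses([planted] + decoys, param_set)
        assert scores[0].pose_id == 0
        assert scores[0].total < 0
        assert all(s.total == 0 for s in scores[1:])

    def test_empty_pose_list_rejected(self, param_set):
        with pytest.raises(ValueError):
            rerank_poses([], param_set)

    def test_score_table_columns(self, param_set):
        spec = ComplexSpec(n_receptor_residues=8, n_ligand_nt=5)
        receptor, ligand, _, _ = make_toy_complex(spec, seed=3)
        poses = toy_pose_sampler(receptor, ligand, 3, seed=3)
        frame = scores_to_frame(rerank_poses(poses, param_set))
        assert frame.columns[0] == "pose_id"
        assert frame.columns[-1] == "total"
        assert len(frame) == 3
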