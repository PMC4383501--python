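"""End-to-end in-silico maturation pipeline.

The workflow mirrors the study design: score a panel of seed aptamers against
the receptor, keep the top-k (default 3) by rescoring value, expand each into
its 63-member paired two-point mutant library, score every mutant the same
way, and report the mutants that score strictly better than their parent,
together with the receptor epitope residues found at each best pose's
interface.

The folding / 3D-modelling / docking stages of the original workflow are
external tools; here they are pluggable backends, and the shipped defaults
are the package's own toy backends (seeded random-walk RNA models and a
clash-filtered rigid pose sampler), which make the pipeline runnable and
deterministically testable end to end.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .seqlib import (
    AptamerSequence,
    MutantRecord,
    MutationScheme,
    build_two_point_library,
    library_to_frame,
)
from .structmodel import (
    Epitope,
    Pose,
    Structure,
    epitope_overlap,
    interface_residues,
    toy_pose_sampler,
)
from .synth_data import make_toy_receptor, make_toy_rna_structure
from .zrank_scoring import ParameterSet, ScoringConfig, rerank_poses

ModelBackend = Callable[[AptamerSequence, int], Structure]
DockBackend = Callable[[Structure, Structure, int, int], list[Pose]]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _stable_seed(master_seed: int, name: str) -> int:
    """Deterministic per-candidate RNG seed below 2**31."""
    return (zlib.crc32(name.encode()) ^ (master_seed * 2654435761)) % (2**31)


def rank_seed_sequences(scores: Mapping[str, float], top_k: int) -> list[str]:
    """Names of the ``top_k`` best (most negative) scores, best first.

    Ties are broken alphabetically by name for reproducibility.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k > len(scores):
        raise ValueError(f"top_k={top_k} exceeds {len(scores)} scored entries")
    ordered = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    return [name for name, _ in ordered[:top_k]]


def select_improved_mutants(
    parent_score: float, mutant_scores: Mapping[str, float]
) -> list[tuple[str, float]]:
    """Mutants scoring strictly better (more negative) than the parent, best first."""
    improved = [
        (name, score) for name, score in mutant_scores.items()
        if score < parent_score
    ]
    return sorted(improved, key=lambda kv: (kv[1], kv[0]))


@dataclass(frozen=True)
class CandidateScore:
    """Best-pose summary for one candidate sequence."""

    name: str
    score: float
    pose_id: int
    epitope_residues: tuple[str, ...] = ()


@dataclass(frozen=True)
class SelectionConfig:
    """All knobs of one pipeline run."""

    top_k_seeds: int = 3
    scheme: MutationScheme = field(default_factory=MutationScheme)
    n_poses: int = 8
    seed: int = 0
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    interface_cutoff: float = 5.0
    epitope: Epitope = field(default_factory=Epitope)
    receptor_n_residues: int = 24
    model_backend: ModelBackend = make_toy_rna_structure
    dock_backend: DockBackend = toy_pose_sampler

    def echo(self) -> dict:
        """JSON-serializable record of the run configuration."""
        return {
            "top_k_seeds": self.top_k_seeds,
            "scheme": {
                "window1": list(self.scheme.window1),
                "window2": list(self.scheme.window2),
                "pairing_offset": self.scheme.pairing_offset,
            },
            "n_poses": self.n_poses,
            "seed": self.seed,
            "weights": list(self.scoring.weights),
            "nonbonded_cutoff": self.scoring.nonbonded_cutoff,
            "short_range_boundary": self.scoring.short_range_boundary,
            "desolvation_cutoff": self.scoring.desolvation_cutoff,
            "interface_cutoff": self.interface_cutoff,
            "epitope": list(self.epitope.residues),
            "receptor_n_residues": self.receptor_n_residues,
            "model_backend": getattr(self.model_backend, "__name__", "custom"),
            "dock_backend": getattr(self.dock_backend, "__name__", "custom"),
        }


@dataclass
class SelectionReport:
    """Everything a run produced, serializable as JSON + CSV."""

    config: dict
    seed_scores: dict[str, float]
    top_seeds: list[str]
    library_sizes: dict[str, int]
    mutant_scores: dict[str, float]
    selected: list[dict]
    epitope_overlaps: dict[str, list[str]]
    provenance: dict[str, dict]

    @property
    def total_library_size(self) -> int:
        return sum(self.library_sizes.values())

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "seed_scores": self.seed_scores,
            "top_seeds": self.top_seeds,
            "library_sizes": self.library_sizes,
            "total_library_size": self.total_library_size,
            "mutant_scores": self.mutant_scores,
            "selected": self.selected,
            "epitope_overlaps": self.epitope_overlaps,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        pd.DataFrame(
            sorted(self.seed_scores.items()), columns=["name", "score"]
        ).to_csv(out / "seed_scores.csv", index=False)
        pd.DataFrame(
            sorted(self.mutant_scores.items()), columns=["name", "score"]
        ).to_csv(out / "mutant_scores.csv", index=False)
        pd.DataFrame(self.selected).to_csv(out / "selected.csv", index=False)


def score_candidate(
    seq: AptamerSequence,
    receptor: Structure,
    config: SelectionConfig,
    parameter_set: ParameterSet,
) -> CandidateScore:
    """Model, dock, rescore and interface-analyze one candidate sequence."""
    sub_seed = _stable_seed(config.seed, seq.name)
    ligand = config.model_backend(seq, sub_seed)
    poses = config.dock_backend(receptor, ligand, config.n_poses, sub_seed)
    scores = rerank_poses(poses, parameter_set, config.scoring)
    best = scores[0]
    best_pose = next(p for p in poses if p.pose_id == best.pose_id)
    report = interface_residues(best_pose, cutoff=config.interface_cutoff)
    overlap = epitope_overlap(report, config.epitope)
    return CandidateScore(
        name=seq.name,
        score=best.total,
        pose_id=best.pose_id,
        epitope_residues=overlap.residues,
    )


def run_pipeline(
    seeds: Sequence[AptamerSequence],
    config: SelectionConfig | None = None,
    receptor: Structure | None = None,
    out_dir: str | Path | None = None,
) -> SelectionReport:
    """Run the full maturation workflow on ``seeds``.

    Deterministic given the config seed: rerunning with identical inputs
    yields a byte-identical report. If ``out_dir`` is given, the report JSON,
    per-stage CSV tables and the mutant libraries are written there.
    """
    config = config or SelectionConfig()
    if receptor is None:
        receptor = make_toy_receptor(
            n_residues=config.receptor_n_residues, seed=config.seed
        )
    pset = ParameterSet.default()

    try:
        seed_candidates = {
            s.name: score_candidate(s, receptor, config, pset) for s in seeds
        }
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage tag
        raise StageError("score_seeds", str(exc)) from exc
    seed_scores = {n: c.score for n, c in seed_candidates.items()}

    try:
        top = rank_seed_sequences(seed_scores, config.top_k_seeds)
    except Exception as exc:
        raise StageError("rank_seeds", str(exc)) from exc

    libraries: dict[str, list[MutantRecord]] = {}
    try:
        for name in top:
            parent = next(s for s in seeds if s.name == name)
            libraries[name] = build_two_point_library(parent, config.scheme)
    except Exception as exc:
        raise StageError("mutate", str(exc)) from exc

    mutant_scores: dict[str, float] = {}
    mutant_candidates: dict[str, CandidateScore] = {}
    provenance: dict[str, dict] = {}
    try:
        for parent_name, records in libraries.items():
            for rec in records:
                # Score under the unique variant label: the positional naming
                # convention is shared by all nine variants of a position pair.
                cand_seq = replace(rec.sequence, name=rec.unique_label)
                cand = score_candidate(cand_seq, receptor, config, pset)
                mutant_scores[cand.name] = cand.score
                mutant_candidates[cand.name] = cand
                provenance[cand.name] = {
                    "positional_name": rec.mutant_name,
                    "parent": rec.parent,
                    "pos1": rec.pos1,
                    "pos2": rec.pos2,
                    "sub1": rec.substitution_labels[0],
                    "sub2": rec.substitution_labels[1],
                    "sequence": rec.sequence.bases,
                    "best_pose_id": cand.pose_id,
                }
    except Exception as exc:
        raise StageError("score_mutants", str(exc)) from exc

    selected: list[dict] = []
    try:
        for parent_name in top:
            parent_score = seed_scores[parent_name]
            per_parent = {
                name: score
                for name, score in mutant_scores.items()
                if provenance[name]["parent"] == parent_name
            }
            for name, score in select_improved_mutants(parent_score, per_parent):
                selected.append(
                    {
                        "name": name,
                        "parent": parent_name,
                        "score": score,
                        "parent_score": parent_score,
                        "pos1": provenance[name]["pos1"],
                        "pos2": provenance[name]["pos2"],
                        "best_pose_id": provenance[name]["best_pose_id"],
                    }
                )
    except Exception as exc:
        raise StageError("select", str(exc)) from exc

    epitope_overlaps = {
        n: list(c.epitope_residues)
        for n, c in {**seed_candidates, **mutant_candidates}.items()
        if c.epitope_residues
    }

    all_labels = [r.unique_label for recs in libraries.values() for r in recs]
    if len(all_labels) != len(set(all_labels)):
        raise StageError("mutate", "mutant label collision across libraries")

    report = SelectionReport(
        config=config.echo(),
        seed_scores=seed_scores,
        top_seeds=top,
        library_sizes={n: len(recs) for n, recs in libraries.items()},
        mutant_scores=mutant_scores,
        selected=selected,
        epitope_overlaps=epitope_overlaps,
        provenance=provenance,
    )
    if out_dir is not None:
        report.write(out_dir)
        out = Path(out_dir)
        for parent_name, records in libraries.items():
            library_to_frame(records).to_csv(
                out / f"library_{parent_name}.csv", index=False
            )
    return report
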