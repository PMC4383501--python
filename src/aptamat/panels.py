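"""Published reference data for the Ang2 aptamer maturation study.

Sixteen RNA aptamers collected from the SELEX literature: Seq1..Seq15 are
Ang2-specific (Seq1 is a high-affinity truncate, K_d ~ 2.2 nM; Seq15 is the
parent of the pegylated anti-angiogenic aptamer), and Seq16 is an
Ang1-specific control expected to bind Ang2 worst. Each carries the docking
rescoring value (more negative = better) obtained for its best pose against
the Ang2 receptor structure (PDB 2GY7 with the Tie2 chain removed).

Also included: the five Ang2 residues that form its Tie2-binding epitope, and
the SPR-measured kinetic constants for the five sequences characterized on a
biosensor (the three selected mutants plus the Seq1/Seq16 controls).
"""

from __future__ import annotations

from .seqlib import AptamerSequence, parse_rna

_PANEL_RAW: tuple[tuple[str, str, float], ...] = (
    ("Seq1", "ACUAGCCUCAUCAGCUCAUGUGCCCCUCCGCCUGGAUCAC", -93.855),
    ("Seq2", "UUAACCAUCAGCUCAUGGCCCCUGCCCUCUCAAGGACCAC", -82.722),
    ("Seq3", "CACCAGACCGACAUCAGCUUAUGGCCCCUCACCCACACCG", -73.128),
    ("Seq4", "CCACCGAUCGCAUCAGCUCAUGGCCCCUCCCGACCCGCCA", -72.227),
    ("Seq5", "CCAGACGUUCUCGCCCCGCCGAUCAUCAGCGCUGGCCCUAU", -69.183),
    ("Seq6", "CACUACCACGCCAUAUCAGCUAAUGGCCCCUCCCUACGCA", -73.305),
    ("Seq7", "ACUCACCAGUCACCAUCAGCUCAUGCGCCCCUCCCCCGAC", -63.518),
    ("Seq8", "UGACCAAGCCUCACGUUGAACCUGCCAGUAGACCCCGCCCA", -70.795),
    ("Seq9", "GGAGCGCAAUUCGCCUCGCAAGUUGAACUCCGCUGGCGG", -74.153),
    ("Seq10", "UAAGCUCUUUGGCUUAGCCCGACACGUUGAACUCCAGAGU", -65.73),
    ("Seq11", "CACGGUACCACCAAGUCACACGUUGAACUCCAUGCAGCUG", -62.02),
    ("Seq12", "CAUGUCUACAACAAUCUCGCCCGUUGAGUCUCGUCGAAUU", -68.159),
    ("Seq13", "CACUCAGCGCCCUGCGAAACGUUGCCGCCUCCCAACGUCU", -74.432),
    ("Seq14", "CUCUUUUUGUCCCCGCACGUUGAACUCCUGUCCCUCUACU", -73.895),
    ("Seq15", "GAGGACGAUGCGGACUAGCCUCAUCAGCUCAUGUGCCCCUC", -80.325),
    ("Seq16", "ACUCGAACAUUUCCACUAACCAACCAUACUAAAGCACCGC", -61.969),
)

#: The 16 seed aptamers, in panel order.
ANG2_PANEL: tuple[AptamerSequence, ...] = tuple(
    parse_rna(name, bases) for name, bases, _ in _PANEL_RAW
)

#: Published docking rescoring value per seed (more negative = better).
PANEL_SCORES: dict[str, float] = {name: score for name, _, score in _PANEL_RAW}


def panel_sequence(name: str) -> AptamerSequence:
    """Look up one panel aptamer by name."""
    for seq in ANG2_PANEL:
        if seq.name == name:
            return seq
    raise KeyError(f"no panel aptamer named {name!r}")


#: Ang2 residues forming the binding epitope for its receptor Tie2,
#: as one-letter residue labels with crystal-structure numbering.
TIE2_EPITOPE_RESIDUES: tuple[str, ...] = (
    "K468", "F469", "K473", "Y475", "Y476",
)

#: SPR-measured kinetics for the five bench-tested aptamers:
#: k_a in M^-1 s^-1, k_d in s^-1, surface coverage in ng/cm^2 (mean, SD over
#: six sensing areas). Analyte: 0.5 uM Ang2 in TBS.
SPR_KINETICS: dict[str, dict[str, float]] = {
    "Seq1": {"ka": 10.02e3, "kd": 1.39e-3, "coverage_mean": 11.17, "coverage_sd": 1.47},
    "Seq16": {"ka": 1.66e3, "kd": 4.99e-3, "coverage_mean": 1.87, "coverage_sd": 0.31},
    "Seq15_12_35": {"ka": 6.03e3, "kd": 0.61e-3, "coverage_mean": 8.12, "coverage_sd": 0.61},
    "Seq15_15_38": {"ka": 8.22e3, "kd": 0.97e-3, "coverage_mean": 11.69, "coverage_sd": 1.11},
    "Seq2_12_35": {"ka": 4.07e3, "kd": 0.79e-3, "coverage_mean": 5.68, "coverage_sd": 0.41},
}
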