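# Methods

## Scope and model overview

`aptamat` implements the computational arm of an aptamer maturation study
against angiopoietin-2: mutant library generation, energetic rescoring of
rigid docking poses, binding-interface analysis, and 1:1 Langmuir kinetics
for SPR data. The external stages of the original workflow — secondary
structure prediction, RNA 3D modelling, and the FFT global docking search —
are deliberately out of scope; they enter the pipeline as pluggable backend
hooks, and the package ships seeded toy backends so every downstream stage is
runnable and testable without web servers or commercial software.

## Mutant library generation

Sequences are 5'→3' RNA over {A, C, G, U}; positions are 1-based on the
undecorated body. Synthesis decorations (5'-biotin, a 5-adenine spacer for
steric accessibility on streptavidin surfaces) are metadata and never shift
position numbering — the mutants of the 41-nt Seq15 at positions 12/35 and
15/38 verify this frame.

The default scheme pairs position *i* ∈ {10..16} with *i* + 23 ∈ {33..39}
and enumerates all 3 × 3 non-identity substitutions per pair: 63 mutants per
parent, all distinct, each differing from the parent at exactly two
positions. Only *i* ↔ *i* + 23 pairs are generated (not the full cross
product of the two windows): that is what yields the canonical 63-per-parent
count and matches the offset of the named bench-tested mutants.

Enumeration order is deterministic: the three substitution candidates of a
base are ordered [Watson–Crick complement, then the remaining two bases in
U < G < C < A precedence], and candidate-index pairs are traversed as
(1,1), (2,2), (3,3), (1,2), (2,3), (3,2), (1,3), (2,1), (3,1). For an (A, U)
position pair this reproduces the published listing order of the nine
variants exactly.

Naming: the field convention `<parent>_<pos1>_<pos2>` identifies a mutant by
its positions only, so all nine substitution variants of a pair share it. The
package keeps that convention (`mutant_name`) and adds an unambiguous
`unique_label` (`<parent>_<pos1><to1>_<pos2><to2>`) wherever distinct keys
are required (pipeline bookkeeping, FASTA export).

One source inconsistency: the high-affinity truncate is described as 41 nt
but its printed sequence has 40 bases; the implementation trusts the printed
string everywhere.

## Pose rescoring energy

Poses keep receptor and ligand structures fixed and store the ligand's rigid
transform explicitly, so rescoring and interface analysis always see the same
geometry. The score sums over intermolecular heavy-atom pairs only
(hydrogens are ignored — the relevant crystal structures, at 3.7 Å, have
none), gathered with a k-d tree; a plain all-pairs double loop is kept as the
test oracle. Beyond the nonbonded cutoff every term is exactly zero, so
separated partners score 0.

Terms and functional forms:

* **van der Waals** — 6-12 potential with rmin = r_i + r_j and
  ε = √(ε_i ε_j). For r ≥ rmin the (negative) value is the attractive term;
  for r < rmin the attraction is floored at −ε and the excess is booked as
  repulsion, so the repulsive term is non-negative and monotone as a clash
  deepens.
* **Electrostatics** — Coulomb's law, 332.0716·q_iq_j / r kcal/mol (unit
  dielectric), binned short/long range at 5 Å and split by sign into
  attractive/repulsive terms. No distance-dependent dielectric is applied;
  with coarse fixed charges the extra parameter is not identifiable and rank
  order, not absolute energies, is the contract here.
* **Desolvation** — an atomic-contact-energy-style pairwise potential: each
  atom maps to one of a few desolvation classes (nonpolar C, polar N, polar
  O, charged +/−, phosphate, sulfur) and pairs within 6 Å accumulate a small
  symmetric class-contact matrix.

Defaults: nonbonded cutoff 12 Å, short/long boundary 5 Å, desolvation cutoff
6 Å; all configurable. Weights default to the published weighting of the
original ZRANK function (vdW attraction fixed at 1.0, the others fitted in
that work: 0.009, 0.31, 0.34, 0.44, 0.50, 1.02) and are a config input so
sensitivity can be explored.

Atom parameters (partial charges, radii, well depths, desolvation classes)
ship as versioned CSVs. They are coarse, force-field-flavoured values —
backbone and charged-group charges carry the right signs and approximate
magnitudes, radii and well depths are conventional — resolved by
(residue, atom name) with a wildcard backbone tier and an element-level
fallback (every fallback is reported). A dedicated `BB` entry supports
one-bead-per-nucleotide coarse RNA models and carries the net nucleotide
charge (−1 e); giving a single bead the all-atom phosphorus charge (+1.17 e)
would make every contact electrostatically repulsive. No attempt is made to
reproduce the score values of the commercial implementation: those depend on
proprietary pose sets and parameterization, and the package's contract is
rank-order behavior, verified against brute-force oracles and planted
optima.

## Interface and epitope analysis

A contact is a receptor-residue/ligand-nucleotide pair whose minimum
heavy-atom distance is ≤ cutoff. The default cutoff is 5.0 Å — a
conventional heavy-atom contact threshold; the software used in the original
study does not document its value, so this is an explicit, configurable
choice. The interface center is the centroid of all heavy atoms (both
partners) participating in at least one contact.

Epitope overlap checks interface residues against the Ang2 residues that
bind Tie2 (K468, F469, K473, Y475, Y476) by (one-letter name, number); a
residue found at an epitope number under a different name is flagged as a
mismatch, never silently counted. Overlap is monotone in the cutoff.

## SPR kinetics

The 1:1 Langmuir model: association
R(t) = (1 − e^−(k_aC + k_d)t)·k_aC·R_max/(k_aC + k_d) and dissociation
R(t) = R₀e^−k_d(t−t₀); K_A = k_a/k_d exactly (exposed as a derived property
so it can never drift from the fitted rates).

Fitting is two-stage by default: k_d and R₀ from the dissociation phase
(log-linear initialization when responses are positive, direct NLS
otherwise), then k_a and R_max from the association phase with k_d fixed —
matching the sequential use of the two equations in practice; a joint
3-parameter association fit is available. Rates are bounded positive.
Degenerate inputs are flagged rather than reported as ordinary fits: a trace
whose fitted total decay over the observed window is below 10⁻⁶ is flagged
`kd_at_lower_bound`, and an all-zero association signal short-circuits to
the k_a lower bound with a `zero_signal` flag (a free fit there is
unidentifiable).

Defaults mirror the bench protocol: analyte 0.5 µM, 9 min association, 6 min
rinse; sampling rate 1 Hz (unstated in the protocol; a round, realistic
imaging-SPR rate). Replicate surface coverages are summarized with the
arithmetic mean and the sample (n−1) standard deviation. Response units are
carried as opaque sensor units; conversion to ng/cm² is an
instrument-specific calibration the user supplies.

## Synthetic data

Generators are pure functions of (spec, seed) and always emit their ground
truth alongside the data.

* **Toy complexes** — one CA bead per protein residue on a widely spaced
  grid, one BB bead per nucleotide. Planted contacts are realized at 4.0 Å
  (between the 2.5 Å clash floor and the 5 Å cutoff); grid spacing guarantees
  every unplanted pair sits beyond cutoff + margin, and the generator
  verifies this, refusing contradictory contact specs. Coarse one-bead
  geometry keeps the all-pairs test oracles fast.
* **Sensorgrams** — forward simulation of the Langmuir equations, the rinse
  continuing from the noiseless association endpoint (phase continuity), plus
  additive i.i.d. Gaussian noise, default SD 1% of the association plateau
  (no noise model is stated for the instrument; homoscedastic Gaussian is the
  standard assumption for imaging-SPR readout).
* **Random libraries** — uniform seeded RNA sequences, default 40 nt so the
  default mutation scheme applies.

What the toy data does *not* emulate: real RNA tertiary folds, realistic
docking pose distributions, base-pairing constraints, mass-transport effects
or baseline drift in sensorgrams. Passing tests therefore demonstrate
correctness of the algorithms and estimators under their stated models, not
predictive accuracy on laboratory data.

## Pipeline and determinism

`run_pipeline` scores seeds (toy model + toy docking + rescoring), ranks them
(ascending score, ties broken by name), expands the top-k (default 3) into
63-mutant libraries, scores every mutant, and selects mutants scoring
*strictly* better than their parent — the comparison has no margin because
none is defined for "improved"; the report keeps all improved mutants and
leaves any further cut (e.g. per-parent quotas) to the user. Per-candidate
RNG seeds derive from the master seed and the candidate name via CRC32, so
reports are byte-identical across reruns and independent of iteration order.
Every selected mutant is traceable to parent, positions, substitutions and
best pose id.

Problem sizes in tests and the end-to-end run (tens of residues, ≤ 10 poses
per candidate, 20 fit replicates) were chosen so brute-force oracles remain
exact cross-checks and the whole suite runs in seconds; the algorithms
themselves are size-independent.

## Known limitations

* The energy function is ZRANK-*style*: same term structure and weighting,
  but simplified parameters and no softening/attenuation refinements; use it
  for ranking, not for absolute binding energies.
* The two-stage fit propagates the dissociation-phase k_d error into k_a;
  when k_a·C ≪ k_d (weak binders at low concentration) k_a is intrinsically
  poorly identified from a single-concentration sensorgram at ~1% noise.
* One published affinity row (k_a = 10.02 × 10³, k_d = 1.39 × 10⁻³, K_A
  printed as 7.23 × 10⁶) is not reproducible from its own printed inputs
  (the ratio gives 7.21 × 10⁶; the original value was evidently computed
  from unrounded fits), so exact K_A checks cover the other four rows.
* PDB handling reads the first model, drops altloc variants beyond the
  first, and ignores crystallographic symmetry and assembly building.
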