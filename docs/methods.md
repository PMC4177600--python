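# Methods

## Problem and model

Given a two-protomer protein complex and one multiple sequence alignment per
chain, the package scores every interface residue with four bounded
subscores — interaction energy E, evolutionary conservation C, mass index
MI, spatial clustering SC — combines them linearly, and thresholds the
result into hotspot / non-hotspot. The model assumes (i) hotspots contribute
disproportionate favorable interaction energy across the interface,
(ii) they are more conserved than the chain average, (iii) they are tightly
packed/occluded, and (iv) they aggregate into hot regions. No solvation,
entropy or conformational relaxation is modelled: the score is a static,
single-structure heuristic, and the output is a class, never a ΔΔG.

## Interface and contacts

A residue is an interface residue when any of its heavy atoms lies within
4.5 Å (inclusive) of any heavy atom of the opposite protomer. The same
contact machinery (KD-tree over heavy atoms) serves the mass index (4.5 Å)
and clustering (7 Å) queries; within a chain, sequence neighbors i±1 are
excluded so backbone connectivity is not mistaken for packing. 4.5 Å
heavy-atom is a common literature convention; it, and every other cutoff,
is a `ParameterSet` field.

Hydrogens are dropped at parse time (most crystal structures lack them);
alternate locations resolve to the highest-occupancy conformer (ties by
altloc identifier); MSE is aliased to Met; other non-standard residues are
skipped with a warning; model 1 of multi-model files is used; coordinates
are taken as deposited (no symmetry expansion).

## Energy kernels

All energies are cross-protomer only and every pair term is attributed to
*both* residues of the pair — required for a per-residue decomposition, and
the reason the per-component sums over the two protomers are exactly equal.

* Van der Waals: 12-6 Lennard-Jones over heavy-atom pairs within 8 Å,
  `ε[(r_min/r)^12 − 2(r_min/r)^6]`, with `r_min = r_i + r_j`
  (Lorentz–Berthelot) and `ε = √(ε_i ε_j)`. United-heavy-atom parameters:
  r (Å) / ε (kcal/mol) = C 1.95/0.12, N 1.85/0.16, O 1.75/0.20, S 2.00/0.25;
  unknown elements fall back to carbon. Pairs engaged in a detected hydrogen
  bond are excluded (no double counting).
* Electrostatics: `332·q_i·q_j/(ε(r)·r)` with ε(r) = 4r over formally
  charged atoms within 10 Å: Asp/Glu −0.5 per carboxylate O, Lys NZ +1,
  Arg +0.5 per NH1/NH2. His is neutral; terminal charges are ignored. The
  distance-dependent dielectric is the standard hydrogen-free screening
  approximation.
* Hydrogen bonds: donor–acceptor heavy-atom distance in [2.5, 3.5] Å and
  antecedent–donor–acceptor angle ≥ 90° (a donor missing its antecedent
  atom is accepted on distance alone). Each unique atom pair is one bond at
  −1.0 kcal/mol, added to both partners. Donor/acceptor tables cover
  backbone N/O and the usual side-chain groups.

These functional forms are this package's own choices — deliberately
standard, parameter-light, and reproducible without placing hydrogens.
Absolute energies are therefore not comparable with any particular force
field; only the normalized subscore enters the classification.

The weighted energy `e_i = 1.4·VW + 1·ES + 9·HB` is divided by the
Zamyatnin mean residue volume and mapped to
`E_i = min(|ne_i|/ne_max, 1)` when favorable, 0 when net unfavorable.

## Conservation

The alignment must contain the chain's exact sequence as its query row.
Redundancy is removed greedily in input order at 80 % pairwise identity
(matches over mutually non-gapped columns; X counts as a gap); the query is
processed first and always survives — without it the profile would be
undefined. Each query column is scored as the mean Johnson–Overington score
over all unordered pairs of non-gap residues, divided by 100 and clamped to
[0, 1]; columns with fewer than two non-gap residues fall back to 0 with a
warning. Averaging over all pairs (rather than query-only pairs, available
as `query_only_conservation` for sensitivity analysis) is depth-independent
and bounded by the matrix maximum, which is what makes the /100
normalization yield [0, 1].

The packaged matrix is the Johnson & Overington (1993) structure-derived
substitution matrix as shipped with Biopython (log-odds, maximum 1.61 at
Cys–Cys), linearly rescaled by 100/1.61 so the Cys–Cys entry is exactly 100
and remains the unique maximum — asserted at load time. A whitespace
square/lower-triangular matrix-file reader allows substituting any other
20×20 symmetric matrix.

## Mass index and clustering

`mi_i` is the summed residue mass (average residue masses, Da) of all
contact partners at 4.5 Å over both protomers; `MI_i = min(mi_i/mi_max, 1)`.
The central residue's own mass is excluded by default (`mass_include_self`
flips this). The clustering candidate set is `{i : (E_i + C_i)/2 > 0.5}`
(strict, since final hotspot calls do not exist yet at this stage);
`sc_i` counts other candidates within 7 Å, split into same- and
cross-protomer counts, and `SC_i = min(sc_i/sc_max, 1)`.

## Combination, side rules, thresholds

`f_i = 0.3·E + 0.9·C + 0.4·SC + 0.4·MI`, `F_i = min(f_i/f_max, 1)`,
hotspot iff `F_i ≥ 0.80` (inclusive). The Ser/Thr veto demotes an
above-threshold Ser/Thr unless `MI > 0.5`; the Trp/Phe rescue promotes a
below-threshold Trp/Phe when `MI > 0.5` **and** `C ≥ 0.68`, so a rescue
still demands independent evidence (the rescue is operationally
under-specified in the literature; requiring conservation as well is this
package's reading, and `trp_phe_rescue=False` disables it). Exactly one of
base-accept / base-reject / ser-thr-veto / trp-phe-rescue fires per residue
and is recorded in the output's `rule` column.

## Calibration

`ne_max, mi_max, sc_max, f_max` are the 95th percentiles (NumPy linear
interpolation) of |ne|, mi, sc and f pooled over all interface residues of a
calibration set — scores are comparable across complexes while the extreme
5 % of the data is ignored. The clustering and combined pools are built with
the freshly calibrated upstream constants, mirroring the dependency order of
the subscores. Degenerate pools floor at 1e-6. The shipped defaults
(ne_max 0.143, mi_max 951, sc_max 5.0, f_max 1.693) come from one
calibration run over the packaged synthetic fixtures (seeds 0–4); they are
sensible for the fixture geometry and should be re-derived with
`hotspotter calibrate` for real structure sets. `f_max` may also be set
analytically to the weight sum 2.0, the maximum of f given unit subscores.

## Evaluation

ddG-labelled benchmarks: hotspot iff ddG ≥ 2.0 kcal/mol, non-hotspot iff
ddG < 0.4, the band [0.4, 2.0) excluded — boundary semantics are inclusive
at 2.0 and strict at 0.4. Strength-labelled benchmarks: "strong" is a
hotspot, intermediate/weak/insignificant are not; unknown labels are an
error. ACC/SE/PR/SP/MCC use the standard confusion-matrix formulas;
zero-denominator metrics report 0 with a flag rather than NaN. ROC curves
sweep one threshold per distinct score (prediction `score ≥ t`, ties grouped
into one step); the elbow rule returns the threshold at the last step whose
TPR gain strictly exceeds its FPR gain, falling back to the highest finite
threshold (flagged uninformative) for curves that never beat the diagonal.
Trapezoid AUC equals the Mann–Whitney rank AUC to 1e-9, which the tests
assert on randomized sets.

## Synthetic fixtures: what they do and do not show

The generator plants features with known ground truth on two rigid
pseudo-atom scaffolds: strong sites (His donating two hydrogen bonds to an
Asp and a Ser, flanked by Trp/Phe packers, in adjacent bands so candidates
cluster within 7 Å, with conserved alignment columns), salt bridges,
isolated hydrogen bonds, weak Ala–Ala contacts and an unconserved,
barely-contacting loner. Coordinates get ±0.03 Å of seeded jitter — small
enough that no planted contact can cross a detection cutoff — and alignments
mutate non-conserved columns at rate 0.3 over 8 rows, keeping pairwise
identities below the 80 % redundancy threshold. Side chains are single
interaction centers carrying exactly the atom names the kernels read; the
geometry is *not* physically realistic protein structure. Passing tests
therefore demonstrate the pipeline's mechanics — detection windows,
attribution, normalization, gating, rule precedence, determinism, rigid-body
invariance — not predictive accuracy on real complexes, which depends on
calibration against real interfaces and on alignment quality.

The benchmark-table generators are likewise synthetic stand-ins: they
reproduce the documented corpus composition (316 ddG records over 19
complexes splitting 78/119/119 under the cutoffs; 125 strength records over
18 complexes with 38 "strong") with seeded values on the correct side of
each cutoff, so the label filters, joins and metrics are exercised as real
computations without redistributing mutagenesis data.

## Numerical and degenerate-input choices

Threshold comparisons are inclusive on the hotspot side (`F ≥ t_f`,
`C ≥ t_c`) except the clustering gate and the MI side-rule gates, which are
strict (`> 0.5`). Interface detection at exactly the cutoff distance is
inclusive. Empty interfaces are legal and yield empty score tables; an empty
calibration pool is an error. Percentiles use linear interpolation.
Altloc occupancy ties break toward the lexicographically smaller identifier.
Scoring is fully deterministic given structure, alignments and parameters;
the only randomness anywhere lives in the seeded generators.

## Known limitations

* Energies are crude: no solvation or entropy, formal charges only, fixed
  hydrogen-bond energy, His always neutral. Ranking within a complex is
  meaningful; absolute values are not.
* Conservation quality is bounded by the supplied alignment; the package
  neither searches for homologues nor re-aligns.
* Multi-chain protomers are supported structurally, but conservation is
  mapped per chain, so each chain needs its own alignment.
* The fixture-derived normalization defaults are placeholders for real
  calibration; scores on real complexes should follow a `calibrate` run
  over a representative complex set.
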