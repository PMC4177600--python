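# hotspotter

Identification of **hotspot residues** at protein–protein interfaces —
interface residues whose mutation to alanine costs at least 2 kcal/mol of
binding free energy. Hotspots carry most of the binding energy of a complex,
tend to be conserved, tightly packed, and to cluster into "hot regions";
they are the prime targets when designing small molecules that block a
protein–protein interaction. The package is aimed at structural
bioinformaticians who have a complex structure (PDB) and per-chain multiple
sequence alignments, and want a per-residue hotspot call without running
expensive free-energy calculations.

## The score

For each interface residue *i* (any heavy atom within 4.5 Å of the partner
protomer), four normalized subscores in [0, 1] are combined:

* **Energy** `E_i`. Cross-interface Van der Waals (12-6 Lennard-Jones),
  electrostatic (Coulomb with distance-dependent dielectric ε(r) = 4r) and
  hydrogen-bond (−1 kcal/mol per geometric bond) energies are summed per
  residue with weights

  `e_i = w_VW·VW_i + w_ES·ES_i + w_HB·HB_i`,  (w_VW, w_ES, w_HB) = (1.4, 1, 9),

  normalized by the residue volume, `ne_i = e_i / V_i`, and mapped to
  `E_i = min(|ne_i| / ne_max, 1)` for favorable energies (0 otherwise).
* **Conservation** `C_i`. From a pre-built alignment containing the chain,
  homologues are de-redundified at 80 % identity, and each column is scored
  as the mean substitution score over all unordered residue pairs using the
  Johnson–Overington structure-derived matrix, divided by 100 (its maximum,
  the Cys–Cys entry): `C_i = c_i / 100`.
* **Mass index** `MI_i`. The summed residue mass of all contact partners
  (≤ 4.5 Å, both protomers, excluding chain neighbors i±1), normalized by
  `mi_max` — a proxy for packing and solvent occlusion.
* **Spatial clustering** `SC_i`. Residues whose energy/conservation average
  exceeds 0.5 count their fellow candidates within 7 Å (hot regions),
  normalized by `sc_max`.

The combined score is

  `F_i = min( (0.3·E_i + 0.9·C_i + 0.4·SC_i + 0.4·MI_i) / f_max, 1 )`

and a residue is called a hotspot when `F_i ≥ 0.80`, with two side rules:
Ser/Thr passing the threshold are demoted unless `MI > 0.5` (their
hydrogen-bond energy is systematically over-represented), and Trp/Phe
failing it are promoted when `MI > 0.5` and `C ≥ 0.68` (volume
normalization deflates their Van der Waals contribution). The normalization
constants `ne_max, mi_max, sc_max, f_max` are 95th percentiles of the raw
quantities over a calibration set, so the extreme 5 % of the data does not
stretch the scales. Per-score thresholds (E 0.58, C 0.68, MI 0.50, SC 0.54,
combined 0.80) and all weights ship as defaults and live in one config file.

## Worked example

The package ships a deterministic synthetic-fixture generator (poly-alanine
scaffolds with planted interactions — hydrogen-bonded His/Asp/Ser sites,
salt bridges, packed aromatics, weak contacts, and a deliberately
featureless "loner"):

```
$ hotspotter fixtures --seed 0 --out-dir demo
$ hotspotter score demo/synthetic_complex.pdb --chains A:B \
    --alignment A=demo/synthetic_chain_A.fasta \
    --alignment B=demo/synthetic_chain_B.fasta --out demo/scores.tsv
20 interface residues, 5 hotspots
  protomer A: H2:A, H6:A
  protomer B: D2:B, D8:B, W12:B
```

The two His residues are the planted strong sites: each donates two
cross-interface hydrogen bonds, sits in a conserved column, and is packed by
aromatic neighbors. The first rows of `demo/scores.tsv`:

```
protomer chain resnum aa   E      C      MI     SC   F      hotspot rule
A        A     2      H  0.995  0.789  0.997  0.80  1.000  1       base-accept
A        A     4      F  0.067  0.000  0.676  0.00  0.172  0       base-reject
A        A     6      H  1.000  0.789  0.903  0.80  0.999  1       base-accept
```

Reading row one: the His at A2 has near-maximal interface energy (E ≈ 1.0),
a conserved column (C = 0.79, the His–His matrix score), is packed by ~950 Da
of contact partners (MI ≈ 1.0) and has four candidate neighbors within 7 Å
(SC = 0.8), so its combined score saturates at F = 1.0 — a hotspot. The Phe
at A4 is a packer: well buried (MI = 0.68) but energetically and
evolutionarily unremarkable, so F = 0.17 and it is rejected. The B-chain
hotspots are the acceptor-side partners of the planted sites plus one
conserved, well-packed Trp promoted by the Trp/Phe rescue rule.

`hotspotter calibrate` re-derives the normalization constants from your own
complex set, and `hotspotter eval` joins a score table against an
alanine-scanning benchmark TSV (columns `complex_id, chain, resnum, aa` plus
either `ddg` in kcal/mol or a `strength` label in
strong/intermediate/weak/insignificant) and reports ACC, SE, PR, SP and MCC.

## Scope notes

The energy kernels are deliberately simple, hydrogen-free standard forms
(united heavy atoms, formal charges, fixed per-bond hydrogen-bond energy);
the package predicts the hotspot *class*, not ΔΔG values. Homologue search
and alignment construction (e.g. PSI-BLAST + ClustalW) are external
preprocessing — the conservation module consumes a finished FASTA/Clustal
alignment. See `docs/methods.md` for model details, parameter defaults and
limitations.
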