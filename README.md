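# rnakit

Machine-learning work on RNA 3D structure needs clean, merged,
per-nucleotide data — but the raw material is scattered: atomic coordinates
live in mmCIF files with idiosyncratic author numbering, ligands and
unresolved stretches; homology information lives in family alignments with
two different gap dialects; and the tables that say *which* chains are worth
keeping (resolution lists, redundancy classes, chain-to-family mappings) are
separate again. `rnakit` implements the computational core of a pipeline
that reconciles the three sources into one multi-scale record set: for every
nucleotide of every selected chain, its sequence and provenance, its full
geometric description, and the base-frequency profile of its alignment
column, stored relationally (SQLite) and exported as flat CSV.

The package is a library: its public face is the importable API plus the
short narrative scripts in `examples/`.  A `fixtures` module generates
synthetic coordinate files, alignments and selection tables with known
ground truth, so everything is testable offline.

## What is computed

**Geometry** (per nucleotide, from coordinates alone; angles in degrees on
[0, 360), NaN where atoms are missing):

- backbone torsions α (O3′ᵢ₋₁–P–O5′–C5′), β, γ, δ, ε, ζ and the glycosidic
  torsion χ (purines O4′–C1′–N9–C4, pyrimidines O4′–C1′–N1–C2) with its
  syn/anti class (syn for χ ∈ [0°, 90°) ∪ [270°, 360°));
- the five endocyclic ribose torsions ν₀..ν₄ and the Altona–Sundaralingam
  pseudorotation: tan P = ((ν₄+ν₁) − (ν₃+ν₀)) / (2 ν₂ (sin 36° + sin 72°)),
  amplitude ν_max with ν₂ = ν_max cos P, and the 36°-wide conformer bin
  (C3′-endo = [0°, 36°), C2′-endo = [144°, 180°), …);
- pseudotorsion pairs over virtual bonds: η/θ on P and C4′ atoms
  (ηᵢ = C4′ᵢ₋₁–Pᵢ–C4′ᵢ–Pᵢ₊₁, θᵢ = Pᵢ–C4′ᵢ–Pᵢ₊₁–C4′ᵢ₊₁), η′/θ′ on C1′, and
  η″/θ″ on the base-ring centroid.

**Homology**: alignment columns summarized into PSSMs (plain counts; '-' and
'.' both count as gaps but stay distinct in the parsed alignment), pairwise
sequence identity (identical-base columns over columns where at least one
row has a base) and Ward hierarchical clustering on 1 − identity.

**Merging**: a two-pointer reconciliation of the gapped 3D sequence with the
chain's aligned row — matching symbols pair; an unresolved residue facing a
non-gap searches ahead for a deletion gap, then an insertion gap, and
otherwise keeps NaN homology; alignment gaps facing bases are skipped;
differing bases are a hard error.  Unresolved residues optionally take the
column consensus in a secondary field (`nt_align_code`) while `nt_code`
keeps the gap.

**Selection**: resolution filtering (default ≤ 4.0 Å, unknown resolution
excluded), propagation of chain→family mappings through redundancy
equivalence classes, and copy/truncation of chains mapped to several
families.

**Analyses**: chain-length histograms by family with an `Other` pool,
identity-matrix panels, and Gaussian kernel densities of (η, θ) pairs on the
torus [0, 360)² with line contours at ρ+σ, ρ+2σ, ρ+4σ (ρ, σ = mean and
standard deviation of the evaluated grid), stratified into non-helical
C3′-endo and C2′-endo nucleotides.

## Worked example

```sh
python examples/01_synthetic_helix_geometry.py
```

```
idx nt    alpha    delta      chi      eta    theta    phase  pucker     chi_class
  1  A        -    81.00   200.00        -        -    18.00  C3'-endo   anti
  2  C   120.26    81.00   200.00   224.62   210.29    18.00  C3'-endo   anti
  3  G   120.26    81.00   200.00   224.62   210.29    18.00  C3'-endo   anti
  4  U   120.26    81.00   200.00   224.62   210.29    18.00  C3'-endo   anti
  5  A   120.26    81.00   200.00   224.62   210.29    18.00  C3'-endo   anti
  6  C   120.26    81.00   200.00        -        -    18.00  C3'-endo   anti
```

The chain was generated with pseudorotation phase 18° and sugars come back
labeled C3′-endo with phase 18.00 on every residue — the ribose embedding
inverts the pseudorotation relation ν_j = ν_max·cos(P + 144°·(j−2)), so the
phase is exact ground truth.  Interior rows are identical because residues
are related by an exact helical symmetry; `-` marks angles that need atoms
of a neighboring residue (the 5′ residue has no phosphate, as in real
structures).  `examples/05_build_dataset.py` continues to the full merge:
an unresolved residue keeps `nt_code='-'`, receives the family consensus in
`nt_align_code`, null geometry, and its alignment column's base
frequencies.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on the synthetic world: it
generates selection tables, coordinate files and family alignments, then
runs selection → parsing/normalization → geometric annotation → PSSM →
remapping → SQLite build → CSV export → density/clustering analyses,
printing a run summary and writing the results manifest to `--out`.
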