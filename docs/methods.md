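# Methods

This note records the models, conventions and numerical choices behind
`rnakit`, what the synthetic generators do and do not emulate, and where a
design was genuinely open.

## Angle conventions

All torsions are reported in degrees on [0, 360).  The dihedral primitive
follows the IUPAC sign convention (atan2 formulation over the two bond-plane
normals) and reduces to [0, 360) at output; signed values are never mixed
into stored fields.  Degenerate quadruples (coincident points, collinear
triples below 1e-9 in normal magnitude) yield NaN rather than raising:
geometry failures must degrade per-angle, not per-chain.  Undefined angles
are NaN and undefined labels `None` — no sentinel numbers anywhere.

Whether a published annotation tool reports these angles signed or wrapped
is a convention, not a fact about the molecules; wrapped was chosen because
the pseudotorsion analyses live naturally on a [0, 360)² torus.

## Backbone, glycosidic and pseudotorsion definitions

The atom quadruples are the standard ones (α: O3′(i−1)–P–O5′–C5′ through
ζ: C3′–O3′–P(i+1)–O5′(i+1); χ over O4′–C1′–N9–C4 for purines and
O4′–C1′–N1–C2 for pyrimidines).  Any angle whose atoms are missing —
termini, unresolved neighbors, incomplete residues — is NaN; an unresolved
residue is entirely NaN.  Consequently the η family is undefined at both
chain ends (ηᵢ needs C4′ᵢ₋₁ *and* Pᵢ₊₁), not only at the first residue.

The syn window for χ is [0°, 90°) ∪ [270°, 360°) — the standard ±90° band
about cis.  The boundary at exactly 90°/270° is assigned to anti; with
float inputs the tie is measure-zero.

η″/θ″ need a "base center": the centroid of the base ring heavy atoms
(N1, C2, N3, C4, C5, C6, plus N7, C8, N9 for purines).  A centroid is the
simplest reproducible operationalization; other tools may use a different
reference point, so η″/θ″ values are comparable within this package but not
necessarily across tools.

## Pseudorotation

Phase and amplitude follow Altona–Sundaralingam:
tan P = ((ν₄+ν₁) − (ν₃+ν₀)) / (2 ν₂ (sin 36° + sin 72°)), computed with the
two-argument arctangent so ν₂ ≈ 0 (P near 90° or 270°) stays well-defined;
the amplitude is the hypotenuse of (ν₂, numerator/(2(sin 36°+sin 72°))),
which equals ν_max exactly when the ν_j follow the cosine law.  The pucker
label is the 36°-wide bin of the pseudorotation wheel containing P, with
C3′-endo = [0°, 36°); a planar ring (all ν_j = 0) has amplitude 0 and no
label.  Inputs may be signed or wrapped; they are folded to signed
internally because the formula lives on (−180°, 180°].

## Synthetic helix fixtures

The generator's purpose is exact ground truth, not physical realism.

*Ribose embedding.*  The five endocyclic torsions implied by the requested
(P, ν_max) are imposed on the ring coordinates by solving the closure
system numerically: torsion residuals (as 2·sin(Δ/2), smooth at the wrap)
weighted 1e4 against soft bond-length residuals at ideal values, solved
with Levenberg–Marquardt from a NeRF-built initial ring.  A closed
five-ring has nine shape degrees of freedom, so five prescribed torsions
plus five fixed lengths are overdetermined — empirically, exact roots
vanish in pockets of the wheel (near P ≈ 45°/225°).  With soft bonds the
worst torsion error over the wheel (amplitudes 20–50°) is ~3e-7°, and
bonds stay within ~0.07 Å of ideal.  The geometry module's recovered phase
therefore matches the requested phase to well below the 1e-3° test
tolerance.

*Helix symmetry.*  One template nucleotide is built per base letter
(exocyclic atoms and a planar base attached by NeRF with fixed internal
coordinates, glycosidic χ a parameter, default 200° = anti); residue i is
the template rotated by i·twist about z and translated by i·rise.  Defaults
are A-form-like: rise 2.81 Å, twist 32.7°, P = 18°, ν_max = 40°.  Because
the symmetry is exact, all interior inter-residue torsions are identical to
machine precision — that is the oracle for the torsion machinery.  The
5′-terminal residue is written without its phosphate, as in real
structures, to exercise undefined-angle bookkeeping.

*What is not emulated*: base pairing and stacking energetics, sequence-
dependent geometry, realistic B-factors/altlocs, crystallographic noise
(only isotropic Gaussian coordinate noise is available).  A green test on
fixtures establishes the correctness of the descriptor computations, not
the biological realism of their distributions.

*Toy alignments* emulate the two gap dialects of covariance-model aligners:
'-' for deletions against the consensus, '.' for insertion padding.
Per-column substitution and deletion rates and per-slot insertion rates are
independent Bernoulli draws; the chain row is the chain sequence with '.'
padding at insertion columns, so degapping it recovers the chain sequence
exactly — the oracle for the remapping stage.

*Selection tables* partition chains round-robin into classes and give only
the first member of each class a direct mapping, making the class-
propagation rule load-bearing.  Resolutions are uniform on (0, 6] Å,
bracketing the 4.0 Å default threshold from both sides.

## mmCIF handling

CIF tokenization is Biopython's `MMCIF2Dict`; chain semantics are local:

- numbering is normalized to 1..L in polymer order, author labels retained;
  duplicate author labels are an error (they would make annotation keys
  ambiguous);
- unresolved residues are materialized only from `entity_poly_seq`; gaps in
  author numbering alone never create residues (author numbering is
  untrustworthy);
- a residue is a ligand when its component id is not a recognized
  (modified) ribonucleotide *and* it is not both C1′-bearing and
  backbone-linked (O3′/P within 2.2 Å) — so a free GTP is stripped while an
  unknown but chain-linked modified nucleotide is kept as parent 'N';
- first model only, first-listed altloc only;
- the bundled modified-nucleotide parent table (~24 common entries) follows
  the wwPDB CCD `mon_nstd_parent_comp_id` field for those entries; it is a
  deliberate subset, documented here, and unknown components fall back to
  ('N', modified).

## PSSM, identity, clustering

PSSMs are plain column counts (no sequence weighting or deduplication —
whether published profiles weight sequences is unknowable from the outside,
and plain counts are the reproducible choice).  Both gap dialects pool into
`gap_fraction`; IUPAC ambiguity codes count as `freq_other`.  Consensus is
the maximal-frequency base with alphabetical tie-break, '-' if gaps beat
every base, 'N' if the other-bucket does.

Sequence identity scores columns where at least one row has a base;
doubly-gapped columns are ignored.  This denominator is a documented local
choice (published pipelines rarely state theirs).  Clustering is Ward
linkage on 1 − identity via scipy; a hand-coded Lance–Williams
implementation serves as the independent cross-check in the tests.

'T' in inputs is folded to 'U' (DNA-alphabet rRNA databases); alignment
lowercase survives parsing and is case-folded during counting and mapping.

## Remapping

The merge is a two-pointer walk with the four cases described in the
README.  Pointer mechanics the prose leaves open are fixed as follows: the
lookahead for an unresolved residue scans from the current alignment
pointer up to (not including) the next base symbol, preferring the first
'-' over any earlier '.'; a matched gap column is consumed (the pointer
advances past it), so no column can pair twice — this is what makes mapped
columns strictly increasing.  When several '-' precede the next base the
leftmost is taken.  The precondition (equal degapped sequences) is
validated up front and raises the same `MappingError` as an in-walk
mismatch, making "error iff sequences disagree" exact — verified
exhaustively over all ~6M sequence pairs up to length 6.

Consensus filling replaces `nt_align_code` (never `nt_code`) of unresolved
residues that mapped to a column; it is switchable off.

## Dataset store

A single-file SQLite database with tables `chains`, `families`,
`align_columns`, `nucleotides`; chain rows are keyed by (structure, chain,
family) so multi-family copies coexist.  Builds are deterministic (sorted
insertion order, no timestamps), so rebuilding on unchanged inputs is
byte-identical in `iterdump` — the idempotence contract.  Pair/form fields
(`paired`, `pair_type`, `form_label`) are only ever ingested from an
external DSSR-style JSON file (dialect documented in the module docstring);
pair labels outside the 12 Leontis–Westhof families (cis/trans ×
WW/WH/WS/HH/HS/SS, edges unordered) are kept under the catch-all 'other',
and inter-chain partners leave `paired` at 0.  The exported CSV schema is
this package's own documented column list, not a claim of byte-level
compatibility with any published export.

Dates are ISO-8601 strings compared lexicographically; "released before" is
strict.  Nulls export as empty strings, keeping the null-vs-0 distinction
of `paired` versus missing homology.

## Density analysis

The (η, θ) plane is a torus, so the KDE uses product wrapped-normal
kernels: periodic images at ±k·360° summed over enough k that truncation
error is far below the 1e-8 oracle tolerance.  The default grid is
256×256 (1.4° resolution); contour levels are ρ+σ, ρ+2σ, ρ+4σ with ρ and σ
the mean and standard deviation of the evaluated grid — note these depend
on grid resolution by construction.  The default bandwidth is Scott's rule
(n^(−1/6) in d = 2) applied to the circular standard deviation of the
sample, since a linear standard deviation is meaningless for seam-
straddling data; it is an explicit parameter everywhere.

Stratification: the C3′-endo panel excludes nucleotides labeled as part of
an A/B/Z helix (they swamp the central peak); whether the C2′-endo panel
should also exclude them is ambiguous in the field's practice, so it is a
flag (`exclude_helical_in_c2`, default off).  "Unique chains" means one
chain per (structure, chain) after dropping multi-family copies.

## Known limitations

- Base-pair classification, stacking and helix-form detection are out of
  scope by design: those fields are ingested, never computed.
- The phosphate-position descriptors some annotators emit are not included;
  the descriptor set is the one defined above.
- The ligand heuristic is explicit but heuristic; exotic linkages (cyclic
  phosphates, covalent adducts) may be misjudged.
- `parse_mmcif` handles the atom_site/entity_poly_seq subset it documents;
  assemblies, symmetry expansion and NMR ensembles are not supported.
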