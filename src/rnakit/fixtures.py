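"""Synthetic inputs with known ground truth.

Three generators cover the pipeline's three input kinds:

* :func:`make_helix_mmcif` -- an idealized RNA helix written as mmCIF.  The
  ribose rings are built by inverting the pseudorotation relation
  ``nu_j = nu_max * cos(P + 144 * (j - 2))``: the five endocyclic torsions
  implied by the requested (phase, amplitude) are imposed exactly on the ring
  coordinates (ring-closure solved numerically with ideal bond lengths), so
  phase and amplitude are exact ground truth for the geometry module.
  Residues are replicated by an exact helical symmetry operation, making all
  interior inter-residue torsions identical by construction.  The
  5'-terminal residue is written without a P atom, as in real structures.

* :func:`make_toy_alignment` -- a toy multiple sequence alignment emitted in
  both Stockholm and aligned-FASTA renditions, using '-' for deletions
  against the consensus and '.' for insertion padding (the two gap dialects
  produced by covariance-model aligners).

* :func:`make_selection_tables` -- a chain list with resolutions, a
  redundancy partition into equivalence classes, and a family-mapping table
  where only the first chain of each class carries a direct mapping, so the
  class-propagation rule of the selection stage has work to do.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .geometry import dihedral, place_atom
from .selection import ChainEntry, FamilyMapping, SelectionTables
from .structure_io import Residue, RnaChain, write_mmcif

BASES = "ACGU"

# ideal ribose bond lengths (Angstrom); soft targets during ring closure
RING_BONDS = {
    ("O4'", "C1'"): 1.414,
    ("C1'", "C2'"): 1.526,
    ("C2'", "C3'"): 1.525,
    ("C3'", "C4'"): 1.527,
    ("C4'", "O4'"): 1.454,
}


class FixtureSpecError(ValueError):
    """Raised when a generator spec violates its invariants."""


@dataclass(frozen=True)
class HelixSpec:
    """Parameters of a synthetic ideal helix.

    Defaults describe an A-form-like geometry: C3'-endo pucker (P = 18,
    nu_max = 40 degrees), 2.81 A rise and 32.7 degree twist per residue.
    """

    n_residues: int
    sequence: str
    pucker_phase_deg: float = 18.0
    pucker_amplitude_deg: float = 40.0
    rise_per_residue: float = 2.81
    twist_per_residue: float = 32.7
    seed: int = 0
    coordinate_noise_sd: float = 0.0
    chi_deg: float = 200.0  # anti by default

    def validate(self) -> None:
        if self.n_residues < 1:
            raise FixtureSpecError("n_residues must be positive")
        if len(self.sequence) != self.n_residues:
            raise FixtureSpecError("len(sequence) must equal n_residues")
        if any(b not in BASES for b in self.sequence):
            raise FixtureSpecError("sequence must be over {A,C,G,U}")
        if not 0.0 <= self.pucker_phase_deg < 360.0:
            raise FixtureSpecError("pucker_phase_deg must lie in [0, 360)")
        if not 0.0 < self.pucker_amplitude_deg < 90.0:
            raise FixtureSpecError("pucker_amplitude_deg must lie in (0, 90)")
        if self.coordinate_noise_sd < 0.0:
            raise FixtureSpecError("coordinate_noise_sd must be >= 0")


@dataclass(frozen=True)
class ToyMsaSpec:
    """Parameters of a synthetic homolog alignment around a consensus."""

    n_sequences: int
    consensus: str
    deletion_rate: float = 0.0
    insertion_rate: float = 0.0
    substitution_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sequences < 1:
            raise FixtureSpecError("n_sequences must be positive")
        if not self.consensus:
            raise FixtureSpecError("consensus must be non-empty")
        if any(b not in BASES for b in self.consensus):
            raise FixtureSpecError("consensus must be over {A,C,G,U}")
        for name in ("deletion_rate", "insertion_rate", "substitution_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise FixtureSpecError(f"{name} must be a probability")


def pseudorotation_torsions(phase_deg: float, amplitude_deg: float) -> list[float]:
    """The five endocyclic torsions implied by (P, nu_max), signed degrees."""
    return [
        amplitude_deg * math.cos(math.radians(phase_deg + 144.0 * (j - 2)))
        for j in range(5)
    ]


def _build_ring(phase_deg: float, amplitude_deg: float) -> dict[str, np.ndarray]:
    cached = _build_ring_cached(float(phase_deg), float(amplitude_deg))
    return {name: np.array(xyz) for name, xyz in cached}


_TORSION_WEIGHT = 1e4  # drives torsion residuals to ~1e-7 deg vs soft bonds


@lru_cache(maxsize=256)
def _build_ring_cached(
    phase_deg: float, amplitude_deg: float
) -> tuple[tuple[str, tuple[float, float, float]], ...]:
    """Embed the ribose ring so its measured torsions equal the target nus.

    Frame: O4' at the origin, C1' on +x, C2' in the z = 0 half-plane y > 0.
    The five torsions are hard constraints (weighted so the solved torsion
    error is ~1e-7 degrees -- the pseudorotation ground truth); the five
    bond lengths are soft targets at ideal values.  A closed five-ring
    cannot satisfy five prescribed torsions and five exact lengths
    simultaneously everywhere on the wheel, so the bonds absorb the
    residual freedom (they stay within ~0.07 A of ideal).
    """
    targets = pseudorotation_torsions(phase_deg, amplitude_deg)
    bond_order = [("O4'", "C1'"), ("C1'", "C2'"), ("C2'", "C3'"), ("C3'", "C4'"), ("C4'", "O4'")]
    bonds = [RING_BONDS[pair] for pair in bond_order]

    def unpack(x):
        return (
            np.zeros(3),
            np.array([x[0], 0.0, 0.0]),
            np.array([x[1], x[2], 0.0]),
            x[3:6],
            x[6:9],
        )

    def quads_of(pts):
        o4, c1, c2, c3, c4 = pts
        return [
            (c4, o4, c1, c2),  # nu0
            (o4, c1, c2, c3),  # nu1
            (c1, c2, c3, c4),  # nu2
            (c2, c3, c4, o4),  # nu3
            (c3, c4, o4, c1),  # nu4
        ]

    def residuals(x):
        pts = unpack(x)
        res = [
            # sin of the half-difference: smooth, zero iff angles equal
            _TORSION_WEIGHT * 2.0 * math.sin(math.radians(dihedral(*quad) - target) / 2.0)
            for target, quad in zip(targets, quads_of(pts))
        ]
        for k, ideal in enumerate(bonds):
            res.append(np.linalg.norm(pts[(k + 1) % 5] - pts[k]) - ideal)
        return res

    # initial guess: NeRF chain with ideal lengths/angles and target nu1, nu2
    o4 = np.zeros(3)
    c1 = np.array([bonds[0], 0.0, 0.0])
    c2 = place_atom([2.0, 1.0, 0.0], o4, c1, bonds[1], 106.0, 180.0)
    if c2[1] < 0:
        c2[1] = -c2[1]
    c2[2] = 0.0
    c3 = place_atom(o4, c1, c2, bonds[2], 102.0, targets[1])
    c4 = place_atom(c1, c2, c3, bonds[3], 102.0, targets[2])
    x0 = np.concatenate([[c1[0], c2[0], c2[1]], c3, c4])
    sol = least_squares(
        residuals, x0, method="lm", xtol=3e-16, ftol=3e-16, gtol=3e-16, max_nfev=4000
    )
    pts = unpack(sol.x)
    torsion_err = max(
        abs((dihedral(*quad) - target + 180.0) % 360.0 - 180.0)
        for target, quad in zip(targets, quads_of(pts))
    )
    if torsion_err > 1e-5:
        raise FixtureSpecError(
            f"ring closure failed for P={phase_deg}, nu_max={amplitude_deg} "
            f"(torsion error {torsion_err:.2e} deg)"
        )
    names = ("O4'", "C1'", "C2'", "C3'", "C4'")
    return tuple((nm, tuple(map(float, p))) for nm, p in zip(names, pts))


def _attach_base(atoms: dict[str, np.ndarray], base: str, chi_deg: float) -> None:
    """Attach a planar base ring at C1' with the requested glycosidic chi."""
    o4, c1, c2 = atoms["O4'"], atoms["C1'"], atoms["C2'"]
    purine = base in "AG"
    n_gly = place_atom(atoms["C4'"], o4, c1, 1.48, 108.0, 240.0)
    if purine:
        atoms["N9"] = n_gly
        atoms["C4"] = place_atom(o4, c1, n_gly, 1.37, 127.0, chi_deg)
        atoms["C8"] = place_atom(o4, c1, n_gly, 1.37, 127.0, chi_deg + 180.0)
        atoms["N7"] = place_atom(atoms["C4"], n_gly, atoms["C8"], 1.31, 113.0, 0.0)
        atoms["C5"] = place_atom(atoms["C8"], n_gly, atoms["C4"], 1.38, 106.0, 0.0)
        atoms["N3"] = place_atom(atoms["C8"], n_gly, atoms["C4"], 1.35, 127.0, 180.0)
        atoms["C2"] = place_atom(n_gly, atoms["C4"], atoms["N3"], 1.33, 111.0, 180.0)
        atoms["N1"] = place_atom(atoms["C4"], atoms["N3"], atoms["C2"], 1.35, 129.0, 0.0)
        atoms["C6"] = place_atom(atoms["N3"], atoms["C4"], atoms["C5"], 1.41, 132.0, 180.0)
    else:
        atoms["N1"] = n_gly
        atoms["C2"] = place_atom(o4, c1, n_gly, 1.40, 120.0, chi_deg)
        atoms["C6"] = place_atom(o4, c1, n_gly, 1.37, 121.0, chi_deg + 180.0)
        atoms["N3"] = place_atom(atoms["C6"], n_gly, atoms["C2"], 1.36, 119.0, 180.0)
        atoms["C5"] = place_atom(atoms["C2"], n_gly, atoms["C6"], 1.34, 121.0, 180.0)
        atoms["C4"] = place_atom(n_gly, atoms["C2"], atoms["N3"], 1.34, 120.0, 0.0)
    del c2  # frame only


def _template_residue(spec: HelixSpec, base: str) -> dict[str, np.ndarray]:
    atoms = dict(_build_ring(spec.pucker_phase_deg, spec.pucker_amplitude_deg))
    c2, c3, c4, o4, c1 = (atoms[k] for k in ("C2'", "C3'", "C4'", "O4'", "C1'"))
    atoms["C5'"] = place_atom(c2, c3, c4, 1.51, 116.0, 240.0)
    atoms["O3'"] = place_atom(atoms["C5'"], c4, c3, 1.42, 110.0, 81.0)
    atoms["O5'"] = place_atom(c3, c4, atoms["C5'"], 1.44, 111.0, 54.0)
    atoms["P"] = place_atom(c4, atoms["C5'"], atoms["O5'"], 1.60, 121.0, 172.0)
    _attach_base(atoms, base, spec.chi_deg)
    del o4, c1
    return atoms


def _rotation_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_helix_chain(
    spec: HelixSpec,
    structure_id: str = "1FIX",
    chain_id: str = "A",
    resolution: float | None = 2.5,
    release_date: str | None = "2020-01-01",
    unresolved: frozenset[int] | set[int] = frozenset(),
    include_5p_phosphate: bool = False,
    auth_offset: int = 0,
) -> RnaChain:
    """Build the in-memory helix chain (see :func:`make_helix_mmcif`)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    templates = {b: _template_residue(spec, b) for b in sorted(set(spec.sequence))}
    residues = []
    for i, base in enumerate(spec.sequence):
        if (i + 1) in unresolved:
            residues.append(
                Residue(
                    index=i + 1,
                    auth_label=str(i + 1 + auth_offset),
                    nt_code="-",
                    is_modified=False,
                    parent_base=base,
                    atoms={},
                    comp_id=base,
                )
            )
            continue
        rot = _rotation_z(i * spec.twist_per_residue)
        shift = np.array([0.0, 0.0, i * spec.rise_per_residue])
        atoms = {}
        for name, xyz in templates[base].items():
            if name == "P" and i == 0 and not include_5p_phosphate:
                continue
            pos = rot @ xyz + shift
            if spec.coordinate_noise_sd > 0:
                pos = pos + rng.normal(0.0, spec.coordinate_noise_sd, 3)
            atoms[name] = pos
        residues.append(
            Residue(
                index=i + 1,
                auth_label=str(i + 1 + auth_offset),
                nt_code=base,
                is_modified=False,
                parent_base=base,
                atoms=atoms,
                comp_id=base,
            )
        )
    return RnaChain(
        structure_id=structure_id,
        chain_id=chain_id,
        residues=residues,
        resolution=resolution,
        release_date=release_date,
    )


def _free_gtp(reference: RnaChain) -> Residue:
    """A free (unlinked) GTP placed well away from the chain."""
    far = np.array([50.0, 50.0, 50.0])
    atoms = {
        name: far + off
        for name, off in {
            "P": np.array([0.0, 0.0, 0.0]),
            "O5'": np.array([1.4, 0.5, 0.0]),
            "C5'": np.array([2.5, 1.2, 0.3]),
            "C4'": np.array([3.8, 0.6, 0.1]),
            "C1'": np.array([5.6, 1.5, 0.4]),
            "N9": np.array([6.9, 0.9, 0.2]),
        }.items()
    }
    return Residue(
        index=len(reference.residues) + 1,
        auth_label="200",
        nt_code="N",
        is_modified=True,
        parent_base="N",
        atoms=atoms,
        comp_id="GTP",
        hetero=True,
    )


def make_helix_mmcif(
    spec: HelixSpec,
    out_path,
    with_ligand: bool = False,
    **chain_kwargs,
) -> RnaChain:
    """Write an idealized helix as mmCIF and return the in-memory chain.

    The riboses realize the requested pseudorotation (phase, amplitude)
    exactly; residues are related by exact helical symmetry (before optional
    Gaussian coordinate noise).  ``with_ligand`` appends a free GTP entity
    marked HETATM, which normalization must strip.  Keyword arguments are
    forwarded to :func:`make_helix_chain` (``unresolved``,
    ``include_5p_phosphate``, ``auth_offset``, ids, resolution, date).
    """
    chain = make_helix_chain(spec, **chain_kwargs)
    extra = [_free_gtp(chain)] if with_ligand else None
    write_mmcif(chain, out_path, extra_residues=extra)
    return chain


# ---------------------------------------------------------------------------
# toy alignments

def make_toy_alignment(
    spec: ToyMsaSpec,
    chain_sequence: str,
    out_path,
    chain_name: str = "1FIX_A",
):
    """Write a toy MSA (Stockholm + aligned FASTA) including the chain row.

    ``chain_sequence`` must have one symbol per consensus column (bases or
    '-' for unresolved positions).  Homolog rows are derived from the
    consensus by per-column substitution ('-' never) and deletion ('-'),
    plus per-slot insertions; insertion columns carry the inserted base in
    the inserting row and '.' padding everywhere else, including the chain
    row.  Returns a Biopython ``MultipleSeqAlignment``.  ``out_path`` is
    used as a stem: ``<stem>.stk`` and ``<stem>.fasta`` are written.
    """
    spec.validate()
    if len(chain_sequence) != len(spec.consensus):
        raise FixtureSpecError(
            "chain_sequence must have one symbol per consensus column"
        )
    if any(c not in BASES + "-" for c in chain_sequence):
        raise FixtureSpecError("chain_sequence must be over {A,C,G,U,-}")
    rng = np.random.default_rng(spec.seed)
    m = len(spec.consensus)

    core_rows = []
    for _ in range(spec.n_sequences):
        row = []
        for base in spec.consensus:
            if rng.random() < spec.deletion_rate:
                row.append("-")
            elif rng.random() < spec.substitution_rate:
                row.append(rng.choice([b for b in BASES if b != base]))
            else:
                row.append(base)
        core_rows.append(row)

    # insertions live in m+1 slots between consensus columns
    inserts = [
        [s for s in range(spec.n_sequences) if rng.random() < spec.insertion_rate]
        for _ in range(m + 1)
    ]
    insert_bases = {
        (slot, s): str(rng.choice(list(BASES)))
        for slot, rows in enumerate(inserts)
        for s in rows
    }

    def expanded(core: str, row_id: int | None) -> str:
        """Interleave a core row with insertion columns; row_id None = chain row."""
        out = []
        for slot in range(m + 1):
            for s in inserts[slot]:
                out.append(insert_bases[(slot, s)] if s == row_id else ".")
            if slot < m:
                out.append(core[slot])
        return "".join(out)

    aligned_rows = [
        expanded("".join(row), row_id) for row_id, row in enumerate(core_rows)
    ]
    chain_row = expanded(chain_sequence, None)

    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(chain_row), id=chain_name, description="")]
    records += [
        SeqRecord(Seq(r), id=f"homolog{k + 1}", description="")
        for k, r in enumerate(aligned_rows)
    ]
    aln = MultipleSeqAlignment(records)

    from Bio import AlignIO

    stem = Path(out_path)
    stem = stem.with_suffix("") if stem.suffix in {".stk", ".sto", ".fasta", ".fa"} else stem
    AlignIO.write(aln, str(stem) + ".stk", "stockholm")
    AlignIO.write(aln, str(stem) + ".fasta", "fasta")
    return aln


# ---------------------------------------------------------------------------
# selection tables

def make_selection_tables(
    n_chains: int,
    n_classes: int,
    n_families: int,
    seed: int = 0,
    chain_length: int = 40,
) -> SelectionTables:
    """Synthetic chain list, equivalence classes and family mappings.

    Chains are partitioned round-robin into ``n_classes`` classes; each
    class is assigned a family (round-robin over ``n_families``) and only
    its first member receives the direct mapping, so the remaining members
    are reachable only through class propagation.  ``n_families = 0`` emits
    no mappings at all.  Resolutions are drawn uniformly from (0, 6].
    """
    if not n_chains >= n_classes >= 1:
        raise FixtureSpecError("need n_chains >= n_classes >= 1")
    rng = np.random.default_rng(seed)
    chains = []
    for k in range(n_chains):
        sid = f"9F{k // 26}{chr(ord('A') + k % 26)}"
        resolution = float(np.round(6.0 - rng.uniform(0.0, 6.0), 2))
        chains.append(ChainEntry(sid, "A", resolution or 6.0))
    classes = [[] for _ in range(n_classes)]
    for k, ch in enumerate(chains):
        classes[k % n_classes].append((ch.structure_id, ch.chain_id))
    mappings = []
    if n_families > 0:
        for ci, members in enumerate(classes):
            fam = f"RF{(ci % n_families) + 1:05d}"
            sid, cid = members[0]
            start = 1
            end = int(rng.integers(chain_length // 2, chain_length + 1))
            mappings.append(FamilyMapping(sid, cid, fam, start, end))
    return SelectionTables(chains=chains, classes=classes, mappings=mappings)
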