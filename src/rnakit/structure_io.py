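"""Reading, normalizing and writing RNA chains from mmCIF coordinate files.

Real-world mmCIF files number nucleotides with letters, negative numbers,
offsets of a thousand and other author conventions, carry crystallized
ligands, ions and waters alongside the polymer, and leave unresolved
residues implicit in the polymer sequence record.  This module extracts RNA
chains from such files and normalizes them into a uniform in-memory
representation: residues renumbered 1..L in polymer order, original author
labels preserved, ligands removed, modified nucleotides folded onto their
parent base, and unresolved polymer positions materialized as explicit gap
residues.

CIF tokenization is delegated to Biopython's ``MMCIF2Dict``; the chain
extraction and normalization semantics are this module's own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB.MMCIF2Dict import MMCIF2Dict

logger = logging.getLogger(__name__)

STANDARD_BASES = {"A", "C", "G", "U"}

#: Parent-base table for modified ribonucleotides, keyed by chemical component
#: identifier.  Entries follow the wwPDB Chemical Component Dictionary field
#: ``_chem_comp.mon_nstd_parent_comp_id`` for these components; the table is
#: intentionally small (common RNA modifications) and is a fallback chain of
#: its own, not a copy of any annotation tool's internal list.  Unknown
#: nucleotide-like components map to parent ``N``.
MODIFIED_NT_PARENT = {
    "PSU": "U",  # pseudouridine
    "H2U": "U",  # 5,6-dihydrouridine
    "4SU": "U",  # 4-thiouridine
    "5MU": "U",  # ribothymidine
    "OMU": "U",  # 2'-O-methyluridine
    "UR3": "U",  # 3-methyluridine
    "5MC": "C",  # 5-methylcytidine
    "OMC": "C",  # 2'-O-methylcytidine
    "4OC": "C",  # N4,2'-O-dimethylcytidine
    "1MA": "A",  # 1-methyladenosine
    "MIA": "A",  # 2-methylthio-N6-isopentenyladenosine
    "T6A": "A",  # N6-threonylcarbamoyladenosine
    "MA6": "A",  # N6,N6-dimethyladenosine
    "RIA": "A",  # 2'-O-ribosyladenosine
    "A2M": "A",  # 2'-O-methyladenosine
    "1MG": "G",  # 1-methylguanosine
    "2MG": "G",  # N2-methylguanosine
    "M2G": "G",  # N2,N2-dimethylguanosine
    "7MG": "G",  # 7-methylguanosine
    "OMG": "G",  # 2'-O-methylguanosine
    "YYG": "G",  # wybutosine
    "QUO": "G",  # queuosine
    "I": "G",    # inosine (reads as G in pairing context)
}

#: Solvent and monoatomic-ion components never treated as residues.
WATERS_AND_IONS = {
    "HOH", "DOD", "NA", "K", "MG", "CA", "ZN", "MN", "CL", "BR", "IOD",
    "CS", "SR", "BA", "CD", "NI", "CO", "FE", "FE2", "CU", "LI", "RB", "F",
}

#: Distance below which O3'(i-1)..P(i) counts as a covalent backbone linkage.
LINKAGE_CUTOFF = 2.2  # Angstrom


class MmcifParseError(ValueError):
    """Raised when an mmCIF file cannot be read or lacks atom records."""


class DuplicateAuthLabelError(ValueError):
    """Raised when two residues of one chain share the same author label."""


@dataclass
class Residue:
    """One polymer position of an RNA chain.

    ``index`` is the normalized 1-based position; ``auth_label`` preserves the
    original author numbering (may contain letters, negative numbers, icodes).
    Unresolved positions have no atoms and carry ``nt_code`` '-'.  Modified
    nucleotides carry the lowercase parent base as ``nt_code``.
    """

    index: int
    auth_label: str
    nt_code: str
    is_modified: bool
    parent_base: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    comp_id: str = ""
    hetero: bool = False

    @property
    def resolved(self) -> bool:
        return bool(self.atoms)

    def validate(self) -> None:
        """Enforce the gap/resolution consistency invariant."""
        if self.resolved and self.nt_code == "-":
            raise ValueError("resolved residue cannot carry gap nt_code")
        if not self.resolved and self.nt_code != "-":
            raise ValueError("unresolved residue must carry nt_code '-'")
        if self.is_modified and self.parent_base not in set("ACGUN"):
            raise ValueError("modified residue must carry an assigned parent base")


@dataclass
class RnaChain:
    """An extracted, renumbered RNA chain with provenance metadata."""

    structure_id: str
    chain_id: str
    residues: list[Residue]
    resolution: float | None = None
    release_date: str | None = None
    mapping: tuple[str, tuple[int, int]] | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """Gapped one-letter sequence; '-' marks unresolved positions."""
        return "".join(r.nt_code for r in self.residues)


def map_modified_base(component_id: str) -> tuple[str, bool]:
    """Map a chemical component id to ``(parent_base, is_modified)``.

    Standard A/C/G/U map to themselves unmodified; known modified
    ribonucleotides map to their parent; anything else nucleotide-like maps
    to ``('N', True)``.
    """
    if not component_id:
        raise ValueError("empty component identifier")
    comp = component_id.strip().upper()
    if comp in STANDARD_BASES:
        return comp, False
    if comp in MODIFIED_NT_PARENT:
        return MODIFIED_NT_PARENT[comp], True
    return "N", True


def _nt_code(parent: str, modified: bool) -> str:
    if parent == "N":
        return "N"
    return parent.lower() if modified else parent


def _as_list(block: dict, key: str, n: int) -> list[str]:
    val = block.get(key)
    if val is None:
        return ["."] * n
    if isinstance(val, str):
        return [val]
    return list(val)


def _get_float(block: dict, key: str) -> float | None:
    val = block.get(key)
    if isinstance(val, list):
        val = val[0] if val else None
    if val in (None, ".", "?"):
        return None
    try:
        return float(val)
    except ValueError:
        return None


def _get_str(block: dict, key: str) -> str | None:
    val = block.get(key)
    if isinstance(val, list):
        val = val[0] if val else None
    if val in (None, ".", "?"):
        return None
    return str(val)


def parse_mmcif(path, chains: list[str] | None = None) -> list[RnaChain]:
    """Parse an mmCIF file into normalized :class:`RnaChain` objects.

    Returns one chain per polymer chain containing at least one
    ribonucleotide.  Waters and ions never appear as residues; ligands are
    stripped; unresolved polymer positions declared by ``entity_poly_seq``
    are materialized as gap residues; numbering is normalized to 1..L.
    Chains with zero nucleotides are skipped with a warning.  Only the first
    model and the first-listed alternate location are kept.
    """
    try:
        block = MMCIF2Dict(str(path))
    except Exception as exc:  # pragma: no cover - Biopython raises various types
        raise MmcifParseError(f"cannot parse mmCIF file {path}: {exc}") from exc
    if "_atom_site.id" not in block:
        raise MmcifParseError(f"no atom_site records in {path}")

    structure_id = str(block.get("data_", "UNKN")).upper()[:4] or "UNKN"
    resolution = _get_float(block, "_refine.ls_d_res_high")
    if resolution is None:
        resolution = _get_float(block, "_em_3d_reconstruction.resolution")
    release_date = _get_str(block, "_pdbx_audit_revision_history.revision_date")
    if release_date is None:
        release_date = _get_str(block, "_pdbx_database_status.recvd_initial_deposition_date")

    n = len(block["_atom_site.id"])
    group = _as_list(block, "_atom_site.group_PDB", n)
    atom_id = _as_list(block, "_atom_site.label_atom_id", n)
    comp_id = _as_list(block, "_atom_site.label_comp_id", n)
    asym_id = _as_list(block, "_atom_site.label_asym_id", n)
    seq_id = _as_list(block, "_atom_site.label_seq_id", n)
    auth_seq = _as_list(block, "_atom_site.auth_seq_id", n)
    icode = _as_list(block, "_atom_site.pdbx_PDB_ins_code", n)
    altloc = _as_list(block, "_atom_site.label_alt_id", n)
    model = _as_list(block, "_atom_site.pdbx_PDB_model_num", n)
    xs = [float(v) for v in block["_atom_site.Cartn_x"]]
    ys = [float(v) for v in block["_atom_site.Cartn_y"]]
    zs = [float(v) for v in block["_atom_site.Cartn_z"]]

    first_model = next((m for m in model if m not in (".", "?")), ".")

    # group atoms into residues, per chain, in file order
    per_chain: dict[str, list[Residue]] = {}
    per_chain_seq_ids: dict[str, list[tuple[str, int | None]]] = {}
    current_key = None
    for i in range(n):
        if model[i] not in (".", "?") and model[i] != first_model:
            continue
        comp = comp_id[i].strip().upper()
        if comp in WATERS_AND_IONS:
            continue
        cid = asym_id[i]
        if chains is not None and cid not in chains:
            continue
        label = auth_seq[i] + (icode[i] if icode[i] not in (".", "?") else "")
        key = (cid, label, comp)
        residues = per_chain.setdefault(cid, [])
        seq_ids = per_chain_seq_ids.setdefault(cid, [])
        if key != current_key:
            parent, modified = map_modified_base(comp)
            residues.append(
                Residue(
                    index=len(residues) + 1,
                    auth_label=label,
                    nt_code=_nt_code(parent, modified),
                    is_modified=modified,
                    parent_base=parent,
                    atoms={},
                    comp_id=comp,
                    hetero=group[i].upper() == "HETATM",
                )
            )
            sid = seq_id[i]
            seq_ids.append((label, int(sid) if sid not in (".", "?") else None))
            current_key = key
        res = residues[-1]
        name = atom_id[i].strip().strip('"')
        if name in res.atoms:
            continue  # first-listed altloc wins
        res.atoms[name] = np.array([xs[i], ys[i], zs[i]], dtype=float)

    poly_seq = _entity_poly_seq(block)

    out: list[RnaChain] = []
    for cid, residues in per_chain.items():
        residues = strip_ligands_list(residues)
        if not any(r.parent_base in STANDARD_BASES or r.parent_base == "N" for r in residues):
            logger.warning(
                "chain %s of %s contains no nucleotides, skipped", cid, structure_id
            )
            continue
        if poly_seq.get(cid):
            label_to_seq = dict(per_chain_seq_ids[cid])
            residues = _materialize_unresolved(residues, label_to_seq, poly_seq[cid])
        chain = RnaChain(
            structure_id=structure_id,
            chain_id=cid,
            residues=residues,
            resolution=resolution,
            release_date=release_date,
        )
        out.append(normalize_numbering(chain))
    if not out:
        logger.warning("no RNA chains found in %s", path)
    return out


def _entity_poly_seq(block: dict) -> dict[str, list[tuple[int, str]]]:
    """Full polymer sequence per label_asym_id, from entity_poly_seq."""
    if "_entity_poly_seq.entity_id" not in block:
        return {}
    ent = _as_list(block, "_entity_poly_seq.entity_id", 0)
    num = _as_list(block, "_entity_poly_seq.num", len(ent))
    mon = _as_list(block, "_entity_poly_seq.mon_id", len(ent))
    by_entity: dict[str, list[tuple[int, str]]] = {}
    for e, nm, m in zip(ent, num, mon):
        by_entity.setdefault(e, []).append((int(nm), m.strip().upper()))
    asym = _as_list(block, "_struct_asym.id", 0)
    asym_ent = _as_list(block, "_struct_asym.entity_id", len(asym))
    return {a: by_entity.get(e, []) for a, e in zip(asym, asym_ent)}


def _materialize_unresolved(
    residues: list[Residue],
    label_to_seq: dict[str, int | None],
    poly: list[tuple[int, str]],
) -> list[Residue]:
    """Insert gap residues for polymer positions with no observed atoms.

    Requires observed residues to carry ``label_seq_id`` values (mapped here
    via their author labels); files without them are returned unchanged --
    author-numbering gaps alone never create unresolved residues.
    """
    seen_nums = {label_to_seq.get(r.auth_label) for r in residues}
    if None in seen_nums:
        return residues
    merged: list[Residue] = []
    res_iter = iter(residues)
    pending = next(res_iter, None)
    for nm, mon in poly:
        if nm in seen_nums:
            if pending is not None:
                merged.append(pending)
                pending = next(res_iter, None)
        else:
            parent, modified = map_modified_base(mon)
            merged.append(
                Residue(
                    index=0,
                    auth_label=f"?{nm}",
                    nt_code="-",
                    is_modified=modified,
                    parent_base=parent,
                    atoms={},
                    comp_id=mon,
                )
            )
    while pending is not None:  # observed residues absent from the polymer record
        merged.append(pending)
        pending = next(res_iter, None)
    return merged


def normalize_numbering(chain: RnaChain) -> RnaChain:
    """Rewrite residue indices to 1..L in polymer order; idempotent.

    Original author labels are retained.  Duplicate identical author labels
    within one chain raise :class:`DuplicateAuthLabelError`.
    """
    labels = [r.auth_label for r in chain.residues]
    dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
    if dupes:
        raise DuplicateAuthLabelError(
            f"duplicate auth labels in {chain.structure_id}:{chain.chain_id}: {dupes}"
        )
    renumbered = [replace(r, index=i + 1) for i, r in enumerate(chain.residues)]
    return replace(chain, residues=renumbered)


def _has_linkage(res: Residue, prev: Residue | None, nxt: Residue | None) -> bool:
    """True when res is covalently linked into the backbone of a neighbor."""
    p = res.atoms.get("P")
    if p is not None and prev is not None:
        o3 = prev.atoms.get("O3'")
        if o3 is not None and np.linalg.norm(p - o3) <= LINKAGE_CUTOFF:
            return True
    o3 = res.atoms.get("O3'")
    if o3 is not None and nxt is not None:
        pn = nxt.atoms.get("P")
        if pn is not None and np.linalg.norm(o3 - pn) <= LINKAGE_CUTOFF:
            return True
    return False


def _is_ligand(res: Residue, prev: Residue | None, nxt: Residue | None) -> bool:
    # Residues whose component id is a recognized (modified) ribonucleotide
    # are always kept.  An unrecognized component is kept only when it both
    # looks like a nucleotide (has C1') and is wired into the chain backbone.
    comp = res.comp_id
    if comp in STANDARD_BASES or comp in MODIFIED_NT_PARENT:
        return False
    if not res.resolved:
        return False
    has_c1 = "C1'" in res.atoms
    return not (has_c1 and _has_linkage(res, prev, nxt))


def strip_ligands_list(residues: list[Residue]) -> list[Residue]:
    out = []
    for i, res in enumerate(residues):
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        if _is_ligand(res, prev, nxt):
            logger.info("removed ligand %s (%s)", res.comp_id, res.auth_label)
        else:
            out.append(res)
    return out


def strip_ligands(chain: RnaChain) -> RnaChain:
    """Remove crystallized ligands misread as chain residues.

    A residue is a ligand when its component id is not a recognized
    (modified) ribonucleotide and it is not simultaneously C1'-bearing and
    backbone-linked to a neighbor.  Removals are logged.
    """
    return replace(chain, residues=strip_ligands_list(list(chain.residues)))


# ---------------------------------------------------------------------------
# writing

_MMCIF_HEADER = """\
data_{sid}
#
_pdbx_database_status.recvd_initial_deposition_date {date}
_refine.ls_d_res_high {res}
#
"""

_ATOM_SITE_LOOP = """\
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.label_atom_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.auth_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
"""


def write_mmcif(chain: RnaChain, path, extra_residues: list[Residue] | None = None) -> None:
    """Write a chain as a minimal, syntactically valid mmCIF file.

    Emits the atom_site loop plus entity_poly_seq/struct_asym records
    declaring the full polymer sequence (so unresolved residues survive a
    round-trip).  ``extra_residues`` are appended verbatim after the polymer
    (used by fixtures to plant ligands); they are not declared in
    entity_poly_seq.
    """
    lines = [
        _MMCIF_HEADER.format(
            sid=chain.structure_id,
            date=chain.release_date or "?",
            res="?" if chain.resolution is None else f"{chain.resolution:.2f}",
        )
    ]
    lines.append("loop_\n_struct_asym.id\n_struct_asym.entity_id\n")
    lines.append(f"{chain.chain_id} 1\n#\n")
    lines.append("loop_\n_entity_poly_seq.entity_id\n_entity_poly_seq.num\n_entity_poly_seq.mon_id\n")
    for res in chain.residues:
        lines.append(f"1 {res.index} {res.comp_id or res.parent_base}\n")
    lines.append("#\n")
    lines.append(_ATOM_SITE_LOOP)
    serial = 1
    for res in chain.residues:
        for name, xyz in res.atoms.items():
            atom = f'"{name}"' if "'" in name else name
            lines.append(
                f"ATOM {serial} {atom} {res.comp_id or res.parent_base} "
                f"{chain.chain_id} {res.index} {res.auth_label} "
                f"{xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f} 1.00\n"
            )
            serial += 1
    for res in extra_residues or []:
        for name, xyz in res.atoms.items():
            atom = f'"{name}"' if "'" in name else name
            lines.append(
                f"HETATM {serial} {atom} {res.comp_id} "
                f"{chain.chain_id} . {res.auth_label} "
                f"{xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f} 1.00\n"
            )
            serial += 1
    lines.append("#\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
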