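"""Relational assembly of the merged per-nucleotide records.

Every selected chain contributes one row per nucleotide joining three
information sources: normalized sequence/provenance fields, the geometric
descriptors, and (through the alignment column) the family PSSM.  Base-base
interaction fields (``paired``, ``pair_type``) and helix-form labels are
*ingested* from an external annotation file in a documented JSON dialect
when supplied -- they are never computed here.  The store is a single-file
SQLite database built deterministically (idempotent rebuilds produce
byte-identical dumps), and per-chain CSV exports with conjunctive
resolution / release-date / family filters round-trip losslessly, keeping
the null-vs-zero distinction.

External annotation JSON dialect::

    {
      "pairs": [{"nt1": "A.1", "nt2": "A.3", "lw": "cWW"}, ...],
      "forms": [{"nt": "A.5", "form": "A"}, ...]
    }

Nucleotides are keyed ``"<chain_id>.<normalized 1-based index>"``.  ``lw``
labels outside the 12 Leontis-Westhof families are carried under the
catch-all label ``other``.
"""

from __future__ import annotations

import json
import logging
import math
import sqlite3
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd

from .geometry import GeometricDescriptors
from .homology import ColumnProfile
from .remap import MappedPosition
from .structure_io import RnaChain

logger = logging.getLogger(__name__)

#: The 12 Leontis-Westhof base-pair families (edge pairs are unordered, so
#: e.g. cHW normalizes to cWH).
LEONTIS_WESTHOF = {
    o + e
    for o in ("c", "t")
    for e in ("WW", "WH", "WS", "HH", "HS", "SS")
}

_GEOM_FIELDS = [
    f.name
    for f in dc_fields(GeometricDescriptors)
    if f.name not in ("index", "form_label")
]

FREQ_FIELDS = ["freq_A", "freq_C", "freq_G", "freq_U", "freq_other", "gap_fraction"]


class AnnotationError(ValueError):
    """Raised for malformed external annotation files."""


class StoreIntegrityError(RuntimeError):
    """Raised when a build would violate referential integrity."""


@dataclass
class NucleotideRecord:
    """One merged per-nucleotide row (see module docstring)."""

    index: int
    auth_label: str
    nt_code: str
    nt_align_code: str
    is_modified: bool
    parent_base: str
    descriptors: GeometricDescriptors
    alignment_column: int | None = None
    homology_known: bool = False
    paired: int = 0  # partner index; 0 = none or inter-chain
    pair_type: list[str] = field(default_factory=list)
    form_label: str | None = None


def assemble_records(
    chain: RnaChain,
    descriptors: list[GeometricDescriptors],
    positions: list[MappedPosition],
) -> list[NucleotideRecord]:
    """Join residues, geometry and mapped alignment columns positionally."""
    if not (len(chain.residues) == len(descriptors) == len(positions)):
        raise ValueError("chain, descriptors and positions must have equal length")
    records = []
    for res, desc, pos in zip(chain.residues, descriptors, positions):
        if res.index != desc.index or res.index != pos.chain_index:
            raise ValueError(f"index mismatch at residue {res.index}")
        records.append(
            NucleotideRecord(
                index=res.index,
                auth_label=res.auth_label,
                nt_code=pos.nt_code,
                nt_align_code=pos.nt_align_code,
                is_modified=res.is_modified,
                parent_base=res.parent_base,
                descriptors=desc,
                alignment_column=pos.alignment_column,
                homology_known=pos.homology_known,
            )
        )
    return records


def normalize_lw(label: str) -> str:
    """Normalize a Leontis-Westhof label; anything unclassifiable -> 'other'."""
    lab = label.strip()
    if len(lab) == 3 and lab[0] in "ct":
        edges = lab[1:].upper()
        canon = "".join(sorted(edges, key="WHS".index)) if set(edges) <= set("WHS") else None
        if canon is not None and lab[0] + canon in LEONTIS_WESTHOF:
            return lab[0] + canon
    return "other"


def _parse_nt_key(key: str) -> tuple[str, int]:
    chain_id, _, idx = key.rpartition(".")
    if not chain_id:
        raise AnnotationError(f"bad nucleotide key {key!r} (want 'CHAIN.INDEX')")
    try:
        return chain_id, int(idx)
    except ValueError as exc:
        raise AnnotationError(f"bad nucleotide key {key!r}") from exc


def ingest_external_annotation(
    records: list[NucleotideRecord],
    annotation_path,
    chain_id: str,
) -> list[NucleotideRecord]:
    """Populate paired / pair_type / form_label from a DSSR-style JSON file.

    Intra-chain pairs set ``paired`` on both partners; inter-chain pairs
    leave ``paired`` at 0 but record the interaction label.  Multiple
    interactions per base accumulate in ``pair_type``.  A missing file
    (``annotation_path`` None) leaves all fields at their defaults.
    Residue keys that do not exist in the chain produce a warning and are
    skipped.
    """
    if annotation_path is None:
        return records
    try:
        with open(annotation_path) as fh:
            data = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationError(f"cannot read annotation file {annotation_path}: {exc}") from exc
    by_index = {rec.index: rec for rec in records}

    for entry in data.get("pairs", []):
        try:
            c1, i1 = _parse_nt_key(entry["nt1"])
            c2, i2 = _parse_nt_key(entry["nt2"])
            label = normalize_lw(entry["lw"])
        except (KeyError, TypeError) as exc:
            raise AnnotationError(f"malformed pair entry {entry!r}") from exc
        for cid, idx, partner_cid, partner_idx in ((c1, i1, c2, i2), (c2, i2, c1, i1)):
            if cid != chain_id:
                continue
            rec = by_index.get(idx)
            if rec is None:
                logger.warning("annotation references unknown residue %s.%s", cid, idx)
                continue
            if partner_cid == chain_id and partner_idx not in by_index:
                logger.warning(
                    "annotation references unknown residue %s.%s", partner_cid, partner_idx
                )
                continue  # field left default
            rec.pair_type.append(label)
            if partner_cid == chain_id:
                rec.paired = partner_idx  # intra-chain
            # inter-chain: paired stays 0, label recorded

    for entry in data.get("forms", []):
        try:
            cid, idx = _parse_nt_key(entry["nt"])
            form = entry["form"]
        except (KeyError, TypeError) as exc:
            raise AnnotationError(f"malformed form entry {entry!r}") from exc
        if cid != chain_id:
            continue
        rec = by_index.get(idx)
        if rec is None:
            logger.warning("annotation references unknown residue %s.%s", cid, idx)
            continue
        if form not in ("A", "B", "Z"):
            raise AnnotationError(f"unknown helix form {form!r}")
        rec.form_label = form
    return records


# ---------------------------------------------------------------------------
# SQLite store

_SCHEMA = f"""
CREATE TABLE chains (
    chain_pk INTEGER PRIMARY KEY,
    structure_id TEXT NOT NULL,
    chain_id TEXT NOT NULL,
    family TEXT,
    resolution REAL,
    release_date TEXT,
    length INTEGER NOT NULL,
    inferred INTEGER,
    UNIQUE (structure_id, chain_id, family)
);
CREATE TABLE families (
    accession TEXT PRIMARY KEY,
    n_columns INTEGER NOT NULL
);
CREATE TABLE align_columns (
    family TEXT NOT NULL REFERENCES families (accession),
    col_index INTEGER NOT NULL,
    {", ".join(f"{name} REAL NOT NULL" for name in FREQ_FIELDS)},
    consensus TEXT NOT NULL,
    depth INTEGER NOT NULL,
    PRIMARY KEY (family, col_index)
);
CREATE TABLE nucleotides (
    chain_pk INTEGER NOT NULL REFERENCES chains (chain_pk),
    idx INTEGER NOT NULL,
    auth_label TEXT NOT NULL,
    nt_code TEXT NOT NULL,
    nt_align_code TEXT NOT NULL,
    is_modified INTEGER NOT NULL,
    parent_base TEXT NOT NULL,
    {", ".join(f"{name} REAL" for name in _GEOM_FIELDS if name not in ("chi_class", "pucker_label"))},
    chi_class TEXT,
    pucker_label TEXT,
    form_label TEXT,
    paired INTEGER NOT NULL DEFAULT 0,
    pair_type TEXT,
    alignment_column INTEGER,
    PRIMARY KEY (chain_pk, idx)
);
"""

_GEOM_NUM_FIELDS = [n for n in _GEOM_FIELDS if n not in ("chi_class", "pucker_label")]

NUCLEOTIDE_COLUMNS = (
    ["idx", "auth_label", "nt_code", "nt_align_code", "is_modified", "parent_base"]
    + _GEOM_NUM_FIELDS
    + ["chi_class", "pucker_label", "form_label", "paired", "pair_type", "alignment_column"]
)


def _num_or_none(value: float) -> float | None:
    return None if value is None or (isinstance(value, float) and math.isnan(value)) else float(value)


def build_store(
    chains: list[tuple[RnaChain, list[NucleotideRecord]]],
    pssms: dict[str, list[ColumnProfile]],
    out_path,
) -> Path:
    """Write the SQLite store; deterministic and idempotent.

    ``chains`` pairs each (possibly truncated, family-tagged) chain with its
    merged records; ``pssms`` maps family accession to its column profiles.
    Chains are keyed by (structure_id, chain_id, family) so a chain copied
    into several family mappings yields several chain rows.  Rebuilding on
    unchanged inputs produces a byte-identical SQL dump.  Records whose
    alignment column does not exist for their family abort the build.
    """
    out_path = Path(out_path)
    if out_path.exists():
        out_path.unlink()
    conn = sqlite3.connect(out_path)
    try:
        conn.executescript(_SCHEMA)
        for fam in sorted(pssms):
            profiles = pssms[fam]
            conn.execute(
                "INSERT INTO families (accession, n_columns) VALUES (?, ?)",
                (fam, len(profiles)),
            )
            for i, p in enumerate(profiles, start=1):
                conn.execute(
                    "INSERT INTO align_columns VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                    (fam, i, p.freq_A, p.freq_C, p.freq_G, p.freq_U,
                     p.freq_other, p.gap_fraction, p.consensus, p.depth),
                )
        ordered = sorted(
            chains, key=lambda cr: (cr[0].structure_id, cr[0].chain_id, cr[0].mapping or ("",))
        )
        for pk, (chain, records) in enumerate(ordered, start=1):
            family = chain.mapping[0] if chain.mapping else None
            conn.execute(
                "INSERT INTO chains VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                (pk, chain.structure_id, chain.chain_id, family,
                 chain.resolution, chain.release_date, len(chain.residues), None),
            )
            for rec in records:
                if rec.alignment_column is not None:
                    if family is None or rec.alignment_column > len(pssms.get(family, [])):
                        raise StoreIntegrityError(
                            f"nucleotide {chain.structure_id}:{chain.chain_id}:{rec.index} "
                            f"references column {rec.alignment_column} missing from "
                            f"family {family!r}"
                        )
                desc = rec.descriptors
                row = [pk, rec.index, rec.auth_label, rec.nt_code, rec.nt_align_code,
                       int(rec.is_modified), rec.parent_base]
                row += [_num_or_none(getattr(desc, name)) for name in _GEOM_NUM_FIELDS]
                row += [desc.chi_class, desc.pucker_label, rec.form_label,
                        rec.paired, ",".join(rec.pair_type) or None, rec.alignment_column]
                conn.execute(
                    f"INSERT INTO nucleotides VALUES ({', '.join('?' * len(row))})", row
                )
        conn.commit()
    finally:
        conn.close()
    return out_path


def dump_store(store_path) -> str:
    """Canonical SQL dump of the store (used for idempotence checks)."""
    conn = sqlite3.connect(store_path)
    try:
        return "\n".join(conn.iterdump())
    finally:
        conn.close()


def check_integrity(store_path) -> None:
    """Raise :class:`StoreIntegrityError` on any dangling reference."""
    conn = sqlite3.connect(store_path)
    try:
        orphans = conn.execute(
            "SELECT COUNT(*) FROM nucleotides n LEFT JOIN chains c USING (chain_pk) "
            "WHERE c.chain_pk IS NULL"
        ).fetchone()[0]
        if orphans:
            raise StoreIntegrityError(f"{orphans} nucleotides reference missing chains")
        dangling = conn.execute(
            "SELECT COUNT(*) FROM nucleotides n JOIN chains c USING (chain_pk) "
            "LEFT JOIN align_columns a ON a.family = c.family "
            "AND a.col_index = n.alignment_column "
            "WHERE n.alignment_column IS NOT NULL AND a.col_index IS NULL"
        ).fetchone()[0]
        if dangling:
            raise StoreIntegrityError(
                f"{dangling} nucleotides reference missing alignment columns"
            )
    finally:
        conn.close()


EXPORT_COLUMNS = NUCLEOTIDE_COLUMNS + FREQ_FIELDS + ["consensus"]


def load_nucleotide_table(store_path) -> pd.DataFrame:
    """All nucleotides joined with chain metadata and PSSM columns."""
    conn = sqlite3.connect(store_path)
    try:
        return pd.read_sql_query(
            "SELECT c.structure_id, c.chain_id, c.family, c.resolution, "
            "c.release_date, c.inferred, n.*, "
            + ", ".join(f"a.{name}" for name in FREQ_FIELDS)
            + ", a.consensus "
            "FROM nucleotides n JOIN chains c USING (chain_pk) "
            "LEFT JOIN align_columns a ON a.family = c.family "
            "AND a.col_index = n.alignment_column "
            "ORDER BY c.chain_pk, n.idx",
            conn,
        )
    finally:
        conn.close()


def export_csv(
    store_path,
    out_dir,
    resolution_max: float | None = None,
    released_before: str | None = None,
    family: str | None = None,
) -> list[Path]:
    """One CSV per selected chain, one row per nucleotide.

    Filters compose conjunctively; ``released_before`` is a strict ISO-date
    comparison.  Nulls are written as empty strings (distinct from 0).
    Returns the written paths; an empty selection writes nothing and logs a
    notice.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conn = sqlite3.connect(store_path)
    try:
        clauses, params = ["1=1"], []
        if resolution_max is not None:
            clauses.append("c.resolution IS NOT NULL AND c.resolution <= ?")
            params.append(resolution_max)
        if released_before is not None:
            clauses.append("c.release_date IS NOT NULL AND c.release_date < ?")
            params.append(released_before)
        if family is not None:
            clauses.append("c.family = ?")
            params.append(family)
        chains = conn.execute(
            f"SELECT chain_pk, structure_id, chain_id, family FROM chains c "
            f"WHERE {' AND '.join(clauses)} ORDER BY chain_pk",
            params,
        ).fetchall()
        if not chains:
            logger.info("export filters selected no chains; nothing written")
            return []
        written = []
        for pk, sid, cid, fam in chains:
            df = pd.read_sql_query(
                "SELECT "
                + ", ".join(f"n.{name}" for name in NUCLEOTIDE_COLUMNS)
                + ", " + ", ".join(f"a.{name}" for name in FREQ_FIELDS)
                + ", a.consensus "
                "FROM nucleotides n LEFT JOIN align_columns a "
                "ON a.family = ? AND a.col_index = n.alignment_column "
                "WHERE n.chain_pk = ? ORDER BY n.idx",
                conn,
                params=(fam, pk),
            )
            name = f"{sid}_{cid}" + (f"_{fam}" if fam else "") + ".csv"
            path = out_dir / name
            df.to_csv(path, index=False, na_rep="")
            written.append(path)
        return written
    finally:
        conn.close()


def read_chain_csv(path) -> pd.DataFrame:
    """Re-import an exported per-chain CSV, restoring null/0 distinctions."""
    df = pd.read_csv(
        path,
        dtype={
            "auth_label": str, "nt_code": str, "nt_align_code": str,
            "parent_base": str, "chi_class": "object", "pucker_label": "object",
            "form_label": "object", "pair_type": "object", "consensus": "object",
        },
    )
    # alignment_column round-trips as float when nulls are present
    if "alignment_column" in df:
        df["alignment_column"] = df["alignment_column"].astype("Int64")
    return df
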