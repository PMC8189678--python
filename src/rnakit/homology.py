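"""Alignment parsing, PSSM summarization, identity matrices and clustering.

Multiple sequence alignments of family homologs arrive in Stockholm or
aligned-FASTA form with two distinct gap dialects: '-' marks a deletion
against the family consensus, '.' marks padding opposite an insertion in
another sequence.  Both symbols are preserved on parsing (the downstream
re-mapping step needs the distinction) and pooled when counting gaps for
the PSSM.  Sequence identity uses plain column counting over positions
where at least one row has a base; hierarchical clustering is Ward linkage
on 1 - identity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy.cluster.hierarchy import dendrogram, leaves_list, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

BASES = "ACGU"
GAP_SYMBOLS = {"-", "."}


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments or unknown residue symbols."""


@dataclass
class ColumnProfile:
    """One PSSM column: base frequencies, gap fraction, consensus, depth."""

    freq_A: float
    freq_C: float
    freq_G: float
    freq_U: float
    freq_other: float
    gap_fraction: float
    consensus: str
    depth: int

    def frequency(self, base: str) -> float:
        return getattr(self, f"freq_{base}")


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # square, symmetric, fractions in [0, 1]


#: IUPAC nucleotide codes accepted beyond A/C/G/U; all count as freq_other.
AMBIGUITY_CODES = set("RYSWKMBDHVNX")


def read_alignment(path, fmt: str = "stockholm"):
    """Read an MSA, preserving '-' and '.' as distinct symbols.

    ``fmt`` is ``stockholm`` or ``afasta``.  'T' is accepted and normalized
    to 'U' (DNA-alphabet inputs are common in rRNA databases) with a logged
    note; any other unknown symbol raises :class:`AlignmentFormatError`
    naming the symbol and column.  Ragged rows raise the same error.
    """
    if fmt == "stockholm":
        # Biopython's Stockholm reader folds '.' into '-', erasing the
        # deletion-vs-insertion distinction the re-mapping step depends on,
        # so Stockholm is tokenized here (writing still goes via AlignIO).
        aln = _read_stockholm_verbatim(path)
    elif fmt in ("afasta", "fasta"):
        try:
            aln = AlignIO.read(str(path), "fasta")
        except ValueError as exc:
            raise AlignmentFormatError(f"cannot read {path} as {fmt}: {exc}") from exc
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")

    cleaned = []
    saw_t = False
    width = aln.get_alignment_length()
    for rec in aln:
        row = str(rec.seq)
        if len(row) != width:
            raise AlignmentFormatError(f"ragged row {rec.id!r}")
        chars = []
        for col, ch in enumerate(row):
            up = ch.upper()
            if up == "T":
                saw_t = True
                ch = "U" if ch.isupper() else "u"
            elif ch not in GAP_SYMBOLS and up not in BASES and up not in AMBIGUITY_CODES:
                raise AlignmentFormatError(
                    f"unknown symbol {ch!r} at column {col + 1} of row {rec.id!r}"
                )
            chars.append(ch)
        rec = rec[:]
        rec.seq = type(rec.seq)("".join(chars))
        cleaned.append(rec)
    if saw_t:
        logger.info("normalized DNA-alphabet 'T' symbols to 'U' in %s", path)
    from Bio.Align import MultipleSeqAlignment

    return MultipleSeqAlignment(cleaned)


def _read_stockholm_verbatim(path):
    """Minimal Stockholm 1.0 reader preserving gap symbols verbatim.

    Handles interleaved blocks; markup (#=GF/#=GC/#=GS/#=GR) is skipped.
    """
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rows: dict[str, list[str]] = {}
    order: list[str] = []
    saw_header = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# STOCKHOLM"):
                saw_header = True
                continue
            if not line.strip() or line.startswith("#"):
                continue
            if line.strip() == "//":
                break
            parts = line.split()
            if len(parts) != 2:
                raise AlignmentFormatError(f"unparseable Stockholm line {line!r}")
            name, chunk = parts
            if name not in rows:
                rows[name] = []
                order.append(name)
            rows[name].append(chunk)
    if not saw_header or not rows:
        raise AlignmentFormatError(f"{path} is not a Stockholm 1.0 alignment")
    records = [
        SeqRecord(Seq("".join(rows[name])), id=name, description="") for name in order
    ]
    widths = {len(rec.seq) for rec in records}
    if len(widths) != 1:
        raise AlignmentFormatError("ragged rows in Stockholm alignment")
    return MultipleSeqAlignment(records)


def _fold_case(ch: str) -> str:
    """Uppercase bases after gap-dialect handling (lowercase = insertion state)."""
    return ch if ch in GAP_SYMBOLS else ch.upper()


def compute_pssm(alignment) -> list[ColumnProfile]:
    """Per-column base frequencies over the alignment (plain counts).

    Both gap dialects pool into ``gap_fraction``; ambiguity and modified
    codes count as ``freq_other``.  Consensus is the maximal-frequency base
    (alphabetical tie-break A < C < G < U), '-' when gaps outnumber every
    base, or 'N' when the 'other' bucket does.
    """
    n = len(alignment)
    if n == 0:
        raise AlignmentFormatError("empty alignment")
    width = alignment.get_alignment_length()
    profiles = []
    for col in range(width):
        counts = {b: 0 for b in BASES}
        gaps = 0
        other = 0
        for rec in alignment:
            ch = _fold_case(str(rec.seq[col]))
            if ch in GAP_SYMBOLS:
                gaps += 1
            elif ch in counts:
                counts[ch] += 1
            else:
                other += 1
        freqs = {b: counts[b] / n for b in BASES}
        gap_fraction = gaps / n
        other_frac = other / n
        best = max(BASES, key=lambda b: (freqs[b], -ord(b)))
        if gap_fraction > freqs[best]:
            consensus = "-"
        elif other_frac > freqs[best]:
            consensus = "N"
        else:
            consensus = best
        profiles.append(
            ColumnProfile(
                freq_A=freqs["A"],
                freq_C=freqs["C"],
                freq_G=freqs["G"],
                freq_U=freqs["U"],
                freq_other=other_frac,
                gap_fraction=gap_fraction,
                consensus=consensus,
                depth=n,
            )
        )
    return profiles


def pssm_to_frame(profiles: list[ColumnProfile]) -> pd.DataFrame:
    """PSSM as a DataFrame, one row per column (1-based ``column`` index)."""
    return pd.DataFrame(
        [
            {
                "column": i + 1,
                "freq_A": p.freq_A,
                "freq_C": p.freq_C,
                "freq_G": p.freq_G,
                "freq_U": p.freq_U,
                "freq_other": p.freq_other,
                "gap_fraction": p.gap_fraction,
                "consensus": p.consensus,
                "depth": p.depth,
            }
            for i, p in enumerate(profiles)
        ]
    )


def sequence_identity(row_i: str, row_j: str) -> float:
    """Fraction of identical-base columns among columns scored.

    A column is scored when at least one of the two rows has a base;
    columns gapped in both rows are ignored.  Rows that are all-gap in
    every scored sense yield NaN.  Case-insensitive; both gap dialects
    equivalent here.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows must have equal aligned length")
    scored = 0
    matches = 0
    for a, b in zip(row_i, row_j):
        a_gap = a in GAP_SYMBOLS
        b_gap = b in GAP_SYMBOLS
        if a_gap and b_gap:
            continue
        scored += 1
        if not a_gap and not b_gap and a.upper() == b.upper():
            matches += 1
    if scored == 0:
        return math.nan
    return matches / scored


def identity_matrix(alignment, labels: list[str] | None = None) -> IdentityMatrix:
    """Pairwise identity over all alignment rows; symmetric, unit diagonal."""
    rows = [str(rec.seq) for rec in alignment]
    if labels is None:
        labels = [rec.id for rec in alignment]
    n = len(rows)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = sequence_identity(rows[i], rows[j])
    return IdentityMatrix(labels=labels, values=values)


def cluster_chains(matrix: IdentityMatrix):
    """Ward hierarchical clustering on distance 1 - identity.

    Returns ``(linkage_matrix, leaf_order)``; requires >= 2 chains (families
    with fewer chains are not plotted).  Deterministic given the input.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("clustering requires at least 2 chains")
    dist = 1.0 - np.asarray(matrix.values, dtype=float)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = linkage(condensed, method="ward")
    order = list(leaves_list(link))
    return link, order


def identity_to_frame(matrix: IdentityMatrix) -> pd.DataFrame:
    return pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)


def dendrogram_dict(link) -> dict:
    """scipy dendrogram structure without rendering (for downstream plots)."""
    return dendrogram(link, no_plot=True)
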