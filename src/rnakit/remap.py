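"""Reconciling the gapped 3D chain sequence with its aligned row.

After realignment, one chain is described by two gapped strings that share
the same underlying resolved sequence: the 3D-side sequence (bases plus '-'
for unresolved residues) and the alignment row (bases plus '-' deletion
gaps and '.' insertion padding).  The merge walks both with two pointers:

1. Matching symbols (same base, or '-' facing '-') pair up; both advance.
2. A 3D '-' facing anything else searches ahead in the alignment for the
   next '-' before the next base (skipping '.'); failing that, for the next
   '.' before the next base; failing both, the residue is emitted with
   unknown homology (all profile fields null).  A matched gap column is
   consumed, so no column pairs twice.
3. An alignment gap facing a 3D base skips the alignment column.
4. Two differing bases are a hard error -- by construction it can only
   happen when the two inputs do not share a resolved sequence, which is
   validated up front.

Unresolved residues paired to an alignment column can optionally take the
column's consensus base in a secondary sequence field (``nt_align_code``);
the primary ``nt_code`` keeps its '-'.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .homology import ColumnProfile

GAPS_3D = {"-"}
GAPS_ALN = {"-", "."}


class MappingError(ValueError):
    """The two gapped sequences do not describe the same resolved chain."""


@dataclass(frozen=True)
class MappedPosition:
    """One chain residue joined to one alignment column (or to none)."""

    chain_index: int  # 1-based residue index
    alignment_column: int | None  # 1-based column index; None = unknown homology
    nt_code: str  # residue symbol, may be '-'
    nt_align_code: str  # consensus-filled variant of nt_code
    homology_known: bool

    def __post_init__(self):
        if not self.homology_known and self.alignment_column is not None:
            raise ValueError("unknown homology implies no alignment column")


def _fold(ch: str) -> str:
    """Case-fold a base symbol (modified bases are lowercase parents)."""
    return ch if ch in GAPS_ALN else ch.upper()


def _degapped(seq: str, gaps: set[str]) -> str:
    return "".join(_fold(c) for c in seq if c not in gaps)


def remap(seq3d: str, seqaln: str) -> list[MappedPosition]:
    """Merge a gapped 3D sequence with the chain's aligned row.

    Returns one :class:`MappedPosition` per 3D position, in order, with
    strictly increasing alignment columns where known.  Raises
    :class:`MappingError` when the resolved sequences differ (including
    unequal lengths after degapping).
    """
    resolved3d = _degapped(seq3d, GAPS_3D)
    resolvedaln = _degapped(seqaln, GAPS_ALN)
    if resolved3d != resolvedaln:
        raise MappingError(
            f"resolved sequences differ: 3D side {resolved3d!r} vs aligned row "
            f"{resolvedaln!r}"
        )

    out: list[MappedPosition] = []
    j = 0  # 0-based alignment pointer
    n_aln = len(seqaln)
    for i, sym3d in enumerate(seq3d, start=1):
        placed = False
        while not placed:
            aln_sym = seqaln[j] if j < n_aln else None
            if aln_sym is not None and (
                (_fold(sym3d) == _fold(aln_sym) and sym3d not in GAPS_3D)
                or (sym3d == "-" and aln_sym == "-")
            ):
                # case 1: symbol match
                out.append(_pair(i, j + 1, sym3d))
                j += 1
                placed = True
            elif sym3d == "-":
                # case 2: unresolved residue facing a non-matching column
                col = _lookahead_gap(seqaln, j)
                if col is None:
                    out.append(
                        MappedPosition(
                            chain_index=i,
                            alignment_column=None,
                            nt_code="-",
                            nt_align_code="-",
                            homology_known=False,
                        )
                    )
                else:
                    out.append(_pair(i, col + 1, sym3d))
                    j = col + 1  # consume everything up to the matched gap
                placed = True
            elif aln_sym is not None and aln_sym in GAPS_ALN:
                # case 3: alignment gap facing a base; skip the column
                j += 1
            else:
                # case 4: differing bases (or alignment exhausted); the
                # up-front validation makes this unreachable
                raise MappingError(
                    f"mismatch at 3D position {i} ({sym3d!r}) vs alignment "
                    f"column {j + 1}"
                )
    return out


def _pair(chain_index: int, column: int, sym3d: str) -> MappedPosition:
    return MappedPosition(
        chain_index=chain_index,
        alignment_column=column,
        nt_code=sym3d,
        nt_align_code=sym3d,
        homology_known=True,
    )


def _lookahead_gap(seqaln: str, j: int) -> int | None:
    """Index of the gap column an unresolved residue should pair with.

    Scan from ``j`` up to (not including) the next base symbol: the first
    '-' wins; with no '-', the first '.'; with neither, None.
    """
    first_dot = None
    k = j
    while k < len(seqaln) and seqaln[k] in GAPS_ALN:
        if seqaln[k] == "-":
            return k
        if first_dot is None:
            first_dot = k
        k += 1
    return first_dot


def fill_missing(
    positions: list[MappedPosition],
    pssm: list[ColumnProfile],
    enabled: bool = True,
) -> list[MappedPosition]:
    """Consensus-fill unresolved residues that map to an alignment column.

    When enabled, every position with ``nt_code`` '-' and known homology
    gets ``nt_align_code`` set to its column's consensus base; ``nt_code``
    keeps the gap.  Disabled, the input is returned unchanged.  Positions
    with unknown homology always keep '-'.
    """
    if not enabled:
        return list(positions)
    out = []
    for pos in positions:
        if pos.nt_code == "-" and pos.homology_known:
            col = pssm[pos.alignment_column - 1]
            out.append(replace(pos, nt_align_code=col.consensus))
        else:
            out.append(pos)
    return out
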