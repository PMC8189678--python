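"""Reconcile a gapped 3D chain sequence with its aligned row.

A chain's 3D side uses '-' for unresolved residues; its aligned row uses
'-' for deletions and '.' for insertion padding.  The merge pairs every
residue with at most one alignment column; when no gap column can absorb
an unresolved residue, the residue keeps its descriptors but gets no
homology information (NaN profile fields downstream).
"""

from rnakit.remap import remap

CASES = [
    ("ACG", "A.CG", "insertion column skipped (case 3 then matches)"),
    ("A-G", "A-G", "matching gaps pair directly (case 1)"),
    ("A-G", "A.G", "unresolved residue absorbed by an insertion gap (case 2)"),
    ("A-G", "AG", "no gap available: homology unknown for residue 2"),
]

for seq3d, seqaln, story in CASES:
    positions = remap(seq3d, seqaln)
    mapping = ", ".join(
        f"{p.chain_index}->{p.alignment_column if p.homology_known else 'NaN'}"
        for p in positions
    )
    print(f"3D {seq3d!r:8} aligned {seqaln!r:8}  {mapping:<22}  # {story}")

print()
print("Each 'i->j' pairs 3D residue i with alignment column j; 'NaN' means")
print("the residue carries no homology descriptors (locally bad alignment).")
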