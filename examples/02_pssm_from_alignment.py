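"""Summarize a toy homolog alignment into a position-specific scoring matrix.

The toy generator emits both gap dialects used by covariance-model
aligners: '-' for deletions against the consensus, '.' for padding
opposite another sequence's insertion.  Both pool into the gap fraction.
"""

import tempfile
from pathlib import Path

from rnakit.fixtures import ToyMsaSpec, make_toy_alignment
from rnakit.homology import compute_pssm, pssm_to_frame, read_alignment

with tempfile.TemporaryDirectory() as td:
    stem = Path(td) / "toy"
    make_toy_alignment(
        ToyMsaSpec(n_sequences=5, consensus="ACGUACGU", deletion_rate=0.15,
                   insertion_rate=0.1, substitution_rate=0.1, seed=42),
        "ACGUACGU",
        stem,
    )
    alignment = read_alignment(f"{stem}.stk", "stockholm")

for rec in alignment:
    print(f"{rec.id:>10}  {rec.seq}")

profile = compute_pssm(alignment)
print()
print(pssm_to_frame(profile).round(2).to_string(index=False))
print()
print("Each row is one alignment column: base frequencies, the pooled gap")
print("fraction, and the consensus base (ties break alphabetically).  The")
print("consensus is what an unresolved 3D residue would be filled with.")
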