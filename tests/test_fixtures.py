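"""Ground-truth recovery and round-trip guarantees of the synthetic generators."""

import numpy as np
import pytest

from rnakit.fixtures import (
    FixtureSpecError,
    HelixSpec,
    ToyMsaSpec,
    make_helix_chain,
    make_helix_mmcif,
    make_selection_tables,
    make_toy_alignment,
    pseudorotation_torsions,
)
from rnakit.geometry import annotate_chain, sugar_pucker
from rnakit.homology import read_alignment
from rnakit.selection import filter_by_resolution, infer_mappings
from rnakit.structure_io import parse_mmcif


class TestHelixFixture:
    def test_roundtrip_through_structure_io(self, helix_spec, tmp_path):
        chain = make_helix_mmcif(
            HelixSpec(n_residues=3, sequence="ACG"), tmp_path / "h.cif"
        )
        parsed = parse_mmcif(tmp_path / "h.cif")
        assert len(parsed) == 1
        assert len(parsed[0]) == 3
        assert all(r.resolved for r in parsed[0].residues)
        for built, reread in zip(chain.residues, parsed[0].residues):
            assert set(built.atoms) == set(reread.atoms)

    @pytest.mark.parametrize(
        "phase,expected_label",
        [(18.0, "C3'-endo"), (162.0, "C2'-endo")],
    )
    def test_pucker_ground_truth_recovered(self, phase, expected_label):
        chain = make_helix_chain(
            HelixSpec(
                n_residues=3, sequence="GCA", pucker_phase_deg=phase,
                pucker_amplitude_deg=40.0,
            )
        )
        for desc in annotate_chain(chain):
            assert desc.pucker_label == expected_label
            assert abs(desc.phase - phase) <= 1e-3
            assert abs(desc.amplitude - 40.0) <= 1e-3

    def test_minimum_atoms_present_and_finite(self, helix_chain):
        required = {"O5'", "C5'", "C4'", "C3'", "O3'", "C2'", "C1'", "O4'"}
        for res in helix_chain.residues:
            assert required <= set(res.atoms)
            for xyz in res.atoms.values():
                assert np.all(np.isfinite(xyz))
        # 5'-terminal residue written without P, all others with it
        assert "P" not in helix_chain.residues[0].atoms
        assert all("P" in r.atoms for r in helix_chain.residues[1:])

    def test_deterministic_given_seed(self, helix_spec):
        a = make_helix_chain(helix_spec)
        b = make_helix_chain(helix_spec)
        for ra, rb in zip(a.residues, b.residues):
            for name in ra.atoms:
                assert np.array_equal(ra.atoms[name], rb.atoms[name])

    def test_noise_perturbs_coordinates(self):
        quiet = make_helix_chain(HelixSpec(3, "ACG"))
        noisy = make_helix_chain(
            HelixSpec(3, "ACG", coordinate_noise_sd=0.1, seed=7)
        )
        deltas = [
            np.linalg.norm(noisy.residues[i].atoms["C4'"] - quiet.residues[i].atoms["C4'"])
            for i in range(3)
        ]
        assert max(deltas) > 0.01

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_residues=0, sequence=""),
            dict(n_residues=2, sequence="A"),
            dict(n_residues=2, sequence="AT"),
            dict(n_residues=2, sequence="AC", pucker_amplitude_deg=0.0),
            dict(n_residues=2, sequence="AC", pucker_phase_deg=360.0),
            dict(n_residues=2, sequence="AC", coordinate_noise_sd=-1.0),
        ],
    )
    def test_invalid_spec_rejected(self, bad, tmp_path):
        with pytest.raises(FixtureSpecError):
            make_helix_mmcif(HelixSpec(**bad), tmp_path / "x.cif")

    def test_forward_inverse_pseudorotation_on_torsions(self, rng):
        # the formula pair is its own oracle: nu_j from (P, nu_max), then back
        for _ in range(200):
            phase = rng.uniform(0.0, 360.0)
            amp = rng.uniform(5.0, 55.0)
            p, a, _ = sugar_pucker(*pseudorotation_torsions(phase, amp))
            assert abs((p - phase + 180.0) % 360.0 - 180.0) <= 1e-6
            assert abs(a - amp) <= 1e-6


class TestToyAlignment:
    def test_identity_case(self, tmp_path):
        aln = make_toy_alignment(
            ToyMsaSpec(n_sequences=1, consensus="ACGU"), "ACGU", tmp_path / "a"
        )
        assert str(aln[1].seq) == "ACGU"
        assert "-" not in str(aln[0].seq) and "." not in str(aln[0].seq)

    def test_full_deletion_row(self, tmp_path):
        aln = make_toy_alignment(
            ToyMsaSpec(n_sequences=1, consensus="ACGU", deletion_rate=1.0),
            "ACGU",
            tmp_path / "a",
        )
        assert str(aln[1].seq) == "----"

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_equal_length_and_chain_row_recovers_sequence(self, seed, tmp_path):
        spec = ToyMsaSpec(
            n_sequences=4, consensus="ACGUACGU", deletion_rate=0.2,
            insertion_rate=0.2, substitution_rate=0.2, seed=seed,
        )
        aln = make_toy_alignment(spec, "ACGUACGU", tmp_path / "a")
        widths = {len(rec.seq) for rec in aln}
        assert len(widths) == 1
        chain_row = str(aln[0].seq)
        assert chain_row.replace("-", "").replace(".", "") == "ACGUACGU"

    def test_gap_dialects(self, tmp_path):
        spec = ToyMsaSpec(
            n_sequences=5, consensus="ACGU", deletion_rate=0.5,
            insertion_rate=0.5, seed=3,
        )
        aln = make_toy_alignment(spec, "ACGU", tmp_path / "a")
        symbols = set("".join(str(r.seq) for r in aln))
        assert "-" in symbols and "." in symbols
        assert symbols <= set("ACGU-.")

    def test_written_files_parse_back_identically(self, tmp_path):
        spec = ToyMsaSpec(n_sequences=3, consensus="ACGUA", insertion_rate=0.3, seed=1)
        aln = make_toy_alignment(spec, "AC-UA", tmp_path / "a")
        stk = read_alignment(tmp_path / "a.stk", "stockholm")
        fas = read_alignment(tmp_path / "a.fasta", "afasta")
        rows = [str(r.seq) for r in aln]
        assert [str(r.seq) for r in stk] == rows
        assert [str(r.seq) for r in fas] == rows


class TestSelectionTables:
    def test_class_propagation_scenario(self):
        # 4 chains, 2 classes, one direct mapping per class: all 4 resolve
        tables = make_selection_tables(4, 2, 2, seed=0)
        selected = infer_mappings(tables)
        assert len(selected) == 4
        assert sum(s.inferred for s in selected) == 2

    def test_no_mappings_nothing_inferable(self):
        tables = make_selection_tables(4, 4, 0, seed=0)
        assert infer_mappings(tables) == []

    def test_resolution_filter_boundary(self):
        tables = make_selection_tables(30, 5, 1, seed=2)
        kept = filter_by_resolution(tables.chains, 4.0)
        assert all(0.0 < c.resolution <= 6.0 for c in tables.chains)
        assert {c.key for c in kept} == {
            c.key for c in tables.chains if c.resolution <= 4.0
        }

    def test_partition_is_valid_and_deterministic(self):
        t1 = make_selection_tables(10, 3, 2, seed=5)
        t2 = make_selection_tables(10, 3, 2, seed=5)
        t1.validate()
        assert t1 == t2
        assert sum(len(c) for c in t1.classes) == 10
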