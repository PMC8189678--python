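"""Record assembly, annotation ingestion, SQLite store, CSV round-trip."""

import dataclasses
import json
import math

import pandas as pd
import pytest

from rnakit.dataset import (
    AnnotationError,
    assemble_records,
    build_store,
    check_integrity,
    dump_store,
    export_csv,
    ingest_external_annotation,
    load_nucleotide_table,
    normalize_lw,
    read_chain_csv,
)
from rnakit.fixtures import HelixSpec, ToyMsaSpec, make_helix_chain, make_toy_alignment
from rnakit.geometry import annotate_chain
from rnakit.homology import compute_pssm, read_alignment
from rnakit.remap import fill_missing, remap


def _built_chain(tmp_path, sid="1AAA", seq="ACGUAC", family="RF00001", unresolved=()):
    chain = make_helix_chain(
        HelixSpec(len(seq), seq, seed=hash(sid) % 1000),
        structure_id=sid,
        unresolved=set(unresolved),
    )
    stem = tmp_path / f"aln_{sid}"
    aln = make_toy_alignment(
        ToyMsaSpec(n_sequences=4, consensus=seq, insertion_rate=0.1, seed=1),
        chain.sequence,
        stem,
        chain_name=f"{sid}_A",
    )
    parsed = read_alignment(f"{stem}.stk", "stockholm")
    pssm = compute_pssm(parsed)
    positions = fill_missing(remap(chain.sequence, str(parsed[0].seq)), pssm)
    records = assemble_records(chain, annotate_chain(chain), positions)
    chain = dataclasses.replace(chain, mapping=(family, (1, len(seq))))
    return chain, records, pssm


class TestAnnotationIngestion:
    def _records(self, tmp_path):
        _, records, _ = _built_chain(tmp_path)
        return records

    def test_intra_chain_pair_symmetric(self, tmp_path):
        records = self._records(tmp_path)
        ann = tmp_path / "ann.json"
        ann.write_text(json.dumps({"pairs": [{"nt1": "A.1", "nt2": "A.3", "lw": "cWW"}]}))
        out = ingest_external_annotation(records, ann, "A")
        assert out[0].paired == 3 and out[2].paired == 1
        assert out[0].pair_type == ["cWW"]

    def test_inter_chain_pair_keeps_zero(self, tmp_path):
        records = self._records(tmp_path)
        ann = tmp_path / "ann.json"
        ann.write_text(json.dumps({"pairs": [{"nt1": "A.2", "nt2": "B.9", "lw": "tHS"}]}))
        out = ingest_external_annotation(records, ann, "A")
        assert out[1].paired == 0
        assert out[1].pair_type == ["tHS"]

    def test_absent_file_leaves_defaults(self, tmp_path):
        out = ingest_external_annotation(self._records(tmp_path), None, "A")
        assert all(r.paired == 0 and r.pair_type == [] and r.form_label is None for r in out)

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(AnnotationError):
            ingest_external_annotation(self._records(tmp_path), bad, "A")

    def test_unknown_residue_warned_and_skipped(self, tmp_path, caplog):
        records = self._records(tmp_path)
        ann = tmp_path / "ann.json"
        ann.write_text(json.dumps({"pairs": [{"nt1": "A.99", "nt2": "A.1", "lw": "cWW"}]}))
        out = ingest_external_annotation(records, ann, "A")
        assert out[0].paired == 0  # partner key missing, field left default

    def test_form_labels(self, tmp_path):
        records = self._records(tmp_path)
        ann = tmp_path / "ann.json"
        ann.write_text(json.dumps({"forms": [{"nt": "A.2", "form": "A"}]}))
        out = ingest_external_annotation(records, ann, "A")
        assert out[1].form_label == "A" and out[0].form_label is None

    @pytest.mark.parametrize(
        "label,expected",
        [
            ("cWW", "cWW"), ("tHS", "tHS"), ("cHW", "cWH"), ("tSW", "tWS"),
            ("n/a", "other"), ("cW?", "other"), ("", "other"),
        ],
    )
    def test_leontis_westhof_normalization(self, label, expected):
        assert normalize_lw(label) == expected


class TestStore:
    def test_row_counts(self, tmp_path):
        c1, r1, p1 = _built_chain(tmp_path, "1AAA", "ACGUAC", "RF00001")
        c2, r2, p2 = _built_chain(tmp_path, "1AAB", "GGCUAGC", "RF00002")
        db = tmp_path / "s.db"
        build_store([(c1, r1), (c2, r2)], {"RF00001": p1, "RF00002": p2}, db)
        check_integrity(db)
        table = load_nucleotide_table(db)
        assert len(table) == len(c1.residues) + len(c2.residues)
        assert table["structure_id"].nunique() == 2

    def test_rebuild_idempotent(self, tmp_path):
        c1, r1, p1 = _built_chain(tmp_path)
        db = tmp_path / "s.db"
        build_store([(c1, r1)], {"RF00001": p1}, db)
        first = dump_store(db)
        build_store([(c1, r1)], {"RF00001": p1}, db)
        assert dump_store(db) == first

    def test_multi_family_copies_have_distinct_rows(self, tmp_path):
        c1, r1, p1 = _built_chain(tmp_path, family="RF00001")
        c2 = dataclasses.replace(c1, mapping=("RF00002", (1, 6)))
        db = tmp_path / "s.db"
        build_store([(c1, r1), (c2, r1)], {"RF00001": p1, "RF00002": p1}, db)
        table = load_nucleotide_table(db)
        assert sorted(table["family"].unique()) == ["RF00001", "RF00002"]
        assert len(table) == 2 * len(c1.residues)


class TestExport:
    def test_no_filter_exports_all(self, tmp_path):
        c1, r1, p1 = _built_chain(tmp_path, "1AAA")
        c2, r2, _ = _built_chain(tmp_path, "1AAB", "GGCU", "RF00001")
        db = tmp_path / "s.db"
        build_store([(c1, r1), (c2, r2)], {"RF00001": p1}, db)
        files = export_csv(db, tmp_path / "csv")
        assert len(files) == 2
        assert len(read_chain_csv(files[0])) == 6
        assert len(read_chain_csv(files[1])) == 4

    def test_date_filter_strict(self, tmp_path):
        c1, r1, p1 = _built_chain(tmp_path)
        db = tmp_path / "s.db"
        build_store([(c1, r1)], {"RF00001": p1}, db)
        assert export_csv(db, tmp_path / "none", released_before="2019-01-01") == []
        assert export_csv(db, tmp_path / "same", released_before=c1.release_date) == []
        assert len(export_csv(db, tmp_path / "later", released_before="2021-01-01")) == 1

    def test_resolution_and_family_filters(self, tmp_path):
        c1, r1, p1 = _built_chain(tmp_path, "1AAA", family="RF00001")
        c2, r2, p2 = _built_chain(tmp_path, "1AAB", "GGCU", family="RF00002")
        c2 = dataclasses.replace(c2, resolution=5.0)
        db = tmp_path / "s.db"
        build_store([(c1, r1), (c2, r2)], {"RF00001": p1, "RF00002": p2}, db)
        assert len(export_csv(db, tmp_path / "r", resolution_max=4.0)) == 1
        assert len(export_csv(db, tmp_path / "f", family="RF00002")) == 1
        assert export_csv(db, tmp_path / "rf", resolution_max=4.0, family="RF00002") == []

    def test_roundtrip_preserves_null_vs_zero(self, tmp_path):
        # an unresolved residue with unknown homology gives null PSSM fields
        # next to genuine zeros elsewhere; both must survive the CSV
        chain, records, pssm = _built_chain(tmp_path, "1AAA", unresolved=(3,))
        records[2] = dataclasses.replace(
            records[2], alignment_column=None, homology_known=False
        )
        db = tmp_path / "s.db"
        build_store([(chain, records)], {"RF00001": pssm}, db)
        (path,) = export_csv(db, tmp_path / "csv")
        df = read_chain_csv(path)
        row = df[df["idx"] == 3].iloc[0]
        assert pd.isna(row["alignment_column"]) and pd.isna(row["freq_A"])
        assert pd.isna(row["phase"])  # no coordinates, no geometry
        assert row["paired"] == 0 and not pd.isna(row["paired"])
        resolved = df[df["idx"] == 1].iloc[0]
        assert not pd.isna(resolved["freq_A"])
        # field-wise equality against the store
        table = load_nucleotide_table(db)
        for col in ("nt_code", "nt_align_code", "paired", "pucker_label"):
            got = df[col].tolist()
            want = table[col].tolist()
            assert [x if not pd.isna(x) else None for x in got] == [
                x if not pd.isna(x) else None for x in want
            ], col
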