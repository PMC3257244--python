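"""Database loading, consensus construction, segment annotation, coverage."""

import random

import pytest

from taxoprimer import markerdb
from taxoprimer.markerdb import (
    TRNL_E1_ANCHOR,
    TRNL_E2_ANCHOR,
    AnchorAmbiguityError,
    ConsensusAnchorError,
    DuplicateRecordError,
    MarkerAnnotation,
    SequenceRecord,
    annotate_marker_regions,
    build_species_consensus,
    coverage_report,
    load_records,
)


def _write_fasta(path, entries):
    path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in entries))
    return path


class TestLoadRecords:
    def test_parses_in_file_order_and_normalizes(self, tmp_path):
        p = _write_fasta(tmp_path / "db.fasta", [("r1", "acgtn"), ("r2", "ACGU")])
        records = load_records(p)
        assert [r.record_id for r in records] == ["r1", "r2"]
        assert records[0].sequence == "ACGTN"
        assert records[1].sequence == "ACGT"  # U -> T

    def test_duplicate_id_is_an_error_naming_the_id(self, tmp_path):
        p = _write_fasta(tmp_path / "dup.fasta", [("same", "ACGT"), ("same", "AAAA")])
        with pytest.raises(DuplicateRecordError, match="same"):
            load_records(p)

    def test_non_iupac_character_reports_position(self, tmp_path):
        p = _write_fasta(tmp_path / "bad.fasta", [("r1", "ACGXT")])
        with pytest.raises(Exception, match="position 3"):
            load_records(p)


def _recs(taxon, *seqs):
    return [SequenceRecord(f"{taxon}|r{i}", taxon, s) for i, s in enumerate(seqs, 1)]


class TestConsensus:
    def test_identical_records_merge_without_conflicts(self):
        cons = build_species_consensus(_recs("sp", "ACGT", "ACGT"))
        assert cons.sequence == "ACGT"
        assert cons.conflict_positions == ()
        assert cons.n_records == 2

    def test_disagreement_becomes_ambiguity_code(self):
        cons = build_species_consensus(_recs("sp", "ACGT", "ACGA"))
        assert cons.sequence == "ACGW"
        assert cons.conflict_positions == (3,)

    def test_partial_overlap_concatenates_flanks(self):
        template = "AAGCTTGCATCGATG"  # 15 bp
        cons = build_species_consensus(_recs("sp", template[:10], template[5:]))
        assert cons.sequence == template

    def test_consensus_of_a_consensus_is_unchanged(self):
        cons = build_species_consensus(_recs("sp", "ACGTACGTTT", "ACGAACGTTT"))
        again = build_species_consensus([cons])
        assert again.sequence == cons.sequence
        assert again.conflict_positions == cons.conflict_positions

    def test_result_is_invariant_to_record_order(self):
        rng = random.Random(5)
        base = "".join(rng.choice("ACGT") for _ in range(120))
        seqs = [base, base[10:], base[:100].replace(base[50], "A", 1)]
        records = _recs("sp", *seqs)
        forward = build_species_consensus(records)
        backward = build_species_consensus(records[::-1])
        assert forward.sequence == backward.sequence
        assert forward.conflict_positions == backward.conflict_positions

    def test_unanchorable_record_is_reported(self):
        rng = random.Random(9)
        a = "".join(rng.choice("ACGT") for _ in range(100))
        b = "".join(rng.choice("TGAC") for _ in range(90))
        records = [SequenceRecord("good", "sp", a), SequenceRecord("junk", "sp", b)]
        with pytest.raises(ConsensusAnchorError, match="junk"):
            build_species_consensus(records)


def _template(rng, e1_at=100, e2_at=400, total=700):
    pre = "".join(rng.choice("ACGT") for _ in range(e1_at))
    mid_len = e2_at - e1_at - len(TRNL_E1_ANCHOR)
    mid = "".join(rng.choice("ACGT") for _ in range(mid_len))
    post = "".join(rng.choice("ACGT") for _ in range(total - e2_at - len(TRNL_E2_ANCHOR)))
    return pre + TRNL_E1_ANCHOR + mid + TRNL_E2_ANCHOR + post


class TestAnnotation:
    def test_planted_anchors_yield_all_five_segments(self):
        rng = random.Random(1)
        seq = _template(rng)
        ann = annotate_marker_regions(SequenceRecord("t", "sp", seq))
        assert ann.span("IS1") == (0, 100)
        assert ann.span("trnL-E1") == (100, 100 + len(TRNL_E1_ANCHOR))
        assert ann.span("trnL-intron") == (100 + len(TRNL_E1_ANCHOR), 400)
        assert ann.span("trnL-E2") == (400, 400 + len(TRNL_E2_ANCHOR))
        assert ann.span("IS2") == (400 + len(TRNL_E2_ANCHOR), len(seq))

    def test_partial_record_flags_missing_segments(self):
        rng = random.Random(2)
        seq = TRNL_E2_ANCHOR + "".join(rng.choice("ACGT") for _ in range(200))
        ann = annotate_marker_regions(SequenceRecord("t", "sp", seq))
        for name in ("IS1", "trnL-E1", "trnL-intron"):
            assert not ann.present(name)
        assert ann.span("trnL-E2") == (0, len(TRNL_E2_ANCHOR))
        assert ann.span("IS2") == (len(TRNL_E2_ANCHOR), len(seq))

    def test_duplicated_anchor_is_ambiguous(self):
        rng = random.Random(3)
        filler = "".join(rng.choice("ACGT") for _ in range(50))
        seq = TRNL_E1_ANCHOR + filler + TRNL_E1_ANCHOR
        with pytest.raises(AnchorAmbiguityError):
            annotate_marker_regions(SequenceRecord("t", "sp", seq))


def _ann(**present):
    segments = {name: None for name in markerdb.SEGMENT_ORDER}
    segments.update(present)
    return MarkerAnnotation(segments)


class TestCoverage:
    def test_fractional_coverage(self):
        db = []
        for i in range(10):
            seg = {"trnL-E1": (0, 36)}
            if i < 9:
                seg["trnL-intron"] = (36, 336)
            db.append((SequenceRecord(f"r{i}", f"sp{i}", "ACGT"), _ann(**seg)))
        report = coverage_report(db)
        assert report.loc["trnL-intron", "coverage_pct"] == pytest.approx(90.0)
        assert report.loc["trnL-E1", "coverage_pct"] == pytest.approx(100.0)

    def test_absent_segment_has_no_lengths(self):
        db = [(SequenceRecord("r0", "sp0", "ACGT"), _ann(**{"trnL-E1": (0, 36)}))]
        report = coverage_report(db)
        import pandas as pd

        assert report.loc["IS1", "coverage_pct"] == 0.0
        assert pd.isna(report.loc["IS1", "min_len"])

    def test_length_range_reflects_planted_lengths(self):
        db = [
            (SequenceRecord("r0", "sp0", "A"), _ann(**{"trnL-intron": (0, 241)})),
            (SequenceRecord("r1", "sp1", "A"), _ann(**{"trnL-intron": (0, 588)})),
        ]
        report = coverage_report(db)
        assert report.loc["trnL-intron", "min_len"] == 241
        assert report.loc["trnL-intron", "max_len"] == 588

    def test_coverage_bounds_and_counts(self, mock_db):
        annotated = [
            (rec, annotate_marker_regions(rec)) for rec in mock_db.records[:20]
        ]
        report = coverage_report(annotated, mock_db.taxonomy)
        assert ((report["coverage_pct"] >= 0) & (report["coverage_pct"] <= 100)).all()
        n_species = len({mock_db.taxonomy[r.record_id].species for r, _ in annotated})
        assert (report["n_species"] <= n_species).all()


def test_bed_export_is_zero_based_half_open():
    rec = SequenceRecord("rec1", "sp", "ACGT")
    bed = markerdb.annotation_to_bed(rec, _ann(**{"IS1": (0, 100), "trnL-E1": (100, 136)}))
    assert bed.splitlines() == ["rec1\t0\t100\tIS1", "rec1\t100\t136\ttrnL-E1"]


def test_taxonomy_rejects_inconsistent_placement(tmp_path):
    p = tmp_path / "tax.tsv"
    p.write_text(
        "record_id\tspecies\tgenus\tfamily\thabitat\n"
        "r1\tsp1\tgA\tfA\tmaize_field\n"
        "r2\tsp1\tgB\tfB\tgrassland\n"
    )
    with pytest.raises(ValueError, match="two placements"):
        markerdb.load_taxonomy(p)
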