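"""Annotation parsing thresholds, the dbCAN rule, compartment logic and
the report summaries."""

import pandas as pd
import pytest

from metasecretome.annotation import (
    AnnotationRecord,
    BlastHit,
    CazyDomain,
    ClassifiedProtein,
    apply_dbcan_rule,
    classify_all,
    classify_compartment,
    parse_annotations,
    parse_blast_tab,
    parse_dbcan_domtbl,
    parse_lineage_table,
    parse_signalp_short,
    parse_tmhmm_short,
    summarize,
)
from metasecretome.seq_io import ParseError
from metasecretome.simulate import generate_annotation_files


def blast_row(qid="orf1", evalue="1e-25", title="hypothetical protein [Cellvibrio japonicus]"):
    return "\t".join(
        [qid, "ref|X|", "95.0", "100", "3", "0", "1", "100", "1", "100",
         evalue, "250.0", title]
    )


class TestBlastParsing:
    def test_evalue_threshold(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text(blast_row(evalue="1e-25") + "\n"
                     + blast_row(qid="orf2", evalue="1e-10") + "\n")
        best = parse_blast_tab(p)
        assert "orf1" in best and "orf2" not in best

    def test_best_hit_selection_and_taxon(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text(blast_row(evalue="1e-25") + "\n"
                     + blast_row(evalue="1e-40") + "\n")
        best = parse_blast_tab(p)
        assert best["orf1"].evalue == pytest.approx(1e-40)
        assert best["orf1"].taxon == "Cellvibrio japonicus"

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("only\tthree\tcols\n")
        with pytest.raises(ParseError, match=":1:"):
            parse_blast_tab(p)


class TestDbcanRule:
    @pytest.mark.parametrize(
        "length,evalue,kept",
        [
            (100, 1e-6, True),    # long + strict E: kept
            (100, 1e-4, False),   # long but weak E: dropped
            (60, 5e-4, True),     # short + lenient E: kept
            (60, 5e-3, False),    # short but too weak: dropped
            (80, 1e-4, True),     # boundary: 80 aa is the lenient branch
        ],
    )
    def test_two_branch_predicate(self, length, evalue, kept):
        d = CazyDomain("GH5", evalue, length)
        assert (apply_dbcan_rule([d]) == [d]) is kept

    def test_domtbl_round_trip_fields(self, tmp_path):
        p = tmp_path / "d.domtbl"
        p.write_text(
            "# comment\n"
            "GH5.hmm - 150 orf1 - 300 1e-12 250.0 0.1 1 1 1e-12 1e-12 "
            "240.0 0.1 1 121 10 130 10 130 0.98 GH5 domain\n"
        )
        hits = parse_dbcan_domtbl(p)
        (d,) = hits["orf1"]
        assert d.family == "GH5"
        assert d.alignment_length == 121
        assert d.evalue == pytest.approx(1e-12)


class TestShortFormats:
    def test_tmhmm_predhel(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("orf1\tlen=300\tExpAA=44\tFirst60=0\tPredHel=2\tTopology=o\n")
        assert parse_tmhmm_short(p) == {"orf1": 2}

    def test_tmhmm_missing_field_is_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("orf1\tlen=300\n")
        with pytest.raises(ParseError):
            parse_tmhmm_short(p)

    def test_signalp_decision(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "# SignalP-4.1\n"
            "orf1 0.5 22 0.5 22 0.6 15 0.45 0.780 Y 0.450 SignalP-noTM\n"
            "orf2 0.2 10 0.2 10 0.2 5 0.15 0.120 N 0.450 SignalP-noTM\n"
        )
        assert parse_signalp_short(p) == {"orf1": True, "orf2": False}

    def test_signalp_any_positive_model_wins(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "orf1 0.2 10 0.2 10 0.2 5 0.15 0.120 N 0.450 SignalP-noTM\n"
            "orf1 0.5 22 0.5 22 0.6 15 0.45 0.780 Y 0.450 SignalP-TM\n"
        )
        assert parse_signalp_short(p) == {"orf1": True}


class TestCompartmentRule:
    @pytest.mark.parametrize(
        "sp,tm,expected",
        [
            (True, 0, "secreted"),
            (True, 3, "membrane"),
            (False, 1, "membrane"),
            (False, 0, "unassigned"),
        ],
    )
    def test_rule_table(self, sp, tm, expected):
        rec = AnnotationRecord(orf_id="o", signal_peptide=sp, tm_helix_count=tm)
        assert classify_compartment(rec).compartment == expected

    def test_classes_exclusive_and_exhaustive(self):
        seen = set()
        for sp in (True, False):
            for tm in (0, 1, 5):
                rec = AnnotationRecord("o", signal_peptide=sp, tm_helix_count=tm)
                seen.add(classify_compartment(rec).compartment)
        assert seen == {"secreted", "membrane", "unassigned"}


class TestGeneratorRoundTrip:
    def test_planted_annotations_recovered(self, community, tmp_path):
        paths = generate_annotation_files(community, tmp_path)
        orf_ids = sorted(community.proteins_by_orf)
        records = parse_annotations(
            orf_ids,
            blast_tsv=paths["blast"],
            dbcan_domtbl=paths["dbcan"],
            signalp_tsv=paths["signalp"],
            tmhmm_tsv=paths["tmhmm"],
            cog_tsv=paths["cog"],
        )
        lineage = parse_lineage_table(paths["lineage"])
        classified = classify_all(records, lineage)
        for orf_id, planted in community.proteins_by_orf.items():
            got = classified[orf_id]
            assert got.compartment == planted.compartment
            assert got.is_cazyme == (planted.cazy_family is not None)
            if planted.cazy_family:
                fams = {d.family for d in got.annotation.cazy_domains}
                assert fams == {planted.cazy_family}
            assert got.taxon_rollup["genus"] == planted.taxon.split()[0]

    def test_missing_orf_gets_neutral_defaults(self, community, tmp_path):
        paths = generate_annotation_files(community, tmp_path)
        records = parse_annotations(
            ["not-a-real-orf"], blast_tsv=paths["blast"],
            signalp_tsv=paths["signalp"], tmhmm_tsv=paths["tmhmm"],
        )
        rec = records["not-a-real-orf"]
        assert rec.blast_best is None
        assert not rec.signal_peptide
        assert rec.tm_helix_count == 0


def make_classified(n_total, n_cazy, n_transporter=0):
    out = {}
    for i in range(n_total):
        orf = f"o{i:03d}"
        is_cazy = i < n_cazy
        desc = ("TonB-dependent receptor [X y]" if n_cazy <= i < n_cazy + n_transporter
                else "hypothetical protein [X y]")
        ann = AnnotationRecord(
            orf_id=orf,
            blast_best=BlastHit("s", "X y", 1e-30, 100.0, description=desc),
            cazy_domains=[CazyDomain("GH5", 1e-10, 120)] if is_cazy else [],
        )
        out[orf] = ClassifiedProtein(
            orf_id=orf, compartment="unassigned", is_cazyme=is_cazy,
            annotation=ann,
        )
    return out


class TestSummaries:
    def test_cazyme_share_worked_example(self):
        tables = summarize(make_classified(312, 17))
        row = tables["cazy_share"].iloc[0]
        assert (row.n_cazymes, row.n_proteins) == (17, 312)
        assert round(row.pct, 2) == 5.45
        assert round(row.pct, 1) == 5.4

    def test_family_distribution_sums_to_100(self):
        tables = summarize(make_classified(50, 8))
        fam = tables["cazy_families"]
        assert fam.pct_of_cazymes.sum() == pytest.approx(100.0)

    def test_empty_cazy_set_no_crash(self):
        tables = summarize(make_classified(10, 0))
        assert tables["cazy_families"].empty
        assert tables["cazy_share"].iloc[0].pct == 0.0

    def test_transporter_keyword_tally(self):
        tables = summarize(make_classified(50, 0, n_transporter=7))
        assert len(tables["transporters"]) == 7

    def test_taxonomy_rollup_sums_to_100(self, community, tmp_path):
        paths = generate_annotation_files(community, tmp_path)
        records = parse_annotations(
            sorted(community.proteins_by_orf),
            blast_tsv=paths["blast"],
        )
        lineage = parse_lineage_table(paths["lineage"])
        tables = summarize(classify_all(records, lineage))
        for rank in ("phylum", "order", "genus"):
            df = tables[f"taxonomy_{rank}"]
            assert df.pct_of_assigned.sum() == pytest.approx(100.0, abs=0.1)
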