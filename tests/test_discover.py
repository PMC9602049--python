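"""Discovery protocol: collapsing, mapping, subtraction, filters, summaries."""

import numpy as np
import pandas as pd
import pytest

from beepirna import discover
from beepirna.discover import (
    AlignmentHit,
    EmptyGroupError,
    PiRNACandidate,
    SmallRNATag,
    call_pirnas,
    collapse_reads,
    first_base_bias,
    group_set_partition,
    ingest_sam,
    length_distribution,
    map_tags,
    subtract_mirna,
    subtract_ncrna,
)
from beepirna.io import FastqParseError, revcomp, write_fastq


def _fastq(path, seqs):
    write_fastq(path, ((f"r{i}", s) for i, s in enumerate(seqs)))
    return path


def make_tag(seq, counts=None):
    return SmallRNATag(seq, counts or {"rep1": 1})


def features_frame(rows):
    return pd.DataFrame(rows, columns=["feature_id", "type", "chrom", "start", "end", "strand"])


class TestCollapse:
    def test_counts_per_replicate(self, tmp_path):
        f1 = _fastq(tmp_path / "r1.fastq", ["ACGT", "ACGT", "ACGT", "GGGG", "GGGG"])
        tags, sizes = collapse_reads({"rep1": f1})
        assert sizes == {"rep1": 5}
        by_seq = {t.sequence: t.counts for t in tags}
        assert by_seq == {"ACGT": {"rep1": 3}, "GGGG": {"rep1": 2}}

    def test_same_sequence_merges_across_replicates(self, tmp_path):
        f1 = _fastq(tmp_path / "r1.fastq", ["ACGTACGT"])
        f2 = _fastq(tmp_path / "r2.fastq", ["ACGTACGT", "ACGTACGT"])
        tags, _ = collapse_reads({"rep1": f1, "rep2": f2})
        assert len(tags) == 1
        assert tags[0].counts == {"rep1": 1, "rep2": 2}
        assert tags[0].pooled == 3

    def test_empty_file_gives_no_tags(self, tmp_path):
        f1 = _fastq(tmp_path / "r1.fastq", [])
        tags, sizes = collapse_reads({"rep1": f1})
        assert tags == [] and sizes == {"rep1": 0}

    def test_malformed_fastq_raises_with_position(self, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\nCCCC\nIIII\n")  # separator line corrupted
        with pytest.raises(FastqParseError, match="line"):
            collapse_reads({"rep1": bad})


class TestMapping:
    GENOME = {"chr1": "".join(
        np.random.default_rng(42).choice(list("ACGT"), size=500)
    )}

    def test_unique_forward_hit(self):
        tag = self.GENOME["chr1"][100:124]
        hits = map_tags([tag], self.GENOME)
        assert hits[tag] == [AlignmentHit(tag, "chr1", 100, 124, "+", 0)]

    def test_reverse_strand_hit(self):
        tag = revcomp(self.GENOME["chr1"][200:230])
        [h] = map_tags([tag], self.GENOME)[tag]
        assert (h.start, h.end, h.strand) == (200, 230, "-")

    def test_two_loci_give_two_hits(self):
        seg = self.GENOME["chr1"][50:74]
        genome = {"chr1": self.GENOME["chr1"] + seg}
        hits = map_tags([seg], genome)[seg]
        assert len(hits) == 2

    def test_best_stratum_only_with_mismatches(self):
        embedded = "CCGTTAGGCATCCGTTAGGCATCC"  # not an RC-palindrome
        g = {"chr1": "A" * 30 + embedded + "A" * 30}
        tag = embedded[:-1] + "G"  # 1 mismatch vs the embedded copy
        hits = map_tags([tag], g, max_mismatches=1)[tag]
        assert hits and all(h.mismatches == 1 for h in hits)
        hits2 = map_tags([embedded], g, max_mismatches=1)[embedded]
        assert [h.mismatches for h in hits2] == [0]

    def test_unmapped_tag_absent_from_results(self):
        assert map_tags(["T" * 40], self.GENOME) == {}

    def test_sam_ingest_reverifies_coordinates(self, tmp_path):
        genome = {"chr1": self.GENOME["chr1"]}
        tag = genome["chr1"][10:40]
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:500\n"
            f"t1\t0\tchr1\t11\t60\t30M\t*\t0\t0\t{tag}\t{'I'*30}\n"
        )
        hits = ingest_sam(sam, genome)
        assert hits[tag][0].start == 10 and hits[tag][0].mismatches == 0

    def test_sam_ingest_rejects_unknown_chromosome(self, tmp_path):
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrX\tLN:500\n"
            f"t1\t0\tchrX\t11\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
        )
        with pytest.raises(ValueError, match="absent from FASTA"):
            ingest_sam(sam, self.GENOME)


class TestSubtraction:
    def test_tag_inside_trna_removed_with_ledger_class(self):
        tag = make_tag("A" * 30)
        hits = {tag.sequence: [AlignmentHit(tag.sequence, "chr1", 100, 130, "+", 0)]}
        feats = features_frame([("t1", "tRNA", "chr1", 90, 170, "+")])
        kept, ledger = subtract_ncrna([tag], hits, feats)
        assert kept == []
        assert ledger.iloc[0].tolist() == ["A" * 30, "ncRNA_subtraction", "tRNA"]

    def test_partial_overlap_below_half_is_retained(self):
        # 10 nt of a 30 nt tag inside the feature: 10/30 < 0.5
        tag = make_tag("A" * 30)
        hits = {tag.sequence: [AlignmentHit(tag.sequence, "chr1", 100, 130, "+", 0)]}
        feats = features_frame([("t1", "tRNA", "chr1", 120, 200, "+")])
        kept, ledger = subtract_ncrna([tag], hits, feats)
        assert len(kept) == 1 and ledger.empty

    def test_no_annotations_retains_everything(self):
        tag = make_tag("A" * 30)
        kept, ledger = subtract_ncrna([tag], {}, features_frame([]))
        assert len(kept) == 1 and ledger.empty

    def test_unknown_class_in_filter_list_is_config_error(self):
        with pytest.raises(ValueError, match="unknown ncRNA classes"):
            subtract_ncrna([], {}, features_frame([]), classes=["tRNA", "lncRNA"])

    def test_mirna_exact_match_removed_one_mismatch_kept(self):
        mir = "TGAGGTAGTAGGTTGTATAGTT"
        near = "TGAGGTAGTAGGTTGTATAGTA"
        kept, ledger = subtract_mirna([make_tag(mir), make_tag(near)], mirna_sequences=[mir])
        assert [t.sequence for t in kept] == [near]
        assert ledger.iloc[0]["reason"] == "miRNA_sequence"

    def test_empty_mirna_set_retains_all(self):
        kept, ledger = subtract_mirna([make_tag("ACGT" * 7)], mirna_sequences=[])
        assert len(kept) == 1 and ledger.empty


class TestCallPirnas:
    def _hits(self, seq, n=1):
        return [AlignmentHit(seq, "chr1", 100 * (i + 1), 100 * (i + 1) + len(seq), "+", 0) for i in range(n)]

    @pytest.mark.parametrize(
        "length,expected", [(23, 0), (24, 1), (28, 1), (33, 1), (34, 0)]
    )
    def test_inclusive_length_window(self, length, expected):
        seq = "C" + "A" * (length - 1)
        cands, _ = call_pirnas([make_tag(seq)], {seq: self._hits(seq)})
        assert len(cands) == expected

    def test_multi_locus_tag_rejected(self):
        seq = "C" + "G" * 27
        cands, ledger = call_pirnas([make_tag(seq)], {seq: self._hits(seq, n=2)})
        assert cands == [] and ledger.iloc[0]["stage"] == "unique_position_filter"

    def test_first_base_reported_as_rna(self):
        seq = "T" + "A" * 25
        cands, _ = call_pirnas([make_tag(seq)], {seq: self._hits(seq)})
        assert cands[0].first_base == "U"

    def test_output_sorted_by_pooled_count_then_sequence(self):
        s1, s2, s3 = ("A" * 26, "C" * 26, "G" * 26)
        tags = [make_tag(s2, {"r": 5}), make_tag(s3, {"r": 9}), make_tag(s1, {"r": 5})]
        hits = {s: self._hits(s) for s in (s1, s2, s3)}
        cands, _ = call_pirnas(tags, hits)
        assert [c.sequence for c in cands] == [s3, s1, s2]


def _cand(seq, presence, counts=None):
    return PiRNACandidate(
        discover.pirna_id(seq), seq,
        AlignmentHit(seq, "chr1", 0, len(seq), "+", 0),
        counts or {"r1": 1}, dict(presence),
    )


class TestSummaries:
    def test_first_base_fractions(self):
        cands = [
            _cand("C" + "A" * 25, {"g1": True}),
            _cand("C" + "G" * 25, {"g1": True}),
            _cand("G" + "A" * 25, {"g1": True}),
        ]
        bias = first_base_bias(cands, "g1")
        assert bias == {"A": 0.0, "C": pytest.approx(2 / 3), "G": pytest.approx(1 / 3), "U": 0.0}
        assert sum(bias.values()) == pytest.approx(1.0, abs=1e-12)

    def test_read_weighted_variant(self):
        cands = [
            _cand("C" + "A" * 25, {"g1": True}, {"r1": 9}),
            _cand("G" + "A" * 25, {"g1": True}, {"r1": 1}),
        ]
        assert first_base_bias(cands, "g1", weighted=True)["C"] == pytest.approx(0.9)

    def test_empty_group_raises(self):
        with pytest.raises(EmptyGroupError):
            first_base_bias([_cand("C" + "A" * 25, {"g1": True})], "g2")

    def test_length_distribution(self):
        cands = [_cand("C" + "A" * 23, {}), _cand("C" + "G" * 23, {}), _cand("C" + "A" * 29, {})]
        hist = length_distribution(cands)
        assert hist[24] == 2 and hist[30] == 1 and sum(hist.values()) == 3
        assert set(hist) == set(range(24, 34))

    def test_partition_example(self):
        # presence sets {a,b}, {a,c}, {a} across groups g1..g3
        cands = [
            _cand("A" * 24, {"g1": True, "g2": True, "g3": True}),   # a
            _cand("C" * 24, {"g1": True, "g2": False, "g3": False}),  # b
            _cand("G" * 24, {"g1": False, "g2": True, "g3": False}),  # c
        ]
        part = group_set_partition(cands, ["g1", "g2", "g3"])
        ids = {c.sequence: c.pirna_id for c in cands}
        assert part.shared == {ids["A" * 24]}
        assert part.unique("g1") == {ids["C" * 24]}
        assert part.unique("g2") == {ids["G" * 24]}
        assert part.unique("g3") == set()

    def test_partition_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(1)
        cands = []
        for i in range(60):
            seq = "".join(rng.choice(list("ACGT"), size=26))
            pres = {g: bool(rng.integers(0, 2)) for g in ("g1", "g2", "g3")}
            cands.append(_cand(seq, pres))
        part = group_set_partition(cands, ["g1", "g2", "g3"])
        all_ids = [pid for cell in part.cells.values() for pid in cell]
        assert len(all_ids) == len(set(all_ids))  # disjoint
        expected = {c.pirna_id for c in cands if any(c.group_presence.values())}
        assert set(all_ids) == expected  # exhaustive over detected candidates


class TestPipelineProperties:
    def test_tag_conservation_through_all_stages(self, small_run):
        disc = small_run.discovery
        assert disc.n_tags_in == len(disc.candidates) + len(disc.ledger)

    def test_every_candidate_satisfies_filters(self, small_run):
        for c in small_run.discovery.candidates:
            assert 24 <= c.length <= 33
            assert c.locus.end - c.locus.start == c.length

    def test_fastq_record_order_does_not_change_output(self, tmp_path, small_study):
        from beepirna.io import iter_fastq
        from beepirna.pipeline import run_discovery

        base = run_discovery(small_study)
        # shuffle the records of one replicate and rerun
        rep = small_study.config.replicate_ids()[0]
        records = list(iter_fastq(small_study.paths.fastq(rep)))
        rng = np.random.default_rng(99)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        new_path = tmp_path / f"{rep}.fastq"
        write_fastq(new_path, shuffled)
        fastqs = {r: small_study.paths.fastq(r) for r in small_study.config.replicate_ids()}
        fastqs[rep] = new_path
        mirnas = [
            row.sequence
            for row in small_study.features[small_study.features["type"] == "miRNA"].itertuples(index=False)
        ]
        again = discover.discover_pipeline(
            fastqs, small_study.genome, small_study.features,
            mirna_sequences=mirnas, rep_to_group=small_study.config.rep_to_group(),
        )
        pd.testing.assert_frame_equal(base.catalog_frame(), again.catalog_frame())
        pd.testing.assert_frame_equal(
            base.ledger.sort_values(["tag"]).reset_index(drop=True),
            again.ledger.sort_values(["tag"]).reset_index(drop=True),
        )
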