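import numpy as np
import pysam
import pytest

from gravirebound import simulate as S
from gravirebound.splice import (
    GeneIndex,
    ReadClass,
    _iter_pairs,
    assign_gene,
    classify_pair,
    count_layers,
)


def _header(ann):
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": c, "LN": n} for c, n in ann.chrom_lengths.items()],
        }
    )


def _read(header, chrom, pos, cigar, name="r1", flag=0x63):
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.flag = flag
    seg.reference_id = list(header.references).index(chrom)
    seg.reference_start = pos
    seg.mapping_quality = 60
    seg.cigarstring = cigar
    return seg


class TestClassifyPair:
    """Rules on the hand-built gene A: exons t1 [100,200),[300,400),[500,600);
    t2 skips the middle exon; constitutive introns [200,300) and [400,500)."""

    def test_exact_intron_gap_is_spliced(self, tiny_ann):
        h = _header(tiny_ann)
        idx = GeneIndex(tiny_ann)
        read = _read(h, "chr1", 150, "50M100N50M")  # gap [200,300) matches t1 intron
        assert classify_pair([read], idx.geometry("A")) is ReadClass.SPLICED

    def test_constitutive_intron_overlap_is_unspliced(self, tiny_ann):
        h = _header(tiny_ann)
        idx = GeneIndex(tiny_ann)
        read = _read(h, "chr1", 220, "50M")
        assert classify_pair([read], idx.geometry("A")) is ReadClass.UNSPLICED

    def test_single_exon_gene_read_is_spliced_by_definition(self, tiny_ann):
        h = _header(tiny_ann)
        idx = GeneIndex(tiny_ann)
        read = _read(h, "chr1", 1100, "75M")
        assert classify_pair([read], idx.geometry("B")) is ReadClass.SPLICED

    def test_exonic_non_junction_read_is_ambiguous(self, tiny_ann):
        h = _header(tiny_ann)
        idx = GeneIndex(tiny_ann)
        read = _read(h, "chr1", 110, "50M")
        assert classify_pair([read], idx.geometry("A")) is ReadClass.AMBIGUOUS

    def test_partial_boundary_gap_is_ambiguous(self, tiny_ann):
        # gap [210, 300) touches only one edge of the intron [200, 300):
        # conservative choice, not spliced; blocks avoid the constitutive
        # intron? block [190,210) overlaps [200,300) -> unspliced wins.
        h = _header(tiny_ann)
        idx = GeneIndex(tiny_ann)
        read = _read(h, "chr1", 190, "20M90N30M")
        assert classify_pair([read], idx.geometry("A")) is ReadClass.UNSPLICED
        # gap inside the t2 long intron matching no annotated intron exactly,
        # blocks exonic in t1 -> ambiguous
        read2 = _read(h, "chr1", 150, "50M150N50M")  # gap [200,350)
        assert classify_pair([read2], idx.geometry("A")) is ReadClass.AMBIGUOUS

    def test_unspliced_evidence_beats_spliced_mate(self, tiny_ann):
        h = _header(tiny_ann)
        idx = GeneIndex(tiny_ann)
        junction = _read(h, "chr1", 150, "50M100N50M", name="p")
        intronic = _read(h, "chr1", 420, "50M", name="p", flag=0x93)
        assert classify_pair([junction, intronic], idx.geometry("A")) is ReadClass.UNSPLICED

    def test_invariant_to_transcript_order(self, tiny_ann):
        h = _header(tiny_ann)
        idx = GeneIndex(tiny_ann)
        geom = idx.geometry("A")
        read = _read(h, "chr1", 150, "50M100N50M")
        before = classify_pair([read], geom)
        geom.transcripts.reverse()
        geom.exon_sets.reverse()
        geom.intron_sets.reverse()
        assert classify_pair([read], geom) is before


class TestAssignGene:
    def test_blocks_within_one_gene(self, tiny_ann):
        h = _header(tiny_ann)
        idx = GeneIndex(tiny_ann)
        assert assign_gene([_read(h, "chr1", 150, "50M")], idx) == "A"

    def test_blocks_spanning_two_genes_unassigned(self, tiny_ann):
        h = _header(tiny_ann)
        idx = GeneIndex(tiny_ann)
        assert assign_gene([_read(h, "chr1", 550, "600M")], idx) is None

    def test_unknown_chromosome_unassigned(self, tiny_ann):
        h = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrX", "LN": 1000}]}
        )
        idx = GeneIndex(tiny_ann)
        assert assign_gene([_read(h, "chrX", 10, "50M")], idx) is None


@pytest.fixture(scope="module")
def fixture(tmp_path_factory):
    ann = S.synthetic_annotation(120, seed=11)
    path = str(tmp_path_factory.mktemp("sam") / "fix.sam")
    truth = S.generate_sam_fixture(ann, 800, seed=12, path=path)
    return ann, path, truth


class TestCountLayers:
    def test_agreement_with_truth_for_unambiguous_reads(self, fixture):
        ann, path, truth = fixture
        idx = GeneIndex(ann)
        for mates in _iter_pairs(path):
            row = truth.loc[mates[0].query_name]
            gid = assign_gene(mates, idx)
            assert gid == row["gene_id"]
            if row["label"] != "ambiguous":
                assert classify_pair(mates, idx.geometry(gid)).value == row["label"]

    def test_layer_sums_conserve_assigned_pairs(self, fixture):
        ann, path, truth = fixture
        lc, summary = count_layers({"s": path}, ann)
        assert int(lc.total.sum().sum()) == len(truth)
        assert int(summary.loc["s", ["spliced", "unspliced", "ambiguous"]].sum()) == len(
            truth
        )
        assert summary.loc["s", "unassigned"] == 0

    def test_secondary_records_not_double_counted(self, fixture):
        # the fixture emits secondary copies every 50th pair; counts must
        # still equal the number of truth pairs
        ann, path, truth = fixture
        lc, _ = count_layers({"s": path}, ann)
        assert int(lc.total.sum().sum()) == len(truth)

    def test_invariant_to_record_order(self, fixture, tmp_path):
        ann, path, _ = fixture
        lines = open(path).read().splitlines()
        header = [l for l in lines if l.startswith("@")]
        records = [l for l in lines if not l.startswith("@")]
        rng = np.random.default_rng(0)
        rng.shuffle(records)
        shuffled = tmp_path / "shuffled.sam"
        shuffled.write_text("\n".join(header + records) + "\n")
        a, _ = count_layers({"s": path}, ann)
        b, _ = count_layers({"s": str(shuffled)}, ann)
        assert a.spliced.equals(b.spliced)
        assert a.unspliced.equals(b.unspliced)
        assert a.ambiguous.equals(b.ambiguous)

    def test_empty_sam_gives_zero_matrices(self, tiny_ann, tmp_path):
        path = tmp_path / "empty.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:2000\n@SQ\tSN:chr2\tLN:1500\n"
        )
        lc, summary = count_layers({"s": str(path)}, tiny_ann)
        assert int(lc.total.sum().sum()) == 0

    def test_headerless_sam_is_error(self, tiny_ann, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text("r1\t0\tchr1\t151\t60\t50M\t*\t0\t0\t*\t*\n")
        with pytest.raises(Exception):
            count_layers({"s": str(path)}, tiny_ann)
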