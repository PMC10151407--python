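"""Coordinate arithmetic: GFF loading, genomic<->CDS maps, codon math."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_transcript
from varcascade.errors import ModelError, OutOfRangeError, ParseError
from varcascade.genome_model import (
    GenomicInterval,
    TranscriptModel,
    cds_to_genomic,
    codon_of,
    genomic_to_cds,
    load_gene_models,
)

CDS64 = "ATG" + "GCT" * 62 + "TAA"  # simple valid ORF for structural tests


# ----------------------------------------------------------------- loading
def _write_gff(tmp_path, lines):
    p = tmp_path / "m.gff3"
    p.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
    return str(p)


def test_single_exon_plus_strand_gene_loads(tmp_path):
    path = _write_gff(tmp_path, [
        "chr1\tx\tgene\t101\t400\t.\t+\t.\tID=g1;Name=G1",
        "chr1\tx\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1;gene_name=G1",
        "chr1\tx\texon\t101\t400\t.\t+\t.\tParent=t1",
        "chr1\tx\tCDS\t151\t350\t.\t+\t0\tParent=t1",
    ])
    models = load_gene_models(path)
    assert len(models) == 1
    t = models[0]
    assert len(t.exons) == 1
    assert t.gene_symbol == "G1"
    assert (t.cds_start, t.cds_end) == (150, 350)


def test_minus_strand_exons_in_transcription_order(tmp_path):
    path = _write_gff(tmp_path, [
        "chr1\tx\tgene\t101\t900\t.\t-\t.\tID=g1",
        "chr1\tx\tmRNA\t101\t900\t.\t-\t.\tID=t1;Parent=g1;gene_name=G1",
        "chr1\tx\texon\t101\t300\t.\t-\t.\tParent=t1",
        "chr1\tx\texon\t601\t900\t.\t-\t.\tParent=t1",
        "chr1\tx\tCDS\t151\t300\t.\t-\t0\tParent=t1",
        "chr1\tx\tCDS\t601\t850\t.\t-\t0\tParent=t1",
    ])
    t = load_gene_models(path)[0]
    # 3'-genomic exon first, i.e. transcription order on the minus strand
    assert [e.start for e in t.exons] == [600, 100]


def test_cds_outside_exons_is_model_error(tmp_path):
    path = _write_gff(tmp_path, [
        "chr1\tx\tgene\t101\t400\t.\t+\t.\tID=g1",
        "chr1\tx\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1",
        "chr1\tx\texon\t101\t400\t.\t+\t.\tParent=t1",
        "chr1\tx\tCDS\t151\t450\t.\t+\t0\tParent=t1",
    ])
    with pytest.raises(ModelError):
        load_gene_models(path)


def test_malformed_line_names_line_number(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("chr1\tx\tgene\t10\tnotanumber\t.\t+\t.\tID=g\n")
    with pytest.raises(ParseError, match=":1:"):
        load_gene_models(str(p))


def test_overlapping_exons_rejected():
    with pytest.raises(ModelError, match="overlap"):
        TranscriptModel(
            "t", "g", "+",
            [GenomicInterval("c", 0, 100), GenomicInterval("c", 50, 150)],
            cds_start=0, cds_end=150,
        )


# ------------------------------------------------------------- coordinates
def test_plus_strand_single_exon_direct_arithmetic():
    # CDS starting at genomic g0: position g0+307 must map to c.308
    t, _ = make_transcript(CDS64 * 2, utr5="A" * 20)  # 384-nt CDS
    g0 = cds_to_genomic(t, 1)
    cc = genomic_to_cds(t, g0 + 307)
    assert (cc.region_tag, cc.c_pos) == ("CDS", 308)


def test_first_intronic_base_has_offset_plus_one():
    cds = CDS64
    t, _ = make_transcript(cds, utr5="ACGTAC", intron_at=50)
    # exon 1 covers spliced positions 0..49 -> last exonic CDS base is c.44
    last_exon_g = t.exons[0].end  # first intronic base (0-based)
    cc = genomic_to_cds(t, last_exon_g + 1)
    assert cc.region_tag == "intron"
    assert cc.intron_offset == 1
    assert cc.c_pos == 44


def test_minus_strand_three_prime_most_cds_base_is_c1():
    # brute-force: walk the spliced sequence of a minus-strand transcript
    cds = CDS64
    t, genome = make_transcript(cds, strand="-", intron_at=60, utr5="GGGG")
    g1 = cds_to_genomic(t, 1)
    # on the minus strand c.1 is the genomically 3'-most (highest) CDS base
    all_cds_g = [cds_to_genomic(t, c) for c in range(1, len(cds) + 1)]
    assert g1 == max(all_cds_g)
    assert genomic_to_cds(t, g1).c_pos == 1


def test_utr_and_flank_classification():
    t, _ = make_transcript(CDS64, utr5="ACGTA", utr3="TTTTTT")
    g_utr5 = t.exons[0].start + 2  # inside the 5' UTR (plus strand)
    cc = genomic_to_cds(t, g_utr5 + 1)
    assert cc.region_tag == "UTR5" and cc.c_pos < 0
    g_utr3 = t.exons[-1].end - 2
    cc = genomic_to_cds(t, g_utr3 + 1)
    assert cc.region_tag == "UTR3" and cc.c_pos > 0
    assert genomic_to_cds(t, t.span.start - 100).region_tag == "upstream"
    assert genomic_to_cds(t, t.span.end + 101).region_tag == "downstream"
    with pytest.raises(OutOfRangeError):
        genomic_to_cds(t, t.span.end + 5001)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(c=st.integers(min_value=1, max_value=192), strand=st.sampled_from("+-"))
def test_round_trip_cds_coordinates(c, strand):
    t, _ = make_transcript(CDS64, strand=strand, intron_at=70, utr5="ACGT")
    g = cds_to_genomic(t, c)
    cc = genomic_to_cds(t, g)
    assert (cc.region_tag, cc.c_pos) == ("CDS", c)


def test_strand_symmetry_of_cds_mapping():
    """A transcript and its reverse-complement mirror give identical c maps."""
    cds = CDS64
    tp, _ = make_transcript(cds, strand="+", intron_at=70, utr5="ACGT")
    tm, _ = make_transcript(cds, strand="-", intron_at=70, utr5="ACGT")
    assert tp.cds_sequence() == tm.cds_sequence() == cds
    for c in (1, 2, 44, 100, 192):
        assert genomic_to_cds(tp, cds_to_genomic(tp, c)).c_pos == c
        assert genomic_to_cds(tm, cds_to_genomic(tm, c)).c_pos == c


# ------------------------------------------------------------------ codons
@pytest.mark.parametrize(
    "c_pos,expected",
    [(308, (103, 1)), (88, (30, 0)), (1, (1, 0)), (3, (1, 2)), (4, (2, 0))],
)
def test_codon_of(c_pos, expected):
    assert codon_of(c_pos) == expected


def test_codon_of_rejects_nonpositive():
    with pytest.raises(ValueError):
        codon_of(0)


def test_codon_of_agrees_with_triplet_partition():
    cds = "ACG" * 100  # 300-nt CDS
    triplets = [cds[i : i + 3] for i in range(0, 300, 3)]
    for c in range(1, 301):
        idx, frame = codon_of(c)
        assert triplets[idx - 1][frame] == cds[c - 1]
        assert (idx - 1) * 3 + frame == c - 1
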