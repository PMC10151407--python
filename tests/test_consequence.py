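"""Consequence annotation: SO terms, effect classes, protein naming."""

import pytest
from Bio.Seq import Seq

from conftest import make_transcript
from varcascade import hgvs as H
from varcascade.consequence import (
    EFFECT_CLASSES,
    SO_TERMS,
    TOP_CATEGORY,
    GenotypeCall,
    Variant,
    annotate,
    annotate_transcript,
    effect_class,
    protein_consequence,
)
from varcascade.errors import ReferenceMismatchError
from varcascade.fixtures import mini_cds
from varcascade.genome_model import GenomicInterval


# ------------------------------------------------------------ effect class
def test_effect_class_examples():
    assert effect_class("missense_variant") == "Missense"
    assert effect_class("splice_region") == "Other"
    assert effect_class("upstream_gene") == "Unknown"
    assert effect_class("stop_gained") == "LoF"
    assert effect_class("disruptive_inframe_deletion") == "Missense"


def test_effect_class_total_over_all_terms():
    classes = {effect_class(t) for t in SO_TERMS}
    assert classes == set(EFFECT_CLASSES)
    with pytest.raises(ValueError):
        effect_class("regulatory_region")


def test_top_category_partitions_all_terms():
    assert set(TOP_CATEGORY) == set(SO_TERMS)


# -------------------------------------------------------- worked examples
def _snv_on(t, c_pos, alt_c):
    """Build the genomic SNV corresponding to a coding-strand substitution."""
    from varcascade.genome_model import cds_to_genomic, reverse_complement

    g1 = cds_to_genomic(t, c_pos)
    ref_c = t.cds_sequence()[c_pos - 1]
    if t.strand == "+":
        ref_p, alt_p = ref_c, alt_c
    else:
        ref_p, alt_p = reverse_complement(ref_c), reverse_complement(alt_c)
    return Variant(GenomicInterval(t.chrom, g1 - 1, g1), ref_p, alt_p)


def test_albino_marker_missense():
    t, _ = make_transcript(mini_cds("TYR_LIKE"))
    ann = annotate_transcript(t, _snv_on(t, 308, "C"))
    assert ann.so_term == "missense_variant"
    assert ann.hgvs_p == "p.Cys103Ser"
    assert ann.hgvs_c == "c.308G>C"


def test_nonsense_at_codon_347():
    t, _ = make_transcript(mini_cds("PDE6B_LIKE"))
    ann = annotate_transcript(t, _snv_on(t, 1041, "A"))  # TAC -> TAA
    assert ann.so_term == "stop_gained"
    assert ann.hgvs_p == "p.Tyr347*"
    assert effect_class(ann.so_term) == "LoF"


def test_six_bp_deletion_is_disruptive_inframe_on_minus_strand():
    """The candidate deletion: minus-strand gene, genomic del CGTCCA = c.89_94delTGGACG."""
    cds = mini_cds("ABHD12_LIKE")
    t, genome = make_transcript(cds, strand="-", utr5="ACGTACG")
    from varcascade.genome_model import cds_to_genomic

    g_hi = cds_to_genomic(t, 89)  # genomic coordinates descend with c on minus
    g_lo = cds_to_genomic(t, 94)
    iv = GenomicInterval(t.chrom, g_lo - 1, g_hi)
    ref_plus = genome[t.chrom][iv.start : iv.end]
    assert ref_plus == "CGTCCA"
    ann = annotate_transcript(t, Variant(iv, ref_plus, ""))
    assert ann.so_term == "disruptive_inframe_deletion"
    assert ann.hgvs_c == "c.89_94delTGGACG"
    assert ann.hgvs_p == "p.Leu30_Ala32delinsPro"


def test_synonymous_third_position():
    t, _ = make_transcript("ATG" + "CTG" * 40 + "TAA")
    # codon 2 CTG -> CTA stays Leu
    ann = annotate_transcript(t, _snv_on(t, 6, "A"))
    assert ann.so_term == "synonymous"


def test_reference_mismatch_raises():
    t, _ = make_transcript(mini_cds("TYR_LIKE"))
    v = _snv_on(t, 308, "C")
    wrong = Variant(v.interval, "T" if v.ref != "T" else "A", v.alt)
    with pytest.raises(ReferenceMismatchError):
        annotate_transcript(t, wrong)


# ----------------------------------------------------- protein consequence
def test_delins_examples(abhd12_cds):
    assert (
        protein_consequence(abhd12_cds, H.parse_hgvs_c("c.88_94delCTGGACGinsT"))
        == "p.Leu30_Ala32delinsSer"
    )
    assert (
        protein_consequence(abhd12_cds, H.parse_hgvs_c("c.89_94delTGGACG"))
        == "p.Leu30_Ala32delinsPro"
    )


def test_codon_aligned_twelve_mer_duplication():
    # residues 5-8 = Trp Glu Met Glu; duplicating their codons -> 4-residue dup
    cds = "ATG" + "GCT" * 3 + "TGGGAGATGGAG" + "CCT" * 5 + "TAA"
    dup = H.CodingEdit("duplication", 13, 24, "", cds[12:24])
    assert protein_consequence(cds, dup) == "p.Trp5_Glu8dup"


def test_frameshift_names_first_changed_residue_and_stop_distance():
    # codon7..8 = GCT|AAG: the +1-shifted frame reads TAA there (new stop)
    cds = "ATG" + "GCT" * 6 + "AAG" + "GCT" * 4 + "TAA"
    dup = H.parse_hgvs_c("c.9dupT")  # 1-nt duplication -> frameshift at codon 4
    hp = protein_consequence(cds, dup)
    assert hp.startswith("p.Ala4") and "fs*" in hp
    # independent check of the new-stop distance by direct translation
    mutant = H.apply_edit(cds, dup)
    prot = str(Seq(mutant[: len(mutant) - len(mutant) % 3]).translate())
    stop = prot.index("*")
    assert hp.endswith(f"fs*{stop - 3 + 1}")


def test_frameshift_without_downstream_stop_uses_question_mark():
    cds = "ATG" + "GCT" * 20 + "TAA"  # shifted frame never hits a stop
    hp = protein_consequence(cds, H.parse_hgvs_c("c.9dupT"))
    assert hp.endswith("fs*?")


def test_whole_codon_deletion_is_plain_del():
    cds = "ATG" + "GCT" + "TGG" + "CCT" * 10 + "TAA"
    e = H.CodingEdit("deletion", 7, 9, "TGG", "")
    assert protein_consequence(cds, e) == "p.Trp3del"


def test_edit_outside_cds_is_domain_error(abhd12_cds):
    with pytest.raises(ValueError):
        protein_consequence(abhd12_cds, H.CodingEdit("substitution", 500, 500, "A", "C"))


# ---------------------------------------------------------- oracle battery
def _oracle_term(cds: str, pos: int, alt: str) -> str | None:
    """Brute-force translate-and-diff classification of a single-base edit."""
    mutant = cds[: pos - 1] + alt + cds[pos:]
    p_ref = str(Seq(cds).translate())
    p_mut = str(Seq(mutant).translate())
    codon_idx = (pos - 1) // 3
    old_aa, new_aa = p_ref[codon_idx], p_mut[codon_idx]
    if old_aa == new_aa:
        return "stop_retained" if old_aa == "*" else "synonymous"
    if new_aa == "*":
        return "stop_gained"
    if old_aa == "*":
        return "stop_lost"
    return "missense_variant"


def test_all_576_single_base_edits_match_oracle(abhd12_cds):
    """Exhaustive SNV battery on the 64-codon CDS vs an independent oracle."""
    assert len(abhd12_cds) == 192
    t, _ = make_transcript(abhd12_cds)
    mismatches = []
    checked = 0
    for pos in range(1, 193):
        for alt in "ACGT":
            if alt == abhd12_cds[pos - 1]:
                continue
            checked += 1
            expected = _oracle_term(abhd12_cds, pos, alt)
            if pos <= 3:
                expected = "start_lost"  # initiator codon outranks the diff
            got = annotate_transcript(t, _snv_on(t, pos, alt)).so_term
            if got != expected:
                mismatches.append((pos, alt, expected, got))
    assert checked == 576
    assert not mismatches


# -------------------------------------------------- indel frame properties
def test_inframe_frameshift_law():
    cds = "ATG" + "GCTTGGGACGCCAAACTTAGACCT" * 6 + "TAA"
    t, genome = make_transcript(cds)
    from varcascade.genome_model import cds_to_genomic

    for c_start, k in [(10, 3), (11, 3), (13, 6), (10, 1), (11, 2), (14, 4)]:
        g1 = cds_to_genomic(t, c_start)
        iv = GenomicInterval(t.chrom, g1 - 1, g1 - 1 + k)
        v = Variant(iv, genome[t.chrom][iv.start : iv.end], "")
        term = annotate_transcript(t, v).so_term
        if k % 3 == 0:
            assert term in (
                "inframe_deletion", "disruptive_inframe_deletion",
            ), (c_start, k, term)
        else:
            assert term == "frameshift_variant", (c_start, k, term)


def test_codon_aligned_deletion_plain_unaligned_disruptive():
    # codon-aligned deletions stay aligned after 3'-normalization here: the
    # base following each deleted span differs from the span's first base
    cds = "ATG" + "GCATGGGACCTTAAGTTC" * 4 + "TAA"
    t, genome = make_transcript(cds)
    from varcascade.genome_model import cds_to_genomic

    def term_for(c_start):
        g1 = cds_to_genomic(t, c_start)
        iv = GenomicInterval(t.chrom, g1 - 1, g1 + 2)
        return annotate_transcript(
            t, Variant(iv, genome[t.chrom][iv.start : iv.end], "")
        ).so_term

    assert term_for(10) == "inframe_deletion"  # codon boundary
    assert term_for(11) == "disruptive_inframe_deletion"  # breaks codons


# -------------------------------------------------------- multi-transcript
def test_most_severe_transcript_reported():
    """Overlapping transcripts: the missense one is the clinically relevant row."""
    cds_a = "ATG" + "TGG" * 30 + "TAA"
    t1, genome = make_transcript(cds_a, gene="GeneA", offset=100)
    # a second, non-coding transcript over the same locus
    from varcascade.genome_model import TranscriptModel

    t2 = TranscriptModel(
        "GeneB.t1", "GeneB", "+",
        [GenomicInterval(t1.chrom, t1.span.start, t1.span.end)],
        biotype="non_coding",
    )
    t2.attach_genome(genome)
    v = _snv_on(t1, 10, "C")  # TGG -> TGC missense in GeneA, exonic in GeneB
    av = annotate(v, [GenotypeCall("s", ("alt", "alt"), 30, 30)], [t1, t2])
    assert av.gene_symbol == "GeneA"
    assert av.so_term == "missense_variant"
    terms = {a.gene_symbol: a.so_term for a in av.transcript_annotations}
    assert terms["GeneB"] == "non_coding_exon"
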