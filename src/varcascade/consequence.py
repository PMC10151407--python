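"""Variant consequence annotation.

Each variant is assigned a sequence-ontology (SO) term against every
overlapping transcript; the reported annotation is the most severe across
transcripts. SO terms roll up into the four-way clinically-relevant effect
classes used for candidate triage: Missense (amino-acid changing but
length-preserving at the reading-frame level), LoF (loss-of-function), Other
(silent or regulatory-adjacent), Unknown (intergenic flanks).

Splice windows follow common annotator convention: the 2 intronic bases at
each junction are splice_acceptor/splice_donor, intronic positions 3-8 and
the last/first 3 exonic bases are splice_region (an exonic splice_region call
is reported only when it outranks the coding consequence in severity).

In-frame indels are *disruptive* when their (3'-normalized) boundaries break
codon boundaries, producing a protein-level delins; whole-codon gains/losses
are plain inframe_insertion/inframe_deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from . import hgvs as H
from .errors import DataError, ReferenceMismatchError
from .genome_model import (
    GenomicInterval,
    TranscriptModel,
    codon_of,
    genomic_to_cds,
    reverse_complement,
)

# ---------------------------------------------------------------- vocabulary
SO_TERMS = (
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "splice_acceptor",
    "splice_donor",
    "disruptive_inframe_deletion",
    "disruptive_inframe_insertion",
    "inframe_deletion",
    "inframe_insertion",
    "missense_variant",
    "splice_region",
    "stop_retained",
    "synonymous",
    "UTR5",
    "UTR3",
    "non_coding_exon",
    "intron",
    "upstream_gene",
    "downstream_gene",
)
#: lower rank = more severe; fixed tie-break for multi-transcript annotation
SEVERITY = {term: i for i, term in enumerate(SO_TERMS)}

EFFECT_CLASSES = ("Missense", "LoF", "Other", "Unknown")

_EFFECT_MAP = {
    "missense_variant": "Missense",
    "inframe_insertion": "Missense",
    "inframe_deletion": "Missense",
    "disruptive_inframe_insertion": "Missense",
    "disruptive_inframe_deletion": "Missense",
    "splice_acceptor": "LoF",
    "splice_donor": "LoF",
    "frameshift_variant": "LoF",
    "stop_gained": "LoF",
    "stop_lost": "LoF",
    "start_lost": "LoF",
    "intron": "Other",
    "synonymous": "Other",
    "splice_region": "Other",
    "UTR3": "Other",
    "UTR5": "Other",
    "non_coding_exon": "Other",
    "stop_retained": "Other",
    "upstream_gene": "Unknown",
    "downstream_gene": "Unknown",
}

#: roll-up of SO terms into the 13 top-level tabulation categories
TOP_CATEGORY = {
    "intron": "intron",
    "synonymous": "synonymous",
    "missense_variant": "missense",
    "splice_acceptor": "splice_site",
    "splice_donor": "splice_site",
    "splice_region": "splice_site",
    "UTR3": "UTR",
    "UTR5": "UTR",
    "non_coding_exon": "non_coding_exon",
    "upstream_gene": "upstream_gene",
    "downstream_gene": "downstream_gene",
    "inframe_deletion": "inframe_indel",
    "inframe_insertion": "inframe_indel",
    "frameshift_variant": "frameshift",
    "stop_gained": "stop_codon",
    "stop_lost": "stop_codon",
    "stop_retained": "stop_codon",
    "start_lost": "start_codon",
    "disruptive_inframe_deletion": "disruptive_inframe_indel",
    "disruptive_inframe_insertion": "disruptive_inframe_indel",
}

TOP_CATEGORIES = (
    "intron",
    "synonymous",
    "missense",
    "splice_site",
    "UTR",
    "non_coding_exon",
    "upstream_gene",
    "downstream_gene",
    "inframe_indel",
    "frameshift",
    "stop_codon",
    "start_codon",
    "disruptive_inframe_indel",
)


def effect_class(so_term: str) -> str:
    """Map an SO term to its clinically-relevant effect class (total mapping)."""
    try:
        return _EFFECT_MAP[so_term]
    except KeyError:
        raise ValueError(f"unknown sequence-ontology term {so_term!r}") from None


AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "*",
}


def aa3(residue: str) -> str:
    return AA3[residue]


#: standard-code codon table as a plain dict (hot path: per-base classification)
CODON_AA = {
    codon: str(Seq(codon).translate())
    for codon in (a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
}


# -------------------------------------------------------------------- inputs
@dataclass(frozen=True)
class Variant:
    """One genomic change in trimmed representation (no shared anchor bases).

    ``interval.start`` is the 0-based position of the first reference base
    affected; for a pure insertion the interval is the single base immediately
    5' (genomically left) of the insertion point.
    """

    interval: GenomicInterval
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref and not self.alt:
            raise DataError("ref and alt cannot both be empty")
        for a in (self.ref, self.alt):
            if a and set(a) - set("ACGT"):
                raise DataError(f"non-ACGT allele {a!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def pos(self) -> int:
        """1-based position of the first affected base (or anchor for insertions)."""
        return self.interval.start + 1

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if not self.ref:
            return "insertion"
        if not self.alt:
            return "deletion"
        return "delins"


def variant_from_vcf(chrom: str, pos1: int, ref: str, alt: str) -> Variant:
    """Trim a VCF-style (anchored) allele pair down to a minimal Variant."""
    # shared suffix first, then shared prefix (keeps VCF left-anchoring)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos1 += 1
    if not ref:  # pure insertion: anchor on the base left of the insertion point
        return Variant(GenomicInterval(chrom, pos1 - 2, pos1 - 1), "", alt)
    return Variant(GenomicInterval(chrom, pos1 - 1, pos1 - 1 + len(ref)), ref, alt)


@dataclass(frozen=True)
class GenotypeCall:
    """Genotype plus read support for one sample at one site.

    Alleles are symbolic ``"ref"``/``"alt"`` labels (unphased pair).
    """

    sample: str
    alleles: tuple[str, str]
    depth: int = 0
    alt_reads: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise DataError("negative read counts")
        if self.alt_reads > self.depth:
            raise DataError("alt_reads exceeds depth")
        bad = set(self.alleles) - {"ref", "alt"}
        if bad:
            raise DataError(f"alleles must be 'ref'/'alt', got {bad}")

    @property
    def has_alt(self) -> bool:
        return "alt" in self.alleles

    @property
    def is_hom_alt(self) -> bool:
        return self.alleles == ("alt", "alt")

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles == ("ref", "ref")

    @property
    def alt_fraction(self) -> float:
        if self.depth == 0:
            raise DataError(f"{self.sample}: zero depth with a called genotype")
        return self.alt_reads / self.depth


@dataclass
class AnnotatedVariant:
    """A variant with its (most severe) transcript-level annotation."""

    variant: Variant
    genotypes: list[GenotypeCall] = field(default_factory=list)
    gene_symbol: str = ""
    transcript_id: str = ""
    so_term: str = "upstream_gene"
    region_label: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    effect_class: str = "Unknown"
    external_scores: dict = field(default_factory=dict)
    #: all per-transcript annotations, most severe first
    transcript_annotations: list = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def genotype(self, sample: str) -> GenotypeCall:
        for g in self.genotypes:
            if g.sample == sample:
                return g
        raise KeyError(sample)

    def has_sample(self, sample: str) -> bool:
        return any(g.sample == sample for g in self.genotypes)


# ------------------------------------------------------- protein consequence
def _translate(seq: str) -> str:
    """Translate up to and including the first stop; ignore a trailing partial codon."""
    usable = seq[: len(seq) - len(seq) % 3]
    prot = str(Seq(usable).translate())
    stop = prot.find("*")
    return prot if stop == -1 else prot[: stop + 1]


def _shift_right_del(p: str, i: int, length: int) -> int:
    while i + length < len(p) and p[i] == p[i + length]:
        i += 1
    return i


def protein_consequence(cds: str, edit: H.CodingEdit) -> str:
    """HGVS ``p.`` description of a coding edit applied to a CDS string.

    Single-residue substitutions are ``p.Xpos Y``; clean whole-codon events are
    ``del``/``dup``/``ins``; boundary-breaking in-frame events are ``delins``;
    frameshifts are ``p.XposYfs*N`` with N counted from the first changed
    residue to the new stop ('?' when no stop is reached).
    """
    if edit.non_cds_flag:
        raise ValueError(f"edit lies outside the CDS ({edit.non_cds_flag})")
    span_end = edit.end_c if edit.kind != "insertion" else edit.end_c - 1
    if edit.start_c < 1 or span_end > len(cds):
        raise ValueError("edit outside CDS")
    mutant = H.apply_edit(cds, edit)
    p_ref = _translate(cds)
    p_mut = _translate(mutant)

    if (len(mutant) - len(cds)) % 3 != 0:
        i = 0
        while i < min(len(p_ref), len(p_mut)) and p_ref[i] == p_mut[i]:
            i += 1
        if i >= len(p_mut):
            return "p.?"
        if p_mut[i] == "*":
            return f"p.{aa3(p_ref[i])}{i + 1}*"
        stop = p_mut.find("*", i)
        n = str(stop - i + 1) if stop != -1 else "?"
        return f"p.{aa3(p_ref[i])}{i + 1}{aa3(p_mut[i])}fs*{n}"

    if p_ref == p_mut:
        return "p.(=)"

    i = 0
    while i < min(len(p_ref), len(p_mut)) and p_ref[i] == p_mut[i]:
        i += 1
    if i < len(p_mut) and p_mut[i] == "*":
        # premature stop: nonsense naming regardless of the nucleotide event
        return f"p.{aa3(p_ref[i])}{i + 1}*"
    s = 0
    while (
        s < len(p_ref) - i and s < len(p_mut) - i and p_ref[-1 - s] == p_mut[-1 - s]
    ):
        s += 1
    ref_ch = p_ref[i : len(p_ref) - s]
    alt_ch = p_mut[i : len(p_mut) - s]

    if len(ref_ch) == 1 and len(alt_ch) == 1:
        if ref_ch == "*":
            stop = p_mut.find("*", i)
            ext = str(stop - i) if stop != -1 else "?"
            return f"p.*{i + 1}{aa3(alt_ch)}ext*{ext}"
        return f"p.{aa3(ref_ch)}{i + 1}{aa3(alt_ch)}"

    if not alt_ch:  # clean residue loss: 3'-most position
        i = _shift_right_del(p_ref, i, len(ref_ch))
        ref_ch = p_ref[i : i + len(ref_ch)]
        if len(ref_ch) == 1:
            return f"p.{aa3(ref_ch)}{i + 1}del"
        return f"p.{aa3(ref_ch[0])}{i + 1}_{aa3(ref_ch[-1])}{i + len(ref_ch)}del"

    if not ref_ch:  # clean residue gain: shift 3', then test for duplication
        ins = alt_ch
        while i < len(p_ref) and p_ref[i] == ins[0]:
            ins = ins[1:] + ins[0]
            i += 1
        k = len(ins)
        if i >= k and p_ref[i - k : i] == ins:
            if k == 1:
                return f"p.{aa3(ins)}{i}dup"
            return f"p.{aa3(ins[0])}{i - k + 1}_{aa3(ins[-1])}{i}dup"
        ins3 = "".join(aa3(a) for a in ins)
        return f"p.{aa3(p_ref[i - 1])}{i}_{aa3(p_ref[i])}{i + 1}ins{ins3}"

    alt3 = "".join(aa3(a) for a in alt_ch)
    if len(ref_ch) == 1:
        return f"p.{aa3(ref_ch)}{i + 1}delins{alt3}"
    return (
        f"p.{aa3(ref_ch[0])}{i + 1}_{aa3(ref_ch[-1])}{i + len(ref_ch)}delins{alt3}"
    )


# ------------------------------------------------------------------ annotate
@dataclass(frozen=True)
class TranscriptAnnotation:
    transcript_id: str
    gene_symbol: str
    so_term: str
    region_label: str
    hgvs_c: str
    hgvs_p: str


def _exonic_splice_proximity(t: TranscriptModel, gpos0: int) -> bool:
    """True when an exonic base lies within 3 nt of an exon/intron junction."""
    idx = t.exon_index_of(gpos0)
    if idx is None:
        return False
    e = t.exons[idx - 1]
    tx_in_exon = (gpos0 - e.start) if t.strand == "+" else (e.end - 1 - gpos0)
    near_start = tx_in_exon < 3 and idx > 1
    near_end = (len(e) - 1 - tx_in_exon) < 3 and idx < len(t.exons)
    return near_start or near_end


def _pick(term: str, alternative: str) -> str:
    return term if SEVERITY[term] <= SEVERITY[alternative] else alternative


def _snv_coding_term(t: TranscriptModel, c_pos: int, alt_c: str) -> tuple[str, str]:
    """(so_term, hgvs_p) for a coding-strand SNV at a CDS position."""
    cds = t.cds_sequence()
    codon_idx, frame = codon_of(c_pos)
    codon = cds[(codon_idx - 1) * 3 : codon_idx * 3]
    new_codon = codon[:frame] + alt_c + codon[frame + 1 :]
    old_aa = CODON_AA[codon]
    new_aa = CODON_AA[new_codon]
    if old_aa == new_aa:
        term = "stop_retained" if old_aa == "*" else "synonymous"
        hp = f"p.{aa3(old_aa)}{codon_idx}=" if old_aa != "*" else f"p.*{codon_idx}="
    elif new_aa == "*":
        term, hp = "stop_gained", f"p.{aa3(old_aa)}{codon_idx}*"
    elif old_aa == "*":
        term, hp = "stop_lost", f"p.*{codon_idx}{aa3(new_aa)}ext*?"
    elif codon_idx == 1:
        term, hp = "start_lost", "p.Met1?"
    else:
        term, hp = "missense_variant", f"p.{aa3(old_aa)}{codon_idx}{aa3(new_aa)}"
    return term, hp


def _annotate_snv(t: TranscriptModel, v: Variant) -> TranscriptAnnotation:
    gpos = v.pos
    cc = genomic_to_cds(t, gpos)
    ref_c = v.ref if t.strand == "+" else reverse_complement(v.ref)
    alt_c = v.alt if t.strand == "+" else reverse_complement(v.alt)
    region_label = ""
    hgvs_p = ""

    if cc.region_tag in ("upstream", "downstream"):
        term = "upstream_gene" if cc.region_tag == "upstream" else "downstream_gene"
        return TranscriptAnnotation(t.transcript_id, t.gene_symbol, term, "", "", "")

    if cc.region_tag == "intron":
        off = cc.intron_offset
        if abs(off) <= 2:
            term = "splice_donor" if off > 0 else "splice_acceptor"
        elif abs(off) <= 8:
            term = "splice_region"
        else:
            term = "intron"
        region_label = f"intron {cc.region_index}"
        anchor = _format_anchor(cc)
        hgvs_c = f"c.{anchor}{off:+d}{ref_c}>{alt_c}"
        if t.biotype != "coding":
            hgvs_c = f"n.{cc.c_pos}{off:+d}{ref_c}>{alt_c}"
        return TranscriptAnnotation(
            t.transcript_id, t.gene_symbol, term, region_label, hgvs_c, ""
        )

    region_label = f"exon {cc.region_index}"
    if cc.region_tag == "non_coding":
        term = "non_coding_exon"
        hgvs_c = f"n.{cc.c_pos}{ref_c}>{alt_c}"
    elif cc.region_tag == "UTR5":
        term = "UTR5"
        hgvs_c = f"c.{cc.c_pos}{ref_c}>{alt_c}"  # c_pos is negative
    elif cc.region_tag == "UTR3":
        term = "UTR3"
        hgvs_c = f"c.*{cc.c_pos}{ref_c}>{alt_c}"
    else:
        # verify the reference against the CDS
        cds = t.cds_sequence()
        if cds[cc.c_pos - 1] != ref_c:
            raise ReferenceMismatchError(
                f"{t.transcript_id}: reference {v.ref} disagrees with CDS at c.{cc.c_pos}"
            )
        term, hgvs_p = _snv_coding_term(t, cc.c_pos, alt_c)
        hgvs_c = f"c.{cc.c_pos}{ref_c}>{alt_c}"
    if _exonic_splice_proximity(t, v.pos - 1):
        term = _pick(term, "splice_region")
        if term == "splice_region":
            hgvs_p = ""
    return TranscriptAnnotation(
        t.transcript_id, t.gene_symbol, term, region_label, hgvs_c, hgvs_p
    )


def _format_anchor(cc) -> str:
    if cc.anchor_region == "UTR3":
        return f"*{cc.c_pos}"
    return str(cc.c_pos)


def _indel_cds_edit(t: TranscriptModel, v: Variant) -> H.CodingEdit | None:
    """Express a genomic indel as a CDS edit, or None if not fully coding."""
    if v.kind == "insertion":
        # insertion between genomic v.interval.start and +1
        left, right = v.interval.start, v.interval.start + 1
        cl = genomic_to_cds(t, left + 1)
        cr = genomic_to_cds(t, right + 1)
        if cl.region_tag != "CDS" or cr.region_tag != "CDS":
            return None
        ins = v.alt if t.strand == "+" else reverse_complement(v.alt)
        start = min(cl.c_pos, cr.c_pos)
        return H.CodingEdit("insertion", start, start + 1, "", ins)
    first, last = v.interval.start, v.interval.end - 1
    ca = genomic_to_cds(t, first + 1)
    cb = genomic_to_cds(t, last + 1)
    if ca.region_tag != "CDS" or cb.region_tag != "CDS":
        return None
    ref_c = v.ref if t.strand == "+" else reverse_complement(v.ref)
    alt_c = v.alt if t.strand == "+" else reverse_complement(v.alt)
    start, end = sorted((ca.c_pos, cb.c_pos))
    if v.alt:
        return H.CodingEdit("delins", start, end, ref_c, alt_c)
    return H.CodingEdit("deletion", start, end, ref_c, "")


def _classify_inframe(edit: H.CodingEdit, cds: str) -> str:
    e = H.normalize(edit, cds)
    if e.kind in ("insertion", "duplication"):
        anchor = e.end_c if e.kind == "duplication" else e.start_c
        aligned = anchor % 3 == 0
        return "inframe_insertion" if aligned else "disruptive_inframe_insertion"
    if e.kind == "deletion":
        aligned = (e.start_c - 1) % 3 == 0 and len(
            e.deleted_seq or cds[e.start_c - 1 : e.end_c]
        ) % 3 == 0
        return "inframe_deletion" if aligned else "disruptive_inframe_deletion"
    # equal-length or mixed delins: judge by the protein-level outcome
    net = e.length_change
    if net < 0:
        return "disruptive_inframe_deletion"
    if net > 0:
        return "disruptive_inframe_insertion"
    hp = protein_consequence(cds, e)
    return "missense_variant" if "delins" not in hp and hp != "p.(=)" else (
        "synonymous" if hp == "p.(=)" else "disruptive_inframe_deletion"
    )


def _annotate_indel(t: TranscriptModel, v: Variant) -> TranscriptAnnotation:
    edit = _indel_cds_edit(t, v)
    if edit is None:
        # not a clean coding indel: classify by the most severe region touched
        positions = range(v.interval.start, v.interval.end)
        terms = []
        for g in positions:
            try:
                terms.append(_annotate_snv(t, Variant(
                    GenomicInterval(v.chrom, g, g + 1), t.base_at(g), _other_base(t.base_at(g))
                )).so_term)
            except Exception:
                continue
        term = min(terms, key=lambda x: SEVERITY[x]) if terms else "intron"
        if term in ("missense_variant", "synonymous", "stop_gained", "stop_lost",
                    "stop_retained", "start_lost"):
            term = "frameshift_variant" if abs(len(v.ref) - len(v.alt)) % 3 else term
        return TranscriptAnnotation(t.transcript_id, t.gene_symbol, term, "", "", "")

    cds = t.cds_sequence()
    # verify the stated reference bases
    if edit.deleted_seq:
        got = cds[edit.start_c - 1 : edit.end_c]
        if got != edit.deleted_seq:
            raise ReferenceMismatchError(
                f"{t.transcript_id}: reference {edit.deleted_seq} vs CDS {got} "
                f"at c.{edit.start_c}"
            )
    norm = H.normalize(edit, cds)
    if abs(edit.length_change) % 3 != 0:
        term = "frameshift_variant"
    else:
        term = _classify_inframe(edit, cds)
    hgvs_c = H.format_hgvs_c(norm)
    hgvs_p = protein_consequence(cds, norm)
    gpos0 = v.interval.start
    idx = t.exon_index_of(gpos0) or t.exon_index_of(v.interval.end - 1) or 0
    return TranscriptAnnotation(
        t.transcript_id, t.gene_symbol, term, f"exon {idx}", hgvs_c, hgvs_p
    )


def _other_base(b: str) -> str:
    return "A" if b != "A" else "G"


def annotate_transcript(t: TranscriptModel, v: Variant) -> TranscriptAnnotation:
    if v.kind == "SNV":
        return _annotate_snv(t, v)
    return _annotate_indel(t, v)


def annotate(
    v: Variant,
    genotypes: list[GenotypeCall],
    models: list[TranscriptModel],
    index: dict[str, list[TranscriptModel]] | None = None,
) -> AnnotatedVariant:
    """Annotate one variant against all overlapping transcript models.

    Every transcript whose span (±5 kb flank) covers the variant is annotated;
    the most severe annotation (by the fixed severity order) is reported at
    the top level, with the per-transcript list preserved.
    """
    from .genome_model import FLANK_WINDOW, index_by_chrom

    if index is None:
        index = index_by_chrom(models)
    hits = []
    for t in index.get(v.chrom, []):
        sp = t.span
        if sp.start - FLANK_WINDOW <= v.interval.start < sp.end + FLANK_WINDOW:
            hits.append(annotate_transcript(t, v))
    if not hits:
        return AnnotatedVariant(variant=v, genotypes=list(genotypes))
    hits.sort(key=lambda a: SEVERITY[a.so_term])
    best = hits[0]
    av = AnnotatedVariant(
        variant=v,
        genotypes=list(genotypes),
        gene_symbol=best.gene_symbol,
        transcript_id=best.transcript_id,
        so_term=best.so_term,
        region_label=best.region_label,
        hgvs_c=best.hgvs_c,
        hgvs_p=best.hgvs_p,
        effect_class=effect_class(best.so_term),
        transcript_annotations=hits,
    )
    if best.so_term == "UTR5":
        av.notes.append("UTR5_effect_class_other")
    return av
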