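"""Gene models and coordinate arithmetic.

Transcript structures are loaded from GFF3 (via :mod:`gffutils`) together with
a reference FASTA, and converted between genomic, spliced-transcript, coding
(HGVS ``c.``), and codon coordinates on either strand.

Conventions
-----------
* Internal coordinates are 0-based half-open; everything read from or written
  to disk (GFF3, VCF, HGVS, marker strings) is 1-based inclusive.
* ``exons`` are kept in *transcription* order: ascending genomic coordinates
  on the plus strand, descending on the minus strand.
* Positions up to ``FLANK_WINDOW`` (5 kb) outside the transcript span are
  classified upstream/downstream; beyond that an :class:`OutOfRangeError` is
  raised.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
from Bio.Seq import Seq

from .errors import ModelError, OutOfRangeError, ParseError

#: Half-width of the upstream/downstream classification window (bp).
FLANK_WINDOW = 5000

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval: ``start`` 0-based inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ModelError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CdsCoordinate:
    """A genomic position expressed in the coding-DNA frame of one transcript.

    ``c_pos`` is the 1-based CDS position for coding positions; for 5'-UTR
    positions it is negative (HGVS ``c.-n``), for 3'-UTR positions it is the
    positive offset past the stop codon (HGVS ``c.*n``), and for non-coding
    transcripts it is the 1-based spliced position (HGVS ``n.``).
    ``intron_offset`` is nonzero only for intronic positions and is the signed
    HGVS offset from the anchor exonic base identified by ``c_pos`` /
    ``anchor_region``.
    """

    c_pos: int
    intron_offset: int
    region_tag: str  # CDS | UTR5 | UTR3 | intron | upstream | downstream | non_coding
    #: region of the anchor base for intronic positions (CDS/UTR5/UTR3/non_coding)
    anchor_region: str = "CDS"
    #: 1-based exon or intron index in transcription order, 0 outside the span
    region_index: int = 0

    def __post_init__(self) -> None:
        if self.intron_offset != 0 and self.region_tag != "intron":
            raise ModelError("intron_offset must be 0 outside introns")
        if self.region_tag == "CDS" and self.c_pos < 1:
            raise ModelError("coding positions are 1-based")


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on one strand."""

    transcript_id: str
    gene_symbol: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int | None = None  # genomic 0-based inclusive bound of the CDS
    cds_end: int | None = None  # genomic 0-based exclusive bound
    biotype: str = "coding"

    # lazy caches
    _tx_offsets: list[int] = field(default_factory=list, repr=False)
    _genome: dict | None = field(default=None, repr=False)
    _cds_seq: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ModelError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ModelError(f"{self.transcript_id}: exons on multiple chromosomes")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ModelError(f"{self.transcript_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if self.exons != expected:
            raise ModelError(
                f"{self.transcript_id}: exon order inconsistent with strand"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ModelError(f"{self.transcript_id}: half-specified CDS")
        if self.cds_start is not None:
            if not self.cds_start < self.cds_end:
                raise ModelError(f"{self.transcript_id}: empty CDS")
            lo, hi = genomic[0].start, genomic[-1].end
            if self.cds_start < lo or self.cds_end > hi:
                raise ModelError(f"{self.transcript_id}: CDS outside exon span")
            # every CDS base must fall in some exon
            for bound in (self.cds_start, self.cds_end - 1):
                if not any(e.contains(bound) for e in self.exons):
                    raise ModelError(
                        f"{self.transcript_id}: CDS bound {bound + 1} outside exons"
                    )
        off = 0
        self._tx_offsets = []
        for e in self.exons:
            self._tx_offsets.append(off)
            off += len(e)
        if self.biotype == "coding" and self.cds_start is None:
            raise ModelError(f"{self.transcript_id}: coding transcript without CDS")

    # ------------------------------------------------------------------ basics
    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, lo, hi)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def attach_genome(self, genome: dict[str, str]) -> None:
        """Attach chromosome sequences (plain upper-case strings)."""
        self._genome = genome
        self._cds_seq = None

    # -------------------------------------------------------- coordinate maps
    def genomic_to_tx(self, gpos0: int) -> int | None:
        """0-based genomic position -> 0-based spliced position, None if intronic."""
        for e, off in zip(self.exons, self._tx_offsets):
            if e.contains(gpos0):
                if self.strand == "+":
                    return off + (gpos0 - e.start)
                return off + (e.end - 1 - gpos0)
        return None

    def tx_to_genomic(self, tx: int) -> int:
        if not 0 <= tx < self.spliced_length:
            raise OutOfRangeError(f"tx position {tx} outside transcript")
        i = bisect_right(self._tx_offsets, tx) - 1
        e, off = self.exons[i], self._tx_offsets[i]
        if self.strand == "+":
            return e.start + (tx - off)
        return e.end - 1 - (tx - off)

    @property
    def cds_tx_bounds(self) -> tuple[int, int] | None:
        """Spliced (0-based, half-open) bounds of the CDS, in transcription order."""
        if self.cds_start is None:
            return None
        if self.strand == "+":
            first, last = self.cds_start, self.cds_end - 1
        else:
            first, last = self.cds_end - 1, self.cds_start
        a = self.genomic_to_tx(first)
        b = self.genomic_to_tx(last)
        if a is None or b is None:
            raise ModelError(f"{self.transcript_id}: CDS bound not exonic")
        return a, b + 1

    @property
    def cds_length(self) -> int:
        b = self.cds_tx_bounds
        return 0 if b is None else b[1] - b[0]

    # --------------------------------------------------------------- sequence
    def _chrom_seq(self) -> str:
        if self._genome is None:
            raise ModelError(f"{self.transcript_id}: no genome attached")
        return self._genome[self.chrom]

    def spliced_sequence(self) -> str:
        seq = self._chrom_seq()
        parts = []
        for e in self.exons:
            s = seq[e.start : e.end]
            parts.append(s if self.strand == "+" else reverse_complement(s))
        return "".join(parts).upper()

    def cds_sequence(self) -> str:
        """Spliced CDS on the coding strand, 5'->3'."""
        if self._cds_seq is None:
            b = self.cds_tx_bounds
            if b is None:
                raise ModelError(f"{self.transcript_id}: non-coding transcript")
            self._cds_seq = self.spliced_sequence()[b[0] : b[1]]
        return self._cds_seq

    def protein_sequence(self) -> str:
        return str(Seq(self.cds_sequence()).translate())

    # -------------------------------------------------------------- exon info
    def exon_index_of(self, gpos0: int) -> int | None:
        """1-based exon index in transcription order, None if intronic."""
        for i, e in enumerate(self.exons, 1):
            if e.contains(gpos0):
                return i
        return None

    def base_at(self, gpos0: int) -> str:
        return self._chrom_seq()[gpos0].upper()


# ----------------------------------------------------------------- operations
def codon_of(c_pos: int) -> tuple[int, int]:
    """Map a 1-based CDS position to (1-based codon index, frame offset 0..2)."""
    if c_pos < 1:
        raise ValueError(f"CDS positions are 1-based, got {c_pos}")
    return math.ceil(c_pos / 3), (c_pos - 1) % 3


def _tx_to_anchor(t: TranscriptModel, tx: int) -> tuple[int, str]:
    """Spliced position -> (signed c-style number, region tag) for exonic bases."""
    if t.biotype != "coding" or t.cds_start is None:
        return tx + 1, "non_coding"
    lo, hi = t.cds_tx_bounds
    if tx < lo:
        return -(lo - tx), "UTR5"
    if tx >= hi:
        return tx - hi + 1, "UTR3"
    return tx - lo + 1, "CDS"


def genomic_to_cds(t: TranscriptModel, gpos: int) -> CdsCoordinate:
    """Map a 1-based genomic position into transcript coding coordinates.

    Exonic coding positions get a plain ``c_pos``; intronic positions get the
    HGVS nearest-exon anchor with a signed offset (ties go to the upstream,
    ``+``, side); UTR and non-coding positions are tagged accordingly.
    """
    gpos0 = gpos - 1
    span = t.span
    if gpos0 < span.start or gpos0 >= span.end:
        if gpos0 < span.start - FLANK_WINDOW or gpos0 >= span.end + FLANK_WINDOW:
            raise OutOfRangeError(
                f"{t.transcript_id}: position {gpos} beyond ±{FLANK_WINDOW} bp flank"
            )
        before = gpos0 < span.start  # genomically left of the span
        upstream = before if t.strand == "+" else not before
        return CdsCoordinate(0, 0, "upstream" if upstream else "downstream")

    tx = t.genomic_to_tx(gpos0)
    if tx is not None:
        c, tag = _tx_to_anchor(t, tx)
        return CdsCoordinate(
            c, 0, tag if tag != "non_coding" else "non_coding",
            anchor_region=tag, region_index=t.exon_index_of(gpos0) or 0,
        )

    # intronic: flanking exons in transcription order
    for i, (a, b) in enumerate(zip(t.exons, t.exons[1:]), 1):
        if t.strand == "+":
            inside = a.end <= gpos0 < b.start
            d_prev, d_next = gpos0 - a.end + 1, b.start - gpos0
        else:
            inside = b.end <= gpos0 < a.start
            d_prev, d_next = a.start - gpos0, gpos0 - b.end + 1
        if not inside:
            continue
        if d_prev <= d_next:
            anchor_tx = t._tx_offsets[i - 1] + len(a) - 1  # last base of prev exon
            offset = d_prev
        else:
            anchor_tx = t._tx_offsets[i]  # first base of next exon
            offset = -d_next
        c, tag = _tx_to_anchor(t, anchor_tx)
        return CdsCoordinate(c, offset, "intron", anchor_region=tag, region_index=i)
    raise OutOfRangeError(f"{t.transcript_id}: position {gpos} unmapped")  # pragma: no cover


def cds_to_genomic(t: TranscriptModel, c_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds` for coding positions (1-based both ways)."""
    if c_pos < 1:
        raise ValueError("CDS positions are 1-based")
    b = t.cds_tx_bounds
    if b is None:
        raise ModelError(f"{t.transcript_id}: non-coding transcript")
    if c_pos > b[1] - b[0]:
        raise OutOfRangeError(f"c.{c_pos} beyond CDS of length {b[1] - b[0]}")
    return t.tx_to_genomic(b[0] + c_pos - 1) + 1


# -------------------------------------------------------------------- loading
_REQUIRED_COLS = 9


def _validate_gff_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < _REQUIRED_COLS:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end:
                raise ParseError(f"{path}:{lineno}: start > end")
            if parts[6] not in "+-.":
                raise ParseError(f"{path}:{lineno}: bad strand {parts[6]!r}")


def load_gene_models(path: str) -> list[TranscriptModel]:
    """Load transcripts from a GFF3 file (gene/mRNA|transcript/exon/CDS features).

    Exons are returned in transcription order; coding transcripts carry genomic
    CDS bounds. Malformed lines raise :class:`ParseError` naming the line;
    structural problems raise :class:`ModelError`.
    """
    _validate_gff_lines(path)
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[TranscriptModel] = []
    for tf in db.features_of_type(("mRNA", "transcript", "ncRNA")):
        gene_symbol = tf.attributes.get("gene_name", [None])[0]
        if gene_symbol is None:
            parents = list(db.parents(tf, featuretype="gene"))
            if parents:
                gene_symbol = parents[0].attributes.get(
                    "Name", parents[0].attributes.get("ID", ["?"])
                )[0]
            else:
                gene_symbol = tf.id
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end)
            for e in db.children(tf, featuretype="exon", order_by="start")
        ]
        if not exons:
            raise ModelError(f"{tf.id}: transcript without exons")
        if tf.strand == "-":
            exons = exons[::-1]
        cds = [
            (c.start - 1, c.end)
            for c in db.children(tf, featuretype="CDS", order_by="start")
        ]
        cds_start = min(c[0] for c in cds) if cds else None
        cds_end = max(c[1] for c in cds) if cds else None
        biotype = "coding" if cds else "non_coding"
        models.append(
            TranscriptModel(
                transcript_id=tf.id,
                gene_symbol=gene_symbol,
                strand=tf.strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
                biotype=biotype,
            )
        )
    return models


def load_genome_fasta(path: str) -> dict[str, str]:
    """Read a FASTA into a dict of plain upper-case strings."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def index_by_chrom(models: Iterable[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    out: dict[str, list[TranscriptModel]] = {}
    for m in models:
        out.setdefault(m.chrom, []).append(m)
    for v in out.values():
        v.sort(key=lambda m: m.span.start)
    return out
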