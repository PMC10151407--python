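"""Self-contained synthetic test worlds.

A *world* is a toy genome (two chromosomes), a set of gene models, a candidate
panel, two known-variant catalogs (a first-release and a later-release one
with strain genotypes), a two-sample VCF (case = mutant strain, ancestral =
progenitor strain), and a truth table of planted variants with intended
cascade outcomes. Variant consequences are sampled from a 13-category
composition whose default weights are the category proportions observed in
the source exome study (87,138 variants, 37.26% intron, 32.24% synonymous,
17.23% missense, ...), so a default-sized world reproduces that composition
up to multinomial sampling error.

Every category placement is realized against the package's own annotator and
verified, so the emitted VCF annotates back to the sampled composition
exactly. All randomness flows from a single seed; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import consequence as Q
from .catalogs import CatalogRecord, VariantCatalog
from .consequence import (
    AnnotatedVariant,
    GenotypeCall,
    TOP_CATEGORY,
    Variant,
    annotate,
)
from .errors import ConfigError, DataError, ModelError
from .genome_model import (
    GenomicInterval,
    TranscriptModel,
    index_by_chrom,
    reverse_complement,
)

# ---------------------------------------------------------------- defaults
#: category counts of the reference exome composition (total 87,138)
TABLE1_COUNTS = {
    "intron": 32_467,
    "synonymous": 28_089,
    "missense": 15_011,
    "splice_site": 4_614,
    "UTR": 4_479,
    "non_coding_exon": 717,
    "upstream_gene": 577,
    "downstream_gene": 453,
    "inframe_indel": 332,
    "frameshift": 210,
    "stop_codon": 147,
    "start_codon": 22,
    "disruptive_inframe_indel": 20,
}
TABLE1_TOTAL = sum(TABLE1_COUNTS.values())  # 87,138

#: sub-type splits within the aggregated categories
TABLE1_SUBTYPES = {
    "splice_site": {"splice_acceptor": 33, "splice_donor": 26, "splice_region": 4556},
    "UTR": {"UTR3": 3034, "UTR5": 1445},
    "inframe_indel": {"inframe_deletion": 177, "inframe_insertion": 155},
    "stop_codon": {"stop_gained": 108, "stop_lost": 20, "stop_retained": 19},
    "disruptive_inframe_indel": {
        "disruptive_inframe_deletion": 9,
        "disruptive_inframe_insertion": 11,
    },
}

DEFAULT_STRAINS = [
    "129", "FVB", "CBA", "DBA", "C3H", "NOD", "SPRET", "CAST", "PWK", "BUB",
    "ST", "BALBc", "KK/HlJ", "MOLF/EiJ", "ZALENDE/EiJ", "I/LnJ",
]

CASE_SAMPLE = "EmJ"
ANCESTRAL_SAMPLE = "CFW"

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_BASES = np.array(list("ACGT"))

#: genotype patterns for the two-sample design (ancestral, case)
PATTERNS = (
    "both_hom_alt",
    "case_hom_alt+anc_het",
    "case_hom_alt+anc_ref",
    "case_het_anc_ref",
    "case_ref",
    "low_coverage_artifact",
)
_PATTERN_PROBS = np.array([0.50, 0.15, 0.05, 0.10, 0.20, 0.0])


@dataclass
class DepthModel:
    """Negative-binomial read depth: mean and overdispersion (var = m + d m^2)."""

    mean: float = 30.0
    dispersion: float = 0.3

    def draw(self, rng: np.random.Generator) -> int:
        if self.mean <= 0:
            raise DataError("depth model mean must be positive")
        r = 1.0 / max(self.dispersion, 1e-6)
        p = r / (r + self.mean)
        return int(max(4, rng.negative_binomial(r, p)))


@dataclass
class PlantSpec:
    """A variant planted with an intended cascade outcome."""

    label: str
    so_term: str = "missense_variant"
    in_panel: bool = True
    pattern: str = "case_hom_alt+anc_het"
    rs_in: str | None = None  # None | "dbsnp146" | "ensembl106"
    strain_carriers: int = 0
    intended_status: str = "candidate"  # candidate | excluded_by:<rule> | flagged


def default_plants() -> list[PlantSpec]:
    return [
        PlantSpec("novel_candidate", intended_status="candidate"),
        PlantSpec(
            "dbsnp146_twin", rs_in="dbsnp146",
            intended_status="excluded_by:dbsnp146_known",
        ),
        PlantSpec(
            "later_release_twin", rs_in="ensembl106", strain_carriers=2,
            intended_status="excluded_by:ensembl106_known",
        ),
        PlantSpec(
            "strain_shared", strain_carriers=3,
            intended_status="excluded_by:strain_or_reference",
        ),
        PlantSpec(
            "off_panel", in_panel=False,
            intended_status="excluded_by:panel",
        ),
        PlantSpec(
            "artifact", pattern="low_coverage_artifact",
            intended_status="flagged",
        ),
    ]


@dataclass
class SimulationConfig:
    n_variants: int = TABLE1_TOTAL
    category_weights: dict = field(
        default_factory=lambda: {
            k: v / TABLE1_TOTAL for k, v in TABLE1_COUNTS.items()
        }
    )
    n_panel_genes: int = 12
    n_decoy_genes: int = 28
    n_noncoding_genes: int = 4
    rs_prob_dbsnp146: float = 0.9
    rs_prob_ensembl106: float = 0.5
    strains: list = field(default_factory=lambda: list(DEFAULT_STRAINS))
    strain_share_prob: float = 0.5
    depth_model: DepthModel = field(default_factory=DepthModel)
    planted: list = field(default_factory=default_plants)
    seed: int = 0

    def __post_init__(self) -> None:
        s = sum(self.category_weights.values())
        if abs(s - 1.0) > 1e-6:
            raise ConfigError(f"category weights sum to {s}, expected 1")
        for p in (self.rs_prob_dbsnp146, self.rs_prob_ensembl106, self.strain_share_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.n_variants < 0:
            raise ConfigError("n_variants must be non-negative")


# --------------------------------------------------------------- gene build
@dataclass
class _Gene:
    model: TranscriptModel
    in_panel: bool


def _split_lengths(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    extra = total - parts * minimum
    if extra < 0:
        raise ModelError("cannot split lengths")
    cuts = rng.multinomial(extra, np.ones(parts) / parts)
    return [minimum + int(c) for c in cuts]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _build_genes(cfg: SimulationConfig, rng: np.random.Generator):
    """Construct the toy genome and transcript models."""
    chrom_parts: dict[str, list[str]] = {"chr1": [], "chr2": []}
    chrom_len: dict[str, int] = {"chr1": 0, "chr2": 0}
    genes: list[_Gene] = []
    n_coding = cfg.n_panel_genes + cfg.n_decoy_genes
    specs = []
    for i in range(n_coding):
        in_panel = i < cfg.n_panel_genes
        name = f"Panelg{i + 1:02d}" if in_panel else f"Decoyg{i - cfg.n_panel_genes + 1:02d}"
        specs.append((name, True, in_panel))
    for i in range(cfg.n_noncoding_genes):
        specs.append((f"Ncrna{i + 1:02d}", False, False))

    for gi, (name, coding, in_panel) in enumerate(specs):
        chrom = "chr1" if gi % 2 == 0 else "chr2"
        strand = "+" if rng.random() < 0.5 else "-"
        if coding:
            n_exons = int(rng.integers(5, 9))
            cds_len = 3 * int(rng.integers(800, 1400))
            utr5 = int(rng.integers(150, 400))
            utr3 = int(rng.integers(300, 800))
            n_cds_codons = cds_len // 3
            body = "".join(
                _SENSE_CODONS[k]
                for k in rng.integers(0, len(_SENSE_CODONS), size=n_cds_codons - 2)
            )
            cds_seq = "ATG" + body + "TAA"
            mrna = _random_seq(rng, utr5) + cds_seq + _random_seq(rng, utr3)
        else:
            n_exons = int(rng.integers(2, 4))
            utr5 = utr3 = 0
            cds_seq = None
            mrna = _random_seq(rng, int(rng.integers(800, 1500)))
        exon_lens = _split_lengths(rng, len(mrna), n_exons, 150)
        intron_lens = [int(rng.integers(600, 2500)) for _ in range(n_exons - 1)]

        # assemble the gene's genomic block in transcription order
        parts, exon_bounds_local, off = [], [], 0
        pos = 0
        mstart = 0
        for k, el in enumerate(exon_lens):
            parts.append(mrna[mstart : mstart + el])
            exon_bounds_local.append((pos, pos + el))
            pos += el
            mstart += el
            if k < n_exons - 1:
                parts.append(_random_seq(rng, intron_lens[k]))
                pos += intron_lens[k]
        block = "".join(parts)

        gap = int(rng.integers(12_000, 18_000))
        start = chrom_len[chrom] + gap
        chrom_parts[chrom].append(_random_seq(rng, gap))
        if strand == "+":
            chrom_parts[chrom].append(block)
            exon_ivs = [
                GenomicInterval(chrom, start + a, start + b)
                for a, b in exon_bounds_local
            ]
        else:
            chrom_parts[chrom].append(reverse_complement(block))
            L = len(block)
            exon_ivs = [
                GenomicInterval(chrom, start + L - b, start + L - a)
                for a, b in exon_bounds_local
            ]
        chrom_len[chrom] = start + len(block)

        if coding:
            # CDS spans mRNA positions utr5 .. utr5+cds_len in transcription order
            tx_lo, tx_hi = utr5, utr5 + len(cds_seq)
            # locate genomic bounds by walking exons in transcription order
            gpos_first = _tx_to_genomic_static(exon_ivs, strand, tx_lo)
            gpos_last = _tx_to_genomic_static(exon_ivs, strand, tx_hi - 1)
            cds_start = min(gpos_first, gpos_last)
            cds_end = max(gpos_first, gpos_last) + 1
        else:
            cds_start = cds_end = None
        model = TranscriptModel(
            transcript_id=f"{name}.t1",
            gene_symbol=name,
            strand=strand,
            exons=exon_ivs,
            cds_start=cds_start,
            cds_end=cds_end,
            biotype="coding" if coding else "non_coding",
        )
        genes.append(_Gene(model, in_panel))

    for chrom in chrom_parts:
        chrom_parts[chrom].append(_random_seq(rng, 8_000))
    genome = {c: "".join(p) for c, p in chrom_parts.items()}
    for g in genes:
        g.model.attach_genome(genome)
        if g.model.biotype == "coding":
            prot = g.model.protein_sequence()
            assert prot.endswith("*") and "*" not in prot[:-1]
    return genome, genes


def _tx_to_genomic_static(exons, strand, tx):
    off = 0
    for e in exons:
        if tx < off + len(e):
            k = tx - off
            return e.start + k if strand == "+" else e.end - 1 - k
        off += len(e)
    raise ModelError("tx position outside exons")


# ------------------------------------------------------------------- pools
@dataclass
class _Pools:
    """Per-world candidate placements, keyed by SO term."""

    snv: dict = field(default_factory=dict)  # term -> list[(gpos1, ref, alt, t)]
    positional: dict = field(default_factory=dict)  # term -> list[(gpos1, t)]
    cds_segments: list = field(default_factory=list)  # (t, c_start, g_start1, length)


def _junction_adjacent(t: TranscriptModel) -> set[int]:
    """0-based genomic positions within 3 nt of an internal junction (exonic side)."""
    out: set[int] = set()
    for i, e in enumerate(t.exons, 1):
        if t.strand == "+":
            first_side = range(e.start, min(e.start + 3, e.end))
            last_side = range(max(e.start, e.end - 3), e.end)
        else:
            first_side = range(max(e.start, e.end - 3), e.end)
            last_side = range(e.start, min(e.start + 3, e.end))
        if i > 1:
            out.update(first_side)
        if i < len(t.exons):
            out.update(last_side)
    return out


def _build_pools(genes: list[_Gene], genome: dict) -> _Pools:
    pools = _Pools()
    for term in (
        "missense_variant", "synonymous", "stop_gained", "stop_lost",
        "stop_retained", "start_lost",
    ):
        pools.snv[term] = []
    for term in (
        "intron", "splice_acceptor", "splice_donor", "splice_region",
        "UTR5", "UTR3", "non_coding_exon", "upstream_gene", "downstream_gene",
    ):
        pools.positional[term] = []

    spans = [g.model.span for g in genes]
    for g in genes:
        t = g.model
        junc = _junction_adjacent(t)
        if t.biotype == "coding":
            cds = t.cds_sequence()
            lo, hi = t.cds_tx_bounds
            off = 0
            for e in t.exons:
                for k in range(len(e)):
                    tx = off + k
                    gpos0 = e.start + k if t.strand == "+" else e.end - 1 - k
                    if tx < lo:
                        if gpos0 not in junc:
                            pools.positional["UTR5"].append((gpos0 + 1, t))
                    elif tx >= hi:
                        if gpos0 not in junc:
                            pools.positional["UTR3"].append((gpos0 + 1, t))
                    else:
                        c = tx - lo + 1
                        ref_c = cds[c - 1]
                        near_junction = gpos0 in junc
                        for alt_c in "ACGT":
                            if alt_c == ref_c:
                                continue
                            term, _ = Q._snv_coding_term(t, c, alt_c)
                            if near_junction and term in (
                                "synonymous", "stop_retained",
                            ):
                                continue  # splice_region would outrank it
                            if term in pools.snv:
                                ref_p = ref_c if t.strand == "+" else reverse_complement(ref_c)
                                alt_p = alt_c if t.strand == "+" else reverse_complement(alt_c)
                                pools.snv[term].append((gpos0 + 2 - 1, ref_p, alt_p, t))
                off += len(e)
            # contiguous coding segments for indel placement (per exon)
            off = 0
            for e in t.exons:
                tx_a, tx_b = off, off + len(e)
                seg_lo, seg_hi = max(tx_a, lo), min(tx_b, hi)
                if seg_hi - seg_lo >= 12:
                    c_start = seg_lo - lo + 1
                    if t.strand == "+":
                        g_start1 = e.start + (seg_lo - tx_a) + 1
                    else:
                        g_start1 = e.end - (seg_lo - tx_a)
                    pools.cds_segments.append((t, c_start, g_start1, seg_hi - seg_lo))
                off += len(e)
        else:
            for e in t.exons:
                for gpos0 in range(e.start, e.end):
                    if gpos0 not in junc:
                        pools.positional["non_coding_exon"].append((gpos0 + 1, t))

        # intron structure
        for a, b in zip(t.exons, t.exons[1:]):
            if t.strand == "+":
                ilo, ihi = a.end, b.start  # 0-based half-open
                donor = [ilo, ilo + 1]
                acceptor = [ihi - 2, ihi - 1]
                region = list(range(ilo + 2, ilo + 8)) + list(range(ihi - 8, ihi - 2))
                interior = range(ilo + 8, ihi - 8)
            else:
                ilo, ihi = b.end, a.start
                donor = [ihi - 1, ihi - 2]
                acceptor = [ilo, ilo + 1]
                region = list(range(ihi - 8, ihi - 2)) + list(range(ilo + 2, ilo + 8))
                interior = range(ilo + 8, ihi - 8)
            if ihi - ilo < 40:
                continue
            pools.positional["splice_donor"].extend((p + 1, t) for p in donor)
            pools.positional["splice_acceptor"].extend((p + 1, t) for p in acceptor)
            pools.positional["splice_region"].extend((p + 1, t) for p in region)
            pools.positional["intron"].extend((p + 1, t) for p in interior)

        # flanks: within 4 kb of the span, at least 5 kb from any other gene
        sp = t.span
        left = [
            (p + 1, t)
            for p in range(max(0, sp.start - 4000), sp.start)
            if _clear_of_others(p, sp, spans)
        ]
        right = [
            (p + 1, t)
            for p in range(sp.end, min(len(genome[t.chrom]), sp.end + 4000))
            if _clear_of_others(p, sp, spans)
        ]
        if t.strand == "+":
            pools.positional["upstream_gene"].extend(left)
            pools.positional["downstream_gene"].extend(right)
        else:
            pools.positional["upstream_gene"].extend(right)
            pools.positional["downstream_gene"].extend(left)
    return pools


def _clear_of_others(p: int, own: GenomicInterval, spans: list[GenomicInterval]) -> bool:
    for sp in spans:
        if sp == own or sp.chrom != own.chrom:
            continue
        if sp.start - 5000 <= p < sp.end + 5000:
            return False
    return True


# --------------------------------------------------------------- genotypes
def simulate_genotypes(
    variant: Variant,
    pattern: str,
    depth_model: DepthModel,
    rng: np.random.Generator,
) -> tuple[GenotypeCall, GenotypeCall]:
    """Draw (ancestral, case) genotype calls for one variant under a pattern.

    ``low_coverage_artifact`` emulates a miscalled site: the case genotype
    asserts hom-alt while only ≤2 of ≥12 reads support the alt allele.
    """
    if pattern not in PATTERNS:
        raise ConfigError(f"unknown genotype pattern {pattern!r}")

    def call(sample: str, zygosity: str) -> GenotypeCall:
        depth = depth_model.draw(rng)
        if zygosity == "hom_alt":
            alt = depth - int(rng.binomial(depth, 0.02))
            alleles = ("alt", "alt")
        elif zygosity == "het":
            alt = int(np.clip(rng.binomial(depth, 0.5), 1, depth - 1)) if depth > 1 else 1
            alleles = ("ref", "alt")
        else:
            alt = int(rng.binomial(depth, 0.01))
            alleles = ("ref", "ref")
            alt = min(alt, depth)
        return GenotypeCall(sample, alleles, depth=depth, alt_reads=alt)

    if pattern == "both_hom_alt":
        return call(ANCESTRAL_SAMPLE, "hom_alt"), call(CASE_SAMPLE, "hom_alt")
    if pattern == "case_hom_alt+anc_het":
        return call(ANCESTRAL_SAMPLE, "het"), call(CASE_SAMPLE, "hom_alt")
    if pattern == "case_hom_alt+anc_ref":
        return call(ANCESTRAL_SAMPLE, "ref"), call(CASE_SAMPLE, "hom_alt")
    if pattern == "case_het_anc_ref":
        return call(ANCESTRAL_SAMPLE, "ref"), call(CASE_SAMPLE, "het")
    if pattern == "case_ref":
        return call(ANCESTRAL_SAMPLE, "hom_alt"), call(CASE_SAMPLE, "ref")
    # low_coverage_artifact
    anc = call(ANCESTRAL_SAMPLE, "ref")
    depth = max(12, depth_model.draw(rng))
    alt = int(rng.integers(1, 3))
    case = GenotypeCall(CASE_SAMPLE, ("alt", "alt"), depth=depth, alt_reads=alt)
    return anc, case


# ------------------------------------------------------------------- world
@dataclass
class TruthRecord:
    label: str
    variant: Variant
    so_term: str
    effect_class: str
    pattern: str
    intended_status: str


@dataclass
class World:
    outdir: Path
    genome_path: Path
    gff_path: Path
    vcf_path: Path
    panel_path: Path
    dbsnp146_path: Path
    ensembl106_path: Path
    truth_path: Path
    config: SimulationConfig
    models: list
    genome: dict
    annotated: list  # AnnotatedVariant, in VCF order
    truth: list  # TruthRecord
    dbsnp146: VariantCatalog
    ensembl106: VariantCatalog

    @property
    def paths(self) -> dict:
        return {
            "genome": self.genome_path,
            "models": self.gff_path,
            "vcf": self.vcf_path,
            "panel": self.panel_path,
            "dbsnp146": self.dbsnp146_path,
            "ensembl106": self.ensembl106_path,
            "truth": self.truth_path,
        }

    def sha256(self) -> dict:
        out = {}
        for name, p in self.paths.items():
            out[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        return out


_RETRY_BOUND = 80  # placement attempts per indel before giving up


def _place_indel(
    term: str,
    pools: _Pools,
    rng: np.random.Generator,
    used: set,
    genome: dict,
) -> Variant:
    """Place one indel of the requested class, verifying with the annotator."""
    segs = pools.cds_segments
    for _ in range(_RETRY_BOUND):
        t, c_start, g_start1, length = segs[int(rng.integers(0, len(segs)))]
        cds_len = t.cds_length
        if term == "frameshift_variant":
            k = int(rng.integers(1, 3))
            ins = k == 1 and rng.random() < 0.5
            if ins:
                k = 1
        elif term in ("inframe_deletion", "disruptive_inframe_deletion"):
            k, ins = 3, False
        else:  # inframe/disruptive insertion
            k, ins = 3, True
        margin = 5
        c_lo = c_start + margin
        c_hi = c_start + length - margin - k
        if c_hi <= c_lo:
            continue
        c = int(rng.integers(c_lo, c_hi))
        if term == "inframe_deletion":
            c += (1 - c) % 3  # align to codon start
        elif term == "disruptive_inframe_deletion":
            if (c - 1) % 3 == 0:
                c += 1
        elif term == "inframe_insertion":
            c += (-c) % 3  # insertion point after a complete codon
        elif term == "disruptive_inframe_insertion":
            if c % 3 == 0:
                c += 1
        if c < 4 or c + k > cds_len - 3:
            continue
        strand = t.strand
        if ins:
            seq_c = (
                _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
                if k == 3
                else _random_seq(rng, k)
            )
            # insertion between CDS positions c and c+1
            g_c = g_start1 + (c - c_start) * (1 if strand == "+" else -1)
            anchor1 = g_c if strand == "+" else g_c - 1
            ins_plus = seq_c if strand == "+" else reverse_complement(seq_c)
            v = Variant(
                GenomicInterval(t.chrom, anchor1 - 1, anchor1), "", ins_plus
            )
        else:
            if strand == "+":
                g_first1 = g_start1 + (c - c_start)
                iv = GenomicInterval(t.chrom, g_first1 - 1, g_first1 - 1 + k)
            else:
                g_last1 = g_start1 - (c + k - 1 - c_start)
                iv = GenomicInterval(t.chrom, g_last1 - 1, g_last1 - 1 + k)
            ref_plus = genome[t.chrom][iv.start : iv.end]
            v = Variant(iv, ref_plus, "")
        key = (v.chrom, v.interval.start, v.ref, v.alt)
        if key in used:
            continue
        ann = Q.annotate_transcript(t, v)
        if TOP_CATEGORY.get(ann.so_term) == TOP_CATEGORY.get(term) and ann.so_term == term:
            used.add(key)
            return v
    raise ModelError(f"could not place indel of class {term} after {_RETRY_BOUND} tries")


def generate_world(cfg: SimulationConfig, outdir: str | Path) -> World:
    """Generate a complete synthetic world under *cfg* and write it to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genome, genes = _build_genes(cfg, rng)
    models = [g.model for g in genes]
    pools = _build_pools(genes, genome)
    panel_models = [g.model for g in genes if g.in_panel and g.model.biotype == "coding"]
    panel_symbols = [m.gene_symbol for m in panel_models]

    cats = list(cfg.category_weights)
    weights = np.array([cfg.category_weights[c] for c in cats], dtype=float)
    counts = rng.multinomial(cfg.n_variants, weights / weights.sum())
    cat_counts = dict(zip(cats, counts))

    used: set = set()
    chosen: list[tuple[Variant, str, TranscriptModel | None]] = []

    def draw_snv_pool(term: str, n: int) -> None:
        pool = pools.snv[term]
        if n > len(pool):
            raise ModelError(f"pool for {term} exhausted ({n} > {len(pool)})")
        idx = rng.choice(len(pool), size=n, replace=False)
        for i in idx:
            gpos1, ref, alt, t = pool[i]
            v = Variant(GenomicInterval(t.chrom, gpos1 - 1, gpos1), ref, alt)
            used.add((v.chrom, v.interval.start, v.ref, v.alt))
            chosen.append((v, term, t))

    def draw_positional(term: str, n: int) -> None:
        # each site supports three alternate alleles (biallelic-split records)
        pool = pools.positional[term]
        if n > 3 * len(pool):
            raise ModelError(f"pool for {term} exhausted ({n} > {3 * len(pool)})")
        idx = rng.choice(3 * len(pool), size=n, replace=False)
        for i in idx:
            gpos1, t = pool[i // 3]
            ref = genome[t.chrom][gpos1 - 1]
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[i % 3]
            v = Variant(GenomicInterval(t.chrom, gpos1 - 1, gpos1), ref, alt)
            used.add((v.chrom, v.interval.start, v.ref, v.alt))
            chosen.append((v, term, t))

    def split_subtypes(cat: str, n: int) -> dict:
        subs = TABLE1_SUBTYPES[cat]
        terms = list(subs)
        w = np.array([subs[s] for s in terms], dtype=float)
        c = rng.multinomial(n, w / w.sum())
        return dict(zip(terms, c))

    for cat in cats:
        n = int(cat_counts[cat])
        if n == 0:
            continue
        if cat == "missense":
            draw_snv_pool("missense_variant", n)
        elif cat == "synonymous":
            draw_snv_pool("synonymous", n)
        elif cat == "start_codon":
            draw_snv_pool("start_lost", n)
        elif cat in ("intron", "non_coding_exon", "upstream_gene", "downstream_gene"):
            draw_positional(cat, n)
        elif cat == "splice_site":
            for term, k in split_subtypes(cat, n).items():
                draw_positional(term, int(k))
        elif cat == "UTR":
            for term, k in split_subtypes(cat, n).items():
                draw_positional(term, int(k))
        elif cat == "stop_codon":
            for term, k in split_subtypes(cat, n).items():
                draw_snv_pool(term, int(k))
        elif cat in ("inframe_indel", "disruptive_inframe_indel", "frameshift"):
            if cat == "frameshift":
                sub = {"frameshift_variant": n}
            else:
                sub = split_subtypes(cat, n)
            for term, k in sub.items():
                for _ in range(int(k)):
                    v = _place_indel(term, pools, rng, used, genome)
                    chosen.append((v, term, None))
        else:  # pragma: no cover
            raise ConfigError(f"unknown category {cat}")

    # ---- planted truths ------------------------------------------------
    truth: list[TruthRecord] = []
    plant_rs: list[tuple[Variant, str, int]] = []
    for spec in cfg.planted:
        pool_term = spec.so_term if spec.so_term in pools.snv else "missense_variant"
        pool = pools.snv[pool_term]
        placed = False
        for _ in range(_RETRY_BOUND):
            gpos1, ref, alt, t = pool[int(rng.integers(0, len(pool)))]
            if (t.gene_symbol in panel_symbols) != spec.in_panel:
                continue
            key = (t.chrom, gpos1 - 1, ref, alt)
            if key in used:
                continue
            used.add(key)
            v = Variant(GenomicInterval(t.chrom, gpos1 - 1, gpos1), ref, alt)
            chosen.append((v, spec.so_term, t))
            truth.append(
                TruthRecord(
                    spec.label, v, spec.so_term,
                    Q.effect_class(spec.so_term), spec.pattern, spec.intended_status,
                )
            )
            if spec.rs_in:
                plant_rs.append((v, spec.rs_in, spec.strain_carriers))
            elif spec.strain_carriers:
                plant_rs.append((v, "strains_only", spec.strain_carriers))
            placed = True
            break
        if not placed:
            raise ModelError(f"could not place planted variant {spec.label}")

    # ---- genotypes ------------------------------------------------------
    truth_keys = {
        (r.variant.chrom, r.variant.interval.start, r.variant.ref, r.variant.alt): r
        for r in truth
    }
    annotated: list[AnnotatedVariant] = []
    for v, term, _t in chosen:
        key = (v.chrom, v.interval.start, v.ref, v.alt)
        rec = truth_keys.get(key)
        pattern = (
            rec.pattern
            if rec is not None
            else PATTERNS[int(rng.choice(len(PATTERNS), p=_PATTERN_PROBS))]
        )
        anc, case = simulate_genotypes(v, pattern, cfg.depth_model, rng)
        annotated.append(
            AnnotatedVariant(variant=v, genotypes=[anc, case], so_term=term)
        )

    # ---- catalogs -------------------------------------------------------
    db_records: list[CatalogRecord] = []
    ens_records: list[CatalogRecord] = []
    rs_counter = 10_000_000

    def strain_map(n_carriers: int | None = None) -> dict:
        strains = {}
        if n_carriers is None:
            for s in cfg.strains:
                if rng.random() < cfg.strain_share_prob:
                    strains[s] = ("alt", "alt") if rng.random() < 0.5 else ("ref", "alt")
        else:
            picks = rng.choice(len(cfg.strains), size=n_carriers, replace=False)
            for i in picks:
                strains[cfg.strains[i]] = ("alt", "alt")
        return strains

    for av in annotated:
        v = av.variant
        key = (v.chrom, v.interval.start, v.ref, v.alt)
        if key in truth_keys:
            continue  # planted catalog membership handled explicitly
        u = rng.random()
        if u < cfg.rs_prob_dbsnp146:
            rs_counter += 1
            rs = f"rs{rs_counter}"
            db_records.append(CatalogRecord(v.interval, v.ref, v.alt, rs))
            ens_records.append(
                CatalogRecord(v.interval, v.ref, v.alt, rs, strain_map())
            )
        elif rng.random() < cfg.rs_prob_ensembl106:
            rs_counter += 1
            ens_records.append(
                CatalogRecord(v.interval, v.ref, v.alt, f"rs{rs_counter}", strain_map())
            )
    for v, where, carriers in plant_rs:
        rs_counter += 1
        if where == "dbsnp146":
            db_records.append(CatalogRecord(v.interval, v.ref, v.alt, f"rs{rs_counter}"))
        elif where == "ensembl106":
            ens_records.append(
                CatalogRecord(
                    v.interval, v.ref, v.alt, f"rs{rs_counter}",
                    strain_map(max(1, carriers)),
                )
            )
        else:  # strains only, no rs
            ens_records.append(
                CatalogRecord(v.interval, v.ref, v.alt, None, strain_map(carriers))
            )

    dbsnp146 = VariantCatalog(db_records, name="dbsnp146_like")
    ensembl106 = VariantCatalog(ens_records, name="ensembl106_like")

    # ---- verification: realized consequence matches the sampled class ---
    index = index_by_chrom(models)
    order = sorted(range(len(annotated)), key=lambda i: (
        annotated[i].variant.chrom, annotated[i].variant.pos,
        annotated[i].variant.ref, annotated[i].variant.alt,
    ))
    annotated = [annotated[i] for i in order]
    for av in annotated:
        full = annotate(av.variant, av.genotypes, models, index=index)
        if TOP_CATEGORY[full.so_term] != TOP_CATEGORY[av.so_term]:
            raise ModelError(
                f"placement check failed at {av.variant.chrom}:{av.variant.pos}: "
                f"sampled {av.so_term}, annotated {full.so_term}"
            )
        av.gene_symbol = full.gene_symbol
        av.transcript_id = full.transcript_id
        av.so_term = full.so_term
        av.region_label = full.region_label
        av.hgvs_c = full.hgvs_c
        av.hgvs_p = full.hgvs_p
        av.effect_class = full.effect_class
        av.transcript_annotations = full.transcript_annotations

    # ---- write ----------------------------------------------------------
    genome_path = outdir / "genome.fa"
    gff_path = outdir / "models.gff3"
    vcf_path = outdir / "variants.vcf"
    panel_path = outdir / "panel.txt"
    db_path = outdir / "dbsnp146_like.tsv"
    ens_path = outdir / "ensembl106_like.tsv"
    truth_path = outdir / "truth.tsv"

    _write_fasta(genome_path, genome)
    _write_gff(gff_path, models)
    with open(panel_path, "w") as fh:
        for s in panel_symbols:
            fh.write(s + "\n")
    dbsnp146.to_tsv(str(db_path))
    ensembl106.to_tsv(str(ens_path), strains=list(cfg.strains))
    _write_vcf(vcf_path, annotated, genome)
    with open(truth_path, "w") as fh:
        fh.write("label\tchrom\tpos\tref\talt\tso_term\teffect_class\tpattern\tintended_status\n")
        for r in truth:
            fh.write(
                f"{r.label}\t{r.variant.chrom}\t{r.variant.pos}\t"
                f"{r.variant.ref or '-'}\t{r.variant.alt or '-'}\t{r.so_term}\t"
                f"{r.effect_class}\t{r.pattern}\t{r.intended_status}\n"
            )

    return World(
        outdir=outdir,
        genome_path=genome_path,
        gff_path=gff_path,
        vcf_path=vcf_path,
        panel_path=panel_path,
        dbsnp146_path=db_path,
        ensembl106_path=ens_path,
        truth_path=truth_path,
        config=cfg,
        models=models,
        genome=genome,
        annotated=annotated,
        truth=truth,
        dbsnp146=dbsnp146,
        ensembl106=ensembl106,
    )


def run_world_cascade(world: World, **kwargs):
    """Run the prioritization cascade over a generated world (in memory)."""
    import copy

    from .cascade import run_cascade
    from .catalogs import GenePanel, PanelGene

    panel = GenePanel(
        [PanelGene(s) for s in Path(world.panel_path).read_text().split()]
    )
    annotated = copy.deepcopy(world.annotated)
    return run_cascade(
        annotated, world.dbsnp146, world.ensembl106, panel,
        case_sample=CASE_SAMPLE, ancestral_sample=ANCESTRAL_SAMPLE, **kwargs,
    )


def truth_outcomes(world: World, result) -> dict:
    """Compare each planted truth with its realized cascade outcome.

    Returns {label: (intended_status, realized_status, matches)} where the
    realized status is expressed in the truth table's vocabulary
    (``candidate`` / ``excluded_by:<rule>`` / ``flagged``).
    """
    by_key = {}
    for r in result.reports:
        v = r.annotated.variant
        by_key[(v.chrom, v.interval.start, v.ref, v.alt)] = r
    out = {}
    for rec in world.truth:
        v = rec.variant
        r = by_key.get((v.chrom, v.interval.start, v.ref, v.alt))
        if r is None:
            realized = "missing"
        elif r.status == "candidate":
            realized = "candidate"
        elif r.status == "flagged_artifact":
            realized = "flagged"
        else:
            realized = f"excluded_by:{r.trail.excluding_rule}"
        out[rec.label] = (rec.intended_status, realized, realized == rec.intended_status)
    return out


# ------------------------------------------------------------------ writers
def _write_fasta(path: Path, genome: dict) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_gff(path: Path, models: list[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(models, key=lambda m: (m.chrom, m.span.start)):
            sp = t.span
            gene_id = t.gene_symbol
            fh.write(
                f"{t.chrom}\tvarcascade\tgene\t{sp.start + 1}\t{sp.end}\t.\t"
                f"{t.strand}\t.\tID={gene_id};Name={t.gene_symbol}\n"
            )
            ftype = "mRNA" if t.biotype == "coding" else "ncRNA"
            fh.write(
                f"{t.chrom}\tvarcascade\t{ftype}\t{sp.start + 1}\t{sp.end}\t.\t"
                f"{t.strand}\t.\tID={t.transcript_id};Parent={gene_id};"
                f"gene_name={t.gene_symbol}\n"
            )
            for e in sorted(t.exons, key=lambda x: x.start):
                fh.write(
                    f"{t.chrom}\tvarcascade\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\tParent={t.transcript_id}\n"
                )
            if t.cds_start is not None:
                for e in sorted(t.exons, key=lambda x: x.start):
                    lo = max(e.start, t.cds_start)
                    hi = min(e.end, t.cds_end)
                    if lo < hi:
                        fh.write(
                            f"{t.chrom}\tvarcascade\tCDS\t{lo + 1}\t{hi}\t.\t"
                            f"{t.strand}\t0\tParent={t.transcript_id}\n"
                        )


def _write_vcf(path: Path, annotated: list[AnnotatedVariant], genome: dict) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(genome):
            fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{ANCESTRAL_SAMPLE}\t{CASE_SAMPLE}\n"
        )
        for av in annotated:
            v = av.variant
            seq = genome[v.chrom]
            if v.kind == "SNV":
                pos1, ref, alt = v.pos, v.ref, v.alt
            elif v.kind == "insertion":
                anchor = seq[v.interval.start]
                pos1, ref, alt = v.interval.start + 1, anchor, anchor + v.alt
            else:  # deletion / delins: anchor base before the affected run
                anchor = seq[v.interval.start - 1]
                pos1 = v.interval.start
                ref = anchor + v.ref
                alt = anchor + v.alt
            cells = []
            for g in av.genotypes:
                gt = {"ref": "0", "alt": "1"}
                gtf = f"{gt[g.alleles[0]]}/{gt[g.alleles[1]]}"
                cells.append(f"{gtf}:{g.depth}:{g.depth - g.alt_reads},{g.alt_reads}")
            fh.write(
                f"{v.chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP:AD\t"
                + "\t".join(cells)
                + "\n"
            )
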