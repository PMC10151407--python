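"""VCF input and annotated-output writing (pysam-backed)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .consequence import (
    AnnotatedVariant,
    GenotypeCall,
    Variant,
    annotate,
    variant_from_vcf,
)
from .errors import DataError
from .genome_model import TranscriptModel, index_by_chrom


def read_vcf(path: str | Path) -> list[tuple[Variant, list[GenotypeCall]]]:
    """Read a VCF 4.x file into trimmed variants with per-sample genotypes.

    Multi-allelic records are split into biallelic variants; the GT, DP and AD
    FORMAT fields populate read support (AD is re-indexed per split allele).
    """
    out: list[tuple[Variant, list[GenotypeCall]]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            for ai, alt in enumerate(rec.alts or (), start=1):
                if alt is None or set(alt) - set("ACGT"):
                    continue
                v = variant_from_vcf(rec.chrom, rec.pos, rec.ref, alt)
                calls = []
                for s in samples:
                    sd = rec.samples[s]
                    gt = sd.get("GT") or ()
                    alleles = tuple(
                        "alt" if a == ai else "ref" for a in gt if a is not None
                    )
                    if len(alleles) != 2:
                        alleles = ("ref", "ref")
                    depth = sd.get("DP") or 0
                    ad = sd.get("AD")
                    alt_reads = int(ad[ai]) if ad is not None and len(ad) > ai and ad[ai] is not None else 0
                    if depth == 0 and ad is not None:
                        depth = int(sum(x for x in ad if x is not None))
                    calls.append(
                        GenotypeCall(s, alleles, depth=int(depth), alt_reads=alt_reads)
                    )
                out.append((v, calls))
    return out


def annotate_vcf(
    vcf_path: str | Path,
    models: list[TranscriptModel],
    genome: dict[str, str],
) -> list[AnnotatedVariant]:
    """Annotate every variant in a VCF against the given gene models."""
    for t in models:
        t.attach_genome(genome)
    index = index_by_chrom(models)
    out = []
    for v, calls in read_vcf(vcf_path):
        out.append(annotate(v, calls, models, index=index))
    return out


def annotated_to_frame(annotated: list[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for av in annotated:
        v = av.variant
        kind = {"SNV": "SNV", "insertion": "Ins", "deletion": "Del", "delins": "Delins"}[
            v.kind
        ]
        row = {
            "marker": f"{v.chrom}:{v.pos}-{kind}",
            "ref": v.ref or "-",
            "alt": v.alt or "-",
            "gene": av.gene_symbol,
            "transcript": av.transcript_id,
            "so_term": av.so_term,
            "region": av.region_label,
            "hgvs_c": av.hgvs_c,
            "hgvs_p": av.hgvs_p,
            "effect_class": av.effect_class,
        }
        for g in av.genotypes:
            row[f"{g.sample}_gt"] = "/".join(g.alleles)
            row[f"{g.sample}_depth"] = g.depth
            row[f"{g.sample}_alt_reads"] = g.alt_reads
        rows.append(row)
    return pd.DataFrame(rows)


def write_annotated_tsv(annotated: list[AnnotatedVariant], path: str | Path) -> None:
    annotated_to_frame(annotated).to_csv(path, sep="\t", index=False)


def load_world_inputs(genome_path, gff_path):
    """Convenience loader for a (genome FASTA, gene-model GFF3) pair."""
    from .genome_model import load_gene_models, load_genome_fasta

    genome = load_genome_fasta(str(genome_path))
    models = load_gene_models(str(gff_path))
    for t in models:
        t.attach_genome(genome)
    if not models:
        raise DataError(f"{gff_path}: no transcript models found")
    return genome, models
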