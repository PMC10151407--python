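"""Packaged in-study fixtures.

* ``load_table2`` — the 43-variant candidate table transcribed verbatim from
  the source study (printed HGVS/SO/rs/strain columns), augmented with
  machine-readable genotype and read-support columns. Printed annotation
  strings are treated as fixture ground truth; they are not re-derived from
  RefSeq models.
* Mini-CDS contexts — short synthetic open reading frames anchoring the
  worked consequence examples: the albino Tyr codon-103 TGT context, the
  Pde6b codon-347 TAC context, and the Abhd12 codon-30..32 CTG GAC GCC
  context. Filler codons are deterministic synthetic sequence; only the
  anchored codons are constrained.
* Decoy variants — synthetic rs-bearing / off-panel / silent variants used to
  exercise the first-round filter alongside the candidate table.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogs import CatalogRecord, GenePanel, VariantCatalog, load_panel
from .consequence import AnnotatedVariant, GenotypeCall, Variant, effect_class
from .errors import ParseError
from .genome_model import GenomicInterval

CASE_SAMPLE = "EmJ"
ANCESTRAL_SAMPLE = "CFW"

#: strain names that legitimately contain a slash (substrain designations)
SLASH_STRAINS = {"KK/HlJ", "MOLF/EiJ", "ZALENDE/EiJ", "I/LnJ"}

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _data_path(name: str) -> Path:
    return Path(resources.files("varcascade").joinpath("data").joinpath(name))


def table2_path() -> Path:
    return _data_path("table2_variants.tsv")


def panel_path() -> Path:
    return _data_path("panel.txt")


def load_table2() -> pd.DataFrame:
    df = pd.read_csv(table2_path(), sep="\t", dtype=str, keep_default_na=False)
    return df


def fixture_panel() -> GenePanel:
    return load_panel(str(panel_path()))


def parse_marker(marker: str) -> tuple[str, int, str]:
    """Split a ``chrom:pos-TYPE`` marker string."""
    loc, _, kind = marker.partition("-")
    chrom, _, pos = loc.partition(":")
    if not pos.isdigit():
        raise ParseError(f"bad marker {marker!r}")
    return chrom, int(pos), kind


def _row_variant(row) -> Variant:
    chrom, pos1, kind = parse_marker(row.marker)
    ref = "" if row.ref == "-" else row.ref
    alt = "" if row.alt == "-" else row.alt
    if kind == "Ins":
        return Variant(GenomicInterval(chrom, pos1 - 1, pos1), "", alt)
    end = pos1 - 1 + max(1, len(ref))
    return Variant(GenomicInterval(chrom, pos1 - 1, end), ref, alt)


def _gt(call: str) -> tuple[str, str]:
    a, b = call.split("/")
    return (a, b)


def _scores(text: str) -> dict:
    out = {}
    for part in text.split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            try:
                out[k.strip()] = float(v)
            except ValueError:
                out[k.strip()] = v.strip()
    return out


def parse_strain_field(text: str) -> dict:
    """Parse an ``A,B = X/Y`` other-strains field into {strain: allele pair}."""
    text = text.strip()
    if not text:
        return {}
    lhs, _, rhs = text.partition("=")
    genotype = tuple(rhs.strip().split("/"))
    strains: list[str] = []
    for token in lhs.split(","):
        token = token.strip()
        if "/" in token and token not in SLASH_STRAINS:
            strains.extend(p.strip() for p in token.split("/"))
        elif token:
            strains.append(token)
    return {s: genotype for s in strains}


def table2_annotated() -> list[AnnotatedVariant]:
    """The 43 candidate-table variants as annotated records ready for the cascade."""
    out = []
    for row in load_table2().itertuples(index=False):
        v = _row_variant(row)
        genotypes = [
            GenotypeCall(
                ANCESTRAL_SAMPLE, _gt(row.cfw_gt),
                depth=int(row.cfw_depth), alt_reads=int(row.cfw_alt_reads),
            ),
            GenotypeCall(
                CASE_SAMPLE, _gt(row.emj_gt),
                depth=int(row.emj_depth), alt_reads=int(row.emj_alt_reads),
            ),
        ]
        out.append(
            AnnotatedVariant(
                variant=v,
                genotypes=genotypes,
                gene_symbol=row.gene_clin,
                transcript_id=row.hgvs_c.split(":", 1)[0] if ":" in row.hgvs_c else "",
                so_term=row.so_term,
                region_label=row.gene_region,
                hgvs_c=row.hgvs_c,
                hgvs_p=row.hgvs_p,
                effect_class=effect_class(row.so_term),
                external_scores=_scores(getattr(row, "scores", "") or ""),
                notes=[row.comments] if row.comments else [],
            )
        )
    return out


def table2_catalog_ensembl106() -> VariantCatalog:
    """Later-release catalog built from the candidate table's rs/strain columns."""
    records = []
    for row in load_table2().itertuples(index=False):
        rs = row.rs_ensembl106.strip() or None
        strains = parse_strain_field(row.other_strains)
        if rs is None and not strains:
            continue
        v = _row_variant(row)
        records.append(
            CatalogRecord(v.interval, v.ref, v.alt, rs, strains)
        )
    return VariantCatalog(records, name="ensembl106_like")


# ------------------------------------------------------------------- decoys
def fixture_decoys(seed: int = 0) -> tuple[list[AnnotatedVariant], VariantCatalog]:
    """Synthetic non-candidate variants plus the dbSNP-146-like catalog.

    Three decoy families: panel-gene missense variants that carry a
    first-release rs identifier, off-panel missense variants, and panel-gene
    silent (Other-class) variants. None survives the first round.
    """
    rng = np.random.default_rng(seed)
    panel_genes = ["Cryaa", "Gja8", "Pax6", "Hsf4", "Mip", "Tdrd7", "Epha2", "Foxe3"]
    off_panel = ["Actb", "Gapdh", "Ttn", "Obscn", "Vmn1r12", "Olfr78", "Muc4", "Sptbn5"]
    silent_terms = ["synonymous", "intron", "UTR3", "upstream_gene"]
    bases = "ACGT"
    decoys: list[AnnotatedVariant] = []
    db_records: list[CatalogRecord] = []

    def mk(gene: str, so: str, pos: int) -> AnnotatedVariant:
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        v = Variant(GenomicInterval("19", pos - 1, pos), str(ref), str(alt))
        return AnnotatedVariant(
            variant=v,
            genotypes=[
                GenotypeCall(ANCESTRAL_SAMPLE, ("alt", "alt"), 30, 30),
                GenotypeCall(CASE_SAMPLE, ("alt", "alt"), 30, 30),
            ],
            gene_symbol=gene,
            so_term=so,
            effect_class=effect_class(so),
        )

    pos = 3_000_000
    for i, gene in enumerate(panel_genes):
        pos += int(rng.integers(5_000, 50_000))
        av = mk(gene, "missense_variant", pos)
        decoys.append(av)
        db_records.append(
            CatalogRecord(
                av.variant.interval, av.variant.ref, av.variant.alt,
                rs_id=f"rs5{i:07d}",
            )
        )
    for gene in off_panel:
        pos += int(rng.integers(5_000, 50_000))
        decoys.append(mk(gene, "missense_variant", pos))
    for i, gene in enumerate(panel_genes):
        pos += int(rng.integers(5_000, 50_000))
        decoys.append(mk(gene, silent_terms[i % len(silent_terms)], pos))
    return decoys, VariantCatalog(db_records, name="dbsnp146_like")


# ----------------------------------------------------------------- mini CDS
_FIXTURE_SEED = 20230309  # fixed: the mini contexts are frozen fixtures


def _filler(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))


def _build_mini_cds() -> dict[str, str]:
    rng = np.random.default_rng(_FIXTURE_SEED)

    def orf(n_codons: int, anchors: dict[int, str]) -> str:
        """n_codons total including ATG start and TAA stop; anchors by codon index."""
        codons = ["ATG"] + [""] * (n_codons - 2) + ["TAA"]
        for i in range(1, n_codons - 1):
            codons[i] = str(rng.choice(_SENSE_CODONS))
        for idx, codon in anchors.items():
            codons[idx - 1] = codon
        return "".join(codons)

    # albino marker context: codon 103 = TGT (Cys); c.308 G>C -> TCT (Ser)
    tyr = orf(120, {103: "TGT"})
    # retinal-degeneration marker context: codon 347 = TAC (Tyr); third-base C>A -> TAA
    pde6b = orf(360, {347: "TAC"})
    # in-frame deletion context: codons 30-32 = CTG GAC GCC (c.88-96)
    abhd12 = orf(64, {30: "CTG", 31: "GAC", 32: "GCC"})
    return {"TYR_LIKE": tyr, "PDE6B_LIKE": pde6b, "ABHD12_LIKE": abhd12}


_MINI_CDS: dict[str, str] | None = None


def mini_cds(name: str) -> str:
    global _MINI_CDS
    if _MINI_CDS is None:
        _MINI_CDS = _build_mini_cds()
    return _MINI_CDS[name]


def package_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the packaged fixtures (candidate table, panel, mini-CDS FASTA)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t2 = outdir / "table2_variants.tsv"
    shutil.copy(table2_path(), t2)
    panel = outdir / "panel.txt"
    shutil.copy(panel_path(), panel)
    fasta = outdir / "mini_cds.fa"
    with open(fasta, "w") as fh:
        for name in ("TYR_LIKE", "PDE6B_LIKE", "ABHD12_LIKE"):
            seq = mini_cds(name)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return {"table2": t2, "panel": panel, "mini_cds": fasta}
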