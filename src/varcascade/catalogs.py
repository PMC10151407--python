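"""Gene panels and known-variant/strain catalogs.

Two catalog instances drive the novelty cascade: a first-release catalog
(dbSNP-146-like) used for the first-round novelty filter, and a later-release
catalog (Ensembl-106-like) that additionally carries per-strain genotypes for
the second-round strain filter. Matching is allele-aware and position-exact
after trimming to the package's minimal variant representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .consequence import Variant
from .errors import DataError, ParseError
from .genome_model import GenomicInterval


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    category: str = ""


class GenePanel:
    """Case-insensitive, deduplicated set of candidate genes."""

    def __init__(self, genes: list[PanelGene]):
        self._by_key: dict[str, PanelGene] = {}
        for g in genes:
            self._by_key.setdefault(g.symbol.casefold(), g)

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self._by_key

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    @property
    def symbols(self) -> set[str]:
        return {g.symbol for g in self._by_key.values()}


def load_panel(path: str) -> GenePanel:
    """Load a plain-text gene panel: one symbol per line, optional tab-separated
    category column, ``#`` comments allowed."""
    genes: list[PanelGene] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            genes.append(PanelGene(parts[0].strip(), parts[1].strip() if len(parts) > 1 else ""))
    if not genes:
        raise DataError(f"{path}: gene panel is empty")
    return GenePanel(genes)


@dataclass(frozen=True)
class CatalogRecord:
    """One known-variant entry with optional rs ID and per-strain genotypes."""

    site: GenomicInterval
    ref: str
    alt: str
    rs_id: str | None = None
    strain_genotypes: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if self.rs_id is not None and not (
            self.rs_id.startswith("rs") and self.rs_id[2:].isdigit()
        ):
            raise ParseError(f"malformed rs identifier {self.rs_id!r}")


def _key(chrom: str, pos1: int, ref: str, alt: str) -> tuple:
    """Allele-aware key in the package's minimal (trimmed) representation."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos1 += 1
    return chrom, pos1, ref, alt


def variant_key(v: Variant) -> tuple:
    if v.kind == "insertion":
        # key insertions by the base after which they occur
        return (v.chrom, v.interval.start + 1, "", v.alt)
    return _key(v.chrom, v.pos, v.ref, v.alt)


class VariantCatalog:
    """Indexed collection of known variants (one release of one resource)."""

    def __init__(self, records: list[CatalogRecord] = (), name: str = ""):
        self.name = name
        self._index: dict[tuple, CatalogRecord] = {}
        for r in records:
            self.add(r)

    def add(self, record: CatalogRecord) -> None:
        if record.alt == "":
            k = (record.site.chrom, record.site.start + 1, record.ref, "")
        elif record.ref == "":
            k = (record.site.chrom, record.site.start + 1, "", record.alt)
        else:
            k = _key(record.site.chrom, record.site.start + 1, record.ref, record.alt)
        self._index[k] = record

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, v: Variant) -> CatalogRecord | None:
        return self._index.get(variant_key(v))

    @classmethod
    def from_tsv(cls, path: str, name: str = "") -> "VariantCatalog":
        """Read a TSV catalog: chrom, pos (1-based), ref, alt, rs_id, then one
        column per strain holding ``X/Y`` genotypes (blank = not genotyped)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = ["chrom", "pos", "ref", "alt", "rs_id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing catalog columns {missing}")
        strain_cols = [c for c in df.columns if c not in required]
        records = []
        for row in df.itertuples(index=False, name=None):
            d = dict(zip(df.columns, row))
            ref = d["ref"].replace("-", "")
            alt = d["alt"].replace("-", "")
            pos0 = int(d["pos"]) - 1
            site = GenomicInterval(d["chrom"], pos0, pos0 + max(1, len(ref)))
            strains = {
                s: tuple(d[s].split("/")) for s in strain_cols if d[s].strip()
            }
            records.append(
                CatalogRecord(site, ref, alt, d["rs_id"] or None, strains)
            )
        return cls(records, name=name or path)

    def to_tsv(self, path: str, strains: list[str] | None = None) -> None:
        if strains is None:
            seen: list[str] = []
            for r in self._index.values():
                for s in r.strain_genotypes:
                    if s not in seen:
                        seen.append(s)
            strains = seen
        rows = []
        for (chrom, pos, ref, alt), r in sorted(self._index.items()):
            row = {
                "chrom": chrom, "pos": pos, "ref": ref or "-", "alt": alt or "-",
                "rs_id": r.rs_id or "",
            }
            for s in strains:
                g = r.strain_genotypes.get(s)
                row[s] = "/".join(g) if g else ""
            rows.append(row)
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "rs_id", *strains]).to_csv(
            path, sep="\t", index=False
        )


def lookup_rs(cat: VariantCatalog, v: Variant) -> str | None:
    """Exact allele-aware rs lookup; None when absent or unnamed."""
    rec = cat.lookup(v)
    return rec.rs_id if rec is not None else None


def strain_hits(cat: VariantCatalog, v: Variant) -> set[str]:
    """Strains whose catalogued genotype carries at least one alt allele.

    Strain genotypes may be written with the literal alt base(s), with the
    symbolic tokens ``alt``/``ins``/``del`` (used for indels), or — when a
    printed source used transcript-strand letters — with the complement of the
    alt base; all are counted as carrying the alt allele.
    """
    rec = cat.lookup(v)
    if rec is None:
        return set()
    comp = str.maketrans("ACGT", "TGCA")
    alt_tokens = {"alt", "ins"}
    if v.alt:
        alt_tokens.add(v.alt)
    else:
        alt_tokens.add("del")
    hits = set()
    for strain, genotype in rec.strain_genotypes.items():
        cleaned = {a.strip() for a in genotype}
        direct = bool(cleaned & alt_tokens)
        # complement fallback only when no allele matches ref or alt directly
        ref_tokens = {v.ref, "ref"}
        if not direct and not (cleaned & ref_tokens) and v.alt:
            comp_alt = v.alt.translate(comp)[::-1]
            direct = comp_alt in cleaned
        if direct:
            hits.add(strain)
    return hits
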