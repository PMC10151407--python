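"""The two-round candidate-gene prioritization cascade.

Stages, in order:

1. ``first_round`` — keep variants whose clinically-relevant effect class is
   Missense or LoF, whose gene is on the candidate panel, and which have no rs
   identifier in the first-release (dbSNP-146-like) catalog.
2. ``second_round`` — against the later-release (Ensembl-106-like) catalog:
   (a) exclude variants that now carry an rs identifier; then (b) exclude
   variants present in other strains and/or not homozygous-alternate in the
   case sample (the mutant strain).
3. ``confidence_filter`` — flag variants whose alt-asserting sample has a low
   alt-read fraction or too few alt reads (sequencing-artifact suspicion).
4. ``finalize`` — drop flagged artifacts; report the surviving genes.

Every input variant receives a :class:`CandidateReport` carrying its full
filter trail, so excluded + flagged + candidates always equals the input
count (conservation), and each excluded report names exactly one excluding
rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalogs import GenePanel, VariantCatalog, lookup_rs, strain_hits
from .consequence import (
    TOP_CATEGORIES,
    TOP_CATEGORY,
    AnnotatedVariant,
)
from .errors import ConfigError, DataError

#: default thresholds for the read-support artifact flag; chosen so that a
#: 2-of-16 (12.5%) call fails while ordinary het (≈50%) and hom-alt calls pass
DEFAULT_MIN_ALT_FRACTION = 0.2
DEFAULT_MIN_ALT_READS = 3

# subtype ordering within the tabulation categories
_SUBTYPES = {
    "splice_site": ("splice_acceptor", "splice_donor", "splice_region"),
    "UTR": ("UTR3", "UTR5"),
    "inframe_indel": ("inframe_deletion", "inframe_insertion"),
    "stop_codon": ("stop_gained", "stop_lost", "stop_retained"),
    "disruptive_inframe_indel": (
        "disruptive_inframe_deletion",
        "disruptive_inframe_insertion",
    ),
}


@dataclass(frozen=True)
class TrailEntry:
    rule_id: str
    outcome: str  # pass | excluded | flagged
    detail: str = ""


@dataclass
class FilterTrail:
    entries: list[TrailEntry] = field(default_factory=list)

    def record(self, rule_id: str, outcome: str, detail: str = "") -> None:
        if outcome == "excluded" and any(e.outcome == "excluded" for e in self.entries):
            raise DataError("a report can carry at most one exclusion")
        self.entries.append(TrailEntry(rule_id, outcome, detail))

    @property
    def excluding_rule(self) -> str | None:
        for e in self.entries:
            if e.outcome == "excluded":
                return e.rule_id
        return None

    @property
    def flagged(self) -> bool:
        return any(e.outcome == "flagged" for e in self.entries)


@dataclass
class CandidateReport:
    annotated: AnnotatedVariant
    trail: FilterTrail = field(default_factory=FilterTrail)
    status: str = "candidate"  # candidate | excluded | flagged_artifact

    @property
    def gene(self) -> str:
        return self.annotated.gene_symbol


@dataclass
class CategorySummary:
    """Counts and percentages over the 13 top-level consequence categories."""

    counts: dict
    subtype_counts: dict
    total: int

    @property
    def percentages(self) -> dict:
        if self.total == 0:
            return {c: 0.0 for c in self.counts}
        return {c: 100.0 * n / self.total for c, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        pct = self.percentages
        for cat in sorted(self.counts, key=lambda c: -self.counts[c]):
            rows.append(
                {
                    "category": cat,
                    "count": self.counts[cat],
                    "percent": round(pct[cat], 2),
                    "subtypes": ";".join(
                        f"{t}={self.subtype_counts[cat].get(t, 0)}"
                        for t in _SUBTYPES.get(cat, ())
                    ),
                }
            )
        rows.append({"category": "total", "count": self.total, "percent": 100.0 if self.total else 0.0, "subtypes": ""})
        return pd.DataFrame(rows)


def tabulate_by_category(annotated: list[AnnotatedVariant]) -> CategorySummary:
    """Partition annotated variants into the 13 top-level categories.

    The categories are mutually exclusive and exhaustive over the SO term set,
    so counts always sum to the input size.
    """
    counts = {c: 0 for c in TOP_CATEGORIES}
    sub: dict = {c: {} for c in TOP_CATEGORIES}
    for av in annotated:
        cat = TOP_CATEGORY[av.so_term]
        counts[cat] += 1
        sub[cat][av.so_term] = sub[cat].get(av.so_term, 0) + 1
    return CategorySummary(counts=counts, subtype_counts=sub, total=len(annotated))


# ------------------------------------------------------------------- round 1
def first_round(
    annotated: list[AnnotatedVariant],
    dbsnp146: VariantCatalog,
    panel: GenePanel,
    *,
    case_sample: str,
    ancestral_sample: str,
) -> list[CandidateReport]:
    """Effect-class + panel + first-release novelty filter.

    Returns one report per input variant; retained variants have status
    ``candidate``, every other report names its single excluding rule.
    """
    reports = []
    for av in annotated:
        for sample in (case_sample, ancestral_sample):
            if not av.has_sample(sample):
                raise ConfigError(
                    f"sample {sample!r} missing from genotypes of "
                    f"{av.variant.chrom}:{av.variant.pos}"
                )
        r = CandidateReport(annotated=av)
        if av.effect_class not in ("Missense", "LoF"):
            r.trail.record(
                "effect_class", "excluded",
                f"{av.so_term} -> {av.effect_class}",
            )
            r.status = "excluded"
        else:
            r.trail.record("effect_class", "pass", av.effect_class)
            if av.gene_symbol not in panel:
                r.trail.record("panel", "excluded", f"{av.gene_symbol} not on panel")
                r.status = "excluded"
            else:
                r.trail.record("panel", "pass", av.gene_symbol)
                rs = lookup_rs(dbsnp146, av.variant)
                if rs is not None:
                    r.trail.record("dbsnp146_known", "excluded", rs)
                    r.status = "excluded"
                else:
                    r.trail.record("dbsnp146_known", "pass", "no rs identifier")
        reports.append(r)
    return reports


# ------------------------------------------------------------------- round 2
def second_round(
    first: list[CandidateReport],
    ensembl106: VariantCatalog,
    case_sample: str,
    reference_rule: str = "require_case_hom_alt",
) -> list[CandidateReport]:
    """Later-release rs exclusion, then strain-presence / case-zygosity exclusion.

    Step (a) excludes variants carrying an rs identifier in the later catalog.
    Step (b) pools two clauses into one rule (the source narrative treats them
    as one, "and/or"): presence in other strains, and a case sample that does
    not assert the variant — homozygous reference always fails; under the
    default ``require_case_hom_alt`` rule heterozygous case calls fail too.
    The trail detail records which clause(s) fired.
    """
    if reference_rule not in ("require_case_hom_alt", "hom_ref_only"):
        raise ConfigError(f"unknown reference rule {reference_rule!r}")
    out = []
    for r in first:
        if r.status != "candidate":
            out.append(r)
            continue
        av = r.annotated
        rs = lookup_rs(ensembl106, av.variant)
        if rs is not None:
            hits = strain_hits(ensembl106, av.variant)
            detail = rs + (f"; strains: {','.join(sorted(hits))}" if hits else "")
            r.trail.record("ensembl106_known", "excluded", detail)
            r.status = "excluded"
            out.append(r)
            continue
        r.trail.record("ensembl106_known", "pass", "no rs identifier")
        hits = strain_hits(ensembl106, av.variant)
        case = av.genotype(case_sample)
        clauses = []
        if hits:
            clauses.append(f"present in strains {','.join(sorted(hits))}")
        if case.is_hom_ref:
            clauses.append(f"{case_sample} = reference")
        elif reference_rule == "require_case_hom_alt" and not case.is_hom_alt:
            clauses.append(f"{case_sample} not homozygous alt")
        if clauses:
            r.trail.record("strain_or_reference", "excluded", "; ".join(clauses))
            r.status = "excluded"
        else:
            r.trail.record("strain_or_reference", "pass", f"{case_sample} hom alt; no strain hits")
        out.append(r)
    return out


# ------------------------------------------------------------------- round 3
def confidence_filter(
    reports: list[CandidateReport],
    min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> list[CandidateReport]:
    """Flag reports whose alt-asserting sample has weak read support.

    A sample asserts the alt allele when its genotype contains it; the flag
    fires when ``alt_reads/depth < min_alt_fraction`` or
    ``alt_reads < min_alt_reads`` in any asserting sample. Flags are recorded
    on every report's trail (the printed low-coverage comments apply to
    excluded rows too); only surviving candidates change status.
    """
    for r in reports:
        av = r.annotated
        for g in av.genotypes:
            if not g.has_alt:
                continue
            if g.depth == 0:
                raise DataError(
                    f"{g.sample}: zero depth with non-missing genotype at "
                    f"{av.variant.chrom}:{av.variant.pos}"
                )
            frac = g.alt_fraction
            if frac < min_alt_fraction or g.alt_reads < min_alt_reads:
                r.trail.record(
                    "read_support", "flagged",
                    f"{g.sample} low coverage ({g.alt_reads} of {g.depth} reads; "
                    f"{100 * frac:.1f}%)",
                )
                if r.status == "candidate":
                    r.status = "flagged_artifact"
    return reports


# -------------------------------------------------------------------- finale
@dataclass
class GeneReport:
    gene: str
    hgvs_c: str
    hgvs_p: str
    so_term: str
    genotype_pattern: str
    external_scores: dict
    trail: FilterTrail
    status: str


@dataclass
class FinalResult:
    reports: list[CandidateReport]
    candidate_genes: list[str]
    gene_reports: list[GeneReport]

    def stage_counts(self) -> dict:
        c = {"candidate": 0, "excluded": 0, "flagged_artifact": 0}
        for r in self.reports:
            c[r.status] += 1
        c["total"] = len(self.reports)
        return c


def _genotype_pattern(av: AnnotatedVariant, case_sample: str) -> str:
    parts = []
    for g in av.genotypes:
        z = "hom alt" if g.is_hom_alt else ("hom ref" if g.is_hom_ref else "het")
        role = "case" if g.sample == case_sample else "ancestral"
        parts.append(f"{role} {z}")
    return "; ".join(parts)


def finalize(
    reports: list[CandidateReport], *, case_sample: str = ""
) -> FinalResult:
    """Drop flagged artifacts and emit the per-gene candidate report.

    With no flags present this is the identity on the surviving gene set.
    """
    genes: list[str] = []
    gene_reports: list[GeneReport] = []
    for r in reports:
        if r.status == "candidate" and r.gene not in genes:
            genes.append(r.gene)
        if r.status in ("candidate", "flagged_artifact"):
            av = r.annotated
            gene_reports.append(
                GeneReport(
                    gene=r.gene,
                    hgvs_c=av.hgvs_c,
                    hgvs_p=av.hgvs_p,
                    so_term=av.so_term,
                    genotype_pattern=_genotype_pattern(av, case_sample),
                    external_scores=dict(av.external_scores),
                    trail=r.trail,
                    status=r.status,
                )
            )
    return FinalResult(reports=reports, candidate_genes=genes, gene_reports=gene_reports)


def run_cascade(
    annotated: list[AnnotatedVariant],
    dbsnp146: VariantCatalog,
    ensembl106: VariantCatalog,
    panel: GenePanel,
    *,
    case_sample: str,
    ancestral_sample: str,
    min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    reference_rule: str = "require_case_hom_alt",
) -> FinalResult:
    """Run the full prioritization cascade and return the final result."""
    r1 = first_round(
        annotated, dbsnp146, panel,
        case_sample=case_sample, ancestral_sample=ancestral_sample,
    )
    r2 = second_round(r1, ensembl106, case_sample, reference_rule=reference_rule)
    r3 = confidence_filter(r2, min_alt_fraction, min_alt_reads)
    return finalize(r3, case_sample=case_sample)


def stage_exclusion_counts(reports: list[CandidateReport]) -> dict:
    """Per-rule exclusion counts plus retained/flagged totals."""
    counts: dict = {}
    for r in reports:
        rule = r.trail.excluding_rule
        if rule:
            counts[rule] = counts.get(rule, 0) + 1
    counts["flagged_artifact"] = sum(1 for r in reports if r.status == "flagged_artifact")
    counts["candidate"] = sum(1 for r in reports if r.status == "candidate")
    counts["total"] = len(reports)
    return counts
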