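"""Human-readable report rendering (candidate-table layout plus status)."""

from __future__ import annotations

import json

from .cascade import CandidateReport, CategorySummary, FinalResult

_COLUMNS = (
    "marker", "ref", "alt", "gene", "so_term", "region", "hgvs_c", "hgvs_p",
    "effect", "genotypes", "rs", "strains", "comments", "status",
)


def _report_row(r: CandidateReport) -> dict:
    av = r.annotated
    v = av.variant
    kind = {"SNV": "SNV", "insertion": "Ins", "deletion": "Del", "delins": "Delins"}[v.kind]
    rs = ""
    strains = ""
    for e in r.trail.entries:
        if e.rule_id in ("dbsnp146_known", "ensembl106_known") and e.outcome == "excluded":
            rs = e.detail.split(";")[0]
        if e.rule_id == "strain_or_reference" and e.outcome == "excluded":
            strains = e.detail
    comments = "; ".join(
        [e.detail for e in r.trail.entries if e.outcome == "flagged"] + av.notes
    )
    return {
        "marker": f"{v.chrom}:{v.pos}-{kind}",
        "ref": v.ref or "-",
        "alt": v.alt or "-",
        "gene": av.gene_symbol,
        "so_term": av.so_term,
        "region": av.region_label,
        "hgvs_c": av.hgvs_c,
        "hgvs_p": av.hgvs_p,
        "effect": av.effect_class,
        "genotypes": ";".join("/".join(g.alleles) for g in av.genotypes),
        "rs": rs,
        "strains": strains,
        "comments": comments,
        "status": r.status,
    }


def render_report(
    reports: list[CandidateReport], summary: CategorySummary | None = None
) -> str:
    """Markdown report: one row per first-round variant, candidates marked."""
    lines = ["# Candidate-gene prioritization report", ""]
    if summary is not None:
        lines += ["## Variant category summary", ""]
        lines.append(summary.to_frame().to_markdown(index=False))
        lines.append("")
    lines += ["## Filter cascade", ""]
    rows = [_report_row(r) for r in reports]
    lines.append("| " + " | ".join(_COLUMNS) + " |")
    lines.append("|" + "---|" * len(_COLUMNS))
    for row in rows:
        lines.append("| " + " | ".join(str(row[c]) for c in _COLUMNS) + " |")
    lines.append("")
    n_cand = sum(1 for r in reports if r.status == "candidate")
    genes = []
    for r in reports:
        if r.status == "candidate" and r.gene not in genes:
            genes.append(r.gene)
    lines.append(
        f"**{n_cand} candidate variant(s)** in gene(s): "
        + (", ".join(genes) if genes else "(none)")
    )
    lines.append("")
    return "\n".join(lines)


def trails_to_json(result: FinalResult) -> str:
    payload = []
    for r in result.reports:
        av = r.annotated
        payload.append(
            {
                "variant": f"{av.variant.chrom}:{av.variant.pos}"
                f" {av.variant.ref or '-'}>{av.variant.alt or '-'}",
                "gene": av.gene_symbol,
                "so_term": av.so_term,
                "status": r.status,
                "trail": [
                    {"rule": e.rule_id, "outcome": e.outcome, "detail": e.detail}
                    for e in r.trail.entries
                ],
            }
        )
    return json.dumps(
        {
            "candidate_genes": result.candidate_genes,
            "stage_counts": result.stage_counts(),
            "reports": payload,
        },
        indent=2,
    )
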