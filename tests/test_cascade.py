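"""The two-round prioritization cascade on the packaged candidate table."""

import copy

import pytest

from varcascade import cascade as C
from varcascade.catalogs import CatalogRecord, GenePanel, PanelGene, VariantCatalog
from varcascade.consequence import AnnotatedVariant, GenotypeCall, Variant
from varcascade.errors import ConfigError, DataError
from varcascade.fixtures import (
    ANCESTRAL_SAMPLE,
    CASE_SAMPLE,
    fixture_decoys,
    fixture_panel,
    table2_annotated,
    table2_catalog_ensembl106,
)
from varcascade.genome_model import GenomicInterval


def _run_fixture(world, **kwargs):
    return C.run_cascade(
        copy.deepcopy(world["annotated"]),
        world["dbsnp146"],
        world["ensembl106"],
        world["panel"],
        case_sample=CASE_SAMPLE,
        ancestral_sample=ANCESTRAL_SAMPLE,
        **kwargs,
    )


# ---------------------------------------------------------------- tabulate
def test_tabulate_empty():
    s = C.tabulate_by_category([])
    assert s.total == 0
    assert all(v == 0 for v in s.counts.values())


def test_tabulate_percentages_consistent(table2_annotated):
    s = C.tabulate_by_category(table2_annotated)
    assert sum(s.counts.values()) == s.total == 43
    pct = s.percentages
    assert abs(sum(pct.values()) - 100.0) < 1e-9
    for cat, n in s.counts.items():
        assert abs(pct[cat] - 100.0 * n / 43) < 0.01
    # sub-type subtotals nest under their parents
    assert sum(s.subtype_counts["disruptive_inframe_indel"].values()) == 1


# ------------------------------------------------------------- first round
def test_first_round_retains_exactly_the_candidate_table(fixture_world):
    r1 = C.first_round(
        fixture_world["annotated"], fixture_world["dbsnp146"], fixture_world["panel"],
        case_sample=CASE_SAMPLE, ancestral_sample=ANCESTRAL_SAMPLE,
    )
    kept = [r for r in r1 if r.status == "candidate"]
    assert len(kept) == 43
    assert len(r1) == len(fixture_world["annotated"])  # conservation
    missense_snv = [
        r for r in kept
        if r.annotated.so_term == "missense_variant" and r.annotated.variant.kind == "SNV"
    ]
    assert len(missense_snv) == 39
    assert len({r.gene for r in kept}) == 26


def test_first_round_excludes_by_named_rules(fixture_world):
    r1 = C.first_round(
        fixture_world["annotated"], fixture_world["dbsnp146"], fixture_world["panel"],
        case_sample=CASE_SAMPLE, ancestral_sample=ANCESTRAL_SAMPLE,
    )
    rules = {r.trail.excluding_rule for r in r1 if r.status == "excluded"}
    assert rules == {"effect_class", "panel", "dbsnp146_known"}
    # a panel-gene variant with an rs identifier is excluded by the rs rule
    rs_excluded = [r for r in r1 if r.trail.excluding_rule == "dbsnp146_known"]
    assert rs_excluded and all(r.gene in fixture_world["panel"] for r in rs_excluded)


def test_first_round_missing_sample_is_config_error(fixture_world):
    av = copy.deepcopy(fixture_world["annotated"][0])
    av.genotypes = [g for g in av.genotypes if g.sample != CASE_SAMPLE]
    with pytest.raises(ConfigError):
        C.first_round(
            [av], fixture_world["dbsnp146"], fixture_world["panel"],
            case_sample=CASE_SAMPLE, ancestral_sample=ANCESTRAL_SAMPLE,
        )


# ------------------------------------------------------------ second round
def test_second_round_20_then_19_then_four_genes(fixture_world):
    r1 = C.first_round(
        copy.deepcopy(fixture_world["annotated"]),
        fixture_world["dbsnp146"], fixture_world["panel"],
        case_sample=CASE_SAMPLE, ancestral_sample=ANCESTRAL_SAMPLE,
    )
    r2 = C.second_round(r1, fixture_world["ensembl106"], CASE_SAMPLE)
    assert sum(1 for r in r2 if r.trail.excluding_rule == "ensembl106_known") == 20
    assert sum(1 for r in r2 if r.trail.excluding_rule == "strain_or_reference") == 19
    survivors = {r.gene for r in r2 if r.status == "candidate"}
    assert survivors == {"Fktn", "Prx", "Adamts10", "Abhd12"}


# -------------------------------------------------------------- confidence
def _report(depth, alt_reads, alleles=("alt", "alt")):
    av = AnnotatedVariant(
        variant=Variant(GenomicInterval("1", 10, 11), "A", "G"),
        genotypes=[GenotypeCall("EmJ", alleles, depth=depth, alt_reads=alt_reads)],
        gene_symbol="G", so_term="missense_variant", effect_class="Missense",
    )
    return C.CandidateReport(annotated=av)


@pytest.mark.parametrize(
    "depth,alt,flagged",
    [(16, 2, True), (18, 2, True), (16, 8, False), (30, 30, False), (30, 4, True)],
)
def test_confidence_thresholds(depth, alt, flagged):
    (r,) = C.confidence_filter([_report(depth, alt)])
    assert r.trail.flagged is flagged
    assert (r.status == "flagged_artifact") is flagged


def test_zero_depth_with_alt_genotype_is_data_error():
    with pytest.raises(DataError):
        C.confidence_filter([_report(0, 0)])


# ---------------------------------------------------------------- finalize
def test_full_cascade_prioritizes_three_genes(fixture_world):
    result = _run_fixture(fixture_world)
    assert result.candidate_genes == ["Abhd12", "Prx", "Adamts10"]
    flagged = [r.gene for r in result.reports if r.status == "flagged_artifact"]
    assert flagged == ["Fktn"]
    counts = result.stage_counts()
    assert counts["total"] == len(fixture_world["annotated"])
    assert counts["candidate"] + counts["excluded"] + counts["flagged_artifact"] == counts["total"]
    # external scores are carried through verbatim on the final gene reports
    scores = {g.gene: g.external_scores for g in result.gene_reports}
    assert scores["Abhd12"]["PROVEAN"] == -20.74
    prx = next(g for g in result.gene_reports if g.gene == "Prx")
    assert prx.genotype_pattern == "ancestral het; case hom alt"


def test_finalize_identity_without_flags(fixture_world):
    r1 = C.first_round(
        copy.deepcopy(fixture_world["annotated"]),
        fixture_world["dbsnp146"], fixture_world["panel"],
        case_sample=CASE_SAMPLE, ancestral_sample=ANCESTRAL_SAMPLE,
    )
    r2 = C.second_round(r1, fixture_world["ensembl106"], CASE_SAMPLE)
    before = {r.gene for r in r2 if r.status == "candidate"}
    result = C.finalize(r2, case_sample=CASE_SAMPLE)  # no confidence pass
    assert set(result.candidate_genes) == before


# --------------------------------------------------------------- properties
def test_monotonicity_more_catalog_never_more_candidates(fixture_world):
    base = _run_fixture(fixture_world)
    bigger = VariantCatalog(list(fixture_world["ensembl106"]._index.values()))
    # catalogue one surviving candidate (the Adamts10 site) in the later release
    bigger.add(
        CatalogRecord(
            GenomicInterval("17", 33549038, 33549039), "C", "T", "rs99999999"
        )
    )
    world2 = dict(fixture_world, ensembl106=bigger)
    more = _run_fixture(world2)
    assert set(more.candidate_genes) <= set(base.candidate_genes)
    assert len(more.candidate_genes) < len(base.candidate_genes)


def test_monotonicity_smaller_panel_never_more_candidates(fixture_world):
    smaller = GenePanel(
        [PanelGene(g.symbol) for g in fixture_world["panel"] if g.symbol != "Prx"]
    )
    world2 = dict(fixture_world, panel=smaller)
    fewer = _run_fixture(world2)
    base = _run_fixture(fixture_world)
    assert set(fewer.candidate_genes) <= set(base.candidate_genes)
    assert "Prx" not in fewer.candidate_genes


def test_cascade_idempotent_on_survivors(fixture_world):
    result = _run_fixture(fixture_world)
    survivors = [
        copy.deepcopy(r.annotated) for r in result.reports if r.status == "candidate"
    ]
    again = C.run_cascade(
        survivors, fixture_world["dbsnp146"], fixture_world["ensembl106"],
        fixture_world["panel"],
        case_sample=CASE_SAMPLE, ancestral_sample=ANCESTRAL_SAMPLE,
    )
    assert set(again.candidate_genes) == set(result.candidate_genes)
    assert all(r.status == "candidate" for r in again.reports)


def test_every_excluded_report_names_exactly_one_rule(fixture_world):
    result = _run_fixture(fixture_world)
    for r in result.reports:
        n_excl = sum(1 for e in r.trail.entries if e.outcome == "excluded")
        assert n_excl == (1 if r.status == "excluded" else 0)
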