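import pytest

from varcascade import fixtures as F
from varcascade import simulate as S
from varcascade.genome_model import GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def abhd12_cds() -> str:
    return F.mini_cds("ABHD12_LIKE")


@pytest.fixture(scope="session")
def table2():
    return F.load_table2()


@pytest.fixture(scope="session")
def table2_annotated():
    return F.table2_annotated()


@pytest.fixture(scope="session")
def fixture_world():
    """Annotated Table-2 rows + decoys, both catalogs, and the panel."""
    annotated = F.table2_annotated()
    decoys, dbsnp146 = F.fixture_decoys(seed=1)
    return {
        "annotated": annotated + decoys,
        "dbsnp146": dbsnp146,
        "ensembl106": F.table2_catalog_ensembl106(),
        "panel": F.fixture_panel(),
    }


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    cfg = S.SimulationConfig(n_variants=600, seed=11)
    return S.generate_world(cfg, tmp_path_factory.mktemp("world"))


def make_transcript(
    cds: str,
    *,
    strand: str = "+",
    chrom: str = "chrT",
    offset: int = 100,
    utr5: str = "",
    utr3: str = "",
    intron_at: int | None = None,
    intron_len: int = 500,
    gene: str = "TestGene",
    filler_seed: int = 0,
):
    """Build a transcript (and its genome dict) around an explicit CDS string.

    ``intron_at`` splits the spliced mRNA after that many bases (two exons).
    """
    import numpy as np

    mrna = utr5 + cds + utr3
    rng = np.random.default_rng(filler_seed)
    bases = "ACGT"

    def rand(n):
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    if intron_at is None:
        exon_seqs = [mrna]
        introns = []
    else:
        exon_seqs = [mrna[:intron_at], mrna[intron_at:]]
        introns = [rand(intron_len)]
    block = exon_seqs[0]
    bounds = [(0, len(exon_seqs[0]))]
    for i, ex in enumerate(exon_seqs[1:]):
        block += introns[i]
        bounds.append((len(block), len(block) + len(ex)))
        block += ex
    genomic = block if strand == "+" else _rc(block)
    genome = {chrom: rand(offset) + genomic + rand(200)}
    L = len(block)
    if strand == "+":
        exons = [GenomicInterval(chrom, offset + a, offset + b) for a, b in bounds]
    else:
        exons = [GenomicInterval(chrom, offset + L - b, offset + L - a) for a, b in bounds]
    tx_lo, tx_hi = len(utr5), len(utr5) + len(cds)
    gl = _tx2g(exons, strand, tx_lo)
    gh = _tx2g(exons, strand, tx_hi - 1)
    t = TranscriptModel(
        transcript_id=f"{gene}.t1",
        gene_symbol=gene,
        strand=strand,
        exons=exons,
        cds_start=min(gl, gh),
        cds_end=max(gl, gh) + 1,
    )
    t.attach_genome(genome)
    assert t.cds_sequence() == cds
    return t, genome


def _rc(s: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return s.translate(comp)[::-1]


def _tx2g(exons, strand, tx):
    off = 0
    for e in exons:
        if tx < off + len(e):
            k = tx - off
            return e.start + k if strand == "+" else e.end - 1 - k
        off += len(e)
    raise AssertionError
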