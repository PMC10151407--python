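# Methods

## Coordinate model

Transcript models carry exons in transcription order on either strand;
internal coordinates are 0-based half-open, while every on-disk format
(GFF3, VCF, HGVS, marker strings) is 1-based inclusive. Genomic positions
map to coding coordinates by walking the spliced exon structure: coding
positions get a plain `c.N`; 5'/3'-UTR positions get `c.-N` / `c.*N`;
intronic positions get the HGVS nearest-exon anchor with a signed offset
(ties at an intron midpoint go to the upstream, `+`, side). Positions up to
5 kb outside the transcript span are classified upstream/downstream — the
common annotator default, adopted because the prioritization protocol this
package reimplements does not define a flank width. Codon arithmetic is
`codon = ceil(c/3)`, `frame = (c-1) mod 3`.

## Consequence calls

Single-nucleotide variants in the CDS are classified by codon substitution
(missense, synonymous, stop_gained, stop_lost, stop_retained, start_lost).
Splice windows follow standard annotator convention: intronic positions 1–2
are splice_donor/splice_acceptor, 3–8 are splice_region, and the 3 exonic
bases flanking an internal junction are splice_region *when that term
outranks the coding consequence* in the fixed severity order (so a missense
change at a junction stays missense; a synonymous one reports
splice_region).

Coding indels are classified by frame and codon alignment of their
**3'-normalized** representation: length changes not divisible by 3 are
frameshift; whole-codon gains/losses (boundaries coincide with codon
boundaries) are inframe_insertion/inframe_deletion; frame-preserving events
that break codon boundaries are disruptive_inframe_* and produce a
protein-level `delins`. Classifying on the normalized form means a
codon-aligned deletion inside a repeat that right-shifts out of alignment is
reported disruptive — the two descriptions are the same molecule, and the
3'-rule picks the canonical one.

When a variant hits several transcripts, all are annotated and the most
severe (by a fixed, documented severity order: stop_gained > frameshift >
stop_lost > start_lost > splice_acceptor > splice_donor >
disruptive_inframe_* > inframe_* > missense > splice_region > stop_retained
> synonymous > UTR5 > UTR3 > non_coding_exon > intron > upstream >
downstream) is reported as clinically relevant; the per-transcript list is
preserved. 5'-UTR variants are classed Other with a note flag — the
alternative reading ("Missense, other") matters only for categories that
never reach the candidate stage.

Effect classes are a total, fixed mapping: missense and all in-frame indels
→ Missense; splice acceptor/donor, frameshift, stop gained/lost, start lost
→ LoF; silent/regulatory-adjacent terms → Other; upstream/downstream →
Unknown.

## Protein-level naming

`protein_consequence` translates the reference and mutant CDS and diffs the
proteins: single-residue substitutions as `p.Xpos Y`; a premature stop at
the first changed residue as `p.Xpos*`; frameshifts as `p.XposYfs*N` with N
counted from the first changed residue to the new stop (`?` when none is
reached); clean residue losses/gains right-shifted to their most C-terminal
position and named `del`/`dup`/`ins`; boundary-breaking in-frame events as
`delins`. Three-letter amino-acid codes are used throughout.

## HGVS engine and indel reconciliation

The parser covers the coding-DNA subset used in exome review (substitution,
del, ins, delins, dup, with UTR and intron-offset positions parsed but
flagged as outside the CDS). `normalize` trims shared bases and applies the
3'-rule, converting insertions that duplicate the immediately 5' span into
duplications; it is idempotent and preserves application semantics.

`equivalent_representations` enumerates, for a bounded reference/mutant
window pair (≤200 nt, pair search focused on a ±12 nt core around the
difference), every single-edit representation plus all two-event
decompositions of one deletion with one deletion or insertion. Two-event
decompositions are limited to such pairs by design: that is the alternative
a Sanger trace can motivate; higher-order rearrangements are unresolvable
and out of scope. `reconcile` applies a caller's edit to the reference
window and, when the product disagrees with the observed haplotype, returns
the minimal normalized delins as the correction together with the
equivalence class — the engine deliberately reports a class, never a unique
physical event.

## Filter cascade

Each input variant receives a report with an ordered rule trail; exclusions
name exactly one rule, so stage counts always conserve the input total.
Round one keeps Missense/LoF effect, panel membership (case-insensitive),
and absence from the first-release catalog. Round two excludes, in order,
(a) variants with an rs identifier in the later-release catalog, then (b)
variants present in other strains **and/or** whose case sample does not
assert the variant; the two clauses are pooled as one rule (the protocol
treats them as one exclusion step) but the trail detail records which
fired. The case-zygosity requirement (homozygous alternate) is enforced in
round two only — enforcing it in round one would change the printed
43/20/19/4 arithmetic. Catalog matching is allele-aware and position-exact
after trimming to a minimal representation.

Read-support flags fire when any alt-asserting sample has alt fraction
< 0.2 or fewer than 3 alt reads. The defaults are calibrated so that 2/16
(12.5%) and 2/18 fail while ordinary heterozygous (~50%) and homozygous
calls pass; both thresholds are configuration-exposed because the protocol
states none. In-silico pathogenicity scores (SIFT/PROVEAN) are carried
through as metadata and never used as a filter — no variant is excluded by
score.

## Packaged fixtures

The 43-row candidate table is transcribed verbatim (HGVS strings, rs
identifiers, strain genotypes, comments), with machine-readable genotype
columns added: printed IGV genotype letters are decoded to ref/alt pairs
(with a complement decode where the printed letters are transcript-strand),
and read depths are taken from the printed comments where stated, otherwise
synthesized at depth 30 with genotype-consistent alt counts. One printed
string carries a typographic artifact (a degree sign inside a `c.` position)
and is transcribed as `c.50C>T`, the only reading consistent with the
printed `p.Ala17Val`; the fixture row carries a note. The low-coverage
case-sample call in the *Fktn* row is coded as the caller's homozygous-alt
assertion (depth 16, 2 alt reads) — that is what lets it reach, and then
fail, the validation stage, as in the source arithmetic.

Mini-CDS contexts anchor the worked consequence examples (codon 103 `TGT`,
codon 347 `TAC`, codons 30–32 `CTG GAC GCC`). They are synthetic open
reading frames: start codon, deterministic non-stop filler codons from a
frozen seed, terminal `TAA`; only the anchored codons are constrained, so
translation invariants hold everywhere.

## Synthetic worlds

The generator builds ~40 coding genes (5–8 exons, CDS 2.4–4.2 kb, UTRs,
introns 0.6–2.5 kb) and 4 non-coding genes across two chromosomes, with
intergenic gaps ≥12 kb so 5 kb flank classifications never overlap
neighboring genes. Gene counts and sizes were chosen so every consequence
category — including the splice-region subclass, the binding constraint —
has enough candidate placements for a full-size (87,138-variant) draw;
each site supports up to three alternate alleles (the biallelic-split
convention). Category counts are drawn from a multinomial over the
reference composition; sub-types (splice acceptor/donor/region, UTR3/5,
indel classes, stop classes) follow the reference sub-splits. SNV
placements come from precomputed per-position classification pools; indels
are placed with bounded retries (80) and re-verified; every emitted variant
is re-annotated through the full multi-transcript path and must reproduce
its sampled category, so the realized composition equals the drawn one
exactly.

Genotypes follow a two-sample pattern mixture (both-hom-alt 0.50,
case-hom/anc-het 0.15, case-hom/anc-ref 0.05, case-het 0.10, case-ref
0.20), reflecting that most non-reference calls are shared ancestrally
derived alleles; read depths are negative-binomial (mean 30, dispersion
0.3). The artifact pattern draws ≤2 alt reads at depth ≥12 under an
asserted hom-alt call. Catalog membership is Bernoulli per variant (0.9
first release, 0.5 of the remainder in the later release, matching the
report that >90% of Missense/LoF calls carried rs identifiers); later-release
records carry per-strain genotypes at sharing probability 0.5. Planted
truths (a novel candidate, rs-bearing twins, a strain-shared twin, an
off-panel twin, and a low-coverage artifact) are embedded with reserved
positions and written to a truth table. All randomness flows from one
`numpy` Generator; fixed seed ⇒ byte-identical files.

What the generator does **not** emulate: read-level errors and alignment
artifacts (beyond the summary depth/alt-count model), linkage
disequilibrium and realistic inter-variant spacing, overlapping gene
structures, multi-isoform loci, and indel-rich repeat contexts. Passing
tests therefore demonstrate the cascade's logic and the annotator's
correctness on clean calls, not robustness to upstream calling error.

## Problem sizes and numerical choices

The default test suite uses worlds of 300–600 variants (plus one 20,000 and
one full 87,138 draw) and 20 seeds for the truth-recovery battery; these
sizes make the full suite run in a couple of minutes while leaving the
composition calibration at the study's full n. Chi-square goodness-of-fit
uses 12 degrees of freedom over the 13 categories at α = 0.01. Exact-match
string tests (HGVS, protein naming) use no tolerance. Ties and degenerate
inputs: empty panel, zero-depth genotypes with non-missing calls, inverted
edit spans, and identical reconciliation windows all raise typed errors
rather than degrading silently.

## Known limitations

Printed annotation strings in the packaged table are fixture ground truth;
they are not re-derived from real RefSeq models, whose proprietary
annotation rules this package only mimics by standard conventions. The HGVS
grammar excludes genomic (`g.`) and RNA (`r.`) descriptions, inversions and
conversions. Indels spanning exon–intron boundaries receive a coarse
most-severe-region classification. The cascade assumes exactly one case and
one ancestral sample.
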