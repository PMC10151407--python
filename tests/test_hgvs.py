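"""HGVS coding-DNA engine: parse/format, apply, normalize, reconcile."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varcascade import hgvs as H
from varcascade.errors import ParseError, ReferenceMismatchError


# ------------------------------------------------------------------- parse
@pytest.mark.parametrize(
    "text,kind,start,end,deleted,inserted",
    [
        ("c.499C>T", "substitution", 499, 499, "C", "T"),
        ("c.499C > T", "substitution", 499, 499, "C", "T"),  # printed typography
        ("c.88_94delCTGGACGinsT", "delins", 88, 94, "CTGGACG", "T"),
        ("c.89_94delTGGACG", "deletion", 89, 94, "TGGACG", ""),
        ("c.6579dupC", "duplication", 6579, 6579, "", "C"),
        ("c.3884_3895dupTGGAGATGGAGC", "duplication", 3884, 3895, "", "TGGAGATGGAGC"),
        ("c.88_89insT", "insertion", 88, 89, "", "T"),
        ("NM_198048:c.499C>T", "substitution", 499, 499, "C", "T"),
    ],
)
def test_parse_examples(text, kind, start, end, deleted, inserted):
    e = H.parse_hgvs_c(text)
    assert (e.kind, e.start_c, e.end_c, e.deleted_seq, e.inserted_seq) == (
        kind, start, end, deleted, inserted,
    )
    assert e.non_cds_flag == ""


def test_utr_and_intron_positions_parse_but_flag():
    e = H.parse_hgvs_c("c.*1138A>C")
    assert e.non_cds_flag == "UTR3"
    e = H.parse_hgvs_c("c.499+3A>G")
    assert e.non_cds_flag == "intron"
    e = H.parse_hgvs_c("n.210A>G")
    assert e.non_cds_flag == "non_coding"
    with pytest.raises(ReferenceMismatchError):
        H.apply_edit("ACGT" * 300, H.parse_hgvs_c("c.*1138A>C"))


def test_garbage_raises_parse_error():
    for bad in ("c.xyz", "p.Cys103Ser", "c.10_delins", "hello"):
        with pytest.raises(ParseError):
            H.parse_hgvs_c(bad)


def test_parse_format_round_trip_on_candidate_table(table2):
    """Every coding HGVS string printed in the candidate table round-trips."""
    checked = 0
    for cell in table2["hgvs_c"]:
        for part in cell.split(","):
            part = part.strip()
            e = H.parse_hgvs_c(part)
            body = part.split(":", 1)[1] if ":" in part else part
            prefix = body[:2]
            assert H.format_hgvs_c(e, prefix=prefix) == body
            checked += 1
    assert checked >= 43


# ------------------------------------------------------------------- apply
def test_apply_delins_by_hand_splice(abhd12_cds):
    e = H.parse_hgvs_c("c.88_94delCTGGACGinsT")
    out = H.apply_edit(abhd12_cds, e)
    assert out == abhd12_cds[:87] + "T" + abhd12_cds[94:]
    assert abhd12_cds[87:96] == "CTGGACGCC"
    assert out[87:90] == "TCC"


def test_apply_substitution_involution(abhd12_cds):
    e = H.parse_hgvs_c("c.10" + abhd12_cds[9] + ">" + ("A" if abhd12_cds[9] != "A" else "G"))
    once = H.apply_edit(abhd12_cds, e)
    inverse = H.CodingEdit("substitution", 10, 10, e.inserted_seq, e.deleted_seq)
    assert H.apply_edit(once, inverse) == abhd12_cds


def test_apply_empty_deletion_errors(abhd12_cds):
    empty = H.CodingEdit("deletion", 10, 9, "", "")  # inverted span = empty deletion
    with pytest.raises(ReferenceMismatchError):
        H.apply_edit(abhd12_cds, empty)


def test_apply_reference_mismatch(abhd12_cds):
    e = H.CodingEdit("deletion", 89, 94, "AAAAAA", "")
    with pytest.raises(ReferenceMismatchError):
        H.apply_edit(abhd12_cds, e)


# --------------------------------------------------------------- normalize
def test_homopolymer_deletion_shifts_three_prime():
    seq = "ATG" + "CCAAAACC" + "TGA"
    # delete the first A of the AAAA run (position 6) -> 3'-most is position 9
    e = H.CodingEdit("deletion", 6, 6, "A", "")
    n = H.normalize(e, seq)
    assert (n.kind, n.start_c, n.end_c) == ("deletion", 9, 9)


def test_insertion_equal_to_five_prime_span_becomes_duplication():
    seq = "ATGTGGAGATGGAGCCCCTAA"
    ins = H.CodingEdit("insertion", 15, 16, "", "TGGAGATGGAGC")
    n = H.normalize(ins, seq)
    assert n.kind == "duplication"
    assert (n.start_c, n.end_c) == (4, 15)
    assert H.apply_edit(seq, n) == H.apply_edit(seq, ins)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.data())
def test_normalize_is_idempotent_and_semantics_preserving(data):
    seq = data.draw(
        st.text(alphabet="ACGT", min_size=20, max_size=40), label="seq"
    )
    kind = data.draw(st.sampled_from(["deletion", "insertion", "substitution"]))
    pos = data.draw(st.integers(min_value=2, max_value=len(seq) - 5), label="pos")
    if kind == "deletion":
        k = data.draw(st.integers(min_value=1, max_value=3))
        e = H.CodingEdit("deletion", pos, pos + k - 1, seq[pos - 1 : pos + k - 1], "")
    elif kind == "insertion":
        ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
        e = H.CodingEdit("insertion", pos, pos + 1, "", ins)
    else:
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != seq[pos - 1]]))
        e = H.CodingEdit("substitution", pos, pos, seq[pos - 1], alt)
    n1 = H.normalize(e, seq)
    n2 = H.normalize(n1, seq)
    assert n1 == n2
    assert H.apply_edit(seq, n1) == H.apply_edit(seq, e)


# --------------------------------------- equivalent representations / recon
def test_identical_windows_raise_empty_diff():
    with pytest.raises(ParseError):
        H.equivalent_representations("ACGT", "ACGT")


def test_single_mismatch_gives_one_substitution():
    reps = H.equivalent_representations("AACGA", "AACTA")
    singles = [r for r in reps if len(r) == 1]
    assert len(singles) == 1
    (e,) = singles[0]
    assert (e.kind, e.start_c, e.deleted_seq, e.inserted_seq) == (
        "substitution", 4, "G", "T",
    )


def test_abhd12_equivalence_class(abhd12_cds):
    """The minimal delins and the paired two-deletion decomposition coexist."""
    delins = H.parse_hgvs_c("c.88_94delCTGGACGinsT")
    mutant = H.apply_edit(abhd12_cds, delins)
    lo, hi = 80, 100
    ref_w = abhd12_cds[lo - 1 : hi]
    mut_w = mutant[lo - 1 : hi - 7 + 1]
    reps = H.equivalent_representations(ref_w, mut_w, window_c_start=lo)
    formatted = [tuple(sorted(H.format_hgvs_c(e) for e in r)) for r in reps]
    assert ("c.88_94delCTGGACGinsT",) in formatted
    assert ("c.88delC", "c.90_94delGGACG") in formatted


def test_all_representations_reapply_identically(abhd12_cds):
    delins = H.parse_hgvs_c("c.88_94delCTGGACGinsT")
    mutant = H.apply_edit(abhd12_cds, delins)
    ref_w = abhd12_cds[79:100]
    mut_w = mutant[79:94]
    reps = H.equivalent_representations(ref_w, mut_w)
    assert reps
    for rep in reps:
        assert H._apply_pair(ref_w, rep) == mut_w


def test_reconcile_discordant_six_bp_deletion(abhd12_cds):
    caller = H.parse_hgvs_c("c.89_94delTGGACG")
    truth = H.parse_hgvs_c("c.88_94delCTGGACGinsT")
    mutant = H.apply_edit(abhd12_cds, truth)
    lo, hi = 80, 100
    verdict = H.reconcile(
        caller, mutant[lo - 1 : hi - 6], abhd12_cds[lo - 1 : hi], window_c_start=lo
    )
    assert not verdict.concordant
    assert H.format_hgvs_c(verdict.corrected) == "c.88_94delCTGGACGinsT"
    pair_forms = [
        tuple(sorted(H.format_hgvs_c(e) for e in r))
        for r in verdict.alternatives
        if len(r) == 2
    ]
    assert ("c.88delC", "c.90_94delGGACG") in pair_forms


def test_reconcile_concordant_substitution(abhd12_cds):
    sub = H.CodingEdit("substitution", 10, 10, abhd12_cds[9], "A" if abhd12_cds[9] != "A" else "C")
    mutant = H.apply_edit(abhd12_cds, sub)
    verdict = H.reconcile(sub, mutant[:30], abhd12_cds[:30])
    assert verdict.concordant and verdict.corrected is None
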