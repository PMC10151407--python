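"""HGVS coding-DNA edits: parsing, application, normalization, reconciliation.

Implements the subset of the coding-DNA grammar needed for exome candidate
review: substitutions (``c.499C>T``), deletions (``c.89_94delTGGACG``),
insertions (``c.88_89insT``), deletion-insertions (``c.88_94delCTGGACGinsT``),
and duplications (``c.6579dupC``). UTR (``c.*N``, ``c.-N``) and intron-offset
(``c.N+M``/``c.N-M``) positions are parsed but flagged as outside the CDS.

Beyond single edits, :func:`equivalent_representations` enumerates the edit
representations — one minimal delins plus two-event (deletion + deletion or
deletion + insertion) decompositions — that all transform a reference window
into an observed mutant window. Sanger traces cannot distinguish members of
such an equivalence class, so :func:`reconcile` reports the class rather than
a unique physical rearrangement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .errors import ParseError, ReferenceMismatchError

_KINDS = {"substitution", "deletion", "insertion", "delins", "duplication"}


@dataclass(frozen=True)
class CodingEdit:
    """One edit on coding DNA, 1-based inclusive CDS bounds.

    For pure insertions and duplications ``start_c``/``end_c`` are the two
    flanking bases (HGVS ``c.N_{N+1}ins``); for duplications they delimit the
    duplicated reference span instead. ``non_cds_flag`` marks edits whose
    printed position lies outside the CDS proper (UTR or intron offset); such
    edits are carried but cannot be applied to a CDS string.
    """

    kind: str
    start_c: int
    end_c: int
    deleted_seq: str = ""
    inserted_seq: str = ""
    non_cds_flag: str = ""  # "", "UTR5", "UTR3", "intron", "non_coding"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParseError(f"unknown edit kind {self.kind!r}")
        if self.kind == "substitution" and not (
            self.start_c == self.end_c
            and len(self.deleted_seq) == 1
            and len(self.inserted_seq) == 1
        ):
            raise ParseError("substitution must replace exactly one base")

    # net length change when applied
    @property
    def length_change(self) -> int:
        if self.kind == "duplication":
            return self.end_c - self.start_c + 1
        if self.kind == "insertion":
            return len(self.inserted_seq)
        return len(self.inserted_seq) - len(self.deleted_seq)


_POS = r"(\*?-?\d+(?:[+-]\d+)?)"
_SUB_RE = re.compile(rf"^{_POS}([ACGT])>([ACGT])$")
_DEL_RE = re.compile(rf"^{_POS}(?:_{_POS})?del([ACGT]*)$")
_DUP_RE = re.compile(rf"^{_POS}(?:_{_POS})?dup([ACGT]*)$")
_INS_RE = re.compile(rf"^{_POS}_{_POS}ins([ACGT]+)$")
_DELINS_RE = re.compile(rf"^{_POS}(?:_{_POS})?del([ACGT]*)ins([ACGT]+)$")
_OFFSET_RE = re.compile(r"^(\*?)(-?\d+)(?:([+-])(\d+))?$")


def _parse_pos(text: str) -> tuple[int, str]:
    """Return (position, non_cds_flag) for one HGVS c. position token."""
    m = _OFFSET_RE.match(text)
    if not m:
        raise ParseError(f"bad HGVS position {text!r}")
    star, base, sign, off = m.groups()
    pos = int(base)
    flag = ""
    if star:
        flag = "UTR3"
    elif pos < 0:
        flag = "UTR5"
    if sign and int(off) != 0:
        flag = "intron"
    return pos, flag


def parse_hgvs_c(text: str) -> CodingEdit:
    """Parse an HGVS coding-DNA string (optionally ``NM_...:``-prefixed).

    Whitespace inside the string (Table-style typography such as
    ``c.499C > T``) is tolerated. UTR and intron-offset edits are returned
    with ``non_cds_flag`` set.
    """
    s = re.sub(r"\s+", "", text)
    if ":" in s:
        s = s.split(":", 1)[1]
    prefix = s[:2]
    if prefix == "n.":
        body, default_flag = s[2:], "non_coding"
    elif prefix == "c.":
        body, default_flag = s[2:], ""
    else:
        raise ParseError(f"not a coding-DNA HGVS string: {text!r}")

    m = _SUB_RE.match(body)
    if m:
        pos, flag = _parse_pos(m.group(1))
        return CodingEdit(
            "substitution", pos, pos, m.group(2), m.group(3),
            non_cds_flag=flag or default_flag,
        )
    m = _DELINS_RE.match(body)
    if m:
        p1, f1 = _parse_pos(m.group(1))
        p2, f2 = _parse_pos(m.group(2)) if m.group(2) else (p1, f1)
        return CodingEdit(
            "delins", p1, p2, m.group(3), m.group(4),
            non_cds_flag=f1 or f2 or default_flag,
        )
    m = _DEL_RE.match(body)
    if m:
        p1, f1 = _parse_pos(m.group(1))
        p2, f2 = _parse_pos(m.group(2)) if m.group(2) else (p1, f1)
        return CodingEdit(
            "deletion", p1, p2, m.group(3), "", non_cds_flag=f1 or f2 or default_flag
        )
    m = _DUP_RE.match(body)
    if m:
        p1, f1 = _parse_pos(m.group(1))
        p2, f2 = _parse_pos(m.group(2)) if m.group(2) else (p1, f1)
        return CodingEdit(
            "duplication", p1, p2, "", m.group(3), non_cds_flag=f1 or f2 or default_flag
        )
    m = _INS_RE.match(body)
    if m:
        p1, f1 = _parse_pos(m.group(1))
        p2, f2 = _parse_pos(m.group(2))
        return CodingEdit(
            "insertion", p1, p2, "", m.group(3), non_cds_flag=f1 or f2 or default_flag
        )
    raise ParseError(f"unsupported HGVS string: {text!r}")


def format_hgvs_c(e: CodingEdit, prefix: str = "c.") -> str:
    """Canonical textual form of a coding edit."""
    star = "*" if e.non_cds_flag == "UTR3" else ""
    p1, p2 = f"{star}{e.start_c}", f"{star}{e.end_c}"
    span = p1 if e.start_c == e.end_c else f"{p1}_{p2}"
    if e.kind == "substitution":
        return f"{prefix}{p1}{e.deleted_seq}>{e.inserted_seq}"
    if e.kind == "deletion":
        return f"{prefix}{span}del{e.deleted_seq}"
    if e.kind == "duplication":
        return f"{prefix}{span}dup{e.inserted_seq}"
    if e.kind == "insertion":
        return f"{prefix}{p1}_{p2}ins{e.inserted_seq}"
    return f"{prefix}{span}del{e.deleted_seq}ins{e.inserted_seq}"


def _check_cds(e: CodingEdit) -> None:
    if e.non_cds_flag:
        raise ReferenceMismatchError(
            f"edit {format_hgvs_c(e)} lies outside the CDS ({e.non_cds_flag})"
        )


def apply_edit(seq: str, e: CodingEdit) -> str:
    """Apply a coding edit to a CDS string (1-based edit coordinates)."""
    _check_cds(e)
    n = len(seq)
    if e.kind in ("substitution", "deletion", "delins"):
        s, t = e.start_c - 1, e.end_c
        if not (0 <= s < t <= n):
            # covers inverted spans, i.e. deletions of an effectively empty string
            raise ReferenceMismatchError(
                f"invalid edit span {e.start_c}_{e.end_c} on sequence of length {n}"
            )
        if e.deleted_seq and seq[s:t] != e.deleted_seq:
            raise ReferenceMismatchError(
                f"reference mismatch at c.{e.start_c}: "
                f"expected {e.deleted_seq}, found {seq[s:t]}"
            )
        if e.deleted_seq and len(e.deleted_seq) != t - s:
            raise ReferenceMismatchError("inconsistent deletion span")
        return seq[:s] + e.inserted_seq + seq[t:]
    if e.kind == "insertion":
        if e.end_c != e.start_c + 1:
            raise ReferenceMismatchError("insertion bounds must be adjacent")
        if not (1 <= e.start_c <= n):
            raise ReferenceMismatchError("insertion point outside sequence")
        return seq[: e.start_c] + e.inserted_seq + seq[e.start_c :]
    # duplication: insert a copy of start..end after end
    s, t = e.start_c - 1, e.end_c
    if not (0 <= s < t <= n):
        raise ReferenceMismatchError("duplication span outside sequence")
    dup = seq[s:t]
    if e.inserted_seq and e.inserted_seq != dup:
        raise ReferenceMismatchError(
            f"duplication sequence mismatch at c.{e.start_c}: "
            f"expected {e.inserted_seq}, found {dup}"
        )
    return seq[:t] + dup + seq[t:]


def _as_del_ins(e: CodingEdit, seq: str) -> tuple[int, str, str]:
    """Uniform (0-based start, deleted, inserted) view of an edit against seq."""
    if e.kind == "insertion":
        return e.start_c, "", e.inserted_seq
    if e.kind == "duplication":
        return e.end_c, "", seq[e.start_c - 1 : e.end_c]
    s = e.start_c - 1
    deleted = e.deleted_seq or seq[s : e.end_c]
    return s, deleted, e.inserted_seq


def _from_del_ins(start0: int, deleted: str, inserted: str, seq: str) -> CodingEdit:
    """Build the canonical CodingEdit for a (start, del, ins) description.

    ``start0`` is the 0-based offset of the first deleted base (or, for a pure
    insertion, of the first base after the insertion point).
    """
    if deleted and inserted:
        if len(deleted) == 1 and len(inserted) == 1:
            return CodingEdit("substitution", start0 + 1, start0 + 1, deleted, inserted)
        return CodingEdit("delins", start0 + 1, start0 + len(deleted), deleted, inserted)
    if deleted:
        return CodingEdit("deletion", start0 + 1, start0 + len(deleted), deleted, "")
    if not inserted:
        raise ParseError("empty edit")
    # pure insertion between start0 and start0+1 (1-based)
    k = len(inserted)
    if start0 >= k and seq[start0 - k : start0] == inserted:
        return CodingEdit("duplication", start0 - k + 1, start0, "", inserted)
    return CodingEdit("insertion", start0, start0 + 1, "", inserted)


def normalize(e: CodingEdit, seq: str) -> CodingEdit:
    """Return the 3'-most (most C-terminal) equivalent representation of *e*.

    Pure deletions and insertions are shifted 3'-wards through repeated
    sequence; insertions equal to the immediately 5' reference span become
    duplications. The operation is idempotent and preserves
    :func:`apply_edit` semantics.
    """
    _check_cds(e)
    apply_edit(seq, e)  # validates
    start0, deleted, inserted = _as_del_ins(e, seq)
    # trim shared prefix/suffix so delins collapse to their minimal core
    while deleted and inserted and deleted[0] == inserted[0]:
        deleted, inserted, start0 = deleted[1:], inserted[1:], start0 + 1
    while deleted and inserted and deleted[-1] == inserted[-1]:
        deleted, inserted = deleted[:-1], inserted[:-1]
    if deleted and not inserted:
        # shift deletion right while the base after the span repeats the first
        while start0 + len(deleted) < len(seq) and seq[start0 + len(deleted)] == deleted[0]:
            deleted = deleted[1:] + seq[start0 + len(deleted)]
            start0 += 1
    elif inserted and not deleted:
        while start0 < len(seq) and seq[start0] == inserted[0]:
            inserted = inserted[1:] + inserted[0]
            start0 += 1
    if not deleted and not inserted:
        raise ParseError("edit is a no-op after trimming")
    return _from_del_ins(start0, deleted, inserted, seq)


def _trim_diff(ref: str, mut: str) -> tuple[int, str, str] | None:
    """Minimal (start0, deleted, inserted) difference, or None if identical."""
    if ref == mut:
        return None
    p = 0
    while p < len(ref) and p < len(mut) and ref[p] == mut[p]:
        p += 1
    s = 0
    while (
        s < len(ref) - p and s < len(mut) - p and ref[-1 - s] == mut[-1 - s]
    ):
        s += 1
    return p, ref[p : len(ref) - s], mut[p : len(mut) - s]


def minimal_delins(ref_window: str, mutant_window: str, window_c_start: int = 1) -> CodingEdit:
    """The single minimal normalized edit turning ref_window into mutant_window."""
    d = _trim_diff(ref_window, mutant_window)
    if d is None:
        raise ParseError("windows are identical: empty diff")
    p, deleted, inserted = d
    e = _from_del_ins(p, deleted, inserted, ref_window)
    e = normalize(e, ref_window)
    return shift_edit(e, window_c_start - 1)


def shift_edit(e: CodingEdit, offset: int) -> CodingEdit:
    """Translate edit coordinates by *offset* bases (window -> CDS frame)."""
    return replace(e, start_c=e.start_c + offset, end_c=e.end_c + offset)


Representation = tuple[CodingEdit, ...]


def _apply_pair(ref: str, pair: Representation) -> str:
    """Apply edits given in one shared reference frame, 3'-most first."""
    out = ref
    for e in sorted(pair, key=lambda x: -x.start_c):
        out = apply_edit(out, e)
    return out


def equivalent_representations(
    ref_window: str,
    mutant_window: str,
    window_c_start: int = 1,
    max_window: int = 200,
) -> list[Representation]:
    """Enumerate edit representations transforming ref_window into mutant_window.

    Returns single-edit representations (always including the minimal
    normalized delins) and two-event decompositions consisting of one deletion
    plus one deletion or insertion, all expressed in the original reference
    frame (apply the 3'-most member first). Representations are deduplicated
    by their canonical formatted form.
    """
    if ref_window == mutant_window:
        raise ParseError("windows are identical: empty diff")
    if max(len(ref_window), len(mutant_window)) > max_window:
        raise ParseError(f"window longer than {max_window} nt")
    d = _trim_diff(ref_window, mutant_window)
    p, deleted, inserted = d
    reps: dict[tuple[str, ...], Representation] = {}

    def add(rep: Representation) -> None:
        key = tuple(sorted(format_hgvs_c(e) for e in rep))
        if key not in reps and _apply_pair(ref_window, rep) == mutant_window:
            reps[key] = tuple(sorted(rep, key=lambda e: e.start_c))

    # single-edit representations: all prefix/suffix trim splits, normalized
    cp = p
    cs = len(ref_window) - p - len(deleted)
    for pp in range(cp + 1):
        for ss in range(cs + 1):
            core_ref = ref_window[pp : len(ref_window) - ss]
            core_mut = mutant_window[pp : len(mutant_window) - ss]
            dd = _trim_diff(core_ref, core_mut)
            if dd is None:
                continue
            q, dsub, isub = dd
            if not dsub and not isub:
                continue
            try:
                e = _from_del_ins(pp + q, dsub, isub, ref_window)
                e = normalize(e, ref_window)
            except (ParseError, ReferenceMismatchError):
                continue
            add((e,))

    # focus pair enumeration on a bounded core around the difference
    lo = max(0, p - 12)
    hi = min(len(ref_window), p + len(deleted) + 12)
    # enumerate first deletion spans within the core; derive the second event
    for i in range(lo, hi):
        for j in range(i + 1, hi + 1):
            first = CodingEdit("deletion", i + 1, j, ref_window[i:j], "")
            intermediate = ref_window[:i] + ref_window[j:]
            dd = _trim_diff(intermediate, mutant_window)
            if dd is None:
                continue
            q, dsub, isub = dd
            if dsub and isub:
                continue  # remainder is itself a delins: not a clean pair
            # map the second event back into the original reference frame
            orig = q if q < i else q + (j - i)
            if dsub:
                # two deletions; skip degenerate contiguous splits (= one event)
                if orig == j or orig + len(dsub) == i:
                    continue
                second = CodingEdit(
                    "deletion", orig + 1, orig + len(dsub),
                    ref_window[orig : orig + len(dsub)], "",
                )
            elif isub:
                # deletion + insertion; adjacent-or-inside = a plain delins
                if i <= orig <= j:
                    continue
                second = CodingEdit("insertion", orig, orig + 1, "", isub)
            else:
                continue
            add((first, second))

    out = [
        tuple(shift_edit(e, window_c_start - 1) for e in rep)
        for rep in reps.values()
    ]

    def _weight(rep: Representation) -> tuple:
        edited = sum(
            len(e.deleted_seq) + len(e.inserted_seq)
            + (e.end_c - e.start_c + 1 if e.kind == "deletion" and not e.deleted_seq else 0)
            for e in rep
        )
        return (len(rep), edited, format_hgvs_c(rep[0]))

    out.sort(key=_weight)
    return out


@dataclass(frozen=True)
class ReconcileVerdict:
    concordant: bool
    corrected: CodingEdit | None = None
    alternatives: tuple[Representation, ...] = ()


def reconcile(
    caller_edit: CodingEdit,
    observed_mutant_window: str,
    ref_window: str,
    window_c_start: int = 1,
) -> ReconcileVerdict:
    """Compare a variant caller's edit against an observed (Sanger) haplotype.

    Concordant iff applying the caller's edit to the reference window
    reproduces the observed mutant window; otherwise the minimal normalized
    delins explaining the observation is returned as the correction, together
    with the equivalent representations (including two-event decompositions)
    that the observation cannot distinguish.
    """
    local = shift_edit(caller_edit, -(window_c_start - 1))
    try:
        produced = apply_edit(ref_window, local)
    except ReferenceMismatchError:
        produced = None
    if produced == observed_mutant_window:
        return ReconcileVerdict(True)
    corrected = minimal_delins(ref_window, observed_mutant_window, window_c_start)
    alts = tuple(
        equivalent_representations(ref_window, observed_mutant_window, window_c_start)
    )
    return ReconcileVerdict(False, corrected=corrected, alternatives=alts)
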