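"""Glocal read-to-reference alignment and error-event extraction.

Reads from a 454 amplicon run are compared against their known (Sanger)
reference with the scoring used in the original analysis: match +2,
mismatch -1, linear gaps -1 per base.  The aligner finds the maximal-scoring
*contiguous* alignment with free end-gaps on both sequences (the
deterministic analog of a BLAST local HSP): unaligned read overhangs are
free, and uncovered reference ends mean the read is truncated — exactly
what the full-length filter then rejects.  A consequence shared with any
reference-based caller is that events touching the reference boundary are
soft-clipped rather than called, so simulated errors are planted at
interior canonical positions only.

The aligner emits a canonical list of :class:`ErrorEvent` objects.  One
coordinate convention binds the whole package: insertions occur *before* a
0-based reference position; deletions and substitutions occupy a half-open
reference interval.  Indels are left-normalized, so an indel inside a
homopolymer run is always reported at the run's leftmost coordinate — the
canonical position that makes simulator truth logs, alignments and
recurrence signatures directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .reference import ReferenceSequence, run_length_at

VALID_READ_CHARS = set("ACGTN")


@dataclass(frozen=True)
class ScoringScheme:
    """Pairwise alignment scores (positive match, negative mismatch/gap)."""

    match_reward: int = 2
    mismatch_penalty: int = -1
    gap_penalty_per_base: int = -1

    def __post_init__(self) -> None:
        if not (self.match_reward > 0 > self.mismatch_penalty
                and self.gap_penalty_per_base < 0):
            raise ValueError("require match > 0 > mismatch, gap")


@dataclass
class ErrorEvent:
    """One insertion, deletion or substitution relative to the reference.

    ``ref_pos`` is the before-position for insertions and the interval start
    for deletions/substitutions; ``read_pos`` is the corresponding 0-based
    read coordinate (start of the inserted/substituted read bases; for a
    deletion, the read coordinate at which the gap sits).
    """

    type: str  # insertion | deletion | substitution
    ref_pos: int
    length: int
    read_bases: str = ""
    ref_bases: str = ""
    read_pos: int = 0
    hp_base: str | None = None
    hp_len: int = 1
    region: str | None = None

    @property
    def is_homopolymeric(self) -> bool:
        return self.hp_len >= 2

    @property
    def ref_end(self) -> int:
        """End of the reference interval (== ref_pos for insertions)."""
        return self.ref_pos + (0 if self.type == "insertion" else self.length)


@dataclass
class AlignmentResult:
    read_id: str
    ref_id: str
    score: int
    aligned_ref_span: tuple[int, int]
    aligned_read_span: tuple[int, int]
    events: list[ErrorEvent]
    identity_pct: float
    read_seq: str = ""


def _dp_matrix(read: str, ref: str, sc: ScoringScheme) -> np.ndarray:
    """Score matrix H[i, j]: best score of a contiguous alignment ending at
    ref[:i] / read[:j] whose start is free on both sequences (local
    recurrence: negative-scoring prefixes are dropped).  Linear gaps permit
    the row-wise prefix-max recurrence used here."""
    m, L = len(read), len(ref)
    g = sc.gap_penalty_per_base
    ra = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
    sub_rows = {
        b: np.where(ra == ord(b), sc.match_reward, sc.mismatch_penalty).astype(np.int32)
        for b in set(ref)
    }
    H = np.empty((L + 1, m + 1), dtype=np.int32)
    H[0, :] = 0
    idx = np.arange(m + 1, dtype=np.int32)
    g_idx = g * idx
    cand = np.empty(m + 1, dtype=np.int32)
    for i in range(1, L + 1):
        prev = H[i - 1]
        cand[0] = 0
        np.maximum(prev[:-1] + sub_rows[ref[i - 1]], prev[1:] + g, out=cand[1:])
        # H[i, j] = max(0, max_{k<=j} cand[k] + g*(j-k))
        np.maximum(np.maximum.accumulate(cand - g_idx) + g_idx, 0, out=H[i])
    return H


def _traceback(H: np.ndarray, read: str, ref: str, sc: ScoringScheme,
               i_end: int, j_end: int) -> list[tuple[str, int, int]]:
    """Columns of the optimal alignment ending at (i_end, j_end), as
    (op, i, j) with op in {M, X, D, I}; i/j are 0-based ref/read indices of
    the column's ref/read character (or the position for gaps).  Stops at a
    zero cell or either border (the free alignment start).  Tie-break:
    diagonal > deletion > insertion (gaps drift left)."""
    g = sc.gap_penalty_per_base
    i, j = i_end, j_end
    cols: list[tuple[str, int, int]] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        s = sc.match_reward if read[j - 1] == ref[i - 1] else sc.mismatch_penalty
        if h == H[i - 1, j - 1] + s:
            cols.append(("M" if s == sc.match_reward else "X", i - 1, j - 1))
            i -= 1
            j -= 1
        elif h == H[i - 1, j] + g:
            cols.append(("D", i - 1, j))
            i -= 1
        else:
            assert h == H[i, j - 1] + g, "traceback invariant broken"
            cols.append(("I", i, j - 1))
            j -= 1
    cols.reverse()
    return cols


def _events_from_columns(cols: list[tuple[str, int, int]], read: str,
                         ref: str) -> list[ErrorEvent]:
    """Collapse runs of identical non-match ops into multi-base events."""
    events: list[ErrorEvent] = []
    k, n = 0, len(cols)
    while k < n:
        op, i, j = cols[k]
        if op == "M":
            k += 1
            continue
        k2 = k
        while k2 + 1 < n and cols[k2 + 1][0] == op:
            k2 += 1
        i_end, j_end = cols[k2][1], cols[k2][2]
        if op == "X":
            events.append(ErrorEvent(
                "substitution", ref_pos=i, length=k2 - k + 1,
                read_bases=read[j:j_end + 1], ref_bases=ref[i:i_end + 1],
                read_pos=j))
        elif op == "I":
            events.append(ErrorEvent(
                "insertion", ref_pos=i, length=k2 - k + 1,
                read_bases=read[j:j_end + 1], read_pos=j))
        else:  # D
            events.append(ErrorEvent(
                "deletion", ref_pos=i, length=k2 - k + 1,
                ref_bases=ref[i:i_end + 1], read_pos=j))
        k = k2 + 1
    return events


def homopolymer_context(ref: ReferenceSequence | str,
                        event: ErrorEvent) -> tuple[str | None, int]:
    """Homopolymer base and run length at an event's reference site.

    For an insertion of a single repeated base B the relevant run is the
    maximal B-run adjacent to the insertion point (length 1 if no B is
    adjacent: a run-creating, not run-extending, insertion).  For deletions
    and substitutions it is the maximal run containing the first affected
    reference base.  An event is called homopolymeric when the run length
    is >= 2.
    """
    seq = ref.seq if isinstance(ref, ReferenceSequence) else ref
    L = len(seq)
    p = event.ref_pos
    if event.type == "insertion":
        if not 0 <= p <= L:
            raise ValueError(f"insertion position {p} out of range")
        bases = set(event.read_bases)
        if len(bases) == 1:
            b = event.read_bases[0]
            if p < L and seq[p] == b:
                return run_length_at(seq, p)
            if p > 0 and seq[p - 1] == b:
                return run_length_at(seq, p - 1)
            return b, 1
        return None, 1
    if not 0 <= p < L:
        raise ValueError(f"event position {p} out of range")
    b, n = run_length_at(seq, p)
    if event.type == "deletion" and set(event.ref_bases) != {b}:
        return b, 1  # multi-base deletion spanning run boundaries
    return b, n


def left_normalize_indels(events: list[ErrorEvent],
                          ref: ReferenceSequence | str) -> list[ErrorEvent]:
    """Shift every indel to its leftmost alignment-equivalent position.

    An insertion before ``p`` may move to ``p-1`` whenever the reference
    base at ``p-1`` equals the last inserted base (rotating the inserted
    string); a deletion ``[s, e)`` may move left whenever ``ref[s-1] ==
    ref[e-1]``.  Insertions that land on the same canonical position and
    deletions that become adjacent are merged, so e.g. two single-G
    insertions planted in one polyG run report as a single "4G in place of
    2"-style event.  Idempotent; substitutions are untouched.
    """
    seq = ref.seq if isinstance(ref, ReferenceSequence) else ref
    out: list[ErrorEvent] = []
    for ev in events:
        if ev.type == "insertion":
            p, bases, rp = ev.ref_pos, ev.read_bases, ev.read_pos
            while p > 0 and seq[p - 1] == bases[-1]:
                bases = seq[p - 1] + bases[:-1]
                p -= 1
                rp -= 1
            out.append(replace(ev, ref_pos=p, read_bases=bases, read_pos=rp))
        elif ev.type == "deletion":
            s, e, rp = ev.ref_pos, ev.ref_pos + ev.length, ev.read_pos
            while s > 0 and seq[s - 1] == seq[e - 1]:
                s -= 1
                e -= 1
                rp -= 1
            out.append(replace(ev, ref_pos=s, ref_bases=seq[s:e], read_pos=rp))
        else:
            out.append(replace(ev))
    out.sort(key=lambda e: (e.ref_pos, e.read_pos))

    merged: list[ErrorEvent] = []
    for ev in out:
        if merged and ev.type == merged[-1].type != "substitution":
            last = merged[-1]
            if ev.type == "insertion" and ev.ref_pos == last.ref_pos:
                merged[-1] = replace(
                    last, length=last.length + ev.length,
                    read_bases=last.read_bases + ev.read_bases)
                continue
            if ev.type == "deletion" and ev.ref_pos == last.ref_pos + last.length:
                merged[-1] = replace(
                    last, length=last.length + ev.length,
                    ref_bases=last.ref_bases + ev.ref_bases)
                continue
        merged.append(ev)

    for k, ev in enumerate(merged):
        hp_base, hp_len = homopolymer_context(seq, ev)
        merged[k] = replace(ev, hp_base=hp_base, hp_len=hp_len)
    return merged


def align_read(read: str, ref: ReferenceSequence,
               scoring: ScoringScheme | None = None,
               read_id: str = "read") -> AlignmentResult:
    """Maximal-scoring contiguous alignment of ``read`` against ``ref``.

    End-gaps are free on both sequences: unaligned read overhangs cost
    nothing, and reference positions left uncovered mean the read is
    truncated (``aligned_ref_span`` is then partial, failing the
    full-length filter).  Traceback is deterministic (diagonal > deletion >
    insertion, ties broken towards the largest aligned spans) and always
    starts and ends on a match column.  Indels are left-normalized and
    annotated with homopolymer context.

    Reads equal to the reference short-circuit to the identity alignment.
    """
    sc = scoring or ScoringScheme()
    if not read or not ref.seq:
        raise ValueError("empty sequence")
    read = read.upper()
    bad = set(read) - VALID_READ_CHARS
    if bad:
        raise ValueError(f"non-IUPAC characters in read: {sorted(bad)}")

    L = ref.length
    if read == ref.seq:  # fast path: the common accurate read
        return AlignmentResult(
            read_id=read_id, ref_id=ref.id, score=sc.match_reward * L,
            aligned_ref_span=(0, L), aligned_read_span=(0, L),
            events=[], identity_pct=100.0, read_seq=read)

    H = _dp_matrix(read, ref.seq, sc)
    best = int(H.max())
    # rightmost optimum: ties broken towards the largest (i, j)
    flat = int(np.argmax(H[::-1, ::-1].ravel()))
    i_end = L - flat // (len(read) + 1)
    j_end = len(read) - flat % (len(read) + 1)
    cols = _traceback(H, read, ref.seq, sc, i_end, j_end)
    if not cols or best <= 0:
        return AlignmentResult(
            read_id=read_id, ref_id=ref.id, score=max(best, 0),
            aligned_ref_span=(0, 0), aligned_read_span=(0, 0),
            events=[], identity_pct=0.0, read_seq=read)

    # optimal local alignments start and end on match columns
    ref_lo, ref_hi = cols[0][1], cols[-1][1] + 1
    read_lo, read_hi = cols[0][2], cols[-1][2] + 1

    events = left_normalize_indels(_events_from_columns(cols, read, ref.seq),
                                   ref)
    for k, ev in enumerate(events):
        events[k].region = ref.region_of(
            ev.ref_pos if ev.ref_pos < L else L - 1)
    matches = sum(1 for c in cols if c[0] == "M")
    return AlignmentResult(
        read_id=read_id, ref_id=ref.id, score=best,
        aligned_ref_span=(ref_lo, ref_hi),
        aligned_read_span=(read_lo, read_hi),
        events=events,
        identity_pct=100.0 * matches / len(cols),
        read_seq=read)


def filter_full_length(alignment: AlignmentResult,
                       ref: ReferenceSequence) -> bool:
    """True iff the alignment covers the entire variable domain.

    Mirrors the study's read filter: only reads spanning the whole FV
    region (all frameworks and CDRs) are analysed.
    """
    return alignment.aligned_ref_span == (0, ref.length)


def apply_events(ref_seq: str, events: list[ErrorEvent]) -> str:
    """Reconstruct a read by replaying error events over the reference.

    The inverse of event extraction: for every alignment or truth log,
    ``apply_events(ref, events) == read`` (over the aligned span).
    """
    ordered = sorted(events, key=lambda e: (e.ref_pos,
                                            0 if e.type == "insertion" else 1))
    out: list[str] = []
    i = 0
    for ev in ordered:
        if ev.ref_pos < i:
            raise ValueError("overlapping events")
        out.append(ref_seq[i:ev.ref_pos])
        i = ev.ref_pos
        if ev.type == "insertion":
            out.append(ev.read_bases)
        elif ev.type == "deletion":
            i += ev.length
        else:
            out.append(ev.read_bases)
            i += ev.length
    out.append(ref_seq[i:])
    return "".join(out)
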