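"""Frameshift-restoring correction and functionality calling.

Pyrosequencing indels usually shift the antibody reading frame, turning a
productive rearrangement into an unproductive one.  Because indels (unlike
substitutions) are visible against a reference, they can be repaired by a
two-pass procedure: align the read and extract indel events, excise every
detected insertion from the read, pad every detected deletion with a pad
symbol (lowercase ``n``) so the reference numbering is restored, then
re-align the edited read and call functionality again.  Substitutions are
never touched — replacement errors that stay in frame and stop-free are
fundamentally undetectable in a single run, and form the residual error
mass that correction cannot remove.

Functionality verdicts follow the standard repertoire convention:
``productive`` = in frame with no stop codon; ``stop_codon`` = any internal
stop; ``unproductive`` = frameshifted but stop-free; ``no_alignment`` =
the read does not align credibly to the reference at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import (AlignmentResult, ErrorEvent, ScoringScheme, align_read,
                    filter_full_length)
from .error_profile import has_premature_stop, net_indel
from .reference import ReferenceSequence, translate_codon

PAD = "n"

#: alignment identity (%) below which a read is called "no rearrangement"
DEFAULT_NO_ALIGNMENT_IDENTITY = 60.0


@dataclass
class FunctionalityCall:
    in_frame: bool
    stop_codons: list[int]
    conserved_ok: bool
    verdict: str  # productive | unproductive | stop_codon | no_alignment


@dataclass
class CorrectionResult:
    read_id: str
    corrected_seq: str
    applied_edits: list[ErrorEvent] = field(default_factory=list)
    functionality_before: str = "no_alignment"
    functionality_after: str = "no_alignment"
    recovered: bool = False
    uncorrectable_reason: str | None = None


def global_identity(alignment, ref: ReferenceSequence) -> float:
    """Alignment identity weighted by reference coverage (percent).

    A short accidental local hit has high column identity but negligible
    coverage; weighting by the covered reference fraction makes the
    no-rearrangement threshold behave like a whole-domain identity.
    """
    lo, hi = alignment.aligned_ref_span
    return alignment.identity_pct * (hi - lo) / ref.length


def _stop_codon_indices(seq: str, frame_offset: int) -> list[int]:
    s = seq[frame_offset:]
    return [i // 3 for i in range(0, len(s) - 2, 3)
            if translate_codon(s[i:i + 3]) == "*"]


def _conserved_ok(seq: str, ref: ReferenceSequence) -> bool:
    """Conserved Cys/Trp codons still translate as expected.

    Only meaningful when ``seq`` is in reference numbering (same length);
    a pad symbol inside a conserved codon breaks it.
    """
    if len(seq) != ref.length:
        return False
    for codon_idx, aa in ref.conserved_positions:
        start = ref.frame_offset + 3 * codon_idx
        if translate_codon(seq[start:start + 3]) != aa:
            return False
    return True


def assess_functionality(
    seq: str,
    ref: ReferenceSequence,
    scoring: ScoringScheme | None = None,
    alignment: AlignmentResult | None = None,
    min_identity: float = DEFAULT_NO_ALIGNMENT_IDENTITY,
) -> FunctionalityCall:
    """Call productive / unproductive / stop_codon / no_alignment for a read.

    The frame is taken from the reference and adjusted by the net indel
    length of the read's alignment; stop codons are scanned over the read's
    own translation (pad codons are never stops).  An alignment may be
    passed in to avoid recomputing it.
    """
    if alignment is None:
        alignment = align_read(seq, ref, scoring)
    if global_identity(alignment, ref) < min_identity:
        return FunctionalityCall(False, [], False, "no_alignment")
    in_frame = net_indel(alignment.events) % 3 == 0
    stops = _stop_codon_indices(seq, ref.frame_offset)
    conserved = in_frame and _conserved_ok(seq, ref)
    if stops:
        verdict = "stop_codon"
    elif in_frame:
        verdict = "productive"
    else:
        verdict = "unproductive"
    return FunctionalityCall(in_frame, stops, conserved, verdict)


def _apply_correction(read: str, events: list[ErrorEvent]) -> tuple[str, list[ErrorEvent]]:
    """Excise insertions and pad deletions, in read coordinates."""
    edits = [ev for ev in events if ev.type != "substitution"]
    edits.sort(key=lambda e: e.read_pos)
    out: list[str] = []
    i = 0
    for ev in edits:
        out.append(read[i:ev.read_pos])
        i = ev.read_pos
        if ev.type == "insertion":
            i += ev.length  # drop the inserted bases
        else:
            out.append(PAD * ev.length)  # restore reference numbering
    out.append(read[i:])
    return "".join(out), edits


def correct_read(
    read: str,
    ref: ReferenceSequence,
    scoring: ScoringScheme | None = None,
    read_id: str = "read",
    min_identity: float = DEFAULT_NO_ALIGNMENT_IDENTITY,
) -> CorrectionResult:
    """Two-pass indel correction of one full-length read.

    Pass 1 aligns the read and records its indels; insertions are excised
    and deletions padded with ``n`` at the deleted coordinates, restoring
    reference length and numbering.  Pass 2 re-aligns the edited read and
    re-calls functionality.  ``recovered`` is true when a read that was not
    productive before correction is productive afterwards.  Substitution
    columns are never modified.
    """
    aln1 = align_read(read, ref, scoring, read_id=read_id)
    if global_identity(aln1, ref) < min_identity:
        return CorrectionResult(
            read_id=read_id, corrected_seq=read,
            functionality_before="no_alignment",
            functionality_after="no_alignment",
            uncorrectable_reason="no credible alignment to reference")
    if not filter_full_length(aln1, ref):
        return CorrectionResult(
            read_id=read_id, corrected_seq=read,
            functionality_before="no_alignment",
            functionality_after="no_alignment",
            uncorrectable_reason="read does not cover the full V domain")

    before = assess_functionality(read, ref, scoring, alignment=aln1,
                                  min_identity=min_identity)
    corrected, edits = _apply_correction(read, aln1.events)
    if edits:
        aln2 = align_read(corrected, ref, scoring, read_id=read_id)
        after = assess_functionality(corrected, ref, scoring, alignment=aln2,
                                     min_identity=min_identity)
    else:
        corrected, after = read, before
    return CorrectionResult(
        read_id=read_id, corrected_seq=corrected, applied_edits=edits,
        functionality_before=before.verdict,
        functionality_after=after.verdict,
        recovered=(after.verdict == "productive"
                   and before.verdict != "productive"))


def recovery_rate(results: list[CorrectionResult]) -> float:
    """Fraction of all reads recovered to productive by indel correction."""
    if not results:
        raise ValueError("recovery_rate of an empty result collection")
    return sum(r.recovered for r in results) / len(results)


def recovery_rate_of_erroneous(results: list[CorrectionResult]) -> float:
    """Recovered fraction among reads that needed correction (the alternative
    reading of a recovery percentage's denominator)."""
    err = [r for r in results if r.applied_edits
           or r.functionality_before != "productive"]
    if not err:
        return 0.0
    return sum(r.recovered for r in err) / len(err)


def functionality_summary(results: list[CorrectionResult]) -> dict[str, float]:
    """Percentages of the four functionality verdicts before correction,
    with the recovered share reported alongside (the parenthetical
    convention of run-level functionality tables)."""
    n = len(results)
    if n == 0:
        raise ValueError("empty result collection")
    counts: dict[str, int] = {"productive": 0, "unproductive": 0,
                              "stop_codon": 0, "no_alignment": 0}
    for r in results:
        counts[r.functionality_before] += 1
    out = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    out["recovered"] = round(100.0 * sum(r.recovered for r in results) / n, 1)
    return out
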