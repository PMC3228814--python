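"""End-to-end replica pipeline: simulate -> align -> profile -> correct.

One call reproduces the whole study design on synthetic data: generate (or
load) a reference, simulate a 454-style read set with the observed error
mixture, align and classify every full-length read, build the error-profile
tables, run indel correction, and write every stage's output plus a single
machine-readable JSON summary.  Fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import ScoringScheme, align_read, filter_full_length
from .correct import (DEFAULT_NO_ALIGNMENT_IDENTITY, correct_read,
                      functionality_summary, recovery_rate,
                      recovery_rate_of_erroneous)
from .error_profile import (classify_read, composition_delta,
                            summarize_profile)
from .io import read_fasta, write_fasta, write_tsv
from .reference import ReferenceSequence, generate_reference
from .simulate import GroundTruthLog, SimulationConfig, simulate_reads

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one replica run."""

    reference_path: str | None = None  # FASTA; generated if None
    layout: dict[str, int] | None = None
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    min_frac: float = 0.005  # recurrence threshold over erroneous reads
    min_identity: float = DEFAULT_NO_ALIGNMENT_IDENTITY
    out_dir: str = "pyroprof_out"
    seed: int = 0

    def __post_init__(self) -> None:
        self.sim.seed = self.seed


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full replica pipeline and return the JSON-style summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.reference_path:
        rid, seq = read_fasta(cfg.reference_path)[0]
        ref = ReferenceSequence(id=rid, seq=seq)
        logger.info("loaded reference %s (%d nt)", rid, len(seq))
    else:
        ref = generate_reference(layout=cfg.layout, seed=cfg.seed)
        logger.info("generated reference %s (%d nt)", ref.id, ref.length)
    write_fasta([(ref.id, ref.seq)], out / "reference.fasta")

    reads, truth = simulate_reads(ref, cfg.sim)
    write_fasta(reads, out / "reads.fasta")
    write_tsv(truth.to_frame(), out / "truth.tsv")
    logger.info("simulated %d reads", len(reads))

    alignments, classifications, deltas = [], [], {}
    n_filtered = 0
    for rid, seq in reads:
        aln = align_read(seq, ref, cfg.scoring, read_id=rid)
        if not filter_full_length(aln, ref):
            n_filtered += 1
            continue
        alignments.append(aln)
        classifications.append(classify_read(aln, ref))
        deltas[rid] = composition_delta(seq, ref)
    logger.info("aligned %d reads, %d failed the full-length filter",
                len(alignments), n_filtered)

    event_rows = [
        (a.read_id, ev.type, ev.ref_pos, ev.ref_end,
         ev.read_bases if ev.type != "deletion" else ev.ref_bases,
         ev.hp_base or "", ev.hp_len, ev.region or "")
        for a in alignments for ev in a.events]
    write_tsv(pd.DataFrame(event_rows, columns=[
        "read_id", "event_type", "ref_pos", "ref_interval_end", "bases",
        "hp_base", "hp_len", "region"]), out / "events.tsv")

    profile = summarize_profile(classifications, ref, deltas,
                                min_frac=cfg.min_frac)
    write_tsv(profile.homopolymer_table, out / "homopolymer_table.tsv")
    if profile.signature_table is not None:
        write_tsv(profile.signature_table, out / "signatures.tsv")

    read_seqs = dict(reads)
    corrections = [
        correct_read(read_seqs[a.read_id], ref, cfg.scoring,
                     read_id=a.read_id, min_identity=cfg.min_identity)
        for a in alignments]
    write_fasta([(c.read_id, c.corrected_seq) for c in corrections],
                out / "corrected.fasta")
    write_tsv(pd.DataFrame(
        [(c.read_id, len(c.applied_edits), c.functionality_before,
          c.functionality_after, c.recovered, c.uncorrectable_reason or "")
         for c in corrections],
        columns=["read_id", "n_edits", "functionality_before",
                 "functionality_after", "recovered", "uncorrectable_reason"]),
        out / "corrections.tsv")
    logger.info("corrected %d reads", len(corrections))

    func = functionality_summary(corrections)
    write_tsv(pd.DataFrame(
        [(k, v) for k, v in func.items()], columns=["functionality", "pct"]),
        out / "functionality_summary.tsv")

    summary = {
        "seed": cfg.seed,
        "n_reads": len(reads),
        "n_full_length": len(alignments),
        "category_pct": profile.category_pct,
        "region_insertions": profile.region_insertions,
        "inserted_base_composition": {
            b: round(f, 4) for b, f in profile.inserted_base_composition.items()},
        "functionality_pct": func,
        "recovery_rate_of_total": round(recovery_rate(corrections), 4),
        "recovery_rate_of_erroneous": round(
            recovery_rate_of_erroneous(corrections), 4),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
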