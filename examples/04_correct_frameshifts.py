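"""Repair frameshift-causing indels and re-call functionality.

Simulates reads whose only errors are indels, corrects each by excising
detected insertions and padding detected deletions ('n'), and shows the
functionality verdicts before and after, plus the recovery rate.
"""

from collections import Counter

from pyroprof import (SimulationConfig, correct_read, generate_reference,
                      recovery_rate, simulate_reads)

ref = generate_reference(seed=1)
cfg = SimulationConfig(
    p_accurate=0.5, p_single_ins=0.25, p_multi_ins=0.1, p_single_del=0.15,
    p_single_sub=0.0, p_mixed=0.0, n_reads=500, seed=5)
reads, _ = simulate_reads(ref, cfg)

results = [correct_read(seq, ref, read_id=rid) for rid, seq in reads]

before = Counter(r.functionality_before for r in results)
after = Counter(r.functionality_after for r in results)
print("functionality before correction:", dict(before))
print("functionality after correction: ", dict(after))
print(f"recovery rate (of all reads): {recovery_rate(results):.3f}")

example = next(r for r in results if r.recovered)
print(f"\n{example.read_id}: {len(example.applied_edits)} edit(s) applied, "
      f"{example.functionality_before} -> {example.functionality_after}")
print("every indel-only read is productive after correction; the recovered "
      "fraction equals the erroneous share, since indels are fully "
      "repairable against a known reference.")
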