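"""454-style read simulation with ground-truth error logs.

Pyrosequencing infers homopolymer run lengths from light intensities and
systematically miscounts short runs, so its error spectrum is dominated by
single-base insertions (G above all), concentrated at runs of 2-4 nt, with
deletions, substitutions and mixed multi-nucleotide variants making up the
rest.  The simulator reproduces that spectrum as a per-read category
mixture over a known reference and logs every planted event, so classifier
and corrector can be validated by parameter recovery.

Default mixture (fractions of all reads): 60% accurate, 12% single
insertion, 8% multi-insertion (insertions combined 20%), 5% single
deletion, 5% single substitution, 10% mixed; 55% of inserted bases are G.

All events are planted at interior canonical positions: an indel whose
left-normalized position touches the reference boundary is alignment-
equivalent to a read overhang or truncation and is invisible to any
reference-based caller, so such placements are resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .align import ErrorEvent, apply_events, homopolymer_context
from .reference import ReferenceSequence, homopolymer_runs

CATEGORIES = ("accurate", "single_insertion", "multi_insertion",
              "single_deletion", "single_substitution", "mixed")

#: minimum canonical separation (nt) between events planted on one read,
#: keeping multi-event reads unambiguous for the aligner
MIN_EVENT_SPACING = 10


@dataclass
class SimulationConfig:
    """Error-category mixture and placement biases for read simulation."""

    p_accurate: float = 0.60
    p_single_ins: float = 0.12
    p_multi_ins: float = 0.08
    p_single_del: float = 0.05
    p_single_sub: float = 0.05
    p_mixed: float = 0.10
    #: probability that an indel is placed inside a homopolymer run (>=2 nt)
    homopolymer_bias: float = 0.8
    insertion_base_probs: dict[str, float] = field(
        default_factory=lambda: {"G": 0.55, "A": 0.20, "C": 0.20, "T": 0.05})
    #: optional (reference position, base, weight) triples up-weighting the
    #: homopolymer runs containing those positions (polyG hotspot mimicry)
    hotspots: list[tuple[int, str, float]] | None = None
    n_reads: int = 5000
    seed: int = 0

    @property
    def category_probs(self) -> dict[str, float]:
        return {
            "accurate": self.p_accurate,
            "single_insertion": self.p_single_ins,
            "multi_insertion": self.p_multi_ins,
            "single_deletion": self.p_single_del,
            "single_substitution": self.p_single_sub,
            "mixed": self.p_mixed,
        }

    def validate(self) -> None:
        probs = self.category_probs
        if any(p < 0 for p in probs.values()):
            raise ValueError("negative category probability")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError(f"category probabilities sum to {sum(probs.values())}")
        if abs(sum(self.insertion_base_probs.values()) - 1.0) > 1e-9:
            raise ValueError("insertion_base_probs must sum to 1")
        if set(self.insertion_base_probs) - set("ACGT"):
            raise ValueError("insertion_base_probs keys must be A/C/G/T")
        if not 0.0 <= self.homopolymer_bias <= 1.0:
            raise ValueError("homopolymer_bias must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass
class GroundTruthLog:
    """Per-read planted events and category labels."""

    categories: dict[str, str] = field(default_factory=dict)
    events: dict[str, list[ErrorEvent]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid, cat in self.categories.items():
            evs = self.events[rid]
            if not evs:
                rows.append((rid, cat, "", "", "", "", "", ""))
            for ev in evs:
                rows.append((
                    rid, cat, ev.type, ev.ref_pos, ev.ref_end,
                    ev.read_bases if ev.type != "deletion" else ev.ref_bases,
                    ev.hp_base or "", ev.hp_len))
        return pd.DataFrame(rows, columns=[
            "read_id", "category", "event_type", "ref_pos",
            "ref_interval_end", "bases", "hp_base", "hp_len"])


class _Placer:
    """Samples event placements on one reference, honouring the boundary
    and homopolymer constraints."""

    def __init__(self, ref: ReferenceSequence, cfg: SimulationConfig,
                 rng: np.random.Generator):
        self.seq = ref.seq
        self.L = ref.length
        self.cfg = cfg
        self.rng = rng
        runs = [r for r in homopolymer_runs(ref.seq) if r[1] - r[0] >= 2]
        # insertion-eligible runs must not touch either boundary: extending a
        # terminal run is alignment-equivalent to a read overhang
        eligible = [r for r in runs if r[0] >= 1 and r[1] <= self.L - 1]
        self.del_runs = eligible
        self.del_weights = self._weights(eligible)
        # run-extending insertions draw their base from insertion_base_probs
        # too, so the inserted-base composition is governed by the config
        # (G-heavy by default) in both placement branches
        self.ins_runs_by_base = {
            b: [r for r in eligible if r[2] == b] for b in "ACGT"}
        self.ins_weights_by_base = {
            b: self._weights(rs) for b, rs in self.ins_runs_by_base.items()}
        self.bases = list(cfg.insertion_base_probs)
        self.base_p = np.array([cfg.insertion_base_probs[b] for b in self.bases])
        run_bases = [b for b in self.bases if self.ins_runs_by_base[b]]
        p = np.array([cfg.insertion_base_probs[b] for b in run_bases])
        self.run_bases = run_bases
        self.run_base_p = p / p.sum() if run_bases else None

    def _weights(self, runs: list[tuple[int, int, str]]) -> np.ndarray | None:
        if not runs:
            return None
        w = np.ones(len(runs))
        for pos, base, weight in self.cfg.hotspots or []:
            for k, (s, e, b) in enumerate(runs):
                if s <= pos < e and b == base:
                    w[k] += weight
        return w / w.sum()

    def _pick_run(self, runs, weights) -> tuple[int, int, str]:
        k = int(self.rng.choice(len(runs), p=weights))
        return runs[k]

    def _canonical_ins(self, pos: int, base: str) -> tuple[int, int]:
        """Leftmost and rightmost alignment-equivalent insertion positions."""
        lo = pos
        while lo > 0 and self.seq[lo - 1] == base:
            lo -= 1
        hi = pos
        while hi < self.L and self.seq[hi] == base:
            hi += 1
        return lo, hi

    def insertion(self) -> ErrorEvent:
        if (self.rng.random() < self.cfg.homopolymer_bias
                and self.run_bases):
            b = self.run_bases[int(self.rng.choice(len(self.run_bases),
                                                   p=self.run_base_p))]
            s, _e, _b = self._pick_run(self.ins_runs_by_base[b],
                                       self.ins_weights_by_base[b])
            return ErrorEvent("insertion", ref_pos=s, length=1, read_bases=b)
        for _ in range(1000):
            pos = int(self.rng.integers(1, self.L))
            base = str(self.rng.choice(self.bases, p=self.base_p))
            lo, hi = self._canonical_ins(pos, base)
            if lo >= 1 and hi <= self.L - 1:
                return ErrorEvent("insertion", ref_pos=lo, length=1,
                                  read_bases=base)
        raise RuntimeError("no valid insertion site found")

    def deletion(self) -> ErrorEvent:
        if self.rng.random() < self.cfg.homopolymer_bias and self.del_runs:
            s, _e, b = self._pick_run(self.del_runs, self.del_weights)
            return ErrorEvent("deletion", ref_pos=s, length=1, ref_bases=b)
        for _ in range(1000):
            pos = int(self.rng.integers(1, self.L - 1))
            s, e = pos, pos + 1
            while s > 0 and self.seq[s - 1] == self.seq[e - 1]:
                s -= 1
                e -= 1
            if s >= 1:
                return ErrorEvent("deletion", ref_pos=s, length=1,
                                  ref_bases=self.seq[s])
        raise RuntimeError("no valid deletion site found")

    def substitution(self) -> ErrorEvent:
        pos = int(self.rng.integers(1, self.L - 1))
        old = self.seq[pos]
        new = str(self.rng.choice([b for b in "ACGT" if b != old]))
        return ErrorEvent("substitution", ref_pos=pos, length=1,
                          read_bases=new, ref_bases=old)


def _spaced(events: list[ErrorEvent], candidate: ErrorEvent) -> bool:
    return all(abs(candidate.ref_pos - e.ref_pos) >= MIN_EVENT_SPACING
               for e in events)


def _merge_coincident(events: list[ErrorEvent]) -> list[ErrorEvent]:
    """Insertions sampled onto the same canonical position merge into one
    longer event (the '4G in place of 2' pattern)."""
    events = sorted(events, key=lambda e: (e.ref_pos,
                                           0 if e.type == "insertion" else 1))
    out: list[ErrorEvent] = []
    for ev in events:
        if (out and ev.type == out[-1].type == "insertion"
                and ev.ref_pos == out[-1].ref_pos):
            out[-1] = replace(out[-1], length=out[-1].length + ev.length,
                              read_bases=out[-1].read_bases + ev.read_bases)
        else:
            out.append(ev)
    return out


def _plant(placer: _Placer, rng: np.random.Generator,
           category: str) -> list[ErrorEvent]:
    if category == "accurate":
        return []
    if category == "single_insertion":
        return [placer.insertion()]
    if category == "single_deletion":
        return [placer.deletion()]
    if category == "single_substitution":
        return [placer.substitution()]
    if category == "multi_insertion":
        n = int(rng.integers(2, 4))  # 2-3 insertions
        events: list[ErrorEvent] = []
        for _ in range(200):
            if len(events) == n:
                break
            ev = placer.insertion()
            if _spaced(events, ev) or any(
                    e.type == "insertion" and e.ref_pos == ev.ref_pos
                    and e.read_bases[0] == ev.read_bases[0] for e in events):
                events.append(ev)
        return _merge_coincident(events)
    # mixed: 2-4 single-nt events spanning >= 2 distinct types
    n = int(rng.integers(2, 5))
    makers = {"insertion": placer.insertion, "deletion": placer.deletion,
              "substitution": placer.substitution}
    while True:
        types = [str(t) for t in rng.choice(list(makers), size=n)]
        if len(set(types)) >= 2:
            break
    events = []
    for t in types:
        for _ in range(200):
            ev = makers[t]()
            if _spaced(events, ev):
                events.append(ev)
                break
    return _merge_coincident(events)


def simulate_reads(
    ref: ReferenceSequence,
    cfg: SimulationConfig,
) -> tuple[list[tuple[str, str]], GroundTruthLog]:
    """Simulate ``cfg.n_reads`` 454-style reads from ``ref``.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` pairs and ``truth`` records each read's planted
    category and left-normalized events (the same canonical coordinates the
    aligner reports).  Deterministic for a fixed ``cfg.seed``.
    """
    cfg.validate()
    ref.validate()
    rng = np.random.default_rng(cfg.seed)
    placer = _Placer(ref, cfg, rng)
    cats = list(CATEGORIES)
    probs = np.array([cfg.category_probs[c] for c in cats])

    reads: list[tuple[str, str]] = []
    truth = GroundTruthLog()
    width = max(5, len(str(max(cfg.n_reads, 1))))
    for k in range(cfg.n_reads):
        category = cats[int(rng.choice(len(cats), p=probs))]
        events = sorted(_plant(placer, rng, category),
                        key=lambda e: (e.ref_pos,
                                       0 if e.type == "insertion" else 1))
        for i, ev in enumerate(events):
            hp_base, hp_len = homopolymer_context(ref, ev)
            events[i] = replace(ev, hp_base=hp_base, hp_len=hp_len,
                                region=ref.region_of(min(ev.ref_pos,
                                                         ref.length - 1)))
        seq = apply_events(ref.seq, events)
        # fill read coordinates of each planted event
        shift = 0
        for i, ev in enumerate(sorted(events, key=lambda e: e.ref_pos)):
            events[i] = replace(ev, read_pos=ev.ref_pos + shift)
            if ev.type == "insertion":
                shift += ev.length
            elif ev.type == "deletion":
                shift -= ev.length
        rid = f"read_{k:0{width}d}"
        reads.append((rid, seq))
        truth.categories[rid] = category
        truth.events[rid] = events
    return reads, truth


def write_truth_tsv(truth: GroundTruthLog, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
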