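"""Classifier rules, region assignment, composition deltas, summaries."""

from itertools import combinations_with_replacement

import numpy as np
import pytest

from pyroprof import (AlignmentResult, ErrorEvent, SimulationConfig,
                      align_read, apply_events, assign_region, classify_read,
                      composition_delta, filter_full_length,
                      recurrent_signatures, simulate_reads, summarize_profile)
from pyroprof.error_profile import (CATEGORY_ORDER, CompositionDelta,
                                    ReadClassification, describe_variation)


def _aln(events, ref_len=60, read_id="r1", seq="A" * 60):
    net = sum(e.length if e.type == "insertion" else
              -e.length if e.type == "deletion" else 0 for e in events)
    return AlignmentResult(
        read_id=read_id, ref_id="ref", score=0,
        aligned_ref_span=(0, ref_len), aligned_read_span=(0, ref_len + net),
        events=list(events), identity_pct=99.0, read_seq=seq)


def rule_table_oracle(events) -> str:
    """Independent statement of the category rules, written as a flat
    decision list over the event multiset."""
    if not events:
        return "accurate"
    types = sorted({e.type for e in events})
    total = sum(e.length for e in events)
    if types == ["insertion"]:
        return "single_insertion" if total == 1 else "multi_insertion"
    if len(types) > 1 or len(events) > 1 or total > 1:
        return "mixed"
    return {"deletion": "single_deletion",
            "substitution": "single_substitution"}[events[0].type]


class TestClassifyRead:
    def test_no_events_is_accurate(self):
        cls = classify_read(_aln([]))
        assert cls.category == "accurate"
        assert cls.n_events == 0 and not cls.frameshift

    def test_one_homopolymer_g_insertion(self, worked_ref_gg):
        read = worked_ref_gg.seq.replace("AGGC", "AGGGC")
        aln = align_read(read, worked_ref_gg)
        cls = classify_read(aln, worked_ref_gg)
        assert cls.category == "single_insertion"
        assert cls.frameshift  # one inserted nt shifts the frame

    def test_two_plus_one_insertion_is_multi(self):
        """A 2-nt run insertion plus one random G insertion: the tabulated
        '2 + 1 insertion' pattern, 3 nt total, still an insertion-only read."""
        events = [
            ErrorEvent("insertion", ref_pos=10, length=2, read_bases="GG",
                       read_pos=10, hp_base="G", hp_len=2),
            ErrorEvent("insertion", ref_pos=40, length=1, read_bases="G",
                       read_pos=42),
        ]
        cls = classify_read(_aln(events))
        assert cls.category == "multi_insertion"
        assert cls.total_nt_changed == 3
        assert not cls.frameshift  # net +3 keeps the frame

    def test_insertion_plus_substitution_is_mixed(self):
        events = [
            ErrorEvent("insertion", ref_pos=5, length=1, read_bases="G",
                       read_pos=5),
            ErrorEvent("substitution", ref_pos=30, length=1, read_bases="A",
                       ref_bases="C", read_pos=31),
        ]
        assert classify_read(_aln(events)).category == "mixed"

    def test_matches_rule_table_on_all_small_event_multisets(self):
        """Exhaustive check against an independently written rule table over
        every multiset of <= 3 events (3 types x lengths 1-2)."""
        kinds = [("insertion", 1), ("insertion", 2), ("deletion", 1),
                 ("deletion", 2), ("substitution", 1), ("substitution", 2)]
        for n in range(4):
            for combo in combinations_with_replacement(kinds, n):
                events = []
                pos = 5
                for t, ln in combo:
                    bases = "G" * ln
                    events.append(ErrorEvent(
                        t, ref_pos=pos, length=ln,
                        read_bases=bases if t != "deletion" else "",
                        ref_bases=bases if t != "insertion" else "",
                        read_pos=pos))
                    pos += 15
                got = classify_read(_aln(events)).category
                assert got == rule_table_oracle(events), combo

    def test_partial_alignment_rejected(self):
        from pyroprof import ReferenceSequence
        aln = _aln([])
        aln.aligned_ref_span = (0, 50)
        ref = ReferenceSequence(id="x", seq="A" * 60)
        with pytest.raises(ValueError, match="full-length"):
            classify_read(aln, ref)

    def test_exhaustive_and_exclusive_on_simulated_batch(self, ref330,
                                                         small_batch):
        reads, truth = small_batch
        for rid, seq in reads:
            aln = align_read(seq, ref330, read_id=rid)
            cls = classify_read(aln, ref330)
            assert cls.category in CATEGORY_ORDER
            assert cls.category == truth.categories[rid]


class TestAssignRegion:
    def test_cdr1_hotspot_insertion(self, ref330):
        c0, _ = ref330.regions["CDR1"]
        ev = ErrorEvent("insertion", ref_pos=c0 + 3, length=1, read_bases="G")
        assert assign_region(ev, ref330) == "CDR1"

    def test_position_zero_is_fr1(self, ref330):
        ev = ErrorEvent("substitution", ref_pos=0, length=1, read_bases="A",
                        ref_bases="C")
        assert assign_region(ev, ref330) == "FR1"

    def test_boundary_insertion_belongs_to_following_region(self, ref330):
        start, _ = ref330.regions["CDR2"]
        ev = ErrorEvent("insertion", ref_pos=start, length=1, read_bases="G")
        assert assign_region(ev, ref330) == "CDR2"

    def test_every_position_matches_interval_scan(self, ref330):
        for pos in range(ref330.length):
            ev = ErrorEvent("substitution", ref_pos=pos, length=1,
                            read_bases="A", ref_bases="C")
            oracle = next(lab for lab, (s, e) in ref330.regions.items()
                          if s <= pos < e)
            assert assign_region(ev, ref330) == oracle


class TestCompositionDelta:
    def test_single_g_insertion_vector(self, ref330):
        read = ref330.seq[:50] + "G" + ref330.seq[50:]
        d = composition_delta(read, ref330)
        assert (d.dA, d.dG, d.dT, d.dC) == (0, 1, 0, 0)

    def test_accurate_read_is_zero(self, ref330):
        d = composition_delta(ref330.seq, ref330)
        assert (d.dA, d.dG, d.dT, d.dC) == (0, 0, 0, 0)

    def test_substitution_a_to_c(self):
        ref = "AATTGG"
        read = "ACTTGG"
        d = composition_delta(read, ref)
        assert (d.dA, d.dC, d.dG, d.dT) == (-1, 1, 0, 0)

    def test_net_equals_length_difference(self, ref330, small_batch):
        reads, _ = small_batch
        for _, seq in reads:
            d = composition_delta(seq, ref330)
            assert d.net == len(seq) - ref330.length


def _cls(read_id, category, events=()):
    return ReadClassification(read_id=read_id, category=category,
                              n_events=len(events),
                              total_nt_changed=sum(e.length for e in events),
                              frameshift=False, premature_stop=False,
                              events=list(events))


class TestRecurrentSignatures:
    def test_all_accurate_is_empty(self):
        cls = [_cls(f"r{i}", "accurate") for i in range(10)]
        table = recurrent_signatures(cls, {})
        assert table.empty

    def test_repeated_signature_reported_at_its_share(self):
        """One G-insertion signature in 7 of 100 erroneous reads -> 7%."""
        ev = ErrorEvent("insertion", ref_pos=80, length=1, read_bases="G",
                        read_pos=80)
        cls, deltas = [], {}
        for i in range(7):
            cls.append(_cls(f"hot{i}", "single_insertion", [ev]))
            deltas[f"hot{i}"] = CompositionDelta(dG=1)
        for i in range(93):
            ev_i = ErrorEvent("substitution", ref_pos=i, length=1,
                              read_bases="A", ref_bases="C", read_pos=i)
            cls.append(_cls(f"bg{i}", "single_substitution", [ev_i]))
            deltas[f"bg{i}"] = CompositionDelta(dA=1, dC=-1)
        table = recurrent_signatures(cls, deltas, min_frac=0.05)
        assert len(table) == 1
        assert table.iloc[0]["count"] == 7
        assert table.iloc[0]["pct_of_erroneous"] == pytest.approx(7.0)

    def test_frequencies_match_counting_oracle(self):
        rng = np.random.default_rng(12)
        sigs = ["a", "b", "c", "d"]
        cls, deltas, expected = [], {}, {}
        for i in range(200):
            s = sigs[rng.integers(0, 4)]
            ev = ErrorEvent("insertion", ref_pos=ord(s), length=1,
                            read_bases="G", read_pos=ord(s))
            cls.append(_cls(f"r{i}", "single_insertion", [ev]))
            deltas[f"r{i}"] = CompositionDelta(dG=1)
            expected[s] = expected.get(s, 0) + 1
        table = recurrent_signatures(cls, deltas, min_frac=0.0)
        assert sorted(table["count"]) == sorted(expected.values())
        assert table["count"].sum() == 200

    def test_composition_only_grouping_option(self):
        ev1 = ErrorEvent("insertion", ref_pos=10, length=1, read_bases="G",
                         read_pos=10)
        ev2 = ErrorEvent("insertion", ref_pos=90, length=1, read_bases="G",
                         read_pos=90)
        cls = [_cls("r1", "single_insertion", [ev1]),
               _cls("r2", "single_insertion", [ev2])]
        deltas = {"r1": CompositionDelta(dG=1), "r2": CompositionDelta(dG=1)}
        by_pos = recurrent_signatures(cls, deltas, min_frac=0.0)
        by_comp = recurrent_signatures(cls, deltas, min_frac=0.0,
                                       by_position=False)
        assert len(by_pos) == 2 and len(by_comp) == 1


class TestSummarizeProfile:
    def test_sixty_forty_split(self, ref330):
        ev = ErrorEvent("insertion", ref_pos=80, length=1, read_bases="G",
                        read_pos=80)
        cls = [_cls(f"a{i}", "accurate") for i in range(6)]
        cls += [_cls(f"e{i}", "single_insertion", [ev]) for i in range(4)]
        summary = summarize_profile(cls, ref330)
        assert summary.category_pct["accurate"] == 60.0
        assert summary.category_pct["single_insertion"] == 40.0
        assert abs(sum(summary.category_pct.values()) - 100.0) <= 0.01

    def test_pure_g_insertions_give_all_g_composition(self, ref330):
        cfg = SimulationConfig(
            p_accurate=0, p_single_ins=1, p_multi_ins=0, p_single_del=0,
            p_single_sub=0, p_mixed=0, insertion_base_probs={"G": 1.0},
            homopolymer_bias=1.0, n_reads=100, seed=6)
        reads, _ = simulate_reads(ref330, cfg)
        cls = [classify_read(align_read(seq, ref330, read_id=rid), ref330)
               for rid, seq in reads]
        summary = summarize_profile(cls, ref330)
        assert summary.inserted_base_composition["G"] == 1.0

    def test_region_totals_match_labelled_insertions(self, ref330,
                                                     small_batch):
        reads, _ = small_batch
        cls = []
        for rid, seq in reads:
            aln = align_read(seq, ref330, read_id=rid)
            if filter_full_length(aln, ref330):
                cls.append(classify_read(aln, ref330))
        summary = summarize_profile(cls, ref330)
        n_ins = sum(1 for c in cls for e in c.events
                    if e.type == "insertion"
                    and assign_region(e, ref330) is not None)
        assert sum(summary.region_insertions.values()) == n_ins

    def test_homopolymer_table_describes_run_miscounts(self, worked_ref_gg):
        read = worked_ref_gg.seq.replace("AGGC", "AGGGC")
        aln = align_read(read, worked_ref_gg)
        cls = classify_read(aln, worked_ref_gg)
        hp, var = describe_variation(cls.events)
        assert hp == "yes: 3G in place of 2"
        assert var == "1 insertion"
        summary = summarize_profile([cls], worked_ref_gg)
        row = summary.homopolymer_table.iloc[0]
        assert (row["n_reads"], row["hp_description"], row["variation"]) == \
            (1, "yes: 3G in place of 2", "1 insertion")
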