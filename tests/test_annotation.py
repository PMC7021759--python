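import numpy as np
import pandas as pd
import pytest

from nblandscape.annotation import (
    DmrRecord,
    Segmentation,
    annotate_g4_rloop,
    dmr_promoter_deg_intersect,
    dominant_state,
    location_class,
    mycn_promoter_binding,
    state13_expansion,
    state_concordance,
)
from nblandscape.intervals import GenomicInterval, IntervalSet
from nblandscape.peaks import ReferencePeak

from conftest import matched_truth


def iset(*tuples):
    return IntervalSet(GenomicInterval(*t) for t in tuples)


def seg(sample, *state_tuples):
    """(seq, start, end, state) tuples -> Segmentation."""
    ivs = [GenomicInterval(s, a, b, payload={"state": st})
           for s, a, b, st in state_tuples]
    return Segmentation(sample=sample, intervals=IntervalSet(ivs))


def ref_peak(seq, start, end, present=("ATRX", "MYCN", "WT")):
    return ReferencePeak(interval=GenomicInterval(seq, start, end),
                         present_in=frozenset(present))


class TestG4Rloop:
    def peaks(self, *tuples):
        return [ref_peak(*t) for t in tuples]

    def test_empty_g4_track(self):
        peaks = self.peaks(("a", 0, 100), ("a", 200, 300))
        summary = annotate_g4_rloop(peaks, iset(), iset(("a", 0, 50)))
        assert summary["frac_g4"] == 0
        assert summary["frac_rlfs_of_g4"] == 0
        assert summary["undefined"] is True

    def test_peaks_equal_track_gives_full_overlap(self):
        peaks = self.peaks(("a", 0, 100), ("a", 200, 300))
        track = iset(("a", 0, 100), ("a", 200, 300))
        summary = annotate_g4_rloop(peaks, track, iset())
        assert summary["frac_g4"] == 1.0

    def test_rlfs_conditional_on_g4(self):
        # peak 2 overlaps RLFS but not G4, so it is not counted
        peaks = self.peaks(("a", 0, 100), ("a", 200, 300))
        summary = annotate_g4_rloop(peaks, iset(("a", 0, 10)),
                                    iset(("a", 0, 10), ("a", 250, 260)))
        assert summary["n_g4"] == 1
        assert summary["n_g4_rlfs"] == 1
        assert peaks[1].rlfs is False

    def test_count_ordering_invariant(self, clean_bundle, clean_result):
        s = clean_result.g4_summary
        assert s["n_g4_rlfs"] <= s["n_g4"] <= s["n_peaks"]

    def test_planted_fractions_recovered(self, clean_bundle, clean_result):
        truth = clean_bundle.truth
        planted_g4 = sum(p.g4 for p in truth.planted_peaks)
        planted_rlfs = sum(p.rlfs for p in truth.planted_peaks)
        assert clean_result.g4_summary["n_g4"] == planted_g4
        assert clean_result.g4_summary["n_g4_rlfs"] == planted_rlfs


class TestDominantState:
    def test_single_cover(self):
        s = seg("x", ("a", 0, 1000, 13))
        assert dominant_state(s, GenomicInterval("a", 100, 200)) == 13

    def test_majority_wins(self):
        s = seg("x", ("a", 0, 60, 2), ("a", 60, 100, 16))
        assert dominant_state(s, GenomicInterval("a", 0, 100)) == 2

    def test_tie_breaks_to_lowest_state(self):
        s = seg("x", ("a", 0, 50, 15), ("a", 50, 100, 4))
        assert dominant_state(s, GenomicInterval("a", 0, 100)) == 4

    def test_unsegmented_returns_none(self):
        s = seg("x", ("a", 0, 100, 1))
        assert dominant_state(s, GenomicInterval("b", 0, 100)) is None

    def test_invariant_to_splitting_same_state(self):
        whole = seg("x", ("a", 0, 100, 7))
        split = seg("x", ("a", 0, 40, 7), ("a", 40, 100, 7))
        iv = GenomicInterval("a", 10, 90)
        assert dominant_state(whole, iv) == dominant_state(split, iv) == 7


class TestStateConcordance:
    SAMPLES = {"ATRX_1": "ATRX", "MYCN_1": "MYCN", "WT_1": "WT"}

    def segs(self, atrx_state, mycn_state, wt_state):
        return {
            "ATRX_1": seg("ATRX_1", ("a", 0, 100, atrx_state)),
            "MYCN_1": seg("MYCN_1", ("a", 0, 100, mycn_state)),
            "WT_1": seg("WT_1", ("a", 0, 100, wt_state)),
        }

    @pytest.mark.parametrize("rule", ["disjoint", "active_class"])
    def test_clean_shift_is_concordant(self, rule):
        peak = ref_peak("a", 10, 90, present=("MYCN", "WT"))
        segs = self.segs(16, 3, 3)
        assert state_concordance(peak, segs, self.SAMPLES, rule=rule) is True

    @pytest.mark.parametrize("rule", ["disjoint", "active_class"])
    def test_uniform_state_not_concordant(self, rule):
        peak = ref_peak("a", 10, 90, present=("MYCN", "WT"))
        segs = self.segs(13, 13, 13)
        assert state_concordance(peak, segs, self.SAMPLES, rule=rule) is False

    def test_unsegmented_sample_excluded(self):
        peak = ref_peak("a", 10, 90, present=("MYCN", "WT"))
        segs = self.segs(16, 3, 3)
        segs["WT_1"] = seg("WT_1", ("b", 0, 100, 3))
        assert state_concordance(peak, segs, self.SAMPLES) is None

    def test_all_present_excluded(self):
        peak = ref_peak("a", 10, 90)  # present in all three
        segs = self.segs(3, 3, 3)
        assert state_concordance(peak, segs, self.SAMPLES) is None

    def test_planted_shifts_fully_concordant(self, clean_bundle, clean_result):
        d_peaks = [p for p in clean_result.reference if p.label == "D"]
        assert d_peaks
        assert all(p.chromhmm_concordant for p in d_peaks)


class TestLocationClass:
    TSS = pd.DataFrame({"gene": ["g1"], "seq": ["a"], "tss": [10_000],
                        "strand": ["+"]})
    SAMPLES = {"WT_1": "WT"}

    def test_peak_at_tss_is_promoter(self):
        peak = ref_peak("a", 9_950, 10_050, present=("WT",))
        got = location_class(peak, self.TSS, {}, self.SAMPLES)
        assert got == "promoter"

    def test_half_open_window_boundary(self):
        # promoter window is [TSS-2000, TSS+2000); a peak starting exactly
        # at TSS+2000 misses it
        peak = ref_peak("a", 12_000, 12_100, present=("WT",))
        segs = {"WT_1": seg("WT_1", ("a", 0, 20_000, 9))}
        assert location_class(peak, self.TSS, segs, self.SAMPLES) == "other"
        inside = ref_peak("a", 11_999, 12_100, present=("WT",))
        assert location_class(inside, self.TSS, segs, self.SAMPLES) == "promoter"

    def test_enhancer_state_far_from_tss(self):
        peak = ref_peak("a", 50_000, 50_100, present=("WT",))
        segs = {"WT_1": seg("WT_1", ("a", 0, 60_000, 6))}
        assert location_class(peak, self.TSS, segs, self.SAMPLES) == "enhancer"

    def test_absent_sample_state_ignored(self):
        peak = ref_peak("a", 50_000, 50_100, present=("WT",))
        segs = {"WT_1": seg("WT_1", ("a", 0, 60_000, 9)),
                "ATRX_1": seg("ATRX_1", ("a", 0, 60_000, 6))}
        samples = {"WT_1": "WT", "ATRX_1": "ATRX"}
        assert location_class(peak, self.TSS, segs, samples) == "other"


class TestState13Expansion:
    def gene(self, strand="+"):
        return pd.DataFrame({"gene": ["g"], "seq": ["a"], "tss": [1000],
                             "strand": [strand]})

    def seg_with_prop(self, sample, prop):
        """State 13 covers the given fraction of [1000, 3000)."""
        cut = 1000 + int(2000 * prop)
        parts = [("a", 0, 1000, 9)]
        if cut > 1000:
            parts.append(("a", 1000, cut, 13))
        parts.append(("a", cut, 5000, 9))
        return seg(sample, *parts)

    @pytest.mark.parametrize("prop_plus,prop_minus,expected", [
        (0.25, 0.10, True),
        (0.20, 0.00, True),    # >= 20% is inclusive and 0.20 > 2*0
        (0.40, 0.25, False),   # fold change fails
        (0.15, 0.05, False),   # floor fails
    ])
    def test_expansion_rule(self, prop_plus, prop_minus, expected):
        res = state13_expansion(self.seg_with_prop("plus", prop_plus),
                                self.seg_with_prop("minus", prop_minus),
                                self.gene())
        assert res.loc["g", "expanded"] == expected
        assert res.loc["g", "prop_plus"] == pytest.approx(prop_plus)
        assert res.loc["g", "prop_minus"] == pytest.approx(prop_minus)

    def test_minus_strand_uses_upstream_coordinates(self):
        # for a - gene the downstream window is [tss-2000, tss)
        s_plus = seg("plus", ("a", 0, 1000, 13), ("a", 1000, 5000, 9))
        s_minus = seg("minus", ("a", 0, 5000, 9))
        res = state13_expansion(s_plus, s_minus, self.gene(strand="-"))
        assert res.loc["g", "prop_plus"] == pytest.approx(1.0)
        assert res.loc["g", "expanded"]

    def test_strandless_gene_rejected(self):
        gene = pd.DataFrame({"gene": ["g"], "seq": ["a"], "tss": [1000],
                             "strand": ["."]})
        with pytest.raises(ValueError, match="strand"):
            state13_expansion(self.seg_with_prop("p", 0.5),
                              self.seg_with_prop("m", 0.1), gene)


class TestMycnPromoterBinding:
    def tss(self, *rows):
        return pd.DataFrame(rows, columns=["gene", "seq", "tss", "strand"])

    def test_peak_at_tss_binds(self):
        table = self.tss(("g", "a", 10_000, "+"))
        flags = mycn_promoter_binding(table, iset(("a", 9_900, 10_100)))
        assert flags["g"]

    def test_peak_ending_at_window_start_does_not_bind(self):
        table = self.tss(("g", "a", 10_000, "+"))
        assert not mycn_promoter_binding(table, iset(("a", 7_000, 8_000)))["g"]
        assert mycn_promoter_binding(table, iset(("a", 7_000, 8_001)))["g"]

    def test_matches_brute_force(self, rng):
        genes = [(f"g{i}", "c", int(t), "+")
                 for i, t in enumerate(rng.integers(2_000, 100_000, 80))]
        peaks = [("c", int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 100_000, 120),
                                 rng.integers(50, 3_000, 120))]
        flags = mycn_promoter_binding(self.tss(*genes), iset(*peaks))
        for name, _, tss, _ in genes:
            expect = any(s < tss + 2000 and tss - 2000 < e
                         for _, s, e in peaks)
            assert flags[name] == expect


class TestDmrIntersect:
    TSS = pd.DataFrame({"gene": ["g1", "g2"], "seq": ["a", "a"],
                        "tss": [10_000, 50_000], "strand": ["+", "+"]})
    DEG = pd.DataFrame({"log2fc": [1.3, 0.1], "adj_p": [0.05, 0.05]},
                       index=["g1", "g2"])

    def dmr(self, start, end, n_cpg=5, meth_diff=0.25, p=0.005):
        return DmrRecord(GenomicInterval("a", start, end), n_cpg, meth_diff, p)

    def test_all_gates_pass(self):
        pairs = dmr_promoter_deg_intersect(
            [self.dmr(9_900, 10_020)], self.TSS, self.DEG)
        assert pairs["gene"].tolist() == ["g1"]

    @pytest.mark.parametrize("kwargs", [
        dict(end=9_949),              # length 49 < 50
        dict(n_cpg=2),                # too few CpGs
        dict(meth_diff=0.15),         # |diff| < 0.2
        dict(p=0.02),                 # caller p > 0.01
    ])
    def test_invalid_dmrs_filtered(self, kwargs):
        base = dict(start=9_900, end=10_020)
        base.update(kwargs)
        d = self.dmr(base["start"], base["end"],
                     n_cpg=base.get("n_cpg", 5),
                     meth_diff=base.get("meth_diff", 0.25),
                     p=base.get("p", 0.005))
        assert dmr_promoter_deg_intersect([d], self.TSS, self.DEG).empty

    def test_non_deg_promoter_excluded(self):
        pairs = dmr_promoter_deg_intersect(
            [self.dmr(49_900, 50_020)], self.TSS, self.DEG)
        assert pairs.empty

    def test_promoter_window_is_1kb(self):
        outside = self.dmr(11_000, 11_100)   # starts exactly at TSS+1000
        inside = self.dmr(10_999, 11_100)
        assert dmr_promoter_deg_intersect([outside], self.TSS, self.DEG).empty
        assert len(dmr_promoter_deg_intersect([inside], self.TSS, self.DEG)) == 1


def test_location_classes_partition(clean_result):
    locs = {p.location for p in clean_result.reference}
    assert locs <= {"promoter", "enhancer", "other"}
    assert all(p.location for p in clean_result.reference)


def test_planted_locations_recovered(clean_bundle, clean_result):
    for rp in clean_result.reference:
        assert rp.location == matched_truth(clean_bundle, rp).location
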