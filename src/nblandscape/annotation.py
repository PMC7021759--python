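"""Annotation of reference peaks with G4/R-loop overlap, location class and
chromatin-state concordance, plus promoter-window rules (state-13 expansion,
MYCN promoter binding, DMR-promoter-DEG intersection).

Promoter windows are symmetric and strand-agnostic (TSS +/- 2 kb for peak
location and MYCN binding, TSS +/- 1 kb for DMRs); only the state-13
expansion metric uses a strand-aware *downstream* window [TSS, TSS + 2 kb),
since it measures spread of a transcription state into the gene body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomicInterval, IntervalSet, overlap_query
from .peaks import ReferencePeak

__all__ = [
    "DEFAULT_STATE_CLASSES",
    "Segmentation",
    "DmrRecord",
    "annotate_g4_rloop",
    "dominant_state",
    "state_concordance",
    "location_class",
    "state13_expansion",
    "mycn_promoter_binding",
    "dmr_promoter_deg_intersect",
]

# 18-state class map. The model distinguishes active euchromatic states
# (1-4), enhancer states (5-7 by convention here), strongly transcribed gene
# body (13, treated as active), inactive heterochromatic states (15-17) and
# CTCF/insulator (18); the remainder are "other".
DEFAULT_STATE_CLASSES: dict[int, str] = {
    **{s: "active" for s in (1, 2, 3, 4, 13)},
    **{s: "enhancer" for s in (5, 6, 7)},
    **{s: "other" for s in (8, 9, 10, 11, 12, 14)},
    **{s: "inactive" for s in (15, 16, 17)},
    18: "ctcf",
}


@dataclass
class Segmentation:
    """One sample's genome tiling by chromatin states 1..18."""

    sample: str
    intervals: IntervalSet
    state_classes: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_STATE_CLASSES)
    )

    def __post_init__(self):
        for iv in self.intervals:
            s = iv.payload.get("state")
            if not isinstance(s, int) or not (1 <= s <= 18):
                raise ValueError(
                    f"{self.sample}: segment {iv.seq}:{iv.start}-{iv.end} "
                    f"has invalid state {s!r}"
                )

    def state_class(self, state: int) -> str:
        return self.state_classes.get(state, "other")


@dataclass
class DmrRecord:
    """A differentially methylated region with caller statistics."""

    interval: GenomicInterval
    n_cpg: int
    meth_diff: float
    p: float

    def __post_init__(self):
        if self.n_cpg < 0:
            raise ValueError("n_cpg must be >= 0")
        if abs(self.meth_diff) > 1:
            raise ValueError("|meth_diff| must be <= 1")


# -- G4 / R-loop -----------------------------------------------------------------

def annotate_g4_rloop(
    reference: list[ReferencePeak],
    g4: IntervalSet,
    rlfs: IntervalSet,
) -> dict:
    """Flag each peak for G4-motif and R-loop-forming-sequence overlap.

    The RLFS fraction is reported *among G4-flagged peaks*, matching the
    conditional phrasing used for these tracks; ``frac_rlfs_of_g4`` is 0 with
    ``undefined=True`` when no peak carries a G4.
    """
    peak_set = IntervalSet([p.interval for p in reference])
    g4_flags, _ = overlap_query(peak_set, g4)
    rlfs_flags, _ = overlap_query(peak_set, rlfs)
    n_g4 = 0
    n_g4_rlfs = 0
    for p, fg, fr in zip(reference, g4_flags, rlfs_flags):
        p.g4 = fg
        p.rlfs = fg and fr
        n_g4 += fg
        n_g4_rlfs += (fg and fr)
    n = len(reference)
    return {
        "n_peaks": n,
        "n_g4": n_g4,
        "frac_g4": (n_g4 / n) if n else 0.0,
        "n_g4_rlfs": n_g4_rlfs,
        "frac_rlfs_of_g4": (n_g4_rlfs / n_g4) if n_g4 else 0.0,
        "undefined": n_g4 == 0,
    }


# -- chromatin states --------------------------------------------------------------

def dominant_state(seg: Segmentation, interval: GenomicInterval) -> int | None:
    """State covering the most base pairs of ``interval``.

    Ties break toward the lowest state number; uncovered base pairs are
    ignored; ``None`` means the interval is entirely unsegmented.
    """
    cover: dict[int, int] = {}
    for hit in seg.intervals.query(interval):
        state = hit.payload["state"]
        cover[state] = cover.get(state, 0) + hit.overlap_length(interval)
    if not cover:
        return None
    return min(
        cover, key=lambda s: (-cover[s], s)
    )


def state_concordance(
    peak: ReferencePeak,
    segmentations: dict[str, Segmentation],
    sample_groups: dict[str, str],
    rule: str = "disjoint",
) -> bool | None:
    """Whether chromatin state tracks the presence/absence of the peak.

    ``disjoint`` (default): the dominant states of peak-present samples and
    peak-absent samples share no state. ``active_class``: every present
    sample's dominant state is active/enhancer-class and every absent
    sample's is inactive-class. Returns ``None`` (excluded) if the peak is
    unsegmented in any sample or if one side is empty.
    """
    if rule not in ("disjoint", "active_class"):
        raise ValueError(f"unknown rule {rule!r}")
    present_states: list[tuple[str, int]] = []
    absent_states: list[tuple[str, int]] = []
    for sample, seg in segmentations.items():
        st = dominant_state(seg, peak.interval)
        if st is None:
            return None
        if sample_groups[sample] in peak.present_in:
            present_states.append((sample, st))
        else:
            absent_states.append((sample, st))
    if not present_states or not absent_states:
        return None
    if rule == "disjoint":
        return not ({s for _, s in present_states} & {s for _, s in absent_states})
    for sample, st in present_states:
        if segmentations[sample].state_class(st) not in ("active", "enhancer"):
            return False
    for sample, st in absent_states:
        if segmentations[sample].state_class(st) != "inactive":
            return False
    return True


# -- location class -----------------------------------------------------------------

def _promoter_windows(tss_table: pd.DataFrame, flank: int) -> IntervalSet:
    ivs = []
    for row in tss_table.itertuples():
        start = max(0, int(row.tss) - flank)
        ivs.append(GenomicInterval(row.seq, start, int(row.tss) + flank,
                                   payload={"gene": row.gene}))
    return IntervalSet(ivs, name=f"promoters±{flank}")


def location_class(
    peak: ReferencePeak,
    tss_table: pd.DataFrame,
    segmentations: dict[str, Segmentation],
    sample_groups: dict[str, str],
    promoter_flank: int = 2000,
) -> str:
    """Classify a peak as promoter / enhancer / other.

    Promoter: overlaps [TSS - 2 kb, TSS + 2 kb) of any gene (strand-agnostic,
    half-open). Otherwise enhancer if the dominant state in any peak-present
    sample is enhancer-class; otherwise other.
    """
    promoters = _promoter_windows(tss_table, promoter_flank)
    if promoters.overlaps_any(peak.interval):
        peak.location = "promoter"
        return "promoter"
    for sample, seg in segmentations.items():
        if sample_groups[sample] not in peak.present_in:
            continue
        st = dominant_state(seg, peak.interval)
        if st is not None and seg.state_class(st) == "enhancer":
            peak.location = "enhancer"
            return "enhancer"
    peak.location = "other"
    return "other"


# -- state-13 expansion ----------------------------------------------------------------

def _downstream_window(row) -> GenomicInterval:
    tss = int(row.tss)
    if row.strand == "+":
        return GenomicInterval(row.seq, tss, tss + 2000)
    if row.strand == "-":
        return GenomicInterval(row.seq, max(0, tss - 2000), max(1, tss))
    raise ValueError(f"gene {row.gene}: downstream window undefined without strand")


def _state13_fraction(seg: Segmentation, window: GenomicInterval) -> float:
    covered = sum(
        hit.overlap_length(window)
        for hit in seg.intervals.query(window)
        if hit.payload["state"] == 13
    )
    return covered / len(window)


def state13_expansion(
    seg_plus: Segmentation,
    seg_minus: Segmentation,
    tss_table: pd.DataFrame,
    fold: float = 2.0,
    min_prop: float = 0.20,
) -> pd.DataFrame:
    """Per-gene expansion of the strongly-transcribed state 13.

    ``prop`` is the base-pair fraction of the strand-aware downstream window
    [TSS, TSS + 2 kb) covered by state 13 in each condition. A gene is
    *expanded* iff ``prop_plus > fold * prop_minus`` and ``prop_plus >=
    min_prop``.
    """
    rows = []
    for row in tss_table.itertuples():
        window = _downstream_window(row)
        prop_plus = _state13_fraction(seg_plus, window)
        prop_minus = _state13_fraction(seg_minus, window)
        rows.append({
            "gene": row.gene,
            "prop_plus": prop_plus,
            "prop_minus": prop_minus,
            "expanded": (prop_plus > fold * prop_minus) and (prop_plus >= min_prop),
        })
    return pd.DataFrame(rows).set_index("gene")


# -- MYCN promoter binding -----------------------------------------------------------

def mycn_promoter_binding(
    tss_table: pd.DataFrame,
    mycn_peaks: IntervalSet,
    flank: int = 2000,
) -> pd.Series:
    """Per-gene flag: a MYCN peak overlaps the promoter [TSS - 2 kb, TSS + 2 kb)."""
    flags = {}
    for row in tss_table.itertuples():
        window = GenomicInterval(row.seq, max(0, int(row.tss) - flank),
                                 int(row.tss) + flank)
        flags[row.gene] = mycn_peaks.overlaps_any(window)
    return pd.Series(flags, name="mycn_bound")


# -- DMR / promoter / DEG -------------------------------------------------------------

def dmr_promoter_deg_intersect(
    dmrs: list[DmrRecord],
    tss_table: pd.DataFrame,
    deg_table: pd.DataFrame,
    min_length: int = 50,
    min_cpg: int = 3,
    min_meth_diff: float = 0.2,
    max_p: float = 0.01,
    promoter_flank: int = 1000,
    min_abs_log2fc: float = 1.0,
    max_adj_p: float = 0.1,
) -> pd.DataFrame:
    """DMR-gene pairs where a valid DMR hits a differentially expressed promoter.

    DMR validity: length >= 50 bp, >= 3 CpGs, |methylation difference| >= 0.2,
    caller p <= 0.01. A surviving DMR is associated with a gene when it
    overlaps [TSS - 1 kb, TSS + 1 kb) and the gene shows at least a twofold
    expression change (|log2 FC| >= 1) at adjusted p <= 0.1.
    """
    surviving = [
        d for d in dmrs
        if len(d.interval) >= min_length
        and d.n_cpg >= min_cpg
        and abs(d.meth_diff) >= min_meth_diff
        and d.p <= max_p
    ]
    deg = deg_table[
        (deg_table["log2fc"].abs() >= min_abs_log2fc)
        & (deg_table["adj_p"] <= max_adj_p)
    ]
    genes = set(deg.index)
    promoters = _promoter_windows(
        tss_table[tss_table["gene"].isin(genes)], promoter_flank
    )
    pairs = []
    for d in surviving:
        for hit in promoters.query(d.interval):
            pairs.append({
                "dmr": f"{d.interval.seq}:{d.interval.start}-{d.interval.end}",
                "gene": hit.payload["gene"],
                "meth_diff": d.meth_diff,
                "log2fc": float(deg.loc[hit.payload["gene"], "log2fc"]),
            })
    return pd.DataFrame(pairs, columns=["dmr", "gene", "meth_diff", "log2fc"])
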