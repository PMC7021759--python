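"""End-to-end landscape workflow: from per-sample tracks to an annotated,
classified reference peak table."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import annotation, peaks
from .intervals import IntervalSet
from .peaks import CountMatrix, ReferencePeak, SampleTrack
from .simulate import LandscapeBundle

__all__ = ["LandscapeResult", "run_landscape_pipeline"]


@dataclass
class LandscapeResult:
    reference: list[ReferencePeak]
    counts: CountMatrix
    diff_stats: pd.DataFrame
    group_sets: dict[str, IntervalSet]
    g4_summary: dict

    def label_counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in peaks.LABELS}
        for p in self.reference:
            out[p.label] += 1
        return out

    def table(self) -> pd.DataFrame:
        return peaks.reference_table(self.reference)


def run_landscape_pipeline(
    bundle: LandscapeBundle,
    mode: str = "presence",
    support: str = "any",
    max_fragment_size: int = 2000,
    concordance_rule: str = "disjoint",
    annotate: bool = True,
) -> LandscapeResult:
    """Run the full peak-landscape analysis on a (simulated or real) bundle.

    Steps: group-wise reproducible peaks -> merged reference set with
    presence flags -> fragment counting (< ``max_fragment_size`` bp) ->
    moderated differential occupancy -> C/E/D/O classification -> optional
    G4/RLFS, location and chromatin-state concordance annotation.
    """
    by_group: dict[str, list[SampleTrack]] = {}
    for t in bundle.tracks:
        by_group.setdefault(t.group, []).append(t)
    group_sets = {
        g: peaks.compile_reproducible_peaks(ts, support=support)
        for g, ts in by_group.items()
    }
    reference = peaks.build_reference_peaks(group_sets)
    counts = peaks.count_fragments(bundle.tracks, reference,
                                   max_fragment_size=max_fragment_size)
    diff = peaks.differential_occupancy(counts)
    peaks.classify_peak_groups(reference, diff, mode=mode)

    g4_summary: dict = {}
    if annotate:
        g4_summary = annotation.annotate_g4_rloop(reference, bundle.g4,
                                                  bundle.rlfs)
        groups = bundle.sample_groups
        for p in reference:
            annotation.location_class(p, bundle.tss_table,
                                      bundle.segmentations, groups)
            p.chromhmm_concordant = annotation.state_concordance(
                p, bundle.segmentations, groups, rule=concordance_rule
            )
    return LandscapeResult(
        reference=reference,
        counts=counts,
        diff_stats=diff,
        group_sets=group_sets,
        g4_summary=g4_summary,
    )
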