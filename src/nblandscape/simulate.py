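"""Synthetic-data generators with known ground truth.

Every pipeline input can be generated here so the full analysis is testable
without any external download:

* :func:`simulate_peak_landscape` — per-sample dual-threshold peak calls,
  fragment intervals, G4/RLFS tracks, chromatin-state segmentations and a
  TSS table, all derived from a planted C/E/D/O peak structure;
* :func:`simulate_cohort` — patient-level cohort tables with exact
  per-stratum mutation counts;
* :func:`simulate_plate` — 96-well screening plates with 4PL cytotoxic
  curves and optional protective bumps.

Defaults emulate the study conditions: three genotype groups (ATRX-mutant,
MYCN-amplified, wild type) with two replicates each, a planted G4 overlap
fraction of 0.35 with 0.70 of G4 peaks also R-loop-forming, the depleted (D)
class largest, and 1:3 dilution series starting at stock/890.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Segmentation
from .intervals import GenomicInterval, IntervalSet, write_bed
from .peaks import GROUPS, SampleTrack
from .screen import PlateData, make_dilution_series

__all__ = [
    "PlantedPeak",
    "LandscapeTruth",
    "LandscapeBundle",
    "PlacementError",
    "plant_landscape",
    "simulate_peak_landscape",
    "CohortSpec",
    "simulate_cohort",
    "FourPLCurve",
    "PlateSpec",
    "simulate_plate",
    "simulate_null_counts",
]

DEFAULT_GENOME = {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}

DEFAULT_LABEL_FRACTIONS = {"C": 0.30, "E": 0.15, "D": 0.40, "O": 0.15}


class PlacementError(ValueError):
    """The genome cannot hold the requested number of planted peaks."""


@dataclass
class PlantedPeak:
    interval: GenomicInterval
    label: str                      # C, E, D or O
    partner: str | None = None      # for O: the non-ATRX group sharing the peak
    g4: bool = False
    rlfs: bool = False
    location: str = "other"         # planted promoter/enhancer/other

    def present_in(self, group: str) -> bool:
        if self.label == "C":
            return True
        if self.label == "E":
            return group == "ATRX"
        if self.label == "D":
            return group != "ATRX"
        return group == "ATRX" or group == self.partner


@dataclass
class LandscapeTruth:
    """Planted ground truth plus the generator's design parameters."""

    genome_sizes: dict[str, int]
    planted_peaks: list[PlantedPeak]
    group_design: dict[str, int] = field(
        default_factory=lambda: {g: 2 for g in GROUPS}
    )
    enrichment: dict[str, float] = field(
        default_factory=lambda: {g: 20.0 for g in GROUPS}
    )
    noise_rate: float = 0.2     # background fragments per kbp
    seed: int = 0

    def __post_init__(self):
        if set(self.group_design) != set(GROUPS):
            raise ValueError(f"group_design must have exactly the groups {GROUPS}")
        merged = IntervalSet([p.interval for p in self.planted_peaks]).merge()
        if len(merged) != len(self.planted_peaks):
            raise ValueError("planted peaks must be non-overlapping")
        for p in self.planted_peaks:
            size = self.genome_sizes.get(p.interval.seq)
            if size is None or p.interval.end > size:
                raise ValueError(
                    f"planted peak {p.interval} outside genome bounds"
                )


def plant_landscape(
    n_peaks: int = 1000,
    genome_sizes: dict[str, int] | None = None,
    label_fractions: dict[str, float] | None = None,
    g4_fraction: float = 0.35,
    rlfs_given_g4: float = 0.70,
    promoter_fraction: float = 0.3,
    enhancer_fraction: float = 0.3,
    peak_width: int = 400,
    min_gap: int = 2500,
    seed: int = 0,
    **truth_kwargs,
) -> LandscapeTruth:
    """Plant non-overlapping peaks with labels, G4/RLFS flags and locations.

    Peaks are spread over the sequences with at least ``min_gap`` bp between
    them (the default keeps planted loci farther apart than any promoter
    window or replicate jitter, so downstream merging never fuses two loci).
    Raises :class:`PlacementError` when the genome is too small.
    """
    rng = np.random.default_rng(seed)
    genome = dict(genome_sizes or DEFAULT_GENOME)
    fracs = dict(label_fractions or DEFAULT_LABEL_FRACTIONS)
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError("label fractions must sum to 1")

    seqs = sorted(genome)
    total = sum(genome.values())
    per_seq = [round(n_peaks * genome[s] / total) for s in seqs]
    per_seq[-1] = n_peaks - sum(per_seq[:-1])

    intervals: list[GenomicInterval] = []
    for seq, k in zip(seqs, per_seq):
        if k <= 0:
            continue
        slot = peak_width + min_gap
        slack = genome[seq] - k * slot
        if slack < 0:
            raise PlacementError(
                f"{seq} ({genome[seq]} bp) cannot hold {k} peaks of "
                f"{peak_width} bp with {min_gap} bp gaps"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=k))
        for i, off in enumerate(offsets):
            start = int(off) + i * slot + min_gap // 2
            intervals.append(GenomicInterval(seq, start, start + peak_width))

    labels = np.concatenate([
        np.full(int(round(fracs[lab] * n_peaks)), lab, dtype=object)
        for lab in ("C", "E", "D", "O")
    ])
    labels = labels[:n_peaks]
    if labels.size < n_peaks:  # rounding shortfall goes to D
        labels = np.concatenate([labels, np.full(n_peaks - labels.size, "D")])
    rng.shuffle(labels)

    g4_flags = rng.random(n_peaks) < g4_fraction
    rlfs_flags = g4_flags & (rng.random(n_peaks) < rlfs_given_g4)
    loc_draw = rng.random(n_peaks)
    partners = rng.choice(["MYCN", "WT"], size=n_peaks)

    planted = []
    for iv, lab, g4, rl, u, partner in zip(
        intervals, labels, g4_flags, rlfs_flags, loc_draw, partners
    ):
        location = ("promoter" if u < promoter_fraction
                    else "enhancer" if u < promoter_fraction + enhancer_fraction
                    else "other")
        planted.append(PlantedPeak(
            interval=iv, label=str(lab),
            partner=str(partner) if lab == "O" else None,
            g4=bool(g4), rlfs=bool(rl), location=location,
        ))
    return LandscapeTruth(
        genome_sizes=genome, planted_peaks=planted, seed=seed, **truth_kwargs
    )


@dataclass
class LandscapeBundle:
    """All simulated inputs for one landscape, plus the generating truth."""

    tracks: list[SampleTrack]
    g4: IntervalSet
    rlfs: IntervalSet
    segmentations: dict[str, Segmentation]
    tss_table: pd.DataFrame
    truth: LandscapeTruth

    @property
    def sample_groups(self) -> dict[str, str]:
        return {t.sample: t.group for t in self.tracks}

    def write(self, outdir: str | Path) -> None:
        """Write the bundle as plain-text files (BED/TSV/JSON)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for t in self.tracks:
            write_bed(t.high_peaks, out / f"{t.sample}.high.bed")
            write_bed(t.low_peaks, out / f"{t.sample}.low.bed")
            write_bed(t.fragments, out / f"{t.sample}.fragments.bed")
            write_bed(self.segmentations[t.sample].intervals,
                      out / f"{t.sample}.segmentation.bed",
                      fmt="segmentation")
        write_bed(self.g4, out / "g4.bed")
        write_bed(self.rlfs, out / "rlfs.bed")
        self.tss_table.to_csv(out / "tss.tsv", sep="\t", index=False)
        truth = {
            "genome_sizes": self.truth.genome_sizes,
            "seed": self.truth.seed,
            "noise_rate": self.truth.noise_rate,
            "group_design": self.truth.group_design,
            "enrichment": self.truth.enrichment,
            "planted_peaks": [
                {
                    "seq": p.interval.seq,
                    "start": p.interval.start,
                    "end": p.interval.end,
                    "label": p.label,
                    "partner": p.partner,
                    "g4": p.g4,
                    "rlfs": p.rlfs,
                    "location": p.location,
                }
                for p in self.truth.planted_peaks
            ],
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def _clipped_normal_lengths(rng, n, mean, sd, clip):
    lens = rng.normal(mean, sd, size=n)
    return np.clip(np.rint(lens), clip[0], clip[1]).astype(int)


def _sample_fragments(rng, truth, group, frag_mean, frag_sd, frag_clip):
    frags: list[GenomicInterval] = []
    # enriched fragments at peaks present in this group
    for p in truth.planted_peaks:
        if not p.present_in(group):
            continue
        n = rng.poisson(truth.enrichment[group])
        if n == 0:
            continue
        centers = rng.integers(p.interval.start, p.interval.end, size=n)
        lengths = _clipped_normal_lengths(rng, n, frag_mean, frag_sd, frag_clip)
        size = truth.genome_sizes[p.interval.seq]
        for c, ln in zip(centers, lengths):
            start = max(0, int(c) - int(ln) // 2)
            end = min(size, start + int(ln))
            if end > start:
                frags.append(GenomicInterval(p.interval.seq, start, end))
    # uniform background
    for seq in sorted(truth.genome_sizes):
        size = truth.genome_sizes[seq]
        n_bg = rng.poisson(truth.noise_rate * size / 1000.0)
        if n_bg == 0:
            continue
        centers = rng.integers(0, size, size=n_bg)
        lengths = _clipped_normal_lengths(rng, n_bg, frag_mean, frag_sd, frag_clip)
        for c, ln in zip(centers, lengths):
            start = max(0, int(c) - int(ln) // 2)
            end = min(size, start + int(ln))
            if end > start:
                frags.append(GenomicInterval(seq, start, end))
    return IntervalSet(frags, name=f"{group}:fragments")


def _decoy_intervals(rng, truth, n, width, margin=2500):
    """Intervals placed at least ``margin`` bp away from every planted peak."""
    out = []
    seqs = sorted(truth.genome_sizes)
    peaks_by_seq = {
        s: [(p.interval.start, p.interval.end) for p in truth.planted_peaks
            if p.interval.seq == s]
        for s in seqs
    }
    attempts = 0
    while len(out) < n and attempts < 50 * n + 100:
        attempts += 1
        seq = seqs[int(rng.integers(0, len(seqs)))]
        size = truth.genome_sizes[seq]
        start = int(rng.integers(0, max(1, size - width)))
        end = start + width
        if all(end + margin <= s or start >= e + margin
               for s, e in peaks_by_seq[seq]):
            out.append(GenomicInterval(seq, start, end))
    return out


def _segmentation_for_sample(
    sample, group, truth, active_state, enhancer_state, inactive_state,
    background_state,
) -> Segmentation:
    ivs = []
    for seq in sorted(truth.genome_sizes):
        size = truth.genome_sizes[seq]
        loci = sorted(
            (p for p in truth.planted_peaks if p.interval.seq == seq),
            key=lambda p: p.interval.start,
        )
        pos = 0
        for p in loci:
            if p.interval.start > pos:
                ivs.append(GenomicInterval(seq, pos, p.interval.start,
                                           payload={"state": background_state}))
            if p.present_in(group):
                state = (enhancer_state if p.location == "enhancer"
                         else active_state)
            else:
                state = inactive_state
            ivs.append(GenomicInterval(seq, p.interval.start, p.interval.end,
                                       payload={"state": state}))
            pos = p.interval.end
        if pos < size:
            ivs.append(GenomicInterval(seq, pos, size,
                                       payload={"state": background_state}))
    return Segmentation(sample=sample, intervals=IntervalSet(ivs, name=sample))


def _tss_table(rng, truth, n_extra_genes=50, margin=2500):
    rows = []
    gene_idx = 0
    for p in truth.planted_peaks:
        if p.location != "promoter":
            continue
        center = (p.interval.start + p.interval.end) // 2
        rows.append({
            "gene": f"gene{gene_idx:05d}", "seq": p.interval.seq,
            "tss": int(center),
            "strand": "+" if rng.random() < 0.5 else "-",
        })
        gene_idx += 1
    for iv in _decoy_intervals(rng, truth, n_extra_genes, width=1, margin=margin):
        rows.append({
            "gene": f"gene{gene_idx:05d}", "seq": iv.seq, "tss": iv.start,
            "strand": "+" if rng.random() < 0.5 else "-",
        })
        gene_idx += 1
    table = pd.DataFrame(rows, columns=["gene", "seq", "tss", "strand"])
    table["fpkm_plus"] = np.round(rng.lognormal(2.0, 1.0, size=len(table)), 3)
    table["fpkm_minus"] = np.round(rng.lognormal(2.0, 1.0, size=len(table)), 3)
    return table


def simulate_peak_landscape(
    truth: LandscapeTruth,
    jitter: int = 20,
    low_pad: int = 100,
    low_only_rate: float = 0.1,
    frag_mean: float = 250.0,
    frag_sd: float = 300.0,
    frag_clip: tuple[int, int] = (50, 4000),
    track_width: int = 200,
    decoy_track_rate: float = 0.2,
    active_state: int = 2,
    enhancer_state: int = 6,
    inactive_state: int = 16,
    background_state: int = 9,
) -> LandscapeBundle:
    """Generate per-sample peak calls, fragments, tracks and segmentations.

    Samples of group g get a high-confidence peak at every planted peak
    present in g, jittered by at most ``jitter`` bp per edge. Low-confidence
    peaks are the high-confidence peaks padded by ``low_pad`` plus extra
    low-only peaks at rate ``low_only_rate`` per planted peak. Fragments
    are drawn around present peaks at the group's enrichment rate on top of
    uniform background (``truth.noise_rate`` per kbp) with lengths from a
    clipped normal. Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    n_peaks = len(truth.planted_peaks)

    tracks = []
    segmentations = {}
    for group in GROUPS:
        for rep in range(truth.group_design[group]):
            sample = f"{group}_{rep + 1}"
            highs = []
            for p in truth.planted_peaks:
                if not p.present_in(group):
                    continue
                iv = p.interval
                if jitter > 0:
                    ds = int(rng.integers(-jitter, jitter + 1))
                    de = int(rng.integers(-jitter, jitter + 1))
                else:
                    ds = de = 0
                start = max(0, iv.start + ds)
                end = min(truth.genome_sizes[iv.seq], max(start + 1, iv.end + de))
                highs.append(GenomicInterval(iv.seq, start, end))
            lows = [
                GenomicInterval(
                    h.seq, max(0, h.start - low_pad),
                    min(truth.genome_sizes[h.seq], h.end + low_pad),
                )
                for h in highs
            ]
            n_decoy = rng.poisson(low_only_rate * n_peaks)
            lows.extend(_decoy_intervals(rng, truth, n_decoy, width=300))
            frags = _sample_fragments(rng, truth, group,
                                      frag_mean, frag_sd, frag_clip)
            tracks.append(SampleTrack(
                sample=sample, group=group,
                high_peaks=IntervalSet(highs, name=f"{sample}:high"),
                low_peaks=IntervalSet(lows, name=f"{sample}:low"),
                fragments=frags,
            ))
            segmentations[sample] = _segmentation_for_sample(
                sample, group, truth, active_state, enhancer_state,
                inactive_state, background_state,
            )

    g4_ivs = []
    rlfs_ivs = []
    for p in truth.planted_peaks:
        center = (p.interval.start + p.interval.end) // 2
        if p.g4:
            g4_ivs.append(GenomicInterval(
                p.interval.seq, center - track_width // 2,
                center + track_width // 2))
        if p.rlfs:
            rlfs_ivs.append(GenomicInterval(
                p.interval.seq, center - track_width // 3,
                center + track_width // 3))
    n_decoy_tracks = rng.poisson(decoy_track_rate * n_peaks)
    g4_ivs.extend(_decoy_intervals(rng, truth, n_decoy_tracks, width=track_width))
    rlfs_ivs.extend(_decoy_intervals(rng, truth, n_decoy_tracks, width=track_width))

    tss = _tss_table(rng, truth)

    return LandscapeBundle(
        tracks=tracks,
        g4=IntervalSet(g4_ivs, name="g4"),
        rlfs=IntervalSet(rlfs_ivs, name="rlfs"),
        segmentations=segmentations,
        tss_table=tss,
        truth=truth,
    )


# -- cohort -----------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Per-stratum totals and mutant counts for a simulated cohort."""

    strata: list[tuple[str, int, int]]  # (stratum, n_total, n_mutant)
    seed: int = 0

    def __post_init__(self):
        for name, n, k in self.strata:
            if not (0 <= k <= n):
                raise ValueError(f"stratum {name}: require 0 <= {k} <= {n}")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per patient; per-stratum mutant counts exactly match the spec.

    Which patients are mutant is randomized by the seed; the margins are
    deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    pid = 0
    for name, n, k in spec.strata:
        mutant = np.zeros(n, dtype=bool)
        mutant[:k] = True
        rng.shuffle(mutant)
        for m in mutant:
            rows.append({"patient": f"pt{pid:05d}", "stratum": name,
                         "mutant": bool(m)})
            pid += 1
    return pd.DataFrame(rows, columns=["patient", "stratum", "mutant"])


# -- plates ------------------------------------------------------------------------

@dataclass
class FourPLCurve:
    """Four-parameter logistic viability curve with an optional protective bump.

    ``bottom``/``top`` are relative viabilities (vehicle = 1), ``ec50`` molar,
    ``hill`` the slope. The bump is Gaussian in log10 concentration and adds
    ``height`` log2-RLU units at its center.
    """

    compound: str
    bottom: float = 0.05
    top: float = 1.0
    ec50: float = 1e-6
    hill: float = 1.5
    bump_center: float | None = None  # log10 molar
    bump_width: float = 0.6
    bump_height: float = 0.0

    def log2_effect(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        viability = self.bottom + (self.top - self.bottom) / (
            1.0 + (conc / self.ec50) ** self.hill
        )
        effect = np.log2(viability)
        if self.bump_center is not None and self.bump_height != 0.0:
            x = np.log10(conc)
            effect = effect + self.bump_height * np.exp(
                -((x - self.bump_center) ** 2) / (2.0 * self.bump_width ** 2)
            )
        return effect


@dataclass
class PlateSpec:
    """Design of a replicate set of 8x12 screening plates.

    Compounds occupy rows (max 8), columns 1-10 carry a 1:3 dilution series
    starting at ``stock_molar / dilution_factor``; column 11 is vehicle and
    column 12 the positive control.
    """

    compounds: list[FourPLCurve]
    stock_molar: float = 10e-3
    dilution_factor: float = 890.0
    steps: int = 10
    ratio: float = 3.0
    baseline_log2_rlu: float = 17.0
    positive_control_viability: float = 0.01
    noise_sd: float = 0.05
    n_plates: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (1 <= len(self.compounds) <= 8):
            raise ValueError("1-8 compounds per plate")
        if self.steps != 10:
            raise ValueError("10 concentrations per compound per plate")
        if self.n_plates < 2:
            raise ValueError("replicate plate count must be >= 2")


def simulate_plate(spec: PlateSpec) -> tuple[list[PlateData], np.ndarray]:
    """Simulated replicate plates plus the concentration series.

    log2 RLU = baseline + curve effect + bump + Gaussian noise; vehicle wells
    omit the curve term and positive-control wells use the positive-control
    viability. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    concs = make_dilution_series(spec.stock_molar, spec.dilution_factor,
                                 spec.steps, spec.ratio)
    layout_rows = []
    for r in range(8):
        compound = spec.compounds[r].compound if r < len(spec.compounds) else None
        for c in range(12):
            if c < 10:
                if compound is None:
                    layout_rows.append({"row": r, "col": c, "compound": "",
                                        "concentration": np.nan, "role": "empty"})
                else:
                    layout_rows.append({"row": r, "col": c, "compound": compound,
                                        "concentration": concs[c], "role": "drug"})
            elif c == 10:
                layout_rows.append({"row": r, "col": c, "compound": "",
                                    "concentration": np.nan, "role": "vehicle"})
            else:
                layout_rows.append({"row": r, "col": c, "compound": "",
                                    "concentration": np.nan,
                                    "role": "positive_control"})
    layout = pd.DataFrame(layout_rows)

    plates = []
    pos_effect = np.log2(spec.positive_control_viability)
    for plate_i in range(spec.n_plates):
        log2 = np.full((8, 12), spec.baseline_log2_rlu)
        for r in range(8):
            if r < len(spec.compounds):
                log2[r, :10] += spec.compounds[r].log2_effect(concs)
            log2[r, 11] += pos_effect
        noise = (rng.normal(0.0, spec.noise_sd, size=(8, 12))
                 if spec.noise_sd > 0 else 0.0)
        rlu = 2.0 ** (log2 + noise)
        # blank out empty wells
        empty = layout[layout["role"] == "empty"]
        rlu[empty["row"], empty["col"]] = 1.0
        plates.append(PlateData(rlu=rlu, layout=layout,
                                plate_id=f"plate{plate_i + 1}"))
    return plates, concs


# -- null count matrices -------------------------------------------------------------

def simulate_null_counts(n_peaks: int = 500, n_per_group: int = 3,
                         seed: int = 0):
    """Poisson count matrix with no group effect, for calibration checks.

    Per-peak means are Gamma(2, 15) so peaks span depths from a handful to a
    few hundred fragments; every sample shares the same mean, so any
    detected contrast is a false positive. Returns a
    :class:`~nblandscape.peaks.CountMatrix` over the ATRX and MYCN groups.
    """
    from .peaks import CountMatrix

    rng = np.random.default_rng(seed)
    mu = rng.gamma(2.0, 15.0, size=n_peaks)
    samples = ([f"ATRX_{i+1}" for i in range(n_per_group)]
               + [f"MYCN_{i+1}" for i in range(n_per_group)])
    counts = rng.poisson(mu[:, None], size=(n_peaks, 2 * n_per_group))
    groups = pd.Series(
        ["ATRX"] * n_per_group + ["MYCN"] * n_per_group, index=samples
    )
    frame = pd.DataFrame(
        counts, columns=samples,
        index=[f"peak{i:05d}" for i in range(n_peaks)],
    )
    lib = frame.sum(axis=0) + 1000  # background fragments outside peaks
    return CountMatrix(counts=frame, library_sizes=lib, groups=groups)
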