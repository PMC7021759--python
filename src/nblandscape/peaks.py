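"""Reproducible-peak compilation, reference peak set, fragment counting,
moderated differential occupancy, and C/E/D/O classification.

The pipeline mirrors a dual-threshold CUT&RUN design: each sample carries a
high-confidence peak set (strict caller FDR) and a low-confidence set
(permissive FDR). A high-confidence peak is *reproducible* within its
genotype group when a low-confidence peak of another sample in the group
supports it. Reproducible peaks from the three groups (ATRX-mutant,
MYCN-amplified, wild type) are merged into one reference peak set; fragments
shorter than 2 kb are counted per reference peak; a moderated two-group test
quantifies differential H3.3 occupancy; and each reference peak is labelled

* ``C`` (constitutive)  — present in all three groups,
* ``E`` (enriched)      — present only in the ATRX group,
* ``D`` (depleted)      — absent in ATRX, present in MYCN and WT,
* ``O`` (overlapping)   — present in ATRX and exactly one other group,
* ``unclassified``      — any other presence pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "GROUPS",
    "SampleTrack",
    "ReferencePeak",
    "CountMatrix",
    "QcResult",
    "qc_filter",
    "compile_reproducible_peaks",
    "build_reference_peaks",
    "count_fragments",
    "differential_occupancy",
    "classify_peak_groups",
]

GROUPS = ("ATRX", "MYCN", "WT")

LABELS = ("C", "E", "D", "O", "unclassified")


@dataclass
class SampleTrack:
    """One sample's peak calls at two confidence thresholds plus fragments."""

    sample: str
    group: str
    high_peaks: IntervalSet
    low_peaks: IntervalSet
    fragments: IntervalSet | None = None
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class ReferencePeak:
    interval: GenomicInterval
    present_in: frozenset = frozenset()
    counts: dict = field(default_factory=dict)
    logfc_vs_atrx: dict = field(default_factory=dict)   # contrast -> log2FC
    adj_p: dict = field(default_factory=dict)           # contrast -> BH-adjusted p
    label: str = "unclassified"
    g4: bool = False
    rlfs: bool = False
    location: str = "other"
    chromhmm_concordant: bool | None = None

    @property
    def peak_id(self) -> str:
        iv = self.interval
        return f"{iv.seq}:{iv.start}-{iv.end}"


@dataclass
class CountMatrix:
    """Fragment counts per reference peak (rows) and sample (columns)."""

    counts: pd.DataFrame
    library_sizes: pd.Series
    groups: pd.Series  # sample -> group

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        self.groups = self.groups.reindex(self.counts.columns)


# -- QC ------------------------------------------------------------------------

#: minimum unique reads per mark class
_QC_DEPTH = {"point_source": 10_000_000, "broad": 20_000_000, "input": 10_000_000}


@dataclass
class QcResult:
    sample: str
    passed: bool
    reasons: list[str]


def qc_filter(tracks: list[SampleTrack]) -> list[QcResult]:
    """ENCODE-style depth / strand-correlation gating per mark class.

    point-source factors need >=10 M unique reads and RSC > 1; broad marks
    need >=20 M unique reads (RSC recorded but not gated); inputs need
    >=10 M unique reads and RSC < 1.
    """
    results = []
    for t in tracks:
        mark = t.qc.get("mark_class")
        if mark not in _QC_DEPTH:
            raise ValueError(f"{t.sample}: unknown mark_class {mark!r}")
        reads = t.qc.get("unique_reads", 0)
        rsc = t.qc.get("rsc")
        reasons = []
        if reads < _QC_DEPTH[mark]:
            reasons.append(
                f"unique_reads {reads} < {_QC_DEPTH[mark]} required for {mark}"
            )
        if mark == "point_source" and not (rsc is not None and rsc > 1):
            reasons.append(f"rsc {rsc} not > 1 (point_source rule)")
        if mark == "input" and not (rsc is not None and rsc < 1):
            reasons.append(f"rsc {rsc} not < 1 (input rule)")
        results.append(QcResult(t.sample, not reasons, reasons))
    return results


# -- reproducible peaks / reference set ----------------------------------------

def compile_reproducible_peaks(
    tracks: list[SampleTrack], support: str = "any"
) -> IntervalSet:
    """Group-level reproducible peak set.

    A sample's high-confidence peak is retained iff it overlaps a
    low-confidence peak of at least one *other* sample in the group
    (``support="any"``) or of every other sample (``support="all"``). The
    retained peaks of all samples are merged.
    """
    if support not in ("any", "all"):
        raise ValueError(f"support must be 'any' or 'all', got {support!r}")
    groups = {t.group for t in tracks}
    if len(groups) != 1:
        raise ValueError(f"tracks must come from a single group, got {groups}")
    if len(tracks) < 2:
        raise ValueError(
            "reproducibility needs >=2 samples per group; the rule is "
            "undefined for a single sample"
        )
    retained: list[GenomicInterval] = []
    for t in tracks:
        others = [o for o in tracks if o is not t]
        for peak in t.high_peaks:
            supported = [o.low_peaks.overlaps_any(peak) for o in others]
            ok = any(supported) if support == "any" else all(supported)
            if ok:
                retained.append(peak)
    return IntervalSet(retained, name=f"{tracks[0].group}:reproducible").merge()


def build_reference_peaks(
    group_sets: dict[str, IntervalSet]
) -> list[ReferencePeak]:
    """Merge the three group sets into a reference list with presence flags.

    ``present_in`` holds every group whose reproducible set overlaps the
    merged reference interval.
    """
    missing = set(GROUPS) - set(group_sets)
    if missing:
        raise ValueError(f"missing group sets: {sorted(missing)}")
    union = IntervalSet(
        [iv for g in GROUPS for iv in group_sets[g]], name="reference"
    ).merge()
    out = []
    for iv in union:
        present = frozenset(
            g for g in GROUPS if group_sets[g].overlaps_any(iv)
        )
        out.append(ReferencePeak(interval=iv, present_in=present))
    return out


# -- fragment counting ----------------------------------------------------------

def count_fragments(
    tracks: list[SampleTrack],
    reference: list[ReferencePeak],
    max_fragment_size: int = 2000,
) -> CountMatrix:
    """Count size-passing fragments per reference peak and sample.

    A fragment contributes iff its length is strictly less than
    ``max_fragment_size``; it increments every reference peak it overlaps by
    >=1 bp. ``library_sizes`` is the number of size-passing fragments per
    sample (the normalization denominator).
    """
    peak_ids = [p.peak_id for p in reference]
    index = IntervalSet([
        GenomicInterval(p.interval.seq, p.interval.start, p.interval.end,
                        payload={"row": i})
        for i, p in enumerate(reference)
    ])
    counts = np.zeros((len(reference), len(tracks)), dtype=np.int64)
    lib = {}
    groups = {}
    import warnings
    for j, t in enumerate(tracks):
        frags = t.fragments
        if frags is None or len(frags) == 0:
            warnings.warn(f"{t.sample}: empty fragment set; zero column")
            lib[t.sample] = 0
            groups[t.sample] = t.group
            continue
        n_pass = 0
        for frag in frags:
            if len(frag) >= max_fragment_size:
                continue
            n_pass += 1
            for hit in index.query(frag):
                counts[hit.payload["row"], j] += 1
        lib[t.sample] = n_pass
        groups[t.sample] = t.group
    samples = [t.sample for t in tracks]
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=peak_ids, columns=samples),
        library_sizes=pd.Series(lib, name="library_size"),
        groups=pd.Series(groups, name="group"),
    )
    for p, row in zip(reference, counts):
        p.counts = dict(zip(samples, row.tolist()))
    return cm


# -- moderated differential test -------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    # Newton iteration on trigamma(y) = x (monotone decreasing)
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Works on log s² so the moments are finite for small residual df.
    Returns (prior df d0, prior variance s0²); d0 = inf when the observed
    spread is no larger than expected under a common variance.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(((e - e_mean) ** 2).sum() / max(len(e) - 1, 1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


def differential_occupancy(cm: CountMatrix) -> pd.DataFrame:
    """Per-peak moderated two-group contrasts ATRX-vs-MYCN and ATRX-vs-WT.

    Counts are converted to log2 counts-per-million with pseudocount 0.5;
    each contrast is a two-sample comparison whose pooled variance is shrunk
    toward an empirical-Bayes prior (scaled inverse-chi-square fitted by
    moment matching); p-values come from a t distribution with augmented
    degrees of freedom and are BH-adjusted per contrast. Deterministic.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = cm.library_sizes.to_numpy(dtype=float)
    present = [g for g in GROUPS if (cm.groups == g).any()]
    if "ATRX" not in present or len(present) < 2:
        raise ValueError("need the ATRX group plus at least one comparison group")
    for g in present:
        members = cm.groups[cm.groups == g]
        if len(members) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        if lib[[cm.counts.columns.get_loc(s) for s in members.index]].sum() == 0:
            raise ValueError(f"group {g} has zero total library size")
    if (lib == 0).any():
        zero = cm.counts.columns[lib == 0].tolist()
        raise ValueError(f"samples with zero library size: {zero}")

    logcpm = np.log2((counts + 0.5) / (lib + 1.0) * 1e6)
    cols = {g: np.flatnonzero((cm.groups == g).to_numpy()) for g in present}

    result = {}
    for other in [g for g in ("MYCN", "WT") if g in present]:
        a = logcpm[:, cols["ATRX"]]
        b = logcpm[:, cols[other]]
        n1, n2 = a.shape[1], b.shape[1]
        lfc = a.mean(axis=1) - b.mean(axis=1)
        df_res = n1 + n2 - 2
        rss = (((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
               + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
        s2 = rss / df_res
        d0, s0 = _fit_variance_prior(s2, df_res)
        if np.isfinite(d0):
            s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)
            df_total = df_res + d0
        else:
            s2_post = np.full_like(s2, s0)
            df_total = 1e9  # effectively normal
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, 0.0, 1.0)
        key = other.lower()
        result[f"logFC_vs_{key}"] = lfc
        result[f"t_vs_{key}"] = t
        result[f"p_vs_{key}"] = p
        result[f"adj_p_vs_{key}"] = _bh(p)
    return pd.DataFrame(result, index=cm.counts.index)


# -- classification ---------------------------------------------------------------

def classify_peak_groups(
    reference: list[ReferencePeak],
    diff_stats: pd.DataFrame | None = None,
    mode: str = "presence",
    alpha: float = 0.05,
) -> list[ReferencePeak]:
    """Assign each reference peak one of C / E / D / O / unclassified.

    ``presence`` mode uses only the presence pattern across groups.
    ``presence+stats`` additionally requires, for E (resp. D), BH-adjusted
    p <= ``alpha`` and a consistent ATRX-higher (resp. ATRX-lower) log fold
    change in both contrasts.
    """
    if mode not in ("presence", "presence+stats"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "presence+stats" and diff_stats is None:
        raise ValueError("presence+stats mode requires differential statistics")

    for p in reference:
        present = p.present_in
        if present == frozenset(GROUPS):
            label = "C"
        elif present == frozenset({"ATRX"}):
            label = "E"
        elif present == frozenset({"MYCN", "WT"}):
            label = "D"
        elif "ATRX" in present and len(present) == 2:
            label = "O"
        else:
            label = "unclassified"

        if mode == "presence+stats" and label in ("E", "D"):
            row = diff_stats.loc[p.peak_id]
            sig = (row["adj_p_vs_mycn"] <= alpha) and (row["adj_p_vs_wt"] <= alpha)
            if label == "E":
                direction = row["logFC_vs_mycn"] > 0 and row["logFC_vs_wt"] > 0
            else:
                direction = row["logFC_vs_mycn"] < 0 and row["logFC_vs_wt"] < 0
            if not (sig and direction):
                label = "unclassified"

        p.label = label
        if diff_stats is not None and p.peak_id in diff_stats.index:
            row = diff_stats.loc[p.peak_id]
            p.logfc_vs_atrx = {
                "mycn": float(row["logFC_vs_mycn"]),
                "wt": float(row["logFC_vs_wt"]),
            }
            p.adj_p = {
                "mycn": float(row["adj_p_vs_mycn"]),
                "wt": float(row["adj_p_vs_wt"]),
            }
    return reference


def reference_table(reference: list[ReferencePeak]) -> pd.DataFrame:
    """Tidy per-peak table with all annotation fields."""
    rows = []
    for p in reference:
        rows.append({
            "peak_id": p.peak_id,
            "seq": p.interval.seq,
            "start": p.interval.start,
            "end": p.interval.end,
            "present_in": ",".join(sorted(p.present_in)),
            "label": p.label,
            "g4": p.g4,
            "rlfs": p.rlfs,
            "location": p.location,
            "chromhmm_concordant": p.chromhmm_concordant,
            "logFC_vs_mycn": p.logfc_vs_atrx.get("mycn"),
            "logFC_vs_wt": p.logfc_vs_atrx.get("wt"),
            "adj_p_vs_mycn": p.adj_p.get("mycn"),
            "adj_p_vs_wt": p.adj_p.get("wt"),
        })
    return pd.DataFrame(rows)
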