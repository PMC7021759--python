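"""Closed-form bench-assay computations: telomere qPCR delta-Ct and
CE-TOF-MS relative peak area."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QpcrMeasurement", "telomere_delta_ct", "relative_peak_area"]


@dataclass
class QpcrMeasurement:
    """Duplicate Ct values for the telomeric and single-copy control reactions."""

    telomere_cts: list[float]
    control_cts: list[float]
    sample: str = ""

    def __post_init__(self):
        for name, vals in (("telomere_cts", self.telomere_cts),
                           ("control_cts", self.control_cts)):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if not np.isfinite(arr).all() or (arr <= 0).any():
                raise ValueError(f"{name} must be finite and positive")


def telomere_delta_ct(m: QpcrMeasurement) -> float:
    """Average delta-Ct: mean control Ct minus mean telomere Ct.

    The telomeric mean is subtracted *from* the control (RPLP0) mean, so a
    larger value means more telomeric template per genome.
    """
    return float(np.mean(m.control_cts) - np.mean(m.telomere_cts))


def relative_peak_area(metabolite_area: float, is_area: float,
                       sample_amount: float) -> float:
    """Metabolite peak area / (internal-standard peak area x sample amount)."""
    if is_area <= 0:
        raise ValueError("internal-standard peak area must be positive")
    if sample_amount <= 0:
        raise ValueError("sample amount must be positive")
    return metabolite_area / (is_area * sample_amount)
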