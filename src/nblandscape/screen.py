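"""Drug-screen analytics: dilution series, plate normalization, smoothing-
spline dose-response fits and the protective AUC score.

The protective score targets compounds that rescue cells from induced death:
such compounds raise viability at low dose and often turn cytotoxic at high
dose, so a classical sigmoidal fit misses them. Instead, per-well log2 RLU
values are normalized to the vehicle wells, fit as a smooth function of
log10 concentration, and scored by the area by which the curve rises above
its own value at the lowest tested concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline

__all__ = [
    "PlateData",
    "DoseResponseSeries",
    "make_dilution_series",
    "normalize_plate",
    "fit_dose_spline",
    "protective_auc",
    "score_plate",
]

ROLES = ("drug", "vehicle", "positive_control", "empty")


@dataclass
class PlateData:
    """A 96-well readout: 8x12 RLU matrix plus a per-well layout table.

    ``layout`` columns: row (0-7), col (0-11), compound, concentration
    (molar; NaN for controls), role.
    """

    rlu: np.ndarray
    layout: pd.DataFrame
    plate_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.rlu = np.asarray(self.rlu, dtype=float)
        if self.rlu.shape != (8, 12):
            raise ValueError("rlu must be 8x12")
        bad = ~self.layout["role"].isin(ROLES)
        if bad.any():
            raise ValueError(f"unknown roles: {self.layout.loc[bad, 'role'].unique()}")
        nonempty = self.layout[self.layout["role"] != "empty"]
        vals = self.rlu[nonempty["row"], nonempty["col"]]
        if (vals <= 0).any():
            raise ValueError("RLU must be positive in non-empty wells")

    def wells(self, role: str) -> np.ndarray:
        sel = self.layout[self.layout["role"] == role]
        return self.rlu[sel["row"], sel["col"]]


@dataclass
class DoseResponseSeries:
    """Normalized responses of one compound over its concentration series."""

    x: np.ndarray  # log10 molar, may contain replicate (tied) values
    y: np.ndarray
    compound: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if not np.isfinite(self.y).all():
            raise ValueError("responses must be finite")


def make_dilution_series(
    stock_molar: float,
    dilution_factor: float = 890.0,
    steps: int = 10,
    ratio: float = 3.0,
) -> np.ndarray:
    """Concentrations of a pin-tool transfer followed by a serial dilution.

    The top concentration is ``stock / dilution_factor`` (the 112 nL pin
    transfer gives an 890-fold dilution); each further step divides by
    ``ratio``. Returned in plate order, highest first.
    """
    if stock_molar <= 0:
        raise ValueError("stock concentration must be positive")
    top = stock_molar / dilution_factor
    return top / ratio ** np.arange(steps)


def normalize_plate(plate: PlateData, mode: str = "protective") -> np.ndarray:
    """Per-well normalized values on the log2 RLU scale.

    ``cytotoxic``: (log2 rlu - mean log2 positive control) /
    (mean log2 vehicle - mean log2 positive control) — vehicle maps to 1 and
    the positive control to 0 in expectation.

    ``protective``: log2 rlu - mean log2 vehicle — vehicle maps to 0; a
    doubling of RLU adds exactly 1.
    """
    if mode not in ("cytotoxic", "protective"):
        raise ValueError(f"unknown mode {mode!r}")
    veh = plate.wells("vehicle")
    if veh.size == 0:
        raise ValueError("plate has no vehicle wells")
    log2 = np.full_like(plate.rlu, np.nan)
    nonempty = plate.layout[plate.layout["role"] != "empty"]
    r, c = nonempty["row"].to_numpy(), nonempty["col"].to_numpy()
    log2[r, c] = np.log2(plate.rlu[r, c])
    veh_mean = float(np.log2(veh).mean())
    if mode == "protective":
        return log2 - veh_mean
    pos = plate.wells("positive_control")
    if pos.size == 0:
        raise ValueError("cytotoxic mode needs positive_control wells")
    pos_mean = float(np.log2(pos).mean())
    return (log2 - pos_mean) / (veh_mean - pos_mean)


def fit_dose_spline(series: DoseResponseSeries) -> BSpline:
    """Cubic smoothing spline of response vs log10 concentration.

    The penalty is chosen by generalized cross-validation. Replicate points
    at the same concentration are pooled: tied x values are averaged with a
    weight equal to the replicate count, which gives the same penalized
    least-squares solution as entering each point separately.
    """
    order = np.argsort(series.x)
    x, y = series.x[order], series.y[order]
    ux, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    if ux.size < 4:
        raise ValueError(
            f"need >=4 distinct concentrations for a spline, got {ux.size}"
        )
    ymean = np.bincount(inv, weights=y) / counts
    return make_smoothing_spline(ux, ymean, w=counts.astype(float))


def protective_auc(curve: BSpline, series: DoseResponseSeries,
                   grid_size: int = 256) -> float:
    """Area of the fitted curve above its value at the lowest concentration.

    The baseline is the *fitted* value at min(x); the curve is evaluated on
    a uniform ``grid_size``-point grid over [min x, max x] and the positive
    part of (curve - baseline) is integrated by the trapezoid rule. Always
    >= 0; exactly 0 for curves that never rise above the baseline.
    """
    lo, hi = float(series.x.min()), float(series.x.max())
    grid = np.linspace(lo, hi, grid_size)
    baseline = float(curve(lo))
    excess = np.asarray(curve(grid)) - baseline
    # spline evaluation of an exactly flat curve leaves ~1e-15 residue
    tol = 1e-10 * max(1.0, abs(baseline))
    excess[excess < tol] = 0.0
    return float(np.trapezoid(excess, grid))


def score_plate(plate: PlateData, mode: str = "protective") -> pd.DataFrame:
    """Normalize a plate and score every compound.

    Returns one row per compound with the protective AUC (protective mode)
    or the mean normalized activity per concentration (cytotoxic mode is
    summarized by the curve minimum).
    """
    norm = normalize_plate(plate, mode=mode)
    drug = plate.layout[plate.layout["role"] == "drug"]
    rows = []
    for compound, sub in drug.groupby("compound", sort=True):
        x = np.log10(sub["concentration"].to_numpy(dtype=float))
        y = norm[sub["row"].to_numpy(), sub["col"].to_numpy()]
        series = DoseResponseSeries(x=x, y=y, compound=str(compound))
        curve = fit_dose_spline(series)
        rec = {"compound": compound}
        if mode == "protective":
            rec["protective_auc"] = protective_auc(curve, series)
        else:
            grid = np.linspace(x.min(), x.max(), 256)
            rec["min_activity"] = float(np.min(curve(grid)))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("compound")
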