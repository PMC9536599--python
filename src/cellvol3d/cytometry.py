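"""Flow-cytometry size-sorting analysis.

Signal gates (live/dead, epithelial marker, DNA <= 1.5x mode) followed by
SSC-W size bins G1-G4, plus the linear SSC-W -> cell-area model.  Events
live in a pandas DataFrame with columns ``ssc_h, ssc_w, fsc_a, ssc_a,
zombie_red, epcam, draq5``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .size_statistics import fd_bins

__all__ = [
    "EVENT_COLUMNS", "GateSet", "AreaModel", "dna_mode",
    "apply_signal_gates", "assign_size_bin", "predict_area",
    "fit_area_model", "yield_report",
]

EVENT_COLUMNS = ["ssc_h", "ssc_w", "fsc_a", "ssc_a", "zombie_red", "epcam", "draq5"]

SIZE_BINS = {"G1": (64.0, 79.0), "G2": (84.0, 99.0),
             "G3": (101.0, 113.0), "G4": (114.0, np.inf)}


@dataclass
class GateSet:
    live_max: float                     # Zombie Red upper cutoff (live = below)
    epcam_min: float
    dna_max_multiplier: float = 1.5     # x DRAQ5 mode
    dna_mode: float | None = None
    ssc_h_range: tuple[float, float] = (50.0, 200.0)
    size_bins: dict = field(default_factory=lambda: dict(SIZE_BINS))

    def __post_init__(self):
        edges = sorted(self.size_bins.values())
        for (a_lo, a_hi), (b_lo, _) in zip(edges, edges[1:]):
            if a_hi >= b_lo:
                raise ValueError("size bins must be non-overlapping and ascending")


@dataclass(frozen=True)
class AreaModel:
    """Linear SSC-W to cell cross-sectional area model, area = a + b*ssc_w."""
    intercept: float = -159.0   # um^2
    slope: float = 4.35         # um^2 per SSC-W unit
    intercept_se: float = float("nan")
    slope_se: float = float("nan")

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be positive")


def dna_mode(draq5_values, rng=None) -> float:
    """DNA-signal mode as the histogram argmax under FD binning."""
    values = np.asarray(draq5_values, dtype=float)
    try:
        _, _, edges = fd_bins(values)
    except ValueError:      # tiny or near-constant samples
        return float(np.median(values))
    counts, edges = np.histogram(values, bins=edges)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def apply_signal_gates(events: pd.DataFrame, gates: GateSet) -> tuple[pd.DataFrame, dict]:
    """Sequential live -> epithelial -> low-DNA filtering.

    The DNA cutoff is ``dna_max_multiplier`` times the DRAQ5 mode; the mode
    is taken from ``gates.dna_mode`` if calibrated, else computed on the
    incoming population.  Returns the surviving subset and per-stage counts.
    """
    counts = {"input": len(events)}
    live = events[events["zombie_red"] <= gates.live_max]
    counts["live"] = len(live)
    epi = live[live["epcam"] >= gates.epcam_min]
    counts["epcam"] = len(epi)
    mode = gates.dna_mode
    if mode is None:
        if len(epi) == 0:
            counts["dna"] = 0
            counts["dna_mode"] = float("nan")
            return epi, counts
        mode = dna_mode(epi["draq5"])
    cutoff = gates.dna_max_multiplier * mode
    gated = epi[epi["draq5"] <= cutoff]
    counts["dna"] = len(gated)
    counts["dna_mode"] = mode
    return gated, counts


def assign_size_bin(ssc_w: float, ssc_h: float, gates: GateSet) -> str:
    """Bin a signal-gated event by SSC-W, requiring SSC-H inside the trim range."""
    h_lo, h_hi = gates.ssc_h_range
    if not (h_lo <= ssc_h <= h_hi):
        return "none"
    for name, (lo, hi) in gates.size_bins.items():
        if lo <= ssc_w <= hi:
            return name
    return "none"


def assign_size_bins(events: pd.DataFrame, gates: GateSet) -> pd.Series:
    return pd.Series(
        [assign_size_bin(w, h, gates)
         for w, h in zip(events["ssc_w"], events["ssc_h"])],
        index=events.index, name="size_bin")


def predict_area(ssc_w, model: AreaModel = AreaModel()):
    """Predicted cell cross-sectional area (um^2); warns on negative output."""
    area = model.intercept + model.slope * np.asarray(ssc_w, dtype=float)
    if np.any(area < 0):
        warnings.warn("predicted area below zero: SSC-W under the model's "
                      "x-intercept", stacklevel=2)
    return area


def fit_area_model(ssc_w, areas) -> AreaModel:
    """OLS fit of mean cell area on SSC-W bin midpoint, with parameter SEs."""
    w = np.asarray(ssc_w, dtype=float)
    a = np.asarray(areas, dtype=float)
    if w.size < 3:
        raise ValueError("need at least 3 (ssc_w, area) pairs")
    X = np.column_stack([np.ones_like(w), w])
    coef, res, *_ = np.linalg.lstsq(X, a, rcond=None)
    fitted = X @ coef
    dof = w.size - 2
    s2 = float(np.sum((a - fitted) ** 2) / dof) if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    return AreaModel(intercept=float(coef[0]), slope=float(coef[1]),
                     intercept_se=float(np.sqrt(cov[0, 0])),
                     slope_se=float(np.sqrt(cov[1, 1])))


def yield_report(events: pd.DataFrame, gates: GateSet) -> dict:
    """Per-bin fractions of the signal-gated total (the none-bin absorbs the rest)."""
    out = {name: 0.0 for name in gates.size_bins}
    out["none"] = 0.0
    if len(events) == 0:
        return out
    bins = assign_size_bins(events, gates)
    frac = bins.value_counts(normalize=True)
    for name in out:
        out[name] = float(frac.get(name, 0.0))
    return out
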