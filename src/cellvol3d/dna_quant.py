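"""Brightness-calibrated nuclear thresholding, DNA totals and ploidy.

The nuclear isosurface volume depends on both the chosen intensity
threshold t and overall stack brightness, summarized by the DNA-histogram
center of mass I.  Two locally linear content models are measured per
stack:

    d(t) = beta_t - m_t * t        (content inside the DNA isosurface)
    d(l) = beta_l + m_l * l        (content inside the dilated lamin surface)

The reported content is d90 = 0.1*beta_l + 0.9*beta_t, reached at threshold
t90 = 0.1*(beta_t - beta_l)/m_t and lamin dilation L90 = 0.9*(beta_t -
beta_l)/m_l.  Fitting t90 against I across stacks of varying brightness
gives the threshold rule t(I) = 0.6 + k1*exp(k2*I), which makes nuclear
volumes robust to global brightness changes.

Ploidy is estimated image-cytometrically: DNA number = nuclear total /
stromal 2n baseline mode, estimated ploidy = 2 * DNA number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "CalibrationCurve", "ThresholdModel", "StromalBaseline", "PloidyEstimate",
    "histogram_center_of_mass", "sweep_threshold", "sweep_dilation",
    "target_content", "target_threshold", "target_dilation",
    "fit_threshold_curve", "segment_nucleus", "stromal_baseline",
    "estimate_ploidy", "NEAR_EUPLOID_RANGE",
]

NEAR_EUPLOID_RANGE = (1.6, 4.4)     # inclusive, haploid-genome units
THRESHOLD_FLOOR = 0.6               # segmentation breaks down below this
MIN_STROMAL_NUCLEI = 20


@dataclass(frozen=True)
class CalibrationCurve:
    I: float          # DNA-histogram center of mass for the stack
    beta_t: float     # content intercept at zero threshold
    m_t: float        # magnitude of d-vs-threshold slope (> 0)
    beta_l: float     # content inside the undilated lamin envelope
    m_l: float        # d-vs-dilation slope (content per um, > 0)

    def __post_init__(self):
        if self.beta_t <= self.beta_l:
            raise ValueError("beta_t must exceed beta_l")
        if self.m_t <= 0 or self.m_l <= 0:
            raise ValueError("slopes must be positive")

    def content_at_threshold(self, t: float) -> float:
        return self.beta_t - self.m_t * t


@dataclass(frozen=True)
class ThresholdModel:
    """t(I) = base + k1 * exp(k2 * I) with the base fixed at 0.6."""
    k1: float
    k2: float
    base: float = THRESHOLD_FLOOR

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")

    def threshold(self, I: float) -> float:
        return self.base + self.k1 * math.exp(self.k2 * I)


@dataclass
class StromalBaseline:
    totals: np.ndarray            # background-subtracted DNA sums per nucleus
    gaussian_mode: float
    gaussian_sd: float

    def __post_init__(self):
        if self.gaussian_mode <= 0:
            raise ValueError("baseline mode must be positive")


@dataclass(frozen=True)
class PloidyEstimate:
    dna_number: float             # genomes' worth of DNA signal
    estimated_ploidy: float       # = 2 * dna_number
    near_euploid: bool


def histogram_center_of_mass(dna: np.ndarray) -> float:
    """Intensity-weighted mean of the DNA channel over nonzero voxels."""
    vals = np.asarray(dna, dtype=float)
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("DNA channel has no positive voxels")
    return float(vals.mean())


def _content_inside(dna, region):
    return float(dna[region].sum())


def sweep_threshold(dna: np.ndarray, nucleus_masks, thresholds) -> tuple[float, float]:
    """Fit d(t) = beta_t - m_t*t per nucleus and average the coefficients.

    ``nucleus_masks`` is a boolean mask or a list of masks; content at each
    threshold is the sum of DNA intensity over above-threshold voxels inside
    the mask.  Raises if the measured d(t) is not decreasing.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size < 3:
        raise ValueError("need at least 3 thresholds")
    if isinstance(nucleus_masks, np.ndarray) and nucleus_masks.dtype == bool:
        nucleus_masks = [nucleus_masks]
    intercepts, slopes = [], []
    for mask in nucleus_masks:
        d = np.array([_content_inside(dna, mask & (dna >= t)) for t in thresholds])
        if not np.all(np.diff(d) <= 0) or d[0] <= d[-1]:
            raise ValueError("DNA content does not decrease with threshold; "
                             "linear content model does not apply")
        slope, intercept = np.polyfit(thresholds, d, 1)
        intercepts.append(intercept)
        slopes.append(-slope)
    return float(np.mean(intercepts)), float(np.mean(slopes))


def sweep_dilation(dna: np.ndarray, lamin_mask: np.ndarray, dilations,
                   voxel_size=1.0) -> tuple[float, float]:
    """Fit d(l) = beta_l + m_l*l by dilating the lamin envelope via EDT."""
    dilations = np.asarray(dilations, dtype=float)
    if dilations.size < 2:
        raise ValueError("need at least 2 dilation amounts")
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    dist = ndimage.distance_transform_edt(~lamin_mask.astype(bool),
                                          sampling=voxel_size)
    d = np.array([_content_inside(dna, dist <= l) for l in dilations])
    slope, intercept = np.polyfit(dilations, d, 1)
    return float(intercept), float(slope)


def target_content(curve: CalibrationCurve) -> float:
    """d90 = 0.1*beta_l + 0.9*beta_t, 90% of the theoretical maximum content."""
    return 0.1 * curve.beta_l + 0.9 * curve.beta_t


def target_threshold(curve: CalibrationCurve) -> float:
    """t90: the threshold whose isosurface holds d90.

    Algebraically 0.1*(beta_t - beta_l)/m_t (the printed two-term form
    (beta_t - beta_l)/m_t - 0.9*(beta_t - beta_l)/m_t simplifies to this).
    """
    return 0.1 * (curve.beta_t - curve.beta_l) / curve.m_t


def target_dilation(curve: CalibrationCurve) -> float:
    """L90 = 0.9*(beta_t - beta_l)/m_l, the matching lamin dilation."""
    return 0.9 * (curve.beta_t - curve.beta_l) / curve.m_l


def fit_threshold_curve(points, base: float = THRESHOLD_FLOOR) -> ThresholdModel:
    """Nonlinear least squares of t90 = base + k1*exp(k2*I) over (I, t90) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (I, t90) points")
    I, t = pts[:, 0], pts[:, 1]
    excess = t - base
    if np.any(excess <= 0):
        raise ValueError("all t90 values must exceed the base threshold")
    # log-linear start, then plain least squares in t
    k2_0, logk1_0 = np.polyfit(I, np.log(excess), 1)
    p0 = [math.exp(logk1_0), max(k2_0, 1e-6)]

    def f(I, k1, k2):
        return base + k1 * np.exp(k2 * I)

    try:
        popt, _ = optimize.curve_fit(f, I, t, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        resid = t - f(I, *p0)
        raise RuntimeError(f"threshold-curve fit did not converge; residuals at "
                           f"start {resid}") from exc
    return ThresholdModel(k1=float(popt[0]), k2=float(popt[1]), base=base)


def segment_nucleus(dna: np.ndarray, cell_mask: np.ndarray, model: ThresholdModel,
                    voxel_size=1.0, smoothing_um: float = 0.3,
                    I: float | None = None):
    """Threshold the masked DNA at t(I), fill cavities slice-wise, measure.

    Returns ``(filled_mask, volume_fl, fill_delta_fl)`` where the fill delta
    is the volume added by the slice-by-slice hole fill.  I defaults to the
    histogram center of mass of the whole DNA channel.
    """
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if I is None:
        I = histogram_center_of_mass(dna)
    t = model.threshold(I)
    raw = (np.asarray(dna, dtype=float) >= t) & cell_mask.astype(bool)
    # smoothing regularizes the binary shape at the half level, which keeps
    # the enclosed volume (unlike thresholding smoothed intensities, which
    # inflates crisp-edged objects by the smoothing tail)
    sigma = smoothing_um / voxel_size
    raw = ndimage.gaussian_filter(raw.astype(float), sigma=sigma) >= 0.5
    if raw.sum():
        lab, n = ndimage.label(raw)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        raw = lab == (1 + int(np.argmax(sizes)))
    filled = np.zeros_like(raw)
    for z in range(raw.shape[0]):
        filled[z] = ndimage.binary_fill_holes(raw[z])
    voxel_volume = float(np.prod(voxel_size))
    volume = float(filled.sum()) * voxel_volume
    fill_delta = float(filled.sum() - raw.sum()) * voxel_volume
    return filled, volume, fill_delta


def stromal_baseline(totals, backgrounds=None, voxel_counts=None) -> StromalBaseline:
    """Gaussian-fit mode of per-nucleus background-subtracted DNA totals.

    ``totals`` are raw sums; when ``backgrounds`` (per-voxel background) and
    ``voxel_counts`` are given, ``total - voxels*background`` is used.
    The mode is the fitted center of a single Gaussian, not the histogram
    argmax.  Warns below the 20-nucleus minimum.
    """
    totals = np.asarray(totals, dtype=float)
    if backgrounds is not None:
        totals = totals - np.asarray(voxel_counts, dtype=float) * np.asarray(
            backgrounds, dtype=float)
    if totals.size < MIN_STROMAL_NUCLEI:
        warnings.warn(f"only {totals.size} stromal nuclei; at least "
                      f"{MIN_STROMAL_NUCLEI} recommended for a stable baseline",
                      stacklevel=2)
    sd0 = float(totals.std()) or 1.0
    if totals.size < 4 or np.allclose(totals, totals[0]):
        return StromalBaseline(totals=totals, gaussian_mode=float(totals.mean()),
                               gaussian_sd=float(totals.std()))

    def gauss(x, k, mu, sigma):
        return k * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    counts, edges = np.histogram(totals, bins=max(8, int(np.sqrt(totals.size) * 2)))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = [counts.max(), float(np.median(totals)), 0.5 * sd0]
    try:
        popt, _ = optimize.curve_fit(gauss, centers, counts, p0=p0, maxfev=20000)
        mode, sd = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        mode, sd = float(np.median(totals)), sd0
    return StromalBaseline(totals=totals, gaussian_mode=mode, gaussian_sd=sd)


def estimate_ploidy(nucleus_total: float, baseline: StromalBaseline) -> PloidyEstimate:
    """Ploidy = 2 x (nuclear DNA total / stromal 2n baseline mode)."""
    dna_number = nucleus_total / baseline.gaussian_mode
    ploidy = 2.0 * dna_number
    lo, hi = NEAR_EUPLOID_RANGE
    return PloidyEstimate(dna_number=float(dna_number),
                          estimated_ploidy=float(ploidy),
                          near_euploid=bool(lo <= ploidy <= hi))
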