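"""Distribution-level statistics for cell and nucleus size data.

Histograms are binned with the Freedman-Diaconis rule and fit by
least-squares regression to one of three empirical models (two-Gaussian
mixture, single Gaussian, lognormal), all with the baseline fixed at zero.
The Gaussian ``width`` parameter relates to the standard deviation by
``sigma = width / sqrt(2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "HistogramFit", "PopulationSummary", "FoldChange",
    "fd_bins", "fit_histogram", "sigma_from_width", "percent_abnormal",
    "fold_change", "coefficient_of_variation",
]


@dataclass
class HistogramFit:
    model: str                       # 'two_gaussian' | 'gaussian' | 'lognormal'
    params: dict = field(default_factory=dict)
    chi2_per_df: float = float("nan")
    bin_width: float = float("nan")
    n: int = 0

    def density(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model == "two_gaussian":
            return (_gauss(x, p["k1"], p["x1"], p["width1"])
                    + _gauss(x, p["k2"], p["x2"], p["width2"]))
        if self.model == "gaussian":
            return _gauss(x, p["k1"], p["x1"], p["width1"])
        if self.model == "lognormal":
            return _lognorm(x, p["k1"], p["x1"], p["width1"])
        raise ValueError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class PopulationSummary:
    mean: float
    sd: float
    n: int = 1

    @property
    def cv(self) -> float:
        return self.sd / self.mean

    @property
    def se(self) -> float:
        return self.sd / math.sqrt(self.n)


@dataclass(frozen=True)
class FoldChange:
    xbar: float
    ybar: float
    sx: float
    sy: float
    nx: int
    ny: int
    fold: float
    var_taylor: float
    se: float
    se_conventional: float


def _gauss(x, k, x0, width):
    return k * np.exp(-(((x - x0) / width) ** 2))


def _lognorm(x, k, x0, width):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = k * np.exp(-((np.log(x[pos] / x0) / width) ** 2))
    return out


def fd_bins(values) -> tuple[float, int, np.ndarray]:
    """Freedman-Diaconis binning: bin width = 2*IQR/n^(1/3).

    Returns (bin_width, n_bins, edges) spanning the data range.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for Freedman-Diaconis binning")
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("IQR is zero (near-constant data); supply explicit bins")
    width = 2.0 * iqr / values.size ** (1.0 / 3.0)
    lo, hi = values.min(), values.max()
    n_bins = max(1, int(np.ceil((hi - lo) / width)))
    edges = lo + width * np.arange(n_bins + 1)
    return width, n_bins, edges


def sigma_from_width(width1: float) -> float:
    """Convert a fitted Gaussian ``width`` parameter to a standard deviation."""
    if width1 <= 0:
        raise ValueError("width must be positive")
    return width1 / math.sqrt(2.0)


def _initial_guesses(values, model):
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    q75, q25 = np.percentile(v, [75, 25])
    spread = max(q75 - q25, 1e-9)
    if model == "two_gaussian":
        return {"x1": med, "x2": np.percentile(v, 97.5),
                "width1": spread, "width2": spread}
    if model == "lognormal":
        return {"x1": med, "width1": 0.5}
    return {"x1": med, "width1": spread}


def fit_histogram(values, model: str = "two_gaussian", edges=None) -> HistogramFit:
    """Least-squares fit of an empirical peak model to FD-binned counts.

    Baseline is fixed at zero.  chi2/df uses Poisson bin variances floored
    at one count.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if edges is None:
        bin_width, _, edges = fd_bins(values)
    else:
        edges = np.asarray(edges, dtype=float)
        bin_width = float(edges[1] - edges[0])
    counts, edges = np.histogram(values, bins=edges)
    if counts.sum() == 0:
        raise ValueError("histogram is empty")
    centers = 0.5 * (edges[:-1] + edges[1:])
    guess = _initial_guesses(values, model)
    peak = counts.max()

    if model == "two_gaussian":
        def f(x, k1, x1, w1, k2, x2, w2):
            return _gauss(x, k1, x1, w1) + _gauss(x, k2, x2, w2)
        p0 = [peak, guess["x1"], guess["width1"], 0.25 * peak, guess["x2"], guess["width2"]]
        names = ["k1", "x1", "width1", "k2", "x2", "width2"]
    elif model == "gaussian":
        def f(x, k1, x1, w1):
            return _gauss(x, k1, x1, w1)
        p0 = [peak, guess["x1"], guess["width1"]]
        names = ["k1", "x1", "width1"]
    elif model == "lognormal":
        def f(x, k1, x1, w1):
            return _lognorm(x, k1, x1, w1)
        p0 = [peak, guess["x1"], guess["width1"]]
        names = ["k1", "x1", "width1"]
    else:
        raise ValueError(f"unknown model {model!r}")

    lo_x, hi_x = float(values.min()), float(values.max())
    span = hi_x - lo_x or 1.0
    if model == "two_gaussian":
        lb = [0.0, lo_x - span, 1e-9, 0.0, lo_x - span, 1e-9]
        ub = [np.inf, hi_x + span, 10 * span, np.inf, hi_x + span, 10 * span]
    else:
        lb = [0.0, lo_x - span if model != "lognormal" else 1e-9, 1e-9]
        ub = [np.inf, hi_x + span, 10 * span]
    try:
        popt, _ = optimize.curve_fit(f, centers, counts, p0=p0,
                                     bounds=(lb, ub), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"histogram fit did not converge (guesses {p0})") from exc

    params = dict(zip(names, (float(v) for v in popt)))
    for key in ("width1", "width2"):
        if key in params:
            params[key] = abs(params[key])
    # order mixture components by center so peak 1 is the lower peak
    if model == "two_gaussian" and params["x1"] > params["x2"]:
        params = {"k1": params["k2"], "x1": params["x2"], "width1": params["width2"],
                  "k2": params["k1"], "x2": params["x1"], "width2": params["width1"]}
    resid = counts - f(centers, *popt)
    var = np.maximum(counts, 1.0)
    dof = max(1, counts.size - len(popt))
    chi2_per_df = float(np.sum(resid ** 2 / var) / dof)
    return HistogramFit(model=model, params=params, chi2_per_df=chi2_per_df,
                        bin_width=float(bin_width), n=int(values.size))


def _support(fit: HistogramFit, extra=(), n_widths: float = 30.0):
    """Finite integration window covering all fitted components."""
    p = fit.params
    if fit.model == "lognormal":
        lo = p["x1"] * math.exp(-4 * max(p["width1"], 0.2))
        hi = p["x1"] * math.exp(6 * max(p["width1"], 0.2))
        lo = min(lo, 1e-9)
    else:
        centers = [p["x1"]] + ([p["x2"]] if "x2" in p else [])
        widths = [p["width1"]] + ([p["width2"]] if "x2" in p else [])
        lo = min(c - n_widths * w for c, w in zip(centers, widths))
        hi = max(c + n_widths * w for c, w in zip(centers, widths))
    if extra:
        lo = min(lo, *extra)
        hi = max(hi, *extra)
    return lo, hi


def percent_abnormal(tumor_fit: HistogramFit, normal_2n: tuple[float, float],
                     region_k: float = 2.0, n: int | None = None) -> tuple[float, float]:
    """Mass of the fitted tumor density outside the normal band.

    The normal band is ``mu +/- region_k * sigma`` of the 2n reference
    Gaussian.  Returns ``(fraction, se)`` where the standard error is the
    proportion SE ``sqrt(p(1-p)/n)``.
    """
    mu, sigma = normal_2n
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lo, hi = mu - region_k * sigma, mu + region_k * sigma
    s_lo, s_hi = _support(tumor_fit, extra=(lo, hi))
    grid = np.linspace(s_lo, s_hi, 40001)
    dens = tumor_fit.density(grid)
    total = float(np.trapezoid(dens, grid))
    if total <= 0:
        raise ValueError("fitted tumor density has zero mass")
    inside = float(np.trapezoid(np.where((grid >= lo) & (grid <= hi), dens, 0.0),
                                grid))
    p = float(np.clip(1.0 - inside / total, 0.0, 1.0))
    n_eff = n if n is not None else tumor_fit.n
    se = math.sqrt(p * (1.0 - p) / n_eff) if n_eff > 0 else float("nan")
    return p, se


def proportion_se(p: float, n: int) -> float:
    """Standard error of a proportion, sqrt(p(1-p)/n)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    return math.sqrt(p * (1.0 - p) / n)


def fold_change(x: PopulationSummary, y: PopulationSummary) -> FoldChange:
    """Fold change x/y with a first-order (delta-method) variance.

    ``var_taylor = sx^2/ybar^2 + xbar^2*sy^2/ybar^4`` (covariance dropped,
    independence assumed).  Two standard-error conventions are reported:
    the literal ``sqrt(var/(nx^2+ny^2))`` and the conventional delta-method
    SE of a ratio of independent means,
    ``sqrt(sx^2/(nx*ybar^2) + xbar^2*sy^2/(ny*ybar^4))``.
    """
    if y.mean == 0:
        raise ValueError("reference mean must be nonzero")
    fold = x.mean / y.mean
    var = (x.sd ** 2) / y.mean ** 2 + (x.mean ** 2) * (y.sd ** 2) / y.mean ** 4
    se_literal = math.sqrt(var / (x.n ** 2 + y.n ** 2))
    se_conv = math.sqrt((x.sd ** 2) / (x.n * y.mean ** 2)
                        + (x.mean ** 2) * (y.sd ** 2) / (y.n * y.mean ** 4))
    return FoldChange(xbar=x.mean, ybar=y.mean, sx=x.sd, sy=y.sd,
                      nx=x.n, ny=y.n, fold=fold, var_taylor=var,
                      se=se_literal, se_conventional=se_conv)


def coefficient_of_variation(summary: PopulationSummary) -> float:
    if summary.mean == 0:
        raise ValueError("mean must be nonzero")
    return summary.sd / summary.mean
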