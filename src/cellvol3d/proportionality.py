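"""Volume-vs-ploidy proportionality classification for cells and patients.

A cell's ratio of cell volume to estimated ploidy is compared against a
wild-type band derived from the normal reference Gaussian (mean, sigma)
scaled per haploid genome.  Patients are called by a conservative compound
test: chi-square against a uniform three-way split, then a binomial test on
the sub/supra counts, then a two-fold enrichment requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from scipy import stats

__all__ = [
    "CellClass", "ProportionalityBounds", "PatientCall",
    "classify_cell", "classify_near_wt", "classify_patient",
    "NEAR_WT_VOLUME_RANGE", "NEAR_EUPLOID_RANGE",
]

NEAR_WT_VOLUME_RANGE = (455.0, 709.0)   # fL, mu_wt +/- sigma_wt
NEAR_EUPLOID_RANGE = (1.6, 4.4)         # haploid genome units, inclusive


class CellClass(str, Enum):
    SUB = "Subproportional"
    PROP = "Proportional"
    SUPRA = "Supraproportional"


@dataclass(frozen=True)
class ProportionalityBounds:
    """Wild-type volume-per-genome band.

    Slopes default to the unrounded (mu +/- sigma)/2 per haploid genome;
    ``truncate=True`` reproduces integer-truncated cutoffs.
    """
    mu_wt: float = 582.0
    sigma_wt: float = 127.0
    truncate: bool = False

    @property
    def lower_slope(self) -> float:
        v = (self.mu_wt - self.sigma_wt) / 2.0
        return float(int(v)) if self.truncate else v

    @property
    def upper_slope(self) -> float:
        v = (self.mu_wt + self.sigma_wt) / 2.0
        return float(int(v)) if self.truncate else v


@dataclass(frozen=True)
class PatientCall:
    n_sub: int
    n_prop: int
    n_supra: int
    chi2: float
    chi2_p: float
    binomial_p: float
    enrichment: float
    call: CellClass


def classify_cell(cell_volume: float, estimated_ploidy: float,
                  bounds: ProportionalityBounds = ProportionalityBounds()) -> CellClass:
    """Classify one cell by its volume-to-ploidy ratio."""
    if estimated_ploidy <= 0:
        raise ValueError("ploidy must be positive")
    ratio = cell_volume / estimated_ploidy
    if ratio < bounds.lower_slope:
        return CellClass.SUB
    if ratio > bounds.upper_slope:
        return CellClass.SUPRA
    return CellClass.PROP


def classify_near_wt(cell_volume: float, estimated_ploidy: float,
                     bounds: ProportionalityBounds = ProportionalityBounds()) -> bool:
    """True iff the cell is both in the wild-type volume window and near-euploid."""
    vlo, vhi = NEAR_WT_VOLUME_RANGE
    plo, phi = NEAR_EUPLOID_RANGE
    return (vlo <= cell_volume <= vhi) and (plo <= estimated_ploidy <= phi)


def classify_patient(counts: tuple[int, int, int], alpha: float = 0.05,
                     enrichment_fold: float = 2.0) -> PatientCall:
    """Compound decision rule on (n_sub, n_prop, n_supra) cell counts.

    1. chi-square vs a uniform 3-way split (df = 2); retain -> Proportional.
    2. two-sided binomial test of n_supra among (n_sub + n_supra) at p = 0.5;
       retain -> Proportional.
    3. the larger of sub/supra must be >= ``enrichment_fold`` times the
       smaller (a zero denominator satisfies the rule); else Proportional.
    4. the call is the direction of the larger bin.
    """
    n_sub, n_prop, n_supra = (int(c) for c in counts)
    if min(n_sub, n_prop, n_supra) < 0:
        raise ValueError("counts must be non-negative")
    total = n_sub + n_prop + n_supra
    if total == 0:
        raise ValueError("no cells to classify")

    expected = total / 3.0
    chi2 = sum((c - expected) ** 2 / expected for c in (n_sub, n_prop, n_supra))
    chi2_p = float(stats.chi2.sf(chi2, df=2))

    n_extreme = n_sub + n_supra
    if n_extreme > 0:
        binom_p = float(stats.binomtest(n_supra, n_extreme, 0.5,
                                        alternative="two-sided").pvalue)
    else:
        binom_p = 1.0

    lo, hi = sorted((n_sub, n_supra))
    enrichment = float("inf") if lo == 0 and hi > 0 else (hi / lo if lo else 1.0)

    if chi2_p > alpha or binom_p > alpha or enrichment < enrichment_fold:
        call = CellClass.PROP
    elif n_supra > n_sub:
        call = CellClass.SUPRA
    elif n_sub > n_supra:
        call = CellClass.SUB
    else:   # equal extremes can only get here with both zero -> proportional
        call = CellClass.PROP
    return PatientCall(n_sub=n_sub, n_prop=n_prop, n_supra=n_supra,
                       chi2=float(chi2), chi2_p=chi2_p, binomial_p=binom_p,
                       enrichment=enrichment, call=call)
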