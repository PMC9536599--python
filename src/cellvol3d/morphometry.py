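"""Per-cell and per-nucleus feature extraction.

The per-cell measurement table (one row per segmented cell) mirrors the
study-style spreadsheet schema: raw volumes/surfaces/shape indices plus
derived DNA and scaling columns.  Missing nucleus measurements propagate as
NaN ("not measured").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .proportionality import NEAR_EUPLOID_RANGE, NEAR_WT_VOLUME_RANGE

__all__ = [
    "RECORD_COLUMNS", "LabelFeatures", "ShellResult",
    "measure_label", "derive_record", "shell_enrichment",
    "ki67_filter", "long_axis_2d",
    "KI67_MIN_TOTAL", "KI67_MIN_SPHERICITY", "KI67_MIN_VOLUME", "CK7_MIN_TOTAL",
]

RECORD_COLUMNS = [
    "patient_id", "genotype", "stage", "stack_id", "cell_id",
    "cell_class",
    "cell_volume", "cell_surface", "cytoplasm_volume",
    "sphericity", "ellipticity_prolate", "ellipticity_oblate",
    "nuclear_volume", "nuclear_surface", "n_nuclei",
    "dna_total", "background", "stromal_mode",
    "dna_number", "estimated_ploidy", "near_euploid",
    "nc_ratio", "cell_sv_ratio", "elongation",
    "genome_concentration", "cv_over_n",
    "proportionality_class", "near_wt",
]

# Ki-67 proliferation filter cascade thresholds
KI67_MIN_TOTAL = 2e4        # strict >
KI67_MIN_SPHERICITY = 0.5   # strict >
KI67_MIN_VOLUME = 150.0     # um^3, strict >
CK7_MIN_TOTAL = 3e4         # nuclei below this are outside the tumor region


@dataclass(frozen=True)
class LabelFeatures:
    volume: float              # fL
    surface: float             # um^2
    sphericity: float
    ellipticity_prolate: float
    ellipticity_oblate: float


@dataclass(frozen=True)
class ShellResult:
    shell_width: float         # um
    shell_density: float       # intensity per voxel
    whole_density: float
    enrichment: float
    degenerate: bool = False


def _semi_axes_from_inertia(coords_um: np.ndarray) -> tuple[float, float, float]:
    """Equivalent-ellipsoid semi-axes a >= b >= c from voxel coordinates."""
    c = coords_um - coords_um.mean(axis=0)
    cov = c.T @ c / len(c)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]   # descending
    # solid ellipsoid: second moments along principal axes are axis^2/5
    axes = np.sqrt(np.clip(5.0 * evals, 0.0, None))
    return tuple(float(v) for v in axes)


def measure_label(mask: np.ndarray, voxel_size) -> LabelFeatures:
    """Volume, meshed surface area, sphericity and ellipticities of one label.

    Volume is exact voxel-count arithmetic.  Surface area comes from a
    marching-cubes mesh so digitized spheres do not exceed sphericity 1.
    Ellipticities use the inertia-tensor semi-axes a >= b >= c:
    prolate = 1 - b/a (elongation), oblate = 1 - c/b (flatness).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty label")
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    volume = float(mask.sum()) * float(np.prod(voxel_size))

    # light smoothing before meshing removes voxel staircase area
    # (raw binary marching cubes overestimates a sphere's area by ~9%);
    # sigma 0.5 keeps digitized spheres at sphericity <= 1
    padded = ndimage.gaussian_filter(np.pad(mask, 2).astype(np.float32), 0.5)
    verts, faces, *_ = measure.marching_cubes(padded, level=0.5,
                                              spacing=tuple(voxel_size))
    surface = float(measure.mesh_surface_area(verts, faces))
    sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / surface)

    coords = np.argwhere(mask) * voxel_size
    if len(coords) < 4:
        prolate = oblate = 0.0
    else:
        a, b, c = _semi_axes_from_inertia(coords)
        prolate = 1.0 - b / a if a > 0 else 0.0
        oblate = 1.0 - c / b if b > 0 else 0.0
    return LabelFeatures(volume=volume, surface=surface, sphericity=sphericity,
                         ellipticity_prolate=prolate, ellipticity_oblate=oblate)


def derive_record(cell: LabelFeatures, nucleus: LabelFeatures | None,
                  estimated_ploidy: float | None = None,
                  dna_total: float | None = None,
                  n_nuclei: int = 1, **meta) -> dict:
    """Assemble one measurement row with all derived columns filled.

    Nucleus-dependent and ploidy-dependent columns become NaN when their
    inputs are absent.  Raises if the nuclear volume exceeds the cell volume.
    """
    rec = {col: np.nan for col in RECORD_COLUMNS}
    rec.update(meta)
    rec["cell_volume"] = cell.volume
    rec["cell_surface"] = cell.surface
    rec["sphericity"] = cell.sphericity
    rec["ellipticity_prolate"] = cell.ellipticity_prolate
    rec["ellipticity_oblate"] = cell.ellipticity_oblate
    rec["cell_sv_ratio"] = cell.surface / cell.volume
    if cell.ellipticity_oblate > 0:
        rec["elongation"] = cell.ellipticity_prolate / cell.ellipticity_oblate

    if nucleus is not None:
        if nucleus.volume > cell.volume:
            raise ValueError(
                f"nuclear volume {nucleus.volume:.1f} exceeds cell volume "
                f"{cell.volume:.1f}")
        rec["nuclear_volume"] = nucleus.volume
        rec["nuclear_surface"] = nucleus.surface
        rec["n_nuclei"] = n_nuclei
        cyto = cell.volume - nucleus.volume
        rec["cytoplasm_volume"] = cyto
        rec["nc_ratio"] = nucleus.volume / cyto if cyto > 0 else np.inf

    if dna_total is not None:
        rec["dna_total"] = dna_total
    if estimated_ploidy is not None:
        rec["estimated_ploidy"] = estimated_ploidy
        rec["dna_number"] = estimated_ploidy / 2.0
        lo, hi = NEAR_EUPLOID_RANGE
        rec["near_euploid"] = bool(lo <= estimated_ploidy <= hi)
        rec["cv_over_n"] = cell.volume / estimated_ploidy
        if nucleus is not None:
            rec["genome_concentration"] = estimated_ploidy / nucleus.volume
        vlo, vhi = NEAR_WT_VOLUME_RANGE
        rec["near_wt"] = bool(vlo <= cell.volume <= vhi
                              and lo <= estimated_ploidy <= hi)
    return rec


def shell_enrichment(nucleus_mask: np.ndarray, dna: np.ndarray,
                     voxel_size, shell_width_um: float = 1.5,
                     vs_core: bool = False) -> ShellResult:
    """DNA density in the outer shell relative to the whole nucleus.

    The shell is the nucleus minus its ``shell_width_um`` erosion (euclidean
    distance transform).  By default the denominator is the whole-nucleus
    mean density; ``vs_core=True`` divides by the core (non-shell) density
    instead.  A nucleus thinner than the shell everywhere degenerates to
    enrichment 1 with a warning.
    """
    mask = np.asarray(nucleus_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty nucleus")
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    dist = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    core = dist > shell_width_um
    shell = mask & ~core
    whole_density = float(dna[mask].mean())
    if not core.any():
        warnings.warn("nucleus thinner than the shell width everywhere; "
                      "shell equals whole nucleus", stacklevel=2)
        return ShellResult(shell_width_um, whole_density, whole_density, 1.0,
                           degenerate=True)
    shell_density = float(dna[shell].mean())
    denom = float(dna[core].mean()) if vs_core else whole_density
    return ShellResult(shell_width_um, shell_density, whole_density,
                       shell_density / denom)


def ki67_filter(records, ck7_totals=None, ki67_totals=None):
    """Retain proliferating tumor nuclei by the fixed threshold cascade.

    Keeps rows with CK7 total >= 3e4 (tumor-region membership) and
    Ki-67 total > 2e4 and sphericity > 0.5 and volume > 150 um^3.
    ``records`` is a DataFrame with columns ``sphericity`` and ``volume``
    (or ``cell_volume``); totals may be columns or separate arrays.
    """
    df = records.copy()
    if ck7_totals is not None:
        df["ck7_total"] = np.asarray(ck7_totals, dtype=float)
    if ki67_totals is not None:
        df["ki67_total"] = np.asarray(ki67_totals, dtype=float)
    vol = df["volume"] if "volume" in df else df["cell_volume"]
    keep = ((df["ck7_total"] >= CK7_MIN_TOTAL)
            & (df["ki67_total"] > KI67_MIN_TOTAL)
            & (df["sphericity"] > KI67_MIN_SPHERICITY)
            & (vol > KI67_MIN_VOLUME))
    return df[keep]


def long_axis_2d(nucleus_mask: np.ndarray, voxel_size) -> float:
    """Long axis (um) of the best-fit ellipse of the z-projection."""
    mask = np.asarray(nucleus_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty label")
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if not np.isclose(voxel_size[1], voxel_size[2]):
        raise ValueError("anisotropic in-plane voxels not supported")
    proj = mask.any(axis=0).astype(np.uint8)
    props = measure.regionprops(proj)[0]
    return float(props.axis_major_length * voxel_size[1])
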