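"""3D cell-body and nucleus label volumes.

Tumor cells: marker-controlled watershed on the boundary-confidence
landscape, with seeds at approximate nuclear centroids and an exterior
marker so basins stop at the outermost confidence ridge.  Normal AT2
cells: coarse marker-channel isosurface, distance-transform erosion and
seeded splitting.  Stromal nuclei: DNA threshold, splitting, and the
edge-distance / marker-negativity filters.  Automatic QC rules replace
manual curation: edge-clipped cells (>10% of volume at the stack faces)
and cells overlapping >10% of a foreign nucleus are fatal; extreme N:C
deciles are flagged for review only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology
from skimage.segmentation import watershed

from .stack import ImageStack

__all__ = [
    "SeedSet", "QCReport", "seeds_from_marks",
    "segment_tumor_cells", "segment_at2_cells", "segment_stromal_nuclei",
    "qc_cells",
    "EDGE_CLIP_FRACTION", "NEIGHBOR_OVERLAP_FRACTION",
]

# seed radius classes (um) for 5-px and 10-px nuclear marks at 0.15 um voxels
SEED_RADIUS_SMALL = 1.6
SEED_RADIUS_LARGE = 2.75
EDGE_CLIP_FRACTION = 0.10
NEIGHBOR_OVERLAP_FRACTION = 0.10


@dataclass
class SeedSet:
    """Approximate nuclear centroids used to seed the watershed."""
    centroids_um: np.ndarray                  # (n, 3) in um, (z, y, x)
    seed_radius: float = SEED_RADIUS_SMALL    # um

    def __post_init__(self):
        self.centroids_um = np.atleast_2d(np.asarray(self.centroids_um, dtype=float))
        if self.seed_radius <= 0:
            raise ValueError("seed radius must be positive")

    def __len__(self):
        return len(self.centroids_um)

    def to_voxels(self, voxel_size) -> np.ndarray:
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        return np.round(self.centroids_um / vs).astype(int)


@dataclass
class QCReport:
    flags: pd.DataFrame     # per-label boolean columns
    passing: list = field(default_factory=list)

    def passes(self, label: int) -> bool:
        return label in self.passing


def seeds_from_marks(mark_volume: np.ndarray, voxel_size,
                     threshold: float = 0.5) -> SeedSet:
    """One seed per connected mark blob; radius class from blob size.

    Touching marks merge into one seed (with a warning when a blob is much
    larger than a single idealized mark).
    """
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    binary = np.asarray(mark_volume) > threshold
    labeled, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no marks found")
    centroids = np.asarray(ndimage.center_of_mass(binary, labeled,
                                                  np.arange(1, n + 1)))
    centroids_um = centroids * vs
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled,
                               np.arange(1, n + 1))
    voxel_vol = float(np.prod(vs))
    vol_small = 4.0 / 3.0 * np.pi * SEED_RADIUS_SMALL ** 3
    vol_large = 4.0 / 3.0 * np.pi * SEED_RADIUS_LARGE ** 3
    median_vol = float(np.median(sizes)) * voxel_vol
    radius = (SEED_RADIUS_SMALL
              if abs(median_vol - vol_small) <= abs(median_vol - vol_large)
              else SEED_RADIUS_LARGE)
    if np.any(sizes * voxel_vol > 3.0 * vol_large):
        warnings.warn("unusually large mark blob(s): touching marks were "
                      "merged into single seeds", stacklevel=2)
    return SeedSet(centroids_um=centroids_um, seed_radius=radius)


def _paint_seeds(shape, seeds_vox):
    markers = np.zeros(shape, dtype=np.int32)
    seen = {}
    for i, (z, y, x) in enumerate(seeds_vox, start=1):
        key = (int(z), int(y), int(x))
        if key in seen:
            raise ValueError(f"duplicate seeds at voxel {key}: "
                             f"{seen[key]} and {i}")
        if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
            raise ValueError(f"seed {i} at voxel {key} outside volume {shape}")
        seen[key] = i
        markers[key] = i
    return markers


def segment_tumor_cells(confidence: np.ndarray, seeds: SeedSet, voxel_size,
                        smoothing_um: float = 0.3,
                        ridge_threshold: float = 0.35,
                        max_radius_um: float = 25.0,
                        foreground: np.ndarray | None = None,
                        closing_iterations: int = 2) -> np.ndarray:
    """Seeded watershed on the smoothed boundary-confidence landscape.

    The cell-occupied foreground defaults to the morphologically closed and
    filled super-threshold ridge shell, eroded by one voxel to compensate
    the closing (slice-wise prediction leaves pinholes at polar caps, hence
    the closing).  Basins grow inside the foreground only and dividing
    lines fall on confidence ridge crests.  A seed landing outside the
    foreground (e.g. a zero-confidence volume) claims a ball of
    ``max_radius_um``; voxels beyond that radius from every seed stay
    background.
    """
    if len(seeds) == 0:
        raise ValueError("need at least one seed")
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    conf = np.asarray(confidence, dtype=float)
    sigma = smoothing_um / vs
    landscape = ndimage.gaussian_filter(conf, sigma=sigma)

    seeds_vox = seeds.to_voxels(vs)
    markers = _paint_seeds(conf.shape, seeds_vox)

    if foreground is None:
        wall = landscape >= ridge_threshold
        closed = ndimage.binary_closing(wall, structure=np.ones((3, 3, 3)),
                                        iterations=closing_iterations)
        # fill per-slice first: slice-wise rings are closed even when the 3D
        # shell has pinholes at the polar caps of a cell
        filled = np.zeros_like(closed)
        for z in range(closed.shape[0]):
            filled[z] = ndimage.binary_fill_holes(closed[z])
        filled = ndimage.binary_fill_holes(filled)
        foreground = ndimage.binary_erosion(filled)
    else:
        foreground = np.asarray(foreground).astype(bool)

    dist_to_seed = ndimage.distance_transform_edt(markers == 0, sampling=vs)
    orphan = [tuple(p) for p in seeds_vox if not foreground[tuple(p)]]
    if orphan:
        orphan_mask = np.ones(conf.shape, dtype=bool)
        for p in orphan:
            orphan_mask[p] = False
        orphan_dist = ndimage.distance_transform_edt(orphan_mask, sampling=vs)
        foreground = foreground | (orphan_dist <= max_radius_um)
    foreground &= dist_to_seed <= max_radius_um

    labels = watershed(landscape, markers=markers, mask=foreground)
    return labels.astype(np.int32)


def _split_by_seeds(binary: np.ndarray, voxel_size, seed_spacing_um: float,
                    prominence_um: float = 1.0):
    """Split a binary region at prominent distance-transform maxima.

    Marker candidates are h-maxima of the EDT (prominence >= 1 um), so a
    single ragged body is not shattered; candidates closer together than
    the seed spacing collapse into one marker.
    """
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    dist = ndimage.distance_transform_edt(binary, sampling=vs)
    peaks_mask = morphology.h_maxima(dist, prominence_um)
    peak_labels, n_peaks = ndimage.label(peaks_mask)
    if n_peaks == 0:
        labeled, _ = ndimage.label(binary)
        return labeled
    centroids = np.asarray(ndimage.center_of_mass(
        peaks_mask, peak_labels, np.arange(1, n_peaks + 1)))
    # merge candidates closer than the seed spacing
    kept: list[np.ndarray] = []
    for c in centroids:
        if all(np.linalg.norm((c - k) * vs) >= seed_spacing_um for k in kept):
            kept.append(c)
    markers = np.zeros(binary.shape, dtype=np.int32)
    for i, c in enumerate(kept, start=1):
        markers[tuple(np.round(c).astype(int))] = i
    return watershed(-dist, markers=markers, mask=binary).astype(np.int32)


def segment_at2_cells(stack: ImageStack, spc_threshold: float = 10.0,
                      erosion_um: float = 0.7,
                      split_seed_diameter_um: float = 5.0,
                      coarse_smoothing_um: float = 1.0,
                      min_volume_fl: float = 50.0) -> np.ndarray:
    """Masked-threshold/erosion pipeline for normal AT2 cell bodies.

    Coarse isosurface on the smoothed SPC channel (captures cell bodies
    plus nearby space, dilated by the smoothing), then 3D erosion via the
    distance transform to trim inappropriately included neighbors (kept
    minimal, 0.7 um default), then a per-slice hole fill (the SPC marker is
    cytoplasmic, leaving a nuclear void), then seeded splitting.  Fragments
    below process scale (``min_volume_fl``) are removed.
    """
    if not stack.has_channel("SPC"):
        raise KeyError("SPC channel required for AT2 segmentation")
    vs = np.asarray(stack.voxel_size, dtype=float)
    spc = stack.channel("SPC").astype(float)
    if spc.max() <= spc_threshold:
        warnings.warn("SPC channel below threshold everywhere; no AT2 cells",
                      stacklevel=2)
        return np.zeros(stack.shape, dtype=np.int32)
    smoothed = ndimage.gaussian_filter(spc, sigma=coarse_smoothing_um / vs)
    coarse = smoothed >= spc_threshold
    if erosion_um > 0:
        dist_in = ndimage.distance_transform_edt(coarse, sampling=vs)
        eroded = dist_in >= erosion_um
    else:
        eroded = coarse
    body = np.stack([ndimage.binary_fill_holes(eroded[z])
                     for z in range(eroded.shape[0])])
    labels = _split_by_seeds(body, vs, split_seed_diameter_um)
    voxel_vol = float(np.prod(vs))
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        if (labels == lbl).sum() * voxel_vol < min_volume_fl:
            labels[labels == lbl] = 0
    return labels


def segment_stromal_nuclei(stack: ImageStack, dna_threshold: float,
                           edge_margin_um: float = 4.0,
                           split_seed_diameter_um: float = 3.0,
                           ck7_max_mean: float = 10.0,
                           smoothing_um: float = 0.3,
                           min_volume_fl: float = 20.0) -> np.ndarray:
    """DNA-thresholded stromal (control) nuclei.

    Nuclei are split with ~3 um seeds, then filtered: every voxel must lie
    at least ``edge_margin_um`` from the stack faces and the mean CK7
    intensity inside must stay below ``ck7_max_mean`` (CK7-negative).
    """
    vs = np.asarray(stack.voxel_size, dtype=float)
    dna = ndimage.gaussian_filter(stack.channel("DNA").astype(float),
                                  sigma=smoothing_um / vs)
    binary = dna >= dna_threshold
    labels = _split_by_seeds(binary, vs, split_seed_diameter_um)
    if labels.max() == 0:
        return labels

    edge = np.zeros(stack.shape, dtype=bool)
    margins = np.maximum(1, np.round(edge_margin_um / vs).astype(int))
    edge[:margins[0]] = edge[-margins[0]:] = True
    edge[:, :margins[1]] = edge[:, -margins[1]:] = True
    edge[:, :, :margins[2]] = edge[:, :, -margins[2]:] = True

    ck7 = stack.channel("CK7").astype(float) if stack.has_channel("CK7") else None
    voxel_vol = float(np.prod(vs))
    out = np.zeros_like(labels)
    next_id = 1
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        region = labels == lbl
        if region.sum() * voxel_vol < min_volume_fl:
            continue
        if (region & edge).any():
            continue
        if ck7 is not None:
            # CK7 stains cytoplasm/boundaries, not the nucleus itself, so
            # the negativity test looks at a dilated neighborhood
            hood = ndimage.binary_dilation(
                region, iterations=max(1, int(round(1.5 / float(vs.min())))))
            if ck7[hood].mean() > ck7_max_mean:
                continue
        out[region] = next_id
        next_id += 1
    return out


def qc_cells(cell_labels: np.ndarray, nucleus_labels: np.ndarray,
             voxel_size=1.0,
             edge_clip_fraction: float = EDGE_CLIP_FRACTION,
             neighbor_overlap_fraction: float = NEIGHBOR_OVERLAP_FRACTION) -> QCReport:
    """Automatic quality screening of matched cell/nucleus labels.

    Fatal: >10% of a cell's volume in the outermost face layer, or a cell
    overlapping >10% of any foreign nucleus.  N:C ratios in the top or
    bottom decile are flagged for review (not fatal), mirroring a curation
    round that deleted only models that also failed visual checks.
    """
    ids = np.unique(cell_labels)
    ids = ids[ids > 0]
    face = np.zeros(cell_labels.shape, dtype=bool)
    face[0] = face[-1] = True
    face[:, 0] = face[:, -1] = True
    face[:, :, 0] = face[:, :, -1] = True

    nuc_sizes = {int(l): int((nucleus_labels == l).sum())
                 for l in np.unique(nucleus_labels) if l > 0}

    rows = []
    nc_ratios = {}
    for lbl in ids:
        region = cell_labels == lbl
        vol = int(region.sum())
        edge_clipped = (region & face).sum() > edge_clip_fraction * vol

        overlap_violation = False
        touched = np.unique(nucleus_labels[region])
        for nl in touched:
            nl = int(nl)
            if nl == 0 or nl == lbl:
                continue
            overlap = int((region & (nucleus_labels == nl)).sum())
            if overlap > neighbor_overlap_fraction * nuc_sizes.get(nl, np.inf):
                overlap_violation = True
                break

        own_nuc = nuc_sizes.get(int(lbl), 0)
        cyto = vol - min(own_nuc, vol)
        nc_ratios[int(lbl)] = own_nuc / cyto if cyto > 0 else np.inf

        n_own_components = ndimage.label(nucleus_labels == lbl)[1]
        rows.append({"label": int(lbl), "edge_clipped": bool(edge_clipped),
                     "nucleus_overlap_violation": bool(overlap_violation),
                     "multinucleate": n_own_components > 1,
                     "nc_ratio": nc_ratios[int(lbl)]})

    df = pd.DataFrame(rows).set_index("label") if rows else pd.DataFrame(
        columns=["edge_clipped", "nucleus_overlap_violation", "multinucleate",
                 "nc_ratio"])
    if len(df):
        finite = df["nc_ratio"].replace(np.inf, np.nan).dropna()
        if len(finite) >= 10:
            lo, hi = finite.quantile([0.1, 0.9])
            df["nc_ratio_extreme"] = (df["nc_ratio"] < lo) | (df["nc_ratio"] > hi)
        else:
            df["nc_ratio_extreme"] = False
        df["pass"] = ~(df["edge_clipped"] | df["nucleus_overlap_violation"])
        passing = df.index[df["pass"]].tolist()
    else:
        df["nc_ratio_extreme"] = []
        df["pass"] = []
        passing = []
    return QCReport(flags=df, passing=passing)
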