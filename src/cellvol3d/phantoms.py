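"""Synthetic inputs with known ground truth.

Four generators: 3D labeled phantom stacks (cells + nuclei with channel
content mimicking the staining roles), measurement tables shaped like the
per-cell spreadsheet, flow-cytometry event tables, and 2D boundary
annotation pairs for training the boundary predictor.

Conventions: coordinates are voxel-indexed, 0-based, z-major; physical
conversions always go through the voxel size; 1 fL = 1 um^3.  All
randomness flows through the explicit per-spec seed.  Intensity-to-ploidy
coupling is exactly linear before noise; depth attenuation is linear in z;
measurement noise is multiplicative lognormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.segmentation import find_boundaries

from .morphometry import RECORD_COLUMNS
from .stack import ImageStack

__all__ = [
    "CellTruth", "PhantomSpec", "PopulationSpec", "FlowGroup",
    "generate_phantom_stack", "generate_measurement_table",
    "generate_flow_events", "generate_annotation_pairs",
    "sphere_radius_for_volume",
]

# channel intensity levels (8-bit scale)
DNA_TOTAL_PER_GENOME = 8e4      # integrated DNA intensity per haploid genome
CK7_BOUNDARY_LEVEL = 140.0
CK7_CYTO_LEVEL = 25.0
SPC_PUNCTA_LEVEL = 160.0
SPC_CYTO_LEVEL = 30.0
LMN_SHELL_LEVEL = 110.0
CAVITY_FRACTION = 0.10          # of nuclear volume, when has_cavity


def sphere_radius_for_volume(volume_fl: float) -> float:
    """Radius (um) of a sphere with the given volume (fL = um^3)."""
    return (3.0 * volume_fl / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class CellTruth:
    """Ground truth for one phantom cell."""
    center: tuple[float, float, float]      # um, (z, y, x)
    cell_volume: float                      # fL
    nuclear_volume: float                   # fL
    ploidy: float = 2.0
    shape: str = "sphere"                   # 'sphere' | 'ellipsoid'
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cell_class: str = "tumor"               # 'AT2' | 'tumor' | 'stromal'
    has_cavity: bool = False

    def __post_init__(self):
        if self.nuclear_volume >= self.cell_volume:
            raise ValueError("nuclear volume must be below cell volume")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")

    def semi_axes(self, volume: float) -> tuple[float, float, float]:
        """Semi-axes (um) of a sphere/ellipsoid of the given volume."""
        r = sphere_radius_for_volume(volume)
        if self.shape == "sphere":
            return (r, r, r)
        ratios = np.asarray(self.axis_ratios, dtype=float)
        scale = r / ratios.prod() ** (1.0 / 3.0)
        return tuple(float(v) for v in ratios * scale)


@dataclass
class PhantomSpec:
    stack_shape: tuple[int, int, int]       # voxels (z, y, x)
    voxel_size: tuple[float, float, float]  # um per axis (z, y, x)
    cells: list[CellTruth] = field(default_factory=list)
    attenuation_factor: float = 1.0         # top/bottom DNA intensity ratio
    background_level: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    include_lamin: bool = True
    overlap_tolerance: float = 0.0          # allowed overlapping voxel fraction

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")
        if self.attenuation_factor <= 0:
            raise ValueError("attenuation factor must be positive")
        extent = np.asarray(self.stack_shape) * np.asarray(self.voxel_size)
        for i, cell in enumerate(self.cells):
            if not all(0 <= c < e for c, e in zip(cell.center, extent)):
                raise ValueError(f"cell {i} center {cell.center} outside stack "
                                 f"extent {tuple(extent)}")


def _ellipsoid_mask(shape, voxel_size, center, semi_axes):
    zz, yy, xx = np.meshgrid(
        *(np.arange(n) * v for n, v in zip(shape, voxel_size)), indexing="ij")
    return (((zz - center[0]) / semi_axes[0]) ** 2
            + ((yy - center[1]) / semi_axes[1]) ** 2
            + ((xx - center[2]) / semi_axes[2]) ** 2) <= 1.0


def generate_phantom_stack(spec: PhantomSpec):
    """Render a phantom stack and its ground-truth label volumes.

    Returns ``(stack, cell_labels, nucleus_labels)``; label value i+1 marks
    cell ``spec.cells[i]``.  Per-nucleus integrated DNA intensity (before
    attenuation, background and noise) is exactly proportional to ploidy.
    The SPC channel is not attenuated (mirrors the green channel's observed
    behavior); CK7, DNA and LMN dim linearly with depth down to
    1/attenuation_factor at the bottom plane.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.stack_shape)
    vs = spec.voxel_size
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    spc = np.zeros(shape)
    ck7 = np.zeros(shape)
    dna = np.zeros(shape)
    lmn = np.zeros(shape)

    claimed = np.zeros(shape, dtype=bool)
    collisions: list[tuple[int, int]] = []
    for i, cell in enumerate(spec.cells, start=1):
        body = _ellipsoid_mask(shape, vs, cell.center, cell.semi_axes(cell.cell_volume))
        overlap = body & claimed
        if overlap.sum() > spec.overlap_tolerance * body.sum():
            prior = set(np.unique(cell_labels[overlap])) - {0}
            collisions.extend((int(p), i) for p in prior)
        claimed |= body
        cell_labels[body & (cell_labels == 0)] = i

        nuc = _ellipsoid_mask(shape, vs, cell.center,
                              cell.semi_axes(cell.nuclear_volume))
        nuc &= body
        nucleus_labels[nuc & (nucleus_labels == 0)] = i

        cyto = body & ~nuc
        n_nuc = int(nuc.sum())
        if n_nuc:
            cavity = np.zeros(shape, dtype=bool)
            if cell.has_cavity:
                cav_vol = CAVITY_FRACTION * cell.nuclear_volume
                cavity = _ellipsoid_mask(shape, vs, cell.center,
                                         cell.semi_axes(cav_vol)) & nuc
            n_bright = n_nuc - int(cavity.sum())
            total = cell.ploidy * DNA_TOTAL_PER_GENOME
            dna[nuc & ~cavity] = total / max(n_bright, 1)

        if cell.cell_class == "tumor":
            interior = _ellipsoid_mask(
                shape, vs, cell.center,
                tuple(max(a - 2 * max(vs), 0.1) for a in cell.semi_axes(cell.cell_volume)))
            ck7[body & ~interior] = CK7_BOUNDARY_LEVEL
            ck7[cyto & interior] = np.maximum(ck7[cyto & interior], CK7_CYTO_LEVEL)
        elif cell.cell_class == "AT2":
            spc[cyto] = SPC_CYTO_LEVEL
            n_puncta = max(3, int(cyto.sum() * 0.02))
            idx = np.flatnonzero(cyto)
            if idx.size:
                chosen = rng.choice(idx, size=min(n_puncta, idx.size), replace=False)
                flat = spc.reshape(-1)
                flat[chosen] = SPC_PUNCTA_LEVEL

        if spec.include_lamin and n_nuc:
            shell = nuc & ~_ellipsoid_mask(
                shape, vs, cell.center,
                tuple(max(a - max(vs), 0.05) for a in cell.semi_axes(cell.nuclear_volume)))
            lmn[shell] = LMN_SHELL_LEVEL

    if collisions:
        raise ValueError(f"overlapping cells beyond tolerance: "
                         f"{sorted(set(collisions))}")

    # linear depth attenuation: gain 1 at z=0 down to 1/factor at the bottom
    n_z = shape[0]
    if n_z > 1:
        gain = 1.0 - (1.0 - 1.0 / spec.attenuation_factor) * (
            np.arange(n_z) / (n_z - 1))
    else:
        gain = np.ones(1)
    gain = gain[:, None, None]
    channels = {"SPC": spc, "CK7": ck7 * gain, "DNA": dna * gain}
    if spec.include_lamin:
        channels["LMN"] = lmn * gain

    data = np.stack(list(channels.values()))
    data = data + spec.background_level
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None).astype(np.float32)
    roles = {name: i for i, name in enumerate(channels)}
    stack = ImageStack(data=data, voxel_size=vs, channel_roles=roles,
                       stack_id=f"phantom-{spec.rng_seed}")
    return stack, cell_labels, nucleus_labels


def demo_phantom_spec(shape=(64, 64, 64), voxel_size=0.5, n_cells: int = 5,
                      rng_seed: int = 0, cell_class: str = "tumor",
                      ploidies=(2.0, 2.0, 4.0, 4.0, 8.0),
                      attenuation_factor: float = 1.0,
                      noise_sd: float = 0.0) -> PhantomSpec:
    """Non-overlapping grid of spherical cells with mixed ploidies.

    Cell volumes ramp from ~600 fL upward with ploidy; includes one stromal
    reference cell per four tumor cells when space allows.
    """
    rng = np.random.default_rng(rng_seed)
    vs = (voxel_size,) * 3 if np.isscalar(voxel_size) else tuple(voxel_size)
    extent = np.asarray(shape) * np.asarray(vs)
    cells = []
    # grid placement with jitter, largest spacing that fits n_cells
    n_side = max(1, int(math.ceil(n_cells ** (1 / 3))))
    pitch = extent / n_side
    slots = [(i, j, k) for i in range(n_side) for j in range(n_side)
             for k in range(n_side)][:n_cells]
    for idx, slot in enumerate(slots):
        ploidy = ploidies[idx % len(ploidies)]
        volume = 300.0 * ploidy * float(rng.uniform(0.9, 1.1))
        max_r = 0.45 * float(pitch.min())
        volume = min(volume, 4.0 / 3.0 * math.pi * max_r ** 3 * 0.9)
        center = (np.asarray(slot) + 0.5) * pitch \
            + rng.uniform(-0.05, 0.05, 3) * pitch
        cells.append(CellTruth(center=tuple(center), cell_volume=volume,
                               nuclear_volume=0.35 * volume, ploidy=ploidy,
                               cell_class=cell_class))
    return PhantomSpec(stack_shape=tuple(shape), voxel_size=vs, cells=cells,
                       attenuation_factor=attenuation_factor,
                       noise_sd=noise_sd, rng_seed=rng_seed)


@dataclass
class PopulationSpec:
    """Mixture specification for a synthetic per-cell measurement table."""
    n_normal: int = 0
    normal_peak1: tuple[float, float] = (582.0, 127.0)    # fL cell volume
    normal_peak2: tuple[float, float] = (1164.0, 180.0)
    peak2_fraction: float = 0.15
    nuclear_peak1: tuple[float, float] = (202.0, 34.2)    # fL nuclear volume
    n_tumor: int = 0
    tumor_model: str = "lognormal"                         # or 'gaussian'
    tumor_params: tuple[float, float] = (7.0, 0.55)        # lognormal: (mu, sigma) of log
    ploidy_mix: tuple = ((2.0, 0.6), (4.0, 0.4))
    proportionality_mode: str | None = None                # 'sub'|'proportional'|'supra'
    slope_multiplier: float = 1.0
    n_stromal: int = 0
    stromal_mode: float = 2 * DNA_TOTAL_PER_GENOME         # 2n DNA total
    dna_noise_cv: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_normal, self.n_tumor, self.n_stromal) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.peak2_fraction <= 1.0:
            raise ValueError("peak2_fraction must be in [0, 1]")
        if abs(sum(f for _, f in self.ploidy_mix) - 1.0) > 1e-9:
            raise ValueError("ploidy fractions must sum to 1")


def _lognormal_noise(rng, cv, size):
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    return rng.lognormal(-0.5 * sigma ** 2, sigma, size=size)


def generate_measurement_table(spec: PopulationSpec) -> pd.DataFrame:
    """Sample a measurement table with the standard per-cell column schema.

    Normal cells come from the two-Gaussian cell-volume mixture (peak 2
    treated as the 4n population); tumor cells from the configured model.
    DNA totals are ploidy/2 x stromal mode x multiplicative lognormal noise.
    When a proportionality mode is set, tumor volume is generated as
    slope x ploidy so the downstream cell classification is controlled:
    slope = slope_multiplier x (582/2) fL per haploid genome.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rows = []

    n2 = rng.binomial(spec.n_normal, spec.peak2_fraction) if spec.n_normal else 0
    n1 = spec.n_normal - n2
    for count, (mu, sd), ploidy in ((n1, spec.normal_peak1, 2.0),
                                    (n2, spec.normal_peak2, 4.0)):
        if count == 0:
            continue
        vols = rng.normal(mu, sd, size=count)
        nuc_scale = spec.nuclear_peak1[0] / spec.normal_peak1[0]
        nuc_sd = spec.nuclear_peak1[1] / spec.normal_peak1[1]
        nvols = vols * nuc_scale + rng.normal(
            0.0, spec.nuclear_peak1[1] * 0.3, size=count)
        nvols *= (ploidy / 2.0) ** 0  # nuclear peak scales through vols already
        nvols = np.clip(nvols, 10.0, vols * 0.9)
        del nuc_sd
        rows.append(_records(vols, nvols, np.full(count, ploidy),
                             "AT2", spec, rng))

    if spec.n_tumor:
        ploidies, fracs = zip(*spec.ploidy_mix)
        counts = rng.multinomial(spec.n_tumor, fracs)
        p_arr = np.repeat(ploidies, counts).astype(float)
        rng.shuffle(p_arr)
        if spec.proportionality_mode is not None:
            slope = spec.slope_multiplier * spec.normal_peak1[0] / 2.0
            vols = slope * p_arr * _lognormal_noise(rng, 0.10, spec.n_tumor)
        elif spec.tumor_model == "lognormal":
            mu, sigma = spec.tumor_params
            vols = rng.lognormal(mu, sigma, size=spec.n_tumor)
        elif spec.tumor_model == "gaussian":
            mu, sigma = spec.tumor_params
            vols = rng.normal(mu, sigma, size=spec.n_tumor)
        else:
            raise ValueError(f"unknown tumor model {spec.tumor_model!r}")
        vols = np.clip(vols, 50.0, None)
        nvols = np.clip(vols * 0.42 * _lognormal_noise(rng, 0.15, spec.n_tumor),
                        10.0, vols * 0.9)
        rows.append(_records(vols, nvols, p_arr, "tumor", spec, rng))

    if spec.n_stromal:
        vols = rng.normal(300.0, 40.0, size=spec.n_stromal)
        nvols = np.clip(rng.normal(120.0, 15.0, size=spec.n_stromal), 10.0,
                        vols * 0.9)
        rows.append(_records(vols, nvols, np.full(spec.n_stromal, 2.0),
                             "stromal", spec, rng))

    if not rows:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    df = pd.concat(rows, ignore_index=True)
    df["cell_id"] = np.arange(1, len(df) + 1)
    return df[RECORD_COLUMNS]


def _records(vols, nvols, ploidies, cell_class, spec, rng):
    n = len(vols)
    dna_totals = (ploidies / 2.0) * spec.stromal_mode * _lognormal_noise(
        rng, spec.dna_noise_cv, n)
    df = pd.DataFrame({col: np.nan for col in RECORD_COLUMNS}, index=range(n))
    df["cell_class"] = cell_class
    df["cell_volume"] = vols
    df["nuclear_volume"] = nvols
    df["cytoplasm_volume"] = vols - nvols
    df["nc_ratio"] = nvols / (vols - nvols)
    df["n_nuclei"] = 1
    df["dna_total"] = dna_totals
    df["stromal_mode"] = spec.stromal_mode
    df["dna_number"] = dna_totals / spec.stromal_mode
    df["estimated_ploidy"] = 2.0 * df["dna_number"]
    df["near_euploid"] = df["estimated_ploidy"].between(1.6, 4.4)
    df["cv_over_n"] = vols / df["estimated_ploidy"]
    df["genome_concentration"] = df["estimated_ploidy"] / nvols
    df["patient_id"] = "synthetic"
    df["genotype"] = "normal" if cell_class != "tumor" else "EGFR"
    df["stage"] = 0 if cell_class != "tumor" else 1
    df["stack_id"] = f"table-{spec.rng_seed}"
    return df


@dataclass(frozen=True)
class FlowGroup:
    """One homogeneous event population for the flow-event generator."""
    area_um2: float
    ploidy: float
    live: bool = True
    epcam: bool = True
    fraction: float = 1.0


def generate_flow_events(n: int, populations, rng_seed: int = 0,
                         intercept: float = -159.0, slope: float = 4.35,
                         noise_cv: float = 0.0) -> pd.DataFrame:
    """Synthesize scatter/fluorescence events from area/ploidy groups.

    SSC-W inverts the linear area model ``area = intercept + slope*ssc_w``;
    DRAQ5 is proportional to ploidy.  Returns a DataFrame with the standard
    event columns plus ``group`` and ``true_area``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    fracs = np.array([g.fraction for g in populations], dtype=float)
    fracs = fracs / fracs.sum()
    rng = np.random.default_rng(rng_seed)
    counts = rng.multinomial(n, fracs)
    frames = []
    for gi, (group, count) in enumerate(zip(populations, counts)):
        if count == 0:
            continue
        ssc_w = (group.area_um2 - intercept) / slope * _lognormal_noise(
            rng, noise_cv, count)
        draq5 = 100.0 * (group.ploidy / 2.0) * _lognormal_noise(
            rng, max(noise_cv, 1e-12), count)
        zombie = (rng.normal(40.0, 8.0, count) if group.live
                  else rng.normal(220.0, 15.0, count))
        epcam = (rng.normal(180.0, 15.0, count) if group.epcam
                 else rng.normal(15.0, 4.0, count))
        frames.append(pd.DataFrame({
            "ssc_h": rng.normal(120.0, 25.0, count),
            "ssc_w": ssc_w,
            "fsc_a": group.area_um2 * _lognormal_noise(rng, max(noise_cv, 0.02), count),
            "ssc_a": group.area_um2 * 1.3 * _lognormal_noise(rng, max(noise_cv, 0.02), count),
            "zombie_red": np.clip(zombie, 0, None),
            "epcam": np.clip(epcam, 0, None),
            "draq5": draq5,
            "group": gi,
            "true_area": group.area_um2,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_annotation_pairs(stack: ImageStack, cell_labels: np.ndarray,
                              channel: str = "CK7"):
    """Slice-wise (image, boundary-mask) training pairs.

    The mask marks 1-voxel-wide label interfaces (inner boundaries, so
    touching cells are marked on both contours); slices without any cell
    are excluded.
    """
    if cell_labels.max() == 0:
        raise ValueError("label volume is empty")
    img = stack.channel(channel)
    pairs = []
    for z in range(cell_labels.shape[0]):
        plane = cell_labels[z]
        if not plane.any():
            continue
        mask = find_boundaries(plane, mode="inner").astype(np.float32)
        pairs.append((img[z].astype(np.float32), mask))
    return pairs
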