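"""Synthetic confocal-like retinal sections and qPCR Ct tables with ground truth.

Scenes are layered strata (ONL/INL/GCL-like bands) of DAPI nuclei, a
PCNA-positive nuclear subset, and leukocyte cell bodies, rendered as filled
per-plane ellipses, blurred by a Gaussian PSF and corrupted by Poisson shot
noise plus Gaussian read noise. Every cell is recorded exactly (centroid,
area, channel memberships, per-channel label maps), so downstream counting
can be validated against known truth.

Each simulated cell is rendered on exactly one z-plane; per-plane counts
therefore sum to the ground-truth totals.

qPCR tables follow the relative-quantification generative model
``Ct(sample, gene) = baseline - programmed_log2_fold - loading_offset + noise``
where the per-sample loading offset is shared by all genes (so the
target-minus-reference difference cancels it exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import draw

from .errors import CapacityError, ConfigurationError
from .imaging import ImageStack

__all__ = [
    "SceneConfig",
    "CellRecord",
    "GroundTruth",
    "QpcrDesign",
    "generate_section",
    "generate_qpcr",
    "DEFAULT_LAYER_BANDS",
]

CHANNELS = ("DAPI", "PCNA", "Lplastin", "HuCD", "TUNEL")
REFERENCE_GENE = "18s"
MAX_PLACEMENT_RETRIES = 1000

DEFAULT_LAYER_BANDS = [("ONL", 20, 80), ("INL", 100, 160), ("GCL", 180, 240)]


@dataclass
class SceneConfig:
    """Parameters of one synthetic retinal-section scene.

    Defaults give a well-separated, high-SNR scene; the source study reports
    neither imaging SNR nor cell densities, so none of these values claims to
    match it.
    """

    image_height_px: int = 260
    image_width_px: int = 620
    n_z: int = 1
    pixel_size_um: float = 0.5
    layer_bands: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(DEFAULT_LAYER_BANDS)
    )
    n_nuclei_per_layer: int = 50
    nucleus_radius_um: tuple[float, float] = (3.0, 0.3)
    pcna_positive_fraction: float = 0.3
    n_leukocytes: int = 0
    leukocyte_radius_um: tuple[float, float] = (5.0, 0.5)
    leukocyte_nuclear_pcna_fraction: float = 0.0
    tunel_positive_fraction: float = 0.0
    hucd_positive_fraction: float = 0.0
    psf_sigma_um: float = 0.4
    background_level: float = 0.1
    photon_scale: float = 200.0
    read_noise_sd: float = 0.05
    shot_noise: bool = True
    min_center_separation_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.photon_scale <= 0:
            raise ConfigurationError("photon_scale must be > 0")
        for name, value in [
            ("psf_sigma_um", self.psf_sigma_um),
            ("background_level", self.background_level),
            ("read_noise_sd", self.read_noise_sd),
            ("min_center_separation_um", self.min_center_separation_um),
            ("nucleus radius mean", self.nucleus_radius_um[0]),
            ("nucleus radius sd", self.nucleus_radius_um[1]),
            ("leukocyte radius mean", self.leukocyte_radius_um[0]),
            ("leukocyte radius sd", self.leukocyte_radius_um[1]),
        ]:
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name, frac in [
            ("pcna_positive_fraction", self.pcna_positive_fraction),
            ("leukocyte_nuclear_pcna_fraction", self.leukocyte_nuclear_pcna_fraction),
            ("tunel_positive_fraction", self.tunel_positive_fraction),
            ("hucd_positive_fraction", self.hucd_positive_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        prev_end = -1
        for name, r0, r1 in sorted(self.layer_bands, key=lambda b: b[1]):
            if r0 >= r1:
                raise ConfigurationError(f"band {name!r}: empty row range")
            if r0 <= prev_end:
                raise ConfigurationError(f"band {name!r} overlaps the previous band")
            if r0 < 0 or r1 > self.image_height_px:
                raise ConfigurationError(f"band {name!r} outside the image")
            prev_end = r1


@dataclass
class CellRecord:
    cell_id: int
    klass: str  # "nucleus" | "leukocyte"
    z: int
    centroid: tuple[float, float]
    area_px: int
    channels: frozenset[str]
    layer: str = ""


@dataclass
class GroundTruth:
    """Exact per-cell simulation records plus per-channel label maps."""

    cells: list[CellRecord]
    label_maps: dict[str, np.ndarray]  # channel -> int32 (n_z, H, W)
    counts: dict[str, int] = field(default_factory=dict)

    def count(self, channels: str | tuple[str, ...]) -> int:
        """Number of cells whose channel set contains every named channel."""
        if isinstance(channels, str):
            channels = tuple(p for p in channels.split("∧"))
        want = set(channels)
        return sum(1 for c in self.cells if want <= c.channels)

    def cells_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": c.cell_id,
                "class": c.klass,
                "z": c.z,
                "centroid_row": c.centroid[0],
                "centroid_col": c.centroid[1],
                "area_px": c.area_px,
                "layer": c.layer,
                "channels": "|".join(sorted(c.channels)),
            }
            for c in self.cells
        )

    def write(self, cells_path: str | Path, counts_path: str | Path | None = None) -> None:
        self.cells_to_frame().to_csv(cells_path, index=False)
        if counts_path is not None:
            pd.DataFrame(
                [{"combo": k, "count": v} for k, v in sorted(self.counts.items())]
            ).to_csv(counts_path, index=False)


def _summary_counts(cells: list[CellRecord]) -> dict[str, int]:
    singles = sorted({ch for c in cells for ch in c.channels})
    combos: list[tuple[str, ...]] = [(s,) for s in singles]
    for pair in [("DAPI", "PCNA"), ("Lplastin", "PCNA"), ("HuCD", "DAPI"), ("TUNEL", "DAPI")]:
        if set(pair) <= set(singles):
            combos.append(pair)
    out = {}
    for combo in combos:
        key = "∧".join(combo)
        out[key] = sum(1 for c in cells if set(combo) <= c.channels)
    return out


def _ellipse_px(
    center: tuple[float, float],
    radius_px: float,
    ratio: float,
    theta: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    return draw.ellipse(
        center[0], center[1], radius_px, radius_px * ratio, shape=shape, rotation=theta
    )


class _Placer:
    """Rejection sampler enforcing center separation and footprint disjointness."""

    def __init__(self, rng: np.random.Generator, shape: tuple[int, int], min_sep_px: float):
        self.rng = rng
        self.shape = shape
        self.min_sep = min_sep_px
        self.centers: list[tuple[float, float]] = []

    def place(
        self,
        row_range: tuple[float, float],
        col_range: tuple[float, float],
        radius_px: float,
        ratio: float,
        theta: float,
        occupancy: list[np.ndarray],
        what: str,
    ) -> tuple[tuple[float, float], tuple[np.ndarray, np.ndarray]]:
        r_lo = max(row_range[0] + radius_px, radius_px)
        r_hi = min(row_range[1] - radius_px, self.shape[0] - radius_px)
        c_lo = max(col_range[0] + radius_px, radius_px)
        c_hi = min(col_range[1] - radius_px, self.shape[1] - radius_px)
        if r_hi <= r_lo or c_hi <= c_lo:
            raise CapacityError(f"{what}: radius {radius_px:.1f}px does not fit the band")
        for _ in range(MAX_PLACEMENT_RETRIES):
            center = (
                float(self.rng.uniform(r_lo, r_hi)),
                float(self.rng.uniform(c_lo, c_hi)),
            )
            if self.centers:
                arr = np.asarray(self.centers)
                if np.min(np.hypot(arr[:, 0] - center[0], arr[:, 1] - center[1])) < self.min_sep:
                    continue
            rr, cc = _ellipse_px(center, radius_px, ratio, theta, self.shape)
            if rr.size == 0:
                continue
            if any(occ[rr, cc].any() for occ in occupancy):
                continue
            self.centers.append(center)
            return center, (rr, cc)
        raise CapacityError(
            f"{what}: no admissible position after {MAX_PLACEMENT_RETRIES} retries "
            "(too many cells for min_center_separation?)"
        )


def generate_section(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic section and its exact ground truth.

    Channels DAPI, PCNA and Lplastin are always present; TUNEL and HuCD are
    added when their positive fractions are non-zero. The noiseless PCNA
    footprint of a PCNA-positive nucleus equals its DAPI footprint, so
    pre-blur containment holds pixelwise.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_assign, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    h, w = config.image_height_px, config.image_width_px
    px = config.pixel_size_um

    channels = ["DAPI", "PCNA", "Lplastin"]
    if config.tunel_positive_fraction > 0:
        channels.append("TUNEL")
    if config.hucd_positive_fraction > 0:
        channels.append("HuCD")
    label_maps = {ch: np.zeros((config.n_z, h, w), dtype=np.int32) for ch in channels}

    placer = _Placer(rng_place, (h, w), config.min_center_separation_um / px)
    cells: list[CellRecord] = []
    next_id = 1

    def stamp(ch: str, z: int, rr: np.ndarray, cc: np.ndarray, cid: int) -> None:
        label_maps[ch][z][rr, cc] = cid

    # layer nuclei
    for band_name, row0, row1 in config.layer_bands:
        for _ in range(config.n_nuclei_per_layer):
            radius = max(1.0, rng_place.normal(*config.nucleus_radius_um) / px)
            ratio = rng_place.uniform(0.7, 1.0)
            theta = rng_place.uniform(0.0, np.pi)
            z = int(rng_assign.integers(config.n_z))
            occ = [label_maps["DAPI"][z]]
            center, (rr, cc) = placer.place(
                (row0, row1), (0, w), radius, ratio, theta, occ, f"nucleus in {band_name}"
            )
            cid = next_id
            next_id += 1
            stamp("DAPI", z, rr, cc, cid)
            chans = {"DAPI"}
            if rng_assign.random() < config.pcna_positive_fraction:
                stamp("PCNA", z, rr, cc, cid)
                chans.add("PCNA")
            if (
                config.tunel_positive_fraction > 0
                and rng_assign.random() < config.tunel_positive_fraction
            ):
                stamp("TUNEL", z, rr, cc, cid)
                chans.add("TUNEL")
            if (
                config.hucd_positive_fraction > 0
                and rng_assign.random() < config.hucd_positive_fraction
            ):
                ring_rr, ring_cc = _ellipse_px(center, radius * 1.6, ratio, theta, (h, w))
                nucleus = np.zeros((h, w), dtype=bool)
                nucleus[rr, cc] = True
                ring = np.zeros((h, w), dtype=bool)
                ring[ring_rr, ring_cc] = True
                ring &= ~nucleus
                ring &= label_maps["HuCD"][z] == 0
                rrr, ccc = np.nonzero(ring)
                stamp("HuCD", z, rrr, ccc, cid)
                chans.add("HuCD")
            cells.append(
                CellRecord(cid, "nucleus", z, center, int(rr.size), frozenset(chans), band_name)
            )

    # leukocytes: ellipse body (Lplastin) containing a DAPI nucleus
    for _ in range(config.n_leukocytes):
        radius = max(1.5, rng_place.normal(*config.leukocyte_radius_um) / px)
        ratio = rng_place.uniform(0.7, 1.0)
        theta = rng_place.uniform(0.0, np.pi)
        z = int(rng_assign.integers(config.n_z))
        occ = [label_maps["Lplastin"][z], label_maps["DAPI"][z]]
        center, (rr, cc) = placer.place((0, h), (0, w), radius, ratio, theta, occ, "leukocyte")
        cid = next_id
        next_id += 1
        stamp("Lplastin", z, rr, cc, cid)
        nrr, ncc = _ellipse_px(center, radius * 0.5, ratio, theta, (h, w))
        stamp("DAPI", z, nrr, ncc, cid)
        chans = {"Lplastin", "DAPI"}
        if rng_assign.random() < config.leukocyte_nuclear_pcna_fraction:
            stamp("PCNA", z, nrr, ncc, cid)
            chans.add("PCNA")
        cells.append(
            CellRecord(cid, "leukocyte", z, center, int(rr.size), frozenset(chans))
        )

    # render: ideal = background + unit-amplitude footprints, PSF, shot+read noise
    from scipy import ndimage as ndi  # local import keeps module load light

    dtype_max = 65535.0
    pixels = np.zeros((len(channels), config.n_z, h, w), dtype=np.float64)
    psf_sigma_px = config.psf_sigma_um / px
    for ci, ch in enumerate(channels):
        for z in range(config.n_z):
            ideal = config.background_level + (label_maps[ch][z] > 0).astype(float)
            if psf_sigma_px > 0:
                ideal = ndi.gaussian_filter(ideal, psf_sigma_px)
            plane = ideal
            if config.shot_noise:
                plane = rng_noise.poisson(plane * config.photon_scale) / config.photon_scale
            if config.read_noise_sd > 0:
                plane = plane + rng_noise.normal(0.0, config.read_noise_sd, plane.shape)
            pixels[ci, z] = np.clip(plane, 0.0, dtype_max)

    stack = ImageStack(
        pixels=pixels.astype(np.float32),
        channel_names=channels,
        pixel_size_um=px,
        z_step_um=2.0,
        dtype_max=dtype_max,
    )
    truth = GroundTruth(cells=cells, label_maps=label_maps, counts=_summary_counts(cells))
    return stack, truth


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

GroupKey = tuple[str, str, int]  # (line, treatment, dpi)


@dataclass
class QpcrDesign:
    """Design of a simulated qPCR experiment.

    ``programmed_log2_fold`` maps ``(gene, (line, treatment, dpi))`` to the
    log2 fold change relative to the matched saline group; entries default to
    0 and must be 0 for the reference gene.
    """

    genes: list[str]
    groups: list[GroupKey]
    n_biological: int = 6
    n_technical: int = 3
    baseline_ct: dict[str, float] = field(default_factory=dict)
    programmed_log2_fold: dict[tuple[str, GroupKey], float] = field(default_factory=dict)
    ct_noise_sd: float = 0.0
    reference_drift_sd: float = 0.0
    nondetect_ct_limit: float = 40.0
    dropout_prob: float = 0.0
    reference_gene: str = REFERENCE_GENE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_gene not in self.genes:
            raise ConfigurationError(
                f"reference gene {self.reference_gene!r} missing from genes"
            )
        if self.ct_noise_sd < 0 or self.reference_drift_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError("dropout_prob must be in [0, 1]")
        if self.n_biological < 1 or self.n_technical < 1:
            raise ConfigurationError("need at least one replicate of each kind")
        for (gene, group), val in self.programmed_log2_fold.items():
            if gene == self.reference_gene and val != 0.0:
                raise ConfigurationError(
                    f"reference gene programmed fold must be 0, got {val} for {group}"
                )
        for gene in self.genes:
            self.baseline_ct.setdefault(gene, 25.0 if gene != self.reference_gene else 12.0)


def generate_qpcr(design: QpcrDesign) -> pd.DataFrame:
    """Simulate a replicate-level Ct table.

    Columns: sample_id, line, treatment, dpi, gene, tech_rep, ct, nondetect.
    ``ct`` is NaN where ``nondetect`` is True. A replicate is non-detect if
    its (noisy) Ct exceeds the cycle limit or by the optional dropout draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(1)[0])
    rows = []
    for line, treatment, dpi in design.groups:
        group: GroupKey = (line, treatment, dpi)
        for b in range(design.n_biological):
            sample_id = f"{line}|{treatment}|{dpi}dpi|s{b + 1}"
            loading = (
                rng.normal(0.0, design.reference_drift_sd)
                if design.reference_drift_sd > 0
                else 0.0
            )
            for gene in design.genes:
                fold = design.programmed_log2_fold.get((gene, group), 0.0)
                true_ct = design.baseline_ct[gene] - fold - loading
                for rep in range(design.n_technical):
                    ct = true_ct + (
                        rng.normal(0.0, design.ct_noise_sd)
                        if design.ct_noise_sd > 0
                        else 0.0
                    )
                    nondetect = ct > design.nondetect_ct_limit or (
                        design.dropout_prob > 0 and rng.random() < design.dropout_prob
                    )
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "line": line,
                            "treatment": treatment,
                            "dpi": dpi,
                            "gene": gene,
                            "tech_rep": rep + 1,
                            "ct": np.nan if nondetect else float(ct),
                            "nondetect": bool(nondetect),
                        }
                    )
    return pd.DataFrame(rows)
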