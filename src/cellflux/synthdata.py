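"""Synthetic well images, flux plates and calibration data with ground truth.

Every generator here emits data in exactly the formats the analysis
modules consume, together with a complete ground-truth record, so the
whole pipeline is testable without any real plate data. Images emulate
brightfield wells: a smooth bright background (constant, linear gradient
or 2-D quadratic) with dark, soft-edged disks for cells and additive
Gaussian noise. Flux plates emulate the five-phase mito-stress-test trace
anatomy: per-phase true rate levels scaled by each well's cell content,
plus per-cycle Gaussian noise.

No attempt is made at photorealistic brightfield rendering; the point is
controlled structure, not optics.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationPoint
from .fluxmetrics import PHASES, FluxTrace, InjectionSchedule

__all__ = [
    "ImageSynthParams",
    "TraceSynthParams",
    "synth_well_image",
    "synth_flux_plate",
    "synth_calibration_points",
    "plate_wells",
    "DEFAULT_OCR_LEVELS",
    "DEFAULT_ECAR_LEVELS",
]

#: Default true OCR levels per phase (pmol/min at the reference cell number).
#: Basal around 100 pmol/min sits inside the 28-110 pmol/min range observed
#: for viable primary epithelial preparations; the oligomycin response is
#: deliberately modest and the proton leak large, matching the trace anatomy
#: of primary gut epithelium, and 2-DG removes a further slice of
#: non-mitochondrial respiration.
DEFAULT_OCR_LEVELS = {
    "basal": 100.0,
    "post_om": 55.0,
    "post_fccp": 160.0,
    "post_rotaa": 20.0,
    "post_2dg": 12.0,
}

#: Default true ECAR levels per phase (mpH/min at the reference cell number):
#: a modest glycolytic compensation after oligomycin, collapse after 2-DG.
DEFAULT_ECAR_LEVELS = {
    "basal": 30.0,
    "post_om": 35.0,
    "post_fccp": 32.0,
    "post_rotaa": 28.0,
    "post_2dg": 5.0,
}


def plate_wells(n: int) -> list[str]:
    """First ``n`` wells of a 96-well plate in row-major order (A01..H12)."""
    if not 0 <= n <= 96:
        raise ValueError("a 96-well plate has 0..96 wells")
    return [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)][:n]


# ---------------------------------------------------------------------------
# Well images


@dataclass(frozen=True)
class ImageSynthParams:
    """Parameters of the synthetic brightfield well image generator.

    ``n_cells`` is the number of rendered blobs; real wells carry tens of
    thousands of cells, so fixtures use area-scaled counts. ``darkness``
    is the intensity drop of a cell below the local background and must
    exceed the noise s.d. for fixtures meant to be detectable.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 100
    radius_range: tuple[float, float] = (2.0, 4.0)
    darkness: float = 60.0
    background: str = "constant"  # constant | gradient | poly
    background_level: float = 200.0
    gradient_amplitude: float = 30.0
    noise_sd: float = 2.0
    overlap_allowed: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.background not in ("constant", "gradient", "poly"):
            raise ValueError(f"unknown background model {self.background!r}")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("invalid radius range")


def _background(params: ImageSynthParams) -> np.ndarray:
    h, w = params.shape
    if params.background == "constant":
        return np.full((h, w), params.background_level, dtype=np.float64)
    cols = np.linspace(-0.5, 0.5, w)
    if params.background == "gradient":
        return params.background_level + params.gradient_amplitude * np.tile(cols, (h, 1))
    rows = np.linspace(-0.5, 0.5, h)[:, None]
    # smooth 2-D quadratic vignette, brighter in the center
    return params.background_level - params.gradient_amplitude * (rows**2 + cols[None, :] ** 2)


def synth_well_image(params: ImageSynthParams) -> tuple[np.ndarray, dict]:
    """Render one synthetic well image and its ground truth.

    Cells are disks of uniformly sampled radius with a 1-pixel linear
    intensity falloff at the rim (soft edges exercise thresholding
    behavior); overlapping cells occlude rather than stack. Returns the
    image (float64, clipped to 0-255) and a truth dict with the cell
    count, centers and radii.

    Raises if overlap is disallowed and the requested cells cannot be
    placed without contact.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    bg = _background(params)
    depth = np.zeros((h, w), dtype=np.float64)

    r_lo, r_hi = params.radius_range
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    margin = r_hi + 1.0
    tries = 0
    while len(centers) < params.n_cells:
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        r = rng.uniform(r_lo, r_hi)
        if not params.overlap_allowed:
            if any((cy - y) ** 2 + (cx - x) ** 2 < (r + rr + 1.0) ** 2 for (y, x), rr in zip(centers, radii)):
                tries += 1
                if tries > 200 * max(params.n_cells, 1):
                    raise ValueError(
                        f"cannot place {params.n_cells} non-overlapping cells in {params.shape}"
                    )
                continue
        centers.append((cy, cx))
        radii.append(r)

    for (cy, cx), r in zip(centers, radii):
        y0 = max(int(np.floor(cy - r - 2)), 0)
        y1 = min(int(np.ceil(cy + r + 2)) + 1, h)
        x0 = max(int(np.floor(cx - r - 2)), 0)
        x1 = min(int(np.ceil(cx + r + 2)) + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        # full depth inside radius r, linear falloff over one pixel at the rim
        profile = params.darkness * np.clip(r + 1.0 - d, 0.0, 1.0)
        np.maximum(depth[y0:y1, x0:x1], profile, out=depth[y0:y1, x0:x1])

    image = bg - depth
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 255.0)
    truth = {
        "n_cells": params.n_cells,
        "centers": centers,
        "radii": radii,
        "params": params,
    }
    return image, truth


# ---------------------------------------------------------------------------
# Flux plates


@dataclass(frozen=True)
class TraceSynthParams:
    """Parameters of the synthetic flux-plate generator.

    Each subject gets ``wells_per_subject`` wells; each well's cell count
    is drawn log-normally around ``mean_cells`` with coefficient of
    variation ``cell_cv`` (log-normal keeps counts positive with a
    controllable CV, mimicking pipetting variation). A well's true rate
    profile is the phase-level profile scaled by
    ``(subject rate factor) * (cells / mean_cells)``; per-cycle
    observations add Gaussian noise of s.d. ``noise_sd``. Subject rate
    factors are log-normal with CV ``subject_rate_cv`` around 1; the
    default 0 makes true per-cell rates identical across subjects, the
    cleanest setting for studying what cell-count normalization removes.
    """

    ocr_levels: dict = field(default_factory=lambda: dict(DEFAULT_OCR_LEVELS))
    ecar_levels: dict = field(default_factory=lambda: dict(DEFAULT_ECAR_LEVELS))
    noise_sd: float = 3.0
    schedule: InjectionSchedule = field(default_factory=InjectionSchedule)
    n_subjects: int = 7
    wells_per_subject: int = 8
    cell_cv: float = 0.25
    mean_cells: float = 100_000.0
    subject_rate_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for levels in (self.ocr_levels, self.ecar_levels):
            if any(v < 0 for v in levels.values()):
                raise ValueError("phase levels must be non-negative")
            unknown = set(levels) - set(PHASES)
            if unknown:
                raise ValueError(f"levels for unknown phases: {sorted(unknown)}")
        if self.n_subjects * self.wells_per_subject > 96:
            raise ValueError("plate capacity (96 wells) exceeded")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 log-normal multipliers with the requested coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def synth_flux_plate(
    params: TraceSynthParams,
) -> tuple[list[FluxTrace], pd.DataFrame, dict]:
    """Simulate one plate of flux traces with a layout and full ground truth.

    Returns ``(traces, layout, truth)``: the per-well traces, a layout
    DataFrame (plate_id, well, subject_id, group, seeded_cells) and a
    truth dict holding per-well true cell counts, per-subject rate
    factors, and the noise-free phase levels per well.
    """
    rng = np.random.default_rng(params.seed)
    sched = params.schedule
    n_wells = params.n_subjects * params.wells_per_subject
    wells = plate_wells(n_wells)
    subject_ids = [f"S{i + 1:02d}" for i in range(params.n_subjects)]

    subj_factor = _lognormal_factor(rng, params.subject_rate_cv, params.n_subjects)
    cell_factor = _lognormal_factor(rng, params.cell_cv, n_wells)
    true_cells = params.mean_cells * cell_factor

    phase_labels = sched.phase_labels()
    times = sched.times_min()
    traces: list[FluxTrace] = []
    layout_rows = []
    well_truth = {}
    for j, well in enumerate(wells):
        s = j // params.wells_per_subject
        scale = subj_factor[s] * cell_factor[j]
        ocr_true = np.array([params.ocr_levels[p] for p in phase_labels]) * scale
        ecar_true = np.array([params.ecar_levels[p] for p in phase_labels]) * scale
        ocr = ocr_true + rng.normal(0.0, params.noise_sd, size=sched.n_cycles)
        ecar = ecar_true + rng.normal(0.0, params.noise_sd, size=sched.n_cycles)
        traces.append(
            FluxTrace(
                well_id=well,
                cycles=np.arange(1, sched.n_cycles + 1),
                time_min=times,
                ocr=ocr,
                ecar=ecar,
                phases=list(phase_labels),
            )
        )
        layout_rows.append(
            {
                "plate_id": "sim1",
                "well": well,
                "subject_id": subject_ids[s],
                "group": "sim",
                "seeded_cells": params.mean_cells,
            }
        )
        well_truth[well] = {
            "true_cells": float(true_cells[j]),
            "subject_id": subject_ids[s],
            "scale": float(scale),
            "ocr_levels": {p: float(params.ocr_levels[p] * scale) for p in params.ocr_levels},
            "ecar_levels": {p: float(params.ecar_levels[p] * scale) for p in params.ecar_levels},
        }

    layout = pd.DataFrame(
        layout_rows, columns=["plate_id", "well", "subject_id", "group", "seeded_cells"]
    )
    truth = {
        "wells": well_truth,
        "subject_factors": dict(zip(subject_ids, subj_factor.astype(float))),
        "params": params,
    }
    return traces, layout, truth


# ---------------------------------------------------------------------------
# Calibration data


def synth_calibration_points(
    densities: tuple[float, ...] = (50_000.0, 75_000.0, 100_000.0, 150_000.0),
    replicates: int = 4,
    n_subjects: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
    pixels_per_cell: float = 0.01,
    saturation: float = 2e-8,
) -> tuple[list[CalibrationPoint], dict]:
    """Standard-curve points emulating a pooled multi-subject calibration.

    The default design covers four seeding densities from 50,000 to
    150,000 cells/well with four replicate wells per density and three
    subjects. The pixel response is mildly saturating,
    ``p = pixels_per_cell * cells - saturation * cells^2`` (denser wells
    overlap more, so pixels grow sublinearly), with multiplicative
    Gaussian noise of CV ``noise_cv`` on the observed pixels. Returns the
    points and a truth dict mapping each point to its noise-free pixel
    value.
    """
    rng = np.random.default_rng(seed)
    points: list[CalibrationPoint] = []
    true_pixels: list[float] = []
    for s in range(n_subjects):
        for cells in densities:
            p_true = pixels_per_cell * cells - saturation * cells**2
            if p_true <= 0:
                raise ValueError("pixel response non-positive; check saturation")
            for _ in range(replicates):
                p_obs = p_true * (1.0 + rng.normal(0.0, noise_cv))
                points.append(
                    CalibrationPoint(
                        cell_pixels=max(p_obs, 0.0),
                        seeded_cells=cells,
                        subject_id=f"S{s + 1:02d}",
                    )
                )
                true_pixels.append(p_true)
    truth = {
        "true_pixels": true_pixels,
        "densities": densities,
        "pixels_per_cell": pixels_per_cell,
        "saturation": saturation,
    }
    return points, truth
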