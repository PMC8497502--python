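"""Quadratic calibration from cell-pixels to cell number.

Standard-curve wells are seeded at known densities, imaged, and quantified
to cell-pixels; a second-order polynomial ``cells = a*p^2 + b*p + c`` is
fitted by ordinary least squares with cell-pixels as the predictor, pooling
all subjects' points into a single external curve. Fitting cells as the
response (rather than inverting a pixels-on-cells fit) lets new wells be
converted to cell numbers by direct evaluation, with no quadratic
root-solving. The curve is applied to every plate; no per-plate calibration
is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "InsufficientDataError",
    "fit_calibration",
    "predict_cells",
    "load_points_csv",
]


class InsufficientDataError(ValueError):
    """Too few (distinct) calibration points for a quadratic fit."""


class RankDeficiencyError(ValueError):
    """The quadratic design matrix is numerically rank deficient."""


@dataclass(frozen=True)
class CalibrationPoint:
    cell_pixels: float
    seeded_cells: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.cell_pixels < 0 or self.seeded_cells < 0:
            raise ValueError("cell_pixels and seeded_cells must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted quadratic ``cells = a*p^2 + b*p + c`` with fit diagnostics."""

    a: float
    b: float
    c: float
    r_squared: float
    n_points: int
    pixel_min: float
    pixel_max: float

    @property
    def pixel_range(self) -> tuple[float, float]:
        return (self.pixel_min, self.pixel_max)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "a": self.a,
                    "b": self.b,
                    "c": self.c,
                    "r_squared": self.r_squared,
                    "n_points": self.n_points,
                    "pixel_min": self.pixel_min,
                    "pixel_max": self.pixel_max,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            a=float(d["a"]),
            b=float(d["b"]),
            c=float(d["c"]),
            r_squared=float(d["r_squared"]),
            n_points=int(d["n_points"]),
            pixel_min=float(d["pixel_min"]),
            pixel_max=float(d["pixel_max"]),
        )


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationCurve:
    """Least-squares quadratic fit of seeded cells on cell-pixels.

    Subjects are pooled by plain concatenation; no per-subject weighting.
    Requires at least three points with at least three distinct predictor
    values (a quadratic through fewer is under-determined).
    """
    if len(points) < 3:
        raise InsufficientDataError(f"need >= 3 calibration points, got {len(points)}")
    p = np.array([pt.cell_pixels for pt in points], dtype=np.float64)
    y = np.array([pt.seeded_cells for pt in points], dtype=np.float64)
    if np.unique(p).size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct cell-pixel values, got {np.unique(p).size}"
        )
    design = np.column_stack([p**2, p, np.ones_like(p)])
    if np.linalg.matrix_rank(design) < 3:
        raise RankDeficiencyError("degenerate quadratic design matrix")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        n_points=len(points),
        pixel_min=float(p.min()),
        pixel_max=float(p.max()),
    )


def predict_cells(
    curve: CalibrationCurve,
    cell_pixels: float | np.ndarray,
    *,
    with_flags: bool = False,
):
    """Convert cell-pixel values to estimated cell numbers.

    Evaluates the quadratic and clips negative predictions to zero (cell
    numbers are physical counts). With ``with_flags=True`` also returns
    boolean arrays ``clipped`` and ``extrapolated``; extrapolation (a
    pixel value outside the fitted range) warns but never fails, since
    plates may legitimately contain sparse wells.
    """
    p = np.asarray(cell_pixels, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("cell_pixels must be non-negative")
    raw = curve.a * p**2 + curve.b * p + curve.c
    clipped = raw < 0
    extrapolated = (p < curve.pixel_min) | (p > curve.pixel_max)
    value = np.where(clipped, 0.0, raw)
    if np.isscalar(cell_pixels) or np.ndim(cell_pixels) == 0:
        value = float(value)
        clipped = bool(clipped)
        extrapolated = bool(extrapolated)
    if with_flags:
        return value, {"clipped": clipped, "extrapolated": extrapolated}
    return value


def load_points_csv(path: str | Path) -> list[CalibrationPoint]:
    """Read calibration points from CSV with columns subject_id,cell_pixels,seeded_cells."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"subject_id", "cell_pixels", "seeded_cells"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    return [
        CalibrationPoint(
            cell_pixels=float(r.cell_pixels),
            seeded_cells=float(r.seeded_cells),
            subject_id=str(r.subject_id),
        )
        for r in df.itertuples()
    ]
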