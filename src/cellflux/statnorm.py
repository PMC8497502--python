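"""Per-cell normalization and cohort variation statistics.

Flux rates scale with the number of cells actually present in a well,
which varies despite careful seeding. Each well's metric is therefore
re-expressed per reference cell number (default 100,000, the plating
target) using the image-derived cell estimate:

    normalized = value * reference_cells / estimated_cells

Two variation statistics quantify the benefit. Within a subject, each
well's standard score

    z = (well - mean(all wells per subject)) / s.d.(all wells per subject)

uses the sample (n-1) standard deviation; the subject-level summary is the
arithmetic mean of |z| (signed scores average to zero by construction).
Between subjects, the coefficient of variation of the subject means,
100 * s.d. / mean, measures cohort spread. Wells failing the basal-OCR
detection limit never contribute to subject means; wells lacking an image
are excluded from normalized summaries rather than back-filled from
seeded counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fluxmetrics import WellMetrics

__all__ = [
    "REFERENCE_CELLS",
    "ZeroVarianceError",
    "InsufficientWellsError",
    "load_layout_csv",
    "normalize_metric",
    "zscore_wells",
    "cohort_cv",
    "energetic_phenotype",
    "summarize_cohort",
    "CohortSummary",
]

#: Default reference cell number: the plating target of 100,000 cells/well.
REFERENCE_CELLS = 100_000.0


class ZeroVarianceError(ValueError):
    """All wells of a subject have the same value; z-scores are undefined."""


class InsufficientWellsError(ValueError):
    """Fewer wells/subjects than the statistic needs."""


LAYOUT_COLUMNS = ["plate_id", "well", "subject_id", "group", "seeded_cells"]


def load_layout_csv(path: str | Path) -> pd.DataFrame:
    """Read a plate layout CSV (plate_id,well,subject_id,group,seeded_cells)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "subject_id": str, "group": str})
    missing = set(LAYOUT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"layout CSV missing columns: {sorted(missing)}")
    if df["subject_id"].isna().any() or (df["subject_id"].astype(str).str.len() == 0).any():
        raise ValueError("layout contains empty subject_id")
    return df


def normalize_metric(
    value: float | np.ndarray,
    estimated_cells: float | np.ndarray,
    reference_cells: float = REFERENCE_CELLS,
) -> float | np.ndarray:
    """Re-express a rate per ``reference_cells`` cells."""
    if not reference_cells > 0:
        raise ValueError("reference_cells must be positive")
    est = np.asarray(estimated_cells, dtype=np.float64)
    if np.any(est <= 0):
        raise ValueError("estimated_cells must be positive; flag such wells un-normalizable")
    out = np.asarray(value, dtype=np.float64) * reference_cells / est
    return float(out) if np.ndim(value) == 0 and np.ndim(estimated_cells) == 0 else out


def zscore_wells(values: Sequence[float]) -> np.ndarray:
    """Standard scores of one subject's wells (sample s.d., n-1)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise InsufficientWellsError(f"need >= 2 wells for z-scores, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("zero within-subject s.d.; z-scores undefined")
    return (v - v.mean()) / sd


def cohort_cv(subject_means: Sequence[float]) -> float:
    """Between-subject coefficient of variation, in percent."""
    m = np.asarray(subject_means, dtype=np.float64)
    if m.size < 2:
        raise InsufficientWellsError(f"need >= 2 subjects for CV, got {m.size}")
    mean = m.mean()
    if mean == 0:
        raise ZeroDivisionError("cohort mean is zero; CV undefined")
    return float(100.0 * m.std(ddof=1) / mean)


def energetic_phenotype(
    metrics: WellMetrics,
    ocr_midpoint: float = 50.0,
    ecar_midpoint: float = 10.0,
) -> dict:
    """(OCR, ECAR) coordinates of the basal and stressed states.

    The basal point is (basal OCR, basal ECAR); the stressed point is
    (maximal OCR, post-oligomycin ECAR) when those phases were run. Each
    point gets a quadrant label relative to configurable axis midpoints:
    'energetic' (high/high), 'aerobic' (high OCR only), 'glycolytic'
    (high ECAR only) or 'quiescent'.
    """

    def quadrant(ocr: float, ecar: float) -> str:
        hi_o, hi_e = ocr >= ocr_midpoint, ecar >= ecar_midpoint
        if hi_o and hi_e:
            return "energetic"
        if hi_o:
            return "aerobic"
        if hi_e:
            return "glycolytic"
        return "quiescent"

    if metrics.basal_ocr is None or metrics.basal_ecar is None:
        raise ValueError("basal metrics required for the energetic phenotype")
    out = {
        "basal": (metrics.basal_ocr, metrics.basal_ecar),
        "basal_quadrant": quadrant(metrics.basal_ocr, metrics.basal_ecar),
        "stressed": None,
        "stressed_quadrant": None,
    }
    if metrics.max_ocr is not None and metrics.post_om_ecar is not None:
        out["stressed"] = (metrics.max_ocr, metrics.post_om_ecar)
        out["stressed_quadrant"] = quadrant(metrics.max_ocr, metrics.post_om_ecar)
    return out


@dataclass(frozen=True)
class CohortSummary:
    """Per-subject and cohort-level summary of one metric."""

    per_subject: pd.DataFrame  # subject_id, n_wells, mean, sd, mean_abs_z
    cv_percent: Optional[float]
    metric: str
    normalized: bool
    well_scores: pd.DataFrame  # well-level values and z-scores


def summarize_cohort(
    metrics_df: pd.DataFrame,
    layout: pd.DataFrame,
    metric: str = "basal_ocr",
    estimated_cells: Optional[pd.Series] = None,
    reference_cells: float = REFERENCE_CELLS,
) -> CohortSummary:
    """Summarize one metric across a cohort of subjects.

    ``metrics_df`` is a :func:`cellflux.fluxmetrics.metrics_table` frame
    (must contain ``well_id``, the metric column, and ``qc_pass``);
    ``layout`` maps wells to subjects. If ``estimated_cells`` (indexed by
    well id) is given, the metric is normalized per reference cell number
    first, and wells without an estimate are dropped from the summary.

    QC-failing wells are excluded everywhere. Subjects with a single
    remaining well keep their mean but get no z-scores; a subject with
    zero within-subject variance raises :class:`ZeroVarianceError`.
    """
    normalized = estimated_cells is not None
    df = metrics_df.merge(
        layout[["well", "subject_id"]], left_on="well_id", right_on="well", how="inner"
    )
    df = df[df["qc_pass"].astype(bool) & df[metric].notna()].copy()
    value_col = metric
    if normalized:
        df["estimated_cells"] = df["well_id"].map(estimated_cells)
        df = df[df["estimated_cells"].notna() & (df["estimated_cells"] > 0)]
        df[f"{metric}_per_{int(reference_cells)}"] = normalize_metric(
            df[metric].to_numpy(), df["estimated_cells"].to_numpy(), reference_cells
        )
        value_col = f"{metric}_per_{int(reference_cells)}"

    per_subject_rows = []
    score_rows = []
    for subject, g in df.groupby("subject_id", sort=True):
        vals = g[value_col].to_numpy(dtype=np.float64)
        row = {
            "subject_id": subject,
            "n_wells": len(vals),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            "mean_abs_z": np.nan,
        }
        if len(vals) >= 2:
            z = zscore_wells(vals)
            row["mean_abs_z"] = float(np.abs(z).mean())
            for well, v, zi in zip(g["well_id"], vals, z):
                score_rows.append(
                    {"subject_id": subject, "well_id": well, "value": float(v), "z": float(zi)}
                )
        else:
            for well, v in zip(g["well_id"], vals):
                score_rows.append(
                    {"subject_id": subject, "well_id": well, "value": float(v), "z": np.nan}
                )
        per_subject_rows.append(row)

    per_subject = pd.DataFrame(
        per_subject_rows, columns=["subject_id", "n_wells", "mean", "sd", "mean_abs_z"]
    )
    cv = None
    if len(per_subject) >= 2 and per_subject["mean"].mean() != 0:
        cv = cohort_cv(per_subject["mean"].to_numpy())
    return CohortSummary(
        per_subject=per_subject,
        cv_percent=cv,
        metric=metric,
        normalized=normalized,
        well_scores=pd.DataFrame(score_rows, columns=["subject_id", "well_id", "value", "z"]),
    )
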