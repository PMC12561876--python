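"""End-to-end runs: images in, per-image metrics and cohort reports out.

This is the library layer behind the CLI.  It reads stent ROI images
(PNG/TIFF, 8- or 16-bit grayscale, or pre-binarized), runs the preprocessing
chain and both curvature metrics, writes per-image metrics CSV rows, and
joins pre/post rows into paired cohorts for the statistical battery.
Per-image failures are recorded as flagged rows and never abort a cohort run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .centerline import Centerline, binarize, extract_centerline, extract_contour, trim_ends
from .cohortstats import CohortReport, PairedCohort, analyze_cohort
from .morphology import algorithm1_change, algorithm1_profile, algorithm2_slope

logger = logging.getLogger("stentmorph")

__all__ = [
    "RunConfig",
    "load_grayscale",
    "image_to_centerline",
    "analyze_image",
    "analyze_manifest",
    "centerlines_to_frame",
    "cohort_reports_from_metrics",
    "report_to_dict",
]

METRIC_COLUMNS = [
    "patient_id",
    "timepoint",
    "alg1_mean_angle_deg",
    "alg2_abs_sum",
    "alg2_mean_abs",
    "n_points",
    "k",
    "trim_fraction",
    "status",
]


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings; the defaults reproduce the published protocol.

    5% end trim, 100 segments, two-tailed tests at alpha = 0.05.  ``pi_approx``
    is the constant in the radian-to-degree conversion (set 3.14 to reproduce
    output of software that hard-codes it).  ``roi_rect`` is an optional
    half-open (row0, col0, row1, col1) crop applied before binarization.
    """

    trim_fraction: float = 0.05
    k_segments: int = 100
    binarize_threshold: float | str = "auto"
    angle_mode: str = "both"
    slope_statistic: str = "both"
    pi_approx: float = math.pi
    alpha: float = 0.05
    seed: int = 0
    roi_rect: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.angle_mode not in ("consecutive", "cross_timepoint", "both"):
            raise ValueError(f"unknown angle_mode {self.angle_mode!r}")
        if self.slope_statistic not in ("mean_abs", "abs_sum", "both"):
            raise ValueError(f"unknown slope_statistic {self.slope_statistic!r}")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError(f"trim_fraction must be in [0, 0.5), got {self.trim_fraction}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_rect"] = list(self.roi_rect) if self.roi_rect is not None else None
        return d


def load_grayscale(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as a 2-D grayscale array."""
    with Image.open(path) as im:
        if im.mode not in ("L", "I", "I;16", "F"):
            im = im.convert("L")
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    return arr


def image_to_centerline(image: np.ndarray, config: RunConfig) -> Centerline:
    """Preprocessing chain: ROI crop, binarize, contour, centerline, trim."""
    if config.roi_rect is not None:
        r0, c0, r1, c1 = config.roi_rect
        image = image[r0:r1, c0:c1]
        if image.size == 0:
            raise ValueError("ROI rectangle selects an empty region")
    mask = binarize(image, config.binarize_threshold)
    cl = extract_centerline(extract_contour(mask))
    return trim_ends(cl, config.trim_fraction)


def analyze_image(
    image: np.ndarray, config: RunConfig, patient_id: str = "", timepoint: str = ""
) -> tuple[dict, Centerline]:
    """Metrics row for one image: mean segment angle plus slope summaries."""
    cl = image_to_centerline(image, config)
    profile = algorithm1_profile(cl, k=config.k_segments, pi_value=config.pi_approx)
    slope = algorithm2_slope(cl)
    row = {
        "patient_id": patient_id,
        "timepoint": timepoint,
        "alg1_mean_angle_deg": profile.mean_deg,
        "alg2_abs_sum": slope.abs_sum,
        "alg2_mean_abs": slope.mean_abs,
        "n_points": len(cl),
        "k": config.k_segments,
        "trim_fraction": config.trim_fraction,
        "status": "ok",
    }
    return row, cl


def _failed_row(patient_id: str, timepoint: str, config: RunConfig, err: Exception) -> dict:
    return {
        "patient_id": patient_id,
        "timepoint": timepoint,
        "alg1_mean_angle_deg": float("nan"),
        "alg2_abs_sum": float("nan"),
        "alg2_mean_abs": float("nan"),
        "n_points": 0,
        "k": config.k_segments,
        "trim_fraction": config.trim_fraction,
        "status": f"error: {err}",
    }


def centerlines_to_frame(centerlines: dict[tuple[str, str], Centerline]) -> pd.DataFrame:
    """Flatten extracted centerlines into a (patient_id, timepoint, axial_px,
    lateral_px) frame, the on-disk centerline format."""
    frames = [
        pd.DataFrame(
            {"patient_id": pid, "timepoint": tp, "axial_px": cl.axial, "lateral_px": cl.lateral}
        )
        for (pid, tp), cl in centerlines.items()
    ]
    cols = ["patient_id", "timepoint", "axial_px", "lateral_px"]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)


def analyze_manifest(
    manifest: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], Centerline], int]:
    """Analyze every image of a cohort manifest.

    ``manifest`` needs columns patient_id, pre_path, post_path.  Returns the
    per-image metrics frame (one row per patient and timepoint, failures
    flagged in ``status``), a per-patient frame of cross-timepoint mean
    segment-angle changes (empty unless ``angle_mode`` includes it), the
    extracted centerlines keyed by (patient_id, timepoint), and the failure
    count.
    """
    required = {"patient_id", "pre_path", "post_path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    rows: list[dict] = []
    change_rows: list[dict] = []
    all_centerlines: dict[tuple[str, str], Centerline] = {}
    n_failures = 0
    want_cross = config.angle_mode in ("cross_timepoint", "both")
    for rec in manifest.itertuples(index=False):
        pid = str(rec.patient_id)
        centerlines: dict[str, Centerline] = {}
        for timepoint, path in (("pre", rec.pre_path), ("post", rec.post_path)):
            try:
                row, cl = analyze_image(load_grayscale(path), config, pid, timepoint)
                centerlines[timepoint] = cl
                all_centerlines[(pid, timepoint)] = cl
            except Exception as err:  # per-image failure: flag and continue
                logger.warning("%s/%s: %s", pid, timepoint, err)
                row = _failed_row(pid, timepoint, config, err)
                n_failures += 1
            rows.append(row)
        if want_cross and len(centerlines) == 2:
            try:
                change = algorithm1_change(
                    centerlines["pre"], centerlines["post"], config.k_segments, config.pi_approx
                )
                change_rows.append(
                    {"patient_id": pid, "alg1_cross_mean_angle_deg": change.mean_deg}
                )
            except Exception as err:
                logger.warning("%s/cross_timepoint: %s", pid, err)
                n_failures += 1
    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    changes = pd.DataFrame(change_rows, columns=["patient_id", "alg1_cross_mean_angle_deg"])
    return metrics, changes, all_centerlines, n_failures


_METRIC_LABELS = {
    "alg1_mean_angle_deg": "alg1_mean_angle_deg",
    "alg2_mean_abs": "alg2_mean_abs",
    "alg2_abs_sum": "alg2_abs_sum",
}


def cohort_reports_from_metrics(metrics: pd.DataFrame, config: RunConfig) -> list[CohortReport]:
    """Paired pre/post battery per metric from a per-image metrics frame.

    Patients missing either timepoint (or with a failed row) are excluded
    with a logged count.  One report is produced per metric column: the mean
    segment angle always, plus the slope statistic(s) selected in the config.
    """
    ok = metrics[metrics["status"] == "ok"]
    pre = ok[ok["timepoint"] == "pre"].set_index("patient_id")
    post = ok[ok["timepoint"] == "post"].set_index("patient_id")
    paired_ids = sorted(set(pre.index) & set(post.index))
    n_dropped = len(set(metrics["patient_id"])) - len(paired_ids)
    if n_dropped:
        logger.warning("excluded %d patients without a valid pre/post pair", n_dropped)
    if len(paired_ids) < 2:
        raise ValueError("insufficient sample: need at least 2 complete pre/post pairs")

    if config.slope_statistic == "both":
        slope_cols = ["alg2_mean_abs", "alg2_abs_sum"]
    else:
        slope_cols = [f"alg2_{config.slope_statistic}"]
    reports = []
    for col in ["alg1_mean_angle_deg", *slope_cols]:
        cohort = PairedCohort(
            patient_ids=list(paired_ids),
            pre_values=pre.loc[paired_ids, col].to_numpy(),
            post_values=post.loc[paired_ids, col].to_numpy(),
            metric_name=_METRIC_LABELS[col],
        )
        reports.append(analyze_cohort(cohort, alpha=config.alpha))
    return reports


def report_to_dict(report: CohortReport) -> dict:
    return dataclasses.asdict(report)


def write_reports(
    reports: list[CohortReport], config: RunConfig, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write cohort reports as CSV and JSON (the JSON embeds the run config)."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([report_to_dict(r) for r in reports])
    csv_path = out_prefix.with_suffix(".csv")
    json_path = out_prefix.with_suffix(".json")
    frame.to_csv(csv_path, index=False, float_format="%.6g")
    payload = {"config": config.to_dict(), "reports": [report_to_dict(r) for r in reports]}
    json_path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
    return csv_path, json_path
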