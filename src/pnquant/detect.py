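"""Pronucleus detection and recognition-accuracy evaluation.

Two input routes feed the tracking stage:

* a baseline classical detector (Gaussian smooth -> Otsu threshold ->
  connected components -> area and circularity filters) adequate for the
  simulator's rendered imagery, and
* ingestion of pre-computed per-frame detection tables, so that outputs of
  an external segmentation model (e.g. a Mask R-CNN) can be plugged in
  without touching any imaging code.

The module also owns the pixel -> micron conversion (the acquisition
optics give 1 pixel = 0.3275 um) and the frame-level recognition-accuracy
bookkeeping used to audit a detector against hand annotations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

log = logging.getLogger(__name__)

__all__ = [
    "PIXEL_SCALE_UM",
    "PNDetection",
    "RecognitionCounts",
    "DetectorParams",
    "detect_pronuclei",
    "area_to_microns",
    "evaluate_recognition",
    "load_detection_table",
    "detections_to_frame",
    "write_detection_table",
]

#: Micrometres per pixel of the acquisition optics.
PIXEL_SCALE_UM = 0.3275

SEX_LABELS = ("unassigned", "female", "male")


def area_to_microns(area_px: float, scale_um_per_px: float = PIXEL_SCALE_UM) -> float:
    """Convert a pixel area to um^2 (``area * scale**2``)."""
    if area_px <= 0:
        raise ValueError(f"area_px must be positive, got {area_px}")
    if scale_um_per_px <= 0:
        raise ValueError(f"scale must be positive, got {scale_um_per_px}")
    return float(area_px) * scale_um_per_px**2


@dataclass
class PNDetection:
    """One detected pronucleus in one frame."""

    embryo_id: str
    frame_index: int
    time_h: float
    center_px: tuple[float, float]
    area_px: float
    area_um2: float
    sex: str = "unassigned"

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError(f"area_px must be > 0, got {self.area_px}")
        if self.area_um2 <= 0:
            raise ValueError(f"area_um2 must be > 0, got {self.area_um2}")
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")
        if self.sex not in SEX_LABELS:
            raise ValueError(f"sex must be one of {SEX_LABELS}, got {self.sex!r}")


@dataclass
class RecognitionCounts:
    """Frame-level tallies of a detector audited against annotation.

    ``correct_2pn`` counts frames where detector and annotation agree on
    exactly two pronuclei; ``overestimated`` counts frames the detector
    called 2PN against a non-2PN annotation; ``missed`` counts annotated
    2PN frames the detector called otherwise (in practice: partial overlap
    of the two pronuclei merging them into one component).
    """

    correct_2pn: int
    overestimated: int
    missed: int

    def __post_init__(self) -> None:
        for name in ("correct_2pn", "overestimated", "missed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def accuracy(self) -> float:
        """correct / (correct + overestimated + missed)."""
        total = self.correct_2pn + self.overestimated + self.missed
        if total == 0:
            raise ValueError("no frames counted")
        return self.correct_2pn / total


@dataclass
class DetectorParams:
    """Settings of the baseline classical detector."""

    smooth_sigma_px: float = 2.0
    min_area_px: float = 50.0
    max_area_px: float = 20000.0
    min_circularity: float = 0.7
    threshold: str = "otsu"  # only mode currently implemented


def _circularity(region) -> float:
    # 4*pi*A / P^2; 1 for a perfect disk, falls toward 0 for ragged shapes
    perim = region.perimeter
    if perim == 0:
        return 0.0
    return 4.0 * np.pi * region.area / perim**2


def detect_pronuclei(
    image: np.ndarray,
    params: DetectorParams | None = None,
    *,
    embryo_id: str = "",
    frame_index: int = 0,
    time_h: float = 0.0,
    scale_um_per_px: float = PIXEL_SCALE_UM,
) -> list[PNDetection]:
    """Detect bright, roughly circular blobs in a focused frame.

    Pipeline: Gaussian smooth (sigma 2 px) -> Otsu threshold -> connected
    components -> keep components with area in ``[min_area, max_area]`` and
    circularity ``4*pi*A/P**2 >= min_circularity``.  Returns zero or more
    detections; a zero-dynamic-range image yields an empty list with a
    logged warning.
    """
    params = params or DetectorParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if np.ptp(img) == 0:
        log.warning("frame %s/%d has zero dynamic range; no detections", embryo_id, frame_index)
        return []
    smoothed = gaussian(img, sigma=params.smooth_sigma_px, preserve_range=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    labels = cc_label(mask)
    detections = []
    for region in regionprops(labels):
        if not (params.min_area_px <= region.area <= params.max_area_px):
            continue
        if _circularity(region) < params.min_circularity:
            continue
        cy, cx = region.centroid
        detections.append(
            PNDetection(
                embryo_id=embryo_id,
                frame_index=frame_index,
                time_h=time_h,
                center_px=(float(cx), float(cy)),
                area_px=float(region.area),
                area_um2=area_to_microns(region.area, scale_um_per_px),
            )
        )
    detections.sort(key=lambda d: d.center_px)
    return detections


# ---------------------------------------------------------------------------
# Recognition audit


def evaluate_recognition(
    auto: Mapping[object, int],
    annotated: Mapping[object, int],
    *,
    frame_times_h: Mapping[object, float] | None = None,
    window_from_h: float | None = None,
) -> tuple[RecognitionCounts, float]:
    """Audit per-frame detector PN counts against annotated PN counts.

    Both mappings go from a frame key to a PN count.  If ``window_from_h``
    is given, overcalled frames are only charged when their
    ``frame_times_h`` is >= the bound: the audit windows of interest
    start at 12 h and 14 h post-insemination, where early-stage
    overcalls have died out, while the correct and missed tallies stay
    global.  Accuracy is therefore monotone non-decreasing as the window
    start moves later.

    Returns ``(RecognitionCounts, accuracy)`` with
    ``accuracy = correct / (correct + overestimated + missed)``.
    """
    frames = set(auto) & set(annotated)
    if not frames:
        raise ValueError("no frames in common")
    if window_from_h is not None and frame_times_h is None:
        raise ValueError("window_from_h requires frame_times_h")
    correct = over = missed = 0
    for f in frames:
        a, t = auto[f], annotated[f]
        if a == 2 and t == 2:
            correct += 1
        elif a == 2 and t != 2:
            if window_from_h is None or frame_times_h[f] >= window_from_h:
                over += 1
        elif a != 2 and t == 2:
            missed += 1
    counts = RecognitionCounts(correct, over, missed)
    return counts, counts.accuracy


# ---------------------------------------------------------------------------
# Detection-table I/O

DETECTION_COLUMNS = ["embryo_id", "frame_index", "time_h", "x_px", "y_px", "area_px"]


def load_detection_table(
    path: str | Path, scale_um_per_px: float = PIXEL_SCALE_UM
) -> list[PNDetection]:
    """Read a detection CSV (``embryo_id, frame_index, time_h, x_px, y_px,
    area_px``) into :class:`PNDetection` objects.

    A ``sex`` column carries provisional per-frame labels from the
    upstream detector; an optional ``sex_override`` column (female/male)
    takes precedence, mirroring manual embryologist correction of
    automatic sexing.
    """
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    out = []
    has_sex = "sex" in df.columns
    has_override = "sex_override" in df.columns
    for row in df.itertuples(index=False):
        sex = "unassigned"
        if has_sex and isinstance(row.sex, str) and row.sex in ("female", "male"):
            sex = row.sex
        if has_override and isinstance(row.sex_override, str) and row.sex_override in (
            "female",
            "male",
        ):
            sex = row.sex_override
        out.append(
            PNDetection(
                embryo_id=str(row.embryo_id),
                frame_index=int(row.frame_index),
                time_h=float(row.time_h),
                center_px=(float(row.x_px), float(row.y_px)),
                area_px=float(row.area_px),
                area_um2=area_to_microns(float(row.area_px), scale_um_per_px),
                sex=sex,
            )
        )
    return out


def detections_to_frame(detections: Iterable[PNDetection]) -> pd.DataFrame:
    """Tabulate detections as a DataFrame with the canonical columns."""
    return pd.DataFrame(
        [
            {
                "embryo_id": d.embryo_id,
                "frame_index": d.frame_index,
                "time_h": d.time_h,
                "x_px": d.center_px[0],
                "y_px": d.center_px[1],
                "area_px": d.area_px,
                "area_um2": d.area_um2,
                "sex": d.sex,
            }
            for d in detections
        ]
    )


def write_detection_table(detections: Sequence[PNDetection], path: str | Path) -> None:
    detections_to_frame(detections).to_csv(path, index=False)
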