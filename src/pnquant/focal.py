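"""Focal-plane selection for z-stacked time-lapse frames.

Time-lapse incubators image each embryo at several focal offsets (the
default acquisition geometry is 11 segments at -75 ... +75 um in 15 um
steps).  Downstream pronucleus measurement wants exactly one, maximally
sharp, image per time point.  Sharpness is scored as the variance of the
discrete Laplacian response: a defocused image loses high-frequency
content, so its Laplacian response collapses toward zero variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

__all__ = [
    "ZStack",
    "LAPLACIAN_KERNEL",
    "laplacian_sharpness",
    "select_clearest_plane",
    "to_grayscale",
    "load_stack_manifest",
    "write_selected_manifest",
]

#: 4-neighbour discrete Laplacian, the standard autofocus kernel.
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)

#: Default focal offsets (um) of the acquisition geometry.
DEFAULT_PLANE_OFFSETS_UM = tuple(range(-75, 76, 15))


@dataclass
class ZStack:
    """One time point's stack of focal-plane images for one embryo.

    Parameters
    ----------
    embryo_id : str
        Embryo identifier.
    time_h : float
        Hours post-ICSI (>= 0).
    planes : sequence of 2-D arrays
        Intensity images, all with identical shape.
    plane_offsets_um : sequence of float
        Strictly increasing focal offsets in micrometres.
    """

    embryo_id: str
    time_h: float
    planes: Sequence[np.ndarray]
    plane_offsets_um: Sequence[float] = field(default=DEFAULT_PLANE_OFFSETS_UM)

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")
        if len(self.planes) < 1:
            raise ValueError("ZStack requires at least one plane")
        shapes = {np.asarray(p).shape[:2] for p in self.planes}
        if len(shapes) != 1:
            raise ValueError(f"planes have mismatched shapes: {sorted(shapes)}")
        offs = list(self.plane_offsets_um)[: len(self.planes)]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("plane_offsets_um must be strictly increasing")
        self.plane_offsets_um = offs


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an (H, W[, 3]) image to float grayscale via Rec. 601 luma."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return image[..., :3] @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"cannot interpret image of shape {image.shape}")


def laplacian_sharpness(image: np.ndarray) -> float:
    """Variance-of-Laplacian focus score of a single image.

    The image is convolved with the 3x3 Laplacian kernel and the population
    variance of the response is taken over the interior (non-border)
    pixels, so that no padding convention enters the score.  The score is
    zero for a constant image, covariant under intensity scaling
    (``score(c*x) == c**2 * score(x)``) and invariant under adding a
    constant offset.

    Raises
    ------
    ValueError
        If the image is smaller than the 3x3 kernel or contains non-finite
        pixels (the error names the first offending pixel).
    """
    image = to_grayscale(image)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError(
            f"image of shape {image.shape} is smaller than the 3x3 Laplacian kernel"
        )
    bad = np.argwhere(~np.isfinite(image))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"non-finite pixel at (row={r}, col={c}): {image[r, c]!r}")
    response = convolve(image, LAPLACIAN_KERNEL, mode="constant")[1:-1, 1:-1]
    return float(np.var(response))


def select_clearest_plane(stack: ZStack) -> tuple[int, np.ndarray]:
    """Pick the sharpest plane of a z-stack.

    Returns ``(plane_index, image)`` for the plane maximising
    :func:`laplacian_sharpness`.  Ties break to the lowest index so reruns
    are deterministic.
    """
    if len(stack.planes) == 0:
        raise ValueError("empty z-stack")
    scores = [laplacian_sharpness(p) for p in stack.planes]
    idx = int(np.argmax(scores))  # argmax returns the first maximum
    return idx, np.asarray(stack.planes[idx])


# ---------------------------------------------------------------------------
# Manifest I/O


def _read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def load_stack_manifest(path: str | Path) -> list[ZStack]:
    """Read a stack manifest CSV into :class:`ZStack` objects.

    Expected columns: ``embryo_id, time_h, plane_offset_um, path`` with one
    row per plane image.  Paths are resolved relative to the manifest.
    """
    df = pd.read_csv(path)
    required = {"embryo_id", "time_h", "plane_offset_um", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = Path(path).parent
    stacks = []
    for (eid, t), grp in df.groupby(["embryo_id", "time_h"], sort=True):
        grp = grp.sort_values("plane_offset_um")
        planes = [_read_image(base / p) for p in grp["path"]]
        stacks.append(
            ZStack(
                embryo_id=str(eid),
                time_h=float(t),
                planes=planes,
                plane_offsets_um=list(grp["plane_offset_um"]),
            )
        )
    return stacks


def write_selected_manifest(
    selections: Sequence[tuple[ZStack, int]], path: str | Path
) -> pd.DataFrame:
    """Write the selected-plane manifest (one row per time point)."""
    rows = [
        {
            "embryo_id": s.embryo_id,
            "time_h": s.time_h,
            "selected_plane_index": idx,
            "selected_offset_um": s.plane_offsets_um[idx],
        }
        for s, idx in selections
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
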