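"""Image-based whole-plant leaf area with in-frame reference calibration.

A top-view RGB photograph contains the green foliage and a 1 cm² black
reference square lying on the same plane.  Leaf area is then a pure pixel
ratio:

    area_cm2 = (green pixel count) / (reference square pixel count)

Green and black are defined by a simple channel rule (``ColorRule``): a pixel
is green when its G channel is bright enough and dominates R and B by stated
margins, black when all channels fall below a ceiling.  The reference square
is found as the largest black connected component (4-connectivity) whose
bounding-box fill ratio passes a square-ness guard, which rejects shadows and
stray dark lines.  No perspective or lens correction is attempted: with the
reference on the leaf plane the ratio is scale-free by construction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "ColorRule",
    "LeafScene",
    "segment_green",
    "find_reference_square",
    "measure_area",
    "batch_measure",
    "CalibrationError",
    "ImageFormatError",
]

logger = logging.getLogger(__name__)


class ImageFormatError(ValueError):
    """Input image is not a 3-channel 8-bit RGB array."""


class CalibrationError(RuntimeError):
    """No acceptable reference square found in the image."""


@dataclass(frozen=True)
class ColorRule:
    """Channel thresholds defining 'green' and 'black' pixels.

    green: G >= min_green and G-R >= margin_r and G-B >= margin_b.
    black: max(R, G, B) <= black_max.
    """

    min_green: int = 60
    margin_r: int = 20
    margin_b: int = 20
    black_max: int = 40

    def __post_init__(self) -> None:
        for name in ("min_green", "black_max"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name}={v} outside 0-255")
        if self.margin_r < 0 or self.margin_b < 0:
            raise ValueError("dominance margins must be >= 0")


@dataclass
class LeafScene:
    """An analysed image: masks, calibration and the derived area."""

    image: np.ndarray
    green_mask: np.ndarray
    reference_mask: np.ndarray
    px_per_cm2: int
    area_cm2: float


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ImageFormatError(
            f"expected an RGB image (H, W, 3), got shape {image.shape}"
        )
    return image[:, :, :3].astype(np.int16)


def segment_green(image: np.ndarray, rule: ColorRule = ColorRule()) -> np.ndarray:
    """Boolean mask of green (foliage) pixels under the channel rule."""
    img = _check_rgb(image)
    r, g, b = img[:, :, 0], img[:, :, 1], img[:, :, 2]
    return (g >= rule.min_green) & (g - r >= rule.margin_r) & (g - b >= rule.margin_b)


def find_reference_square(
    image: np.ndarray,
    rule: ColorRule = ColorRule(),
    min_fill_ratio: float = 0.85,
    force: bool = False,
) -> tuple[np.ndarray, int]:
    """Locate the 1 cm² black reference square; returns (mask, pixel count).

    The largest black 4-connected component is the candidate; it must fill at
    least ``min_fill_ratio`` of its bounding box (square-ness guard) unless
    ``force`` is set.
    """
    img = _check_rgb(image)
    black = np.all(img <= rule.black_max, axis=2)
    if not black.any():
        raise CalibrationError("no black pixels found: cannot calibrate")
    labels = measure.label(black, connectivity=1)
    props = measure.regionprops(labels)
    best = max(props, key=lambda p: p.area)
    fill = best.area / best.area_bbox
    if fill < min_fill_ratio:
        msg = (f"largest black component fails square-ness guard "
               f"(fill ratio {fill:.2f} < {min_fill_ratio})")
        if not force:
            raise CalibrationError(msg)
        logger.warning("%s -- proceeding under force", msg)
    mask = labels == best.label
    return mask, int(best.area)


def measure_area(image: np.ndarray, rule: ColorRule = ColorRule(),
                 force: bool = False) -> LeafScene:
    """Measure leaf area in cm² as green count over reference count."""
    green = segment_green(image, rule)
    ref_mask, ref_px = find_reference_square(image, rule, force=force)
    green = green & ~ref_mask  # a pixel is never both
    area = green.sum() / ref_px
    return LeafScene(image=np.asarray(image), green_mask=green,
                     reference_mask=ref_mask, px_per_cm2=ref_px,
                     area_cm2=float(area))


#: filename pattern: <plant>_<group>_day<D>.<ext>, e.g. p1_control_day3.png
FILENAME_RE = re.compile(
    r"^(?P<plant>[^_]+)_(?P<group>[^_]+)_day(?P<day>-?\d+)\.[A-Za-z]+$"
)


def batch_measure(paths, rule: ColorRule = ColorRule()) -> pd.DataFrame:
    """Measure every image in ``paths``; one row per file, failures flagged.

    Filenames must follow ``<plant>_<group>_day<D>.<ext>``.  Unparseable names
    and unreadable or uncalibratable images produce an error row (status
    column) rather than being dropped.
    """
    rows = []
    for path in paths:
        path = Path(path)
        rec = {"plant": "", "group": "", "day": np.nan, "area_cm2": np.nan,
               "green_px": np.nan, "ref_px": np.nan, "status": "ok"}
        m = FILENAME_RE.match(path.name)
        if m:
            rec.update(plant=m["plant"], group=m["group"], day=int(m["day"]))
        else:
            rec["status"] = f"error: unparseable filename {path.name!r}"
            rows.append(rec)
            logger.error("%s", rec["status"])
            continue
        try:
            scene = measure_area(iio.imread(path), rule)
        except Exception as exc:  # isolate per-file failures
            rec["status"] = f"error: {exc}"
            logger.error("failed on %s: %s", path, exc)
        else:
            rec.update(area_cm2=scene.area_cm2,
                       green_px=int(scene.green_mask.sum()),
                       ref_px=scene.px_per_cm2)
        rows.append(rec)
    return pd.DataFrame(rows, columns=["plant", "group", "day", "area_cm2",
                                       "green_px", "ref_px", "status"])
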