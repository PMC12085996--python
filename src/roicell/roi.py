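"""Loading and cropping of exported circular-ROI images.

Digital spatial profiling platforms export each region of interest (ROI) as a
square RGB TIFF with the circular ROI centered on a white margin.  This module
loads those images, finds the circular ROI by thresholding the near-white
background, crops to the tight bounding square of the fitted circle, and masks
everything outside the circle.

Coordinate convention: ``x`` = column, ``y`` = row, origin at the top-left,
0-based.  Masked-out pixels are set to white ``(255, 255, 255)`` — not zero —
so they can never contaminate channel statistics; all downstream computation
is restricted to ``roi_mask``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage import measure

from .errors import EmptyRoiError, FormatError

__all__ = ["RoiImage", "load_roi_tiff", "detect_and_crop_roi", "save_roi"]

#: Sentinel value written to pixels outside the ROI mask.
BACKGROUND_SENTINEL = 255


@dataclass
class RoiImage:
    """An RGB raster plus its circular ROI mask.

    Parameters
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array, channels ordered (R, G, B).
    roi_mask:
        Boolean ``(H, W)`` array, True inside the ROI.  For a freshly loaded
        (uncropped) image the mask is all-True.
    center:
        ``(x, y)`` pixel coordinates of the ROI circle center, or None if the
        image has not been cropped yet.
    radius_px:
        ROI circle radius in pixels, or None before cropping.
    um_per_px:
        Physical scale in micrometers per pixel; None when unknown, in which
        case all spatial statistics are reported in pixels.
    """

    pixels: np.ndarray
    roi_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    center: tuple[float, float] | None = None
    radius_px: float | None = None
    um_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise FormatError(
                f"pixels must be (H, W, 3); got shape {self.pixels.shape}"
            )
        if self.roi_mask is None:
            self.roi_mask = np.ones(self.pixels.shape[:2], dtype=bool)
        if self.roi_mask.shape != self.pixels.shape[:2]:
            raise FormatError("roi_mask shape does not match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def is_cropped(self) -> bool:
        return self.radius_px is not None


def load_roi_tiff(path: str | Path) -> RoiImage:
    """Load an exported ROI TIFF as an (uncropped) :class:`RoiImage`.

    Accepts 8- or 16-bit RGB or RGBA TIFFs; an alpha channel is dropped and
    16-bit intensities are rescaled to 0–255.  Raises :class:`FormatError`
    for single-channel images and propagates I/O errors for unreadable files.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        raise FormatError(
            f"{path}: single-channel image; expected at least 3 (R, G, B) channels"
        )
    if arr.ndim != 3:
        raise FormatError(f"{path}: unsupported TIFF layout with shape {arr.shape}")
    # Channel-first layouts (C, H, W) occasionally come out of exporters.
    if arr.shape[0] in (3, 4) and arr.shape[-1] not in (3, 4):
        arr = np.moveaxis(arr, 0, -1)
    if arr.shape[-1] < 3:
        raise FormatError(
            f"{path}: {arr.shape[-1]} channels; expected at least 3 (R, G, B)"
        )
    arr = arr[..., :3]
    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    return RoiImage(pixels=arr)


def detect_and_crop_roi(
    img: RoiImage,
    shape: str = "circle",
    background_tol: int = 10,
    roi_diameter_um: float | None = None,
) -> RoiImage:
    """Locate the circular ROI and crop/mask away everything outside it.

    The near-white margin (all channels ``>= 255 - background_tol``) is
    treated as background; the largest connected non-background component is
    taken as the ROI, an area-equivalent circle is fitted to it (center =
    component centroid, radius = sqrt(area / pi), both rounded to integer
    pixels), the image is cropped to the circle's tight bounding square, and
    pixels outside the circle are set to the white sentinel.

    If the non-background region touches all four image borders the image is
    assumed pre-cropped: a warning is emitted and only masking is applied,
    which makes the operation idempotent.

    Parameters
    ----------
    roi_diameter_um:
        If given (e.g. the vendor-default 300 µm), ``um_per_px`` is derived as
        ``roi_diameter_um / (2 * radius_px)``; otherwise the scale is unknown
        and spatial statistics stay in pixels.
    """
    if shape != "circle":
        raise ValueError(f"unsupported ROI shape {shape!r}; only 'circle'")
    px = img.pixels
    h, w = px.shape[:2]
    foreground = ~np.all(px >= 255 - background_tol, axis=-1)
    if not foreground.any():
        raise EmptyRoiError("no non-background region found (image is all white)")

    labeled = measure.label(foreground, connectivity=2)
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    comp = labeled == int(np.argmax(counts))
    rows, cols = np.nonzero(comp)

    cy = int(round(float(rows.mean())))
    cx = int(round(float(cols.mean())))
    radius = int(round(math.sqrt(comp.sum() / math.pi)))
    if radius < 1:
        raise EmptyRoiError("detected region too small to fit a circle")

    touches_all_borders = (
        rows.min() == 0 and cols.min() == 0 and rows.max() == h - 1 and cols.max() == w - 1
    )
    if touches_all_borders:
        warnings.warn(
            "ROI touches all four image borders; assuming the image is "
            "pre-cropped and skipping the crop step",
            stacklevel=2,
        )
        y0, y1, x0, x1 = 0, h, 0, w
    else:
        y0 = max(0, cy - radius)
        y1 = min(h, cy + radius + 1)
        x0 = max(0, cx - radius)
        x1 = min(w, cx + radius + 1)

    cropped = px[y0:y1, x0:x1].copy()
    ccx, ccy = cx - x0, cy - y0
    yy, xx = np.ogrid[: cropped.shape[0], : cropped.shape[1]]
    mask = (xx - ccx) ** 2 + (yy - ccy) ** 2 <= radius**2
    cropped[~mask] = BACKGROUND_SENTINEL

    um_per_px = None
    if roi_diameter_um is not None:
        um_per_px = float(roi_diameter_um) / (2.0 * radius)
    return RoiImage(
        pixels=cropped,
        roi_mask=mask,
        center=(float(ccx), float(ccy)),
        radius_px=float(radius),
        um_per_px=um_per_px,
    )


def save_roi(img: RoiImage, path: str | Path) -> Path:
    """Write a cropped ROI as TIFF plus a JSON sidecar with its geometry."""
    path = Path(path)
    tifffile.imwrite(str(path), img.pixels)
    sidecar = path.with_suffix(".json")
    meta = {
        "center": list(img.center) if img.center is not None else None,
        "radius_px": img.radius_px,
        "um_per_px": img.um_per_px,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path
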