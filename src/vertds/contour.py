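"""Endplate image segmentation and boundary extraction.

Converts an isolated antero-superior endplate grayscale image into a scaled,
baseline-free boundary point set:

1. Otsu threshold (``I >= theta`` foreground convention) -> binary mask.
2. External boundary of each 8-connected foreground component, traced as a
   full pixel-center chain (no polygonal simplification); holes suppressed.
3. Largest-area contour retained.
4. Baseline removal: the modal integer y-coordinate ``y*`` locates the
   straight cut line; every point with ``|y - y*| <= tau`` is discarded.
5. Pixel -> millimetre scaling from a reference length, with the y-axis
   flipped to mathematical orientation and the origin moved to the centroid.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateGeometryError, EmptyResultError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Contour",
    "otsu_threshold",
    "extract_external_contours",
    "select_largest_contour",
    "remove_baseline",
    "scale_contour",
    "image_to_contour",
    "shoelace_area",
    "load_image",
]


@dataclass(frozen=True)
class Contour:
    """Ordered planar boundary points.

    Parameters
    ----------
    points : (n, 2) float array of (x, y) coordinates.
    units : "px" or "mm".
    closed : whether the chain is a closed loop.
    """

    points: np.ndarray
    units: str = "px"
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValidationError("contour needs an (n, 2) array with n >= 1")
        if self.units not in ("px", "mm"):
            raise ValidationError(f"unknown units {self.units!r}")
        if len(pts) > 1 and np.any(np.all(pts[1:] == pts[:-1], axis=1)):
            raise ValidationError("consecutive duplicate contour points")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def to_csv(self, path: str | Path) -> None:
        """Write the two-column ``x,y`` CSV used throughout the pipeline."""
        pd.DataFrame(self.points, columns=["x", "y"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "mm") -> "Contour":
        df = pd.read_csv(path)
        if not {"x", "y"} <= set(df.columns):
            raise ValidationError(f"{path}: contour CSV must have x,y columns")
        return cls(df[["x", "y"]].to_numpy(dtype=float), units=units)


def shoelace_area(points: np.ndarray) -> float:
    """Absolute polygon area of a point chain (implicitly closed)."""
    p = np.asarray(points, dtype=float)
    if len(p) < 3:
        return 0.0
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF as an 8-bit single-channel array."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse RGB(A) of a grayscale export
        img = img[..., :3].mean(axis=2).round().astype(np.uint8)
    if img.ndim != 2:
        raise ValidationError(f"{path}: expected a single-channel image")
    return img.astype(np.uint8)


def otsu_threshold(image: np.ndarray) -> tuple[int, np.ndarray]:
    """Otsu threshold with the ``I >= theta`` foreground convention.

    Returns the integer threshold maximizing between-class variance of the
    256-bin intensity histogram (smallest maximizer on ties) and the binary
    mask ``image >= theta``.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValidationError("empty image")
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateGeometryError("constant image: Otsu histogram is degenerate")
    total = hist.sum()
    omega_bg = np.cumsum(hist)[:-1]  # class {I < theta} for theta = 1..255
    mu_cum = np.cumsum(hist * np.arange(256))[:-1]
    omega_fg = total - omega_bg
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_bg = mu_cum / omega_bg
        mu_fg = (mu_cum[-1] + hist[-1] * 255 - mu_cum) / omega_fg
        sigma_b = omega_bg * omega_fg * (mu_bg - mu_fg) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=0.0)
    theta = int(np.argmax(sigma_b)) + 1  # candidate theta = 1 splits {0} | {>=1}
    mask = (img >= theta).astype(np.uint8)
    return theta, mask


# Moore neighbourhood, clockwise starting at west (image coords: row down).
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}


def _trace_outer_boundary(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbour trace of the outer boundary of one component.

    Returns the ordered (row, col) chain through pixel centers, using Jacob's
    stopping criterion so that spurs one pixel wide are traversed both ways.
    """
    padded = np.pad(mask.astype(bool), 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # row-major first: topmost-leftmost
    chain = [start]
    cur = start
    back_idx = 0  # backtrack at west of the start pixel is guaranteed background
    first_move: tuple | None = None
    while True:
        hit = None
        for k in range(1, 9):
            idx = (back_idx + k) % 8
            nb = (cur[0] + _MOORE[idx][0], cur[1] + _MOORE[idx][1])
            if padded[nb]:
                hit = (idx, k, nb)
                break
        if hit is None:  # isolated single pixel
            break
        idx, k, nb = hit
        if first_move is None:
            first_move = (cur, nb)
        elif (cur, nb) == first_move:
            break
        chain.append(nb)
        # new backtrack: the background neighbour examined just before the hit
        prev_bg = (cur[0] + _MOORE[(back_idx + k - 1) % 8][0],
                   cur[1] + _MOORE[(back_idx + k - 1) % 8][1])
        back_idx = _MOORE_INDEX[(prev_bg[0] - nb[0], prev_bg[1] - nb[1])]
        cur = nb
    if len(chain) > 1 and chain[-1] == chain[0]:
        chain.pop()
    arr = np.asarray(chain, dtype=float) - 1.0  # undo padding offset
    return arr


def extract_external_contours(mask: np.ndarray) -> list[Contour]:
    """Outer boundary chain of every 8-connected foreground component.

    Inner hole boundaries are never returned. Components appear in raster-scan
    order of their first pixel.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise EmptyResultError("empty mask: no foreground pixels")
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    contours = []
    for lab in range(1, n + 1):
        rc = _trace_outer_boundary(labels == lab)
        pts = rc[:, ::-1]  # (row, col) -> (x, y)
        # collapse consecutive duplicates (cannot occur, but keep the contract)
        if len(pts) > 1:
            keep = np.r_[True, np.any(pts[1:] != pts[:-1], axis=1)]
            pts = pts[keep]
        contours.append(Contour(pts, units="px", closed=True))
    return contours


def select_largest_contour(contours: Sequence[Contour]) -> Contour:
    """Contour with the maximal enclosed polygon area; first wins on ties."""
    if len(contours) == 0:
        raise EmptyResultError("no contours to select from")
    areas = [shoelace_area(c.points) for c in contours]
    best = int(np.argmax(areas))
    if areas.count(areas[best]) > 1:
        logger.warning("area tie among contours; keeping the first in scan order")
    return contours[best]


def _modal_y(y_round: np.ndarray, y: np.ndarray, tau_px: float) -> int:
    """Modal integer y; ties broken by points within +/- tau, then smaller y."""
    vals, counts = np.unique(y_round, return_counts=True)
    cands = vals[counts == counts.max()]
    if len(cands) == 1:
        return int(cands[0])
    within = [np.sum(np.abs(y - c) <= tau_px) for c in cands]
    cands = cands[np.asarray(within) == max(within)]
    return int(cands.min())


def remove_baseline(contour: Contour, tau_px: float = 2.0) -> Contour:
    """Drop points within ``tau_px`` of the modal (rounded) y-coordinate.

    The straight posterior cut line produced during endplate isolation shares
    one image row; removing the band around the most frequent y preserves only
    the true surface undulations.
    """
    if contour.units != "px":
        raise ValidationError("baseline removal operates on pixel coordinates")
    if tau_px < 0:
        raise ValidationError("tau_px must be >= 0")
    y = contour.y
    y_star = _modal_y(np.rint(y).astype(int), y, tau_px)
    keep = np.abs(y - y_star) > tau_px
    if not keep.any():
        raise EmptyResultError(
            f"baseline filter removed all {len(y)} points "
            f"(y* = {y_star}, tau = {tau_px}, y range {y.min():.1f}-{y.max():.1f})"
        )
    return Contour(contour.points[keep], units="px", closed=False)


def scale_contour(contour: Contour, ref_len_mm: float, ref_len_px: float) -> Contour:
    """Convert pixel coordinates to millimetres.

    Multiplies by ``ref_len_mm / ref_len_px``, flips the y-axis to
    mathematical orientation (y up) and re-centers the contour on its
    centroid so downstream fits share a fixed convention.
    """
    if ref_len_mm <= 0 or ref_len_px <= 0:
        raise ValidationError("reference lengths must be positive")
    if contour.units != "px":
        raise ValidationError("contour already scaled")
    factor = ref_len_mm / ref_len_px
    pts = contour.points * factor
    pts[:, 1] *= -1.0
    pts -= pts.mean(axis=0)
    return Contour(pts, units="mm", closed=contour.closed)


def image_to_contour(
    image: np.ndarray,
    ref_len_mm: float,
    ref_len_px: float,
    tau_px: float = 2.0,
    median_prefilter: bool = False,
    out_csv: str | Path | None = None,
) -> Contour:
    """Full image -> scaled baseline-free contour pipeline.

    Composition: Otsu threshold, external contours, largest contour, baseline
    removal, mm scaling. Optionally applies a 3x3 median pre-filter and writes
    the contour CSV.
    """
    img = np.asarray(image)
    if median_prefilter:
        img = ndimage.median_filter(img, size=3)
    _, mask = otsu_threshold(img)
    largest = select_largest_contour(extract_external_contours(mask))
    filtered = remove_baseline(largest, tau_px=tau_px)
    scaled = scale_contour(filtered, ref_len_mm, ref_len_px)
    if out_csv is not None:
        scaled.to_csv(out_csv)
    return scaled
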