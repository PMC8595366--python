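"""Camera corrections and the empirical FRET ratio-correction image.

Apparent FRET ratio shows a smooth field-dependent bias (a top-to-bottom
gradient in practice) caused by imperfections in the light path. The bias is
estimated empirically from many unstimulated cells imaged at systematically
varied stage positions so that cells tile the whole sensor: the per-pixel
median ratio over all cell pixels is block-aggregated, smoothed, and resized
back to full resolution to yield a multiplicative "ratio correction image".
Dividing ratio images by it removes the bias. The correction is optional in
the pipeline configuration (myosin imaging does not need it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

#: Side of the square aggregation block, pixels.
BLOCK_SIZE = 24
#: Gaussian smoothing sigma applied to the block-median image, in block units.
BLOCK_SIGMA = 5.0


@dataclass
class CorrectionSet:
    """Dark image, chip-sensitivity map and full-field ratio correction."""

    dark_image: np.ndarray
    sensitivity_image: np.ndarray
    ratio_correction_image: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dark_image = np.asarray(self.dark_image, dtype=float)
        self.sensitivity_image = np.asarray(self.sensitivity_image, dtype=float)
        if self.sensitivity_image.shape != self.dark_image.shape:
            raise ValueError("dark and sensitivity maps must have the same shape")
        if not np.all(self.sensitivity_image > 0):
            raise ValueError("sensitivity map must be strictly positive")
        if self.ratio_correction_image is not None:
            rci = np.asarray(self.ratio_correction_image, dtype=float)
            if rci.shape != self.dark_image.shape:
                raise ValueError("ratio correction image shape mismatch")
            if not np.all(rci > 0):
                raise ValueError("ratio correction image must be strictly positive")
            self.ratio_correction_image = rci

    @classmethod
    def flat(cls, shape: tuple[int, int], dark: float = 0.0) -> "CorrectionSet":
        return cls(np.full(shape, dark), np.ones(shape))


def apply_camera_corrections(raw_frame: np.ndarray, corr: CorrectionSet) -> np.ndarray:
    """Correct a raw frame for dark offset and chip sensitivity.

    ``(raw - dark) / sensitivity`` elementwise. Negative outputs are legal
    (noise can undershoot the dark level) and are deliberately not clipped.
    """
    raw = np.asarray(raw_frame, dtype=float)
    if raw.shape != corr.dark_image.shape:
        raise ValueError(
            f"frame shape {raw.shape} != correction shape {corr.dark_image.shape}"
        )
    return (raw - corr.dark_image) / corr.sensitivity_image


def _block_median(img: np.ndarray, block: int) -> np.ndarray:
    """Median over ``block x block`` tiles; partial edge tiles use the median
    of their available pixels so the field is never shrunk."""
    nr, nc = img.shape
    nbr = -(-nr // block)
    nbc = -(-nc // block)
    out = np.empty((nbr, nbc))
    for i in range(nbr):
        for j in range(nbc):
            tile = img[i * block : (i + 1) * block, j * block : (j + 1) * block]
            out[i, j] = np.median(tile)
    return out


def _plane_coef(values: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Least-squares plane a + b*row + c*col fit to a grid of values."""
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    A = np.column_stack([np.ones(values.size), rr.ravel(), cc.ravel()])
    coef, *_ = np.linalg.lstsq(A, values.ravel(), rcond=None)
    return coef


def _eval_plane(coef: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return coef[0] + coef[1] * rr + coef[2] * cc


def build_ratio_correction(
    ratio_images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    block: int = BLOCK_SIZE,
    sigma: float = BLOCK_SIGMA,
) -> np.ndarray:
    """Build the full-field ratio-correction image from a cell-tiling stack.

    Steps: per-pixel median of the ratio over all frames, restricted to cell
    pixels -> median over each ``block x block`` tile -> Gaussian smoothing
    (``sigma`` in block units) -> smooth cubic-spline resize back to the full
    field. Smoothing acts on the residual about a least-squares plane so that
    a genuine large-scale linear trend passes through unattenuated instead of
    being flattened by the filter's boundary handling.

    Raises ``ValueError`` (naming the uncovered fraction) if any field pixel
    is never covered by a cell.
    """
    if len(ratio_images) == 0 or len(ratio_images) != len(masks):
        raise ValueError("need equal, nonzero numbers of ratio images and masks")
    shape = np.asarray(ratio_images[0]).shape
    stack = np.full((len(ratio_images),) + shape, np.nan)
    for k, (img, m) in enumerate(zip(ratio_images, masks)):
        img = np.asarray(img, dtype=float)
        m = np.asarray(m, dtype=bool)
        if img.shape != shape or m.shape != shape:
            raise ValueError("all ratio images and masks must share one shape")
        stack[k][m] = img[m]

    with np.errstate(all="ignore"):
        med = np.nanmedian(stack, axis=0)
    uncovered = np.isnan(med)
    if uncovered.any():
        frac = uncovered.mean()
        raise ValueError(
            f"{frac:.1%} of the field is never covered by a cell; "
            "collect cells at more stage positions"
        )

    blocks = _block_median(med, block)
    nbr, nbc = blocks.shape
    # Tile-center coordinates in full-field pixels (edge tiles may be partial).
    rows_c = np.array([
        (min((i + 1) * block, shape[0]) - 1 + i * block) / 2.0 for i in range(nbr)
    ])
    cols_c = np.array([
        (min((j + 1) * block, shape[1]) - 1 + j * block) / 2.0 for j in range(nbc)
    ])
    coef = _plane_coef(blocks, rows_c, cols_c)
    resid = blocks - _eval_plane(coef, rows_c, cols_c)
    resid_smooth = ndimage.gaussian_filter(resid, sigma, mode="nearest")

    rows_f = np.arange(shape[0], dtype=float)
    cols_f = np.arange(shape[1], dtype=float)
    plane_full = _eval_plane(coef, rows_f, cols_f)
    kx = min(3, nbr - 1)
    ky = min(3, nbc - 1)
    if kx < 1 or ky < 1:
        correction = plane_full + float(resid_smooth.mean())
    else:
        spl = RectBivariateSpline(rows_c, cols_c, resid_smooth, kx=kx, ky=ky, s=0)
        correction = plane_full + spl(rows_f, cols_f)
    if not np.all(correction > 0):
        raise ValueError("ratio correction image came out non-positive; check inputs")
    return correction


def apply_ratio_correction(ratio_image: np.ndarray, correction: np.ndarray) -> np.ndarray:
    """Divide a ratio image by the correction map (NaN pixels stay NaN)."""
    ratio = np.asarray(ratio_image, dtype=float)
    correction = np.asarray(correction, dtype=float)
    if ratio.shape != correction.shape:
        raise ValueError("ratio image and correction shape mismatch")
    if not np.all(correction > 0):
        raise ValueError("correction image must be strictly positive")
    return ratio / correction
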