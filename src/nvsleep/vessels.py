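"""Arteriole diameter extraction from two-photon-style frames.

Pial (surface) vessels: average the intensity along the vessel's long axis
and take the full width at half maximum of the cross-sectional profile.
Penetrating vessels (imaged in cross-section): threshold in Radon space
(TiRS) — per-projection thresholding of the Radon transform, inverse
reconstruction, and an equivalent diameter from the area of the largest
connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import iradon, radon

VESSEL_FRAME_RATE = 5.0  # Hz, nominal 2-photon frame rate


@dataclass
class DiameterTrace:
    """Per-frame vessel diameter with a normalized percent-change view."""

    diameter: np.ndarray
    rate: float = VESSEL_FRAME_RATE
    baseline_diameter: float | None = None
    units: str = "px"

    def __post_init__(self):
        self.diameter = np.asarray(self.diameter, dtype=float)
        finite = self.diameter[np.isfinite(self.diameter)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("diameters must be positive")

    def normalized(self) -> np.ndarray:
        """Percent change from baseline, (D - D0)/D0 * 100."""
        d0 = self.baseline_diameter
        if d0 is None:
            d0 = float(np.nanmean(self.diameter))
        return (self.diameter - d0) / d0 * 100.0


def fwhm_diameter(frame: np.ndarray, box: tuple[slice, slice] | None = None,
                  axis: int = 0) -> float:
    """Pial vessel diameter as the FWHM of the averaged cross profile.

    The boxed region is averaged along the vessel's long axis (``axis``) and
    the width at half maximum of the resulting profile measured with linear
    interpolation between the samples bracketing the half-max crossing.  The
    half-max level is ``(max - baseline)/2 + baseline`` with the baseline
    taken as the mean of the outer 10% of the profile, so the estimate is
    insensitive to uniform background offsets and to intensity scaling.

    Returns NaN when the profile never crosses the half-max level.
    """
    img = np.asarray(frame, dtype=float)
    if box is not None:
        img = img[box]
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("need a 2-D box at least 3 px wide")
    profile = img.mean(axis=axis)
    n = profile.size
    edge = max(1, n // 10)
    baseline = float(np.concatenate((profile[:edge], profile[-edge:])).mean())
    peak_idx = int(np.argmax(profile))
    peak = profile[peak_idx]
    if peak <= baseline:
        return np.nan
    half = (peak - baseline) / 2.0 + baseline

    def _cross(idx_range, reverse: bool) -> float | None:
        prev = peak_idx
        it = idx_range
        for i in it:
            if profile[i] < half:
                # linear interpolation between i and prev
                x0, x1 = (i, prev) if reverse else (prev, i)
                y0, y1 = profile[x0], profile[x1]
                if y1 == y0:
                    return float(i)
                return x0 + (half - y0) / (y1 - y0) * (x1 - x0)
            prev = i
        return None

    left = _cross(range(peak_idx - 1, -1, -1), reverse=True)
    right = _cross(range(peak_idx + 1, n), reverse=False)
    if left is None or right is None:
        return np.nan
    return float(right - left)


#: backprojection coverage of the true boundary of a uniform circular lumen
#: when each projection is cut at half maximum: (2/pi) * asin(sqrt(3)/2)
TIRS_IMAGE_FRACTION = 2.0 / 3.0


def tirs_diameter(frame: np.ndarray, projection_fraction: float = 0.5,
                  image_fraction: float = TIRS_IMAGE_FRACTION) -> float:
    """Penetrating-vessel equivalent diameter via thresholding in Radon space.

    The background (median) is subtracted and the frame Radon transformed over
    0-179 degrees; each projection is thresholded at ``projection_fraction``
    (default half maximum) of its own peak; the binary sinogram is
    backprojected (unfiltered), the reconstruction re-binarized at
    ``image_fraction`` of its maximum, and the area A of the largest connected
    component converted to an equivalent diameter ``2 sqrt(A / pi)``.

    The default image threshold of 2/3 is the exact coverage level of the true
    boundary for a uniform circular lumen: half-maximum strips of a disk of
    diameter d are sqrt(3)/2 d wide, and the fraction of projection angles
    whose strip covers a point on the circle is (2/pi) asin(sqrt(3)/2) = 2/3.

    Returns NaN when no component survives.
    """
    img = np.asarray(frame, dtype=float)
    img = np.clip(img - np.median(img), 0.0, None)
    if img.max() <= 0:
        return np.nan
    img = img / img.max()
    thetas = np.arange(180.0)
    sino = radon(img, theta=thetas, circle=False, preserve_range=True)
    col_max = sino.max(axis=0, keepdims=True)
    binarized = (sino >= projection_fraction * col_max).astype(float)
    recon = iradon(binarized, theta=thetas, circle=False, filter_name=None,
                   output_size=max(img.shape))
    if recon.max() <= 0:
        return np.nan
    mask = recon >= image_fraction * recon.max()
    labeled, n_lab = ndimage.label(mask)
    if n_lab == 0:
        return np.nan
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n_lab + 1))
    area = float(areas.max())
    return float(2.0 * np.sqrt(area / np.pi))


def smooth_diameter(trace: DiameterTrace, window: int = 10) -> DiameterTrace:
    """Median-filter a diameter trace (default 10-sample window).

    Even windows average the two central order statistics; edges use a
    shrinking window so the output has the input length.
    """
    d = trace.diameter
    if d.size < window:
        raise ValueError(f"trace shorter than the {window}-sample window")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    out = np.empty_like(d)
    for i in range(d.size):
        lo = max(0, i - half_lo)
        hi = min(d.size, i + half_hi + 1)
        win = d[lo:hi]
        win = np.sort(win[np.isfinite(win)])
        if win.size == 0:
            out[i] = np.nan
        elif win.size % 2:
            out[i] = win[win.size // 2]
        else:
            out[i] = 0.5 * (win[win.size // 2 - 1] + win[win.size // 2])
    return DiameterTrace(out, trace.rate, trace.baseline_diameter, trace.units)
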