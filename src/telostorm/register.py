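"""Registration of localization clusters to wide-field images, QC, DDR classes.

The merged localizations are rendered into a fine 2D histogram and aligned to
the (upsampled) wide-field probe image by FFT cross-correlation. The estimated
offset is *added* to localization coordinates to overlay them on the wide-field
frame; the same offset applies to the DDR-marker channel, which is acquired
back-to-back with the probe channel so the stage does not move between them.
Automated surrogates then replace the analyst: clusters are kept when they sit
on a bright wide-field locus (and, if a nucleus mask is supplied, inside a
nucleus) with a shape roughly matching the local wide-field patch; DDR overlap
is classified none/partial/complete from the fraction of cluster localizations
inside a thresholded DDR-locus mask.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu

from telostorm.cluster import Cluster
from telostorm.simulate import WideFieldImage


@dataclass
class RegisterParams:
    """Histogram/alignment settings.

    ``hist_bin_nm`` should equal the wide-field pixel size divided by
    ``upsample_factor`` so the two rasters share a grid (108 nm / 5 = 21.6 nm,
    i.e. the ~22 nm bins used for alignment). ``expected_offset_range_nm`` is
    diagnostic only: typical chromatic/drift offsets fall in 40-60 nm.
    """

    hist_bin_nm: float = 21.6
    upsample_factor: int = 5
    expected_offset_range_nm: tuple[float, float] = (40.0, 60.0)

    def __post_init__(self) -> None:
        if self.hist_bin_nm <= 0:
            raise ValueError("hist_bin_nm must be > 0")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")


def render_histogram(
    table: pd.DataFrame,
    bin_nm: float = 21.6,
    field_size_nm: tuple[float, float] | None = None,
) -> np.ndarray:
    """Bin localizations into a 2D count image (row = y bin, col = x bin).

    Bins are half-open intervals [k*b, (k+1)*b), so a localization exactly on a
    bin boundary lands in the higher bin; the histogram total always equals the
    number of localizations. Points at negative coordinates are clipped into
    bin 0 rather than dropped, preserving conservation.
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be > 0")
    x = table["x_nm"].to_numpy()
    y = table["y_nm"].to_numpy()
    ix = np.floor(x / bin_nm).astype(np.int64)
    iy = np.floor(y / bin_nm).astype(np.int64)
    if field_size_nm is not None:
        ncol = int(math.ceil(field_size_nm[0] / bin_nm))
        nrow = int(math.ceil(field_size_nm[1] / bin_nm))
    else:
        if len(x) == 0:
            return np.zeros((1, 1))
        ncol = int(ix.max()) + 1
        nrow = int(iy.max()) + 1
    ix = np.clip(ix, 0, ncol - 1)
    iy = np.clip(iy, 0, nrow - 1)
    hist = np.zeros((nrow, ncol))
    np.add.at(hist, (iy, ix), 1.0)
    return hist


def upsample_nearest(image: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor upsampling (each pixel becomes a factor x factor block)."""
    return np.repeat(np.repeat(image, factor, axis=0), factor, axis=1)


def estimate_offset(
    hist: np.ndarray,
    widefield: WideFieldImage,
    params: RegisterParams | None = None,
) -> tuple[float, float]:
    """Cross-correlate histogram and wide-field image; return (dx_nm, dy_nm).

    Sign convention: the returned offset is the vector to *add* to localization
    coordinates so that they overlap the wide-field features. The wide-field
    image is upsampled by nearest neighbor to the histogram bin size (preserving
    counts and avoiding interpolation bias), both rasters are mean-subtracted,
    and the correlation peak is located with an FFT-based convolution.
    """
    params = params or RegisterParams()
    if hist.sum() == 0:
        raise ValueError("histogram is empty")
    wf = upsample_nearest(np.asarray(widefield.pixels, float), params.upsample_factor)
    nrow = min(wf.shape[0], hist.shape[0])
    ncol = min(wf.shape[1], hist.shape[1])
    wf = wf[:nrow, :ncol] - wf[:nrow, :ncol].mean()
    h = hist[:nrow, :ncol] - hist[:nrow, :ncol].mean()
    corr = fftconvolve(wf, h[::-1, ::-1], mode="full")
    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
    shift_row = peak[0] - (nrow - 1)
    shift_col = peak[1] - (ncol - 1)
    return (shift_col * params.hist_bin_nm, shift_row * params.hist_bin_nm)


def apply_offset(table: pd.DataFrame, offset_nm: tuple[float, float]) -> pd.DataFrame:
    out = table.copy()
    out["x_nm"] = out["x_nm"] + offset_nm[0]
    out["y_nm"] = out["y_nm"] + offset_nm[1]
    return out


def _pixel_indices(
    xy: np.ndarray, widefield: WideFieldImage
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map nm coordinates to wide-field pixel indices; flag out-of-image points."""
    p = widefield.pixel_size_nm
    col = np.floor(xy[:, 0] / p).astype(np.int64)
    row = np.floor(xy[:, 1] / p).astype(np.int64)
    nrow, ncol = widefield.pixels.shape
    inside = (col >= 0) & (col < ncol) & (row >= 0) & (row < nrow)
    return row, col, inside


def robust_locus_threshold(image: np.ndarray) -> float:
    """Foreground threshold for spot-like images.

    Otsu's threshold computed on log intensity -- spot images can mix loci of
    very different brightness (e.g. dim foci next to bright beads), and on a
    linear scale Otsu then separates background from the brightest class only.
    The result is floored at median + 5 robust sigma so that an image with no
    real loci (pure shot noise) yields an essentially empty mask instead of a
    random bisection of the background.
    """
    img = np.asarray(image, float)
    med = np.median(img)
    mad = np.median(np.abs(img - med))
    floor = med + 5 * 1.4826 * max(mad, 1e-12)
    try:
        otsu = float(np.expm1(threshold_otsu(np.log1p(img))))
    except ValueError:  # constant image
        otsu = floor
    return max(otsu, floor)


def qc_clusters(
    clusters: list[Cluster],
    table: pd.DataFrame,
    probe_widefield: WideFieldImage,
    offset_nm: tuple[float, float],
    nucleus_mask: np.ndarray | None = None,
    locus_threshold: float | None = None,
    f_locus: float = 0.5,
    r_min: float = 0.3,
) -> list[Cluster]:
    """Automated surrogate of analyst cluster rejection; sets ``qc_status``.

    A cluster is kept iff (1) at least ``f_locus`` of its localizations fall on
    wide-field pixels brighter than the locus threshold, (2) its centroid lies
    inside ``nucleus_mask`` when one is given (skipped with a warning
    otherwise), and (3) the Pearson correlation between the cluster's rendered
    histogram and the local wide-field patch exceeds ``r_min`` (shape match).
    The first failing criterion is recorded in ``qc_reason``.
    """
    if locus_threshold is None:
        locus_threshold = robust_locus_threshold(probe_widefield.pixels)
    if nucleus_mask is None:
        warnings.warn("no nucleus mask supplied; QC criterion 2 skipped", stacklevel=2)
    bright = probe_widefield.pixels > locus_threshold
    p = probe_widefield.pixel_size_nm
    for c in clusters:
        xy = table.iloc[c.member_indices][["x_nm", "y_nm"]].to_numpy() + offset_nm
        row, col, inside = _pixel_indices(xy, probe_widefield)
        on_locus = np.zeros(len(xy), dtype=bool)
        on_locus[inside] = bright[row[inside], col[inside]]
        if on_locus.mean() < f_locus:
            c.qc_status, c.qc_reason = "rejected", "not_on_locus"
            continue
        cx, cy = xy.mean(axis=0)
        if nucleus_mask is not None:
            r0, c0 = int(cy / p), int(cx / p)
            ok = (
                0 <= r0 < nucleus_mask.shape[0]
                and 0 <= c0 < nucleus_mask.shape[1]
                and bool(nucleus_mask[r0, c0])
            )
            if not ok:
                c.qc_status, c.qc_reason = "rejected", "outside_nucleus"
                continue
        # shape match: cluster counts vs wide-field intensity on a local patch
        pr, pc = int(cy / p), int(cx / p)
        half = 3
        r0, r1 = max(0, pr - half), min(probe_widefield.pixels.shape[0], pr + half + 1)
        c0, c1 = max(0, pc - half), min(probe_widefield.pixels.shape[1], pc + half + 1)
        patch = probe_widefield.pixels[r0:r1, c0:c1]
        counts = np.zeros_like(patch)
        rr = row - r0
        cc = col - c0
        ok = inside & (rr >= 0) & (rr < patch.shape[0]) & (cc >= 0) & (cc < patch.shape[1])
        np.add.at(counts, (rr[ok], cc[ok]), 1.0)
        if patch.std() == 0 or counts.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(patch.ravel(), counts.ravel())[0, 1])
        if r <= r_min:
            c.qc_status, c.qc_reason = "rejected", "shape_mismatch"
            continue
        c.qc_status, c.qc_reason = "kept", None
    return clusters


def classify_ddr(
    clusters: list[Cluster],
    table: pd.DataFrame,
    ddr_widefield: WideFieldImage,
    offset_nm: tuple[float, float],
    f_lo: float = 0.1,
    f_hi: float = 0.9,
    threshold: float | None = None,
) -> list[Cluster]:
    """Classify each cluster's overlap with DDR-marker loci; sets ``ddr_class``.

    The DDR image is thresholded into a binary locus mask; f = fraction of the
    cluster's localizations (after the probe-channel offset) inside the mask.
    ``f < f_lo`` -> "none", ``f > f_hi`` -> "complete", else "partial".
    """
    if threshold is None:
        threshold = robust_locus_threshold(ddr_widefield.pixels)
    mask = ddr_widefield.pixels > threshold
    for c in clusters:
        xy = table.iloc[c.member_indices][["x_nm", "y_nm"]].to_numpy() + offset_nm
        row, col, inside = _pixel_indices(xy, ddr_widefield)
        hit = np.zeros(len(xy), dtype=bool)
        hit[inside] = mask[row[inside], col[inside]]
        f = float(hit.mean()) if len(xy) else 0.0
        c.ddr_fraction = f
        c.ddr_class = "none" if f < f_lo else ("complete" if f > f_hi else "partial")
    return clusters
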