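"""Radial axon-density profiling from the ganglion origin.

After orientation the ganglion sits at the top-left image corner, coordinate
(0, 0).  Each pixel is assigned the distance of its centre from that corner,
``d = pixel_scale_um * sqrt((col + 0.5)^2 + (row + 0.5)^2)``, and pixels are
grouped into half-open radial bins ``[b*w, (b+1)*w)`` of width ``w`` (default
20 um).  The bins are quarter annuli clipped to the image rectangle; the
density of a bin is the fraction of its *present* pixels that are mask-true,
so clipping does not deflate far bins.  Bins holding no pixels are reported
as missing (NaN), distinct from zero density.

Conservation holds exactly: sum over bins of density * pixel count equals the
total number of mask-true pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import DEFAULT_PIXEL_SCALE_UM, ExplantMeta
from .masking import BinaryMask

__all__ = [
    "DEFAULT_BIN_WIDTH_UM",
    "DEFAULT_COARSE_WIDTH_UM",
    "RadialProfile",
    "radial_density",
    "coarse_bin",
    "fit_decay_length",
]

DEFAULT_BIN_WIDTH_UM = 20.0
DEFAULT_COARSE_WIDTH_UM = 500.0


@dataclass
class RadialProfile:
    """Per-bin axon density versus distance from the explant origin."""

    bin_edges_um: np.ndarray          # length n_bins + 1, starts at 0, uniform width
    density: np.ndarray               # in [0, 1]; NaN where bin_pixel_count == 0
    bin_pixel_count: np.ndarray       # image pixels whose centre falls in the bin
    pixel_scale_um: float
    bin_width_um: float
    meta: ExplantMeta | None = None

    @property
    def bin_starts_um(self) -> np.ndarray:
        return self.bin_edges_um[:-1]

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def masked_pixel_total(self) -> int:
        """Total mask-true pixels recovered from the profile (conservation)."""
        d = np.nan_to_num(self.density, nan=0.0)
        return int(np.rint(np.sum(d * self.bin_pixel_count)))


def radial_density(
    mask: BinaryMask | np.ndarray,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    meta: ExplantMeta | None = None,
) -> RadialProfile:
    """Bin a binary mask into radial occupancy fractions.

    Pixel-centre convention: the pixel at row ``r``, column ``c`` lies at
    distance ``pixel_scale_um * sqrt((c + 0.5)^2 + (r + 0.5)^2)`` from the
    origin corner; it belongs to bin ``floor(d / bin_width_um)``.  Bins extend
    to the farthest pixel of the image.
    """
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError(f"mask must be a non-empty 2D array, got shape {pixels.shape}")
    pixels = pixels.astype(bool, copy=False)
    if not pixel_scale_um > 0:
        raise ValueError(f"pixel_scale_um must be > 0, got {pixel_scale_um!r}")
    if not bin_width_um > 0:
        raise ValueError(f"bin_width_um must be > 0, got {bin_width_um!r}")

    rows, cols = pixels.shape
    yy = (np.arange(rows, dtype=np.float64) + 0.5)[:, None]
    xx = (np.arange(cols, dtype=np.float64) + 0.5)[None, :]
    dist = pixel_scale_um * np.sqrt(xx * xx + yy * yy)
    bin_idx = np.floor(dist / bin_width_um).astype(np.int64)

    n_bins = int(bin_idx.max()) + 1
    total = np.bincount(bin_idx.ravel(), minlength=n_bins)
    occupied = np.bincount(bin_idx.ravel()[pixels.ravel()], minlength=n_bins)

    density = np.full(n_bins, np.nan)
    nonempty = total > 0
    density[nonempty] = occupied[nonempty] / total[nonempty]

    edges = bin_width_um * np.arange(n_bins + 1, dtype=np.float64)
    return RadialProfile(
        bin_edges_um=edges,
        density=density,
        bin_pixel_count=total.astype(np.int64),
        pixel_scale_um=float(pixel_scale_um),
        bin_width_um=float(bin_width_um),
        meta=meta,
    )


def coarse_bin(profile: RadialProfile, coarse_width_um: float = DEFAULT_COARSE_WIDTH_UM) -> RadialProfile:
    """Aggregate a fine profile into wider statistical bins by averaging.

    The coarse density over ``[c*W, (c+1)*W)`` is the unweighted mean of the
    fine-bin densities whose bin start lies in that interval, skipping missing
    fine bins; a coarse bin with no contributing fine bins is missing.  The
    coarse width must be a positive integer multiple of the fine width.
    ``bin_pixel_count`` of a coarse bin is the summed count of its fine bins
    (informational: the unweighted mean does not preserve pixel conservation).
    """
    ratio = coarse_width_um / profile.bin_width_um
    if not coarse_width_um > 0 or abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"coarse_width_um ({coarse_width_um}) must be a positive multiple "
            f"of the fine bin width ({profile.bin_width_um})"
        )
    starts = profile.bin_starts_um
    coarse_idx = np.floor(starts / coarse_width_um + 1e-9).astype(np.int64)
    n_coarse = int(coarse_idx.max()) + 1

    density = np.full(n_coarse, np.nan)
    counts = np.zeros(n_coarse, dtype=np.int64)
    for c in range(n_coarse):
        sel = coarse_idx == c
        vals = profile.density[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            density[c] = float(np.mean(vals))
        counts[c] = int(profile.bin_pixel_count[sel].sum())

    edges = coarse_width_um * np.arange(n_coarse + 1, dtype=np.float64)
    return RadialProfile(
        bin_edges_um=edges,
        density=density,
        bin_pixel_count=counts,
        pixel_scale_um=profile.pixel_scale_um,
        bin_width_um=float(coarse_width_um),
        meta=profile.meta,
    )


def fit_decay_length(
    bin_centers_um: np.ndarray,
    density: np.ndarray,
    *,
    d_min_um: float | None = None,
    d_max_um: float | None = None,
    distance_compensated: bool = True,
    coverage_corrected: bool = True,
) -> tuple[float, float]:
    """Least-squares exponential fit of the radial decay length.

    Fits ``A * exp(-d / lam)`` and returns ``(lam, A)``.  Two geometric
    corrections separate the axon survival curve from the raw occupancy
    profile of outgrowth radiating from a corner origin:

    - ``coverage_corrected`` (default): occupancy saturates where axons
      overlap; for quasi-random placement the occupied fraction ``p`` relates
      to the underlying axon abundance by ``p = 1 - exp(-rho)``, so fitting
      ``rho = -log(1 - p)`` removes the overlap nonlinearity.  Fully
      saturated bins (``p = 1``) carry no decay information and are dropped.
    - ``distance_compensated`` (default): the quarter-annulus pixel count
      grows linearly with ``d`` while each surviving axon contributes a fixed
      crossing area, so the occupancy carries a geometric ``1/d`` factor; the
      fit is performed on ``y * d`` — the per-arc-length abundance — whose
      expectation is a pure exponential under exponential survival.

    With both corrections ``lam`` estimates the survival decay length.  Set
    both to ``False`` to fit the raw profile.
    """
    d = np.asarray(bin_centers_um, dtype=np.float64)
    y = np.asarray(density, dtype=np.float64)
    keep = ~np.isnan(y) & (y > 0)
    if coverage_corrected:
        keep &= y < 1.0
    if d_min_um is not None:
        keep &= d >= d_min_um
    if d_max_um is not None:
        keep &= d <= d_max_um
    d, y = d[keep], y[keep]
    if d.size < 3:
        raise ValueError("need at least 3 positive bins in range to fit a decay length")
    if coverage_corrected:
        y = -np.log1p(-y)
    if distance_compensated:
        y = y * d
    # log-linear regression for the starting point, then nonlinear refinement
    slope, intercept = np.polyfit(d, np.log(y), 1)
    lam0 = -1.0 / slope if slope < 0 else d.max()
    a0 = float(np.exp(intercept))
    popt, _ = curve_fit(
        lambda x, a, lam: a * np.exp(-x / lam),
        d, y, p0=(a0, max(lam0, 1.0)), maxfev=10000,
    )
    return float(popt[1]), float(popt[0])
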