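"""Attenuation-histogram indices of pulmonary congestion and the air/tissue
volume partition.

The lung attenuation histogram carries the signature of extravascular lung
water (EVLW): fluid raises voxel attenuation, producing a heavy right-hand
tail.  The indices computed here summarise that tail — mean HU, sample
skewness and excess kurtosis, the full width at half maximum (FWHM) of the
histogram, and the percentage of voxels above -500 HU (the congestion
index).  Each voxel is additionally partitioned linearly between pure air
(-1000 HU) and pure tissue (+55 HU) to yield whole-lung air and tissue
volumes (Vair, Vtis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CTVolume, RegionMask

__all__ = [
    "DensityHistogram",
    "DensityMetrics",
    "distribution_moments",
    "build_histogram",
    "fwhm",
    "congestion_index",
    "voxel_air_fraction",
    "lung_air_tissue_volumes",
    "compute_density_metrics",
    "percent_change",
]

#: Calibration span of the linear air/tissue partition: pure air to pure tissue.
HU_AIR = -1000.0
HU_TISSUE = 55.0

#: Congestion-index threshold (strictly-greater-than).
CONGESTION_THRESHOLD_HU = -500.0


@dataclass
class DensityHistogram:
    """Binned attenuation distribution of the analysis region."""

    bin_edges: np.ndarray  # length n_bins + 1, strictly increasing, HU
    counts: np.ndarray  # length n_bins, voxel counts
    bin_width: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class DensityMetrics:
    """Per-scan histogram indices and air/tissue volumes."""

    mean_hu: float
    skewness: float
    kurtosis: float  # excess kurtosis (Normal = 0)
    kurtosis_raw: float  # m4/m2^2 (Normal = 3)
    fwhm: float  # HU
    pct_gt_m500: float  # % of analysis voxels > -500 HU
    v_air: float  # L
    v_tis: float  # L
    n_voxels: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_hu": self.mean_hu,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "kurtosis_raw": self.kurtosis_raw,
            "fwhm": self.fwhm,
            "pct_gt_m500": self.pct_gt_m500,
            "v_air": self.v_air,
            "v_tis": self.v_tis,
            "n_voxels": self.n_voxels,
        }


def distribution_moments(values: np.ndarray) -> tuple[float, float, float]:
    """Mean, sample skewness g1 and excess kurtosis g2 of an HU sample.

    g1 = m3 / m2^1.5 and g2 = m4 / m2^2 - 3 with mk the k-th central
    sample moment (biased, i.e. divided by n).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 3:
        raise ValueError(f"need at least 3 values, got {values.size}")
    if np.ptp(values) == 0:
        raise ValueError("degenerate distribution: zero variance")
    mean = float(np.mean(values))
    g1 = float(stats.skew(values, bias=True))
    g2 = float(stats.kurtosis(values, fisher=True, bias=True))
    return mean, g1, g2


def build_histogram(values: np.ndarray, bin_width: float = 1.0) -> DensityHistogram:
    """Histogram an HU sample with bins of fixed width aligned to multiples
    of ``bin_width``."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return DensityHistogram(bin_edges=edges, counts=counts, bin_width=float(bin_width))


def fwhm(hist: DensityHistogram) -> float:
    """Full width at half maximum of a histogram, in HU.

    The mode bin is located (ties broken toward lower HU) and the two
    half-maximum crossings are found searching outward from the mode, with
    linear interpolation between adjacent bin centers.  The distribution is
    taken to be zero outside the binned range, so a flat-topped histogram
    of width W returns W and a single occupied bin returns the bin width.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if counts.size == 0 or counts.max() <= 0:
        raise ValueError("empty histogram")
    centers = hist.bin_centers
    # pad with one empty bin per side: zero density outside the binned range
    bw = hist.bin_width
    counts = np.concatenate([[0.0], counts, [0.0]])
    centers = np.concatenate([[centers[0] - bw], centers, [centers[-1] + bw]])
    mode = int(np.argmax(counts))  # argmax takes the first (lowest-HU) tie
    half = counts[mode] / 2.0

    def crossing(direction: int) -> float:
        i = mode
        while 0 <= i + direction < counts.size:
            j = i + direction
            if counts[j] < half:
                # interpolate between centers i (>= half) and j (< half)
                frac = (counts[i] - half) / (counts[i] - counts[j])
                return float(centers[i] + frac * (centers[j] - centers[i]))
            i = j
        side = "left" if direction < 0 else "right"
        raise ValueError(f"half maximum never crossed on the {side} side")

    return crossing(+1) - crossing(-1)


def congestion_index(
    values: np.ndarray, threshold: float = CONGESTION_THRESHOLD_HU
) -> float:
    """Percentage of voxels with attenuation strictly greater than
    ``threshold`` (default -500 HU) — an index of pulmonary congestion."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    return 100.0 * float(np.count_nonzero(values > threshold)) / values.size


def voxel_air_fraction(hu: np.ndarray | float) -> np.ndarray | float:
    """Per-voxel air fraction from the linear attenuation partition.

    f_air = (55 - HU) / (55 - (-1000)), clamped to [0, 1]; the tissue
    fraction is 1 - f_air by construction.
    """
    f = (HU_TISSUE - np.asarray(hu, dtype=float)) / (HU_TISSUE - HU_AIR)
    return np.clip(f, 0.0, 1.0)


def lung_air_tissue_volumes(
    volume: CTVolume, mask: RegionMask
) -> tuple[float, float]:
    """Air and tissue volumes (L) of the masked lung.

    The mean per-voxel air (tissue) fraction is multiplied by the total
    masked volume, itself the voxel count times the voxel volume.
    """
    mask.check_aligned(volume)
    n = mask.n_voxels
    if n == 0:
        raise ValueError("empty mask")
    total_l = n * volume.voxel_volume_mm3 * 1e-6  # mm^3 -> L
    f_air = voxel_air_fraction(volume.values[mask.mask])
    v_air = float(np.mean(f_air)) * total_l
    return v_air, total_l - v_air


def compute_density_metrics(
    volume: CTVolume, mask: RegionMask, bin_width: float = 1.0
) -> DensityMetrics:
    """All congestion indices of a masked volume in one pass.

    Moments and the congestion index are computed on the raw voxel values;
    only the FWHM uses the binned histogram.
    """
    mask.check_aligned(volume)
    values = volume.values[mask.mask]
    if values.size == 0:
        raise ValueError("empty mask")
    mean_hu, g1, g2 = distribution_moments(values)
    hist = build_histogram(values, bin_width=bin_width)
    v_air, v_tis = lung_air_tissue_volumes(volume, mask)
    return DensityMetrics(
        mean_hu=mean_hu,
        skewness=g1,
        kurtosis=g2,
        kurtosis_raw=g2 + 3.0,
        fwhm=fwhm(hist),
        pct_gt_m500=congestion_index(values),
        v_air=v_air,
        v_tis=v_tis,
        n_voxels=int(values.size),
    )


def percent_change(
    pre: DensityMetrics,
    post: DensityMetrics,
    mean_convention: str = "magnitude",
) -> dict[str, float]:
    """Per-index percent change from pre- to post-bronchodilator metrics.

    For the mean HU the default ``magnitude`` convention reports
    100*(|post| - |pre|)/|pre|, so a leftward shift of the histogram toward
    -1000 HU (fluid clearance) is a POSITIVE change; ``signed`` applies the
    plain formula instead.  Every other index uses 100*(post - pre)/|pre|.
    Indices whose baseline is zero are returned as NaN.
    """
    if mean_convention not in ("magnitude", "signed"):
        raise ValueError(f"unknown mean convention {mean_convention!r}")
    out: dict[str, float] = {}
    pre_d, post_d = pre.as_dict(), post.as_dict()
    for key in ("mean_hu", "skewness", "kurtosis", "fwhm", "pct_gt_m500"):
        a, b = pre_d[key], post_d[key]
        if key == "mean_hu" and mean_convention == "magnitude":
            a, b = abs(a), abs(b)
        out[key] = 100.0 * (b - a) / abs(a) if a != 0 else float("nan")
    return out
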