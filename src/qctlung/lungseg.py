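"""Lung-field segmentation and the analysis-mask exclusion rules.

Lung parenchyma is far darker than the surrounding soft tissue, so the lung
fields are recovered by thresholding, discarding the background air that
touches the grid border, and keeping the two largest interior components
(left and right lung).  The analysis mask applied before any histogram
measurement then removes airway-lumen voxels and voxels outside the
-1000..0 HU range (boundary values inclusive).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import CTVolume, RegionMask

__all__ = ["segment_lung_fields", "apply_analysis_exclusions"]

# face connectivity for component labeling: a diagonal-only contact through a
# one-voxel airway wall must not merge lumen air with the lung fields
_STRUCT6 = ndimage.generate_binary_structure(3, 1)
# 26-neighborhood element for morphological closing
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _border_labels(labels: np.ndarray) -> set[int]:
    faces = [
        labels[0], labels[-1],
        labels[:, 0], labels[:, -1],
        labels[:, :, 0], labels[:, :, -1],
    ]
    out: set[int] = set()
    for f in faces:
        out.update(np.unique(f).tolist())
    out.discard(0)
    return out


def segment_lung_fields(
    volume: CTVolume,
    threshold_hu: float = -320.0,
    min_component_voxels: int = 64,
) -> RegionMask:
    """Segment the lung fields of a thoracic CT volume.

    Voxels below ``threshold_hu`` are candidate air; components connected
    to the grid border (ambient air) are discarded, components smaller than
    ``min_component_voxels`` are dropped, and the two largest remaining
    components are kept as the lungs.  A one-voxel morphological closing
    and hole filling absorb bright intra-parenchymal voxels (vessels,
    edema) into the field.

    Raises
    ------
    ValueError
        If no interior sub-threshold component remains ("no lung fields").

    Warns if only a single component is found (fused lungs) and proceeds.
    """
    air = volume.values < threshold_hu
    labels, n = ndimage.label(air, structure=_STRUCT6)
    if n == 0:
        raise ValueError("no lung fields: no voxels below threshold")
    drop = _border_labels(labels)
    sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels,
                               index=np.arange(1, n + 1))
    candidates = [
        (int(sz), lab)
        for lab, sz in zip(range(1, n + 1), sizes)
        if lab not in drop and sz >= min_component_voxels
    ]
    if not candidates:
        raise ValueError("no lung fields: all sub-threshold voxels are "
                         "border-connected or below the size floor")
    candidates.sort(reverse=True)
    keep = [lab for _, lab in candidates[:2]]
    if len(candidates) == 1:
        warnings.warn("single lung component found (fused lungs?); proceeding",
                      stacklevel=2)
    mask = np.isin(labels, keep)
    mask = ndimage.binary_closing(mask, structure=_STRUCT26, border_value=0)
    mask = ndimage.binary_fill_holes(mask)
    return RegionMask(mask=mask, label="lung")


def apply_analysis_exclusions(
    volume: CTVolume,
    lung: RegionMask,
    airway_lumen: RegionMask | None = None,
    hu_range: tuple[float, float] = (-1000.0, 0.0),
) -> tuple[RegionMask, dict[str, int]]:
    """Restrict a lung mask to the voxels entering histogram analysis.

    Voxels outside ``hu_range`` (inclusive at both ends) and airway-lumen
    voxels are excluded.  Returns the analysis mask and a per-rule count of
    excluded voxels (a voxel failing both rules is counted under each).
    """
    lung.check_aligned(volume)
    lo, hi = hu_range
    in_range = (volume.values >= lo) & (volume.values <= hi)
    mask = lung.mask & in_range
    excluded = {
        "outside_hu_range": int(np.count_nonzero(lung.mask & ~in_range)),
        "airway_lumen": 0,
    }
    if airway_lumen is not None:
        airway_lumen.check_aligned(volume)
        excluded["airway_lumen"] = int(np.count_nonzero(lung.mask & airway_lumen.mask))
        mask &= ~airway_lumen.mask
    if not mask.any():
        raise ValueError("empty analysis mask")
    return RegionMask(mask=mask, label="analysis"), excluded
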