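"""Lesion masks: Otsu baselines and morphological refinement.

A lesion should be one connected region (the ablation temperature field is
continuous), so predicted masks are refined by filling holes and keeping
only the largest 8-connected foreground component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import ParameterError
from .homodyned_k import EstimationError
from .mapping import ParametricMap

logger = logging.getLogger(__name__)

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)

OTSU_BINS = 256


@dataclass
class BinaryMask:
    """0/1 mask with pixel geometry and provenance (svm | otsu:<param> | truth)."""

    data: np.ndarray
    pixel_size_mm: tuple[float, float] = (1.0, 1.0)  # (row, col)
    provenance: str = ""
    empty_warning: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(self.data, (0, 1)).all():
            raise ParameterError("mask values must be 0 or 1")
        self.data = self.data.astype(np.uint8)

    @property
    def area_px(self) -> int:
        return int(self.data.sum())


def otsu_segment(pmap: ParametricMap, pixel_size_mm=(1.0, 1.0)) -> BinaryMask:
    """Global Otsu threshold on the normalized map; above-threshold -> 1."""
    values = pmap.normalized_values
    if values is None:
        raise ParameterError("map must be normalized before Otsu segmentation")
    if values.max() == values.min():
        raise EstimationError("constant map has no Otsu threshold")
    threshold = threshold_otsu(values, nbins=OTSU_BINS)
    return BinaryMask(
        data=(values > threshold).astype(np.uint8),
        pixel_size_mm=pixel_size_mm,
        provenance=f"otsu:{pmap.parameter_name}",
    )


def refine_mask(mask: BinaryMask) -> BinaryMask:
    """Fill holes (4-connected background), keep the largest 8-connected component."""
    data = mask.data.astype(bool)
    if not data.any():
        logger.warning("refine_mask: empty input mask (%s)", mask.provenance)
        return BinaryMask(
            data=np.zeros_like(mask.data),
            pixel_size_mm=mask.pixel_size_mm,
            provenance=mask.provenance,
            empty_warning=True,
        )
    filled = ndimage.binary_fill_holes(data)
    labels, n = ndimage.label(filled, structure=_STRUCTURE_8)
    if n > 1:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        order = np.flatnonzero(areas == areas.max()) + 1
        if len(order) > 1:
            logger.info("refine_mask: %d equal-area largest components; "
                        "keeping the first in scan order", len(order))
        filled = labels == order[0]  # scan order => topmost-leftmost tie-break
    return BinaryMask(
        data=filled.astype(np.uint8),
        pixel_size_mm=mask.pixel_size_mm,
        provenance=mask.provenance,
    )


def save_mask_png(mask: BinaryMask, path) -> None:
    import imageio.v3 as iio
    import json
    from pathlib import Path

    iio.imwrite(path, mask.data * np.uint8(255))
    sidecar = {
        "pixel_size_mm": list(mask.pixel_size_mm),
        "provenance": mask.provenance,
    }
    p = Path(path)
    p.with_suffix(p.suffix + ".json").write_text(json.dumps(sidecar))


def load_mask_png(path) -> BinaryMask:
    import imageio.v3 as iio
    import json
    from pathlib import Path

    data = (np.asarray(iio.imread(path)) > 127).astype(np.uint8)
    p = Path(path)
    sidecar_path = p.with_suffix(p.suffix + ".json")
    pixel_size, provenance = (1.0, 1.0), ""
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size = tuple(sidecar.get("pixel_size_mm", pixel_size))
        provenance = sidecar.get("provenance", "")
    return BinaryMask(data=data, pixel_size_mm=pixel_size, provenance=provenance)
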