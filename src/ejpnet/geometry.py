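"""Layer segmentation, mean fluorescence intensity, and epithelial height.

The stratified squamous epithelium of the ectocervix is divided into three
strata by where the junction protein is expressed: a superficial layer
toward the lumen without staining, an intermediate layer carrying the
strand net, and a basal layer toward the basement membrane without
staining.  The intermediate layer is recovered by morphologically closing
the detected strand mask (so whole cells, not just their borders, belong
to the layer); the superficial layer is whatever part of the remaining
compartment is geodesically connected to the apical border without
crossing the intermediate band, and the basal layer is the rest.

Epithelial height is measured from a Euclidean distance transform seeded
on the basal border: every apical-border pixel reads off its distance (µm)
to the nearest basal-border pixel, and the ROI height is the mean of those
one-way distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .core import CROSS, EpitheliumROI, FluorescenceImage
from .ridge import StrandMask

__all__ = [
    "EpitheliumROI",
    "LayerSegmentation",
    "GeometryMetrics",
    "NoStrandExpressionError",
    "segment_layers",
    "compute_mfi",
    "compute_height",
]

logger = logging.getLogger(__name__)


class NoStrandExpressionError(ValueError):
    """Raised when an ROI shows no junction-protein expression at all."""


@dataclass
class LayerSegmentation:
    """Disjoint superficial / intermediate / basal masks covering the ROI."""

    superficial: np.ndarray
    intermediate: np.ndarray
    basal: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.superficial = np.asarray(self.superficial, dtype=bool)
        self.intermediate = np.asarray(self.intermediate, dtype=bool)
        self.basal = np.asarray(self.basal, dtype=bool)


@dataclass
class GeometryMetrics:
    mfi_epithelium: float
    mfi_intermediate: float
    height_um: float


def segment_layers(
    strands: StrandMask, roi: EpitheliumROI, closing_radius_px: int = 15
) -> LayerSegmentation:
    """Partition the ROI interior into the three epithelial layers.

    The intermediate layer is the disc closing (radius
    ``closing_radius_px``, default roughly half a cell diameter) of the
    strand mask, hole-filled and clipped to the interior.  Interior pixels
    reachable from the apical border without entering the intermediate
    band form the superficial layer; all remaining interior pixels are
    basal.  The three masks always partition the interior exactly.

    Raises
    ------
    NoStrandExpressionError
        If the strand mask is empty ("no EJP expression").
    """
    mask = np.asarray(strands.mask, dtype=bool)
    if mask.shape != roi.shape:
        raise ValueError("strand mask and ROI shapes differ")
    if not mask.any():
        raise NoStrandExpressionError("no EJP expression: empty strand mask")
    if np.any(mask & ~roi.interior):
        mask = mask & roi.interior

    r = int(closing_radius_px)
    if r > 0:
        padded = np.pad(mask, r + 1)
        closed = ndimage.binary_closing(padded, structure=disk(r))
        closed = closed[r + 1 : -(r + 1), r + 1 : -(r + 1)]
    else:
        closed = mask
    intermediate = ndimage.binary_fill_holes(closed) & roi.interior
    intermediate |= mask  # closing is extensive, but guard the clip

    notes: list[str] = []
    free = roi.interior & ~intermediate
    superficial = np.zeros(roi.shape, dtype=bool)
    if free.any():
        labels, _ = ndimage.label(free, structure=CROSS)
        apical_adjacent = ndimage.binary_dilation(roi.apical_border, structure=CROSS) & free
        seed_labels = np.unique(labels[apical_adjacent])
        seed_labels = seed_labels[seed_labels > 0]
        if seed_labels.size:
            superficial = np.isin(labels, seed_labels)
    basal = free & ~superficial

    if not superficial.any():
        notes.append("empty superficial layer (strands reach the apical border)")
    if not basal.any():
        notes.append("empty basal layer (strands reach the basal border)")
    for note in notes:
        logger.warning("%s/%s: %s", roi.sample_id, roi.roi_id, note)
        warnings.warn(note, stacklevel=2)

    return LayerSegmentation(superficial, intermediate, basal, notes)


def compute_mfi(image: FluorescenceImage, mask: np.ndarray) -> float:
    """Mean fluorescence intensity of the raw image over a mask.

    MFI is a proxy of protein expression, so it is always computed on raw
    intensities, never on the enhanced response.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    if not mask.any():
        raise ValueError("cannot compute MFI over an empty mask")
    return float(image.intensities[mask].mean())


def compute_height(
    roi: EpitheliumROI, pixel_size_um: float = 0.325, report_round_trip: bool = False
) -> float:
    """Mean epithelial thickness in micrometres.

    A Euclidean distance transform seeded on the basal border assigns each
    pixel its distance to the nearest basal-border pixel; the height is
    the mean of that distance over apical-border pixels.  By default the
    one-way apical-to-basal distance is reported (the standard thickness
    estimator); ``report_round_trip=True`` doubles it to the
    there-and-back distance.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    if not roi.apical_border.any() or not roi.basal_border.any():
        raise ValueError("both border sets must be non-empty")
    dist_to_basal = ndimage.distance_transform_edt(
        ~roi.basal_border, sampling=pixel_size_um
    )
    height = float(dist_to_basal[roi.apical_border].mean())
    return 2.0 * height if report_round_trip else height
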