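"""Core containers shared across the pipeline.

A :class:`FluorescenceImage` holds one channel of a scanned slide; an
:class:`EpitheliumROI` holds the manually annotated epithelial compartment
with its apical (lumen-facing) and basal (membrane-facing) borders.  ROI
annotations travel as integer label masks with the convention

    0 = outside the compartment
    1 = epithelium interior
    2 = apical border
    3 = basal border
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Recognised staining channels (junction proteins) plus a catch-all.
CHANNELS = ("DSG1", "CLDN1", "ZO1", "ECAD", "other")

LABEL_OUTSIDE = 0
LABEL_INTERIOR = 1
LABEL_APICAL = 2
LABEL_BASAL = 3


@dataclass
class FluorescenceImage:
    """Single-channel fluorescence intensity grid.

    Parameters
    ----------
    intensities
        2-D array of non-negative intensities in arbitrary units.
    pixel_size_um
        Physical pixel size in micrometres (0.325 µm at 20x on the
        slide scanner the defaults assume).
    channel
        Staining channel; one of :data:`CHANNELS`.
    """

    intensities: np.ndarray
    pixel_size_um: float = 0.325
    channel: str = "other"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 2-D array")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class EpitheliumROI:
    """Annotated epithelial compartment.

    ``interior`` is the compartment proper; ``apical_border`` and
    ``basal_border`` are disjoint one-pixel-thick border sets adjacent to
    the interior.  Flooding starts from interior pixels touching the
    apical border; height is measured between the two borders.
    """

    interior: np.ndarray
    apical_border: np.ndarray
    basal_border: np.ndarray
    roi_id: str = "roi0"
    sample_id: str = "sample0"

    def __post_init__(self) -> None:
        self.interior = np.asarray(self.interior, dtype=bool)
        self.apical_border = np.asarray(self.apical_border, dtype=bool)
        self.basal_border = np.asarray(self.basal_border, dtype=bool)
        if not (self.interior.shape == self.apical_border.shape == self.basal_border.shape):
            raise ValueError("interior and border masks must share a shape")
        if not self.apical_border.any():
            raise ValueError("no apical border pixels in ROI")
        if not self.basal_border.any():
            raise ValueError("no basal border pixels in ROI")
        if np.any(self.apical_border & self.basal_border):
            raise ValueError("apical and basal borders overlap")
        if np.any(self.interior & (self.apical_border | self.basal_border)):
            raise ValueError("border pixels must not be labelled interior")

    @property
    def shape(self) -> tuple[int, int]:
        return self.interior.shape

    def to_label_mask(self) -> np.ndarray:
        """Serialize to the 0/1/2/3 integer label convention."""
        labels = np.zeros(self.shape, dtype=np.uint8)
        labels[self.interior] = LABEL_INTERIOR
        labels[self.apical_border] = LABEL_APICAL
        labels[self.basal_border] = LABEL_BASAL
        return labels

    @classmethod
    def from_label_mask(
        cls, labels: np.ndarray, roi_id: str = "roi0", sample_id: str = "sample0"
    ) -> "EpitheliumROI":
        labels = np.asarray(labels)
        known = {LABEL_OUTSIDE, LABEL_INTERIOR, LABEL_APICAL, LABEL_BASAL}
        present = set(np.unique(labels).tolist())
        unknown = present - known
        if unknown:
            raise ValueError(f"unknown label code(s) {sorted(unknown)} in ROI mask")
        if LABEL_APICAL not in present:
            raise ValueError("no apical border (label code 2) in ROI mask")
        if LABEL_BASAL not in present:
            raise ValueError("no basal border (label code 3) in ROI mask")
        return cls(
            interior=labels == LABEL_INTERIOR,
            apical_border=labels == LABEL_APICAL,
            basal_border=labels == LABEL_BASAL,
            roi_id=roi_id,
            sample_id=sample_id,
        )


#: 4-connectivity structuring element used whenever traversable background
#: is flooded; strands themselves are treated as 8-connected, so diagonal
#: strand steps block 4-connected flow (digital Jordan duality).
CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
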