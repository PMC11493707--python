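"""Net fragmentation, flooded accessibility, and intact/fragmented partition.

The junction net is treated as a physical barrier to an incoming virion.
A break wider than one pixel (0.325 µm at the default resolution) is wide
enough for viral passage; one-pixel breaks are rasterisation noise and are
sealed.  The sealed net then gates a digital flood that starts at the
apical border and advances through 4-connected free pixels — the reached
set is the "accessible region", the geometric depth an external microbe
could penetrate.  Finally the intermediate (net-bearing) layer is split
into intact and fragmented territory by a watershed over the holes of the
net: each hole seeds a basin bounded by strand ridgelines, and basins
whose hole the flood reached are fragmented.

Connectivity duality is load-bearing throughout: strands are 8-connected,
traversable background is 4-connected, so flow can never slip through the
corner of a diagonal strand step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .core import CROSS, EpitheliumROI
from .geometry import LayerSegmentation
from .ridge import StrandMask

__all__ = [
    "NetIntegrityResult",
    "seal_small_breaks",
    "flood_accessible",
    "partition_intact_fragmented",
    "coverage",
    "assess_net_integrity",
]

logger = logging.getLogger(__name__)

# Clockwise ring of 8-neighbour offsets; consecutive entries are the
# adjacent ring positions, so runs of 1s in this cyclic order are the
# connected arcs of strand pixels around a background pixel.
_RING = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def _bridge_lut() -> np.ndarray:
    """For every 8-bit ring pattern: does it contain >= 2 strand arcs?"""
    lut = np.zeros(256, dtype=bool)
    for pattern in range(1, 256):
        bits = [(pattern >> i) & 1 for i in range(8)]
        arcs = sum(1 for i in range(8) if bits[i] and not bits[(i - 1) % 8])
        lut[pattern] = arcs >= 2
    return lut


_BRIDGE_LUT = _bridge_lut()


@dataclass
class NetIntegrityResult:
    """Masks and coverage percentages describing one ROI's net."""

    sealed_strands: np.ndarray
    accessible: np.ndarray
    intact_region: np.ndarray
    fragmented_region: np.ndarray
    pct_accessible: float  # % of the epithelial interior
    pct_intact: float  # % of the epithelial interior
    pct_fragmented_intermediate: float  # % of the intermediate layer
    n_interior_px: int
    n_intermediate_px: int


def seal_small_breaks(strands: StrandMask | np.ndarray) -> np.ndarray:
    """Bridge one-pixel breaks in the strand mask.

    A background pixel is filled when its 8-neighbour ring carries two or
    more mutually disconnected strand arcs — the morphological *bridge*
    operation.  This seals breaks of exactly one pixel while leaving any
    two-pixel (or wider) break open, implementing the rule that only
    breaks *greater* than one pixel count as fragmentation.  A plain 3x3
    closing would not do: it also bridges two-pixel breaks.
    """
    mask = np.asarray(strands.mask if isinstance(strands, StrandMask) else strands, dtype=bool)
    if not mask.any():
        return mask.copy()
    padded = np.pad(mask, 1)
    pattern = np.zeros(mask.shape, dtype=np.uint8)
    for bit, (dr, dc) in enumerate(_RING):
        shifted = padded[1 + dr : 1 + dr + mask.shape[0], 1 + dc : 1 + dc + mask.shape[1]]
        pattern |= (shifted.astype(np.uint8)) << bit
    return mask | (~mask & _BRIDGE_LUT[pattern])


def flood_accessible(sealed: np.ndarray, roi: EpitheliumROI) -> np.ndarray:
    """Flood the interior from the apical border, gated by the sealed net.

    4-connected flood fill over ``interior \\ sealed``, seeded from every
    free interior pixel adjacent to an apical-border pixel.  Returns the
    reached set; empty (with a logged warning) when the net blocks the
    apical border completely.
    """
    sealed = np.asarray(sealed, dtype=bool)
    if sealed.shape != roi.shape:
        raise ValueError("sealed mask and ROI shapes differ")
    free = roi.interior & ~sealed
    seeds = free & ndimage.binary_dilation(roi.apical_border, structure=CROSS)
    if not seeds.any():
        logger.warning(
            "%s/%s: no free pixel adjacent to the apical border; accessible region empty",
            roi.sample_id,
            roi.roi_id,
        )
        return np.zeros(roi.shape, dtype=bool)
    labels, _ = ndimage.label(free, structure=CROSS)
    reached = np.unique(labels[seeds])
    reached = reached[reached > 0]
    return np.isin(labels, reached)


def partition_intact_fragmented(
    sealed: np.ndarray,
    accessible: np.ndarray,
    layers: LayerSegmentation,
    min_hole_px: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the intermediate layer into intact and fragmented regions.

    Holes (4-connected components of ``intermediate \\ sealed``) seed a
    watershed whose elevation is the negated Euclidean distance to the
    sealed net, so basin boundaries sit on strand ridgelines and each
    basin coincides with one morphological cell.  Strand pixels join the
    adjacent basin.  A basin is fragmented when its seed hole intersects
    the accessible region — the flood got into that cell — and intact
    otherwise.  The two outputs always partition the intermediate layer.

    Slivers smaller than ``min_hole_px`` are rasterisation debris inside
    the strand lines, not holes of the net; they do not seed basins and
    are absorbed into the surrounding cell.
    """
    sealed = np.asarray(sealed, dtype=bool)
    accessible = np.asarray(accessible, dtype=bool)
    intermediate = layers.intermediate
    if not (sealed.shape == accessible.shape == intermediate.shape):
        raise ValueError("inputs must share a shape")
    if not intermediate.any():
        raise ValueError("intermediate layer is empty")

    holes = intermediate & ~sealed
    hole_labels, n_holes = ndimage.label(holes, structure=CROSS)
    if n_holes and min_hole_px > 1:
        sizes = np.bincount(hole_labels.ravel())
        sizes[0] = 0
        keep = sizes >= min_hole_px
        hole_labels = np.where(keep[hole_labels], hole_labels, 0)
        n_holes = int(keep.sum())
    if n_holes == 0:
        # Net (or its closure) tiles the whole layer: everything intact.
        return intermediate.copy(), np.zeros_like(intermediate)

    elevation = -ndimage.distance_transform_edt(~sealed)
    basins = watershed(elevation, markers=hole_labels, mask=intermediate)

    fragmented_ids = np.unique(hole_labels[accessible & (hole_labels > 0)])
    fragmented_ids = fragmented_ids[fragmented_ids > 0]
    fragmented = np.isin(basins, fragmented_ids) & intermediate
    intact = intermediate & ~fragmented
    return intact, fragmented


def coverage(mask: np.ndarray, reference: np.ndarray) -> float:
    """Percentage of ``reference`` covered by ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if mask.shape != reference.shape:
        raise ValueError("mask and reference shapes differ")
    n_ref = int(reference.sum())
    if n_ref == 0:
        raise ValueError("reference mask is empty")
    return 100.0 * int((mask & reference).sum()) / n_ref


def assess_net_integrity(
    strands: StrandMask, roi: EpitheliumROI, layers: LayerSegmentation
) -> NetIntegrityResult:
    """Run seal → flood → partition → coverage for one ROI."""
    sealed = seal_small_breaks(strands)
    accessible = flood_accessible(sealed, roi)
    intact, fragmented = partition_intact_fragmented(sealed, accessible, layers)
    n_interior = int(roi.interior.sum())
    n_intermediate = int(layers.intermediate.sum())
    return NetIntegrityResult(
        sealed_strands=sealed,
        accessible=accessible,
        intact_region=intact,
        fragmented_region=fragmented,
        pct_accessible=coverage(accessible, roi.interior),
        pct_intact=coverage(intact, roi.interior),
        pct_fragmented_intermediate=coverage(fragmented, layers.intermediate),
        n_interior_px=n_interior,
        n_intermediate_px=n_intermediate,
    )
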