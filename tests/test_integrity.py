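"""One-pixel break rule, apical flooding, and intact/fragmented partition."""

import numpy as np
import pytest
from scipy import ndimage

from ejpnet import (
    EpitheliumSimParams,
    LayerSegmentation,
    StrandMask,
    assess_net_integrity,
    coverage,
    flood_accessible,
    generate_epithelium,
    partition_intact_fragmented,
    seal_small_breaks,
)
from conftest import make_band_roi


def _strand_with_gap(rows=60, cols=80, strand_row=30, gap_width=0, gap_col=40):
    """1-px horizontal strand across the whole ROI with an optional gap."""
    mask = np.zeros((rows, cols), dtype=bool)
    mask[strand_row, :] = True
    if gap_width:
        mask[strand_row, gap_col : gap_col + gap_width] = False
    return mask


def test_one_pixel_break_is_sealed():
    mask = _strand_with_gap(gap_width=1)
    sealed = seal_small_breaks(StrandMask(mask))
    _, n = ndimage.label(sealed, structure=np.ones((3, 3)))
    assert n == 1  # net classified intact


def test_two_pixel_break_stays_open():
    mask = _strand_with_gap(gap_width=2)
    sealed = seal_small_breaks(StrandMask(mask))
    _, n = ndimage.label(sealed, structure=np.ones((3, 3)))
    assert n == 2  # net classified fragmented


def test_seal_on_empty_mask_is_empty():
    sealed = seal_small_breaks(StrandMask(np.zeros((10, 10), dtype=bool)))
    assert not sealed.any()


@pytest.mark.parametrize("gap_width", [1, 2, 3, 4, 5])
def test_gap_width_law_flips_between_one_and_two_pixels(gap_width):
    """Flooding passes a sealed net exactly when the break exceeds 1 px."""
    roi = make_band_roi(60, 80)
    mask = _strand_with_gap(gap_width=gap_width)
    sealed = seal_small_breaks(StrandMask(mask))
    accessible = flood_accessible(sealed, roi)
    reaches_below = accessible[31:, :].any()
    assert reaches_below == (gap_width >= 2)


def test_flood_with_empty_net_covers_whole_interior():
    roi = make_band_roi(50, 60)
    accessible = flood_accessible(np.zeros((50, 60), dtype=bool), roi)
    assert np.array_equal(accessible, roi.interior)
    assert coverage(accessible, roi.interior) == 100.0


def test_flood_blocked_by_unbroken_strand_matches_bfs(bfs_oracle):
    roi = make_band_roi(100, 80)
    sealed = _strand_with_gap(rows=100, cols=80, strand_row=30)
    accessible = flood_accessible(sealed, roi)
    rows = np.arange(100)[:, None] * np.ones((1, 80), dtype=int)
    assert np.array_equal(accessible, roi.interior & (rows < 30))
    free = roi.interior & ~sealed
    seeds = ndimage.binary_dilation(roi.apical_border, structure=np.array([[0,1,0],[1,1,1],[0,1,0]], bool))
    assert np.array_equal(accessible, bfs_oracle(free, seeds))


def test_flood_through_three_pixel_gap_reaches_everything(bfs_oracle):
    roi = make_band_roi(100, 80)
    sealed = _strand_with_gap(rows=100, cols=80, strand_row=30, gap_width=3)
    accessible = flood_accessible(sealed, roi)
    assert np.array_equal(accessible, roi.interior & ~sealed)


def test_flood_equals_bfs_on_random_grids(bfs_oracle):
    rng = np.random.default_rng(12)
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    for _ in range(20):
        roi = make_band_roi(64, 64)
        sealed = rng.random((64, 64)) < 0.35
        sealed &= roi.interior
        accessible = flood_accessible(sealed, roi)
        seeds = ndimage.binary_dilation(roi.apical_border, structure=cross)
        assert np.array_equal(accessible, bfs_oracle(roi.interior & ~sealed, seeds))


def test_no_leak_through_diagonal_strand():
    """8-connected strands block 4-connected flow at diagonal steps."""
    roi = make_band_roi(40, 40)
    sealed = np.zeros((40, 40), dtype=bool)
    for c in range(40):  # staircase from (10,0) to (30, 40)
        r = 10 + (c // 2)
        sealed[r, c] = True
    accessible = flood_accessible(sealed, roi)
    # nothing below the staircase is reachable
    for c in range(40):
        r = 10 + (c // 2)
        assert not accessible[r + 1 :, c].any()


def _grid_net(rows=44, cols=44):
    """3x3 grid of square cells: strands on rows/cols 10,20,30 within 10..30."""
    net = np.zeros((rows, cols), dtype=bool)
    for r in (10, 20, 30):
        net[r, 10:31] = True
    for c in (10, 20, 30):
        net[10:31, c] = True
    return net


def _grid_layers(roi):
    # intermediate = the net's own footprint (rows and cols 10..30), the
    # way the closing-based segmentation hugs the expressed strands
    intermediate = np.zeros(roi.shape, dtype=bool)
    intermediate[10:31, 10:31] = True
    intermediate &= roi.interior
    superficial = np.zeros_like(intermediate)
    basal = roi.interior & ~intermediate
    return LayerSegmentation(superficial, intermediate, basal)


def test_closed_grid_net_is_fully_intact():
    roi = make_band_roi(44, 44)
    net = _grid_net()
    layers = _grid_layers(roi)
    sealed = seal_small_breaks(StrandMask(net))
    accessible = flood_accessible(sealed, roi)
    intact, fragmented = partition_intact_fragmented(sealed, accessible, layers)
    assert not fragmented.any()
    assert coverage(intact, layers.intermediate) == 100.0


def test_single_breached_cell_is_the_only_fragmented_basin():
    roi = make_band_roi(44, 44)
    net = _grid_net()
    net[10, 14:16] = False  # 2-px gap in the lid of the top-left cell
    layers = _grid_layers(roi)
    sealed = seal_small_breaks(StrandMask(net))
    accessible = flood_accessible(sealed, roi)
    intact, fragmented = partition_intact_fragmented(sealed, accessible, layers)
    # the breached cell's hole is fragmented, the other three stay intact
    assert fragmented[11:20, 11:20].all()
    assert intact[11:20, 21:30].all()
    assert intact[21:30, 11:20].all()
    assert intact[21:30, 21:30].all()


@pytest.mark.parametrize("seed,rate", [(0, 0.1), (1, 0.5), (2, 0.9)])
def test_partition_covers_intermediate_disjointly(seed, rate):
    p = EpitheliumSimParams(seed=seed, gap_rate=rate)
    _, roi, truth = generate_epithelium(p)
    layers = LayerSegmentation(*truth.true_layer_masks)
    res = assess_net_integrity(StrandMask(truth.strand_mask_with_gaps()), roi, layers)
    assert np.array_equal(res.intact_region | res.fragmented_region, layers.intermediate)
    assert not np.any(res.intact_region & res.fragmented_region)
    assert not np.any(res.accessible & res.sealed_strands)
    assert 0 <= res.pct_accessible <= 100
    assert 0 <= res.pct_intact <= 100


def test_partition_requires_nonempty_intermediate():
    roi = make_band_roi(20, 20)
    empty = np.zeros((20, 20), dtype=bool)
    layers = LayerSegmentation(roi.interior, empty, empty)
    with pytest.raises(ValueError, match="intermediate"):
        partition_intact_fragmented(empty, empty, layers)


def test_coverage_counting():
    ref = np.zeros((10, 10), dtype=bool)
    ref[2:8, 2:8] = True
    assert coverage(ref, ref) == 100.0
    assert coverage(np.zeros_like(ref), ref) == 0.0
    rng = np.random.default_rng(3)
    m = rng.random((10, 10)) < 0.5
    expected = 100.0 * sum(
        1 for r in range(10) for c in range(10) if m[r, c] and ref[r, c]
    ) / int(ref.sum())
    assert coverage(m, ref) == pytest.approx(expected)
    with pytest.raises(ValueError):
        coverage(m, np.zeros_like(ref))


def test_adding_gaps_never_decreases_accessibility():
    rates = np.linspace(0.0, 0.9, 6)
    acc, intact = [], []
    for rate in rates:
        p = EpitheliumSimParams(seed=7, gap_rate=float(rate), noise_sd=0.0)
        _, roi, truth = generate_epithelium(p)
        layers = LayerSegmentation(*truth.true_layer_masks)
        res = assess_net_integrity(StrandMask(truth.strand_mask_with_gaps()), roi, layers)
        acc.append(res.pct_accessible)
        intact.append(res.pct_intact)
    assert all(b >= a - 1e-9 for a, b in zip(acc, acc[1:]))
    assert all(b <= a + 1e-9 for a, b in zip(intact, intact[1:]))
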