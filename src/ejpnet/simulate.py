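"""Synthetic ectocervical epithelium and cohort generator.

Every downstream stage is validated against images with known ground
truth.  The generator emulates what the real slides look like: a
band-shaped stratified epithelium between an apical and a basal border,
whose intermediate stratum carries a honeycomb net of junction-protein
strands along the borders of a Voronoi tessellation (jittered-grid seed
points, so cell size is controllable).  Fragmentation is injected by
erasing a slab of controllable width across randomly selected cell edges,
one gap per selected edge, which makes break width exactly controllable
for the one-pixel-rule tests.  Additive Gaussian noise, clipped at zero,
stands in for staining noise.

Break indicators and break centres are drawn for *all* edges before the
selection is applied, so at a fixed seed the set of broken edges is nested
as ``gap_rate`` grows — the property the monotonicity checks rely on.

A cohort generator draws log-normal plasma hormone levels and couples the
per-sample image parameters to standardised log-estradiol through linear
links with stated effect sizes, censoring values below the assay's lower
limit of detection exactly the way a real hormone table arrives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Voronoi
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .core import EpitheliumROI, FluorescenceImage

__all__ = [
    "EpitheliumSimParams",
    "GroundTruth",
    "CohortSimParams",
    "RoiBundle",
    "generate_epithelium",
    "generate_cohort",
    "write_cohort",
]

BoundarySpec = int | float | Sequence[int] | Callable[[np.ndarray], np.ndarray] | None


@dataclass
class EpitheliumSimParams:
    """Parameters of one synthetic epithelium image.

    ``band_top`` / ``band_bottom`` give the apical and basal border rows
    as a scalar, a per-column array, or a callable of the column index;
    ``None`` defaults to 10% / 90% of the image height.
    """

    image_shape: tuple[int, int] = (256, 320)
    pixel_size_um: float = 0.325
    band_top: BoundarySpec = None
    band_bottom: BoundarySpec = None
    intermediate_fraction: float = 0.5
    cell_diameter_px: float = 30.0
    strand_width_px: int = 3
    strand_intensity: float = 180.0
    background_intensity: float = 25.0
    gap_rate: float = 0.3
    gap_width_px: int = 4
    noise_sd: float = 8.0
    seed: int = 0
    channel: str = "DSG1"

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 8 or cols < 8:
            raise ValueError("image_shape too small")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0 < self.intermediate_fraction <= 1:
            raise ValueError("intermediate_fraction must be in (0, 1]")
        if self.gap_width_px < 1:
            raise ValueError("gap_width_px must be >= 1")
        if self.strand_width_px < 1:
            raise ValueError("strand_width_px must be >= 1")
        if min(self.strand_intensity, self.background_intensity) < 0:
            raise ValueError("intensities must be non-negative")
        if not 0 <= self.gap_rate <= 1:
            raise ValueError("gap_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cell_diameter_px < 4:
            raise ValueError("cell_diameter_px too small")


@dataclass
class GroundTruth:
    """Everything the generator knows before noise is added."""

    true_layer_masks: tuple[np.ndarray, np.ndarray, np.ndarray]  # sup, inter, basal
    true_strand_mask: np.ndarray  # before gap injection
    gap_locations: list[tuple[np.ndarray, int]]  # (erased (N,2) pixel sets, width)
    true_gap_fraction: float
    true_height_um: float
    n_edges: int

    def strand_mask_with_gaps(self) -> np.ndarray:
        """The drawn net after gap injection (still noise-free)."""
        mask = self.true_strand_mask.copy()
        for pixels, _width in self.gap_locations:
            mask[pixels[:, 0], pixels[:, 1]] = False
        return mask


@dataclass
class CohortSimParams:
    """Study-condition parameters of a synthetic imaging cohort.

    Defaults emulate a follicular-phase visit: estradiol log-normal around
    ~100 pg/mL with the 22 pg/mL assay limit, progesterone mostly near its
    0.05 ng/mL limit, 2 ROIs per sample, and a negative link from
    standardised log-estradiol to the fragmentation rate (higher estradiol
    → fewer gaps) with a weaker positive link to strand intensity.
    """

    n_samples: int = 40
    rois_per_sample: int = 2
    phase: str = "FOL"
    estradiol_log_mean: float = float(np.log(100.0))  # pg/mL scale
    estradiol_log_sd: float = 0.8
    progesterone_log_mean: float = float(np.log(0.08))  # ng/mL scale
    progesterone_log_sd: float = 1.0
    hormone_corr: float = 0.45
    lld_estradiol: float = 22.0
    lld_progesterone: float = 0.05
    base_gap_rate: float = 0.35
    gap_rate_sd: float = 0.05  # biological scatter independent of hormones
    effect_gap: float = -0.15
    effect_intensity: float = 0.10
    image_params: EpitheliumSimParams = field(default_factory=EpitheliumSimParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if not 1 <= self.rois_per_sample <= 6:
            raise ValueError("rois_per_sample must be in [1, 6]")
        if min(self.estradiol_log_sd, self.progesterone_log_sd) <= 0:
            raise ValueError("log-sds must be positive")
        if not 0 <= self.base_gap_rate <= 1:
            raise ValueError("base_gap_rate must be in [0, 1]")


@dataclass
class RoiBundle:
    """One generated ROI: image + annotation + ground truth + parameters."""

    sample_id: str
    roi_id: str
    image: FluorescenceImage
    roi: EpitheliumROI
    truth: GroundTruth
    params: EpitheliumSimParams


def _boundary_rows(spec: BoundarySpec, cols: int, default_row: int) -> np.ndarray:
    c = np.arange(cols)
    if spec is None:
        arr = np.full(cols, default_row, dtype=float)
    elif callable(spec):
        arr = np.asarray(spec(c), dtype=float) * np.ones(cols)
    elif np.isscalar(spec):
        arr = np.full(cols, float(spec))
    else:
        arr = np.asarray(spec, dtype=float)
        if arr.shape != (cols,):
            raise ValueError("boundary array must have one entry per column")
    return np.round(arr).astype(int)


def _clip_segment(
    p0: np.ndarray, p1: np.ndarray, rows: int, cols: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Liang-Barsky clip of a segment to the image box (2-px margin).

    Degenerate Voronoi ridges from near-collinear seeds can have vertices
    astronomically far away; rasterising them unclipped is unbounded.
    """
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    # standard p/q formulation over the four box edges
    for p, q in (
        (-d[0], p0[0] + 2.0),
        (d[0], rows + 1.0 - p0[0]),
        (-d[1], p0[1] + 2.0),
        (d[1], cols + 1.0 - p0[1]),
    ):
        if p == 0:
            if q < 0:
                return None
            continue
        t = q / p
        if p < 0:
            t0 = max(t0, t)
        else:
            t1 = min(t1, t)
        if t0 > t1:
            return None
    return p0 + t0 * d, p0 + t1 * d


def _voronoi_edges(
    inter_mask: np.ndarray,
    cell_d: float,
    rng: np.random.Generator,
    min_edge_px: int,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Rasterised Voronoi cell walls clipped to the intermediate band.

    Seed points are a jittered grid extending two cell diameters beyond
    the band so every wall inside the band comes from a finite ridge.
    The band's top and bottom boundary rows are drawn as per-cell "lid"
    segments (split wherever the nearest seed changes), so cells at the
    band margin are closed like every other cell; lids long enough to
    carry a gap join the breakable edge list.  Returns (edge list, 1-px
    net mask); each edge is (pixels (N,2), unit tangent).
    """
    rows, cols = inter_mask.shape
    rr = np.where(inter_mask.any(axis=1))[0]
    r0, r1 = rr.min(), rr.max()
    margin = 2.0 * cell_d
    grid_r = np.arange(r0 - margin, r1 + margin + cell_d, cell_d)
    grid_c = np.arange(-margin, cols + margin + cell_d, cell_d)
    gr, gc = np.meshgrid(grid_r, grid_c, indexing="ij")
    pts = np.column_stack([gr.ravel(), gc.ravel()])
    pts += rng.uniform(-0.35 * cell_d, 0.35 * cell_d, size=pts.shape)

    vor = Voronoi(pts)
    net = np.zeros(inter_mask.shape, dtype=bool)
    edges: list[tuple[np.ndarray, np.ndarray]] = []
    for v0, v1 in vor.ridge_vertices:
        if v0 == -1 or v1 == -1:
            continue
        p0, p1 = vor.vertices[v0], vor.vertices[v1]
        if not (np.all(np.isfinite(p0)) and np.all(np.isfinite(p1))):
            continue
        clipped = _clip_segment(p0, p1, rows, cols)
        if clipped is None:
            continue
        q0, q1 = clipped
        rr_px, cc_px = draw_line(
            int(round(q0[0])), int(round(q0[1])), int(round(q1[0])), int(round(q1[1]))
        )
        keep = (rr_px >= 0) & (rr_px < rows) & (cc_px >= 0) & (cc_px < cols)
        rr_px, cc_px = rr_px[keep], cc_px[keep]
        if rr_px.size == 0:
            continue
        inside = inter_mask[rr_px, cc_px]
        rr_px, cc_px = rr_px[inside], cc_px[inside]
        if rr_px.size < min_edge_px:
            continue
        vec = p1 - p0
        norm = float(np.hypot(*vec))
        if norm == 0:
            continue
        pixels = np.column_stack([rr_px, cc_px])
        edges.append((pixels, vec / norm))
        net[rr_px, cc_px] = True

    # Close the band with per-cell lids along its top and bottom rows.
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    col_has = inter_mask.any(axis=0)
    cols_in = np.flatnonzero(col_has)
    for boundary_row in ("top", "bottom"):
        if boundary_row == "top":
            r_of_c = np.argmax(inter_mask[:, cols_in], axis=0)
        else:
            r_of_c = rows - 1 - np.argmax(inter_mask[::-1, cols_in], axis=0)
        lid_pts = np.column_stack([r_of_c, cols_in])
        net[lid_pts[:, 0], lid_pts[:, 1]] = True
        _, owner = tree.query(lid_pts.astype(float))
        splits = np.flatnonzero(np.diff(owner)) + 1
        for run in np.split(np.arange(cols_in.size), splits):
            pixels = lid_pts[run]
            if pixels.shape[0] < min_edge_px:
                continue
            vec = (pixels[-1] - pixels[0]).astype(float)
            norm = float(np.hypot(*vec))
            if norm == 0:
                continue
            edges.append((pixels, vec / norm))
    return edges, net


def generate_epithelium(
    params: EpitheliumSimParams,
) -> tuple[FluorescenceImage, EpitheliumROI, GroundTruth]:
    """Generate one synthetic epithelium with full ground truth.

    Same parameters and seed give bit-identical outputs.
    """
    rows, cols = params.image_shape
    top = _boundary_rows(params.band_top, cols, int(round(0.1 * rows)))
    bottom = _boundary_rows(params.band_bottom, cols, int(round(0.9 * rows)))
    if np.any(top >= bottom):
        raise ValueError("band_top must lie above band_bottom everywhere")
    if np.any(top < 0) or np.any(bottom >= rows):
        raise ValueError("band boundaries outside the image")
    band_height = bottom - top - 1  # interior rows per column
    if band_height.min() < params.cell_diameter_px:
        raise ValueError("degenerate band: height smaller than cell diameter")
    if params.gap_width_px >= params.cell_diameter_px:
        raise ValueError("gap_width_px must be smaller than cell_diameter_px")

    r_idx = np.arange(rows)[:, None]
    apical = r_idx == top[None, :]
    basal = r_idx == bottom[None, :]
    interior = (r_idx > top[None, :]) & (r_idx < bottom[None, :])

    # Intermediate sub-band centred within the compartment.
    f = params.intermediate_fraction
    inter_top = top + 1 + (1 - f) / 2 * band_height
    inter_bottom = inter_top + f * band_height
    inter_mask = (r_idx >= np.round(inter_top)[None, :]) & (
        r_idx < np.round(inter_bottom)[None, :]
    )
    inter_mask &= interior
    superficial = interior & (r_idx < np.round(inter_top)[None, :])
    basal_layer = interior & ~inter_mask & ~superficial

    rng = np.random.default_rng(params.seed)
    min_edge_px = max(4, params.gap_width_px + 2)
    edges, net1px = _voronoi_edges(inter_mask, params.cell_diameter_px, rng, min_edge_px)

    w = params.strand_width_px
    radius = (w - 1) // 2
    strands_full = (
        ndimage.binary_dilation(net1px, structure=disk(radius)) if radius > 0 else net1px.copy()
    )
    strands_full &= inter_mask

    # Per-edge break indicators and centres drawn up front for nesting.
    n_edges = len(edges)
    edge_u = rng.random(n_edges)
    center_frac = rng.random(n_edges)
    broken = edge_u < params.gap_rate

    strands = strands_full.copy()
    g = params.gap_width_px
    gap_locations: list[tuple[np.ndarray, int]] = []
    for k in np.flatnonzero(broken):
        pixels, tangent = edges[k]
        m = pixels.shape[0]
        lo, hi = g, m - 1 - g
        if hi < lo:
            lo, hi = m // 3, max(m // 3, 2 * m // 3)
        idx = int(lo + center_frac[k] * (hi - lo))
        center = pixels[idx].astype(float)
        # erase a slab of thickness g across the strand, local to the edge
        half = g + w + 2
        r_lo = max(0, int(center[0]) - half)
        r_hi = min(rows, int(center[0]) + half + 1)
        c_lo = max(0, int(center[1]) - half)
        c_hi = min(cols, int(center[1]) + half + 1)
        win = strands[r_lo:r_hi, c_lo:c_hi]
        wr, wc = np.nonzero(win)
        if wr.size == 0:
            continue
        d = np.column_stack([wr + r_lo - center[0], wc + c_lo - center[1]])
        proj = d @ tangent
        perp = d @ np.array([-tangent[1], tangent[0]])
        erase = (proj > -g / 2 - 1e-9) & (proj <= g / 2 + 1e-9) & (np.abs(perp) <= w + 0.5)
        if not erase.any():
            continue
        erased = np.column_stack([wr[erase] + r_lo, wc[erase] + c_lo])
        win[wr[erase], wc[erase]] = False
        gap_locations.append((erased, g))

    image = np.zeros((rows, cols), dtype=float)
    compartment = interior | apical | basal
    image[compartment] = params.background_intensity
    image[strands] = params.strand_intensity
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    np.clip(image, 0.0, None, out=image)

    truth = GroundTruth(
        true_layer_masks=(superficial, inter_mask, basal_layer),
        true_strand_mask=strands_full,
        gap_locations=gap_locations,
        true_gap_fraction=float(broken.sum() / n_edges) if n_edges else 0.0,
        true_height_um=float((bottom - top).mean() * params.pixel_size_um),
        n_edges=n_edges,
    )
    fimg = FluorescenceImage(image, params.pixel_size_um, params.channel)
    roi = EpitheliumROI(interior, apical, basal)
    return fimg, roi, truth


def generate_cohort(
    params: CohortSimParams,
) -> tuple[list[RoiBundle], pd.DataFrame]:
    """Generate a cohort of image bundles plus its hormone table.

    Hormone levels are log-normal (progesterone correlated with estradiol
    on the log scale); per-sample gap rate and strand intensity follow
    linear / log-linear links in standardised log-estradiol.  Below-LLD
    values are stored censored at the limit with their flag set, the way a
    real table arrives from the assay lab.
    """
    n = params.n_samples
    rng = np.random.default_rng(params.seed)
    z = rng.standard_normal(n)
    log_e = params.estradiol_log_mean + params.estradiol_log_sd * z
    w = rng.standard_normal(n)
    rho = params.hormone_corr
    log_p = params.progesterone_log_mean + params.progesterone_log_sd * (
        rho * z + np.sqrt(1 - rho**2) * w
    )
    estradiol = np.exp(log_e)
    progesterone = np.exp(log_p)
    e_below = estradiol < params.lld_estradiol
    p_below = progesterone < params.lld_progesterone

    gap_noise = params.gap_rate_sd * rng.standard_normal(n)
    gap_rates = np.clip(params.base_gap_rate + params.effect_gap * z + gap_noise, 0.02, 0.95)
    intensities = params.image_params.strand_intensity * np.exp(params.effect_intensity * z)
    roi_seeds = rng.integers(0, 2**31, size=(n, params.rois_per_sample))

    bundles: list[RoiBundle] = []
    records = []
    for i in range(n):
        sample_id = f"S{i:03d}"
        for j in range(params.rois_per_sample):
            p_ij = replace(
                params.image_params,
                gap_rate=float(gap_rates[i]),
                strand_intensity=float(intensities[i]),
                seed=int(roi_seeds[i, j]),
            )
            img, roi, truth = generate_epithelium(p_ij)
            roi.sample_id = sample_id
            roi.roi_id = f"R{j}"
            bundles.append(RoiBundle(sample_id, f"R{j}", img, roi, truth, p_ij))
        records.append(
            {
                "sample_id": sample_id,
                "phase": params.phase,
                "estradiol_pg_ml": float(
                    params.lld_estradiol if e_below[i] else estradiol[i]
                ),
                "estradiol_below_lld": bool(e_below[i]),
                "progesterone_ng_ml": float(
                    params.lld_progesterone if p_below[i] else progesterone[i]
                ),
                "progesterone_below_lld": bool(p_below[i]),
            }
        )
    return bundles, pd.DataFrame.from_records(records)


def write_cohort(
    bundles: list[RoiBundle], hormones: pd.DataFrame, outdir: str | Path
) -> None:
    """Write a cohort to disk: per-ROI TIFF pairs, truth sidecars, CSV.

    Image as float32 grayscale TIFF, annotation as the uint8 0/1/2/3 label
    mask, ground-truth summary as JSON.
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        stem = f"{b.sample_id}_{b.roi_id}_{b.image.channel}"
        tifffile.imwrite(outdir / f"{stem}_image.tif", b.image.intensities.astype(np.float32))
        tifffile.imwrite(outdir / f"{stem}_labels.tif", b.roi.to_label_mask())
        sidecar = {
            "sample_id": b.sample_id,
            "roi_id": b.roi_id,
            "channel": b.image.channel,
            "gap_rate": b.params.gap_rate,
            "true_gap_fraction": b.truth.true_gap_fraction,
            "true_height_um": b.truth.true_height_um,
            "n_edges": b.truth.n_edges,
            "n_gaps": len(b.truth.gap_locations),
        }
        (outdir / f"{stem}_truth.json").write_text(json.dumps(sidecar, indent=1))
    hormones.to_csv(outdir / "hormones.csv", index=False)
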