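# ejpnet

Quantification of epithelial junction protein (EJP) net integrity in
ectocervical immunofluorescence images, with the downstream
hormone-correlation statistics.

## The problem

Junction proteins — desmoglein-1 (DSG1), claudin-1, ZO-1, E-cadherin —
outline keratinocyte borders in stratified squamous epithelium as
bright, net-like strands.  A continuous net blocks intercellular passage
of microorganisms; breaks open routes toward the basal membrane.  Given
a per-channel grayscale fluorescence image (TIFF, 0.325 µm/px by
default) and a manually annotated epithelial compartment (label mask:
0 outside, 1 interior, 2 apical border, 3 basal border), `ejpnet`
measures per ROI:

* **MFI** — mean raw fluorescence intensity of the whole compartment and
  of the strand-bearing intermediate layer (proxy of protein
  expression);
* **height** — mean apical→basal distance from a Euclidean distance
  transform seeded on the basal border (µm);
* **barrier integrity** — strands are enhanced with a multi-scale
  Hessian ridge measure (response `max_sigma sigma^2 max(0, -lambda_min)`,
  normalised within the ROI so it is invariant to image contrast),
  binarised, and treated as a physical barrier: breaks of one pixel are
  sealed (only breaks **greater** than one pixel, 0.325 µm, admit viral
  passage), a 4-connected flood from the apical border yields the
  **accessible region**, and a watershed over the holes of the net
  partitions the intermediate layer into **intact** and **fragmented**
  regions (a cell is fragmented when the flood reached its hole).

Per-ROI metrics are averaged per participant, hormone values below the
assay detection limit receive the phase-specific substitutes (follicular:
22 pg/mL estradiol, 0.05 ng/mL progesterone; luteal: 10 pg/mL,
0.05 ng/mL), and hormone–metric association is assessed with Spearman's
rho (mid-ranks; exact permutation p for n ≤ 9, t approximation
otherwise; no multiple-comparison correction).

A synthetic-data module generates band-shaped epithelia with
ground-truthed Voronoi honeycomb nets, controllable fragmentation, and
hormone cohorts with engineered effect sizes, so every stage is testable
without tissue data.  See `docs/methods.md` for the full model.

## Worked example

```python
import ejpnet as ej
from ejpnet.io import quantify_bundle

params = ej.EpitheliumSimParams(seed=0, gap_rate=0.3)   # break 30% of cell edges
image, roi, truth = ej.generate_epithelium(params)
row = quantify_bundle(image, roi, ej.PipelineConfig())
for k in ("mfi_epithelium", "mfi_intermediate", "height_um",
          "pct_accessible", "pct_intact", "pct_fragmented_intermediate"):
    print(f"{k:>28s}: {row[k]:.2f}")
```

prints

```
              mfi_epithelium: 39.67
            mfi_intermediate: 55.35
                   height_um: 66.30
              pct_accessible: 64.93
                  pct_intact: 31.22
 pct_fragmented_intermediate: 35.27
```

With 30% of cell edges broken (this draw landed at 28.7%), the apical
flood reaches 64.9% of the epithelium, 31.2% of it remains behind
continuous strands, and 35.3% of the intermediate layer belongs to
breached cells.  The measured height (66.30 µm) matches the generator's
true band thickness (66.3 µm), and with `gap_rate=0` the same pipeline
reports an intact region tiling 100% of the intermediate layer.

The same workflow runs from the shell:

```bash
ejpnet simulate --out cohort/ --n-samples 10 --seed 1
ejpnet quantify cohort/ --out metrics.csv          # add --qc-overlays for PNGs
ejpnet correlate --metrics-csv metrics.csv --hormones-csv cohort/hormones.csv \
                 --out correlations.csv
```

`correlations.csv` is tidy: channel, hormone, metric, rho, p, n.

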