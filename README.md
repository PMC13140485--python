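# norn-spatial

Spatial microenvironment analysis of renal Epo-producing (REP) cells.

Circulating erythropoietin (Epo) in the adult comes mainly from kidney
Norn cells, interstitial cells that switch into REP cells when local tissue
oxygen falls. REP cells sit in small clusters in the corticomedullary
border, wedged between proximal-tubule (PT) segments whose sodium-glucose
cotransporters Sglt2 (*Slc5a2*, PT S1) and Sglt1 (*Slc5a1*, PT S2/S3)
dominate local oxygen consumption — and they stop producing Epo when those
tubules are injured. Quantifying *which* cells surround an active REP cell,
and how that neighbourhood changes in injury, requires stitching together
several measurement modalities: marker immunofluorescence, mRNA-FISH
centroids, and Visium-style spot transcriptomics.

This package implements that analysis chain as a tested, reusable library,
together with a synthetic kidney-tissue generator with known ground truth
so every stage can be validated by recovery rather than by eye. It is
aimed at computational biologists working on spatial transcriptomics or
quantitative tissue imaging who want the individual primitives (calibrated
nearest-object distances, NB Pearson residuals, simplex-constrained
deconvolution, distance-gated communication scores, ORA) or the end-to-end
pipeline.

## What it computes

- **`norn.simulate`** — synthetic 2-D kidney sections: zone-structured
  geometry (cortex / corticomedullary border / inner medulla), circular
  tubule cross-sections with segment-specific markers, Neyman–Scott
  clustered interstitial REP cells with configurable proximity preference,
  luminal brush-border marker channels at 0.33 µm/px, a hexagonal 55 µm
  spot lattice with negative-binomial mixture counts, and a UUO-injury
  transform. Ground truth (classes, compositions, masks) is returned for
  recovery tests.
- **`norn.segment`** — ANN/MLP pixel classification on a multi-scale
  Gaussian feature stack, trained from sparse wand-tool-style strokes;
  per-class masks and area fractions (object area / kidney area).
- **`norn.proximity`** — the core measurement: for each REP centroid, the
  exact-EDT distance (µm) to the nearest object of each marker class, the
  15 µm three-class rule (`Sglt2_only` / `Sglt1_only` / `shared` /
  ignored; 15 µm = half an average mouse PT diameter, "within" inclusive),
  within-threshold percentages, per-area and per-fraction class densities,
  and per-animal aggregation for external statistics.
- **`norn.spots`** — depth-offset negative-binomial Pearson residuals with
  kernel-regularized dispersion (variance-stabilized, clipped at √n_spots),
  strict `> 0.8` Epo⁺ spot selection, marker-panel summaries on the
  all-spots z-scale, and rank-sum differential expression with BH
  correction.
- **`norn.deconv`** — per-spot cell-type proportions by Poisson-mixture
  maximum likelihood on the simplex (multiplicative EM; likelihood is
  provably non-decreasing), dominant-type calls, composition profiles of
  spot subsets.
- **`norn.commun`** — ligand–receptor communication between
  deconvolution-defined sender groups within 250 µm of Epo⁺ receiver
  spots: P = [Lⁿ/(Kⁿ+Lⁿ)]·[Rⁿ/(Kⁿ+Rⁿ)] with subunit geometric means, and
  one-sided permutation p-values.
- **`norn.enrich`** — hypergeometric over-representation analysis of DEG
  lists (upper-tail P(X ≥ k), BH-adjusted, gene ratio k/n).
- **`norn.pipeline` / `norn` CLI** — orchestration, config validation,
  consolidated JSON report, healthy-vs-injured comparison.

## Worked example

```python
from norn import pipeline

report = pipeline.run_pipeline(pipeline.demo_config(seed=1))
healthy = report["conditions"]["healthy"]
print(healthy["proximity_fractions"])
print(healthy["within_threshold_pct"])
print(report["comparison"]["area_fraction_ratio"])
print(report["comparison"]["gene_rank_upregulated"])
```

prints (seed 1):

```
{'Sglt2_only': 0.2, 'Sglt1_only': 0.36, 'shared': 0.44}
{'Sglt2': 64.0, 'Sglt1': 80.0, 'Nkcc2': 20.0, 'Ncc': 0.0, 'Ut-a': 0.0}
{'Sglt2': 0.301, 'Sglt1': 1.0, 'Nkcc2': 1.0, 'Ncc': 1.0, 'Ut-a': 1.0}
{'Havcr1': 1, 'Lcn2': 4, 'Vcam1': 3, 'Acta2': 63, 'Epo': 26}
```

Reading: of the classified REP cells in the simulated healthy section, 20%
lie within 15 µm of Sglt2 only, 36% of Sglt1 only and 44% of both
("shared proximity"), recovering the generator's configured preference;
64% / 80% of all REP cells are within 15 µm of Sglt2 / Sglt1, against 20%
for the TAL marker Nkcc2 and ~0% for distal markers. In the injured run
the classifier-measured Sglt2⁺ protein area drops to 30% of the healthy
value while Sglt1 is unchanged, and *Havcr1* (KIM1) is the top upregulated
gene in Epo⁺ spots while *Acta2* (αSMA) ranks 63rd — the injury signature
appears in the REP-cell neighbourhood without myofibroblast conversion.

The same stages are available individually, e.g.

```bash
norn simulate --seed 3 --out demo/           # tissue bundle with ground truth
norn proximity --cells demo/rep_cells.csv --masks demo/masks \
     --markers Sglt2,Sglt1 --threshold-um 15 --out demo/prox
norn spots select --counts demo/counts --gene Epo --threshold 0.8 --out demo/sel
```

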