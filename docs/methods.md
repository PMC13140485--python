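# Methods

This note records the models, defaults and numerical choices behind
`norn-spatial`, what the synthetic tissue does and does not emulate, and
the known limitations.

## Synthetic kidney tissue

**Geometry.** Sections are 2-D (the imaging and Visium modalities are
8–10 µm sections, so volumes add nothing). The default extent is
1.2 × 1.2 mm split into three horizontal zone bands — cortex (40%),
corticomedullary border (25%), inner medulla (35%). Tubule cross-sections
are non-overlapping circles (default diameter 30 µm ± 15%, ≥ 2 µm wall
gap) placed by rejection sampling wholly inside one zone; segment
identities are drawn with zone-dependent frequencies (PT S1
cortex-enriched, PT S2/S3 border-enriched, DCT cortical, TAL broad, IMCD
restricted to the inner medulla). The default 500 tubules give ~25% areal
coverage; real cortex is denser, but the interstitium must remain wide
enough to host REP cells, and mRNA dominance of the PT is restored through
cell-size weights (below).

**REP cells.** Each cell first draws its true proximity class — near-S1
only, near-S2/S3 only, shared, far — from the configured preference vector
(default 0.20 / 0.35 / 0.45 / 0), allocated by exact quota so the
configured proportions are reproduced up to integer rounding. Locations
come from a Neyman–Scott cluster process: Poisson parents (150/mm²) in the
corticomedullary band, Gaussian offspring dispersal (σ = 40 µm),
restricted to the interstitium and to the class's distance conditions with
a 1 µm guard band around the 15 µm threshold so pixelation cannot flip a
constructed label. Distance conditions are verified against the exact
tubule polygons. The class-conditional construction makes the proximity
module's recovery testable cell by cell. REP density defaults to
~70 cells/mm², keeping Epo⁺ spots a small minority of spots, as in real
sections. Cluster size and dispersal are free parameters (the biology
is only described as "small clusters").

**Marker images.** Each segment's channel is a ring of elevated intensity
(amplitude 200 over background 10, Gaussian noise SD 8) along the *inner*
tubule wall — transporters sit on the luminal brush border — of width
2 µm, rendered at 0.33 µm/px. Because the ring hugs the wall from inside,
the distance from an interstitial point to the marker mask equals its
distance to the tubule polygon, which is what makes constructed class
labels exactly recoverable. KIM1 marks the luminal ring of injured
tubules; αSMA marks a peritubular band around them (myofibroblast
recruitment). Not emulated: autofluorescence structure, optical blur,
z-projection artefacts, antibody cross-reactivity — so segmentation
scores on synthetic images are upper bounds on real-tissue performance.

**Spot counts.** Spots form a pointy-top hexagonal lattice (100 µm pitch,
55 µm capture discs — the Visium convention). A spot's true composition is
the area of each cell type inside its disc, weighted by relative mRNA
content: PT types ×3 (large, mRNA-rich cells), interstitial types ×0.3
(sparse cells in thin peritubular spaces). These weights make PT mRNA
dominate cortical spots (>50%), matching whole-kidney transcriptome
behaviour; with pure area weighting the interstitium (~75% of area) would
implausibly dominate every spot. The remaining disc area splits
Endo/Norn/Macro 0.60/0.35/0.05. Counts are negative binomial with mean
`depth · Σ_k w_k s_gk` (depth 5000, dispersion θ = 10; θ = ∞ is the
Poisson limit). Epo has zero baseline rate everywhere; Epo counts are
injected only into spots overlapping REP centroids (expected 40 per
overlapping cell), so the generator knows exactly which spots are Epo⁺.

**Gene panel.** Segment markers (Slc5a2, Slc5a1, Slc12a1, Slc12a3,
Slc14a2), cell-type markers (Pecam1, Pdgfrb, Cd68), an injury panel
(Havcr1, Lcn2, Vcam1, Tgfb1, Spp1), receptors (Cd44, Itgav, Itgb3,
Tgfbr1, Tgfbr2), Acta2, Epo, plus 120 background genes with log-normal
type-specific rates. The panel depends only on the seed, never on the
injury flag, so paired conditions share identical genes.

**Injury transform.** With severity f (default 0.6): f of each spot's
PT S2/S3 mass becomes injured PT; f·10% of PT mass shifts to macrophages;
Norn and endothelial mass are untouched; Slc5a2 expression is scaled by
1 − f·0.7 across all types while Slc5a1 is left alone; injury markers are
elevated in the injured-PT signature (Havcr1 ×200 at f = 1, interpolating
linearly to ×1 at f = 0 — KIM1 is massively induced in injured PT, and the
strong elevation also keeps injured PT identifiable from the otherwise
S2/S3-like profile). Every term scales with f, so f = 0 is the identity.
On the imaging side, injury marks each PT S1 tubule Sglt2-silent with
probability 0.7 and each PT S2/S3 tubule injured (KIM1⁺, Sglt1-retaining)
with probability f.

## Pixel classification

Features are, per channel, the raw intensity plus Gaussian-smoothed
intensity at σ ∈ {1, 2} px. σ = 4 was evaluated and rejected: it exceeds
the ~6 px brush-border ring thickness at full resolution and smears the
ring into a halo that the classifier then labels positive (noise-free IoU
drops from ≥0.95 to ~0.6–0.76). The classifier is a one-hidden-layer
(32-unit) MLP with standardized inputs, early stopping on a 10% annotation
holdout, initial learning rate 0.01 (the sklearn default of 0.001 stalls
under early stopping on small annotation sets), seeded and deterministic.
Prediction is argmax posterior (ties to the lowest class index);
components under 5 px are removed. Sequential-IF markers can overlap on
the same pixels (Sglt1 and KIM1 on an injured tubule), so the pipeline
trains one binary classifier per channel rather than one multi-class
model over all channels.

## Proximity

Distances are computed on the exact Euclidean distance transform of the
inverted class mask, sampled at the centroid's pixel and calibrated to µm
*before* thresholding. Against brute-force enumeration the EDT value is
exact up to half a pixel diagonal (the centroid's sub-pixel offset).
The source reference is the centroid (REP cells are small relative to
tubules); a boundary option is reserved in the config. "Within 15 µm" is
inclusive (≤); cells beyond the threshold of *both* markers are ignored —
reading "beyond 15 µm from either" as "from both", since the alternative
would empty the single-marker classes by definition. Both density
normalizations are provided (counts/mm² of annotated tissue, and fractions
of classified cells) because published "REP cell density" panels are
consistent with either; section values are averaged per animal
(two-sections-per-mouse design) for export to external ANOVA.

## Normalization and selection

The variance-stabilizing model is a depth-offset negative binomial per
gene: µ_gj = exp(β_g)·m_j with the MLE intercept exp(β_g) = Σ_j x_gj / Σ_j
m_j; overdispersion θ_g by method of moments, clipped to [10⁻³, 10⁶], then
regularized by Nadaraya–Watson kernel regression of log₁₀θ on log₁₀ mean
expression (Silverman bandwidth). Residuals (x − µ)/√(µ + µ²/θ) are
clipped to ±√n_spots; zero-count genes get zero rows and are excluded
from regularization. This is the spot-data reduction of the
SCTransform-style GLM: spot data carry no cell-level covariates, so the
per-gene intercept plus depth offset is the entire model. On Poisson
simulations all expressed genes land in the SD band [0.8, 1.25].

Epo⁺ spots are selected by residual strictly greater than 0.8 (0.80
excluded, 0.81 included). The residual layer (not a corrected-counts
layer) carries the threshold; this is configurable. Panel summaries
z-standardize residuals per gene across all spots first, so a value above
zero means above-slide-average expression.

Differential expression is a two-sided Mann–Whitney rank-sum on residuals
with BH correction (the effect columns are the residual-mean difference
and the log2 fold change of depth-normalized means, pseudocount 1 per
10k); groups under 3 spots fall back to the exact null with a warning.
A rank test was chosen because the DE procedure behind the published
volcano plots is not specified; it is robust to the clipping.

## Deconvolution

Per spot, the multinomial/Poisson mixture MLE over the simplex via
multiplicative EM: w ← w ∘ ((x/ŵS)Sᵀ), renormalized — each iteration is an
exact EM step, so the likelihood never decreases and the simplex is
preserved without projection. Uniform initialization makes the fit
deterministic; iteration stops at relative log-likelihood change < 10⁻⁸
or 500 iterations (non-convergence flagged, not fatal). Genes are
restricted to those shared with the reference (≥25 required), by default
the top half by count variance. No platform-effect term is modelled
(single-platform synthetic data); this is an explicit extension point.
A duplicate-profile caveat: before injury remodels its signature, the
injured-PT profile is indistinguishable from PT S2/S3, so healthy
sections are fit against a reference without the injured type (mirroring
the practice of choosing the reference per condition).

## Communication

Senders are non-receiver spots within 250 µm (inclusive) of an Epo⁺
receiver, grouped by dominant deconvolved type; groups under the size
floor are dropped with a log entry. The score is a product of Hill
functions of the sender-side ligand and receiver-side receptor levels,
subunit levels combined by geometric mean (every subunit of a complex
required); defaults K = 0.5, n = 1, with a mass-action alternative
L·R/(1+L·R). Expression enters as log1p(counts per 10k); on that scale
marker-level expression is ~2–6, so the demo configuration sets K = 3 to
sit inside the dynamic range. Significance is a one-sided permutation
test relabelling the pooled sender + receiver set with group sizes
preserved, p = (1 + #{P_perm ≥ P_obs})/(1 + B), B = 1000 by default
(add-one correction avoids p = 0). A limitation: because Epo⁺ receivers
themselves neighbour injured tubules, receiver ligand levels co-rise with
sender levels in the injury condition, and the sender-vs-receiver
permutation contrast has limited, seed-dependent power at desk-scale spot
counts; the paired pipeline reports per-condition significant pairs and
restricts the condition comparison to sender groups present in both
conditions.

## Over-representation

Upper-tail hypergeometric p = P(X ≥ k | N, K, n) per set, BH across sets,
gene ratio k/n, overlap counts reported. The universe is the genes tested
for DE (not the genome) and is configurable. Sets are flat; GO-hierarchy
pruning is out of scope. Exactness is verified against brute-force
enumeration of the tail for all small-universe instances.

## Pipeline and problem sizes

The demo pipeline simulates an 0.8 × 0.8 mm section at 1 µm/px with 220
tubules, 50 REP cells and depth 3000 — sizes chosen so a paired
healthy/injured run with segmentation, proximity, normalization,
deconvolution, DE, ORA and communication completes in a few seconds while
every stage retains clear signal. `scripts/acceptance.py` uses n = 500
REP cells for proximity recovery, 200 spots × 8 types for deconvolution,
500 × 300 for normalization, and 500 repeats × 200 permutations for
calibration. Run configs are schema-validated (unknown keys rejected) and
every report carries the config hash and seed; identical configs give
byte-identical outputs.

## Known limitations

- 2-D only; no vasculature, no oxygen field, no H&E rendering.
- The synthetic marker panel is small (~140 genes); genome-scale effects
  (gene–gene correlation structure, ambient RNA, segmentation-free
  platforms) are not represented.
- Deconvolution accuracy on closely collinear signatures (injured PT vs
  PT S2/S3 at low severity) degrades gracefully but is not resolved —
  the types share most of their profile by construction.
- Communication significance at small spot counts is power-limited (see
  above); the machinery is validated on controlled constructions and by
  null calibration.
- The pixel classifier targets contract-level fidelity (QuPath-like
  behaviour), not bit-compatibility with any specific tool.
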