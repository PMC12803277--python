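# Methods

This note documents the models, conventions and numerical choices behind
`duplexium`, and what the synthetic benchmark does and does not establish
about real instrument data.

## Coordinate frames and registration

All coordinates are micrometres in a continuous 2D slide frame; pixel
coordinates never appear. The two decoding runs image the same physical
section, but removing and re-seating the slide cassette between runs shifts
the second run's frame by a small, rigid-like offset. The map from the
segmentation (run-1) frame into the run-2 frame is modelled as a linear
transform `T(p) = A·p + t`.

* **Model choice.** The default model is `similarity` (rotation + uniform
  scale + translation): cassette re-seating is a rigid effect, and a scale
  degree of freedom absorbs small optical magnification differences. Because
  it is not documented whether shear can occur, a full 6-parameter `affine`
  model is available behind a flag rather than assumed.
* **Estimation.** For `similarity`, the closed-form Procrustes/Umeyama
  solution of `argmin Σ‖T(mᵢ) − fᵢ‖²` with the reflection branch excluded
  (a slide cannot mirror itself); for `affine`, ordinary least squares on
  the design `[x, y, 1]`. Collinear or insufficient anchors raise a
  rank-deficiency error rather than returning a degenerate fit. The RMS
  anchor residual is stored on the transform.
* **ICP refinement.** Anchor placement is manual and coarse, so a fine-scale
  correction alternates (a) greedy one-to-one nearest-neighbour matching of
  transformed moving cell centroids to fixed centroids within a 15 µm cutoff
  (about one cell diameter — beyond that a "match" is more likely a
  neighbouring cell) and (b) re-estimation of a **rigid** correction
  (scale fixed at 1, so the refinement cannot drift the scale estimated
  from anchors). Iteration stops when the mean matched distance improves by
  less than 1e-4 µm or after 50 iterations; the best iterate seen is
  returned, so refinement never worsens the mean matched distance. In the
  pipeline, the fixed targets are per-cell centroids of run-2 transcripts
  under a preliminary assignment against the coarsely moved masks; zero
  matches raise an error carrying the unrefined transform.

## Transcript filtering and assignment

Transcript-level QC keeps a record iff `qv ≥ 20` (threshold inclusive —
the filter removes QV < 20), it overlaps a segmented nucleus, and it is
assigned to a cell. The nuclear-overlap and assignment requirements are
flags: matrix construction uses nuclear transcripts only, while slide-level
transcript tallies include non-nuclear ones. A removed transcript is
attributed to the *first* failing check in the order qv → nucleus →
unassigned, so tallies sum exactly to the removed count.

Assignment is point-in-polygon against the (transformed) masks using the
even-odd rule, **boundary-inclusive** — whether the instrument's own
assignment includes boundaries is unknown, so the choice is stated rather
than inferred. A point inside several (overlapping) masks is resolved by
smallest cell area, then lexicographic cell id: deterministic, and
conservative in favour of the more specific mask. An STRtree spatial index
makes the operation sub-quadratic; the index is an implementation detail
and its output is required (and tested) to equal a brute-force ray-casting
oracle exactly. Areas and centroids come from the shoelace formula (via
shapely), in µm².

## Matrix merging and cell QC

Both runs are assigned against one segmentation, so a cell has one id and
two transcript streams. Features are tagged `<gene>-<panel>`; a gene on
both panels yields two distinct features, making the concatenated matrix
well-defined. The cell roster is every segmented cell — a cell silent in
one run carries zeros rather than being dropped — so the three panel views
(V1-only, Prime-only, Combined) are comparable cell-for-cell.

Cell-level QC retains a cell iff all four hold on the view under test,
boundaries inclusive exactly as written: `n_counts ≥ 50`, `n_genes ≥ 5`,
`5 ≤ cell_area ≤ 140` µm², `nucleus_area ≥ 3` µm². Area units are taken as
µm² (the thresholds are bare numbers in common usage). Per-threshold
attrition counts identify the dominant filter (minimum counts, in
practice). Because the area filters are shared and combined counts/genes
dominate each single panel's, any cell retained on a single-panel view is
retained on the combined view — Combined ≥ max(V1, Prime) retention is an
exact invariant, not a statistical tendency.

## Panel statistics

* **Aggregates and correlations.** Pseudobulk totals are column sums per
  gene, slide-level and per TMA sample. Correlations between runs default
  to Pearson on log1p totals — raw-scale Pearson is dominated by a handful
  of high expressors — but both raw/log1p and Pearson/Spearman variants are
  computed, since the appropriate convention is analysis-dependent.
* **Z-score shift test.** Within each run, `z_g = (x_g − x̄)/s` over that
  run's panel genes, where `x_g` is the log1p slide total and `s` the
  sample (ddof = 1) standard deviation. The solo-vs-dual shift
  `Δz_g = z_solo,g − z_dual,g` is summarised per group (panel-overlap genes
  vs a seeded, without-replacement random subset of non-overlap genes) by
  its median and a Wilcoxon signed-rank test. The signed-rank statistic is
  implemented in-package (zeros dropped, average ranks, normal
  approximation with tie and continuity corrections) because the statistic
  is the contract here; it is cross-checked against scipy in the tests.
  Detection is judged at α = 0.05. The random subset's *null consistency*
  is judged at a stricter α = 0.01: z-scoring within a run forces the
  panel-mean to zero, so any real shift in the overlap genes arithmetically
  leaks a small opposite-sign shift (≈ overlap fraction × effect) into all
  other genes, and a liberal threshold would flag the control subset for
  that purely compositional reason.
* **Per-gene cross-chemistry ρ.** Spearman rank correlation across cells
  between a gene's V1-tagged and Prime-tagged counts, average ranks for
  ties, genes with zero variance in either view flagged undefined rather
  than silently dropped.
* **Secretome diversity.** Per cell, the number of distinct secreted genes
  with count ≥ 1 on the view; bounded by both the view's detected genes and
  the secreted set size.
* **Concordance.** Clustering itself is external; the module cross-tabulates
  two label series (cells missing from one labelling appear as a
  `filtered` stratum — the alluvial-plot input) and reports the adjusted
  Rand index on shared cells, implemented from the contingency table and
  cross-checked against scikit-learn in the tests.

## The synthetic generator

The generator emulates the benchmark study design; its defaults are the
study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 17 | TMA cores (rectangular sample regions) |
| `n_genes_v1` / `n_genes_prime` | 480 / 5001 | panel sizes |
| `n_overlap` | 239 | genes targeted by both panels |
| `mean_counts_v1` / `mean_counts_prime` | 125 / 115 | expected per-cell transcripts (match observed per-cell medians of the solo runs) |
| `prime_overlap_attenuation` | 0.8 | multiplier on broad-panel rates of overlap genes in the dual run |
| `qv_fail_fraction` | 0.1 | transcripts drawn from the failing QV component |
| `true_transform` | 0.4°, (8, −5) µm | cassette re-seating offset (magnitude is not documented for real slides, so it is an explicit parameter) |
| `n_cells` | 400 | desk-scale default; cells per slide, not a biological constant |

Cells are jittered hexagons (circumradius 5 µm, pitch 2.6 r, so masks are
simple and non-overlapping by construction without collision logic) with a
nucleus ring scaled 0.5 about the centroid; areas (~60 µm² cell, ~16 µm²
nucleus) sit inside the QC windows so the area filters are exercised but
not dominant, as in tissue. Counts are Poisson per cell × gene with
gamma-distributed per-cell size factors (shape 3, i.e. negative-binomial
marginals with CV ≈ 0.58 — enough spread that the `n_counts ≥ 50` filter
bites realistically at the default means). Gene relative abundances are
lognormal(σ = 1); a gene shared by both panels has one abundance, so panel
pseudobulks of shared genes correlate. Overlap genes additionally carry a
per-cell lognormal activity whose log is shared between panels with
correlation `latent_corr` (default 0.5, a knob because only "modest"
cross-chemistry correlation is established) — this, plus the shared size
factors, makes the same gene's V1 and Prime counts positively correlated
across cells. 70% of transcripts are placed inside the nucleus ring so the
nuclear-overlap filter removes a realistic minority. QV values come from a
two-component mixture (pass ≈ N(40, 3) clipped at 20, fail ≈ N(10, 3)
clipped below 19.5) strictly straddling the threshold. Background
transcripts are uniform outside all masks at 0.002 µm⁻², labelled
`UNASSIGNED`. Landmarks are six cell centroids paired with their
transformed positions, with optional Gaussian jitter.

**What the generator does not emulate:** optical crowding and segmentation
error (masks are exact), spatial expression structure within a sample
(cells are exchangeable), probe-level sequence effects, z-stacks, and
density variation between TMA cores. Passing tests therefore demonstrate
that the *pipeline arithmetic and inference* behave correctly under a
faithful statistical model of the design — not that any particular slide
will show a 0.8 attenuation.

## Problem sizes and numerical conventions

Simulation-based checks run at reduced scale chosen for statistical
adequacy: sensitivity-shift simulations use 1000 broad-panel genes with 48
overlapping (preserving the ~4.8% overlap fraction of the real panels,
which controls the compositional leakage described above) and 250 cells;
registration Monte-Carlo uses 6 anchors over 50 seeds; the assignment
oracle uses 10,000 points against 200 polygons; retention ordering runs the
full default design (400 cells × 5,481 features). Type-I calibration uses
500 null simulations against a ±2 percentage-point band around the nominal
5% level.

Determinism: every stochastic routine takes an explicit seed or Generator;
the pipeline derives all randomness from one master seed and is
byte-identical across reruns (verified by manifest SHA-256 hashes).
Transcript tables round-trip exactly (`float_precision="round_trip"` on
read). MatrixMarket files use 1-based indices per the standard. The
`UNASSIGNED` sentinel is the literal string used by the platform's
transcript tables.

## Known limitations

* The ICP refinement estimates a rigid correction only; a residual scale or
  shear error from the anchor stage is not corrected.
* Pseudobulk correlations at desk scale are tighter than slide-scale values
  from hundreds of millions of transcripts; the package reports both raw
  and log1p variants rather than asserting which convention external
  figures used.
* The cell-matching step assumes the shared segmentation gives one id per
  physical cell; doublet detection and imputation across panels are out of
  scope.
* The real pre-filter roster can be slightly smaller than the segmented
  cell count (upstream exclusions outside this pipeline); retention
  percentages are always reported against the roster actually filtered.
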