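# Methods

## The per-cell RNAscope quantification model

RNAscope renders each detected mRNA molecule (or a small cluster) as a
punctate fluorescent "speckle".  The quantification model treats an image as a
set of cells, each owning the speckles whose centroids fall inside its
territory:

- **Cell territory.**  Nuclei are detected on the DAPI channel and each
  nucleus is expanded radially by a fixed Euclidean distance
  (`expansion_radius_px = 10`, i.e. 1.6 µm at 0.16 µm/px) to stand in for the
  cytoplasm.  Expansion assigns every background pixel within the radius to
  its nearest object; exact ties go to the lower label id, which makes the
  operation deterministic and independent of processing order once objects
  are canonically relabeled (raster order of their top-left pixel).  Objects
  can only grow, never merge, and radius 0 is the identity.  The
  implementation runs one bounding-box-cropped Euclidean distance transform
  per object and keeps a running best-distance image; the ascending-label,
  strictly-closer update realizes the lower-label tie-break exactly.  The test
  suite checks it pixel-for-pixel against an exhaustive per-pixel
  nearest-object oracle.
- **Speckles.**  A speckle is an 8-connected component of pixels at or above
  the intensity threshold with area ≥ `min_spot_area_px = 8`; the area gate
  removes single-pixel detection artifacts.  Spot counts are non-increasing
  in the threshold because the suprathreshold pixel set shrinks (in the
  operating regime above the noise floor; see the calibration grid below).
- **Threshold calibration.**  The threshold is the smallest candidate at
  which the pooled rate of speckles on negative-control images (total
  retained speckles ÷ total cells) drops to at most
  `target_background_rate = 0.1` speckles/cell — one speckle per ten cells,
  the accepted unspecific-background level for the assay.  Candidates are
  quantiles of the pooled negative-control intensities, geometric in tail
  probability (200 steps) and capped at a suprathreshold fraction of 10⁻⁴:
  genuine speckles on a negative control occupy at most a few 10⁻⁴ of the
  field, and thresholds lighting up more than that sit inside the noise
  floor where connected components stop being speckle-like (at the extreme,
  one percolating image-wide blob) and the count-vs-threshold trace stops
  being monotone.  Rates are pooled over all images, not averaged per image,
  because one threshold serves the whole dataset.
- **Classification.**  KCC2 mRNA is the neuronal marker: ≥ 10 KCC2 speckles →
  neuron; 0 → non-neuronal; 1–9 → `unclassified`, excluded from both
  denominators (the two printed rules define only the extremes; naming the
  middle explicitly keeps the partition total).  NKCC1 counts are binned
  none (0), low (1–4), moderate (5–10), high (11–15), very_high (≥ 16); the
  "high" name fills the gap between the published "5–10" and ">15" bins so
  the bins partition ℕ.

## The splice-variant model

The *Slc12a2* cassette exon-21 (16 codons, 48 nt) distinguishes NKCC1a
(included) from NKCC1b (skipped).  Junction evidence is extracted from
alignments by walking each read's CIGAR from its alignment start, advancing
on reference-consuming operations (M/D/N/=/X) and emitting one junction per N
gap; or read from junction tables (native TSV 0-based half-open; STAR
`SJ.out.tab` 1-based closed, converted on read).  Classification is exact
coordinate matching against three templates derived from the exon model —
skip (end of exon-20 → start of exon-22) and the two inclusion flanks — with
an optional ± tolerance (default 0) for noisy aligners.

Inclusion is tallied from the 5′ flank by default (`five_prime`), because a
single transcript produces both flanking junctions and counting both would
double-count; `mean` and `sum` rules are selectable, and `mean` equals
`five_prime` whenever the two flanks carry equal counts.  Percentages are
rounded to the nearest integer and reconciled
(`percent_b = 100 − percent_a`) so the pair always sums to 100.

## The expression harmonization model

Per-cell normalization is `ln(gene_umi / total_umi × 10⁶ + 1)` — ln, not
log₂, and no alternative pseudocounts.  The transform is monotone in the
gene count, zero iff the gene is unobserved, and invariant to rescaling a
cell's whole count vector; summed over all genes the pre-log TPM values give
exactly 10⁶ per cell.  Detection follows the source dataset's rule: any
single transcript by default, or an inclusive threshold on the ln(TPM+1)
scale (one published source uses 1.1, a constant taken as given because its
original scale is not reconstructible here).  Data provided only as
subcluster aggregates bypass per-cell normalization and are carried through
flagged `subcluster`, without any attempt at deconvolution.  Per-type
aggregation warns about and excludes unannotated cells, and its
cell-count-weighted per-type means recombine exactly to the global mean.

## The synthetic-data generator

The generator exists to make every downstream claim checkable against exact
ground truth, so its geometry is chosen to make recovery exact by
construction, not merely likely:

- **Scenes** are single 2-D planes (the quantified data are single optical
  planes) with disk nuclei of constant radius (default 25 px ≈ 4 µm at
  0.16 µm/px) rendered on DAPI, probe speckles as isotropic Gaussians
  (σ = 1.5 px, a standard smFISH PSF approximation; amplitude constant per
  channel, default 2500), additive Gaussian read-out noise (σ = 100, so the
  default peak SNR is 25), and a negative-control channel.
- **Resolvability constraints.**  Per-cell spot counts are i.i.d.
  Poisson(λ_channel), but placements respect (i) a minimum pairwise spot
  separation (8 px) so that threshold + connected-components detection cannot
  fuse two true spots — at the Gaussian saddle between two spots 8 px apart
  the summed intensity (≈ 0.06 × peak) sits far below any calibrated
  threshold — and (ii) a ≥ 4 px margin from the equidistant boundary to
  every neighbouring cell so centroid assignment is unambiguous.  Placement
  is rejection sampling with whole-configuration restarts; an infeasible
  spec raises an explicit error naming the spacing constraint rather than
  silently dropping spots.  The separation constraint is the simulator's
  departure from spatial-Poisson realism: it declares that spots are
  optically resolvable, which real tissue does not guarantee — passing
  recovery tests therefore demonstrates correctness of the counting chain,
  not robustness to optically merged molecules.
- **Negative-control background** is Poisson(rate × n_cells) false spots
  (default 0.3/cell) with a bimodal amplitude mix: a dominant dim mode
  (250, weight 0.8) below any sensible detection threshold — diffuse
  sub-threshold junk — and a sparse bright mode (1500, weight 0.2) of
  speckle-like background within the one-per-ten-cells budget.  This mirrors
  what an acceptable negative control looks like in practice and gives the
  calibration bound a stable margin; a mix whose countable rate straddles the
  0.1 target at the chosen threshold would make the smallest-passing-candidate
  rule sit exactly at the budget boundary, where a held-out rate is a coin
  flip by construction.
- **What is not simulated:** 3-D stacks, autofluorescence and bleaching
  gradients, irregular nucleus shapes, optical aberrations, amplitude
  variation between molecules.  Junction reads and UMI matrices are exact
  realizations (the read generator writes the requested counts verbatim; UMI
  counts are Poisson per gene with a filler gene absorbing the remaining
  library so the expected total matches the requested library size).

## Numerical choices and degenerate inputs

- Nucleus detection is Gaussian smoothing (σ = 2) + Otsu + connected
  components + optional watershed declumping seeded from distance-transform
  peaks; every sub-choice is an argument.  A flat or pure-noise DAPI plane
  yields an empty mask via a contrast guard (foreground–background mean
  separation ≥ 4 background SDs): plain Otsu on unimodal noise would return
  a percolating pseudo-object.  Border-touching nuclei are kept by default.
- Objects smaller than 50 px are discarded (no published nucleus size gate
  exists; 50 px ≈ 1.3 µm² is far below any nucleus section).
- A scene with zero cells short-circuits the pipeline: empty record and
  summary tables, no calibration attempted.
- Calibration requires ≥ 10 pooled cells; zero skip+inclusion evidence gives
  an undefined (None) variant fraction with a warning rather than a NaN.
- Default cohort sizes keep everything desk-scale: 100-cell scenes at
  1300 × 1300 px for recovery and calibration runs, 25-cell scenes at
  560 × 560 px in the unit suite; the acceptance script runs in about half a
  minute and the full test suite in under a minute.

## Known limitations

- Segmentation is intensity-based; densely packed or irregular nuclei would
  need learned or shape-aware methods (out of scope by design).
- The centroid assignment rule cannot split a speckle straddling two cells;
  the generator's boundary margin sidesteps the case that real tissue does
  present.
- Tissue-derived cohort percentages (e.g. the fraction of NKCC1-positive
  neurons in a real section) depend on the original images and are not
  reproduced here; synthetic cohorts only mirror their design (cohort sizes,
  rate ranges, mixture weights).
- Splice quantification assumes the aligner reports junctions at exact
  template coordinates; the matching tolerance exists but defaults to 0.
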