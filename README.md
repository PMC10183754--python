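# specklesplice

Tools for quantifying NKCC1 (*Slc12a2*) expression at cellular resolution in
the mouse brain, built around three procedures that are usually run by hand or
in ad-hoc spreadsheets:

1. **Per-cell RNAscope speckle counting.**  Nuclei are segmented on the DAPI
   channel and expanded radially by 10 px (1.6 µm at 0.16 µm/px) to
   approximate the cytoplasm; probe speckles are connected components above an
   intensity threshold, filtered by a minimum area of 8 px, and related to
   cells by centroid containment.  The intensity threshold is not free: it is
   calibrated on sections stained with a negative-control probe so that the
   pooled false-speckle rate is at most one speckle per ten cells.  Cells with
   ≥ 10 KCC2 speckles are classified as neurons, cells with zero KCC2 speckles
   as non-neuronal, and NKCC1 counts are binned (0 / 1–4 / 5–10 / 11–15 / ≥ 16).
2. **Exon-21 splice-variant quantification.**  NKCC1a includes the 48-nt
   cassette exon-21, NKCC1b skips it.  From spliced alignments (SAM/BAM) or
   junction tables, intron gaps are extracted by a CIGAR walk, classified
   against the exon model (skip = exon-20→exon-22; inclusion = a flanking
   junction of exon-21), and summarized as integer percentages,
   `%NKCC1a = round(100 · n_inc / (n_inc + n_skip))`, `%NKCC1b = 100 − %NKCC1a`.
3. **Single-cell expression harmonization.**  Per-cell UMI counts from public
   atlases are placed on a common scale, `ln(gene_umi / total_umi × 10⁶ + 1)`
   (= ln(TPM+1)), with per-dataset detection rules, and aggregated by
   annotated cell type.

Every stage is testable without any download: the `synthgen` module renders
multi-channel FISH scenes, spliced reads and UMI matrices with exact exported
ground truth (spot coordinates, per-cell counts, junction tallies).

## Worked example

```python
from specklesplice.synthgen import SceneSpec, generate_fish_scene
from specklesplice.celltyping import run_rnascope_pipeline

spec = SceneSpec(n_cells=25, image_height_px=560, image_width_px=560,
                 channel_rates={"KCC2": 20.0, "NKCC1": 8.0}, seed=7)
bundle, truth = generate_fish_scene(spec)
records, summary, calibration = run_rnascope_pipeline([bundle])
print(f"threshold {calibration.threshold:.0f}, "
      f"{calibration.achieved_rate:.2f} speckles/cell on the negative control")
print(summary[["cell_class", "n_cells", "frac_nkcc1_pos", "mean_nkcc1"]])
```

prints

```
threshold 387, 0.04 speckles/cell on the negative control
  cell_class  n_cells  frac_nkcc1_pos  mean_nkcc1
0     neuron       25             1.0        8.28
```

i.e. the calibrated threshold keeps the negative-control rate within the 0.1
speckles/cell budget, all 25 cells are classified as neurons (KCC2 rate 20),
every cell has at least one NKCC1 speckle, and the mean recovered NKCC1 count
(8.28) sits near the simulated rate of 8.

For the splice side:

```python
from specklesplice.splicejx import (ExonModel, classify_junctions,
                                    compute_variant_fractions, extract_junctions)
from specklesplice.synthgen import generate_junction_reads

model = ExonModel("chr18", "+", ((10_000, 10_200), (15_000, 15_048),
                                 (20_000, 20_100)), focal_index=1)
generate_junction_reads([(model.skip_template, 44),
                         (model.include_5p_template, 14),
                         (model.include_3p_template, 14)], "neurons.sam")
jx = classify_junctions(extract_junctions("neurons.sam"), model)
vf = compute_variant_fractions(jx)
print(f"NKCC1b {vf.percent_b}% ({vf.n_skip}/{vf.total}), NKCC1a {vf.percent_a}%")
# NKCC1b 76% (44/58), NKCC1a 24%
```

A thin CLI mirrors the library: `specklesplice simulate scene|junctions|umi`,
`specklesplice segment`, `specklesplice spots`, `specklesplice run`,
`specklesplice splice`, `specklesplice scrna`.

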