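# hsrskit

Single-cell analysis of hyperspectral stimulated-Raman-scattering (hSRS)
microscopy, built for detecting and quantifying chemical aggregates — such as
limonene droplets in engineered *E. coli* — directly from label-free image
stacks.

An hSRS acquisition yields a λ-x-y cube: a Raman spectrum (here the
fingerprint region, 670–900 cm⁻¹ at 10 cm⁻¹ steps) at every pixel. The
package turns such a cube into per-cell chemistry:

1. **Spectral unmixing.** Each pixel spectrum *d* ∈ ℝ^{N_λ} is modeled as a
   linear mixture of k reference spectra S ∈ ℝ^{k×N_λ} (pure limonene, the
   wild-type cell body, and the non-cell background of the stack):

       d = c S + e,     ĉ = argmin_c ½‖d − cS‖₂² + λ‖c‖₁,  c ≥ 0

   solved per pixel by cyclic coordinate descent with exact soft-threshold
   updates. The L1 penalty encodes the sparsity premise — limonene is
   confined to intracellular aggregates — and the output is one
   concentration map per channel plus a residual-norm image.
2. **Segmentation.** Cells from the spectrally summed image (smooth →
   threshold → watershed split), aggregates from the limonene map (white
   top-hat → threshold, restricted to cells, parented by centroid).
   Externally curated label masks import through the same interface.
3. **Quantification.** Per-cell and per-aggregate feature tables: areas,
   central-line length L, the polar-localization metric d/L (distance from
   the aggregate to the furthest cell pole over cell length; 0.5 = midcell,
   1 = pole), 760 cm⁻¹ peak intensity, summed spectral windows, unmixed
   channel statistics; threshold-sweep classification of limonene-rich
   aggregates against control strains; Wilcoxon rank-sum population
   comparisons; calibration curves with a 3σ_blank/slope detection limit.
4. **Colocalization.** Mander's coefficient
   MCC = Σᵢ Limᵢ·[LimSynᵢ ≥ T] / Σᵢ Limᵢ between the limonene map and an
   enzyme-fluorescence channel, evaluated inside cells.
5. **Synthetic scenes.** A ground-truthed generator (rod-shaped cells, a
   minority subpopulation bearing polar aggregates, forward-modeled spectra
   with additive noise, a matched fluorescence channel, dilution series)
   makes every stage testable end to end without microscope data.

## Worked example

The bundled demo simulates a small scene (40 cells, half of them carrying
aggregates), runs every stage, and prints the population summary:

```sh
hsrskit demo --out demo_run --seed 0
```

```
"n_cells": 40,
"n_aggregates": 23,
"frac_cells_with_aggregates": 0.45,
"frac_cells_limonene_rich": 0.225,
"aggregate_count_histogram": {"0": 22, "1": 13, "2": 5},
"mcc": 0.8600731653420846,
"rich_threshold": 1.1,
"lam": 0.01
```

Reading: 18 of 40 cells carry at least one detected aggregate (0.45, matching
the simulated probability 0.5 to within sampling error); 9 cells have an
aggregate whose mean limonene-channel value exceeds 1.1× the cell-body
normalization, so 22.5% are classified limonene-rich; and 86% of total
limonene intensity falls on pixels where the (fully colocalized, but blurred
and noisy) fluorescence channel exceeds its Otsu threshold. `demo_run/`
contains the channel maps, masks, feature tables and a checksummed manifest;
running the same command twice reproduces it byte for byte.

The same stages are available as library calls (`generate_scene`,
`unmix_stack`, `segment_cells`, `extract_cell_features`, `mcc`, ...) and as
CLI subcommands (`simulate`, `unmix`, `segment`, `quantify`, `colocalize`,
`run`).

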