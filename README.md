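# tps3d

Depth-resolved PD-L1 tumor proportion scoring for 3-D fluorescence volumes.

## The problem

The PD-L1 tumor proportion score (TPS) guides immunotherapy selection in
non-small-cell lung cancer.  Clinically it is read from a single 4 μm
section, yet PD-L1 expression varies through tissue depth: a thick, cleared,
fluorescently stained section imaged as a confocal z-stack can score *every*
depth level and reveal cases whose superficial layers under-represent the
tumor's expression.  `tps3d` implements the computational side of such a 3-D
scoring workflow for volumes with a nuclear dye, a PD-L1 marker and a
lipophilic counterstain:

1. **Nuclear segmentation** per z-plane: Li minimum-cross-entropy threshold →
   hole filling → connected components → distance-transform-seeded watershed
   to split touching nuclei.
2. **Tumor masking**: a pluggable per-plane tumor-region model (a classical
   nuclear-density baseline ships; a trained network can be dropped in).
   A nucleus is a tumor cell iff its centroid lies in the mask.
3. **Membranous classification**: each tumor cell's marker signal is
   summarized over an annulus around the nucleus; the default rule calls a
   cell positive iff `ring_coverage_fraction >= 0.3` and
   `annulus_to_nucleus_ratio >= 1.2` ("any membranous staining" semantics).
4. **Scoring**: per depth bin of 5 μm,

       TPS = 100 x (# tumor cells with membranous staining) / (# tumor cells),

   with clinical categories `< 1 %`, `1–49 %` (read as [1, 50)) and `>= 50 %`,
   plus heterogeneity summaries (max–min spread with depth, category
   crossings).
5. **Pseudo-needle biopsy**: an 8 mm × 1 mm track through the volume's
   intensity-weighted centre of mass, spanning the full depth, simulating a
   core-needle specimen.
6. **Concordance**: weighted kappa (linear or quadratic weights) and percent
   category concordance for paired ordinal TPS calls, with interpretation
   bands (> 0.6 good, > 0.8 excellent).

Because no patient volumes ship with the package, a first-class **phantom
generator** produces 3-channel synthetic z-stacks with exact per-cell ground
truth (position, tumor status, PD-L1 status) and programmable depth gradients
in positivity, so the whole chain is verifiable end to end.

## Worked example

```python
import tps3d as t

cfg = t.PhantomConfig(
    field_size_um=(256.0, 256.0), depth_um=60.0, n_cells=400, seed=42,
    positivity_profile=t.PositivityProfile(kind="linear", p_top=0.05, p_bottom=0.35),
)
volume, truth = t.generate_phantom(cfg)
result = t.run_pipeline(volume, t.PipelineConfig(masker="constant"))
print(result.profile.to_frame().to_string(index=False))
```

```
 depth_start_um  depth_end_um  n_tumor_cells  n_positive_cells  tps_percent category
            0.0           5.0              9                 0     0.000000     < 1%
            5.0          10.0            202                12     5.940594    1-49%
           10.0          15.0            312                46    14.743590    1-49%
           15.0          20.0            291                48    16.494845    1-49%
           20.0          25.0            281                33    11.743772    1-49%
           25.0          30.0            274                58    21.167883    1-49%
           30.0          35.0            291                62    21.305842    1-49%
           35.0          40.0            286                60    20.979021    1-49%
           40.0          45.0            312                73    23.397436    1-49%
           45.0          50.0            335                76    22.686567    1-49%
           50.0          55.0            188                51    27.127660    1-49%
           55.0          60.0              7                 5    71.428571   >= 50%
```

Each row is one 5 μm depth window; `n_tumor_cells` counts per-plane
detections (one physical cell contributes to every plane its nucleus
crosses, mirroring per-layer scoring).  The simulated linear gradient
(5 % → 35 % positivity) is visible as rising `tps_percent`; the first and
last bins hold very few detections (axial placement margins) and are
correspondingly noisy — which is exactly the kind of sparse-bin behavior the
profile summaries must be read against:

```python
prof = result.profile
print(f"average TPS (mean of 5 um bins): {prof.average_tps:.2f}%")   # 21.42%
print(f"cell-pooled TPS:                 {prof.pooled_tps:.2f}%")    # 18.79%
print(f"category of average:             {prof.category_of_average.value}")  # 1-49%
```

The ground truth for this seed has a cell-pooled TPS of 19.00 %, so the
pipeline recovers the simulated expression level to within a percentage
point.

A command-line interface mirrors the library
(`tps3d simulate | segment | mask | score | profile | needle | kappa | run`);
every subcommand takes `--config` (YAML with `phantom`/`pipeline` sections)
and `--seed`.

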