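# centrotrace

Quantification of centromeric fluorescence spots with local-background
correction, exercised entirely on seeded synthetic two-channel microscopy
scenes, together with deterministic models of how a centromeric protein
mark propagates across generations, sexes and chromosomes.

The package has five parts:

- **`centrotrace.synthetic`** — seeded generator of GFP + DNA image pairs
  (16-bit TIFF) with ground-truth tables: sperm nuclei with 2–4 partially
  clustered spots, late spermatocytes with three chromosome territories
  (two major-autosome territories with two spots each; a paired-4 spot next
  to a bright DNA dot, an X spot near an irregular intense DNA region, and
  an elevated Y spot), embryo metaphase fields with paternal/maternal
  half-sets, and wing-disc nuclei. Spots are rendered as pixel-integrated
  isotropic Gaussians whose total mass equals the recorded true signal.
- **`centrotrace.quantify`** — thresholded spot segmentation (an automated
  stand-in for manual region selection), the background-corrected
  integrated intensity `I_s − A_s·(I_l − I_s)/(A_l − A_s)` from a selected
  region and its slightly enlarged superset, per-cell totals with ploidy
  correction, within-cell normalization (relative intensities summing to
  exactly 100%), control-mean-100 normalization, DNA-landmark-based
  chromosome assignment, an intensity-outlier rule, and Welch-t group
  comparison.
- **`centrotrace.inheritance`** — deterministic recursion for the level of
  the mark under sex-specific germline loading (additive or multiplicative),
  with parent-of-origin transmission weights (autosomes 1/2, Y always male,
  X 2/3 female), stabilization detection, perturbation propagation,
  template-governed maintenance, and a seeded stochastic lineage sampler as
  a cross-check.
- **`centrotrace.dilution`** — closed-form arithmetic: the 4-fold per-genome
  meiotic dilution of a conserved pool, the `(1/2)^(k−1)` label dilution
  across cleavage cycles with a detectability threshold, the
  nucleocytoplasmic-ratio cellularization trigger (cycle 13 diploid /
  14 haploid, 2-fold density ratio), and Mendelian transgene transmission.
- **`centrotrace.pipeline` / `centrotrace.cli`** — orchestration of
  generate → quantify → normalize → compare with one top-level seed, CSV/JSON
  outputs and a run log.

## CLI

```sh
# one synthetic scene: two TIFFs + masks + ground-truth and landmark CSVs
centrotrace simulate --stage spermatocyte_S5 --n-nuclei 4 --seed 1 --out out/scene

# segment + background-correct + assign chromosomes
centrotrace quantify --gfp out/scene_gfp.tif --masks out/scene_masks.tif \
    --landmarks out/scene_landmarks.csv --out out/measurements.csv

# transgenerational model + dilution arithmetic, printed as JSON
centrotrace model --male-increment 10 --female-increment 10 --stochastic-lineages 10000

# full experiment: control vs perturbed sperm, image path end to end
centrotrace report --seed 1 --factors 0.5,7.0 --out out/run
```

All commands accept YAML configs (`--config`); every output records the
seed, and reruns with the same seed reproduce files byte-identically.

## Conventions

Images are 2-D, 0-based (row, col) indexed with the origin at the top
left; channels are written as separate single-channel 16-bit TIFFs; ground
truth and measurements are plain CSV with documented columns.
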