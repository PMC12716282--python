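# wingfa

Wing venation morphometrics and fluctuating-asymmetry (FA) analysis for
paired insect wings.

Damselfly and dragonfly wings develop during the aquatic larval stage, so
small random deviations from perfect bilateral symmetry — fluctuating
asymmetry — are used as a proxy for developmental stress experienced in the
water. `wingfa` implements the full measurement-to-inference chain for such
studies:

- a **synthetic wing generator** producing ground-truth left/right wing
  pairs (tessellated wings with per-side junction jitter, directional
  offsets, antisymmetry and cell merge/split events), rendered images,
  12-landmark sets, and stressor-structured cohorts;
- **segmentation** of wing images into outline, membrane cells and vein
  junctions, with a proximal/distal (Set 1 / Set 2) partition;
- per-cell and whole-wing **geometric features** (area, perimeter,
  principal-axis length/width, circularity = 4πA/P², wing load);
- **pair asymmetry**: reflect–translate–rotate alignment, Hungarian
  sister-cell matching, trait NRMSE averaged over both comparison
  directions, matched junction/centroid distances, outline distance, and
  count differences (subtract values);
- **landmark FA**: generalized Procrustes analysis with matching bilateral
  symmetry, directional-asymmetry removal, and a per-individual FA score
  ‖aᵢ − ā‖ (the Procrustes distance of the individual's FA component from
  the mean symmetric shape), plus screening tests against directional
  asymmetry and antisymmetry;
- **spatial asymmetry maps**: sister-cell values interpolated onto a
  300 × 300 grid in a common wing frame, averaged per group, subtracted
  (treatment − control) and Gaussian-blurred (σ = 10 grid cells);
- a **GLM layer**: Poisson/log models for count responses and
  gaussian/identity models otherwise, Type-II likelihood-ratio χ² tests for
  factorial designs, and effect sizes as predicted percentage changes
  relative to the control group with standard errors.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Inject two stressor effects into a 2 × 2 factorial cohort — an altered
hydrological regime scaling wing size by 1.25 and a treatment scaling
junction jitter by 1.5 — then recover them (`examples/05_stressor_glms.py`):

```python
from wingfa import SyntheticConfig, analyze_cohort, generate_cohort, mesocosm_design

config = SyntheticConfig(
    cells_target=100, seed=11,
    effect_map={"hydrology": {"outline_length_mm": 1.25},
                "bti": {"fa_position_sd_um": 1.5}},
)
cohort = generate_cohort(config, mesocosm_design(15))  # 60 individuals
records, analysis = analyze_cohort(cohort, mode="mesocosm")
```

which prints

```
wing_length            hydrology  chi2= 120.41 p=5.15e-28 change= +23.7% +- 0.2%
fa_score               bti        chi2=  63.18 p=1.89e-15 change= +51.2% +- 1.3%
mean_dist_junctions    bti        chi2=  28.71 p=8.39e-08 change= +33.9% +- 0.3%
n_cells                hydrology  chi2=   0.00 p=9.89e-01 change=  -0.0% +- 0.0%
```

Reading: the likelihood-ratio tests detect both injected effects; the
predicted percentage changes recover the size effect (+23.7% measured vs
+25% injected) and the FA-score effect (+51.2% vs +50%). The matched
junction-distance response is significant and positive but attenuated
(+33.9% for a +50% injection) because optimal sister assignment
lower-bounds true correspondence distances — see `docs/methods.md`. The
cell count, which carries no injected effect, stays flat.

The other scripts in `examples/` each demonstrate one capability:
generation and ground truth, image segmentation round-trip, the pair
asymmetry record, landmark FA scores with symmetry-type screening, and
spatial difference maps.

## Command line

A thin CLI orchestrates file-based runs:

```sh
wingfa simulate --config run.json --out data/
wingfa analyze  --input data/ --mode mesocosm --out results/
wingfa spatial  --input data/ --trait centroid --groups hydrology --out maps/
wingfa stats    --records results/records.csv --mode mesocosm --out refit/
```

Every run writes a `manifest.json` (config, seed, version, input hashes);
fixed-seed runs are byte-identical. Exit codes: 0 ok, 1 partial failures,
2 fatal.

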