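# perinexus

Microdomain simulation and image analysis of cardiac conduction with
separable gap-junctional and ephaptic (cleft) coupling.

The package has three pillars:

1. **Microdomain conduction model** — a 2-D sheet of discrete myocytes
   with explicit extracellular clefts. Each cell is a brick-and-mortar
   polygon meshed with linear finite elements; the membrane is split into
   lateral and junctional patches, each facing its own extracellular
   node. Gap-junctional coupling (`g_j_bar`) and extracellular cleft
   conductivities (`sigma_eff_lateral`, `sigma_eff_junctional`) are
   independent knobs, so purely ephaptic effects can be isolated. Sodium
   channels can be distributed uniformly over the sarcolemma or polarized
   toward the intercalated-disk junctional membrane.
2. **Wavefront quantification** — activation-time detection (maximum
   upstroke derivative) and conduction-velocity estimation from
   activation maps or simulated sheets, including the longitudinal /
   transverse anisotropy ratio (AR).
3. **Cluster association pipeline** — Otsu thresholding, connected
   components, and object-based edge-distance classification of Nav1.5
   clusters relative to Cx43 plaques (overlapping / perinexal within
   200 nm / distal), plus synthetic two-channel image generators with
   exact ground truth.

## Quick start

```python
from perinexus import (ModelConfig, apply_interventions, run_protocol,
                       cv_from_simulation, AIE)

cfg = apply_interventions(ModelConfig(), [AIE])   # interstitial edema
_, system = cfg.build()
result = run_protocol(system, cfg.solver)
print(cv_from_simulation(result, "longitudinal"), "cm/s")
```

```python
from perinexus import (LocalizationImageSpec, make_localization_image,
                       analyze_images, summarize)

cx43, nav, truth = make_localization_image(
    LocalizationImageSpec(n_cx43=6, blur_fwhm_nm=22.0, seed=1))
print(summarize(analyze_images(cx43, nav)))
```

The `examples/` directory contains narrative scripts for the three
pillars: an intervention sweep (`01_conduction_sweep.py`), the cluster
association pipeline (`02_cluster_association.py`), and CV estimation
from activation maps (`03_activation_map_cv.py`).

## Named interventions

| name | effect |
|------|--------|
| `AIE` (acute interstitial edema) | σ̄_effe 159.1 → 203.5, σ̄_effj 17.8 → 62.8 mS/cm |
| `GJ_UNCOUPLING` (carbenoxolone) | ḡ_j 100 → 50 mS/cm² |
| `INA_INHIBITION` (flecainide) | g_Na at 86 % of nominal |

`run_sweep` evaluates CV_L/CV_T/AR over grids of these parameters and
returns a tidy DataFrame; conduction block is recorded per row.

## Testing

```sh
python -m pytest            # unit + acceptance tests
python scripts/acceptance.py --seed 0 --out results.json
```

Three acceptance sub-assertions concerning the polarized-model response
to raised extracellular conductivity are expected to fail: in this
implementation the ephaptic hand-off at nominal gap-junctional coupling
is sub-threshold, so edema speeds rather than slows transverse
conduction. See `docs/methods.md` for the analysis.

## Documentation

`docs/methods.md` describes the model formulation, numerical scheme,
estimators, and known limitations.
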