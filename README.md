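# ventact

Inference of ventricular activation properties — earliest-activation sites
(root nodes) and four conduction speeds — from 12-lead QRS complexes or
epicardial activation time maps.

The pipeline couples:

* a **synthetic biventricular geometry** generator (thick-walled
  truncated-ellipsoid LV + crescent RV shell, rule-based fibre frames with a
  60° → −60° transmural helix, endocardial root-node candidate sets with
  guaranteed 2.5 cm / 1.5 cm coverage radii, torso electrode placement);
* an **anisotropic graph-Eikonal simulator** (multi-source Dijkstra over an
  augmented mesh edge graph; orthotropic fibre/sheet/sheet-normal metric in
  the myocardium, fast isotropic endocardial layer);
* a **pseudo-ECG** forward model (per-element transmembrane-gradient ·
  grad(1/r) volume sum → standardised 12-lead QRS at 1 kHz);
* a **constrained dynamic-time-warping discrepancy** for QRS data
  (warping-slope ≤ 2 consecutive same-direction warps, Itakura-style
  parallelogram band, common start/end, linearly decaying warp penalties,
  QRS-width penalty) and RMSE for activation maps;
* an **SMC-ABC engine** over the mixed continuous (speeds) + discrete
  (root-node subset) space: Latin-hypercube prior (512 members), per-iteration
  replacement of the worst 12.5% by mutated-or-copied survivors, stopping on
  tolerance match or >50% population duplicates;
* **aggregation and metrics**: median speeds, k-means root-node centroids
  initialised from the modal configuration, percentage speed errors,
  per-ventricle closest-centroid distances and count errors, Pearson
  correlations;
* a **virtual-subject cohort** builder (4 anatomy presets × 5 named
  conduction-speed configurations, clean + 20 dB white-noise targets).

Units: lengths cm, times ms, speeds cm/s; node indices are 0-based.

## CLI

```bash
# generate a mesh bundle (mesh.vtk + CSVs + candidates + electrodes)
ventact --config config.yaml mesh --out out/mesh

# forward-simulate an activation map and 12-lead QRS
ventact --config config.yaml simulate --mesh-dir out/mesh --out out/sim

# infer activation properties from a target (ATM or ECG modality)
ventact --config config.yaml infer --mesh-dir out/mesh \
    --target out/sim/atm_epi.csv --modality ATM --out out/inference

# build the 20-subject virtual cohort
ventact --config config.yaml cohort --out out/cohort

# agreement between predicted and target data
ventact evaluate --predicted pred.csv --target target.csv --modality ATM
```

Minimal configuration (YAML; unknown keys are rejected):

```yaml
seed: 1
geometry:
  preset: mid_a          # or axes: [a, b, c] + wall_thickness
  edge_length: 0.42      # cm, in [0.1, 0.5]
  resolution: LOW        # LOW | HIGH | HYBRID
inference:
  population_size: 512
  tolerance: 3.0
  max_iterations: 100
```

Exit codes: 0 success, 2 configuration error, 3 numerical failure.

## Package layout

```
src/ventact/
  geometry.py     synthetic meshes, fibres, candidates, electrodes, I/O
  eikonal.py      conduction speeds, parameter sets, graph-Eikonal solver
  pseudo_ecg.py   transmembrane surrogate, electrode potentials, QRS
  discrepancy.py  ATM RMSE, constrained DTW, QRS-width penalty
  smc_abc.py      prior sampling, mutation, replacement, stopping, loop
  aggregation.py  median speeds, k-means centroids, error metrics
  cohort.py       speed presets, noise contamination, virtual subjects
  cli.py          configuration and subcommands
```
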