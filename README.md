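# gratiomap

Aggregate MR fiber g-ratio mapping of the cervical spinal cord, for
quantitative-MRI researchers studying microstructural damage in
compressive myelopathy (and anyone who wants a fully synthetic,
end-to-end testbed for g-ratio pipelines).

In cervical spondylotic myelopathy the canal narrows and compresses the
cord, injuring axons while — at least above the compressed level —
largely sparing myelin. Conventional T1/T2 imaging cannot separate those
two tissue components. This package implements the quantitative pipeline
that can:

* **Myelin**: magnetization-transfer saturation (MTsat) mapping from
  three spoiled gradient-echo (FLASH) volumes. With signals S and flip
  angles α (radians), TRs in seconds:

  R1app = ½ · (S_T1 α_T1/TR_T1 − S_PD α_PD/TR_PD) / (S_PD/α_PD − S_T1/α_T1)

  Aapp = S_PD S_T1 (TR_PD α_T1/α_PD − TR_T1 α_PD/α_T1) / (S_T1 TR_PD α_T1 − S_PD TR_T1 α_PD)

  δapp = (Aapp α_MT / S_MT − 1) · R1app · TR_MT − α_MT²/2

  δapp is corrected for transmit-field inhomogeneity with a double-angle
  B1 map and calibrated linearly to a myelin volume fraction,
  MVF = c·δapp, by anchoring the mean g-ratio of a reference
  white-matter region at 0.70.

* **Axons**: the three-compartment NODDI model (Watson-dispersed
  intra-neurite sticks, tortuosity-coupled extra-neurite Gaussian
  compartment, free water) fitted voxelwise to a two-shell diffusion
  acquisition (1 b=0 + 20 directions at b=1000 + 20 at b=2000 s/mm²),
  yielding the intra-neurite fraction Vic and free-water fraction Viso.

* **g-ratio**: AVF = (1 − MVF)(1 − Viso)·Vic and
  g = √(AVF / (MVF + AVF)), the aggregate ratio of inner (axon) to
  outer (axon + myelin) fiber diameter per voxel.

* **Tract statistics**: probability-weighted means of AVF/MVF/g over
  left/right fasciculus gracilis, fasciculus cuneatus and lateral
  corticospinal tract at an analysis level above the stenosis, compared
  across affected / unaffected / control cord sides with one-way ANOVA
  and Scheffé's post hoc test, plus Spearman correlations against
  clinical scores.

Because no patient data are distributed, the package ships a
first-class digital spinal-cord phantom (`gratiomap.phantom`) that
forward-simulates every acquisition from known ground truth — FLASH
with MT saturation, the NODDI diffusion signal, double-angle B1 maps,
Rician noise, a co-registered probabilistic tract atlas, and whole
patient/control cohorts with affected-side axon loss and preserved
myelin. All pipeline claims are validated against this phantom.

## Worked example

Run the whole pipeline — simulate a small cohort, calibrate MVF, fit
NODDI, build maps, extract tract metrics, compare groups — from a YAML
config:

```yaml
# demo.yaml
seed: 42
outdir: demo_run
cohort:
  n_patients: 6
  n_controls: 3
  laterality: [left, left, right, bilateral, bilateral, left]
  affected_avf_reduction: 0.15   # 15% axon loss on affected sides
  snr: 30.0
  phantom:
    shape: [24, 24, 4]
    level_slices: [2]
noddi:
  grid_depth: 6
```

```bash
gratiomap run-all --config demo.yaml
```

This takes ~12 s and writes `cohort_table.csv`, `group_comparison.csv`,
`clinical_correlations.csv`, `report.txt` and `provenance.json` under
`demo_run/`. The report begins:

```
fasciculus_cuneatus / avf:
  affected   0.3245 ± 0.0271 (n=8)
  unaffected 0.3858 ± 0.0277 (n=4)
  control    0.3818 ± 0.0210 (n=6)
  ANOVA F = 12.023, p = 0.0008
  Scheffé affected_vs_unaffected    p = 0.0048 *
  Scheffé affected_vs_control       p = 0.0030 *
  Scheffé unaffected_vs_control     p = 0.9710

fasciculus_cuneatus / mvf:
  affected   0.2804 ± 0.0357 (n=8)
  unaffected 0.2901 ± 0.0275 (n=4)
  control    0.2865 ± 0.0270 (n=6)
  ANOVA F = 0.144, p = 0.8672
  ...
```

Read: the axon volume fraction of affected cord sides is significantly
lower than in unaffected sides and controls (0.32 vs 0.38), while the
myelin volume fraction shows no group difference — the
axon-loss-with-preserved-myelin signature the simulation plants, exactly
the pattern the statistics recover. The provenance record also shows the
fitted calibration factor (c = 7.4532 here; the simulated ground truth
couples δ and MVF with a factor of 8, and the residual gap comes from
the Rician noise floor and the approximate B1 correction).

Each stage is also available as its own subcommand (`simulate`,
`mtsat`, `noddi`, `gratio`, `run-all`) operating on NIfTI volumes and
FSL-style bval/bvec files, and as plain library functions.

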