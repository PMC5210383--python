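# tdtract

Tract-density based tendon segmentation and muscle fascicle-length
estimation for skeletal-muscle diffusion-tensor MRI (DT-MRI).

## The problem

Muscle architecture — above all the fascicle length per muscle — governs
how a muscle trades force for excursion, and it changes with training,
disuse, disease and surgery. DT-MRI fiber tractography can reconstruct
fascicles in 3D over a whole limb, but conventional streamline stopping
rules fail at tendinous tissue: because voxels at a muscle–tendon
interface average the diffusion of both tissues, their principal
diffusion direction points **along** the tendon, and tracks happily
continue across the aponeurosis into free tendon or the neighbouring
muscle. Mean fascicle lengths come out too long. Halting instead at
manually segmented muscle boundaries clips fascicles short wherever the
segmentation is off by a voxel or two.

## The method

The package implements a semi-automatic tendon segmentation built from
the tractography itself:

1. **Whole-volume pass.** Deterministic streamline tractography is seeded
   on a 1 mm lattice across the whole volume (FA window 0.1–0.7, ≤20° per
   step, minimum length 2 mm).
2. **Tract density (TD).** Each voxel's TD is the number of distinct
   streamlines crossing it, normalized by the mean TD over the tissue
   foreground, so muscle sits at TD ≈ 1. Tracks from both sides of an
   aponeurosis funnel into it and run along it, so tendinous voxels show
   TD well above muscle. Voxels with **TD > 1.5** are tendinous (or
   artifact) and become a stopping mask.
3. **Per-muscle pass.** Each muscle's mask is eroded to ~90 % of its
   volume and re-seeded; tracking (≤10° per step, minimum length 20 mm,
   step 0.2 voxel) halts wherever normalized TD exceeds 1.5.
4. **Fascicle length.** Tracks ending at the axial field-of-view edges
   are discarded; a skew-normal distribution SN(ξ, ω, α) is fitted to the
   remaining length sample by maximum likelihood, and the muscle's
   fascicle length is the fitted distribution's mean
   ξ + ω·δ·√(2/π), δ = α/√(1+α²).
5. **Repeatability.** Paired-session agreement is summarized with
   Bland–Altman bias and limits of agreement, the coefficient of
   variation CV = 100·SD/mean (SD of paired differences, mean of all
   measurements) and the minimal detectable difference MDD = 1.96·SD.

Because no scanner data ship with the package, a synthetic **unipennate
phantom** generates the full acquisition: two muscle compartments at a
pennation angle to a central aponeurosis, bounded by fasciae, partial
volume at every interface, a mono-exponential Stejskal–Tanner signal
(12 directions, b = 400 s/mm², SNR 40) with Rician noise, and an exactly
known ground-truth fascicle length L = w / sin θ. Every pipeline stage is
tested against it.

## Worked example

Run the whole two-pass pipeline on the default phantom (44 mm true
fascicle length), including the comparison against the two conventional
stopping rules:

```bash
tdtract run --phantom --compare-muscle 2 --out out --seed 0
```

or in Python:

```python
from tdtract.pipeline import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(out_dir="out", phantom={}, compare_muscle=2, seed=0))
for mode, r in bundle["comparison"].items():
    print(f"{mode:9s} {r.mean_length_cm:.2f} cm  (n={r.n_tracts})")
```

prints

```
td        4.59 cm  (n=15065)
fa_only   5.87 cm  (n=14366)
boundary  4.48 cm  (n=17311)
```

against a ground truth of 4.40 cm: the TD-stopped estimate lands within
~4 %, the FA-window-only method overshoots by a third (its tracks run
along the aponeurosis), and the boundary-stopped method is close on
average but carries a heavy short-length tail from segmentation error
(9 % of its tracks are shorter than 0.8·L, versus 0.3 % for TD). The
output directory holds the FA/TD maps (NIfTI), per-muscle length tables
(CSV), area-normalized length histograms per method, and a manifest with
content hashes that make the run bit-reproducible.

## Layout

| module | contents |
| --- | --- |
| `tdtract.phantom` | synthetic unipennate DT-MRI generator with ground truth |
| `tdtract.dwi_data` | NIfTI / FSL bvec-bval I/O, resampling, SNR maps |
| `tdtract.tensor_fit` | WLLS tensor fit, eigensystem, FA/MD maps |
| `tdtract.tracking` | deterministic tracker with pluggable stopping rules |
| `tdtract.tract_density` | per-streamline voxel-crossing counts, TD normalization, tendon mask |
| `tdtract.fascicle_length` | FOV-edge exclusion, skew-normal fit, method comparison |
| `tdtract.repeatability` | Bland–Altman, CV, MDD, tidy summary tables |
| `tdtract.pipeline` / `tdtract.cli` | orchestration, config, manifest, `tdtract` command |
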