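# bonemorph

Micro-CT bone morphometry for longitudinal specimen studies, with a
synthetic long-bone phantom so the whole pipeline is verifiable without
scan data.

## The problem

Museum and laboratory specimens spend years in fixatives (10 % neutral
buffered formalin, 70 % ethanol), and long-term storage can change the very
quantities micro-CT is used to measure: bone compartment volumes and the
linear attenuation coefficient μ (mm⁻¹), a proxy for mineral content.
Detecting a few-percent drift over years of scans requires a pipeline whose
own segmentation choices are held fixed across the series — otherwise
threshold drift masquerades as tissue change.

`bonemorph` implements that pipeline for reconstructed attenuation volumes
of long bones:

1. **Segmentation** — bone is binarized by Otsu's criterion (the threshold
   maximizing the between-class variance of the attenuation histogram), with
   a single *common threshold* computed from the pooled histogram of every
   scan in a series; speckle components below 27 voxels (26-connectivity)
   are removed.
2. **Compartments** — the cortical shell is isolated by a morphological
   opening (ball radius ~1.5× the trabecular rod radius), re-dilated and
   intersected with the mask; the remainder of the bone mask is trabecular.
   The filled periosteal envelope (morphological closing + hole filling)
   defines the total volume TV.
3. **Regions** — the bone axis is partitioned into proximal
   epiphysis+metaphysis (EM) zone, diaphysis, and distal EM zone from the
   envelope's cross-sectional area profile A(z): the diaphysis is the
   contiguous run with A(z) ≤ A_min + β·(A_end − A_min), β = 0.5 by default.
4. **Morphometry** — per region and whole-sample: TV, BV, Ct.BV, Tb.BV
   (mm³, voxel counts × voxel volume), BV/TV = 100·BV/TV (%), and the
   **median** attenuation μ.B, μ.Ct, μ.Tb over each voxel class. Regions
   holding < 2 % of the total trabecular volume report their trabecular
   fields as absent.
5. **Longitudinal analysis** — every parameter becomes a baseline-relative
   change curve, Δ(t) = 100·(x(t) − x(0))/x(0) (%), plus a first/last
   endpoint table.

The **phantom generator** builds a long bone with known ground truth —
flared cortical shell, marrow cavity, trabecular rod lattice in the EM
zones — and evolves it under a parametric fixation model: a formalin-like
preset swells all bone compartments (up to +8.6 %) while attenuation drifts
down (μ.Ct up to −5.3 %) along a saturating-exponential schedule, and an
ethanol-like preset changes nothing. Defaults emulate bone imaged at
17.5 keV with 9 μm isotropic voxels (μ.Ct ≈ 1.288 mm⁻¹, μ.Tb ≈ 0.86 mm⁻¹).

## Worked example

```python
import bonemorph as bm

spec = bm.PhantomSpec(noise_sigma=0.05, seed=1)          # 172x124x124 voxels
vols, truths = bm.simulate_series(spec, bm.formalin_like(), [0, 700, 1565])

records, thr = bm.process_series(vols)                   # common threshold
print(f"common Otsu threshold: {thr:.3f} mm^-1")

curves, table = bm.series_curves(records)
f = table.formatted()
print(f[f.region == "whole sample"].to_string(index=False))
```

prints

```
common Otsu threshold: 0.628 mm^-1
      region parameter first  last diff_pct
whole sample        TV  0.83  0.91     8.63
whole sample        BV  0.40  0.43     8.48
whole sample     Ct.BV  0.35  0.38     8.71
whole sample     Tb.BV  0.05  0.05     6.68
whole sample     BV/TV  47.6  47.5    -0.14
whole sample      mu.B 1.279 1.211    -5.31
whole sample     mu.Ct 1.287 1.219    -5.29
whole sample     mu.Tb 0.860 0.835    -2.91
```

The programmed +8.6 % swelling and −5.3 % cortical demineralization are
recovered within a few tenths of a percentage point by the full
segmentation → compartments → morphometry chain; volumes are in mm³,
attenuation in mm⁻¹, differences in percent relative to day 0. The same
series under `bm.ethanol_like()` stays flat to within ±0.2 points.

A command-line front end covers the same flow on stored TIFF series:

```sh
bonemorph phantom --out-dir series/ --model formalin --days 0,700,1565
bonemorph segment --manifest series/series.yaml --out-dir masks/
bonemorph analyze --manifest series/series.yaml --out-dir results/
```

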