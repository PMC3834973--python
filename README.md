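# mrmar — MR-guided metal artifact reduction for CT

Metallic dental implants scatter bright and dark streaks across
reconstructed CT slices: rays through metal are so strongly attenuated
that their projection data is effectively lost, and filtered
back-projection smears the inconsistency over the whole image. `mrmar`
implements an image-domain repair that exploits a co-registered MR
acquisition of the same anatomy (as produced by PET/CT+MR trimodality
systems): dental metal barely disturbs the MR image, so the MR can say
which *uncorrupted* CT pixels depict tissue similar to each corrupted
one.

The method has two stages:

1. **Detection.** The slice's gray-level histogram is clustered into
   *n* intensity classes (default *n* = 50) with an exact multi-class
   Otsu criterion — thresholds that maximize the between-class variance
   `Σ_k ω_k μ_k²`, solved by dynamic programming over histogram bins.
   The corrupted-pixel mask is the union of the brightest classes
   (metal and bright streaks) with the darkest classes inside the body
   support (dark streak bands).
2. **Correction.** A 5×5 window slides over the CT. For each corrupted
   center pixel, the candidates are the 24 window neighbors ranked by
   `|MR(neighbor) − MR(center)|`; the first candidate whose CT position
   is uncorrupted donates its CT value. Sweeps repeat so that pixels
   corrected in one sweep become donors in the next; uncorrupted pixels
   are never modified. Borders are handled by edge replication.

Because the clinical data behind the method is not public, the package
ships its own validation apparatus: a parallel-beam projection engine
(Radon transform + ramp-filtered back-projection), a head-phantom
simulator that produces dental-implant streak artifacts through beam
hardening, saturation and Poisson noise on the metal trace, a paired
pseudo-MR synthesizer, and the classical sinogram linear-interpolation
baseline (LI-MAR) for comparison.

## Worked example

```python
import mrmar as M

spec = M.default_head_spec(128)
clean = M.make_phantom(spec)
ct_metal, metal = M.insert_implants(clean, M.default_implants(2))
geom = M.Geometry.default_for(clean.shape)

artifact, trace = M.simulate_artifact_ct(ct_metal, metal, geom, M.PhysicsConfig(), seed=0)
mr = M.synthesize_mr(clean, metal, seed=0)

mask = M.detect_artifacts(artifact)
corrected, residual = M.correct_image(artifact, mr, mask)

reference = M.fbp_reconstruct(M.forward_project(clean, geom), clean.shape)
roi = M.ArtifactMask(mask.flags & ~metal.flags)
print(f"corrupted pixels flagged : {mask.n_flagged} ({100*mask.n_flagged/mask.flags.size:.1f}% of image)")
print(f"metal pixels covered     : {100*(mask.flags & metal.flags).sum()/metal.flags.sum():.1f}%")
print(f"artifact-ROI RMSE before : {M.rmse(artifact, reference, roi):.4f}")
print(f"artifact-ROI RMSE after  : {M.rmse(corrected, reference, roi):.4f}")
print(f"residual (no donor found): {residual.n_flagged} pixels")
```

prints

```
corrupted pixels flagged : 528 (3.2% of image)
metal pixels covered     : 94.4%
artifact-ROI RMSE before : 0.3478
artifact-ROI RMSE after  : 0.1910
residual (no donor found): 0 pixels
```

The detector flags the metal disks plus the strongest streak bands
(3.2% of the slice, 94% of the true metal); replacing those pixels
with MR-matched donors roughly halves the RMS error in the flagged
region against the clean reconstruction, with every flagged pixel
finding a donor within the default five sweeps.

The same pipeline is available from the shell:

```
mrmar simulate --implants 2 --seed 0 --out sim/
mrmar detect   --ct sim/artifact_ct.tif --out mask.png
mrmar correct  --ct sim/artifact_ct.tif --mr sim/mr.tif --mask mask.png --out corrected.tif
mrmar baseline --ct sim/artifact_ct.tif --metal-mask sim/metal_mask.png --out li.tif
mrmar evaluate --out study/
```

All commands are byte-reproducible for a fixed `--seed`.

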