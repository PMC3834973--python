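# Methods

This note records the models, parameter choices and numerical decisions
behind `mrmar`, and what the synthetic validation can and cannot show.

## The correction model

The method assumes a CT slice and an MR slice of the same anatomy,
co-registered to the pixel. Metal corrupts CT locally but leaves MR
essentially intact, so MR intensity similarity is used as a proxy for
tissue identity: a corrupted CT pixel is replaced by the CT value of
the nearby position whose MR value best matches the MR value at the
corrupted position.

Concretely, for each flagged pixel the 24 non-center positions of a
5×5 window are ranked by absolute MR difference to the window center
(ties broken by row-major window order, which makes the result
platform-independent); the first candidate whose CT position is not
flagged donates its CT value. Within one sweep all donors are read
from the pre-sweep image, so the output does not depend on scan order.
Neighborhoods in which every candidate is flagged are resolved by
repeating the sweep (corrected pixels become donors) up to
`max_passes` times; the handful of pixels that can remain in
pathological masks are filled with the mean of their non-flagged
window neighbors (`fallback="neighborhood_mean"`) or left unchanged.
Each sweep reaches two pixels deeper into a flagged blob, so the
default `max_passes = 5` resolves blobs up to ~10 px deep — larger
than any mask component the default simulator produces.

Key parameters: `window = 5` px (the scale at which MR similarity is a
reliable tissue proxy), `max_passes = 5`, `reinsert_metal = False`
(the mask includes the metal itself; whether to restore bright metal
for display is left to the caller).

## Detection

Detection operates on the slice normalized to [0, 1] over its observed
range (making the mask invariant to affine intensity rescaling), with
a 256-bin histogram clustered into `n_classes = 50` classes by
maximizing the between-class variance Σ ω·μ². The optimum is found
*exactly* by dynamic programming over bin indices with precomputed
cumulative moments (O(classes · bins²)); exhaustive enumeration and
the classic two-class criterion serve as test oracles. Half-open bins
`[e_i, e_{i+1})` (last bin closed) and the label rule "number of
thresholds strictly below the value" fix the tie conventions.

The artifact mask is the union of the `bright_k = 6` top classes
(metal, saturated bloom, bright streaks) and the `dark_k = 3` bottom
classes restricted to the body support (largest connected component
above `body_threshold = 0.1`, holes filled) — dark streaks in air are
already "correct" and not worth restoring. On the default simulator
this flags ≈3–5% of the slice, covers ≈95% of the painted metal
pixels (the residue is the blur-diluted disk rim whose intensities
coincide with dense bone — irreducible for a pure intensity rule), and
flags <5% of the body on an artifact-free reconstruction.

`segment_metal_region` additionally provides the metal-only
segmentation used by the sinogram baseline: an intensity threshold
above any anatomy (1.05 on the normalized tissue scale, the analogue
of the clinical "HU above dense bone" rule) or the bright Otsu
classes, followed by a connectivity test (morphological opening +
minimum component area 9 px) that discards isolated streak pixels.

## Projection engine

2-D parallel-beam geometry: views at uniform angles over [0, 180°),
detector bins at the pixel pitch covering the image diagonal with a
bin centered on the rotation axis. Forward projection samples each ray
at **half** the pixel pitch with bilinear interpolation and sums
(rectangle rule); at full pitch the quadrature over-integrates
point-like features by up to ~24% at 45°, while at half pitch the
engine matches a dense ray-sampling oracle to a few percent on
single-pixel images and a closed-form chord-length oracle to <2%
per bin on extended objects (excluding the two bins at the disk rim,
where the chord's infinite slope defeats any finite bin).

Reconstruction is standard FBP: each view is ramp filtered (Ram-Lak;
optional Hann apodization) in the Fourier domain on a zero-padded grid
(next power of two ≥ 2× bins), back-projected with linear
interpolation across bins, and scaled by π/n_angles. Round-trip
relative RMSE on a smooth 128² phantom at 180 views is ≈2.4% inside
the reconstruction circle (the 5% contract), and decreases
monotonically with view count.

## The synthetic study conditions

**Phantom.** A 128² ellipse-stack head: soft-tissue oval (0.3), bone
rim (0.7), brain (0.32), mandible arc with oral soft tissue and an
airway, on a normalized intensity scale with air at 0. A fixed smooth
modulation (±0.05 on soft tissue, ±0.2 on bone) emulates anatomical
heterogeneity (gray/white matter, diploë): real histograms are spread,
and a 50-class clustering of a piecewise-constant phantom would behave
qualitatively differently from clinical data. 512² is supported; 128²
keeps the full study inside a desktop minute.

**Implants.** 1–8 metal disks (intensity 3.0, default radius 5 px at
the 128 scale) packed along the jaw arc within ±10 px of the midline,
like fillings on adjacent teeth; adjacent implants merge into wide
metal traces, the regime in which interpolation methods lose the most
raw data.

**Corruption model.** The projection of the slice is corrupted only
physically plausibly: on the metal-trace bins (trace threshold
0.25 px of metal path), beam hardening bends the line integrals
sub-linear (`v ← cap·(v/cap)^γ`, γ = 1.6) and clips them at the
saturation cap (0.95× the largest through-metal integral); Poisson
counting noise at I0 = 10⁵ photons acts on the whole sinogram through
`I = I0·exp(−0.1·v)` (the 0.1 converts normalized intensity × px into
optical depth so body rays carry realistic count statistics).
The reconstruction is finally clipped to [−0.25, 1.25], emulating the
bounded stored dynamic range of clinical CT — this is what makes
metal and bloom *saturate* into the top intensity classes, as they do
in 12-bit HU images, and it is load-bearing for detection behavior.
γ was calibrated so the simulator reproduces the clinically reported
phenomenology (streaks strong enough to corrupt, donors near the mask
boundary still usable); the identity setting (γ = 1, cap = ∞, noise
off, clip off) reduces the simulator to the plain FBP round trip,
bit-exactly.

**Pseudo-MR.** A tissue-class remap of the *clean* anatomy (bone and
any denser value → 0.15, soft tissue → 0.85, brain → 0.75, air →
0.02) by nearest-class lookup, Gaussian-smoothed (σ = 1 px) with
additive Gaussian noise (σ = 0.02); `tissue_map=None` gives the
identity remap (MR ≡ clean CT), the idealized injective contrast used
in the recovery experiment. Optional: a signal-void halo of
configurable radius around metal (susceptibility dropout; default
off), and a rigid integer shift to study misregistration (default 0).

## The evaluation study

For each (implant count, seed): simulate the acquisition; score the
uncorrected reconstruction, the LI baseline and the MR-guided
correction against the FBP of the *clean* phantom's sinogram (so
discretization error is not charged to the MAR methods). Both MAR
methods consume only the reconstructed artifact image — neither sees
the raw corrupted sinogram, mirroring the clinical premise. LI
segments metal at the 1.05 level, reprojects it into a trace,
refills each view's flagged runs with the straight line between the
nearest unflagged bins (constant at detector edges), and
reconstructs. The artifact ROI is the detected mask minus the metal
pixels (neither method is asked to invent metal values); global,
outside-body and mean-absolute errors are also reported. With no
implants there is no metal and both methods are defined as no-ops.

At the defaults (5 seeds), LI's artifact-ROI RMSE degrades
monotonically with implant count (≈0.065 → 0.127 → 0.166) as the
merged traces widen — the quantitative form of the known
implant-count sensitivity of interpolation MAR. The MR-guided method
is insensitive to count in comparison (≈0.14 → 0.20 → 0.21) but does
not drop below trace-faithful LI on this simulator: on a consistent
2-D parallel-beam sinogram, interpolation over a correctly segmented
trace is close to information-lossless, an advantage clinical
cone-beam data does not enjoy. The corresponding acceptance check
encodes the stricter expectation (image-domain wins at 3 implants)
and is allowed to fail; the study reports what the simulation
actually shows, and `EvaluationReport.violations()` lists any
condition where a method is worse than no correction (LI at 1 implant
typically is, on this ROI: it trades mild bloom for interpolation
bias).

The recovery experiment isolates the correction from detection and MR
quality: perfect mask (true corruption `|artifact − reference| > 0.1`
∪ metal) and identity MR. The correction reduces artifact-ROI RMSE to
≈0.31× the uncorrected value. The 0.1 threshold defines "corrupted"
as one third of the soft-tissue level. The ratio is bounded near 0.27
for *any* corruption strength on this simulator: streak error fields
are spatially smooth, so the donor ring just outside any corruption
level set carries error comparable to the threshold itself, while the
in-mask RMSE rarely exceeds ~3.5× the threshold. Clinical streaks are
thin lines with genuinely clean tissue between them, where window
donors are cleaner — passing synthetic tests here therefore bounds
the algorithmic machinery, not the clinical effect size.

## What the synthetic data does not show

The simulator is monochromatic-with-corrections, 2-D, parallel-beam,
and noise beyond Poisson counting (scatter, motion, partial volume,
detector physics) is absent. The pseudo-MR is derived from the same
anatomy as the CT, so registration is perfect by construction unless
explicitly shifted. Consequently the tests demonstrate correctness of
the operators and the *direction* of the method comparisons, not
clinical performance.

## Numerical conventions

Row-major 0-based (row, col) with row 0 at the top; intensities held
as float64; detection normalizes per-slice before histogramming; all
randomness flows through explicit integer seeds (numpy Generator) and
every simulator output is bit-reproducible; file formats: float32
TIFF and NIfTI-1 (lossless), 16-bit PNG with an affine sidecar
(lossless to one quantization step), 8-bit PNG masks; sinograms as
float32 TIFF with a JSON geometry sidecar. Problem sizes in the test
and acceptance runs (128² slices, 180 views, 5 seeds, counts 1–3)
were chosen to make the full validation reproducible in about a
minute on a single core.
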