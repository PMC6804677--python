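# Methods

`holocyte` re-implements the computational core of a magnetically
modulated lensless speckle-imaging cytometer.  A fluid sample containing
magnetic-bead-labelled target cells sits in a capillary tube ~1 mm above a
bare CMOS sensor under coherent illumination (650 nm, unit magnification,
1.67 µm pixel pitch).  Two electromagnets drive the sample with an
alternating square-wave force (1 s period), so labelled cells oscillate —
mostly a rolling rotation with a small vertical swing — at exactly the
drive frequency, while unbound debris stays static or moves randomly.  A
120-frame in-line hologram video (26.7 fps) per field of view records the
interference of every object's scattered wave with the reference beam.
The pipeline turns those videos into a count of target cells per mL of
whole blood.

## Screening model

**Drift correction.** The sample fluid creeps along the tube axis.  Each
frame is registered to the middle frame by phase correlation with
correlation-peak upsampling (0.05 px resolution), and only the horizontal
component is removed by bilinear resampling: the vertical axis carries the
magnetically driven motion and must be left untouched.

**Filtered back-propagation.** Each drift-corrected frame `A_i` (the raw
intensity is used directly as a real-valued field; taking its square root
is a config option) is numerically refocused to each depth `z_j` of a
search grid with the angular spectrum method, then spatially high-pass
filtered:

    B_i(z_j) = HP[ P(A_i, -z_j) ]

The default grid spans 800–5000 µm in 100 µm steps (43 planes), covering
the tube's interior.  `P` is the exact scalar transfer function with
evanescent components zeroed; frames are mean-subtracted and zero-padded
2× before the FFT to suppress wrap-around.  `HP` is a radially symmetric
Gaussian high-pass, `1 − exp(−f²/2σ_f²)` with σ_f = 0.01 cycles/µm: it
removes the DC term and slowly varying background while passing object
diffraction detail.  The exact filter shape is a package choice — any
monotone high-pass with an exact zero at DC serves the same role — and is
configurable.

**Motion contrast (CMA).** For each depth, the reconstruction sequence is
reduced to a periodic-motion contrast map

    C = mean_i ( ½|B_i − B_{i+N/2}| + ½|B_{i+N/2} − B_{i+N}| − |B_i − B_{i+N}| )

with `N` the number of frames per drive period.  26.7 fps × 1 s = 26.7 is
not an even integer, so `N` is the nearest even integer, 26 (a ≤1.3 %
period mismatch).  Objects oscillating at the drive frequency produce
large half-period differences and a small whole-period difference, hence
`C > 0`; static content cancels exactly; monotonically moving content
(drift residue, Brownian walkers on average) gives `C ≤ 0` by the triangle
inequality.  Negative values are retained — they carry information — but
the subsequent maximum projection and thresholding ignore them naturally.

**Detection.** The volume is flattened by a maximum intensity projection
`D(x,y) = max_z C`, binarized at an adaptive threshold (mean + 6·std of
`D`; an absolute threshold is also supported), closed with a small disk
(radius 3 px), and segmented into 8-connected components of ≥ 4 px.  The
closing step exists because the motion-contrast response of one object is
dipole-like — the difference of a displaced pattern has two lobes — and
without it a single cell can split into two components whose centroids sit
~3 px off the object.  Component centroids are intensity-weighted;
components near the frame border (within 32 px, half the crop size) are
flagged.

## Autofocusing

All focus criteria score the contrast volume inside an asymmetric
40 × 40 px window around the candidate (offsets −19…+20; 66.8 µm per side).
Three criteria are provided, because the classic windowed *sum* turns out
not to localize sharply on linear scalar-diffraction data:

* `max` — argmax of the windowed sum.  For a band-limited difference field
  of fixed energy, the L1 norm inside a window *grows* as defocus spreads
  the field (amplitude ∝ 1/spread but area ∝ spread², so Σ|·| ∝ spread),
  so the sum is V-shaped with a minimum at focus and broad maxima at
  ±150–300 µm defocus shoulders; its argmax localizes only to a shoulder.
  It is kept as the reference criterion and for constructed volumes.
* `peak` — argmax of the window's pointwise maximum.  Contrast
  concentrates approaching focus, so the peak rises monotonically toward
  the in-focus plane; on synthetic scenes it lands within one 100 µm grid
  step.  This is the screening pipeline's coarse criterion.
* `sparsity` — argmin of the windowed sum, i.e. the V-dip itself.  On a
  *local* depth span it is the sharpest criterion available (the L1 growth
  is linear in |Δz|); used by the refinement stage, it recovers the true
  plane to ~10 µm on synthetic scenes.  It must not be applied globally:
  far from focus the sum decays again as energy leaves the window.

Refinement recomputes the reconstruction and CMA score on a 10 µm grid
within ±150 µm of the coarse estimate, restricted to a 256 px patch around
the candidate (full-field recomputation at 10 µm steps would be
needlessly expensive; the patch bounds the captured numerical aperture at
~0.2 for objects ~1 mm up, which is also the sensor's Nyquist limit).
Ties break toward the smallest depth, deterministically.

Axial accuracy is physics-limited: localizing to ±20 µm needs fringe
content out to NA ≈ 0.18 (depth of focus λ/NA²), i.e. recorded fringes out
to radius ≈ 0.18·z around the object.  The synthetic benchmark therefore
keeps target cells at z = 0.9–1.2 mm with a 64 px margin on a 320² px
field of view; deeper objects or objects at the frame edge cannot be
focused that precisely from a small sensor — with a full-size sensor the
constraint relaxes proportionally.

**Candidate video.** Every drift-corrected frame is back-propagated to the
refined depth and cropped to 64 × 64 px around the centroid (mean-padded
at frame borders).  The crop's magnitude becomes the amplitude channel,
normalized per candidate to unit 99th percentile so the classifier is
independent of illumination brightness; the argument becomes the phase
channel, wrapped to (−π, π] and not unwrapped.  The result is a
2 × 120 × 64 × 64 video per candidate.

## Classifier

The classifier is a densely connected pseudo-3D (P3D) CNN implemented in
numpy (explicit forward/backward passes; Adam).  A P3D factorization
replaces each 3D convolution with a 1×3×3 spatial and a 3×1×1 temporal
convolution; each is a batch-norm → ReLU → convolution stage with k = 8
output channels (the growth rate).  A dense block concatenates input and
stage outputs channel-wise and max-pools 2×2×2 stride 2:

    m_{p+1} = Max[ Conv_t(Conv_s(m_p) ⊕ m_p) ⊕ (Conv_s(m_p) ⊕ m_p) ]

so channels grow c → c + 2k while every extent halves.  The full network:
1×7×7 stride-2 spatial stem and 9×1×1 stride-3 temporal stem (16 channels
each; the figure-level channel counts are not recoverable, so both stems
default to 16 and are configurable), five dense blocks, and a 3×1×1
unpadded, channel-preserving convolution between blocks 2 and 3 that trims
the time axis so time and space extents match — the only pooling scheme
consistent with that constraint is 2×2×2 stride 2 (120/3 = 40 → 20 → 10 →
−2 = 8 = 64/2³).  Shape trace, validated at build time:

    2×120×64×64 → 16×120×32×32 → 16×40×32×32 → 32×20×16×16 → 48×10×8×8
    → 48×8×8×8 → 64×4×4×4 → 80×2×2×2 → 96×1×1×1 → dropout(0.5) → FC → softmax

Training: Adam at 1e-4, batch 240, 800–1000 epochs at full scale;
truncated-normal init (mean 0, std 0.05, clipped at ±2 std — the reference
protocol names the distribution but not its parameters) for convolutions
and zero init for the fully connected layer; augmentation by random
mirroring and 90°/180°/270° rotations applied per video, preserving
temporal coherence.  A desk-scale profile (2×24×16×16 inputs, 8-channel
stems, three dense blocks, no mid convolution, lr 2e-3, batch 50, 30
epochs) trains the two-class synthetic benchmark to ≥0.95 validation
sensitivity/specificity in under a minute on one CPU; the reduced problem
sizes are the package's own test-scale choice.

**Decision threshold.** A rare-cell counter must make essentially no false
calls, so after training the probability cutoff is raised from 0.5 along
the decade grid 0.9, 0.99, … until the pooled training+validation scores
contain zero false positives, then raised one more decade as a safety
margin against score-distribution overfitting (e.g. 0.99999 → 0.999999).
A negative example scoring exactly 1.0 makes the procedure fail loudly.
Raising the threshold trades sensitivity for specificity; the monotone
TPR/threshold relationship is property-tested.

## Concentration estimate

positives / V_equiv, with V_equiv = V_screened · V_blood / V_final.  The
screened volume is (FOV area) × (tube inner depth, default 2 mm) × number
of FOVs; e.g. screening 0.942 mL of a 4 mL → 3.2 mL (0.7 mL buffer +
2.5 mL viscous medium) preparation interrogates 1.1775 mL of whole blood.
FOV failures are isolated: a failing FOV is logged and skipped, partial
results carry a completeness flag.

## Synthetic data

No raw instrument data is bundled, so a simulator renders the study
conditions end to end.  Scenes hold four object classes: bead-labelled
cells (absorbing disk, default radius 8 µm, containing 8 strongly
scattering bead spots recentred on the cell — heavily labelled cells are
the instrument's targets); unbound bead chains (3–6 beads in a line,
swinging ±0.7 rad); Brownian walkers (seeded random walk, per-axis MSD
2·D·t); and static debris plus a static speckle background.  Driven motion
follows the square-wave drive with first-order exponential relaxation
(cells τ = 0.15 s; chains 3× faster, having less drag): appearance
(rolling bead pattern) as well as position (±0.8 px vertical swing)
oscillates at the drive frequency.  The magnetic force field itself is
deliberately *not* modelled — motion is phenomenological.

Rendering is single-pass weak scattering: each object's transmittance
perturbation is forward-propagated from its depth to the sensor and
superposed on a unit reference wave; intensity is scaled to a 110 DN
background, Gaussian read noise added (σ = 2 DN), and quantized to 8 bits.
An optional dense "debris" layer of diffusing particles, rendered as
full-field slabs, emulates dynamic blood-debris speckle.  Everything
derives from the scene seed; rendering is bit-reproducible.

What the simulator does *not* emulate: multiple scattering and
object-object occlusion, non-translational flow, sensor fixed-pattern
noise and rolling shutter, bead-binding chemistry, and the morphological
diversity of real cells.  Passing tests therefore demonstrate the
*computational* pipeline — reconstruction, motion statistics, focusing,
learning — under controlled conditions, not clinical performance.  The
amplitude/phase contrasts of bead-cell conjugates are order-of-magnitude
choices exposed in the scene config.

## Benchmarks the tests run

* Screening benchmark: 10 oscillating cells among 20 walkers, 6 static
  particles, static speckle and light debris on a 320² px FOV with
  horizontal drift (0.15 px/frame), fixed seed.  Expected: ≥90 % of cells
  detected within 2 px, refined depth within 20 µm, no detections at
  static-only sites.
* Classifier benchmark: 200 cell and 200 chain candidate videos generated
  through the full screening+focusing pipeline at desk scale (96² px
  scenes, 24 frames at 8 fps, 16 px crops), 3:1 train/validation split.
  Expected: validation sensitivity and specificity ≥ 0.9 at threshold 0.5,
  and a zero-false-positive tuned threshold on the pooled scores.

Problem sizes (field of view, frame count, epochs, object counts) are the
package's desk-scale test profile; the full-scale profile mirrors the
instrument's acquisition geometry.

## Numerical choices and degenerate inputs

float32/complex64 throughout the pipeline (the optics operators preserve
float64 inputs for oracle-grade tests); FFT-based propagation is unitary
on the unpadded grid (round trip ~1e-16).  Degenerate cases are explicit:
constant frames yield zero drift with a warning; score-flat focus
neighbourhoods return the coarse depth with a warning; ties in every
argmax resolve to the smallest depth; empty detections are a valid result;
a negative example scoring 1.0 aborts threshold tuning.  Dropout and batch
shuffling draw from a generator seeded by the training config, so training
is bit-deterministic per seed.

## Known limitations

* Axial refinement assumes the candidate's fringe system is captured; for
  objects deeper than ~1.5 mm on small sensors the 20 µm target is not
  physically reachable (depth of focus scales as λ/NA²).
* The windowed-sum focus criterion (`max`) is kept for reference but is
  shoulder-biased on clean linear data; the pipeline defaults (`peak` +
  `sparsity`) were chosen for that reason and are documented above.
* The classifier is trained per cell/bead-conjugate type; weights do not
  transfer across magnetic labels.
* At one CPU, screening one 320² px FOV over 43 depths takes a few
  minutes; throughput scales linearly with cores/FOV area (the per-plane
  FFT work is embarrassingly parallel).
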