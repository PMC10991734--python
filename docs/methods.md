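# Methods

This note documents the models, estimators, calibrations and design choices
behind `osseodic`, in the order the data flows through the pipeline.

## Coordinate conventions and units

All lab coordinates are millimetres in a right-handed anatomical frame with
columns ML (medio-lateral), AP (antero-posterior), CC (cranio-caudal);
ML × AP = CC and CC points proximally. Reported quantities are fixed
throughout the API: translations in μm, rotations in degrees, strains in
microstrain (με), loads in N. The osteotomy plane sits at CC = 0; the
residual femur occupies CC > 0 and the prosthesis (with its marker set)
protrudes distally to CC < 0.

## Loading protocol and event extraction

The load channel is analytic: a fully unloaded segment (0 N, the strain and
displacement reference), a 150 N preload plateau, then `n_cycles` sinusoidal
cycles between `load_min` = 150 N and `load_max` = 850 N at 1 Hz, sampled at
100 frames/s. Acquisition is restricted to cycles 1–10, 45–55 and 90–100.
Peak and valley frames are located by windowed argmax/argmin around the
analytic extremum times, with ties broken to the earliest frame; an event
whose load deviates from the protocol extreme by more than 25 % of the load
range is rejected, so constant or truncated channels raise an error rather
than fabricating cycles. At 100 frames/s and 1 Hz the analytic extrema fall
exactly on the sampling grid, so the simulator's "events" frame policy
(generate only the reference, preload and extremum frames) is a strict
subsample of dense sampling; all stability and strain analyses consume only
those frames, which is why the canonical experiments use the events policy.

## Rigid kinematics

Both bodies are registered per frame against the reference frame with the
closed-form least-squares rigid transform (Kabsch/SVD), dropping non-finite
points and requiring ≥ 3 non-collinear correspondences. The implant-vs-bone
pose is the composition `T_bone⁻¹ ∘ T_implant`; rigidly co-moving bodies give
the identity exactly. The body-frame origin is placed at the reference marker
centroid (the distal end of the prosthesis), so the translation components
read as the displacement of that physical point relative to the bone — this
choice minimises the leverage of the implant's own rotational noise on the
reported translations.

Rotations are intrinsic Cardan angles in the sequence ML → AP → CC. The
sequence choice matters only at second order in the angles (~θ²): ≈ 8·10⁻⁴
deg at 0.3°, the largest rotation magnitude relevant here, versus rotational
measurement uncertainties of ~0.01°. It is therefore immaterial in practice,
but it is fixed and documented so that results are exactly reproducible.

**Inducible micromotion** of cycle *N* is the component-wise difference
between the position at the peak of cycle *N*+1 and at the valley terminating
cycle *N*, summarised by the per-component median over acquired cycles (the
median tolerates < 30 % outlier cycles with < 5 % summary shift, verified by
test). **Permanent migration** is the difference between the component-wise
median position over the last acquisition window's peaks and over the first
window's. Using windowed medians rather than the single first/last peak
trades a small bias (drift accrued inside the windows is partially averaged)
for robustness: with 10–11 peaks per window the migration repeatability stays
below 2 μm at the declared noise calibration, whereas single frames would
carry the full ≈ 3 μm per-frame noise, twice. The helper
`GroundTruthKinematics.expected_migration` returns the analytic value this
estimator reads back for any drift profile, and the ramp profile
(`ramp_profile`, flat during the first and last windows) makes the round trip
exact for validation.

An axis is classified **unstable** when the magnitude of its median inducible
translation reaches the 150 μm fibrous-tissue threshold, boundary inclusive
(a value exactly at threshold is flagged, the conservative call for a
screening method).

## Surface strain

The speckle grid is differentiated by a local least-squares plane fit: in a
square window of nodes (default 7×7) each in-plane displacement component is
regressed on the in-plane coordinates; the infinitesimal strain tensor is the
symmetric part of the fitted gradient. On a regular grid this reduces to
separable convolutions, is **exact for any affine displacement field
regardless of window size**, is linear (strains superpose) and objective
(principal strains invariant under in-plane rotation of the material frame) —
all verified as properties in the test suite. Green–Lagrange strain
`E = (H + Hᵀ + HᵀH)/2` differs from the infinitesimal tensor by < 1 % below
10⁴ με, so the linear form is used; the quadratic term is the correction to
apply should larger deformations ever be of interest.

Principal strains are the closed-form eigenvalues of the 2×2 tensor, sorted
ε1 ≥ ε2. Nodes whose fit window touches the border of the correlated region
(or any invalid node) are flagged as edge nodes and excluded from ROI
statistics, mirroring the larger edge errors of real DIC fields. ROI
membership is by node CC position in half-open intervals: ROI 1 =
[stem tip − 10 mm, stem tip + 10 mm), ROI 2 = [osteotomy, osteotomy + 20 mm).
ROI summaries are medians over valid interior nodes. Strain magnitudes are
classified against configurable cut-offs: 2000 με (physiological peak for
cortical bone) and 7000 με (onset of the failure range). The lower bound
separating "below-physiological" from "physiological" is a convention the
literature does not pin down; 1000 με (the lower edge of the habitual strain
window) is the default, and only the 2000/7000 cut-offs carry biological
claims.

## The virtual specimen

The simulator replaces cadaver, rig and stereo-DIC hardware with a
parameterised ground truth:

* **Geometry.** 25 fiducial markers on a cylinder (radius 25 mm, length
  60 mm) around the prosthesis extension, centred 40 mm distal to the
  osteotomy; a planar speckle patch (the DIC-visible bone face) spanning
  0–80 mm CC × 40 mm ML at 1.19 mm node spacing (= 17 px grid spacing ×
  0.07 mm pixels); stem tip at CC = 50 mm. Marker count and layout are
  declared defaults — the physical experiment does not fix them. The specimen
  is notionally tilted 10° in flexion and adduction; the rig lever arm is
  solved from the constraint that 850 N produces a 30 Nm bending moment at
  the stem tip (144.8 mm), since it is a free rig parameter.
* **Kinematics.** The implant moves rigidly relative to the bone: an
  inducible component proportional to the instantaneous load above the valley
  load (clamped at zero below it), plus a migration component following a
  monotone drift profile of the cycle count (saturating exponential,
  τ = 20 cycles, by default — press-fit implants migrate mostly early).
  Injected 6-DOF amplitudes are recovered by the analysis chain to < 1e-9 in
  the noise-free case (a test invariant).
* **Strain.** The peak-load field has longitudinal strain
  ε_cc(z) = A·exp(−((z−z₀)/w)²) with transverse ratio ν: defaults A = 1632 με,
  z₀ = 50 mm (stem tip), w = 38.4 mm, ν = 0.455, chosen so the noise-free ROI
  medians emulate the magnitudes typical of an instrumented implanted femur
  (ROI 1 ≈ +1604/−730 με, decaying distally) while keeping a closed-form
  displacement field (error-function integral) whose exact symmetric gradient
  is the injected tensor. The field scales linearly with load from zero at
  the unloaded reference. The deformation is injected with its best-fit rigid
  component over the patch removed: the tracked bone frame then stays put
  under load, and the injected kinematics are defined relative to the tracked
  bone patch — the same frame the relative-pose analysis measures. (Without
  this convention the patch's own mean stretch displacement masquerades as
  bone rigid motion and absorbs part of the injected implant motion; strain
  estimation is indifferent, since rigid fields carry no strain.)
* **Noise.** Zero-mean isotropic Gaussian, independent per point, frame and
  axis: 15 μm SD for markers, 0.7 μm SD for speckle nodes. The asymmetry is
  deliberate: a DIC engine localises a high-contrast speckle facet to
  ~0.01 px (0.7 μm at 0.07 mm/px), while small circular markers carry a
  larger centroiding error. With 25 markers this calibration propagates to a
  relative-translation random error of √2·15/√25 ≈ 4.2 μm and rotational
  errors of ~0.01°, at the level a well-optimised stereo-DIC setup achieves
  on this class of test. Identical seeds give bit-identical sequences; all
  child seeds derive from one `SeedSequence`.
* **Population.** Between-specimen variation draws per-specimen inducible
  amplitudes, migrations and a strain-field scale from declared distributions
  (e.g. ROI-1 ε1 median ~ N(1604, 700) με, inducible translation SDs of
  13–27 μm) that emulate the inter-specimen spread of cadaveric femurs while
  keeping every specimen far below the instability threshold.

What the simulator does **not** emulate: spatially correlated DIC noise
(facet windows overlap in a real engine, correlating neighbouring nodes),
heteroscedastic errors near the edges of the correlated region beyond a
binary flag, out-of-plane reconstruction error, specimen conditioning drift,
and any camera/optics physics (the 2D DIC engine exists to demonstrate the
facet-size trade-off, not to feed the 3D pipeline). Passing tests therefore
certify the estimator chain and its noise propagation, not the behaviour of
a particular commercial correlator on real images.

## Error-quantification protocol

"Systematic" error is the signed mean and "random" error the sample SD
(n−1 throughout) of estimates whose truth is zero, across repeated simulated
unloaded pairs — the zero-displacement analysis for the 6-DOF components, the
zero-strain analysis for the strain components (pooled over interior nodes
and pairs). Repeatability is the per-component SD across four mount/remount
repetitions of one specimen; because an SD from n = 4 has only 3 degrees of
freedom, the canonical experiments average it over 25 independent seed
replicates. Inter-specimen variability is the median and SD across
specimens.

One estimator property deserves emphasis: **the maximum principal strain is
positively biased under pure noise.** The zero-strain analysis at the default
calibration gives each pair-difference gradient an SD of
√2·0.7 μm/(1.19 mm·√196) ≈ 59 με per tensor component; sorting the
eigenvalues then makes ε1 = m + √(d² + ε_xz²) with m, d, ε_xz zero-mean, so
E[ε1] is a Rayleigh-type mean ≈ 53 με even though every signed component is
unbiased (and the report's e_xx/e_zz/e_xz entries confirm ≈ 0 systematic).
This is intrinsic to reporting extremal eigenvalues of a noisy tensor, not a
pipeline defect; real DIC fields show smaller apparent ε1 biases because
their noise is spatially correlated and partially averaged. Consumers who
need unbiased zero-level checks should read the signed tensor components;
consumers of loaded-field ROI medians are unaffected, because there the
signal (≈ 1600 με) dominates the ordering.

Uncertainties are compared to the biological thresholds as ratios
(default pass at ≤ 0.1, i.e. one order of magnitude of margin): ~4.5 μm
random micromotion error vs 150 μm gives 0.03; ~50 με strain error vs
2000 με gives 0.025 — the method can discriminate stable from unstable
implants and physiological from critical strain levels.

## DIC engine

Speckle patterns are white-on-black ellipses with log-normal diameters
(defaults: mean 0.35 mm, SD 0.10 mm at 0.07 mm/px, density 4 dots/mm²,
slight Gaussian blur for subpixel texture); coverage above 80 % warns as
degenerate. Correlation is subset-based NCC (`match_template`) with subpixel
localisation by a separable quadratic fit to the 3×3 peak neighbourhood —
documented as a replaceable stand-in for proprietary engines. When the peak
correlation is numerically 1 the subpixel step is skipped, which makes
integer shifts of exactly resampled images recover exactly. Featureless or
low-score facets are flagged invalid rather than propagating NaNs. The
uncertainty sweep (zero-displacement pairs of noisy re-acquisitions per
facet/grid combination) reproduces the motivating trade-off: random error
falls from ≈ 0.05 px at 15 px facets to ≈ 0.008 px at 40 px facets at equal
noise, which is why 40 px facets with 17 px spacing (≈ 2 mm spatial
resolution at 0.07 mm/px) are the default.

## Numerical choices and problem sizes

Registration uses SVD with the determinant-corrected proper rotation;
collinearity is detected on the second singular value (≤ 1e-9 relative).
Pose matrices are validated to orthogonality and det = +1 within 1e-9.
Strain windows must be odd and ≥ 3; ties in event detection break to the
earliest frame; ROI intervals are half-open; medians are `numpy.median`
(mean of central pair for even counts). The canonical experiments run at
desk scale — 100 zero-displacement pairs, 50 zero-strain pairs, 4 × 25
repeatability trials on a 400-node pose grid and the full 1.19 mm strain
grid — sizes at which every experiment completes in seconds while the
Monte-Carlo SDs of the reported figures are a few percent.

## Known limitations

* The error figures certify the synthetic calibration, not any particular
  hardware; transferring them to a lab requires re-measuring the two noise
  SDs (marker and speckle) from that system's own zero pairs.
* Micromotion is purely kinematic: no contact or friction model, no
  interface mechanics, no bone ingrowth.
* The strain model is a surface field on a developed plane; curvature,
  through-thickness gradients and volumetric strain are out of scope, as in
  surface DIC itself.
* The 2D DIC engine is single-camera and is not connected to the 3D track
  pipeline; stereo matching and calibration-target processing are explicitly
  excluded.
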