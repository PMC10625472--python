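# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `tfmlab`, in the order data flows through the pipeline.

## Coordinate and unit conventions

One frame everywhere: image row = +y, column = +x, origin at the center of
pixel [0, 0]; physical coordinates and displacements in µm, moduli and
tractions in Pa, integrated forces in Pa·µm² (= pN; nN = 10³ pN). A +1
pixel shift of an image along columns appears as +`pixel_size_um` in x in
every downstream field, and every ASCII writer states this frame. After
drift correction all channels are cropped to one common box; fields
computed on cropped frames keep their origin at the cropped pixel [0, 0],
and the crop offsets are recorded in the drift table so results can be
mapped back to the acquisition frame. Intensities are held as float64
regardless of the source bit depth, since focus metrics and correlation
need full precision.

## Elastic model

The substrate is a linear-elastic half-space, incompressible (ν = 0.5, the
appropriate idealization for hydrogels, which are mostly water). The
surface Green tensor is then

G(r) = 3/(4πE r³)·[[r²+x², xy], [xy, r²+y²]],

whose 2D Fourier transform decomposes per wavevector into a longitudinal
eigenvalue 3/(2Ek) (along k̂) and a transverse eigenvalue 3/(Ek). ν < 0.5
is deliberately rejected rather than approximated: the reduced tensor is
only valid at ν = 0.5, and supporting general ν would require a different
kernel throughout. Finite gel thickness is likewise out of scope; for gels
much thicker than the displacement correlation length the half-space model
is standard.

Discretization: the analytic Fourier kernel is sampled on the discrete
wavevector lattice of the (padded) grid. On Nyquist rows/columns the sign
of k is ambiguous, so the anisotropic (shear-coupling) part of the tensor
is replaced by its isotropic average there; this keeps the kernel
Hermitian-symmetric and inverse transforms real to machine precision. The
k = 0 mode is excluded (traction constrained to zero mean), which encodes
global force balance and makes the per-mode operator invertible — the
synthetic generator therefore only produces exactly force-balanced
tractions.

The forward model zero-pads the grid ×2 per axis before transforming
(`pad_factor`, default 2) to suppress periodic-wrap bias of the open-plane
convolution; for inversion the displacement is extended into the pad
region by edge replication under a half-cosine ramp to zero. With
`pad_factor=1` forward and inverse share one circulant lattice and are
exact inverses of each other — the configuration used to verify inverse
exactness. A direct O(N²) real-space summation (piecewise-constant
traction per cell, cell-integrated Green tensor with the analytic
self-cell integral 9h·ln(1+√2)/(2πE) on the diagonal) serves as an
independent reference implementation; on a 16×16 grid the FFT path agrees
with it to ~1.2% relative RMS, the residue being discretization, not
either implementation.

## Regularized inversion and the choice of λ

The traction estimate is the exact per-mode minimizer of
J(f) = ‖Gf − u‖² + λ²‖f‖², computed in the kernel eigenbasis
(f̂ = g·û/(g² + λ²) per channel). Residual and solution norms are defined
over the padded computational lattice via Parseval, so the identity
J = r² + λ²s² holds to rounding and both norms are provably monotone in λ
— which is what makes a half-interval (bisection) search valid.

λ is selected by Morozov's discrepancy principle: find λ* with
r(λ*) = σ·√(2N), the residual a solution that fits everything except the
noise should leave (N = valid displacement nodes, 2 components). The
bracket is [10⁻⁶, 10²]·‖G̃‖, bisection runs on log₁₀λ to 10⁻³ relative
residual tolerance or 60 halvings. If the target is below the bracket
floor's residual, λ stays at the floor (noise-free limit); if it exceeds
the residual at λmax, the data are indistinguishable from noise and λmax
is returned with a warning and `converged=False`. The criterion is
pluggable in the sense that `invert_traction` exposes the norms for any λ;
alternatives such as L-curve selection are not built in.

Before inversion, invalid displacement nodes are in-filled with the median
of their valid neighbors (iteratively, so hole clusters fill), and the
spatial mean of the padded field is removed: a uniform displacement is an
unobservable rigid translation (residual drift), not deformation, and the
zero-mean traction constraint could never fit it.

When σ is not supplied, `auto_lambda` falls back to
1.4826·MAD(u − median₃ₓ₃(u)). This estimator is blind to error that is
correlated across neighboring nodes, which gridded bead measurements do
exhibit (neighboring nodes share beads), so the displacement stage
computes and forwards its own estimate instead: the maximum of (a) a
split-half estimate — the matches are split into two interleaved halves,
each gridded separately, and half the standard deviation of the half-field
difference taken — and (b) the per-component RMS disagreement between the
gridded hybrid field and the PIV field. The disagreement term is the
operative one: the two estimators have independent error mechanisms
(window averaging vs per-bead centroids), so their disagreement bounds
their combined uncertainty, including components a split-half estimate
cannot see. On synthetic scenes this tracks the true per-node error
closely; it is mildly conservative where PIV is the worse of the two.

## Displacement measurement

**PIV.** Normalized cross-correlation per interrogation window (default
32 px, 75% overlap in the pipeline), peak located with a 3-point Gaussian
fit per axis (parabolic fallback for non-positive samples). Two passes by
default: the second offsets the stressed-side window by the rounded
first-pass displacement (discrete window offset), removing the
loss-of-correlation bias in strong displacement gradients. Validation:
first/second correlation peak ratio ≥ 1.2, the second peak searched
outside a ±3 px exclusion zone (anything closer is the same peak's
shoulder at this bead-image size); then a Westerweel-style normalized
median test over 8-neighborhoods with threshold 2.0 and fluctuation floor
0.2 px — the sub-pixel fit noise at the default bead density; smaller
floors flag ordinary fit scatter as outliers. Rejected vectors are
replaced by the median of valid neighbors and flagged in the validity
mask, never silently.

**Particle detection.** Boxcar background subtraction (4r+1 window),
local maxima above an intensity percentile (default 90) with two floors: a
robust noise floor (6 robust σ of the background-subtracted residual) and
2% of the brightest feature (so noise-free images do not admit
background-subtraction plateau artifacts). Centroids are refined
iteratively in a disk of radius 3 px; m₀ is the integrated
background-subtracted intensity there and m₂ the second radial intensity
moment (px²). Detections closer than the radius merge, keeping the
brighter — at the default density (~0.01 beads/px², PSF σ 1.5 px) this
costs a few percent of beads in compressed regions, the main accuracy
limit of the stage.

**Linking.** Each reference (equilibrium) bead's search is centered at its
position plus the seed field interpolated there; stressed candidates
within the exploration radius (default 2 px) are scored by
cost = ‖Δposition‖² + w₀·Δm₀² + w₂·Δm₂², with w₀, w₂ the inverse pooled
variances of the moments, so the three terms are commensurate without
hand-set weights. Assignment is greedy by
ascending cost with pairwise swap relaxation (near-optimal at TFM
densities, linear-log cost); the Hungarian algorithm is available via
`method="hungarian"`. Matches deviating from the median of their 8 nearest
matches by more than 3 local MADs plus a 0.02 µm floor are rejected as
mislinks.

**Gridding.** The hybrid field is assembled as PIV baseline plus gridded
PTV residuals: per-bead residuals relative to the PIV field are averaged
onto the PIV node lattice with Gaussian weights (bandwidth = grid spacing,
read as FWHM, i.e. σ = spacing/2.355; weights truncated at 3σ), and nodes
with insufficient bead support simply keep the PIV value instead of
inheriting a stale distant vector. A σ equal to the full spacing was
rejected because it low-passes the traction estimate by a factor
σ_g²/(σ_patch² + σ_g²) ≈ 40% at the default scene scale — the gridding
kernel convolves the recovered traction directly, since smoothing
commutes with the (linear) inversion.

## Focus selection and drift correction

Two sharpness scores: excess kurtosis of the intensity histogram
(maximum = sharpest; suited to bright field, where defocus suppresses the
heavy tails produced by edges) and Laplacian energy after σ = 1 px
Gaussian pre-smoothing (suited to fluorescence). "EDF" here means
best-slice *selection* by high-frequency energy, not a wavelet composite
image: a per-pixel composite would alter bead photometry, which the PTV
scoring relies on. Ties break toward the lowest z-index. The kurtosis
variant (excess, intensity domain) is this package's documented choice,
not a claim about any other implementation.

Drift is modeled as rigid translation per frame (rotation is unobservable
at these fields of view): FFT cross-correlation against the equilibrium
reference, 3-point parabolic sub-pixel refinement, correlation peak
required within `max_drift_px` (default a quarter of the image). One
global crop box (original size minus the ceiling of the largest shift) is
applied to all frames and channels of a position — a single crop keeps all
shapes identical across the series, which per-frame cropping would not.
Sub-pixel translation uses bilinear interpolation rather than Fourier
shifting to avoid ringing around bright beads; measured accuracy is
~0.02 px with ~0.03 px residual after correction.

## Synthetic scenes

The generator produces what the pipeline consumes, with exact truth at
every stage: a force-balanced contractile dipole (two Gaussian traction
patches pulling toward each other), its forward-model displacement field,
a uniform random bead carpet in equilibrium and warped (bilinear
interpolation of the truth field) into the stressed configuration,
per-frame cumulative stage drift, defocus z-stacks (blur width
√(σ² + (rate·|i−i₀|·dz)²), photon count conserved), and a cell channel
(soft-edged elliptical plateau with non-overlapping adhesion puncta placed
near the rim). Beads are rendered as pixel-integrated Gaussians (erf
differences), so the fixture itself contributes negligible centroid bias;
all generators are pure functions of their arguments and seed.

Default study conditions: 512×512 px at 0.108 µm/px, E = 2 kPa (a soft
gel, chosen so a 300 Pa dipole produces multi-pixel bead displacements
that exercise the seeded-tracking path), dipole peak 300 Pa with
σ = 3 µm patches 20 µm apart (patch width ≳ 3 traction-grid nodes, the
regime a linear reconstruction at this sampling can resolve), bead density
0.01 /px² with PSF σ = 1.5 px, camera background 100 counts, bead peak
≈ 2000 counts, Poisson shot noise plus σ = 5 read noise, five time frames
with a 0.5 px/frame drift walk, and 14-slice z-stacks at 200 nm steps.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: non-Gaussian PSFs and depth-dependent
aberrations, photobleaching and illumination drift, gel nonlinearity or
viscoelasticity, out-of-plane displacements, bead aggregation, and cells
whose traction pattern is not a smooth compact patch field. On real data
the noise estimate and the segmentation defaults are the first things to
re-examine.

## Pipeline, outputs and determinism

The two-unit workflow (job creation, then sequential execution) stores the
entire analysis description in a plain-ASCII INI job file; execution
rewrites it after every completed step, keeps a pristine backup from the
first launch, and `--resume` skips completed steps. Steps communicate only
through files under `<output_root>/<position>/<step>/`, so a killed run
resumes to byte-identical outputs (fixed numeric formats, no timestamps in
any writer). The analysis path contains no randomness; seeds appear only
in simulation and are recorded in the scene sidecar.

Measured behavior under the default study conditions (recomputed by
`scripts/acceptance.py`): peak traction recovered to within ~10–20% of
truth with the peak on or adjacent to the true node, total integrated
force within ~10% of the analytic patch integral, ≥95% (typically 100%)
of assignable beads linked to their true partner with seeding versus
~84% without, focus selection correct on 50/50 random stacks, and drift
recovered to ~0.02 px. Scene-to-scene variation of the peak error spans
roughly 9–20%: the limiting factor is correlated bead-centroid error in
the compressed regions near traction patches, not the inversion.

## Sizes and defaults used by the test and acceptance runs

Elastic-model cross-checks run on 16–32 node grids (the direct-summation
oracle is O(N²)); the end-to-end run uses one full-scale position
(512×512 px, ~2600 beads, 5 frames, 64×64 traction nodes at 8 px
spacing); focus accuracy uses fifty 128×128 stacks; restartability uses a
compact 192×192 scene. These sizes keep the whole suite in the
half-minute-to-minute range per group while exercising every code path at
the documented study conditions.
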