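# Methods

This note documents the models, conventions, numerical choices and known
limitations of `mmpol`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Measurement model

The simulated instrument is an ideal 16-state transmission polarimeter.
Generator and analyzer each produce one of four states — linear horizontal
(H), linear vertical (V), linear +45° (P), right circular (R) — and the
recorded intensity for generator state `g` and analyzer state `a` is

    I_ga = ¼ · (1, â)ᵀ M (1, ĝ)

where `ĝ, â` are the normalized Stokes 3-vectors of the states. The ¼ scale
makes the reconstructed `m11` equal the medium's unpolarized transmission.
Reconstruction inverts this linear system in the closed form given in
`mmpol.reconstruction`; on noiseless input it is exact to machine precision
(verified against the numerically inverted 16×16 design matrix in the test
suite). No instrument calibration, registration, or PSG/PSA imperfections
are modeled: stacks are assumed ideal and co-registered.

Stokes basis: `(I, Q, U, V)` with H = +Q, +45° = +U, right circular = +V.
The reference axis is horizontal, positive angles counterclockwise toward
the source, axial angles reported in `(−π/2, π/2]`, API angles in radians.

**Handedness.** The elementary linear retarder uses
`m24 = −sin δ · sin 2θ`, which reproduces the textbook quarter-waveplate
matrix at 30° element-for-element, and a positive circular retardance
rotates Stokes vectors clockwise about S3 (azimuth φ → φ − δC). The
differential generator's CB sign is chosen to match, so forward model and
decomposition are self-consistent. The physical handedness of real samples
cannot be pinned without an instrument; this internally consistent
convention is documented rather than silently assumed.

## Media: simultaneous properties via the differential formalism

A homogeneous medium is generated by a 4×4 differential matrix `L` with
nondepolarizing entries (LB, LB′, CB, LD, LD′, CD) in the standard layout
and a diagonal depolarizing part `diag(0, α1, α2, α3)`, `αi ≤ 0`; the
Mueller matrix is `expm(L)`. This represents retardance, diattenuation and
depolarization acting *simultaneously and continuously* through the sample
thickness, as opposed to an ordered product of pure elements. Homogeneity
within a pixel (transverse and through-thickness) is a modeling assumption,
not enforced.

The generator restricts the depolarizing part to its diagonal (no
polarizance vector), which keeps parameter recovery identifiable; the
decomposer tolerates a full `Lu` because the extraction only reads the
entries it needs.

## Logarithm decomposition

Per pixel: classify the eigenvalues of `M`, take the principal matrix
logarithm, split with the `G = diag(1,−1,−1,−1)` metric, extract
properties.

- **Classification tolerance.** Imaginary parts above `1e−9·‖M‖_F` count as
  complex; real eigenvalues at or below that count as zero. Spectra that
  are neither a complex-pair case nor all-real-positive (including any real
  negative or zero eigenvalue) are *undefined*; undefined is a per-pixel
  value that propagates through every downstream map, never an exception.
- **Logarithm.** `scipy.linalg.logm` computes the principal branch, which
  is real for both physical cases and places the rotation angle in
  `(−π, π]`. Each pixel's result is back-checked with `expm(L) ≈ M`
  (residual ≤ 1e−10·‖M‖); non-convergence demotes the pixel to undefined.
  Identical matrices in an image (piecewise-uniform scenes) are decomposed
  once and broadcast.
- **Normalization and depolarization.** Measured matrices are
  m11-normalized, which shifts the whole diagonal of `L` by `−log m11`.
  Depolarization coefficients are therefore read relative to the isotropic
  term: `αi = Lu[i,i] − Lu[0,0]`. This makes recovery exact in the presence
  of diattenuation (which makes the unnormalized `m11 = cosh(·) > 1`) and
  means isotropic absorption never masquerades as depolarization.
- **Extraction.** `δL = hypot(LB, LB′)`, `θFA = ½·atan2(LB′, LB)`,
  `δC = CB`, `DL = tanh(hypot(LD, LD′))`, `θTA = ½·atan2(LD′, LD)`,
  `DC = tanh(CD)`, `Δ = 1 − |Σ e^{αi}|/3`. The `tanh`/exponential-mean
  forms are fixed here and validated by forward→inverse self-consistency
  (noiseless recovery of all seven properties to better than 1e−6 over
  1000 random media, measured each run by the acceptance script) rather
  than by an external reference. Orientation angles are NaN sentinels when
  their magnitude vanishes (δL or DL ≈ 0, threshold 1e−12), with the pixel
  still defined. `Δ` is clipped to `[0, 1]`.
- **Wrapping.** The decomposition always returns principal-branch values,
  as an instrument does: a pure retarder generated with `δ = π + x` reads
  as `δL = π − x` with the axis flipped by π/2, and `δ = π` exactly is
  undefined (double −1 eigenvalue). Half-order correction
  (`deltaL → 2π − deltaL`, axis + π/2) lives in the anisotropy module and
  takes a *manual* order assignment — automatic order estimation would
  need a second wavelength or sample thickness and is out of scope.

## Naive Stokes estimator and the deviation law

The comparison estimator uses only the R-generator rows of the stack:
`I0 = I_RH + I_RV`, `ŝᵐ = (2I_RH − I0, 2I_RP − I0, 2I_RR − I0)/I0`, then
`δL(S) = arccos(ŝⁱ·ŝᵐ)` and the axis from `ŝᵐ×ŝⁱ` against S1, signed by the
S2 component. Circular illumination makes `δL(S)` independent of the sample
axis. Pixels with `|ŝᵐ| < 0.05` (configurable) are masked: the model
normalizes depolarization away and the axis becomes noise-dominated.

For a circular retarder composed *after* a linear retarder
(`M = C(δC)·R(δL, θ)`) the naive axis deviates from the true axis by
exactly `−δC/2`, independent of `δL` and `θ` — the relation the deviation
sweep (`deviation_sweep` + `axis_deviation_analysis`) verifies with
regression slope −0.5 and r = −1. For a *simultaneous* medium (generator
with both LB and CB) the closed form is instead
`deviation = −½·atan(tan(δT/2)·δC/δT)`, which approaches `−δC/4` for small
total retardance and `−δC/2` only near `δT ≈ 2.3`. Consequently the
pericardium-like scenes show a strong negative deviation-vs-δC correlation
(further diluted by the random low diattenuation perturbing the naive
axis), not an exact −½ slope; the acceptance checks assert the exact law on
the serial sweep and the qualitative strong negative correlation
(r < −0.6) on the simultaneous tissue scene.

## Anisotropy maps and axial statistics

Orientations are axial (period π); every mean, variance and difference is
computed on doubled angles (`mean = ½·atan2(Σ sin 2θ, Σ cos 2θ)`,
`variance = 1 − |Σ e^{2iθ}|/n`). Slow-axis (fiber) maps are
`θFA + π/2` folded. Blocks default to 112 px ≈ 1 mm at the 8.90 µm pixel
pitch; blocks with more than 25% undefined pixels are omitted (both
defaults configurable). Rendered line length uses `1 − variance`; the raw
variance is stored so any other normalization can be reproduced.

## Synthetic phantoms

The generator defaults encode the study conditions the package emulates:

- **Transparent strain phantom**: pure linear retarder,
  `δL = 28.2·ε + 0.3` rad, fast axis along the strain direction
  (default 0.393 rad, the mounting angle of the emulated test). The wrap
  onset is at `ε = (π − 0.3)/28.2 ≈ 0.1008`.
- **Scattering strain phantom**: adds isotropic depolarization (net
  Δ = 0.4, the 1% lipid level) and linear diattenuation `DL = d_slope·ε`
  with transmission axis orthogonal to the strain; retardance slope
  21.4 rad/strain, intercept 0.03. The diattenuation-strain slope is not
  quantified by the emulated experiments; `d_slope = 1.0` (DL ≈ 0.06 at 6%
  strain) is a fixture choice keeping the phantom in the low-diattenuation
  regime.
- **Pericardium-like scene**: piecewise-uniform slow-axis domains with
  wrapped-normal axis jitter (σ = 3° on doubled angles — a fixture choice;
  real within-region dispersion is not quantified), per-region draws of
  δL ∈ (0.2, 2.8) rad, δC ∈ [−1, 0] rad, Δ ∈ [0.31, 0.73],
  DL ∈ [0.08, 0.16]. Defaults keep `δT < π` so recovery is exact; widening
  `deltaL_range` past π intentionally produces the wrap artifact (abrupt
  π/2 axis flips next to high-retardance domains).

What the phantoms do *not* emulate: multiple scattering (no Monte-Carlo
radiative transfer — depolarization is imposed, not emergent),
out-of-plane optic axes, instrument imperfections, spatial
misregistration, and speckle. Passing tests therefore demonstrate the
correctness of the algebra, decomposition and statistics on media that
satisfy the homogeneous in-plane model — not robustness to every real
tissue artifact.

## Noise model

Optional per-stack noise: Poisson shot noise at a stated photon budget at
full scale, then additive Gaussian noise with σ given as a fraction of the
stack's noiseless full scale, then clipping at zero (cameras record no
negative counts; at the σ = 0.5% level used in validation the clip is
inactive for the scenes tested). Seeds are explicit everywhere; the same
seed reproduces a stack bit-for-bit.

## Problem sizes and tolerances used in validation

The validation suite uses 1×1-to-64×64-pixel scenes, 100-media
reconstruction round trips, 1000-media recovery sweeps, 25-point
retardance/strain sweeps and 5×5-domain tissue scenes; these sizes give
fully converged statistics for deterministic checks while keeping the
whole suite and the acceptance script each under a minute. Headline
tolerances: machine precision for analytic matrices and reconstruction
(≤1e−12), 1e−6 for noiseless parameter recovery, 1e−8 for the wrap law,
1e−6 for the deviation-law slope, and a 0.02 rad bound on the median δL
error at 0.5% Gaussian noise (measured ≈ 0.008 rad).

## Known limitations

- Retardance order ambiguity is resolved only by user-supplied half-order
  assignments; no automatic (e.g. multi-wavelength) disambiguation.
- The decomposition returns undefined for matrices with negative or zero
  real eigenvalues; physically these occur at exact half-wave retardance
  and for strongly non-physical (noise-corrupted) pixels.
- `scipy.linalg.logm` is applied per unique matrix; very large images of
  fully heterogeneous noisy data decompose at roughly 1–2 ms/pixel.
- The polarimeter model is ideal; applying the pipeline to real data
  assumes upstream calibration has produced physically valid Mueller
  matrices.
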