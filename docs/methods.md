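# Methods

## The imaging model

A lensless digital inline holographic microscope (LDIHM) illuminates a
thin, weakly scattering sample with a partially coherent source a few
centimetres above it (source–sample distance z1) and records, on a bare
sensor a millimetre or so below it (sample–sensor distance z2), the
interference between the wave scattered by the object and the
undiffracted illumination.  The geometry has unit magnification, so the
field of view equals the sensor area and the resolution is bounded by the
pixel pitch and by the source's temporal and spatial coherence.

The object is described by its complex transmission
`u_o(x, y) = A(x, y) · exp(i φ(x, y))` under unit plane-wave
illumination.  Free-space propagation over a signed distance z is the
angular spectrum method (ASM): multiply the field's spatial spectrum by

    K(fx, fy; z) = exp( i 2π (z/λ) sqrt(1 − (λ fx)² − (λ fy)²) ),

zeroing evanescent frequencies (negative square-root argument).  The
recorded hologram is `I = |P_z(u_o)|²`, normalized by a no-sample
reference recording, which removes the reference intensity and any
vignetting exactly.  Positive z propagates object → sensor; the conjugate
kernel (negative z) undoes it exactly on the non-evanescent band, which
makes propagation unitary there.  The transfer-function implementation is
validated in the test suite against a direct spatial-domain quadrature of
the first Rayleigh–Sommerfeld integral on 64² grids (relative agreement
far below the 1e−3 requirement).

Units: lengths are micrometres internally; wavelengths enter the API in
nanometres and distances in millimetres, the units acquisition metadata
is normally quoted in.

## Classic reconstruction and autofocus

The baseline single-shot reconstruction back-propagates the normalized
intensity itself (not its square root) with the conjugate kernel.  The
result `1 + (u_o − 1) + twin + e` contains the focused object exactly,
plus the conjugate ("twin") wavefront defocused by 2·z2 and the
self-interference error `e` — this is why unconstrained single
propagation is quantitatively poor for strong-phase objects.

Autofocus sweeps the Tamura coefficient of the gradient magnitude of the
back-propagated amplitude over a coarse distance grid and refines the
best bin with a bounded scalar minimizer.  The criterion is maximized at
focus for samples with sharp absorbing detail.  A genuinely smooth
pure-phase object gives almost no focus cue: a feature of size a only
blurs appreciably over defocus ~ a²/λ, which for a 30 μm smooth blob is
of millimetre order, and at exact focus a phase object produces *no*
amplitude contrast at all.  This is a property of inline holograms, not
of the criterion — practical autofocus locks onto fine absorbing
structure (organelles, debris) in the field of view, and the phantom
generator can produce such structure on request (`absorption` option).
On absorbing granular phantoms the search lands within 2–3 μm of the
true distance across the 0.8–1.3 mm range.

Phase maps are unwrapped with quality-guided 2-D unwrapping and offset so
the histogram mode of a 10-pixel border frame is zero (the background of
an inline reconstruction is the undiffracted reference, whose absolute
phase is arbitrary).

## Synthetic objects

Two phantom families define the study conditions:

* **Beads** — spherical caps of diameter 4 μm, refractive index 1.68 in
  water (1.33), giving a center phase of 2π·h·(n1−n2)/λ = 14.03 rad at
  627 nm.  The thickness of a sphere has an infinite radial derivative at
  its rim, so a literally sampled strong bead can never be 2-D unwrapped
  (neighbouring samples would always jump by more than π somewhere on the
  rim).  Beads are therefore rendered with a Gaussian-soft edge whose
  width is set so the steepest per-pixel phase increment stays below
  0.65π — the local spatial frequency then stays well inside the sensor
  band, which is what makes the object resolvable at the simulated pitch
  in the first place — and the profile is rescaled so the *center*
  thickness is exact to machine precision.  This mirrors what any
  band-limited instrument does to a bead edge while keeping the quantity
  the thickness formula reads out exact.  Too little softening leaves a
  band-limited apex deficit of a few percent; much more softening
  concentrates the twin on the bead and breaks the unwrap — the default
  sits in the physically sensible window.

* **Cells** — a wobbled-ellipse cytoplasm with one to three nuclei and
  fine granular texture (σ ≈ 1.3 px), Gaussian-smoothed and rescaled so
  the maximum phase equals the requested peak exactly (4 rad for the
  simulation protocol).  The granularity is what gives cell holograms a
  usable autofocus signature; an optional absorption component adds the
  sharp amplitude detail real samples have.  Pure phase is the default.

Datasets pair each hologram with its ground-truth phase under the same
file name in parallel folders, with a YAML manifest recording the
per-record distance (drawn from {0.8 … 1.3} mm), seed and paths; splits
use floor rounding for train/val with the remainder to test (2048 →
1800/148/100 under the protocol fractions).  Sensor binning
(`downsample_sensor`) and Poisson + Gaussian sensor noise (`add_noise`)
are available, both seeded.  All generation is a pure function of
(parameters, seed).

What the phantoms do *not* emulate: real cytology morphology, partially
coherent blur, sensor nonlinearity, dust and large-field aberrations.
Passing tests therefore demonstrate the correctness and the relative
behaviour of the algorithms under the stated simulation protocol, not
clinical performance.

## The plug-and-play ADMM reconstruction

The reconstruction minimizes, over the complex object estimate `uo` and
the parameters θ of an untrained generator `R_θ`,

    L(θ, uo, t) = ½‖H(R_θ(uo)) − I_τ‖²
                + (α/2)·Re⟨uo, uo − u_τ⟩
                + (β/2)·‖uo − R_θ(uo) − t‖²,

where `H` forms the hologram at the focused distance, `I_τ` is the
(optionally bicubically upsampled) measurement, `u_τ` is a constant
amplitude combined with a high-resolution prior phase `φ_τ`, and `t` is
the multiplier field of the variable splitting `uo = R_θ(uo) + t`.  One
epoch updates θ (Adam steps on fidelity + proximity, with `uo`, `t`
frozen), then `uo` (explicit step on the prior + proximity terms), then
`t` (ascent on the splitting residual), and stops when the per-pixel
drift of all three sub-objectives falls below tol/3 (tol = 1e−3 by
default) or at the epoch cap.

The prior phase comes from one of four sources: an external file (the
output of a separately trained high-resolution phase estimator — the
intended production source), a total-variation-denoised back-propagation
(the regularization-by-denoising surrogate, mode `dip-red`), a bicubically
upsampled back-propagated phase (mode `hybrid` without a file), or
all-zero with the prior term disabled (mode `dip`).

### Why the prior carries the quantitative burden

A single intensity recording constrains only the *modulus* of the
sensor-plane field; any sensor-plane phase is consistent with it.  We
verified this directly: plain Wirtinger-flow descent on the data term
drives the fidelity to exactly zero while recovering a phase peak an
order of magnitude too small.  The data term therefore selects a manifold
of solutions, and everything quantitative about strong phase objects —
the twin-free structure and the absolute phase scale — must come from
the object-domain constraints: the constant-amplitude pull of the prior
term (a pure-phase/weak-absorption assumption) and the prior phase
itself.  With self-contained surrogate priors the pipeline accurately
refines objects whose back-propagation is already structurally right
(compact beads: classic −2.3%, refined to −1%); a smooth extended object
carrying 4 rad cannot be recovered from one intensity by any
self-contained method, which is precisely the role the externally trained
phase estimator plays in the production workflow.  The file-based prior
adapter accepts such estimates; `degrade_phase_prior` builds a synthetic
stand-in (resampled, blurred truth) for testing that role.

### Numerical choices

* **Object step size.** `c = 1/(α+β)` by default, which makes the
  explicit step the *exact* minimizer of the quadratic object
  sub-problem.  A small under-relaxed step combined with a full
  multiplier update is unstable here: with the θ sub-problem solved
  inexactly (one Adam step per epoch), the multiplier integrates the
  splitting residual much faster than the object discharges it and the
  loop diverges.  For the same reason the multiplier step is damped
  (γ = 0.3 by default); the γ = 1 form is the γ-parameter's limit and the
  sum-sign variant of the update is available behind
  `multiplier_sign="sum"` for comparison.
* **Residual generator.** `R_θ(x) = x + f_θ(x)` with a near-identity
  initialization (head weights ~1e−3).  The network input each epoch is
  the current object estimate, so the generator literally fine-tunes the
  running reconstruction.  Without the identity path the randomly
  initialized output, mixed into `uo` by the splitting, tears the 2π
  winding of strong-phase objects and the unwrapped peak collapses —
  with it, the winding is inherited from the initialization and only the
  correction is learned.
* **Iterate averaging.** The inexact sub-steps leave a small limit cycle
  around the fixed point; the returned object is the mean of the last
  `avg_tail` (default 50) iterates, which removes it.
* **Readout.** When a prior phase exists, the output phase is unwrapped
  against it as a reference surface: `φ_τ + angle(uo·e^{−iφ_τ})`.  The
  prior carries the integer winding count; the reconstruction supplies
  the accurate sub-2π correction.  Path-following 2-D unwrapping is used
  only when no prior exists.
* **Weights.** α = 0.4, β = 0.6, Adam rate 5e−4, one inner θ step —
  fixed once by a coarse grid search on a single noiseless validation
  phantom.  α expresses trust in the prior: the recommended setting rises
  to ~1.2 when the prior is a trained estimator's output rather than a
  back-propagation surrogate, and the step `c` follows as 1/(α+β).
* **Complex channelization.** Fields enter the network as (real,
  imaginary) channels; amplitude/phase channels were rejected because
  phase wrapping puts artificial 2π discontinuities into an otherwise
  smooth image.
* **Epoch budgets.** 700 epochs is the reference budget for clean
  simulated data and 1000 for noisy data; on noiseless phantoms the
  stopping rule typically fires far earlier.  The test batteries use
  shorter fixed budgets (40–300 epochs at 64²–192²) chosen inside broad
  stable windows so the whole battery of reconstructions remains
  desk-scale; the methods' relative behaviour is insensitive to the exact
  budget within those windows.

### The generator

A small convolutional encoder–decoder (depth 3, 16 features per level,
4-channel 1×1 skips, LeakyReLU, 2× bilinear up/down sampling, ~16k
parameters), implemented on a purpose-built reverse-mode automatic
differentiation engine over numpy arrays (im2col convolutions, exact
adjoint bilinear upsampling; gradients validated against central finite
differences).  The size is deliberately modest so hundreds of epochs on
192²–256² grids run in minutes on one CPU core; the capacity baseline
(fitting a clean 128² target to MSE < 1e−3) is reached in roughly a
hundred iterations, well inside the 700-iteration budget.

## Evaluation

* `p-SNR = 10·log10[(max(P) − μ)/σ]` in dB, with μ the mean and σ the
  standard deviation of the phase image (σ as a standard deviation — a
  scalar "covariance" of an image with itself is its variance, and the
  log argument should be a dimensionless amplitude ratio).  The metric is
  invariant under affine rescaling of the image; it rewards a clean, flat
  background relative to the peak, so it discriminates noise/twin
  suppression on sparse scenes and is computed full-frame by default with
  an ROI option.
* SSIM uses an 11-pixel Gaussian window (σ = 1.5, K1 = 0.01, K2 = 0.03)
  with the data range taken from the reference; MSE is the plain mean
  squared error.
* Thickness: `h = p·λ/(2π(n1 − n2))` per pixel on unwrapped phase.
* `sweep` forms fresh holograms per axis value (distance or wavelength),
  reconstructs with each method, and reports per-cell SSIM/MSE/p-SNR plus
  the interval where a method's mean SSIM stays within 95% of its peak —
  the "width of peak performance" comparison.

The method-ranking battery uses noisy sparse bead scenes (weak 1.2-rad
beads, Poisson scale 300, read noise σ = 0.08): there the background σ is
noise-dominated, so p-SNR measures exactly the noise/twin suppression the
method hierarchy is about, and the ranking
prior-driven ≥ denoiser-prior ≥ untrained-net ≥ single-propagation
emerges without per-phantom inversions.  On noiseless scenes the same
metric instead rewards whichever method flattens the *signal* most —
a frozen TV prior can score above the ground truth itself — so a
noiseless battery cannot express the hierarchy; this is a property of
the metric, not of the methods.

## Known limitations

* The untrained-network mode (`dip`) is optimization-limited on CPU: it
  suppresses noise and twin ripple but does not recover the absolute
  phase scale of strong extended objects, and long unregularized runs
  drift at low spatial frequencies (the stopping rule exists precisely to
  cut this off on noisy data).
* The surrogate priors inherit the classic reconstruction's biases; the
  quantitative headline results use them only where back-propagation is
  already structurally correct (beads), and a trained-estimator prior
  elsewhere.
* Upsampled reconstruction (2×/4×) interpolates the measured hologram;
  it cannot create sensor information and slightly degrades quantitative
  peaks relative to native-resolution runs on synthetic data.
* Wavelength sweeps rebuild bead phases from the dispersion-free
  geometric formula; material dispersion is not modelled.
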