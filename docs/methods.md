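# Methods

This note documents the models implemented in `flimcrowd`, the default
parameters and why they hold those values, the numerical choices that
affect results, and what the synthetic-data generators do and do not
emulate.

## The crowding sensor

Monomeric red fluorescent proteins such as mCherry show a monotonic
reduction of fluorescence lifetime once the fractional volume occupancy
(FVO) of crowders in the surrounding solution rises above a threshold near
30%. The mechanism is a crowding-induced compaction of the β-barrel that
perturbs the chromophore pocket and opens a nonradiative channel; it is a
*local density* effect, not a viscosity or concentration readout. Because
the dilute-regime lifetime is flat (~1.44–1.50 ns for mCherry), the sensor
is **one-sided**: a mean lifetime below a calibrated boundary (default
1.44 ns, `flimcrowd.flim.CROWDING_BOUNDARY_NS`) reports a local density
above ~30% FVO, while lifetimes at or above the boundary are *not
resolved* — they are never interpreted as "dilute". The boundary is an
instrument- and fluorophore-specific constant and is exposed as a
parameter everywhere it is used.

## TCSPC decay model and fitting

**Model.** A decay with components (τᵢ, aᵢ) on a uniform grid over the
repetition window T is represented by per-bin integrals of
Σᵢ aᵢ e^{−t/τᵢ}, wrapped on T (factor 1/(1−e^{−T/τ})); wrap-around is
negligible for τ ≈ 1.5 ns at T = 50 ns (20 MHz) but keeps the model
correct for long lifetimes. The instrument response (IRF) is either a
parametric Gaussian (default FWHM 0.1 ns, matching a 100 ps excitation
pulse) or a measured histogram, normalized to unit area. Convolution is
circular (FFT), which implements inter-pulse wrap exactly. For parametric
IRFs the convolution runs on an internally oversampled grid (8–16× finer)
and is re-binned; without this, the discrete convolution of bin-integrated
factors misrepresents the rising edge when the IRF width is comparable to
the bin width (the kernel is only 1–2 bins wide on a 512-bin, 50 ns grid).
The Gaussian kernel holds per-bin mass on offsets centered at multiples of
the bin width so the discrete convolution stays aligned on bin centers; a
closed-form check against the exponentially modified Gaussian is part of
the test suite.

**Bulk fits.** `ConvolvedBiexponentialFitter` performs weighted least
squares with Poisson weights. Parameters are the component lifetimes, the
*photon fraction* of the first component, and the total photon count —
a normalized parameterization that keeps the Jacobian well-conditioned
(fitting raw per-component amplitudes in counts stalls
Levenberg–Marquardt). Weights start at σ² = max(counts, 1) and are then
re-estimated once from the fitted model (σ² = max(model, 1)); this single
re-weighting pass removes the classic low-count bias of observed-count
weights (≈ 1% on the mean lifetime at 3×10⁴ photons, < 0.2% after).
Photon fractions fᵢ ∝ aᵢτᵢ are converted back to decay amplitudes for
reporting. An additive background is fitted only when the pre-pulse region
(> 5 IRF widths before the pulse) averages more than 1 count/bin, and is
initialized at that average (initializing a bounded parameter exactly at
its bound stalls the optimizer). Components are reported sorted ascending
in lifetime. Non-convergence sets a flag on the result; it never raises.

**Mean lifetime.** Two conventions are implemented:
amplitude-weighted τ̄ = Σaᵢτᵢ/Σaᵢ (default — the natural reading of a
mean "calculated from component values and their amplitudes") and
intensity-weighted τ̄ = Σaᵢτᵢ²/Σaᵢτᵢ. Intensity weighting is never below
amplitude weighting (Chebyshev's sum inequality); both are available by
flag.

**Reduced χ² scale.** With the unit variance floor, far-tail bins that are
empty in both data and model contribute ≈ 0 to χ² while inflating the
degrees of freedom, deflating χ²red by up to a factor ~2 on a 50 ns
window. The χ² scale and dof therefore count only *informative* bins
(expected counts ≥ 1). This matters for the confidence intervals below.

**Confidence interval on τ̄.** The 95% interval profiles the mean
lifetime: for target τ̄ values walked outward from the optimum, the
component lifetimes and total counts are re-optimized with the photon
fraction pinned by the target (for amplitude weighting
f = (1/τ̄ − 1/τ₂)/(1/τ₁ − 1/τ₂)); a target is accepted while its minimal
χ² stays below χ²min·(1 + p/(n−p)·F_{p,n−p}(0.95)). This realizes the
projection of the joint F-statistic acceptance region onto τ̄, which is
conservative for a single derived quantity; simulated coverage at 3×10⁴
photons is ≈ 98–99% (a Monte-Carlo acceptance-sampling variant was tried
first and under-covered, because samples rarely trace the thin correlated
χ² valley). On noiseless data the threshold collapses onto the optimum and
the interval degenerates to the point estimate. A surface still flat at
the walk boundary is flagged with a warning (open interval).

**Per-pixel tail fits.** `tail_fit_monoexponential` starts the tail at the
histogram peak plus 0.2 ns (≈ 2 IRF FWHM; the start offset is a
parameter) and maximizes the binned Poisson (multinomial) likelihood of a
window-truncated exponential, solved by bounded scalar minimization. MLE
was chosen over least squares on the tail because the pixel gates run down
to 30 photons, where least squares on counts is strongly biased while the
MLE is exact on noiseless histograms and nearly unbiased at the gate.
Pixels below the photon gate (default 100 photons in cells, 30 in vitro)
or with fewer than 3 nonzero tail bins return the no-value sentinel.

## FLIM images and condensate statistics

Photon streams (frame, x, y, channel, micro-time) are accumulated across
frames per pixel; gated pixels are tail-fitted on a common grid, ungated
pixels carry an exact 0 in the lifetime map. ROI statistics (mean, SD,
fraction of pixels below the boundary) are computed over nonzero pixels
only — sentinel pixels can never shift a mean. A ROI is classed
`above_30pct_FVO` iff its mean lifetime is strictly below the boundary.
ROIs are externally supplied label masks (they are typically drawn
manually); an Otsu + connected-components proposer is included for
convenience only. Coordinates are 0-based, row-major, pixel centers.
No spatial binning of neighbouring pixels is applied before per-pixel fits.

Populations of condensate means are compared with a two-sided T test
(Welch by default; Student's by flag) and a two-sided variance-ratio F
test, p = 2·min(P(F≤f), P(F≥f)) with (nA−1, nB−1) dof, with stars
`n.s.` (p > 0.05), `*` (0.01 < p ≤ 0.05), `**` (0.001 < p ≤ 0.01),
`***` (p ≤ 0.001).

## Time-resolved anisotropy

r(t) = (I∥ − G·I⊥)/(I∥ + 2G·I⊥) after (1) G-factor correction of the
perpendicular channel and (2) alignment of the two channels by the
inter-detector delay, estimated by cross-correlating the rising edges with
parabolic sub-bin refinement. G defaults to 1 for simulated data and is
always an explicit input for real data (measured with a freely rotating
dye). Bins whose denominator counts fall below 25 are masked — this keeps
the relative error of r below roughly 20%; the floor is configurable.
Rotational fits use r(t) = r₀·Σwᵢe^{−t/θᵢ} over a 10 ns window after the
peak (the widest window with workable noise); model selection between one
and two components requires a > 20% χ²red improvement. A decay flat within
noise returns θ = ∞ (frozen-rotation sentinel). The steady-state Perrin
relation r = r₀/(1 + τ/θ) and the photoselection limit
r₀ = (2/5)·(3cos²β − 1)/2 (0.4 for collinear dipoles) are provided;
anisotropy images mask pixels failing either channel's intensity threshold
and any pixel with r > 0.4, which can only arise from edge artifacts.

## FCS

G(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩² with symmetric normalization (left/right means
over the overlapping segments). The multi-tau correlator uses 16 lags per
octave with pairwise rebinning; rebinning is part of the estimator, so its
brute-force oracle in the tests shares it. The diffusion model is the
standard two-component 3D translational form with structure parameter
s = w_z/w_xy fixed at 5 by default (typical confocal; optionally fitted).
The *slow* diffusion time is the reported value — in cells the fast
component often takes values only consistent with free dye — and
components with τ_D below 10 bin times are flagged non-physical. No
detrending is applied before correlation; the photobleaching analysis
(bi-exponential fit of the rebinned trace, components fast-first) verifies
the timescale separation instead: fitted 1/k values must exceed the fitted
diffusion times. With bleaching enabled the mean-occupancy estimate N is
unreliable (the fluorophore pool decays), while diffusion times remain
usable.

## Calibration and Trp spectra

%-w/v crowder concentration converts to FVO via the partial specific
volume (default 0.84 mL/g for PEG; 1.0 gives the identity used by the
synthetic tests). The lifetime-reduction onset is a two-segment
changepoint fit — flat plateau then linear decline, the breakpoint
profiled on a 400-point grid with exact linear sub-problems, refined
continuously, with a residual-bootstrap 95% interval (200 resamples). A
curve is declared onset-free when the decline is negligible relative to
the data scale or the two-segment fit fails a variance-ratio comparison
against the flat model. Trp spectra are summarized by trapezoidal area
and the wavelength of maximum intensity (optional 3-point smoothing); the
area-vs-FVO transition is fitted by a 4-parameter logistic whose midpoint
uncertainty comes from the covariance diagonal. The fit accepts either
sign of transition; quenching reads as a decreasing curve.

## Trajectory pocket analysis

Analyses run on generic coordinate arrays plus an atom table, so
multi-frame XYZ/PDB text inputs suffice; no binary MD formats are needed.
The first quarter of each trajectory is dropped as equilibration
(ceiling convention on the frame count). Two residues are in contact when
*any* of their atoms (hydrogens included when present; heavy-atom-only by
flag) are within 3.5 Å; pocket residues are those in contact with the
target in > 0.33% of snapshots, pooled over replicas (per-replica mode
available), with a strict ">". Pocket volume is the convex hull of the
pocket Cα atoms (SciPy/Qhull); rank-deficient point sets return 0 with a
degeneracy flag. Distributions are summarized with the SEM computed over
replica means — each trajectory is one independent observation — and the
SEM is NaN for a single replica. Hydrogen bonds use a 3.5 Å
donor–acceptor distance and a D–H···A angle at the hydrogen of ≥ 150°
(boundary inclusive). SASA is Shrake–Rupley with golden-spiral sphere
points (default 960), probe 1.4 Å and Bondi radii; it is implemented
directly because the module operates on bare coordinate arrays with a
user-supplied radii map, and is validated against closed-form sphere and
spherical-cap areas. Minimum-image distances apply only when a periodic
box is supplied; toy data is non-periodic.

## Synthetic data: what it emulates, and what it does not

Every generator is the generative inverse of a fitting operation and draws
all randomness from one explicit integer seed (no global RNG state):

- **TCSPC decays** — per photon: component by amplitude weight,
  exponential delay, Gaussian IRF jitter, wrap modulo the 50 ns window;
  optional uniform background. Simulator amplitudes weight *photons*
  (intensity fractions). Not emulated: detector afterpulsing, dead time,
  pile-up, IRF asymmetry.
- **FLIM scenes** — disk condensates (optionally split into column bands
  of different lifetimes with per-condensate proportions) on a uniform
  background; per-pixel Poisson photon budgets split across frames.
  Overlapping condensates: the later entry wins. Not emulated: optics
  (PSF blur), detector noise, irregular condensate shapes, motion.
- **FCS** — Brownian steps in a periodic box (box 5 µm, ≥ 4 axial waists,
  to keep wrap artifacts out of the focal correlations), 3D Gaussian
  observation profile (w_xy 0.25 µm, w_z 1.25 µm, s = 5), per-bin Poisson
  counts, optional excitation-weighted irreversible bleaching. The spec
  carries a `mean_occupancy` field (default N ≈ 5) because per-species
  fractions alone do not fix an absolute concentration. The default
  duration follows the 2-minute acquisition protocol; tests and the
  recovery suite use 10–40 s traces at 0.2–0.5 ms bins, sizes chosen so a
  recovery run completes in seconds while leaving hundreds of diffusion
  times per trace. Not emulated: triplet blinking, flow, cross-correlation.
- **Anisotropy pairs** — Poisson-sampled channel curves
  I∥ ∝ I(t)(1+2r(t)), I⊥ ∝ I(t)(1−r(t))/G with
  r(t) = r₀Σwᵢe^{−t/θᵢ}; r₀ is capped at the 0.4 photoselection limit.
- **Toy trajectories** — Cα sites on a cylindrical lattice (radius 8 Å,
  12 residues/ring, 1.5 Å ring spacing); pocket residues displaced
  radially by a per-state offset plus isotropic Gaussian noise. This is a
  geometric stand-in for a β-barrel with a breathing pocket, not a
  physical model.
- **Calibration tables** — flat plateau to the onset, linear decline
  above, Gaussian noise.

Passing tests on these generators demonstrates estimator correctness and
statistical calibration under the stated noise models; they do not
demonstrate robustness to the instrument and biology effects listed as not
emulated.

## Problem sizes used by tests and the acceptance script

Recovery checks use 50 histograms × 10⁵ photons (tail-fit boundary
recovery), 100 noisy curves each for the sigmoid midpoint and the
changepoint onset, 200 repetitions × 3×10⁴ photons for interval coverage,
4–6 Brownian traces of 10–40 s for FCS, and 20 + 20 simulated condensates
with ~200-pixel ROIs for the heterogeneity discrimination. These sizes
were chosen to give stable means (Monte-Carlo error well below each
tolerance) while keeping a full run fast on one core.

## Known limitations

- The bulk fitter is limited to one or two exponential components; no
  global multi-curve fitting or phasor analysis.
- The profile confidence interval assumes the two-component model class;
  it is conservative (joint-region projection) rather than exact.
- The multi-tau correlator reports no per-lag error bars; fits are
  unweighted over the quasi-logarithmic grid.
- The anisotropy module does not model homoFRET quantitatively or
  lifetime-linked (associated) anisotropy.
- `fvo_from_concentration` is a linear partial-specific-volume conversion;
  it ignores non-ideal mixing.
- The 1.44 ns boundary and the ~30% FVO threshold are calibration
  constants for mCherry on a specific instrument class; other fluorophores
  or detection chains need their own calibration curve.
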