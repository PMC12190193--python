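# Methods

`lensepr` implements the analysis chain used in saturation-recovery (SR)
EPR spin-labeling studies of lens lipid membranes: exponential recovery
fitting, spin-label oximetry, cholesterol-bilayer-domain (CBD)
discrimination, CW-spectrum observables, transmembrane profiles, and a
composition-weighted model of cholesterol phase boundaries. This note
records the models, the defaults that matter, and the choices made where
the design was genuinely open.

## Saturation-recovery kinetics (`lensepr.sr`)

**Model.** After a saturating pulse the signal relaxes as

    I(t) = baseline + Σ_k I_ok · exp(−t / T1k),      k = 1 or 2,

with T1 the spin–lattice relaxation time (µs). Two components arise when
the spin label distributes over two lipid environments with different
oxygen accessibility. Signals are stored as decays toward a baseline;
rising recovery curves must be inverted on import, `I ← I(∞) − I(t)`.

**Baseline.** The strict model forms have no offset, but recorded signals
generally do, so `fit_single`/`fit_double` leave the baseline free by
default and accept `fix_baseline=0` for the strict form. The *oximetry*
entry points (`otp_from_decays`, `detect_cbd_onset`, and the
discrimination examples) pin the baseline to 0 by default instead: for a
two-component decay the offset is nearly collinear with the slow
component, and the Cramér–Rao bound on the CBD oxygen transport parameter
degrades from ~12% to ~28% (relative SD, standard scenario below) when the
offset floats. Pass `fix_baseline=None` there for data with a genuine
unknown offset.

**Fitting.** Nonlinear least squares (`scipy.optimize.curve_fit`,
trust-region reflective, positivity bounds on amplitudes and times).
Initialization: the single fit starts from a weighted log-linear
regression on the baseline-subtracted signal; the double fit multi-starts
from five time-constant ratios (2, 3, 5, 8, 12) placed geometrically
around the single-fit T1, keeping the start with the lowest residual sum
of squares. Components are relabelled so T11 > T12. Standard errors come
from the residual-scaled covariance (`absolute_sigma=False`), the standard
choice when the noise variance is unknown; over 200 seeded replicates the
covariance SEs agree with the empirical SD well within a factor of 1.5.

**Degeneracy.** A two-component fit is flagged `degenerate` when the time
constants collapse (T11/T12 < 1.05) or either amplitude fraction falls
below 2% — the data do not support two environments.

**Model selection.** The number of components is chosen by the corrected
Akaike information criterion (AICc, Gaussian least-squares form, noise
variance counted as a parameter). Two components are accepted only when
ΔAICc > 10 *and* the fit is non-degenerate. With 2048-point decays at 1%
amplitude noise this operating point gives a false-positive rate of 0/100
seeds on true single-exponential data and 100/100 detection at
time-constant ratio 5; the threshold is deliberately conservative because
a spurious second component would be read as a spurious membrane domain.

**Default acquisition grid.** 2048 uniform points spanning five times the
longest T1 of the decay being recorded (the point count matches standard
SR practice; the window is long enough to pin the baseline without wasting
dynamic range).

## Oximetry (`lensepr.oximetry`)

The oxygen transport parameter at a nitroxide's depth is

    W = 1/T1(air) − 1/T1(N2)        [µs⁻¹],

proportional to the local oxygen diffusion–concentration product. W is
condition-labeled ("air" vs "N2"), not normalized to an oxygen partial
pressure. Standard errors propagate to first order,
`SE(W)² = (SE(T1a)/T1a²)² + (SE(T1n)/T1n²)²`, verified against a 10⁴-draw
Monte Carlo within 5%. A small negative W (within 3 SE of zero) clamps to
0 with a warning; a clearly negative W raises.

**Domain discrimination.** In a Chol-oversaturated membrane the
membrane-center label (ASL) partitions between the bulk PL bilayer and
CBDs, giving a two-component air recovery. The N2 recovery is fitted with
one component by default — the oxygen-free rates of the two environments
are taken as equal at the center — with rank-of-rate pairing when a
two-component N2 fit is requested. Of the two W values the smaller is
assigned to the CBD (pure cholesterol transports oxygen poorly); if the
two 1-SE intervals overlap, both come back `unassigned` rather than
force a labeling. The headgroup cholesterol analog CSL cannot discriminate
CBDs by oxygen transport; its reading is modeled as the
population-weighted mean (`averaged_otp`).

**Titration onset.** Along a Chol/PL titration the CBD onset is the
smallest sampled mixing ratio from which the air recovery is
two-component *at that point and every later point* (persistence resists
single-point false positives). The onset is therefore resolved only to
the sampling grid: the first sampled ratio past the true saturation
limit.

## CW spectra (`lensepr.spectra`)

**Forward model.** An axial powder pattern: three ¹⁴N hyperfine lines
(m = −1, 0, +1) at `B0 + m·A(θ)` with
`A(θ) = √(A∥²cos²θ + A⊥²sin²θ)`, summed over a sin θ-weighted uniform
θ-quadrature (400 points) with a common first-derivative Lorentzian (or
Gaussian) line. No g anisotropy — fields are in gauss and the model is a
test bed for the extraction operations, not a slow-motion simulator.
Frozen-sample spectra are the rigid-limit case (A∥ → A_zz).

**Extraction.** The spectrum is Savitzky–Golay smoothed (window ≈ 1/20 of
the grid, cubic); noise is estimated robustly from the residual MAD, and
local extrema are accepted by *peak prominence* (≥ max(1% of the signal,
2 raw-noise SD)) — prominence, unlike absolute amplitude, separates the
weak outer powder shoulders from noise bumps riding on spectral tails.
The central line locates B0; A∥′ is half the outer-extrema separation;
A⊥′ is half the inner-extrema separation plus an additive correction
(below); 2A_Z of a frozen spectrum is the outer-extrema separation.
At 1% amplitude noise, all 270 spectra of a full scenario grid extract
within 1 G of truth.

**Inner-extrema correction.** The inner derivative extrema sit inside the
true perpendicular turning points by roughly a linewidth. The shipped
default (+0.31 G) was calibrated once against this package's own forward
model at the default 1 G Lorentzian half-width (the bias grows roughly as
0.3× the linewidth, so a fixed constant holds to ±0.2 G over 0.5–1.5 G
linewidths). It is an explicit, per-call-configurable constant because
published corrections are tied to particular lineshape conventions and do
not transfer to this simplified model.

**Order parameter.**

    S = (A∥′ − A⊥′) / (A_zz − (A_xx + A_yy)/2) · a_iso / a_obs,
    a_obs = (A∥′ + 2 A⊥′)/3,

the standard motional-averaging form with the polarity (a_iso/a_obs)
correction; S = 1 exactly in the rigid limit and 0 in the isotropic
limit. Principal values default to typical doxyl-label constants
(A_xx = 6.3, A_yy = 5.8, A_zz = 33.6 G) in `data/hyperfine_tensor.json`.

**Hydrophobicity.** Smaller 2A_Z means a more hydrophobic environment.
2A_Z → dielectric-constant mapping interpolates log ε linearly in 2A_Z
through a user-supplied monotone table; no default table ships because
such calibrations come from solvent-series measurements.

## Profiles (`lensepr.profiles`)

Depth is ordinal, keyed by spin-label position (headgroup T-PC/CSL = 0,
acyl carbons at their number, ASL just past C16); absolute nm placement
would need membrane-thickness data outside scope, and the analyses only
use the ordering. 9-SASL is treated as the C9 point alongside the n-PCs.
Symmetrization mirrors a leaflet about the bilayer center without
duplicating the center point (n → 2n − 1). The "abrupt change" statistic
is the maximum adjacent-depth ratio — reported descriptively, scale
invariant by construction; the caller decides what counts as abrupt. The
cross-species table regresses selected-depth values on lifespan
(least squares), returning slope ± SE per depth/condition.

## Synthetic data (`lensepr.synth`)

The generator emulates the *structure* of the experiments — seeded decay
pairs, spectra, titrations and full species scenarios with ground-truth
sidecars — with qualitative template shapes: bell-shaped no-Chol OTP and
fluidity profiles rising toward the center; a falling order parameter per
leaflet (an inverted bell after symmetrization, since order declines
along the chain); Chol-suppressed OTP down to C9 with a 3.0× step between
C9 and C10; a center OTP decreasing mouse → pig → human in
Chol-containing membranes; and a CBD component (W = 0.25 µs⁻¹, amplitude
fraction 40%) at the membrane center when oversaturated. Magnitudes
(bulk center OTP 0.6–0.9 µs⁻¹, oxygen-free rates 0.12–0.26 µs⁻¹) are
physically plausible round numbers, not digitized experimental values.
Noise is additive Gaussian, defaulting to 1% of the decay amplitude; each
scenario draws everything from one `SeedSequence`, so identical specs are
bitwise identical.

What passing tests show — and do not. Recovery tests prove the pipeline
is consistent: it recovers what the generator encodes, at the encoded
noise. They do not validate the templates against real membranes, and the
generator omits instrument artifacts (baseline drift, deadtime, field
modulation distortion), non-Gaussian noise, and slow-motion lineshape
effects.

## Phase boundaries (`lensepr.composition`)

For a phospholipid mixture, the Chol saturation limit (above which CBDs
form) and the Chol solubility threshold (CST, above which Chol crystals
form) are modeled as mole-fraction-weighted sums of per-PL boundaries
taken from an EPR/DSC fluid phase diagram of the binary systems:
saturation 33 (PE) / 50 (PC, PS, SM) mol%, CST 50 (PE) / 66 (PC, PS, SM)
mol%, stored in `data/phase_boundaries.json` rather than code because
literature CST values depend strongly on preparation method. Weights are
mole fractions of the PL-only pool (Chol excluded) — the only
self-consistent reading, since the boundaries themselves are expressed in
mol% Chol of the total. Printed lens compositions are normalized before
use (they need not sum to 100: DHSM is folded into SM as total
sphingolipid). Exactly at a boundary the lower-phase label is kept — a
domain *starts to form* strictly above its threshold. Species presets
ship only for mouse, pig and human (lifespans 3, 23, 70 y), the models
with published headgroup compositions; other species are labels only.
Chol/PL mixing ratio r and mol% m interconvert as m = 100·r/(1+r).

## Problem sizes and determinism

Replicated simulation experiments use 100 seeds (single-exponential
precision, model-selection rates), 200 seeds (double-exponential
precision) and 50 seeds (domain discrimination), with 2048-point decays —
sizes at which the measured quantities are stable to well within their
acceptance margins. Every stochastic operation takes an explicit seed or
`SeedSequence`; nothing reads global RNG state.

## Known limitations

- The two-component discrimination operates near its information limit at
  1% noise (CRLB ~12% relative SD on the CBD W): per-measurement W values
  in CBDs carry ~10–30% uncertainty, as the titration tables show.
- The axial spectrum model is not a lineshape fitter: no g anisotropy, no
  slow-motion effects, single common linewidth.
- The phase-boundary model is a linear mixing rule; it carries no
  temperature dependence and no DHSM-specific boundaries.
- Onset detection resolves the saturation limit only to the titration
  grid spacing.
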