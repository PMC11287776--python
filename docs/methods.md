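# Methods

## Ordinal symbolization

A real-valued series x_1..x_M is scanned with overlapping windows of D
samples whose elements are taken at stride τ (offsets 0, τ, …, (D−1)τ);
consecutive windows advance by one sample, giving n = M − (D−1)τ windows.
Each window maps to the permutation listing its element positions in
ascending value order; relative frequencies over the N = D! permutations
form the ordinal-pattern distribution P. Equal values are ranked by order
of appearance (a stable sort). This tie rule is a convention, not a theorem:
with continuous-valued signals ties are measure-zero, and the stable rule
makes results deterministic and matches the dominant implementation
practice. Probabilities are materialized densely over all D! patterns
because the disequilibrium term needs unobserved patterns (p_j = 0)
explicitly. A warning (not an error) is raised when n < 100·D!, where
pattern statistics degrade.

## Quantifiers

For order q > 0 (natural logarithms):

- S_q = (1/(1−q)) ln Σ_j p_j^q, with the Shannon limit −Σ p_j ln p_j
  dispatched exactly when |q−1| < 1e−9.
- H_q = S_q / ln N ∈ [0,1]; ln N always uses the full pattern-space size.
- D_q, the Jensen–Rényi divergence between P and the uniform P_e through
  their even mixture m_j = (p_j + 1/N)/2, equals
  ½[R_q(P‖M) + R_q(P_e‖M)] where R_q is the order-q Rényi divergence.
  The mixture keeps every term ≥ 1/(2N), so no singularities arise for any
  q > 0; 0^q ≡ 0 and 0·ln 0 ≡ 0.
- D_q* is the closed-form maximum of D_q over the simplex, attained by a
  delta distribution; the implementation verifies this identity to machine
  precision (delta input reproduces the closed form exactly).
- C_q = D_q·H_q / D_q*.

The Shannon-case (MPR) complexity C = Q_0·J·H uses base-2 logarithms by
convention; Q_0 is the reciprocal of the Jensen–Shannon divergence between
a delta distribution and the uniform, so Q_0·J ∈ [0,1] with equality 1 at a
delta. H and C are invariant to the base choice, which is what makes the
q → 1 cross-check between the two formulations meaningful.

## Complexity frontiers

The admissible (H_q, C_q) region is bounded by extremal frontiers that
depend on (D, q). The maximal frontier is the upper envelope of the N−1
one-parameter families in which m−1 states carry probability 0, one state
carries p ∈ [0, 1/(N−m)], and the remaining N−m states share 1−p equally.
The minimal frontier is the lower envelope of the two-level families
{p/n × n states, (1−p)/(N−n) × (N−n) states} for n = 1..N−1,
p ∈ [n/N, 1]. At q = 1 the n = 1 member — the classical single-parameter
minimal family — is provably minimal and the envelope coincides with it.
Away from q = 1 the single family is no longer extremal: at q = 0.5 and
N = 720, observed ordinal distributions of correlated noise undercut it by
up to ~1e−2, while the two-level envelope remains a valid lower bound in
Monte-Carlo extremality checks (30,000 Dirichlet draws at N = 24, q = 0.5:
no undercut beyond 1e−5). Both frontiers are therefore validated by
Monte-Carlo oracles rather than taken on faith.

Every extremal-family member takes at most three distinct probability
values, so frontier evaluation works from (value, multiplicity) pairs; the
D = 6 (N = 720) frontiers cost milliseconds instead of materializing
720-dimensional vectors. Frontiers are scattered onto a uniform H grid
(running max/min per bin; default 1000–5000 bins depending on resolution)
and interpolated piecewise-linearly. Containment checks use a 5e−3 band:
this covers interpolation error and the residual near-extremality slack of
the family construction away from q = 1.

## Simulators

- **Power-law noise.** White Gaussian noise is Fourier transformed, each
  positive-frequency amplitude is scaled by f^(−k/2) so the *power*
  spectral density follows f^−k, the DC term is zeroed (exactly zero-mean
  output), and the inverse real FFT returns the series, normalized to unit
  SD by default. The amplitude exponent −k/2 is the convention that makes
  the PSD claim true and is verified end-to-end by the spectral-recovery
  oracle. An optional high-pass corner removes content below a cutoff (in
  Hz, given a sampling rate), emulating hardware filtering.
- **Maps.** Logistic x←rx(1−x) (default r = 4), Hénon x←1−ax²+y, y←bx
  (a = 1.4, b = 0.3; the x series is returned, the standard observable),
  Schuster x←(x+x^z) mod 1 (z ∈ {3/2, 2, 5/2}). All maps discard a
  1000-iteration burn-in (transient removal; unstated in the source
  protocols, chosen conservatively) and draw initial conditions from a
  seeded uniform distribution over the valid domain when not given.
- Every generator is a pure function of (parameters, seed) and
  bit-reproducible.

## Synthetic atlas

The generator emulates the structure of the open iEEG atlas this pipeline
targets: channels at 200 samples/s zero-padded to 13,600 samples (68 s;
60 s of valid signal), grouped by region × state (W/N2/N3/R) × sex, with
per-patient ages and left-hemisphere labels. Each channel is

  f^−k background + state-specific narrowband oscillations + white noise,

with per-state baseline exponents k = 2.0 (W), 2.5 (N2), 3.0 (N3), 2.2 (R)
— in the range reported for intracranial recordings in the 10–40 Hz band,
steepening with sleep depth — plus per-channel exponent jitter of SD 0.1
(patient heterogeneity), a 0.5 Hz high-pass on the background, and a white
measurement floor at 2% of signal SD. Oscillations are frequency-domain
Gaussian bumps (SD 0.5 Hz): pure sinusoids would put a line with filter
skirts at the edge of the spectral-fit band and wreck linear-scale fits in
a way real, broadband neural oscillations do not. Defaults: alpha 8.5 Hz
(W), spindle 13 Hz + slow 1.2 Hz (N2), slow waves 0.8 Hz (N3), theta 6 Hz
(R), with amplitudes 0.15–0.5 of background SD. Sex differences are planted
as exponent offsets Δk per (region, state) on male channels.

What the generator does **not** emulate: epileptiform or artifactual
transients, line noise, non-stationary state transitions, spatial
correlation between neighboring channels, electrode-type differences, and
1/f "knees". Passing pipeline tests therefore demonstrate the machinery —
cohort selection, quantifier computation, flag logic, calibration and
power — under clean scale-free conditions, not clinical performance on
real recordings.

## Characteristic time, stationarity, Rényi order

The autocorrelation is computed on the demeaned signal via FFT and
normalized to R(0) = 1. The characteristic time of a channel is the mean
spacing of the strict local maxima of R over lags 1..M/2 (no prominence
filtering — the short "sawtooth" spacing is exactly what is wanted; lag 0
is never a peak); channels with fewer than two peaks are excluded and
counted. Group τ_s averages per-channel spacings and is converted to
seconds by the sampling rate when known. Because the Bandt–Pompe delay must
be an integer, the pipeline rounds τ_s to the nearest integer ≥ 1 and
records both values. The ADF screen uses AIC lag selection and calls a
channel stationary iff p < α (strict, α = 0.05); constant channels are
flagged degenerate. Screened-but-nonstationary channels are retained by
default (a strict mode drops them). q_max is the grid argmax of the
channel-averaged C_q on the 0.1..7 (step 0.01) grid, computed at τ = 1,
ties broken toward smaller q. On the synthetic atlas, the steep-background
states (N2/N3) produce interior maxima near q ≈ 0.9–1.1; shallow states
can ride to the grid edge — the location is a data property, not a
constant of the method.

## Spectral analysis

Welch PSD: 2-s blocks, 1-s step, Hamming taper, density normalized to unit
total power (amplitude-free). A 60-s channel yields 59 blocks. The
aperiodic exponent is fitted as A·f^−k over 10–40 Hz by nonlinear least
squares on the linear scale, initialized from the log–log regression; R² is
reported on the linear scale, and the fit space is recorded so the log–log
alternative can be compared. Caveat established during validation: the
Hamming/constant-detrend combination has a flat ~−43 dB sidelobe floor, so
for pure power-law inputs with k ≳ 3 low-frequency leakage floods the fit
band and the estimated slope saturates. The estimator therefore accepts
window/detrend overrides, and slope-recovery studies use a Hann taper with
linear detrending (sidelobes decay fast enough to track k up to 5 within a
few percent). The pipeline keeps the protocol defaults, which are adequate
for high-passed, oscillation-bearing signals.

Group difference in exponents: boxplot notches, median ± 1.57·IQR/√n, flag
1 iff the two intervals are disjoint (shared endpoints count as overlap).
The notch is an asymptotic 95% CI of the median and is anti-conservative
for very small n (measured ~13% false-positive rate at n = 5, ~4% at
n = 10); group sizes of ten (5 patients × 2 channels) restore the nominal
level.

## Curve separation

The space stacks per-channel (q, H_q, C_q) curves over a common grid with
frontiers attached at the materialized q planes (default {0.5, 0.7, 1, 1.4,
2, 3, 4, 5, 6, 7}). Because visual judgements of group separation are not
reproducible, the pipeline uses an explicit rule: at each q, groups are
separated iff (ΔH)²/(s_H^A+s_H^B)² + (ΔC)²/(s_C^A+s_C^B)² > 1 — disjoint
axis-aligned 1-SD ellipses, a conservative sufficient condition — and a
cell is flagged iff a contiguous separated run spans ≥ 0.5 in q inside the
inspection window (default [1, 7], where the frontier volume is widest).
The SD multiplier and run length are parameters. The primary 3-D
separation metric between two curves is the minimum Euclidean (H, C)
distance at matched q — q is the shared parameter, not a coordinate to mix
with differently scaled axes; the 2-D projected minimum over all q pairs is
reported alongside, and is necessarily ≤ the matched-q value, which is how
projection overlap is quantified.

## Pipeline

Channels load from a TSV/CSV manifest (signals as CSV/TSV columns or EDF
channels through mne), are cleaned of undefined entries, and have trailing
zero-padding trimmed (analyzing padding would inject spurious ascending
patterns); every cleaning action is logged per channel. Cohorts: per
region × state, exactly five patients per sex chosen to minimize
|mean-age gap| with |SD gap| as tiebreak — exhaustively over all C(pool,5)²
pairs when both pools hold ≤ 12 patients, otherwise by greedy swap descent
from the age-sorted middle. Regions failing the ≥ 5-per-sex rule are
excluded with a reason, never raised. Selection reads only metadata.
Per cell the pipeline computes the ADF screen, per-channel spectral fits
with the notch flag, and per-channel curves at τ = 1 and τ = round(τ_s)
with sex-group statistics and ellipse flags; failures are isolated per
cell and recorded as missing. The output table carries one row per
region × state with the three binary flags plus cohort sizes and the τ_s
used, and the report counts co-occurrence of the exponent flag with each
τ flag.

## Problem sizes used in tests and validation

The validation suite runs simulated series of M = 10,000 (reference
systems, exponent recovery at 20 seeds per k), a null synthetic atlas of
3 regions × 4 states × 12 patients × 2 channels, a 20-replicate planted
atlas (2 regions × 1 state, Δk = 1, spectral analysis path), and a
0.05-step q grid for pipeline ellipse flags (the default 0.01 grid is used
everywhere quantifiers are the object of study). Frontier resolutions of
2,000–10,000 points per family member leave interpolation error well below
the 5e−3 containment band.

## Known limitations

- The minimal-complexity frontier away from q = 1 is an envelope over a
  restricted (two-level) family class, validated by Monte Carlo, not a
  proven extremum.
- The ellipse rule is a stand-in for visual separation judgements; its
  thresholds (1 SD, 0.5-q run) are conventions, exposed as parameters.
- Real-data characteristic times and complexity-maximizing orders depend
  on recording properties the synthetic atlas does not model; numbers
  obtained on synthetic fixtures are demonstrations of the machinery.
- EDF signals are 16-bit quantized at the source; ordinal patterns of
  near-tied samples can differ from a float CSV of the same signal at the
  level of a fraction of a percent of windows.
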