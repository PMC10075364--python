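# Methods

This note documents the models, estimators and numerical choices behind
`hippolfp`, what the synthetic-session generator does and does not
emulate, and the design decisions taken where several defensible options
existed.

## Behavioral-state segmentation

States are a pure function of per-frame speed
`‖pos[i] − pos[i−1]‖ · frame_rate` (frame 0 copies frame 1 so the first
label is defined): exploration above 0.05 m/s, grooming in (0, 0.05]
m/s, wake immobility at "zero". Literal zero speed is numerically
fragile with real trackers, so immobility means speed ≤ `zero_tol`
(default 1e−3 m/s, configurable). Maximal same-label runs become
half-open `[start, end)` epochs; grooming epochs and epochs shorter than
1 s are removed, and removed material leaves gaps — neighbors are never
merged across it. No hysteresis is applied beyond the 1-s minimum.

Camera-to-LFP alignment fits `t_lfp = a·t_cam + b` through the matched
TTL pulses (one pulse: pure offset; two or more: offset plus drift by
least squares). Sample indices are 0-based and half-open everywhere.

Open-field metrics use a centered square inner zone whose side is
`inner_fraction` (default 0.5) of the arena side — a conventional
open-field-test geometry; entries count outside→inside transitions, and
each displacement is attributed to its destination frame. Trials are
windowed into 5-min segments; a trailing partial window is kept and
flagged rather than dropped.

## Spectral analysis

Welch PSDs use 1-s Hann windows with 50 % overlap, constant detrend
(removes DC without touching the 0.4 Hz delta edge), density scaling.
Epochs of one state are pooled with equal weight per Welch segment, so
long epochs contribute proportionally more segments. Band power is the
rectangle-rule integral over half-open `[lo, hi)` bands; normalized
power divides by total 0.5–250 Hz power, making every reported fraction
invariant to amplitude rescaling (verified exactly in tests). The
"three channels with the highest power" summary ranks channels per band
pooled across states, so the same channel set enters the within-subject
state comparison. Full-pipeline spectral and PAC analyses run at
1200 Hz after polyphase anti-aliased decimation, which keeps the 250 Hz
band edge valid and matches the ripple-detection rate.

## Phase–amplitude coupling

The MI is the envelope-normalized mean vector length
`|Σ A·e^{iφ}| / Σ A` — bounded in [0, 1], invariant to rescaling either
signal, equal to ½ for a sinusoidally modulated envelope in the
continuous limit. This normalized MVL was chosen over the binned
Kullback–Leibler index as the primary estimator because between-group
comparisons require amplitude independence; an 18-bin KL index is
provided as a cross-check (`pac.kl_mi`) and must agree on orderings.

Filtering is zero-phase (forward–backward) 4th-order Butterworth in
second-order sections. Because filtfilt squares the magnitude response,
the −3 dB corners of a filter designed at the nominal edges would land
inside the passband; the design corners are therefore calibrated
iteratively so the measured two-pass −3 dB points fall on the requested
edges (cached per band). Comodulogram phase bins are 1-Hz-centered with
2 Hz width; each amplitude filter's width is 3× the phase frequency of
the pair. A 2× width would place the modulation sidebands (f_amp ±
f_phase) exactly on the corners and halve the measured coupling,
displacing the comodulogram peak — 3× keeps the sidebands inside the
passband. Half a filter transient (two cycles of the phase band's low
edge) is discarded at each epoch boundary before MI computation; tPAC
filters the whole epoch once, then cuts the interior into 1-s
non-overlapping windows (remainder discarded). A 1-s window at 6.5 Hz
holds only ~7 cycles, so single-window MI estimates are noisy; subject
means average across windows.

Significance uses circular time-shifts of the envelope (≥ 1 s, 200
surrogates). A caveat the synthetic fixtures expose: if the slow rhythm
is strictly periodic, a time shift merely rotates the mean vector and
the null collapses onto the observed MI. Real theta wanders in
frequency, which is what makes shift surrogates destructive; the
generator therefore supports `freq_jitter_hz` (slow Gaussian
instantaneous-frequency excursions), and surrogate-based claims should
only be made on signals with non-degenerate phase progression.

## Sharp wave–ripple detection

The ripple chain: band-pass 120–250 Hz, decimate to 1200 Hz, segment by
behavioral epoch, z-score per segment, rectify, smooth with a centered
8-ms boxcar. The band-pass is an 8th-order Butterworth applied
forward–backward in second-order sections; a literal 400th-order IIR is
numerically unrealizable, and the SOS cascade reproduces the corner
frequencies with zero phase. Thresholds are `mean + k·SD` of each
segment's own power signal (core k = 3, edge k = 2): maximal runs above
the edge threshold containing at least one sample above the core become
candidates (maximal runs are disjoint, which realizes merge-on-touch),
then duration (≥ 30 ms) and peak-spectral-frequency (≥ 140 Hz, from a
periodogram zero-padded to ≥ 1 Hz resolution over 120–250 Hz) filters
apply. Constant or in-band-silent segments are flagged degenerate
rather than z-scored (z-scoring numerical filter residue would
manufacture noise).

Sharp waves: band-pass 0.5–40 Hz, threshold `mean + 2.5·SD` applied to
the magnitude of the filtered signal — polarity-agnostic, since
electrode referencing can flip the conventionally negative radiatum
deflection — and a 20–400 ms duration window. Note that the 0.5 Hz
high-pass (τ ≈ 0.3 s) relaxes any long plateau, so threshold crossings
physically cannot much exceed ~350 ms with this band; the 400 ms cap
only binds for slower high-pass corners, and is tested that way.
Co-occurrence is plain interval overlap (half-open), with no tolerance
window. Ripples come from a single configured pyramidal-layer channel
and sharp waves from a single radiatum channel. Slow-gamma event
features (default band 30–45 Hz; a 25–55 Hz variant is a config option)
extend sub-100-ms windows symmetrically, because a 30 ms window cannot
resolve a 15-Hz-wide band. The occurrence ratio is
`(events/s in exploration) / (events/s in immobility)`, with zero
immobility events reported as +inf and zero state duration an error.

## Statistical layer

Outliers are masked per genotype × state × trial cell: rows are
projected onto the principal components explaining ≥ 95 % of variance,
each row's Hotelling T² is compared with the F-form 95 % bound
`k(n−1)/(n−k) · F_{k,n−k,0.95}`, and the inclusion mask is returned,
never silently applied. Singular covariance falls back to a univariate
z rule with a warning.

Mixed models are REML random-intercept fits (statsmodels MixedLM) with
treatment coding and WT / exploration / trial-1 reference levels; this
package owns the design-matrix construction and effect extraction, the
optimizer is delegated. The random-intercept variance often sits on the
zero boundary in small balanced designs, where the default L-BFGS can
fail — the fit falls back through BFGS/Powell/CG and flags
non-convergence instead of raising. p-values are the fitting machinery's
Wald-z defaults (recorded in the result metadata). The two-factor
(genotype × trial) analyses drop a non-significant (p ≥ 0.05)
interaction and refit on main effects, as per the pre-registered
analysis plan of the study design this mirrors. Post hocs are Welch t
tests on subject-level values (robust to unequal variances at n = 5 per
group) within one measure family; Benjamini–Hochberg q-values come from
the step-up rule, with the family defined per measure, not across all
measures.

The null false-positive rate of the full gated path (LMM genotype term
significant AND ≥ 1 BH-surviving post hoc) is verified by simulation at
the study's cohort geometry — 5 subjects per genotype, 2 states × 2
trials, subject SD = residual SD — and sits well under α because the
gate intersects two ~α-level events.

## Synthetic sessions: what they emulate, and what they do not

Each channel carries independent Gaussian 1/f^α background (α = 1
default) built by frequency-domain shaping. Below a 3 Hz floor the
spectrum rolls off like a second-order high-pass rather than diverging:
recorded LFP is high-passed by the acquisition chain, and an unbounded
power law would hide a large fraction of the variance below the
resolution of any 1-s spectral window, making variance-based checks
meaningless. Theta is a state-gated cosine; gamma's envelope is
`A(t) = a_γ·[1 − d + d·(1 + cos φ_θ)/2]` with per-state depth d — so
d = 0 gives a constant envelope, d = 1 an envelope that touches zero,
and the envelope peak-to-trough ratio is `1/(1−d)`. The pyramidal
channel carries full-amplitude rhythms plus ripple bursts, the radiatum
channel attenuated theta plus sharp waves, remaining channels attenuated
rhythms only.

SWR events are Poisson per state bout at the configured rate, resampled
on collision so ground-truth intervals never overlap. The ripple burst
is a Tukey-windowed (taper fraction 0.15) sinusoid: the flat
plateau makes the detector's supra-threshold extent track the injected
duration, so duration-bias measurements are meaningful; a full-cosine
(Hann) envelope is available via `taper=1.0` but biases detected
durations short by construction, since the dual-threshold crossing sits
at ~40 % of the peak envelope. The sharp wave is a fast (~8 ms) ramp
into a Gaussian decay sized by `sw_width_ms` (FWHM convention). The
detector benchmark defines SNR against the event peak *as seen through
the detection band* (each waveform is calibrated by its own filter
gain); ripple amplitude defaults to 5× the in-band background SD, and
sharp waves to 8× — radiatum sharp waves stand far above the slow
background in vivo, and marginal-amplitude deflections fragment on the
20 ms minimum-duration rule, which would measure noise robustness
rather than detector correctness.

Tracking is a heading-random-walk whose step into frame i carries frame
i's state speed exactly (exploration 0.15 m/s, grooming 0.02 m/s,
immobility 0), with wall reflections preserving step length — so a
speed classifier can recover the schedule frame-perfectly, and any
disagreement is a pipeline defect, not generator noise.

Not emulated: spiking, compartmental biophysics, sleep states,
electrode drift, movement artifacts, inter-channel correlated noise,
and theta harmonics. Passing tests therefore demonstrate correctness of
the estimators and detectors under the stated signal model, not
robustness to every pathology of in-vivo recordings.

## Problem sizes and defaults

Synthetic sessions default to 2500 Hz sampling (the generator supports
25 kHz; 2500 Hz keeps every Nyquist requirement of the 120–250 Hz
ripple band with margin). Validation runs use: 10-s fixtures for the
MI depth sweep (30 s for the closed form), 12-s fixtures for
comodulograms, a 600-s benchmark with 100 joint + 40 distractor events
for the SWR detector, 10 min per state for occurrence-ratio recovery,
and 500 replicates for the null false-positive simulation. The demo
pipeline configuration is a 64-s, 4-channel session.
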