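# Methods

This note documents the models, conventions and numerical choices behind
`crosswave`, and what the synthetic validation does and does not establish.

## Signal model and preprocessing

The object of analysis is the *tremor signal*: surface EMG of the wrist
flexor and extensor occupies roughly 60–240 Hz and is amplitude-modulated at
the tremor frequency, so the Hilbert envelope of the band-passed EMG is the
tremor waveform.  The pipeline (`preprocess`) applies, per channel:

1. IIR notch filters at 50, 100, 150, 200 Hz (mains and harmonics), quality
   factor Q = 30 by default — the notch width is a free choice, exposed as
   `notch_q`;
2. an 8th-order Butterworth band-pass 60–240 Hz applied forward and then in
   reverse (`sosfiltfilt`): zero phase lag, effective attenuation doubled.
   "8th order" is the one-pass design order.  All IIR filters run as
   second-order sections: an 8th-order band-pass in transfer-function form is
   numerically unreliable.  A design whose sections have poles on or outside
   the unit circle, or whose output is non-finite, raises instead of
   returning garbage; the diagram sweep marks such bands undefined rather
   than aborting;
3. the Hilbert envelope |hilbert(x)|;
4. decimation by 4 (500 → 125 Hz) preceded by an anti-alias low-pass
   (8th-order Butterworth at 0.8 × the new Nyquist, zero-phase).  Tiny
   negative excursions the low-pass leaves on the envelope are clipped to 0.

Filter and Hilbert edge effects are handled by exclusion: averaging
operations drop a configurable edge fraction (default 5% per side), and the
wavelet analysis flags a cone of influence (below).

## Phase conventions

Phase is computed as the four-quadrant angle of the analytic signal.  Two
decisions are exposed rather than hidden because they change results for
alternating tremor:

* **Difference.** The default `as_printed` mode is the literal vector
  subtraction angle(e^{iΨ₁} − e^{iΨ₂}).  Note this is *not* the offset
  Ψ₁ − Ψ₂: for a constant true offset φ it evaluates to Ψ₁ + (π + φ)/2 and
  rotates with Ψ₁.  The `quotient` mode angle(e^{i(Ψ₁−Ψ₂)}) returns the
  constant offset and is what all parameter-recovery tests use.  Neither is
  silently substituted for the other.
* **Averaging.** `arithmetic` (default) is the plain mean of the wrapped
  angles; it is discontinuous at ±π, which matters when a cohort's offsets
  straddle the antiphase boundary.  `circular` is the angle of the mean unit
  vector; an exact antipodal tie (zero-length mean vector) deterministically
  returns +π.
* **Orientation.** Package-wide, positive phase ⟺ the flexor leads the
  extensor: ΔΨ = Ψ_flexor − Ψ_extensor and the cross-wavelet spectrum is
  W_x·W_y* with x = flexor.  The synthetic generator plants `phase_offset`
  in this same convention, so planted offsets are recovered with their sign
  by both routes.
* angle(0) (all-zero signal, or coincident phases in `as_printed` mode)
  returns 0 with a degenerate-signal warning.

## Cross-wavelet spectra

The analyzing wavelet is the complex Morlet
M(t) = (πF_b)^{-1/2} e^{2πiF_c t} e^{−t²/F_b} with F_b = F_c = 1.  Scales map
to pseudo-frequencies by f = F_c/(s·Δt).  The transform is evaluated per
scale by FFT multiplication with the wavelet's closed-form frequency
response H(f) = exp(−π²F_bF_c²(f/f_c − 1)²), zero-padded past the widest
wavelet support (5√F_b e-folding widths) to suppress circular wrap-around,
in blocks of 64 scales to bound memory.

Normalization is L1: a cosine of amplitude A yields ridge magnitude A/2 at
any analysis frequency, so cross-wavelet power is comparable across scales.
Reported PSD values are therefore in this implementation's cross-wavelet
power units; they are not calibrated against any external spectral unit, and
numeric PSD ranges quoted from other instruments should be treated as
order-of-magnitude presets only.

The cone of influence flags, per frequency row, samples within one e-folding
width of the wavelet envelope (√F_b·F_c·fs/f samples) of either record edge;
flagged cells are excluded from train detection by default.

The cross spectrum is assembled with explicit real arithmetic
(re = x_r y_r + x_i y_i, im = x_i y_r − x_r y_i) so that swapping the
channels conjugates the matrix bit-exactly — the Hermitian-swap symmetry is
testable with exact equality.

## Cross-wave trains

A cross-wave train is a strict 8-neighborhood local maximum of |W_xy| in the
(frequency × time) matrix, measured by:

* duration: the contiguous run of |W| ≥ ½·peak along the peak's frequency
  row, in seconds, and × central frequency in periods;
* bandwidth: the contiguous half-power run along the peak's time column, in
  Hz (one grid step is added so a single-row extent has nonzero width);
* PSD and phase: |W| and angle(W) at the peak.

The half-power fraction (default 0.5) is a convention knob.  Detection is
threshold-free — the count is invariant to a global amplitude rescaling of
both channels — except for a relative floor (10⁻⁶ × the global maximum) that
discards numerical-noise maxima of an exactly-zero background without
breaking that invariance.  Overlapping maxima (each within the other's
half-power time × frequency box) are deduplicated, keeping the stronger:
one physical burst yields one train.  Matrix borders cannot host a strict
interior maximum and are excluded.

## AUC diagrams and statistics

Every diagram cell compares a per-subject scalar between the positive (PD)
and negative (ET) cohorts by the ROC area, computed via midranks; ties
contribute ½.  Orientation is fixed: AUC > 0.5 ⟺ the score tends larger in
PD; rendered diagrams anchor the jet colormap to [0, 1] (blue → 0,
green 0.5, red → 1).  The per-subject score for train diagrams is the train
*rate* (count / recording duration), normalizing for recording length.
Cohort-swap complement symmetry (AUC ↦ 1 − AUC) is exact on the underlying
rational pair-counts; the stored floats agree to one unit in the last place
(a division rounds once in each orientation).

The phase diagram is two-triangle because phase is cyclic: the upper
triangle (ordinate > abscissa) counts trains with phase inside
[abscissa, ordinate]; the lower triangle counts all trains *except* those in
the cyclic range [ordinate, abscissa] — the complement ranges that wrap
through ±π, which a single triangle cannot express.  The default phase grid
step is π/20 (a resolution choice).

Mann-Whitney p-values are exact for tie-free samples with combined n ≤ 20,
otherwise the normal approximation with tie and continuity correction
(scipy).  No multiple-testing correction is applied anywhere: diagram cells
are exploratory and heavily correlated; any cell selected by inspection
needs confirmation on independent data.

## Filter fitting

`fit_train_filter` is greedy coordinate descent on the ten bounds of the
five attribute ranges, in the fixed sweep order frequency.lo, frequency.hi,
psd.lo, psd.hi, duration.lo, duration.hi, bandwidth.lo, bandwidth.hi,
phase.lo, phase.hi; each proposal moves one bound one grid step and is
accepted iff it increases |AUC − 0.5| (an exact tie prefers the wider range,
biasing against overfit filters).  Attribute grids default to 25 evenly
spaced values spanning the pooled data.  The search is deterministic,
terminates when a full sweep accepts nothing (or after `max_sweeps` = 50),
and its accepted-objective trace is non-decreasing by construction.  It is a
local search: it sharpens a seed region (e.g. an extreme diagram cell) and
may converge to either the PD-typical (AUC → 1) or ET-typical (AUC → 0)
optimum; the reported AUC is in-sample, with no cross-validation.

## Synthetic data: what it emulates, what it does not

`synthetic` generates 90 s envelope-domain pairs at 125 Hz: folded-Gaussian
baseline noise plus raised-cosine (Hann) bursts at Poisson onsets with
non-overlap rejection, each burst a sinusoid at the component frequency with
the configured inter-channel offset; components with offset ±π draw the sign
per subject (the antiphase boundary has no preferred side).  The `pd_like`
preset plants an alternating 4–6 Hz component (0.5 bursts/s, amplitude 20 μV
over a 1 μV noise floor — rates and amplitudes chosen so the planted kind
separates the cohorts nearly perfectly, as the clearly separable clinical
groups this emulates do) plus a weaker synchronous 8–18 Hz component;
`et_like` plants 2.2–3.9 Hz and 10–37 Hz components with unconstrained
offsets.  Raw-EMG mode modulates a band-limited 60–240 Hz noise carrier with
the tremor waveform and adds 50 Hz line interference, exercising the full
preprocessing chain.

What passing tests show: the implementation recovers planted frequencies,
phases, rates and group differences through the complete pipeline, and its
structural invariants hold.  What they do not show: performance on real EMG
— real recordings contain movement artifacts, nonstationary noise,
inter-subject amplitude variation over orders of magnitude, and burst shapes
that are not raised cosines; no motor-unit physiology is simulated, and
amplitude distributions are not matched to any clinical population.

## Numerical sizes used in validation

The test suite and the acceptance script run cohorts of 10 + 10 subjects,
90 s each, with a 0.5 Hz cross-wavelet grid over 2–48 Hz and 2 Hz diagram
cells; single-burst recovery uses a 0.1 Hz grid.  These sizes are the
package's validation defaults; finer grids (the 0.1 Hz diagram step) are
configuration options of the same functions.
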