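# Methods

This note records the models implemented in `synastro`, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions a maintainer would want
to know about.

## Synthetic-event traces (`synthio.gen_event_trace`)

Spontaneous/miniature synaptic currents are modelled as a homogeneous
Poisson process: the event count over a recording of duration *T* is
drawn Poisson(λT) and onsets are uniform on [0, T). Each event is a
difference-of-exponentials kernel

    k(t) = exp(−t/τ_decay) − exp(−t/τ_rise),

normalized to unit peak and scaled by an amplitude drawn
Normal(µ_A, σ_A) (magnitudes floored at 0.5 pA), signed by the polarity
(−1 = inward). Defaults τ_rise = 1.5 ms, τ_decay = 8 ms are a plausible
CA1 EPSC scale; the recordings this emulates report event kinetics but
not kernel constants, so these are stand-ins, not reconstructions.
Noise is white Gaussian on a constant holding current. Real recordings
additionally carry 1/f and line components, filter ringing, and
series-resistance filtering of fast events; none of these are modelled,
so detector performance on these phantoms bounds, but does not
guarantee, performance on real data. Sampling rate defaults to 10 kHz,
typical for this recording configuration.

The truth record carries every generated event, including those below
the analysis floor, so sensitivity/false-positive bookkeeping against
truth is exact.

## Event detection (`ephys_events`)

Detection follows the scaled-template (Clements–Bekkers-style) scheme:
for a template *w* of length *L*, at every offset the least-squares fit
`y ≈ a·w + b` is solved in closed form (running sums via FFT
convolution), and the detection statistic is `a / SE(a)` with
`SE(a) = s·(Σw² − (Σw)²/L)^(−1/2)`, `s²` the residual variance on
`L − 2` degrees of freedom. Candidates are local maxima of the
statistic above the **criterion 3.0** (the conventional setting for
this detector family; the source workflow names template fitting but
no criterion). Fitted amplitudes in (0, 10) pA are discarded — the
10 pA floor is part of the measurement definition, applied to the
magnitude with inward currents negative.

**Overlap resolution.** Accepted candidates exclude further candidates
within a window equal to the template's onset-to-peak span plus the
span over which it decays to 1/e of peak (~11 ms for the default
kernel), resolved greedily by fit score. A rise-time-only refractory
was measured to admit duplicate detections 5–7 ms after each true event
(criterion side-lobes on the decay tail, ~50 % excess detections at
control-like conditions); the template-derived window removes these at
a coincidence cost below 2 % at the event rates of interest. True event
pairs closer than this window are reported as one event.

**Template construction** collects candidates by a coarse robust
threshold pass (4 robust SD of the polarity-corrected signal), averages
the 10–20 largest after local baseline subtraction and peak alignment,
then runs one refinement pass: re-detection with the first-pass
template, re-alignment on the *fitted onset* (far less noise-sensitive
than per-event sample maxima), an amplitude floor at half the median
first-pass amplitude (keeps tail-remnant fits out of the average), and
re-averaging. Fewer than 10 candidates is a hard error. With noisy
probe recordings the normalization of the averaged waveform by its
noisy peak leaves a small (~2–5 %) multiplicative uncertainty on
amplitudes fitted with that template; templates built from known
kinetics carry no such scale error, and are what the recovery analyses
use.

**Per-event kinetics.** Rise time is 10–90 %, from the last upward
level crossings before the peak (robust to baseline noise blips);
decay τ is a log-linear single-exponential fit from the 90 % to the
10 % level after the peak — starting at 90 % rather than the peak
because the residual rise component of a biexponential flattens the
first fraction of a millisecond and would bias τ upward by ~4 %.
Rise-time estimates under realistic noise remain noisy for small
events; they are reported as means over the analysis window, not as
per-event precision measurements.

The interactive review step of the source workflow is replaced by a
machine-readable accept/reject audit table (`return_audit=True`).

Resting membrane potential is the window mean after masking samples
more than 20 mV above the median (action-potential excursions). The
access-resistance gate passes a recording iff (max − min)/first < 30 %.

## Tonic current (`tonic`)

The tonic GABA current is the difference of two 60-s mean holding
currents: the last minute before drug onset and the earliest
post-onset minute whose drift passes a stability test. Window length
is contractual — anything other than 60 s is refused. The drift
estimate is the larger in magnitude of (a) the Theil–Sen slope and
(b) the difference of half-window means divided by the half-span, on a
10 Hz block-averaged copy. The second estimator matters: for a
first-order wash-in the pairwise-median slope systematically
understates the convex tail and will declare stability while the level
is still moving. For an exponential approach, the residual bias left
in the earliest accepted window is ≈ 24× the slope tolerance
(independent of shift size), while the wait for stability grows only
logarithmically in shift/tolerance — hence the small default tolerance
of **0.01 pA/s** (≈ 0.25 pA residual bias), reachable within a 5-min
recording for shifts up to several hundred pA at wash-in constants of
tens of seconds. Whether the original analysis excluded phasic events
from the window means is unstated; the default includes every sample,
with an optional percentile-trimmed mean (`trim_percent`).

Sign convention: blocking an inhibitory tonic conductance shifts the
holding current positive, so a genuine tonic GABA current is positive.

## fEPSP and LTP (`fepsp`)

Slope is a linear least-squares fit between the 10 % and 70 %
crossings of the peak amplitude, measured from the post-artifact local
baseline to the (negative-going) peak, on a sweep lightly smoothed
with a 3-sample moving average for threshold crossing only (the fit
uses raw samples). The peak is searched 2–20 ms post-stimulus behind a
1-ms artifact blank; a sweep whose deflection does not exceed 4× the
pre-stimulus noise SD is flagged invalid. Whether "peak amplitude" is
referenced to the pre-stimulus or post-artifact baseline is ambiguous
in the source description; the post-artifact local baseline is the
default here.

Normalization divides every slope by the mean of the last 10 min of
baseline sweeps (3 sweeps/min at the 0.05 Hz evoked rate) and averages
per minute, bins aligned to the induction (minute 0 starts at the
tetanus). Window summaries at 0–5 and 55–60 min are means of the
per-minute values.

The generator's potentiation profile holds the early factor through
the first 5 min, then relaxes exponentially toward the late factor,
completing the transition by 55 min. The plateaus are deliberate: the
two measurement windows then sample exactly the early and late factors,
so noiseless recovery is exact to machine precision and the factors
are interpretable as the window means they generate. Sweep-to-sweep
variability is multiplicative Gaussian with coefficient of variation
`noise_cv` (mean-unbiased).

The theta-burst protocol object encodes 10 bursts of 4 pulses at
100 Hz separated by 200 ms (40 pulses, first at t = 0).

## Astrocyte morphometry (`morph`)

Phantoms are rendered as soft-edged capsules (default process radius
0.5 µm) along known skeleton polylines plus a soma sphere, with a
Gaussian DAPI nucleus and Cx43 puncta scattered uniformly and
concentrated where two cells' masks touch. Rendering is at
"post-deconvolution" quality — noise but no PSF blur — so segmentation
scores on phantoms are upper bounds for raw confocal data;
deconvolution is assumed upstream.

The trained interactive pixel classifier of the source workflow is
replaced by a deterministic rule: subtract a 10-µm Gaussian
background, threshold at half the robust maximum (99.9th percentile)
of the residual — the half-maximum boundary of the stained structures —
floored at 3 robust SD so pure noise never passes, then remove objects
under 27 voxels. The manual Cx43-guided separation of the syncytium is
replaced by a nucleus-seeded watershed on the negated distance
transform with smoothed Cx43 puncta density added as elevation, so
basins close preferentially at gap-junction-rich contact zones. These
are documented substitutions chosen for reproducibility, not
reconstructions of the original tools.

Sholl profiles use 20 radii (7, 9, …, 45 µm) around the nucleus
centroid; at each radius the count is the number of 26-connected
components of the cell mask within a spherical shell one voxel
diagonal thick, with distances computed in physical units (anisotropy
respected). The source description does not say whether intersections
were counted in 2-D projections or 3-D; this implementation counts in
3-D and records the choice. The independent oracle used in tests
counts sphere crossings of the generating skeleton analytically;
rendered-mask counts match it except within one shell of a
bifurcation, where tube thickness merges components.

Convex-hull volume is the Qhull volume of foreground voxel centers in
µm³ (degenerate masks — under 4 points or coplanar — return 0 with a
flag). Any label with a voxel on any face of the stack is excluded as
truncated. The vimentin path maximum-projects along z, thresholds
(Otsu if unspecified), and sums thresholded intensity over connected
ROIs within size bounds (default 10–1000 projected px²) and
eccentricity < 0.98; the bounds are stated defaults, since the source
names a vessel-excluding size filter without numbers.

## Emotionality z-score (`behavior`)

Per parameter, `z = direction · (X − µ_c)/σ_c` with control-group mean
and *sample* SD (ddof = 1; the SD convention is not stated at the
source and n−1 is the conservative default). Direction codes make
larger always mean more emotionality. Parameter scores average into a
test score, test scores into the individual emotionality score, so
tests weigh equally regardless of parameter count; missing parameters
are dropped from averages, never imputed. Locomotion-confounded open
field and plus-maze parameters can be divided by travelled distance
before scoring. The shipped battery (open field, elevated plus maze,
forced swim, splash, sucrose preference, with standard direction
codes) is a documented reconstruction — the exact parameter list of
the original study is not public — and is user-editable.

The generator simulates control values Normal(µ_p, σ_p) per parameter
with case values offset along the emotionality direction in σ units.
Values are generated on the final scoring scale (the generated specs
carry no distance flag); the distance-normalization path is exercised
separately with explicit distances, because injecting an exact σ-unit
offset *through* a ratio of two random variables would make the truth
offset itself approximate. Cohort-level calibration holds by
construction: null cohorts give mean case-group scores near zero and
~5 % false positives under the gated two-group test.

## Gated statistics (`stats`)

The branching contract is: Student t-test iff Shapiro–Wilk is
non-significant in both groups *and* Levene's test is non-significant,
at α = 0.05 two-sided; otherwise Mann–Whitney. Groups with zero
variance cannot be gated (Shapiro–Wilk undefined) and return a
degenerate Mann–Whitney record. The underlying tests are scipy's; the
bespoke content is the gate, the audit record, and the Bonferroni
orchestration (`p_adj = min(1, m·p)`) over all factor-level cell pairs
after a statsmodels type-II OLS ANOVA.

## Pipeline and problem sizes

`pipeline.run_experiment` executes simulate → analyze → statistics per
stage from a YAML config, derives every stochastic seed from the config
seed by hashing stage/group/replicate tags, and writes a manifest with
a SHA-256 per output so a run is verifiable from config + manifest.

The recovery analyses use the study-condition magnitudes throughout:
60-s traces at 0.56 Hz (control) and 0.26 Hz (treated) with amplitudes
near 21.7 pA; 5-min tonic recordings with 103.8 / 39.83 / 3.94 pA
shifts at a 20-s wash-in; 10-min baseline + 60-min follow-up slope
series with early/late factors 1.70/1.519 and 1.51/1.23; behavioral
cohorts with a uniform 0.42 σ offset. Replicate counts (50 traces, 20
tonic seeds, 200 noisy LTP series, 500 null cohorts, 10 × 200-animal
offset cohorts) were chosen so that Monte-Carlo error is small against
each recovery tolerance.

## Known limitations

- No 1/f, line noise, or filter artifacts in trace generation; no PSF
  in phantom rendering.
- Probe-built templates carry a small noise-dependent amplitude scale
  uncertainty (see above).
- Sholl counts within one shell of a bifurcation depend on tube radius.
- Rise-time estimates for events near the detection floor are noisy.
- The behavioral battery composition is a reconstruction; direction
  codes follow standard test interpretations.
- The repeated-measures structure of multi-trial behavioral analyses is
  not modelled; factor coding for the factorial ANOVA is exposed and
  logged instead.
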