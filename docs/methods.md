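# Methods

## Signal model

The whole-nerve cuff ENG is modeled as a zero-mean Gaussian process whose
variance is modulated by afferent activity. A generated recording is

    x(t) = n_bb(t) + n_emg(t) + n_amp(t) + Σ_c g_c · e_c(t) · b_c(t)

with three stationary background components and, per stimulus class *c*, a
band-limited unit-variance Gaussian burst process `b_c` gated by an
envelope `e_c` that is 1 inside each stimulus interval with 50 ms
raised-cosine onset/offset ramps (the ramps avoid broadband edge artifacts
that would leak into every feature; their length is our choice, short
relative to the ~1 s stimuli).

Background components (levels are standard deviations relative to the
broadband floor of 1.0):

| component | spectrum | default level | role |
|---|---|---|---|
| broadband | white | 1.0 | in-band rest noise floor |
| EMG-like | low-pass 400 Hz + 0.23× (400–800 Hz) | 1.5 | muscle contamination; ~95% of its power below 400 Hz |
| amplifier | high-pass 3 kHz | 0.8 | front-end noise at high frequencies |

Only the broadband floor survives the 0.8–2.2 kHz analysis band, so the
EMG and amplifier levels shape the raw trace realistically without
affecting calibrated SNR. The rest-noise spectral composition is not
independently characterized in vivo; these levels are stated assumptions,
exposed in `GeneratorConfig`.

Burst spectra default to class-specific centers — proprioceptive 1.6 kHz,
tactile 1.3 kHz, nociceptive 1.1 kHz, all 0.6 kHz wide — emulating the
fiber-diameter/conduction-velocity ordering (larger fibers, faster and
stronger signals). `identical_spectra=True` collapses all classes onto one
1.1–1.7 kHz band, the same-modality control in which, at equal SNR,
classes are statistically indistinguishable and the pipeline must fall to
chance.

## SNR convention and gain calibration

SNR is defined from mean absolute values on the band-passed signal framed
into disjoint 100 ms windows:

    SNR_dB = 20 · log10( mean window MAV, stimulus / mean window MAV, rest )

MAV is an amplitude-scale statistic, so the 20·log10 convention is used; it
maps the observed 1.2–3.8 dB range to amplitude ratios 1.15–1.55, which is
what whole-nerve recordings plausibly deliver. (The alternative 10·log10
would imply power ratios indistinguishable from these amplitudes and fails
to reproduce the measured-vs-requested round trip as cleanly.)

`calibrate_gain` inverts this measurement. For independent zero-mean
Gaussians the filtered mixture has std sqrt(σ_n² + g²σ_b²), giving the
closed-form initial guess g = (σ_n/σ_b)·sqrt(ρ² − 1), ρ = 10^(target/20).
The guess is then refined by fixed-point iteration against the SNR
actually measured on a 60 s calibration recording (alternating 1.5 s
on/off epochs) to within 0.05 dB; the linearity of the filter lets the
two filtered components be precomputed so each iteration is O(n). Windows
overlapping a ramp are excluded from both numerator and denominator during
calibration, since the deployed measurement resolves them by
majority-coverage labeling. A 0 dB target yields gain 0 exactly; negative
targets are rejected (additive bursts cannot reduce stimulus-epoch MAV).

Measured end-to-end (generate → filter → frame → label → measure), targets
in [0, 6] dB are recovered within ±0.3 dB; the residual scatter comes from
the finite number of stimulus windows in a ~30 s recording.

## Stimulus schedule

Each class is applied 10 times (the in-vivo protocol), with durations from
truncated normals — touch 0.96 ± 0.11 s, proprioceptive 1.17 ± 0.18 s,
nociceptive 0.97 ± 0.25 s, truncated at 0.1 s — and inter-trial gaps from
N(1.5, 0.3²) s truncated at 0.3 s, deliberately short relative to the
stimuli (the harder, realistic regime). Classes are cycled round-robin by
default so that the chronological half-split leaves ~5 applications of
every class in each half; a one-block-per-class order is available
(`schedule_order="block"`) but is incompatible with half-split evaluation
of multi-class problems, since a class confined to one half can never be
learned or tested. 2 s of rest pad the recording ends.

## Pre-processing

The band-pass is a 201-tap Hamming windowed-sinc FIR (0.8–2.2 kHz at
20 kHz sampling: ≤ −40 dB at 400 Hz and 3 kHz), applied once via centered
convolution — exactly zero phase for symmetric odd-length taps — so window
labels stay time-aligned. Framing discards a trailing partial window.
Window labels follow plurality of covered time with ties resolved to rest,
conservative toward the background class at stimulus transitions.

## Features and classifiers

All window statistics are implemented directly (see README for the
formulas). Parameter defaults where the protocol leaves them open:
AR/cepstral order P = 4 (short windows do not support higher orders; EMG
practice), HOS Toeplitz dimension M = 10, wavelet level 4 at 20 kHz. The
HOS eigen-statistics are returned as features rather than thresholded
detections — the downstream classifier replaces any empirical threshold.
The autocorrelation estimator is biased (divide by N) for positive
semidefiniteness; ACORR returns only the first-local-minimum value, the
variant that separates noise from evoked activity best. WDEN estimates the
noise σ as MAD/0.6745 of the finest detail coefficients.

AR coefficients are reported in the monic-polynomial convention
A(z) = 1 + Σ aᵢ z⁻ⁱ, the convention under which the cepstrum recursion
c₁ = −a₁, c_m = −a_m − Σ (k/m)c_k a_{m−k} is the power series of −log A(z).

The SVM grid searches cost ∈ 10^{−1..3} × width ∈ 10^{−3..1} (5×5), then a
5×5 refinement spanning one decade around the optimum, selected by mean
4-fold shuffled CV accuracy with a fixed seed, refit on all training data,
one-vs-one multiclass. The ANN is 2 hidden layers × 10 units, ≤ 500
back-propagation epochs with 20% validation early stopping (patience 20),
learning rate 0.01, seeded random init (so, unlike the SVM, it is only
repeatable per seed — the documented non-repeatability of the training
process). Rest windows dominate the label distribution and no reweighting
is applied, matching raw-accuracy evaluation; accuracies should be read
against the modal-class baseline.

## Majority vote and the real-time bound

The smoothed decision at position i is the mode of the 2k+1 raw decisions
centered on i (truncated at stream edges); ties keep the raw center
decision, preserving information. Because the k future decisions must be
awaited, an acceptable delay budget D bounds k:

    k = round((D − t_processing) / step),   step = ROW·(1 − overlap)

This is the unique simple rule consistent with all four published
operating points — 5, 7, 9 and 17 vote points for a 100 ms ROW at overlaps
0, ¼, ½, ¾ with D = 200 ms and zero processing time. D is configurable
within the 175–300 ms imperceptible-delay range.

## Evaluation protocol

Chronological half-split at the recording midpoint (no shuffling — the
realistic deployment test), accuracy = correctly classified test windows /
total test windows, full confusion matrix retained, per-class SNR measured
on the same filtered recording. Configuration comparisons use the
Kruskal–Wallis rank test (tie-corrected, χ² approximation, α = 0.05);
all-identical inputs degenerate to H = 0, p = 1 with a warning rather than
an error.

## What the synthetic surface does and does not show

The generator reproduces the *statistical* structure that drives the
method: variance-modulated Gaussian bursts at calibrated SNR, class-
dependent spectra, realistic stimulus timing, dominant rest class. It does
not reproduce spike-level temporal structure, stimulus-strength drift,
electrode-coupling nonstationarity, movement artifacts, or efferent
traffic. Consequently, passing tests demonstrate that the pipeline
recovers class structure down to the measured in-vivo SNRs under the
stated model — accuracies on synthetic data at a given SNR are upper
bounds on, not predictions of, in-vivo performance, and are expected to
sit above the in-vivo medians since the model's within-class statistics
are perfectly stationary. The ordering effects (accuracy monotone in SNR;
nociceptive hardest; chance at zero SNR with identical spectra; 25 ms
windows worse than 100 ms; majority vote never hurting) are the
transferable findings, and all are asserted by the suite.

## Problem sizes and numerical choices

Default experiment scale: 10 applications/class, ~28 s (one class) to
~80 s (three classes) of 20 kHz signal per dataset; five datasets for the
median analyses; five-seed batches for best-case and monotonicity
statistics. Calibration uses 60 s at 0.05 dB tolerance, ≤ 100 iterations
(2–3 in practice). Truncated-normal draws use redraw (not clipping).
Feature matrices reject non-finite entries; an all-zero feature column
normalizes by 1 with a warning. Degenerate inputs (single-class training
halves, windows shorter than a statistic supports, empty streams) raise
typed errors rather than propagating NaNs.
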