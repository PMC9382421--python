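# Methods

This note documents the models and procedures implemented in `neuroquant`,
the defaults they run with, the design choices made where the underlying
study protocol left the procedure open, and what the synthetic-data
generators do and do not emulate.

## Conventions

Time is in seconds everywhere; frames are 0-based; time bins are half-open
`[t, t + dt)`. A burst interval `[start, end]` is closed (its end is the last
spike time), so a burst ending exactly on a bin boundary marks that bin as
active. All stochastic operations take an explicit integer seed
(`numpy.random.default_rng(seed)`); there is no global RNG state, and every
generator is a pure function of (parameters, seed).

## MEA spike and burst analysis

**Noise estimation.** The spike threshold is defined as a multiple
(default k = 5) of the baseline noise SD. The estimator is the median
absolute deviation of the voltage trace scaled to Gaussian SD
(MAD / 0.6745). The MAD is insensitive to the rare, large spike deflections
riding on the noise, so it approximates the "spike-free baseline" SD without
needing a spike-free segment to be identified first; on a pure-noise trace
it agrees with the sample SD to within a few percent.

**Spike detection.** Negative-going crossings of −k·σ, one spike per
crossing, timed at the local voltage minimum, with a 1 ms dead time after
each detection. Negative-only polarity and the dead time are the standard
choices for extracellular MEA electrodes: the primary deflection of a
somatic action potential at a substrate electrode is negative, and the dead
time prevents a biphasic waveform from being counted twice. At a planted
signal-to-noise ratio of 8 (60 s at 10 kHz) recall and precision against
planted spike times exceed 0.95 with ±1 ms matching.

**Burst detection.** A burst is a maximal run of at least `n_min = 5`
consecutive spikes whose internal inter-spike intervals are all
≤ `isi_max = 100 ms`; burst duration is last minus first spike time. The
implementation is a linear scan over the ISI sequence and is verified
against a brute-force oracle that enumerates all index ranges and keeps
maximal valid runs, across a grid of (n_min, isi_max) values.

**Network metrics.** Per electrode: firing rate = spikes/duration; burst
rate = bursts/min; mean burst duration; % spikes in bursts
= 100·(spikes inside bursts)/(total spikes); intraburst spike frequency
= mean over bursts of (n_spikes − 1)/duration. The study protocol names
these metrics without formulas; the intraburst definition above is the
conventional one (spike intervals per unit burst time). The well-level value
is the unweighted mean over all 9 electrodes for the rates (silent
electrodes contribute zeros) and the mean over electrodes with at least one
burst for the duration/intraburst means (undefined means are NaN, never
zero). Whether the original analysis averaged electrodes or pooled spikes is
not recoverable; averaging electrodes weights each sensor equally and is
reported per `WELL_MEAN` row next to the per-electrode rows so either
aggregation can be recomputed.

## Burst synchrony

"Burst activity" is binarized per electrode on a 100 ms grid (equal to
ISI_max; configurable, and burst-count or spike-count signals are
selectable): a bin is active iff any burst interval intersects it. For every
unordered pair of electrodes with ≥ 5 bursts in the recording, the Pearson
r of the two state series is computed with a two-sided p from
t = r·√((B − 2)/(1 − r²)) on B − 2 degrees of freedom. Pairs are classified
at α = 0.05 into positive / negative / non-correlated; electrodes below the
burst minimum, and pairs involving a zero-variance series, are excluded with
a recorded reason. Classification distributions of two conditions are
compared with a Pearson chi-square (no continuity correction). No
multiple-testing correction is applied across pairs: the classification
distribution, not per-pair inference, is the unit of analysis.

**Calibration caveat (known limitation).** The t-transform assumes
exchangeable observations. Burst-state bins are not exchangeable: a burst
lasting ~0.2 s occupies 2–3 consecutive bins, and this autocorrelation makes
the t-based p anticonservative. On simulated wells with *independent*
electrodes and the default burst microstructure, ~10 % of pairs classify as
positively correlated at α = 0.05 (nominal would be α/2 = 2.5 % for a
calibrated two-sided test; sparse sub-bin bursts give ~5 % because the
sparse-binary r distribution is right-skewed, putting essentially all false
positives on the positive side). A circular-shift permutation p
(`pvalue="perm"`), which preserves each series' autocorrelation, is provided
and is exchangeability-exact; it is the recommended option when absolute
false-positive rates matter, while the t-based default matches conventional
per-pair Pearson classification for cross-condition comparisons (both
conditions share the same anticonservatism, which the chi-square compares
out).

## Drug time courses

Metric values are normalized per well to the pre-drug baseline
(timepoint 0 → 100 %); a non-positive baseline excludes the well with a
logged reason rather than propagating NaNs. The normalized course is fitted
with the four-parameter logistic
y(t) = y_min + (y_max − y_min)/(1 + exp(−(t − t50)/τ)) by bounded
least squares (τ ∈ (0, 10·t_max]). Decreasing responses are handled by
allowing y_max < y_min. The fit is multistarted from data-driven heuristics
(y-range endpoints, a coarse grid of t50 quantiles and τ scales, and a
flat-mean start), so the returned RSS is never worse than the flat model and
non-convergence returns the best iterate with `converged=False` instead of
raising. Group-mean fitting (`fit_group_mean`) is the default unit of
analysis, matching a design with several wells per condition; a per-well
option remains available.

**Identifiability (known limitation).** With the six sampling times
0/10/30/60/120/240 min and a transition at t50 ≈ 60 min, τ ≈ 20 min, only
two timepoints fall inside the transition. At 5 % multiplicative noise the
plateau parameters recover to a few percent and t50 to ~5–7 % on 6-well
group means, but τ is weakly identified (median error ~20 % even on 8-well
means, ~45 % on single courses). This is a property of the sampling design,
not of the optimizer: a denser multistart global fit does not improve it.
τ estimates from this design should be treated as qualitative.

## Calcium transient analysis

**Background correction.** Corrected trace = raw − twin-ROI background,
framewise. The noise SD is MAD/0.6745 of the first difference of the
corrected trace divided by √2, which is insensitive to the slow transients
riding on the trace. An ROI whose corrected trace is nowhere positive is
rejected.

**Detection.** The running baseline is a 20th-percentile filter over a 2 s
window (robust to transients occupying part of the window). Because the
20th percentile of Gaussian noise sits 0.8416·SD below the quiescent mean,
the detection threshold is formed as baseline + 0.8416·SD + k·SD (default
k = 2), i.e. k SDs above the quiescent *mean*. A candidate event must stay
above threshold for ≥ 5 consecutive frames (~0.33 s at 15.3 Hz); it then
extends with hysteresis until the trace falls below 0.5·k·SD above the
quiescent level, and events closer than 3 frames are merged. The minimum
duration is what keeps the false-positive rate on pure-noise traces below
1 % per 5-min trace at k = 2; real indicator transients (decay ~1 s) far
exceed it, while sub-0.3 s events are not detectable at this frame rate
anyway.

**Quantification.** F₀ is the mean corrected intensity over the 1 s window
preceding onset (truncated and flagged for events near the record start).
The amplitude is ΔF/F₀ = (F_peak − F₀)/F₀ with the peak estimated in three
steps: (1) each event's decay is fitted with a free (A, τ) exponential,
(2) τ is pooled per ROI as the median across events (the decay constant is
a property of the indicator and ROI, not of the event), and (3) the event
amplitude is the closed-form linear projection of ~2 s of pre-onset and
~4 s of post-onset frames onto [constant, decay kernel], with the event
time fixed half a frame before the first supra-threshold sample. Estimating
the local baseline jointly keeps the F₀ measurement noise out of the
amplitude coefficient, and the half-frame offset removes the sampling-delay
bias of the raw peak sample (the rise is fast relative to one frame). At a
planted SNR of 10 the mean per-event amplitude error is ~4.5 %; for
noiseless transients the residual error is the ±half-frame sampling
ambiguity (< 2 % at a 1 s decay).

**Statistics and synchrony.** Frequency = events/min per ROI; ROIs with no
transient are excluded from the analysis set (mirroring the inclusion rule
that a neuron must show at least one spontaneous transient). Transient
peaks across ROIs within ±2 frames (~±130 ms) are clustered into network
events; each ROI contributes its peak amplitude, or 0 if it did not
participate — zero-filling encodes non-participation, which is what makes
the amplitude-profile correlation a synchrony measure. Pearson r + p per
ROI pair, with the negative category enabled in classification.

## Molecular quantification

**Efficiency.** E = 10^(−1/slope) from the least-squares slope of Ct vs
log10(input) over a serial dilution (≥ 3 distinct points; non-negative
slopes are rejected). A perfect-doubling chemistry (slope −3.3219) gives
E = 2.000.

**geNorm stability.** Per candidate reference j: relative quantity
Q_j = E_j^(min Ct_j − Ct_j) across samples; M_j = mean over other
candidates k of the SD across samples of log2(Q_j/Q_k); lower M = more
stable. Requires ≥ 3 candidates and ≥ 2 samples. Iterative exclusion is
available, but the three named references (GAPDH, ACTB, HPRT1) are used
as-is by default with M reported for QC, matching a fixed reference set.

**Relative expression.** Technical replicates are averaged per
(sample, gene) — arithmetic mean of Ct, with replicate SD > 0.5 cycles
flagged but not dropped. Q = E^(mean calibrator Ct − sample Ct) per gene;
normalization factor = geometric mean of the reference-gene Q; normalized
expression = Q_target/NF rescaled so the calibrator-group mean is exactly 1.
Samples missing a reference measurement are dropped with a recorded reason.
The construction is invariant to per-gene constant Ct shifts (plate
offsets).

**ChIP-qPCR.** Percent input = 100·E^((Ct_input − log_E(dilution)) − Ct_IP);
the input dilution factor is a required parameter (standard percent-input
algebra). Fold enrichment = group-mean percent input over the control
group's mean.

**Immunoblots.** Band intensities are divided by the mean of the
within-membrane control samples; with a phospho→total pairing, the
phospho/total ratio is formed first.

**Localization and colocalization.** The spine/shaft statistic
(S − D)/(S + D) ranges from −1 (fully dendritic) to +1 (fully synaptic),
is antisymmetric and scale-invariant; pairs with non-positive total signal
after background subtraction are excluded (the protocol leaves this case
open; exclusion with logging is the declared rule). Manders coefficients:
M_A = Σ A over pixels where both channels exceed their thresholds ÷ Σ A over
pixels where A exceeds its threshold (symmetrically M_B); thresholds are
inputs (image thresholding is upstream of this package); an empty
supra-threshold mask yields NaN.

## Statistical primitives

Pearson r with the two-sided t-transform p; Pearson chi-square of
independence without continuity correction (Yates optional), rejecting
zero expected counts with a merge hint; one-way ANOVA with Tukey HSD
adjusted p-values from the studentized range distribution; unpaired
two-tailed t test with pooled variance ("Student's" reading) and a Welch
option. These are thin validated wrappers over SciPy; their fixtures
(χ² = 8.27 for [[51,49],[31,69]], F = 3.0 for the three-group ladder,
r = 0.5 for (1,2,3)/(1,3,2)) are hand-derived in the tests, and null
simulations confirm 5 % ± 1.5 % type-I error for all three tests.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume, plus machine-readable planted truth for oracle tests.

**MEA wells** (`NetworkSimParams`): 9 electrodes, 300 s. Network-burst
events are Poisson with rate `genotype_factor · lambda_net` (default
12/min; WT factor 1.0, Het/KO 0.5 — a pure rate scaling with unchanged
burst microstructure, so recovery tests stay interpretable). Each electrode
joins an event with probability `p_part` (0.9), emitting
5 + Poisson(mu_spikes − 5) spikes (mu 12) with exponential ISIs of scale
20 ms (< ISI_max, so planted bursts are detectable by construction;
parameter combinations violating this are rejected), its onset jittered by
N(0, jitter_sd²) (10 ms — jitter controls synchrony). Tonic background
spikes are Poisson at `genotype_factor · 0.5` Hz per electrode. Defaults
are typical of mature (~DIV 16) glia-free cortical cultures: mean firing
~2.7 Hz, burst rate ~11/min, ~80 % of spikes in bursts. An
`independent_electrodes` switch gives each electrode its own event process
for null-calibration experiments.

**Raw voltage**: unit-variance Gaussian noise plus a ~1 ms biphasic
template (negative peak −snr·σ at the spike time, 40 % positive rebound) at
each planted spike; 10 kHz default.

**Fluorescence** (`CaSimParams`): 15.3 Hz, 300 s, network events Poisson at
3/min thinned to a 4 s minimum gap (network-burst refractoriness; it also
keeps planted events individually resolvable so detection-count oracles
compare like with like). Per event a shared lognormal scale
(σ = `shared_scale_sd`, default 0.4) multiplies every participating ROI's
amplitude; per-ROI lognormal noise (σ = 0.2) and a participation
probability (0.8) sit on top; base amplitude 0.5 ΔF/F₀, decay τ = 1 s
(red indicator on network bursts), Gaussian camera noise on both the cell
ROI and its twin background ROI. The shared scale is a single dial for
amplitude-profile synchrony: at σ_shared = 0 pairwise correlations fall to
the type-I level; mean pairwise r increases monotonically with it.

**Ct tables** (`QpcrSimParams`): Ct = ct0 − log_E(expression) + N(0,
replicate_sd²) per replicate (triplicates; replicate SD 0.1 cycles);
target expression = planted group fold × per-sample lognormal biological
noise; reference genes carry small log2-scale stability noise (0.05), so
an unstable reference can be planted by raising it.

**What the generators do not emulate**: electrode crosstalk and shared
noise, bursting-rate nonstationarity over the recording, indicator
saturation and photobleaching, cell-to-cell variation in decay constants,
qPCR inhibitors or between-plate batch effects. Passing recovery tests on
this synthetic structure validates the estimators' algebra and calibration
under the stated model, not robustness to those real-data artifacts.

## Numerical choices and degenerate inputs

Result tables are written with 12 significant digits (bit-exact for
integers on round-trip); identical inputs and seed yield byte-identical
outputs. Constant voltage traces yield noise SD 0 with a warning; constant
series make correlations undefined and are excluded with a reason;
zero-spike electrodes report zero rates and NaN means; a chi-square with a
zero expected count raises with a category-merge recommendation; ANOVA with
zero within-group variance is flagged degenerate (F = ∞ or 0/0). Duplicate
spike timestamps are rejected at read time (spike times are strictly
increasing by invariant).
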