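# Methods notes

This note records the modeling assumptions, numerical choices and known
limitations behind `mtspike`, in the order data flow through the package.

## Data containers and preprocessing (`spikeio`)

Spike times, trial events and heart rate travel as UTF-8 tab-separated
tables; times are seconds from recording start. Binning is half-open
`[left, left + width)` anchored at the window start, with any trailing
partial bin dropped, so spike counts are conserved against the source train
over complete bins. The edge convention is ours — nothing in the analysis
depends on it beyond consistency, which the property tests pin down.

Rates are computed with a boxcar kernel of width 2 s sampled every 2 s, and
the first and last 2 s of each recording are trimmed to remove smoothing
edge artifacts. We read "a smoothing kernel and sampling period, both of
width 2 seconds" as a moving-window rate; a Gaussian kernel (SD = width/2)
is available behind the `kernel` argument for sensitivity checks.

Trial windows span −10 s to +100 s around the alignment event (withdrawal
or heat onset), with the event at exactly 0 in window coordinates; times
before withdrawal are negative. A window is excluded when the recording
ends inside it or the next trial's heat onset intrudes before +100 s.
The PSTH bin width defaults to 50 ms, matching the evoked model's bin.

## Evoked piecewise models (`evoked_bayes`)

Pooled counts (summed over cells and trials per 50 ms bin — a
pseudo-population; no per-cell random effects, deliberately) are Poisson
with a piecewise rate, continuous at the switch time t_s. Free parameters
and priors:

| parameter | prior | note |
| --- | --- | --- |
| log r_pre, log r_post | N(3, 1) | ON baselines, counts/bin |
| log k_pre, log k_fast | N(1, 1) | ON amplitudes |
| β₁, β₂, β₃ | HalfNormal(5) | τᵢ = 1/βᵢ, seconds |
| b | HalfNormal(4) | OFF lower asymptote |
| a, c (, d) | b + HalfNormal(4) | OFF upper/recovery asymptotes |
| k | N(0, 1) | signed sigmoid slope (negative = pause) |
| 1/τ | HalfNormal(1) | OFF recovery rate |
| k₃ | HalfNormal(1) | OFF linear drift, counts/bin/s |
| u₀ | U(b, a) | rate at the switch (sampled as u₀ = b + w(a−b), w ~ U(0,1)) |
| t_s | U[−4, 4] | switch time, s |

Design choices worth flagging:

- **OFF slope sign.** The sigmoid response must *decrease* for OFF cells,
  which under f = b + (a−b)/(1+e^{−k(t−t*)}) requires k < 0. We sample the
  signed slope under its N(0, 1) prior and report the magnitude; the
  reparameterized midpoint t* = t_s + (1/k)·ln((a−b)/(u₀−b) − 1) makes the
  sigmoid pass through (t_s, u₀) exactly for either sign.
- **OFF recovery time constant.** The recovery formula needs a positive
  τ; we parameterize its rate 1/τ with a HalfNormal(1) prior (a negative
  rate would make the recovery non-recovering).
- **Ordering constraint.** The two recovery components of the
  double-exponential variants carry exchangeable priors, which leaves the
  posterior bimodal under label switching; we restrict τ_fast < τ_slow,
  consistent with the components' names.
- **Branch assignment.** t_s enters the likelihood through an indicator on
  bin centers, so the likelihood is piecewise-constant in t_s within a bin;
  posterior summaries of t_s therefore carry ~25 ms quantization.

Sampling uses an affine-invariant ensemble (64 walkers, 2500 steps, 1000
burn-in, thin 5), initialized in a tight ball around a posterior mode found
by Nelder-Mead restarts over several switch-time starting points. The
sampler state is seeded; fits are bit-reproducible. Convergence is judged
by mean acceptance fraction and integrated autocorrelation time and flagged
on the result — never silently dropped. Pointwise Poisson log-likelihoods
on a 1000-draw subsample feed PSIS-LOO ELPD comparison (arviz); HDIs are
minimum-width intervals over sorted draws.

Threshold-crossing times solve, per posterior draw and by vectorized
bisection on the monotone branch, for the time at which the rate completes
a stated fraction of its departure (response: pre-baseline → extremum at
t_s) or return (recovery: extremum → post-baseline). The post-baseline is
the model's t → ∞ asymptote except for the linear+exponential OFF recovery,
which has none; there we use the rate at the window end. Draws whose branch
never reaches the target inside the window are counted as undefined and
excluded from the summary.

## Synthetic cohorts (`synthdata`)

The generator emulates the study conditions: heat trials at 5-minute
intervals (3–4 per cell, withdrawal ~8.7 s after onset), ON/OFF evoked
shapes from the piecewise models, NEUTRAL cells as gamma-renewal trains
(shape 8 → CV ≈ 0.35, mean ISI 0.1 s — a Poisson train cannot be that
regular), ~300 s sinusoidal or GP-drawn latent modulation of ongoing
firing passed through the SoftPlus link with generalized-Poisson
dispersion, and a heart-rate series of mean 391.1 bpm with optional
additive coupling to the per-animal latent. Spikes come from a thinning
sampler against the supremum rate; generalized-Poisson counts from pmf
inversion (renormalized over the truncated support when α < 0). Everything
is a pure function of (config, seed); cohort files are byte-identical
across reruns.

Evoked pooled baselines/amplitudes (ON r_pre = 40, r_post = 36, k_pre = 80,
k_fast = 30; OFF a = 24, b = 1, u₀ = 1.4, c = 16 counts/bin, nominally ~300
pooled trial-equivalents) are package defaults, chosen so that posterior
HDI widths recovered from synthetic fits match the widths of the reference
posterior summaries — i.e. the synthetic cohort carries the same
information content as the study data. Recovered posterior means therefore
scatter within those HDI widths across seeds (for τ_slow, roughly ±12%);
passing recovery tests demonstrate calibration at that information level,
not unlimited precision. Time constants, switch times, slope and drift
defaults are the reference posterior means themselves.

Two latent modes exist for ongoing data: an exact sinusoid (deterministic
phase; used by recovery tests, where ground truth must be sharp) and a GP
draw (realistic roughness). Inter-cell correlation within an animal is
modeled only through a shared latent phase (strength configurable); the
generator makes no claim about finer cross-correlation structure, so tests
on it say nothing about real synchrony.

## Ongoing spectra (`ongoing_spectra`)

PSDs use Welch's averaged periodogram (Hann window, 50% overlap, segments
of at least 600 s so a 300 s cycle is resolved); the low-frequency peak is
the band maximum below 0.1 Hz excluding DC, with FWHM from interpolated
half-power crossings converted to period units. Peaks are flagged
non-prominent when below 3× the median band power and unreliable for
series shorter than two 300 s cycles. FWHM in period units degrades
quickly toward DC; at desk-scale durations it is much wider than values
obtainable from hour-long recordings.

The period scan computes the exact Gaussian-process NLML of the
mean-centered rate under the periodic kernel with fixed variance 5.0 and
lengthscale 1.0, per candidate period on a 200-point logarithmic grid over
0.1–1500 s (the wider of the two ranges the source material quotes). The
Gaussian noise variance is fixed at the sample variance of the centered
rate; Cholesky failures escalate through jitter (1e−8 → 1e−4 of the kernel
variance). Periodic inputs produce a global minimum at the true period
with subharmonic minima at its multiples; white inputs give flat profiles
(range ≪ the periodic case).

## Latent GP (`latent_gp`)

The count model is exactly the generative model of `synthdata`: periodic
kernel, SoftPlus link (A = 10 spikes/s), generalized Poisson with shared
α and uniform contamination p_noise = 0.001. For α < 0 the raw pmf is
deficient on its truncated support; we renormalize explicitly (with a fast
path skipping the summation when the truncation point lies far outside the
bulk, where the constant is 1 to machine precision).

Fitting is type-II maximum a posteriori with a sparse inducing-point
representation: 200 equally spaced, fixed inducing points; whitened
inducing values are driven to their conditional mode by damped Newton
iterations (likelihood derivatives taken elementwise by central
differences, which keeps the contamination mixture and truncation exactly
inside the derivative), and a Laplace approximation of the marginal
likelihood — mode value minus half log-determinant of the scaled Hessian —
forms the outer objective, plus Gaussian log-prior penalties ℓ ~ N(0.1,
0.1) and α ~ N(0, 0.5). The outer optimizer is Nelder-Mead over (log σ²,
log p, log ℓ, c, atanh α), started from the 300 s period initialization
and, in a second deterministic start, from a near-zero outputscale so that
non-rhythmic cells can collapse the latent instead of overfitting it. The
periodic kernel makes inducing points separated by whole periods perfectly
correlated, so the inducing covariance is rank-deficient by construction;
whitening through its eigendecomposition (dropping null directions) handles
this without jitter tuning. When the latent collapses (σ² → 0), the period
is unconstrained and its fitted value is not meaningful — mirrored in real
data by non-rhythmic cells whose period estimates reflect weak constraint.

Training uses all but the final 300 s; predictions for the held-out window
come from the trained model only (the held-out counts cannot influence any
fitted quantity — covered by a bitwise purity test). Pseudo-R² is
1 − SSE(pred)/SSE(train mean), computed on counts; it is negative when the
model generalizes worse than the training mean, which is the expected
outcome for amplitude-zero cells. Phase folding averages the predicted
training-span rate modulo the fitted period into 50 bins, phase 0 at the
training-window start; profiles are meaningful up to cyclic shift.

## Coherence (`coherence`)

Both series are binned at 2 s (counts for spikes, mean bpm for heart
rate), segmented into 500 s windows with 50% overlap and demeaned per
segment. DPSS tapers with NW = 3.5 and K = 6 give bandwidth 0.007 Hz at
0.002 Hz resolution; cross- and auto-spectra are averaged over tapers and
segments before forming the magnitude-squared coherence. K = 6 equals
2NW − 1; larger K triggers a leakage warning. A ~0.0033 Hz rhythm is
therefore smeared across the lowest frequency bins, and no sub-bandwidth
frequency claims should be made from these spectra.

The max-statistic null randomizes the spike-rate series: phases of
non-overlapping hop-length (250 s) blocks are randomized independently and
the surrogate series re-segmented exactly like the observed one. This
destroys cross-segment phase consistency (so genuinely coherent
frequencies exceed the null) while preserving the overlap dependence of
the averaged spectra; randomizing each overlapping segment independently
instead understates the null and inflates the family-wise error roughly
fifty-fold at α = 0.001 in our calibration runs. The threshold is the
conservative empirical (1−α) quantile (k-th largest with
k = ⌊α(n+1)⌋), and n_surrogates defaults to 2000 with a warning below
1/α. Measured on 400 independent pairs, the family-wise false-positive
rate was 1/400 at nominal 0.001.

## Group statistics (`groupstats`)

The sign-flip test uses the median across cells as its statistic and flips
all cells of an animal jointly — one ±1 per animal per permutation —
which is what "accounting for within-animal correlation" means
operationally; with ≤ log₂(n_perm) animals the full 2^n flip set is
enumerated and the p-value is exact (the +1 correction applies only to
sampled permutations). Note the median's robustness: with few animals the
attainable p floor is above 2/2^n. The Mann–Whitney permutation moves
whole animals between groups; Bonferroni multiplies by the number of
pairwise class comparisons (default 3) and caps at 1. Kruskal–Wallis uses
the chi-square reference with mid-ranked ties.

`run_pipeline` chains the stages on a synthetic cohort config, writes
per-stage TSVs plus a JSON summary with all seeds and the package version,
and is byte-reproducible for a fixed (config, seed).

## Problem sizes and limitations

Default experiment sizes — 2200 bins per evoked fit, 1500 s / 300 bins per
latent-GP cell, 748 rate samples per period scan, 1000 noise pairs ×
1000 surrogates for the coherence calibration — were chosen so each
analysis completes in seconds to a few minutes on one CPU; all are
configurable upward. Known limitations: posterior means of skewed
parameters (notably τ_slow, τ_fast) inherit upward bias of order a tenth
of their scale at the default information level; the evoked model treats
pooled counts as exchangeable and cannot speak to per-animal
heterogeneity; the latent GP's period posterior is a point estimate (the
outer optimization is type-II, not fully Bayesian); and the coherence
surrogate scheme assumes approximate stationarity within 500 s segments.
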