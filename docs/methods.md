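# Methods

## Design

The simulated experiment is a 2 (visual reliability: high/low) × 2
(modality-specific report: auditory/visual) spatial ventriloquist design.
Stimuli are sampled from four azimuthal locations, by default the physical
grid (−10°, −3.3°, 3.3°, 10°). Unisensory auditory (4 conditions),
unisensory visual (4 locations × 2 reliabilities) and audiovisual sessions
are separate; an audiovisual session crosses all 4 × 4 location
combinations with reliability (32 conditions × 11 trials = 352 stimulus
trials), while unisensory sessions present 4 × 88 (auditory) or 8 × 44
(visual) trials. 5.9% null events are interspersed *in addition to* the
352 stimulus trials and flagged distinctly; nothing downstream consumes
them (they exist only so session plans have the full event structure).
Pseudorandomization is a seeded uniform shuffle — design-efficiency
optimization matters only for hemodynamic estimation, which is out of
scope.

The cue-combination analysis uses the 52-condition subset: all unisensory
conditions plus the audiovisual congruent (ΔAV = A − V = 0) and
small-conflict conditions (adjacent grid locations), crossed with report.
The physical grid makes adjacent disparities 6.6°–6.7°, but the weight
algebra uses a **nominal disparity** of 6°, stored per condition alongside
the true locations. `design.idealized_grid()` returns the evenly spaced
grid (−9, −3, 3, 9) on which nominal and physical disparities coincide;
the exact round-trip identities are tested there, and `weight_variance_table`
accepts an explicit `delta` for callers who want per-pair physical
disparities instead of the nominal convention.

## Generative observers

`ObserverParams` defines a forced-fusion observer: on each trial it draws
internal estimates Ŝ_A ~ N(S_A, σ_A²), Ŝ_V ~ N(S_V, σ_V²), fuses
audiovisual estimates with reliability weights w_V = σ_V⁻²/(σ_A⁻² + σ_V⁻²),
and presses the button nearest the estimate (exact midpoint ties break
toward the outer location — any fixed rule preserves the left/right
binarization, and this one is deterministic). With probability 2λ the
response is replaced by a uniformly random button, which reproduces the
symmetric guess-equals-lapse tails of the fitted function exactly: for the
four-button grid, a lapse is "right" half the time, so ψ gains λ at each
tail.

Because the binarization boundary is 0 (between the two middle buttons),
the generative probability of a "right" response is exactly
λ + (1 − 2λ)Φ((m − 0)/σ) with m the mean of the fused estimate — the
fitted functional form is the true model, so large-sample fits recover the
generative parameters (tested).

**Defaults**: σ_A = 12°, σ_V,high = 2.5°, σ_V,low = 10°, λ = 0.03. The
visual values track the stimulus manipulation (dot-cloud horizontal SD of
2° vs 14°: visual noise well below auditory noise at high reliability,
comparable at low reliability), and σ_A reflects typical free-field
auditory localization noise with non-individualized spatial rendering.
These put the predicted visual weight at ≈ 0.96 (high) and ≈ 0.59 (low),
a high-but-not-degenerate ventriloquist regime. Between-subject scatter
multiplies each σ by a log-normal factor (SD 0.15 on the log scale).

The `report_weighted` mode emulates the top-down account in which
attention raises the reliability of the reported modality: in audiovisual
trials the reported modality's σ is divided by √attention_gain *before*
both the noise draw and the weighting, so the effective weights — and the
fitted audiovisual slopes — shift with report while unisensory sessions
(where the reported modality is the only one present) keep the base σs
and hence the MLE predictions fixed. With attention_gain = 1 the mode is
identical to pure fusion. The alternative causal-inference account is
deliberately not modeled. A `null` mode presses uniformly random buttons.

## Psychometric fitting

Responses are binarized (two leftmost buttons → "left"), tallied into
per-condition binomial rows (x, n, k) with the abscissa being the true
location (unisensory) or the mean audiovisual location (AV), and fitted
with ψ(x) = λ + (1 − 2λ)Φ((x − μ)/σ) by maximizing the product-binomial
log-likelihood Σ[k log ψ + (n − k) log(1 − ψ)] (Bernoulli form, no
binomial coefficient, so a saturated fit has LL = 0).

Parameter schemes tie slots across conditions:

| scheme | free parameters | PSEs | slopes |
|---|---|---|---|
| main17 / model_IV | 17 | 1 shared (unisensory + AV congruent) + 8 conflict (2 rel × 2 report × 2 signs) | A, V-high, V-low + 4 AV cells (shared congruent/conflict) |
| congruent21 | 21 | as main17 | main17 + 4 extra AV-congruent slopes |
| model_I (null) | 8 | shared + 2 conflict signs | A, V-high, V-low, single AV |
| model_II (MLE) | 5 | shared (AV tethered) | A, V-high, V-low (AV tethered) |
| model_III | 11 | shared + conflict per rel × sign | A, V-high, V-low + AV per rel |

All schemes share one guess-equals-lapse λ (optionally pinned, e.g., to 0
for the constrained slope tests). In model_II the audiovisual parameters
are not free: on every likelihood evaluation they are recomputed from the
current unisensory slots — σ_AV from the fused-variance formula and the
conflict PSE as μ₀ + (w_V − ½)·ΔAV, a parameterization derived so that the
PSE-difference weight formula returns w_V exactly (round-trip tested).

Optimization: internal reparameterization (μ raw, log σ, logit 2λ),
multi-start L-BFGS-B (default 20 seeded starts; one data-driven start plus
jittered restarts) with an analytic gradient, including the chain rule
through the tethered model_II parameters; convergence tolerance 1e-10 on
the objective. Refitting from a returned optimum moves the log-likelihood
by < 1e-6 (tested). Degenerate all-left/all-right data trigger a boundary
warning; a fit error carrying the best candidate is raised only if every
restart diverges.

`fit_probit_batch` is a vectorized Fisher-scoring probit fit for the
λ = 0 single-condition case — the same maximum-likelihood estimator as the
generic path (equivalence tested to 1e-3) — used where hundreds of
thousands of independent refits are needed (the bootstrap calibration
study). Near-separation steps are damped and the slope is kept in
[1/50, 1e4]⁻¹ degrees to keep estimates finite.

Model scores: BIC on the larger-is-better convention LL − 0.5·M·ln(N)
with N = 52 summary rows; pseudo-R² is the likelihood-ratio statistic
rescaled by its maximum attainable value for binary outcomes
(Nagelkerke-style, using total Bernoulli count), so the chance model
scores 0 and a perfect saturated fit scores 1. The exact correction used
by the original toolbox is not public; this choice is documented rather
than inferred, and no published R² value is treated as a target.

## Weights and variances

`weight_variance_table` derives, per design cell: the empirical weight
from the fitted conflict PSEs (nominal ΔAV = 6° by default), the
empirical audiovisual σ (the fitted AV slope — congruent and conflict
jointly in the main scheme; congruent-only available from congruent21),
and the MLE predictions from the fitted unisensory σs. Empirical weights
can leave [0, 1] under noise; they are flagged, never clipped. Report-
pooled estimates come from model_III fits (AV parameters shared across
report), mirroring the pooled-and-refitted comparison against MLE
predictions; the pooled visual σ for the single-cell (model_I) layout is
the root-mean-square of the two reliability σs.

## Neural surrogate and decoding

`simulate_patterns` is a synthetic stand-in for condition-level BOLD
patterns (no HRF, GLM, or ROI machinery): voxel i's mean response is
gain_i × side_i × E × report_gain, where E is the encoded location —
w_V,neural·S_V + (1 − w_V,neural)·S_A for audiovisual conditions, the
single location otherwise — and side_i = ±1 implements contralateral
preference by hemisphere. Per-voxel gains are log-normal
(`voxel_gain_spread`, default 0.5), which places location information
*within* each hemisphere; setting the spread to 0 leaves only a global
hemispheric offset, the failure mode the per-hemisphere normalization
control is designed to remove (tested both ways). Gaussian noise (default
SD 20 activation units, scaled ×1.5 for low visual reliability) is chosen
so that congruent left/right decoding sits near 85–90% — reliably above
chance but below ceiling, the regime in which neurometric functions are
graded, as in real regional decoding; at low noise the neurometric
functions degenerate into step functions with boundary slopes.

Decoding follows the study's scheme: patterns are z-normalized across all
voxels of the region (or per hemisphere, for the control) within each
(session, condition) slice; a linear SVC (libsvm, C = 1, deterministic)
is trained on the audiovisual *congruent* conditions of all but one
session — across both report conditions, labeled by the true stimulus
side — and labels the held-out session's congruent and conflict patterns;
a final classifier trained on all audiovisual sessions labels the
unisensory-session patterns. One pattern per condition per session is
decoded (condition-level estimates, not trials). Decoded labels are
pooled over sessions and simulated participants (default 5) into a
fixed-effects neurometric binomial summary and fitted with the identical
scheme machinery, including the shared-lapse convention (assumed to carry
over; nothing in the neurometric pipeline requires a different lapse
structure). The regularization constant and kernel scaling of the
original classifier are not published; C = 1 with sklearn's defaults is a
documented choice.

## Inference

**Parametric bootstrap.** Counts are resampled k* ~ Binomial(n, ψ_fit)
per summary row; the same scheme is refitted to each draw, warm-started
at the observed optimum (plus two jittered restarts), and derived
statistics are recorded per draw. Defaults follow the study: 1000 draws
for confidence intervals, 5000 for tests (the pipeline's neural stage
accepts a smaller override; the analysis driver uses 1000). Percentile
intervals default to 68% coverage. Test p-values use the shifted-null
closed-inequality convention exactly: null = draws − observed,
p = mean(|null| ≥ |observed|) for two tails, the signed inequality for
one — no +1 smoothing, so p lives on the grid j/n_boot. Refit failures
are dropped and warned about above a 5% rate.

**Calibration.** `pse_bootstrap_calibration` simulates replicate null
experiments (two conditions from one cumulative Gaussian, μ = 0, σ = 6°,
four abscissae on the idealized grid, 110 trials each — the pooled
per-condition count of the audiovisual design), tests the PSE difference
with the 500-draw bootstrap above, and reports the rejection rate at
α = 0.05 and the 68%-interval coverage. Both sit at their nominal values
within Monte-Carlo error (tested; the acceptance script reports this
quantity).

**Classic statistics.** The Wilcoxon signed-rank test drops zero
differences, midranks ties, and enumerates all 2ⁿ sign assignments
exactly for n ≤ 15 (tie-corrected normal approximation above, no
continuity correction); the exact path matches a brute-force enumeration
oracle and scipy's exact mode. The 2×2 repeated-measures rank ANOVA ranks
all 4n values jointly, then computes each df1 = 1 effect as the squared
paired t on the per-subject contrast of ranks (df2 = n − 1), verified
against pingouin's repeated-measures ANOVA on the ranked data; an
all-zero contrast (possible with tied ranks at very small n) raises a
degenerate-contrast error, which the pipeline records as missing rather
than failing the run. Bonferroni correction is min(1, m·p), default
m = 3 as in the three-region correction.

**Group Bayesian model selection.** Fixed effects: softmax of summed
log-evidences (subject-wise BICs), plus group BIC relative to the first
(null) model. Random effects: the standard variational Dirichlet scheme
over model frequencies with uniform prior α₀ = 1; exceedance
probabilities by Monte-Carlo sampling of the posterior Dirichlet (default
10⁶ samples, seeded); protected exceedance blends exceedance with chance
1/K via the Bayes omnibus risk BOR = 1/(1 + exp(F1 − F0)), where F1 is
the variational free energy of the frequency model and F0 that of the
equal-frequency null. Limits verified: equal evidences → all
probabilities 1/K with BOR → 1; a dominant model → exceedance → 1 with
BOR → 0.

## Problem sizes

The analysis drivers run the full study scale (5 participants, 10
audiovisual sessions per report, 352 stimuli per session) for behavior
and decoding; bootstrap tests in the neural driver use 1000 draws and the
calibration driver 2000 replicates × 500 bootstraps — each driver
completes in well under a minute to ~1 minute on one core. The test suite
uses reduced scales (2 participants, 2 audiovisual sessions per report,
150-draw bootstraps) except where a property needs large samples, where a
single 52-condition experiment with 1200 trials per condition is shared
across tests as a session fixture.

## Limitations

- The synthetic observers and the neural surrogate are the *intended*
  generative processes of the analysis; passing tests show the pipeline
  recovers what it assumes, not that real observers or BOLD patterns obey
  forced fusion. In particular the neural encoder mixes locations
  linearly and does not implement genuine probabilistic fusion, so its
  "MLE predictions" (from decoded unisensory σs) need not be satisfied —
  which is precisely what the bootstrap tests are for.
- Session counts, null events, and trial budgets reproduce the published
  design; inter-stimulus timing, eye movements, motor confounds, HRF
  convolution and ROI definition are out of scope.
- Only the symmetric guess-equals-lapse tail structure is modeled; no
  asymmetric lapses, alternative sigmoids, or causal-inference observers.
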