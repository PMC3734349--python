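# Methods

This note documents the models, algorithms, defaults and design
choices behind `rtdcm`, and what the synthetic experiments do and do
not establish.

## Generative model

**Neuronal level.** Activity `z` of the four regions (VC_L, VC_R,
SPL_L, SPL_R — always in this canonical order) follows the bilinear
state equation `dz/dt = (A + Σⱼ uⱼ B⁽ʲ⁾) z + C u`. The intrinsic
structure is reciprocal VC↔SPL coupling within each hemisphere and no
interhemispheric connections; structurally absent entries are exactly
zero everywhere (they carry no free parameter at all, which is the
strongest form of a zero-variance prior). Self-connections are fixed
at −0.5 Hz rather than estimated: on 90-scan windows with seven free
coupling parameters, freeing the decay as well degrades
identifiability without changing the model comparison, and fixing it
guarantees the stability invariant (the largest real eigenvalue of `A`
is negative at any prior-mean parameterization).

**Hemodynamic level.** Each region runs an independent
balloon/Windkessel cascade (vasodilatory signal, inflow, venous
volume, deoxyhemoglobin) with classical constants κ = 0.64 s⁻¹,
γ = 0.32 s⁻¹, τ = 2.0 s, α = 0.32, ρ = 0.32, V₀ = 0.04, and BOLD
readout coefficients k₁ = 7ρ, k₂ = 2, k₃ = 2ρ − 0.2. Hemodynamic
parameters are held at these values during inversion by default; the
code paths support per-region values should a fit require freeing
transit time. BOLD is computed internally as a fraction of baseline
and exposed in percent.

**Integration.** Fixed-step classical RK4 with dt = TR/8 (0.125 s at
TR = 1 s), inputs zero-order-held between scans, state sampled at each
volume onset (no slice-timing offset — the acquisition convention is
not modeled). The step-halving error on the default design is below
1e−4 percent signal and the observed convergence order matches RK4.
A batched kernel integrates many parameter vectors at once (the
inversion's finite-difference Jacobians need 2p+1 simulations per
iteration); it exists twice — a numba-jit loop version and a
vectorized numpy version — which agree to 1e−12 and are selected by
import availability. Trajectories whose neuronal activity exceeds
|z| = 10 are flagged as diverged; the top-level simulator raises with
the divergence time, while the inversion treats such proposals as
rejected steps.

## Variational-Laplace inversion

Free parameters θ are the free A/B/C entries with zero-mean Gaussian
shrinkage priors (variance 0.25 Hz² each — weak enough not to bias
couplings of a few tenths of a Hz, strong enough to regularize a
90-scan window). Observation noise is iid Gaussian per region with
log-precision λ, Gaussian hyperprior N(0, 32) (data are in percent
units, so λ = 0 corresponds to 1% noise SD). A per-window nuisance
basis (constant + linear drift) is projected out of data and
prediction, and the effective number of observations per region is
reduced accordingly. Temporal autocorrelation is deliberately *not*
modeled at this level: the streaming cleaner whitens the data before
windows reach the inversion.

Each iteration: central-difference Jacobian (relative step 1e−4),
Levenberg-damped Gauss–Newton proposal (damping ×2 on rejection, ÷2 on
acceptance), then a co-update of the posterior covariance and λ (four
fixed-point sweeps with one Newton step on λ each — the two quantities
are mutually dependent through the expected squared residuals). The
free energy

F = Σ_r [ −½ e^{λ_r}(‖e_r‖² + tr(J_r Σ J_rᵀ)) + ½N_r λ_r − ½N_r log 2π ]
    − KL[q(θ)‖p(θ)] − KL[q(λ)‖p(λ)]

is evaluated with a point approximation e^{E[λ]} for the expected
precision. A step is accepted only if it does not decrease F;
convergence is declared after two consecutive iterations (accepted or
rejected) with |ΔF| < 0.05 nats, and the default cap is 44 iterations
— the budget that keeps a dual-model comparison inside a 60-s rest
block. With `max_iter = 0` the posterior equals the prior and F is
evaluated there (both KL terms vanish), which makes F additive over
duplicated data — a property the tests exploit. On linear-Gaussian
surrogates with fixed λ, F reproduces the analytic log evidence to
better than 1e−6 nats, and the whole procedure is deterministic:
identical inputs give bit-identical F.

Typical fits on the default synthetic trials converge in 5–15
iterations, so the 44-iteration operating point usually coincides with
full convergence; the budget study reads the capped value off the
recorded per-iteration F trajectory of fits run with a raised cap.

## Model space

`attention_pair()` builds M_aL/M_aR: attention input on the SPL of the
hemisphere contralateral to the attended side, modulation of both
directions of that hemisphere's VC↔SPL coupling. Reading the
modulation as covering *both* directions is a declared choice; the
single-direction variants exist as the "top_down"/"bottom_up" patterns.
`model_family()` enumerates the 3×4 grid (input to SPL / VC / both ×
modulation both / top-down / bottom-up / none), model 1 being the
neurofeedback architecture. There is a single external input channel
(attention); the counting-backwards baseline is modeled as zero input.

## Model comparison

logBF = F(M_aL) − F(M_aR); ties (exactly 0) count as failures — a
conservative choice. Bayes factors map to evidence categories at the
conventional thresholds 3 and 20. RFX BMS uses a uniform Dirichlet
prior (α₀ = 1 per model) and the standard variational update;
exceedance probabilities are exact via the Beta distribution for two
models and seeded Dirichlet Monte-Carlo (10⁵ draws) otherwise. For
group analyses each subject's per-trial log Bayes factors are summed
into one log evidence per condition; per-trial entries can be used
instead by passing them as rows.

## Streaming cleaner

Three strictly causal per-region stages: (1) drift removal by
subtracting an exponentially weighted running mean with exact warm-up
weights (half-life 10 scans); (2) spike clipping — samples further
than 3 robust SDs (1.4826 × running MAD) from the running median of
the drift-removed history are replaced by that median, active after a
10-sample warm-up; (3) a 2-tap exponential moving average (weight 0.6
on the current sample). Two subtleties are deliberate: the robust
statistics are computed over the *unclipped* history (feeding clipped
values back shrinks the MAD until ordinary signal gets clipped), and
the half-life default of 10 scans is the largest value at which a pure
ramp's residual slope stays below 0.005 per scan on a 200-scan run
while the 20-s block-design fundamental retains ≈0.9 gain. Because
every stage uses only past samples, streaming and offline application
are bit-identical.

The cleaner is a causal filter the generative model does not describe,
so windows that pass through it yield distorted *parameter* estimates
(the model comparison is robust to this; the credible-interval
recovery study therefore evaluates the inversion on raw simulated
windows, and the pipeline-level study evaluates only model selection).

## Synthetic data

The generator emulates the study conditions: TR = 1 s; neurofeedback
trials of five 10-s baseline blocks interleaved with four 10-s
regulation blocks (the 90-scan window), followed by 60 s rest and 5 s
feedback display; aL/aR alternating; 8 trials per run; localizer runs
of 11 baseline + 10 task blocks (210 scans). Ground truth is a single
union model with separate aL/aR input channels driving the right/left
hemisphere respectively, so one forward simulation covers a mixed
session and reduces exactly to the noiseless forward model when noise
is off.

Default effect sizes are a = 0.15 Hz intrinsic coupling, b = 0.15 Hz
modulatory increase, c = 0.04 Hz input weight. They were chosen for
three a-priori properties: the modulated network keeps a stability
margin ≥ 0.1 Hz (larger textbook-style values such as 0.3/0.4 Hz on
*both* directions of a reciprocal pair make the effective coupling
exceed the 0.5 Hz self-decay and the dynamics diverge); the
regulation-window signal is ~0.5–1% — SNR ≈ 1–2 against the default
noise; and percent signal changes land in the range attention
paradigms actually show. Noise is AR(1) (coefficient 0.3, innovation
SD 0.5% signal) plus 0.01%/scan linear drift and Bernoulli spikes
(p = 0.005 per scan, 8 SD, random sign). The volume renderer places
each ROI as a contiguous cluster in its own grid quadrant (24 voxels
SPL, 16 VC by default) with independent voxel noise.

What the synthetic data does **not** emulate: head motion,
cardiac/respiratory waveforms, scanner-specific autocorrelation
structure, spatial noise correlations, or hemodynamic variability
across regions and subjects. Passing recovery tests therefore shows
the estimator is correct and well calibrated *under its own model
class plus the stated nuisances* — not that real attention data would
yield the same rates.

## Problem sizes and numerical choices

The recovery study uses 50 seeded single-trial sessions at default
SNR (its credible-interval coverage target is 80–98% at the nominal
90%); the null-calibration study uses 200 noise-only trials (input
weight 0); both sizes keep the full suite comfortably reproducible on
a laptop-class single core. Quartiles are linearly interpolated
(type-7). Sign-test p-values always come from the unrounded z. The
permutation slope test permutes values across runs (999 permutations,
one-tailed, p never below 1/(n_perm+1)). GLM localizer: double-gamma
HRF (peak 6 s, undershoot 16 s, ratio 6), one-sided t, Bonferroni
correction over voxels — a simplified stand-in for a full
random-field-corrected localizer.

## Known limitations

- Hemodynamic parameters are fixed during inversion; regional
  hemodynamic variability is absorbed into coupling estimates.
- The Laplace posterior understates uncertainty along strongly
  nonlinear ridges (input weight vs coupling gain trade-offs), which
  is why interval coverage sits slightly below nominal.
- The cleaner is not part of the generative model (see above).
- RFX BMS does not implement protected exceedance probabilities.
- No scanner ingest, motion correction, or display hardware paths:
  the package starts at ROI time series (TSV or NIfTI + masks).
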