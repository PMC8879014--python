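# Methods

## Synthetic campaign generator

The generator emulates four sampling campaigns (dry/wet season × surface/
ground water), each summarized in the source tables by per-variable
minimum, maximum, and mean over 80 sites. Three layers:

**Marginals.** Every variable follows a scaled Beta distribution on its
published [min, max] with the mean matched exactly and a fixed
concentration α + β = 6. With only three published numbers per variable
this is the simplest bounded family with an exact mean match; α + β = 6
gives unimodal, moderately dispersed shapes. Variables whose mean sits
near a range endpoint (wet-season groundwater Pb: mean 0.11831 of range
[0.05496, 0.12178], mean fraction 0.95) become strongly skewed — a real
property of the field summaries, with consequences discussed under
*Limitations*.

**Feature dependence.** The four physicochemical features are coupled by a
Gaussian copula. The EC–TDS Spearman target (0.6 by default) is converted
to the Gaussian correlation by r = 2·sin(πρ/6); any non-PSD user matrix is
projected to the nearest positive-semidefinite correlation by eigenvalue
clipping.

**Response surface.** Each metal's latent score is
s = Σᵢ aᵢ·tanh(zᵢ) + b·tanh(z_p z_q), with z the features standardized by
their Beta-implied moments — smooth, bounded, nonlinear, and learnable by
a small tansig network. The noisy score (Gaussian noise with sd =
`noise_rel_sd` × the latent spread, default 5 %) is rank-transformed to
plotting positions (r − ½)/n and pushed through the metal's Beta quantile
function. Injecting noise *before* the monotone mapping keeps every
marginal exactly calibrated even at skewed endpoints, where post-mapping
multiplicative noise plus clipping would bias the mean. Metals reported as
positively associated (Cr–Cd everywhere; Cu–Zn, Cd–Cu, Cd–Pb, Ni–Pb in
surface water; Cr–Ni, Cr–Pb, Cd–Ni, Cd–Pb, Fe–Zn in groundwater) share
closely aligned coefficient vectors, which produces Spearman correlations
≥ 0.95 for every configured pair; pH carries a negative loading for the
dissolved-metal cluster, consistent with acid-mine-drainage chemistry.

What the generator does **not** emulate: spatial structure and kriging
smoothness, temporal autocorrelation, censoring at detection limits, and
any feature→metal relationship beyond the assumed smooth monotone surface.
Passing tests therefore demonstrate that the pipeline recovers a smooth
learnable relationship under realistic marginals and dependence — not that
such a relationship holds in any particular aquifer.

## Preprocessing

Min–max normalization to [−1, +1] is affine and unclipped (values outside
the fitted range map outside [−1, 1]), so it is exactly invertible. The
default fitting scope is the whole dataset, with a leakage-safe
`train_only` option. The 70/15/15 split uses floor rounding for train and
validation with the remainder to test, giving 56/12/12 at n = 80.

## Training

The 4-HN-1 network uses exact `tanh` hidden units and a linear output
(targets are already on [−1, 1]; a tansig output is available by flag but
saturates at the range endpoints). Parameters flatten to a vector of
6·HN + 1 entries in the order: input weights row-major, hidden biases,
output weights, output bias.

PSO defaults are the standard constriction values ω = 0.729,
C_a = C_b = 1.49445, swarm 10, positions initialized uniform in [−1, 1]^D,
velocities in [−0.1, 0.1]^D, velocity clamp 1.0, positions clipped to
[−10, 10]^D (bounded weights keep tansig units out of deep saturation).
The fitness is the training-partition MSE. Each iteration the incumbent
global best is scored on the validation partition; the run stops after 200
validation-stagnant iterations and the best-by-validation incumbent is
returned.

The swarm solution is then refined by a damped Gauss–Newton
(Levenberg–Marquardt) descent with an analytic Jacobian, run from the
swarm solution and from two deterministically jittered restarts (the swarm
can park in a shallow basin); validation MSE is monitored at every
accepted step and the best-validation iterate across all paths is kept.
Refinement never returns a model worse on validation than its input.

Topology selection sweeps hidden-neuron counts (full mode 1–30 with 2000
iterations; desk mode 5..30 step 5 with 500 iterations) and picks the AIC
minimum, AIC = N·ln(validation MSE, normalized scale) + 2·HN with N the
full dataset size; ties break toward the smaller HN. The study protocol
repeats the sweep under 3 replicate seeds and keeps the governing model
with the lowest validation MSE. Every seed is derived deterministically
from the root seed via hashed seed sequences, so any run replays exactly.

## Metrics

MSE and Pearson R are standard; AIC uses the validation MSE as above and
reports −∞ for an exactly zero MSE. KGE uses population standard
deviations and predicted/observed ratios for the variability (VE) and bias
(BT) terms, and is computed on the natural (mg/L) scale — normalized
targets can have near-zero means, which makes BT ill-conditioned — on the
combined validation+test partition by default. Metric tables report both
normalized and natural-scale MSE.

## Baselines and sensitivity

Linear families: ordinary least squares, Huber-robust IRLS (tuning
constant 1.345), and bidirectional stepwise selection by AIC. Kernel
families: epsilon-insensitive SVR with box constraint 1, epsilon =
iqr(target)/13.49, polynomial kernels of degree 2 and 3, and Gaussian
kernels at scales √p/4, √p, 4√p for p = 4 predictors (γ = 1/scale²). All
baselines fit on the training partition only; the comparison report
divides the network's test-partition R by the best linear and best kernel
R per metal.

Olden importance normalizes by the sum of *absolute* per-input
contributions (the signed grand total can be zero or negative) and reports
the signed contributions alongside, so percentages always sum to 100 and
direction is preserved.

## Problem sizes and numerical choices

Desk mode — the default for routine runs, tests, and the acceptance
script — uses n = 80 per campaign, 500 swarm iterations, hidden neurons
5..30 step 5, and 3 seed replicates; the whole 32-model study completes in
about two minutes on one CPU. Full mode restores the 1–30 sweep at 2000
iterations. Degenerate inputs are rejected with explanatory errors:
constant columns in the normalizer, empty sample sets in the fitness,
zero-variance vectors in Pearson R, zero observed mean or variance in KGE,
all-zero contributions in the Olden analysis.

## Known limitations

At n = 80 a skewed metal's sample minimum is an isolated point in
normalized space (for wet-season groundwater Cr the lowest normalized
value is −1.0 against −0.71 for the runner-up). When such a point falls in
the 24 held-out rows — probability ≈ 0.3 per metal under the random
split — no regressor trained on the remaining 56 points can resolve it,
and the natural-scale KGE of that model drops into the 0.82–0.95 range
even though validation R stays above 0.98. Independent flexible regressors
(a 50×50 MLP, RBF kernel ridge) hit the same ceiling, confirming this is a
small-sample extrapolation limit of the study conditions rather than a
trainer defect. Consequently a handful of the 32 desk-scale models
typically fall below the 0.95 KGE mark that the remaining models clear
comfortably; validation MSE and R envelopes are unaffected. Larger
campaigns (n ≳ 500) remove the effect.

The copula covers the features only; metal–metal dependence is induced
through shared response structure, which yields somewhat stronger pair
correlations (≈ 0.95) than the moderate positive associations reported for
field data. Pair-specific response designs could weaken them if needed.
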