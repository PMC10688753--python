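# Methods

This note documents the models, numerical choices and limitations of the
`spikemeta` pipeline: simulation of a two-population spiking network,
spectral summaries of its activity and local field potential (LFP),
conditional-density metamodels of those spectra, and posterior inference
over the network parameters.

## Point-neuron network

The network contains an excitatory population (N_E = 8000) and an inhibitory
population (N_I = 2000) of leaky integrate-and-fire neurons with
current-based alpha synapses. Subthreshold dynamics follow

    tau_m dV/dt = -V + R_m I,     R_m = tau_m / C_m,

with the leak reversal at 0 mV. A synaptic event injects an alpha current
`I(t) = J (t/tau_syn) exp(1 - t/tau_syn)` with peak amplitude J (excitatory)
or -gJ (inhibitory); the charge transferred per event is `e tau_syn J`.
Because J and tau_syn act multiplicatively on the charge, the synaptic
strength is parameterized by the total charge transfer `Q_s = tau_syn J`.
Each neuron receives a fixed number of incoming connections — C_E = 800
excitatory and C_I = 200 inhibitory sources drawn uniformly with
replacement, so multapses and autapses occur — plus an independent external
Poisson drive at rate `nu_ext = eta * nu_thr`, where
`nu_thr = V_thr C_m / (J tau_m e tau_syn)` is the rheobase rate: the
constant input rate at which the stationary mean membrane potential equals
the threshold. Ten parameters are varied (eta, g, Q_s, tau_m, C_m, t_d,
t_ref, tau_syn, V_thr, V_reset) inside a box domain; eta is capped at 3.5
because larger external drive pushes the network into strongly synchronous,
unbalanced regimes that the study deliberately avoids.

**Exact integration.** The state (V, I, z) of each neuron — membrane
potential plus the two stages of the alpha-synapse cascade — is linear
between spikes, so one time step is the matrix exponential of the system
matrix times dt, computed once per parameter point with `scipy.linalg.expm`.
A unit test checks one propagator step against adaptive high-accuracy ODE
integration to relative error below 1e-8. Threshold crossings are detected
on the grid (no interpolation), after which V is clamped to V_reset for
t_ref; delays and refractory periods are rounded to the nearest step
(minimum one). Poisson input enters as per-step event counts folded into the
synaptic channel; each event carries the same charge as a recurrent
excitatory event, and the per-event charge is exact under the propagator
regardless of dt. Both excitatory and inhibitory inputs share one synaptic
channel with signed weights, which is valid because tau_syn is common to
both synapse types. The inner loop is JIT-compiled with numba.

**Units.** All internal computation uses (ms, mV, pA, pF); charge is then
fC, and the rheobase formula yields a rate in 1/ms which the public API
converts to spikes/s.

**Activity and exclusion.** Population spike counts are recorded in
half-open 1 ms bins over the post-transient window (default 500–10500 ms).
Runs with strongly synchronous activity are flagged by two ad hoc counts:
bins in which more than 10% of all neurons fire, and bins in which fewer
than 0.25% fire. A run is excluded when the first count exceeds 150 *and*
the second exceeds 500; the conjunctive reading was chosen because the two
criteria jointly describe the oscillatory silent/burst signature, and both
counts are reported so the disjunctive reading can be audited. The fractions
are network-wide; this choice is isolated in `synchrony_flags`.

## Kernel-based LFP

The LFP at six depth channels is computed as the convolution of each
population's spike-count signal with a population-averaged spatiotemporal
kernel, summed over the excitatory and inhibitory presynaptic populations.
Each averaged kernel factorizes into a *unit* kernel (channel response to a
unit synaptic current in one time step) convolved with the alpha PSC and
shifted by the synaptic delay; the inhibitory sign enters through the PSC
amplitude (-gJ), so the final sum needs no extra bookkeeping. Unit kernels
are tabulated on a grid of per-area membrane capacitance
c_m ∈ {0.4, 0.6, 0.8, 1.0, 1.2} and membrane time constant
tau_m ∈ {15, 18, 21, 24, 27, 30} ms and queried by bilinear interpolation
(no extrapolation). The point-network C_m (pF) maps onto the per-area axis
proportionally around a declared baseline of 200 pF ↦ c_m = 1.0 (the domain
midpoint); the anchor is a convention of this package, isolated in
`cm_scale_query`.

Morphology-derived kernels require a multi-compartment electrostatic
forward model, which is outside this package's scope. `synthetic_kernel_bank`
generates a synthetic stand-in with the qualitative features of laminar
kernels: a derivative-of-Gaussian depth profile (sign inversion across
channels, amplitude decaying away from the sink/source pair), a causal
difference-of-exponentials time course whose slow component scales with
tau_m and whose amplitude scales inversely with c_m, and population-specific
depth centres and rise times. Kernels are 200 ms long (the slowest time
course decays well below 1% of peak) and are generated and convolved at the
1 ms analysis resolution; the PSC is composed at the 0.1 ms simulation
resolution and bin-integrated down to 1 ms so the per-event charge is
preserved without aliasing.

## Spectra

Power spectral densities use Welch's method (`scipy.signal.welch`) on the
1 kHz signals: Hann window of length 256, overlap 128, one-sided, density
scaling, no detrending. Metamodels are trained on log10 power. The DC bin is
dropped from metamodel targets — it is dominated by the mean rate or LFP
offset rather than fluctuations — leaving 128 bins per channel; a power
floor of 1e-20 guards exactly silent channels before the logarithm. The
spike-variant dataset concatenates both populations' spectra (256 outputs);
the LFP variant concatenates the six channels (768 outputs). Excluded runs
never enter a dataset.

## Deep-GP metamodel

The conditional density p(spectrum | parameters) is modelled by a two-layer
deep Gaussian process: ten first-layer GPs map the unit-cube-scaled
parameters to hidden features, P = 16 second-layer GPs map the features to
latent functions g, and the D-dimensional output is a learned linear mixture
f = W g plus per-dimension Gaussian noise, giving a low-rank predictive
covariance. All GPs use Matérn 5/2 kernels with ARD lengthscales and zero
mean; each layer shares one kernel across its GPs to keep the parameter
count down. Training maximizes the doubly stochastic variational bound:
first-layer outputs are sampled with the reparameterization trick, while the
second layer's expected log-likelihood is closed-form through the linear
mixing. Inducing outputs are whitened, so each GP's KL term is a standard
normal KL. The hidden width (10), latent dimension (16) and inducing count
(128 at full scale, fewer when the training set is small) are configuration
keys with declared defaults rather than tuned values.

Because no GPU autodiff framework is part of this package's dependency set,
training runs on a small in-repo reverse-mode autodiff engine
(`spikemeta.autodiff`) with an Adam optimizer; its gradients — including the
Cholesky and triangular-solve primitives — are verified against finite
differences in the test suite. Two further choices matter in practice:

- **Natural initialization.** The final layer's variational means and
  covariances are initialized at their closed-form optimum given the initial
  kernel, with pseudo-targets `W⁺x` and per-latent effective noise
  precisions. For the collapsed configuration this *is* the optimum; in
  general it removes most of the optimization burden from Adam. W itself is
  initialized from the principal components of the standardized outputs, and
  the first layer's whitened means are chosen so its posterior mean
  approximates the centred inputs (an identity-like warm start, since the
  layers have zero mean functions).
- **Oracle equivalence.** In the collapsed configuration (one layer,
  inducing points at all training inputs, identity mixing, fixed
  hyperparameters) the trained model is checked against the closed-form GP
  posterior: predictive mean within 1e-2 and variance within 10%.

Predictions treat outputs as independent Gaussians given the parameters
(mean W E[g], variance W² Var[g] + noise); the latent low-rank structure is
retained on the prediction object, and `sample` uses the generative path
(draw g, then W g + noise). By default prediction propagates the first
layer's posterior mean deterministically; moment-matched averaging over
sampled features is available via `n_samples`. Inputs are min-max scaled to
[0, 1] by the domain bounds, outputs standardized per dimension; both
transforms are stored with the model. Cholesky factorizations carry a 1e-6
jitter.

## MAF baseline

The masked autoregressive flow stacks five autoregressive affine transforms,
each a one-hidden-layer MADE network (50 tanh units) with the conditioning
vector fed unmasked into every layer; the variable order reverses between
transforms and the base distribution is standard normal. Log-scales are
tanh-clamped at ±7 for stability. Training maximizes conditional
log-likelihood with Adam and early stopping on a validation split
(patience 50 checks); dropout and other regularization are off by default.
Inputs and outputs are standardized, and the log-density carries the
standardization Jacobian, so densities refer to the original data scale.
The MAF and deep-GP models expose the same log_prob/sample interface, and
the inference module runs unchanged against either.

## Posterior inference

The posterior p(theta | x0) ∝ p(x0 | theta) p(theta) uses a uniform prior
over the parameter box and the metamodel's log-density as surrogate
likelihood. Sampling is Gaussian random-walk Metropolis with covariance
adaptation: during the burn-in phase the proposal covariance is re-estimated
every 100 proposals from the chain's own history (after the first 500
proposals; before that, a diagonal fallback), with a 1e-10 regularization
jitter, and a separate scalar factor is tuned on the log scale by
Robbins-Monro stochastic approximation toward an acceptance ratio of 0.3.
Both are frozen at the end of burn-in. Defaults: five chains of 40000
proposals each with the first 12000 discarded, no thinning; chains start at
independent uniform draws from the prior box. Convergence is diagnosed per
parameter with the Gelman-Rubin potential scale reduction factor in the
split-chain variant (each chain halved; the plain variant is available via a
flag). On a well-conditioned 10-D correlated Gaussian the realized
post-burn-in acceptance ratio lands within a few hundredths of the 0.3
target, the posterior mean within Monte-Carlo error and the covariance
within 10% Frobenius error.

Posterior-predictive checks draw parameter vectors from a posterior, re-run
the simulator pipeline, and report the maximum absolute log-spectral
distance to the conditioning output over frequencies and draws.

## Scaled-down study conditions

The full-scale study (10000 simulations of the 10000-neuron network for
10.5 s) is far beyond a single desk CPU, so the packaged tests and the
`desk` pipeline scale run a reduced protocol chosen to preserve the
qualitative behaviour: N_E = 800, N_I = 200 (in-degrees scaled by the same
ε = 0.1), T_sim = 2500 ms with the same 500 ms transient, a 250-run Latin
hypercube corpus (200 training, 50 held out), 64 inducing points and 300
training epochs for the deep GP, and four MCMC chains of 6000 proposals for
recovery checks. Under these conditions the deep-GP metamodel beats the
constant train-mean predictor on held-out max-over-frequency error, and
posteriors conditioned on held-out spectra cover the true parameters with a
mean standardized distance below 1.5. Quantities that depend on absolute
scale (error magnitudes, exclusion fraction, posterior widths) are *not*
expected to match the full-scale study; directions and orderings are.

## What the synthetic data do and do not show

The synthetic kernel bank reproduces the structure the LFP pipeline needs
(causality, smooth laminar dipole profile, correct parameter scalings) but
not the quantitative shape of morphology-derived kernels, so LFP results are
structurally faithful and physically uncalibrated. The reduced network is a
genuine spiking simulation, not a surrogate, but its finite-size
fluctuations are ~10x stronger than at full scale, which widens the spectra's
conditional distribution and hence the posteriors. Passing tests demonstrate
correctness of the machinery and direction of the scientific effects, not
the full-scale effect sizes.

## Known limitations

- Metamodel training is CPU-bound numpy; full-scale (8000-example, 768-D)
  training is feasible but slow compared to GPU frameworks.
- The deep GP is fixed at two layers or fewer; no non-Gaussian likelihoods;
  the full D×D predictive covariance is never materialized.
- MAF sampling inverts the autoregression dimension-by-dimension, so
  drawing high-dimensional spectra is O(D) network passes per transform.
- No sequential (multi-round) inference; posteriors are single-round over
  the whole prior box.
- The exclusion-criterion bin thresholds are absolute counts defined for the
  10000-bin full-scale window; at reduced window lengths they are
  proportionally lenient, which matters only near the synchrony boundary.
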