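# Methods

## Overview

`alnbrain` implements a whole-brain network model of resting-state cortical
activity and the analysis battery used to compare connectivity and temporal
dynamics between conditions or groups. Each of 80 cortical regions is a
two-population mean-field node (the ALN model: a linear–nonlinear cascade
reduction of coupled excitatory/inhibitory populations of adaptive
exponential integrate-and-fire neurons). Nodes are coupled
excitatory-to-excitatory through a structural connectome with axonal delays,
excitatory rates are converted to BOLD with the Balloon–Windkessel model, and
the resulting regional time-series are scored with functional connectivity
(FC), global brain connectivity (GBC), Kuramoto synchrony and metastability.
Perturbation experiments scale disease-associated parameters over a cohort of
fixed-seed "virtual subjects" and test condition differences with effect
sizes and permutation inference.

Unit conventions: currents are expressed per capacitance (mV/ms), rates in
kHz, time in ms inside the model; Hz and seconds appear only at reporting
boundaries.

## Population transfer functions (`transfer_tables`)

The mean-field node needs three stationary maps of the exponential
integrate-and-fire (EIF) population driven by white noise with mean `mu` and
amplitude `sigma`:

* `Phi_r(mu, sigma)` — stationary population rate. Computed by threshold
  integration of the stationary Fokker–Planck equation: the scaled density
  `q = p/r` is marched downward from the spike threshold `V_s` with unit
  probability flux above the reset and zero below, using an
  exponential (frozen-coefficient) integrator that is robust in the stiff
  drift regions; the rate follows from normalization including the
  refractory mass `r*T_ref`. Deep subthreshold points overflow the scaled
  density; a running renormalization keeps the integrals finite and returns
  a rate that underflows to zero gracefully.
* `Phi_V(mu, sigma)` — mean membrane voltage of the same stationary density,
  with the refractory mass placed at the reset potential. It drives the
  subthreshold adaptation current.
* `Phi_tau(mu, sigma)` — the effective timescale of the exponential filter
  in the cascade model. The linearized Fokker–Planck system is solved at
  five low frequencies (2–60 Hz) by the same downward marching with delayed
  re-injection at the reset, and a one-pole filter
  `|R(omega)| = R(0)/sqrt(1 + (omega*tau)^2)` is least-squares fitted, with
  `R(0)` from a finite difference of the stationary rate. Where the rate is
  below 1e-5 kHz (quiescent, timescale irrelevant) `tau` falls back to the
  membrane time constant; `tau` is clamped to [1, 100] ms, the lower bound
  keeping the forward-Euler network integration stable.

Grids default to `mu` in [−4, 6] mV/ms (step 0.05) and `sigma` in
[0.1, 5] mV/√ms (step 0.1). The lower `mu` bound is dictated by the
adaptation-shifted lookup current `mu_E − I_A/C`, which visits ≈ −3 mV/ms in
the down-state phase of the slow oscillation at the default adaptation
strength. Queries interpolate bilinearly and clamp at the grid edges.
Surfaces are validated against an independent Monte-Carlo simulation of
uncoupled EIF neurons (Euler–Maruyama); agreement is below 1% relative in
the supra-threshold regime, far inside the 20% band the tests enforce.

The AdEx reset potential is not part of the published parameter table; it is
set to −70 mV, the conventional value for this parameter set.

## Node and network dynamics (`network`)

State per node and population `a ∈ {E, I}`: mean membrane current `mu_a`, OU
noise current, four synaptic activation means `s_ab` and variances
`var_s_ab`, the mean adaptation current `I_A` (E only), and the rates/voltage
refreshed from the tables. The effective input rate from population `b` to
`a` is

    r_ab = (c_ab/|J_ab|) * tau_s_b * (K_b * r_b(t − d_a)
           + delta_abE * K_gl * sum_j C_ij * r_E,j(t − D_ij))

with the variance drive `rho_ab` using the squared prefactor and `C_ij^2`.
One presynaptic spike contributes a postsynaptic current of amplitude
`c_ab`, i.e. activates a fraction `c_ab/|J_ab|` of the remaining inactive
synapses; this makes `r_ab` dimensionless and reproduces the spiking
network's synapse exactly, and the sign of `J_ab` lives only in the current
`mu_syn_a = J_aE*s_aE + J_aI*s_aI`. Inter-regional coupling is exclusively
E→E, scaled by the global coupling strength `K_gl`; local delays are
target-population specific (`d_E` = 4 ms, `d_I` = 2 ms) and inter-regional
delays come from fiber length over signal speed, rounded to the 0.1 ms step.

The membrane currents integrate `tau_a(mu,sigma) * dmu_a/dt = mu_syn + mu_ext
+ mu_ou − mu_a`; the current variance combines the synaptic variances with
the external noise floor `sigma_ext^2`. The mean adaptation current follows
the adiabatic form `dI_A/dt = (alpha*(V_E − E_A) − I_A)/tau_A + beta*r_E`
and shifts the E population's table lookups by `−I_A/C`. The spike-triggered
term enters with a positive sign (adaptation grows with firing and is
subtracted from the drive); the opposite sign would make adaptation vanish
with activity, contradicting its role as an activity-dependent inhibitory
current.

Numerics: forward Euler at `dt = 0.1 ms` for the slow variables (membrane
currents, adaptation, OU noise, with the OU update in Euler–Maruyama form).
The synaptic mean/variance equations are stiff when the drive is large
(`r_ab` of order 50 gives a local rate constant beyond Euler's stability
limit at 0.1 ms), so they use the exponential update of the locally linear
ODE — exact for frozen drive, identical to Euler as `dt → 0`, and keeping
`s` in [0,1] and the variance non-negative without clamping. Halving `dt`
moves stationary rates by well under 2%. Each simulation is a pure function
of (connectome, parameters, seed): noise streams (one OU process per
population per region) derive from a single seeded generator, and history
buffers start from a small common rate (0.05 kHz) so that coupling-sustained
network states are reachable from rest; the first 5 s are discarded.
Rate traces are stored at 1 ms resolution.

Default parameters are the whole-brain resting-state set (external drives
`mu_E_ext = 1.63`, `mu_I_ext = 0.05` mV/ms, noise `sigma_ou = 0.19`,
`tau_ou = 5 ms`, adaptation `alpha = 28.26 nS`, `beta = 24.04 pA`,
`tau_A = 200 ms`, coupling `K_gl = 250`, signal speed 20 m/s; synaptic
weights as in `PopulationParams`). Runs default to 70 s with a 5 s transient.

### Fidelity and its limits

Against a 10,000-neuron recurrent AdEx network (8,000 E with per-neuron
adaptation, 2,000 I; 800/200 random inputs per neuron; saturating
current-based synapses; identical parameters), the mean-field node matches
the stationary excitatory rate to ~1% with adaptation disabled and to ~5% in
stationary adapted states (external E drives ≥ 5 mV/ms). At the default
fitted drive the isolated node is in a bistable/bursting regime where the
adiabatic mean-adaptation approximation over-synchronizes the population:
the mean-field produces coherent burst cycles where the spiking network
holds a noisy steady state, and time-averaged rates can differ by a factor
of ~2. The fidelity tests therefore pin the stationary operating points
(5.5 and 6.0 mV/ms); the bursting-regime discrepancy is a known limitation
of this model class, not of the implementation, and whole-brain conclusions
rest on condition *contrasts*, which share the regime.

## Hemodynamics (`hemodynamics`)

Standard four-state Balloon–Windkessel system per region (vasodilatory
signal, inflow, venous volume, deoxyhemoglobin) with the conventional
resting-state parameter values (kappa = 0.65 s⁻¹, gamma = 0.41 s⁻¹,
tau_h = 0.98 s, Grubb exponent 0.32, resting extraction 0.34, V0 = 0.02,
k1 = 7*rho_E, k2 = 2, k3 = 2*rho_E − 0.2). The neural drive is the
excitatory rate minus its run mean, scaled by 1 per kHz; starting the system
exactly at its resting fixed point removes the hemodynamic onset transient,
which matters for runs of tens of seconds. Output is percent signal change
decimated to the scanner TR (2 s by default, matching the empirical arm).
Correlation-based measures are insensitive to the drive scale in the
operating range. Euler at the input resolution (1 ms) is within 1% of an
adaptive-step reference.

## Measures (`metrics`)

* FC: Pearson correlations over the whole acquisition.
* GBC: a region's mean correlation to the *other* regions (self-correlation
  excluded, divisor n−1); the literal all-j reading is available via
  `include_self=True` and differs only by an affine shift that cancels in
  group contrasts. Global, per-network, and association/sensory summaries
  are means of regional GBC over the respective region sets (association =
  default-mode + control + salience/ventral-attention; sensory =
  somato-motor + visual + dorsal-attention; limbic belongs to neither).
* Synchrony/metastability: signals are band-passed to 0.04–0.07 Hz with a
  2nd-order zero-phase Butterworth (reflective padding, no trimming), phases
  come from the analytic signal, and the Kuramoto order parameter
  `R(t) = |mean_k exp(i*phi_k)|` is summarized by its time mean (synchrony)
  and standard deviation (metastability). Series covering fewer than five
  passband cycles trigger a warning: phase estimates are then
  edge-dominated, which inflates between-subject variance of `mean_R` (the
  30 s desk-scale runs have ~3.4 cycles; both conditions of any comparison
  share the bias).

## Statistics (`stats`)

Welch's t-test (the default variant; it reproduces the demographic worked
example to the printed precision) from summary statistics, Pearson 2×2
chi-square with optional Yates correction, Hedges' g (small-sample corrected
standardized mean difference, CI from the normal-approximation variance),
and a two-sided label-permutation test (exhaustive enumeration up to 12
observations, otherwise Monte-Carlo with the identity permutation counted in
numerator and denominator). A paired sign-flip permutation test is provided
for the fixed-seed virtual-subject design and reported alongside the
label-permutation p in comparison tables; the label permutation is the
convention of the published comparison tables and is what the experiment
summaries use for significance calls. No multiple-testing correction is
applied across measures, matching the original analysis; consumers should
read the tables accordingly.

## Perturbation experiments (`experiments`)

Four families, each applied multiplicatively to its parameters with the
reference scale 1.0 always included: `gaba_weights` scales J_EI and J_II
jointly (range 100%→60%), `glut_drive_to_I` scales J_IE (100%→60%),
`global_coupling` scales K_gl (100%→60%), `noise_level` scales sigma_ou
(100%→140%). A virtual cohort is a fixed list of master seeds reused in
every condition, so conditions differ only through the perturbed parameter.
Desk-scale defaults for the validation suites are 10 subjects, 30 s runs and
5,000 permutations; the full-scale design (40 subjects, 70 s) runs through
the same code path.

The evolutionary fit is a rank-selection (mu+lambda) strategy: uniform
initialization within box bounds, tournament-of-3 parent selection,
per-dimension arithmetic crossover, Gaussian mutation with scale
0.2·range·0.9^generation, elitist truncation. Individuals whose objective
fails are discarded with a log entry. The default objective is the Pearson
correlation between simulated and target FC (upper triangle). The fit stage
is optional: default parameters already define the reference model.

## Synthetic data (`synthetic`)

The generators replace the study's MRI-derived inputs so every stage runs
and is tested offline; all are pure functions of (parameters, seed).

* Connectome: regions on a 70 mm sphere; weights `exp(−d/35 mm)` with
  multiplicative lognormal jitter (sd 0.8), thresholded to 30% density,
  symmetrized and max-normalized; fiber lengths are Euclidean distances.
  The defaults reproduce what matters statistically about max-normalized
  probabilistic-tractography matrices: heavy-tailed weights and a total
  normalized input per region near 2. That scale places the default model on
  the *rising* branch of the coupling–connectivity relationship — the regime
  the perturbation analysis assumes (reducing coupling must reduce
  connectivity). Substantially stronger substrates push the network past its
  synchronization peak and invert that relationship; substantially weaker
  ones leave it silent at the default drive.
* Group-average connectome (`synth_average_connectome`): the perturbation
  experiments model on an averaged substrate, as the study design does. A
  fixed spatial layout plays the role of the atlas (identical across seeds),
  43 per-subject jitter realizations are averaged after max-normalization
  and re-normalized, and the kernel length (15 mm) is set so that the
  averaged, re-normalized matrix again delivers total relative input per
  region near 2. Averaging matters beyond realism: a *single* jittered
  matrix's total coupling fluctuates by a factor of ~2 across realizations,
  enough to push individual substrates across the synchronization peak and
  flip the sign of the coupling contrast; the average substrate holds the
  operating point stable for any generator seed.
* Partition: seven functional networks with realistic size imbalance;
  association/sensory super-groups derive from the standard grouping.
* Two-group BOLD: each subject mixes a shared narrowband (0.04–0.07 Hz)
  latent drive, phase-offset per region, into independent narrowband region
  noise. The mixing coefficient is calibrated analytically per subject
  (expected off-diagonal correlation `lam^2 * exp(−jitter^2)` equals a GBC
  target drawn around the group mean), so an imposed mean GBC reduction of
  0.11 with subject SD 0.17 yields a standardized effect near −0.65.
  Patients additionally receive larger static phase jitter
  (`0.25 + 2*sync_effect` rad), reducing the Kuramoto order parameter by
  approximately the requested amount — the synchrony calibration is
  first-order, not exact. This latent-drive construction is deliberately
  independent of the network simulator, so the empirical-arm pipeline is
  tested without circularity. It does not emulate scanner noise physics,
  spatial autocorrelation of real parcellations, or hemodynamic variability
  across regions; passing tests therefore demonstrate correct *pipeline
  inference*, not realism of any single subject's series.
* Motion table: lognormal framewise-displacement summaries with a group
  shift; the exclusion filter refuses to proceed if a group would drop below
  two subjects.

## Validation suites (`validation`) and problem sizes

The packaged checks are sized for a single CPU: the perturbation pattern
suite uses 10 virtual subjects × 30 s runs on the 80-region group-average
synthetic connectome (≈10 minutes), mean-field fidelity uses two operating
points × 12 s of 10,000-neuron spiking (≈4 minutes), calibration uses 500
null replicates and 100 effect-recovery replicates at 40 regions. At these
sizes the global-connectivity contrasts of the two global families are
large and significant (g ≈ 1.6–4 depending on the seed, permutation
p ≤ 0.006) and the local synaptic families stay non-significant. The
*synchrony* contrasts carry the right sign but limited power: mean_R is
estimated from 12 volumes (~3.4 passband cycles), which puts most of the
per-subject variance in the estimator rather than the dynamics, and its
permutation p fluctuates between ~0.001 and ~0.5 across seeds at n = 10.
Detecting the synchrony effects reliably needs the full-scale design
(40 subjects, 65 s of signal), which is what gave the published comparison
tables their synchrony significance.

## Known limitations

* The adiabatic mean-adaptation bursting mismatch described above.
* Desk-scale synchrony estimates rest on ~3 passband cycles.
* The synthetic substrate is statistically, not anatomically, realistic;
  absolute measure values are not comparable to empirical cohorts, only
  within-package contrasts are.
* Heterogeneous per-region parameters, subcortical nodes and stimulation
  protocols are out of scope.
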