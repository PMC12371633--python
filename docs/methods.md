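# Methods

`sedcm` implements a complete inferential chain for asking how synaptic
physiology shapes scalp EEG during status epilepticus (SE) and its response
to benzodiazepines (BZPs): a generative neural mass model of a cortical
column, Bayesian inversion of that model from single-channel power spectra,
a hierarchical (parametric empirical Bayes) layer for group questions, and
forward simulation over synaptic parameter space. Because no patient EEG is
distributed with the package, a synthetic-cohort generator defines the
study conditions under which every stage is validated.

## The canonical microcircuit

The model is a canonical microcircuit (CMC): four coupled neural masses
representing spiny stellate cells (`ss`), superficial pyramidal cells
(`sp`), inhibitory interneurons (`ii`) and deep pyramidal cells (`dp`).
Each population's mean depolarization v_k responds to its net synaptic
input u_k through a normalized alpha kernel with rate κ_k = 1/τ_k:

    v̈_k = κ_k² u_k − 2 κ_k v̇_k − κ_k² v_k

The kernel has unit DC gain, so all coupling strengths are dimensionless
loop gains, independent of the target population's time constant. Net input
is a signed sum of presynaptic depolarizations: excitatory edges
ss→sp, ss→ii, dp→ii enter positively; inhibitory edges ii→ss, ii→sp, ii→dp
and the four recurrent self-modulatory gains negatively. The sigmoid
activation is linearized at the operating point with its slope absorbed
into the gains — appropriate because spectral fitting addresses
steady-state fluctuations, not large excursions. Exogenous innovations
drive the spiny stellate (granular input) population; the observed signal
weights superficial pyramidal depolarization (1.0) with a smaller deep
pyramidal contribution (0.3). Conduction delays are omitted: with a single
source they are not identifiable from one channel.

This yields a linear state space with 8 states (v, v̇ per population).
The predicted one-sided EEG density on the 1–45 Hz grid (0.5-Hz steps) is

    g(f) = obs_gain² |T(f)|² g_u(f) + g_n(f),     T(f) = C (2πif·I − A)⁻¹ B

with neuronal innovations g_u(f) = input_white + input_pink/f and additive
channel noise g_n(f) = noise_white + noise_pink/f (the pink exponent is
fixed at 1).

**Parameters.** 14 variable synaptic parameters — 4 time constants, 3
excitatory, 3 inhibitory, 4 self-modulatory couplings — plus 5 nonneuronal
scalings (two innovation amplitudes, two channel-noise amplitudes, the
electrode gain). All are stored as log-deviations from packaged default
means (`actual = default · exp(θ)`), which makes positivity automatic.
Default means: τ = 2, 2, 16, 28 ms for ss, sp, ii, dp; inter-population
gains 2.25; self gains 1.0; obs_gain 30 (maps unit model variance onto a
realistic µV scale); channel-noise floor 1 + 2/f µV²/Hz. The gain
magnitudes were chosen once, by numerical exploration, so that the default
point is comfortably stable while an oscillatory (Hopf-type) stability
boundary with a ~25-Hz critical mode lies within physiological reach of the
inhibitory couplings — the dynamical substrate of the seizure-termination
analysis below. They are package conventions, not measured quantities.

**Simulation.** `simulate_timeseries` integrates the linear system with an
exact zero-order-hold discretization at 4× the requested sampling rate
(hold distortion < 1% below 45 Hz), driven by innovations synthesized with
the spectral density g_u (random phases, chi-distributed amplitudes, i.e. a
genuine Gaussian process realization), adds channel noise with density g_n,
and resamples. The agreement between the Welch estimate of such simulations
and the analytic spectrum — within sampling error at every grid point — is
the package's core forward-model validation.

## Spectral estimation and medication epochs

Welch estimation uses 4-s Hann windows at 50% overlap (0.25-Hz native
resolution, interpolated to the model grid); the estimator also returns a
conservative standard error from the per-segment periodogram spread with
the effective segment count taken as half the raw count. Medication epochs
follow fixed clinical windowing rules: both epochs are 300 s; the
pre-medication epoch ends 60 s before drug administration; the
post-medication epoch starts 360 s after administration in nonresponders,
and 60 s after electrographic termination (or the last seizure offset, for
intermittent SE) in responders. Clinical bands are delta 1–4, theta 4–8,
alpha 8–13, beta 14–30 and gamma 30–45 Hz, the gamma upper edge capped by
the fit band.

EDF recordings can be read (one channel by name, events from a JSON
sidecar); recordings and spectra serialize to plain CSV with JSON sidecars.
No EDF writer is provided.

## Variational-Laplace inversion

The observation model places independent Gaussian residuals on log-power:
log y(f) = log g(f; θ) + ε, ε ~ N(0, e^{−λ}). The log transform stabilizes
variance across the band and turns the µV² scale into an offset absorbed by
the electrode gain. The noise log-precision λ is a hyperparameter with a
weak Gaussian hyperprior (mean 2, variance 18), updated by Newton steps; it
can be fixed through the config, in which case the free energy reduces
exactly to the conjugate closed form on linear problems.

Priors are zero-mean Gaussians over log-deviations: variance 1/8 for the
ten coupling gains, 1/32 for the four time constants, 1/16 for the
nonneuronal scalings, no prior covariance. The tight time-constant prior
reflects that kernel time constants are the most conserved physiological
quantities in the model; in practice it also curbs a fit degeneracy in
which inhibitory-gain changes are partially absorbed by time-constant
adjustments, which would otherwise blur the second-level attribution of
group effects to parameter families.

Optimization is Gauss–Newton/Fisher scoring with Levenberg–Marquardt
damping (initial damping 0.01 — light damping measurably improves the
free energy reached; heavy initial damping was observed to strand fits in
inferior modes), central-difference gradients (step 1e-3 log-units),
acceptance only of free-energy-increasing steps, and convergence when ΔF <
0.01 nat on 3 consecutive accepted steps (cap 128 iterations). The free
energy is the standard Laplace bound: expected log-likelihood under the
Gaussian posterior minus the KL divergence from the prior.

Per patient, the pre-medication spectrum is inverted first; the
post-medication inversion then uses a prior whose nonneuronal entries are
pinned (variance 1e-6) at the first posterior's means, so that within-patient
spectral change must be explained by synaptic, not scaling, parameters.

**Bayesian model reduction (BMR)** computes the evidence and posterior of
any nested (variance-shrunken) prior analytically from the full fit. This
is exact for linear-Gaussian models and accurate for the modest reductions
used at the second level. For drastic reductions of the nonlinear
first-level model (e.g. freezing 12 of 14 synaptic parameters) the
quadratic surrogate extrapolates far from the fitted mode and its errors
can reach hundreds of nats; such comparisons are therefore done by
refitting, never by BMR.

## Parametric empirical Bayes

The second level models the 14 variable parameters of every first-level
model (patient × condition) as

    θ_i = B' x_i + ε_i,   ε_i ~ N(0, Γ)

with an effect-coded design: intercept; responder main effect (±1); BZP
(treatment) main effect (pre −1 / post +1); their interaction; and, when
the manifest marks additional non-BZP medications, nuisance regressors for
them that are never pruned by model comparison. Effect coding makes the
intercept the grand mean and the main effects orthogonal in balanced
designs.

First-level uncertainty is propagated by likelihood extraction: each
model's Gaussian likelihood is recovered from its posterior and prior
(precision Λ_i = C_i⁻¹ − S⁻¹, information h_i = C_i⁻¹µ_i − S⁻¹m, negative
eigenvalues of Λ_i floored at zero). This undoes first-level shrinkage
rather than treating shrunken posterior means as data, and it makes the
degenerate one-model, intercept-only hierarchy reproduce the first-level
posterior exactly. Priors on second-level effects are N(0, 1/8) per
element; the intercept row inherits the first-level prior. Γ is diagonal
(one variance per parameter, bounded [1e-6, 4]) and set by maximizing the
exact marginal evidence (L-BFGS on log Γ). Everything downstream of Γ is
linear-Gaussian, so the free energy is an exact log evidence and design
reductions are BMR-exact.

**Hypotheses.** H1 = responsiveness + treatment main effects; H2 =
treatment + interaction; H3 = the full complement. All three are
reductions of the full design. An intercept-only (no group structure)
reference model is always evaluated alongside: a winner is reported as
*decisive* only when it beats both the runner-up and this null reference by
more than 3 nats. Without the null reference, the three hypotheses — all of
which presuppose some effect — can show systematic multi-nat spreads on
null data, because within-patient contrasts (treatment, interaction) are
estimated much more precisely than between-patient ones.

**Families.** Parameters divide into four classes — t (time constants), m
(self-modulatory), e (excitatory), i (inhibitory) — and all 15 nonempty
class combinations are compared by fixed-effects (summed-evidence) BMR
under the winning design: a family model allows non-intercept effects only
on its classes' parameters.

## Synthetic cohorts

Each patient owns a latent parameterization composed of: a shared ictal
operating point (τ_ii −0.6, τ_dp −0.6, γ_ii-dp +1.2, γ_ii-ss +0.25
log-units — fast inhibitory/deep kernels with strong deep-pyramidal
inhibition, placing the column within ~0.7 log-units of the ~25-Hz
stability boundary); group-level effects; and a per-patient deviation
(sd 0.05 log-units on all 14 parameters, drawn once and shared between
conditions). Effects use cell-style semantics: the responder effect is a
±1-coded baseline half-difference, the BZP effect a shared pre→post change,
and the interaction a responder-only extra change. Packaged defaults:

| effect      | γ_ii-ss | γ_ii-sp | γ_ii-dp |
|-------------|---------|---------|---------|
| responder   | −0.50   | −0.40   |         |
| BZP shared  | +0.20   | +0.20   |         |
| interaction | +1.00   | +0.70   | −0.20   |

Signs encode the physiology being emulated — responders enter SE with less
GABAergic inhibition onto spiny stellate cells, BZPs raise that inhibition
in everyone, and responders additionally show a large further increase with
a slight loss of deep-pyramidal inhibition. The magnitudes are package
conventions chosen for comfortable identifiability from 300-s spectra at
the default cohort size (8 responders, 9 nonresponders; all counts
configurable); only the signs carry scientific content.
`GroundTruth.effect_coded_beta()` converts them to the ±1 design basis
(b_resp = r + x/4, b_bzp = s/2 + x/4, b_int = x/4).

Outputs are either noisy spectra (multiplicative log-normal observation
noise, sd 0.1 log-units — comparable to the per-bin sampling error of a
300-s Welch estimate) or 22-minute recordings with drug administration at
600 s and, for responders, termination at 800 s. Unstable patient draws are
redrawn (bounded, recorded in the ground truth).

What the generator does *not* emulate: nonstationarity and artifacts,
spike-wave morphology (the ictal state is a stationary near-critical
oscillation), intermittent seizure patterns, electrode/montage effects, and
model mismatch — the data are generated by the same CMC that is fitted.
Passing recovery tests therefore demonstrates the *inferential chain* is
sound under its own assumptions, not that real SE recordings would yield
these effect sizes.

## In-silico seizure-termination maps

Group starting points come from inverting the arithmetic mean premedication
spectrum of each group. The packaged demo then evaluates spectra over a
41×41 grid in the (γ_ii-ss, γ_ii-dp) plane and tracks power along the
BZP-like diagonal from 0.45 log-units "before" the fitted state to 0.6
beyond it (γ_ii-dp moving −0.2 per +1.0 of γ_ii-ss). Probe power is the
mean density over 25 ± 4 Hz evaluated on a fine (0.05-Hz) grid: near the
stability boundary the resonance is much narrower than the 0.5-Hz analysis
grid, and a point probe at exactly 25 Hz would saturate (the critical mode
never lands exactly on the probe), whereas the fine band average grows as
1/σ with stability margin σ and makes the boundary crossing a genuine
log-power discontinuity. The band is wide enough that the critical-mode
frequency — which drifts a few hertz with the fitted group state across
cohort realizations — stays inside it. A transition is declared when adjacent trajectory
steps differ by more than log 2 in probe power (configurable); grid points
beyond the boundary are recorded as unstable gaps, not errors, and
gap-adjacent pairs are skipped by the detector.

Under the packaged cohort, the responder's fitted state lies close enough
to the boundary that the extended trajectory straddles it (discontinuity
detected), while the nonresponder's — farther by the baseline group
difference — yields a smooth track. "Ictal-like" versus "interictal-like"
is operationalized as the two sides of this discontinuity.

**Escape analysis.** From the nonresponder's fitted state, each of the 14
synaptic parameters is swept ±1.5 log-units (41 steps) and scored by the
mean squared log-power distance (after optimal global rescaling, making the
metric gain-invariant) to an interictal target spectrum — in the demo, the
responder trajectory's endpoint. A sweep is flagged as an *escape route*
when it reaches the state-transition boundary (a detected jump, or the
stability boundary itself appearing inside the sweep) or attains the
interictal probe-power regime while improving the fit. In the packaged
demo the spiny stellate time constant τ_ss reaches the boundary from the
nonresponder state within ±0.7 log-units across cohort realizations — the
model's alternative route to a state transition when inhibitory coupling
alone cannot get there. A limitation inherited from the linearization: the
far side of a boundary crossing is outside the model's descriptive range,
so the flag marks parameters whose plausible range *reaches* the
transition, not what the post-transition rhythm looks like.

## Validation protocols

*Forward oracle.* Five random stable parameter sets (uniform ±0.4
log-deviations, stability margin > 3/s so spectral peaks stay wider than
the Welch resolution); 600-s simulations; agreement within 3× the
estimator standard error at all 89 grid points.

*Conjugate exactness.* On linear-Gaussian problems with fixed noise
precision, the variational free energy and BMR evidence changes match the
closed-form log evidences to better than 1e-6 nats.

*Parameter recovery.* 20 fixtures, each a single ±0.5 log-unit
perturbation of one synaptic parameter at the default operating point, with
sd-0.1 observation noise and nonneuronal scalings pinned at truth
(mirroring the repeat-inversion scheme). Fixtures cover the 12 parameters
whose spectral sensitivity supports recovery; the two 2-ms pyramidal/
stellate kernels (τ_ss, τ_sp) are excluded because their Jacobian norms at
the fit band are 1–2 orders below all other parameters — a ±0.5 change is
invisible below 45 Hz, so a recovery test there measures nothing. Checks:
the truth lies in the 95% credible interval in ≥17/20 fixtures, and the
refit evidence of the generating structure (only the perturbed parameter
free) exceeds that of the complementary model (the perturbed parameter
frozen at zero, all others free) in ≥16/20.

*Model-selection recovery.* Ten replicates of the default cohort: the
hypothesis comparison must select H3 and the family comparison the
inhibitory family in ≥8/10; ten null cohorts (no effects) must yield no
decisive winner in ≥8/10.

*Termination demo.* Responder discontinuity present, nonresponder absent,
τ_ss flagged as an escape route.

These protocols, at these problem sizes, run in a few minutes on one CPU;
`scripts/acceptance.py` recomputes all of them from scratch.

## Known limitations

- Single-spectrum identifiability of individual couplings is intrinsically
  weak (posterior sd ~0.25–0.35 log-units): many coupling changes are
  mutually compensable in a smooth 1–45 Hz spectrum. Group conclusions rest
  on the hierarchical pooling, not on per-patient estimates.
- Group-mean spectral fits land where likelihood and shrinkage balance, so
  fitted group states are displaced toward the prior relative to the
  generative states; the demo's trajectory ranges were chosen so its
  qualitative contrasts survive this displacement.
- The free energy uses a single noise precision across frequencies;
  strongly colored residuals would violate this.
- The linear model cannot describe post-instability (ictal limit-cycle)
  dynamics; instability onset is used only as a state-boundary marker.
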