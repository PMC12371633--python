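# sedcm

Spectral dynamic causal modelling of benzodiazepine response in status
epilepticus.

Status epilepticus (SE) is prolonged, self-sustaining seizure activity;
benzodiazepines (BZPs) — positive allosteric modulators of the GABA_A
receptor — are first-line treatment, yet a third of pediatric patients do
not respond. Animal work attributes that failure to seizure-induced changes
in synaptic inhibition. `sedcm` provides the computational machinery to
test this in humans from routine single-channel EEG: it fits a generative
cortical-column model to EEG power spectra, asks at the group level *which*
synaptic parameters separate responders from nonresponders, and maps, in
silico, the routes through synaptic parameter space that terminate a
seizure.

The package is aimed at computational neurologists and methods researchers
working with neural mass models and Bayesian model comparison. It is used
from Python (see `examples/`); a thin `sedcm` command-line interface covers
batch runs.

## The model and the inference chain

**Generative model.** A canonical microcircuit (CMC): four neural masses —
spiny stellate (ss), superficial pyramidal (sp), inhibitory interneurons
(ii), deep pyramidal (dp) — coupled by three excitatory, three inhibitory
and four self-modulatory gains, each population filtering its input through
an alpha kernel with time constant τ (14 variable synaptic parameters in
all). Linearized at its fixed point, the circuit predicts the one-sided EEG
density on 1–45 Hz:

    g(f) = obs_gain² · |C (2πif·I − A)⁻¹ B|² · g_u(f) + g_n(f)

with 1/f-plus-white innovations g_u and channel noise g_n.

**Inversion.** Variational Laplace on log-power residuals: Gauss–Newton
ascent of the free energy F = accuracy − complexity, returning a Gaussian
posterior over log-scale parameters and F as a log-evidence bound. Per
patient, the pre-medication spectrum is fitted first; nonneuronal scaling
parameters are then pinned for the post-medication fit.

**Group level.** Parametric empirical Bayes: a design matrix with
responsiveness, treatment and interaction regressors over all first-level
posteriors; hypotheses H1–H3 about responder/nonresponder differences and
all 15 parameter-family models compared by free energy via Bayesian model
reduction.

**In silico.** From fitted group states, spectra over grids in the
inhibitory-coupling plane; a discontinuity in 25-Hz band power along the
BZP-like trajectory marks the ictal→interictal transition; single-parameter
sweeps rank alternative "escape" routes for nonresponders.

Patient EEG is not distributed; a fully seeded synthetic-cohort generator
(`sedcm.cohort`) emulates the study's structure — group-dependent
inhibitory coupling, pre/post conditions, observation noise — with ground
truth for every latent quantity, so the whole chain is validated by
parameter- and model-recovery.

## A worked example

```bash
python examples/fit_single_spectrum.py
```

```
converged in 7 iterations; fit correlation r = 0.998
gamma_ii-ss: true +0.50, posterior +0.28 [95% CI -0.19, +0.74] log-units
free energy (log evidence bound): 133.6 nats
```

A spectrum was generated with the inhibitory coupling onto spiny stellate
cells (γ_ii-ss) raised by 0.5 log-units, noise added, and the full
19-parameter model fitted: the fit reproduces the spectrum (r = 0.998) and
the posterior places the true perturbation inside its credible interval —
single-spectrum estimates are honest but deliberately uncertain; group
conclusions come from the hierarchical layer. For the group analysis and
the seizure-termination map:

```bash
python examples/cohort_group_analysis.py   # H3 and the inhibitory family win
python examples/termination_map.py         # responder crosses the boundary, nonresponder does not
```

`examples/predict_and_simulate.py` and `examples/medication_epochs.py`
cover the forward model and the clinical epoch/band-power utilities. The
full pipeline (cohort → inversions → PEB → maps, with artifacts) runs as
`sedcm run --seed 7 --out myrun`.

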