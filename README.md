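# tcdcm

Dynamic causal modelling of fronto-parietal EEG cross-spectra with a
thalamocortical conductance model — built to study the acute cortical
pharmacodynamics of ketamine-like interventions, where the questions are:
which synaptic parameters (receptor time constants, laminar and
cortico-cortical gains) change between a pre-drug baseline, a bolus and an
infusion, and do those changes predict the clinical response?

The package is aimed at computational-psychiatry / EEG-pharmacology
researchers who want a self-contained, fully testable version of that
analysis chain. Because patient EEG of this kind is generally not
shareable, a first-class synthetic-cohort generator reproduces the study's
statistical structure, so every stage — forward model, model inversion,
group statistics — can be validated end to end.

## What is inside

- **`tcdcm.model`** — a two-node (medial prefrontal, superior parietal),
  eight-population conductance neural-mass model (SP, SI, SS, DP, DI, TP,
  RT, RL per node) with AMPA/NMDA/GABA-A receptor kinetics,
  `C V̇ = g_L(V_L−V) + Σ_r g_r m_r(V)(V_r−V) + u`, `ġ_r = κ_r(u_r − g_r)`,
  NMDA gated by the magnesium switch `m(V) = 1/(1+0.2e^{−αV})`; plus a
  stochastic Euler–Maruyama integrator used as a brute-force oracle.
- **`tcdcm.spectral`** — linearization at the fixed point and the analytic
  cross-spectral density `S(ω) = H(ω)G_u(ω)H(ω)* + noise`, with conduction
  delays as exact frequency-domain phase factors.
- **`tcdcm.inversion`** — variational-Laplace fitting: Gauss–Newton /
  Levenberg–Marquardt ascent on the free energy (accuracy − complexity),
  F = −½se'e + (N/2)(h−ln2π) − ½s·tr(JΣJ') − KL[q‖prior], with noise
  precision re-estimated between parameter steps.
- **`tcdcm.features`** — 2200 ms epoching with pre/bolus/infusion labels,
  Welch cross-spectra, the seven-band (delta…high-gamma) fourth-order
  bidirectional Butterworth filter bank, Hilbert amplitude envelopes.
- **`tcdcm.cohort`** — synthetic cohorts: per-subject parameter
  variability, planted drug effects (forward AMPA gain up; frontal GABA-A
  time constant down), spectra with observation noise, and clinical-change
  scores calibrated to target correlations (r = 0.43 / −0.38 at 24 h).
- **`tcdcm.stats`** — repeated-measures ANOVA over the three conditions,
  Benjamini–Hochberg FDR within parameter families (extrinsics,
  intrinsics, time constants), Pearson correlations with clinical change,
  and table-shaped reports.
- **`tcdcm.cli`** — `tcdcm simulate | fit | cohort | stats | full`.

See `docs/methods.md` for the model equations, defaults, and numerical
choices.

## Worked example

Fit the model to a synthetic spectrum generated from its own prior means:

```python
import numpy as np
import tcdcm as T

params = T.build_default_model()          # 2 nodes x 8 populations, 64 states
priors = T.PriorSpec.from_model(params)

clean = T.predict_csd(params.evaluate())  # 4-90 Hz cross-spectral density
data = T.add_observation_noise(clean, 0.05, np.random.default_rng(1))

res = T.invert(data, priors, params=params)
print(f"variance explained: {res.variance_explained:.2f}%")
print(f"free energy trace:  {res.F_trace[0]:.1f} -> {res.F_trace[-1]:.1f}"
      f"  ({res.n_iter} iterations, converged={res.converged})")
print(f"forward AMPA latent: {res.posterior('ext_ampa_fwd'):+.3f}")
```

prints

```
variance explained: 99.91%
free energy trace:  -129.8 -> 842.2  (18 iterations, converged=True)
forward AMPA latent: +0.067
```

i.e. the fitted spectrum explains 99.9% of the (mean-centred) spectral
variance — comfortably above the >90% fit-quality criterion used to accept
individual fits — and the forward-gain latent stays near its true value of
zero (log-scaling units). A small end-to-end group analysis:

```python
effects = T.default_effects()             # AMPA fwd +0.3, frontal GABA tau down
recs = T.generate_cohort(n=4, effects=effects, master_seed=11, params=params)
fits = {r.subject: {c: T.invert(sd, priors, params=params)
                    for c, sd in r.spectra.items()} for r in recs}
report = T.run_group_analysis(fits, T.clinical_table(recs))
print(report.render())
```

ranks "AMPA forward" as the extrinsic family's strongest condition effect
(F(2,6) = 13.3, p_FDR = 0.025 in this 4-subject demo), with the per-subject
fitted pre→infusion changes matching the planted signs.

The same pipeline from a shell:

```sh
tcdcm --out demo full --seed 5 --n 6
```

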