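# Methods

## The model

`tcdcm` implements a two-node conductance neural-mass model of
fronto-parietal cortex. Each node — medial prefrontal (MNI −12 36 60) and
superior parietal (MNI −24 −66 66) — contains eight populations: superficial
pyramidal (SP), superficial interneuron (SI), spiny stellate (SS), deep
pyramidal (DP), deep interneuron (DI), thalamic-projection pyramidal (TP),
reticular (RT) and relay (RL) cells. SP, SS, DP, TP, RL are excitatory; SI,
DI, RT inhibitory. Every population carries AMPA, NMDA and GABA-A
conductances on a leaky capacitive membrane:

    C dV/dt = g_L(V_L − V) + g_A(V_A − V) + g_N m(V)(V_N − V) + g_G(V_G − V) + u
    dg_r/dt = κ_r (u_r − g_r)

with the magnesium switch `m(V) = 1/(1 + 0.2 exp(−αV))` gating the NMDA
current. The afferent drive `u_r` is the gain-weighted, delay-lagged sigmoid
firing of the presynaptic populations connected through receptor class `r`
(clamped at zero; with nonnegative gains it is nonnegative anyway, so
conductances stay nonnegative along trajectories).

Wiring follows the canonical laminar microcircuit extended by a thalamic
loop: granular input RL→SS, superficial processing SS→SP/SI with SP↔SI and
SP self-inhibition, deep processing SP→DP, DP↔DI, and the corticothalamic
leg DP→TP, TP→RL/RT, RT→RL, RL→RT. Excitatory edges drive AMPA and (scaled
by a fixed fraction, 0.5) NMDA conductances; inhibitory edges drive GABA-A.
Extrinsic connections are AMPA- and NMDA-mediated: forward
(parietal→frontal, from SP) onto the granular targets SS and DP, backward
(frontal→parietal, from DP) onto SP and SI.

Every scalar parameter θ is carried as a prior mean with a log-scaling
latent λ, θ = θ̄·exp(λ); λ = 0 reproduces the prior mean. The "SP
self-gain" latent scales SP's own inhibitory recurrent strength *down*
(effective γ = θ̄·exp(−λ)), so a larger gain means less self-inhibition.

### Default constants and priors

| quantity | default | unit | note |
|---|---|---|---|
| V_L, V_AMPA, V_NMDA, V_GABA | −70, 60, 10, −90 | mV | reversal potentials |
| α (Mg slope) | 0.06 | 1/mV | |
| C, g_L | 10, 1 | — | membrane time constant 10 ms |
| ρ1, ρ2 (sigmoid) | 0.15, −55 | 1/mV, mV | see "operating point" below |
| τ_AMPA, τ_GABA, τ_NMDA priors | 4, 16, 100 | ms | κ = 1/τ, per node |
| intrinsic γ priors | 0.15–1.4 | — | order 1, log-scaled |
| extrinsic AMPA / NMDA gain priors | 0.1 / 0.05 | — | forward and backward |
| delays: intrinsic / cortex↔thalamus and extrinsic | 1 / 8 | ms | |
| prior variances (free latents) | 1/8 gains, 1/16 κ, 1/64 L and α_u | log² units | |

Free (estimated) latents: the four extrinsic gains; per node SP self-gain,
SI→SP, RL→SS and TP→RL; per node κ_AMPA/GABA/NMDA; electrode gains L and
innovation amplitudes α_u — 22 in total. The remaining intrinsic gains and
the noise-spectrum shape parameters are fixed (prior variance 0).

### Operating point

The firing sigmoid is centred near rest (ρ2 = −55 mV, slope ρ1 = 0.15/mV)
and the conductance kinetics are driven by the raw sigmoid rate, which is
strictly positive. The model therefore relaxes to a tonically active fixed
point (membrane potentials a few mV above leak, rates ≈ 0.1–0.25) at which
the sigmoid slope — and hence the linearized coupling between populations —
is healthy. A threshold far above rest would pin the fixed point at the
leak equilibrium with vanishing sigmoid slope, making the spectral response
independent of every coupling parameter; the chosen operating point is what
makes the inverse problem well-posed. The exposed `firing_rate` operation
additionally subtracts the baseline rate at V = 0 so that it is a
normalized rate in (−σ0, 1−σ0).

The fixed point is found by damped Newton iteration from the leak
equilibrium using the analytic delay-free Jacobian (residual tolerance
1e-8, fallback through a 400 ms noiseless relaxation). It is deterministic
and, for the default priors, unique in practice; random prior-plausible
draws converge in >95% of cases (tested).

## Spectral forward model

The model is linearized at the fixed point. Delays enter the frequency
domain exactly as phase factors exp(−iωd) on the delayed coupling blocks.
Innovations — one pink (G_u(f) = α_u f^−β, β prior 1) source per node —
enter the membrane equations of SS and RL (thalamo-granular drive). The
observed "virtual electrode" per node is a fixed SP-dominant mixture of
population depolarizations (J = 0.8 SP + 0.2 DP + 0.1 TP) scaled by an
electrode gain L. The predicted cross-spectrum is

    S(ω) = H(ω) G_u(ω) H(ω)* + channel noise (α_s f^−β_s + floor) + common noise (α_c f^−β_c)

with H = L·J·(iωI − A(ω))⁻¹·B. Because the conductance states are
first-order low-pass filters of the delayed rates, they are eliminated
exactly, leaving a 16×16 frequency-domain solve — algebraically identical
to the 64-state resolvent (asserted in tests) and several-fold faster.
Stability (all delay-free Jacobian eigenvalues in the left half-plane) is
checked before every evaluation; unstable parameter proposals are rejected
by the optimizer with a large negative free-energy sentinel rather than
clamped.

The analysis grid is 4–90 Hz at 1 Hz (configurable). A stochastic
Euler–Maruyama integrator (dt = 0.1 ms, frequency-synthesized pink
innovations, delay ring-buffer) provides a brute-force oracle: band-averaged
Welch auto-spectra of a 120 s low-noise simulation match the analytic
prediction within 20% in all seven analysis bands. The inter-node
cross-spectrum is verified as a complex band average at 4–8 Hz only: above
that, the default model's coherence lies below the Welch noise floor of a
120 s record (the estimator's magnitude bias, ≈√(S11·S22/n_avg), exceeds
the true |S12|), so no feasible simulation length can resolve it.

## Inversion (variational Laplace)

Data are reduced to real feature vectors: Re/Im of S11, S22 and S12 per
frequency (6F values). Residuals are weighted by the inverse median data
amplitude per frequency band (band partition at 8, 14, 27, 41, 54, 67.5 Hz)
to balance the 1/f dynamic range; the weights are stored in the result.
The free energy is

    F = −½·s·e'e − ½·s·tr(JΣJ') + N/2·(h − ln 2π) − KL[N(μ,Σ) ‖ N(μ0,Σ0)] − (h−h0)²/(2v_h)

with s = exp(h) the noise precision (flat hyperprior by default; the
constant of a proper hyperprior is omitted as it cancels in all
comparisons). For a linear-Gaussian model evaluated at the analytic
posterior this equals the closed-form log evidence (tested to 1e-6).

Optimization is Gauss–Newton with Levenberg–Marquardt damping: the feature
Jacobian is computed by central differences (step 1e-3 log-units) over the
free latents; a proposal is accepted only if it increases F over the best
value seen (so the recorded trace is non-decreasing by construction),
otherwise the damping is ×4 and the step retried up to 8 times; damping
halves after acceptance. The noise precision is re-estimated by scalar
Newton ascent after every proposal. Iteration stops after 4 consecutive
accepted steps with ΔF < 1e-2, or 128 iterations. The whole procedure is
deterministic given (data, priors, config).

Percent variance explained is mean-centred: 100·(1 − ‖f_pred − f_data‖² /
‖f_data − mean(f_data)‖²) on unweighted features.

## Synthetic cohorts

The generator emulates the repeated-measures study structure: per subject,
baseline latents ~ N(0, 0.15²) on the free latents; drug conditions add
planted shifts — forward AMPA gain +0.15 (bolus) / +0.30 (infusion)
log-units ("linear" response), frontal GABA-A κ +0.20 / +0.25 (time
constant shortened, mostly in the bolus) — plus a per-subject response drawn
once per shifted latent (SD 0.15) and scaled across conditions in
proportion to the planted means. Spectra get 5% Hermitian-preserving
complex Gaussian observation noise. Clinical change (MADRS points at 24 h
and 7 d; negative = improvement) is a linear-Gaussian function of the
subject-level shifts with residual SD 6, calibrated in closed form so the
expected sample correlation with the planted forward-AMPA shift is +0.43
and with the GABA-A time-constant shift −0.38 at 24 h (GABA only at 7 d).
Per-subject seeds split deterministically from the master seed via
`SeedSequence(master_seed, spawn_key=(i,))`.

What the generator does **not** emulate: real scalp EEG (no MR artifacts,
no beamforming, no volume conduction beyond the two virtual electrodes),
model mismatch (data are generated by the same model family that is
fitted), and heavy-tailed or non-stationary noise. Passing recovery tests
therefore demonstrates the internal consistency and calibration of the
pipeline, not the adequacy of the model for patient EEG.

## Group statistics

For each of 18 parameters (4 extrinsic gains; 8 intrinsic gains; 6 receptor
time constants, reported on the τ scale, i.e. the κ latent sign-flipped) a
one-way within-subject ANOVA over pre/bolus/infusion is run on posterior
means; F = MS_condition / MS_(condition×subject). The primary p uses the
univariate dfs (k−1, (k−1)(n−1)); the multivariate-convention dfs
(k−1, n−k+1) are reported alongside because repeated-measures software
commonly prints them. BH-FDR is applied within each family separately
(m = 4, 8, 6). Parameters significant before correction are correlated
(Pearson, two-sided t on n−2 df) with the clinical change at both
timepoints, and those p-values are FDR-adjusted as a set. Correlations use
the absolute (point) MADRS change; percent change is carried descriptively.

Null calibration: the per-test type-I error of the ANOVA is nominal
(empirically within [2%, 9%] at α = 0.05 over 200 null cohorts). Note that
BH's family-wise any-rejection rate under the global null equals α per
family, so across three families roughly one null cohort in seven shows
some FDR-significant member — the expected behaviour of a correctly
calibrated procedure, asserted as such in the specificity test.

## Problem sizes used in the test suite

Inversions in unit tests run on a 3-Hz grid (30 frequencies); acceptance
checks run the fit-quality criterion on the full 1-Hz grid and the
recovery criterion on three replicate 4-subject cohorts (36 full
inversions). The simulation oracle uses one 120 s run at dt = 0.1 ms.
These sizes were chosen to exercise every code path at desk scale; all
thresholds are identical to the full-scale analysis.

## Known limitations

- NMDA-related latents (extrinsic NMDA gains, κ_NMDA) are weakly identified:
  at the resting operating point the Mg block suppresses the NMDA current
  and its kinetics are slow relative to the analysis band, so their
  posteriors stay near the prior. This mirrors the weak/null NMDA effects
  the analysis is designed to test for, but means planted NMDA effects
  would recover poorly.
- Posterior cross-talk: estimation errors of different latents from the
  same spectrum are correlated (|r| ≈ 0.4 on average), which the group
  statistics inherit.
- The J observation weights are fixed, not estimated; electrode gain and
  innovation amplitude absorb overall scale.
- Single-subject inversion is a local optimizer; it is deterministic but
  not guaranteed to find the global free-energy optimum.
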