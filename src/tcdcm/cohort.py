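"""Synthetic-cohort generator.

Creates virtual subjects with the repeated-measures structure the analysis
assumes: per-subject baseline variability of the log-scaling latents around
the priors, drug-condition shifts on named latents (forward AMPA gain up;
frontal GABA-A rate constant up, i.e. time constant down), cross-spectra
with Hermitian-preserving observation noise, and clinical-change scores
(MADRS points, negative = improvement) linearly coupled to each subject's
realized parameter shifts at calibrated correlation targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .inversion import PriorSpec
from .model import TCMParameters, build_default_model, FixedPointError
from .spectral import SpectralData, StabilityError, default_freqs, predict_csd

__all__ = [
    "EffectSpec",
    "add_observation_noise",
    "CohortRecord",
    "default_effects",
    "calibrate_clinical_coupling",
    "sample_subject",
    "generate_cohort",
    "cohort_manifest",
    "clinical_table",
    "subject_seed",
]

CONDITIONS = ("pre", "bolus", "infusion")


@dataclass
class EffectSpec:
    """Planted drug effects and their clinical coupling.

    ``shifts[condition][latent]`` are additive shifts in log-scaling units;
    ``shift_sd[latent]`` is the between-subject SD of the realized shift
    (scaled across conditions in proportion to the planted means, so each
    subject's response is linear across conditions); ``clinical_coef[tp]``
    maps latents to MADRS points per log-unit of subject-level shift.
    """

    shifts: dict = field(default_factory=dict)        # cond -> {latent: shift}
    shift_sd: dict = field(default_factory=dict)      # latent -> SD
    baseline_sd: float = 0.15                          # SD of baseline latents
    clinical_coef: dict = field(default_factory=dict)  # tp -> {latent: coef}
    clinical_resid_sd: dict = field(
        default_factory=lambda: {"24h": 6.0, "7d": 6.0})
    clinical_mean: dict = field(
        default_factory=lambda: {"24h": -12.0, "7d": -10.0})
    madrs_baseline_mean: float = 31.0
    madrs_baseline_sd: float = 5.0
    obs_noise: float = 0.05                            # fractional CSD noise

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.shift_sd.values()) or self.baseline_sd < 0:
            raise ValueError("standard deviations must be nonnegative")

    def reference_shift(self, latent: str) -> float:
        """The infusion (or largest) planted shift, used to scale the
        subject-level response across conditions."""
        vals = [self.shifts.get(c, {}).get(latent, 0.0) for c in CONDITIONS]
        ref = self.shifts.get("infusion", {}).get(latent, 0.0)
        if ref == 0.0:
            ref = max(vals, key=abs)
        return ref


def calibrate_clinical_coupling(effects: EffectSpec, target_r: float,
                                latent: str = "ext_ampa_fwd",
                                timepoint: str = "24h") -> EffectSpec:
    """Set one clinical coupling so the expected sample correlation between
    the subject-level planted shift and the clinical-change score equals
    ``target_r`` (other couplings and the residual SD held fixed)."""
    if not abs(target_r) < 1.0:
        raise ValueError(
            f"|target_r| must be < 1 (got {target_r}); r = +/-1 would require "
            "zero residual variance")
    sd_x = effects.shift_sd.get(latent, 0.0)
    coefs = dict(effects.clinical_coef.get(timepoint, {}))
    if target_r == 0.0:
        coefs[latent] = 0.0
    else:
        if sd_x <= 0:
            raise ValueError(f"latent {latent} has zero shift SD; cannot "
                             "calibrate a nonzero correlation")
        other_var = sum((c * effects.shift_sd.get(k, 0.0)) ** 2
                        for k, c in coefs.items() if k != latent)
        resid = effects.clinical_resid_sd[timepoint] ** 2 + other_var
        coefs[latent] = target_r * np.sqrt(resid) / (
            sd_x * np.sqrt(1.0 - target_r ** 2))
    new_coef = dict(effects.clinical_coef)
    new_coef[timepoint] = coefs
    return replace(effects, clinical_coef=new_coef)


def default_effects(r_ampa: float = 0.43, r_gaba: float = 0.38) -> EffectSpec:
    """Default planted effects: forward AMPA gain +0.15 (bolus) / +0.30
    (infusion) log-units and frontal GABA-A kappa +0.20 / +0.25 (time
    constant shortened, with most of the change in the bolus); clinical
    couplings calibrated so larger planted shifts predict less improvement
    at 24 h (positive correlation with the signed MADRS change)."""
    eff = EffectSpec(
        shifts={
            "bolus": {"ext_ampa_fwd": 0.15, "kappa_frontal_gaba": 0.20},
            "infusion": {"ext_ampa_fwd": 0.30, "kappa_frontal_gaba": 0.25},
        },
        shift_sd={"ext_ampa_fwd": 0.15, "kappa_frontal_gaba": 0.15},
    )
    # joint closed form: with independent subject-level shifts,
    # sigma_y = sigma_eps / sqrt(1 - r_A^2 - r_G^2) and c_i = r_i sigma_y / sd_i
    for tp, targets in (("24h", {"ext_ampa_fwd": r_ampa,
                                 "kappa_frontal_gaba": r_gaba}),
                        ("7d", {"kappa_frontal_gaba": r_gaba})):
        rsq = sum(r * r for r in targets.values())
        sigma_y = eff.clinical_resid_sd[tp] / np.sqrt(1.0 - rsq)
        eff.clinical_coef[tp] = {
            k: r * sigma_y / eff.shift_sd[k] for k, r in targets.items()}
    return eff


@dataclass
class CohortRecord:
    """One synthetic subject: truth, spectra and clinical scores."""

    subject: str
    true_lam: dict                 # condition -> latent vector
    spectra: dict                  # condition -> SpectralData (may be empty)
    clinical: dict                 # madrs_baseline, change_24h, change_7d, ...
    subject_shift: dict            # latent -> realized subject-level shift
    resample_count: int = 0


def add_observation_noise(csd: SpectralData, frac: float, rng) -> SpectralData:
    """Hermitian-preserving complex Gaussian noise, SD = frac * |S(f)| per
    entry."""
    S = csd.S.copy()
    a11, a22, a12 = (np.abs(S[:, 0, 0]), np.abs(S[:, 1, 1]),
                     np.abs(S[:, 0, 1]))
    F = S.shape[0]
    S[:, 0, 0] += frac * a11 * rng.standard_normal(F)
    S[:, 1, 1] += frac * a22 * rng.standard_normal(F)
    z = (rng.standard_normal(F) + 1j * rng.standard_normal(F)) / np.sqrt(2.0)
    S[:, 0, 1] += frac * a12 * z
    S[:, 1, 0] = np.conj(S[:, 0, 1])
    return SpectralData(freqs=csd.freqs.copy(), S=S, subject=csd.subject,
                        condition=csd.condition)


def sample_subject(priors: PriorSpec, effects: EffectSpec, seed: int,
                   params: TCMParameters | None = None, freqs=None,
                   subject_id: str | None = None, spectra: bool = True,
                   max_resample: int = 10) -> CohortRecord:
    """Draw one subject; deterministic per seed.

    Baseline latents ~ N(0, baseline_sd^2) on the free latents; condition
    latents add the planted shift plus the subject-level response (one draw
    per shifted latent, scaled across conditions in proportion to the
    planted means).  If a planted latent vector yields an unstable model the
    whole subject is resampled (counted in ``resample_count``).
    """
    if params is None:
        params = build_default_model()
    if freqs is None:
        freqs = default_freqs()
    rng = np.random.default_rng(seed)
    free = priors.free
    sid = subject_id or f"sub-{seed}"

    for attempt in range(max_resample):
        lam_base = np.zeros(params.n_params)
        lam_base[free] = rng.normal(0.0, effects.baseline_sd, free.sum())
        shifted = sorted(effects.shift_sd)
        u = {k: rng.normal(0.0, effects.shift_sd[k]) for k in shifted}

        true_lam, spec_out = {}, {}
        try:
            for cond in CONDITIONS:
                lam = lam_base.copy()
                for k, shift in effects.shifts.get(cond, {}).items():
                    ref = effects.reference_shift(k)
                    scale = shift / ref if ref != 0 else 1.0
                    lam[params.index(k)] += shift + u.get(k, 0.0) * scale
                true_lam[cond] = lam
                if spectra:
                    clean = predict_csd(params.evaluate(lam), freqs,
                                        subject=sid, condition=cond)
                    spec_out[cond] = add_observation_noise(clean, effects.obs_noise, rng)
                else:
                    # keep the stability contract even without spectra
                    from .model import find_fixed_point
                    find_fixed_point(params.evaluate(lam))
        except (StabilityError, FixedPointError):
            continue

        clinical = {"madrs_baseline": float(rng.normal(
            effects.madrs_baseline_mean, effects.madrs_baseline_sd))}
        for tp in ("24h", "7d"):
            y = effects.clinical_mean[tp]
            for k, c in effects.clinical_coef.get(tp, {}).items():
                y += c * u.get(k, 0.0)
            y += rng.normal(0.0, effects.clinical_resid_sd[tp])
            clinical[f"change_{tp}"] = float(y)
            clinical[f"pct_change_{tp}"] = float(
                100.0 * y / clinical["madrs_baseline"])
        return CohortRecord(subject=sid, true_lam=true_lam, spectra=spec_out,
                            clinical=clinical, subject_shift=u,
                            resample_count=attempt)
    raise RuntimeError(
        f"subject {sid}: no stable parameter draw in {max_resample} attempts")


def subject_seed(master_seed: int, i: int) -> int:
    """Per-subject seed splitting rule: child i of SeedSequence(master_seed)."""
    child = np.random.SeedSequence(master_seed, spawn_key=(i,))
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(n: int = 27, priors: PriorSpec | None = None,
                    effects: EffectSpec | None = None, master_seed: int = 0,
                    params: TCMParameters | None = None, freqs=None,
                    spectra: bool = True) -> list[CohortRecord]:
    """n independent subjects with per-subject seeds split from master_seed."""
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if params is None:
        params = build_default_model()
    if priors is None:
        priors = PriorSpec.from_model(params)
    if effects is None:
        effects = default_effects()
    return [sample_subject(priors, effects, subject_seed(master_seed, i),
                           params=params, freqs=freqs,
                           subject_id=f"sub-{i:03d}", spectra=spectra)
            for i in range(n)]


def cohort_manifest(records: list[CohortRecord], params: TCMParameters):
    """Long-format table of true latent values (for recovery scoring)."""
    import pandas as pd
    rows = []
    for rec in records:
        for cond, lam in rec.true_lam.items():
            for name, val in zip(params.names, lam):
                rows.append((rec.subject, cond, name, val))
    return pd.DataFrame(rows, columns=["subject", "condition", "latent",
                                       "true_value"])


def clinical_table(records: list[CohortRecord]):
    import pandas as pd
    return pd.DataFrame([
        {"subject": r.subject, **r.clinical} for r in records])
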