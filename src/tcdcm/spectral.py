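"""Linearized spectral response of the thalamocortical model.

The model is linearized at its fixed point; conduction delays enter the
frequency domain exactly, as phase factors exp(-i w d) on the delayed
coupling blocks of the Jacobian.  The predicted cross-spectral density is

    S(w) = H(w) G_u(w) H(w)* + S_channel(w) + S_common(w)

with H(w) = L J (i w I - A(w))^-1 B the transfer function from the per-node
innovation sources (pink, G_u(f) = alpha_u f^-beta_u) to the two observed
virtual electrodes, plus 1/f-form channel-specific noise with a white floor
and a common (shared across electrodes) noise term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ConcreteModel,
    N_POP,
    N_STATE_PER_POP,
    _as_model,
    _dmg,
    _drate,
    find_fixed_point,
    mg_block,
)

__all__ = [
    "SpectralData",
    "StabilityError",
    "default_freqs",
    "jacobian",
    "jacobian_parts",
    "transfer_function",
    "predict_csd",
    "spectral_fingerprint_shift",
    "band_power",
]


class StabilityError(RuntimeError):
    pass


def default_freqs() -> np.ndarray:
    """Default analysis grid: 4-90 Hz at 1 Hz resolution."""
    return np.arange(4.0, 91.0)


@dataclass
class SpectralData:
    """Frequency grid plus Hermitian cross-spectral matrix per frequency."""

    freqs: np.ndarray             # (F,) Hz, strictly increasing
    S: np.ndarray                 # (F, n, n) complex
    subject: str | None = None
    condition: str | None = None  # pre | bolus | infusion

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.S = np.asarray(self.S, complex)
        if self.S.ndim != 3 or self.S.shape[0] != self.freqs.size:
            raise ValueError("S must have shape (n_freqs, n, n)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.S.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        """Assert Hermitian symmetry and real nonnegative diagonals."""
        if not np.allclose(self.S, np.conj(np.swapaxes(self.S, 1, 2)),
                           atol=atol):
            raise ValueError("cross-spectral matrices are not Hermitian")
        d = np.diagonal(self.S, axis1=1, axis2=2)
        if np.any(d.real < -atol) or np.any(np.abs(d.imag) > atol):
            raise ValueError("diagonal spectra must be real and nonnegative")

    def hermitize(self) -> "SpectralData":
        self.S = 0.5 * (self.S + np.conj(np.swapaxes(self.S, 1, 2)))
        return self


# ---------------------------------------------------------------------------
# linearization
# ---------------------------------------------------------------------------

def jacobian_parts(params, fp: np.ndarray) -> dict[float, np.ndarray]:
    """Jacobian of the vector field split by delay group.

    Returns ``{0.0: A0, d1: A1, d2: A2}`` such that the delay-free Jacobian
    is the sum and the frequency-domain Jacobian is
    ``A(w) = A0 + sum_d exp(-i w d) A_d``.  A0 holds the local membrane and
    conductance-decay terms; each A_d the kappa-scaled, gain-weighted
    sigmoid-slope couplings conveyed with delay d.
    """
    m = _as_model(params)
    c = m.constants
    x = np.asarray(fp, float)
    s = x.reshape(m.n_flat, N_STATE_PER_POP)
    V, gA, gN, gG = s[:, 0], s[:, 1], s[:, 2], s[:, 3]
    nst = x.size
    iV = np.arange(m.n_flat) * N_STATE_PER_POP

    mg = mg_block(V, c["alpha_mg"])
    dmg = _dmg(V, c["alpha_mg"])
    Cm = c["C_m"]

    A0 = np.zeros((nst, nst))
    dV_dV = (-c["g_L"] - gA - gG - gN * mg + gN * dmg * (c["V_NMDA"] - V)) / Cm
    A0[iV, iV] = dV_dV
    A0[iV, iV + 1] = (c["V_AMPA"] - V) / Cm
    A0[iV, iV + 2] = mg * (c["V_NMDA"] - V) / Cm
    A0[iV, iV + 3] = (c["V_GABA"] - V) / Cm
    for off, rec in ((1, "ampa"), (2, "nmda"), (3, "gaba")):
        A0[iV + off, iV + off] = -m.kappa[rec]

    dr = _drate(V, c["rho1"], c["rho2"])
    parts: dict[float, np.ndarray] = {0.0: A0}
    for d in sorted(m.W["ampa"]):
        Ad = np.zeros((nst, nst))
        for off, rec in ((1, "ampa"), (2, "nmda"), (3, "gaba")):
            Ad[np.ix_(iV + off, iV)] = (m.kappa[rec][:, None]
                                        * m.W[rec][d] * dr[None, :])
        parts[d] = Ad
    return parts


def jacobian(params, fp: np.ndarray) -> np.ndarray:
    """Delay-free Jacobian (all delay groups summed) at the fixed point."""
    return sum(jacobian_parts(params, fp).values())


def _stable_parts(m: ConcreteModel, fp=None):
    if fp is None:
        fp = find_fixed_point(m)
    parts = jacobian_parts(m, fp)
    A = sum(parts.values())
    ev = np.linalg.eigvals(A)
    k = np.argmax(ev.real)
    if ev.real[k] >= 0:
        raise StabilityError(
            f"unstable linearization: eigenvalue {ev[k]:.5f} has nonnegative "
            "real part")
    return fp, parts


def transfer_function(params, freqs, fp=None) -> np.ndarray:
    """Complex response H(w) of each observed node to each innovation source.

    Shape (F, n_nodes, n_sources); H(w) = L J (i w I - A(w))^-1 B with delay
    phase factors folded into A(w).  The conductance states are first-order
    low-pass filters of the delayed presynaptic rates, so they are eliminated
    exactly, leaving one 16 x 16 (membrane-potential) solve per frequency —
    algebraically identical to the full 64-state resolvent.
    """
    m = _as_model(params)
    c = m.constants
    freqs = np.asarray(freqs, float)
    fp, parts = _stable_parts(m, fp)

    s = np.asarray(fp, float).reshape(m.n_flat, N_STATE_PER_POP)
    V, gA, gN, gG = s[:, 0], s[:, 1], s[:, 2], s[:, 3]
    mg = mg_block(V, c["alpha_mg"])
    dmg = _dmg(V, c["alpha_mg"])
    Cm = c["C_m"]
    # diagonal membrane terms of the Jacobian
    a = (-c["g_L"] - gA - gG - gN * mg + gN * dmg * (c["V_NMDA"] - V)) / Cm
    cg = {"ampa": (c["V_AMPA"] - V) / Cm,
          "nmda": mg * (c["V_NMDA"] - V) / Cm,
          "gaba": (c["V_GABA"] - V) / Cm}
    dr = _drate(V, c["rho1"], c["rho2"])

    w = 2.0 * np.pi * freqs / 1000.0  # rad/ms
    nf = m.n_flat
    delays = sorted(m.W["ampa"])
    phase = {d: np.exp(-1j * w * d) for d in delays}
    M = (1j * w[:, None, None] * np.eye(nf)[None]
         - np.diag(a)[None, :, :].astype(complex))
    for rec in ("ampa", "nmda", "gaba"):
        kap = m.kappa[rec]
        lp = kap[None, :] / (1j * w[:, None] + kap[None, :])   # (F, 16)
        Wd = sum(phase[d][:, None, None] * (m.W[rec][d] * dr[None, :])[None]
                 for d in delays)                               # (F, 16, 16)
        M -= (cg[rec][None, :, None] * lp[:, :, None]) * Wd

    # innovations enter the membrane rows of SS and RL per node
    B = np.zeros((nf, m.n_nodes))
    from .model import _PIDX
    for n in range(m.n_nodes):
        for p in ("SS", "RL"):
            B[n * N_POP + _PIDX[p], n] = c["input_gain"] / Cm
    Lo = (m.L[:, None] * np.vstack([
        np.concatenate([m.Jw if k == n else np.zeros(N_POP)
                        for k in range(m.n_nodes)])
        for n in range(m.n_nodes)]))
    X = np.linalg.solve(M, np.broadcast_to(B, (freqs.size,) + B.shape))
    return Lo[None, :, :] @ X


def _noise_spectra(m: ConcreteModel, freqs: np.ndarray):
    th = m.theta
    f = np.asarray(freqs, float)
    Gu = m.alpha_u[None, :] * f[:, None] ** (-th["beta_u"])   # (F, nodes)
    Gs = th["alpha_s"] * f ** (-th["beta_s"]) + th["white_floor"]
    Gc = th["alpha_c"] * f ** (-th["beta_c"])
    return Gu, Gs, Gc


def predict_csd(params, freqs=None, include_noise: bool = True,
                subject=None, condition=None) -> SpectralData:
    """Analytic cross-spectral density of the linearized model."""
    m = _as_model(params)
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, float)
    H = transfer_function(m, freqs)
    Gu, Gs, Gc = _noise_spectra(m, freqs)
    S = np.einsum("fij,fj,fkj->fik", H, Gu, np.conj(H))
    if include_noise:
        n = H.shape[1]
        S = S + Gs[:, None, None] * np.eye(n)[None, :, :]
        S = S + Gc[:, None, None] * np.ones((n, n))[None, :, :]
    return SpectralData(freqs=freqs, S=S, subject=subject,
                        condition=condition).hermitize()


# ---------------------------------------------------------------------------
# band summaries
# ---------------------------------------------------------------------------

def band_power(csd: SpectralData, lo: float, hi: float,
               node: int | None = None) -> float | np.ndarray:
    """Rectangle-rule integral of the diagonal CSD magnitude over [lo, hi]."""
    f = csd.freqs
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        return 0.0 if node is not None else np.zeros(csd.n_channels)
    diag = np.abs(np.diagonal(csd.S, axis1=1, axis2=2))[mask]
    power = np.trapezoid(diag, x=f[mask], axis=0)
    return float(power[node]) if node is not None else power


def spectral_fingerprint_shift(params_pre, params_drug, freqs=None,
                               bands=None):
    """Per-band signed change (drug minus pre) of band-integrated amplitude.

    A qualitative sanity surface for planted drug effects: returns a
    ``{band_name: (per-node shift array)}`` mapping over the seven analysis
    bands (or any (name, lo, hi) iterable passed as ``bands``).
    """
    if bands is None:
        from .features import BAND_TABLE
        bands = [(b.name, b.lo, b.hi) for b in BAND_TABLE]
    pre = predict_csd(params_pre, freqs)
    drug = predict_csd(params_drug, freqs)
    return {name: band_power(drug, lo, hi) - band_power(pre, lo, hi)
            for name, lo, hi in bands}
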