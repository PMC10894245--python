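"""Two-node, eight-population thalamocortical conductance neural-mass model.

Each cortical node (medial prefrontal "frontal", superior parietal "parietal")
contains eight populations — superficial pyramidal (SP), superficial
interneuron (SI), spiny stellate (SS), deep pyramidal (DP), deep interneuron
(DI), thalamic-projection pyramidal (TP), reticular (RT) and relay (RL) —
each carrying AMPA, NMDA and GABA-A conductances on a leaky capacitive
membrane.  The state of a population is (V, g_AMPA, g_NMDA, g_GABA), so the
default two-node model has 2 x 8 x 4 = 64 dynamical states.

Dynamics (units mV, ms; conductances are dimensionless scalings of a unit
leak conductance):

    C dV/dt  = g_L (V_L - V) + g_A (V_A - V) + g_N m(V) (V_N - V)
               + g_G (V_G - V) + drive
    dg_r/dt  = kappa_r (u_r - g_r)

where m(V) = 1 / (1 + 0.2 exp(-alpha V)) is the voltage-dependent magnesium
switch on the NMDA channel and u_r is the gain-weighted, delay-lagged
presynaptic sigmoid firing rate arriving through receptor class r (clamped
at zero).  Every scalar parameter theta is carried as a prior mean with a
log-scaling latent lambda, theta = mean * exp(lambda), the convention used
throughout the fitting pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POPULATIONS",
    "EXCITATORY",
    "NodeSpec",
    "PopulationSet",
    "ParamSpec",
    "TCMParameters",
    "ConcreteModel",
    "build_default_model",
    "firing_rate",
    "sigmoid_rate",
    "mg_block",
    "state_derivative",
    "find_fixed_point",
    "integrate",
    "FixedPointError",
    "IntegrationError",
]

# ---------------------------------------------------------------------------
# populations and wiring
# ---------------------------------------------------------------------------

POPULATIONS = ("SP", "SI", "SS", "DP", "DI", "TP", "RT", "RL")
EXCITATORY = ("SP", "SS", "DP", "TP", "RL")
_PIDX = {p: i for i, p in enumerate(POPULATIONS)}

N_POP = 8
N_STATE_PER_POP = 4  # V, gA, gN, gG


@dataclass(frozen=True)
class NodeSpec:
    """A modelled cortical source (virtual electrode location)."""

    name: str
    mni: tuple[int, int, int]


DEFAULT_NODES = (
    NodeSpec("frontal", (-12, 36, 60)),
    NodeSpec("parietal", (-24, -66, 66)),
)


@dataclass(frozen=True)
class PopulationSet:
    """Ordered population labels with excitatory flags."""

    labels: tuple[str, ...] = POPULATIONS

    @property
    def excitatory(self) -> tuple[bool, ...]:
        return tuple(p in EXCITATORY for p in self.labels)


# Intrinsic laminar/thalamic edge set: (source, target, receptor-kind, delay ms).
# "E" edges drive AMPA (and, scaled by nmda_frac, NMDA); "G" edges drive GABA-A.
# Cortex<->thalamus legs carry the long (8 ms) conduction delay; within-layer
# and within-thalamus legs the short (1 ms) delay.
INTRINSIC_EDGES = (
    ("SP", "SP", "G", 1.0),   # SP self-inhibition; scaled down by SP self-gain
    ("SI", "SP", "G", 1.0),
    ("SS", "SP", "E", 1.0),
    ("SS", "SI", "E", 1.0),
    ("SP", "SI", "E", 1.0),
    ("SP", "DP", "E", 1.0),
    ("DP", "DI", "E", 1.0),
    ("DI", "DP", "G", 1.0),
    ("DP", "TP", "E", 1.0),
    ("TP", "RL", "E", 8.0),
    ("TP", "RT", "E", 8.0),
    ("RT", "RL", "G", 1.0),
    ("RL", "SS", "E", 8.0),
    ("RL", "RT", "E", 1.0),
)

# default intrinsic gain prior means, per edge (order 1, log-scaled)
_DEFAULT_GAMMA = {
    "sp_sp": 0.6,
    "si_sp": 1.4,
    "ss_sp": 0.3,
    "ss_si": 0.2,
    "sp_si": 0.3,
    "sp_dp": 0.2,
    "dp_di": 0.2,
    "di_dp": 1.0,
    "dp_tp": 0.2,
    "tp_rl": 0.2,
    "tp_rt": 0.15,
    "rt_rl": 0.8,
    "rl_ss": 0.2,
    "rl_rt": 0.15,
}

# intrinsic edges whose gains are free (estimated) in the default prior set
_FREE_INTRINSIC = ("sp_sp", "si_sp", "rl_ss", "tp_rl")

# fixed biophysical constants (overridable through TCMParameters.constants)
DEFAULT_CONSTANTS = {
    "V_L": -70.0,     # leak reversal, mV
    "V_AMPA": 60.0,   # AMPA reversal, mV
    "V_NMDA": 10.0,   # NMDA reversal, mV
    "V_GABA": -90.0,  # GABA-A reversal, mV
    "alpha_mg": 0.06,  # Mg-block slope, 1/mV
    "C_m": 10.0,      # membrane capacitance (tau_m = C_m/g_L = 10 ms)
    "g_L": 1.0,       # unit leak conductance
    "rho1": 0.15,     # sigmoid slope, 1/mV
    "rho2": -55.0,    # sigmoid threshold, mV
    "nmda_frac": 0.5,  # NMDA drive as a fraction of the AMPA-edge gain
    "delay_intrinsic": 1.0,    # ms
    "delay_extrinsic": 8.0,    # ms (also cortex<->thalamus)
    "input_gain": 1.0,         # scaling of exogenous innovations
}

# receptor rate-constant prior means (1/ms): tau = 4, 16, 100 ms
_DEFAULT_KAPPA = {"ampa": 0.25, "gaba": 1.0 / 16.0, "nmda": 0.01}

# observation defaults: superficial-pyramidal-dominant contribution weights
DEFAULT_J = {"SP": 0.8, "DP": 0.2, "TP": 0.1}


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    """One log-scaled scalar parameter: theta = mean * exp(lambda)."""

    name: str
    mean: float
    var: float  # prior variance of the log-scaling latent; 0 => fixed


@dataclass
class TCMParameters:
    """Full prior specification of the two-node thalamocortical model."""

    nodes: tuple[NodeSpec, ...] = DEFAULT_NODES
    specs: tuple[ParamSpec, ...] = ()
    constants: dict = field(default_factory=lambda: dict(DEFAULT_CONSTANTS))

    def __post_init__(self) -> None:
        self._index = {s.name: i for i, s in enumerate(self.specs)}

    # -- vector views -------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    @property
    def n_params(self) -> int:
        return len(self.specs)

    @property
    def n_states(self) -> int:
        return len(self.nodes) * N_POP * N_STATE_PER_POP

    @property
    def prior_means(self) -> np.ndarray:
        """Prior mean of the latents (zero: evaluating at 0 gives the means)."""
        return np.zeros(self.n_params)

    @property
    def prior_variances(self) -> np.ndarray:
        return np.array([s.var for s in self.specs])

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs if s.var > 0)

    def index(self, name: str) -> int:
        return self._index[name]

    def lam_from_dict(self, shifts: dict[str, float]) -> np.ndarray:
        lam = np.zeros(self.n_params)
        for k, v in shifts.items():
            lam[self._index[k]] = v
        return lam

    def evaluate(self, lam: np.ndarray | dict | None = None) -> "ConcreteModel":
        """Evaluate theta = mean * exp(lambda) and assemble coupling matrices."""
        if lam is None:
            lam = np.zeros(self.n_params)
        elif isinstance(lam, dict):
            lam = self.lam_from_dict(lam)
        lam = np.asarray(lam, float)
        if lam.shape != (self.n_params,):
            raise ValueError(
                f"latent vector has shape {lam.shape}, expected ({self.n_params},)")
        theta = {s.name: s.mean * float(np.exp(l))
                 for s, l in zip(self.specs, lam)}
        return ConcreteModel._assemble(self, theta, lam)


def build_default_model(n_nodes: int = 2) -> TCMParameters:
    """Default prior specification of the hierarchical two-node model.

    Forward (parietal -> frontal) connections target the granular populations
    (SS, DP) of the receiving node; backward (frontal -> parietal) connections
    target the superficial populations (SP, SI).  Only ``n_nodes=2`` is
    supported.
    """
    if n_nodes != 2:
        raise ValueError(f"only the two-node model is supported, got {n_nodes}")
    specs: list[ParamSpec] = []

    # extrinsic cortico-cortical gains (AMPA- and NMDA-mediated)
    for name, mean in (("ext_ampa_fwd", 0.1), ("ext_ampa_bwd", 0.1),
                       ("ext_nmda_fwd", 0.05), ("ext_nmda_bwd", 0.05)):
        specs.append(ParamSpec(name, mean, 1.0 / 8.0))

    # intrinsic gains per node; only the analysed subset is free
    for node in ("frontal", "parietal"):
        for edge, mean in _DEFAULT_GAMMA.items():
            var = 1.0 / 8.0 if edge in _FREE_INTRINSIC else 0.0
            specs.append(ParamSpec(f"g_{node}_{edge}", mean, var))

    # receptor rate constants per node (tau = 1/kappa)
    for node in ("frontal", "parietal"):
        for rec, mean in _DEFAULT_KAPPA.items():
            specs.append(ParamSpec(f"kappa_{node}_{rec}", mean, 1.0 / 16.0))

    # observation and innovation parameters
    for node in ("frontal", "parietal"):
        specs.append(ParamSpec(f"L_{node}", 1.0, 1.0 / 64.0))
    for node in ("frontal", "parietal"):
        specs.append(ParamSpec(f"alpha_u_{node}", 1.0, 1.0 / 64.0))
    specs.append(ParamSpec("beta_u", 1.0, 0.0))
    specs.append(ParamSpec("alpha_s", 1e-6, 0.0))   # channel 1/f noise
    specs.append(ParamSpec("beta_s", 1.0, 0.0))
    specs.append(ParamSpec("white_floor", 1e-8, 0.0))
    specs.append(ParamSpec("alpha_c", 1e-7, 0.0))   # common noise
    specs.append(ParamSpec("beta_c", 1.0, 0.0))

    return TCMParameters(specs=tuple(specs))


# ---------------------------------------------------------------------------
# concrete (evaluated) model
# ---------------------------------------------------------------------------

@dataclass
class ConcreteModel:
    """A TCMParameters set evaluated at a particular latent vector.

    Couplings are compiled to per-receptor, per-delay-group matrices W acting
    on the flattened (node, population) rate vector, so that the afferent
    drive through receptor r is ``u_r(t) = sum_d W[r][d] @ rate(V(t - d))``.
    """

    params: TCMParameters
    theta: dict[str, float]
    lam: np.ndarray
    kappa: dict[str, np.ndarray]          # receptor -> (16,) rate constants
    W: dict[str, dict[float, np.ndarray]]  # receptor -> delay -> (16,16)
    L: np.ndarray                          # (2,) electrode gains
    Jw: np.ndarray                         # (8,) population contribution weights
    alpha_u: np.ndarray                    # (2,) innovation amplitudes

    @property
    def constants(self) -> dict:
        return self.params.constants

    @property
    def n_nodes(self) -> int:
        return len(self.params.nodes)

    @property
    def n_flat(self) -> int:
        return self.n_nodes * N_POP

    @classmethod
    def _assemble(cls, params: TCMParameters, theta: dict[str, float],
                  lam: np.ndarray) -> "ConcreteModel":
        c = params.constants
        nn = len(params.nodes)
        nflat = nn * N_POP
        d_int = c["delay_intrinsic"]
        d_ext = c["delay_extrinsic"]
        W = {r: {d_int: np.zeros((nflat, nflat)), d_ext: np.zeros((nflat, nflat))}
             for r in ("ampa", "nmda", "gaba")}

        for n, node in enumerate(params.nodes):
            off = n * N_POP
            for src, dst, kind, delay in INTRINSIC_EDGES:
                key = f"g_{node.name}_{src.lower()}_{dst.lower()}"
                g = theta[key]
                if src == "SP" and dst == "SP" and g != 0.0:
                    # SP self-gain modulates SP's own inhibitory recurrent term:
                    # a larger gain latent means *less* self-inhibition.
                    spec = params.specs[params.index(key)]
                    g = spec.mean ** 2 / g
                d = d_int if delay == 1.0 else d_ext
                si, di = off + _PIDX[src], off + _PIDX[dst]
                if kind == "E":
                    W["ampa"][d][di, si] += g
                    W["nmda"][d][di, si] += c["nmda_frac"] * g
                else:
                    W["gaba"][d][di, si] += g

        if nn == 2:
            # forward parietal(1)->frontal(0): SP source onto SS and DP
            for dst in ("SS", "DP"):
                W["ampa"][d_ext][_PIDX[dst], N_POP + _PIDX["SP"]] += theta["ext_ampa_fwd"]
                W["nmda"][d_ext][_PIDX[dst], N_POP + _PIDX["SP"]] += theta["ext_nmda_fwd"]
            # backward frontal(0)->parietal(1): DP source onto SP and SI
            for dst in ("SP", "SI"):
                W["ampa"][d_ext][N_POP + _PIDX[dst], _PIDX["DP"]] += theta["ext_ampa_bwd"]
                W["nmda"][d_ext][N_POP + _PIDX[dst], _PIDX["DP"]] += theta["ext_nmda_bwd"]

        kappa = {}
        for rec in ("ampa", "nmda", "gaba"):
            k = np.empty(nflat)
            for n, node in enumerate(params.nodes):
                k[n * N_POP:(n + 1) * N_POP] = theta[f"kappa_{node.name}_{rec}"]
            kappa[rec] = k

        Jw = np.zeros(N_POP)
        for p, w in DEFAULT_J.items():
            Jw[_PIDX[p]] = w
        L = np.array([theta[f"L_{node.name}"] for node in params.nodes])
        alpha_u = np.array([theta[f"alpha_u_{node.name}"] for node in params.nodes])
        return cls(params=params, theta=theta, lam=lam, kappa=kappa, W=W,
                   L=L, Jw=Jw, alpha_u=alpha_u)

    # -- helpers ------------------------------------------------------------
    def leak_equilibrium(self) -> np.ndarray:
        """Decoupled rest state: V = V_L, g = 0."""
        x = np.zeros((self.n_flat, N_STATE_PER_POP))
        x[:, 0] = self.constants["V_L"]
        return x.ravel()

    def innovation_matrix(self) -> np.ndarray:
        """Input matrix B: one white/pink innovation per node, entering the
        membrane equation of the granular targets (SS and RL)."""
        c = self.constants
        B = np.zeros((self.n_flat * N_STATE_PER_POP, self.n_nodes))
        for n in range(self.n_nodes):
            for p in ("SS", "RL"):
                q = n * N_POP + _PIDX[p]
                B[q * N_STATE_PER_POP, n] = c["input_gain"] / c["C_m"]
        return B

    def observation_matrix(self) -> np.ndarray:
        """Lead-field row per node: electrode gain times J over populations."""
        nst = self.n_flat * N_STATE_PER_POP
        Lo = np.zeros((self.n_nodes, nst))
        for n in range(self.n_nodes):
            for p in range(N_POP):
                Lo[n, (n * N_POP + p) * N_STATE_PER_POP] = self.L[n] * self.Jw[p]
        return Lo


def _as_model(params) -> ConcreteModel:
    if isinstance(params, ConcreteModel):
        return params
    return params.evaluate()


# ---------------------------------------------------------------------------
# activation functions
# ---------------------------------------------------------------------------

def firing_rate(V, rho1: float, rho2: float):
    """Baseline-subtracted sigmoid firing rate in (-sigma0, 1 - sigma0).

    sigma(V) = 1/(1 + exp(-rho1 (V - rho2))) - sigma0 with
    sigma0 = 1/(1 + exp(rho1 rho2)), so sigma(0) = 0 for any slope/threshold.
    """
    if rho1 <= 0:
        raise ValueError(f"sigmoid slope must be positive, got {rho1}")
    V = np.asarray(V, float)
    from scipy.special import expit
    return expit(rho1 * (V - rho2)) - expit(-rho1 * rho2)


def sigmoid_rate(V, rho1: float, rho2: float):
    """Raw sigmoid rate in (0, 1) driving the conductance kinetics."""
    from scipy.special import expit
    return expit(rho1 * (np.asarray(V, float) - rho2))


def _drate(V, rho1, rho2):
    r = sigmoid_rate(V, rho1, rho2)
    return rho1 * r * (1.0 - r)


def mg_block(V, alpha: float):
    """Voltage-dependent magnesium switch of the NMDA channel, in (0, 1)."""
    if alpha <= 0:
        raise ValueError(f"Mg-block slope must be positive, got {alpha}")
    V = np.asarray(V, float)
    # clip the exponent: the switch saturates to 0 long before overflow
    return 1.0 / (1.0 + 0.2 * np.exp(np.minimum(-alpha * V, 700.0)))


def _dmg(V, alpha):
    m = mg_block(V, alpha)
    return 0.2 * alpha * np.exp(np.minimum(-alpha * V, 700.0)) * m * m


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

class FixedPointError(RuntimeError):
    pass


class IntegrationError(RuntimeError):
    pass


def state_derivative(state: np.ndarray, params, drive=0.0,
                     lagged_rates: dict[float, np.ndarray] | None = None
                     ) -> np.ndarray:
    """Time derivative of the flattened state vector.

    ``drive`` is added to the membrane equation of the innovation targets
    (SS, RL) of each node; it may be a scalar or an array of per-node values.
    ``lagged_rates`` optionally supplies the delay-lagged presynaptic rate
    vector per delay group (used by the integrator); by default the
    instantaneous rates are used (the delay-free vector field, whose zeros
    are the fixed points of the delayed system as well).
    """
    m = _as_model(params)
    c = m.constants
    x = np.asarray(state, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite entries in state vector")
    s = x.reshape(m.n_flat, N_STATE_PER_POP)
    V, gA, gN, gG = s[:, 0], s[:, 1], s[:, 2], s[:, 3]

    rates = {d: (sigmoid_rate(V, c["rho1"], c["rho2"])
                 if lagged_rates is None else lagged_rates[d])
             for d in m.W["ampa"]}

    u = {}
    for rec in ("ampa", "nmda", "gaba"):
        acc = np.zeros(m.n_flat)
        for d, Wd in m.W[rec].items():
            acc += Wd @ rates[d]
        u[rec] = np.maximum(acc, 0.0)

    mg = mg_block(V, c["alpha_mg"])
    I = (c["g_L"] * (c["V_L"] - V) + gA * (c["V_AMPA"] - V)
         + gN * mg * (c["V_NMDA"] - V) + gG * (c["V_GABA"] - V))

    drive_vec = np.zeros(m.n_flat)
    drv = np.atleast_1d(np.asarray(drive, float))
    for n in range(m.n_nodes):
        val = drv[n] if drv.size > 1 else drv[0]
        for p in ("SS", "RL"):
            drive_vec[n * N_POP + _PIDX[p]] += c["input_gain"] * val
    I = I + drive_vec

    out = np.empty_like(s)
    out[:, 0] = I / c["C_m"]
    out[:, 1] = m.kappa["ampa"] * (u["ampa"] - gA)
    out[:, 2] = m.kappa["nmda"] * (u["nmda"] - gN)
    out[:, 3] = m.kappa["gaba"] * (u["gaba"] - gG)
    return out.ravel()


def _jacobian_delay_free(m: ConcreteModel, x: np.ndarray) -> np.ndarray:
    from .spectral import jacobian_parts
    return sum(jacobian_parts(m, x).values())


def find_fixed_point(params, tol: float = 1e-10, max_iter: int = 200
                     ) -> np.ndarray:
    """Deterministic fixed point of the (delay-free) vector field.

    Damped Newton iteration started from the leak equilibrium, with a
    fallback through a long noiseless relaxation.  Raises FixedPointError if
    the residual cannot be brought below 1e-8.
    """
    m = _as_model(params)
    x = m.leak_equilibrium()

    def newton(x0):
        x = x0.copy()
        f = state_derivative(x, m)
        for _ in range(max_iter):
            fn = np.max(np.abs(f))
            if fn < tol:
                return x, fn
            A = _jacobian_delay_free(m, x)
            try:
                dx = np.linalg.solve(A, -f)
            except np.linalg.LinAlgError:
                break
            step = 1.0
            while step > 1e-6:
                xn = x + step * dx
                try:
                    fnew = state_derivative(xn, m)
                except ValueError:
                    step *= 0.5
                    continue
                if np.max(np.abs(fnew)) < fn:
                    x, f = xn, fnew
                    break
                step *= 0.5
            else:
                break
        return x, np.max(np.abs(state_derivative(x, m)))

    x, res = newton(x)
    if res < 1e-8:
        return x
    # fallback: relax by noiseless integration, then polish with Newton
    dt = 0.05
    for _ in range(int(400.0 / dt)):
        x = x + dt * state_derivative(x, m)
    x, res = newton(x)
    if res < 1e-8:
        return x
    raise FixedPointError(
        f"no fixed point within residual 1e-8 (residual {res:.3e}) for "
        f"latents {np.array2string(m.lam, precision=3)}")


def _pink_noise(n_steps: int, dt: float, alpha_u: float, beta_u: float,
                rng: np.random.Generator, f_min: float = 1.0) -> np.ndarray:
    """Gaussian innovations with one-sided PSD alpha_u * f**-beta_u (units^2/Hz)
    above f_min Hz, synthesized in the frequency domain."""
    fs = 1000.0 / dt  # Hz
    freqs = np.fft.rfftfreq(n_steps, d=1.0 / fs)
    psd = np.zeros_like(freqs)
    band = freqs >= f_min
    psd[band] = alpha_u * freqs[band] ** (-beta_u)
    amp = np.sqrt(psd * fs * n_steps / 2.0)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    X = amp * z / np.sqrt(2.0)
    X[0] = 0.0
    if n_steps % 2 == 0:
        X[-1] = X[-1].real * np.sqrt(2.0)
    return np.fft.irfft(X, n=n_steps)


def integrate(params, duration: float, dt: float = 0.1,
              noise_scale: float = 1.0, seed: int = 0,
              x0: np.ndarray | None = None, state_stride: int = 10):
    """Euler-Maruyama integration with pink innovations driving SS and RL.

    Innovations per node have one-sided PSD ``noise_scale**2 * alpha_u *
    f**-beta_u`` so the Welch spectrum of the observed series can be compared
    directly with ``noise_scale**2`` times the analytic prediction.  Returns
    ``(t, obs, traj)`` where ``obs`` is the J-weighted, gain-scaled
    depolarization per node at every step and ``traj`` the state trajectory
    subsampled by ``state_stride``.  Identical seeds give identical output.
    """
    if dt > 0.5:
        raise ValueError(f"dt must be <= 0.5 ms, got {dt}")
    m = _as_model(params)
    c = m.constants
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise ValueError("duration shorter than one step")
    rng = np.random.default_rng(seed)
    beta_u = m.theta["beta_u"]
    if noise_scale > 0:
        noise = np.column_stack([
            noise_scale * _pink_noise(n_steps, dt, m.alpha_u[n], beta_u, rng)
            for n in range(m.n_nodes)])
    else:
        noise = np.zeros((n_steps, m.n_nodes))

    if x0 is None:
        x0 = find_fixed_point(m)
    x = np.asarray(x0, float).copy()

    delays = sorted(m.W["ampa"])
    lag_steps = {d: max(1, int(round(d / dt))) for d in delays}
    max_lag = max(lag_steps.values())
    n_hist = max_lag + 1
    rho1, rho2 = c["rho1"], c["rho2"]
    V0 = x.reshape(m.n_flat, N_STATE_PER_POP)[:, 0]
    rate_hist = np.tile(sigmoid_rate(V0, rho1, rho2), (n_hist, 1))

    Lo = m.observation_matrix()
    obs = np.empty((n_steps, m.n_nodes))
    n_keep = (n_steps + state_stride - 1) // state_stride
    traj = np.empty((n_keep, x.size))
    t = np.arange(n_steps) * dt

    # inlined vector field (same maths as state_derivative) for speed
    Ws = {rec: [m.W[rec][d] for d in delays] for rec in ("ampa", "nmda", "gaba")}
    kA, kN, kG = m.kappa["ampa"], m.kappa["nmda"], m.kappa["gaba"]
    gL, VL, VA, VN, VG = c["g_L"], c["V_L"], c["V_AMPA"], c["V_NMDA"], c["V_GABA"]
    amg, Cm, igain = c["alpha_mg"], c["C_m"], c["input_gain"]
    drive_idx = [(n * N_POP + _PIDX[p], n)
                 for n in range(m.n_nodes) for p in ("SS", "RL")]
    s = x.reshape(m.n_flat, N_STATE_PER_POP)
    check_every = max(1, int(round(50.0 / dt)))

    for k in range(n_steps):
        # record the pre-step state, then advance
        obs[k] = Lo @ x
        if k % state_stride == 0:
            traj[k // state_stride] = x
        V, gA, gN, gG = s[:, 0], s[:, 1], s[:, 2], s[:, 3]
        rate_hist[k % n_hist] = 1.0 / (1.0 + np.exp(-rho1 * (V - rho2)))
        lagged = [rate_hist[(k - lag_steps[d]) % n_hist] for d in delays]
        uA = np.maximum(sum(W @ r for W, r in zip(Ws["ampa"], lagged)), 0.0)
        uN = np.maximum(sum(W @ r for W, r in zip(Ws["nmda"], lagged)), 0.0)
        uG = np.maximum(sum(W @ r for W, r in zip(Ws["gaba"], lagged)), 0.0)
        mg = 1.0 / (1.0 + 0.2 * np.exp(-amg * V))
        I = (gL * (VL - V) + gA * (VA - V) + gN * mg * (VN - V)
             + gG * (VG - V))
        for q, n in drive_idx:
            I[q] += igain * noise[k, n]
        s[:, 0] = V + dt * I / Cm
        s[:, 1] = gA + dt * kA * (uA - gA)
        s[:, 2] = gN + dt * kN * (uN - gN)
        s[:, 3] = gG + dt * kG * (uG - gG)
        if k % check_every == 0 and np.max(np.abs(s[:, 0])) > 500.0:
            raise IntegrationError(
                f"numerical blow-up (|V| > 500 mV) at t = {k * dt:.1f} ms")
    return t, obs, traj
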