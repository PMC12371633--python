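"""Linearized canonical-microcircuit dynamics and its spectral predictions.

Each population k responds to net synaptic input u_k(t) through a normalized
alpha kernel with rate kappa_k = 1/tau_k::

    v''_k = kappa_k^2 * u_k - 2 kappa_k * v'_k - kappa_k^2 * v_k

so the kernel has unit DC gain and coupling gains are dimensionless loop
gains.  Net input is the signed, weighted sum of presynaptic depolarizations
(excitatory +, inhibitory and recurrent self-modulatory -), with the sigmoid
slope at the operating point absorbed into the gains.  Exogenous innovations
drive the spiny stellate population (the granular input layer); the observed
signal is dominated by superficial pyramidal depolarization.

The predicted one-sided EEG power density is

    g(f) = obs_gain^2 |T(f)|^2 g_u(f) + g_n(f)

with neuronal innovations g_u(f) = input_white + input_pink / f and additive
channel noise g_n(f) = noise_white + noise_pink / f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .parameters import CMCParameters, POPULATIONS, TAU_NAMES, edge_name
from .spectra import Recording, SpectralData, default_grid

#: observation weights per population depolarization (superficial pyramidal
#: dominant; a smaller deep pyramidal contribution reflects its distance
#: from the scalp sensor)
OBS_WEIGHTS = {"ss": 0.0, "sp": 1.0, "ii": 0.0, "dp": 0.3}

#: population receiving exogenous innovations
INPUT_POPULATION = "ss"


class InstabilityError(RuntimeError):
    """The linearized system is not asymptotically stable at these parameters."""


class InvalidParameterError(ValueError):
    pass


@dataclass(frozen=True)
class StateSpaceModel:
    """Linear state-space (A, B, C): 8 states = (v, v') per population."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        if self.A.shape != (8, 8) or self.B.shape != (8,) or self.C.shape != (8,):
            raise ValueError("expected A (8,8), B (8,), C (8,) for 4 populations x 2 states")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))):
            raise ValueError("non-finite state-space entries")

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    @property
    def stable(self) -> bool:
        return bool(np.max(self.eigenvalues.real) < 0)

    @property
    def stability_margin(self) -> float:
        """-max(Re(eigenvalues)); positive for stable systems, 1/s."""
        return float(-np.max(self.eigenvalues.real))


def coupling_matrix(params: CMCParameters) -> np.ndarray:
    """Signed 4x4 coupling matrix W[target, source] in physical gains."""
    phys = params.physical()
    idx = {p: i for i, p in enumerate(POPULATIONS)}
    W = np.zeros((4, 4))
    for src, dst in params.exc_edges:
        W[idx[dst], idx[src]] += phys[edge_name(src, dst)]
    for src, dst in params.inh_edges:
        W[idx[dst], idx[src]] -= phys[edge_name(src, dst)]
    for p in POPULATIONS:
        W[idx[p], idx[p]] -= phys[f"g_self_{p}"]
    return W


def build_jacobian(params: CMCParameters) -> StateSpaceModel:
    """Jacobian of the linearized rate equations at the fixed point.

    State ordering: x = (v_ss, v_sp, v_ii, v_dp, v'_ss, v'_sp, v'_ii, v'_dp).
    """
    phys = params.physical()
    taus = np.array([phys[n] for n in TAU_NAMES])
    if np.any(taus <= 0) or not np.all(np.isfinite(taus)):
        raise InvalidParameterError(f"non-positive or non-finite time constants: {taus}")
    kappa = 1.0 / taus
    W = coupling_matrix(params)
    A = np.zeros((8, 8))
    A[:4, 4:] = np.eye(4)
    A[4:, :4] = (kappa**2)[:, None] * W - np.diag(kappa**2)
    A[4:, 4:] = -2.0 * np.diag(kappa)
    B = np.zeros(8)
    k_in = POPULATIONS.index(INPUT_POPULATION)
    B[4 + k_in] = kappa[k_in] ** 2
    C = np.zeros(8)
    for p, w in OBS_WEIGHTS.items():
        C[POPULATIONS.index(p)] = w
    return StateSpaceModel(A, B, C)


def transfer_function(ssm: StateSpaceModel, freqs: np.ndarray) -> np.ndarray:
    """Complex response T(f) = C (i 2 pi f I - A)^(-1) B per grid frequency."""
    freqs = np.asarray(freqs, dtype=float)
    lam, V = np.linalg.eig(ssm.A)
    try:
        Vb = np.linalg.solve(V, ssm.B.astype(complex))
    except np.linalg.LinAlgError as err:  # defective A: fall back to per-frequency solves
        return _transfer_function_direct(ssm, freqs, err)
    CV = ssm.C.astype(complex) @ V
    omega = 2j * np.pi * freqs
    denom = omega[None, :] - lam[:, None]
    if np.any(np.abs(denom) < 1e-12):
        bad = int(np.argwhere(np.min(np.abs(denom), axis=0) < 1e-12)[0, 0])
        raise InstabilityError(f"(i w I - A) singular at frequency index {bad}")
    return (CV * Vb) @ (1.0 / denom)


def _transfer_function_direct(ssm, freqs, err):
    out = np.empty(freqs.size, dtype=complex)
    eye = np.eye(8)
    for i, f in enumerate(freqs):
        try:
            out[i] = ssm.C @ np.linalg.solve(2j * np.pi * f * eye - ssm.A, ssm.B)
        except np.linalg.LinAlgError:
            raise InstabilityError(f"(i w I - A) singular at frequency index {i}") from err
    return out


def innovation_density(params: CMCParameters, freqs: np.ndarray) -> np.ndarray:
    phys = params.physical()
    return phys["input_white"] + phys["input_pink"] / np.asarray(freqs, dtype=float)


def channel_noise_density(params: CMCParameters, freqs: np.ndarray) -> np.ndarray:
    phys = params.physical()
    return phys["noise_white"] + phys["noise_pink"] / np.asarray(freqs, dtype=float)


def predict_spectrum(params: CMCParameters, freqs: np.ndarray | None = None) -> SpectralData:
    """Predicted one-sided power spectral density (uV^2/Hz) on the grid."""
    if freqs is None:
        freqs = default_grid()
    ssm = build_jacobian(params)
    if not ssm.stable:
        raise InstabilityError(
            "parameters yield an unstable microcircuit "
            f"(max Re eigenvalue = {np.max(ssm.eigenvalues.real):.3g} 1/s)"
        )
    T = transfer_function(ssm, freqs)
    gain = params.physical()["obs_gain"]
    g = gain**2 * np.abs(T) ** 2 * innovation_density(params, freqs)
    g = g + channel_noise_density(params, freqs)
    return SpectralData(np.asarray(freqs, dtype=float), g, {"kind": "predicted"})


def simulate_timeseries(
    params: CMCParameters,
    duration: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    oversample: int = 4,
) -> Recording:
    """Stochastic integration of the linearized circuit; seeded, reproducible.

    Innovations with density g_u drive the input population through an exact
    zero-order-hold discretization computed at ``oversample * fs`` (keeping
    hold distortion negligible below 45 Hz); channel noise with density g_n
    is added after observation.  Returns the signal resampled to ``fs``.
    """
    from scipy.signal import resample_poly

    if duration * fs < 2 * fs:
        raise ValueError("duration must cover at least 2 s of signal")
    ssm = build_jacobian(params)
    if not ssm.stable:
        raise InstabilityError("cannot simulate an unstable parameterization")
    rng = np.random.default_rng(seed)
    fs_sim = fs * oversample
    n_sim = int(round(duration * fs_sim))
    from .spectra import _randomized_spectrum_signal

    u = _randomized_spectrum_signal(
        lambda f: innovation_density(params, f), n_sim, fs_sim, rng, rayleigh=True
    )
    dt = 1.0 / fs_sim
    M = np.zeros((9, 9))
    M[:8, :8] = ssm.A * dt
    M[:8, 8] = ssm.B * dt
    Md = expm(M)
    Ad, Bd = Md[:8, :8], Md[:8, 8]
    # diagonalize the discrete system into 8 scalar recursions (C-speed filters)
    lam_d, V = np.linalg.eig(Ad)
    bd = np.linalg.solve(V, Bd.astype(complex))
    cd = ssm.C.astype(complex) @ V
    y = np.zeros(n_sim)
    from scipy.signal import lfilter

    for m in range(8):
        zm = lfilter([bd[m]], [1.0, -lam_d[m]], u)
        y += np.real(cd[m] * zm)
    y *= params.physical()["obs_gain"]
    noise = _randomized_spectrum_signal(
        lambda f: channel_noise_density(params, f), n_sim, fs_sim, rng, rayleigh=True
    )
    y = y + noise
    if oversample > 1:
        y = resample_poly(y, 1, oversample)
    y = y[: int(round(duration * fs))]
    return Recording(y, fs, (), {"kind": "simulated", "duration_s": duration})
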