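"""Variational-Laplace inversion of CMC parameters from an observed spectrum.

The observation model places independent Gaussian residuals on *log* power:

    log y(f) = log g(f; theta) + eps,   eps ~ N(0, exp(-lambda))

The log transform stabilizes variance across the 1-45 Hz range and turns the
uV^2 scale into an additive offset absorbed by the electrode gain.  The
noise log-precision ``lambda`` is a hyperparameter estimated alongside the
parameters under a weak Gaussian hyperprior (or fixed via the config).

Inference maximizes the Laplace free energy

    F = <log p(y | theta)>_q - KL(q || prior),   q = N(mu, C)

by Gauss-Newton / Fisher-scoring steps with Levenberg-Marquardt damping,
giving a Gaussian posterior over log-scale parameters and F as an
approximation to log model evidence.  Accepted steps never decrease F.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .cmc import InstabilityError, predict_spectrum
from .parameters import CMCParameters, NONNEURONAL_NAMES, default_parameters
from .spectra import SpectralData

__all__ = [
    "PriorDensity",
    "PosteriorDensity",
    "InversionResult",
    "InversionConfig",
    "default_prior",
    "variational_laplace",
    "invert_spectrum",
    "free_energy",
    "tie_nonneuronal_parameters",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class PriorDensity:
    """Gaussian density over log-scale parameters, with per-parameter flags."""

    names: tuple
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        p = len(self.names)
        if mean.shape != (p,) or cov.shape != (p, p):
            raise ValueError("prior mean/covariance shapes inconsistent with names")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("prior covariance must be symmetric")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def with_entries(self, means: Mapping[str, float] | None = None,
                     variances: Mapping[str, float] | None = None) -> "PriorDensity":
        mean = self.mean.copy()
        cov = self.cov.copy()
        for k, v in (means or {}).items():
            mean[self.index(k)] = v
        for k, v in (variances or {}).items():
            i = self.index(k)
            cov[i, :] = 0.0
            cov[:, i] = 0.0
            cov[i, i] = v
        return replace(self, mean=mean, cov=cov)

    def marginal(self, names: Sequence[str]) -> "PriorDensity":
        idx = [self.index(n) for n in names]
        return PriorDensity(tuple(names), self.mean[idx], self.cov[np.ix_(idx, idx)])


@dataclass(frozen=True)
class PosteriorDensity(PriorDensity):
    """Gaussian posterior with the free energy reached at its mode."""

    free_energy: float = float("-inf")

    def __post_init__(self):
        super().__post_init__()
        if not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite")
        # symmetrize + tiny jitter guard against numerical asymmetry
        cov = 0.5 * (self.cov + self.cov.T)
        object.__setattr__(self, "cov", cov)

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        i = self.index(name)
        hw = norm.ppf(0.5 + level / 2) * np.sqrt(self.cov[i, i])
        return (float(self.mean[i] - hw), float(self.mean[i] + hw))

    def marginal(self, names: Sequence[str]) -> "PosteriorDensity":
        idx = [self.index(n) for n in names]
        return PosteriorDensity(
            tuple(names), self.mean[idx], self.cov[np.ix_(idx, idx)], self.free_energy
        )


@dataclass(frozen=True)
class InversionResult:
    posterior: PosteriorDensity
    predicted: SpectralData
    fit_correlation: float
    iterations: int
    converged: bool
    noise_log_precision: float = float("nan")

    def __post_init__(self):
        if not -1.0 <= self.fit_correlation <= 1.0:
            raise ValueError("fit correlation must lie in [-1, 1]")


# variances: 1/8 for coupling gains, 1/32 for kernel time constants (which are
# physiologically the most conserved quantities and otherwise trade off against
# inhibitory gains), 1/16 for nonneuronal scalings
_PRIOR_VAR_COUPLING = 1.0 / 8.0
_PRIOR_VAR_TAU = 1.0 / 32.0
_PRIOR_VAR_NONNEURONAL = 1.0 / 16.0


def default_prior(params: CMCParameters | None = None) -> PriorDensity:
    """Packaged shrinkage prior centered on zero log-deviations."""
    params = params or default_parameters()
    names = params.names
    var = []
    for n in names:
        if n.startswith("tau_"):
            var.append(_PRIOR_VAR_TAU)
        elif n in NONNEURONAL_NAMES:
            var.append(_PRIOR_VAR_NONNEURONAL)
        else:
            var.append(_PRIOR_VAR_COUPLING)
    return PriorDensity(names, params.vector(names), np.diag(var))


@dataclass(frozen=True)
class InversionConfig:
    max_iter: int = 128
    tol_nats: float = 0.01          # convergence: dF below this ...
    patience: int = 3               # ... for this many consecutive accepted steps
    fd_step: float = 1e-3           # central-difference step, log-units
    noise_log_precision: float | None = None  # fix lambda; None -> estimate
    lambda_init: float = 2.0
    lambda_prior_mean: float = 2.0
    lambda_prior_var: float = 18.0
    damping_init: float = 0.01
    damping_max: float = 1e8


def _logdet(M: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-positive-definite matrix in log-determinant")
    return float(val)


def _jacobian(forward: Callable, theta: np.ndarray, h0: np.ndarray, step: float) -> np.ndarray:
    """Central finite differences; falls back to one-sided at instability."""
    n, p = h0.size, theta.size
    J = np.zeros((n, p))
    for i in range(p):
        d = np.zeros(p)
        d[i] = step
        hp = hm = None
        try:
            hp = forward(theta + d)
        except InstabilityError:
            pass
        try:
            hm = forward(theta - d)
        except InstabilityError:
            pass
        if hp is not None and hm is not None:
            J[:, i] = (hp - hm) / (2 * step)
        elif hp is not None:
            J[:, i] = (hp - h0) / step
        elif hm is not None:
            J[:, i] = (h0 - hm) / step
        # both sides unstable: leave the column at zero for this iteration
    return J


def _free_energy_terms(r, J, q, prior_prec, logdet_prior_cov, lam, cfg, estimate_lambda):
    n = r.size
    elam = np.exp(lam)
    P = elam * (J.T @ J) + prior_prec
    C = np.linalg.inv(P)
    C = 0.5 * (C + C.T)
    F = (
        -0.5 * elam * float(r @ r)
        + 0.5 * n * lam
        - 0.5 * n * np.log(2 * np.pi)
        - 0.5 * float(q @ prior_prec @ q)
        + 0.5 * (-_logdet(P) - logdet_prior_cov)
    )
    if estimate_lambda:
        G = float(r @ r) + float(np.sum((J @ C) * J))
        v_lam = 1.0 / (0.5 * elam * G + 1.0 / cfg.lambda_prior_var)
        F += (
            -0.5 * (lam - cfg.lambda_prior_mean) ** 2 / cfg.lambda_prior_var
            + 0.5 * (np.log(v_lam) - np.log(cfg.lambda_prior_var))
        )
    return F, C


def _update_lambda(r, J, C, lam, cfg):
    """One Newton step on the noise log-precision, under its hyperprior."""
    n = r.size
    G = float(r @ r) + float(np.sum((J @ C) * J))
    for _ in range(8):
        elam = np.exp(lam)
        g = -0.5 * elam * G + 0.5 * n - (lam - cfg.lambda_prior_mean) / cfg.lambda_prior_var
        H = -0.5 * elam * G - 1.0 / cfg.lambda_prior_var
        step = -g / H
        lam += np.clip(step, -4.0, 4.0)
        if abs(step) < 1e-6:
            break
    return float(np.clip(lam, -10.0, 20.0))


def variational_laplace(
    forward: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    prior: PriorDensity,
    config: InversionConfig | None = None,
) -> tuple[PosteriorDensity, dict]:
    """Fit ``y = forward(theta) + noise`` by free-energy ascent.

    Returns the Gaussian posterior and a diagnostics dict (trajectory of
    accepted free energies, iteration count, convergence flag, lambda).
    """
    cfg = config or InversionConfig()
    y = np.asarray(y, dtype=float)
    m = prior.mean
    prior_prec = np.linalg.inv(prior.cov)
    logdet_prior_cov = _logdet(prior.cov)
    estimate_lambda = cfg.noise_log_precision is None
    lam = cfg.lambda_init if estimate_lambda else cfg.noise_log_precision

    theta = m.copy()
    try:
        h = forward(theta)
    except InstabilityError as err:
        raise ConvergenceError("forward model unstable at the prior mean") from err
    r = y - h
    J = _jacobian(forward, theta, h, cfg.fd_step)
    if estimate_lambda:
        _, C0 = _free_energy_terms(r, J, theta - m, prior_prec, logdet_prior_cov, lam, cfg, False)
        lam = _update_lambda(r, J, C0, lam, cfg)
    F, C = _free_energy_terms(r, J, theta - m, prior_prec, logdet_prior_cov, lam, cfg, estimate_lambda)

    nu = cfg.damping_init
    trajectory = [F]
    n_small = 0
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        elam = np.exp(lam)
        P = elam * (J.T @ J) + prior_prec
        grad = elam * (J.T @ r) - prior_prec @ (theta - m)
        accepted = False
        while nu <= cfg.damping_max:
            H = P + nu * np.diag(np.diag(P))
            try:
                delta = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                nu *= 8
                continue
            theta_new = theta + delta
            try:
                h_new = forward(theta_new)
            except InstabilityError:
                nu *= 8
                continue
            r_new = y - h_new
            J_new = _jacobian(forward, theta_new, h_new, cfg.fd_step)
            lam_new = lam
            if estimate_lambda:
                _, C_tmp = _free_energy_terms(
                    r_new, J_new, theta_new - m, prior_prec, logdet_prior_cov, lam, cfg, False
                )
                lam_new = _update_lambda(r_new, J_new, C_tmp, lam, cfg)
            F_new, C_new = _free_energy_terms(
                r_new, J_new, theta_new - m, prior_prec, logdet_prior_cov, lam_new, cfg,
                estimate_lambda,
            )
            if np.isfinite(F_new) and F_new > F - 1e-12:
                dF = F_new - F
                theta, h, r, J, lam, F, C = theta_new, h_new, r_new, J_new, lam_new, F_new, C_new
                trajectory.append(F)
                nu = max(nu / 4, 1e-8)
                accepted = True
                n_small = n_small + 1 if dF < cfg.tol_nats else 0
                break
            nu *= 8
        if not accepted:
            # no uphill step found at any damping: treat as converged at mode
            converged = True
            break
        if n_small >= cfg.patience:
            converged = True
            break

    posterior = PosteriorDensity(prior.names, theta, C, float(F))
    info = {
        "iterations": it,
        "converged": converged,
        "trajectory": np.array(trajectory),
        "noise_log_precision": float(lam),
    }
    return posterior, info


def _spectrum_forward(template: CMCParameters, freqs: np.ndarray, names: tuple):
    def forward(theta: np.ndarray) -> np.ndarray:
        params = template.with_vector(theta, names)
        return np.log(predict_spectrum(params, freqs).values)

    return forward


def invert_spectrum(
    spec: SpectralData,
    prior: PriorDensity | None = None,
    config: InversionConfig | None = None,
    template: CMCParameters | None = None,
) -> InversionResult:
    """Fit the CMC model to an observed power spectrum.

    Deterministic given (spec, prior, config).  Raises
    :class:`ConvergenceError` if no finite free-energy ascent is possible.
    """
    template = template or default_parameters()
    prior = prior or default_prior(template)
    cfg = config or InversionConfig()
    freqs = spec.freqs
    if freqs[0] < 0.999 or freqs[-1] > 45.001:
        raise ValueError("spectrum grid must lie within 1-45 Hz")
    y = np.log(np.asarray(np.real(spec.values), dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("observed spectrum must be strictly positive and finite")
    forward = _spectrum_forward(template, freqs, prior.names)
    posterior, info = variational_laplace(forward, y, prior, cfg)
    predicted = predict_spectrum(template.with_vector(posterior.mean, prior.names), freqs)
    robs, rpred = np.real(spec.values), predicted.values
    fit_r = float(np.corrcoef(robs, rpred)[0, 1]) if np.std(rpred) > 0 and np.std(robs) > 0 else 0.0
    return InversionResult(
        posterior=posterior,
        predicted=predicted,
        fit_correlation=float(np.clip(fit_r, -1.0, 1.0)),
        iterations=info["iterations"],
        converged=info["converged"],
        noise_log_precision=info["noise_log_precision"],
    )


def free_energy(
    mean: np.ndarray,
    prior: PriorDensity,
    spec: SpectralData,
    config: InversionConfig | None = None,
    posterior_cov: np.ndarray | None = None,
    template: CMCParameters | None = None,
) -> float:
    """Laplace free energy at a given posterior mean (nats).

    F = <log p(y|theta)>_q - KL(q || prior).  If ``posterior_cov`` is not
    given, the Laplace curvature (J' Pi J + S^-1)^-1 at ``mean`` is used, in
    which case the value coincides with the optimizer's objective.
    """
    cfg = config or InversionConfig()
    template = template or default_parameters()
    y = np.log(np.asarray(np.real(spec.values), dtype=float))
    forward = _spectrum_forward(template, spec.freqs, prior.names)
    return _free_energy_at(forward, y, np.asarray(mean, float), prior, cfg, posterior_cov)


def _free_energy_at(forward, y, mean, prior, cfg, posterior_cov=None) -> float:
    h = forward(mean)
    r = y - h
    J = _jacobian(forward, mean, h, cfg.fd_step)
    prior_prec = np.linalg.inv(prior.cov)
    lam = cfg.noise_log_precision if cfg.noise_log_precision is not None else cfg.lambda_init
    estimate = cfg.noise_log_precision is None
    if estimate:
        _, C0 = _free_energy_terms(r, J, mean - prior.mean, prior_prec, _logdet(prior.cov), lam, cfg, False)
        lam = _update_lambda(r, J, C0, lam, cfg)
    if posterior_cov is None:
        F, _ = _free_energy_terms(
            r, J, mean - prior.mean, prior_prec, _logdet(prior.cov), lam, cfg, estimate
        )
        return float(F)
    # explicit posterior covariance: generic expected-log-likelihood form
    C = np.asarray(posterior_cov, dtype=float)
    n = y.size
    elam = np.exp(lam)
    q = mean - prior.mean
    accuracy = (
        -0.5 * elam * float(r @ r)
        + 0.5 * n * lam
        - 0.5 * n * np.log(2 * np.pi)
        - 0.5 * elam * float(np.sum((J @ C) * J))
    )
    kl = 0.5 * (
        float(np.trace(np.linalg.solve(prior.cov, C)))
        - len(mean)
        + float(q @ prior_prec @ q)
        + _logdet(prior.cov)
        - _logdet(C)
    )
    return float(accuracy - kl)


def tie_nonneuronal_parameters(
    first: InversionResult, prior: PriorDensity, shrink_var: float = 1e-6
) -> PriorDensity:
    """Prior for a repeat inversion with nonneuronal scalings pinned.

    The returned prior centers the nonneuronal entries (innovation and
    channel-noise amplitudes, electrode gain) on the first inversion's
    posterior means with prior variance shrunk to ``shrink_var``, leaving
    the 14 synaptic parameters untouched.  This suppresses changes in
    nonneuronal scaling between repeat inversions for the same patient.
    """
    if not first.converged:
        raise ValueError("first inversion did not converge; refusing to tie its posterior")
    post = first.posterior
    means = {n: float(post.mean[post.index(n)]) for n in NONNEURONAL_NAMES if n in post.names}
    variances = {n: shrink_var for n in means}
    return prior.with_entries(means=means, variances=variances)
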