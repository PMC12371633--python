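"""Parametric empirical Bayes (PEB) over first-level posteriors.

The second level models systematic variation of the first-level (per
patient and condition) synaptic parameters theta_i with a linear design::

    theta_i = B' x_i + eps_i,    eps_i ~ N(0, Gamma)

where x_i is the row of the design matrix (intercept, responder main
effect, treatment main effect, interaction, optional other-ASM nuisance
columns; effect-coded +/-1), B is the (regressor x parameter) matrix of
second-level effects with a Gaussian prior, and Gamma is a diagonal
between-model (random-effects) variance optimized by empirical Bayes.

Uncertainty is propagated from the first level by representing each
first-level *likelihood* through its Gaussian posterior and prior:
precision Lambda_i = C_i^-1 - S^-1 and information h_i = C_i^-1 mu_i -
S^-1 m.  This undoes first-level shrinkage instead of treating shrunken
posterior means as data, and makes the degenerate one-model hierarchy
reproduce the first-level posterior exactly.  Everything is
linear-Gaussian, so the evidence (free energy) and the posterior over B
are analytic, and nested-model comparisons (hypotheses H1-H3, the 15
parameter-family models) are computed by Bayesian model reduction without
refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .inversion import PosteriorDensity, PriorDensity
from .parameters import CMCParameters, FAMILY_LETTERS, default_parameters, family_members

__all__ = [
    "DesignMatrix",
    "FamilyMask",
    "PEBResult",
    "PEBConfig",
    "build_design_matrix",
    "fit_peb",
    "bayesian_model_reduction",
    "compare_hypotheses",
    "enumerate_family_models",
    "compare_family_models",
    "NestingError",
    "DesignError",
]

HYPOTHESIS_COLUMNS = {
    # which non-intercept effects each hypothesis retains
    "H1": ("resp", "bzp"),
    "H2": ("bzp", "resp_x_bzp"),
    "H3": ("resp", "bzp", "resp_x_bzp"),
}

#: nuisance regressors never pruned by hypothesis/family reductions
NUISANCE_COLUMNS = ("other_asm", "other_asm_x_resp")


class NestingError(ValueError):
    pass


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class DesignMatrix:
    """Effect-coded between-DCM regressor matrix (one row per first-level model)."""

    values: np.ndarray
    columns: tuple
    rows: tuple  # (patient_id, condition) per row

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "columns", tuple(self.columns))
        object.__setattr__(self, "rows", tuple(self.rows))
        if vals.shape != (len(self.rows), len(self.columns)):
            raise DesignError("design shape inconsistent with row/column labels")
        if "intercept" in self.columns and not np.allclose(vals[:, self.columns.index("intercept")], 1):
            raise DesignError("intercept column must be all ones")
        rank = np.linalg.matrix_rank(vals)
        if rank < len(self.columns):
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.nan_to_num(np.corrcoef(vals.T))
            bad = [
                (self.columns[i], self.columns[j])
                for i in range(len(self.columns))
                for j in range(i + 1, len(self.columns))
                if abs(corr[i, j]) > 0.999
            ]
            raise DesignError(f"rank-deficient design; collinear columns: {bad or 'unknown'}")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.rows, names=["patient_id", "condition"])
        return pd.DataFrame(self.values, index=idx, columns=list(self.columns))


def build_design_matrix(cohort_meta: pd.DataFrame) -> DesignMatrix:
    """Second-level design from a cohort manifest.

    ``cohort_meta`` needs columns patient_id, group (responder|nonresponder),
    condition (pre|post); an optional boolean ``other_asm`` column marks
    conditions recorded under an additional non-BZP antiseizure medication,
    which enters as nuisance regressors (treatment and group-interaction
    terms for the other medication).
    """
    df = cohort_meta.copy()
    required = {"patient_id", "group", "condition"}
    if not required <= set(df.columns):
        raise DesignError(f"cohort manifest must have columns {sorted(required)}")
    counts = df.groupby("patient_id")["condition"].agg(lambda s: sorted(s))
    for pid, conds in counts.items():
        if conds != ["post", "pre"]:
            raise DesignError(f"patient {pid} must have exactly a pre and a post entry, got {conds}")
    # row order follows the manifest so callers can align first-level models
    resp = np.where(df["group"].to_numpy() == "responder", 1.0, -1.0)
    bzp = np.where(df["condition"].to_numpy() == "post", 1.0, -1.0)
    cols = {"intercept": np.ones(len(df)), "resp": resp, "bzp": bzp, "resp_x_bzp": resp * bzp}
    if "other_asm" in df.columns and df["other_asm"].astype(bool).any():
        asm = np.where(df["other_asm"].astype(bool).to_numpy(), 1.0, 0.0)
        cols["other_asm"] = asm
        cols["other_asm_x_resp"] = asm * resp
    rows = tuple(zip(df["patient_id"], df["condition"]))
    return DesignMatrix(np.column_stack(list(cols.values())), tuple(cols), rows)


@dataclass(frozen=True)
class FamilyMask:
    """Subset of the four parameter families allowed to express group effects."""

    name: str  # e.g. "i", "ti", "tmei"
    parameter_names: tuple

    def __post_init__(self):
        letters = tuple(self.name)
        if not letters or any(l not in FAMILY_LETTERS for l in letters) or len(set(letters)) != len(letters):
            raise ValueError(f"family name must be a nonempty subset of {FAMILY_LETTERS}: {self.name!r}")

    @classmethod
    def from_letters(cls, letters: str, params: CMCParameters | None = None) -> "FamilyMask":
        params = params or default_parameters()
        unknown = set(letters) - set(FAMILY_LETTERS)
        if unknown:
            raise ValueError(f"unknown family letter(s) {sorted(unknown)}; expected {FAMILY_LETTERS}")
        ordered = "".join(l for l in FAMILY_LETTERS if l in letters)
        return cls(ordered, family_members(params, ordered))

    def bool_vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([n in self.parameter_names for n in names])


def enumerate_family_models(params: CMCParameters | None = None) -> list[FamilyMask]:
    """All 15 nonempty combinations of {t, m, e, i}, lexicographic by size then letters."""
    out = []
    for k in range(1, 5):
        for combo in combinations(FAMILY_LETTERS, k):
            out.append(FamilyMask.from_letters("".join(combo), params))
    return out


@dataclass(frozen=True)
class PEBConfig:
    beta_prior_var_effect: float = 1.0 / 8.0
    pruned_var: float = 1e-8
    gamma_init: float = 0.01
    gamma_bounds: tuple = (1e-6, 4.0)
    optimize_gamma: bool = True
    gamma_maxiter: int = 60


@dataclass(frozen=True)
class PEBResult:
    """Posterior over second-level effects with the empirical-Bayes free energy."""

    design: DesignMatrix
    parameter_names: tuple
    beta: np.ndarray                 # (n_regressors, n_parameters) posterior mean
    beta_covariance: np.ndarray      # over vec(beta), row-major (regressor, parameter)
    beta_prior: PriorDensity         # prior over the same vectorization
    random_effects_variance: np.ndarray  # diagonal of Gamma, one entry per parameter
    free_energy: float

    def __post_init__(self):
        k, p = len(self.design.columns), len(self.parameter_names)
        if self.beta.shape != (k, p) or self.beta_covariance.shape != (k * p, k * p):
            raise ValueError("beta/covariance shapes inconsistent with design and parameters")
        if not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite")

    def effect(self, regressor: str, parameter: str) -> tuple[float, float]:
        """Posterior (mean, sd) of one second-level effect."""
        i = self.design.columns.index(regressor)
        j = self.parameter_names.index(parameter)
        flat = i * len(self.parameter_names) + j
        return float(self.beta[i, j]), float(np.sqrt(self.beta_covariance[flat, flat]))

    def to_posterior(self) -> PosteriorDensity:
        names = tuple(
            f"{c}:{p}" for c in self.design.columns for p in self.parameter_names
        )
        return PosteriorDensity(names, self.beta.reshape(-1), self.beta_covariance, self.free_energy)


def _beta_prior(design: DesignMatrix, parameter_names, mask: FamilyMask | None,
                cfg: PEBConfig, fl_prior: PriorDensity) -> PriorDensity:
    """Prior over vec(B): the intercept row inherits the first-level prior
    (so a one-model hierarchy reproduces the first-level posterior); effect
    rows get zero-mean shrinkage priors, pruned outside the mask."""
    names, mean, var = [], [], []
    masked = None if mask is None else set(mask.parameter_names)
    fl_var = np.diag(fl_prior.cov)
    for c in design.columns:
        for j, p in enumerate(parameter_names):
            names.append(f"{c}:{p}")
            if c == "intercept":
                mean.append(fl_prior.mean[j])
                var.append(fl_var[j])
            else:
                mean.append(0.0)
                if masked is not None and p not in masked and c not in NUISANCE_COLUMNS:
                    var.append(cfg.pruned_var)
                else:
                    var.append(cfg.beta_prior_var_effect)
    return PriorDensity(tuple(names), np.array(mean), np.diag(var))


def _extract_likelihoods(mu, Ci, fl_prior: PriorDensity):
    """Per-model likelihood precision/information from posterior and prior.

    Lambda_i = C_i^-1 - S^-1 (negative eigenvalues floored at zero) and
    h_i = C_i^-1 mu_i - S^-1 m, plus the log-normalizing constant of the
    Gaussian likelihood-ratio representation.
    """
    P0 = np.linalg.inv(fl_prior.cov)
    m = fl_prior.mean
    _, ld_P0 = np.linalg.slogdet(P0)
    lams, hs, consts = [], [], []
    for i in range(mu.shape[0]):
        Pi = np.linalg.inv(Ci[i])
        Pi = 0.5 * (Pi + Pi.T)
        Lam = Pi - P0
        w, V = np.linalg.eigh(Lam)
        Lam = (V * np.clip(w, 0.0, None)) @ V.T
        h = Pi @ mu[i] - P0 @ m
        _, ld_Pi = np.linalg.slogdet(Pi)
        consts.append(0.5 * (ld_Pi - ld_P0) - 0.5 * (mu[i] @ Pi @ mu[i]) + 0.5 * (m @ P0 @ m))
        lams.append(Lam)
        hs.append(h)
    return np.stack(lams), np.stack(hs), np.array(consts)


def _evidence_and_posterior(lams, hs, consts, X, gamma_diag, prior: PriorDensity):
    """Exact marginal log evidence and Gaussian posterior over vec(B)."""
    n, p = hs.shape
    Ginv = np.diag(1.0 / gamma_diag)
    _, ld_G = np.linalg.slogdet(np.diag(gamma_diag))
    Sb_inv = np.linalg.inv(prior.cov)
    precision = Sb_inv.copy()
    rhs = Sb_inv @ prior.mean
    F = float(np.sum(consts)) - 0.5 * float(prior.mean @ Sb_inv @ prior.mean)
    for i in range(n):
        Q = lams[i] + Ginv
        Q_inv = np.linalg.inv(Q)
        _, ld_Q = np.linalg.slogdet(Q)
        M = Ginv - Ginv @ Q_inv @ Ginv          # = (Gamma + Lambda_i^+)^-1
        M = 0.5 * (M + M.T)
        v = Ginv @ (Q_inv @ hs[i])
        F += -0.5 * ld_G - 0.5 * ld_Q + 0.5 * float(hs[i] @ Q_inv @ hs[i])
        precision += np.kron(np.outer(X[i], X[i]), M)
        rhs += np.kron(X[i], v)
    cov = np.linalg.inv(precision)
    cov = 0.5 * (cov + cov.T)
    b = cov @ rhs
    _, ld_prior = np.linalg.slogdet(prior.cov)
    _, ld_post = np.linalg.slogdet(precision)
    F += -0.5 * ld_prior - 0.5 * ld_post + 0.5 * float(rhs @ b)
    return float(F), b, cov


def fit_peb(
    first_level: Sequence[PosteriorDensity],
    X: DesignMatrix,
    mask: FamilyMask | None = None,
    config: PEBConfig | None = None,
    parameter_names: Sequence[str] | None = None,
    first_level_prior: PriorDensity | None = None,
) -> PEBResult:
    """Fit the hierarchical linear model over first-level posteriors.

    Only parameters selected by ``mask`` may express non-intercept effects
    (``mask=None`` allows all).  ``first_level_prior`` is the prior the
    first-level inversions used (the packaged default if omitted); it is
    needed to recover each model's likelihood from its posterior.  The
    diagonal random-effects variance Gamma is optimized by maximizing the
    exact marginal evidence; the returned free energy is that evidence at
    the optimum.
    """
    cfg = config or PEBConfig()
    if len(first_level) != len(X.rows):
        raise DesignError(f"{len(first_level)} posteriors but {len(X.rows)} design rows")
    if parameter_names is None:
        parameter_names = first_level[0].names
    parameter_names = tuple(parameter_names)
    for fl in first_level:
        if not set(parameter_names) <= set(fl.names):
            raise DesignError("first-level posteriors do not share the requested parameterization")
    if first_level_prior is None:
        from .inversion import default_prior

        first_level_prior = default_prior()
    fl_prior = first_level_prior.marginal(parameter_names)
    marg = [fl.marginal(parameter_names) for fl in first_level]
    mu = np.stack([m.mean for m in marg])
    Ci = np.stack([m.cov for m in marg])
    lams, hs, consts = _extract_likelihoods(mu, Ci, fl_prior)
    prior = _beta_prior(X, parameter_names, mask, cfg, fl_prior)
    p = len(parameter_names)

    def neg_evidence(log_gamma):
        F, _, _ = _evidence_and_posterior(lams, hs, consts, X.values, np.exp(log_gamma), prior)
        return -F

    lg0 = np.full(p, np.log(cfg.gamma_init))
    if cfg.optimize_gamma:
        lo, hi = np.log(cfg.gamma_bounds[0]), np.log(cfg.gamma_bounds[1])
        res = minimize(
            neg_evidence, lg0, method="L-BFGS-B",
            bounds=[(lo, hi)] * p, options={"maxiter": cfg.gamma_maxiter},
        )
        log_gamma = res.x
    else:
        log_gamma = lg0
    gamma = np.exp(log_gamma)
    F, b, cov = _evidence_and_posterior(lams, hs, consts, X.values, gamma, prior)
    k = len(X.columns)
    return PEBResult(
        design=X,
        parameter_names=parameter_names,
        beta=b.reshape(k, p),
        beta_covariance=cov,
        beta_prior=prior,
        random_effects_variance=gamma,
        free_energy=F,
    )


def bayesian_model_reduction(
    full_posterior: PosteriorDensity,
    full_prior: PriorDensity,
    reduced_prior: PriorDensity,
    tol: float = 1e-9,
) -> tuple[float, PosteriorDensity]:
    """Analytic evidence change and posterior under a shrunken (nested) prior.

    The reduced prior may only shrink prior variances (with means fixed
    wherever the variance is unchanged); the evidence update

        dF = ln E_q[ p_reduced(theta) / p_full(theta) ]

    is exact for linear-Gaussian models and requires no refitting.
    """
    if reduced_prior.names != full_prior.names:
        raise NestingError("reduced prior must be over the same parameters")
    dv = np.diag(reduced_prior.cov) - np.diag(full_prior.cov)
    if np.any(dv > tol * (1 + np.abs(np.diag(full_prior.cov)))):
        raise NestingError("reduced prior must not inflate any prior variance (non-nested)")
    P_post = np.linalg.inv(full_posterior.cov)
    P_full = np.linalg.inv(full_prior.cov)
    P_red = np.linalg.inv(reduced_prior.cov)
    Lam = P_post + P_red - P_full
    w = (
        P_post @ full_posterior.mean
        + P_red @ reduced_prior.mean
        - P_full @ full_prior.mean
    )
    sign, ld_lam = np.linalg.slogdet(Lam)
    if sign <= 0:
        raise NestingError("reduction yields an improper posterior (non-nested prior?)")
    _, ld_post = np.linalg.slogdet(P_post)
    _, ld_red = np.linalg.slogdet(P_red)
    _, ld_full = np.linalg.slogdet(P_full)
    mean_r = np.linalg.solve(Lam, w)
    cov_r = np.linalg.inv(Lam)
    cov_r = 0.5 * (cov_r + cov_r.T)
    dF = 0.5 * (
        ld_post + ld_red - ld_full - ld_lam
        + (w @ mean_r)
        - (full_posterior.mean @ P_post @ full_posterior.mean)
        - (reduced_prior.mean @ P_red @ reduced_prior.mean)
        + (full_prior.mean @ P_full @ full_prior.mean)
    )
    reduced_post = PosteriorDensity(
        full_posterior.names, mean_r, cov_r, full_posterior.free_energy + float(dF)
    )
    return float(dF), reduced_post


def _reduce_columns(full: PEBResult, keep_effects: Sequence[str], cfg: PEBConfig) -> float:
    """Free energy of a design reduction keeping only the given non-intercept effects."""
    keep = set(keep_effects) | {"intercept"} | set(NUISANCE_COLUMNS)
    variances = {}
    for name in full.beta_prior.names:
        col = name.split(":", 1)[0]
        if col not in keep:
            variances[name] = cfg.pruned_var
    reduced_prior = full.beta_prior.with_entries(variances=variances)
    dF, _ = bayesian_model_reduction(full.to_posterior(), full.beta_prior, reduced_prior)
    return full.free_energy + dF


def compare_hypotheses(
    first_level: Sequence[PosteriorDensity],
    cohort_meta: pd.DataFrame,
    config: PEBConfig | None = None,
    parameter_names: Sequence[str] | None = None,
    first_level_prior: PriorDensity | None = None,
) -> dict:
    """Free energies of the three between-group hypotheses.

    H1: responders differ during SE and respond like nonresponders to BZP
    (responsiveness + treatment main effects); H2: groups are alike during
    SE but respond differently (treatment + interaction); H3: both a
    baseline difference and a differential response (full complement).
    All three are reductions of the full design evaluated analytically.
    """
    cfg = config or PEBConfig()
    X = build_design_matrix(cohort_meta)
    full = fit_peb(first_level, X, None, cfg, parameter_names, first_level_prior)
    F = {h: _reduce_columns(full, cols, cfg) for h, cols in HYPOTHESIS_COLUMNS.items()}
    # intercept-only (no group structure) reference: a winner is only called
    # decisive if it also clearly beats this null model
    F_null = _reduce_columns(full, (), cfg)
    ranked = sorted(F, key=F.get, reverse=True)
    margin = F[ranked[0]] - F[ranked[1]]
    null_margin = F[ranked[0]] - F_null
    return {
        "free_energy": F,
        "null_free_energy": float(F_null),
        "winner": ranked[0],
        "ranked": ranked,
        "decisive": bool(margin > 3.0 and null_margin > 3.0),
        "margin_nats": float(margin),
        "null_margin_nats": float(null_margin),
        "full": full,
    }


def compare_family_models(
    first_level: Sequence[PosteriorDensity],
    cohort_meta: pd.DataFrame,
    design_effects: Sequence[str] = HYPOTHESIS_COLUMNS["H3"],
    config: PEBConfig | None = None,
    parameter_names: Sequence[str] | None = None,
    first_level_prior: PriorDensity | None = None,
) -> dict:
    """Fixed-effects Bayesian model comparison over the 15 family models.

    Each family model allows non-intercept (group/treatment) effects only on
    the parameters of its families; all are reductions of the full model
    under the winning design, compared by free energy.
    """
    cfg = config or PEBConfig()
    X = build_design_matrix(cohort_meta)
    full = fit_peb(first_level, X, None, cfg, parameter_names, first_level_prior)
    if parameter_names is None:
        parameter_names = full.parameter_names
    masks = enumerate_family_models()
    rows = []
    for mask in masks:
        variances = {}
        for name in full.beta_prior.names:
            col, par = name.split(":", 1)
            if col == "intercept" or col in NUISANCE_COLUMNS:
                continue
            if col not in design_effects or par not in mask.parameter_names:
                variances[name] = cfg.pruned_var
        reduced_prior = full.beta_prior.with_entries(variances=variances)
        dF, _ = bayesian_model_reduction(full.to_posterior(), full.beta_prior, reduced_prior)
        rows.append((mask.name, full.free_energy + dF))
    table = pd.DataFrame(rows, columns=["family", "free_energy"])
    table = table.sort_values("free_energy", ascending=False, ignore_index=True)
    margin = float(table.free_energy.iloc[0] - table.free_energy.iloc[1])
    # no-effects reference (all group effects pruned, intercept/nuisance kept)
    variances = {
        name: cfg.pruned_var
        for name in full.beta_prior.names
        if name.split(":", 1)[0] not in ("intercept", *NUISANCE_COLUMNS)
    }
    dF_none, _ = bayesian_model_reduction(
        full.to_posterior(), full.beta_prior, full.beta_prior.with_entries(variances=variances)
    )
    F_none = full.free_energy + dF_none
    null_margin = float(table.free_energy.iloc[0] - F_none)
    return {
        "table": table,
        "null_free_energy": float(F_none),
        "winner": table.family.iloc[0],
        "decisive": bool(margin > 3.0 and null_margin > 3.0),
        "margin_nats": margin,
        "null_margin_nats": null_margin,
        "full": full,
    }
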