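"""Maximum-likelihood fitting of the panel multi-state model.

The process is observed only at assessment times, so each consecutive pair of
observations (state ``r`` at ``t``, state ``s`` at ``t + dt``) contributes
``log P_rs(dt; z)`` to the log-likelihood, where ``P(dt; z) = expm(Q(z) dt)``
and ``Q(z)`` is the proportional-intensity generator evaluated at the
covariates in force at the start of the interval.  Parameters are the six
baseline log-intensities ``theta_rs = log q_rs0`` (log scale enforces
positivity without constraints) followed by one coefficient block per
covariate.  Standard errors come from the inverse of the observed information
matrix, obtained by central finite differences at the optimum; hazard ratios
are ``exp(beta)`` with Wald 95% intervals on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .ctmc import TRANSITIONS, build_intensity_matrix
from .panel_data import PanelDataset

__all__ = [
    "ModelSpec",
    "FittedModel",
    "panel_log_likelihood",
    "crude_initial_estimates",
    "fit",
    "hazard_ratios",
    "univariate_screen",
]

_RATE_FLOOR = 1e-4  # keeps log-intensities finite for unobserved transitions
_MAX_ETA = 30.0  # |log intensity| cap inside the likelihood; beyond it -> -inf


@dataclass(frozen=True)
class ModelSpec:
    """Declares which covariates enter which transitions.

    By default every covariate receives its own coefficient on every allowed
    transition (36 hazard ratios for six covariates); ``covariate_transitions``
    restricts a covariate to a subset, e.g. ``{"exposure": ((1, 3),)}``.
    """

    covariates: tuple[str, ...] = ()
    transitions: tuple[tuple[int, int], ...] = TRANSITIONS
    covariate_transitions: Mapping[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(
            self, "transitions", tuple(tuple(t) for t in self.transitions)
        )
        object.__setattr__(
            self,
            "covariate_transitions",
            {k: tuple(tuple(t) for t in v) for k, v in self.covariate_transitions.items()},
        )
        for name, trans in self.covariate_transitions.items():
            if name not in self.covariates:
                raise ValueError(f"covariate_transitions given for unknown covariate {name!r}")
            bad = set(trans) - set(self.transitions)
            if bad:
                raise ValueError(f"covariate {name!r} assigned to unmodelled transitions {sorted(bad)}")

    def transitions_for(self, covariate: str) -> tuple[tuple[int, int], ...]:
        return self.covariate_transitions.get(covariate, self.transitions)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = [f"theta_{r}{s}" for r, s in self.transitions]
        for c in self.covariates:
            names += [f"beta_{c}_{r}{s}" for r, s in self.transitions_for(c)]
        return tuple(names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def split(self, params: np.ndarray) -> tuple[np.ndarray, dict[str, dict[tuple[int, int], float]]]:
        """Split a parameter vector into (theta over transitions, beta per covariate)."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_parameters,):
            raise ValueError(
                f"parameter vector of length {params.size}, expected {self.n_parameters}"
            )
        k = len(self.transitions)
        theta = params[:k]
        betas: dict[str, dict[tuple[int, int], float]] = {}
        i = k
        for c in self.covariates:
            trans = self.transitions_for(c)
            betas[c] = dict(zip(trans, params[i : i + len(trans)]))
            i += len(trans)
        return theta, betas


@dataclass
class FittedModel:
    """Result of a maximum-likelihood fit."""

    spec: ModelSpec
    params: np.ndarray
    covariance: np.ndarray | None
    log_likelihood: float
    converged: bool
    n_iter: int
    gradient_norm: float
    message: str = ""
    n_subjects: int = 0
    n_pairs: int = 0

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.spec.parameter_names

    def intensity_matrix(self, z: Mapping[str, float] | None = None) -> np.ndarray:
        """Fitted generator at covariate vector ``z`` (baseline if omitted)."""
        theta, betas = self.spec.split(self.params)
        rates: dict[tuple[int, int], float] = {}
        for j, trans in enumerate(self.spec.transitions):
            eta = theta[j]
            if z is not None:
                for c, per_trans in betas.items():
                    if trans in per_trans:
                        eta += per_trans[trans] * float(z[c])
            rates[trans] = float(np.exp(eta))
        return build_intensity_matrix(rates, n_states=3)

    def standard_errors(self) -> np.ndarray | None:
        if self.covariance is None:
            return None
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def to_dict(self) -> dict:
        return {
            "parameter_names": list(self.parameter_names),
            "estimates": self.params.tolist(),
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "log_likelihood": self.log_likelihood,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "gradient_norm": float(self.gradient_norm),
            "message": self.message,
            "n_subjects": int(self.n_subjects),
            "n_pairs": int(self.n_pairs),
            "spec": {
                "covariates": list(self.spec.covariates),
                "transitions": [list(t) for t in self.spec.transitions],
                "covariate_transitions": {
                    k: [list(t) for t in v] for k, v in self.spec.covariate_transitions.items()
                },
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        spec = ModelSpec(
            covariates=tuple(d["spec"]["covariates"]),
            transitions=tuple(tuple(t) for t in d["spec"]["transitions"]),
            covariate_transitions={
                k: tuple(tuple(t) for t in v)
                for k, v in d["spec"]["covariate_transitions"].items()
            },
        )
        cov = d.get("covariance")
        return cls(
            spec=spec,
            params=np.asarray(d["estimates"], dtype=float),
            covariance=None if cov is None else np.asarray(cov, dtype=float),
            log_likelihood=float(d["log_likelihood"]),
            converged=bool(d["converged"]),
            n_iter=int(d.get("n_iter", 0)),
            gradient_norm=float(d.get("gradient_norm", np.nan)),
            message=str(d.get("message", "")),
            n_subjects=int(d.get("n_subjects", 0)),
            n_pairs=int(d.get("n_pairs", 0)),
        )


# ---------------------------------------------------------------------------
# likelihood


def _group_pairs(ds: PanelDataset, spec: ModelSpec) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Group observation pairs by (interval length, covariate pattern).

    Returns a list of ``(dt, z_values, counts)`` with ``counts`` the 3x3
    matrix of pair frequencies in that cell; pairs sharing a cell share one
    matrix-exponential evaluation.  The grouped likelihood is identical to
    the naive per-pair sum.
    """
    pairs = ds.pairs(spec.covariates)
    if not len(pairs):
        return []
    keys = ["dt", *spec.covariates]
    groups = []
    for key, sub in pairs.groupby(keys, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        dt = float(key[0])
        z = np.asarray(key[1:], dtype=float)
        counts = np.zeros((3, 3))
        np.add.at(counts, (sub["from_state"].to_numpy() - 1, sub["to_state"].to_numpy() - 1), 1.0)
        groups.append((dt, z, counts))
    return groups


def _eta_matrix(theta: np.ndarray, betas, spec: ModelSpec, z_order: Sequence[str]):
    """Linear predictors per transition as functions of z; returns (base, coef)."""
    m = len(spec.transitions)
    base = np.asarray(theta, dtype=float)
    coef = np.zeros((m, len(z_order)))
    for j, trans in enumerate(spec.transitions):
        for c_idx, c in enumerate(z_order):
            coef[j, c_idx] = betas.get(c, {}).get(trans, 0.0)
    return base, coef


def _grouped_neg_loglik(params: np.ndarray, groups, spec: ModelSpec) -> float:
    theta, betas = spec.split(params)
    base, coef = _eta_matrix(theta, betas, spec, spec.covariates)
    total = 0.0
    for dt, z, counts in groups:
        eta = base + (coef @ z if z.size else 0.0)
        if np.any(np.abs(eta) > _MAX_ETA):
            return np.inf
        rates = {trans: float(np.exp(eta[j])) for j, trans in enumerate(spec.transitions)}
        Q = build_intensity_matrix(rates, n_states=3)
        P = expm(Q * dt)
        mask = counts > 0
        if np.any(P[mask] <= 0.0):
            return np.inf
        total += float(np.sum(counts[mask] * np.log(P[mask])))
    return -total


def panel_log_likelihood(
    params: Sequence[float], ds: PanelDataset, spec: ModelSpec | None = None
) -> float:
    """Panel log-likelihood: sum of ``log P_rs(dt; z)`` over observation pairs.

    Returns ``-inf`` (never raises) when a required transition probability is
    numerically zero or a linear predictor overflows, so optimizers can
    backtrack.  An empty dataset has log-likelihood 0 (empty product).
    """
    if spec is None:
        spec = ModelSpec()
    groups = _group_pairs(ds, spec)
    nll = _grouped_neg_loglik(np.asarray(params, dtype=float), groups, spec)
    return -nll


def crude_initial_estimates(freq: np.ndarray, mean_interval: float = 1.0) -> np.ndarray:
    """Moment-style initial generator from a transition frequency matrix.

    ``q_rs = counts[r][s] / (row_total(r) * mean_interval)``, floored at a
    small positive constant so log-intensities stay finite.  Doubling all
    counts leaves the result unchanged.
    """
    freq = np.asarray(freq, dtype=float)
    if mean_interval <= 0:
        raise ValueError("mean_interval must be positive")
    if freq.sum() == 0:
        warnings.warn("all-zero frequency matrix; using uniform small initialization")
        Q0 = np.full_like(freq, _RATE_FLOOR, dtype=float)
        np.fill_diagonal(Q0, 0.0)
        np.fill_diagonal(Q0, -Q0.sum(axis=1))
        return Q0
    row_tot = freq.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Q0 = np.where(row_tot > 0, freq / (row_tot * mean_interval), 0.0)
    np.fill_diagonal(Q0, 0.0)
    Q0 = np.where(Q0 < _RATE_FLOOR, _RATE_FLOOR, Q0)
    np.fill_diagonal(Q0, 0.0)
    np.fill_diagonal(Q0, -Q0.sum(axis=1))
    return Q0


def _observed_information(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Hessian of ``f`` at ``x`` by central differences of central-difference gradients."""
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))

    def grad(y: np.ndarray) -> np.ndarray:
        g = np.empty(p)
        for i in range(p):
            e = np.zeros(p)
            e[i] = h[i]
            g[i] = (f(y + e) - f(y - e)) / (2 * h[i])
        return g

    H = np.empty((p, p))
    for j in range(p):
        e = np.zeros(p)
        e[j] = h[j]
        H[:, j] = (grad(x + e) - grad(x - e)) / (2 * h[j])
    return 0.5 * (H + H.T)


def fit(
    ds: PanelDataset,
    spec: ModelSpec | None = None,
    mean_interval: float | None = None,
    compute_covariance: bool = True,
    maxiter: int = 500,
    gtol: float = 1e-4,
) -> FittedModel:
    """Maximize the panel log-likelihood by quasi-Newton (BFGS) iteration.

    Initialization: baseline log-intensities from :func:`crude_initial_estimates`
    on the observed transition frequencies, covariate coefficients at zero.
    The covariance matrix is the inverse observed information (central-difference
    Hessian of the negative log-likelihood at the optimum); when the information
    matrix is singular the covariance is omitted with a warning and estimates
    are still returned.
    """
    from .panel_data import count_transitions

    if spec is None:
        spec = ModelSpec()
    groups = _group_pairs(ds, spec)
    if not groups:
        raise ValueError("dataset has no observation pairs to fit")
    n_pairs = int(sum(c.sum() for _, _, c in groups))
    if mean_interval is None:
        mean_interval = float(
            sum(dt * c.sum() for dt, _, c in groups) / n_pairs
        )
    Q0 = crude_initial_estimates(count_transitions(ds), mean_interval)
    x0 = np.zeros(spec.n_parameters)
    for j, (r, s) in enumerate(spec.transitions):
        x0[j] = np.log(max(Q0[r - 1, s - 1], _RATE_FLOOR))

    nll = lambda x: _grouped_neg_loglik(x, groups, spec)
    # optimize the mean per-pair deviance so the gradient tolerance is
    # scale-free in the number of observation pairs
    mean_nll = lambda x: nll(x) / n_pairs
    ll0 = -nll(x0)
    res = minimize(mean_nll, x0, method="BFGS", options={"gtol": gtol, "maxiter": maxiter})
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success or grad_norm < gtol)
    ll_hat = -float(res.fun) * n_pairs
    if ll_hat < ll0 - 1e-9:  # optimizer must not end below its start
        warnings.warn("optimizer ended below the initial log-likelihood; keeping start values")
        res.x, ll_hat, converged = x0, ll0, False

    covariance = None
    if compute_covariance:
        H = _observed_information(nll, res.x)
        try:
            covariance = np.linalg.inv(H)
            if not np.all(np.isfinite(covariance)) or np.any(np.diag(covariance) < -1e-8):
                raise np.linalg.LinAlgError("information matrix not positive definite")
            covariance = 0.5 * (covariance + covariance.T)
        except np.linalg.LinAlgError:
            # Weakly identified fits (e.g. a log-intensity at its flat boundary)
            # yield a singular information matrix.  Along non-identified
            # directions the Wald variance is effectively infinite, so invert
            # with the near-zero eigenvalues floored at a tiny positive value:
            # those directions get enormous, not zero, variance.
            eigval, eigvec = np.linalg.eigh(0.5 * (H + H.T))
            if np.all(eigval < 1e-8):
                warnings.warn("observed information has no positive curvature; covariance omitted")
                covariance = None
            else:
                warnings.warn(
                    "singular or indefinite observed information; variance inflated "
                    "along non-identified parameter directions"
                )
                floored = np.maximum(eigval, 1e-10)
                covariance = eigvec @ np.diag(1.0 / floored) @ eigvec.T
                covariance = 0.5 * (covariance + covariance.T)

    return FittedModel(
        spec=spec,
        params=np.asarray(res.x, dtype=float),
        covariance=covariance,
        log_likelihood=ll_hat,
        converged=converged,
        n_iter=int(res.nit),
        gradient_norm=grad_norm,
        message=str(res.message),
        n_subjects=ds.n_subjects,
        n_pairs=n_pairs,
    )


# ---------------------------------------------------------------------------
# hazard ratios


def hazard_ratios(fitted: FittedModel, alpha: float = 0.05) -> pd.DataFrame:
    """Hazard-ratio table: ``exp(beta)`` with Wald CIs per (covariate, transition).

    The interval is ``exp(beta +/- z_{alpha/2} * SE)`` on the log scale; the
    ``significant`` flag marks intervals excluding 1 (two-sided p < alpha).
    """
    from scipy.stats import norm

    if fitted.covariance is None:
        raise ValueError(
            "fit has no covariance matrix (singular information); "
            "inspect the fit diagnostics before requesting hazard ratios"
        )
    if not fitted.spec.covariates:
        raise ValueError("model has no covariates; no hazard ratios to report")
    zcrit = float(norm.ppf(1 - alpha / 2))
    se = fitted.standard_errors()
    names = fitted.parameter_names
    rows = []
    for idx, name in enumerate(names):
        if not name.startswith("beta_"):
            continue
        _, cov_name, trans = name.rsplit("_", 2)
        beta = float(fitted.params[idx])
        s = float(se[idx])
        with np.errstate(over="ignore"):  # an infinite bound is the honest Wald limit
            lo, hi = np.exp(beta - zcrit * s), np.exp(beta + zcrit * s)
        rows.append(
            {
                "covariate": cov_name,
                "transition": f"{trans[0]}-{trans[1]}",
                "hr": float(np.exp(beta)),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "significant": bool(lo > 1.0 or hi < 1.0),
            }
        )
    return pd.DataFrame(rows)


def univariate_screen(
    ds: PanelDataset, covariates: Sequence[str], **fit_kwargs
) -> dict[str, pd.DataFrame]:
    """One single-covariate fit per covariate, each entering all transitions.

    A failed fit for one covariate is recorded as an empty table with the
    error message in ``attrs['error']``; the remaining covariates are still
    screened.
    """
    out: dict[str, pd.DataFrame] = {}
    for c in covariates:
        try:
            f = fit(ds, ModelSpec(covariates=(c,)), **fit_kwargs)
            out[c] = hazard_ratios(f)
        except Exception as exc:  # propagate per covariate, not globally
            tbl = pd.DataFrame(
                columns=["covariate", "transition", "hr", "ci_low", "ci_high", "significant"]
            )
            tbl.attrs["error"] = str(exc)
            out[c] = tbl
    return out
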