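"""Two-state Markov and Bernoulli mixed-effects models for daily adherence.

Model
-----
Daily dose-taking is a first-order two-state Markov chain with states
dose-missing (0) and dose-taking (1).  The transition probabilities are
parameterized on the logit scale,

    logit P01 = theta1 + x·beta01 + eta1_i        (re-initiation)
    logit P10 = theta2 + x·beta10 + eta2_i        (discontinuation)

with P00 = 1 - P01 and P11 = 1 - P10.  Covariate effects enter linearly in
the logit domain; ``eta`` are subject-level normal random effects with mean 0
and variance omega^2 (by default one independent effect per logit; a single
shared effect, or none, are options).  The Bernoulli comparator drops the
state dependence entirely: logit P1 = theta1 + eta_i, a "coin flip" each day.

Estimation maximizes the marginal likelihood, integrating the random effects
out by a Laplace approximation (default) or by adaptive / non-adaptive
Gauss-Hermite quadrature, which serve as accuracy oracles for the Laplace
path.  With independent effects per logit the likelihood factorizes over the
prev=0 and prev=1 records, so the Markov fit reduces to two independent
mixed-effects logistic problems; the fitter exploits this.

Wald standard errors come from a central finite-difference Hessian of the
objective at the optimum; odds ratios are exp(beta) with exp(beta ± 1.96 SE)
confidence limits.  Per-subject posterior modes of the random effects
(empirical Bayes estimates) are retained for individual transition matrices
and predictive simulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logit as _logit, logsumexp
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, DataError, FitError
from .transitions import TransitionDataset

_WALD_Z = 1.96          # fixed multiplier for 95% intervals
_PCLIP = 1e-12          # probability clip applied inside logs only
_OMEGA_ZERO = 1e-10     # below this, omega^2 is treated as exactly zero


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class BernoulliParams:
    """Logit-scale intercept for the daily dose-taking probability P1."""

    theta1: float
    omega_sq: float = 0.0

    def __post_init__(self):
        if self.omega_sq < 0:
            raise ConfigurationError("omega_sq must be >= 0")

    @property
    def p1(self) -> float:
        return float(expit(self.theta1))


@dataclass
class MarkovParams:
    """Fixed effects and random-effect variances of the two-state model.

    ``omega_sq`` is a pair (variance on the P01 logit, variance on the P10
    logit); with ``random_effects="shared"`` both entries hold the single
    shared variance.
    """

    theta1: float
    theta2: float
    beta01: dict[str, float] = field(default_factory=dict)
    beta10: dict[str, float] = field(default_factory=dict)
    omega_sq: tuple[float, float] = (0.0, 0.0)
    random_effects: str = "separate"

    def __post_init__(self):
        if self.random_effects not in ("separate", "shared", "none"):
            raise ConfigurationError(
                f"unknown random_effects structure {self.random_effects!r}")
        if any(w < 0 for w in self.omega_sq):
            raise ConfigurationError("random-effect variances must be >= 0")


@dataclass
class ModelSpec:
    """Which covariates act on which transition logit, and how to estimate."""

    p01_terms: tuple[str, ...] = ()
    p10_terms: tuple[str, ...] = ()
    random_effects: str = "separate"
    method: str = "laplace"
    nodes: int = 9

    def effects(self) -> list[tuple[str, str]]:
        return [("p01", t) for t in self.p01_terms] + \
               [("p10", t) for t in self.p10_terms]

    def drop(self, effects: Sequence[tuple[str, str]]) -> "ModelSpec":
        drop = set(effects)
        return ModelSpec(
            p01_terms=tuple(t for t in self.p01_terms if ("p01", t) not in drop),
            p10_terms=tuple(t for t in self.p10_terms if ("p10", t) not in drop),
            random_effects=self.random_effects,
            method=self.method,
            nodes=self.nodes,
        )


@dataclass
class EffectEstimate:
    """One covariate effect on one transition logit, on the odds-ratio scale."""

    name: str
    target: str                       # "p01" or "p10"
    beta: float
    se: float | None
    odds_ratio: float
    ci_low: float | None
    ci_high: float | None

    @property
    def significant(self) -> bool | None:
        """True when the 95% CI excludes an odds ratio of 1."""
        if self.ci_low is None or self.ci_high is None:
            return None
        return not (self.ci_low <= 1.0 <= self.ci_high)


@dataclass
class FitResult:
    """Maximum-likelihood fit: estimates, SEs, objective, diagnostics, EBEs."""

    params: MarkovParams | BernoulliParams
    se: dict[str, float]
    neg2ll: float
    converged: bool
    ebe: pd.DataFrame                 # indexed by subject_id
    spec: ModelSpec | None = None
    n_subjects: int = 0
    n_records: int = 0
    optimizer: dict = field(default_factory=dict)
    modal_covariates: pd.DataFrame | None = None
    dataset: TransitionDataset | None = field(default=None, repr=False)

    def to_json(self, path=None) -> str:
        payload = {
            "model": type(self.params).__name__,
            "params": _params_to_dict(self.params),
            "se": self.se,
            "neg2ll": self.neg2ll,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_records": self.n_records,
            "optimizer": {k: v for k, v in self.optimizer.items()
                          if isinstance(v, (int, float, str, bool))},
            "ebe": self.ebe.reset_index().to_dict(orient="list"),
        }
        if self.spec is not None:
            payload["spec"] = {
                "p01_terms": list(self.spec.p01_terms),
                "p10_terms": list(self.spec.p10_terms),
                "random_effects": self.spec.random_effects,
                "method": self.spec.method,
                "nodes": self.spec.nodes,
            }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _params_to_dict(params) -> dict:
    d = asdict(params)
    if isinstance(params, MarkovParams):
        d["omega_sq"] = list(params.omega_sq)
    return d


# ---------------------------------------------------------------------------
# Probabilities and conditional likelihood
# ---------------------------------------------------------------------------

def _linpred(theta: float, beta: Mapping[str, float],
             covariates: Mapping[str, float] | None) -> float:
    lp = theta
    for name, b in beta.items():
        if covariates is None or name not in covariates:
            raise ConfigurationError(
                f"covariate {name!r} required by the model but not supplied")
        lp += b * float(covariates[name])
    return lp


def transition_probabilities(
    params: MarkovParams,
    covariates: Mapping[str, float] | None = None,
    eta: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float, float, float]:
    """(P01, P10, P00, P11) at a covariate vector and random-effect value.

    Each logit is intercept + covariate·coefficients + eta; complements
    satisfy P00 = 1 - P01 and P11 = 1 - P10 exactly.
    """
    l1 = _linpred(params.theta1, params.beta01, covariates) + eta[0]
    l2 = _linpred(params.theta2, params.beta10, covariates) + eta[1]
    p01 = float(expit(l1))
    p10 = float(expit(l2))
    return p01, p10, 1.0 - p01, 1.0 - p10


def transition_matrix(
    params: MarkovParams,
    covariates: Mapping[str, float] | None = None,
    eta: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Row-stochastic 2x2 matrix; row = current state, column = next state."""
    p01, p10, p00, p11 = transition_probabilities(params, covariates, eta)
    return np.array([[p00, p01], [p10, p11]])


def conditional_nll(
    prev: np.ndarray,
    state: np.ndarray,
    params: MarkovParams,
    covariates: pd.DataFrame | None = None,
    eta: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Negative log likelihood of one subject's chain at fixed random effects.

    Equals minus the sum over days of the log transition probability matching
    (prev_state -> state) on that day; computed on the log scale with
    probabilities clipped to [1e-12, 1 - 1e-12] inside the logs.
    """
    prev = np.asarray(prev, dtype=np.int8)
    state = np.asarray(state, dtype=np.int8)
    if prev.shape != state.shape:
        raise DataError("prev and state must be aligned")
    n = len(prev)

    def col(name):
        if covariates is None or name not in covariates:
            raise ConfigurationError(f"covariate {name!r} not supplied")
        return np.asarray(covariates[name], dtype=float)

    l1 = np.full(n, params.theta1 + eta[0])
    for name, b in params.beta01.items():
        l1 += b * col(name)
    l2 = np.full(n, params.theta2 + eta[1])
    for name, b in params.beta10.items():
        l2 += b * col(name)
    p01 = np.clip(expit(l1), _PCLIP, 1 - _PCLIP)
    p10 = np.clip(expit(l2), _PCLIP, 1 - _PCLIP)
    # log P(state | prev): prev=0 -> Bernoulli(p01) on state;
    #                      prev=1 -> Bernoulli(p10) on (1 - state)
    ll = np.where(
        prev == 0,
        np.where(state == 1, np.log(p01), np.log1p(-p01)),
        np.where(state == 0, np.log(p10), np.log1p(-p10)),
    )
    return float(-ll.sum())


# ---------------------------------------------------------------------------
# Mixed-effects logistic block engine
# ---------------------------------------------------------------------------
# A "block" is a Bernoulli likelihood with record-level linear predictors plus
# one scalar random intercept per subject: exactly the shape of each factor of
# the Markov marginal likelihood (and of the Bernoulli comparator).

def _bernoulli_ll_terms(lo: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*lo - log(1 + e^lo), stable for large |lo|
    return y * lo - np.logaddexp(0.0, lo)


def _find_modes(offset, y, subj, n_groups, omega_sq, eta0=None,
                tol=1e-10, maxiter=200):
    """Posterior modes of the subject random effects by damped Newton.

    The per-subject objective eta -> loglik(eta) - eta^2/(2 omega^2) is
    strictly concave, so Newton with step clipping converges; steps are
    clipped to +/-4 on the logit scale to avoid overshoot from flat tails.
    """
    eta = np.zeros(n_groups) if eta0 is None else np.array(eta0, dtype=float)
    inv_w = 1.0 / omega_sq
    for _ in range(maxiter):
        p = expit(offset + eta[subj])
        score = np.bincount(subj, weights=y - p, minlength=n_groups) - eta * inv_w
        if np.max(np.abs(score)) < tol:
            break
        curv = np.bincount(subj, weights=p * (1.0 - p), minlength=n_groups) + inv_w
        step = score / curv
        np.clip(step, -4.0, 4.0, out=step)
        eta += step
    return eta


def _block_marginal(offset, y, subj, n_groups, omega_sq, *,
                    method="laplace", nodes=9, eta0=None):
    """-2 x marginal log-likelihood of one block plus posterior modes.

    Returns (neg2ll, eta_hat, curvature) where curvature is the negative
    second derivative of the joint log density at the mode (per subject).
    """
    offset = np.asarray(offset, dtype=float)
    y = np.asarray(y, dtype=float)
    if omega_sq <= _OMEGA_ZERO:
        ll = _bernoulli_ll_terms(offset, y).sum()
        return -2.0 * ll, np.zeros(n_groups), np.full(n_groups, np.inf)

    eta = _find_modes(offset, y, subj, n_groups, omega_sq, eta0=eta0)
    lo = offset + eta[subj]
    p = expit(lo)
    ll_g = np.bincount(subj, weights=_bernoulli_ll_terms(lo, y), minlength=n_groups)
    curv = np.bincount(subj, weights=p * (1.0 - p), minlength=n_groups) + 1.0 / omega_sq
    if not np.all(curv > 0):  # cannot occur for Bernoulli+normal, but be safe
        warnings.warn("non-positive curvature at mode; falling back to 21-node "
                      "adaptive quadrature", RuntimeWarning)
        method, nodes = "agq", max(nodes, 21)
        curv = np.maximum(curv, 1.0 / omega_sq)

    if method == "laplace":
        logmarg = ll_g - eta**2 / (2.0 * omega_sq) - 0.5 * np.log(omega_sq * curv)
    elif method == "agq":
        z, w = hermgauss(nodes)
        s = 1.0 / np.sqrt(curv)
        terms = np.empty((nodes, n_groups))
        for k in range(nodes):
            ek = eta + np.sqrt(2.0) * s * z[k]
            lk = offset + ek[subj]
            llk = np.bincount(subj, weights=_bernoulli_ll_terms(lk, y),
                              minlength=n_groups)
            terms[k] = np.log(w[k]) + z[k]**2 + llk - ek**2 / (2.0 * omega_sq)
        logmarg = (logsumexp(terms, axis=0) + np.log(np.sqrt(2.0) * s)
                   - 0.5 * np.log(2.0 * np.pi * omega_sq))
    elif method == "ghq":
        z, w = hermgauss(nodes)
        terms = np.empty((nodes, n_groups))
        sd = np.sqrt(omega_sq)
        for k in range(nodes):
            ek = np.sqrt(2.0) * sd * z[k]
            llk = np.bincount(subj, weights=_bernoulli_ll_terms(offset + ek, y),
                              minlength=n_groups)
            terms[k] = np.log(w[k]) + llk
        logmarg = logsumexp(terms, axis=0) - 0.5 * np.log(np.pi)
    else:
        raise ConfigurationError(f"unknown estimation method {method!r}")
    return -2.0 * float(logmarg.sum()), eta, curv


@dataclass
class _Block:
    """One mixed-logistic factor of the likelihood, ready for optimization."""

    names: list[str]          # parameter names for the columns of Xfull
    Xfull: np.ndarray         # (n_records, n_params) incl. intercept column(s)
    y: np.ndarray
    subj: np.ndarray
    n_groups: int
    has_re: bool

    def n_fixed(self) -> int:
        return self.Xfull.shape[1]


def _fit_block(block: _Block, *, method="laplace", nodes=9, omega_start=0.1,
               maxiter=200, fd_step=1e-4, start=None):
    """Maximize one block's marginal likelihood; return a raw result dict."""
    p = block.n_fixed()
    if start is None:
        ybar = float(np.clip(block.y.mean() if len(block.y) else 0.5, 0.01, 0.99))
        start_coefs = np.zeros(p)
        # intercept columns are the all-ones / indicator columns named theta*
        for j, name in enumerate(block.names):
            if name.endswith("intercept") or name.startswith("theta"):
                start_coefs[j] = _logit(ybar)
        x0 = start_coefs
    else:
        x0 = np.asarray(start, dtype=float)[:p]
    if block.has_re:
        x0 = np.append(x0, np.log(omega_start))

    eta_cache = {"eta": None}

    def objective(x):
        offset = block.Xfull @ x[:p]
        wsq = float(np.exp(x[p])) if block.has_re else 0.0
        val, eta, _ = _block_marginal(offset, block.y, block.subj,
                                      block.n_groups, wsq, method=method,
                                      nodes=nodes, eta0=eta_cache["eta"])
        eta_cache["eta"] = eta
        return val

    bounds = [(None, None)] * p + ([(-12.0, 6.0)] if block.has_re else [])
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "maxfun": 20 * maxiter},
                   jac=None)
    xopt = res.x
    coefs = xopt[:p]
    omega_sq = float(np.exp(xopt[p])) if block.has_re else 0.0

    # recompute at optimum for final EBEs and curvature
    offset = block.Xfull @ coefs
    neg2ll, eta, curv = _block_marginal(offset, block.y, block.subj,
                                        block.n_groups, omega_sq,
                                        method=method, nodes=nodes,
                                        eta0=eta_cache["eta"])

    # Wald covariance from a central finite-difference Hessian of the
    # -2 log-likelihood on the working scale (log omega^2)
    H = _fd_hessian(objective, xopt, step=fd_step)
    se = np.full(len(xopt), np.nan)
    cov = None
    try:
        cov = 2.0 * np.linalg.inv(H)   # Hess(-2ll) = 2 * observed information
        d = np.diag(cov)
        se = np.where(d > 0, np.sqrt(np.maximum(d, 0)), np.nan)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian at optimum; SEs unavailable", RuntimeWarning)

    return {
        "names": list(block.names),
        "coefs": coefs,
        "se": se[:p],
        "omega_sq": omega_sq,
        "se_log_omega_sq": float(se[p]) if block.has_re else None,
        "neg2ll": float(neg2ll),
        "eta": eta,
        "converged": bool(res.success and np.isfinite(neg2ll)),
        "message": str(res.message),
        "nit": int(res.nit),
        "nfev": int(res.nfev),
        "cov": cov,
    }


def _fd_hessian(f, x, step=1e-4):
    """Central finite-difference Hessian; step scaled by max(1, |x_i|)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i]**2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# Block construction from a TransitionDataset
# ---------------------------------------------------------------------------

def _design(dataset: TransitionDataset, rows: np.ndarray, terms, prefix: str):
    cols = [np.ones(int(rows.sum()))]
    names = [f"{prefix}:intercept"]
    for t in terms:
        cols.append(dataset.column(t)[rows])
        names.append(f"{prefix}:{t}")
    return np.column_stack(cols), names


def _markov_blocks(dataset: TransitionDataset, spec: ModelSpec) -> list[_Block]:
    prev0 = dataset.prev == 0
    prev1 = ~prev0
    has_re = spec.random_effects != "none"
    if spec.random_effects in ("separate", "none"):
        X0, n0 = _design(dataset, prev0, spec.p01_terms, "p01")
        X1, n1 = _design(dataset, prev1, spec.p10_terms, "p10")
        return [
            _Block(n0, X0, dataset.state[prev0].astype(float),
                   dataset.subj[prev0], dataset.n_subjects, has_re),
            _Block(n1, X1, (1 - dataset.state[prev1]).astype(float),
                   dataset.subj[prev1], dataset.n_subjects, has_re),
        ]
    # shared: one block over all records; the event modelled is "the theta
    # transition happens" (re-initiate after a miss, discontinue after a dose),
    # so the shared eta enters every record's logit with coefficient +1.
    X0, n0 = _design(dataset, prev0, spec.p01_terms, "p01")
    X1, n1 = _design(dataset, prev1, spec.p10_terms, "p10")
    n = dataset.n_records
    Xfull = np.zeros((n, X0.shape[1] + X1.shape[1]))
    Xfull[prev0, :X0.shape[1]] = X0
    Xfull[prev1, X0.shape[1]:] = X1
    y = np.where(prev0, dataset.state, 1 - dataset.state).astype(float)
    return [_Block(n0 + n1, Xfull, y, dataset.subj, dataset.n_subjects, True)]


def _modal_covariates(dataset: TransitionDataset) -> pd.DataFrame:
    """Per-subject modal covariate vector (most frequent observed row)."""
    if not dataset.covariate_names:
        return pd.DataFrame(index=pd.Index(dataset.subject_ids, name="subject_id"))
    df = pd.DataFrame(dataset.X, columns=dataset.covariate_names)
    df["__subj"] = dataset.subj
    modal = (df.groupby("__subj")
               .agg(lambda s: s.mode().iloc[0]))
    modal.index = pd.Index(dataset.subject_ids[modal.index], name="subject_id")
    return modal


# ---------------------------------------------------------------------------
# Public marginal likelihood at fixed parameters
# ---------------------------------------------------------------------------

def marginal_nll(
    dataset: TransitionDataset,
    params: MarkovParams,
    *,
    method: str = "laplace",
    nodes: int = 9,
) -> float:
    """-2 x marginal log-likelihood of the Markov model at fixed parameters.

    Each subject's conditional chain likelihood is integrated over the
    random-effect distribution; per-subject contributions are summed, so the
    value is invariant to subject ordering.
    """
    spec = ModelSpec(tuple(params.beta01), tuple(params.beta10),
                     random_effects=params.random_effects)
    blocks = _markov_blocks(dataset, spec)
    total = 0.0
    if params.random_effects == "shared":
        coefs = np.concatenate([[params.theta1],
                                [params.beta01[t] for t in spec.p01_terms],
                                [params.theta2],
                                [params.beta10[t] for t in spec.p10_terms]])
        val, _, _ = _block_marginal(blocks[0].Xfull @ coefs, blocks[0].y,
                                    blocks[0].subj, blocks[0].n_groups,
                                    params.omega_sq[0], method=method, nodes=nodes)
        return val
    for block, theta, beta, terms, wsq in (
        (blocks[0], params.theta1, params.beta01, spec.p01_terms, params.omega_sq[0]),
        (blocks[1], params.theta2, params.beta10, spec.p10_terms, params.omega_sq[1]),
    ):
        coefs = np.concatenate([[theta], [beta[t] for t in terms]])
        wsq_eff = 0.0 if params.random_effects == "none" else wsq
        val, _, _ = _block_marginal(block.Xfull @ coefs, block.y, block.subj,
                                    block.n_groups, wsq_eff,
                                    method=method, nodes=nodes)
        total += val
    return total


# ---------------------------------------------------------------------------
# Estimators (scikit-learn style)
# ---------------------------------------------------------------------------

class MarkovTransitionModel(BaseEstimator):
    """Mixed-effects two-state Markov model of daily adherence.

    Parameters
    ----------
    p01_terms, p10_terms : sequence of str or "all"
        Covariate names acting on the re-initiation (P01) and discontinuation
        (P10) logits.  ``"all"`` uses every covariate in the fitted dataset.
    random_effects : {"separate", "shared", "none"}
        One independent normal random intercept per logit (default), a single
        intercept added to both logits, or no between-subject variability.
    method : {"laplace", "agq", "ghq"}
        Marginal-likelihood approximation; ``nodes`` sets the quadrature order.
    omega_start : float
        Starting value for each random-effect variance.
    maxiter, fd_step : optimizer iteration cap and finite-difference Hessian
        step (relative, on the working scale).

    Attributes (after ``fit``)
    --------------------------
    params_ : MarkovParams
    se_ : dict mapping "p01:<name>" / "p10:<name>" to Wald standard errors
    neg2ll_ : float, -2 x marginal log-likelihood at the optimum
    converged_ : bool
    ebe_ : DataFrame of per-subject posterior-mode random effects
    result_ : FitResult with everything above plus optimizer diagnostics
    """

    def __init__(self, p01_terms="all", p10_terms="all",
                 random_effects="separate", method="laplace", nodes=9,
                 omega_start=0.1, maxiter=200, fd_step=1e-4):
        self.p01_terms = p01_terms
        self.p10_terms = p10_terms
        self.random_effects = random_effects
        self.method = method
        self.nodes = nodes
        self.omega_start = omega_start
        self.maxiter = maxiter
        self.fd_step = fd_step

    # -- data plumbing ------------------------------------------------------
    @staticmethod
    def _as_dataset(X, y=None, groups=None, prev_state=None) -> TransitionDataset:
        if isinstance(X, TransitionDataset):
            return X
        if y is None or groups is None or prev_state is None:
            raise DataError(
                "fit needs either a TransitionDataset or (X, y, groups, prev_state)")
        X = pd.DataFrame(X)
        rec = pd.DataFrame({
            "subject_id": np.asarray(groups).astype(str),
            "day_index": 0,
            "prev_state": np.asarray(prev_state, dtype=np.int8),
            "state": np.asarray(y, dtype=np.int8),
        })
        for c in X.columns:
            rec[str(c)] = np.asarray(X[c], dtype=float)
        return TransitionDataset.from_records(rec, [str(c) for c in X.columns])

    def _spec_for(self, dataset: TransitionDataset) -> ModelSpec:
        p01 = tuple(dataset.covariate_names) if self.p01_terms == "all" \
            else tuple(self.p01_terms)
        p10 = tuple(dataset.covariate_names) if self.p10_terms == "all" \
            else tuple(self.p10_terms)
        for t in (*p01, *p10):
            if t not in dataset.covariate_names:
                raise ConfigurationError(
                    f"model term {t!r} absent from dataset covariates "
                    f"{dataset.covariate_names}")
        return ModelSpec(p01, p10, self.random_effects, self.method, self.nodes)

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y=None, *, groups=None, prev_state=None, start=None):
        dataset = self._as_dataset(X, y, groups, prev_state)
        spec = self._spec_for(dataset)
        blocks = _markov_blocks(dataset, spec)
        kw = dict(method=self.method, nodes=self.nodes,
                  omega_start=self.omega_start, maxiter=self.maxiter,
                  fd_step=self.fd_step)

        if spec.random_effects == "shared":
            raw = _fit_block(blocks[0], start=start, **kw)
            n0 = 1 + len(spec.p01_terms)
            theta1 = raw["coefs"][0]
            beta01 = dict(zip(spec.p01_terms, raw["coefs"][1:n0]))
            theta2 = raw["coefs"][n0]
            beta10 = dict(zip(spec.p10_terms, raw["coefs"][n0 + 1:]))
            omega = (raw["omega_sq"], raw["omega_sq"])
            se = dict(zip(raw["names"], raw["se"]))
            neg2ll = raw["neg2ll"]
            converged = raw["converged"]
            eta01 = eta10 = raw["eta"]
            optinfo = {"message": raw["message"], "nit": raw["nit"],
                       "nfev": raw["nfev"]}
        else:
            raws = [_fit_block(b, start=None, **kw) for b in blocks]
            r0, r1 = raws
            theta1 = r0["coefs"][0]
            beta01 = dict(zip(spec.p01_terms, r0["coefs"][1:]))
            theta2 = r1["coefs"][0]
            beta10 = dict(zip(spec.p10_terms, r1["coefs"][1:]))
            omega = (r0["omega_sq"], r1["omega_sq"])
            se = {**dict(zip(r0["names"], r0["se"])),
                  **dict(zip(r1["names"], r1["se"]))}
            neg2ll = r0["neg2ll"] + r1["neg2ll"]
            converged = r0["converged"] and r1["converged"]
            eta01, eta10 = r0["eta"], r1["eta"]
            optinfo = {"message": f"p01: {r0['message']} | p10: {r1['message']}",
                       "nit": r0["nit"] + r1["nit"],
                       "nfev": r0["nfev"] + r1["nfev"]}

        params = MarkovParams(float(theta1), float(theta2),
                              {k: float(v) for k, v in beta01.items()},
                              {k: float(v) for k, v in beta10.items()},
                              (float(omega[0]), float(omega[1])),
                              spec.random_effects)
        ebe = pd.DataFrame(
            {"eta_p01": eta01, "eta_p10": eta10},
            index=pd.Index(dataset.subject_ids, name="subject_id"))
        self.result_ = FitResult(
            params=params,
            se={k: float(v) for k, v in se.items()},
            neg2ll=float(neg2ll),
            converged=converged,
            ebe=ebe,
            spec=spec,
            n_subjects=dataset.n_subjects,
            n_records=dataset.n_records,
            optimizer=optinfo,
            modal_covariates=_modal_covariates(dataset),
            dataset=dataset,
        )
        self.params_ = params
        self.se_ = self.result_.se
        self.neg2ll_ = self.result_.neg2ll
        self.converged_ = converged
        self.ebe_ = ebe
        return self

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, X, prev_state, eta=(0.0, 0.0)) -> np.ndarray:
        """P(state = 1 | prev_state, covariates) per row, at fixed eta."""
        p = self.params_
        X = pd.DataFrame(X)
        n = len(X)
        l1 = np.full(n, p.theta1 + eta[0])
        for name, b in p.beta01.items():
            l1 += b * np.asarray(X[name], dtype=float)
        l2 = np.full(n, p.theta2 + eta[1])
        for name, b in p.beta10.items():
            l2 += b * np.asarray(X[name], dtype=float)
        prev = np.asarray(prev_state, dtype=np.int8)
        return np.where(prev == 0, expit(l1), 1.0 - expit(l2))

    def predict(self, X, prev_state, eta=(0.0, 0.0)) -> np.ndarray:
        return (self.predict_proba(X, prev_state, eta) >= 0.5).astype(np.int8)


class BernoulliAdherenceModel(BaseEstimator):
    """Mixed-effects daily "coin flip" comparator: logit P1 = theta1 + eta_i.

    Ignores state history entirely; used as the baseline against which the
    Markov model's fit improvement and predictive behaviour are judged.
    """

    def __init__(self, random_effects="single", method="laplace", nodes=9,
                 omega_start=0.1, maxiter=200, fd_step=1e-4):
        self.random_effects = random_effects    # "single" or "none"
        self.method = method
        self.nodes = nodes
        self.omega_start = omega_start
        self.maxiter = maxiter
        self.fd_step = fd_step

    def fit(self, X, y=None, *, groups=None):
        if isinstance(X, TransitionDataset):
            dataset = X
            yv = dataset.state.astype(float)
            subj, n_groups = dataset.subj, dataset.n_subjects
            ids = dataset.subject_ids
        else:
            if y is None or groups is None:
                raise DataError("fit needs a TransitionDataset or (y, groups)")
            yv = np.asarray(y, dtype=float)
            ids, subj = np.unique(np.asarray(groups).astype(str),
                                  return_inverse=True)
            n_groups = len(ids)
            dataset = None
        has_re = self.random_effects != "none"
        block = _Block(["p1:intercept"], np.ones((len(yv), 1)), yv, subj,
                       n_groups, has_re)
        raw = _fit_block(block, method=self.method, nodes=self.nodes,
                         omega_start=self.omega_start, maxiter=self.maxiter,
                         fd_step=self.fd_step)
        params = BernoulliParams(float(raw["coefs"][0]), float(raw["omega_sq"]))
        ebe = pd.DataFrame({"eta": raw["eta"]},
                           index=pd.Index(ids, name="subject_id"))
        self.result_ = FitResult(
            params=params,
            se={"p1:intercept": float(raw["se"][0])},
            neg2ll=float(raw["neg2ll"]),
            converged=raw["converged"],
            ebe=ebe,
            spec=None,
            n_subjects=n_groups,
            n_records=len(yv),
            optimizer={"message": raw["message"], "nit": raw["nit"],
                       "nfev": raw["nfev"]},
            modal_covariates=None,
            dataset=dataset,
        )
        self.params_ = params
        self.se_ = self.result_.se
        self.neg2ll_ = self.result_.neg2ll
        self.converged_ = raw["converged"]
        self.ebe_ = ebe
        return self

    def predict_proba(self, n: int = 1, eta: float = 0.0) -> np.ndarray:
        return np.full(n, expit(self.params_.theta1 + eta))


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit(dataset: TransitionDataset, spec: ModelSpec | None = None, *,
        start=None, **kwargs) -> FitResult:
    """Maximum-likelihood fit of the Markov model (thin estimator wrapper)."""
    if spec is None:
        spec = ModelSpec(tuple(dataset.covariate_names),
                         tuple(dataset.covariate_names))
    est = MarkovTransitionModel(
        p01_terms=tuple(spec.p01_terms), p10_terms=tuple(spec.p10_terms),
        random_effects=spec.random_effects, method=spec.method,
        nodes=spec.nodes, **kwargs)
    return est.fit(dataset, start=start).result_


def fit_bernoulli(dataset: TransitionDataset, *, random_effects="single",
                  **kwargs) -> FitResult:
    """Maximum-likelihood fit of the Bernoulli comparator."""
    est = BernoulliAdherenceModel(random_effects=random_effects, **kwargs)
    return est.fit(dataset).result_


def odds_ratios(result: FitResult) -> list[EffectEstimate]:
    """Wald odds ratios exp(beta) with exp(beta +/- 1.96 SE) 95% limits.

    Effects whose SE is unavailable are emitted without confidence limits.
    """
    if not isinstance(result.params, MarkovParams):
        raise FitError("odds_ratios requires a Markov model fit")
    out = []
    for target, betas in (("p01", result.params.beta01),
                          ("p10", result.params.beta10)):
        for name, b in betas.items():
            se = result.se.get(f"{target}:{name}")
            if se is None or not np.isfinite(se):
                out.append(EffectEstimate(name, target, b, None,
                                          float(np.exp(b)), None, None))
                continue
            out.append(EffectEstimate(
                name, target, float(b), float(se), float(np.exp(b)),
                float(np.exp(b - _WALD_Z * se)), float(np.exp(b + _WALD_Z * se))))
    return out


def effects_frame(effects: list[EffectEstimate]) -> pd.DataFrame:
    """Odds-ratio table with effect, OR, 95% CI and interpretation columns."""
    rows = []
    for e in effects:
        if e.target == "p01":
            interp = ("Increased P01 leading to increased adherence"
                      if e.odds_ratio > 1
                      else "Reduced P01 leading to reduced adherence")
        else:
            interp = ("Increased P10 leading to reduced adherence"
                      if e.odds_ratio > 1
                      else "Reduced P10 leading to increased adherence")
        rows.append({
            "effect": e.name, "parameter": e.target.upper(),
            "beta": e.beta, "se": e.se, "OR": e.odds_ratio,
            "ci_low": e.ci_low, "ci_high": e.ci_high,
            "interpretation": interp,
        })
    return pd.DataFrame(rows)


def empirical_bayes_matrix(
    result: FitResult,
    subject_id,
    covariates: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Subject-specific 2x2 transition matrix at the posterior-mode etas.

    Evaluated at the subject's modal covariate vector unless an explicit
    covariate mapping is supplied; rows sum to 1.
    """
    if not isinstance(result.params, MarkovParams):
        raise FitError("empirical_bayes_matrix requires a Markov model fit")
    sid = str(subject_id)
    if sid not in result.ebe.index:
        raise DataError(f"subject {sid!r} absent from fit")
    eta = (float(result.ebe.loc[sid, "eta_p01"]),
           float(result.ebe.loc[sid, "eta_p10"]))
    if covariates is None:
        covariates = {}
        if result.modal_covariates is not None and sid in result.modal_covariates.index:
            covariates = result.modal_covariates.loc[sid].to_dict()
    return transition_matrix(result.params, covariates, eta)
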