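"""Mixture-distribution Rasch estimation by marginal-maximum-likelihood EM.

The response model for patient p in latent class c with medical complexity
theta is

    P(x_i = 1 | theta, c) = logistic(a * (theta - beta_ic)),

a product-Bernoulli over conditions given (theta, c).  The latent trait is
normal within class, theta | c ~ N(mu_c, sigma_c), and class membership is
categorical with mixing proportions pi_c.  The marginal likelihood
integrates theta by Gauss-Hermite quadrature on standardized nodes z_q, so
theta_qc = mu_c + sigma_c * z_q.

Estimation is EM.  The E-step computes exact posteriors over (class, node).
The M-step is exact too: within a class the linear predictor
a*(mu_c + sigma_c*z_q - beta_ic) is *linear* in (mu_c, sigma_c, beta_ic),
so maximizing the expected complete-data log-likelihood is a weighted
logistic regression, solved by Newton iterations with step halving.  With
both steps exact, the marginal log-likelihood is non-decreasing across EM
iterations — a property the test-suite asserts on every fit.

Identifiability: difficulties are sum-zero within each class (the class
location lives in mu_c), classes are sorted by descending mixing
proportion, and the discrimination a is a fixed constant (1.7, the Rasch
convention that makes the logistic curve approximate a normal ogive).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import log_expit, expit, logsumexp
from scipy.special import roots_hermitenorm

from .cohort_io import DiagnosisMatrix

logger = logging.getLogger("mdirt")

__all__ = [
    "MixtureRaschModel",
    "PersonEstimate",
    "ModelFit",
    "ClassSelection",
    "response_probability",
    "pattern_probability",
    "marginal_loglik",
    "fit_mixture",
    "compute_fit",
    "select_classes",
    "assign_classes",
]

DEFAULT_DISCRIMINATION = 1.7
SIGMA_FLOOR = 0.05


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class MixtureRaschModel:
    """Fitted mixture Rasch model.

    ``difficulties`` is a (C, I) array on the logit scale, sum-zero within
    each class; classes are ordered by descending mixing proportion.
    """

    n_classes: int
    mixing: np.ndarray
    difficulties: np.ndarray
    trait_means: np.ndarray
    trait_sds: np.ndarray
    discrimination: float
    item_names: list[str]
    n_quadrature: int = 21
    n_iter: int = 0
    converged: bool = True
    loglik: float = np.nan
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.difficulties = np.atleast_2d(np.asarray(self.difficulties, dtype=float))
        self.trait_means = np.asarray(self.trait_means, dtype=float)
        self.trait_sds = np.asarray(self.trait_sds, dtype=float)
        C, I = self.difficulties.shape
        if C != self.n_classes or len(self.item_names) != I:
            raise ValueError("inconsistent model dimensions")
        if not np.isclose(self.mixing.sum(), 1.0):
            raise ValueError("mixing proportions must sum to 1")
        if (self.trait_sds <= 0).any():
            raise ValueError("trait standard deviations must be positive")
        if self.discrimination <= 0:
            raise ValueError("discrimination must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_classes": self.n_classes,
            "mixing": self.mixing.tolist(),
            "difficulties": self.difficulties.tolist(),
            "trait_means": self.trait_means.tolist(),
            "trait_sds": self.trait_sds.tolist(),
            "discrimination": self.discrimination,
            "item_names": self.item_names,
            "n_quadrature": self.n_quadrature,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "loglik": self.loglik,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MixtureRaschModel":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


@dataclass
class PersonEstimate:
    """Posterior class membership and complexity estimate for one patient."""

    patient_id: str
    posterior: np.ndarray
    modal_class: int  # 1-based
    theta: float


@dataclass
class ModelFit:
    """Deviance-based fit summary: BIC = -2LL + k * ln(n)."""

    minus2LL: float
    k: int
    n: int

    @property
    def bic(self) -> float:
        return self.minus2LL + self.k * np.log(self.n) if self.k else self.minus2LL


# ---------------------------------------------------------------------------
# Response model primitives
# ---------------------------------------------------------------------------


def response_probability(theta, beta, a: float = DEFAULT_DISCRIMINATION):
    """Item characteristic curve: P(x=1 | theta) = logistic(a*(theta - beta)).

    At theta == beta the probability is exactly 0.5 for any discrimination.
    Stable for |a*(theta-beta)| up to ~700.
    """
    if a <= 0:
        raise ValueError("discrimination a must be positive")
    return expit(a * (np.asarray(theta, dtype=float) - np.asarray(beta, dtype=float)))


def pattern_probability(
    x: Sequence[float], theta: float, beta: Sequence[float], a: float = DEFAULT_DISCRIMINATION
) -> float:
    """Probability of a binary condition vector given (theta, class difficulties).

    Missing entries (NaN) are skipped; an all-missing vector has probability 1
    (empty product).
    """
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape != beta.shape:
        raise ValueError("x and beta must have the same length")
    obs = ~np.isnan(x)
    eta = a * (theta - beta[obs])
    logp = np.where(x[obs] == 1, log_expit(eta), log_expit(-eta))
    return float(np.exp(logp.sum()))


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal Gauss-Hermite nodes and probability weights."""
    z, w = roots_hermitenorm(n)
    return z, w / w.sum()


def _log_item_probs(eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return log_expit(eta), log_expit(-eta)


def _pattern_loglik_nodes(
    X0: np.ndarray, M: np.ndarray, theta_nodes: np.ndarray, beta: np.ndarray, a
) -> np.ndarray:
    """(n_patients, Q) log-likelihood of each pattern at each node.

    ``X0`` is the response matrix with missing set to 0; ``M`` the observed
    mask; ``a`` a scalar or per-item array of slopes.
    """
    eta = np.asarray(a) * (theta_nodes[:, None] - beta[None, :])  # Q x I
    lp, lq = _log_item_probs(eta)
    return X0 @ lp.T + (M - X0) @ lq.T


def marginal_loglik(
    matrix: DiagnosisMatrix, model: MixtureRaschModel, quadrature: int | None = None
) -> float:
    """Quadrature-approximated marginal log-likelihood of the matrix."""
    if matrix.n_patients == 0:
        raise ValueError("empty matrix")
    if matrix.condition_names != model.item_names:
        raise ValueError("matrix conditions do not align with model items")
    Q = quadrature or model.n_quadrature
    if Q < 5:
        raise ValueError("quadrature must use at least 5 nodes")
    z, w = _gh_nodes(Q)
    V = matrix.values
    M = matrix.observed_mask.astype(float)
    X0 = np.where(M > 0, np.nan_to_num(V), 0.0)
    per_class = np.empty((matrix.n_patients, model.n_classes))
    for c in range(model.n_classes):
        nodes = model.trait_means[c] + model.trait_sds[c] * z
        ll = _pattern_loglik_nodes(X0, M, nodes, model.difficulties[c], model.discrimination)
        per_class[:, c] = logsumexp(ll + np.log(w)[None, :], axis=1)
    return float(logsumexp(per_class + np.log(model.mixing)[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# EM machinery
# ---------------------------------------------------------------------------


def _build_design(z: np.ndarray, I: int, a: float) -> np.ndarray:
    """Design matrix for the per-class M-step logistic regression.

    Rows are (node q, item i) pairs; columns are (mu, sigma, beta_1..beta_{I-1})
    with beta_I = -sum(beta_j) enforcing the sum-zero constraint.
    """
    Q = len(z)
    D = np.zeros((Q * I, I + 1))
    D[:, 0] = a
    D[:, 1] = a * np.repeat(z, I)
    items = np.tile(np.arange(I), Q)
    for j in range(I - 1):
        D[items == j, 2 + j] = -a
        D[items == I - 1, 2 + j] = a
    return D


def _mstep_class(
    D: np.ndarray,
    t0: np.ndarray,
    n_w: np.ndarray,
    s_w: np.ndarray,
    max_newton: int = 50,
    gtol: float = 1e-9,
) -> np.ndarray:
    """Maximize the weighted Bernoulli log-likelihood sum(s*log p + (n-s)*log(1-p))
    over the linear coefficients, by damped Newton from warm start ``t0``."""

    def qfun(t):
        eta = D @ t
        lp, lq = _log_item_probs(eta)
        return float(s_w @ lp + (n_w - s_w) @ lq)

    t = t0.copy()
    q_old = qfun(t)
    for _ in range(max_newton):
        p = expit(D @ t)
        g = D.T @ (s_w - n_w * p)
        if np.max(np.abs(g)) < gtol:
            break
        W = n_w * p * (1 - p)
        H = D.T @ (D * W[:, None])
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(t)), g)
        except np.linalg.LinAlgError:
            break
        # step halving preserves the GEM ascent property
        for _ in range(30):
            t_new = t + step
            q_new = qfun(t_new)
            if q_new >= q_old - 1e-12:
                break
            step = step / 2
        else:
            break
        if q_new < q_old:
            break
        t, q_old = t_new, q_new
    return t


def _unpack_class_params(t: np.ndarray) -> tuple[float, float, np.ndarray]:
    # coefficients t[2:] are beta_1..beta_{I-1}; the last item closes the sum to 0
    mu, sigma = float(t[0]), float(t[1])
    beta_free = t[2:]
    beta = np.concatenate([beta_free, [-beta_free.sum()]])
    return mu, sigma, beta


def _em(
    X0: np.ndarray,
    M: np.ndarray,
    C: int,
    a: float,
    z: np.ndarray,
    w: np.ndarray,
    init: dict,
    max_iter: int,
    tol: float,
) -> dict:
    """Run EM from one initialization; returns parameters and loglik trace."""
    n, I = X0.shape
    Q = len(z)
    pi = init["pi"].copy()
    beta = init["beta"].copy()
    mu = init["mu"].copy()
    sigma = init["sigma"].copy()
    D = _build_design(z, I, a)
    logw = np.log(w)
    trace: list[float] = []
    converged = False
    it = 0
    # warm-start coefficient vectors per class
    tvecs = [None] * C
    for it in range(1, max_iter + 1):
        # ---- E-step: log joint over (class, node) per patient
        log_jc = np.empty((n, C, Q))
        for c in range(C):
            nodes = mu[c] + sigma[c] * z
            ll = _pattern_loglik_nodes(X0, M, nodes, beta[c], a)
            log_jc[:, c, :] = ll + logw[None, :] + np.log(pi[c])
        ll_p = logsumexp(log_jc.reshape(n, -1), axis=1)
        loglik = float(ll_p.sum())
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        r = np.exp(log_jc - ll_p[:, None, None])  # n x C x Q posteriors

        # ---- M-step
        pi = r.sum(axis=(0, 2)) / n
        pi = np.clip(pi, 1e-12, None)
        pi = pi / pi.sum()
        for c in range(C):
            rc = r[:, c, :]  # n x Q
            n_w = (rc.T @ M).reshape(-1)  # Q*I weights
            s_w = (rc.T @ X0).reshape(-1)
            if tvecs[c] is None:
                t0 = np.concatenate([[mu[c], sigma[c]], beta[c][:-1]])
            else:
                t0 = tvecs[c]
            t = _mstep_class(D, t0, n_w, s_w)
            m_c, s_c, b_c = _unpack_class_params(t)
            if s_c < 0:  # node set is symmetric: sign of sigma is unidentified
                s_c = -s_c
                t = t.copy()
                t[1] = s_c
            s_c = max(s_c, SIGMA_FLOOR)
            t[1] = s_c
            tvecs[c] = t
            mu[c], sigma[c], beta[c] = m_c, s_c, b_c
    return {
        "pi": pi,
        "beta": beta,
        "mu": mu,
        "sigma": sigma,
        "loglik": trace[-1],
        "trace": trace,
        "n_iter": it,
        "converged": converged,
    }


def _initialize(rng: np.random.Generator, prev: np.ndarray, C: int, a: float, spread: float) -> dict:
    logit_prev = np.log(prev) - np.log1p(-prev)
    base = -logit_prev / a
    beta = np.empty((C, len(prev)))
    for c in range(C):
        noise = rng.normal(0.0, spread, size=len(prev)) if C > 1 else 0.0
        b = base + noise
        beta[c] = b - b.mean()
    return {
        "pi": np.full(C, 1.0 / C),
        "beta": beta,
        "mu": np.zeros(C),
        "sigma": np.ones(C),
    }


def _canonicalize(res: dict) -> dict:
    order = np.lexsort((res["mu"], -res["pi"]))
    for key in ("pi", "beta", "mu", "sigma"):
        res[key] = res[key][order]
    return res


def fit_mixture(
    matrix: DiagnosisMatrix,
    n_classes: int,
    *,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    quadrature: int = 21,
    seed: int = 0,
    discrimination: float = DEFAULT_DISCRIMINATION,
    short_iter: int = 50,
) -> tuple[MixtureRaschModel, ModelFit, list[PersonEstimate]]:
    """Fit a C-class mixture Rasch model by multistart EM.

    Each random start runs ``short_iter`` EM iterations; the best is then
    run to convergence (absolute log-likelihood change < ``tol`` or
    ``max_iter`` iterations).  Non-convergence flags the returned model
    rather than raising.  Deterministic given (data, config, seed).
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    V = matrix.values
    M = matrix.observed_mask.astype(float)
    X0 = np.where(M > 0, np.nan_to_num(V), 0.0)
    patterns = {tuple(row) for row in np.where(M > 0, X0, -1.0).tolist()}
    if n_classes > len(patterns):
        raise ValueError(
            f"C={n_classes} exceeds the {len(patterns)} distinct observed patterns"
        )
    z, w = _gh_nodes(quadrature)
    n = matrix.n_patients
    prev = np.clip(np.nanmean(V, axis=0), 0.5 / n, 1 - 0.5 / n)
    rng = np.random.default_rng(seed)
    a = discrimination

    n_starts_eff = 1 if n_classes == 1 else max(1, n_starts)
    best = None
    if n_starts_eff == 1:
        init = _initialize(rng, prev, n_classes, a, spread=0.5)
        best = _em(X0, M, n_classes, a, z, w, init, max_iter, tol)
    else:
        shorts = []
        for _ in range(n_starts_eff):
            init = _initialize(rng, prev, n_classes, a, spread=0.75)
            shorts.append(_em(X0, M, n_classes, a, z, w, init, short_iter, tol))
        best_short = max(shorts, key=lambda r: r["loglik"])
        if best_short["converged"]:
            best = best_short
        else:
            warm = {k: best_short[k] for k in ("pi", "beta", "mu", "sigma")}
            best = _em(X0, M, n_classes, a, z, w, warm, max_iter, tol)
            best["trace"] = best_short["trace"][:-1] + best["trace"]
            best["n_iter"] += best_short["n_iter"]
    best = _canonicalize(best)

    model = MixtureRaschModel(
        n_classes=n_classes,
        mixing=best["pi"],
        difficulties=best["beta"],
        trait_means=best["mu"],
        trait_sds=best["sigma"],
        discrimination=a,
        item_names=matrix.condition_names,
        n_quadrature=quadrature,
        n_iter=best["n_iter"],
        converged=best["converged"],
        loglik=best["loglik"],
        loglik_trace=best["trace"],
    )
    if not model.converged:
        logger.warning("fit_mixture(C=%d) did not converge in %d iterations", n_classes, max_iter)
    fit = compute_fit(model, matrix, loglik=best["loglik"])
    estimates = assign_classes(model, matrix)
    return model, fit, estimates


def compute_fit(
    model: MixtureRaschModel,
    matrix: DiagnosisMatrix,
    *,
    loglik: float | None = None,
    k: int | None = None,
) -> ModelFit:
    """BIC-style fit summary.

    The default free-parameter count is ``k = C*(I-1) + (C-1) + 2*C`` —
    sum-zero difficulties, mixing proportions, and a per-class trait mean
    and sd.  An explicit ``k`` may be supplied to reproduce fit tables
    computed under a different parameter-counting convention.
    """
    if loglik is None:
        loglik = marginal_loglik(matrix, model)
    C, I = model.n_classes, len(model.item_names)
    if k is None:
        k = C * (I - 1) + (C - 1) + 2 * C
    return ModelFit(minus2LL=-2.0 * loglik, k=k, n=matrix.n_patients)


@dataclass
class ClassSelection:
    """Fit table over a range of class counts plus the selected C."""

    table: pd.DataFrame
    chosen: int
    models: dict[int, MixtureRaschModel]
    errors: dict[int, str]


def select_classes(
    matrix: DiagnosisMatrix,
    class_range: Sequence[int] = range(1, 8),
    *,
    override: int | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> ClassSelection:
    """Fit each candidate class count and select by minimum BIC.

    ``override`` lets the caller pick a different C (interpretability can
    trump the BIC minimum); the full fit table is reported either way.
    Individual fit failures are recorded and selection proceeds over the
    successes.
    """
    class_range = list(class_range)
    if not class_range:
        raise ValueError("class_range must be non-empty")
    rows = []
    models: dict[int, MixtureRaschModel] = {}
    errors: dict[int, str] = {}
    for C in class_range:
        try:
            model, fit, _ = fit_mixture(matrix, C, seed=seed + C, **fit_kwargs)
        except Exception as exc:  # recorded, selection continues
            errors[C] = str(exc)
            logger.warning("select_classes: C=%d failed: %s", C, exc)
            continue
        models[C] = model
        rows.append(
            {
                "n_classes": C,
                "minus2LL": fit.minus2LL,
                "k": fit.k,
                "BIC": fit.bic,
                "converged": model.converged,
            }
        )
    if not rows:
        raise RuntimeError("every candidate class count failed to fit")
    table = pd.DataFrame(rows).set_index("n_classes")
    chosen = int(table["BIC"].idxmin())
    if override is not None:
        if override not in models:
            raise ValueError(f"override C={override} was not successfully fitted")
        chosen = override
    return ClassSelection(table=table, chosen=chosen, models=models, errors=errors)


def assign_classes(
    model: MixtureRaschModel, matrix: DiagnosisMatrix
) -> list[PersonEstimate]:
    """Posterior class probabilities, modal class, and within-class EAP theta.

    Modal assignment breaks exact posterior ties toward the lowest class
    index (logged).  Classes are 1-based, mutually exclusive and exhaustive.
    """
    if matrix.condition_names != model.item_names:
        raise ValueError("matrix conditions do not align with model items")
    z, w = _gh_nodes(model.n_quadrature)
    V = matrix.values
    M = matrix.observed_mask.astype(float)
    X0 = np.where(M > 0, np.nan_to_num(V), 0.0)
    n, C = matrix.n_patients, model.n_classes
    log_marg = np.empty((n, C))
    node_ll = np.empty((n, C, len(z)))
    thetas_c = np.empty((C, len(z)))
    for c in range(C):
        thetas_c[c] = model.trait_means[c] + model.trait_sds[c] * z
        ll = _pattern_loglik_nodes(X0, M, thetas_c[c], model.difficulties[c], model.discrimination)
        node_ll[:, c, :] = ll
        log_marg[:, c] = logsumexp(ll + np.log(w)[None, :], axis=1)
    log_post = log_marg + np.log(model.mixing)[None, :]
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    estimates = []
    n_ties = 0
    for p, pid in enumerate(matrix.patient_ids):
        row = post[p]
        top = np.flatnonzero(np.isclose(row, row.max(), rtol=0, atol=0))
        if len(top) > 1:
            n_ties += 1
        modal = int(top[0])
        lw = node_ll[p, modal] + np.log(w)
        lw -= logsumexp(lw)
        theta = float(np.exp(lw) @ thetas_c[modal])
        estimates.append(
            PersonEstimate(
                patient_id=pid, posterior=row, modal_class=modal + 1, theta=theta
            )
        )
    if n_ties:
        logger.info("assign_classes: %d exact posterior ties broken to lowest index", n_ties)
    return estimates


def estimates_to_frame(estimates: list[PersonEstimate]) -> pd.DataFrame:
    """Tabulate person estimates (one posterior column per class)."""
    C = len(estimates[0].posterior)
    rows = {
        "patient_id": [e.patient_id for e in estimates],
        **{
            f"posterior_{c + 1}": [float(e.posterior[c]) for e in estimates]
            for c in range(C)
        },
        "modal_class": [e.modal_class for e in estimates],
        "theta": [e.theta for e in estimates],
    }
    return pd.DataFrame(rows)
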