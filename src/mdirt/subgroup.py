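"""Subgroup-specific 1PL/2PL calibration and item characteristic curves.

After a subgroup's items survive Mokken selection and its ill-fitting
patients are excluded, a unidimensional IRT model is calibrated on the
survivors.  The 1PL (Rasch) form fixes a common discrimination (1.7 by
convention, making the logistic curve track the normal ogive) and
estimates sum-zero difficulties plus the latent-trait mean and sd.  The
2PL form gives every condition its own slope; the latent sd is fixed to 1
to identify the slopes.  Both are fitted by MML-EM with Gauss-Hermite
quadrature, exactly as in the mixture stage but with a single class.

Model choice between them defaults to BIC; because "similar enough slopes"
is also a legitimate informal criterion, the comparison record carries the
fitted slope dispersion (max/min ratio) and a likelihood-ratio statistic so
callers can apply their own rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .cohort_io import DiagnosisMatrix
from .mixture import (
    DEFAULT_DISCRIMINATION,
    ModelFit,
    _em,
    _gh_nodes,
    _log_item_probs,
)

logger = logging.getLogger("mdirt")

__all__ = [
    "SubgroupIRTModel",
    "ICCProfile",
    "ModelComparison",
    "fit_1pl",
    "fit_2pl",
    "compare_1pl_2pl",
    "icc_profile",
]

SLOPE_BOUNDS = (0.2, 5.0)


@dataclass
class SubgroupIRTModel:
    """Calibrated subgroup model (1PL or 2PL)."""

    model_type: str  # "1PL" | "2PL"
    item_names: list[str]
    difficulties: np.ndarray
    discriminations: np.ndarray
    mu: float
    sigma: float
    fit: ModelFit
    converged: bool = True
    n_iter: int = 0
    notes: list[str] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.difficulties = np.asarray(self.difficulties, dtype=float)
        self.discriminations = np.asarray(self.discriminations, dtype=float)
        if self.model_type == "1PL" and len(set(np.round(self.discriminations, 12))) > 1:
            raise ValueError("1PL requires identical discriminations")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: one row per condition (difficulty, discrimination)."""
        return pd.DataFrame(
            {
                "item": self.item_names,
                "difficulty": self.difficulties,
                "discrimination": self.discriminations,
            }
        )


@dataclass
class ICCProfile:
    """Item characteristic curves evaluated on a theta grid."""

    theta_grid: np.ndarray
    curves: pd.DataFrame  # one column per item
    locations: pd.Series  # theta at probability 0.5, equals difficulty

    def to_frame(self) -> pd.DataFrame:
        out = self.curves.copy()
        out.insert(0, "theta", self.theta_grid)
        return out


@dataclass
class ModelComparison:
    chosen: str
    bic_1pl: float
    bic_2pl: float
    lr_stat: float
    lr_df: int
    slope_ratio: float
    rationale: str


def _prepare(matrix: DiagnosisMatrix, drop_constant: bool):
    if matrix.n_patients < 2:
        raise ValueError("insufficient data: need at least 2 patients")
    if matrix.n_conditions < 2:
        raise ValueError("need at least 2 items")
    notes = []
    if matrix.n_patients < 50:
        notes.append(f"only {matrix.n_patients} patients; estimates may be unstable")
        logger.warning("subgroup fit on only %d patients", matrix.n_patients)
    keep = list(matrix.condition_names)
    if drop_constant:
        prev = matrix.prevalence()
        constant = [c for c in keep if prev[c] in (0.0, 1.0) or np.isnan(prev[c])]
        if constant:
            notes.append(f"dropped constant items: {constant}")
            logger.warning("dropping all-identical response columns: %s", constant)
            keep = [c for c in keep if c not in set(constant)]
            if len(keep) < 2:
                raise ValueError("fewer than 2 non-constant items")
    sub = matrix.select_conditions(keep)
    V = sub.values
    M = sub.observed_mask.astype(float)
    X0 = np.where(M > 0, np.nan_to_num(V), 0.0)
    return sub, X0, M, notes


def fit_1pl(
    matrix: DiagnosisMatrix,
    a: float = DEFAULT_DISCRIMINATION,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    quadrature: int = 21,
) -> SubgroupIRTModel:
    """Rasch/1PL calibration: common fixed slope, sum-zero difficulties,
    latent N(mu, sigma) estimated.  k = (I-1) + 2."""
    if a <= 0:
        raise ValueError("discrimination must be positive")
    sub, X0, M, notes = _prepare(matrix, drop_constant=True)
    z, w = _gh_nodes(quadrature)
    n, I = X0.shape
    prev = np.clip(X0.sum(axis=0) / np.maximum(M.sum(axis=0), 1), 0.5 / n, 1 - 0.5 / n)
    logit_prev = np.log(prev) - np.log1p(-prev)
    b0 = -logit_prev / a
    init = {
        "pi": np.array([1.0]),
        "beta": (b0 - b0.mean())[None, :],
        "mu": np.zeros(1),
        "sigma": np.ones(1),
    }
    res = _em(X0, M, 1, a, z, w, init, max_iter, tol)
    fit = ModelFit(minus2LL=-2.0 * res["loglik"], k=(I - 1) + 2, n=n)
    if not res["converged"]:
        logger.warning("fit_1pl did not converge in %d iterations", max_iter)
    return SubgroupIRTModel(
        model_type="1PL",
        item_names=sub.condition_names,
        difficulties=res["beta"][0],
        discriminations=np.full(I, a),
        mu=float(res["mu"][0]),
        sigma=float(res["sigma"][0]),
        fit=fit,
        converged=res["converged"],
        n_iter=res["n_iter"],
        notes=notes,
        loglik_trace=res["trace"],
    )


def _mstep_item(z, n_w, s_w, c0, s0, max_newton=50, gtol=1e-9):
    """Per-item weighted logistic regression of x on z: eta = c + s*z."""

    def qfun(c, s):
        lp, lq = _log_item_probs(c + s * z)
        return float(s_w @ lp + (n_w - s_w) @ lq)

    c, s = c0, s0
    q_old = qfun(c, s)
    D = np.column_stack([np.ones_like(z), z])
    for _ in range(max_newton):
        p = expit(c + s * z)
        g = D.T @ (s_w - n_w * p)
        if np.max(np.abs(g)) < gtol:
            break
        W = n_w * p * (1 - p)
        H = D.T @ (D * W[:, None]) + 1e-10 * np.eye(2)
        step = np.linalg.solve(H, g)
        for _ in range(30):
            c_new, s_new = c + step[0], s + step[1]
            q_new = qfun(c_new, s_new)
            if q_new >= q_old - 1e-12:
                break
            step = step / 2
        else:
            break
        if q_new < q_old:
            break
        c, s, q_old = c_new, s_new, q_new
    return c, s


def fit_2pl(
    matrix: DiagnosisMatrix,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    quadrature: int = 21,
    slope_bounds: tuple[float, float] = SLOPE_BOUNDS,
    equal_slopes: bool = False,
) -> SubgroupIRTModel:
    """2PL calibration: per-item slopes and difficulties by MML-EM.

    The latent sd is fixed at 1 for slope identifiability; the latent mean
    is recovered from the sum-zero difficulty constraint.  Slopes are kept
    inside ``slope_bounds`` (boundary-pinned slopes are flagged).  With
    ``equal_slopes=True`` the common-slope constrained variant is fitted —
    a reparameterization of the 1PL family, useful as a cross-check.
    k = (I-1) + I + 2.
    """
    sub, X0, M, notes = _prepare(matrix, drop_constant=True)
    z, w = _gh_nodes(quadrature)
    logw = np.log(w)
    n, I = X0.shape
    prev = np.clip(X0.sum(axis=0) / np.maximum(M.sum(axis=0), 1), 0.5 / n, 1 - 0.5 / n)
    intercepts = np.log(prev) - np.log1p(-prev)
    slopes = np.ones(I)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = intercepts[None, :] + slopes[None, :] * z[:, None]  # Q x I
        lp, lq = _log_item_probs(eta)
        ll = X0 @ lp.T + (M - X0) @ lq.T  # n x Q
        ll_p = logsumexp(ll + logw[None, :], axis=1)
        loglik = float(ll_p.sum())
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        r = np.exp(ll + logw[None, :] - ll_p[:, None])  # n x Q
        n_w = r.T @ M  # Q x I
        s_w = r.T @ X0
        if equal_slopes:
            # joint Newton over (intercepts, common slope)
            D = np.zeros((len(z) * I, I + 1))
            items = np.tile(np.arange(I), len(z))
            for jcol in range(I):
                D[items == jcol, jcol] = 1.0
            D[:, I] = np.repeat(z, I)
            t = np.concatenate([intercepts, [slopes[0]]])
            nw, sw = n_w.reshape(-1), s_w.reshape(-1)
            for _ in range(50):
                p = expit(D @ t)
                g = D.T @ (sw - nw * p)
                if np.max(np.abs(g)) < 1e-9:
                    break
                W = nw * p * (1 - p)
                H = D.T @ (D * W[:, None]) + 1e-10 * np.eye(I + 1)
                t = t + np.linalg.solve(H, g)
            intercepts, slopes = t[:I], np.full(I, t[I])
        else:
            for i in range(I):
                c_i, s_i = _mstep_item(z, n_w[:, i], s_w[:, i], intercepts[i], slopes[i])
                intercepts[i], slopes[i] = c_i, s_i
        slopes = np.abs(slopes)  # node symmetry: slope sign unidentified
        clipped = (slopes < slope_bounds[0]) | (slopes > slope_bounds[1])
        slopes = np.clip(slopes, *slope_bounds)
        if clipped.any():
            pinned = [sub.condition_names[i] for i in np.flatnonzero(clipped)]
            note = f"slopes pinned at bounds: {pinned}"
            if note not in notes:
                notes.append(note)
    # theta = mu + z (sigma = 1): eta = a_i*(theta - b_i) = (a_i*mu - a_i*b_i) + a_i*z
    mu = float(np.mean(intercepts / slopes))
    beta = mu - intercepts / slopes
    fit = ModelFit(minus2LL=-2.0 * trace[-1], k=(I - 1) + I + 2, n=n)
    if not converged:
        logger.warning("fit_2pl did not converge in %d iterations", max_iter)
    return SubgroupIRTModel(
        model_type="2PL",
        item_names=sub.condition_names,
        difficulties=beta,
        discriminations=slopes,
        mu=mu,
        sigma=1.0,
        fit=fit,
        converged=converged,
        n_iter=it,
        notes=notes,
        loglik_trace=trace,
    )


def compare_1pl_2pl(m1: SubgroupIRTModel, m2: SubgroupIRTModel) -> ModelComparison:
    """Choose between a fitted 1PL and 2PL on the same items and patients.

    Default criterion is BIC (lower wins; ties favour the more parsimonious
    1PL).  The record also carries the 2PL slope max/min ratio and the
    likelihood-ratio statistic for users who prefer a similar-slopes rule.
    """
    if m1.item_names != m2.item_names:
        raise ValueError("models were fitted on different items")
    if m1.fit.n != m2.fit.n:
        raise ValueError("models were fitted on different patients")
    bic1, bic2 = m1.fit.bic, m2.fit.bic
    lr = m1.fit.minus2LL - m2.fit.minus2LL
    df = m2.fit.k - m1.fit.k
    slope_ratio = float(m2.discriminations.max() / m2.discriminations.min())
    chosen = "2PL" if bic2 < bic1 else "1PL"
    rationale = (
        f"BIC 1PL={bic1:.1f} vs 2PL={bic2:.1f}; LR={lr:.1f} on {df} df; "
        f"slope max/min ratio {slope_ratio:.2f}"
    )
    return ModelComparison(
        chosen=chosen,
        bic_1pl=bic1,
        bic_2pl=bic2,
        lr_stat=lr,
        lr_df=df,
        slope_ratio=slope_ratio,
        rationale=rationale,
    )


def icc_profile(
    model: SubgroupIRTModel,
    theta_range: tuple[float, float] = (-4.0, 4.0),
    n_points: int = 101,
) -> ICCProfile:
    """Evaluate every item characteristic curve on a theta grid.

    Each item's location — the trait value where the curve crosses 0.5 —
    equals its difficulty exactly, which is what makes cross-subgroup
    location comparisons meaningful.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(theta_range[0], theta_range[1], n_points)
    curves = pd.DataFrame(
        {
            item: expit(a_i * (grid - b_i))
            for item, a_i, b_i in zip(
                model.item_names, model.discriminations, model.difficulties
            )
        }
    )
    locations = pd.Series(model.difficulties, index=model.item_names, name="location")
    return ICCProfile(theta_grid=grid, curves=curves, locations=locations)
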