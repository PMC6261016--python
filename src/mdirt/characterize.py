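"""Describe latent subgroups on demographic and utilization covariates.

Raw categorical covariates are dichotomized (most populated category versus
everything else, unknowns included in the rest).  For each binary covariate
the class-membership model yields per-class predicted probabilities (pp)
with 95% confidence intervals; in the single-covariate saturated case the
model-based margin for class k equals the class-k sample proportion, with
the CI formed on the logit scale and back-transformed.  All pairwise
class contrasts are then tested with a Scheffé correction — valid for the
whole family of contrasts at once — and classes that cannot be
distinguished share a letter, compact-letter-display style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import chi2, norm

logger = logging.getLogger("mdirt")

__all__ = [
    "dichotomize",
    "fit_characterization",
    "scheffe_groups",
    "descriptive_table",
    "render_descriptive",
    "characterize_covariates",
]


def dichotomize(
    raw: pd.Series, rule: str | dict = "modal_vs_rest"
) -> pd.Series:
    """Map a categorical column to {0, 1}.

    ``"modal_vs_rest"`` sends the most frequent category to 1 and every
    other category (including "unknown") to 0; a dict gives an explicit
    category -> {0,1} mapping (categories absent from the mapping go to 0).
    A tie for the modal category is an error: supply an explicit mapping.
    """
    raw = pd.Series(raw)
    if raw.empty:
        raise ValueError("covariate column is empty")
    if isinstance(rule, dict):
        out = raw.map(lambda v: int(rule.get(v, 0)) if pd.notna(v) else np.nan)
        return out.astype(float)
    if rule != "modal_vs_rest":
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    counts = raw.value_counts(dropna=True)
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        tied = counts.index[counts == counts.iloc[0]].tolist()
        raise ValueError(
            f"modal-category tie between {tied}; supply an explicit mapping"
        )
    modal = counts.index[0]
    return raw.map(lambda v: float(v == modal) if pd.notna(v) else np.nan)


def fit_characterization(
    assignments: pd.Series | np.ndarray,
    covariate: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-class predicted probability of the covariate's positive category.

    Fits the saturated one-covariate class-membership model, whose margins
    are the class-conditional proportions, and builds Wald intervals on the
    logit scale with se = 1/sqrt(n*p*(1-p)).  Degenerate classes (covariate
    constant within the class) get pp in {0, 1}, a [0, 1] interval, and a
    ``flagged`` mark; empty classes are excluded with a warning.

    Returns a DataFrame indexed by class with columns
    ``pp, lo, hi, se, n, flagged``.
    """
    cls = pd.Series(np.asarray(assignments), name="class")
    cov = pd.Series(np.asarray(covariate, dtype=float), name="cov")
    ok = cov.notna().to_numpy()
    cls, cov = cls[ok], cov[ok]
    classes = sorted(pd.unique(cls))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes present")
    if cov.nunique() < 2:
        raise ValueError("covariate is constant; nothing to characterize")
    z_crit = norm.ppf(1 - alpha / 2)
    rows = []
    for k in classes:
        sub = cov[cls == k]
        n_k = len(sub)
        if n_k == 0:
            logger.warning("class %s has no members; excluded", k)
            continue
        p = float(sub.mean())
        if p in (0.0, 1.0):
            rows.append(
                {"class": k, "pp": p, "lo": 0.0, "hi": 1.0, "se": np.nan, "n": n_k, "flagged": True}
            )
            logger.warning("class %s separated on covariate (p=%g); CI widened", k, p)
            continue
        se_p = np.sqrt(p * (1 - p) / n_k)
        se_logit = 1.0 / np.sqrt(n_k * p * (1 - p))
        lo = float(expit(logit(p) - z_crit * se_logit))
        hi = float(expit(logit(p) + z_crit * se_logit))
        rows.append(
            {"class": k, "pp": p, "lo": lo, "hi": hi, "se": se_p, "n": n_k, "flagged": False}
        )
    out = pd.DataFrame(rows).set_index("class")
    out.attrs["alpha"] = alpha
    return out


def scheffe_groups(pps: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Compact letter display of class equivalences under Scheffé correction.

    Every pairwise contrast z = (p_i - p_j)/sqrt(se_i^2 + se_j^2) is
    compared with the Scheffé critical value sqrt(chi2_{K-1, 1-alpha}),
    which protects the whole family of contrasts among the K classes.
    Classes joined by a letter are pairwise non-significant (letters are
    maximal cliques of the non-significance graph, assigned in class
    order).  Classes with missing standard errors fall back to a wide
    (flagged) comparison treated as non-significant.
    """
    K = len(pps)
    if K < 2:
        raise ValueError("need at least 2 classes")
    crit = np.sqrt(chi2.ppf(1 - alpha, K - 1))
    classes = list(pps.index)
    G = nx.Graph()
    G.add_nodes_from(range(K))
    se = pps["se"].to_numpy(dtype=float)
    pp = pps["pp"].to_numpy(dtype=float)
    for i in range(K):
        for j in range(i + 1, K):
            if np.isnan(se[i]) or np.isnan(se[j]):
                G.add_edge(i, j)  # cannot distinguish without an SE
                continue
            denom = np.sqrt(se[i] ** 2 + se[j] ** 2)
            z = 0.0 if denom == 0 else abs(pp[i] - pp[j]) / denom
            if z < crit:
                G.add_edge(i, j)
    cliques = [sorted(c) for c in nx.find_cliques(G)]
    cliques.sort()
    letters = {i: "" for i in range(K)}
    for letter_idx, clique in enumerate(cliques):
        letter = chr(ord("A") + letter_idx % 26) * (1 + letter_idx // 26)
        for i in clique:
            letters[i] += letter
    return pd.Series([letters[i] for i in range(K)], index=classes, name="letters")


def characterize_covariates(
    assignments: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tidy table of pp, CI and equivalence letters per (covariate, class)."""
    frames = []
    for name in covariates.columns:
        if name == "patient_id":
            continue
        try:
            pps = fit_characterization(assignments, covariates[name], alpha=alpha)
        except ValueError as exc:
            logger.warning("covariate %s skipped: %s", name, exc)
            continue
        letters = scheffe_groups(pps, alpha=alpha)
        block = pps.reset_index()
        block.insert(0, "covariate", name)
        block["letters"] = letters.to_numpy()
        frames.append(block)
    if not frames:
        raise ValueError("no usable covariates")
    return pd.concat(frames, ignore_index=True)


def descriptive_table(
    assignments: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Per class x variable x category counts and percentages.

    Percentages are within-variable within-class, so they sum to 100
    (up to rounding) for each categorical variable in each class.  Empty
    classes are omitted with a warning.
    """
    cls = pd.Series(np.asarray(assignments), name="class")
    rows = []
    classes = sorted(pd.unique(cls))
    for k in classes:
        in_k = (cls == k).to_numpy()
        n_k = int(in_k.sum())
        if n_k == 0:
            logger.warning("class %s is empty; omitted from descriptive table", k)
            continue
        for var in covariates.columns:
            if var == "patient_id":
                continue
            col = covariates.loc[in_k, var]
            for category, count in col.value_counts(dropna=False).items():
                rows.append(
                    {
                        "class": k,
                        "class_n": n_k,
                        "variable": var,
                        "category": category,
                        "n": int(count),
                        "percent": round(100.0 * count / n_k, 1),
                    }
                )
    return pd.DataFrame(rows)


def render_descriptive(table: pd.DataFrame) -> pd.DataFrame:
    """Format the descriptive table as "19.3% (1,802)" cells, classes as columns."""
    t = table.copy()
    t["cell"] = [
        f"{p:.1f}% ({n:,})" for p, n in zip(t["percent"], t["n"])
    ]
    return t.pivot(index=["variable", "category"], columns="class", values="cell")
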