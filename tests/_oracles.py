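"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the package's vectorized implementations: Loevinger
coefficients come from explicit 2x2 cross-tabs, Guttman errors from pair
enumeration, and marginal likelihoods from dense Riemann integration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm


def loevinger_brute(values: np.ndarray, order: list[int]):
    """(H_pair, H_item, H_scale) by exhaustive cross-tab recomputation.

    ``values`` is a patients x items float array (NaN = missing); ``order``
    lists item indices from most to least prevalent.
    """
    I = values.shape[1]
    F = {}
    E = {}
    for a in range(I):
        for b in range(a + 1, I):
            i, j = order[a], order[b]
            f = e_n = 0
            n00 = n01 = n10 = n11 = 0
            for row in values:
                if math.isnan(row[i]) or math.isnan(row[j]):
                    continue
                e_n += 1
                if row[i] == 0 and row[j] == 1:
                    n01 += 1
                elif row[i] == 0:
                    n00 += 1
                elif row[j] == 1:
                    n11 += 1
                else:
                    n10 += 1
            if e_n == 0:
                continue
            f = n01
            p_i0 = (n00 + n01) / e_n
            p_j1 = (n01 + n11) / e_n
            e = e_n * p_i0 * p_j1
            F[(i, j)] = f
            E[(i, j)] = e
    H_pair = {
        pair: 1.0 - F[pair] / E[pair] for pair in F if E[pair] > 0
    }
    H_item = {}
    for it in range(I):
        fs = sum(F[p] for p in F if it in p and E[p] > 0)
        es = sum(E[p] for p in F if it in p and E[p] > 0)
        H_item[it] = 1.0 - fs / es if es > 0 else float("nan")
    fs = sum(F[p] for p in F if E[p] > 0)
    es = sum(E[p] for p in F if E[p] > 0)
    H_scale = 1.0 - fs / es if es > 0 else float("nan")
    return H_pair, H_item, H_scale


def guttman_brute(pattern, order: list[int]) -> int:
    """Guttman errors by explicit enumeration over ordered pairs."""
    count = 0
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            xi, xj = pattern[order[a]], pattern[order[b]]
            if math.isnan(xi) or math.isnan(xj):
                continue
            if xi == 0 and xj == 1:
                count += 1
    return count


def marginal_loglik_riemann(
    values: np.ndarray,
    mixing,
    difficulties,
    trait_means,
    trait_sds,
    a: float,
    grid_points: int = 100_001,
    span: float = 12.0,
) -> float:
    """Dense-grid (trapezoid) integration of the mixture marginal likelihood."""
    grid = np.linspace(-span, span, grid_points)
    total = 0.0
    for row in values:
        obs = ~np.isnan(row)
        person = 0.0
        for c, pi_c in enumerate(mixing):
            dens = norm.pdf(grid, trait_means[c], trait_sds[c])
            eta = a * (grid[:, None] - np.asarray(difficulties[c])[None, obs])
            P = 1.0 / (1.0 + np.exp(-eta))
            like = np.prod(np.where(row[obs] == 1, P, 1 - P), axis=1)
            person += pi_c * np.trapezoid(like * dens, grid)
        total += np.log(person)
    return float(total)
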