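"""Independent brute-force oracles used by the tests.

These deliberately re-derive results along a different route than the
package: a step-by-step Gaussian vergence trace with bisection instead of
the closed-form formula chains, direct normal equations instead of the
regression helper, and a direct ECDF scan instead of library KS statistics.
"""

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm


def vergence_trace_refraction(k_power, elp, lopt, iol_power, na=1.336, vertex=12.0):
    """Spectacle refraction focusing at ``lopt`` via explicit vergence steps.

    Cornea = thin lens of ``k_power`` D at the corneal plane; vergence is
    translated ``elp`` mm through index ``na`` to the IOL plane; the IOL
    adds ``iol_power``; the image must land at ``lopt`` mm.  The spectacle
    refraction is solved by bracketed bisection.
    """
    target = 1000.0 * na / (lopt - elp)

    def residual(r_spec):
        r_cornea = r_spec / (1.0 - 0.001 * vertex * r_spec)
        u = r_cornea + k_power
        u_at_iol = u / (1.0 - (0.001 * elp / na) * u)
        return u_at_iol + iol_power - target

    return brentq(residual, -40.0, 40.0, xtol=1e-12, rtol=8.9e-16)


def ols_normal_equations(x, y):
    """Straight-line OLS via the normal equations: slope, intercept, R^2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    sst = ((y - ym) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / sst
    return slope, intercept, r2


def ks_statistic_ecdf(x, mean, sd):
    """max |ECDF - normal CDF| evaluated on both sides of every jump."""
    xs = np.sort(np.asarray(x, float))
    n = xs.size
    cdf = norm.cdf(xs, mean, sd)
    upper = np.abs(np.arange(1, n + 1) / n - cdf).max()
    lower = np.abs(np.arange(0, n) / n - cdf).max()
    return max(upper, lower)


def friedman_statistic_bruteforce(matrix):
    """Friedman chi-square from first principles (within-row average ranks)."""
    m = np.asarray(matrix, float)
    n, k = m.shape
    ranks = np.empty_like(m)
    for i, row in enumerate(m):
        order = np.argsort(row)
        rank = np.empty(k)
        j = 0
        sorted_row = row[order]
        while j < k:
            j2 = j
            while j2 + 1 < k and sorted_row[j2 + 1] == sorted_row[j]:
                j2 += 1
            rank[order[j:j2 + 1]] = (j + j2) / 2.0 + 1.0
            j = j2 + 1
        ranks[i] = rank
    col = ranks.sum(axis=0)
    num = (k - 1) * ((col - n * (k + 1) / 2.0) ** 2).sum()
    den = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0
    return num / den
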