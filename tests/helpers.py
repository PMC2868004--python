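"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: ordering
probabilities come from numerical quadrature of scipy beta densities, and
ROC AUC from brute-force Mann-Whitney pair counting.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


def prob_x_greater_y(a1: float, b1: float, a2: float, b2: float) -> float:
    """P(X > Y) for independent X ~ Beta(a1,b1), Y ~ Beta(a2,b2) by quadrature."""
    val, _ = integrate.quad(
        lambda x: stats.beta.pdf(x, a1, b1) * stats.beta.cdf(x, a2, b2),
        0.0,
        1.0,
        limit=200,
    )
    return val


def pair_counting_auc(scores, truth) -> float:
    """Mann-Whitney AUC: fraction of concordant positive-negative pairs, ties 1/2."""
    pos = [scores[g] for g in scores if truth[g]]
    neg = [scores[g] for g in scores if not truth[g]]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def classical_yules_q(n11: float, n10: float, n01: float, n00: float) -> float:
    """Textbook Yule's Q of a 2x2 table."""
    return (n11 * n00 - n10 * n01) / (n11 * n00 + n10 * n01)


def mixture_mean(components: list[tuple[float, float]]) -> float:
    """Analytic mean of an equal-weight beta mixture."""
    return float(np.mean([a / (a + b) for a, b in components]))
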