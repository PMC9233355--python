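"""Independent oracles shared by the test modules.

Everything here is written from first principles (enumeration / closed
forms / grid search) and never calls the code paths it is used to check.
"""

import itertools

import numpy as np


def f2_class_probs(r, error_prob):
    """3x3 dosage-pair class probabilities for an F2 intercross by direct
    enumeration of ordered gamete pairs."""
    probs = np.zeros((3, 3))
    gametes = [(0, 0), (0, 1), (1, 0), (1, 1)]

    def p_gamete(gt):
        return (1 - r) / 2 if gt[0] == gt[1] else r / 2

    for g1, g2 in itertools.product(gametes, repeat=2):
        probs[g1[0] + g2[0], g1[1] + g2[1]] += p_gamete(g1) * p_gamete(g2)
    e = error_prob
    E = np.full((3, 3), e / 2)
    np.fill_diagonal(E, 1 - e)
    return E @ probs @ E.T


def grid_search_ml(counts9, error_prob, grid=None):
    """Exhaustive multinomial-likelihood scan for the recombination fraction."""
    if grid is None:
        grid = np.arange(0.0005, 0.4995, 0.001)
    counts = np.asarray(counts9, float).reshape(3, 3)
    best_r, best_ll = None, -np.inf
    for r in grid:
        q = f2_class_probs(r, error_prob)
        with np.errstate(divide="ignore"):
            ll = np.where(counts > 0, counts * np.log(q), 0.0).sum()
        if ll > best_ll:
            best_r, best_ll = r, ll
    return best_r


def half_normal_af_moments(n):
    """Mean and sd of |AF - 0.5| for pooled Binomial(2n, 1/2) frequencies."""
    sigma = 0.5 / np.sqrt(2 * n)
    return sigma * np.sqrt(2 / np.pi), sigma * np.sqrt(1 - 2 / np.pi)
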