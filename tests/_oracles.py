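"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles (exhaustive
enumeration, vectorised permutation, grid refinement) without calling the
implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def logrank_statistic_matrix(times, events, group_matrix) -> np.ndarray:
    """Log-rank chi-squared statistics for many group labellings at once.

    ``group_matrix`` is (n_labellings, n_patients) boolean membership of
    group 1.  Derived directly from the O−E / hypergeometric-variance
    definition, vectorised over labellings.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g = np.asarray(group_matrix, float)
    event_times = np.unique(times[events == 1])
    at_risk = times[:, None] >= event_times[None, :]
    dying = (times[:, None] == event_times[None, :]) & (events[:, None] == 1)
    n = at_risk.sum(axis=0)
    d = dying.sum(axis=0)
    n1 = g @ at_risk
    d1 = g @ dying
    e1 = d * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(n > 1, d * (n1 / n) * (1 - n1 / n) * (n - d) / np.maximum(n - 1, 1), 0.0)
    o_minus_e = (d1 - e1).sum(axis=1)
    variance = v.sum(axis=1)
    return np.where(variance > 0, o_minus_e**2 / variance, 0.0)


def permutation_pvalue(times, events, groups, n_permutations: int, rng) -> float:
    """Upper-tail permutation p of the log-rank statistic (labels shuffled)."""
    g = np.asarray(groups)
    member = g == np.unique(g)[0]
    observed = logrank_statistic_matrix(times, events, member[None, :])[0]
    perms = np.array([rng.permutation(member) for _ in range(n_permutations)])
    stats = logrank_statistic_matrix(times, events, perms)
    return float((stats >= observed - 1e-12).mean())


def auroc_bruteforce(scores, labels) -> float:
    """All-pairs concordance count (ties half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (pos.size * neg.size))


def penalised_loglik(beta, design, y, ridge):
    eta = design @ beta
    return float((y * eta - np.log1p(np.exp(eta))).sum() - 0.5 * ridge * (beta[1:] ** 2).sum())


def logistic_grid_oracle(x, y, ridge, rounds: int = 8, grid: int = 13, half_width: float = 8.0):
    """Maximise the penalised logistic likelihood by iterated grid refinement.

    Independent of IRLS: each round lays a ``grid``-point lattice per
    parameter around the current best and shrinks the window.
    """
    design = np.column_stack([np.ones(len(y)), np.atleast_2d(x)])
    k = design.shape[1]
    centre = np.zeros(k)
    width = half_width
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, grid) for c in centre]
        mesh = np.meshgrid(*axes, indexing="ij")
        candidates = np.stack([m.ravel() for m in mesh], axis=1)
        values = [penalised_loglik(b, design, y, ridge) for b in candidates]
        centre = candidates[int(np.argmax(values))]
        width *= 2.0 / (grid - 1)
    return centre


def breslow_partial_loglik(beta, x, times, events) -> float:
    """Breslow partial log-likelihood of a scalar Cox coefficient."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    ll = 0.0
    w = np.exp(beta * x)
    for t in np.unique(times[events == 1]):
        dying = (times == t) & (events == 1)
        risk = times >= t
        ll += beta * x[dying].sum() - dying.sum() * np.log(w[risk].sum())
    return float(ll)


def cox_grid_oracle(x, times, events, rounds: int = 10, grid: int = 41, half_width: float = 10.0):
    """Maximise the Breslow partial likelihood on a shrinking 1-d grid."""
    centre = 0.0
    width = half_width
    for _ in range(rounds):
        candidates = np.linspace(centre - width, centre + width, grid)
        values = [breslow_partial_loglik(b, x, times, events) for b in candidates]
        centre = float(candidates[int(np.argmax(values))])
        width *= 2.0 / (grid - 1)
    return centre
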