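"""Independent oracles used by the test suite.

Each function here re-derives an expected result by a different route from
the implementation under test: a literal truth table for the course rule,
a general-purpose QP solver for the SVM, and explicit padded convolution
for the smoother.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# Illness-course rule: truth table + exhaustive history enumeration

SIX_MONTHS = 183


def course_truth_table(episodes, remissions) -> str:
    """Literal clause-by-clause coding of the outcome rule.

    Precedence: single short episode -> remitting; long remission without
    long episode -> remitting; long remission with long episode ->
    excluded; otherwise continuous.
    """
    episode_durations = [d for _, d in episodes]
    remission_durations = [d for _, d in remissions]
    has_episode_over_6m = any(d > SIX_MONTHS for d in episode_durations)
    has_remission_at_least_6m = any(d >= SIX_MONTHS for d in remission_durations)
    if len(episode_durations) == 1 and episode_durations[0] <= SIX_MONTHS:
        return "remitting"
    if has_remission_at_least_6m and not has_episode_over_6m:
        return "remitting"
    if has_remission_at_least_6m and has_episode_over_6m:
        return "excluded"
    return "continuous"


def enumerate_histories(n_slots: int = 12, slot_days: int = 30,
                        max_episodes: int = 2, max_remissions: int = 2):
    """All interval histories with up to 2 episodes and 2 remissions on a
    coarse day grid, as (episodes, remissions, follow_up_days) tuples.

    Intervals are pairwise disjoint; each is (start_day, duration_days)
    with boundaries on multiples of ``slot_days``.
    """
    follow_up = n_slots * slot_days
    intervals = [
        (s * slot_days, d * slot_days)
        for s in range(n_slots)
        for d in range(1, n_slots - s + 1)
    ]

    def disjoint(chosen):
        spans = sorted((s, s + d) for s, d in chosen)
        return all(b0 >= a1 for (a0, a1), (b0, b1) in zip(spans, spans[1:]))

    out = []
    for n_ep in range(max_episodes + 1):
        for n_rem in range(max_remissions + 1):
            for eps in itertools.combinations(intervals, n_ep):
                if not disjoint(eps):
                    continue
                for rems in itertools.combinations(intervals, n_rem):
                    if not disjoint(eps + rems):
                        continue
                    out.append((eps, rems, follow_up))
    return out


# ---------------------------------------------------------------------------
# Soft-margin linear SVM: dual quadratic program via SLSQP

def svm_qp(X, y, C):
    """Solve max_a sum a - 1/2 a'Qa, 0 <= a <= C, a'y = 0; return (w, b).

    Small problems only.  The bias is recovered from the margin support
    vectors (0 < a < C).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Z = y[:, None] * X
    Q = Z @ Z.T

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def grad(a):
        return -(np.ones(n) - Q @ a)

    res = minimize(
        neg_dual,
        np.full(n, min(C, 1.0) / 2),
        jac=grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 5000, "ftol": 1e-16},
    )
    a = res.x
    w = (a * y) @ X
    free = (a > 1e-8 * C) & (a < C * (1 - 1e-8))
    if not free.any():  # fall back to any support vector
        free = a > 1e-8 * C
    b = float(np.mean(y[free] - X[free] @ w))
    return w, b


# ---------------------------------------------------------------------------
# Gaussian smoothing: explicit padded direct convolution

def direct_gaussian(volume, sigma_per_axis):
    """Separable truncated-Gaussian convolution with symmetric padding,
    applied by explicit 1-D convolution along each axis."""
    out = np.asarray(volume, dtype=float)
    for axis, sigma in enumerate(sigma_per_axis):
        if sigma == 0:
            continue
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1, dtype=float)
        kernel = np.exp(-(x ** 2) / (2.0 * sigma * sigma))
        kernel /= kernel.sum()

        def conv1d(line):
            padded = np.pad(line, radius, mode="symmetric")
            return np.convolve(padded, kernel, mode="valid")

        out = np.apply_along_axis(conv1d, axis, out)
    return out
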