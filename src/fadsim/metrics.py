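"""Population-level read-outs: trend color, uniformity, chance threshold,
trend-change speed and the per-agent impact index.

*Uniformity* is the mean resultant length of the members' unit-normalized
choice vectors — 1 when everyone displays the same color, near 0 when
colors are spread evenly around the circle.  The *trend color* is the
angle of that same summed vector.  Because both derive from one vector
sum, members are unit-normalized once and shared between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import DEGENERATE_NORM, angle_of, angular_difference, unit_from_angle

__all__ = [
    "TrendSeries",
    "UndefinedTrendError",
    "trend_of",
    "uniformity_of",
    "chance_threshold",
    "change_speed",
    "trend_series",
    "impact_index",
    "impact_trace",
]


class UndefinedTrendError(ValueError):
    """All member choices were degenerate; no trend direction exists."""


def _normalized_sum(choices: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Unit-normalize members, skipping degenerate ones, and sum.

    Returns (summed vector, number of contributing members, number skipped).
    """
    choices = np.asarray(choices, dtype=float)
    norms = np.linalg.norm(choices, axis=-1)
    ok = norms >= DEGENERATE_NORM
    n_skipped = int((~ok).sum())
    if not ok.any():
        raise UndefinedTrendError("every choice vector is degenerate")
    s = (choices[ok] / norms[ok, None]).sum(axis=0)
    return s, int(ok.sum()), n_skipped


def trend_of(choices) -> tuple[np.ndarray, float]:
    """Trend vector and trend angle (turns) of a set of choices.

    Members are unit-normalized before summation; degenerate members are
    skipped.  Raises :class:`UndefinedTrendError` when no member has a
    direction, and propagates a degenerate-vector error when the sum
    itself cancels to zero.
    """
    s, _, _ = _normalized_sum(choices)
    return s, angle_of(s)


def uniformity_of(choices) -> float:
    """Mean resultant length ``||sum of unit choices|| / n_members`` in [0, 1].

    Normalization uses the full member count including skipped
    degenerate members, so a population of mostly-degenerate choices
    scores low rather than being silently shrunk.
    """
    choices = np.asarray(choices, dtype=float)
    s, _, _ = _normalized_sum(choices)
    # rounding can push a perfectly aligned sum a few ulp above n
    return float(min(np.linalg.norm(s) / choices.shape[0], 1.0))


def chance_threshold(
    n_members: int,
    iters: int = 10_000,
    percentile: float = 99.0,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Uniformity expected by chance: the given percentile of the
    uniformity distribution over ``iters`` draws of ``n_members``
    independent unit vectors at uniformly random angles.

    For n = 200 and the 99th percentile this sits near 0.153; it scales
    roughly as 1/sqrt(n) (Rayleigh statistics of random walks).
    """
    if n_members < 2:
        raise ValueError("n_members must be >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    phi = 2.0 * np.pi * rng.random((iters, n_members))
    s1 = np.sin(phi).sum(axis=1)
    s2 = np.cos(phi).sum(axis=1)
    uniformity = np.hypot(s1, s2) / n_members
    return float(np.percentile(uniformity, percentile))


def change_speed(trend_vectors) -> np.ndarray:
    """Trial-to-trial trend turnover in units of pi, range [0, 1].

    For each consecutive pair of trend vectors, the minimal arc between
    them divided by pi.  This equals the turn-difference procedure of
    folding differences above half a turn (``1 - diff``) and doubling.
    Steps touching a degenerate trend entry are returned as NaN.
    """
    v = np.asarray(trend_vectors, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need a sequence of at least 2 trend vectors")
    norms = np.linalg.norm(v, axis=-1)
    ok = (norms[:-1] >= DEGENERATE_NORM) & (norms[1:] >= DEGENERATE_NORM)
    out = np.full(v.shape[0] - 1, np.nan)
    if ok.any():
        a, b = v[:-1][ok], v[1:][ok]
        out[ok] = angular_difference(a, b)
    return out


@dataclass
class TrendSeries:
    """Per-trial trend read-outs of a group of agents.

    ``change_speed`` has one entry fewer than the trend itself.
    ``n_skipped[t]`` counts degenerate member choices excluded on trial
    ``t``.
    """

    trend_vector: np.ndarray  # (n_t, 2)
    trend_angle: np.ndarray  # (n_t,) turns
    uniformity: np.ndarray  # (n_t,)
    change_speed: np.ndarray  # (n_t - 1,) units of pi
    n_skipped: np.ndarray  # (n_t,) int


def trend_series(choices: np.ndarray) -> TrendSeries:
    """Compute the full trend read-out for ``choices`` of shape
    ``(n_trials, n_members, 2)``."""
    choices = np.asarray(choices, dtype=float)
    n_t, n_i = choices.shape[0], choices.shape[1]
    norms = np.linalg.norm(choices, axis=-1)
    ok = norms >= DEGENERATE_NORM
    safe = np.where(ok, norms, 1.0)
    units = np.where(ok[..., None], choices / safe[..., None], 0.0)
    s = units.sum(axis=1)  # (n_t, 2)
    uniformity = np.minimum(np.linalg.norm(s, axis=-1) / n_i, 1.0)
    s_norms = np.linalg.norm(s, axis=-1)
    angles = np.full(n_t, np.nan)
    defined = s_norms >= DEGENERATE_NORM
    if defined.any():
        angles[defined] = angle_of(s[defined])
    return TrendSeries(
        trend_vector=s,
        trend_angle=angles,
        uniformity=uniformity,
        change_speed=change_speed(s) if n_t >= 2 else np.empty(0),
        n_skipped=(~ok).sum(axis=1),
    )


def impact_index(result, t: int) -> np.ndarray:
    """Per-agent impact on the population trend at trial ``t``.

    For agent ``i``: the sum over all agents ``j`` that sampled ``i`` on
    trial ``t`` of the boredom weight ``w_j(d)`` that ``j`` stored,
    times the arc angle (radians) between ``i``'s displayed choice and
    the full population's trend vector on trial ``t + 1``.  Zero for
    agents sampled by nobody.
    """
    n_t, n = result.choices.shape[0], result.choices.shape[1]
    if not 0 <= t < n_t - 1:
        raise ValueError("t must leave a following trial for the trend target")
    if np.any(result.partners[t] < 0) or np.any(np.isnan(result.sample_weights[t])):
        raise ValueError("simulation result carries no usable sampling log")
    s_next, _, _ = _normalized_sum(result.choices[t + 1])
    y = result.choices[t]
    norms = np.linalg.norm(y, axis=-1)
    ok = norms >= DEGENERATE_NORM
    arc = np.zeros(n)
    cos_d = np.clip(
        np.sum(y[ok] * s_next[None, :], axis=-1)
        / (norms[ok] * np.linalg.norm(s_next)),
        -1.0,
        1.0,
    )
    arc[ok] = np.arccos(cos_d)
    contrib = result.sample_weights[t] * arc[result.partners[t]]
    return np.bincount(result.partners[t], weights=contrib, minlength=n)


def impact_trace(result) -> np.ndarray:
    """Impact index for every agent on trials ``0 .. n_t - 2``;
    shape ``(n_t - 1, n_agents)``."""
    n_t = result.choices.shape[0]
    return np.vstack([impact_index(result, t) for t in range(n_t - 1)])
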