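"""Experiment orchestration and statistics.

Parameter-space sweeps over memory size and boredom shift, subgroup
trend comparisons (anti-conformity, avantgarde lag profiles), the
drift-propagation experiment, permutation (shuffle) tests for
non-random trend dynamics, and thin wrappers around the rank-based
hypothesis tests used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import stats

from .colorspace import DEGENERATE_NORM, angle_of, angular_difference
from .engine import GroupSpec, PopulationConfig, run_simulation
from .metrics import change_speed, trend_series

__all__ = [
    "SweepResult",
    "LagProfile",
    "sweep",
    "subgroup_trend_comparison",
    "lag_profile",
    "signed_trend_changes",
    "drift_propagation_test",
    "moving_vector_sum_smooth",
    "shuffle_test",
    "mean_boredom_equivalence",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "pearson",
    "spearman",
    "ks_uniform_angles",
]

MIN_TEST_N = 5


# ---------------------------------------------------------------------------
# parameter-space sweeps


@dataclass
class SweepResult:
    """Read-outs over a full (m, x0) grid, one simulation per cell.

    ``max_uniformity[i, j]`` and ``mean_change_speed[i, j]`` belong to
    ``m_grid[i]`` and ``x0_grid[j]``; ``seeds`` records the per-cell
    master seed.  The maximal uniformity over trials is the headline
    read-out: it flags convergence even when it only occurs late.
    """

    m_grid: np.ndarray
    x0_grid: np.ndarray
    max_uniformity: np.ndarray
    mean_change_speed: np.ndarray
    seeds: np.ndarray
    overlay: GroupSpec | None = None
    overlay_fraction: float = 0.0


def sweep(
    base_cfg: PopulationConfig,
    m_grid,
    x0_grid,
    overlay: GroupSpec | None = None,
    overlay_fraction: float = 0.0,
) -> SweepResult:
    """One simulation per (m, x0) cell; the x0 of the residual group is
    varied while an optional ``overlay`` subgroup (e.g. highly bored or
    highly popular agents) keeps its own attributes in every cell.
    """
    m_grid = np.asarray(list(m_grid), dtype=int)
    x0_grid = np.asarray(list(x0_grid), dtype=float)
    if m_grid.size == 0 or x0_grid.size == 0:
        raise ValueError("sweep grids must be non-empty")
    max_u = np.empty((m_grid.size, x0_grid.size))
    mean_cs = np.empty_like(max_u)
    seeds = np.empty_like(max_u, dtype=np.int64)
    for i, m in enumerate(m_grid):
        for j, x0 in enumerate(x0_grid):
            if overlay is None:
                groups = (GroupSpec(fraction=1.0, x0=float(x0)),)
            else:
                groups = (
                    dc_replace(overlay, fraction=overlay_fraction),
                    GroupSpec(fraction=1.0 - overlay_fraction, x0=float(x0)),
                )
            cfg = dc_replace(base_cfg, m=int(m), groups=groups)
            try:
                ts = trend_series(run_simulation(cfg).choices)
            except Exception as exc:  # noqa: BLE001 - annotate cell and re-raise
                raise RuntimeError(f"sweep cell (m={m}, x0={x0}) failed") from exc
            max_u[i, j] = ts.uniformity.max()
            mean_cs[i, j] = np.nanmean(ts.change_speed)
            seeds[i, j] = cfg.seed
    return SweepResult(m_grid, x0_grid, max_u, mean_cs, seeds, overlay, overlay_fraction)


def mean_boredom_equivalence(hetero: SweepResult, homo: SweepResult, decimals: int = 10):
    """Match heterogeneous cells to homogeneous cells of equal memory and
    equal population-mean boredom shift, and test the paired
    max-uniformity differences against a zero median.

    The mean shift of a heterogeneous cell is
    ``frac_overlay * x0_overlay + (1 - frac) * x0_residual`` (e.g.
    0.8*0.65 + 0.2*0.9 = 0.70 matches the homogeneous x0 = 0.70 cell).
    Returns (paired differences hetero - homo, test result).
    """
    if hetero.overlay is None:
        raise ValueError("heterogeneous sweep must carry an overlay subgroup")
    f = hetero.overlay_fraction
    mean_x0 = np.round(f * hetero.overlay.x0 + (1.0 - f) * hetero.x0_grid, decimals)
    homo_x0 = np.round(homo.x0_grid, decimals)
    diffs = []
    for i, m in enumerate(hetero.m_grid):
        homo_i = np.flatnonzero(homo.m_grid == m)
        if homo_i.size == 0:
            continue
        for j, mx in enumerate(mean_x0):
            k = np.flatnonzero(homo_x0 == mx)
            if k.size:
                diffs.append(
                    hetero.max_uniformity[i, j] - homo.max_uniformity[homo_i[0], k[0]]
                )
    if not diffs:
        raise ValueError("no cells with matching (m, mean x0) between the sweeps")
    diffs = np.asarray(diffs)
    test = (
        wilcoxon_signed_rank(diffs, np.zeros_like(diffs))
        if diffs.size >= MIN_TEST_N
        else None
    )
    return diffs, test


# ---------------------------------------------------------------------------
# subgroup trend analyses


def subgroup_trend_comparison(result, subgroup_ids, rng=None):
    """Per-trial arc difference (units of pi) of (a) the subgroup trend
    and (b) a size-matched random residual subsample trend, each from
    the full-population trend.

    The residual comparison uses one fixed subsample so both series are
    plain per-trial statistics of a single run.  Returns
    ``(delta_subgroup, delta_residual, residual_ids)``.
    """
    subgroup_ids = np.asarray(subgroup_ids)
    n = result.choices.shape[1]
    if subgroup_ids.size == 0 or subgroup_ids.size >= n:
        raise ValueError("subgroup must be non-empty and smaller than the population")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    residual_pool = np.setdiff1d(np.arange(n), subgroup_ids)
    residual_ids = rng.choice(residual_pool, size=subgroup_ids.size, replace=False)

    full = trend_series(result.choices).trend_vector
    delta = {}
    for name, ids in (("sub", subgroup_ids), ("res", residual_ids)):
        tv = trend_series(result.choices[:, ids]).trend_vector
        ok = (np.linalg.norm(tv, axis=-1) >= DEGENERATE_NORM) & (
            np.linalg.norm(full, axis=-1) >= DEGENERATE_NORM
        )
        d = np.full(tv.shape[0], np.nan)
        d[ok] = angular_difference(tv[ok], full[ok])
        delta[name] = d
    return delta["sub"], delta["res"], residual_ids


@dataclass
class LagProfile:
    """Mean arc difference between a subgroup trend and the time-shifted
    full-population trend, per lag.

    Positive lag compares the subgroup at trial t with the population at
    trial t + lag: a minimum at positive lag means the subgroup's trend
    pattern shows up in the population's near future (avantgarde).
    """

    lags: np.ndarray
    mean_abs_diff: np.ndarray
    sem: np.ndarray

    @property
    def min_lag(self) -> int:
        return int(self.lags[np.nanargmin(self.mean_abs_diff)])


def lag_profile(subgroup_trend, full_trend, max_lag: int = 30) -> LagProfile:
    sub = np.asarray(subgroup_trend, dtype=float)
    full = np.asarray(full_trend, dtype=float)
    n = sub.shape[0]
    if n <= 2 * max_lag:
        raise ValueError("series too short for the requested lag range")
    lags = np.arange(-max_lag, max_lag + 1)
    means = np.empty(lags.size)
    sems = np.empty(lags.size)
    for k, lag in enumerate(lags):
        if lag >= 0:
            a, b = sub[: n - lag], full[lag:]
        else:
            a, b = sub[-lag:], full[: n + lag]
        ok = (np.linalg.norm(a, axis=-1) >= DEGENERATE_NORM) & (
            np.linalg.norm(b, axis=-1) >= DEGENERATE_NORM
        )
        d = angular_difference(a[ok], b[ok])
        means[k] = np.mean(d)
        sems[k] = np.std(d, ddof=1) / np.sqrt(d.size)
    return LagProfile(lags, means, sems)


# ---------------------------------------------------------------------------
# drift propagation


def signed_trend_changes(trend_vectors, interval: int = 25) -> np.ndarray:
    """Signed trend-angle change per ``interval`` trials, in units of pi.

    Positive values are clockwise (the direction of the imposed drift);
    changes are folded to the minimal signed arc in (-1, 1].
    """
    tv = np.asarray(trend_vectors, dtype=float)
    idx = np.arange(0, tv.shape[0], interval)
    if idx.size < 2:
        raise ValueError("series shorter than one interval")
    angles = np.full(idx.size, np.nan)
    ok = np.linalg.norm(tv[idx], axis=-1) >= DEGENERATE_NORM
    angles[ok] = np.atleast_1d(angle_of(tv[idx][ok]))
    step_turns = np.diff(angles)
    folded = (step_turns + 0.5) % 1.0 - 0.5
    folded[folded == -0.5] = 0.5
    return folded * 2.0


def drift_propagation_test(result_bias_on, result_bias_off, residual_group: int = 1,
                           interval: int = 25):
    """Does an imposed clockwise drift in a bored subgroup reach the
    residual agents' trend only when the subgroup is held uniform?

    Computes signed residual-trend changes at ``interval``-trial steps
    for both conditions and compares them with a one-sided rank-sum test
    (bias-on > bias-off).  Returns (changes_on, changes_off, test).
    """
    out = []
    for res in (result_bias_on, result_bias_off):
        ids = res.agents_in_group(residual_group)
        tv = trend_series(res.choices[:, ids]).trend_vector
        out.append(signed_trend_changes(tv, interval))
    ch_on, ch_off = out
    test = wilcoxon_rank_sum(ch_on[~np.isnan(ch_on)], ch_off[~np.isnan(ch_off)],
                             alternative="greater")
    return ch_on, ch_off, test


# ---------------------------------------------------------------------------
# shuffle (permutation) test for non-random trend dynamics


def moving_vector_sum_smooth(vectors: np.ndarray, bin_size: int) -> np.ndarray:
    """Trailing moving vector sum over ``bin_size`` entries
    (length ``n - bin_size + 1``)."""
    v = np.asarray(vectors, dtype=float)
    if bin_size < 1 or bin_size > v.shape[0]:
        raise ValueError("bin_size must be in [1, len(series)]")
    c = np.cumsum(np.vstack([np.zeros((1, 2)), v]), axis=0)
    return c[bin_size:] - c[:-bin_size]


def shuffle_test(vectors, smooth_bin: int, rng=None, n_shuffles: int = 1):
    """Permutation test: are trend changes of the observed sequence
    smaller than those of a time-shuffled sequence?

    The sequence order is permuted, then both versions are smoothed with
    the moving vector sum (smoothing always happens after shuffling) and
    their change-speed distributions compared with a one-sided rank-sum
    test (observed < shuffled).  With ``n_shuffles > 1`` the shuffled
    changes are pooled.  When both change distributions are identical
    (e.g. a constant series) the rank statistic carries no information
    and p = 0.5 is returned, making ties explicit.
    """
    v = np.asarray(vectors, dtype=float)
    if v.shape[0] <= smooth_bin:
        raise ValueError("series must be longer than the smoothing bin")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    emp = change_speed(moving_vector_sum_smooth(v, smooth_bin))
    emp = emp[~np.isnan(emp)]
    shuf_all = []
    for _ in range(n_shuffles):
        perm = rng.permutation(v.shape[0])
        sh = change_speed(moving_vector_sum_smooth(v[perm], smooth_bin))
        shuf_all.append(sh[~np.isnan(sh)])
    shuf = np.concatenate(shuf_all)
    if emp.size and shuf.size and np.array_equal(np.sort(emp), np.sort(shuf)):
        return emp, shuf, {"statistic": np.nan, "p_value": 0.5, "note": "identical distributions"}
    test = wilcoxon_rank_sum(emp, shuf, alternative="less")
    return emp, shuf, test


# ---------------------------------------------------------------------------
# hypothesis-test wrappers


def _check_n(*samples):
    for s in samples:
        if np.asarray(s).size < MIN_TEST_N:
            raise ValueError(f"need at least {MIN_TEST_N} observations per sample")


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided") -> dict:
    """Paired signed-rank test; identical pairs (all differences zero)
    yield p = 1 rather than an error."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    _check_n(d)
    if np.all(d == 0):
        return {"statistic": 0.0, "p_value": 1.0, "n": d.size, "note": "all differences zero"}
    res = stats.wilcoxon(d, alternative=alternative, zero_method="wilcox")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "n": d.size}


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> dict:
    """Two-sample rank-sum (Mann-Whitney) test: exact for small
    tie-free samples, mid-rank normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_n(x, y)
    small = max(x.size, y.size) <= 25
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n": (x.size, y.size), "method": method}


def pearson(x, y, alternative: str = "two-sided") -> dict:
    _check_n(x, y)
    res = stats.pearsonr(x, y, alternative=alternative)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


def spearman(x, y, alternative: str = "two-sided") -> dict:
    _check_n(x, y)
    res = stats.spearmanr(x, y, alternative=alternative)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


def ks_uniform_angles(angles_turns, n_sample: int = 100, rng=None) -> dict:
    """One-sample KS test of trend angles against Uniform(0, 1) turns.

    ``n_sample`` angles are drawn without replacement and the origin is
    rotated by a random offset before testing, so the arbitrary cut
    point of the circle cannot manufacture non-uniformity.
    """
    a = np.asarray(angles_turns, dtype=float)
    a = a[~np.isnan(a)]
    _check_n(a)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if a.size > n_sample:
        a = rng.choice(a, size=n_sample, replace=False)
    a = np.mod(a + rng.random(), 1.0)
    res = stats.kstest(a, "uniform")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "n": a.size}
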