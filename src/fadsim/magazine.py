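"""Empirical color-trend pipeline for monthly cover-color sequences.

A CSV of dated RGB codes (columns ``date,r,g,b``, one row per month) is
converted to CIELAB (sRGB, D65 white point), projected onto the plane
of the first two principal components of the pooled Lab colors, and
represented as clockwise angles on that plane.  Trends are the moving
vector sum of the unit color vectors over a time bin (default 8
months); turnover and its statistical structure are analyzed with the
same change-speed and shuffle machinery as the simulator.

The original magazine-cover dataset is not public, so
:func:`generate_fixture` produces a synthetic stand-in with the
qualitative structure reported for real covers: long phases of slow
angular drift interrupted by occasional large jumps, optionally
attracted to a few color clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import color as skcolor
from sklearn.decomposition import PCA

from .colorspace import DEGENERATE_NORM, angle_of, unit_from_angle
from .metrics import change_speed, uniformity_of
from .analysis import moving_vector_sum_smooth, shuffle_test

__all__ = [
    "PcaPlane",
    "rgb_to_lab",
    "lab_to_rgb",
    "fit_plane",
    "project",
    "load_colors",
    "pipeline",
    "moving_vector_sum",
    "cross_series_uniformity",
    "generate_fixture",
]


def rgb_to_lab(rgb) -> np.ndarray:
    """sRGB (0-255 integers) -> CIELAB (D65), vectorized over rows."""
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("RGB components must lie in [0, 255]")
    return skcolor.rgb2lab(rgb / 255.0)


def lab_to_rgb(lab) -> np.ndarray:
    """CIELAB -> sRGB 0-255 integers, clipped into gamut."""
    rgb = skcolor.lab2rgb(np.asarray(lab, dtype=float))
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(int)


@dataclass
class PcaPlane:
    """Plane of the two leading principal components of a Lab cloud."""

    mean: np.ndarray  # (3,)
    components: np.ndarray  # (2, 3), orthonormal rows
    explained_variance_fraction: float
    rank_deficient: bool = False


def fit_plane(labs) -> PcaPlane:
    """Centered PCA of the pooled Lab colors; colors on the returned
    plane keep their full variance (explained fraction 1)."""
    labs = np.asarray(labs, dtype=float)
    if labs.shape[0] < 3:
        raise ValueError("need at least 3 colors for a stable plane")
    rank = np.linalg.matrix_rank(labs - labs.mean(axis=0))
    n_comp = min(2, rank) if rank > 0 else 1
    pca = PCA(n_components=n_comp).fit(labs)
    comps = pca.components_
    if comps.shape[0] < 2:
        # degenerate cloud: complete the basis with any orthogonal axis
        null = np.linalg.svd(comps)[2][-1]
        comps = np.vstack([comps, null])
    return PcaPlane(
        mean=pca.mean_,
        components=comps,
        explained_variance_fraction=float(pca.explained_variance_ratio_.sum()),
        rank_deficient=rank < 2,
    )


def project(lab, plane: PcaPlane):
    """Project Lab color(s) onto the plane.

    Returns ``(pc, angle_turns)`` where ``pc`` are the 2-D plane
    coordinates and the angle is measured clockwise from the reference
    direction.  A color at the dataset mean has no direction and raises
    a degenerate-vector error (scalar input) / yields NaN (array input).
    """
    lab = np.asarray(lab, dtype=float)
    pc = (lab - plane.mean) @ plane.components.T
    if pc.ndim == 1:
        return pc, angle_of(pc)
    norms = np.linalg.norm(pc, axis=-1)
    angles = np.full(pc.shape[0], np.nan)
    ok = norms >= DEGENERATE_NORM
    if ok.any():
        angles[ok] = np.atleast_1d(angle_of(pc[ok]))
    return pc, angles


def load_colors(path) -> pd.DataFrame:
    """Read a ``date,r,g,b`` CSV; dates parsed as ISO year-month.

    Duplicate or unparsable months raise; missing months are left as
    gaps (no imputation) but reported via the frame's attrs.
    """
    df = pd.read_csv(path)
    required = {"date", "r", "g", "b"}
    if not required.issubset(df.columns):
        raise ValueError(f"input CSV must have columns {sorted(required)}")
    df = df.copy()
    df["date"] = pd.PeriodIndex(pd.to_datetime(df["date"].astype(str)), freq="M")
    if df["date"].duplicated().any():
        raise ValueError("duplicate months in input")
    df = df.sort_values("date").reset_index(drop=True)
    full = pd.period_range(df["date"].iloc[0], df["date"].iloc[-1], freq="M")
    df.attrs["missing_months"] = [str(p) for p in full.difference(df["date"])]
    return df


def moving_vector_sum(angles_turns, dates=None, bin_months: int = 8) -> pd.DataFrame:
    """Trailing moving vector sum of unit color vectors over
    ``bin_months`` entries.

    Returns a frame with the window-end date (when given), trend angle
    (turns), the window resultant length, and the per-step change speed
    (units of pi; NaN for the first window).
    """
    a = np.asarray(angles_turns, dtype=float)
    if bin_months > a.size:
        raise ValueError("bin longer than the series")
    units = unit_from_angle(a)
    sums = moving_vector_sum_smooth(units, bin_months)
    norms = np.linalg.norm(sums, axis=-1)
    angles = np.full(sums.shape[0], np.nan)
    ok = norms >= DEGENERATE_NORM
    if ok.any():
        angles[ok] = np.atleast_1d(angle_of(sums[ok]))
    cs = np.concatenate([[np.nan], change_speed(sums)]) if sums.shape[0] > 1 else [np.nan]
    out = pd.DataFrame(
        {
            "trend_angle_turns": angles,
            "resultant_length": norms,
            "change_speed": cs,
        }
    )
    out.attrs["trend_vectors"] = sums
    if dates is not None:
        out.insert(0, "date", np.asarray(dates)[bin_months - 1 :])
    return out


def pipeline(df: pd.DataFrame, plane: PcaPlane | None = None,
             bin_months: int = 8) -> tuple[pd.DataFrame, PcaPlane]:
    """Full single-series pipeline: RGB -> Lab -> PCA plane -> angles ->
    moving trend.  A shared ``plane`` (e.g. fitted on colors pooled over
    magazines) may be passed in; otherwise it is fitted on this series.
    """
    labs = rgb_to_lab(df[["r", "g", "b"]].to_numpy())
    if plane is None:
        plane = fit_plane(labs)
    _, angles = project(labs, plane)
    trend = moving_vector_sum(angles, dates=df["date"].astype(str).to_numpy(),
                              bin_months=bin_months)
    return trend, plane


def cross_series_uniformity(series: list[pd.DataFrame], rng=None):
    """Coherence of trends across magazines: per-month uniformity of the
    magazines' unit trend vectors, compared against time-shuffled series.

    All frames must share identical ``date`` columns.  Returns
    ``(per-month uniformity, shuffled per-month uniformity, rank-sum test)``
    with the test two-sided (coherence could fall either way).
    """
    from .analysis import wilcoxon_rank_sum

    if len(series) < 2:
        raise ValueError("need at least two aligned series")
    dates = series[0]["date"].to_numpy()
    for s in series[1:]:
        if not np.array_equal(s["date"].to_numpy(), dates):
            raise ValueError("series are not aligned on dates")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    angles = np.vstack([s["trend_angle_turns"].to_numpy() for s in series])  # (k, n)
    units = unit_from_angle(angles)
    emp = np.array([uniformity_of(units[:, t]) for t in range(units.shape[1])])
    shuffled = units[
        np.arange(len(series))[:, None],
        np.vstack([rng.permutation(units.shape[1]) for _ in series]),
    ]
    shuf = np.array([uniformity_of(shuffled[:, t]) for t in range(units.shape[1])])
    test = wilcoxon_rank_sum(emp[~np.isnan(emp)], shuf[~np.isnan(shuf)])
    return emp, shuf, test


def generate_fixture(
    months: int = 268,
    start: str = "2000-01",
    regime: str = "walk",
    step_sd_turns: float = 0.02,
    jump_rate: float = 0.05,
    cluster_angles=(0.08, 0.45, 0.80),
    cluster_pull: float = 0.0,
    radius: float = 40.0,
    lightness: float = 60.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic monthly cover-color sequence (stand-in for the
    non-deposited magazine data).

    ``walk`` is a circular random walk with small Gaussian steps (long
    low-change phases) plus Poisson-thinned uniform jumps at
    ``jump_rate`` per month (short high-change bursts); a nonzero
    ``cluster_pull`` attracts the walk toward a few fixed hue clusters.
    ``iid`` draws independent angles each month (null control).  Angles
    are laid out on a circle of ``radius`` in the (a*, b*) plane at
    fixed ``lightness`` and emitted as in-gamut RGB.
    """
    rng = np.random.default_rng(seed)
    if regime == "iid":
        angles = rng.random(months)
    elif regime == "walk":
        angles = np.empty(months)
        angles[0] = rng.random()
        steps = rng.normal(0.0, step_sd_turns, size=months - 1)
        jumps = rng.random(months - 1) < jump_rate
        jump_to = rng.random(months - 1)
        for t in range(1, months):
            if jumps[t - 1]:
                angles[t] = jump_to[t - 1]
                continue
            a = angles[t - 1] + steps[t - 1]
            if cluster_pull > 0.0:
                diffs = (np.asarray(cluster_angles) - a + 0.5) % 1.0 - 0.5
                nearest = diffs[np.argmin(np.abs(diffs))]
                a += cluster_pull * nearest
            angles[t] = a % 1.0
    else:
        raise ValueError(f"unknown regime {regime!r}")
    pc = radius * unit_from_angle(angles)
    labs = np.column_stack([np.full(months, lightness), pc[:, 0], pc[:, 1]])
    rgbs = lab_to_rgb(labs)
    dates = pd.period_range(start, periods=months, freq="M").astype(str)
    return pd.DataFrame({"date": dates, "r": rgbs[:, 0], "g": rgbs[:, 1], "b": rgbs[:, 2]})
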