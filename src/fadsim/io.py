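"""Writers for the tabular outputs (UTF-8 CSV with header row, JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .colorspace import DEGENERATE_NORM, angle_of
from .engine import SimulationResult
from .metrics import TrendSeries

__all__ = ["write_choices", "write_summary", "write_trends", "write_impact", "write_sweep"]


def write_choices(result: SimulationResult, path) -> pd.DataFrame:
    """``choices.csv``: one row per (trial, agent) with the displayed
    color's angle (turns) and vector length."""
    n_t, n, _ = result.choices.shape
    flat = result.choices.reshape(-1, 2)
    norms = np.linalg.norm(flat, axis=-1)
    angles = np.full(flat.shape[0], np.nan)
    ok = norms >= DEGENERATE_NORM
    if ok.any():
        angles[ok] = np.atleast_1d(angle_of(flat[ok]))
    df = pd.DataFrame(
        {
            "trial": np.repeat(np.arange(n_t), n),
            "agent_id": np.tile(np.arange(n), n_t),
            "group_id": np.tile(result.group_id, n_t),
            "angle_turns": angles,
            "vector_length": norms,
        }
    )
    df.to_csv(path, index=False)
    return df


def write_summary(result: SimulationResult, path, runtime_s: float | None = None) -> dict:
    """``summary.json``: the full configuration echoed for provenance,
    plus run diagnostics."""
    summary = {
        "config": result.config.to_dict(),
        "seed": result.config.seed,
        "runtime_s": runtime_s,
        "n_degenerate_choices": int(result.n_degenerate),
    }
    Path(path).write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    return summary


def write_trends(ts: TrendSeries, path) -> pd.DataFrame:
    """``trends.csv``: per-trial trend angle, uniformity and change speed
    (change speed of trial t is the step from t to t+1; last row NaN)."""
    n_t = ts.uniformity.shape[0]
    df = pd.DataFrame(
        {
            "trial": np.arange(n_t),
            "trend_angle_turns": ts.trend_angle,
            "uniformity": ts.uniformity,
            "change_speed": np.concatenate([ts.change_speed, [np.nan]]),
        }
    )
    df.to_csv(path, index=False)
    return df


def write_impact(impact: np.ndarray, path) -> pd.DataFrame:
    """``impact.csv``: long-format per-trial per-agent impact index."""
    n_t, n = impact.shape
    df = pd.DataFrame(
        {
            "trial": np.repeat(np.arange(n_t), n),
            "agent_id": np.tile(np.arange(n), n_t),
            "impact": impact.reshape(-1),
        }
    )
    df.to_csv(path, index=False)
    return df


def write_sweep(sw, path) -> pd.DataFrame:
    """``sweep.csv``: one row per (m, x0) cell."""
    rows = []
    for i, m in enumerate(sw.m_grid):
        for j, x0 in enumerate(sw.x0_grid):
            rows.append(
                {
                    "m": int(m),
                    "x0": float(x0),
                    "overlay_fraction": sw.overlay_fraction,
                    "max_uniformity": sw.max_uniformity[i, j],
                    "mean_change_speed": sw.mean_change_speed[i, j],
                    "seed": int(sw.seeds[i, j]),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
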