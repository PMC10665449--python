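"""Reference implementations used only by the test suite.

``naive_simulate`` is a literal, loop-based transcription of the model's
per-trial update rules (initialize unit memories; choice = memory sum;
drift/bias; sample a partner; weight by the boredom sigmoid of the
angular difference; store, dropping the oldest).  It shares the
engine's random-stream discipline (three child streams of the master
seed; partner draws in (trial, agent-index) order) and stores memory in
a fixed-size slot array replacing the oldest entry, so that floating
point summation order matches and results can be compared bit for bit.

Also here: the turn-difference fold/double formulation of change speed
and the closed-form Rayleigh expectation for the mean resultant length
of random unit vectors.
"""

from __future__ import annotations

import numpy as np

from fadsim.colorspace import rotate_clockwise, unit_from_angle

DEG = 1e-12


def _norm(v):
    # axis-form norm to match the engine's vectorized code path bit for bit
    return float(np.linalg.norm(v[None, :], axis=-1)[0])


def _unit(v, fallback, rng_fb):
    n = _norm(v)
    if n >= DEG:
        return v / n, 0
    nf = _norm(fallback)
    if nf >= DEG:
        return fallback / nf, 1
    return unit_from_angle(rng_fb.random()), 1


def naive_simulate(cfg):
    """Literal small-scale simulation; refuses sizes beyond 5 agents or
    10 trials.  Returns (choices, partners, weights) arrays."""
    n, m, n_t = cfg.n_agents, cfg.m, cfg.n_trials
    if n > 5 or n_t > 10:
        raise ValueError("naive oracle is limited to n_agents <= 5, n_trials <= 10")
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_init, rng_partner, rng_fb = (np.random.default_rng(s) for s in ss)

    gids = cfg.group_ids()
    groups = [cfg.groups[g] for g in gids]
    pop_w = [g.popularity_weight for g in groups]

    # Step 0: every memory slot holds a unit vector at a random angle
    mem = [[None] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            mem[i][j] = unit_from_angle(rng_init.random())
    mem = [np.stack(rows) for rows in mem]  # (m, 2) slot arrays
    head = m - 1

    choices = np.empty((n_t, n, 2))
    partners = np.empty((n_t, n), dtype=np.int64)
    weights = np.empty((n_t, n))
    s_prev = {}
    sequential = cfg.update_mode == "sequential"

    for t in range(n_t):
        raw = np.stack([np.sum(mem[i], axis=0) for i in range(n)])
        disp = _apply_drift_bias(raw, cfg, gids, s_prev)
        head_next = (head + 1) % m

        if not sequential:
            newest = [mem[i][head].copy() for i in range(n)]
            dirs = []
            for i in range(n):
                d_i, _ = _unit(disp[i], newest[i], rng_fb)
                dirs.append(d_i)
            new_heads = []
            for i in range(n):
                u = rng_partner.random()
                p = _cdf_partner(u, i, pop_w)
                cos_d = float(np.clip(np.sum(dirs[i] * dirs[p]), -1.0, 1.0))
                d = np.arccos(cos_d) / np.pi
                w = 1.0 / (1.0 + np.exp(-groups[i].slope * (d - groups[i].x0)))
                new_heads.append(w * dirs[p])
                partners[t, i] = p
                weights[t, i] = w
                choices[t, i] = disp[i]
            for i in range(n):
                mem[i][head_next] = new_heads[i]
        else:
            for i in range(n):
                y_i = _seq_choice(mem[i], i, cfg, gids, disp, raw)
                choices[t, i] = y_i
                u = rng_partner.random()
                p = _cdf_partner(u, i, pop_w)
                z = _seq_choice(mem[p], p, cfg, gids, disp, raw)
                p_head = head_next if p < i else head
                dir_y, _ = _unit(y_i, mem[i][head], rng_fb)
                dir_z, _ = _unit(z, mem[p][p_head], rng_fb)
                cos_d = float(np.clip(np.dot(dir_y, dir_z), -1.0, 1.0))
                d = np.arccos(cos_d) / np.pi
                w = 1.0 / (1.0 + np.exp(-groups[i].slope * (d - groups[i].x0)))
                mem[i][head_next] = w * dir_z
                partners[t, i] = p
                weights[t, i] = w
        head = head_next
    return choices, partners, weights


def _cdf_partner(u, i, pop_w):
    w = np.array(pop_w, dtype=float)
    w[i] = 0.0
    cdf = np.cumsum(w)
    for j in range(len(w)):
        if cdf[j] > u * cdf[-1]:
            return j
    return len(w) - 1


def _apply_drift_bias(raw, cfg, gids, s_prev):
    y = raw.copy()
    for g_idx, g in enumerate(cfg.groups):
        if g.drift_deg != 0.0:
            for i in np.flatnonzero(gids == g_idx):
                y[i] = rotate_clockwise(y[i], g.drift_deg)
    for g_idx, g in enumerate(cfg.groups):
        if not g.uniform_bias:
            continue
        rows = np.flatnonzero(gids == g_idx)
        s_ref = s_prev.get(g_idx)
        if s_ref is None:
            s_ref = _member_unit_sum(y[rows])
        ns = np.linalg.norm(s_ref)
        if ns >= DEG:
            members = y[rows]
            norms = np.linalg.norm(members, axis=-1)
            y[rows] = members + 0.4 * norms[:, None] * (s_ref / ns)[None, :]
        s_prev[g_idx] = _member_unit_sum(y[rows])
    return y


def _member_unit_sum(members):
    norms = np.linalg.norm(members, axis=-1)
    ok = norms >= DEG
    return (members[ok] / norms[ok, None]).sum(axis=0) if ok.any() else np.zeros(2)


def _seq_choice(mem_i, i, cfg, gids, disp_frozen, raw_frozen):
    g = cfg.groups[gids[i]]
    y = np.sum(mem_i, axis=0)
    if g.drift_deg != 0.0:
        y = rotate_clockwise(y, g.drift_deg)
    if g.uniform_bias:
        y = y + (disp_frozen[i] - rotate_clockwise(raw_frozen[i], g.drift_deg))
    return y


# ---------------------------------------------------------------------------
# independent formulations used as numeric cross-checks


def fold_double_change_speed(angles_turns):
    """Turn-difference formulation of trend change speed: absolute
    angle difference in turns, differences above half a turn folded as
    1 - diff, then doubled to express the result in units of pi."""
    a = np.asarray(angles_turns, dtype=float)
    diff = np.abs(np.diff(a))
    folded = np.where(diff > 0.5, 1.0 - diff, diff)
    return 2.0 * folded


def rayleigh_expected_resultant(n):
    """Expected mean resultant length of n i.i.d. uniform unit vectors:
    sqrt(pi) / (2 sqrt(n)) for large n."""
    return np.sqrt(np.pi) / (2.0 * np.sqrt(n))
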