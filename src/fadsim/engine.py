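"""Agent-based simulator of boredom-driven collective color choice.

Each agent carries a FIFO memory of the last ``m`` sampled colors and
chooses, on every trial, the vector sum of that memory.  It then samples
the displayed choice of one random other agent and stores it, scaled by
a sigmoid *boredom weight* of the angular difference ``d`` between its
own choice and the sample:

    w(d) = 1 / (1 + exp(-slope * (d - x0)))        slope fixed at 20

A high shift ``x0`` means only very novel samples (large ``d``) receive
substantial weight — the agent is easily bored by familiar colors.
Heterogeneous populations assign groups of agents different ``x0``,
sampling popularity, a per-trial clockwise drift of their displayed
choice, or a bias pulling members toward their subgroup's summed color.

Two update disciplines are provided.  ``synchronous`` (default) freezes
every displayed choice at the start of a trial; all samples are read
from that frozen set and all memory writes land afterwards.
``sequential`` processes agents in index order, each sampling the
recomputed current choice of its partner (which may already have been
updated on this trial).  Both modes consume partner draws from a single
stream in (trial, agent-index) order, so runs are comparable seed for
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import colorspace
from .colorspace import DEGENERATE_NORM, rotate_clockwise, unit_from_angle

__all__ = [
    "BoredomFunction",
    "GroupSpec",
    "AgentState",
    "PopulationConfig",
    "SimulationResult",
    "ConfigurationError",
    "boredom_weight",
    "initialize_population",
    "choose_color",
    "apply_drift_and_bias",
    "sample_partner",
    "update_memory",
    "run_simulation",
]

SIGMOID_SLOPE = 20.0
BIAS_FACTOR = 0.4


class ConfigurationError(ValueError):
    """Invalid population configuration."""


@dataclass(frozen=True)
class BoredomFunction:
    """Sigmoid decision weight ``w(d)`` with horizontal shift ``x0``.

    ``x0`` is the difference value (in units of pi) at which the weight
    crosses 0.5; the slope is fixed so that only the horizontal shift is
    varied between conditions.
    """

    x0: float
    slope: float = SIGMOID_SLOPE

    def __post_init__(self):
        if not 0.0 < self.x0 < 1.0:
            raise ConfigurationError(f"x0 must lie in (0, 1), got {self.x0}")

    def __call__(self, d):
        return boredom_weight(d, self)


def boredom_weight(d, f: BoredomFunction):
    """Evaluate the boredom sigmoid at difference ``d`` (units of pi)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0.0) or np.any(d > 1.0):
        raise ValueError("difference d must lie in [0, 1] (units of pi)")
    w = 1.0 / (1.0 + np.exp(-f.slope * (d - f.x0)))
    return float(w) if w.ndim == 0 else w


@dataclass(frozen=True)
class GroupSpec:
    """One homogeneous block of agents within the population."""

    fraction: float
    x0: float
    popularity_weight: float = 1.0
    drift_deg: float = 0.0
    uniform_bias: bool = False
    slope: float = SIGMOID_SLOPE  # expert override; fixed in all reported regimes

    def boredom(self) -> BoredomFunction:
        return BoredomFunction(self.x0, self.slope)


@dataclass
class AgentState:
    """Memory and attributes of a single agent.

    ``memory`` has shape ``(m, 2)`` with row 0 the newest entry.  Stored
    vectors have length in ``(0, 1]``: unit at initialization, ``w(d)``
    times a unit direction thereafter.
    """

    memory: np.ndarray
    boredom: BoredomFunction
    popularity_weight: float = 1.0
    drift_deg: float = 0.0
    uniform_bias: bool = False
    group_id: int = 0


@dataclass(frozen=True)
class PopulationConfig:
    """Complete description of one simulation experiment."""

    n_agents: int
    n_trials: int
    m: int
    groups: tuple = (GroupSpec(fraction=1.0, x0=0.7),)
    seed: int = 0
    update_mode: str = "synchronous"

    def __post_init__(self):
        if self.n_agents < 2:
            raise ConfigurationError("need at least 2 agents")
        if self.m < 1 or self.n_trials < 1:
            raise ConfigurationError("m and n_trials must be >= 1")
        if self.update_mode not in ("synchronous", "sequential"):
            raise ConfigurationError(f"unknown update_mode {self.update_mode!r}")
        groups = tuple(
            g if isinstance(g, GroupSpec) else GroupSpec(**g) for g in self.groups
        )
        object.__setattr__(self, "groups", groups)
        if not groups:
            raise ConfigurationError("at least one group required")
        if abs(sum(g.fraction for g in groups) - 1.0) > 1e-9:
            raise ConfigurationError("group fractions must sum to 1")
        for g in groups:
            g.boredom()  # validates x0
            if g.popularity_weight <= 0:
                raise ConfigurationError("popularity_weight must be > 0")
        if any(s <= 0 for s in self.group_sizes()):
            raise ConfigurationError("every group must receive at least one agent")

    def group_sizes(self) -> list[int]:
        """Agents per group: fraction * n rounded to nearest (ties up);
        any rounding remainder is absorbed by the last group."""
        sizes = [int(np.floor(g.fraction * self.n_agents + 0.5)) for g in self.groups]
        sizes[-1] += self.n_agents - sum(sizes)
        return sizes

    def group_ids(self) -> np.ndarray:
        """Group index per agent; groups occupy contiguous index blocks."""
        return np.repeat(np.arange(len(self.groups)), self.group_sizes())

    def to_dict(self) -> dict:
        return {
            "n_agents": self.n_agents,
            "n_trials": self.n_trials,
            "m": self.m,
            "seed": self.seed,
            "update_mode": self.update_mode,
            "groups": [
                {
                    "fraction": g.fraction,
                    "x0": g.x0,
                    "popularity_weight": g.popularity_weight,
                    "drift_deg": g.drift_deg,
                    "uniform_bias": g.uniform_bias,
                }
                for g in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        d["groups"] = tuple(GroupSpec(**g) for g in d.get("groups", ()))
        return cls(**d)


@dataclass
class SimulationResult:
    """Recorded displayed choices plus the sampling log.

    ``choices[t, i]`` is agent ``i``'s displayed (post-drift, post-bias)
    color vector on trial ``t``.  ``partners[t, j]`` is the agent whose
    color ``j`` sampled, and ``sample_weights[t, j]`` the boredom weight
    ``j`` attributed to that sample — together the log needed for the
    per-agent impact index.
    """

    config: PopulationConfig
    choices: np.ndarray  # (n_trials, n_agents, 2)
    group_id: np.ndarray  # (n_agents,)
    partners: np.ndarray  # (n_trials, n_agents) int
    sample_weights: np.ndarray  # (n_trials, n_agents)
    n_degenerate: int = 0

    def agents_in_group(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.group_id == group)


# ---------------------------------------------------------------------------
# single-agent operations


def initialize_population(cfg: PopulationConfig, rng: np.random.Generator):
    """Fill every agent's memory with ``m`` unit vectors at uniformly
    random angles.  Draw order is (agent, slot), row-major."""
    angles = rng.random((cfg.n_agents, cfg.m))
    mem = unit_from_angle(angles)
    gids = cfg.group_ids()
    agents = []
    for i in range(cfg.n_agents):
        g = cfg.groups[gids[i]]
        agents.append(
            AgentState(
                memory=mem[i].copy(),
                boredom=g.boredom(),
                popularity_weight=g.popularity_weight,
                drift_deg=g.drift_deg,
                uniform_bias=g.uniform_bias,
                group_id=int(gids[i]),
            )
        )
    return agents


def choose_color(a: AgentState) -> np.ndarray:
    """Raw choice: the vector sum of the agent's memory (no normalization)."""
    return np.sum(a.memory, axis=0)


def apply_drift_and_bias(y: np.ndarray, a: AgentState, s_sub=None) -> np.ndarray:
    """Displayed choice: rotate by the agent's drift, then (if the agent
    carries the uniformity bias) add 40% of the choice's length in the
    direction of the subgroup's summed vector ``s_sub``.

    ``s_sub`` is the subgroup's summed displayed vector from the
    previous trial (unit-normalized members); on the first trial the
    current trial's pre-bias vector seeds it.  A zero-length ``s_sub``
    skips the bias term for this trial.
    """
    y = rotate_clockwise(np.asarray(y, dtype=float), a.drift_deg)
    if a.uniform_bias and s_sub is not None:
        ns = np.linalg.norm(s_sub)
        if ns >= DEGENERATE_NORM:
            y = y + BIAS_FACTOR * np.linalg.norm(y) * (np.asarray(s_sub) / ns)
    return y


def _partner_from_uniform(u: float, i: int, weights: np.ndarray) -> int:
    """Invert the popularity CDF over partners ``j != i`` at quantile ``u``."""
    w = np.array(weights, dtype=float)
    w[i] = 0.0
    cdf = np.cumsum(w)
    return int(np.argmax(cdf > u * cdf[-1]))


def sample_partner(i: int, weights, rng: np.random.Generator) -> int:
    """Draw a partner ``i* != i`` with probability proportional to the
    partners' popularity weights.  Consumes exactly one uniform."""
    return _partner_from_uniform(rng.random(), i, np.asarray(weights, dtype=float))


def update_memory(a: AgentState, z: np.ndarray, own_y: np.ndarray) -> AgentState:
    """Store the sampled color, weighted by boredom, dropping the oldest.

    The sampled vector is unit-normalized before weighting, so the
    stored length is exactly ``w(d)`` where ``d`` is the angular
    difference between the agent's own displayed choice and the sample.
    """
    z = np.asarray(z, dtype=float)
    d = colorspace.angular_difference(own_y, z)
    head = a.boredom(d) * (z / np.linalg.norm(z))
    memory = np.vstack([head[None, :], a.memory[:-1]])
    return replace(a, memory=memory)


# ---------------------------------------------------------------------------
# full simulation


def _directions(vectors: np.ndarray, fallback_dirs: np.ndarray, rng_fb) -> tuple:
    """Unit directions for each row of ``vectors``.

    Rows of (near-)zero length fall back to the matching row of
    ``fallback_dirs`` (the agent's newest memory direction); if that is
    degenerate too, a random unit direction is drawn.  Returns the
    directions and the number of degenerate rows encountered.
    """
    norms = np.linalg.norm(vectors, axis=-1)
    bad = norms < DEGENERATE_NORM
    safe = np.where(bad, 1.0, norms)
    dirs = vectors / safe[:, None]
    n_bad = int(bad.sum())
    if n_bad:
        for i in np.flatnonzero(bad):
            fb = fallback_dirs[i]
            nfb = np.linalg.norm(fb)
            if nfb >= DEGENERATE_NORM:
                dirs[i] = fb / nfb
            else:
                dirs[i] = unit_from_angle(rng_fb.random())
    return dirs, n_bad


def _unit_sum(members: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(members, axis=-1)
    ok = norms >= DEGENERATE_NORM
    return (members[ok] / norms[ok, None]).sum(axis=0) if ok.any() else np.zeros(2)


def _displayed(raw: np.ndarray, cfg, gids, log, s_prev: dict) -> np.ndarray:
    """Apply per-group drift and uniformity bias to raw choices.

    The bias pulls each member toward the subgroup's summed displayed
    vector from the previous trial (``s_prev``, seeded with the current
    pre-bias vector on the first trial), so a drifting subgroup's
    attractor carries the accumulated rotation from trial to trial.
    ``s_prev`` is updated in place with this trial's post-bias vectors.
    """
    y = raw
    for g_idx, g in enumerate(cfg.groups):
        if g.drift_deg != 0.0:
            rows = gids == g_idx
            y = y.copy() if y is raw else y
            y[rows] = rotate_clockwise(y[rows], g.drift_deg)
    for g_idx, g in enumerate(cfg.groups):
        if not g.uniform_bias:
            continue
        rows = np.flatnonzero(gids == g_idx)
        members = y[rows]
        s_ref = s_prev.get(g_idx)
        if s_ref is None:
            s_ref = _unit_sum(members)
        ns = np.linalg.norm(s_ref)
        if ns >= DEGENERATE_NORM:
            y = y.copy() if y is raw else y
            norms = np.linalg.norm(members, axis=-1)
            y[rows] = members + BIAS_FACTOR * norms[:, None] * (s_ref / ns)[None, :]
        else:
            log["bias_skipped"] += 1
        s_prev[g_idx] = _unit_sum(y[rows])
    return y


def run_simulation(cfg: PopulationConfig) -> SimulationResult:
    """Run the full model and return the recorded choices + sampling log.

    Deterministic given ``cfg`` (including its seed): three independent
    child streams are derived from the master seed — memory
    initialization, partner draws, and the (rare) degenerate-direction
    fallback — so that partner sampling is unaffected by fallback use.
    """
    n, m, n_t = cfg.n_agents, cfg.m, cfg.n_trials
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_init, rng_partner, rng_fb = (np.random.default_rng(s) for s in ss)

    mem = unit_from_angle(rng_init.random((n, m)))  # (n, m, 2)
    head = m - 1  # index of newest entry; next write overwrites the oldest
    gids = cfg.group_ids()
    pop_w = np.repeat([g.popularity_weight for g in cfg.groups], cfg.group_sizes())
    uniform_pop = np.allclose(pop_w, pop_w[0])
    if not uniform_pop:
        W = np.tile(pop_w, (n, 1))
        np.fill_diagonal(W, 0.0)
        Wcdf = np.cumsum(W, axis=1)

    choices = np.empty((n_t, n, 2))
    partners = np.empty((n_t, n), dtype=np.int64)
    weights_log = np.empty((n_t, n))
    log = {"degenerate": 0, "bias_skipped": 0}
    s_prev: dict = {}
    slopes = np.repeat([g.slope for g in cfg.groups], cfg.group_sizes())
    x0s = np.repeat([g.x0 for g in cfg.groups], cfg.group_sizes())
    sequential = cfg.update_mode == "sequential"

    for t in range(n_t):
        raw = mem.sum(axis=1)
        disp = _displayed(raw, cfg, gids, log, s_prev)
        newest = mem[:, head, :]
        if not sequential:
            choices[t] = disp
            u = rng_partner.random(n)
            if uniform_pop:
                idx = np.minimum((u * (n - 1)).astype(np.int64), n - 2)
                ptn = idx + (idx >= np.arange(n))
            else:
                ptn = (Wcdf > (u * Wcdf[:, -1])[:, None]).argmax(axis=1)
            dirs, n_bad = _directions(disp, newest, rng_fb)
            log["degenerate"] += n_bad
            cos_d = np.clip(np.sum(dirs * dirs[ptn], axis=-1), -1.0, 1.0)
            d = np.arccos(cos_d) / np.pi
            w = 1.0 / (1.0 + np.exp(-slopes * (d - x0s)))
            head = (head + 1) % m
            mem[:, head, :] = w[:, None] * dirs[ptn]
            partners[t] = ptn
            weights_log[t] = w
        else:
            # bias term frozen at trial start (disp above); partners'
            # choices are recomputed from their current memories
            head_next = (head + 1) % m
            for i in range(n):
                y_i = _seq_displayed(mem, i, cfg, gids, disp, raw)
                choices[t, i] = y_i
                u = float(rng_partner.random())
                if uniform_pop:
                    idx = min(int(u * (n - 1)), n - 2)
                    ptn_i = idx + (idx >= i)
                else:
                    ptn_i = int(np.argmax(Wcdf[i] > u * Wcdf[i, -1]))
                z = _seq_displayed(mem, ptn_i, cfg, gids, disp, raw)
                pair = np.vstack([y_i, z])
                # newest entry of an already-updated partner sits at head_next
                ptn_head = head_next if ptn_i < i else head
                fb = np.vstack([mem[i, head], mem[ptn_i, ptn_head]])
                dirs, n_bad = _directions(pair, fb, rng_fb)
                log["degenerate"] += n_bad
                cos_d = np.clip(float(np.dot(dirs[0], dirs[1])), -1.0, 1.0)
                d = np.arccos(cos_d) / np.pi
                w = 1.0 / (1.0 + np.exp(-slopes[i] * (d - x0s[i])))
                mem[i, head_next, :] = w * dirs[1]
                partners[t, i] = ptn_i
                weights_log[t, i] = w
            head = head_next

    return SimulationResult(
        config=cfg,
        choices=choices,
        group_id=gids,
        partners=partners,
        sample_weights=weights_log,
        n_degenerate=log["degenerate"],
    )


def _seq_displayed(mem, i, cfg, gids, disp_frozen, raw_frozen):
    """Current displayed choice of agent ``i`` in sequential mode.

    Recomputed from ``i``'s current memory; drift is re-applied, while
    the uniformity-bias displacement is taken from the trial-start
    frozen pass (``disp_frozen - raw-with-drift``) to avoid a
    within-trial feedback loop.
    """
    g = cfg.groups[gids[i]]
    y = np.sum(mem[i], axis=0)
    if g.drift_deg != 0.0:
        y = rotate_clockwise(y, g.drift_deg)
    if g.uniform_bias:
        drifted_frozen = rotate_clockwise(raw_frozen[i], g.drift_deg)
        y = y + (disp_frozen[i] - drifted_frozen)
    return y
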