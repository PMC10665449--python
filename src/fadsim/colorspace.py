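"""Circular color-vector algebra.

Colors are points on a circle, represented as two-component vectors
``[c1, c2]``.  A color's *angle* is measured clockwise from the fixed
reference direction ``[0, 1]`` and is stored as a turn fraction in
``[0, 1)`` (so ``[1, 0]`` sits at 0.25 turns and ``[0, -1]`` at 0.5).
Dissimilarity between two colors is the unsigned arc angle between their
vectors, reported in units of pi so that diametral colors are maximally
different with a value of 1.

All functions are vectorized over a trailing axis of size 2: inputs may
be a single vector of shape ``(2,)`` or a stack of shape ``(..., 2)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateVectorError",
    "angle_of",
    "unit_from_angle",
    "angular_difference",
    "rotate_clockwise",
]

#: Vectors shorter than this are considered degenerate (no direction).
DEGENERATE_NORM = 1e-12


class DegenerateVectorError(ValueError):
    """A direction was requested from a (near-)zero-length vector."""


def _as_vectors(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 2:
        raise ValueError(f"expected trailing axis of size 2, got shape {v.shape}")
    return v


def angle_of(v) -> np.ndarray | float:
    """Clockwise angle of ``v`` from the reference direction ``[0, 1]``.

    Returns the angle as a turn fraction in ``[0, 1)``.  Raises
    :class:`DegenerateVectorError` for zero-length input; callers that
    need a fallback direction must supply one themselves.
    """
    v = _as_vectors(v)
    norms = np.linalg.norm(v, axis=-1)
    if np.any(norms < DEGENERATE_NORM):
        raise DegenerateVectorError("zero-length vector has no angle")
    # atan2(c1, c2) measures clockwise from [0, 1]: [1,0] -> +pi/2.
    turns = np.arctan2(v[..., 0], v[..., 1]) / (2.0 * np.pi)
    turns = np.mod(turns, 1.0)
    # mod can return 1.0 for angles within rounding of a full turn
    turns = np.where(turns >= 1.0, 0.0, turns)
    return float(turns) if turns.ndim == 0 else turns


def unit_from_angle(turns) -> np.ndarray:
    """Unit vector at clockwise angle ``turns`` (turn fractions) from ``[0, 1]``."""
    turns = np.asarray(turns, dtype=float)
    phi = 2.0 * np.pi * turns
    return np.stack([np.sin(phi), np.cos(phi)], axis=-1)


def angular_difference(y, z) -> np.ndarray | float:
    """Unsigned arc angle between ``y`` and ``z`` in units of pi.

    The result lies in ``[0, 1]``: 0 for parallel vectors, 1 for
    diametral ones.  Invariant under positive rescaling of either
    argument.  Raises :class:`DegenerateVectorError` if either vector is
    (near) zero.
    """
    y = _as_vectors(y)
    z = _as_vectors(z)
    ny = np.linalg.norm(y, axis=-1)
    nz = np.linalg.norm(z, axis=-1)
    if np.any(ny < DEGENERATE_NORM) or np.any(nz < DEGENERATE_NORM):
        raise DegenerateVectorError("angular difference of zero-length vector")
    cos_delta = np.clip(np.sum(y * z, axis=-1) / (ny * nz), -1.0, 1.0)
    d = np.arccos(cos_delta) / np.pi
    return float(d) if d.ndim == 0 else d


def rotate_clockwise(v, deg) -> np.ndarray:
    """Rotate ``v`` clockwise by ``deg`` degrees, preserving length."""
    v = _as_vectors(v)
    phi = np.deg2rad(deg)
    c, s = np.cos(phi), np.sin(phi)
    return np.stack(
        [c * v[..., 0] + s * v[..., 1], -s * v[..., 0] + c * v[..., 1]],
        axis=-1,
    )
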