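"""Shared errors and small geometric helpers."""

from __future__ import annotations

import numpy as np


class GeometryError(ValueError):
    """Raised when an input geometry violates a precondition."""


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a ratio's denominator is zero (names the offending item)."""


def as_points(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise GeometryError(f"expected an (N, 2) coordinate array, got shape {v.shape}")
    return v


def polyline_length(vertices) -> float:
    v = as_points(vertices)
    return float(np.sum(np.hypot(*np.diff(v, axis=0).T)))


def point_line_distance(p, a, b) -> float:
    """Perpendicular distance from ``p`` to the infinite line through ``a`` and ``b``.

    Equivalent to |ax+by+c| / sqrt(a^2+b^2) for the line's implicit form.
    """
    p, a, b = (np.asarray(x, dtype=float) for x in (p, a, b))
    ab = b - a
    n = np.hypot(*ab)
    if n == 0:
        raise GeometryError("line endpoints coincide")
    ap = p - a
    return float(abs(ab[0] * ap[1] - ab[1] * ap[0]) / n)


def circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean array.

    Returns (start, length) pairs; a run may wrap past the end.  If every
    element is True a single full-length run is returned.
    """
    mask = np.asarray(mask, dtype=bool)
    n = mask.size
    if n == 0 or not mask.any():
        return []
    if mask.all():
        return [(0, n)]
    # rotate so position 0 is False, then runs cannot straddle the seam
    first_false = int(np.argmin(mask))
    rolled = np.roll(mask, -first_false)
    edges = np.flatnonzero(np.diff(np.concatenate([[False], rolled, [False]]).astype(int)))
    starts, stops = edges[::2], edges[1::2]
    return [((int(s) + first_false) % n, int(e - s)) for s, e in zip(starts, stops)]


def run_indices(start: int, length: int, n: int) -> np.ndarray:
    """Vertex indices of a circular run."""
    return (start + np.arange(length)) % n
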