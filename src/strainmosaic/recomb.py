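"""Genetic-map interpolation.

A recombination map is a piecewise-linear rate function given as
``(position bp, rate cM/Mb)`` knots. Genetic positions are obtained by
trapezoid integration of the rate, which is exact for a linear rate
between knots; beyond the mapped range the terminal rates are held
constant.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cumulative_cM", "interval_cM"]


def _validate_map(recomb_map) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray([p for p, _ in recomb_map], dtype=float)
    rate = np.asarray([r for _, r in recomb_map], dtype=float)
    if pos.size == 0:
        raise ValueError("recombination map is empty")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("recombination map positions must be strictly increasing")
    if np.any(rate < 0):
        raise ValueError("recombination rates must be non-negative")
    return pos, rate


def cumulative_cM(positions, recomb_map) -> np.ndarray:
    """Genetic position in cM for each physical position (bp).

    The zero of the genetic scale is the first map knot; positions before
    it get (possibly negative) extrapolated values, which is harmless
    because only differences are ever used.
    """
    mpos, mrate = _validate_map(recomb_map)
    pos = np.atleast_1d(np.asarray(positions, dtype=float))

    if mpos.size == 1:
        return (pos - mpos[0]) / 1e6 * mrate[0]

    # cumulative cM at the knots (trapezoid over each segment)
    seg = np.diff(mpos) / 1e6 * (mrate[:-1] + mrate[1:]) / 2.0
    cum = np.concatenate([[0.0], np.cumsum(seg)])

    out = np.empty_like(pos)
    below = pos < mpos[0]
    above = pos >= mpos[-1]
    mid = ~(below | above)

    out[below] = (pos[below] - mpos[0]) / 1e6 * mrate[0]
    out[above] = cum[-1] + (pos[above] - mpos[-1]) / 1e6 * mrate[-1]

    if np.any(mid):
        i = np.searchsorted(mpos, pos[mid], side="right") - 1
        frac = (pos[mid] - mpos[i]) / (mpos[i + 1] - mpos[i])
        rate_at = mrate[i] + (mrate[i + 1] - mrate[i]) * frac
        out[mid] = cum[i] + (mrate[i] + rate_at) / 2.0 * (pos[mid] - mpos[i]) / 1e6
    return out


def interval_cM(positions, recomb_map) -> np.ndarray:
    """Genetic distance (cM) between consecutive physical positions."""
    return np.diff(cumulative_cM(positions, recomb_map))
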