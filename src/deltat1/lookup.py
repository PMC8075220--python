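"""Lookup-table inversion of the UNI image to a quantitative T1 map.

For a fixed protocol the UNI value is a smooth function of T1 which, over a
wide central range, is strictly monotone (decreasing for the default 7 T
protocol).  :func:`build_lookup` tabulates UNI on a dense T1 grid and keeps
only the largest strictly monotone branch; :func:`t1_from_uni` inverts it by
linear interpolation, clamping out-of-range UNI values to the branch edge
and flagging them for QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .protocol import SequenceProtocol
from .signal import simulate_signals, uni_from_signals

__all__ = ["LookupTable", "build_lookup", "t1_from_uni"]


@dataclass(frozen=True)
class LookupTable:
    """Tabulated UNI(T1) restricted to its largest strictly monotone branch.

    ``t1_grid`` is strictly ascending (seconds); ``uni_values`` are the
    corresponding UNI values, strictly monotone; ``valid_range`` is
    (min(uni), max(uni)) of the branch.
    """

    t1_grid: np.ndarray
    uni_values: np.ndarray
    valid_range: tuple[float, float]

    @property
    def step(self) -> float:
        """Nominal grid spacing in seconds."""
        return float(np.median(np.diff(self.t1_grid)))

    @property
    def t1_range(self) -> tuple[float, float]:
        return float(self.t1_grid[0]), float(self.t1_grid[-1])

    @property
    def decreasing(self) -> bool:
        return bool(self.uni_values[0] > self.uni_values[-1])


def _largest_monotone_branch(values: np.ndarray) -> slice:
    """Index slice of the longest run of strictly same-sign differences."""
    diffs = np.sign(np.diff(values))
    best_start, best_len = 0, 1
    start = 0
    for i in range(len(diffs)):
        if diffs[i] == 0 or (i > start and diffs[i] != diffs[start]):
            start = i
        if i - start + 2 > best_len:
            best_start, best_len = start, i - start + 2
    return slice(best_start, best_start + best_len)


def build_lookup(
    protocol: SequenceProtocol,
    t1_min: float = 0.3,
    t1_max: float = 5.0,
    step: float = 0.001,
    b1_scale: float = 1.0,
) -> LookupTable:
    """Tabulate UNI versus T1 and retain the largest strictly monotone branch.

    The default 1 ms step over 0.3-5.0 s is far finer than any tissue effect
    of interest (the smallest |ΔT1| the analysis cares about is ~4 ms).
    """
    if not (0 < t1_min < t1_max):
        raise ConfigurationError("require 0 < t1_min < t1_max")
    if step <= 0:
        raise ConfigurationError("step must be positive")
    if step > t1_max - t1_min:
        raise ConfigurationError("step is larger than the T1 range")
    n = int(round((t1_max - t1_min) / step)) + 1
    t1_grid = t1_min + step * np.arange(n)
    uni = uni_from_signals(simulate_signals(protocol, t1_grid, b1_scale=b1_scale))
    branch = _largest_monotone_branch(uni)
    t1_b, uni_b = t1_grid[branch], uni[branch]
    if len(t1_b) < 2:
        raise ConfigurationError(
            "UNI is nowhere strictly monotone in T1 for this protocol"
        )
    return LookupTable(
        t1_grid=t1_b,
        uni_values=uni_b,
        valid_range=(float(uni_b.min()), float(uni_b.max())),
    )


def t1_from_uni(uni, table: LookupTable):
    """Invert UNI to T1 by linear interpolation on the monotone branch.

    Returns ``(t1, out_of_range)`` where ``out_of_range`` is True wherever
    the input UNI fell outside the branch's valid range and the returned T1
    is the clamped branch edge.  Accepts scalars or arrays.
    """
    uni_arr = np.asarray(uni, dtype=float)
    lo, hi = table.valid_range
    out = (uni_arr < lo) | (uni_arr > hi) | ~np.isfinite(uni_arr)
    if table.decreasing:
        x, y = table.uni_values[::-1], table.t1_grid[::-1]
    else:
        x, y = table.uni_values, table.t1_grid
    t1 = np.interp(np.clip(uni_arr, lo, hi), x, y)
    if uni_arr.ndim == 0:
        return float(t1), bool(out)
    return t1, out
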