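"""Sparse scan patterns and stream-file serialization.

The second pass visits only HIA pixels, row by row: the beam is unblanked
when entering an HIA run and blanked when leaving it.  Patterns are
serialized in a small ASCII stream-file dialect (documented below) that
mirrors the conventions of 16-bit scan generators driven by patterning
stream files, without claiming bit-compatibility with any vendor format.

Stream dialect::

    s16                 magic
    <passes>            repeat count
    <n_points>          number of visit points
    <dwell_ticks> <x> <y>    one line per point

Dwell is stored in integer ticks of 100 ns; x = column, y = row, 0-based,
origin top-left.  Dwell values are rounded to the nearest tick on write;
reading returns tick-exact seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanPattern",
    "ScanBudget",
    "build_pattern",
    "write_stream",
    "read_stream",
    "average_dwell",
    "STREAM_MAGIC",
    "TICK_SECONDS",
]

STREAM_MAGIC = "s16"
#: One dwell tick of the scan generator, in seconds.
TICK_SECONDS = 100e-9


@dataclass
class ScanPattern:
    """Ordered list of beam visit points (x=column, y=row, dwell seconds)."""

    points: list[tuple[int, int, float]]
    image_shape: tuple[int, int]
    passes: int = 1

    def __post_init__(self) -> None:
        h, w = self.image_shape
        prev = None
        for x, y, dwell in self.points:
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"point ({x}, {y}) outside image bounds {self.image_shape}")
            if dwell <= 0:
                raise ValueError("dwell must be positive for every point")
            key = (y, x)
            if prev is not None and key <= prev:
                raise ValueError("points must be strictly row-major ordered")
            prev = key
        if self.passes < 1:
            raise ValueError("passes must be >= 1")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ScanBudget:
    """Dwell-time bookkeeping of a two-pass acquisition.

    The average per-pixel dwell is t_initial + A * t_sparse: every pixel
    pays the initial scan, and a fraction A additionally pays the sparse
    rescan.
    """

    t_initial: float
    t_sparse: float
    area_fraction: float
    t_avg: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "t_avg", average_dwell(self.t_initial, self.area_fraction, self.t_sparse)
        )


def average_dwell(t_initial: float, area_fraction: float, t_sparse: float) -> float:
    """Average per-pixel dwell time t_initial + area_fraction * t_sparse."""
    if t_initial < 0 or t_sparse < 0 or not 0 <= area_fraction <= 1:
        raise ValueError("dwell times must be >= 0 and area_fraction in [0, 1]")
    return t_initial + area_fraction * t_sparse


def build_pattern(mask, dwell: float) -> ScanPattern:
    """One visit point per HIA pixel, in row-major scan order."""
    if dwell <= 0:
        raise ValueError("dwell must be positive")
    values = np.asarray(getattr(mask, "values", mask), dtype=bool)
    ys, xs = np.nonzero(values)  # row-major by construction
    points = [(int(x), int(y), float(dwell)) for y, x in zip(ys, xs)]
    return ScanPattern(points=points, image_shape=values.shape)


def write_stream(pattern: ScanPattern, path) -> None:
    """Serialize a pattern in the ASCII stream dialect (see module docs)."""
    lines = [STREAM_MAGIC, str(pattern.passes), str(len(pattern.points))]
    for x, y, dwell in pattern.points:
        ticks = round(dwell / TICK_SECONDS)
        if ticks < 1:
            ticks = 1  # the generator cannot dwell for less than one tick
        lines.append(f"{ticks} {x} {y}")
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\n".join(lines) + "\n")


def read_stream(path, image_shape: tuple[int, int] | None = None) -> ScanPattern:
    """Parse a stream file; raises ValueError naming the offending line."""
    with open(path, "r", encoding="ascii") as fh:
        raw = [ln.strip() for ln in fh]
    lines = [ln for ln in raw if ln]
    if not lines or lines[0] != STREAM_MAGIC:
        raise ValueError(f"line 1: expected magic {STREAM_MAGIC!r}")
    try:
        passes = int(lines[1])
        n_points = int(lines[2])
    except (IndexError, ValueError) as exc:
        raise ValueError("line 2-3: malformed pass/point count header") from exc
    body = lines[3:]
    if len(body) != n_points:
        raise ValueError(
            f"line 3: declared {n_points} points but file contains {len(body)} point lines"
        )
    points: list[tuple[int, int, float]] = []
    max_x = max_y = 0
    for i, ln in enumerate(body, start=4):
        parts = ln.split()
        if len(parts) != 3:
            raise ValueError(f"line {i}: expected 'dwell_ticks x y'")
        try:
            ticks, x, y = (int(p) for p in parts)
        except ValueError as exc:
            raise ValueError(f"line {i}: non-integer field") from exc
        if ticks < 1:
            raise ValueError(f"line {i}: dwell ticks must be >= 1")
        points.append((x, y, ticks / 1e7))
        max_x = max(max_x, x)
        max_y = max(max_y, y)
    if image_shape is None:
        image_shape = (max_y + 1, max_x + 1)
    return ScanPattern(points=points, image_shape=image_shape, passes=passes)
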