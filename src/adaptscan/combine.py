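"""Fusion of the filtered initial image with the sparse high-dose image.

HIA pixels take their value verbatim from the sparse rescan.  Filter-region
pixels take the filtered initial signal, optionally mixed with the raw
initial signal to re-introduce a controlled amount of shot noise
("noise-level adaptation"): with a sufficiently large filter kernel the
filter region would otherwise be visually noise-free while the HIA still
carries the residual noise of its finite rescan dwell, and the eye
registers the mismatch as an artifact.

Shot-noise std scales as 1/sqrt(dwell), so the mixing factor
i = sqrt(t_initial / t_sparse) is the ratio of the noise level in the
initial and sparse images; weighting the noisy initial signal by i (and the
essentially noise-free filtered signal by 1 - i) leaves the filter region
with residual noise i * sigma_initial = sigma_sparse, matching the HIA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FusionParams", "mixing_factor", "fuse"]


def mixing_factor(t_initial: float, t_sparse: float) -> float:
    """i = sqrt(t_initial / t_sparse), the initial-to-sparse noise ratio."""
    if t_initial <= 0 or t_sparse <= 0:
        raise ValueError("dwell times must be positive")
    return float(np.sqrt(t_initial / t_sparse))


@dataclass(frozen=True)
class FusionParams:
    """Fusion settings; the mixing factor i is derived from the dwells."""

    t_initial: float
    t_sparse: float
    adapt_noise: bool = True
    i: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "i", mixing_factor(self.t_initial, self.t_sparse))


def fuse(initial, filtered, sparse, mask, params: FusionParams) -> np.ndarray:
    """Assemble the final image from the sparse scan and the filtered
    initial scan.

    HIA pixels <- sparse value; filter-region pixels <-
    i * initial + (1 - i) * filtered when ``params.adapt_noise`` is on,
    else the filtered value alone.
    """
    initial = np.asarray(initial, dtype=float)
    filtered = np.asarray(filtered, dtype=float)
    sparse = np.asarray(sparse, dtype=float)
    hia = np.asarray(getattr(mask, "values", mask), dtype=bool)
    if not (initial.shape == filtered.shape == sparse.shape == hia.shape):
        raise ValueError("initial, filtered, sparse and mask must share one shape")
    if params.adapt_noise:
        background = params.i * initial + (1.0 - params.i) * filtered
    else:
        background = filtered
    out = np.where(hia, sparse, background)
    if not np.all(np.isfinite(out)):
        raise ValueError("fused image contains non-finite values")
    return out
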