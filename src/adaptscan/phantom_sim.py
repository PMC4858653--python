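"""Synthetic two-phase specimens and shot-noise-limited scan simulation.

The simulator stands in for the microscope: phantoms emulate polished
cast-iron sections (a bright pearlitic matrix with dark graphite inclusions,
either nodular or lamellar), and acquisitions are modelled as Poisson
electron counting, so the residual noise of a scan scales with the inverse
square root of the pixel-dwell time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Phantom",
    "AcquisitionModel",
    "make_phantom",
    "simulate_scan",
    "simulate_sparse_scan",
]

#: Intensity of the matrix phase in the noise-free truth.
MATRIX_LEVEL = 0.8
#: Intensity of the inclusion phase.
INCLUSION_LEVEL = 0.2
#: Peak amplitude of the low-frequency shading field.
SHADING_AMPLITUDE = 0.05
#: Point-spread blur applied to phase boundaries (pixels).
PSF_SIGMA = 1.0

PHANTOM_KINDS = ("nodular", "lamellar")


@dataclass(frozen=True)
class Phantom:
    """Noise-free ground truth plus the phase-label map it was built from.

    Attributes
    ----------
    truth : ndarray
        Normalized intensities in [0, 1]; what an infinitely long scan
        would measure.
    phases : ndarray
        Integer labels, 0 = matrix, 1 = inclusion, same shape as ``truth``.
    pixel_size : float
        Physical edge length of one pixel in metres (informational).
    """

    truth: np.ndarray
    phases: np.ndarray
    pixel_size: float = 35e-9

    def __post_init__(self) -> None:
        truth = np.asarray(self.truth, dtype=float)
        phases = np.asarray(self.phases)
        if truth.ndim != 2 or phases.shape != truth.shape:
            raise ValueError("truth and phases must be 2D arrays of equal shape")
        if not np.all(np.isfinite(truth)) or truth.min() < 0 or truth.max() > 1:
            raise ValueError("truth must be finite and within [0, 1]")
        if np.unique(phases).size < 2:
            raise ValueError("phantom must contain at least two phase labels")
        object.__setattr__(self, "truth", truth)
        object.__setattr__(self, "phases", phases.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth.shape


@dataclass(frozen=True)
class AcquisitionModel:
    """Poisson counting model of the detector chain.

    dose_rate is the expected number of detected electrons per second for a
    pixel at unit intensity.  The default (2e9 /s, i.e. 2000 counts per µs
    of dwell) corresponds to a ~340 pA probe with partial detection
    efficiency and is a documented calibration assumption.
    """

    dose_rate: float = 2e9
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose_rate <= 0:
            raise ValueError("dose_rate must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


def _nodular_labels(shape, n_inclusions, rng):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros(shape, dtype=bool)
    r_base = min(h, w) / 20.0
    for _ in range(n_inclusions):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        # mildly elliptical nodules with varied size
        ry = r_base * rng.uniform(0.6, 1.4)
        rx = r_base * rng.uniform(0.6, 1.4)
        theta = rng.uniform(0, np.pi)
        dy = yy - cy
        dx = xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        labels |= (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    return labels


def _lamellar_labels(shape, n_inclusions, rng):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros(shape, dtype=bool)
    length = min(h, w) / 3.0
    for _ in range(n_inclusions):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        theta = rng.uniform(0, np.pi)
        half_len = length * rng.uniform(0.5, 1.0) / 2.0
        half_th = rng.uniform(1.5, 3.5)
        # slight curvature so lamellae are not perfect bars
        curv = rng.uniform(-1.0, 1.0) / (4.0 * half_len)
        dy = yy - cy
        dx = xx - cx
        along = dy * np.cos(theta) + dx * np.sin(theta)
        across = -dy * np.sin(theta) + dx * np.cos(theta) - curv * along**2
        labels |= (np.abs(along) <= half_len) & (np.abs(across) <= half_th)
    return labels


def make_phantom(
    kind: str,
    height: int,
    width: int,
    n_inclusions: int = 20,
    seed: int = 0,
    pixel_size: float = 35e-9,
) -> Phantom:
    """Generate a two-phase phantom with dark inclusions in a bright matrix.

    The truth image is the phase map rendered at intensities 0.8 (matrix)
    and 0.2 (inclusion), blurred with a σ = 1 px Gaussian point spread so
    boundaries are not single-pixel steps, plus a ±0.05 low-frequency
    shading field.  Deterministic for a fixed seed.

    Parameters
    ----------
    kind : {"nodular", "lamellar"}
        Inclusion morphology: roundish nodules or thin elongated flakes.
    height, width : int
        Image size in pixels, at least 64 each.
    n_inclusions : int
        Number of inclusion primitives placed (>= 1).
    seed : int
        Seed for the phantom's random geometry.
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; accepted kinds: {PHANTOM_KINDS}")
    if height < 64 or width < 64:
        raise ValueError("height and width must be at least 64 pixels")
    if n_inclusions < 1:
        raise ValueError("n_inclusions must be >= 1")

    rng = np.random.default_rng(seed)
    shape = (int(height), int(width))
    if kind == "nodular":
        inclusion = _nodular_labels(shape, n_inclusions, rng)
    else:
        inclusion = _lamellar_labels(shape, n_inclusions, rng)
    if not inclusion.any():  # pragma: no cover - placement always hits the frame
        inclusion[shape[0] // 2, shape[1] // 2] = True

    truth = np.where(inclusion, INCLUSION_LEVEL, MATRIX_LEVEL).astype(float)
    truth = ndimage.gaussian_filter(truth, PSF_SIGMA, mode="reflect")

    # low-frequency shading: two random-phase sinusoids, one period per image
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    shading = 0.5 * (
        np.sin(2 * np.pi * xx / shape[1] + ph1) + np.sin(2 * np.pi * yy / shape[0] + ph2)
    )
    truth = truth + SHADING_AMPLITUDE * shading
    truth = np.clip(truth, 0.0, 1.0)

    return Phantom(truth=truth, phases=inclusion.astype(np.int64), pixel_size=pixel_size)


def _truth_of(phantom) -> np.ndarray:
    if isinstance(phantom, Phantom):
        return phantom.truth
    arr = np.asarray(phantom, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a Phantom or a 2D intensity array")
    return arr


def simulate_scan(phantom, dwell, model: AcquisitionModel) -> np.ndarray:
    """Simulate one raster scan with Poisson shot noise.

    Per pixel a count is drawn from Poisson(dose_rate * dwell * truth) and
    the recorded gray value is count / (dose_rate * dwell), so the output is
    an unbiased estimate of the truth whose noise std scales as
    1/sqrt(dwell).  ``dwell`` may be a scalar or a per-pixel dwell map.
    One seeded generator is used per call, with draws in row-major order.
    """
    truth = _truth_of(phantom)
    dwell_arr = np.asarray(dwell, dtype=float)
    if dwell_arr.ndim not in (0, 2):
        raise ValueError("dwell must be a scalar or a 2D map")
    if dwell_arr.ndim == 2 and dwell_arr.shape != truth.shape:
        raise ValueError("dwell map shape must match the phantom shape")
    if np.any(dwell_arr <= 0):
        raise ValueError("all dwell values must be positive")

    expected = model.dose_rate * dwell_arr * truth
    rng = np.random.default_rng(model.seed)
    counts = rng.poisson(np.broadcast_to(expected, truth.shape))
    return counts / (model.dose_rate * dwell_arr)


def simulate_sparse_scan(phantom, mask, dwell: float, model: AcquisitionModel) -> np.ndarray:
    """Simulate the second-pass sparse scan: HIA pixels carry an acquisition
    at ``dwell``, filter-region pixels are exactly zero (beam blanked)."""
    truth = _truth_of(phantom)
    mask_arr = np.asarray(getattr(mask, "values", mask), dtype=bool)
    if mask_arr.shape != truth.shape:
        raise ValueError("mask shape must match the phantom shape")
    image = simulate_scan(truth, dwell, model)
    image[~mask_arr] = 0.0
    return image
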