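"""Kernel-wise 2D spatial frequency analysis of B-mode speckle texture.

Every admissible square kernel inside an ROI is zero-padded, transformed
with an unnormalized 2D DFT, highpass-filtered in physical frequency
(mm^-1), and reduced to four scalar parameters:

* ``psfr``     - radial distance (mm^-1) from DC to the largest non-DC bin
* ``mmax``     - that largest magnitude
* ``mmax_pct`` - 100 * mmax / sum
* ``sum``      - total magnitude over the whole filtered spectrum

Per-ROI values are the arithmetic means over all kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .errors import ROITooSmallError, ValidationError
from .image_io import BModeImage, ROIMask

_BATCH = 128  # kernels transformed per FFT call; bounds peak memory


@dataclass(frozen=True)
class SFAConfig:
    """Analysis settings.

    Defaults follow the published muscle protocol: 96 px kernels padded
    to 128 samples, stride 1 ("all possible" kernels), and an order-2
    radially symmetric Butterworth highpass with its -3 dB point at
    1.0 mm^-1.
    """

    kernel_px: int = 96
    pad_px: int = 128
    stride_px: int = 1
    hp_cutoff: float = 1.0
    hp_order: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.kernel_px <= self.pad_px):
            raise ValidationError(f"need 0 < kernel_px <= pad_px, got {self.kernel_px}/{self.pad_px}")
        if self.stride_px < 1:
            raise ValidationError("stride_px must be >= 1")
        if not (self.hp_cutoff > 0 and np.isfinite(self.hp_cutoff)):
            raise ValidationError("hp_cutoff must be a positive frequency in mm^-1")
        if self.hp_order < 1:
            raise ValidationError("hp_order must be >= 1")


@dataclass(frozen=True)
class KernelSpectrum:
    """DC-centered magnitude spectrum with physical frequency axes."""

    magnitude: np.ndarray       # (pad_px, pad_px), |F(u,v)| >= 0
    freq_u: np.ndarray          # lateral axis, mm^-1 (columns)
    freq_v: np.ndarray          # axial axis, mm^-1 (rows)
    origin_index: tuple[int, int]

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitude, dtype=float)
        if m.ndim != 2:
            raise ValidationError("magnitude must be 2D")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValidationError("magnitude must be finite and >= 0")
        object.__setattr__(self, "magnitude", m)

    def radius_grid(self) -> np.ndarray:
        """Physical radius sqrt(u^2 + v^2) in mm^-1 for every bin."""
        return np.hypot(self.freq_v[:, None], self.freq_u[None, :])


@dataclass(frozen=True)
class SFAParameters:
    psfr: float
    mmax: float
    mmax_pct: float
    sum: float
    n_kernels: int = 1
    degenerate: bool = False


def _centered_freq_axis(pad_px: int, spacing_mm: float) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftfreq(pad_px, d=spacing_mm))


def enumerate_kernels(mask: ROIMask, config: SFAConfig) -> list[tuple[int, int]]:
    """Top-left ``(row, col)`` of every kernel fully contained in the mask.

    Positions are restricted to the stride grid anchored at (0, 0) and
    returned in row-major order. A kernel is admissible only when every
    one of its ``kernel_px**2`` pixels is inside the mask.
    """
    k = config.kernel_px
    m = mask.mask
    rows, cols = m.shape
    if rows < k or cols < k:
        return []
    # Integral image gives each window's true-pixel count in O(1).
    integral = np.zeros((rows + 1, cols + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(m, axis=0), axis=1)
    win = (
        integral[k:, k:] - integral[:-k, k:] - integral[k:, :-k] + integral[:-k, :-k]
    )
    full = win == k * k
    rr, cc = np.nonzero(full)
    keep = (rr % config.stride_px == 0) & (cc % config.stride_px == 0)
    return [(int(r), int(c)) for r, c in zip(rr[keep], cc[keep])]


def kernel_spectrum(
    image: BModeImage, position: tuple[int, int], config: SFAConfig
) -> KernelSpectrum:
    """Magnitude spectrum of one kernel at ``position`` (top-left row, col).

    The kernel is zero-padded with trailing zeros to ``pad_px`` per axis
    (the magnitude spectrum is invariant to pad placement), transformed
    with the unnormalized forward DFT, and DC-centered.
    """
    r, c = position
    k, p = config.kernel_px, config.pad_px
    rows, cols = image.shape
    if r < 0 or c < 0 or r + k > rows or c + k > cols:
        raise ValidationError(f"kernel at {position} exceeds image bounds {image.shape}")
    block = image.pixels[r : r + k, c : c + k].astype(float)
    mag = np.abs(np.fft.fftshift(np.fft.fft2(block, s=(p, p))))
    return KernelSpectrum(
        magnitude=mag,
        freq_u=_centered_freq_axis(p, image.spacing_lateral),
        freq_v=_centered_freq_axis(p, image.spacing_axial),
        origin_index=(p // 2, p // 2),
    )


def butterworth_highpass_gain(
    radius: np.ndarray | float, cutoff: float, order: int
) -> np.ndarray | float:
    """Radially symmetric Butterworth highpass amplitude gain.

    ``|H(r)|^2 = 1 / (1 + (cutoff / r)^(2 * order))`` so the squared gain
    is exactly 1/2 (-3.0103 dB) at ``r = cutoff`` and H(0) = 0.
    """
    r = np.asarray(radius, dtype=float)
    with np.errstate(divide="ignore"):
        gain = 1.0 / np.sqrt(1.0 + (cutoff / np.where(r > 0, r, np.inf)) ** (2 * order))
    gain = np.where(r > 0, gain, 0.0)
    return float(gain) if np.isscalar(radius) else gain


def highpass_filter(spectrum: KernelSpectrum, config: SFAConfig) -> KernelSpectrum:
    """Attenuate low spatial frequencies; DC is nulled entirely."""
    gain = butterworth_highpass_gain(spectrum.radius_grid(), config.hp_cutoff, config.hp_order)
    return replace(spectrum, magnitude=spectrum.magnitude * gain)


def spectral_parameters(spectrum: KernelSpectrum) -> SFAParameters:
    """Reduce one (filtered) spectrum to the four scalar parameters.

    The peak search excludes the DC bin; ties are broken by the smallest
    physical radius, then by row-major bin order. The total includes
    every bin of the padded spectrum. An all-zero spectrum yields the
    degenerate all-zero result.
    """
    mag = spectrum.magnitude
    total = float(mag.sum())
    non_dc = np.ones(mag.shape, dtype=bool)
    non_dc[spectrum.origin_index] = False
    search = np.where(non_dc, mag, -np.inf)
    mmax = float(search.max())
    if total <= 0.0 or mmax <= 0.0:
        return SFAParameters(psfr=0.0, mmax=0.0, mmax_pct=0.0, sum=total, degenerate=True)
    radius = spectrum.radius_grid()
    ties = np.argwhere(search == mmax)
    tie_radii = radius[ties[:, 0], ties[:, 1]]
    # argwhere is row-major, so the first minimal-radius hit is the winner.
    best = ties[int(np.argmin(tie_radii))]
    psfr = float(radius[best[0], best[1]])
    return SFAParameters(psfr=psfr, mmax=mmax, mmax_pct=100.0 * mmax / total, sum=total)


def _iter_kernel_parameters(
    image: BModeImage, positions: list[tuple[int, int]], config: SFAConfig
) -> Iterator[SFAParameters]:
    """Batched per-kernel parameters (identical to the one-at-a-time path)."""
    k, p = config.kernel_px, config.pad_px
    freq_u = _centered_freq_axis(p, image.spacing_lateral)
    freq_v = _centered_freq_axis(p, image.spacing_axial)
    radius = np.hypot(freq_v[:, None], freq_u[None, :])
    gain = butterworth_highpass_gain(radius, config.hp_cutoff, config.hp_order)
    origin = (p // 2, p // 2)
    px = image.pixels.astype(float)
    for start in range(0, len(positions), _BATCH):
        chunk = positions[start : start + _BATCH]
        stack = np.stack([px[r : r + k, c : c + k] for r, c in chunk])
        mags = np.abs(np.fft.fftshift(np.fft.fft2(stack, s=(p, p)), axes=(-2, -1))) * gain
        for mag in mags:
            yield spectral_parameters(
                KernelSpectrum(magnitude=mag, freq_u=freq_u, freq_v=freq_v, origin_index=origin)
            )


def analyze_kernels(
    image: BModeImage, mask: ROIMask, config: SFAConfig | None = None
) -> list[SFAParameters]:
    """Filtered per-kernel parameters for every admissible kernel."""
    config = config or SFAConfig()
    if mask.shape != image.shape:
        raise ValidationError(f"mask shape {mask.shape} != image shape {image.shape}")
    positions = enumerate_kernels(mask, config)
    return list(_iter_kernel_parameters(image, positions, config))


def analyze_roi(
    image: BModeImage, mask: ROIMask, config: SFAConfig | None = None
) -> SFAParameters:
    """Mean of each spectral parameter over all admissible kernels."""
    config = config or SFAConfig()
    per_kernel = analyze_kernels(image, mask, config)
    if not per_kernel:
        raise ROITooSmallError(
            "ROI too small: no admissible kernel. The mask must fully contain "
            f"at least one {config.kernel_px}x{config.kernel_px} pixel square."
        )
    n = len(per_kernel)
    return SFAParameters(
        psfr=float(np.mean([q.psfr for q in per_kernel])),
        mmax=float(np.mean([q.mmax for q in per_kernel])),
        mmax_pct=float(np.mean([q.mmax_pct for q in per_kernel])),
        sum=float(np.mean([q.sum for q in per_kernel])),
        n_kernels=n,
        degenerate=all(q.degenerate for q in per_kernel),
    )


def frequency_bin_width(config: SFAConfig, spacing_mm: float) -> float:
    """Spectral bin width 1 / (pad_px * spacing) in mm^-1 for one axis."""
    return 1.0 / (config.pad_px * spacing_mm)
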