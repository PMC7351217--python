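"""Ground-truth generators: banded speckle phantoms and ratings tables.

The phantom is a first-order speckle field (exponential envelope
smoothed by a Gaussian point-spread kernel, renormalized to unit mean)
multiplied by a sinusoidal band pattern of known spatial frequency, so
the dominant spectral peak of the texture is known by construction. The
ratings generator draws from the additive two-way model
``y_ij = mu + b_i + r_j + e_ij`` so the implied consistency ICC
``subject_sd^2 / (subject_sd^2 + error_sd^2)`` is known exactly.

Every generator takes an explicit integer seed; there is no global
random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import BModeImage, ROIPolygon
from .reliability import RatingsTable


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic banded-speckle image."""

    shape: tuple[int, int] = (128, 128)
    spacing: float = 6.6 / 96          # mm per pixel, both axes
    band_freq: float = 0.75            # mm^-1, along the band normal
    band_orientation: float = 0.0      # degrees from the lateral axis
    band_contrast: float = 0.6         # modulation depth in [0, 1]
    speckle_scale: float = 0.15        # Gaussian PSF sigma, mm
    mean_intensity: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 1 or cols < 1:
            raise ValidationError("phantom shape must be positive")
        if self.spacing <= 0 or not math.isfinite(self.spacing):
            raise ValidationError("spacing must be positive and finite")
        nyquist = 1.0 / (2.0 * self.spacing)
        if not (0 < self.band_freq < nyquist):
            raise ValidationError(
                f"band_freq must lie in (0, {nyquist:.3f}) mm^-1 (Nyquist), got {self.band_freq}"
            )
        if not (0.0 <= self.band_contrast <= 1.0):
            raise ValidationError("band_contrast must be in [0, 1]")
        if self.speckle_scale < 0:
            raise ValidationError("speckle_scale must be >= 0")
        if self.mean_intensity <= 0:
            raise ValidationError("mean_intensity must be > 0")


@dataclass(frozen=True)
class RatingsSpec:
    """Parameters of one synthetic subjects x raters ratings table."""

    n_subjects: int = 10
    k_raters: int = 2
    grand_mean: float = 10.0
    subject_sd: float = 2.0
    rater_sd: float = 0.0
    error_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.k_raters < 2:
            raise ValidationError("need >= 2 subjects and >= 2 raters")
        if min(self.subject_sd, self.rater_sd, self.error_sd) < 0:
            raise ValidationError("standard deviations must be >= 0")

    @property
    def true_consistency_icc(self) -> float:
        var = self.subject_sd**2 + self.error_sd**2
        return self.subject_sd**2 / var if var > 0 else float("nan")


def generate_phantom(
    spec: PhantomSpec, roi_margin_px: int = 8
) -> tuple[BModeImage, ROIPolygon]:
    """Banded speckle image plus a rectangular ROI inset from the edges."""
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed)
    envelope = rng.exponential(scale=1.0, size=(rows, cols))
    sigma_px = spec.speckle_scale / spec.spacing
    if sigma_px > 0:
        envelope = ndimage.gaussian_filter(envelope, sigma=sigma_px, mode="reflect")
    envelope /= envelope.mean()

    theta = math.radians(spec.band_orientation)
    row_mm = np.arange(rows)[:, None] * spec.spacing
    col_mm = np.arange(cols)[None, :] * spec.spacing
    # s measures distance along the band normal; orientation 0 puts the
    # bands parallel to the lateral axis (variation along depth).
    s = row_mm * math.cos(theta) + col_mm * math.sin(theta)
    bands = 1.0 + spec.band_contrast * np.cos(2.0 * math.pi * spec.band_freq * s)

    pixels = np.clip(spec.mean_intensity * envelope * bands, 0.0, None)
    image = BModeImage(
        pixels=pixels,
        spacing_axial=spec.spacing,
        spacing_lateral=spec.spacing,
        source_id=f"phantom-seed{spec.seed}",
    )
    m = roi_margin_px
    if rows - 2 * m < 2 or cols - 2 * m < 2:
        raise ValidationError("phantom too small for the requested ROI margin")
    roi = ROIPolygon(
        vertices=np.array(
            [
                [m, m],
                [cols - 1 - m, m],
                [cols - 1 - m, rows - 1 - m],
                [m, rows - 1 - m],
            ],
            dtype=float,
        ),
        image_id=image.source_id,
    )
    return image, roi


def generate_ratings(spec: RatingsSpec) -> RatingsTable:
    """Draw a complete table from ``y_ij = mu + b_i + r_j + e_ij``."""
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_subjects, spec.k_raters
    subjects = rng.normal(0.0, spec.subject_sd, size=n)
    raters = rng.normal(0.0, spec.rater_sd, size=k)
    noise = rng.normal(0.0, spec.error_sd, size=(n, k))
    values = spec.grand_mean + subjects[:, None] + raters[None, :] + noise
    return RatingsTable(values=values)
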