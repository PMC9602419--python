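"""Fast discrete curvelet transform (frequency-wrapping construction).

The transform tiles the 2-D frequency plane with smooth Meyer-type
windows: one isotropic low-pass window (the *coarse band*, which carries
image contour and contrast) and, at every finer scale, a ring of angular
wedges whose count doubles every other scale.  Each window ``U`` is
built so that the squares of all windows sum to exactly one at every
frequency — a tight frame — which gives

* perfect reconstruction to machine precision,
* exact energy preservation (Parseval), and
* linearity of both directions.

For a real image, opposite wedges carry conjugate information; they are
combined into a single real-valued coefficient matrix per orientation
(orientations therefore live on the half-circle, modulo pi).  Every band
except the finest is wrapped (periodised) onto a small centred grid that
contains its whole frequency support; because the support fits, the
wrapping is a pure re-indexing and costs nothing in accuracy, while the
coarse-scale coefficient matrices shrink by the expected dyadic factors.

Coefficients are indexed ``c[j][d][k1, k2]`` with ``j = 0`` the
second-coarsest scale, plus a separate ``coarse`` matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "FdctConfig",
    "CurveletMeta",
    "CurveletCoefficients",
    "fdct_forward",
    "fdct_inverse",
    "default_n_scales",
]


class FdctConfigurationError(ValueError):
    """Raised when image size and transform configuration are incompatible."""


class FdctValidationError(ValueError):
    """Raised for structurally invalid inputs (non-finite pixels, shape mismatch)."""


def default_n_scales(height: int, width: int) -> int:
    """Standard default scale count: ``max(2, ceil(log2(min(H, W))) - 3)``."""
    return max(2, math.ceil(math.log2(min(height, width))) - 3)


@dataclass(frozen=True)
class FdctConfig:
    """Transform configuration.

    ``n_scales`` is the total number of scales J including the coarse
    band (``None`` selects the size-dependent default).
    ``n_angles_coarse`` is the number of *directions on the full circle*
    at the second-coarsest scale; since opposite wedges are merged for
    real input, the number of stored orientation matrices at that scale
    is ``n_angles_coarse // 2``.
    """

    n_scales: Optional[int] = None
    n_angles_coarse: int = 16

    def __post_init__(self) -> None:
        if self.n_angles_coarse < 8 or self.n_angles_coarse % 4 != 0:
            raise FdctConfigurationError(
                "n_angles_coarse must be a multiple of 4 and >= 8"
            )
        if self.n_scales is not None and self.n_scales < 2:
            raise FdctConfigurationError("n_scales must be >= 2")

    def resolve_scales(self, height: int, width: int) -> int:
        j = self.n_scales if self.n_scales is not None else default_n_scales(height, width)
        if j > math.log2(min(height, width)) - 2:
            raise FdctConfigurationError(
                f"n_scales={j} too large for a {height}x{width} image "
                f"(need n_scales <= log2(min(H,W)) - 2)"
            )
        return j


@dataclass(frozen=True)
class CurveletMeta:
    """Bookkeeping needed to invert a decomposition."""

    shape: Tuple[int, int]  # original image shape
    padded_shape: Tuple[int, int]  # even working shape
    n_scales: int
    angles_per_scale: Tuple[int, ...]  # stored orientation matrices, scales 2..J


@dataclass
class CurveletCoefficients:
    """Coarse band plus per-scale, per-orientation wedge matrices."""

    coarse: np.ndarray
    bands: List[List[np.ndarray]]
    meta: CurveletMeta

    def copy(self) -> "CurveletCoefficients":
        return CurveletCoefficients(
            self.coarse.copy(),
            [[w.copy() for w in scale] for scale in self.bands],
            self.meta,
        )

    def iter_wedges(self):
        """Yield ``(scale_index, direction_index, matrix)`` over all wedges."""
        for j, scale in enumerate(self.bands):
            for d, w in enumerate(scale):
                yield j, d, w

    def energy(self) -> float:
        e = float(np.sum(self.coarse**2))
        for _, _, w in self.iter_wedges():
            e += float(np.sum(w**2))
        return e


def _meyer_step(t: np.ndarray) -> np.ndarray:
    """Polynomial Meyer ramp: 0 for t<=0, 1 for t>=1, C^3 in between."""
    t = np.clip(t, 0.0, 1.0)
    return t**4 * (35.0 - 84.0 * t + 70.0 * t**2 - 20.0 * t**3)


def _fft_order_indices(k: int, n: int) -> np.ndarray:
    """Full-grid indices of the frequencies -k..k, laid out in FFT order
    (DC first) for a (2k+1)-point grid, so the wrapped band is itself a
    valid FFT spectrum."""
    return np.concatenate([np.arange(0, k + 1), np.arange(-k, 0)]) % n


def _negate_indices(a: np.ndarray) -> np.ndarray:
    """a evaluated at index -k (mod N) on both axes of an FFT grid."""
    return np.roll(a[::-1, ::-1], shift=(1, 1), axis=(0, 1))


def _angles_on_circle(scale_offset: int, n_angles_coarse: int) -> int:
    """Full-circle wedge count at the scale ``scale_offset`` above the coarsest
    directional scale; doubles every other scale toward fine."""
    return n_angles_coarse * 2 ** (scale_offset // 2)


@lru_cache(maxsize=8)
def _build_windows(padded_shape: Tuple[int, int], n_scales: int, n_angles_coarse: int):
    """Construct the full window system on the padded FFT grid.

    Returns ``(coarse_window, band_windows, crops)`` where
    ``band_windows[j][d]`` is the full-grid real window of orientation d
    at scale j (j = 0 is the second-coarsest scale) and ``crops[j]`` is
    the list of FFT-grid indices of the centred wrapping box of scale j
    along each axis (``None`` for the finest scale, kept at full size).
    """
    h, w = padded_shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    rho = np.hypot(fy, fx)
    theta = np.arctan2(fx, fy)  # angle measured from the k1 axis; any fixed convention works

    j_total = n_scales
    # Radial octave boundaries: the band at scale j (directional scales
    # j = 2..J) is supported in rho < b_j, with b_{J-1} = 1/4 and the
    # finest band extending to the grid corners.
    bounds = [0.5 * 2.0 ** (i - (j_total - 1)) for i in range(1, j_total)]

    def lowpass(b: float) -> np.ndarray:
        with np.errstate(divide="ignore"):
            t = np.log2(np.maximum(rho, 1e-300) / b) + 1.0
        return np.cos(0.5 * np.pi * _meyer_step(t))

    lows = [lowpass(b) for b in bounds]
    highs = [np.sqrt(np.maximum(0.0, 1.0 - lp**2)) for lp in lows]

    coarse_win = lows[0].copy()
    # Radial windows for scales 2..J.  The telescoping partition
    # s_1^2 + (h_1 s_2)^2 + ... + (h_1...h_{J-1})^2 = 1 holds exactly; with
    # octave-separated transitions h_i == 1 wherever s_{i+1} < 1, so each
    # nested product collapses to the two adjacent factors.
    radial = []
    for j in range(1, j_total):
        if j < j_total - 1:
            radial.append(highs[j - 1] * lows[j])
        else:
            radial.append(highs[j - 1])  # finest: no upper taper, covers the corners

    band_windows: List[List[np.ndarray]] = []
    crops: List[Optional[Tuple[np.ndarray, np.ndarray]]] = []
    for j, rad in enumerate(radial):
        n_circle = _angles_on_circle(j, n_angles_coarse)
        delta = 2.0 * np.pi / n_circle
        scale_wins = []
        for d in range(n_circle // 2):
            centre = d * delta
            # symmetric pair: wedge at `centre` plus its antipode
            win = np.zeros((h, w))
            for c in (centre, centre + np.pi):
                off = np.angle(np.exp(1j * (theta - c)))  # wrapped to (-pi, pi]
                win += np.cos(0.5 * np.pi * _meyer_step(np.abs(off) / delta)) * (
                    np.abs(off) < delta
                )
            win *= rad
            # enforce exact symmetry under frequency negation (matters only
            # on the Nyquist row/column of even grids)
            win = 0.5 * (win + _negate_indices(win))
            scale_wins.append(win)
        band_windows.append(scale_wins)

        if j < len(radial) - 1:
            b = bounds[j + 1]
            k1 = min(int(np.floor(b * h)) + 1, (h - 1) // 2)
            k2 = min(int(np.floor(b * w)) + 1, (w - 1) // 2)
            crops.append((_fft_order_indices(k1, h), _fft_order_indices(k2, w)))
        else:
            crops.append(None)

    coarse_win = 0.5 * (coarse_win + _negate_indices(coarse_win))
    b = bounds[0]
    k1 = min(int(np.floor(b * h)) + 1, (h - 1) // 2)
    k2 = min(int(np.floor(b * w)) + 1, (w - 1) // 2)
    coarse_crop = (_fft_order_indices(k1, h), _fft_order_indices(k2, w))

    # Exact pointwise normalisation to a tight frame.
    total = coarse_win**2
    for scale_wins in band_windows:
        for win in scale_wins:
            total += win**2
    norm = 1.0 / np.sqrt(total)
    coarse_win *= norm
    for scale_wins in band_windows:
        for k in range(len(scale_wins)):
            scale_wins[k] = scale_wins[k] * norm

    return coarse_win, band_windows, coarse_crop, crops


def _pad_to_even(image: np.ndarray) -> np.ndarray:
    h, w = image.shape
    return np.pad(image, ((0, h % 2), (0, w % 2)), mode="symmetric")


def fdct_forward(image: np.ndarray, config: FdctConfig | None = None) -> CurveletCoefficients:
    """Decompose a real 2-D image into curvelet coefficients.

    Parameters
    ----------
    image
        Real 2-D array, both dimensions >= 32, finite values.
    config
        Transform configuration; ``None`` uses the defaults.

    Returns
    -------
    CurveletCoefficients
        Real coarse band plus per-scale, per-orientation real wedge
        matrices; :func:`fdct_inverse` reconstructs the image exactly.
    """
    config = config or FdctConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise FdctValidationError("image must be 2-D")
    if min(image.shape) < 32:
        raise FdctConfigurationError("both image dimensions must be >= 32")
    if not np.all(np.isfinite(image)):
        raise FdctValidationError("image contains non-finite values")

    n_scales = config.resolve_scales(*image.shape)
    padded = _pad_to_even(image)
    coarse_win, band_windows, coarse_crop, crops = _build_windows(
        padded.shape, n_scales, config.n_angles_coarse
    )

    spectrum = np.fft.fft2(padded, norm="ortho")

    def band_from(win, crop):
        y = win * spectrum
        if crop is not None:
            y = y[np.ix_(*crop)]
        return np.fft.ifft2(y, norm="ortho").real

    coarse = band_from(coarse_win, coarse_crop)
    bands = [
        [band_from(win, crops[j]) for win in scale_wins]
        for j, scale_wins in enumerate(band_windows)
    ]
    meta = CurveletMeta(
        shape=image.shape,
        padded_shape=padded.shape,
        n_scales=n_scales,
        angles_per_scale=tuple(len(s) for s in bands),
    )
    return CurveletCoefficients(coarse, bands, meta)


def fdct_inverse(coeffs: CurveletCoefficients) -> np.ndarray:
    """Reconstruct the image from curvelet coefficients (exact inverse)."""
    meta = coeffs.meta
    n_angles_coarse = 2 * meta.angles_per_scale[0]
    coarse_win, band_windows, coarse_crop, crops = _build_windows(
        meta.padded_shape, meta.n_scales, n_angles_coarse
    )
    if tuple(len(s) for s in band_windows) != meta.angles_per_scale:
        raise FdctValidationError("coefficient structure does not match meta")

    spectrum = np.zeros(meta.padded_shape, dtype=complex)

    def add_band(band, win, crop):
        band = np.asarray(band, dtype=float)
        c = np.fft.fft2(band, norm="ortho")
        if crop is None:
            if band.shape != meta.padded_shape:
                raise FdctValidationError("wedge shape does not match meta")
            spectrum[...] += win * c
        else:
            if band.shape != (len(crop[0]), len(crop[1])):
                raise FdctValidationError("wedge shape does not match meta")
            ix = np.ix_(*crop)
            spectrum[ix] += win[ix] * c

    add_band(coeffs.coarse, coarse_win, coarse_crop)
    if len(coeffs.bands) != len(band_windows):
        raise FdctValidationError("wrong number of scales")
    for j, scale in enumerate(coeffs.bands):
        if len(scale) != len(band_windows[j]):
            raise FdctValidationError("wrong number of directions at a scale")
        for d, wedge in enumerate(scale):
            add_band(wedge, band_windows[j][d], crops[j])

    out = np.fft.ifft2(spectrum, norm="ortho").real
    h, w = meta.shape
    return out[:h, :w]
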