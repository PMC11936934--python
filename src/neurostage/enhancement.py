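"""Haze-reduced local-global (HRLG) contrast enhancement.

Brain-slice images are treated with the hazy-image formation model

    C(x) = gamma(x) * t(x) + A * (1 - t(x)),

where ``C`` is the observed intensity, ``gamma`` the scene radiance, ``t`` the
per-pixel transmission and ``A`` the atmospheric light.  The dark-channel
prior supplies estimates of ``t`` and ``A``; the recovered radiance is then
re-contrasted globally,

    G = (1 + g_k) * (gamma - k_mean) + sigma,

and locally (windowed standard deviation plus a small multiple of the global
mean), and the two contrast maps are fused with the original image as

    Y = clip(G + H - I, 0, 1).

All stages are deterministic, operate on ``float64`` arrays in ``[0, 1]``
with shape ``H x W x 3`` (grayscale sources are channel-replicated on load),
and preserve spatial dimensions.  Windowed operators replicate edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import NumericError, ParameterError, ShapeError

__all__ = [
    "DehazeParams",
    "ContrastParams",
    "DehazeIntermediates",
    "compute_dark_channel",
    "estimate_atmospheric_light",
    "estimate_transmission",
    "recover_radiance",
    "global_contrast_map",
    "local_contrast_map",
    "fuse_and_clip",
    "enhance_image",
]


@dataclass(frozen=True)
class DehazeParams:
    """Dark-channel dehazing parameters.

    patch_size
        Odd window for the dark-channel minimum filter (pixels).
    omega
        Haze retention factor in the transmission estimate, in ``(0, 1]``.
        ``omega = 1`` removes all estimated haze.
    t0
        Transmission floor used during radiance recovery, in ``(0, 1)``.
    light_fraction
        Fraction of brightest dark-channel pixels averaged to estimate the
        atmospheric light.
    """

    patch_size: int = 15
    omega: float = 0.95
    t0: float = 0.1
    light_fraction: float = 0.001

    def __post_init__(self) -> None:
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ParameterError(f"patch_size must be odd and >= 1, got {self.patch_size}")
        if not 0.0 < self.omega <= 1.0:
            raise ParameterError(f"omega must be in (0, 1], got {self.omega}")
        if not 0.0 < self.t0 < 1.0:
            raise ParameterError(f"t0 must be in (0, 1), got {self.t0}")
        if not 0.0 < self.light_fraction <= 1.0:
            raise ParameterError(
                f"light_fraction must be in (0, 1], got {self.light_fraction}"
            )


@dataclass(frozen=True)
class ContrastParams:
    """Global/local contrast parameters: gain ``g_k``, offset weight ``phi``
    and the odd window used for the local standard deviation."""

    gain_k: float = 1.0
    phi: float = 0.2
    local_window: int = 7

    def __post_init__(self) -> None:
        if self.gain_k <= 0:
            raise ParameterError(f"gain_k must be > 0, got {self.gain_k}")
        if self.phi < 0:
            raise ParameterError(f"phi must be >= 0, got {self.phi}")
        if self.local_window < 3 or self.local_window % 2 == 0:
            raise ParameterError(
                f"local_window must be odd and >= 3, got {self.local_window}"
            )


@dataclass
class DehazeIntermediates:
    """Per-stage maps retained for inspection; ``radiance`` is unclipped."""

    dark_channel: np.ndarray
    transmission: np.ndarray
    atmospheric_light: np.ndarray
    radiance: np.ndarray


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError(f"expected H x W x 3 image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise NumericError("image contains non-finite values")
    return image


def compute_dark_channel(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Minimum over channels and over a ``patch_size`` square neighborhood.

    Edge pixels use replicated borders.  Returns an ``H x W`` map.
    """
    if patch_size < 1 or patch_size % 2 == 0:
        raise ParameterError(f"patch_size must be odd and >= 1, got {patch_size}")
    image = _as_rgb(image)
    channel_min = image.min(axis=2)
    return ndimage.minimum_filter(channel_min, size=patch_size, mode="nearest")


def estimate_atmospheric_light(
    image: np.ndarray, dark_channel: np.ndarray, light_fraction: float
) -> np.ndarray:
    """Per-channel mean over the brightest ``light_fraction`` of dark-channel
    pixels (ties broken by flat index, so the estimate is deterministic)."""
    image = _as_rgb(image)
    if not 0.0 < light_fraction <= 1.0:
        raise ParameterError(f"light_fraction must be in (0, 1], got {light_fraction}")
    flat_dark = np.asarray(dark_channel, dtype=np.float64).ravel()
    n_select = int(np.ceil(light_fraction * flat_dark.size))
    if n_select < 1:
        raise ParameterError("light_fraction selects no pixels")
    order = np.argsort(-flat_dark, kind="stable")[:n_select]
    flat_pixels = image.reshape(-1, 3)
    return flat_pixels[order].mean(axis=0)


def estimate_transmission(
    image: np.ndarray, light: np.ndarray, omega: float, patch_size: int
) -> np.ndarray:
    """Standard dark-channel transmission estimate
    ``t = 1 - omega * dark_channel(image / A)``, clamped to ``[0, 1]``."""
    image = _as_rgb(image)
    light = np.asarray(light, dtype=np.float64)
    if np.any(light <= 0):
        raise NumericError(f"atmospheric light must be positive, got {light}")
    normalized = image / light[None, None, :]
    transmission = 1.0 - omega * compute_dark_channel(normalized, patch_size)
    return np.clip(transmission, 0.0, 1.0)


def recover_radiance(
    image: np.ndarray,
    transmission: np.ndarray,
    light: np.ndarray,
    t0: float,
    clip: bool = True,
) -> np.ndarray:
    """Invert the haze model: ``gamma = (C - A) / max(t, t0) + A`` per channel.

    With ``clip=False`` the raw (possibly out-of-range) radiance is returned;
    the pipeline keeps that version in :class:`DehazeIntermediates`.
    """
    if not 0.0 < t0 < 1.0:
        raise ParameterError(f"t0 must be in (0, 1), got {t0}")
    image = _as_rgb(image)
    light = np.asarray(light, dtype=np.float64)
    divisor = np.maximum(np.asarray(transmission, dtype=np.float64), t0)
    radiance = (image - light[None, None, :]) / divisor[:, :, None] + light[None, None, :]
    if clip:
        radiance = np.clip(radiance, 0.0, 1.0)
    return radiance


def global_contrast_map(radiance: np.ndarray, gain_k: float) -> np.ndarray:
    """``G = (1 + g_k) * (gamma - k_mean) + sigma``.

    ``k_mean`` and ``sigma`` are the mean and population (1/N) standard
    deviation of the radiance over all pixels and channels; a constant input
    therefore maps to the zero image.
    """
    radiance = np.asarray(radiance, dtype=np.float64)
    k_mean = radiance.mean()
    sigma = radiance.std()  # population convention, ddof=0
    return (1.0 + gain_k) * (radiance - k_mean) + sigma


def local_contrast_map(radiance: np.ndarray, phi: float, local_window: int) -> np.ndarray:
    """Windowed standard deviation (per channel, replicated edges) plus
    ``phi`` times the global scalar mean of the dehazed image."""
    if local_window < 3 or local_window % 2 == 0:
        raise ParameterError(f"local_window must be odd and >= 3, got {local_window}")
    radiance = np.asarray(radiance, dtype=np.float64)
    squeeze = radiance.ndim == 2
    if squeeze:
        radiance = radiance[:, :, None]
    local_std = np.empty_like(radiance)
    for c in range(radiance.shape[2]):
        plane = radiance[:, :, c]
        mean = ndimage.uniform_filter(plane, size=local_window, mode="nearest")
        mean_sq = ndimage.uniform_filter(plane * plane, size=local_window, mode="nearest")
        # E[x^2] - E[x]^2 can dip slightly below 0 through rounding
        local_std[:, :, c] = np.sqrt(np.clip(mean_sq - mean * mean, 0.0, None))
    result = local_std + phi * radiance.mean()
    return result[:, :, 0] if squeeze else result


def fuse_and_clip(
    global_map: np.ndarray, local_map: np.ndarray, original: np.ndarray
) -> np.ndarray:
    """Final fusion ``Y = clip(G + H - I, 0, 1)``."""
    global_map = np.asarray(global_map, dtype=np.float64)
    local_map = np.asarray(local_map, dtype=np.float64)
    original = _as_rgb(original)
    if global_map.shape[:2] != original.shape[:2] or local_map.shape[:2] != original.shape[:2]:
        raise ShapeError(
            f"spatial shapes differ: G {global_map.shape}, H {local_map.shape}, "
            f"I {original.shape}"
        )
    if global_map.ndim == 2:
        global_map = global_map[:, :, None]
    if local_map.ndim == 2:
        local_map = local_map[:, :, None]
    return np.clip(global_map + local_map - original, 0.0, 1.0)


def enhance_image(
    image: np.ndarray,
    dehaze: DehazeParams = DehazeParams(),
    contrast: ContrastParams = ContrastParams(),
    return_intermediates: bool = False,
):
    """Full HRLG enhancement: dehaze, global contrast, local contrast, fuse.

    Deterministic; output lies in ``[0, 1]`` with the input's spatial shape.
    """
    image = _as_rgb(image)
    dark = compute_dark_channel(image, dehaze.patch_size)
    light = estimate_atmospheric_light(image, dark, dehaze.light_fraction)
    light = np.maximum(light, 1e-6)  # guard against an all-black image
    transmission = estimate_transmission(image, light, dehaze.omega, dehaze.patch_size)
    radiance_raw = recover_radiance(image, transmission, light, dehaze.t0, clip=False)
    radiance = np.clip(radiance_raw, 0.0, 1.0)
    g_map = global_contrast_map(radiance, contrast.gain_k)
    h_map = local_contrast_map(radiance, contrast.phi, contrast.local_window)
    enhanced = fuse_and_clip(g_map, h_map, image)
    if return_intermediates:
        return enhanced, DehazeIntermediates(
            dark_channel=dark,
            transmission=transmission,
            atmospheric_light=light,
            radiance=radiance_raw,
        )
    return enhanced
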