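"""Synthetic ultrasound-like image generation, speckle noise, and Wiener denoising.

Images are plain 2-D ``float64`` arrays with intensities in [0, 1]; they are
read and written as 8-bit grayscale PNG/TIFF.  Two texture classes are
emulated: *normal* liver parenchyma (a smooth, correlated speckle-free base
texture) and *cirrhotic* tissue (coarser texture, brighter overall
echogenicity, and bright lesion-like blobs).  The degradation model is

    g(q, r) = h(q, r) + m(q, r)

with ``m`` a zero-mean Gaussian noise field (a multiplicative variant
``h * (1 + m)``, the conventional speckle form, is available behind a flag).
Restoration uses the classic local-statistics adaptive Wiener filter and is
scored with MSE/PSNR on the 8-bit (0-255) intensity scale.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

__all__ = [
    "SpeckleMode",
    "SpeckleParams",
    "TextureClassSpec",
    "NORMAL_SPEC",
    "CIRRHOTIC_SPEC",
    "default_spec",
    "generate_image",
    "add_speckle",
    "adaptive_wiener",
    "mse_image",
    "psnr",
    "read_image",
    "write_image",
]

MIN_DIM = 8


class SpeckleMode(str, enum.Enum):
    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"


@dataclasses.dataclass(frozen=True)
class SpeckleParams:
    """Parameters of the speckle noise field ``m(q, r)``.

    ``noise_sigma`` is the standard deviation of the zero-mean Gaussian noise
    field; ``mode`` selects the additive model (default, as the degradation
    equation is written) or the conventional multiplicative speckle variant.
    """

    noise_sigma: float
    mode: SpeckleMode = SpeckleMode.ADDITIVE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not self.noise_sigma < 1:
            raise ValueError(f"noise_sigma must be < 1, got {self.noise_sigma}")


@dataclasses.dataclass(frozen=True)
class TextureClassSpec:
    """Generative recipe for one tissue class.

    base_mean / base_variance set the first two moments of the correlated
    Gaussian base texture; ``correlation_length`` (pixels) sets its smoothness.
    ``blob_count`` bright Gaussian blobs of amplitude ``blob_contrast`` model
    focal lesion-like structure in the cirrhotic class.
    """

    label: str
    base_mean: float
    base_variance: float
    blob_count: int = 0
    blob_contrast: float = 0.0
    correlation_length: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_mean < 1.0:
            raise ValueError(f"base_mean must lie in (0, 1), got {self.base_mean}")
        if self.base_variance < 0:
            raise ValueError("base_variance must be >= 0")
        if self.blob_count < 0:
            raise ValueError("blob_count must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")


#: Default class recipes.  Normal parenchyma: mid-dark, smooth, homogeneous.
#: Cirrhotic tissue: brighter (coarse echotexture reads as higher overall
#: echogenicity), higher variance, shorter correlation length, and bright
#: lesion-like blobs.
NORMAL_SPEC = TextureClassSpec(
    label="normal", base_mean=0.35, base_variance=0.010,
    blob_count=0, blob_contrast=0.0, correlation_length=6.0,
)
CIRRHOTIC_SPEC = TextureClassSpec(
    label="cirrhotic", base_mean=0.55, base_variance=0.020,
    blob_count=12, blob_contrast=0.25, correlation_length=3.0,
)


def default_spec(label: str) -> TextureClassSpec:
    """Return the default generative spec for ``"normal"`` or ``"cirrhotic"``."""
    specs = {"normal": NORMAL_SPEC, "cirrhotic": CIRRHOTIC_SPEC}
    try:
        return specs[label]
    except KeyError:
        raise ValueError(f"unknown class label {label!r}") from None


def _validate_image(img: np.ndarray) -> np.ndarray:
    """Basic checks for filter/metric inputs (generation enforces MIN_DIM)."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={img.ndim}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"empty image: {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite intensities")
    return img


def generate_image(
    spec: TextureClassSpec, height: int, width: int, seed: int
) -> np.ndarray:
    """Generate one synthetic tissue image for ``spec``, deterministic per seed.

    The base texture is a correlated Gaussian random field (white noise
    smoothed at ``correlation_length`` and rescaled to ``base_variance``)
    centred on ``base_mean``; bright blobs are then superimposed and the
    result clipped to [0, 1].
    """
    if height < MIN_DIM or width < MIN_DIM:
        raise ValueError(
            f"dimensions must be >= {MIN_DIM}, got {height}x{width}"
        )
    rng = np.random.default_rng(seed)
    img = np.full((height, width), spec.base_mean, dtype=float)
    if spec.base_variance > 0:
        field = rng.standard_normal((height, width))
        field = gaussian_filter(field, sigma=spec.correlation_length, mode="reflect")
        sd = field.std()
        if sd > 0:
            field *= np.sqrt(spec.base_variance) / sd
        img += field
    if spec.blob_count > 0 and spec.blob_contrast != 0.0:
        yy, xx = np.mgrid[0:height, 0:width]
        for _ in range(spec.blob_count):
            cy = rng.uniform(0, height)
            cx = rng.uniform(0, width)
            radius = rng.uniform(0.015, 0.05) * min(height, width)
            amp = spec.blob_contrast * rng.uniform(0.6, 1.0)
            img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius**2))
    return np.clip(img, 0.0, 1.0)


def add_speckle(img: np.ndarray, p: SpeckleParams) -> np.ndarray:
    """Corrupt ``img`` with the speckle model; same seed gives the same field."""
    img = _validate_image(img)
    if p.noise_sigma == 0:
        return img.copy()
    rng = np.random.default_rng(p.seed)
    m = rng.normal(0.0, p.noise_sigma, size=img.shape)
    if p.mode is SpeckleMode.ADDITIVE or p.mode == "additive":
        noisy = img + m
    else:
        noisy = img * (1.0 + m)
    return np.clip(noisy, 0.0, 1.0)


def adaptive_wiener(
    img: np.ndarray, window: int = 3, noise_variance: float | str = "auto"
) -> np.ndarray:
    """Local-statistics adaptive Wiener filter.

    For every pixel, with local mean mu and variance s2 over a ``window`` x
    ``window`` neighbourhood (symmetric boundary padding) and noise variance
    nu (``"auto"`` = mean of the local variances):

        out = mu + max(s2 - nu, 0) / max(s2, nu) * (in - mu)

    Smoothing therefore adapts to local variation: flat regions are averaged,
    high-variance regions (edges) pass through nearly unchanged.
    """
    img = _validate_image(img)
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if window > min(img.shape):
        raise ValueError(
            f"window {window} exceeds smallest image dimension {min(img.shape)}"
        )
    mu = uniform_filter(img, size=window, mode="reflect")
    mu2 = uniform_filter(img * img, size=window, mode="reflect")
    local_var = np.maximum(mu2 - mu * mu, 0.0)
    if noise_variance == "auto":
        nu = float(local_var.mean())
    else:
        nu = float(noise_variance)
        if nu < 0:
            raise ValueError("noise_variance must be >= 0")
    gain = np.maximum(local_var - nu, 0.0) / np.maximum(local_var, max(nu, 1e-300))
    return mu + gain * (img - mu)


def mse_image(reference: np.ndarray, test: np.ndarray) -> float:
    """Mean squared error between two images on the 8-bit (0-255) scale."""
    reference = _validate_image(reference)
    test = _validate_image(test)
    if reference.shape != test.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {test.shape}"
        )
    diff = (reference - test) * 255.0
    return float(np.mean(diff * diff))


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB (255 peak); +inf for identical images."""
    mse = mse_image(reference, test)
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(255.0**2 / mse))


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF into a [0, 1] float image."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) written by other tools
        arr = arr[..., :3].mean(axis=2)
    return _validate_image(arr.astype(float) / 255.0)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale (format from extension)."""
    img = _validate_image(img)
    iio.imwrite(path, np.round(np.clip(img, 0, 1) * 255).astype(np.uint8))
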