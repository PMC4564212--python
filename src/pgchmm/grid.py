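"""Image container with an explicit intensity-range convention.

Photon-limited acquisitions are handled on two conventional scales: the unit
scale [0, 1] used for low-count experiments, and the byte scale [0, 255] used
for classic 8-bit benchmarks.  Because the Poisson slope ``a`` of the noise
model has intensity units, silently rescaling an image would silently rescale
the noise model; the convention is therefore always declared, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["ImageGrid", "NoiseParams", "read_image", "write_image"]

_RANGE_MAX = {"unit": 1.0, "byte": 255.0}


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D intensity field plus its declared value-range convention.

    Parameters
    ----------
    values : ndarray
        2-D array of finite real intensities.
    range_convention : {"unit", "byte"}
        Declared scale: ``"unit"`` for [0, 1], ``"byte"`` for [0, 255].
    """

    values: np.ndarray
    range_convention: str = "unit"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if self.range_convention not in _RANGE_MAX:
            raise ValueError(f"unknown range convention {self.range_convention!r}")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def range_max(self) -> float:
        return _RANGE_MAX[self.range_convention]

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        return ImageGrid(values, self.range_convention)

    def clipped(self) -> "ImageGrid":
        return self.with_values(np.clip(self.values, 0.0, self.range_max))

    def to_scale(self, range_convention: str) -> "ImageGrid":
        """Explicitly convert between the unit and byte conventions."""
        if range_convention == self.range_convention:
            return self
        factor = _RANGE_MAX[range_convention] / self.range_max
        return ImageGrid(self.values * factor, range_convention)

    def assert_same_scale(self, other) -> None:
        o = getattr(other, "range_convention", getattr(other, "scale", None))
        if o != self.range_convention:
            raise ValueError(
                f"range-convention mismatch: {self.range_convention!r} vs {o!r}"
            )


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the affine noise-variance law ``sigma^2(y) = a*y + b``.

    ``a`` is the Poisson slope (variance added per unit of intensity;
    equivalently the reciprocal of the photon scale factor chi), ``b`` the
    variance of the signal-independent Gaussian read noise.  Both refer to the
    intensity scale named by ``scale``.
    """

    a: float
    b: float
    scale: str = "unit"

    def __post_init__(self):
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("noise parameters must be finite")
        if self.a < 0 or self.b < 0:
            raise ValueError("noise parameters must satisfy a >= 0, b >= 0")
        if self.scale not in _RANGE_MAX:
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def chi(self) -> float:
        """Photon scale factor chi = 1/a (infinite for pure Gaussian noise)."""
        return np.inf if self.a == 0 else 1.0 / self.a

    def to_scale(self, scale: str) -> "NoiseParams":
        """Rescale (a, b) to the other intensity convention.

        Under y -> c*y the Poisson slope transforms as a -> c*a and the
        Gaussian variance as b -> c^2*b.
        """
        if scale == self.scale:
            return self
        c = _RANGE_MAX[scale] / _RANGE_MAX[self.scale]
        return NoiseParams(self.a * c, self.b * c * c, scale)


def read_image(path, range_convention: str = "unit") -> ImageGrid:
    """Read an 8/16-bit grayscale PNG or TIFF into an :class:`ImageGrid`.

    The stored integer range is mapped onto the requested convention
    explicitly: an 8-bit file read as ``"unit"`` is divided by 255, as
    ``"byte"`` it is kept in 0..255; 16-bit files use 65535 as full scale.
    Multi-channel files must be split by the caller.
    """
    path = str(path)
    arr = tifffile.imread(path) if path.lower().endswith((".tif", ".tiff")) else iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(
            f"expected a single-channel image, got shape {arr.shape}; "
            "process multi-channel images one channel at a time"
        )
    if arr.dtype == np.uint8:
        full = 255.0
    elif arr.dtype == np.uint16:
        full = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        full = 1.0
    else:
        raise ValueError(f"unsupported dtype {arr.dtype}")
    scaled = arr.astype(np.float64) / full * _RANGE_MAX[range_convention]
    return ImageGrid(scaled, range_convention)


def write_image(path, image: ImageGrid, dtype: str = "uint16") -> None:
    """Write an image as 8- or 16-bit grayscale PNG/TIFF (values clipped)."""
    path = str(path)
    full = 255.0 if dtype == "uint8" else 65535.0
    v = np.clip(image.values / image.range_max, 0.0, 1.0) * full
    out = np.round(v).astype(dtype)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
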