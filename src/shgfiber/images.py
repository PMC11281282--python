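"""Core image containers and TIFF I/O for SHG micrographs.

Second-harmonic-generation (SHG) microscopy detects fibrillar collagen through
an intrinsic frequency-doubled signal: illumination at wavelength ``lambda_ex``
produces emission at exactly ``lambda_ex / 2``.  Images are non-negative
grayscale intensity grids, either a single 2D field of view (y, x) or a z-stack
(z, y, x), with a physical in-plane pixel size in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import tifffile

#: Default in-plane sampling of a single field of view, um per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.497

#: Default z spacing of tiled-scan stacks, um between planes.
DEFAULT_Z_STEP_UM = 3.0

#: Excitation wavelength of the two-photon source, nm.
DEFAULT_EXCITATION_NM = 860.0


def shg_detection_wavelength_nm(excitation_nm: float = DEFAULT_EXCITATION_NM) -> float:
    """Wavelength at which the SHG signal is detected, in nm.

    Second-harmonic emission is frequency doubled, so the detection band sits
    at exactly half the excitation wavelength (860 nm excitation -> 430 nm).
    """
    if excitation_nm <= 0:
        raise ValueError("excitation wavelength must be positive")
    return excitation_nm / 2.0


@dataclass
class ShgImage:
    """A grayscale SHG intensity grid with physical voxel sizes.

    Parameters
    ----------
    intensities
        Non-negative float array, 2D ``(y, x)`` or 3D ``(z, y, x)``.
    pixel_size_um
        In-plane sampling, um per pixel.
    z_step_um
        Spacing between planes for 3D stacks; ignored for 2D images.
    """

    intensities: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D grid, got ndim={self.intensities.ndim}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    @property
    def is_stack(self) -> bool:
        return self.intensities.ndim == 3

    def max_project(self) -> "ShgImage":
        """Maximum-intensity projection of a z-stack; identity for 2D."""
        if not self.is_stack:
            return self
        return ShgImage(self.intensities.max(axis=0), pixel_size_um=self.pixel_size_um)


@dataclass
class FiberMask:
    """Boolean grid of segmented fiber voxels, aligned to its source image."""

    mask: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D mask, got ndim={self.mask.ndim}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def union(self, other: "FiberMask") -> "FiberMask":
        if self.shape != other.shape:
            raise ValueError("masks must share a shape")
        return FiberMask(self.mask | other.mask, pixel_size_um=self.pixel_size_um)


def read_tiff(path, pixel_size_um: float | None = None, z_step_um: float = DEFAULT_Z_STEP_UM) -> ShgImage:
    """Read a single- or multi-page grayscale TIFF as an :class:`ShgImage`.

    Pixel size is taken from the ``XResolution`` tag (pixels per um) when
    present and not overridden.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        if pixel_size_um is None:
            pixel_size_um = DEFAULT_PIXEL_SIZE_UM
            try:
                xres = tf.pages[0].tags["XResolution"].value
                if xres[0] > 0:
                    pixel_size_um = xres[1] / xres[0]
            except (KeyError, TypeError, ZeroDivisionError):
                warnings.warn("TIFF has no usable XResolution tag; using default pixel size")
    data = np.asarray(data, dtype=float)
    if data.ndim not in (2, 3):
        raise ValueError("only single-channel grayscale TIFFs are supported")
    return ShgImage(data, pixel_size_um=pixel_size_um, z_step_um=z_step_um)


def write_tiff(path, image: ShgImage) -> None:
    """Write an image as single-page (2D) or multi-page (3D) TIFF.

    Pixel size is recorded through the resolution tags (pixels per um).
    """
    res = 1.0 / image.pixel_size_um
    tifffile.imwrite(
        str(path),
        image.intensities.astype(np.float32),
        photometric="minisblack",
        resolution=(res, res),
        metadata={"pixel_size_um": image.pixel_size_um},
    )


def write_mask_tiff(path, mask: FiberMask) -> None:
    """Write a fiber mask as 8-bit TIFF with fiber voxels at 255."""
    res = 1.0 / mask.pixel_size_um
    tifffile.imwrite(
        str(path),
        (mask.mask.astype(np.uint8) * 255),
        resolution=(res, res),
        metadata={"pixel_size_um": mask.pixel_size_um},
    )


def read_mask_tiff(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> FiberMask:
    """Read an 8-bit 0/255 mask TIFF back into a :class:`FiberMask`."""
    data = tifffile.imread(str(path))
    return FiberMask(np.asarray(data) > 0, pixel_size_um=pixel_size_um)
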