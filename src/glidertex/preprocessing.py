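"""Image preprocessing: block averaging, patching, whitening, binarization.

The pipeline converts grayscale photographs into an ensemble of binary
patches suitable for glider-statistic extraction:

1. block-average over N x N pixel squares (downsampling, removes sensor
   Nyquist artifacts),
2. tile the reduced image into non-overlapping R x R patches,
3. whiten the whole patch ensemble with a single Fourier filter, the
   inverse square root of the ensemble-averaged power spectrum (removes
   the predictable average pairwise structure),
4. binarize each patch about its median intensity (equal numbers of black
   and white pixels, which pins the first-order coordinate gamma at zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glider_stats import COORD_NAMES, coords_from_histogram, count_colorings

__all__ = [
    "GrayImage",
    "PatchEnsemble",
    "ImageTooSmallError",
    "load_image",
    "block_average",
    "extract_patches",
    "whiten_ensemble",
    "binarize_median",
    "run_pipeline",
]


class ImageTooSmallError(ValueError):
    pass


class UnsupportedPatchSizeError(ValueError):
    pass


@dataclass
class GrayImage:
    """A single-channel luminance image with provenance."""

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage expects a 2-D array")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite values")


@dataclass
class PatchEnsemble:
    """Real-valued R x R patches with provenance (image id, grid position)."""

    patches: np.ndarray  # (n, R, R)
    provenance: list[tuple[str, int, int]] = field(default_factory=list)
    R: int = 0
    N: int = 1

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=float)
        if self.patches.ndim != 3 or self.patches.shape[1] != self.patches.shape[2]:
            raise ValueError("patches must be an (n, R, R) array")
        self.R = int(self.patches.shape[1])


def load_image(path: str | Path, image_id: str | None = None) -> GrayImage:
    """Read a grayscale PGM/PNG/TIFF image (16-bit supported)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim == 3:  # collapse any color channels to luminance
        arr = arr[..., :3].mean(axis=-1)
    return GrayImage(arr, image_id or Path(path).stem)


def block_average(img: GrayImage, N: int) -> GrayImage:
    """Average contiguous N x N pixel blocks; trailing remainders are dropped."""
    if N < 1:
        raise ValueError("block factor N must be >= 1")
    L1, L2 = img.pixels.shape
    if N > min(L1, L2):
        raise ImageTooSmallError(f"block factor {N} exceeds image size {L1}x{L2}")
    m1, m2 = L1 // N, L2 // N
    cropped = img.pixels[: m1 * N, : m2 * N]
    reduced = cropped.reshape(m1, N, m2, N).mean(axis=(1, 3))
    return GrayImage(reduced, img.image_id)


def extract_patches(img: GrayImage, R: int, N: int = 1) -> PatchEnsemble:
    """Tile non-overlapping R x R patches from the top-left corner."""
    if R < 1:
        raise ValueError("patch size R must be >= 1")
    L1, L2 = img.pixels.shape
    n1, n2 = L1 // R, L2 // R
    if n1 == 0 or n2 == 0:
        warnings.warn(
            f"image {img.image_id!r} ({L1}x{L2}) too small for R={R}: 0 patches"
        )
        return PatchEnsemble(np.empty((0, R, R)), [], R=R, N=N)
    patches = []
    prov = []
    for i in range(n1):
        for j in range(n2):
            patches.append(img.pixels[i * R : (i + 1) * R, j * R : (j + 1) * R])
            prov.append((img.image_id, i, j))
    return PatchEnsemble(np.stack(patches), prov, R=R, N=N)


def whitening_filter(patches: np.ndarray) -> np.ndarray:
    """Inverse square root of the ensemble-averaged Fourier power spectrum.

    The DC gain is zero (the ensemble mean is removed rather than
    amplified), and any frequency with exactly zero ensemble power gets
    zero gain with a warning.
    """
    spectra = np.fft.fft2(patches, axes=(-2, -1))
    power = np.mean(np.abs(spectra) ** 2, axis=0)
    W = np.zeros_like(power)
    nonzero = power > 0
    W[nonzero] = power[nonzero] ** -0.5
    W[0, 0] = 0.0
    dead = ~nonzero
    dead[0, 0] = False
    if dead.any():
        warnings.warn(f"{dead.sum()} frequencies have zero ensemble power; gain set to 0")
    return W


def whiten_ensemble(ens: PatchEnsemble) -> PatchEnsemble:
    """Apply the single ensemble whitening filter to every patch."""
    if ens.patches.shape[0] < 2:
        raise ValueError("whitening requires at least 2 patches")
    W = whitening_filter(ens.patches)
    spectra = np.fft.fft2(ens.patches, axes=(-2, -1))
    out = np.fft.ifft2(spectra * W, axes=(-2, -1)).real
    return PatchEnsemble(out, list(ens.provenance), R=ens.R, N=ens.N)


def binarize_median(patch: np.ndarray) -> np.ndarray:
    """Binarize about the median: lower half of the ranked pixels -> -1.

    Requires an even pixel count so the split is exact.  Ties at the
    median are broken deterministically in raster-scan order (stable sort).
    """
    patch = np.asarray(patch, dtype=float)
    R2 = patch.size
    if R2 % 2 != 0:
        raise UnsupportedPatchSizeError("patch must have an even number of pixels")
    order = np.argsort(patch.ravel(), kind="stable")
    out = np.empty(R2, dtype=np.int8)
    out[order[: R2 // 2]] = -1
    out[order[R2 // 2 :]] = 1
    return out.reshape(patch.shape)


def run_pipeline(
    images: list[GrayImage],
    N: int,
    R: int,
    whiten: bool = True,
    log_luminance: bool = True,
) -> pd.DataFrame:
    """Full preprocessing + glider-statistic extraction.

    Returns the per-patch stats table with provenance columns and the ten
    coordinates in canonical order (the gamma column is identically zero
    after median binarization and is retained for audit).

    ``log_luminance`` applies log(x + eps) with eps the smallest strictly
    positive pixel value over the image set; the whitening filter is
    computed once over the pooled patch ensemble of all images.
    """
    if not images:
        raise ValueError("empty image list")
    if log_luminance:
        positive = [img.pixels[img.pixels > 0] for img in images]
        positive = [p for p in positive if p.size]
        eps = min(p.min() for p in positive) if positive else 1.0
        images = [GrayImage(np.log(img.pixels + eps), img.image_id) for img in images]

    ensembles = [extract_patches(block_average(img, N), R, N=N) for img in images]
    patches = np.concatenate([e.patches for e in ensembles], axis=0)
    provenance = [p for e in ensembles for p in e.provenance]
    if patches.shape[0] == 0:
        raise ValueError("no patches extracted; images too small for N, R")
    ens = PatchEnsemble(patches, provenance, R=R, N=N)
    if whiten:
        ens = whiten_ensemble(ens)

    rows = []
    for patch, (image_id, i, j) in zip(ens.patches, ens.provenance):
        binary = binarize_median(patch)
        coords = coords_from_histogram(count_colorings(binary))
        rows.append((image_id, i, j, *coords))
    columns = ["image_id", "patch_row", "patch_col", *COORD_NAMES]
    return pd.DataFrame(rows, columns=columns)
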