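"""Micrograph I/O, patch extraction and the display-only bandpass filter.

A :class:`Micrograph` is a 2D real-valued intensity array with a physical
pixel size in nanometres. Intensity is brightness: electron-dense material
is dark. Coordinates are 0-based ``(row, col)`` pixel indices; the physical
position of a pixel centre is ``index * pixel_size`` nm. Public APIs that
take point coordinates use ``(x_nm, y_nm)`` with ``x = col * pixel_size``
and ``y = row * pixel_size``.

Supported on-disk formats are TIFF (uint16 or float32, pixel size in a JSON
sidecar ``<stem>.json``) and MRC mode 2 (float32, pixel size in the map
header using the EM convention cell/grid). Images are read back without any
rescaling or normalisation; integer data are promoted to float64 as-is.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import tifffile
from scipy import ndimage


class FormatError(ValueError):
    """File is not a recognised micrograph format."""


class PixelSizeError(ValueError):
    """No pixel size available from header, sidecar or override."""


@dataclass
class Micrograph:
    """2D intensity image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Intensity values; finite, at least 16 x 16.
    pixel_size : float
        Pixel size in nm/px, > 0.
    provenance : dict
        Free-form metadata. The key ``"bandpass"`` marks display-filtered
        images; symmetry analysis refuses to trust them silently.
    """

    pixels: np.ndarray
    pixel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError(f"micrograph must be at least 16x16 px, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph contains non-finite values")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_float(self) -> "Micrograph":
        """Return a float64 view-copy (no rescaling)."""
        return Micrograph(self.pixels.astype(np.float64), self.pixel_size, dict(self.provenance))


@dataclass
class PatchStack:
    """Square odd-sided patches plus originating centers (x_nm, y_nm)."""

    patches: list[Micrograph]
    centers_nm: list[tuple[float, float]]
    pixel_size: float

    def __post_init__(self) -> None:
        sides = {p.pixels.shape for p in self.patches}
        if len(sides) > 1:
            raise ValueError(f"patches differ in shape: {sides}")
        for p in self.patches:
            s = p.pixels.shape[0]
            if p.pixels.shape[1] != s or s % 2 == 0:
                raise ValueError("patches must be square with odd side")

    def __len__(self) -> int:
        return len(self.patches)


# ---------------------------------------------------------------------------
# Reading and writing


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_micrograph(m: Micrograph, path: str | Path) -> Path:
    """Write ``m`` to TIFF or MRC mode 2 depending on the extension.

    uint16 arrays go to TIFF unchanged; everything else is written float32.
    A JSON sidecar ``<name>.<ext>.json`` records ``pixel_size_nm`` for both
    formats (for MRC the header also carries it, EM cell/grid convention).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = m.pixels if m.pixels.dtype == np.uint16 else m.pixels.astype(np.float32)
        tifffile.imwrite(path, data)
    elif suffix == ".mrc":
        ccp4 = gemmi.Ccp4Map()
        # gemmi grids are (nx, ny, nz); store image as x=col, y=row, z=1
        data = np.ascontiguousarray(m.pixels.T.astype(np.float32)[:, :, np.newaxis])
        ccp4.grid = gemmi.FloatGrid(data)
        nx, ny = m.pixels.shape[1], m.pixels.shape[0]
        a = nx * m.pixel_size * 10.0  # nm -> Angstrom
        b = ny * m.pixel_size * 10.0
        ccp4.grid.unit_cell = gemmi.UnitCell(a, b, m.pixel_size * 10.0, 90, 90, 90)
        ccp4.update_ccp4_header()
        ccp4.write_ccp4_map(str(path))
    else:
        raise FormatError(f"unsupported micrograph extension {suffix!r} (use .tif/.tiff/.mrc)")
    _sidecar_path(path).write_text(json.dumps({"pixel_size_nm": m.pixel_size}))
    return path


def read_micrograph(path: str | Path, pixel_size_override: float | None = None) -> Micrograph:
    """Read a TIFF or MRC micrograph.

    Pixel size resolution order: explicit override, then MRC header (for
    MRC), then the JSON sidecar. Missing pixel size raises
    :class:`PixelSizeError` rather than guessing a default.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
        header_ps = None
    elif suffix == ".mrc":
        ccp4 = gemmi.read_ccp4_map(str(path))
        arr = np.array(ccp4.grid, copy=True)
        if arr.ndim != 3 or arr.shape[2] != 1:
            raise FormatError(f"expected a single-section 2D MRC map, got grid {arr.shape}")
        pixels = arr[:, :, 0].T
        header_ps = ccp4.grid.unit_cell.a / ccp4.grid.nu / 10.0  # Angstrom -> nm
    else:
        raise FormatError(f"unsupported micrograph extension {suffix!r} (use .tif/.tiff/.mrc)")

    if pixel_size_override is not None:
        ps = float(pixel_size_override)
    elif header_ps is not None and header_ps > 0:
        ps = float(header_ps)
    else:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            ps = float(json.loads(sidecar.read_text())["pixel_size_nm"])
        else:
            raise PixelSizeError(
                f"no pixel size for {path.name}: supply a sidecar {sidecar.name} "
                "or pixel_size_override"
            )
    if np.issubdtype(pixels.dtype, np.integer):
        pixels = pixels.astype(np.float64)
    return Micrograph(pixels, ps, {"source": str(path)})


# ---------------------------------------------------------------------------
# Patch extraction


def patch_side_px(radius_nm: float, pixel_size: float) -> int:
    """Odd patch side in pixels covering ``radius_nm``: 2*ceil(r/ps) + 1."""
    return 2 * math.ceil(radius_nm / pixel_size) + 1


def extract_patch(m: Micrograph, center_nm: tuple[float, float], radius_nm: float) -> Micrograph:
    """Extract the square odd-sided patch centred on the pixel nearest ``center_nm``.

    ``center_nm`` is ``(x, y)`` in nm. The window must lie wholly inside the
    image; a window crossing the border raises ValueError (no padding).
    """
    x_nm, y_nm = center_nm
    col = int(round(x_nm / m.pixel_size))
    row = int(round(y_nm / m.pixel_size))
    half = math.ceil(radius_nm / m.pixel_size)
    r0, r1 = row - half, row + half + 1
    c0, c1 = col - half, col + half + 1
    nrow, ncol = m.pixels.shape
    if r0 < 0 or c0 < 0 or r1 > nrow or c1 > ncol:
        raise ValueError(
            f"patch window rows[{r0}:{r1}] cols[{c0}:{c1}] crosses the border of "
            f"a {nrow}x{ncol} image"
        )
    prov = dict(m.provenance)
    prov.update({"patch_center_nm": (float(x_nm), float(y_nm)), "patch_radius_nm": float(radius_nm)})
    return Micrograph(m.pixels[r0:r1, c0:c1].copy(), m.pixel_size, prov)


def extract_patches(
    m: Micrograph, centers_nm: list[tuple[float, float]], radius_nm: float
) -> PatchStack:
    """Extract a stack of same-sized patches; centres whose window crosses
    the border are skipped with a warning."""
    patches, kept = [], []
    for c in centers_nm:
        try:
            patches.append(extract_patch(m, c, radius_nm))
            kept.append((float(c[0]), float(c[1])))
        except ValueError:
            warnings.warn(f"skipping patch at {c}: window crosses image border", stacklevel=2)
    return PatchStack(patches, kept, m.pixel_size)


# ---------------------------------------------------------------------------
# Display-only bandpass


def bandpass_filter(m: Micrograph, low_cut_px: float = 40.0, high_cut_px: float = 3.0) -> Micrograph:
    """Fourier-domain Gaussian bandpass with feature-size semantics.

    Suppresses structures larger than ``low_cut_px`` and smaller than
    ``high_cut_px`` (defaults 40 and 3 px). Implemented as a difference of
    Gaussians in frequency space with sigmas chosen so the half-power points
    sit at the cutoff feature sizes; the mean (DC) is restored afterwards.

    This filter exists FOR DISPLAY ONLY. Symmetry reinforcement must run on
    raw data; the output is tagged ``provenance["bandpass"]`` so downstream
    analysis can warn.
    """
    if not low_cut_px > high_cut_px > 0:
        raise ValueError(f"need low_cut_px > high_cut_px > 0, got ({low_cut_px}, {high_cut_px})")
    img = m.pixels.astype(np.float64)
    fy = np.fft.fftfreq(img.shape[0])[:, None]
    fx = np.fft.fftfreq(img.shape[1])[None, :]
    f2 = fy * fy + fx * fx
    # half-power at f = 1/cutoff: exp(-f^2 / (2 sigma^2)) = 1/2
    two_sig2_low = (1.0 / low_cut_px) ** 2 / math.log(2.0)
    two_sig2_high = (1.0 / high_cut_px) ** 2 / math.log(2.0)
    transfer = np.exp(-f2 / two_sig2_high) * (1.0 - np.exp(-f2 / two_sig2_low))
    out = np.fft.ifft2(np.fft.fft2(img) * transfer).real
    out += img.mean() - out.mean()
    prov = dict(m.provenance)
    prov["bandpass"] = {"low_cut_px": float(low_cut_px), "high_cut_px": float(high_cut_px)}
    return Micrograph(out, m.pixel_size, prov)


def median_prefilter(m: Micrograph, radius_px: int = 1) -> Micrograph:
    """Optional detector-noise cleanup: median filter of the given pixel
    radius. Off by default everywhere; provided for very noisy detectors."""
    size = 2 * radius_px + 1
    out = ndimage.median_filter(m.pixels.astype(np.float64), size=size)
    prov = dict(m.provenance)
    prov["median_prefilter_px"] = radius_px
    return Micrograph(out, m.pixel_size, prov)
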