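"""Core containers and I/O for calibrated microscopy and spectroscopy data.

Every downstream stage consumes the validated objects defined here:
time-lapse image stacks with physical pixel size and timestamps, circular
sampling regions, traced cell outlines, and Raman spectra on a uniform
wavenumber grid. Conventions: image origin top-left, x rightward, y
downward, 0-based pixel indices; physical coordinates are pixel index
times ``pixel_size``; a pixel belongs to a circular ROI iff its center
lies within the radius (inclusive).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import LinearRing

__all__ = [
    "ImageStack",
    "CircularROI",
    "Outline",
    "Spectrum",
    "StackFormatError",
    "ValidationError",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "roi_mask",
    "read_outlines",
    "write_outlines",
    "read_spectrum",
    "write_spectrum",
    "register_translation",
    "select_best_focus",
]

ROI_LABELS = frozenset(
    {"IF-SCW", "IF-CML", "IF-CC", "IF", "XF", "PX", "MX", "SX", "phloem"}
)
MORPHOTYPES = frozenset({"PX", "MX", "SX"})


class StackFormatError(ValueError):
    """Raised when image files cannot be assembled into a stack."""


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


@dataclass
class ImageStack:
    """Time-ordered raster stack with physical calibration.

    Parameters
    ----------
    frames : ndarray
        ``(T, H, W)`` grayscale or ``(T, H, W, 3)`` RGB, uint8 or uint16.
    timestamps : ndarray
        Acquisition times in minutes, strictly increasing, length ``T``.
    pixel_size : float
        Physical pixel size in µm per pixel, finite and positive.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim not in (3, 4):
            raise ValidationError(
                f"frames must be (T,H,W) or (T,H,W,3), got shape {self.frames.shape}"
            )
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise ValidationError("color stacks must have exactly 3 channels (RGB)")
        if self.frames.dtype not in (np.uint8, np.uint16):
            raise ValidationError(f"bit depth must be 8 or 16, got {self.frames.dtype}")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValidationError(
                f"{len(self.timestamps)} timestamps for {self.frames.shape[0]} frames"
            )
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValidationError(f"pixel_size must be finite and > 0, got {self.pixel_size}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def is_color(self) -> bool:
        return self.frames.ndim == 4

    @property
    def bit_depth(self) -> int:
        return 8 if self.frames.dtype == np.uint8 else 16

    @property
    def white_level(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class CircularROI:
    """Labeled circular sampling region in physical units (µm)."""

    image_id: str
    label: str
    center: tuple[float, float]  # (x, y) µm
    diameter: float  # µm

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValidationError(f"ROI diameter must be > 0, got {self.diameter}")
        if self.label not in ROI_LABELS:
            raise ValidationError(
                f"unknown ROI label {self.label!r}; expected one of {sorted(ROI_LABELS)}"
            )


@dataclass
class Outline:
    """Ordered closed boundary of a traced cell perimeter.

    Vertices are implicitly closed (last vertex differs from the first);
    orientation is normalized to counter-clockwise on construction.
    """

    shape_id: str
    vertices: np.ndarray  # (n, 2)
    morphotype: str = "MX"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be an (n, 2) array")
        if np.allclose(self.vertices[0], self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 4:
            raise ValidationError(f"outline needs >= 4 vertices, got {len(self.vertices)}")
        if self.morphotype not in MORPHOTYPES:
            raise ValidationError(f"morphotype must be one of {sorted(MORPHOTYPES)}")
        ring = LinearRing(self.vertices)
        if not ring.is_simple:
            raise ValidationError(f"outline {self.shape_id!r} is self-intersecting")
        if not ring.is_ccw:
            self.vertices = self.vertices[::-1].copy()

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Spectrum:
    """Wavenumber/intensity pairs on a uniform grid.

    The axis must be strictly increasing with uniform spacing (relative
    tolerance 1e-6); intensities may dip below zero only after baseline
    subtraction.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    spectrum_id: str = ""
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape or self.wavenumbers.ndim != 1:
            raise ValidationError("wavenumber and intensity axes must be equal-length 1-D")
        d = np.diff(self.wavenumbers)
        if len(d) and not np.all(d > 0):
            raise ValidationError("wavenumbers must be strictly increasing")
        if len(d) and (d.max() - d.min()) > 1e-6 * abs(d.mean()):
            raise ValidationError("wavenumber axis must be uniformly spaced")

    @property
    def spacing(self) -> float:
        return float(np.mean(np.diff(self.wavenumbers)))

    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.wavenumbers = out.wavenumbers.copy()
        out.intensities = out.intensities.copy()
        return out


# ---------------------------------------------------------------------------
# Raster I/O


def read_stack(paths, pixel_size: float, timestamps) -> ImageStack:
    """Assemble an :class:`ImageStack` from an ordered list of image files.

    A single multi-page TIFF path is also accepted. 16-bit inputs are
    retained at native depth; color order is RGB.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    frames = []
    for p in paths:
        if not os.path.exists(p):
            raise StackFormatError(f"file not found: {p}")
        arr = iio.imread(p)
        if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.ndim == 3 and arr.shape[-1] not in (3,) and str(p).lower().endswith((".tif", ".tiff")):
            # multi-page grayscale TIFF: (pages, H, W)
            frames.extend(arr)
            continue
        if arr.ndim == 4:  # multi-page color TIFF
            frames.extend(arr)
            continue
        frames.append(arr)
    shapes = {f.shape for f in frames}
    dtypes = {f.dtype for f in frames}
    if len(shapes) > 1 or len(dtypes) > 1:
        for p in paths:
            a = iio.imread(p)
            if a.shape != frames[0].shape or a.dtype != frames[0].dtype:
                raise StackFormatError(
                    f"frame {p} has shape {a.shape}/{a.dtype}, expected "
                    f"{frames[0].shape}/{frames[0].dtype}"
                )
        raise StackFormatError("frames have mismatched shapes or bit depths")
    return ImageStack(np.stack(frames), np.asarray(timestamps, dtype=float), pixel_size)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF (lossless, native bit depth)."""
    tifffile.imwrite(path, stack.frames, photometric="rgb" if stack.is_color else "minisblack")


# ---------------------------------------------------------------------------
# Table I/O

_ROI_COLS = ["image_id", "label", "x_um", "y_um", "diameter_um"]


def read_rois(path) -> pd.DataFrame:
    """Read a circular-ROI table (image_id,label,x_um,y_um,diameter_um)."""
    df = pd.read_csv(path)
    missing = [c for c in _ROI_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"ROI table missing columns: {missing}")
    for _, row in df.iterrows():
        CircularROI(str(row.image_id), str(row.label), (row.x_um, row.y_um), row.diameter_um)
    return df[_ROI_COLS + [c for c in df.columns if c not in _ROI_COLS]]


def write_rois(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def roi_mask(shape: tuple[int, int], row, pixel_size: float) -> np.ndarray:
    """Boolean pixel mask of one ROI table row on an image of given shape.

    Membership rule: pixel center (index × pixel_size) within the radius,
    inclusive. Raises if the circle is not fully inside the image bounds.
    """
    h, w = shape
    cx, cy, r = row["x_um"], row["y_um"], row["diameter_um"] / 2.0
    if cx - r < 0 or cy - r < 0 or cx + r > (w - 1) * pixel_size or cy + r > (h - 1) * pixel_size:
        raise ValidationError(
            f"ROI {row.get('label', '?')} at ({cx:g}, {cy:g}) µm extends outside image bounds"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx * pixel_size - cx) ** 2 + (yy * pixel_size - cy) ** 2
    m = d2 <= r * r + 1e-12
    if not m.any():  # sub-pixel ROI: fall back to nearest pixel center
        iy, ix = int(round(cy / pixel_size)), int(round(cx / pixel_size))
        m[iy, ix] = True
    return m


def read_outlines(path) -> list[Outline]:
    """Read outlines from CSV (shape_id,morphotype,vertex_index,x,y)."""
    df = pd.read_csv(path)
    need = {"shape_id", "morphotype", "vertex_index", "x", "y"}
    if not need.issubset(df.columns):
        raise ValidationError(f"outline table missing columns: {sorted(need - set(df.columns))}")
    out = []
    for sid, g in df.groupby("shape_id", sort=False):
        g = g.sort_values("vertex_index")
        out.append(Outline(str(sid), g[["x", "y"]].to_numpy(), str(g.morphotype.iloc[0])))
    return out


def write_outlines(outlines: list[Outline], path) -> None:
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(o.vertices):
            rows.append((o.shape_id, o.morphotype, i, x, y))
    pd.DataFrame(rows, columns=["shape_id", "morphotype", "vertex_index", "x", "y"]).to_csv(
        path, index=False
    )


def read_spectrum(path, spectrum_id: str | None = None) -> Spectrum:
    """Read a 2-column delimited spectrum; '#' lines are comments."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValidationError(f"spectrum file {path} must have 2 columns")
    sid = spectrum_id if spectrum_id is not None else os.path.splitext(os.path.basename(path))[0]
    return Spectrum(arr[:, 0], arr[:, 1], spectrum_id=sid)


def write_spectrum(spec: Spectrum, path, header: str = "") -> None:
    np.savetxt(
        path,
        np.column_stack([spec.wavenumbers, spec.intensities]),
        fmt="%.8g",
        header=header,
        comments="# ",
    )


# ---------------------------------------------------------------------------
# Registration and focus selection


def _as_gray_float(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=float)
    if f.ndim == 3:
        f = f.mean(axis=-1)
    return f


@dataclass
class RegistrationResult:
    shift: tuple[int, int]  # (dx, dy): displacement of moving relative to reference
    registered: np.ndarray  # moving shifted back into the reference frame
    mask: np.ndarray  # True where registered carries real data (not edge fill)
    peak_correlation: float
    low_confidence: bool = False


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_translation(
    moving: np.ndarray,
    reference: np.ndarray,
    window: int = 10,
    correlation_floor: float = 0.3,
) -> RegistrationResult:
    """Integer-pixel translation registration by normalized cross-correlation.

    Searches shifts within ``±window`` pixels and returns the displacement
    ``(dx, dy)`` of the moving frame relative to the reference (the shift
    the moving frame underwent), together with the moving frame resampled
    back onto the reference grid with edge fill recorded in ``mask``. If
    the best correlation falls below ``correlation_floor`` a zero shift is
    returned and ``low_confidence`` is set.
    """
    mov = _as_gray_float(moving)
    ref = _as_gray_float(reference)
    if mov.shape != ref.shape:
        raise ValidationError(f"shape mismatch: {mov.shape} vs {ref.shape}")
    h, w = ref.shape
    if 2 * window >= min(h, w):
        raise ValidationError("search window too large for frame size (overlap < 50%)")
    best = (-np.inf, 0, 0)
    for dy in range(-window, window + 1):
        for dx in range(-window, window + 1):
            # moving displaced by (dx, dy): moving[y, x] ~ ref[y - dy, x - dx]
            ys0, ys1 = max(0, dy), min(h, h + dy)
            xs0, xs1 = max(0, dx), min(w, w + dx)
            sub_m = mov[ys0:ys1, xs0:xs1]
            sub_r = ref[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
            c = _ncc(sub_m, sub_r)
            if c > best[0]:
                best = (c, dx, dy)
    peak, dx, dy = best
    low = peak < correlation_floor
    if low:
        warnings.warn(
            f"registration peak correlation {peak:.3f} below floor "
            f"{correlation_floor}; returning zero shift",
            stacklevel=2,
        )
        dx = dy = 0
    registered = np.zeros_like(moving)
    mask = np.zeros((h, w), dtype=bool)
    ys0, ys1 = max(0, -dy), min(h, h - dy)
    xs0, xs1 = max(0, -dx), min(w, w - dx)
    registered[ys0:ys1, xs0:xs1] = moving[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx]
    mask[ys0:ys1, xs0:xs1] = True
    return RegistrationResult((dx, dy), registered, mask, peak, low)


def sharpness(frame: np.ndarray) -> float:
    """Focus score: variance of the Laplacian high-pass response."""
    from scipy.ndimage import laplace

    return float(laplace(_as_gray_float(frame)).var())


@dataclass
class FocusSelection:
    stack: ImageStack
    provenance: list[int] = field(default_factory=list)  # chosen Z index per timepoint


def select_best_focus(stacks: list[ImageStack]) -> FocusSelection:
    """Pick, per timepoint, the sharpest frame across co-acquired Z stacks.

    All stacks must share frame counts and timestamps; the winning Z index
    per frame is recorded in ``provenance``. Selection is invariant to the
    order of the input stacks (ties go to the lowest Z index).
    """
    if not stacks:
        raise ValidationError("need at least one stack")
    t0 = stacks[0].timestamps
    for s in stacks[1:]:
        if s.n_frames != stacks[0].n_frames or not np.allclose(s.timestamps, t0):
            raise ValidationError("stacks must share frame counts and timestamps")
    if len(stacks) == 1:
        return FocusSelection(stacks[0], [0] * stacks[0].n_frames)
    frames, chosen = [], []
    for t in range(stacks[0].n_frames):
        scores = [sharpness(s.frames[t]) for s in stacks]
        z = int(np.argmax(scores))
        frames.append(stacks[z].frames[t])
        chosen.append(z)
    return FocusSelection(
        ImageStack(np.stack(frames), t0.copy(), stacks[0].pixel_size), chosen
    )
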