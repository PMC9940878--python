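"""Histochemical stain quantification.

Wiesner (phloroglucinol-HCl) staining reports coniferaldehyde-type lignin
units; it is quantified as uncalibrated optical density of the stained
section minus the unstained section, corrected against unlignified phloem
reference regions to absorb tissue clearing and illumination changes.
Mäule (KMnO4) staining reports syringyl-rich lignin through its red hue;
it is quantified as HSB hue in degrees plus uncalibrated absorbance of
the stained image alone, with no unstained reference.

Uncalibrated OD follows the convention ``OD = log10(white / value)`` with
the pixel value clamped at one count, so a saturated white pixel has OD 0
and OD grows monotonically with darkening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ImageStack, ValidationError, roi_mask

__all__ = [
    "rgb_to_od",
    "differential_absorbance",
    "maule_measure",
    "circular_mean_deg",
]


def rgb_to_od(frame: np.ndarray, bit_depth: int | None = None, per_channel: bool = False) -> np.ndarray:
    """Transform a color frame into uncalibrated optical density.

    Parameters
    ----------
    frame : ndarray
        ``(H, W, 3)`` color raster, uint8 or uint16.
    bit_depth : int, optional
        8 or 16; inferred from dtype when omitted.
    per_channel : bool
        If True, return per-channel OD ``(H, W, 3)``; default averages the
        three channels before the log transform.

    Returns
    -------
    ndarray
        ``OD = log10(white / max(v, 1))`` with ``white = 2**depth - 1``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise TypeError(f"expected (H, W, 3) color frame, got shape {frame.shape}")
    if bit_depth is None:
        if frame.dtype == np.uint8:
            bit_depth = 8
        elif frame.dtype == np.uint16:
            bit_depth = 16
        else:
            raise TypeError(f"cannot infer bit depth from dtype {frame.dtype}")
    if bit_depth not in (8, 16):
        raise ValidationError(f"bit depth must be 8 or 16, got {bit_depth}")
    white = float(2**bit_depth - 1)
    v = frame.astype(float) if per_channel else frame.astype(float).mean(axis=-1)
    return np.log10(white / np.maximum(v, 1.0))


def _frame_of(img) -> np.ndarray:
    if isinstance(img, ImageStack):
        if img.n_frames != 1:
            raise ValidationError("expected a single-frame stack")
        return img.frames[0]
    return np.asarray(img)


def differential_absorbance(
    stained,
    unstained,
    rois: pd.DataFrame,
    reference_label: str = "phloem",
    pixel_size: float | None = None,
    bit_depth: int | None = None,
) -> pd.DataFrame:
    """Background-corrected differential absorbance per ROI (Wiesner test).

    Per ROI, ``od_diff`` is the mean OD over ROI pixels in the stained
    frame minus the same in the unstained frame; ``od_corrected`` subtracts
    the mean ``od_diff`` of the reference-label (unlignified phloem) ROIs,
    so the corrected reference mean is zero by construction. Frames must
    already be registered.
    """
    s_frame, u_frame = _frame_of(stained), _frame_of(unstained)
    if pixel_size is None:
        if not isinstance(stained, ImageStack):
            raise ValidationError("pixel_size required when passing bare arrays")
        pixel_size = stained.pixel_size
    if s_frame.shape != u_frame.shape:
        raise ValidationError("stained/unstained frames differ in shape")
    ref = rois[rois["label"] == reference_label]
    if ref.empty:
        raise ValidationError(f"no ROI with reference label {reference_label!r}")
    od_s = rgb_to_od(s_frame, bit_depth)
    od_u = rgb_to_od(u_frame, bit_depth)
    rows = []
    for _, r in rois.iterrows():
        m = roi_mask(od_s.shape[:2], r, pixel_size)
        od = float(od_s[m].mean())
        rows.append(
            {
                "image_id": r["image_id"],
                "label": r["label"],
                "od": od,
                "od_diff": od - float(od_u[m].mean()),
            }
        )
    out = pd.DataFrame(rows)
    ref_mean = out.loc[out["label"] == reference_label, "od_diff"].mean()
    out["od_corrected"] = out["od_diff"] - ref_mean
    return out


def circular_mean_deg(deg: np.ndarray) -> float:
    """Circular mean of angles in degrees via the mean unit vector."""
    rad = np.deg2rad(np.asarray(deg, dtype=float))
    ang = float(np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))) % 360.0
    return 0.0 if ang >= 360.0 else ang  # (-eps % 360) rounds to 360.0 in float


@dataclass
class HueSample:
    image_id: str
    label: str
    hue_deg: float  # NaN when undefined
    absorbance: float
    hue_undefined: bool


def maule_measure(
    stained,
    rois: pd.DataFrame,
    pixel_size: float | None = None,
    bit_depth: int | None = None,
    circular: bool = True,
) -> pd.DataFrame:
    """Hue and absorbance per ROI for Mäule-stained sections.

    Hue comes from the HSB transform of the RGB frame, scaled so the 8-bit
    hue range maps onto 0–360°, and is averaged circularly (mean unit
    vector) by default. ``circular=False`` switches to the plain
    arithmetic mean of the 8-bit-scaled hue values — beware the 0°/360°
    wraparound, which makes the arithmetic mean of reds straddling 0°
    meaningless. Absorbance is uncalibrated OD of the stained image with
    no unstained reference. Zero-saturation (gray) pixels carry no hue and
    are excluded; an ROI of only such pixels is flagged undefined.
    """
    from skimage.color import rgb2hsv

    frame = _frame_of(stained)
    if pixel_size is None:
        if not isinstance(stained, ImageStack):
            raise ValidationError("pixel_size required when passing bare arrays")
        pixel_size = stained.pixel_size
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise TypeError("Mäule measurement needs a color frame")
    hsv = rgb2hsv(frame)  # hue, saturation in [0, 1]
    hue_deg = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    od = rgb_to_od(frame, bit_depth)
    rows = []
    for _, r in rois.iterrows():
        m = roi_mask(frame.shape[:2], r, pixel_size)
        chromatic = m & (sat > 0)
        if not chromatic.any():
            hue, undefined = float("nan"), True
        elif circular:
            hue, undefined = circular_mean_deg(hue_deg[chromatic]), False
        else:
            # compatibility mode: arithmetic mean of 8-bit hue, h/255*360
            h8 = np.round(hue_deg[chromatic] / 360.0 * 255.0)
            hue, undefined = float(h8.mean() / 255.0 * 360.0), False
        rows.append(
            {
                "image_id": r["image_id"],
                "label": r["label"],
                "hue_deg": hue,
                "absorbance": float(od[m].mean()),
                "hue_undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
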