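"""Time-lapse enzyme-activity kinetics.

Laccase activity in tissue sections is read out as the darkening of
chromogenic substrates (DAF, DAB, PYGL) over time. Per sampling region the
absorbance trace is background-corrected against unlignified phloem at the
same timepoint, the linear phase of product formation — after the initial
unspecific staining, before the plateau — is located automatically as the
contiguous window maximizing the R² of an ordinary-least-squares fit under
a minimum-span constraint, and the oxidation rate is that window's slope
in OD·min⁻¹. Non-enzymatic oxidation measured on autoclaved sections can
be subtracted to compare activities across pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histochem import rgb_to_od
from .io_core import ImageStack, ValidationError, roi_mask

__all__ = [
    "KineticTrace",
    "OxidationRate",
    "extract_traces",
    "detect_linear_phase",
    "subtract_control",
    "ph_profile",
]

SUBSTRATES = ("DAF", "DAB", "PYGL")


@dataclass
class KineticTrace:
    """Background-corrected absorbance vs time at one ROI."""

    label: str
    times: np.ndarray  # minutes
    absorbance: np.ndarray  # OD, reference-subtracted
    condition: dict = field(default_factory=dict)  # substrate, ph, treatment, genotype

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise ValidationError("times and absorbance must be equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")


@dataclass
class OxidationRate:
    """Fitted linear-phase slope with its window and fit quality."""

    slope: float  # OD per minute
    window: tuple[float, float]  # (t_start, t_end) minutes
    r2: float
    n_points: int
    corrected: bool = False
    condition: dict = field(default_factory=dict)
    label: str = ""

    @property
    def negative(self) -> bool:
        return self.slope < 0


def extract_traces(
    stack: ImageStack,
    rois: pd.DataFrame,
    reference_label: str = "phloem",
    condition: dict | None = None,
) -> list[KineticTrace]:
    """Per-ROI absorbance traces, phloem-corrected per timepoint.

    For every frame the OD image is computed (color frames via the mean-
    channel log transform; grayscale frames treated as a single channel),
    each ROI's mean OD is taken, and the same-timepoint mean OD over the
    reference-label ROIs is subtracted, cancelling any background drift
    shared by the whole section. Frames must be mutually registered.
    """
    ref = rois[rois["label"] == reference_label]
    if ref.empty:
        raise ValidationError(f"no ROI with reference label {reference_label!r}")
    masks = [roi_mask(stack.shape, r, stack.pixel_size) for _, r in rois.iterrows()]
    white = float(stack.white_level)
    od_per_roi = np.empty((len(masks), stack.n_frames))
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        if frame.ndim == 3:
            od = rgb_to_od(frame, stack.bit_depth)
        else:
            od = np.log10(white / np.maximum(frame.astype(float), 1.0))
        for i, m in enumerate(masks):
            od_per_roi[i, t] = od[m].mean()
    is_ref = (rois["label"] == reference_label).to_numpy()
    background = od_per_roi[is_ref].mean(axis=0)
    cond = dict(condition or {})
    return [
        KineticTrace(
            str(rois["label"].iloc[i]),
            stack.timestamps.copy(),
            od_per_roi[i] - background,
            cond,
        )
        for i in range(len(masks))
    ]


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R² of an OLS line; constant y gives (0, y̅, 0)."""
    tm, ym = t.mean(), y.mean()
    sxx = float(((t - tm) ** 2).sum())
    syy = float(((y - ym) ** 2).sum())
    if syy == 0.0:  # zero-variance fit: slope 0, R² 0 by convention
        return 0.0, ym, 0.0
    sxy = float(((t - tm) * (y - ym)).sum())
    slope = sxy / sxx
    ss_res = syy - slope * sxy
    return slope, ym - slope * tm, 1.0 - ss_res / syy


def detect_linear_phase(
    trace: KineticTrace,
    min_fraction: float = 1.0 / 3.0,
    min_points: int = 4,
) -> OxidationRate:
    """Locate the linear phase and return its slope.

    The trace is fitted globally by a piecewise flat–linear–flat model
    (initial unspecific-staining lag, linear product formation, terminal
    plateau): ``y ≈ b + s·clip(t − t1, 0, t2 − t1)``, linear in (b, s)
    for fixed breakpoints, with (t1, t2) searched over the observed
    timepoints subject to at least ``min_points`` points and a span of at
    least ``min_fraction`` of the trace duration inside the window.
    Interior breakpoints are charged as extra parameters under BIC, so a
    lag or plateau segment is kept only when it genuinely improves the
    fit — a purely linear trace selects the full span and recovers its
    slope exactly. Ties go to the model with fewer breakpoints, then the
    longer window, then the earlier start. The reported R² is that of the
    OLS line restricted to the window. Negative slopes are allowed and
    simply reported.
    """
    t, y = trace.times, trace.absorbance
    n = len(t)
    if n < min_points:
        raise ValidationError(f"trace has {n} points; need at least {min_points} to fit")
    total_span = t[-1] - t[0]
    min_span = min_fraction * total_span
    best = None  # (key, slope, i, j)
    log_n = np.log(n)
    for i in range(n):
        for j in range(i + min_points - 1, n):
            if t[j] - t[i] < min_span:
                continue
            x = np.clip(t - t[i], 0.0, t[j] - t[i])
            xm, ym = x.mean(), y.mean()
            sxx = float(((x - xm) ** 2).sum())
            slope = float(((x - xm) * (y - ym)).sum()) / sxx if sxx > 0 else 0.0
            sse = float(((y - (ym + slope * (x - xm))) ** 2).sum())
            k = 2 + (i > 0) + (j < n - 1)
            if sse > 0:
                key = (-(n * np.log(sse / n) + k * log_n), -k, j - i + 1, -i)
            else:  # exact fit: prefer the most parsimonious, widest window
                key = (np.inf, -k, j - i + 1, -i)
            if best is None or key > best[0]:
                best = (key, slope, i, j)
    if best is None:
        raise ValidationError("no window satisfies the minimum-span constraint")
    _, slope, i, j = best
    _, _, r2 = _ols(t[i : j + 1], y[i : j + 1])
    return OxidationRate(
        slope=slope,
        window=(float(t[i]), float(t[j])),
        r2=float(max(r2, 0.0)),
        n_points=j - i + 1,
        condition=dict(trace.condition),
        label=trace.label,
    )


def subtract_control(native: OxidationRate, autoclaved: OxidationRate) -> OxidationRate:
    """Remove non-enzymatic substrate oxidation measured on autoclaved tissue.

    Both rates must come from the same substrate, pH and label; the result
    carries slope(native) − slope(autoclaved), the native window for
    provenance, and the ``corrected`` flag. A negative corrected rate is
    reported as-is (``.negative``).
    """
    for k in ("substrate", "ph"):
        if native.condition.get(k) != autoclaved.condition.get(k):
            raise ValidationError(
                f"condition mismatch on {k!r}: "
                f"{native.condition.get(k)} vs {autoclaved.condition.get(k)}"
            )
    if native.label != autoclaved.label:
        raise ValidationError(f"label mismatch: {native.label} vs {autoclaved.label}")
    cond = dict(native.condition)
    cond["treatment"] = "control-subtracted"
    return OxidationRate(
        slope=native.slope - autoclaved.slope,
        window=native.window,
        r2=native.r2,
        n_points=native.n_points,
        corrected=True,
        condition=cond,
        label=native.label,
    )


def ph_profile(rates: list[OxidationRate]) -> pd.DataFrame:
    """Assemble corrected rates into a per-(genotype, substrate, label) pH profile.

    Returns a tidy table keyed by (genotype, substrate, label, ph) with a
    ``is_max`` column marking the pH of maximal rate per profile
    (``max_tie`` is set when the maximum is not unique) and ``is_local_max``
    marking every local maximum of the pH scan.
    """
    rows = []
    for r in rates:
        rows.append(
            {
                "genotype": r.condition.get("genotype", ""),
                "substrate": r.condition.get("substrate", ""),
                "label": r.label,
                "ph": r.condition.get("ph"),
                "slope": r.slope,
                "corrected": r.corrected,
            }
        )
    df = pd.DataFrame(rows)
    keys = ["genotype", "substrate", "label", "ph"]
    if df.duplicated(keys).any():
        dup = df[df.duplicated(keys, keep=False)][keys].iloc[0].tolist()
        raise ValidationError(f"duplicate rate for key {dup}")
    if df.groupby(["genotype", "substrate", "label"])["ph"].nunique().min() < 2:
        raise ValidationError("need rates at >= 2 pH levels per profile")
    out = []
    for _, g in df.groupby(["genotype", "substrate", "label"], sort=False):
        g = g.sort_values("ph").reset_index(drop=True)
        s = g["slope"].to_numpy()
        is_max = s == s.max()
        g["is_max"] = is_max
        g["max_tie"] = is_max.sum() > 1
        loc = np.zeros(len(s), dtype=bool)
        for k in range(len(s)):
            left_ok = k == 0 or s[k] > s[k - 1]
            right_ok = k == len(s) - 1 or s[k] > s[k + 1]
            loc[k] = left_ok and right_ok
        g["is_local_max"] = loc
        out.append(g)
    return pd.concat(out, ignore_index=True)
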