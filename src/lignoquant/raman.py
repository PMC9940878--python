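"""Raman spectral processing for cell-wall lignin chemotyping.

Spectra acquired on a uniform 2 cm⁻¹ grid are baseline-corrected by
asymmetric least squares (AsLS), aligned on the 378 cm⁻¹ cellulose band
to absorb instrument-calibration drift, and reduced to ratiometric band
descriptors: total lignin relative to cellulose, S/G ratio, terminal
coniferaldehyde to coniferyl-alcohol ratio (G_CHO/G_CHOH), and a
two-band cellulose crystallinity index. All descriptors are relative,
never absolute concentrations.

AsLS estimates the baseline z as the minimizer of

    sum_i w_i (y_i - z_i)^2 + lambda * sum (Δ² z)^2

with asymmetric weights w_i = p where y_i > z_i and 1 − p otherwise,
iterated to convergence. A small asymmetry p pins the baseline under
the peaks while the smoothness penalty lambda keeps it slowly varying.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .io_core import Spectrum, ValidationError

__all__ = [
    "BaselineParams",
    "BandDefinition",
    "BandIntensity",
    "BandRatioSet",
    "als_baseline",
    "align_to_reference",
    "band_intensity",
    "compute_ratios",
    "scale_to_band",
    "load_band_config",
    "default_band_config",
]


@dataclass(frozen=True)
class BaselineParams:
    """AsLS parameters. Defaults: λ = 100,000, p = 0.01, 50-iteration cap,
    convergence when fewer than 0.1% of weights change between iterations."""

    lambda_smooth: float = 1e5
    p_asym: float = 0.01
    max_iter: int = 50
    tol: float = 1e-3
    boundary_pad: int = 50

    def __post_init__(self) -> None:
        if not self.lambda_smooth > 0:
            raise ValidationError("lambda_smooth must be > 0")
        if not 0 < self.p_asym < 0.5:
            raise ValidationError("p_asym must lie in (0, 0.5)")
        if self.boundary_pad < 0:
            raise ValidationError("boundary_pad must be >= 0")


@dataclass(frozen=True)
class BandDefinition:
    """A named band: windowed-maximum intensity at center ± half_window cm⁻¹."""

    name: str
    center: float
    half_window: float = 4.0


@dataclass
class BandIntensity:
    value: float
    clamped: bool = False  # negative windowed maximum clamped to 0
    zero_signal: bool = False


@dataclass
class BandRatioSet:
    ratios: dict[str, float]
    undefined: set[str]
    spectrum_id: str
    config_hash: str


def als_baseline(spectrum: Spectrum, params: BaselineParams | None = None) -> tuple[Spectrum, Spectrum]:
    """Asymmetric least-squares baseline estimation (Whittaker-type).

    Returns ``(baseline, corrected)`` spectra; ``corrected = y - z`` may
    legitimately dip below zero. The penalized system
    ``(W + λ DᵀD) z = W y`` with second-difference D is solved sparsely
    each iteration; weights are re-assigned asymmetrically and iteration
    stops when fewer than ``tol`` of them change. The signal is extended
    at both ends by ``boundary_pad`` point-symmetric (trend-preserving)
    samples before fitting and trimmed afterwards; the free boundary of
    the second-difference penalty otherwise flattens the baseline at the
    spectrum edges and the asymmetric weights then mistake the edges for
    peaks.
    """
    params = params or BaselineParams()
    y0 = spectrum.intensities
    if len(y0) < 4:
        raise ValidationError("spectrum too short for baseline estimation")
    pad = min(params.boundary_pad, len(y0) - 1)
    y = _pad_reflect(y0, pad)
    n = len(y)
    D = sp.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(n - 2, n))
    DtD = (params.lambda_smooth * (D.T @ D)).tocsc()
    w = np.ones(n)
    z = y.copy()
    converged = False
    for it in range(1, params.max_iter + 1):
        W = sp.diags_array(w, format="csc")
        z = spsolve(W + DtD, w * y)
        w_new = np.where(y > z, params.p_asym, 1.0 - params.p_asym)
        changed = np.count_nonzero(w_new != w)
        w = w_new
        if changed < params.tol * n:
            converged = True
            break
    if not converged:
        warnings.warn(f"AsLS did not converge within {params.max_iter} iterations", stacklevel=2)
    z = z[pad : pad + len(y0)] if pad else z
    baseline = spectrum.copy(intensities=z)
    corrected = spectrum.copy(intensities=y0 - z, baseline_corrected=True)
    return baseline, corrected


def _pad_reflect(y: np.ndarray, pad: int) -> np.ndarray:
    """Point-symmetric extension about each endpoint (preserves the trend)."""
    if pad == 0:
        return y
    left = 2.0 * y[0] - y[pad:0:-1]
    right = 2.0 * y[-1] - y[-2 : -pad - 2 : -1]
    return np.concatenate([left, y, right])


def als_baseline_dense(y: np.ndarray, params: BaselineParams | None = None) -> np.ndarray:
    """Dense-matrix AsLS solve of the identical penalized least squares.

    Intended for cross-checking the sparse path at small n; identical
    iteration and stopping rules.
    """
    params = params or BaselineParams()
    y = np.asarray(y, dtype=float)
    pad = min(params.boundary_pad, len(y) - 1)
    n0 = len(y)
    y = _pad_reflect(y, pad)
    n = len(y)
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    DtD = params.lambda_smooth * (D.T @ D)
    w = np.ones(n)
    for _ in range(params.max_iter):
        z = np.linalg.solve(np.diag(w) + DtD, w * y)
        w_new = np.where(y > z, params.p_asym, 1.0 - params.p_asym)
        if np.count_nonzero(w_new != w) < params.tol * n:
            w = w_new
            break
        w = w_new
    return z[pad : pad + n0] if pad else z


def align_to_reference(
    spectrum: Spectrum, reference_center: float = 378.0, search: float = 10.0
) -> tuple[Spectrum, float]:
    """Shift the wavenumber axis so the reference band apex sits at its
    nominal position.

    The apex is the highest local maximum within ``reference_center ±
    search``; its sub-bin position is refined by fitting a parabola
    through the three bins around it. Returns the shifted spectrum and
    the applied shift in cm⁻¹ (nominal − observed apex).
    """
    wn, y = spectrum.wavenumbers, spectrum.intensities
    in_win = np.flatnonzero(np.abs(wn - reference_center) <= search)
    if len(in_win) < 3:
        raise ValidationError("search window covers fewer than 3 bins")
    best_i, best_v = -1, -np.inf
    for i in in_win:
        if 0 < i < len(y) - 1 and y[i] >= y[i - 1] and y[i] >= y[i + 1] and y[i] > best_v:
            best_i, best_v = i, y[i]
    if best_i < 0:
        raise ValidationError(
            f"no local maximum within {reference_center} ± {search} cm⁻¹ "
            "(spectrum likely not cell wall)"
        )
    y0, y1, y2 = y[best_i - 1], y[best_i], y[best_i + 1]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    frac = float(np.clip(frac, -0.5, 0.5))
    apex = wn[best_i] + frac * spectrum.spacing
    shift = reference_center - apex
    return spectrum.copy(wavenumbers=wn + shift), float(shift)


def band_intensity(spectrum: Spectrum, band: BandDefinition) -> BandIntensity:
    """Windowed-maximum intensity of a baseline-corrected band.

    The maximum over center ± half_window tolerates residual misalignment
    up to the window half-width. A negative maximum (over-subtracted
    baseline, no real band) is clamped to 0 and flagged.
    """
    wn = spectrum.wavenumbers
    if band.half_window < spectrum.spacing:
        raise ValidationError(
            f"half_window {band.half_window} below spectral spacing {spectrum.spacing}"
        )
    m = np.abs(wn - band.center) <= band.half_window + 1e-9
    if not m.any() or band.center < wn[0] or band.center > wn[-1]:
        raise ValidationError(f"band {band.name!r} at {band.center} cm⁻¹ outside spectral range")
    v = float(spectrum.intensities[m].max())
    if v < 0:
        return BandIntensity(0.0, clamped=True)
    return BandIntensity(v, zero_signal=(v == 0.0))


def _band_defs(config: dict) -> dict[str, BandDefinition]:
    return {
        name: BandDefinition(name, float(b["center"]), float(b.get("half_window", 4.0)))
        for name, b in config["bands"].items()
    }


def compute_ratios(spectrum: Spectrum, config: dict) -> BandRatioSet:
    """Evaluate every configured band ratio on a corrected, aligned spectrum.

    ``config`` holds ``bands`` (name → center/half_window) and ``ratios``
    (name → num/den band-name lists; multi-band lists are summed). A zero
    denominator marks the ratio undefined (NaN) rather than raising.
    """
    import hashlib
    import json

    bands = _band_defs(config)
    intens = {name: band_intensity(spectrum, b).value for name, b in bands.items()}
    ratios: dict[str, float] = {}
    undefined: set[str] = set()
    for name, spec_r in config["ratios"].items():
        for ref in list(spec_r["num"]) + list(spec_r["den"]):
            if ref not in bands:
                raise ValidationError(f"ratio {name!r} references undefined band {ref!r}")
        num = sum(intens[b] for b in spec_r["num"])
        den = sum(intens[b] for b in spec_r["den"])
        if den == 0:
            ratios[name] = float("nan")
            undefined.add(name)
        else:
            ratios[name] = num / den
    digest = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
    return BandRatioSet(ratios, undefined, spectrum.spectrum_id, digest)


def scale_to_band(spectrum: Spectrum, config: dict, band_name: str = "cellulose_378") -> Spectrum:
    """Scale a whole spectrum to a band intensity (display convention).

    After scaling, band intensities are relative to that band (typically
    total cellulose at 378 cm⁻¹).
    """
    b = _band_defs(config)[band_name]
    v = band_intensity(spectrum, b).value
    if v == 0:
        raise ValidationError(f"cannot scale: band {band_name!r} has zero intensity")
    return spectrum.copy(intensities=spectrum.intensities / v)


def load_band_config(path) -> dict:
    import yaml

    with open(path) as fh:
        config = yaml.safe_load(fh)
    if "bands" not in config or "ratios" not in config:
        raise ValidationError("band config needs 'bands' and 'ratios' tables")
    return config


def default_band_config() -> dict:
    """Shipped literature-standard band assignments (editable defaults)."""
    import yaml

    text = resources.files("lignoquant").joinpath("data/raman_bands.yaml").read_text()
    return yaml.safe_load(text)
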