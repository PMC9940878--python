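# Methods

This note documents the models behind each pipeline, the parameters that
matter, the numerical choices made where the design was genuinely open,
and what the synthetic phantoms do and do not emulate.

## Optical density and image conventions

All absorbance measurements use uncalibrated optical density,
`OD = log10(white / v)` with `white = 2^depth − 1` and the pixel value
clamped at one count, so a saturated pixel has OD 0 and a fully dark
pixel a finite maximum (≈2.41 at 8 bit, ≈4.82 at 16 bit). `v` defaults
to the mean of the three color channels; per-channel OD is available
where stain spectra matter. Images use a top-left origin, x rightward, y
downward, 0-based pixel indices; physical coordinates are pixel index ×
pixel size (µm). A pixel belongs to a circular ROI iff its center lies
within the radius, inclusive.

Frame-to-frame registration is translation-only: exhaustive normalized
cross-correlation over an integer-pixel search window (±10 px default).
Rigid section time-lapses drift but do not deform, so feature-based
registration adds complexity without benefit here. A peak correlation
below 0.3 (configurable) returns a zero shift with a low-confidence
flag rather than an arbitrary jump. When sections are imaged at several
Z positions to absorb focus drift, the sharpest frame per timepoint is
selected by variance of the Laplacian; averaging the Z planes would blur
the in-focus plane with the defocused ones.

## Kinetics: linear-phase detection

Chromogenic traces follow three phases: an initial unspecific-staining
lag, a linear product-formation phase whose slope is the oxidation rate,
and a plateau when substrate or signal saturates. Rather than selecting
the phase by eye, the trace is fitted globally with the piecewise model

    y(t) ≈ b + s · clip(t − t1, 0, t2 − t1)

which is linear in (b, s) for fixed breakpoints; (t1, t2) are searched
over the observed timepoints subject to a minimum of 4 points and a
minimum span of one third of the trace duration inside the window.
Because a short spurious "plateau" at a terminal noise dip would
otherwise be free, interior breakpoints are charged as extra parameters
under BIC; ties are resolved toward fewer breakpoints, then the longer
window, then the earlier start. On noise-free linear traces this
reduces to ordinary least squares over the full span and recovers the
generating slope to machine precision; the reported R² is that of the
OLS line restricted to the selected window, with the zero-variance
(constant-trace) fit defined as slope 0, R² 0. Negative slopes are
reported and flagged, never suppressed. Autoclaved-control subtraction
(`slope_native − slope_autoclaved`) is applied for cross-pH comparisons;
same-pH genotype comparisons may omit it, controlled by the caller.

## Histochemistry

Wiesner quantification is the mean OD over each ROI in the stained frame
minus the unstained frame, then minus the mean of that difference over
unlignified-phloem reference ROIs. The double subtraction cancels, by
construction, any illumination field shared by the two acquisitions and
any uniform offset (e.g. tissue clearing by the acidic reagent); the
corrected phloem mean is exactly zero. Mäule staining has no unstained
reference; it is quantified as stained-image OD plus hue. Hue comes from
the HSB transform scaled so the 8-bit hue range maps to 0–360°, and is
averaged circularly (direction of the mean unit vector): the arithmetic
mean of {350°, 10°} is a meaningless 180°, the circular mean the correct
0°. An arithmetic-averaging compatibility mode exists for comparison
with 8-bit-hue workflows, wraparound hazard documented. Zero-saturation
(gray) pixels carry no hue and are excluded; an all-gray ROI is flagged
undefined rather than given a fabricated hue.

## Raman processing

Baselines are estimated by asymmetric least squares: minimize
`Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)²` with `wᵢ = p` where `yᵢ > zᵢ` else `1−p`,
iterated until fewer than 0.1% of weights change (cap 50 iterations).
Defaults λ = 100,000 and p = 0.01 suit fluorescence backgrounds under
sharp Raman bands on a 2 cm⁻¹ grid. The free boundary of the
second-difference penalty flattens the smoother at the spectrum ends;
on curved baselines the flattened fit dips below the data there and the
asymmetric weights then misread the edges as peaks. The signal is
therefore extended by 50 point-symmetric (trend-preserving) samples at
each end before fitting and trimmed afterwards — a standard
Whittaker-smoother edge treatment. The sparse solve is verified against
a brute-force dense solve of the identical penalized least squares.

Instrument-calibration drift is absorbed by shifting the wavenumber axis
so the cellulose band apex sits at 378 cm⁻¹; the apex is located as the
highest local maximum within ±10 cm⁻¹ and refined to sub-bin precision
by a parabola through the three surrounding bins. Band intensity is the
windowed maximum of the corrected spectrum within center ± 4 cm⁻¹
(configurable), which tolerates residual misalignment up to the window
half-width; height rather than area keeps the descriptor robust to
neighboring-band overlap at this spectral resolution. Negative maxima
are clamped to zero and flagged. Band centers and ratio formulas ship as
an editable YAML configuration of literature-standard assignments
(cellulose 378/380/1096, total lignin 1600, S 1331, G 1271,
coniferaldehyde 1621, coniferyl alcohol 1654; crystallinity as the
380/1096 two-band cellulose ratio) — they are data, not code, and real
instruments may warrant adjustment. All ratios are relative descriptors,
never absolute concentrations; a zero denominator flags the ratio
undefined instead of raising.

## Morphometrics and profiles

Traced vessel perimeters carry pixelation artifacts, so each vertex is
replaced by a Gaussian-weighted circular average of its neighbors with
distance measured as arc length along the perimeter and σ = 2% of the
perimeter length (configurable; zero bandwidth is the identity). If
smoothing ever produces a self-intersection the bandwidth is halved, up
to three times. Convexity = area / convex-hull area is computed with
shapely on the smoothed outline by default, with the raw-outline value
always co-reported; the metric is invariant to rotation, translation,
scaling and vertex order, equals 1 for convex shapes, and is checked in
the tests against an independent shoelace + monotone-chain
implementation. Synthetic collapsed outlines are generated as
`r(θ) = R(1 − a·max(0, cos kθ)^q)` with ground-truth convexity from a
10,000-vertex dense evaluation.

Fluorescence line profiles are sampled by bilinear interpolation at a
fixed step along a user-drawn segment. Layer labels (CML, CC, SCW-S1/S2,
SCW-S3) are supplied by the user or the generator — automatic layer
segmentation is out of scope. Normalization divides all intensities by
the mean over CML-labeled positions (≥3 required), making the CML mean
exactly 1; the operation is idempotent and scale-invariant. Wall
thickness is the Euclidean distance between opposing lumen-boundary
endpoints; swelling ratios are fresh/dried and rehydrated/dried, with
missing states left empty, never imputed.

## Statistics

Biological replicates (individual plants) are the unit of analysis:
technical measurements are averaged per replicate before testing, so
duplicating technical rows cannot manufacture significance. Pairwise
comparisons use studentized-range (Tukey-HSD) p-values computed from the
pooled one-way ANOVA mean square error, cross-checked in the tests
against statsmodels. The compact letter display uses insert-and-absorb:
start with one letter covering all groups, split on each significant
pair, absorb subset columns; two groups share a letter iff their
adjusted p ≥ α (non-strict at the boundary), letters are assigned with
groups ordered by mean descending so the output is deterministic. A
rank-based Kruskal–Wallis/Dunn backend with identical letter semantics
is available for non-normal metrics (two-sided normal-approximation z
tests on mean ranks with tie correction, no additional p-adjustment).
No correction is applied across metrics or cell types beyond Tukey
within each comparison panel.

PCA standardizes columns (mean 0, SD 1 with ddof 1 — constant columns
are an error when scaling, as are missing values; no imputation) and
factors by SVD. Variance fractions are σᵢ²/Σσ²; the sign of each
component is fixed by making its largest-magnitude loading positive.
Pyrogram composition is percent of summed peak area per residue class
(H, G_CHO, G_CHOH, S_CHO, S_CHOH, 5H, P, benzaldehyde, other), with no
response-factor correction; S/G = (S_CHO + S_CHOH)/(G_CHO + G_CHOH).

## Synthetic phantoms

The generators emulate the statistical structure of the real inputs, not
their appearance. Kinetic traces are lag/linear/plateau with additive
Gaussian noise at 5% of each trace's dynamic range by default, rates
log-uniform on [5×10⁻⁴, 5×10⁻³] OD·min⁻¹, lags up to 30 min, sampled
every 10 min over 3 h — plausible ranges for chromogenic oxidation
assays at this frame rate. Image-stack phantoms put those kinetics on a
uniformly drifting background with reference regions that follow the
background only; frames are 8-bit like a color camera's default
rendering, which sets the OD quantization floor. Section phantoms are
annular cells (SCW/CML rings, CC disks) with per-layer stain OD (0.9 /
0.6 / 0.3 defaults), a low-order polynomial illumination field applied
to both members of a stained/unstained pair, a −0.05 OD uniform clearing
offset that the phloem correction must cancel, and a 0.1 OD base tissue
density so cleared regions stay within gamut; they are rendered at 16
bit. Spectra are Gaussian bands at the configured wavenumbers on
polynomial baselines; calibration drift displaces the bands while the
baseline stays put. Profile phantoms are blurred step profiles with
positions within 2 blur-σ of a layer boundary labeled `unassigned` so
plateau labels stay pure.

Not emulated: optical point-spread beyond Gaussian blur, stain
chemistry and its saturation behavior, tissue autofocus failures,
correlated (structured) noise, and segmentation/tracing error. Passing
the phantom-recovery tests therefore demonstrates the correctness of
the measurement chain, not robustness to every real-world artifact.
Every generator is a pure function of its seed and parameters and emits
a ground-truth table sufficient to score the downstream estimators.

## Verification problem sizes

The acceptance script exercises 1,000 random polygons (8–64 vertices)
against the convexity oracle, 8 collapse amplitudes against the
10⁴-vertex oracle, 200 noisy plus 25 noise-free kinetic traces plus one
20-ROI image-stack pipeline, dense-vs-sparse AsLS at n ≤ 64 and peak
recovery on three 851-bin spectra, one Wiesner and one Mäule phantom,
one blurred noisy profile, Tukey letter displays on 3–5-group cases
against statsmodels, and two byte-compared end-to-end CLI replicates —
all freshly generated from the supplied seed.
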