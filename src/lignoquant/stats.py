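"""Genotype-comparison statistics.

Biological replicates (individual plants) are the unit of analysis:
within-replicate technical measurements are averaged before testing.
Groups are compared by one-way ANOVA followed by Tukey's HSD, summarized
as a compact letter display (CLD) — groups sharing a letter are not
significantly different at the chosen alpha. A rank-based
Kruskal–Wallis/Dunn backend with identical CLD semantics is available for
non-normal metrics. Multivariate lignin-chemistry descriptors are
summarized by PCA on the column-standardized matrix via singular value
decomposition, and pyrolysis-GC/MS pyrograms are reduced to percent
composition per residue class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import ValidationError

__all__ = [
    "LetterDisplay",
    "PCAResult",
    "replicate_means",
    "tukey_cld",
    "pairwise_pvalues",
    "compact_letters",
    "pca_svd",
    "pyrogram_composition",
]


@dataclass
class LetterDisplay:
    letters: dict[str, str]  # group -> letter set, e.g. "a", "ab"
    pvalues: pd.DataFrame  # symmetric pairwise adjusted p-value matrix
    means: pd.Series  # group means (of replicate means), descending
    alpha: float
    backend: str


def replicate_means(
    table: pd.DataFrame,
    metric: str,
    group: str = "genotype",
    replicate: str = "replicate_id",
    value: str = "value",
    metric_col: str = "metric_name",
) -> pd.DataFrame:
    """Average technical measurements down to one value per replicate."""
    df = table
    if metric_col in df.columns:
        df = df[df[metric_col] == metric]
        if df.empty:
            raise ValidationError(f"metric {metric!r} not present in table")
    return df.groupby([group, replicate], as_index=False, sort=False)[value].mean()


def pairwise_pvalues(groups: dict[str, np.ndarray], backend: str = "tukey") -> pd.DataFrame:
    """Symmetric matrix of pairwise adjusted p-values.

    ``tukey``: studentized-range p-values from the pooled one-way ANOVA
    mean square error. ``dunn``: rank-based z tests on Kruskal–Wallis
    mean ranks with tie correction, unadjusted (two-sided).
    """
    names = list(groups)
    k = len(names)
    p = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    if backend == "tukey":
        data = [np.asarray(groups[g], dtype=float) for g in names]
        ns = np.array([len(d) for d in data])
        means = np.array([d.mean() for d in data])
        df_err = int(ns.sum() - k)
        mse = sum(((d - d.mean()) ** 2).sum() for d in data) / df_err
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(means[i] - means[j]) / se if se > 0 else 0.0
                pv = sps.studentized_range.sf(q, k, df_err) if se > 0 else 1.0
                p.iloc[i, j] = p.iloc[j, i] = float(np.clip(pv, 0.0, 1.0))
    elif backend == "dunn":
        all_vals = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
        ranks = sps.rankdata(all_vals)
        n = len(all_vals)
        idx = np.cumsum([0] + [len(groups[g]) for g in names])
        mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(k)]
        _, counts = np.unique(all_vals, return_counts=True)
        tie_corr = (counts**3 - counts).sum() / (12.0 * (n - 1))
        for i in range(k):
            for j in range(i + 1, k):
                ni, nj = idx[i + 1] - idx[i], idx[j + 1] - idx[j]
                se = np.sqrt((n * (n + 1) / 12.0 - tie_corr) * (1.0 / ni + 1.0 / nj))
                z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
                p.iloc[i, j] = p.iloc[j, i] = float(2.0 * sps.norm.sf(z))
    else:
        raise ValidationError(f"unknown backend {backend!r}")
    return p


def compact_letters(p: pd.DataFrame, means: pd.Series, alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their adjusted p ≥ alpha (non-strict).
    Letters are assigned deterministically: groups ordered by mean
    descending, letters alphabetical; redundant (subset) letter columns
    are absorbed, giving a minimal display.
    """
    order = list(means.sort_values(ascending=False, kind="stable").index)
    columns: list[set[str]] = [set(order)]
    for a_i in range(len(order)):
        for b_i in range(a_i + 1, len(order)):
            a, b = order[a_i], order[b_i]
            if p.loc[a, b] < alpha:  # significantly different: split columns holding both
                new_cols = []
                for col in columns:
                    if a in col and b in col:
                        new_cols.append(col - {a})
                        new_cols.append(col - {b})
                    else:
                        new_cols.append(col)
                # absorb: drop any column that is a subset of another
                columns = [
                    c
                    for i, c in enumerate(new_cols)
                    if c and not any(i != j and c <= d and (c < d or i > j) for j, d in enumerate(new_cols))
                ]
    # order columns by their highest-mean member for stable letter naming
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for li, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[li]
    return letters


def tukey_cld(
    table: pd.DataFrame,
    metric: str,
    group: str = "genotype",
    replicate: str = "replicate_id",
    value: str = "value",
    alpha: float = 0.05,
    backend: str = "tukey",
) -> LetterDisplay:
    """ANOVA/Tukey-HSD (or Kruskal–Wallis/Dunn) with compact letter display.

    Operates on the average value of each biological replicate; groups
    with fewer than 2 replicates are excluded with a warning.
    """
    reps = replicate_means(table, metric, group, replicate, value)
    sizes = reps.groupby(group)[value].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding groups with < 2 replicates: {small}", stacklevel=2)
        reps = reps[~reps[group].isin(small)]
    groups = {str(g): d[value].to_numpy() for g, d in reps.groupby(group, sort=False)}
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups with >= 2 replicates each")
    p = pairwise_pvalues(groups, backend)
    means = pd.Series({g: v.mean() for g, v in groups.items()})
    letters = compact_letters(p, means, alpha)
    return LetterDisplay(letters, p, means.sort_values(ascending=False), alpha, backend)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # metrics × components
    variance_fraction: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Centered/scaled data re-assembled from scores and loadings."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def pca_svd(table: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA of a wide metric matrix by singular value decomposition.

    Columns are centered and scaled to unit variance (ddof 1) by default;
    missing values raise (no imputation), as does a constant column when
    scaling. Sign convention: the largest-magnitude loading of each
    component is made positive. Variance fractions sum to 1.
    """
    num = table.select_dtypes(include=[np.number])
    if num.shape[0] < 2 or num.shape[1] < 2:
        raise ValidationError("need >= 2 samples and >= 2 numeric metrics")
    if num.isna().any().any():
        bad = num.columns[num.isna().any()].tolist()
        raise ValidationError(f"missing values in columns {bad}; no imputation is performed")
    X = num.to_numpy(dtype=float)
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = num.std(axis=0, ddof=1).to_numpy()
        const = np.flatnonzero(sd == 0)
        if const.size:
            raise ValidationError(f"constant column {num.columns[const[0]]!r} cannot be scaled")
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    for c in range(len(s)):  # deterministic sign: dominant loading positive
        i = np.argmax(np.abs(vt[c]))
        if vt[c, i] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    scores = u * s
    comps = [f"PC{i + 1}" for i in range(len(s))]
    var = s**2
    return PCAResult(
        pd.DataFrame(scores, index=num.index, columns=comps),
        pd.DataFrame(vt.T, index=num.columns, columns=comps),
        var / var.sum(),
    )


RESIDUE_CLASSES = ("H", "G_CHO", "G_CHOH", "S_CHO", "S_CHOH", "5H", "P", "benzaldehyde", "other")


def pyrogram_composition(peaks: pd.DataFrame, sample: str = "sample") -> pd.DataFrame:
    """Percent composition per residue class from an identified peak table.

    Input rows carry a residue ``class`` and a peak ``area`` (plus an
    optional sample column). Percentages are summed class area over total
    pyrogram area × 100 — no response-factor correction — and sum to 100
    per sample. Derived ratios: S/G = (S_CHO + S_CHOH)/(G_CHO + G_CHOH)
    and G_CHO/G_CHOH; a zero denominator leaves the ratio NaN.
    """
    df = peaks.copy()
    if "class" not in df.columns or "area" not in df.columns:
        raise ValidationError("peak table needs 'class' and 'area' columns")
    if (df["area"] < 0).any():
        raise ValidationError("peak areas must be >= 0")
    if sample not in df.columns:
        df[sample] = "sample"
    rows = []
    for sid, g in df.groupby(sample, sort=False):
        total = g["area"].sum()
        if total == 0:
            raise ValidationError(f"sample {sid!r} has zero total pyrogram area")
        by_class = g.groupby("class")["area"].sum()
        row = {sample: sid}
        for c in RESIDUE_CLASSES:
            row[c] = float(by_class.get(c, 0.0)) / total * 100.0
        extra = set(by_class.index) - set(RESIDUE_CLASSES)
        for c in sorted(extra):
            row[c] = float(by_class[c]) / total * 100.0
        g_tot = row["G_CHO"] + row["G_CHOH"]
        s_tot = row["S_CHO"] + row["S_CHOH"]
        row["s_over_g"] = s_tot / g_tot if g_tot > 0 else float("nan")
        row["gcho_over_gchoh"] = row["G_CHO"] / row["G_CHOH"] if row["G_CHOH"] > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
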