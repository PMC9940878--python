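"""Independent reference implementations used only to cross-check results.

Deliberately simple, self-contained code paths: shoelace area plus a
monotone-chain convex hull (no shapely), a dense NumPy solve of the
asymmetric-least-squares normal equations (no sparse algebra), and
studentized-range pairwise p-values via statsmodels. These never call the
package's own implementations.
"""

from __future__ import annotations

import numpy as np


def shoelace_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def monotone_chain_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices in counter-clockwise order (Andrew's algorithm)."""
    pts = sorted(map(tuple, points))
    if len(pts) <= 2:
        return np.asarray(pts)

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return np.asarray(lower[:-1] + upper[:-1])


def convexity_dense(verts: np.ndarray) -> float:
    """Area over convex-hull area, entirely via the shoelace + monotone chain."""
    return shoelace_area(verts) / shoelace_area(monotone_chain_hull(verts))


def random_star_polygon(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random simple (star-shaped) polygon: sorted angles, random radii."""
    theta = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n))
    # enforce distinct angles so edges never degenerate
    while np.any(np.diff(theta) < 1e-3):
        theta = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n))
    r = rng.uniform(0.3, 1.0, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def asls_dense(
    y: np.ndarray, lam: float, p: float, max_iter: int = 50, tol: float = 1e-3, pad: int = 50
) -> np.ndarray:
    """Brute-force dense solve of the AsLS penalized least squares (with the
    same point-symmetric boundary extension as the analysis route)."""
    y = np.asarray(y, dtype=float)
    pad = min(pad, len(y) - 1)
    n0 = len(y)
    if pad:
        ext_l = [2.0 * y[0] - y[k] for k in range(pad, 0, -1)]
        ext_r = [2.0 * y[-1] - y[-2 - k] for k in range(pad)]
        y = np.array(ext_l + list(y) + ext_r)
    n = len(y)
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i] = 1.0
        D[i, i + 1] = -2.0
        D[i, i + 2] = 1.0
    P = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        z = np.linalg.solve(np.diag(w) + P, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.count_nonzero(w_new != w) < tol * n:
            break
        w = w_new
    return z[pad : pad + n0] if pad else z


def tukey_pairwise_pvalues(groups: dict[str, np.ndarray]):
    """Pairwise Tukey-HSD p-values via statsmodels (reference route)."""
    import pandas as pd
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    res = pairwise_tukeyhsd(values, labels)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    out = {}
    for _, row in frame.iterrows():
        out[(str(row["group1"]), str(row["group2"]))] = float(row["p-adj"])
    return out


def ols_window_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Plain least-squares slope and R² (reference for window fits)."""
    A = np.vstack([t, np.ones_like(t)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0, 0.0
    ss_res = float(res[0]) if len(res) else float(((y - A @ coef) ** 2).sum())
    return float(coef[0]), 1.0 - ss_res / ss_tot
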