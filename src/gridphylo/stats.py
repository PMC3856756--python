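"""Richness–environment statistics.

Four tools used to relate gridded richness and phylogenetic structure to the
environment table:

* Spearman rank correlations (screening, mirroring the classic
  variable-by-group correlation table);
* variance partitioning of a univariate response between two predictor sets
  via the R² of three nested OLS models (the univariate reduction of partial
  redundancy analysis), with Monte-Carlo permutation tests;
* piecewise (segmented) regression with a single estimated breakpoint,
  fitted as the continuous hinge model y = β0 + β1·x + β2·max(x − ψ, 0);
* Moran's I spatial autocorrelation with inverse great-circle-distance
  weights, applied to a raw response and to the residuals of a full OLS
  model to diagnose how much spatial structure the predictors absorb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "spearman",
    "spearman_table",
    "VariancePartition",
    "variance_partition",
    "PiecewiseFit",
    "piecewise_fit",
    "great_circle_distances",
    "great_circle_weights",
    "MoranResult",
    "morans_i",
    "residual_autocorrelation",
]

EARTH_RADIUS_KM = 6371.0


def spearman(x, y) -> float:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def spearman_table(richness: pd.DataFrame, pd_div: pd.DataFrame,
                   env: pd.DataFrame) -> pd.DataFrame:
    """Environment-variable x group Spearman table.

    Rows are the environment columns; columns are richness (all / herbaceous
    / woody) and phylogenetic diversity (pd_all / pd_herb / pd_woody).
    Groups with constant values (e.g. no woody species anywhere) give NaN.
    """
    groups = {
        "richness_all": richness["all"],
        "richness_herbaceous": richness["herbaceous"],
        "richness_woody": richness["woody"],
        "pd_all": pd_div["pd_all"],
        "pd_herbaceous": pd_div["pd_herb"],
        "pd_woody": pd_div["pd_woody"],
    }
    out = pd.DataFrame(index=env.columns, columns=list(groups), dtype=float)
    for var in env.columns:
        for name, series in groups.items():
            aligned = pd.concat([env[var], series], axis=1, join="inner").dropna()
            try:
                out.loc[var, name] = spearman(aligned.iloc[:, 0], aligned.iloc[:, 1])
            except ValueError:
                out.loc[var, name] = np.nan
    out.index.name = "variable"
    return out


# ---------------------------------------------------------------------------
# Variance partitioning

@dataclass(frozen=True)
class VariancePartition:
    """Four-fraction decomposition of response variance.

    frac_a: pure fraction of set A; frac_c: pure fraction of set B;
    frac_b: shared fraction (may be negative with suppressor structure);
    frac_d: residual.  The four always sum to exactly 1.
    """

    frac_a: float
    frac_b: float
    frac_c: float
    frac_d: float
    r2_full: float
    r2_A: float
    r2_B: float
    p_full: float
    p_A: float
    p_B: float
    label_A: str = "A"
    label_B: str = "B"

    def summary(self) -> str:
        return (
            f"Variance partition of response between {self.label_A} and {self.label_B}\n"
            f"  [a] pure {self.label_A:<22s} {self.frac_a: .4f}\n"
            f"  [b] shared                      {self.frac_b: .4f}\n"
            f"  [c] pure {self.label_B:<22s} {self.frac_c: .4f}\n"
            f"  [d] residual                    {self.frac_d: .4f}\n"
            f"  R2: full={self.r2_full:.4f} (p={self.p_full:.4g}), "
            f"{self.label_A}={self.r2_A:.4f} (p={self.p_A:.4g}), "
            f"{self.label_B}={self.r2_B:.4f} (p={self.p_B:.4g})"
        )


def _r2(q: np.ndarray, y: np.ndarray, tss: float) -> float:
    """R² of OLS with design QR factor ``q`` (includes the intercept column)."""
    coef = q.T @ y
    rss = float(y @ y - coef @ coef)
    return 1.0 - rss / tss


def _design_q(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the design's column space (intercept included).

    Built by SVD so an exactly collinear design projects onto its true column
    space (the pseudo-inverse fit) instead of an inflated one.
    """
    n = X.shape[0]
    D = np.column_stack([np.ones(n), X])
    u, s, _ = np.linalg.svd(D, full_matrices=False)
    keep = s > s[0] * max(D.shape) * np.finfo(float).eps
    if keep.sum() < D.shape[1]:
        warnings.warn("rank-deficient design; using the pseudo-inverse fit")
    return u[:, keep]


def variance_partition(
    response,
    factor_set_A: pd.DataFrame,
    factor_set_B: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    adjusted: bool = False,
) -> VariancePartition:
    """Partition response variance between predictor sets A and B.

    Fits OLS of the response on A, on B and on A∪B; with R² of the three
    models, frac_a = R²_full − R²_B, frac_c = R²_full − R²_A,
    frac_b = R²_A + R²_B − R²_full and frac_d = 1 − R²_full.  Significance of
    each model comes from a Monte-Carlo permutation test that permutes the
    response rows, p = (1 + #{R²_perm ≥ R²_obs}) / (1 + n_perm).
    ``adjusted=True`` applies the Ezekiel small-sample adjustment to every R²
    before partitioning (fractions then no longer sum to 1 − adj frac_d
    identity is preserved by construction through frac_d = 1 − R²_full_adj).
    """
    y = np.asarray(response, dtype=float)
    A = np.asarray(factor_set_A, dtype=float)
    B = np.asarray(factor_set_B, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if not (len(y) == len(A) == len(B)):
        raise ValueError("response and factor sets must have the same number of rows")
    if A.shape[1] == 0 or B.shape[1] == 0:
        raise ValueError("each factor set must contain at least one predictor")
    n = len(y)
    if n <= A.shape[1] + B.shape[1] + 1:
        raise ValueError("need more observations than combined predictors")

    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("constant response")

    q_A = _design_q(A)
    q_B = _design_q(B)
    q_AB = _design_q(np.column_stack([A, B]))

    def adj(r2: float, p: int) -> float:
        if not adjusted:
            return r2
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    r2_A = adj(_r2(q_A, y, tss), A.shape[1])
    r2_B = adj(_r2(q_B, y, tss), B.shape[1])
    r2_full = adj(_r2(q_AB, y, tss), A.shape[1] + B.shape[1])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(3, dtype=int)
    raw = (_r2(q_A, y, tss), _r2(q_B, y, tss), _r2(q_AB, y, tss))
    for _ in range(n_perm):
        yp = rng.permutation(y)
        tssp = float(yp @ yp - n * yp.mean() ** 2)
        exceed[0] += _r2(q_A, yp, tssp) >= raw[0]
        exceed[1] += _r2(q_B, yp, tssp) >= raw[1]
        exceed[2] += _r2(q_AB, yp, tssp) >= raw[2]
    p_A, p_B, p_full = (1.0 + exceed) / (1.0 + n_perm)

    frac_a = r2_full - r2_B
    frac_c = r2_full - r2_A
    frac_b = r2_A + r2_B - r2_full
    frac_d = 1.0 - r2_full
    if frac_b < 0:
        warnings.warn(f"negative shared fraction ({frac_b:.4f}); reported as-is")

    la = getattr(factor_set_A, "columns", None)
    lb = getattr(factor_set_B, "columns", None)
    return VariancePartition(
        frac_a=float(frac_a),
        frac_b=float(frac_b),
        frac_c=float(frac_c),
        frac_d=float(frac_d),
        r2_full=float(r2_full),
        r2_A=float(r2_A),
        r2_B=float(r2_B),
        p_full=float(p_full),
        p_A=float(p_A),
        p_B=float(p_B),
        label_A="+".join(map(str, la)) if la is not None else "A",
        label_B="+".join(map(str, lb)) if lb is not None else "B",
    )


# ---------------------------------------------------------------------------
# Piecewise (segmented) regression

@dataclass(frozen=True)
class PiecewiseFit:
    """Single-breakpoint continuous segmented fit of y on x."""

    breakpoint: float
    slope_left: float
    slope_right: float
    intercept_left: float
    intercept_right: float
    r2_overall: float
    r2_left: float
    r2_right: float
    n_left: int
    n_right: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.intercept_left
            + self.slope_left * x
            + (self.slope_right - self.slope_left) * np.maximum(x - self.breakpoint, 0.0)
        )

    def summary(self) -> str:
        return (
            f"Segmented fit: breakpoint psi = {self.breakpoint:.4f}\n"
            f"  left  (n={self.n_left}):  slope={self.slope_left: .4f}, "
            f"R2={self.r2_left:.3f}\n"
            f"  right (n={self.n_right}): slope={self.slope_right: .4f}, "
            f"R2={self.r2_right:.3f}\n"
            f"  overall R2 = {self.r2_overall:.3f}"
        )


def _hinge_rss(x: np.ndarray, y: np.ndarray, psi: float) -> tuple[float, np.ndarray]:
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def _simple_r2(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def piecewise_fit(x, y, n_grid: int = 100, min_segment: int = 3) -> PiecewiseFit:
    """Fit y = β0 + β1·x + β2·max(x − ψ, 0), estimating ψ.

    The breakpoint is chosen to minimize the residual sum of squares over
    ``n_grid`` interior x-quantiles (each candidate leaving at least
    ``min_segment`` points per side), then refined by golden-section search
    in the bracketing interval.  Ties in RSS resolve to the smallest ψ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 2 * min_segment or len(x) < 10:
        raise ValueError("too few points for segmented regression")

    xs = np.sort(x)
    lo, hi = xs[min_segment - 1], xs[-min_segment]
    if lo >= hi:
        raise ValueError("no admissible breakpoint: x values too tied")
    qs = np.linspace(0, 1, n_grid + 2)[1:-1]
    candidates = np.unique(np.clip(np.quantile(x, qs), lo, hi))
    candidates = candidates[(candidates > xs[0]) & (candidates < xs[-1])]
    if candidates.size == 0:
        raise ValueError("no admissible breakpoint candidates")

    rss = np.array([_hinge_rss(x, y, c)[0] for c in candidates])
    best = int(np.argmin(rss))  # argmin takes the first (smallest psi) on ties

    # golden-section refinement within the bracketing grid interval
    a = candidates[max(best - 1, 0)]
    b = candidates[min(best + 1, len(candidates) - 1)]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = _hinge_rss(x, y, c)[0], _hinge_rss(x, y, d)[0]
    for _ in range(60):
        if b - a < 1e-10 * max(1.0, abs(a)):
            break
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _hinge_rss(x, y, c)[0]
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _hinge_rss(x, y, d)[0]
    psi = float((a + b) / 2.0)
    if _hinge_rss(x, y, candidates[best])[0] < _hinge_rss(x, y, psi)[0]:
        psi = float(candidates[best])

    final_rss, beta = _hinge_rss(x, y, psi)
    yc = y - y.mean()
    tss = float(yc @ yc)
    r2_overall = 1.0 - final_rss / tss if tss > 0 else np.nan

    left = x <= psi
    right = ~left
    return PiecewiseFit(
        breakpoint=psi,
        slope_left=float(beta[1]),
        slope_right=float(beta[1] + beta[2]),
        intercept_left=float(beta[0]),
        intercept_right=float(beta[0] - beta[2] * psi),
        r2_overall=float(r2_overall),
        r2_left=_simple_r2(x[left], y[left]),
        r2_right=_simple_r2(x[right], y[right]),
        n_left=int(left.sum()),
        n_right=int(right.sum()),
    )


# ---------------------------------------------------------------------------
# Spatial autocorrelation

def great_circle_distances(lon, lat, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Pairwise haversine distances (km) between points on a spherical Earth."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2.0) ** 2
    )
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def great_circle_weights(lon, lat) -> np.ndarray:
    """Inverse-distance weights w_ij = 1/d_ij, zero diagonal.

    Coincident distinct points would make a weight infinite; they are
    reported rather than silently clipped.
    """
    d = great_circle_distances(lon, lat)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if d[i, j] == 0
        ]
        raise ValueError(f"coincident points (infinite weight): {pairs[:10]}")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    return w


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    n: int

    def summary(self) -> str:
        return (
            f"Moran's I = {self.I:.4f} (E[I] = {self.expected:.4f}, "
            f"z = {self.z:.2f}, p = {self.p_value:.4g}, n = {self.n})"
        )


def morans_i(values, weights) -> MoranResult:
    """Global Moran's I with significance under the normality approximation.

    I = (n/S0) Σ_ij w_ij (x_i − x̄)(x_j − x̄) / Σ_i (x_i − x̄)²,
    E[I] = −1/(n−1); the variance uses the standard normality moments.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if w.shape != (n, n):
        raise ValueError("weights must be n x n")
    if (w < 0).any() or np.diag(w).any():
        raise ValueError("weights must be non-negative with a zero diagonal")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    s0 = float(w.sum())
    num = float(z @ w @ z)
    I = n / s0 * num / denom

    e_i = -1.0 / (n - 1)
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2 = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    var = (n**2 * s1 - n * s2 + 3.0 * s0**2) / ((n**2 - 1) * s0**2) - e_i**2
    zscore = (I - e_i) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(zscore))
    return MoranResult(float(I), float(e_i), float(var), float(zscore), float(p), n)


def residual_autocorrelation(
    response, predictors: pd.DataFrame, weights
) -> tuple[MoranResult, float, MoranResult]:
    """Moran's I of the raw response, full-model OLS R², and Moran's I of the
    OLS residuals — the diagnostic for how much spatial structure the
    environmental predictors absorb."""
    y = np.asarray(response, dtype=float)
    X = sm.add_constant(np.asarray(predictors, dtype=float))
    fit = sm.OLS(y, X).fit()
    raw = morans_i(y, weights)
    resid = morans_i(fit.resid, weights)
    return raw, float(fit.rsquared), resid
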