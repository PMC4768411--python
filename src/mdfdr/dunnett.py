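"""Dunnett many-to-one statistics and two-sided multivariate-t tail areas.

The many-to-one comparison of q experimental groups with one reference group
uses, per feature j,

    T_ij = (mean_i - mean_0) / (s_j * sqrt(1/n_i + 1/n_0)),

with s_j^2 the variance pooled across all p = q+1 groups (df = sum n_g - p).
Under the per-feature global null the vector (T_1j, ..., T_qj) follows a
central q-variate t with correlation

    r_ik = sqrt(lambda_i * lambda_k),   lambda_i = n_i / (n_i + n_0),

(the shared reference mean induces the product-form correlation; a balanced
design gives r_ik = 1/2). Single-step adjusted p-values and the max-|T|
screening p-value are both tail areas of max_i |T_i| under this law.

The tail P(max_i |T_i| >= c) is evaluated by deterministic quadrature on the
conditional-independence representation: conditionally on the latent
reference variate Z0 and the pooled scale W = s/sigma, the T_i are
independent with

    P(all |T_i| < c | Z0=z, W=w)
        = prod_i [ Phi((c*w - a_i z)/b_i) - Phi((-c*w - a_i z)/b_i) ],

a_i = sqrt(lambda_i), b_i = sqrt(1 - lambda_i). The z-integral uses
Gauss-Hermite nodes and the w-integral generalized Gauss-Laguerre nodes for
the chi2_df mixing density, so results are deterministic to ~1e-10. A
Monte-Carlo fallback handles correlation matrices without the product form.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special, stats

from .data import ExpressionMatrix, FeatureStats, GroupDesign

__all__ = [
    "DunnettNullModel",
    "dunnett_statistics",
    "max_abs_t_tail",
    "screening_pvalue",
    "dunnett_pairwise_pvalue",
]


def _factor_product_correlation(rho: np.ndarray) -> np.ndarray | None:
    """Recover lambda_i from r_ik = sqrt(lambda_i lambda_k), or None.

    Solves the log-linear system by least squares and accepts the factors
    only if they reproduce rho to 1e-8.
    """
    rho = np.asarray(rho, dtype=float)
    q = rho.shape[0]
    if q == 1:
        return np.array([0.5])  # immaterial: no off-diagonals to honour
    off = rho[np.triu_indices(q, k=1)]
    if np.any(off <= 0) or np.any(off >= 1):
        return None
    # 2*log r_ik = log lambda_i + log lambda_k
    rows, cols = np.triu_indices(q, k=1)
    A = np.zeros((len(rows), q))
    A[np.arange(len(rows)), rows] = 1.0
    A[np.arange(len(rows)), cols] = 1.0
    sol, *_ = np.linalg.lstsq(A, 2.0 * np.log(off), rcond=None)
    lam = np.exp(sol)
    if np.any(lam <= 0) or np.any(lam >= 1):
        return None
    fitted = np.sqrt(np.outer(lam, lam))
    np.fill_diagonal(fitted, 1.0)
    if not np.allclose(fitted, rho, atol=1e-8):
        return None
    return lam


@dataclass(frozen=True)
class DunnettNullModel:
    """Null distribution of the q many-to-one statistics within one feature."""

    q: int
    df: int
    rho: np.ndarray
    lam: tuple | None = None
    mc_draws: int = 200_000
    mc_seed: int = 0

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (self.q, self.q):
            raise ValueError("rho must be q x q")
        object.__setattr__(self, "rho", rho)
        if self.lam is not None:
            object.__setattr__(self, "lam", tuple(float(v) for v in self.lam))

    @classmethod
    def from_design(cls, design: GroupDesign) -> "DunnettNullModel":
        sizes = design.group_sizes
        n0 = sizes[design.reference_label]
        n = np.array([sizes[g] for g in design.experimental_labels], dtype=float)
        lam = n / (n + n0)
        rho = np.sqrt(np.outer(lam, lam))
        np.fill_diagonal(rho, 1.0)
        return cls(q=design.q, df=design.df, rho=rho, lam=tuple(lam))

    @property
    def lambdas(self) -> np.ndarray | None:
        """Product-form factors of rho, or None if rho has no such form.

        Factors known from the group sizes take precedence; otherwise they
        are recovered from rho (any valid factorization yields the same
        joint law, so non-uniqueness at q = 2 is harmless).
        """
        if self.lam is not None:
            return np.asarray(self.lam)
        return _factor_product_correlation(self.rho)


@lru_cache(maxsize=32)
def _nodes(df: int, n_z: int = 64, n_w: int | None = None):
    """Joint quadrature nodes over (Z0, W) with W^2 ~ chi2_df / df.

    Returns flattened (z, w, weight) arrays of length n_z * n_w. The scale
    integral needs more Laguerre nodes at small df, where the t tail is
    heavy; counts below keep the absolute error under ~1e-9 for df >= 10
    (a few 1e-6 at df = 4, still far below any decision threshold).
    """
    if n_w is None:
        n_w = 40 if df >= 30 else 96 if df >= 10 else 160
    z, wz = special.roots_hermitenorm(n_z)
    wz = wz / np.sqrt(2.0 * np.pi)
    # chi2 integral via q = 2t: weight t^(df/2-1) e^-t / Gamma(df/2)
    t, wt = special.roots_genlaguerre(n_w, df / 2.0 - 1.0)
    w = np.sqrt(2.0 * t / df)
    wt = wt / special.gamma(df / 2.0)
    zz, ww = np.meshgrid(z, w, indexing="ij")
    weight = np.outer(wz, wt)
    return zz.ravel(), ww.ravel(), weight.ravel()


def max_abs_t_tail(
    c,
    model: DunnettNullModel,
    *,
    return_se: bool = False,
):
    """P(max_i |T_i| >= c) under the central many-to-one null model.

    Vectorized over ``c`` (scalar or array, c >= 0); monotone nonincreasing
    in c with values clipped to [0, 1]. Product-form correlation matrices
    are integrated by deterministic quadrature; anything else falls back to
    Monte Carlo with the model's fixed seed (``return_se=True`` then also
    returns the Monte-Carlo standard error; for quadrature the SE is 0).
    """
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    if np.any(c_arr < 0):
        raise ValueError("c must be nonnegative")
    lam = model.lambdas
    if lam is None:
        p, se = _tail_mc(c_arr, model)
    else:
        p = _tail_interpolated(c_arr, lam, model.df)
        se = np.zeros_like(p)
    p = np.clip(p, 0.0, 1.0)
    if np.isscalar(c) or np.ndim(c) == 0:
        p = float(p[0])
        se = float(se[0])
    if return_se:
        return p, se
    return p


_GRID_MAX = 15.0


@lru_cache(maxsize=16)
def _tail_spline(df: int, lam_key: tuple):
    """Dense cubic-spline fit of the tail curve for one null model.

    The tail is a smooth monotone function of c, so a spline through
    quadrature values on a step-0.005 grid reproduces it to ~1e-10; caching
    it makes repeated evaluation (screening plus pairwise p-values over
    thousands of features) essentially free and keeps every evaluation of
    the same null model numerically identical.
    """
    from scipy.interpolate import CubicSpline

    grid = np.linspace(0.0, _GRID_MAX, 3001)
    vals = _tail_quadrature(grid, np.asarray(lam_key), df)
    return CubicSpline(grid, vals)


def _tail_interpolated(c: np.ndarray, lam: np.ndarray, df: int) -> np.ndarray:
    spline = _tail_spline(int(df), tuple(np.round(lam, 12)))
    out = np.empty_like(c)
    inside = c <= _GRID_MAX
    out[inside] = spline(c[inside])
    if not inside.all():
        out[~inside] = _tail_quadrature(c[~inside], lam, df)
    return out


def _tail_quadrature(c: np.ndarray, lam: np.ndarray, df: int) -> np.ndarray:
    z, w, weight = _nodes(int(df))
    a = np.sqrt(lam)
    b = np.sqrt(1.0 - lam)
    out = np.empty_like(c)
    chunk = 4096
    equal = np.allclose(lam, lam[0])
    for start in range(0, len(c), chunk):
        cw = c[start : start + chunk, None] * w[None, :]  # (M, K)
        if equal:
            d = special.ndtr((cw - a[0] * z) / b[0]) - special.ndtr(
                (-cw - a[0] * z) / b[0]
            )
            prod = d ** len(lam)
        else:
            prod = np.ones_like(cw)
            for ai, bi in zip(a, b):
                prod *= special.ndtr((cw - ai * z) / bi) - special.ndtr(
                    (-cw - ai * z) / bi
                )
        out[start : start + chunk] = 1.0 - prod @ weight
    return out


def _tail_mc(c: np.ndarray, model: DunnettNullModel) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(model.mc_seed)
    n = model.mc_draws
    L = np.linalg.cholesky(model.rho + 1e-12 * np.eye(model.q))
    zmax = np.empty(n)
    block = 100_000
    for start in range(0, n, block):
        k = min(block, n - start)
        zn = rng.standard_normal((k, model.q)) @ L.T
        s = np.sqrt(rng.chisquare(model.df, size=k) / model.df)
        zmax[start : start + k] = np.abs(zn).max(axis=1) / s
    hits = (zmax[None, :] >= c[:, None]).mean(axis=1)
    se = np.sqrt(hits * (1.0 - hits) / n)
    return hits, se


def dunnett_statistics(
    matrix: ExpressionMatrix, design: GroupDesign
) -> FeatureStats:
    """Compute T_ij for every feature and comparison.

    Features whose pooled variance is exactly zero (constant across all
    samples) get a NaN row: the statistic is undefined and such features
    carry no evidence (they receive screening p = 1 downstream).
    """
    model = DunnettNullModel.from_design(design)
    values = matrix.values
    sizes = design.group_sizes
    n0 = sizes[design.reference_label]
    ref_idx = design.indices(design.reference_label)
    ref_mean = values[:, ref_idx].mean(axis=1)

    ss = np.zeros(matrix.m)
    diffs = np.empty((matrix.m, design.q))
    for i, g in enumerate(design.experimental_labels):
        idx = design.indices(g)
        grp = values[:, idx]
        mean = grp.mean(axis=1)
        diffs[:, i] = mean - ref_mean
        ss += ((grp - mean[:, None]) ** 2).sum(axis=1)
    ss += ((values[:, ref_idx] - ref_mean[:, None]) ** 2).sum(axis=1)
    s2 = ss / design.df

    n = np.array([sizes[g] for g in design.experimental_labels], dtype=float)
    scale = np.sqrt(1.0 / n + 1.0 / n0)  # (q,)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diffs / (np.sqrt(s2)[:, None] * scale[None, :])
    t[s2 == 0.0] = np.nan
    return FeatureStats(t=t, df=design.df, rho=model.rho)


def screening_pvalue(
    stats_: FeatureStats, model: DunnettNullModel
) -> np.ndarray:
    """Per-feature screening p-value, p_j = P(max_i |T_i| >= max_i |T_ij|).

    One p-value per feature; features with undefined statistics get p = 1.
    """
    t = stats_.t
    defined = np.all(np.isfinite(t), axis=1)
    p = np.ones(t.shape[0])
    if defined.any():
        cmax = np.abs(t[defined]).max(axis=1)
        p[defined] = max_abs_t_tail(cmax, model)
    return p


def dunnett_pairwise_pvalue(t_value, model: DunnettNullModel):
    """Single-step adjusted p-value P(max_k |T_k| >= |t|) for one statistic.

    Vectorized over ``t_value``; NaN inputs map to p = 1.
    """
    t_arr = np.atleast_1d(np.asarray(t_value, dtype=float))
    p = np.ones_like(t_arr)
    ok = np.isfinite(t_arr)
    if ok.any():
        p[ok] = max_abs_t_tail(np.abs(t_arr[ok]), model)
    if np.isscalar(t_value) or np.ndim(t_value) == 0:
        return float(p[0])
    return p


def two_sided_t_pvalues(stats_: FeatureStats) -> np.ndarray:
    """Raw two-sided p-values 2*P(t_df >= |T_ij|), NaN statistics -> 1.

    These are the inputs to the Holm/Hochberg/Bonferroni pairwise variants
    and to the Bonferroni screening comparator.
    """
    t = stats_.t
    p = np.ones_like(t)
    ok = np.isfinite(t)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), stats_.df)
    return p
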