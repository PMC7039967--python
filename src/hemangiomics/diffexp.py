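"""Differential-expression statistics.

Three ingredients used across the pipeline layers:

* two-group t tests (pooled, Welch, or empirical-Bayes moderated) for the
  consecutive-stage and propranolol-vs-control contrasts;
* Benjamini-Hochberg FDR adjustment;
* a spline time-course F test for two-arm designs: each feature's
  temporal trend is modelled with a natural cubic spline basis and the
  arm x basis interaction is tested with an F statistic whose numerator
  degrees of freedom equal the basis dimension (3 in the default
  configuration), optionally with moderated denominator variances.

Results are tidy DataFrames with one row per feature and columns
``feature, contrast, effect, stat, df, p, q, degenerate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exprmatrix import ExpressionMatrix

# smallest positive double: degenerate zero-variance features get this p
TINY_P = np.nextafter(0.0, 1.0)

RESULT_COLUMNS = ["feature", "contrast", "effect", "stat", "df", "p", "q", "degenerate"]


@dataclass
class SplineTestConfig:
    """Configuration for the spline time-course test.

    ``n_knots`` sets the natural-cubic basis dimension (and therefore the
    interaction degrees of freedom reported); ``moderation`` turns
    empirical-Bayes variance shrinkage on.
    """

    n_knots: int = 3
    moderation: bool = False

    def __post_init__(self) -> None:
        if self.n_knots < 1:
            raise ValueError(f"n_knots must be >= 1, got {self.n_knots}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderate_variances(variances, df: float):
    """Empirical-Bayes shrinkage of per-feature variances.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the ensemble of
    sample variances by method of moments on log variances, then returns
    the posterior variances (d0*s0^2 + df*s^2) / (d0 + df) and the
    augmented degrees of freedom df + d0.

    Returns
    -------
    (posterior_variances, augmented_df, d0, s0_sq, no_spread_flag)
        ``no_spread_flag`` is True when the variances carry no excess
        spread (d0 = inf) and every posterior equals s0^2.
    """
    s2 = np.asarray(variances, dtype=float)
    if s2.size < 10:
        raise ValueError("moderation needs >= 10 features to estimate hyperparameters")
    if (s2 < 0).any():
        raise ValueError("variances must be non-negative")
    # work on log variances; zeros are excluded from hyperparameter fitting
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("too few positive variances to moderate")
    z = np.log(s2[ok])
    if np.ptp(z) < 1e-12:
        # literally identical variances: the prior is that common value
        s0_sq = float(s2[ok][0])
        return np.full_like(s2, s0_sq), np.inf, np.inf, s0_sq, True
    # E[log s^2] = log s0^2 + psi(d/2) - log(d/2) - (psi(d0/2) - log(d0/2))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = np.var(e, ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # spread no larger than sampling noise: infinite prior df
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
        post = np.full_like(s2, s0_sq)
        return post, np.inf, d0, s0_sq, True
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, df + d0, d0, s0_sq, False


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations on 1/trigamma)."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def two_group_ttest(matrix: ExpressionMatrix, groups, contrast: tuple[str, str],
                    variant: str = "pooled", fdr: float = 0.05) -> pd.DataFrame:
    """Per-feature two-sided t test of contrast (A, B); effect = mean(A) - mean(B).

    ``groups`` maps sample ID -> group label (dict or Series).  ``variant``
    is one of ``pooled``, ``welch``, ``moderated``.  Zero-variance features
    with a nonzero difference receive the smallest representable positive
    p and a degenerate flag; zero difference gives t = 0, p = 1.
    """
    if variant not in ("pooled", "welch", "moderated"):
        raise ValueError(f"unknown variant {variant!r}")
    groups = pd.Series(groups)
    a_label, b_label = contrast
    a_cols = [s for s in matrix.sample_ids if groups.get(s) == a_label]
    b_cols = [s for s in matrix.sample_ids if groups.get(s) == b_label]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"both groups need >= 2 samples; got {len(a_cols)} in {a_label!r}, "
            f"{len(b_cols)} in {b_label!r}")
    xa = matrix.data[a_cols].to_numpy(dtype=float)
    xb = matrix.data[b_cols].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    effect = xa.mean(axis=1) - xb.mean(axis=1)
    degenerate = np.zeros(len(effect), dtype=bool)

    if variant == "welch":
        stat, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
        va = xa.var(axis=1, ddof=1)
        vb = xb.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        zero = (va + vb) == 0
        stat, p, df, degenerate = _patch_degenerate(stat, p, df, effect, zero,
                                                    float(na + nb - 2))
    else:
        d = float(na + nb - 2)
        s2 = ((na - 1) * xa.var(axis=1, ddof=1) + (nb - 1) * xb.var(axis=1, ddof=1)) / d
        if variant == "moderated":
            s2_used, df_used, *_ = moderate_variances(s2, d)
            df = np.full_like(effect, df_used)
        else:
            s2_used = s2
            df = np.full_like(effect, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(s2_used * (1.0 / na + 1.0 / nb))
            stat = effect / se
        finite_df = np.where(np.isfinite(df), df, 1e6)  # moderated d0=inf -> normal limit
        p = 2.0 * stats.t.sf(np.abs(stat), finite_df)
        zero = s2_used == 0
        stat, p, df, degenerate = _patch_degenerate(stat, p, df, effect, zero, d)

    q = bh_adjust(p)
    return pd.DataFrame({
        "feature": matrix.feature_ids,
        "contrast": f"{a_label}_vs_{b_label}",
        "effect": effect,
        "stat": stat,
        "df": df,
        "p": p,
        "q": q,
        "degenerate": degenerate,
    })


def _patch_degenerate(stat, p, df, effect, zero_var, fallback_df):
    """Zero-variance handling: nonzero effect -> tiny p + flag; zero -> t=0, p=1."""
    stat = np.asarray(stat, dtype=float).copy()
    p = np.asarray(p, dtype=float).copy()
    df = np.asarray(df, dtype=float).copy()
    degenerate = np.zeros(len(p), dtype=bool)
    nz = zero_var & (effect != 0)
    z0 = zero_var & (effect == 0)
    stat[nz] = np.sign(effect[nz]) * np.inf
    p[nz] = TINY_P
    degenerate[nz] = True
    stat[z0] = 0.0
    p[z0] = 1.0
    degenerate[z0] = True
    df[zero_var & ~np.isfinite(df)] = fallback_df
    return stat, p, df, degenerate


# ---------------------------------------------------------------------------
# spline time-course test


def natural_spline_basis(x, df: int = 3, boundary: tuple[float, float] | None = None,
                         interior_knots=None) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns, excluding the intercept.

    Boundary knots sit at the min/max of ``x`` and ``df - 1`` interior
    knots at evenly spaced quantiles (the R ``ns(x, df=)`` convention),
    so a model [1, basis] has ``df + 1`` parameters.  The basis is linear
    beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if boundary is None:
        boundary = (float(x.min()), float(x.max()))
    lo, hi = boundary
    if interior_knots is None:
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior_knots = np.quantile(np.unique(x), probs) if df > 1 else np.array([])
    knots = np.concatenate([[lo], np.atleast_1d(interior_knots), [hi]])
    knots = np.unique(knots)
    if len(knots) != df + 1:
        raise ValueError(
            f"need {df + 1} distinct knots for a {df}-column basis, got {len(knots)}")

    def d(k, t):
        # truncated-cubic differences; constant second derivative cancels
        return (np.clip(t - knots[k], 0, None) ** 3
                - np.clip(t - knots[-1], 0, None) ** 3) / (knots[-1] - knots[k])

    cols = [x]
    for k in range(len(knots) - 2):
        cols.append(d(k, x) - d(len(knots) - 2, x))
    return np.column_stack(cols)


def spline_timecourse_test(matrix: ExpressionMatrix, time, arm,
                           cfg: SplineTestConfig | None = None) -> pd.DataFrame:
    """Two-arm time-course F test on the arm x spline interaction.

    Null model: intercept + arm offset + shared spline curve.  Full model
    adds arm-specific spline coefficients.  The F statistic tests the
    interaction block (numerator df = basis dimension); with moderation
    on, denominator variances are shrunk across features and the residual
    df augmented accordingly.
    """
    cfg = cfg or SplineTestConfig()
    time = pd.Series(time)
    arm = pd.Series(arm)
    samples = matrix.sample_ids
    t = np.array([float(time[s]) for s in samples])
    a = np.array([str(arm[s]) for s in samples])
    arms = sorted(set(a))
    if len(arms) != 2:
        raise ValueError(f"need exactly two arms, got {arms}")
    distinct = np.unique(t)
    if len(distinct) < 4:
        raise ValueError(f"need >= 4 distinct time points, got {len(distinct)}")
    if len(distinct) < cfg.n_knots + 1:
        raise ValueError(
            f"{cfg.n_knots}-column basis needs >= {cfg.n_knots + 1} distinct times")
    for lab in arms:
        if len(np.unique(t[a == lab])) < 2:
            raise ValueError(f"arm {lab!r} observed at fewer than 2 times")

    basis = natural_spline_basis(t, df=cfg.n_knots)
    ind = (a == arms[1]).astype(float)
    x_null = np.column_stack([np.ones(len(t)), ind, basis])
    x_full = np.column_stack([x_null, basis * ind[:, None]])
    p_null = np.linalg.matrix_rank(x_null)
    p_full = np.linalg.matrix_rank(x_full)
    if p_null < x_null.shape[1] or p_full < x_full.shape[1]:
        raise ValueError(
            "rank-deficient design: arm/spline columns are collinear "
            f"(rank {p_full} of {x_full.shape[1]})")
    df_num = x_full.shape[1] - x_null.shape[1]
    df_den = len(t) - x_full.shape[1]
    if df_den < 1:
        raise ValueError("no residual degrees of freedom")

    y = matrix.values.T  # samples x features
    rss_null = _rss(x_null, y)
    rss_full = _rss(x_full, y)
    msr = (rss_null - rss_full) / df_num
    msr = np.clip(msr, 0.0, None)  # guard tiny negative round-off
    s2 = rss_full / df_den

    degenerate = np.zeros(y.shape[1], dtype=bool)
    if cfg.moderation:
        s2_used, df_den_used, *_ = moderate_variances(s2, float(df_den))
        df_den_arr = np.full(y.shape[1], df_den_used)
    else:
        s2_used = s2
        df_den_arr = np.full(y.shape[1], float(df_den))

    with np.errstate(divide="ignore", invalid="ignore"):
        f = msr / s2_used
    p = np.empty_like(f)
    finite_dfd = np.where(np.isfinite(df_den_arr), df_den_arr, 1e9)
    ok = np.isfinite(f)
    p[ok] = stats.f.sf(f[ok], df_num, finite_dfd[ok])
    # constant (or perfectly fitted) features: 0/0 -> no interaction evidence
    bad = ~ok | ((s2_used == 0) & (msr == 0))
    f[bad & ~ok] = 0.0
    p[bad] = 1.0
    degenerate[bad] = True
    # zero residual variance but real interaction signal
    inf_sig = (s2_used == 0) & (msr > 0)
    f[inf_sig] = np.inf
    p[inf_sig] = TINY_P
    degenerate[inf_sig] = True

    q = bh_adjust(p)
    return pd.DataFrame({
        "feature": matrix.feature_ids,
        "contrast": f"{arms[1]}_vs_{arms[0]}_timecourse",
        "effect": np.sqrt(np.maximum(rss_null - rss_full, 0.0) / len(t)),
        "stat": f,
        "df": float(df_num),
        "p": p,
        "q": q,
        "degenerate": degenerate,
    })


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of y (samples x features) on design x via QR.

    Residuals are formed explicitly (not total - fitted) and sums below
    the round-off floor of the projection are snapped to exactly zero, so
    noise-free features register as degenerate instead of yielding
    garbage F ratios of two round-off errors.
    """
    q, _ = np.linalg.qr(x)
    resid = y - q @ (q.T @ y)
    rss = (resid ** 2).sum(axis=0)
    floor = (y ** 2).sum(axis=0) * 1e-22
    rss[rss <= floor] = 0.0
    return rss
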