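"""Single-step many-to-one (Dunnett) comparisons against a shared control.

The adjusted two-sided p-value for contrast ``i`` is

    p_adj_i = 1 - Pr( max_j |T_j| <= |t_i| )

under the k-variate central t distribution with the contrast correlation
matrix and a common degrees of freedom.  The equicoordinate probability
is evaluated by scrambled-Sobol quasi-Monte-Carlo (t variates built as
correlated normals over a shared chi scale mixture), with the Monte-Carlo
half-width estimated from independent scramble replicates and reported on
every result.  For df above 500 the scale mixture is dropped (multivariate
normal limit); for a single contrast the exact univariate t tail is used.

Comparisons are two-sided throughout: the screen cares about increases
and decreases alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

from .kinetics import percent_change, round_percent

__all__ = [
    "ComparisonResult",
    "dunnett_adjust",
    "compare_to_control",
    "significance_tier",
    "max_abs_studentized_exceedance",
    "DEFAULT_QMC_POINTS",
    "DEFAULT_QMC_SEED",
]

DEFAULT_QMC_POINTS = 200_000
DEFAULT_QMC_SEED = 20180918
_N_BATCHES = 8
_NORMAL_DF_CUTOFF = 500.0


@dataclass
class ComparisonResult:
    """One compound-vs-control contrast with raw and adjusted inference."""

    compound_id: str
    metric: str
    estimate: float
    control_mean: float
    treated_mean: float
    percent_change: float
    se: float
    df: float
    t_stat: float
    p_raw: float
    p_adj: float
    mc_error: float
    se_control: float = float("nan")
    se_treated: float = float("nan")

    @property
    def percent_change_int(self) -> int:
        """Reporting form: integer percent, halves rounded away from zero."""
        return round_percent(self.percent_change)

    def percent_change_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Delta-method confidence interval for the percent change.

        The control and treated group means are independent under the
        cell-means covariance, so Var(pct) ≈ 100² (v_t / m_c² +
        m_t² v_c / m_c⁴); the critical value is a t quantile at the
        contrast df.
        """
        mc, mt = self.control_mean, self.treated_mean
        var = 1e4 * (
            self.se_treated**2 / mc**2 + mt**2 * self.se_control**2 / mc**4
        )
        crit = float(stats.t.ppf(0.5 + level / 2.0, self.df))
        half = crit * float(np.sqrt(var))
        return self.percent_change - half, self.percent_change + half

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adj <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")


def _cholesky_psd(corr: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a correlation matrix, tolerant of semi-definiteness."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return np.linalg.cholesky(corr + jitter * np.eye(len(corr)))
        except np.linalg.LinAlgError:
            continue
    # semi-definite fallback via eigendecomposition
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def _one_factor_loadings(corr: np.ndarray) -> np.ndarray | None:
    """Loadings lambda with corr_ij = lambda_i lambda_j off-diagonal, or None.

    The shared-control design always has this structure
    (``lambda_i = sqrt(n_i / (n_i + n_0))`` in the balanced case).  Signs of
    individual loadings do not affect the distribution of the coordinate-wise
    absolute maximum, so the factorization is fitted on magnitudes.
    """
    k = corr.shape[0]
    iu = np.triu_indices(k, 1)
    off = np.abs(corr[iu])
    if np.all(off < 1e-14):
        return np.zeros(k)
    if np.any(off < 1e-14):
        return None
    # log lambda_i + log lambda_j = log |rho_ij|, least squares
    a = np.zeros((len(off), k))
    a[np.arange(len(off)), iu[0]] = 1.0
    a[np.arange(len(off)), iu[1]] = 1.0
    x, *_ = np.linalg.lstsq(a, np.log(off), rcond=None)
    lam = np.exp(x)
    if np.any(lam > 1.0 - 1e-9):
        return None
    if np.max(np.abs(np.outer(lam, lam)[iu] - off)) > 1e-9:
        return None
    return lam


def max_abs_studentized_exceedance(
    tvals: np.ndarray,
    corr: np.ndarray,
    df: float,
    n_points: int = DEFAULT_QMC_POINTS,
    seed: int = DEFAULT_QMC_SEED,
) -> tuple[np.ndarray, np.ndarray]:
    """Pr(max_j |T_j| > |t_i|) for each threshold, by scrambled-Sobol QMC.

    When the correlation matrix has the one-factor form of the
    shared-control design, the k idiosyncratic coordinates are integrated
    analytically conditional on the common factor and the chi scale,
    leaving a smooth two-dimensional integrand.  Arbitrary PSD matrices
    fall back to direct sampling of the coordinate maximum.

    Returns (probabilities, mc_half_widths); the half-width is three
    standard errors across scramble replicates.  Deterministic for a given
    (inputs, seed).
    """
    tvals = np.abs(np.asarray(tvals, dtype=float))
    corr = np.asarray(corr, dtype=float)
    L = _cholesky_psd(corr)  # validates symmetry/PSD up front
    k = L.shape[0]
    use_t = np.isfinite(df) and df <= _NORMAL_DF_CUTOFF
    lam = _one_factor_loadings(corr)
    d = (2 if use_t else 1) if lam is not None else k + (1 if use_t else 0)
    m = int(np.ceil(np.log2(max(n_points // _N_BATCHES, 2))))
    eps = 1e-12
    p_batches = np.empty((_N_BATCHES, len(tvals)))
    ss = np.random.SeedSequence([int(seed), k, int(df) if np.isfinite(df) else -1])
    child_seeds = ss.spawn(_N_BATCHES)
    for b in range(_N_BATCHES):
        sob = qmc.Sobol(d=d, scramble=True, seed=np.random.default_rng(child_seeds[b]))
        u = np.clip(sob.random_base2(m), eps, 1.0 - eps)
        if use_t:
            s = np.sqrt(stats.chi2.ppf(u[:, -1], df) / df)
        else:
            s = np.ones(u.shape[0])
        if lam is not None:
            z0 = ndtri(u[:, 0])
            sig = np.sqrt(np.clip(1.0 - lam**2, 1e-16, None))
            shared = z0[:, None] * lam[None, :]  # (n, k)
            for i, t in enumerate(tvals):
                ts = t * s
                hi = ndtr((ts[:, None] - shared) / sig[None, :])
                lo = ndtr((-ts[:, None] - shared) / sig[None, :])
                p_batches[b, i] = 1.0 - np.mean(np.prod(hi - lo, axis=1))
        else:
            z = ndtri(u[:, :k]) @ L.T
            mx = np.max(np.abs(z), axis=1) / s
            p_batches[b] = np.mean(mx[:, None] > tvals[None, :], axis=0)
    p = p_batches.mean(axis=0)
    mc = 3.0 * p_batches.std(axis=0, ddof=1) / np.sqrt(_N_BATCHES)
    return p, mc


def dunnett_adjust(
    tvals,
    corr,
    df: float,
    n_points: int = DEFAULT_QMC_POINTS,
    seed: int = DEFAULT_QMC_SEED,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided raw and Dunnett-adjusted p-values for t statistics.

    Parameters
    ----------
    tvals : array-like
        The k contrast t statistics.
    corr : (k, k) array
        Correlation matrix of the contrast estimators (unit diagonal, PSD).
    df : float
        Common degrees of freedom for all contrasts.

    Returns
    -------
    (p_raw, p_adj, mc_error)
        ``p_adj`` clipped to honour ``p_raw <= p_adj <= min(1, k p_raw)``
        up to the reported Monte-Carlo half-width; a single contrast is
        computed analytically (``p_adj == p_raw``, zero error).
    """
    tvals = np.asarray(tvals, dtype=float)
    if tvals.ndim != 1:
        raise ValueError("tvals must be 1-D")
    k = len(tvals)
    if k == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    if df < 1:
        raise ValueError("df must be >= 1")
    p_raw = 2.0 * stats.t.sf(np.abs(tvals), df)
    if k == 1:
        return p_raw, p_raw.copy(), np.zeros(1)
    p_adj, mc = max_abs_studentized_exceedance(
        tvals, np.asarray(corr, dtype=float), df, n_points=n_points, seed=seed
    )
    p_adj = np.clip(p_adj, p_raw, 1.0)
    return p_raw, p_adj, mc


def compare_to_control(
    results,
    n_points: int = DEFAULT_QMC_POINTS,
    seed: int = DEFAULT_QMC_SEED,
) -> list[ComparisonResult]:
    """Full many-to-one comparison for a fitted week.

    Takes :class:`~rodscreen.mixedlm.RandomInterceptResults`, builds the
    control contrasts, assigns one common df (the minimum Satterthwaite df
    across contrasts — a conservative tie-break for the joint
    distribution), and returns one :class:`ComparisonResult` per compound.
    """
    cs = results.contrast_control()
    i0 = results.level_index(results.model.control)
    k = len(cs.names)
    p = results.k_levels
    dfs = []
    for name in cs.names:
        c = np.zeros(p)
        c[results.level_index(name)] = 1.0
        c[i0] = -1.0
        dfs.append(results.satterthwaite_df(c))
    df = float(min(dfs))
    tvals = cs.estimates / cs.se
    p_raw, p_adj, mc = dunnett_adjust(
        tvals, cs.correlation, df, n_points=n_points, seed=seed
    )
    out = []
    for j, name in enumerate(cs.names):
        out.append(
            ComparisonResult(
                compound_id=name,
                metric=results.metric,
                estimate=float(cs.estimates[j]),
                control_mean=cs.control_mean,
                treated_mean=float(cs.treated_means[j]),
                percent_change=percent_change(float(cs.treated_means[j]), cs.control_mean),
                se=float(cs.se[j]),
                df=df,
                t_stat=float(tvals[j]),
                p_raw=float(p_raw[j]),
                p_adj=float(p_adj[j]),
                mc_error=float(mc[j]),
                se_control=cs.control_se,
                se_treated=float(cs.treated_se[j]),
            )
        )
    return out


def significance_tier(p_adj: float) -> str:
    """The screen's significance ladder; boundaries exclusive as printed."""
    if not 0.0 <= p_adj <= 1.0:
        raise ValueError("p_adj must be in [0, 1]")
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"
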