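"""Random-intercept mixed model for one screening week, fitted by REML.

The design is strictly nested: rods within fish within treatment group,
one shared control group per week.  The model for rod ``r`` of fish ``i``
under treatment ``l`` is::

    y_{lir} = beta_l + b_i + e_{lir},   b_i ~ N(0, tau^2),  e ~ N(0, sigma^2)

Estimation profiles the variance ratio ``theta = tau^2 / sigma^2``: for a
given theta the fixed effects are generalized least squares — each group
mean is the precision-weighted combination of its fish means with fish
weight ``n_i / (1 + theta n_i)`` — and sigma^2 has a closed-form REML
profile estimate, leaving a one-dimensional restricted-likelihood search
over theta on [0, 1e6].  Degrees of freedom for contrasts use the
Satterthwaite approximation from finite differences of the restricted
deviance, the convention of the mixed-model software family this design
is usually analysed with.

Everything here is in closed form per fish, so fits cost O(#fish) per
likelihood evaluation regardless of rod counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "RandomInterceptModel",
    "RandomInterceptResults",
    "ContrastSet",
    "LineageError",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_SIGMA_FLOOR = 1e-12
_THETA_MAX = 1e6


class LineageError(ValueError):
    """A fish appears under more than one treatment."""


@dataclass
class ContrastSet:
    """Compound-vs-control contrasts from one fitted week.

    ``correlation`` is the full k×k correlation matrix of the contrast
    estimators, needed by the many-to-one adjustment; for the shared-control
    design it has the one-factor form ``rho_ij = lambda_i lambda_j``.
    """

    names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    correlation: np.ndarray
    covariance: np.ndarray
    control_mean: float
    treated_means: np.ndarray
    control_se: float
    treated_se: np.ndarray


@dataclass
class RandomInterceptResults:
    """REML estimates for one week's model, statsmodels-results flavoured."""

    model: "RandomInterceptModel"
    metric: str
    week_id: str | None
    treatment_levels: list[str]
    fixed_estimates: np.ndarray
    fixed_covariance: np.ndarray
    var_fish: float
    var_resid: float
    theta: float
    log_restricted_likelihood: float
    converged: bool
    n_per_fish: pd.Series
    flags: dict = field(default_factory=dict)

    # -- basic accessors -------------------------------------------------
    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def k_levels(self) -> int:
        return len(self.treatment_levels)

    @property
    def fixed_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.fixed_covariance))

    def level_index(self, level: str) -> int:
        return self.treatment_levels.index(level)

    # -- contrasts -------------------------------------------------------
    def contrast_control(self) -> ContrastSet:
        """Each non-control level minus the control, with SEs and correlations."""
        if self.model.control is None:
            raise ValueError("no control level present in this fit")
        i0 = self.level_index(self.model.control)
        others = [j for j in range(self.k_levels) if j != i0]
        if not others:
            raise ValueError("no non-control levels to contrast")
        est = self.fixed_estimates[others] - self.fixed_estimates[i0]
        v = np.diag(self.fixed_covariance)
        var = v[others] + v[i0]  # cell-means covariance is diagonal
        se = np.sqrt(np.maximum(var, 0.0))
        se = np.maximum(se, 1e-12)  # guard noise-free degenerate fits
        k = len(others)
        lam = np.sqrt(v[i0] / var)
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        cov = corr * np.outer(se, se)
        return ContrastSet(
            names=[self.treatment_levels[j] for j in others],
            estimates=est,
            se=se,
            correlation=corr,
            covariance=cov,
            control_mean=float(self.fixed_estimates[i0]),
            treated_means=self.fixed_estimates[others],
            control_se=float(np.sqrt(v[i0])),
            treated_se=np.sqrt(v[others]),
        )

    # -- degrees of freedom ----------------------------------------------
    def satterthwaite_df(self, contrast: Sequence[float]) -> float:
        """Satterthwaite effective df for the variance of ``c' beta``.

        Uses the delta method on the contrast variance as a function of
        (tau^2, sigma^2), with the asymptotic covariance of the variance
        components taken from the finite-difference Hessian of the
        restricted deviance.  Falls back to ``n_fish - levels`` (flagged)
        if that Hessian is singular, and collapses to the OLS residual df
        when the fish component is estimated at zero.
        """
        c = np.asarray(contrast, dtype=float)
        m = self.model
        p = self.k_levels
        if self.var_fish <= 0.0:
            return float(max(m.nobs - p, 1))

        def cvar(tau2: float, sigma2: float) -> float:
            theta = tau2 / sigma2
            w = m.fish_n / (1.0 + theta * m.fish_n)
            wl = np.bincount(m.fish_level, weights=w, minlength=p)
            return float(np.sum(c**2 / wl) * sigma2)

        t2, s2 = self.var_fish, self.var_resid
        h1 = max(1e-4 * t2, 1e-8)
        h2 = max(1e-4 * s2, 1e-8)
        g = np.array(
            [
                (cvar(t2 + h1, s2) - cvar(max(t2 - h1, 0.0), s2))
                / (h1 + min(h1, t2)),
                (cvar(t2, s2 + h2) - cvar(t2, s2 - h2)) / (2 * h2),
            ]
        )
        vc_cov = self._vc_covariance()
        fallback = float(max(len(m.fish_n) - p, 1))
        if vc_cov is None:
            self.flags["df_fallback"] = True
            return fallback
        denom = float(g @ vc_cov @ g)
        if not np.isfinite(denom) or denom <= 0:
            self.flags["df_fallback"] = True
            return fallback
        v = cvar(t2, s2)
        df = 2.0 * v**2 / denom
        if not np.isfinite(df):
            self.flags["df_fallback"] = True
            return fallback
        return float(np.clip(df, 1.0, m.nobs - p))

    def _vc_covariance(self) -> np.ndarray | None:
        """Asymptotic covariance of (tau^2, sigma^2); cached; None if singular."""
        if not hasattr(self, "_vc_cov_cache"):
            H = self._deviance_hessian(self.var_fish, self.var_resid)
            try:
                cov = 2.0 * np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = None
            self._vc_cov_cache = cov
        return self._vc_cov_cache

    def _deviance_hessian(self, t2: float, s2: float) -> np.ndarray:
        m = self.model
        h1 = max(1e-4 * t2, 1e-8)
        h2 = max(1e-4 * s2, 1e-8)
        # keep tau^2 evaluations non-negative (boundary-safe)
        t_lo = max(t2 - h1, 0.0)
        dt = t2 + h1 - t_lo

        def d(a: float, b: float) -> float:
            return m._restricted_deviance(a / b, sigma2=b)

        d00 = d(t2, s2)
        H = np.empty((2, 2))
        H[0, 0] = (d(t2 + h1, s2) - 2 * d00 + d(t_lo, s2)) / (dt / 2) ** 2 \
            if t_lo == t2 - h1 else \
            (d(t2 + 2 * h1, s2) - 2 * d(t2 + h1, s2) + d00) / h1**2
        H[1, 1] = (d(t2, s2 + h2) - 2 * d00 + d(t2, s2 - h2)) / h2**2
        H[0, 1] = H[1, 0] = (
            d(t2 + h1, s2 + h2)
            - d(t2 + h1, s2 - h2)
            - d(t_lo, s2 + h2)
            + d(t_lo, s2 - h2)
        ) / (2 * h2 * (t2 + h1 - t_lo))
        return H

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Random-intercept model (REML)",
            f"  metric: {self.metric}" + (f"   week: {self.week_id}" if self.week_id else ""),
            f"  observations: {self.nobs}   fish: {len(self.model.fish_n)}   "
            f"levels: {self.k_levels}",
            f"  var(fish) tau^2 = {self.var_fish:.6g}   "
            f"var(resid) sigma^2 = {self.var_resid:.6g}",
            f"  restricted log-likelihood = {self.log_restricted_likelihood:.4f}   "
            f"converged: {self.converged}",
            "",
            f"  {'level':<24}{'estimate':>12}{'se':>12}",
        ]
        for name, b, s in zip(
            self.treatment_levels, self.fixed_estimates, self.fixed_se
        ):
            lines.append(f"  {name:<24}{b:>12.4f}{s:>12.4f}")
        if self.flags:
            lines.append(f"  flags: {sorted(self.flags)}")
        return "\n".join(lines)


class RandomInterceptModel:
    """One week's rods-within-fish model with treatment fixed effects.

    Parameters
    ----------
    y : array-like
        Rod-level distances (µm).
    treatment : array-like of str
        Treatment label per rod; the control label is put first.
    fish : array-like of str
        Fish identifier per rod; each fish must sit in exactly one treatment.
    control : str, optional
        Which treatment level is the shared control (enables contrasts).
    """

    def __init__(
        self,
        y,
        treatment,
        fish,
        control: str | None = None,
        metric: str = "y",
        week_id: str | None = None,
    ) -> None:
        y = np.asarray(y, dtype=float)
        treatment = np.asarray(treatment, dtype=object)
        fish = np.asarray(fish, dtype=object)
        if not (len(y) == len(treatment) == len(fish)):
            raise ValueError("y, treatment and fish must have equal length")
        if len(y) == 0:
            raise ValueError("no observations")
        if np.isnan(y).any():
            keep = ~np.isnan(y)
            y, treatment, fish = y[keep], treatment[keep], fish[keep]
            if len(y) == 0:
                raise ValueError("no non-missing observations")

        levels = sorted(set(treatment))
        if control is not None:
            if control not in levels:
                raise ValueError(f"control level {control!r} not in data")
            levels = [control] + [l for l in levels if l != control]
        self.control = control
        self.treatment_levels = levels
        self.metric = metric
        self.week_id = week_id
        self.nobs = len(y)

        level_of = {l: i for i, l in enumerate(levels)}
        rod_level = np.array([level_of[t] for t in treatment])

        # fish lineage: one treatment each
        df = pd.DataFrame({"fish": fish, "level": rod_level, "y": y})
        lineage = df.groupby("fish")["level"].nunique()
        bad = lineage.index[lineage > 1]
        if len(bad):
            raise LineageError(
                f"fish {list(bad)} appear under more than one treatment"
            )
        agg = df.groupby("fish").agg(
            n=("y", "size"), total=("y", "sum"), ss=("y", lambda v: float(np.sum(np.square(v)))),
            level=("level", "first"),
        )
        self.fish_ids = list(agg.index)
        self.fish_n = agg["n"].to_numpy(dtype=float)
        self.fish_sum = agg["total"].to_numpy(dtype=float)
        self.fish_ss = agg["ss"].to_numpy(dtype=float)
        self.fish_level = agg["level"].to_numpy(dtype=int)
        self.fish_mean = self.fish_sum / self.fish_n
        counts = np.bincount(self.fish_level, minlength=len(levels))
        if (counts == 0).any():
            raise ValueError("every treatment level needs at least one fish")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        metric: str = "d_growth_um",
        control: str | None = None,
        week_id: str | None = None,
    ) -> "RandomInterceptModel":
        """Build from a measurement table (one week's rows).

        If ``control`` is omitted it is resolved from ``treatment_role ==
        'control'`` when that column is present and names a single compound.
        """
        if control is None and "treatment_role" in df.columns:
            ctl = df.loc[df["treatment_role"] == "control", "compound_id"].unique()
            if len(ctl) == 1:
                control = str(ctl[0])
            elif len(ctl) > 1:
                raise ValueError(f"multiple control groups in week: {list(ctl)}")
        if week_id is None and "week_id" in df.columns:
            wk = df["week_id"].unique()
            week_id = str(wk[0]) if len(wk) == 1 else None
        return cls(
            y=df[metric],
            treatment=df["compound_id"],
            fish=df["fish_id"],
            control=control,
            metric=metric,
            week_id=week_id,
        )

    # -- restricted likelihood machinery ----------------------------------
    def _gls_beta(self, theta: float) -> tuple[np.ndarray, np.ndarray]:
        """Fixed effects and per-level GLS weights at a given variance ratio."""
        p = len(self.treatment_levels)
        w = self.fish_n / (1.0 + theta * self.fish_n)
        wl = np.bincount(self.fish_level, weights=w, minlength=p)
        wy = np.bincount(self.fish_level, weights=w * self.fish_mean, minlength=p)
        return wy / wl, wl

    def _quad_and_logdet(self, theta: float) -> tuple[float, float, float, np.ndarray]:
        """(r' V^-1 r on unit scale, log|I+theta ZZ'|, log|X'V^-1X| term, beta)."""
        beta, wl = self._gls_beta(theta)
        b = beta[self.fish_level]
        rss = self.fish_ss - 2.0 * b * self.fish_sum + self.fish_n * b**2
        dev = self.fish_sum - self.fish_n * b
        quad = float(np.sum(rss - theta / (1.0 + theta * self.fish_n) * dev**2))
        logdet_v = float(np.sum(np.log1p(theta * self.fish_n)))
        logdet_xvx = float(np.sum(np.log(wl)))
        return quad, logdet_v, logdet_xvx, beta

    def _restricted_deviance(self, theta: float, sigma2: float | None = None) -> float:
        """-2 restricted log-likelihood; profiles sigma^2 when not given."""
        n, p = self.nobs, len(self.treatment_levels)
        quad, logdet_v, logdet_xvx, _ = self._quad_and_logdet(theta)
        if sigma2 is None:
            sigma2 = max(quad / (n - p), _SIGMA_FLOOR)
            q_term = float(n - p)
        else:
            sigma2 = max(sigma2, _SIGMA_FLOOR)
            q_term = quad / sigma2
        return (
            (n - p) * (_LOG2PI + np.log(sigma2))
            + logdet_v
            + logdet_xvx
            + q_term
        )

    def _restricted_deviance_grad(self, theta: float) -> float:
        """Analytic d/dtheta of the profiled restricted deviance.

        Uses the envelope theorem: beta and sigma^2 are at their profiled
        optima, so only the explicit theta dependence contributes.
        """
        n, p = self.nobs, len(self.treatment_levels)
        quad, _, _, beta = self._quad_and_logdet(theta)
        b = beta[self.fish_level]
        dev = self.fish_sum - self.fish_n * b
        shrink = 1.0 + theta * self.fish_n
        d_quad = -float(np.sum((dev / shrink) ** 2))
        d_logdet_v = float(np.sum(self.fish_n / shrink))
        w = self.fish_n / shrink
        wl = np.bincount(self.fish_level, weights=w, minlength=p)
        d_wl = np.bincount(
            self.fish_level, weights=-((self.fish_n / shrink) ** 2), minlength=p
        )
        d_logdet_xvx = float(np.sum(d_wl / wl))
        return (n - p) * d_quad / max(quad, _SIGMA_FLOOR) + d_logdet_v + d_logdet_xvx

    def _polish_theta(self, theta0: float, theta_max: float) -> float:
        """Refine an interior optimum by bracketing the derivative's root."""
        from scipy.optimize import brentq

        lo, hi = 0.0, max(theta0, 1e-8)
        g_hi = self._restricted_deviance_grad(hi)
        while g_hi < 0.0 and hi < theta_max:
            lo, hi = hi, min(hi * 8.0, theta_max)
            g_hi = self._restricted_deviance_grad(hi)
        if g_hi < 0.0:
            return float(theta_max)  # optimum at the upper bound
        if g_hi == 0.0:
            return float(hi)
        try:
            return float(
                brentq(self._restricted_deviance_grad, lo, hi, xtol=1e-14, rtol=1e-15)
            )
        except ValueError:
            return float(theta0)

    # -- fitting -----------------------------------------------------------
    def fit(self, theta_max: float = _THETA_MAX, xatol: float = 1e-10) -> RandomInterceptResults:
        """REML fit by bounded 1-D search over the variance ratio.

        The profiled restricted deviance is minimised over
        ``theta in [0, theta_max]`` (golden-section with parabolic
        refinement), then polished to machine precision by root-finding
        the analytic derivative; the boundary ``theta = 0`` is checked
        explicitly so a negative between-fish moment truncates cleanly to
        zero.
        """
        n, p = self.nobs, len(self.treatment_levels)
        flags: dict = {}

        res = minimize_scalar(
            self._restricted_deviance,
            bounds=(0.0, theta_max),
            method="bounded",
            options={"xatol": xatol},
        )
        theta = float(res.x)
        converged = bool(res.success)
        if self._restricted_deviance(0.0) <= res.fun:
            theta = 0.0
        if theta <= xatol:
            theta = 0.0
            flags["tau_truncated"] = True
        elif self._restricted_deviance_grad(0.0) >= 0.0:
            # profiled deviance increasing at the origin: boundary optimum
            theta = 0.0
            flags["tau_truncated"] = True
        else:
            theta = self._polish_theta(theta, theta_max)

        quad, *_, beta = self._quad_and_logdet(theta)
        sigma2 = quad / (n - p) if n > p else 0.0
        if sigma2 <= _SIGMA_FLOOR:
            sigma2 = _SIGMA_FLOOR
            flags["degenerate_variance"] = True
        tau2 = theta * sigma2
        _, wl = self._gls_beta(theta)
        cov = np.diag(sigma2 / wl)
        dev = self._restricted_deviance(theta)
        return RandomInterceptResults(
            model=self,
            metric=self.metric,
            week_id=self.week_id,
            treatment_levels=list(self.treatment_levels),
            fixed_estimates=beta,
            fixed_covariance=cov,
            var_fish=tau2,
            var_resid=sigma2,
            theta=theta,
            log_restricted_likelihood=-0.5 * dev,
            converged=converged,
            n_per_fish=pd.Series(self.fish_n, index=self.fish_ids, name="n_rods"),
            flags=flags,
        )
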