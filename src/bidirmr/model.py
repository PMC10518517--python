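"""Causal-effect estimators for two-sample Mendelian randomization.

The central objects follow the model/results convention: :class:`MRModel`
wraps a harmonized instrument set (per-SNP exposure effects gamma and
outcome effects Gamma with their SEs) and ``fit(method=...)`` returns an
:class:`MRResults` carrying the causal estimate, its uncertainty and
heterogeneity diagnostics.

Methods
-------
wald
    Single-instrument ratio Gamma/gamma with first-order delta SE.
ivw_fixed / ivw_mre
    Inverse-variance-weighted meta-analysis of Wald ratios, equivalent to a
    zero-intercept weighted regression of Gamma on gamma with weights
    1/se_Gamma^2.  The multiplicative-random-effects variant inflates the SE
    by sqrt(max(1, Q/(J-1))) so it never undercuts the fixed-effect SE.
egger
    Weighted regression with a free intercept; a nonzero intercept signals
    directional horizontal pleiotropy.  Inference on t(J-2).
weighted_median
    Weighted median of per-SNP ratios; consistent when valid instruments
    carry more than half the weight.  SE by parametric bootstrap.
weighted_mode
    Mode of a normal-kernel weighted density over per-SNP ratios
    (modified-Silverman bandwidth); consistent when the largest cluster of
    ratios is valid.  SE by parametric bootstrap.

Heterogeneity is summarised by Cochran's Q over the per-SNP ratios and
I^2 = max(0, (Q - df)/Q).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrumentSet

logger = logging.getLogger("bidirmr")

__all__ = [
    "MRModel",
    "MRResults",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "cochran_q",
    "leave_one_out",
    "funnel_data",
    "InsufficientInstrumentsError",
]

METHODS = ("wald", "ivw_fixed", "ivw_mre", "egger", "weighted_median", "weighted_mode")


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


@dataclass
class MRResults:
    """One method's causal estimate with uncertainty and diagnostics.

    ``theta`` is the causal effect on the outcome scale per unit exposure;
    for binary outcomes on the log-odds scale ``exp(theta)`` is the odds
    ratio (see :meth:`odds_ratio`).
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_snps: int
    q_statistic: float | None = None
    q_df: int | None = None
    q_p_value: float | None = None
    i_squared: float | None = None
    dispersion: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"

    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) on the exponentiated scale."""
        return float(np.exp(self.theta)), float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_row(self) -> dict:
        or_, lo, hi = self.odds_ratio()
        return {
            "method": self.method,
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "n_snps": self.n_snps,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "or": or_,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "p": self.p_value,
            "q": self.q_statistic,
            "i2": self.i_squared,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
        }

    def summary(self) -> str:
        or_, lo, hi = self.odds_ratio()
        lines = [
            f"{'Two-sample MR: ' + self.method:^60}",
            "=" * 60,
            f"exposure: {self.exposure_id}    outcome: {self.outcome_id}",
            f"instruments (J): {self.n_snps}",
            f"theta      {self.theta: .4f}  (SE {self.se:.4f})",
            f"95% CI     [{self.ci_low: .4f}, {self.ci_high: .4f}]",
            f"OR         {or_:.3f}  [{lo:.3f}, {hi:.3f}]",
            f"p-value    {self.p_value:.4g}",
        ]
        if self.q_statistic is not None:
            lines.append(
                f"Cochran Q  {self.q_statistic:.3f} (df {self.q_df}, p {self.q_p_value:.3g}), "
                f"I^2 {self.i_squared:.1%}"
            )
        if self.egger_intercept is not None:
            lines.append(
                f"intercept  {self.egger_intercept: .4f} "
                f"(SE {self.egger_intercept_se:.4f}, p {self.egger_intercept_p:.3g})"
            )
        lines.append("=" * 60)
        return "\n".join(lines)


def _normal_ci_p(theta: float, se: float) -> tuple[float, float, float]:
    z = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(theta) / se) if se > 0 else (1.0 if theta == 0 else 0.0)
    return theta - z * se, theta + z * se, p


def wald_ratio(gamma: float, se_gamma: float, Gamma: float, se_Gamma: float,
               second_order: bool = False) -> MRResults:
    """Single-SNP causal estimate Gamma/gamma with delta-method SE.

    First-order SE is se_Gamma/|gamma|; the second-order form adds the
    gamma-uncertainty term Gamma^2 se_gamma^2 / gamma^4.
    """
    if gamma == 0:
        raise ZeroDivisionError("Wald ratio undefined for gamma = 0")
    theta = Gamma / gamma
    var = se_Gamma**2 / gamma**2
    if second_order:
        var += Gamma**2 * se_gamma**2 / gamma**4
    se = float(np.sqrt(var))
    lo, hi, p = _normal_ci_p(theta, se)
    return MRResults("wald", float(theta), se, lo, hi, p, n_snps=1)


class MRModel:
    """Two-sample MR model over a harmonized instrument set.

    Parameters
    ----------
    hset
        :class:`HarmonizedInstrumentSet` of aligned (gamma, se_gamma,
        Gamma, se_Gamma) rows.
    second_order_se
        Use second-order delta-method variances for per-SNP ratios
        (default first-order).
    """

    def __init__(self, hset: HarmonizedInstrumentSet, second_order_se: bool = False):
        if len(hset) == 0:
            raise ValueError("empty instrument set")
        self.hset = hset
        self.second_order_se = second_order_se

    # -- per-SNP quantities -------------------------------------------------

    def ratio_estimates(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP Wald ratios and their delta-method variances."""
        g, sg, G, sG = (self.hset.gamma, self.hset.se_gamma,
                        self.hset.Gamma, self.hset.se_Gamma)
        if np.any(g == 0):
            raise ZeroDivisionError("ratio estimates undefined: some gamma = 0")
        theta = G / g
        var = sG**2 / g**2
        if self.second_order_se:
            var = var + G**2 * sg**2 / g**4
        return theta, var

    # -- estimators ---------------------------------------------------------

    def fit(self, method: str = "ivw_mre", n_boot: int = 1000,
            seed: int | np.random.Generator | None = None,
            phi: float = 1.0) -> MRResults:
        """Fit one causal estimator; returns :class:`MRResults`.

        ``seed`` drives the parametric bootstrap of the median/mode SEs;
        ``phi`` multiplies the weighted-mode bandwidth.
        """
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        if method == "wald":
            if len(self.hset) != 1:
                raise ValueError("wald requires exactly one instrument")
            res = wald_ratio(self.hset.gamma[0], self.hset.se_gamma[0],
                             self.hset.Gamma[0], self.hset.se_Gamma[0],
                             self.second_order_se)
        elif method in ("ivw_fixed", "ivw_mre"):
            res = self._fit_ivw(random_effects=(method == "ivw_mre"))
        elif method == "egger":
            res = self._fit_egger()
        elif method == "weighted_median":
            res = self._fit_wmedian(n_boot, seed)
        else:
            res = self._fit_wmode(phi, n_boot, seed)
        res.exposure_id = self.hset.exposure_id
        res.outcome_id = self.hset.outcome_id
        return res

    def _fit_ivw(self, random_effects: bool = True) -> MRResults:
        J = len(self.hset)
        if J == 0:
            raise InsufficientInstrumentsError("IVW requires at least one instrument")
        if J == 1:
            logger.info("IVW with J=1 falls back to the Wald ratio")
            return self.fit("wald")
        g, G, sG = self.hset.gamma, self.hset.Gamma, self.hset.se_Gamma
        w = 1.0 / sG**2
        denom = float(np.sum(w * g**2))
        theta = float(np.sum(w * g * G) / denom)
        se_fixed = denom**-0.5
        q = float(np.sum(w * (G - theta * g) ** 2))
        df = J - 1
        disp = q / df
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
        se = se_fixed * np.sqrt(max(1.0, disp)) if random_effects else se_fixed
        lo, hi, p = _normal_ci_p(theta, se)
        return MRResults("ivw_mre" if random_effects else "ivw_fixed",
                         theta, float(se), lo, hi, p, J,
                         q_statistic=q, q_df=df,
                         q_p_value=float(stats.chi2.sf(q, df)),
                         i_squared=i2, dispersion=disp)

    def _fit_egger(self) -> MRResults:
        J = len(self.hset)
        if J < 3:
            raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
        g, G, sG = (self.hset.gamma.copy(), self.hset.Gamma.copy(), self.hset.se_Gamma)
        # orient every gamma positive so the intercept sign is well defined
        flip = g < 0
        g[flip] *= -1.0
        G[flip] *= -1.0
        w = 1.0 / sG**2
        X = np.column_stack([np.ones(J), g])
        xtwx = X.T @ (w[:, None] * X)
        xtwy = X.T @ (w * G)
        coef = np.linalg.solve(xtwx, xtwy)
        resid = G - X @ coef
        df = J - 2
        sigma2 = float(np.sum(w * resid**2) / df)  # weighted residual scale
        cov = np.linalg.inv(xtwx) * max(1.0, sigma2)  # SE floored at the unit-scale SE
        intercept, slope = float(coef[0]), float(coef[1])
        se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        tcrit = stats.t.ppf(0.975, df)
        p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, df)
        p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, df)
        q = float(np.sum(w * resid**2))
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
        return MRResults("egger", slope, se_slope,
                         slope - tcrit * se_slope, slope + tcrit * se_slope,
                         float(p_slope), J,
                         q_statistic=q, q_df=df,
                         q_p_value=float(stats.chi2.sf(q, df)),
                         i_squared=i2, dispersion=sigma2,
                         egger_intercept=intercept, egger_intercept_se=se_int,
                         egger_intercept_p=float(p_int))

    @staticmethod
    def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
        """Interpolated weighted median at standardized cumulative weight 0.5."""
        order = np.argsort(theta, kind="stable")
        t, ww = theta[order], w[order]
        s = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
        return float(np.interp(0.5, s, t))

    def _boot_se(self, point_fn, n_boot: int,
                 seed: int | np.random.Generator | None) -> float:
        """Parametric bootstrap: resample gamma*, Gamma* from their normals."""
        rng = np.random.default_rng(seed)
        g, sg, G, sG = (self.hset.gamma, self.hset.se_gamma,
                        self.hset.Gamma, self.hset.se_Gamma)
        J = len(g)
        gs = rng.normal(g, sg, size=(n_boot, J))
        Gs = rng.normal(G, sG, size=(n_boot, J))
        ests = np.empty(n_boot)
        for b in range(n_boot):
            ests[b] = point_fn(gs[b], Gs[b])
        return float(np.std(ests, ddof=1))

    def _fit_wmedian(self, n_boot: int, seed) -> MRResults:
        J = len(self.hset)
        if J < 3:
            raise InsufficientInstrumentsError("weighted median requires at least 3 instruments")
        theta_j, var_j = self.ratio_estimates()
        w = 1.0 / var_j
        est = self._weighted_median(theta_j, w)
        sG, sg = self.hset.se_Gamma, self.hset.se_gamma

        def point(gb, Gb):
            tb = Gb / gb
            vb = sG**2 / gb**2
            if self.second_order_se:
                vb = vb + Gb**2 * sg**2 / gb**4
            return self._weighted_median(tb, 1.0 / vb)

        se = self._boot_se(point, n_boot, seed)
        lo, hi, p = _normal_ci_p(est, se)
        return MRResults("weighted_median", est, se, lo, hi, p, J)

    @staticmethod
    def _mode_point(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
        """Grid argmax of the normal-kernel weighted density of ratios."""
        J = len(theta)
        wn = w / np.sum(w)
        mean = float(np.sum(wn * theta))
        sd = float(np.sqrt(np.sum(wn * (theta - mean) ** 2)))
        med = MRModel._weighted_median(theta, w)
        mad = MRModel._weighted_median(np.abs(theta - med), w) / 0.6745
        # modified Silverman rule over the weighted spread measures
        spread = min(s for s in (sd, mad) if s > 0) if (sd > 0 or mad > 0) else 0.0
        h = phi * 0.9 * spread * J ** (-1 / 5)
        if h <= 0:
            return float(theta[0])  # all ratios identical
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
        dens = np.sum(wn[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2),
                      axis=0)
        return float(grid[np.argmax(dens)])

    def _fit_wmode(self, phi: float, n_boot: int, seed) -> MRResults:
        J = len(self.hset)
        if J < 3:
            raise InsufficientInstrumentsError("weighted mode requires at least 3 instruments")
        theta_j, var_j = self.ratio_estimates()
        w = 1.0 / var_j
        est = self._mode_point(theta_j, w, phi)
        sG, sg = self.hset.se_Gamma, self.hset.se_gamma

        def point(gb, Gb):
            tb = Gb / gb
            vb = sG**2 / gb**2
            if self.second_order_se:
                vb = vb + Gb**2 * sg**2 / gb**4
            return self._mode_point(tb, 1.0 / vb, phi)

        se = self._boot_se(point, n_boot, seed)
        if se == 0:
            se = float(np.finfo(float).tiny)
        lo, hi, p = _normal_ci_p(est, se)
        return MRResults("weighted_mode", est, se, lo, hi, p, J)

    # -- diagnostics --------------------------------------------------------

    def cochran_q(self) -> tuple[float, int, float, float]:
        """Cochran's Q over per-SNP ratios against the IVW estimate.

        Returns (Q, df, p, I^2) with I^2 = max(0, (Q - df)/Q).
        """
        J = len(self.hset)
        if J < 2:
            raise InsufficientInstrumentsError("Q undefined for J < 2")
        theta_j, var_j = self.ratio_estimates()
        w = 1.0 / var_j
        theta_ivw = float(np.sum(w * theta_j) / np.sum(w))
        q = float(np.sum(w * (theta_j - theta_ivw) ** 2))
        df = J - 1
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
        return q, df, float(stats.chi2.sf(q, df)), i2

    def leave_one_out(self) -> tuple[list[tuple[str, MRResults]], bool]:
        """IVW-MRE estimates each omitting one SNP.

        Also returns ``all_same_side``: True iff every leave-one-out CI
        excludes zero on the same side as the full estimate.
        """
        J = len(self.hset)
        if J < 3:
            raise InsufficientInstrumentsError("leave-one-out requires at least 3 instruments")
        full = self.fit("ivw_mre")
        side = np.sign(full.theta)
        out: list[tuple[str, MRResults]] = []
        same_side = True
        for vid in self.hset.variant_ids:
            res = MRModel(self.hset.drop([vid]), self.second_order_se).fit("ivw_mre")
            out.append((vid, res))
            excludes_zero = (res.ci_low > 0) if side > 0 else (res.ci_high < 0)
            same_side = same_side and bool(excludes_zero)
        return out, same_side

    def funnel_data(self):
        """Per-SNP (ratio, precision) table for funnel plotting.

        Precision is 1/SE of the per-SNP ratio.  The symmetry score is the
        standardized Wilcoxon signed-rank statistic of the ratios around the
        IVW estimate (None when J < 2 or all deviations are zero).
        """
        import pandas as pd

        theta_j, var_j = self.ratio_estimates()
        df = pd.DataFrame({
            "variant_id": self.hset.variant_ids,
            "ratio": theta_j,
            "precision": 1.0 / np.sqrt(var_j),
        })
        symmetry = None
        if len(theta_j) >= 2:
            w = 1.0 / var_j
            theta_ivw = float(np.sum(w * theta_j) / np.sum(w))
            d = theta_j - theta_ivw
            nz = d[d != 0]
            if len(nz) > 0:
                ranks = stats.rankdata(np.abs(nz))
                W = float(np.sum(np.sign(nz) * ranks))
                symmetry = W / float(np.sqrt(np.sum(ranks**2)))
        else:
            logger.info("funnel: single instrument, symmetry undefined")
        return df, symmetry

    def fit_all(self, n_boot: int = 1000, seed=None, phi: float = 1.0
                ) -> list[MRResults]:
        """Fit the standard estimator battery (IVW-MRE, Egger, median, mode;
        Wald when only one instrument survives)."""
        J = len(self.hset)
        if J == 1:
            return [self.fit("wald")]
        out = [self.fit("ivw_mre")]
        if J >= 3:
            rng = np.random.default_rng(seed)
            for method, kw in (("egger", {}),
                               ("weighted_median", {"seed": rng, "n_boot": n_boot}),
                               ("weighted_mode", {"seed": rng, "n_boot": n_boot,
                                                  "phi": phi})):
                try:
                    out.append(self.fit(method, **kw))
                except (np.linalg.LinAlgError, ZeroDivisionError) as err:
                    logger.warning("%s failed on degenerate design: %s", method, err)
        return out


# -- thin functional surface ------------------------------------------------

def ivw(hset: HarmonizedInstrumentSet, random_effects: bool = True,
        **kw) -> MRResults:
    """Inverse-variance-weighted estimate (multiplicative random effects by default)."""
    return MRModel(hset, **kw).fit("ivw_mre" if random_effects else "ivw_fixed")


def mr_egger(hset: HarmonizedInstrumentSet, **kw) -> MRResults:
    """MR-Egger regression: slope is the causal estimate, intercept the pleiotropy test."""
    return MRModel(hset, **kw).fit("egger")


def weighted_median(hset: HarmonizedInstrumentSet, n_boot: int = 1000,
                    seed=None, **kw) -> MRResults:
    return MRModel(hset, **kw).fit("weighted_median", n_boot=n_boot, seed=seed)


def weighted_mode(hset: HarmonizedInstrumentSet, phi: float = 1.0,
                  n_boot: int = 1000, seed=None, **kw) -> MRResults:
    return MRModel(hset, **kw).fit("weighted_mode", n_boot=n_boot, seed=seed, phi=phi)


def cochran_q(hset: HarmonizedInstrumentSet) -> tuple[float, int, float, float]:
    return MRModel(hset).cochran_q()


def leave_one_out(hset: HarmonizedInstrumentSet):
    return MRModel(hset).leave_one_out()


def funnel_data(hset: HarmonizedInstrumentSet):
    return MRModel(hset).funnel_data()
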