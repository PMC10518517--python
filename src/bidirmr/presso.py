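"""MR-PRESSO: pleiotropy residual sum and outlier tests by parametric simulation.

The global test compares the observed weighted residual sum of squares

    RSS = sum_j w_j (Gamma_j - theta_(-j) * gamma_j)^2,   w_j = 1/se_Gamma_j^2,

where theta_(-j) is the leave-one-out IVW slope, against its null
distribution simulated by drawing Gamma_j* ~ N(theta_(-j) gamma_j,
se_Gamma_j^2) and gamma_j* ~ N(gamma_j, se_gamma_j^2).  Per-SNP residual
contributions yield outlier p-values (Bonferroni-adjusted across J), and the
distortion test asks whether removing the flagged outliers moves the causal
estimate more than removing the same number of random SNPs would.

Empirical p-values use the +1 correction, so they lie in [1/(K+1), 1] and
are never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .harmonize import HarmonizedInstrumentSet
from .model import InsufficientInstrumentsError, MRModel, MRResults

logger = logging.getLogger("bidirmr")

__all__ = ["PressoResult", "presso_global", "presso_outlier",
           "presso_distortion", "run_presso"]


@dataclass
class PressoResult:
    """Global, outlier and distortion test results of one MR-PRESSO run."""

    rss_observed: float
    global_p: float
    per_snp: list[tuple[str, float, float, float]]  # (id, residual, p, bonferroni p)
    outliers: list[str]
    raw_estimate: MRResults
    corrected_estimate: MRResults | None
    distortion_p: float | None
    n_sim: int
    seed: int | None

    def to_rows(self) -> list[dict]:
        rows = [{
            "row": "global",
            "variant_id": "",
            "rss": self.rss_observed,
            "p": self.global_p,
            "p_bonferroni": None,
            "outlier": "",
        }]
        for vid, resid, p, padj in self.per_snp:
            rows.append({
                "row": "snp",
                "variant_id": vid,
                "rss": resid,
                "p": p,
                "p_bonferroni": padj,
                "outlier": vid in self.outliers,
            })
        return rows


def _loo_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes theta_(-j), vectorised over j (and over a
    leading simulation axis when present)."""
    num = np.sum(w * g * G, axis=-1, keepdims=True) - w * g * G
    den = np.sum(w * g * g, axis=-1, keepdims=True) - w * g * g
    return num / den


def presso_global(hset: HarmonizedInstrumentSet, n_sim: int = 1000,
                  seed: int | np.random.Generator | None = None
                  ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """MR-PRESSO global pleiotropy test.

    Returns (rss_observed, global_p, observed per-SNP residuals,
    simulated per-SNP residual matrix of shape (n_sim, J)); the simulated
    residuals feed :func:`presso_outlier`.
    """
    J = len(hset)
    if J < 4:
        raise InsufficientInstrumentsError(
            "MR-PRESSO requires at least 4 instruments (leave-one-out slopes need >= 3)")
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    rng = np.random.default_rng(seed)
    g, sg, G, sG = hset.gamma, hset.se_gamma, hset.Gamma, hset.se_Gamma
    w = 1.0 / sG**2

    slopes = _loo_slopes(g, G, w)
    resid_obs = w * (G - slopes * g) ** 2
    rss_obs = float(np.sum(resid_obs))

    g_sim = rng.normal(g, sg, size=(n_sim, J))
    G_sim = rng.normal(slopes * g, sG, size=(n_sim, J))
    slopes_sim = _loo_slopes(g_sim, G_sim, w)
    resid_sim = w * (G_sim - slopes_sim * g_sim) ** 2
    rss_sim = np.sum(resid_sim, axis=1)

    global_p = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)
    return rss_obs, global_p, resid_obs, resid_sim


def presso_outlier(hset: HarmonizedInstrumentSet, resid_obs: np.ndarray,
                   resid_sim: np.ndarray, alpha: float = 0.05
                   ) -> tuple[list[tuple[str, float, float, float]], list[str]]:
    """Per-SNP outlier test on the retained simulated residuals.

    Empirical per-SNP p-values are Bonferroni-adjusted across J; SNPs with
    adjusted p below ``alpha`` are flagged.
    """
    J = len(hset)
    K = resid_sim.shape[0]
    per_snp: list[tuple[str, float, float, float]] = []
    outliers: list[str] = []
    for j, vid in enumerate(hset.variant_ids):
        p = (1.0 + float(np.sum(resid_sim[:, j] >= resid_obs[j]))) / (K + 1.0)
        padj = min(1.0, p * J)
        per_snp.append((vid, float(resid_obs[j]), p, padj))
        if padj < alpha:
            outliers.append(vid)
            logger.info("MR-PRESSO outlier: %s (p=%.3g, adjusted %.3g)", vid, p, padj)
    return per_snp, outliers


def presso_distortion(hset: HarmonizedInstrumentSet, outliers: list[str],
                      n_sim: int = 1000,
                      seed: int | np.random.Generator | None = None
                      ) -> tuple[float, MRResults, MRResults]:
    """Distortion test: does outlier removal move the estimate more than
    removing the same number of random SNPs would?

    Returns (two-sided empirical p, raw estimate, outlier-corrected
    estimate).
    """
    if not outliers:
        raise ValueError("distortion test requires a non-empty outlier set")
    J = len(hset)
    n_out = len(outliers)
    if J - n_out < 2:
        raise InsufficientInstrumentsError(
            "corrected estimate needs at least 2 remaining instruments")
    rng = np.random.default_rng(seed)
    raw = MRModel(hset).fit("ivw_mre")
    corrected = MRModel(hset.drop(outliers)).fit("ivw_mre")
    d_obs = (corrected.theta - raw.theta) / abs(raw.theta)

    ids = np.array(hset.variant_ids)
    d_null = np.empty(n_sim)
    for k in range(n_sim):
        drop = rng.choice(ids, size=n_out, replace=False)
        d_null[k] = (MRModel(hset.drop(drop)).fit("ivw_mre").theta - raw.theta) / abs(raw.theta)
    p = (1.0 + float(np.sum(np.abs(d_null) >= abs(d_obs)))) / (n_sim + 1.0)
    return p, raw, corrected


def run_presso(hset: HarmonizedInstrumentSet, n_sim: int = 1000,
               seed: int | None = None, alpha: float = 0.05) -> PressoResult:
    """Full MR-PRESSO: global test, outlier test, and (when outliers are
    found) the outlier-corrected estimate and distortion test."""
    rng = np.random.default_rng(seed)
    rss_obs, global_p, resid_obs, resid_sim = presso_global(hset, n_sim, rng)
    per_snp, outliers = presso_outlier(hset, resid_obs, resid_sim, alpha)
    raw = MRModel(hset).fit("ivw_mre")
    corrected = None
    distortion_p = None
    if outliers and len(hset) - len(outliers) >= 2:
        distortion_p, raw, corrected = presso_distortion(hset, outliers, n_sim, rng)
    return PressoResult(rss_obs, global_p, per_snp, outliers, raw, corrected,
                        distortion_p, n_sim, seed)
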