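"""Sensitivity diagnostics for one exposure-outcome instrument set.

Four procedures: the MR-Egger intercept test for directional pleiotropy, the
MR-PRESSO global simulation test for horizontal pleiotropy with per-SNP
outlier flags, Cochran's Q heterogeneity test, and leave-one-out IVW
re-estimation.  All are pure functions of the instrument set plus seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import InsufficientInstrumentsError, ivw_mre, mr_egger
from .harmonize import HarmonizedInstrumentSet


@dataclass
class EggerInterceptResult:
    intercept: float
    se: float
    pval: float
    pleiotropy_detected: bool


@dataclass
class CochranQResult:
    q: float
    df: int
    pval: float
    heterogeneity_detected: bool


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    n_sim: int
    per_snp: pd.DataFrame  # SNP, contribution, pval, outlier
    outlier_detected: bool
    distortion: dict | None = None


@dataclass
class SensitivityReport:
    egger: EggerInterceptResult
    cochran: CochranQResult
    presso: PressoResult | None
    loo: pd.DataFrame  # SNP, beta, se, pval
    loo_stable: bool
    verdict: dict = field(default_factory=dict)

    def clean(self) -> bool:
        """No pleiotropy, no heterogeneity, no outliers, leave-one-out stable."""
        return (
            not self.egger.pleiotropy_detected
            and not self.cochran.heterogeneity_detected
            and (self.presso is None or not self.presso.outlier_detected
                 and self.presso.global_pval >= 0.05)
            and self.loo_stable
        )


def egger_intercept_test(hset: HarmonizedInstrumentSet,
                         alpha: float = 0.05) -> EggerInterceptResult:
    """Directional-pleiotropy test: the MR-Egger intercept estimates the
    average direct effect of the instruments on the outcome."""
    est = mr_egger(hset)
    p = est.extras["intercept_pval"]
    return EggerInterceptResult(
        intercept=est.extras["intercept"],
        se=est.extras["intercept_se"],
        pval=p,
        pleiotropy_detected=p < alpha,
    )


def cochran_q_test(hset: HarmonizedInstrumentSet,
                   alpha: float = 0.05) -> CochranQResult:
    """Heterogeneity of per-SNP ratio estimates about the IVW fit, referred to
    χ² with k−1 degrees of freedom."""
    if hset.k < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    est = ivw_mre(hset)
    q = est.extras["Q"]
    df = hset.k - 1
    p = float(stats.chi2.sf(q, df))
    return CochranQResult(q=q, df=df, pval=p, heterogeneity_detected=p < alpha)


def _loo_betas(bx, by, sy) -> np.ndarray:
    """Leave-one-out IVW point estimates, vectorized over the left-out SNP."""
    w = 1.0 / sy**2
    num = np.sum(w * bx * by)
    den = np.sum(w * bx**2)
    return (num - w * bx * by) / (den - w * bx**2)


def presso_global_test(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
    distortion: bool = False,
) -> PressoResult:
    """MR-PRESSO global test for horizontal pleiotropy.

    The observed statistic is the leave-one-out weighted residual sum of
    squares RSS = Σ_j (β_out,j − β̂₍₋ⱼ₎ β_exp,j)²/se_out,j²; its null
    distribution is simulated by redrawing each β_out,j from
    Normal(β̂₍₋ⱼ₎ β_exp,j, se_out,j²) and recomputing RSS.  The global
    p-value is the fraction of simulated RSS at or above the observed one;
    per-SNP outlier p-values compare each SNP's observed contribution with
    its simulated contributions, Bonferroni-corrected across SNPs.
    """
    if hset.k < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs >= 4 instruments, got {hset.k}"
        )
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    bx, by, sy = hset.bx, hset.by, hset.sy
    k = hset.k
    w = 1.0 / sy**2

    beta_loo = _loo_betas(bx, by, sy)
    expected = beta_loo * bx
    contrib_obs = w * (by - expected) ** 2
    rss_obs = float(np.sum(contrib_obs))

    by_sim = rng.normal(expected, sy, size=(n_sim, k))
    # leave-one-out estimates within each simulated dataset
    num = np.sum(w * bx * by_sim, axis=1, keepdims=True)
    den = np.sum(w * bx**2)
    beta_loo_sim = (num - w * bx * by_sim) / (den - w * bx**2)
    contrib_sim = w * (by_sim - beta_loo_sim * bx) ** 2
    rss_sim = contrib_sim.sum(axis=1)

    global_p = float(np.mean(rss_sim >= rss_obs))
    per_p = np.mean(contrib_sim >= contrib_obs[None, :], axis=0)
    outlier = per_p * k < outlier_alpha
    per = pd.DataFrame({
        "SNP": hset.snp_ids, "contribution": contrib_obs,
        "pval": per_p, "outlier": outlier,
    })

    dist = None
    if distortion and outlier.any() and (~outlier).sum() >= 2:
        full = ivw_mre(hset).beta
        pruned = ivw_mre(hset.subset(~outlier)).beta
        dist = {"beta_full": full, "beta_outlier_free": pruned,
                "shift": pruned - full}

    return PressoResult(
        rss_obs=rss_obs, global_pval=global_p, n_sim=n_sim, per_snp=per,
        outlier_detected=bool(outlier.any()), distortion=dist,
    )


def leave_one_out(hset: HarmonizedInstrumentSet,
                  threshold: float = 0.05) -> tuple[pd.DataFrame, bool]:
    """IVW re-estimated with each instrument left out in turn.

    The set is called stable when every leave-one-out estimate keeps the
    full-set estimate's sign and every p-value stays on the same side of
    ``threshold`` as the full-set p-value."""
    if hset.k < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    full = ivw_mre(hset)
    rows = []
    for j in range(hset.k):
        keep = np.ones(hset.k, dtype=bool)
        keep[j] = False
        est = ivw_mre(hset.subset(keep))
        rows.append({"SNP": hset.snp_ids[j], "beta": est.beta,
                     "se": est.se, "pval": est.pval})
    loo = pd.DataFrame(rows)
    same_sign = np.all(np.sign(loo["beta"]) == np.sign(full.beta))
    same_side = np.all((loo["pval"] < threshold) == (full.pval < threshold))
    return loo, bool(same_sign and same_side)


def run_sensitivity(
    hset: HarmonizedInstrumentSet,
    seed: int | None = None,
    n_sim: int = 1000,
    alpha: float = 0.05,
    loo_threshold: float = 0.05,
) -> SensitivityReport:
    """All four diagnostics; PRESSO is skipped (None) below 4 instruments."""
    egger = egger_intercept_test(hset, alpha)
    cochran = cochran_q_test(hset, alpha)
    presso = presso_global_test(hset, n_sim=n_sim, seed=seed) if hset.k >= 4 else None
    loo, stable = leave_one_out(hset, threshold=loo_threshold)
    report = SensitivityReport(
        egger=egger, cochran=cochran, presso=presso, loo=loo, loo_stable=stable,
    )
    report.verdict = {
        "pleiotropy_detected": egger.pleiotropy_detected,
        "heterogeneity_detected": cochran.heterogeneity_detected,
        "outlier_detected": bool(presso and presso.outlier_detected),
        "loo_stable": stable,
    }
    return report
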