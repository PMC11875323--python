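"""Causal-effect estimators for two-sample Mendelian randomization.

Seven estimators, all consuming a :class:`HarmonizedInstrumentSet`:

* IVW with multiplicative random effects (the primary method);
* MR-Egger regression (slope robust to directional pleiotropy under InSIDE);
* weighted median (valid if >= half the weight is on valid instruments);
* weighted mode (valid if the largest cluster of similar ratios is valid);
* MR-RAPS (robust adjusted profile score: profile likelihood with an
  overdispersion parameter and a robust loss, tolerant of weak instruments
  and idiosyncratic pleiotropy);
* contamination mixture (valid/invalid two-component likelihood over a grid);
* debiased IVW (corrects the weak-instrument attenuation of IVW).

Point estimates are on the outcome scale; for binary outcomes the
exponentiated odds-ratio fields are populated as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .harmonize import HarmonizedInstrumentSet

Z_95 = stats.norm.ppf(0.975)

METHODS = (
    "IVW-MRE", "MR-Egger", "weighted-median", "weighted-mode",
    "MR-RAPS", "contamination-mixture", "debiased-IVW",
)


class EstimationError(ValueError):
    pass


class InsufficientInstrumentsError(EstimationError):
    pass


class ConvergenceError(EstimationError):
    pass


@dataclass
class EstimatorConfig:
    """Tuning constants the cited methods need but leave to package defaults."""

    bootstrap_reps: int = 1000
    rng_seed: int | None = None
    mode_bandwidth_phi: float = 1.0
    conmix_psi: float | None = None  # None -> 1.5 x SD of ratio estimates
    conmix_grid_points: int = 1000
    raps_overdispersion: bool = True
    raps_loss: str = "huber"  # "squared" | "huber"

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 100:
            raise EstimationError("bootstrap_reps must be >= 100")
        if self.conmix_grid_points < 100:
            raise EstimationError("conmix_grid_points must be >= 100")
        if self.raps_loss not in ("squared", "huber"):
            raise EstimationError(f"unknown raps_loss {self.raps_loss!r}")


@dataclass
class CausalEstimate:
    """One method's causal effect with normal-approximation inference."""

    method: str
    beta: float
    se: float | None
    ci_low: float
    ci_high: float
    pval: float
    n_iv: int
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "method": self.method, "n_iv": self.n_iv, "beta": self.beta,
            "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pval": self.pval, "or_": self.or_, "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
        }


def _finish(method, beta, se, pval, n_iv, hset, extras=None,
            ci=None) -> CausalEstimate:
    if ci is None:
        ci = (beta - Z_95 * se, beta + Z_95 * se)
    est = CausalEstimate(
        method=method, beta=float(beta),
        se=None if se is None else float(se),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        pval=float(pval), n_iv=int(n_iv), extras=extras or {},
    )
    if hset.outcome_type == "binary":
        est.or_ = math.exp(est.beta)
        est.or_ci_low = math.exp(est.ci_low)
        est.or_ci_high = math.exp(est.ci_high)
    return est


def _require(hset: HarmonizedInstrumentSet, k_min: int, method: str) -> None:
    if hset.k < k_min:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {k_min} instruments, got {hset.k}"
        )


def wald_ratios(hset: HarmonizedInstrumentSet) -> pd.DataFrame:
    """Per-SNP ratio estimates β_out/β_exp with first-order SE se_out/|β_exp|.

    SNPs with a zero exposure effect are excluded; the count is recorded in
    ``df.attrs['n_excluded']``."""
    bx, by, sy = hset.bx, hset.by, hset.sy
    keep = bx != 0
    df = pd.DataFrame({
        "SNP": np.asarray(hset.snp_ids)[keep],
        "ratio": by[keep] / bx[keep],
        "se": sy[keep] / np.abs(bx[keep]),
    })
    df.attrs["n_excluded"] = int((~keep).sum())
    return df


def cochran_q(bx, by, sy, beta_hat) -> float:
    """Cochran's Q of the per-SNP ratios about ``beta_hat`` with first-order
    inverse-variance weights β_exp²/se_out²."""
    return float(np.sum((by - beta_hat * bx) ** 2 / sy**2))


def ivw_mre(hset: HarmonizedInstrumentSet) -> CausalEstimate:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Weighted regression of β_out on β_exp through the origin, weights
    1/se_out².  The SE is the fixed-effect SE inflated by
    max(1, sqrt(Q/(k−1))), so heterogeneity widens but never narrows the
    interval."""
    _require(hset, 2, "IVW-MRE")
    bx, by, sy = hset.bx, hset.by, hset.sy
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    beta_hat = np.sum(w * bx * by) / denom
    se_fixed = np.sqrt(1.0 / denom)
    q = cochran_q(bx, by, sy, beta_hat)
    k = hset.k
    inflation = max(1.0, math.sqrt(q / (k - 1))) if k > 1 else 1.0
    se = se_fixed * inflation
    pval = 2 * stats.norm.sf(abs(beta_hat / se))
    return _finish("IVW-MRE", beta_hat, se, pval, k, hset,
                   extras={"Q": q, "se_fixed": float(se_fixed)})


def mr_egger(hset: HarmonizedInstrumentSet) -> CausalEstimate:
    """MR-Egger regression: weighted regression of β_out on β_exp with an
    intercept, instruments oriented so every β_exp >= 0.

    The slope estimates the causal effect under InSIDE; the intercept (stored
    in ``extras``) estimates the average directional pleiotropic effect.
    SEs are inflated by max(1, sqrt(Q'/(k−2)))."""
    _require(hset, 3, "MR-Egger")
    bx, by, sy = hset.bx.copy(), hset.by.copy(), hset.sy
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    k = hset.k
    # fit.scale = Q'/(k-2) in whitened units; undo it, then re-apply capped at 1
    inflation = max(1.0, math.sqrt(fit.scale))
    bse = fit.bse / math.sqrt(fit.scale) * inflation
    slope, intercept = fit.params[1], fit.params[0]
    se_slope, se_intercept = bse[1], bse[0]
    # Egger inference conventionally uses the t reference with k-2 df
    pval = 2 * stats.t.sf(abs(slope / se_slope), df=k - 2)
    p_intercept = 2 * stats.t.sf(abs(intercept / se_intercept), df=k - 2)
    return _finish("MR-Egger", slope, se_slope, pval, k, hset, extras={
        "intercept": float(intercept),
        "intercept_se": float(se_intercept),
        "intercept_pval": float(p_intercept),
        "Q_prime": float(fit.scale * (k - 2)),
    })


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median located by linear interpolation of the cumulative
    weight at 0.5."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] < 0.5:
        return float(v[-1])
    below = int(np.max(np.nonzero(cum < 0.5)[0]))
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(v[below] + (v[below + 1] - v[below]) * frac)


def _bootstrap_se(hset, point_fn, config) -> float:
    """Parametric bootstrap: redraw (β_exp, β_out) from normals with their
    SEs and recompute the point estimate."""
    rng = np.random.default_rng(config.rng_seed)
    bx, sx, by, sy = hset.bx, hset.sx, hset.by, hset.sy
    reps = config.bootstrap_reps
    bxs = rng.normal(bx, sx, size=(reps, hset.k))
    bys = rng.normal(by, sy, size=(reps, hset.k))
    ests = np.empty(reps)
    for r in range(reps):
        ests[r] = point_fn(bxs[r], bys[r], sy)
    return float(np.std(ests, ddof=1))


def _median_point(bx, by, sy) -> float:
    ok = bx != 0
    ratio = by[ok] / bx[ok]
    w = bx[ok] ** 2 / sy[ok] ** 2  # = 1/se_ratio^2
    return _weighted_median(ratio, w)


def weighted_median(hset: HarmonizedInstrumentSet,
                    config: EstimatorConfig | None = None) -> CausalEstimate:
    """Weighted median of the per-SNP ratio estimates; consistent when valid
    instruments carry at least half of the inverse-variance weight.  SE by
    seeded parametric bootstrap."""
    _require(hset, 3, "weighted-median")
    config = config or EstimatorConfig()
    beta = _median_point(hset.bx, hset.by, hset.sy)
    se = _bootstrap_se(hset, _median_point, config)
    pval = 2 * stats.norm.sf(abs(beta / se))
    return _finish("weighted-median", beta, se, pval, hset.k, hset)


def _mode_bandwidth(ratio: np.ndarray, phi: float) -> float:
    k = len(ratio)
    sd = np.std(ratio, ddof=1)
    iqr = np.subtract(*np.percentile(ratio, [75, 25]))
    return phi * 0.9 * min(sd, iqr / 1.349) * k ** (-0.2)


def _mode_point(bx, by, sy, phi=1.0, grid_points=512) -> float:
    ok = bx != 0
    ratio = by[ok] / bx[ok]
    w = bx[ok] ** 2 / sy[ok] ** 2
    h = _mode_bandwidth(ratio, phi)
    if not (h > 0):
        # degenerate spread: every ratio (or the IQR) collapses to a point
        return float(ratio[np.argmax(w)]) if len(np.unique(ratio)) > 1 \
            else float(ratio[0])
    grid = np.linspace(ratio.min(), ratio.max(), grid_points)
    dens = np.sum(
        w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / h) ** 2),
        axis=1,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(hset: HarmonizedInstrumentSet,
                  config: EstimatorConfig | None = None) -> CausalEstimate:
    """Mode of the inverse-variance-weighted kernel density of the ratio
    estimates (bandwidth phi x 0.9 min(SD, IQR/1.349) k^{-1/5}); consistent
    when the largest cluster of agreeing instruments is valid."""
    _require(hset, 3, "weighted-mode")
    config = config or EstimatorConfig()
    phi = config.mode_bandwidth_phi

    def point(bx, by, sy):
        return _mode_point(bx, by, sy, phi=phi)

    beta = point(hset.bx, hset.by, hset.sy)
    se = _bootstrap_se(hset, point, config)
    pval = 2 * stats.norm.sf(abs(beta / se))
    return _finish("weighted-mode", beta, se, pval, hset.k, hset)


_HUBER_C = 1.345
# Fisher-consistency constant for the Huber score at c = 1.345 under N(0,1):
# delta = E[psi(Z) Z] = E[psi'(Z)] = 2 Phi(c) - 1 (Stein's identity), used to
# keep the overdispersion estimate unbiased under the robust loss.
_HUBER_DELTA = 2 * stats.norm.cdf(_HUBER_C) - 1


def _huber_rho(t: np.ndarray) -> np.ndarray:
    a = np.abs(t)
    return np.where(a <= _HUBER_C, 0.5 * t**2, _HUBER_C * a - 0.5 * _HUBER_C**2)


def mr_raps(hset: HarmonizedInstrumentSet,
            config: EstimatorConfig | None = None) -> CausalEstimate:
    """Robust adjusted profile score estimate.

    Maximizes the profile likelihood of (β, τ²) under
    β_out,j ~ N(β·β_exp,j, se_out,j² + τ² + β²·se_exp,j²), replacing the
    squared residual term with a Huber loss when ``raps_loss='huber'`` (with
    the matching Fisher-consistency constant on the log-variance penalty).
    τ² captures systematic (overdispersed) pleiotropy; the exposure-side
    variance term removes the weak-instrument attenuation of plain IVW.
    SE from an empirical sandwich at the optimum."""
    _require(hset, 3, "MR-RAPS")
    config = config or EstimatorConfig()
    bx, sx, by, sy = hset.bx, hset.sx, hset.by, hset.sy
    use_tau = config.raps_overdispersion
    squared = config.raps_loss == "squared"
    delta = 1.0 if squared else _HUBER_DELTA

    def per_snp_obj(theta):
        beta = theta[0]
        tau2 = theta[1] if use_tau else 0.0
        var = sy**2 + tau2 + beta**2 * sx**2
        t = (by - beta * bx) / np.sqrt(var)
        rho = 0.5 * t**2 if squared else _huber_rho(t)
        # the log-normalization carries sy^2 + tau^2 only: profiling the
        # latent per-SNP effect puts beta^2 sx^2 in the residual variance
        # but not in the density normalization; keeping it there would
        # re-introduce weak-instrument attenuation
        return rho + 0.5 * delta * np.log(sy**2 + tau2)

    def objective(theta):
        return float(np.sum(per_snp_obj(theta)))

    w = 1.0 / sy**2
    beta0 = np.sum(w * bx * by) / np.sum(w * bx**2)
    if use_tau:
        x0 = np.array([beta0, 1e-6])
        bounds = [(None, None), (0.0, None)]
    else:
        x0 = np.array([beta0])
        bounds = [(None, None)]
    res = optimize.minimize(objective, x0, bounds=bounds, method="L-BFGS-B")
    if not res.success:
        # L-BFGS-B line searches can fail near the tau^2 = 0 boundary;
        # a simplex restart from the same point is slower but dependable
        res2 = optimize.minimize(objective, res.x if np.all(np.isfinite(res.x))
                                 else x0, bounds=bounds, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12,
                                          "maxiter": 5000})
        if res2.fun <= res.fun or res2.success:
            res = res2
    if not res.success:
        raise ConvergenceError(
            f"MR-RAPS failed to converge for pair "
            f"({hset.exposure_name!r}, {hset.outcome_name!r}): {res.message}"
        )
    theta = res.x
    beta_hat = float(theta[0])
    tau2_hat = float(theta[1]) if use_tau else 0.0

    # empirical sandwich: H^-1 B H^-1 from per-SNP score contributions
    free = [0] + ([1] if use_tau and tau2_hat > 1e-10 else [])
    eps = 1e-5 * np.maximum(np.abs(theta), 1.0)

    def scores(th):
        g = np.zeros((hset.k, len(free)))
        for a, idx in enumerate(free):
            up, dn = th.copy(), th.copy()
            up[idx] += eps[idx]
            dn[idx] -= eps[idx]
            g[:, a] = (per_snp_obj(up) - per_snp_obj(dn)) / (2 * eps[idx])
        return g

    g = scores(theta)
    B = g.T @ g
    H = np.zeros((len(free), len(free)))
    for a, ia in enumerate(free):
        for b, ib in enumerate(free):
            up, dn = theta.copy(), theta.copy()
            up[ib] += eps[ib]
            dn[ib] -= eps[ib]
            gu = np.sum(per_snp_obj(up))
            gd = np.sum(per_snp_obj(dn))
            if a == b and ia == ib:
                H[a, b] = (gu - 2 * res.fun + gd) / eps[ib] ** 2
            else:
                upa = up.copy(); upa[ia] += eps[ia]
                dna = dn.copy(); dna[ia] += eps[ia]
                H[a, b] = (
                    (np.sum(per_snp_obj(upa)) - gu)
                    - (np.sum(per_snp_obj(dna)) - gd)
                ) / (2 * eps[ia] * eps[ib])
    try:
        Hinv = np.linalg.inv(H)
        V = Hinv @ B @ Hinv
        se = float(np.sqrt(max(V[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se = float("nan")
    if not (se > 0):
        # fall back to inverse-information on beta alone
        se = float(np.sqrt(1.0 / max(H[0, 0], 1e-300)))
    pval = 2 * stats.norm.sf(abs(beta_hat / se))
    return _finish("MR-RAPS", beta_hat, se, pval, hset.k, hset,
                   extras={"tau2": tau2_hat})


def contamination_mixture(hset: HarmonizedInstrumentSet,
                          config: EstimatorConfig | None = None) -> CausalEstimate:
    """Contamination-mixture estimate over a grid of candidate effects.

    Each ratio estimate is either valid (Normal(β, se²)) or invalid
    (Normal(0, se² + ψ²)); each SNP is assigned to its higher-likelihood
    component at every grid value of β.  The estimate maximizes the resulting
    profile likelihood; the 95% CI collects grid points within
    χ²₁(0.95)/2 log-likelihood of the maximum (the reported interval is the
    hull, with a multimodality flag when the accepted region is
    non-contiguous).  The p-value is a likelihood-ratio test of β = 0."""
    _require(hset, 3, "contamination-mixture")
    config = config or EstimatorConfig()
    wr = wald_ratios(hset)
    ratio = wr["ratio"].to_numpy()
    se = wr["se"].to_numpy()
    psi = config.conmix_psi
    if psi is None:
        psi = 1.5 * float(np.std(ratio, ddof=1))
    psi = max(psi, 1e-6)

    lo = ratio.min() - 2 * se.max()
    hi = ratio.max() + 2 * se.max()
    grid = np.linspace(lo, hi, config.conmix_grid_points)

    def loglik(betas):
        betas = np.atleast_1d(betas)
        ll_valid = stats.norm.logpdf(ratio[None, :], loc=betas[:, None],
                                     scale=se[None, :])
        ll_invalid = stats.norm.logpdf(ratio[None, :], loc=0.0,
                                       scale=np.sqrt(se**2 + psi**2)[None, :])
        return np.sum(np.maximum(ll_valid, ll_invalid), axis=1)

    ll = loglik(grid)
    i_max = int(np.argmax(ll))
    beta_hat = float(grid[i_max])
    cut = ll.max() - stats.chi2.ppf(0.95, 1) / 2.0
    accepted = np.nonzero(ll >= cut)[0]
    ci = (float(grid[accepted.min()]), float(grid[accepted.max()]))
    multimodal = bool(np.any(np.diff(accepted) > 1))
    lr = 2.0 * (ll.max() - float(loglik(0.0)[0]))
    pval = float(stats.chi2.sf(max(lr, 0.0), 1))
    se_hull = (ci[1] - ci[0]) / (2 * Z_95)
    return _finish(
        "contamination-mixture", beta_hat, se_hull, pval, hset.k, hset,
        ci=ci, extras={"psi": float(psi), "multimodal": multimodal,
                       "grid_step": float(grid[1] - grid[0])},
    )


def debiased_ivw(hset: HarmonizedInstrumentSet) -> CausalEstimate:
    """Debiased IVW: replaces IVW's denominator Σ β_exp²/se_out² with
    Σ (β_exp² − se_exp²)/se_out², removing the weak-instrument attenuation
    caused by exposure-side measurement error.  Sandwich variance from the
    estimating-equation influence function."""
    _require(hset, 2, "debiased-IVW")
    bx, sx, by, sy = hset.bx, hset.sx, hset.by, hset.sy
    w = 1.0 / sy**2
    denom = float(np.sum(w * (bx**2 - sx**2)))
    if denom <= 0:
        raise EstimationError(
            "debiased-IVW denominator non-positive: instruments too weak"
        )
    beta_hat = float(np.sum(w * bx * by) / denom)
    gamma2 = np.maximum(bx**2 - sx**2, 0.0)
    var_score = np.sum(
        w**2 * (sx**2 * sy**2 + beta_hat**2 * gamma2 * sx**2
                + gamma2 * sy**2 + 2 * beta_hat**2 * sx**4)
    )
    se = float(np.sqrt(var_score) / denom)
    pval = 2 * stats.norm.sf(abs(beta_hat / se))
    return _finish("debiased-IVW", beta_hat, se, pval, hset.k, hset, extras={
        "weak_correction": float(np.sum(sx**2 / sy**2)),
        "denominator": denom,
    })


def all_estimates(hset: HarmonizedInstrumentSet,
                  config: EstimatorConfig | None = None) -> dict[str, CausalEstimate]:
    """Run all seven estimators; returns a method-keyed dict."""
    config = config or EstimatorConfig()
    return {
        "IVW-MRE": ivw_mre(hset),
        "MR-Egger": mr_egger(hset),
        "weighted-median": weighted_median(hset, config),
        "weighted-mode": weighted_mode(hset, config),
        "MR-RAPS": mr_raps(hset, config),
        "contamination-mixture": contamination_mixture(hset, config),
        "debiased-IVW": debiased_ivw(hset),
    }
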