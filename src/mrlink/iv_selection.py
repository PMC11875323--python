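"""Instrument-selection cascade for two-sample MR.

The cascade, in order: genome-wide significance filter on the exposure,
greedy LD clumping, harmonization (delegated to :mod:`mrlink.harmonize`),
removal of instruments associated with the outcome, Steiger directionality
filtering, removal of instruments associated with declared confounders, and
radial Cochran's-Q outlier pruning.  Instrument strength (per-SNP r², total
R², F statistic) is computed on the surviving set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import ConfounderSnpList, GwasSummaryTable, LdReference
from .harmonize import HarmonizedInstrumentSet, harmonize_pair


class SelectionError(ValueError):
    pass


class InsufficientInstrumentsError(SelectionError):
    pass


@dataclass
class SelectionConfig:
    """Thresholds of the selection cascade.

    Defaults: genome-wide significance 5e-8 on the exposure; clumping at
    r² = 0.001 within a 1,000 kb window; outcome-association and confounder
    removal at p < 5e-5; radial-Q outlier removal at p < 5e-5; Steiger
    one-sided alpha 0.05; at least four instruments for a pair to be
    evaluable.
    """

    p_exposure: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 1000.0
    p_outcome_assoc: float = 5e-5
    p_confounder: float = 5e-5
    p_radial_outlier: float = 5e-5
    steiger_alpha: float = 0.05
    min_ivs: int = 4
    palindrome_band: float = 0.08
    iterate_radial: bool = False

    def __post_init__(self) -> None:
        for name in ("p_exposure", "p_outcome_assoc", "p_confounder",
                     "p_radial_outlier", "steiger_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise SelectionError(f"{name} must be in (0,1), got {v}")
        if self.min_ivs < 1:
            raise SelectionError("min_ivs must be >= 1")


@dataclass
class InstrumentStrength:
    """Variance explained and F statistic of an instrument set.

    Per-SNP r² = β² / (β² + se²·n) on the exposure side; R² is their sum;
    F = R²(n − k − 1) / ((1 − R²)·k).
    """

    r2_total: float
    f_stat: float
    k: int
    n: float
    per_snp_r2: dict = field(default_factory=dict)


def filter_exposure_significant(
    table: GwasSummaryTable, p_exposure: float = 5e-8
) -> GwasSummaryTable:
    """Retain records with exposure p-value strictly below the threshold."""
    return table.subset((table.df["P"] < p_exposure).to_numpy())


def ld_clump(
    table: GwasSummaryTable,
    ld: LdReference,
    clump_r2: float = 0.001,
    clump_window_kb: float = 1000.0,
) -> GwasSummaryTable:
    """Greedy LD clumping.

    Repeatedly take the unprocessed SNP with the smallest p-value as an index
    SNP and remove every other unprocessed SNP on the same chromosome within
    ``clump_window_kb`` whose r² with the index exceeds ``clump_r2``.  Ties
    on p-value break by smaller position, then lexicographic SNP id.  Output
    preserves the input's row order.  Records with a missing position are
    excluded (counted, not fatal).
    """
    df = table.df
    has_pos = df["POS"].notna().to_numpy()
    df = df[has_pos].reset_index(drop=True)
    n = len(df)
    order = sorted(
        range(n),
        key=lambda i: (df["P"].iat[i], df["POS"].iat[i], df["SNP"].iat[i]),
    )
    window_bp = clump_window_kb * 1000.0
    alive = np.ones(n, dtype=bool)
    processed = np.zeros(n, dtype=bool)
    index_rows = []
    for i in order:
        if processed[i]:
            continue
        processed[i] = True
        index_rows.append(i)
        snp_i = df["SNP"].iat[i]
        chr_i, pos_i = df["CHR"].iat[i], df["POS"].iat[i]
        for j in range(n):
            if processed[j] or not alive[j]:
                continue
            if df["CHR"].iat[j] != chr_i:
                continue
            if abs(df["POS"].iat[j] - pos_i) > window_bp:
                continue
            if ld.r2(snp_i, df["SNP"].iat[j]) > clump_r2:
                alive[j] = False
                processed[j] = True
    keep = np.zeros(n, dtype=bool)
    keep[index_rows] = True
    out = GwasSummaryTable(
        table.trait_name, table.trait_type, df[keep].reset_index(drop=True),
        table.provenance, table.case_fraction,
    )
    return out


def filter_outcome_associated(
    hset: HarmonizedInstrumentSet, p_outcome_assoc: float = 5e-5
) -> HarmonizedInstrumentSet:
    """Remove instruments whose outcome-side association p-value is below the
    threshold (they may act on the outcome directly)."""
    return hset.subset((hset.df["pval_out"] >= p_outcome_assoc).to_numpy())


def snp_r2(beta, se, n):
    """Variance in a trait explained by one SNP: β² / (β² + se²·n)."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    n = np.asarray(n, float)
    b2 = beta**2
    return b2 / (b2 + se**2 * n)


def steiger_filter(
    hset: HarmonizedInstrumentSet, steiger_alpha: float = 0.05
) -> HarmonizedInstrumentSet:
    """Drop instruments that explain significantly more variance in the
    outcome than in the exposure (reverse-causation guard).

    Per SNP, r² is computed on each side; the SNP is dropped when
    r²_out > r²_exp and the one-sided Fisher-z test of the correlation
    difference is significant at ``steiger_alpha``.  Records with n <= 3 on
    either side are excluded outright (test undefined)."""
    df = hset.df
    n_exp = df["n_exp"].to_numpy(float)
    n_out = df["n_out"].to_numpy(float)
    defined = (n_exp > 3) & (n_out > 3)
    r2_exp = snp_r2(df["beta_exp"], df["se_exp"], n_exp)
    r2_out = snp_r2(df["beta_out"], df["se_out"], n_out)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_exp = np.arctanh(np.sqrt(r2_exp))
        z_out = np.arctanh(np.sqrt(r2_out))
        se_z = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
        p_one = stats.norm.cdf((z_exp - z_out) / se_z)
    drop = (r2_out > r2_exp) & (p_one < steiger_alpha)
    keep = defined & ~drop
    out = hset.subset(keep)
    out.audit.extra["steiger_undefined_n"] = int((~defined).sum())
    return out


def filter_confounder_snps(
    hset: HarmonizedInstrumentSet,
    confounders: ConfounderSnpList,
    p_confounder: float = 5e-5,
) -> HarmonizedInstrumentSet:
    """Remove instruments listed as confounder-associated below the threshold.

    List entries without a p-value are treated as below threshold."""
    def flagged(snp: str) -> bool:
        if snp not in confounders:
            return False
        p = confounders.entries[snp]
        return p is None or p < p_confounder

    keep = ~hset.df["SNP"].map(flagged).to_numpy(dtype=bool)
    return hset.subset(keep)


def _ivw_point(bx, by, sy):
    w = bx**2 / sy**2
    ratio = by / bx
    return float(np.sum(w * ratio) / np.sum(w)), w, ratio


def radial_q_prune(
    hset: HarmonizedInstrumentSet, p_radial_outlier: float = 5e-5,
    iterate: bool = False,
) -> tuple[HarmonizedInstrumentSet, pd.DataFrame]:
    """First-order radial-IVW outlier pruning.

    Fits IVW with weights w_j = β_exp,j² / se_out,j²; each SNP's heterogeneity
    contribution Q_j = w_j (ratio_j − β̂)² is referred to χ²₁, and SNPs with
    tail probability below ``p_radial_outlier`` are removed in a single pass
    (optionally iterated) before one refit.  Returns the pruned set and the
    per-SNP Q table of the first pass.
    """
    if hset.k < 2:
        raise InsufficientInstrumentsError(
            f"radial pruning needs >= 2 instruments, got {hset.k}"
        )
    first_q = None
    current = hset
    while True:
        beta_hat, w, ratio = _ivw_point(current.bx, current.by, current.sy)
        q_j = w * (ratio - beta_hat) ** 2
        p_j = stats.chi2.sf(q_j, df=1)
        table = pd.DataFrame({
            "SNP": current.snp_ids, "Q": q_j, "pval": p_j,
            "outlier": p_j < p_radial_outlier,
        })
        if first_q is None:
            first_q = table
        outliers = table["outlier"].to_numpy()
        if not outliers.any():
            break
        current = current.subset(~outliers)
        if not iterate:
            break
        if current.k < 2:
            break
    return current, first_q


def instrument_strength(hset_or_table) -> InstrumentStrength:
    """Total variance explained and F statistic on the exposure side."""
    if isinstance(hset_or_table, HarmonizedInstrumentSet):
        beta = hset_or_table.bx
        se = hset_or_table.sx
        n = float(np.max(hset_or_table.df["n_exp"]))
        snps = hset_or_table.snp_ids
    else:
        df = hset_or_table.df
        beta = df["BETA"].to_numpy(float)
        se = df["SE"].to_numpy(float)
        n = float(np.max(df["N"]))
        snps = df["SNP"].tolist()
    k = len(beta)
    if k < 1:
        raise InsufficientInstrumentsError("instrument strength needs k >= 1")
    if n <= k + 1:
        raise SelectionError(f"F undefined: n={n} <= k+1={k + 1}")
    per = snp_r2(beta, se, n)
    r2_total = float(np.sum(per))
    f_stat = r2_total * (n - k - 1) / ((1 - r2_total) * k)
    return InstrumentStrength(
        r2_total=r2_total, f_stat=float(f_stat), k=k, n=n,
        per_snp_r2=dict(zip(snps, per.astype(float))),
    )


def select_instruments(
    exposure: GwasSummaryTable,
    outcome: GwasSummaryTable,
    ld: LdReference,
    confounders: ConfounderSnpList | None = None,
    config: SelectionConfig | None = None,
) -> tuple[HarmonizedInstrumentSet, dict]:
    """Run the full selection cascade; returns the pruned instrument set and a
    stage-by-stage audit of counts (retained after each stage and removed at
    each stage)."""
    cfg = config or SelectionConfig()
    confounders = confounders or ConfounderSnpList()
    audit: dict = {"input_exposure_snps": len(exposure)}

    sig = filter_exposure_significant(exposure, cfg.p_exposure)
    audit["after_significance"] = len(sig)

    clumped = ld_clump(sig, ld, cfg.clump_r2, cfg.clump_window_kb)
    audit["after_clump"] = len(clumped)

    hset = harmonize_pair(clumped, outcome, cfg.palindrome_band)
    audit["after_harmonize"] = hset.k
    audit["harmonization"] = hset.audit.as_dict()

    hset = filter_outcome_associated(hset, cfg.p_outcome_assoc)
    audit["after_outcome_filter"] = hset.k

    hset = steiger_filter(hset, cfg.steiger_alpha)
    audit["after_steiger"] = hset.k

    hset = filter_confounder_snps(hset, confounders, cfg.p_confounder)
    audit["after_confounder"] = hset.k

    if hset.k >= 2:
        hset, q_table = radial_q_prune(hset, cfg.p_radial_outlier,
                                       iterate=cfg.iterate_radial)
        audit["radial_outliers_removed"] = int(q_table["outlier"].sum())
    else:
        audit["radial_outliers_removed"] = 0
    audit["after_radial"] = hset.k
    return hset, audit
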