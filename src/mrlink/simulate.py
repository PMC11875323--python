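"""Synthetic two-sample GWAS summary statistics with controllable causal
structure.

The generator emulates two independent GWAS samples over a shared SNP panel.
Per SNP j with minor-allele frequency maf_j, the latent exposure effect is
γ_j, the direct (pleiotropic) outcome effect is α_j, and the marginal
outcome effect is Γ_j = β·γ_j + α_j for causal effect β.  Reverse-acting
SNPs get γ_j = 0 and a nonzero Γ_j drawn on the instrument scale — they are
instruments for the outcome trait, not the exposure.  Observed effects add
independent sampling noise on each side with the standard GWAS standard
error se = 1/sqrt(2·maf(1−maf)·n) (scaled by 1/sqrt(K(1−K)) for a binary
trait with case fraction K).

Latent draws, sampling noise, and allele-label bookkeeping use three
separate seeded streams, so label randomization can vary while the
underlying effects stay fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import GwasSummaryTable, LdReference, table_from_frame
from .harmonize import HarmonizedInstrumentSet, harmonize_pair

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "inside_violating")


class ScenarioError(ValueError):
    pass


@dataclass
class SimulationScenario:
    """Generative parameters for one synthetic two-sample GWAS pair."""

    k_snps: int = 50
    n_exp: float = 100_000
    n_out: float = 100_000
    true_beta: float = 0.2
    # per-SNP exposure-effect distribution: (mean, sd, minimum-|effect| floor)
    gamma_mean: float = 0.0
    gamma_sd: float = 0.06
    gamma_floor: float = 0.03
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.01
    prop_invalid: float = 0.0
    inside_corr: float = 0.7
    reverse_snps: int = 0
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_blocks: list[tuple[int, float]] | None = None
    outcome_type: str = "continuous"
    case_fraction: float = 0.3
    palindromic_fraction: float = 0.0
    allele_flip_fraction: float = 0.0
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_snps < 1:
            raise ScenarioError("k_snps must be >= 1")
        if not (0 <= self.prop_invalid <= 1):
            raise ScenarioError("prop_invalid must be in [0,1]")
        if self.reverse_snps < 0 or self.reverse_snps > self.k_snps:
            raise ScenarioError("reverse_snps must be in [0, k_snps]")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ScenarioError(
                f"unknown pleiotropy regime {self.pleiotropy!r}; "
                f"valid: {PLEIOTROPY_REGIMES}"
            )
        if not (0 < self.maf_low < self.maf_high <= 0.5):
            raise ScenarioError("need 0 < maf_low < maf_high <= 0.5")

    def replace(self, **kw) -> "SimulationScenario":
        return dataclasses.replace(self, **kw)


def _gwas_se(maf: np.ndarray, n: float, binary: bool, k_frac: float) -> np.ndarray:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    if binary:
        se = se / np.sqrt(k_frac * (1.0 - k_frac))
    return se


def _floored(raw: np.ndarray, floor: float) -> np.ndarray:
    sign = np.where(raw >= 0, 1.0, -1.0)
    return sign * np.maximum(np.abs(raw), floor)


def simulate_two_sample_gwas(
    s: SimulationScenario,
) -> tuple[GwasSummaryTable, GwasSummaryTable, LdReference, dict]:
    """Draw one synthetic exposure/outcome GWAS pair.

    Returns (exposure table, outcome table, LD reference, truth record); the
    truth record stores every latent value so estimator bias can be computed
    without external data.
    """
    latent = np.random.default_rng([int(s.seed), 0])
    noise = np.random.default_rng([int(s.seed), 1])
    labels = np.random.default_rng([int(s.seed), 2])

    k = s.k_snps
    maf = latent.uniform(s.maf_low, s.maf_high, size=k)
    gamma = _floored(latent.normal(s.gamma_mean, s.gamma_sd, size=k),
                     s.gamma_floor)

    is_reverse = np.zeros(k, dtype=bool)
    if s.reverse_snps:
        is_reverse[k - s.reverse_snps:] = True
    gamma[is_reverse] = 0.0
    # reverse-acting SNPs get an outcome-side effect on the instrument scale
    gamma_rev = _floored(latent.normal(s.gamma_mean, s.gamma_sd, size=k),
                         s.gamma_floor)

    forward_idx = np.nonzero(~is_reverse)[0]
    n_invalid = int(round(s.prop_invalid * len(forward_idx)))
    invalid_idx = latent.permutation(forward_idx)[:n_invalid]
    is_invalid = np.zeros(k, dtype=bool)
    is_invalid[invalid_idx] = True

    alpha = np.zeros(k)
    alpha_raw = latent.normal(0.0, 1.0, size=k)  # drawn unconditionally
    if s.pleiotropy == "balanced":
        alpha[is_invalid] = s.pleiotropy_sd * alpha_raw[is_invalid]
    elif s.pleiotropy == "directional":
        alpha[is_invalid] = s.pleiotropy_mean + s.pleiotropy_sd * alpha_raw[is_invalid]
    elif s.pleiotropy == "inside_violating":
        rho = s.inside_corr
        std_gamma = (gamma - s.gamma_mean) / s.gamma_sd
        corr_part = rho * std_gamma + np.sqrt(1 - rho**2) * alpha_raw
        alpha[is_invalid] = (s.pleiotropy_mean
                             + s.pleiotropy_sd * corr_part[is_invalid])

    Gamma = s.true_beta * gamma + alpha
    Gamma[is_reverse] = gamma_rev[is_reverse]

    # LD blocks: append proxy SNPs carrying attenuated copies of index signals
    snp_ids = [f"rs{i + 1}" for i in range(k)]
    chrom = [(i % 22) + 1 for i in range(k)]
    pos = [(i // 22 + 1) * 2_000_000 for i in range(k)]
    block_member = np.zeros(k, dtype=bool)
    ld = LdReference()
    if s.ld_blocks:
        proxies = []
        for b, (size, r2) in enumerate(s.ld_blocks):
            if b >= k or size < 2:
                continue
            r = float(np.sqrt(r2))
            for m in range(1, size):
                proxies.append((b, m, r, r2))
        for b, m, r, r2 in proxies:
            idx = len(snp_ids)
            pid = f"rs{b + 1}_proxy{m}"
            snp_ids.append(pid)
            chrom.append(chrom[b])
            pos.append(pos[b] + m * 10_000)
            maf = np.append(maf, maf[b])
            # a proxy in LD r2 tags the index signal attenuated by r
            gamma = np.append(gamma, r * gamma[b])
            Gamma = np.append(Gamma, r * Gamma[b])
            alpha = np.append(alpha, r * alpha[b])
            is_reverse = np.append(is_reverse, is_reverse[b])
            is_invalid = np.append(is_invalid, is_invalid[b])
            block_member = np.append(block_member, True)
            ld.set_r2(snp_ids[b], pid, r2)
        # proxies of the same index are mutually linked
        for b in {p[0] for p in proxies}:
            members = [f"rs{b + 1}_proxy{m}" for bb, m, _, _ in proxies if bb == b]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    ld.set_r2(members[i], members[j], s.ld_blocks[b][1])

    k_total = len(snp_ids)
    for i in range(k_total):
        ld.positions[snp_ids[i]] = (str(chrom[i]), pos[i])

    binary_out = s.outcome_type == "binary"
    se_exp = _gwas_se(maf, s.n_exp, False, s.case_fraction)
    se_out = _gwas_se(maf, s.n_out, binary_out, s.case_fraction)
    beta_exp = noise.normal(gamma, se_exp)
    beta_out = noise.normal(Gamma, se_out)
    p_exp = 2 * stats.norm.sf(np.abs(beta_exp / se_exp))
    p_out = 2 * stats.norm.sf(np.abs(beta_out / se_out))

    # allele labels: per-SNP pair choice, palindrome choice, flip choice —
    # all drawn unconditionally so stream alignment never depends on fractions
    pair_draw = labels.integers(0, 4, size=k_total)
    palin_draw = labels.uniform(size=k_total)
    flip_draw = labels.uniform(size=k_total)
    flip_kind = labels.integers(0, 3, size=k_total)  # swap | complement | both

    ea, oa = [], []
    for i in range(k_total):
        if palin_draw[i] < s.palindromic_fraction:
            ea_i, oa_i = _PALINDROMIC_PAIRS[pair_draw[i] % 2]
        else:
            ea_i, oa_i = _NONPALINDROMIC_PAIRS[pair_draw[i]]
        ea.append(ea_i)
        oa.append(oa_i)

    exp_df = pd.DataFrame({
        "SNP": snp_ids, "CHR": [str(c) for c in chrom], "POS": pos,
        "EA": ea, "OA": oa, "EAF": maf,
        "BETA": beta_exp, "SE": se_exp, "P": p_exp, "N": s.n_exp,
    })

    out_ea, out_oa = list(ea), list(oa)
    out_beta, out_eaf = beta_out.copy(), maf.copy()
    for i in range(k_total):
        if flip_draw[i] >= s.allele_flip_fraction:
            continue
        kind = flip_kind[i]
        if kind in (0, 2):  # swap effect/other labels
            out_ea[i], out_oa[i] = out_oa[i], out_ea[i]
            out_beta[i] = -out_beta[i]
            out_eaf[i] = 1 - out_eaf[i]
        if kind in (1, 2):  # report the other strand
            out_ea[i] = _COMP[out_ea[i]]
            out_oa[i] = _COMP[out_oa[i]]

    out_df = pd.DataFrame({
        "SNP": snp_ids, "CHR": [str(c) for c in chrom], "POS": pos,
        "EA": out_ea, "OA": out_oa, "EAF": out_eaf,
        "BETA": out_beta, "SE": se_out, "P": p_out, "N": s.n_out,
    })
    if binary_out:
        out_df["N_CASES"] = s.case_fraction * s.n_out

    exposure = table_from_frame(exp_df, s.exposure_name, "continuous")
    outcome = table_from_frame(
        out_df, s.outcome_name, s.outcome_type,
        case_fraction=s.case_fraction if binary_out else None,
    )
    truth = {
        "scenario": dataclasses.asdict(s),
        "snp_ids": snp_ids,
        "maf": maf.tolist(),
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "Gamma": Gamma.tolist(),
        "is_reverse": is_reverse.tolist(),
        "is_invalid": is_invalid.tolist(),
        "is_block_member": block_member.tolist(),
        "true_beta": s.true_beta,
    }
    return exposure, outcome, ld, truth


def simulate_instrument_set(s: SimulationScenario) -> tuple[HarmonizedInstrumentSet, dict]:
    """Simulate a pair and harmonize it directly (no selection cascade);
    convenience for estimator studies on the full panel."""
    exposure, outcome, _, truth = simulate_two_sample_gwas(s)
    return harmonize_pair(exposure, outcome), truth


PRESETS: dict[str, dict] = {
    # all-valid strong instruments, moderate causal effect
    "valid_instruments": dict(true_beta=0.2, k_snps=50,
                              n_exp=100_000, n_out=100_000, pleiotropy="none"),
    # zero-mean direct effects on 30% of instruments
    "balanced_pleiotropy": dict(true_beta=0.2, k_snps=50, pleiotropy="balanced",
                                prop_invalid=0.3, pleiotropy_sd=0.01),
    # constant-sign direct effects on every instrument, InSIDE holding;
    # exposure effects all positive so orientation preserves the direction
    "directional_pleiotropy": dict(true_beta=0.2, k_snps=50,
                                   pleiotropy="directional", prop_invalid=1.0,
                                   pleiotropy_mean=0.02, pleiotropy_sd=0.01,
                                   gamma_mean=0.07, gamma_sd=0.02,
                                   gamma_floor=0.01),
    # direct effects correlated with instrument strength (InSIDE broken)
    "inside_violation": dict(true_beta=0.2, k_snps=50,
                             pleiotropy="inside_violating", prop_invalid=1.0,
                             pleiotropy_mean=0.02, pleiotropy_sd=0.01,
                             gamma_mean=0.07, gamma_sd=0.02, gamma_floor=0.01),
    # gamma scale tuned during development so the mean per-SNP F is near 10
    "weak_instruments": dict(true_beta=0.2, k_snps=100,
                             gamma_mean=0.0, gamma_sd=0.015, gamma_floor=0.002),
    # 10 of 50 panel SNPs act on the outcome only
    "reverse_causation": dict(true_beta=0.2, k_snps=50, reverse_snps=10),
    # no causal effect in either direction
    "null_effect": dict(true_beta=0.0, k_snps=50,
                        n_exp=100_000, n_out=100_000, pleiotropy="none"),
    # negative-control trait: no effect either way, but both traits carry
    # their own instruments so both directions are evaluable
    "negative_control": dict(true_beta=0.0, k_snps=80, reverse_snps=30,
                             pleiotropy="none"),
}


def scenario_preset(name: str, seed: int = 0, **overrides) -> SimulationScenario:
    """Named, fully specified scenario; unknown names raise with the list of
    valid presets.  Keyword overrides replace individual fields."""
    if name not in PRESETS:
        raise ScenarioError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}"
        )
    params = dict(PRESETS[name])
    params.update(overrides)
    return SimulationScenario(seed=seed, **params)
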