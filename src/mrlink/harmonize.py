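"""Place exposure and outcome effects on a common effect-allele frame.

Two-sample MR requires that each instrument's exposure and outcome effects
refer to the same allele on the same DNA strand.  The exposure table defines
the frame: outcome records are kept as-is, sign-flipped (allele labels
swapped), strand-complemented, or both; palindromic A/T and C/G variants,
whose strand cannot be read off the allele labels, are resolved by allele
frequency when it is informative and dropped as ambiguous when the minor
allele frequency is too close to 0.5 or missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import GwasSummaryTable

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default half-width of the ambiguity band around eaf = 0.5 inside which a
#: palindromic SNP is dropped (drop when eaf in [0.42, 0.58]).
DEFAULT_PALINDROME_BAND = 0.08

HARMONIZED_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA",
    "beta_exp", "se_exp", "pval_exp", "n_exp", "eaf_exp",
    "beta_out", "se_out", "pval_out", "n_out", "eaf_out",
]


class HarmonizationError(ValueError):
    pass


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (single-base only; the rule
    does not apply to indels)."""
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def complement(allele: str) -> str | None:
    """Strand complement of an allele string, or None if non-ACGT."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele.upper())) \
            if len(allele) > 1 else _COMPLEMENT[allele.upper()]
    except KeyError:
        return None


@dataclass
class HarmonizationAudit:
    direct: int = 0
    flipped: int = 0
    strand_corrected: int = 0
    strand_corrected_flipped: int = 0
    palindromic_kept: int = 0
    palindromic_dropped: int = 0
    incompatible: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "direct", "flipped", "strand_corrected", "strand_corrected_flipped",
            "palindromic_kept", "palindromic_dropped", "incompatible")}
        d.update(self.extra)
        return d


@dataclass
class HarmonizedInstrumentSet:
    """Per-SNP exposure and outcome effects on a common effect-allele frame.

    This is the unit every causal estimator and sensitivity procedure
    consumes. ``df`` has the :data:`HARMONIZED_COLUMNS` columns.
    """

    exposure_name: str
    outcome_name: str
    outcome_type: str  # "continuous" | "binary"
    df: pd.DataFrame
    audit: HarmonizationAudit = field(default_factory=HarmonizationAudit)

    @property
    def k(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    # array accessors used throughout the estimators
    @property
    def bx(self) -> np.ndarray:
        return self.df["beta_exp"].to_numpy(float)

    @property
    def sx(self) -> np.ndarray:
        return self.df["se_exp"].to_numpy(float)

    @property
    def by(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(float)

    @property
    def sy(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(float)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["SNP"].tolist()

    def subset(self, keep) -> "HarmonizedInstrumentSet":
        """New set retaining rows selected by boolean mask or index array."""
        sub = self.df.iloc[np.asarray(keep)] if np.asarray(keep).dtype.kind in "iu" \
            else self.df[np.asarray(keep)]
        return HarmonizedInstrumentSet(
            self.exposure_name, self.outcome_name, self.outcome_type,
            sub.reset_index(drop=True), self.audit,
        )

    def drop_snps(self, snp_ids) -> "HarmonizedInstrumentSet":
        mask = ~self.df["SNP"].isin(set(snp_ids)).to_numpy()
        return self.subset(mask)

    @classmethod
    def from_arrays(
        cls, bx, sx, by, sy,
        pval_exp=None, pval_out=None, n_exp=1e5, n_out=1e5,
        snp_ids=None, outcome_type="continuous",
        exposure_name="exposure", outcome_name="outcome",
        eaf=None,
    ) -> "HarmonizedInstrumentSet":
        """Convenience constructor for tests and simulations."""
        from scipy import stats

        bx = np.asarray(bx, float)
        sx = np.asarray(sx, float)
        by = np.asarray(by, float)
        sy = np.asarray(sy, float)
        k = len(bx)
        if pval_exp is None:
            pval_exp = 2 * stats.norm.sf(np.abs(bx / sx))
        if pval_out is None:
            pval_out = 2 * stats.norm.sf(np.abs(by / sy))
        df = pd.DataFrame({
            "SNP": snp_ids if snp_ids is not None else [f"rs{i}" for i in range(k)],
            "CHR": "1", "POS": np.arange(1, k + 1) * 10**6,
            "EA": "A", "OA": "G",
            "beta_exp": bx, "se_exp": sx, "pval_exp": pval_exp,
            "n_exp": np.broadcast_to(np.asarray(n_exp, float), k).copy(),
            "eaf_exp": eaf if eaf is not None else 0.3,
            "beta_out": by, "se_out": sy, "pval_out": pval_out,
            "n_out": np.broadcast_to(np.asarray(n_out, float), k).copy(),
            "eaf_out": eaf if eaf is not None else 0.3,
        })
        return cls(exposure_name, outcome_name, outcome_type, df)


def _try_match(ea_x, oa_x, ea_o, oa_o):
    """Classify the outcome allele pair against the exposure frame.

    Returns one of 'direct', 'swap', 'comp', 'comp_swap', or None.
    """
    if (ea_o, oa_o) == (ea_x, oa_x):
        return "direct"
    if (ea_o, oa_o) == (oa_x, ea_x):
        return "swap"
    cea, coa = complement(ea_o), complement(oa_o)
    if cea is None or coa is None:
        return None
    if (cea, coa) == (ea_x, oa_x):
        return "comp"
    if (cea, coa) == (oa_x, ea_x):
        return "comp_swap"
    return None


def harmonize_pair(
    exposure: GwasSummaryTable,
    outcome: GwasSummaryTable,
    palindrome_band: float = DEFAULT_PALINDROME_BAND,
) -> HarmonizedInstrumentSet:
    """Harmonize the outcome table onto the exposure's effect-allele frame.

    For each SNP shared between the tables:

    * alleles match directly -> keep;
    * alleles match with effect/other swapped -> negate beta_out,
      eaf_out <- 1 - eaf_out;
    * alleles match after strand complement -> complement, then as above;
    * palindromic pair with minor allele frequency within ``palindrome_band``
      of 0.5 on either side, or with a missing frequency -> dropped as
      ambiguous; outside the band the orientation is taken from frequency
      agreement (both eafs on the same side of 0.5 -> keep; opposite
      sides -> flip);
    * anything else -> dropped as incompatible.
    """
    shared = exposure.df.merge(
        outcome.df, on="SNP", how="inner", suffixes=("_x", "_o"),
    )
    if shared.empty:
        raise HarmonizationError(
            f"no shared SNPs between {exposure.trait_name!r} and "
            f"{outcome.trait_name!r}"
        )
    audit = HarmonizationAudit()
    rows = []
    for rec in shared.itertuples(index=False):
        ea_x, oa_x = rec.EA_x, rec.OA_x
        ea_o, oa_o = rec.EA_o, rec.OA_o
        beta_out, eaf_out = rec.BETA_o, rec.EAF_o
        eaf_exp = rec.EAF_x

        if is_palindromic(ea_x, oa_x):
            # palindromic on the exposure frame: labels cannot resolve strand
            if not is_palindromic(ea_o, oa_o) or _try_match(ea_x, oa_x, ea_o, oa_o) is None:
                audit.incompatible += 1
                continue
            # drop when eaf lies in [0.5 - band, 0.5 + band] on either side
            # (tiny tolerance so the inclusive edges survive float rounding)
            tol = 1e-12
            ambiguous = (
                np.isnan(eaf_exp) or np.isnan(eaf_out)
                or abs(eaf_exp - 0.5) <= palindrome_band + tol
                or abs(eaf_out - 0.5) <= palindrome_band + tol
            )
            if ambiguous:
                audit.palindromic_dropped += 1
                continue
            same_side = (eaf_exp < 0.5) == (eaf_out < 0.5)
            if not same_side:
                beta_out = -beta_out
                eaf_out = 1 - eaf_out
            audit.palindromic_kept += 1
        else:
            match = _try_match(ea_x, oa_x, ea_o, oa_o)
            if match is None:
                audit.incompatible += 1
                continue
            if match == "direct":
                audit.direct += 1
            elif match == "swap":
                beta_out = -beta_out
                eaf_out = 1 - eaf_out
                audit.flipped += 1
            elif match == "comp":
                audit.strand_corrected += 1
            else:  # comp_swap
                beta_out = -beta_out
                eaf_out = 1 - eaf_out
                audit.strand_corrected_flipped += 1

        rows.append({
            "SNP": rec.SNP, "CHR": rec.CHR_x, "POS": rec.POS_x,
            "EA": ea_x, "OA": oa_x,
            "beta_exp": rec.BETA_x, "se_exp": rec.SE_x,
            "pval_exp": rec.P_x, "n_exp": rec.N_x, "eaf_exp": eaf_exp,
            "beta_out": beta_out, "se_out": rec.SE_o,
            "pval_out": rec.P_o, "n_out": rec.N_o, "eaf_out": eaf_out,
        })

    df = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return HarmonizedInstrumentSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        df=df,
        audit=audit,
    )
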