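"""Reading, validating and writing GWAS summary statistics and auxiliary inputs.

Canonical column names are ``SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N,
N_CASES`` (tab-separated, one header row).  A built-in alias map covers the
common dialects found in PGC / FinnGen / GWAS Catalog exports; callers can
override any mapping explicitly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "N_CASES",
]

MANDATORY_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P", "N"]

#: Built-in header aliases (upper-cased before lookup).
COLUMN_ALIASES = {
    "SNP": {"SNP", "RSID", "RS_ID", "MARKERNAME", "VARIANT_ID", "ID", "SNPID"},
    "CHR": {"CHR", "CHROM", "CHROMOSOME", "#CHROM", "CHR_ID"},
    "POS": {"POS", "BP", "POSITION", "BASE_PAIR_LOCATION", "POS_B37", "POS_B38"},
    "EA": {"EA", "A1", "EFFECT_ALLELE", "ALT", "ALLELE1", "TESTED_ALLELE"},
    "OA": {"OA", "A2", "OTHER_ALLELE", "REF", "ALLELE2", "ALLELE0", "NEA",
           "NON_EFFECT_ALLELE"},
    "EAF": {"EAF", "FREQ", "AF", "EFFECT_ALLELE_FREQUENCY", "MAF", "FRQ", "A1FREQ"},
    "BETA": {"BETA", "B", "EFFECT", "EFFECT_SIZE", "LOGOR"},
    "SE": {"SE", "STDERR", "STANDARD_ERROR", "SEBETA"},
    "P": {"P", "PVAL", "PVALUE", "P_VALUE", "P_BOLT_LMM"},
    "N": {"N", "NTOTAL", "N_TOTAL", "SAMPLESIZE", "SAMPLE_SIZE", "NEFF"},
    "N_CASES": {"N_CASES", "NCASE", "NCASES", "N_CASE", "CASES"},
}


class GwasIoError(ValueError):
    """Raised for unreadable or structurally invalid summary-statistic input."""


class DuplicateSnpError(GwasIoError):
    pass


@dataclass
class GwasRecord:
    """One per-SNP association record.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log-odds for binary traits); ``eaf`` may be NaN when the source file
    omits frequencies.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    n_cases: float = math.nan

    def is_valid(self) -> bool:
        if not (self.se > 0):
            return False
        if not (0 < self.pval <= 1):
            return False
        if self.effect_allele == self.other_allele:
            return False
        if not math.isnan(self.eaf) and not (0 <= self.eaf <= 1):
            return False
        return True


@dataclass
class GwasSummaryTable:
    """One trait's validated summary statistics, stored as a DataFrame with
    the canonical columns."""

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    df: pd.DataFrame
    provenance: str = ""
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise GwasIoError(f"unknown trait_type {self.trait_type!r}")
        dup = self.df["SNP"][self.df["SNP"].duplicated()]
        if len(dup):
            raise DuplicateSnpError(
                f"duplicate snp_id in {self.trait_name!r}: {dup.iloc[0]!r}"
            )
        if self.trait_type == "binary":
            has_cases = "N_CASES" in self.df.columns and self.df["N_CASES"].notna().any()
            if not has_cases and self.case_fraction is None:
                raise GwasIoError(
                    "binary trait requires N_CASES or a declared case_fraction"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> pd.Series:
        return self.df["SNP"]

    def subset(self, mask) -> "GwasSummaryTable":
        return GwasSummaryTable(
            self.trait_name, self.trait_type, self.df[mask].reset_index(drop=True),
            self.provenance, self.case_fraction,
        )


def _resolve_columns(header: list[str], column_map: dict | None) -> dict:
    """Map canonical names to actual file columns via overrides then aliases."""
    out = {}
    upper = {h.upper(): h for h in header}
    column_map = {k.upper(): v for k, v in (column_map or {}).items()}
    for canon in CANONICAL_COLUMNS:
        if canon in column_map:
            if column_map[canon] not in header:
                raise GwasIoError(
                    f"column_map names {column_map[canon]!r} for {canon}, "
                    f"not present in file header"
                )
            out[canon] = column_map[canon]
            continue
        for alias in COLUMN_ALIASES[canon]:
            if alias in upper:
                out[canon] = upper[alias]
                break
    missing = [c for c in MANDATORY_COLUMNS if c not in out]
    if missing:
        raise GwasIoError(f"cannot resolve mandatory columns: {missing}")
    return out


def read_summary_stats(
    path,
    column_map: dict | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    case_fraction: float | None = None,
    sep: str = "\t",
) -> GwasSummaryTable:
    """Read a delimited summary-statistics file into a validated table.

    Rows violating per-record invariants (se <= 0, p outside (0,1], equal
    alleles, eaf outside [0,1]) are dropped with a logged count.  Duplicate
    SNP ids raise; an empty result raises.
    """
    raw = pd.read_csv(path, sep=sep)
    resolved = _resolve_columns(list(raw.columns), column_map)
    df = pd.DataFrame({canon: raw[col] for canon, col in resolved.items()})
    for canon in CANONICAL_COLUMNS:
        if canon not in df.columns:
            df[canon] = np.nan
    df = df[CANONICAL_COLUMNS]

    df["SNP"] = df["SNP"].astype(str)
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()
    for col in ("EAF", "BETA", "SE", "P", "N", "N_CASES", "POS"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["CHR"] = df["CHR"].astype(str)

    ok = (
        (df["SE"] > 0)
        & (df["P"] > 0)
        & (df["P"] <= 1)
        & (df["EA"] != df["OA"])
        & (df["EAF"].isna() | ((df["EAF"] >= 0) & (df["EAF"] <= 1)))
        & df["BETA"].notna()
        & df["N"].notna()
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d invalid rows from %s", n_dropped, path)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise GwasIoError(f"no valid rows in {path}")
    return GwasSummaryTable(
        trait_name=trait_name or str(path),
        trait_type=trait_type,
        df=df,
        provenance=str(path),
        case_fraction=case_fraction,
    )


def table_from_frame(
    df: pd.DataFrame,
    trait_name: str,
    trait_type: str = "continuous",
    case_fraction: float | None = None,
) -> GwasSummaryTable:
    """Build a table from an in-memory canonical-column frame (simulation path)."""
    df = df.copy()
    for canon in CANONICAL_COLUMNS:
        if canon not in df.columns:
            df[canon] = np.nan
    return GwasSummaryTable(trait_name, trait_type, df[CANONICAL_COLUMNS],
                            provenance="in-memory", case_fraction=case_fraction)


def write_summary_stats(table: GwasSummaryTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


@dataclass
class LdReference:
    """Pairwise r-squared provider over a SNP panel.

    Absent pairs are unlinked (r² = 0); storage is symmetric. A small
    haplotype panel file can back the reference for tests via
    :meth:`from_haplotypes`.
    """

    pairs: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise GwasIoError(f"r2 {r2} outside [0,1] for pair ({a},{b})")
        self.pairs[(a, b)] = r2
        self.pairs[(b, a)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get((a, b), 0.0)

    @classmethod
    def from_haplotypes(cls, path) -> "LdReference":
        """Compute r² from a haplotype panel: TSV, first column SNP, CHR, POS,
        remaining columns 0/1 haplotype alleles."""
        df = pd.read_csv(path, sep="\t")
        snps = df.iloc[:, 0].astype(str).tolist()
        ref = cls()
        hap = df.iloc[:, 3:].to_numpy(dtype=float)
        for i, s in enumerate(snps):
            ref.positions[s] = (str(df.iloc[i, 1]), int(df.iloc[i, 2]))
        corr = np.corrcoef(hap)
        for i in range(len(snps)):
            for j in range(i + 1, len(snps)):
                r = corr[i, j]
                if np.isfinite(r):
                    ref.set_r2(snps[i], snps[j], float(r * r))
        return ref


def read_ld_reference(path) -> LdReference:
    """Read long-format (SNP_A, SNP_B, R2) triples into a symmetric reference."""
    ref = LdReference()
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and not header.upper().startswith("SNP"):
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise GwasIoError(f"malformed LD row at line {lineno}: {line!r}")
            a, b, r2s = parts
            try:
                r2 = float(r2s)
            except ValueError:
                raise GwasIoError(f"malformed LD row at line {lineno}: {line!r}")
            if not (0 <= r2 <= 1):
                raise GwasIoError(f"r2 outside [0,1] at line {lineno}: {r2}")
            ref.set_r2(a, b, r2)
    return ref


def write_ld_reference(ref: LdReference, path) -> None:
    seen = set()
    with open(path, "w") as fh:
        fh.write("SNP_A\tSNP_B\tR2\n")
        for (a, b), r2 in ref.pairs.items():
            if (b, a) in seen:
                continue
            seen.add((a, b))
            fh.write(f"{a}\t{b}\t{r2:.17g}\n")


@dataclass
class ConfounderSnpList:
    """SNPs reported associated with a potential confounder trait.

    Entries map snp_id -> listed p-value, or None when the source list gives
    no p-value (treated as below any removal threshold).
    """

    entries: dict = field(default_factory=dict)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_confounder_list(path) -> ConfounderSnpList:
    entries: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].upper() in ("SNP", "RSID"):
                continue
            entries[parts[0]] = float(parts[1]) if len(parts) > 1 else None
    return ConfounderSnpList(entries)


RESULT_COLUMNS = [
    "exposure", "outcome", "direction", "method", "n_iv",
    "beta", "se", "ci_low", "ci_high", "pval",
    "or_", "or_ci_low", "or_ci_high",
]


def write_results_table(rows: list[dict], path) -> None:
    """Write one row per (pair, method); OR columns populated only for binary
    outcomes. Floats are written at full precision so the file round-trips."""
    if not rows:
        raise GwasIoError("no results to write")
    df = pd.DataFrame(rows)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
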