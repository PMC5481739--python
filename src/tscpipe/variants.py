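"""Variant inclusion rules and somatic mutation burden.

Two filters are implemented:

* pathogenic TSC1/TSC2 hit acceptance — a variant (at >10x depth) is kept
  if it is database-flagged pathogenic/probably pathogenic, or absent from
  the database but rare (no population frequency) and of moderate/high
  functional impact; large deletions and CN-LOH events over the loci are
  always considered detrimental;
* stringent somatic calling against a matched normal — SNVs need >10x
  tumour depth and zero variant reads in the normal; INDELs need >5x depth
  in both samples, >5 supporting reads, zero normal reads and VAF > 0.10.

The somatic burden is (SNVs + INDELs) per callable megabase, where
callable means >5x depth in both tumour and normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CallableSummary",
    "PairingError",
    "ValidationError",
    "filter_tsc_pathogenic",
    "filter_somatic",
    "mutation_rate",
    "count_unique_mutations",
    "is_indel",
]

REQUIRED_COLUMNS = (
    "CHROM", "POS", "REF", "ALT", "SAMPLE", "DP", "AD_REF", "AD_ALT",
    "IMPACT", "PATHOGENIC_DB", "POP_AF",
)

ACCEPT_FLAGS = frozenset({"pathogenic", "probably_pathogenic"})
RARE_FLAGS = frozenset({"unknown", "absent"})
ALWAYS_DETRIMENTAL = frozenset({"large_deletion", "cn_loh"})

_KEY = ["CHROM", "POS", "REF", "ALT"]


class ValidationError(ValueError):
    """A variant table is missing required annotation fields."""


class PairingError(ValueError):
    """Tumour and normal call sets cannot be joined."""


@dataclass(frozen=True)
class CallableSummary:
    """Callable-territory summary for one tumour/normal pair."""

    pair_id: str
    callable_bases: int

    def __post_init__(self) -> None:
        if self.callable_bases < 0:
            raise ValueError("callable_bases must be >= 0")


def _check_columns(calls: pd.DataFrame, required=REQUIRED_COLUMNS) -> None:
    missing = [c for c in required if c not in calls.columns]
    if missing:
        raise ValidationError(f"variant table missing fields: {missing}")


def is_indel(calls: pd.DataFrame) -> pd.Series:
    """SNV/INDEL split from allele lengths; symbolic ALTs count as non-SNV."""
    ref_len = calls["REF"].astype(str).str.len()
    alt = calls["ALT"].astype(str)
    symbolic = alt.str.startswith("<")
    return (ref_len != 1) | (alt.str.len() != 1) | symbolic


def filter_tsc_pathogenic(calls: pd.DataFrame) -> pd.DataFrame:
    """Accept pathogenic TSC-gene hits from an annotated call table.

    Acceptance requires total depth strictly >10 and either a pathogenic /
    probably-pathogenic database flag, or no database entry together with
    absence from population panels and moderate/high impact.  Large
    deletions and CN-LOH rows pass unconditionally.
    """
    _check_columns(calls)
    if len(calls) == 0:
        return calls.copy()
    depth_ok = calls["DP"] > 10
    flag = calls["PATHOGENIC_DB"].astype(str)
    db_accept = flag.isin(ACCEPT_FLAGS)
    pop_absent = calls["POP_AF"].isna()
    rare_impactful = (
        flag.isin(RARE_FLAGS)
        & pop_absent
        & calls["IMPACT"].isin(("moderate", "high"))
    )
    accepted = depth_ok & (db_accept | rare_impactful)
    if "CLASS" in calls.columns:
        accepted = accepted | calls["CLASS"].isin(ALWAYS_DETRIMENTAL)
    return calls.loc[accepted].copy()


def filter_somatic(
    tumour_calls: pd.DataFrame, normal_calls: pd.DataFrame
) -> pd.DataFrame:
    """Stringent somatic SNV/INDEL filter against the matched normal.

    A variant locus absent from the normal table is treated as having zero
    variant reads but *unknown* depth: SNVs (which only constrain normal
    variant reads) may still pass, INDELs (which require >5x normal
    coverage) fail.
    """
    _check_columns(tumour_calls)
    _check_columns(normal_calls)
    if len(tumour_calls) == 0:
        return tumour_calls.copy()
    n_samples = normal_calls["SAMPLE"].nunique()
    if n_samples > 1:
        raise PairingError(
            f"normal call set mixes {n_samples} samples; one matched normal expected"
        )
    normal = normal_calls[_KEY + ["DP", "AD_ALT"]].rename(
        columns={"DP": "N_DP", "AD_ALT": "N_ALT"}
    )
    merged = tumour_calls.merge(normal, on=_KEY, how="left")
    n_dp = merged["N_DP"].fillna(0)
    n_alt = merged["N_ALT"].fillna(0)
    vaf = merged["AD_ALT"] / merged["DP"].replace(0, np.nan)
    indel = is_indel(merged)
    snv_pass = ~indel & (merged["DP"] > 10) & (n_alt == 0)
    indel_pass = (
        indel
        & (merged["DP"] > 5)
        & (n_dp > 5)
        & (merged["AD_ALT"] > 5)
        & (n_alt == 0)
        & (vaf > 0.10)
    )
    keep = (snv_pass | indel_pass).to_numpy()
    return tumour_calls.loc[keep].copy()


def count_unique_mutations(
    calls: pd.DataFrame, locus: tuple[str, int, int] | None = None
) -> int:
    """Unique SNV/INDEL mutations (distinct CHROM/POS/REF/ALT) in a table,
    optionally restricted to a locus (0-based half-open); symbolic alleles
    (large deletions) are excluded from the tally."""
    df = calls.loc[~calls["ALT"].astype(str).str.startswith("<")]
    if locus is not None:
        chrom, start, end = locus
        pos0 = df["POS"] - 1
        df = df.loc[(df["CHROM"] == chrom) & (pos0 >= start) & (pos0 < end)]
    return int(df.drop_duplicates(subset=list(_KEY)).shape[0])


def mutation_rate(somatic: pd.DataFrame, callable_summary: CallableSummary) -> float:
    """Somatic mutations (SNVs + INDELs combined) per callable megabase."""
    if callable_summary.callable_bases == 0:
        raise ZeroDivisionError(
            f"pair {callable_summary.pair_id}: zero callable bases, rate undefined"
        )
    return len(somatic) / (callable_summary.callable_bases / 1e6)
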