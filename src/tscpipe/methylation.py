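"""Methylation-array statistics: hypermethylation fraction, lesion-specific
probe selection, and the 2x2 methylation-vs-expression association test.

The hypermethylation fraction of a lesion is the fraction of probes it
methylates (beta above a "methylated" cutoff) among probes that lack
methylation across a panel of normal tissues (max beta below an
"unmethylated" cutoff).  The association between hypermethylation and
differential expression is a Pearson chi-square on a 2x2 gene table,
without continuity correction:

    chi2 = n * (a*d - b*c)^2 / ((a+b) * (c+d) * (a+c) * (b+d))

which on the published table (13, 114, 1156, 15125) gives 1.873 on 1 df
(the Yates-corrected value, ~1.43, does not match the printed statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "hypermethylation_fraction",
    "select_specific_probes",
    "association_chi2",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a (hyperM & DEG), b (hyperM & not), c (not & DEG), d (neither)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def hypermethylation_fraction(
    sample_betas: np.ndarray | pd.Series,
    normal_betas: np.ndarray | pd.DataFrame,
    beta_meth: float = 0.3,
    beta_unmeth: float = 0.1,
) -> float:
    """Fraction of normally-unmethylated probes methylated in the sample.

    Eligible probes have max beta < ``beta_unmeth`` across the normal
    panel (>=2 samples required); the fraction counts eligible probes with
    sample beta > ``beta_meth``.  Missing betas are ignored per probe.
    """
    sample = np.asarray(sample_betas, dtype=float)
    panel = np.asarray(normal_betas, dtype=float)
    if panel.ndim != 2 or panel.shape[1] < 2:
        raise ValueError("normal panel must be probes x >=2 samples")
    if panel.shape[0] != sample.shape[0]:
        raise ValueError("sample and panel must share the probe axis")
    eligible = (np.nanmax(panel, axis=1) < beta_unmeth) & np.isfinite(sample)
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError("no eligible probes (none unmethylated across the panel)")
    return float(np.sum(sample[eligible] > beta_meth)) / n_eligible


def select_specific_probes(
    lesion_betas: pd.DataFrame,
    normal_betas: pd.DataFrame,
    probe_genes: dict[str, list[str]] | None = None,
    delta_min: float = 0.2,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Probes with enriched methylation in the lesion group.

    A probe is selected iff its mean beta difference (lesion - normal) is
    >= ``delta_min`` and its Welch-t p value, BH-adjusted across all
    probes, is < ``alpha``.  Returns the selection table (probe, delta,
    p, p_adj, genes) and the deduplicated mapped gene set.
    """
    if lesion_betas.shape[1] < 3 or normal_betas.shape[1] < 3:
        raise ValueError("both groups need >=3 samples")
    lesion = lesion_betas.to_numpy(dtype=float)
    normal = normal_betas.reindex(lesion_betas.index).to_numpy(dtype=float)
    delta = np.nanmean(lesion, axis=1) - np.nanmean(normal, axis=1)
    t, p = stats.ttest_ind(lesion, normal, axis=1, equal_var=False,
                           nan_policy="omit")
    p = np.where(np.isfinite(p), p, 1.0)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    selected = (delta >= delta_min) & (p_adj < alpha)
    probes = lesion_betas.index[selected]
    probe_genes = probe_genes or {}
    table = pd.DataFrame(
        {
            "probe": probes,
            "delta_beta": delta[selected],
            "p": p[selected],
            "p_adj": p_adj[selected],
            "genes": [";".join(probe_genes.get(pr, [])) for pr in probes],
        }
    ).reset_index(drop=True)
    genes = sorted({g for pr in probes for g in probe_genes.get(pr, [])})
    return table, genes


def association_chi2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Raises ``ValueError`` on a degenerate table (any zero marginal).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    marginals = (a + b, c + d, a + c, b + d)
    if min(marginals) == 0:
        raise ValueError(f"degenerate 2x2 table, zero marginal: {marginals}")
    n = table.n
    chi2 = n * (a * d - b * c) ** 2 / (
        float(a + b) * (c + d) * (a + c) * (b + d)
    )
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), 1, p
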