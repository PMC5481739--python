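"""Count normalization (TMM + log2-CPM) and moderated-t differential
expression.

TMM (trimmed mean of M-values) scale factors are computed against a
reference sample (the one whose upper-quartile count fraction is closest
to the cohort mean), trimming 30% of each tail of the gene-wise log-ratios
M and 5% of each tail of the average log-abundances A, and weighting the
surviving M values by inverse delta-method binomial variances.  Factors
are rescaled to geometric mean 1 and fold into effective library sizes for
log2-CPM with a 0.5 prior count.

The moderated t shrinks gene-wise sample variances s_g^2 (on d_g residual
df) toward a prior s0^2 with d0 prior df:

    s_post^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and refers t = dmean / (s_post * sqrt(1/n1 + 1/n2)) to d0 + d_g df.
(d0, s0^2) are estimated by moment matching on log s_g^2 via digamma /
trigamma identities for the log F distribution.  Genes are flagged DEG iff
|log2 fold-change| > 2 and BH-adjusted p < 0.001.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "tmm_factors",
    "normalize_logcpm",
    "moderated_de",
    "deg_overlap",
    "filter_low_counts",
]

logger = logging.getLogger(__name__)


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.shape[1] < 2:
        raise ValueError("need >=2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")


def _reference_column(counts: pd.DataFrame) -> int:
    """Sample whose upper-quartile count fraction is closest to the mean."""
    frac = counts.to_numpy(dtype=float) / counts.sum(axis=0).to_numpy()
    uq = np.quantile(frac, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float = 0.3, abundance_trim: float = 0.05,
) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("sample shares no expressed genes with the reference")
    obs, ref = obs[keep], ref[keep]
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    w = 1.0 / (
        (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    )
    if np.allclose(m, m[0], atol=1e-10):
        return 1.0  # identical composition
    n = len(m)
    lo_m, hi_m = math.floor(n * logratio_trim) + 1, n - math.floor(n * logratio_trim)
    lo_a, hi_a = math.floor(n * abundance_trim) + 1, n - math.floor(n * abundance_trim)
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not trimmed.any():
        return 1.0
    f = np.sum(w[trimmed] * m[trimmed]) / np.sum(w[trimmed])
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """TMM scale factors per sample, rescaled to geometric mean 1."""
    _check_counts(counts)
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    r = _reference_column(counts)
    factors = np.array(
        [
            1.0 if k == r else _tmm_pair(mat[:, k], mat[:, r], lib[k], lib[r])
            for k in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_logcpm(
    counts: pd.DataFrame, prior_count: float = 0.5
) -> tuple[pd.Series, pd.DataFrame]:
    """(TMM factors, log2-CPM matrix on TMM-effective library sizes)."""
    factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0).to_numpy() * factors.to_numpy()
    logcpm = np.log2(
        (counts.to_numpy(dtype=float) + prior_count) / (eff_lib + 1.0) * 1e6
    )
    return factors, pd.DataFrame(logcpm, index=counts.index, columns=counts.columns)


def filter_low_counts(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 3
) -> pd.DataFrame:
    """Keep genes with CPM > min_cpm in at least min_samples samples."""
    cpm = counts.to_numpy(dtype=float) / counts.sum(axis=0).to_numpy() * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]


def _trigamma_inverse(x: float, iters: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def _fit_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-matched (d0, s0^2) from log sample variances.

    Under s^2 ~ s0^2 * F(d, d0):  E[log s^2] and Var[log s^2] involve
    digamma/trigamma of d/2 and d0/2; matching the empirical moments of
    z = log s^2 yields the prior df and variance.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    if len(z) < 2:
        return math.inf, float(np.mean(s2)) if len(s2) else 1.0
    e = z - special.digamma(df_resid / 2.0) + math.log(df_resid / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df_resid / 2.0))
    if not np.isfinite(evar) or evar <= 0:
        logger.info("moderated_de: near-constant variances; pooled-variance limit")
        return math.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    if not np.isfinite(d0):
        return math.inf, float(np.exp(np.mean(e)))
    s0_sq = float(
        np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return d0, s0_sq


@dataclass
class ModeratedDEResult:
    table: pd.DataFrame  # log2fc, t, p, p_adj, deg
    d0: float
    s0_sq: float

    @property
    def degs(self) -> pd.Index:
        return self.table.index[self.table["deg"]]


def moderated_de(
    logcpm: pd.DataFrame,
    groups: pd.Series | dict | np.ndarray,
    group_a: str | None = None,
    group_b: str | None = None,
    lfc_cut: float = 2.0,
    fdr_cut: float = 0.001,
    d0_override: float | None = None,
) -> ModeratedDEResult:
    """Two-group moderated-t differential expression on log2-CPM values.

    ``groups`` labels the columns; ``group_b`` vs ``group_a`` defines the
    fold-change sign (B minus A).  ``d0_override`` forces the prior df
    (0 recovers the ordinary t, inf the pooled-variance t).
    """
    labels = pd.Series(np.asarray(groups), index=logcpm.columns)
    uniq = pd.unique(labels)
    if group_a is None or group_b is None:
        if len(uniq) != 2:
            raise ValueError("specify group_a/group_b when labels are not binary")
        group_a, group_b = uniq[0], uniq[1]
    xa = logcpm.loc[:, (labels == group_a).to_numpy()].to_numpy(dtype=float)
    xb = logcpm.loc[:, (labels == group_b).to_numpy()].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    if na < 3 or nb < 3:
        raise ValueError("each group needs >=3 samples")
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    df_resid = na + nb - 2
    s2 = ((na - 1) * va + (nb - 1) * vb) / df_resid
    if d0_override is not None:
        d0 = d0_override
        # pooled-variance limit shares the mean gene variance
        s0_sq = float(np.mean(s2)) if not np.isfinite(d0) else float(
            np.median(s2[s2 > 0])
        ) if d0 > 0 else 1.0
    else:
        d0, s0_sq = _fit_prior(s2, df_resid)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e6  # normal limit
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = float(d0 + df_resid)
    lfc = mb - ma
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(p), p, 1.0)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "deg": (np.abs(lfc) > lfc_cut) & (p_adj < fdr_cut),
        },
        index=logcpm.index,
    )
    return ModeratedDEResult(table=table, d0=float(d0), s0_sq=float(s0_sq))


def _set_overlap(a: set, b: set) -> dict[str, int]:
    return {
        "intersection": len(a & b),
        "a_only": len(a - b),
        "b_only": len(b - a),
    }


def deg_overlap(
    table_a: pd.DataFrame | set, table_b: pd.DataFrame | set
) -> dict:
    """DEG-set overlap, split by direction of change when available.

    Accepts two moderated_de tables over the same gene universe (returns
    per-direction overlap counts) or two plain gene sets (returns a single
    overlap count dict).
    """
    if not isinstance(table_a, pd.DataFrame):
        return _set_overlap(set(table_a), set(table_b))
    out: dict[str, dict[str, int]] = {}
    for direction, sign in (("increased", 1), ("decreased", -1)):
        a = set(table_a.index[table_a["deg"] & (np.sign(table_a["log2fc"]) == sign)])
        b = set(table_b.index[table_b["deg"] & (np.sign(table_b["log2fc"]) == sign)])
        out[direction] = _set_overlap(a, b)
    return out
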