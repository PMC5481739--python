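"""Two-hit genotype integration (Knudson model) and grouped expression tests.

Each lesion's accepted TSC1/TSC2 evidence — point mutations, large
deletions and CN-LOH segments — is classified by origin (germline,
somatic, mosaic, or VAF-based predictions for lesions without a matched
normal), deduplicated per gene and tallied into a 1-hit/2-hit genotype
with a mutation-combination label.  A CN-LOH over the locus counts as the
second hit; when the germline mutation is truncating, CN-LOH yields two
truncating alleles because it duplicates the mutant one.

TSC1/TSC2 transcript comparisons across genotype groups use pair-wise
Welch's t-tests with Benjamini-Hochberg correction, with Bartlett's
statistic reported as the variance-homogeneity rationale for avoiding
ANOVA.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cna import CopySegment
from .config import GENE_LOCI, TRUNCATING_CLASSES

__all__ = [
    "LesionGenotype",
    "GroupTestResult",
    "classify_origin",
    "assign_origins_unmatched",
    "integrate_hits",
    "summarize_cohort",
    "grouped_expression_test",
]

logger = logging.getLogger(__name__)

TRUNCATING = TRUNCATING_CLASSES
GERMLINE_LIKE = frozenset({"germline", "mosaic", "predicted_germline"})
POINT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splicing", "inframe_deletion", "silent"}
)


@dataclass
class LesionGenotype:
    patient: str
    lesion_id: str
    lesion_type: str
    hits: list[dict] = field(default_factory=list)  # {gene, class, origin}
    eligible: bool = True  # all DNA platforms completed (1-hit denominators)

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def n_hits_capped(self) -> int:
        """'2+' collapses to 2 for cohort-level tallies."""
        return min(self.n_hits, 2)

    @property
    def genes(self) -> set[str]:
        return {h["gene"] for h in self.hits}

    @property
    def combination(self) -> str | None:
        if self.n_hits < 2:
            return None
        return "+".join(sorted(_hit_group(h) for h in self.hits))

    @property
    def truncating(self) -> int:
        """Truncating allele count in {0, 1, 2}.

        CN-LOH contributes a truncating allele only via duplication of a
        truncating germline mutation.
        """
        base = sum(
            1 for h in self.hits if h["class"] in TRUNCATING and h["class"] != "cn_loh"
        )
        has_cnloh = any(h["class"] == "cn_loh" for h in self.hits)
        germ_trunc = any(
            h["class"] in TRUNCATING and h["origin"] in GERMLINE_LIKE
            for h in self.hits
            if h["class"] != "cn_loh"
        )
        if has_cnloh and germ_trunc:
            base += 1
        return min(base, 2)


def _hit_group(hit: dict) -> str:
    if hit["class"] in ("large_deletion", "cn_loh"):
        return hit["class"]
    return "point"


def classify_origin(
    call: pd.Series | dict,
    normal_call: pd.Series | dict | None,
    copy_state: str | None = None,
    mosaic_vaf: float = 0.05,
    germline_window: tuple[float, float] = (0.35, 0.65),
    loh_vaf: float = 0.6,
) -> str:
    """Origin label of one accepted tumour call.

    With a matched normal: germline iff the variant is present in the
    normal (mosaic when its normal VAF is below 5%), otherwise somatic.
    Without one, the origin is *predicted* from the tumour VAF: a
    germline heterozygote sits near 0.5 on a copy-neutral locus, while
    inside a CN-LOH or deletion segment the wild-type allele is lost and
    a germline mutation rises to (1+p)/2 or 1/(2-p) — above 0.6 for any
    purity p, which is why ``loh_vaf`` defaults to 0.6.  Without copy
    context the prediction falls back to the VAF windows alone, where
    only a near-one VAF (>= 0.9) indicates a duplicated germline allele.
    """
    t_vaf = call["AD_ALT"] / call["DP"]
    if normal_call is not None:
        n_vaf = normal_call["AD_ALT"] / max(normal_call["DP"], 1)
        if normal_call["AD_ALT"] > 0:
            return "mosaic" if n_vaf < mosaic_vaf else "germline"
        return "somatic"
    if copy_state is None:
        logger.warning(
            "classify_origin: no copy-state context at %s:%s; VAF-only prediction",
            call.get("CHROM", "?"), call.get("POS", "?"),
        )
        if germline_window[0] <= t_vaf <= germline_window[1] or t_vaf >= 0.9:
            return "predicted_germline"
        return "predicted_somatic"
    if copy_state == "normal" and germline_window[0] <= t_vaf <= germline_window[1]:
        return "predicted_germline"
    if copy_state in ("cn_loh", "deletion") and t_vaf >= loh_vaf:
        return "predicted_germline"
    return "predicted_somatic"


def assign_origins_unmatched(
    accepted_calls: pd.DataFrame,
    segments: list[CopySegment],
    gene_loci: dict[str, tuple[str, int, int]] | None = None,
    **origin_kwargs,
) -> list[str]:
    """Predicted origins for an unmatched lesion's accepted calls, jointly.

    Each call is first classified by :func:`classify_origin` from its VAF
    and local copy state; then the single-germline-allele constraint is
    enforced per gene: when several point calls on one gene are predicted
    germline, only the best-supported one (inside a CN-LOH/deletion
    segment, or otherwise closest to VAF 0.5) keeps the label and the
    rest become predicted somatic.
    """
    gene_loci = gene_loci or GENE_LOCI

    def state_at(call) -> str | None:
        pos0 = int(call["POS"]) - 1
        for seg in segments:
            if seg.chromosome == call["CHROM"] and seg.start <= pos0 < seg.end:
                return seg.state
        return None

    rows = list(accepted_calls.iterrows())
    origins = [
        classify_origin(call, None, state_at(call), **origin_kwargs)
        for _, call in rows
    ]
    by_gene: dict[str, list[int]] = {}
    for i, (_, call) in enumerate(rows):
        if origins[i] != "predicted_germline":
            continue
        gene = _gene_at(call["CHROM"], int(call["POS"]) - 1, gene_loci)
        if gene is not None:
            by_gene.setdefault(gene, []).append(i)
    for gene, idxs in by_gene.items():
        if len(idxs) < 2:
            continue

        def score(i: int) -> tuple[int, float]:
            call = rows[i][1]
            vaf = call["AD_ALT"] / call["DP"]
            in_loh = state_at(call) in ("cn_loh", "deletion")
            # prefer the allele the copy state vouches for, then VAF near 0.5
            return (0 if in_loh else 1, abs(vaf - 0.5))

        keep = min(idxs, key=score)
        for i in idxs:
            if i != keep:
                origins[i] = "predicted_somatic"
    return origins


def _gene_at(chrom: str, pos0: int, gene_loci: dict) -> str | None:
    for gene, (gchrom, gstart, gend) in gene_loci.items():
        if chrom == gchrom and gstart <= pos0 < gend:
            return gene
    return None


def _overlaps_locus(seg: CopySegment, locus: tuple[str, int, int]) -> bool:
    chrom, start, end = locus
    return seg.chromosome == chrom and seg.start < end and seg.end > start


def integrate_hits(
    accepted_calls: pd.DataFrame,
    segments: list[CopySegment],
    gene_loci: dict[str, tuple[str, int, int]] | None = None,
    patient: str = "",
    lesion_id: str = "",
    lesion_type: str = "",
    eligible: bool = True,
) -> LesionGenotype:
    """Integrate one lesion's accepted calls and segments into a genotype.

    ``accepted_calls`` must carry an ``ORIGIN`` column (see
    :func:`classify_origin`).  Hits are deduplicated per gene and class;
    an array deletion segment that covers an already-recorded deletion
    call is treated as the same event.  CN-LOH over a locus is counted as
    a hit only alongside another hit on that gene — on its own it leaves
    two intact alleles and is not scored.  Hits on both genes are kept
    verbatim (trans-heterozygous case).
    """
    gene_loci = gene_loci or GENE_LOCI
    geno = LesionGenotype(patient, lesion_id, lesion_type, eligible=eligible)
    hits: list[dict] = []

    for _, call in accepted_calls.iterrows():
        pos0 = int(call["POS"]) - 1
        end0 = call.get("END")
        if end0 is not None and not pd.isna(end0):
            end0 = int(end0)  # symbolic allele spanning an interval
            gene = next(
                (
                    g for g, (gc, gs, ge) in gene_loci.items()
                    if call["CHROM"] == gc and pos0 < ge and end0 > gs
                ),
                None,
            )
        else:
            end0 = pos0 + 1
            gene = _gene_at(call["CHROM"], pos0, gene_loci)
        if gene is None:
            continue
        hits.append(
            {
                "gene": gene,
                "class": call.get("CLASS", "missense"),
                "origin": call.get("ORIGIN", "somatic"),
                "pos": pos0,
                "end": end0,
                "source": "variant",
            }
        )

    for gene, locus in gene_loci.items():
        for seg in segments:
            if seg.state == "deletion" and _overlaps_locus(seg, locus):
                same = [
                    h for h in hits
                    if h["gene"] == gene
                    and h["class"] == "large_deletion"
                    and seg.start < h.get("end", h["pos"] + 1)
                    and seg.end > h["pos"]
                ]
                if not same:
                    hits.append(
                        {
                            "gene": gene,
                            "class": "large_deletion",
                            "origin": "somatic",
                            "pos": seg.start,
                            "source": "segment",
                        }
                    )
            elif seg.state == "cn_loh" and _overlaps_locus(seg, locus):
                hits.append(
                    {
                        "gene": gene,
                        "class": "cn_loh",
                        "origin": "somatic",
                        "pos": seg.start,
                        "source": "segment",
                    }
                )

    # per-gene deduplication on (class, origin); then drop CN-LOH that does
    # not accompany another hit on the same gene
    seen = set()
    deduped = []
    for h in hits:
        key = (h["gene"], h["class"], h["origin"])
        if key in seen:
            continue
        seen.add(key)
        deduped.append(h)
    final = []
    for h in deduped:
        if h["class"] == "cn_loh":
            others = [
                o for o in deduped if o["gene"] == h["gene"] and o["class"] != "cn_loh"
            ]
            if not others:
                continue
        final.append({k: h[k] for k in ("gene", "class", "origin")})
    geno.hits = final
    if len(geno.genes) > 1:
        logger.info("lesion %s: hits on both genes (trans-heterozygous)", lesion_id)
    return geno


def summarize_cohort(genotypes: list[LesionGenotype]) -> dict:
    """Cohort tallies: gene split, per-type 2-hit rates, class-by-origin
    distributions and the mutation-combination histogram."""
    if not genotypes:
        return {}
    by_patient: dict[str, set[str]] = {}
    for g in genotypes:
        by_patient.setdefault(g.patient, set()).update(g.genes)
    gene_counts = {"TSC1": 0, "TSC2": 0, "both": 0, "NMI": 0}
    for genes in by_patient.values():
        if not genes:
            gene_counts["NMI"] += 1
        elif len(genes) > 1:
            gene_counts["both"] += 1
        else:
            gene_counts[next(iter(genes))] += 1
    n_pat = len(by_patient)
    gene_pct = {k: 100.0 * v / n_pat for k, v in gene_counts.items()}

    two_hit: dict[str, dict] = {}
    for g in genotypes:
        if g.n_hits == 0:
            continue
        # 1-hit lesions enter the denominator only with all platforms complete
        if g.n_hits_capped < 2 and not g.eligible:
            continue
        d = two_hit.setdefault(g.lesion_type, {"two_hit": 0, "eligible": 0})
        d["eligible"] += 1
        if g.n_hits_capped >= 2:
            d["two_hit"] += 1
    for d in two_hit.values():
        d["pct"] = 100.0 * d["two_hit"] / d["eligible"] if d["eligible"] else math.nan

    combos: dict[str, int] = {}
    for g in genotypes:
        if g.combination is not None:
            combos[g.combination] = combos.get(g.combination, 0) + 1

    class_by_origin: dict[str, dict[str, int]] = {"germline": {}, "somatic": {}}
    for g in genotypes:
        for h in g.hits:
            side = "germline" if h["origin"] in GERMLINE_LIKE else "somatic"
            d = class_by_origin[side]
            d[h["class"]] = d.get(h["class"], 0) + 1

    return {
        "n_patients": n_pat,
        "n_lesions": len(genotypes),
        "gene_counts": gene_counts,
        "gene_pct": gene_pct,
        "pct_patients_with_mutation": 100.0 * (n_pat - gene_counts["NMI"]) / n_pat,
        "two_hit_by_type": two_hit,
        "combination_histogram": combos,
        "class_by_origin": class_by_origin,
    }


@dataclass(frozen=True)
class GroupTestResult:
    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    p_adj: float = math.nan


def grouped_expression_test(
    values: np.ndarray, labels: np.ndarray
) -> tuple[list[GroupTestResult], float, float]:
    """Pair-wise Welch's t-tests across genotype groups, BH-adjusted.

    Returns (results, bartlett statistic, bartlett p); groups with fewer
    than 2 samples are skipped with a log message.  The Bartlett statistic
    documents the variance heterogeneity that rules out pooled ANOVA.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = {}
    for lab in pd.unique(labels):
        x = values[labels == lab]
        if len(x) < 2:
            logger.info("grouped_expression_test: group %r has <2 samples, skipped", lab)
            continue
        groups[lab] = x
    if len(groups) < 2:
        raise ValueError("need >=2 groups with >=2 samples each")
    bart_stat, bart_p = stats.bartlett(*groups.values())

    raw = []
    for a, b in itertools.combinations(groups, 2):
        xa, xb = groups[a], groups[b]
        res = stats.ttest_ind(xa, xb, equal_var=False)
        va, vb = np.var(xa, ddof=1), np.var(xb, ddof=1)
        na, nb = len(xa), len(xb)
        if va == 0 and vb == 0:
            diff = float(np.mean(xa) - np.mean(xb))
            t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
            df, p = float(na + nb - 2), (1.0 if diff == 0 else 0.0)
        else:
            se2a, se2b = va / na, vb / nb
            df = (se2a + se2b) ** 2 / (
                se2a**2 / (na - 1) + se2b**2 / (nb - 1)
            )
            t, p = float(res.statistic), float(res.pvalue)
        raw.append((str(a), str(b), t, df, p))
    _, p_adj, _, _ = multipletests([r[4] for r in raw], method="fdr_bh")
    results = [
        GroupTestResult(a, b, t, df, p, float(q))
        for (a, b, t, df, p), q in zip(raw, p_adj)
    ]
    return results, float(bart_stat), float(bart_p)
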