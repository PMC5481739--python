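"""Synthetic TSC-like cohort generator.

Produces a full simulated cohort — ground truth plus every data layer the
downstream stages consume: a paired tumour/normal variant table with
germline, somatic and mosaic TSC1/TSC2 hits; purity-attenuated SNP-array
tracks (BAF/LRR) containing CN-LOH segments, focal deletions and arm-level
events; a methylation beta matrix with lesion-specific hypermethylated
probes; and negative-binomial count matrices generated as mixtures of
reference cell-type profiles.

The central piece of array modelling is :func:`expected_allelic_signal`:
for a locus with tumour allele copy numbers (nA, nB) in a sample of purity
p, the expected B-allele frequency at a probe heterozygous in the germline
is

    BAF = ((1 - p) + p * nB) / (2 * (1 - p) + p * (nA + nB))

and the expected log-R ratio is

    LRR = log2((2 * (1 - p) + p * (nA + nB)) / 2).

Copy-neutral LOH therefore moves BAF away from 0.5 while leaving LRR flat,
which is exactly the signature the caller in :mod:`tscpipe.cna` looks for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import (
    ARMS,
    CELL_TYPES,
    GENE_LOCI,
    GENOME,
    LESION_TYPES,
    MIXTURE_MEANS,
    TRUNCATING_CLASSES,
    CohortConfig,
)

__all__ = [
    "AllelicTrack",
    "CohortTruth",
    "CohortBundle",
    "expected_allelic_signal",
    "generate_cohort",
    "sample_truth",
    "simulate_layers",
    "simulate_variant_table",
    "simulate_track",
    "draw_deletion_sizes",
    "make_reference_profiles",
]

#: germline point/deletion mutation class frequencies: frameshift and
#: splicing dominate germline alleles, as observed in TSC cohorts
GERMLINE_CLASS_WEIGHTS = {
    "frameshift": 0.28,
    "nonsense": 0.20,
    "splicing": 0.12,
    "missense": 0.25,
    "inframe_deletion": 0.05,
    "large_deletion": 0.10,
}

#: class mix of somatic *point* second hits (frameshift/splicing rare somatically)
SOMATIC_POINT_WEIGHTS = {
    "nonsense": 0.40,
    "frameshift": 0.15,
    "missense": 0.35,
    "splicing": 0.10,
}

IMPACT_BY_CLASS = {
    "nonsense": "high",
    "frameshift": "high",
    "splicing": "high",
    "large_deletion": "high",
    "missense": "moderate",
    "inframe_deletion": "moderate",
    "silent": "low",
}

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class AllelicTrack:
    """Ordered SNP probes on one chromosome with BAF, LRR and normal genotype."""

    chromosome: str
    positions: np.ndarray  # ascending bp
    baf: np.ndarray        # in [0, 1]
    lrr: np.ndarray        # log2 copy ratios
    genotype: np.ndarray   # 'AA' | 'AB' | 'BB' (matched-normal genotype)

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.baf) == len(self.lrr) == len(self.genotype) == n):
            raise ValueError("track arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("probe positions must be strictly increasing")
        if np.any((self.baf < 0) | (self.baf > 1)):
            raise ValueError("BAF values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def het_mask(self) -> np.ndarray:
        return self.genotype == "AB"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosome,
                "pos": self.positions,
                "baf": self.baf,
                "lrr": self.lrr,
                "genotype": self.genotype,
            }
        )


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort; every data layer derives from it.

    Intervals are 0-based half-open.
    """

    patients: list[dict]
    lesions: list[dict]
    somatic_background: list[dict]
    callable_bases: dict[str, int]
    fractions: dict[str, list[float]]
    cell_types: tuple[str, ...]
    meth: dict
    marker_genes: dict[str, list[str]]
    config: dict

    def lesion(self, lesion_id: str) -> dict:
        for les in self.lesions:
            if les["lesion_id"] == lesion_id:
                return les
        raise KeyError(lesion_id)

    def to_json_dict(self) -> dict:
        return {
            "patients": self.patients,
            "lesions": self.lesions,
            "somatic_background": self.somatic_background,
            "callable_bases": self.callable_bases,
            "fractions": self.fractions,
            "cell_types": list(self.cell_types),
            "meth": self.meth,
            "marker_genes": self.marker_genes,
            "config": self.config,
        }


@dataclass
class CohortBundle:
    """All simulated data layers plus generation metadata."""

    variants: pd.DataFrame
    tracks: dict[str, dict[str, AllelicTrack]]
    betas: pd.DataFrame
    counts: pd.DataFrame
    reference_counts: dict[str, pd.DataFrame]
    probe_genes: dict[str, list[str]]
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# allelic signal model
# ---------------------------------------------------------------------------

def expected_allelic_signal(
    allele_copy_numbers: tuple[int, int], purity: float
) -> tuple[tuple[float, float], float]:
    """Expected (BAF, LRR) for tumour allele copy numbers at given purity.

    Returns ``((baf_b, baf_a), lrr)`` where the two BAF values are the
    mirror alternatives at a germline-heterozygous probe (the B allele on
    one or the other parental chromosome); they always sum to 1.

    Raises ``ValueError`` if purity is outside (0, 1] or copy numbers are
    invalid (negative, or both zero in a pure tumour).
    """
    nA, nB = allele_copy_numbers
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity {purity} outside (0, 1]")
    if nA < 0 or nB < 0:
        raise ValueError("allele copy numbers must be >= 0")
    total = 2.0 * (1.0 - purity) + purity * (nA + nB)
    if total <= 0:
        raise ValueError("total copy number is zero (homozygous deletion at purity 1)")
    baf_b = ((1.0 - purity) + purity * nB) / total
    baf_a = ((1.0 - purity) + purity * nA) / total
    lrr = math.log2(total / 2.0)
    return (baf_b, baf_a), lrr


def _mixture_signal(
    normal_cn: tuple[int, int], tumour_cn: tuple[int, int], purity: float
) -> tuple[np.ndarray, float]:
    """(BAF alternatives, LRR) when the *germline* is itself aberrant.

    Generalizes :func:`expected_allelic_signal` to loci where the normal
    component has copy numbers other than (1, 1), e.g. germline deletions.
    """
    c1n, c2n = normal_cn
    c1t, c2t = tumour_cn
    total = (c1n + c2n) * (1.0 - purity) + (c1t + c2t) * purity
    if total <= 0:
        return np.array([0.5, 0.5]), -8.0  # fully deleted: signal floor
    b1 = (c1n * (1.0 - purity) + c1t * purity) / total
    b2 = (c2n * (1.0 - purity) + c2t * purity) / total
    return np.array([b1, b2]), math.log2(total / 2.0)


# ---------------------------------------------------------------------------
# truth sampling
# ---------------------------------------------------------------------------

def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = list(weights)
    probs = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def draw_deletion_sizes(
    rng: np.random.Generator, n: int, config: CohortConfig
) -> np.ndarray:
    """Log-normal deletion sizes with the configured median, truncated by rejection."""
    lo, hi = config.deletion_size_range
    mu = math.log(config.deletion_size_log_median)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, config.deletion_size_log_sd, size=2 * (n - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def _place_deletion(rng: np.random.Generator, gene: str, size: float) -> tuple[str, int, int]:
    """Place a deletion of `size` bp overlapping the gene locus."""
    chrom, gstart, gend = GENE_LOCI[gene]
    size = int(round(size))
    # anchor: deletion must overlap the gene; slide its start uniformly
    lo = max(0, gstart - size + 1)
    hi = gend - 1
    start = int(rng.integers(lo, hi + 1))
    end = min(start + size, GENOME[chrom])
    return chrom, start, end


def _place_cnloh(rng: np.random.Generator, gene: str) -> tuple[str, int, int]:
    """CN-LOH segment running from the gene to the telomere (mitotic recombination)."""
    chrom, gstart, gend = GENE_LOCI[gene]
    ext = rng.exponential(2e6)
    if gene == "TSC2":  # 16p: telomere at 0
        return chrom, 0, min(int(gend + ext), GENOME[chrom])
    # TSC1 on 9q: runs to the chromosome end
    arm_start = ARMS[(chrom, "q")][0]
    start = max(arm_start, int(gstart - ext))
    return chrom, start, GENOME[chrom]


def sample_truth(config: CohortConfig) -> CohortTruth:
    """Draw the latent cohort structure (who has which hits) from the config."""
    ss = np.random.SeedSequence([config.seed, 0])
    rng = np.random.default_rng(ss)

    patients: list[dict] = []
    lesions: list[dict] = []
    somatic_bg: list[dict] = []
    callable_bases: dict[str, int] = {}

    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        gene = _weighted_choice(rng, config.gene_split)
        gene = None if gene == "none" else gene
        mosaic = bool(gene) and rng.random() < config.mosaic_rate
        germline = None
        if gene is not None:
            gclass = _weighted_choice(rng, GERMLINE_CLASS_WEIGHTS)
            chrom, gstart, gend = GENE_LOCI[gene]
            if gclass == "large_deletion":
                size = draw_deletion_sizes(rng, 1, config)[0]
                dchrom, dstart, dend = _place_deletion(rng, gene, size)
                germline = {
                    "class": gclass, "chrom": dchrom, "start": dstart, "end": dend,
                }
            else:
                pos = int(rng.integers(gstart, gend))
                germline = {"class": gclass, "chrom": chrom, "pos": pos}
            germline["mosaic"] = mosaic
            germline["mosaic_vaf"] = (
                float(rng.uniform(0.005, 0.05)) if mosaic else None
            )
        matched = bool(rng.random() < config.matched_normal_prob)
        patients.append(
            {
                "patient": pid,
                "gene": gene,
                "germline": germline,
                "matched_normal": matched,
            }
        )

        ltype = _weighted_choice(rng, config.lesion_mix)
        lesion_id = f"{pid}-{ltype}1"
        purity = float(rng.uniform(*config.purity_range))
        second = None
        if gene is not None and rng.random() < config.second_hit_prob[ltype]:
            sclass = _weighted_choice(rng, config.second_hit_class_weights)
            if sclass == "point":
                pclass = _weighted_choice(rng, SOMATIC_POINT_WEIGHTS)
                chrom, gstart, gend = GENE_LOCI[gene]
                second = {
                    "class": pclass, "kind": "point",
                    "chrom": chrom, "pos": int(rng.integers(gstart, gend)),
                }
            elif sclass == "large_deletion":
                size = draw_deletion_sizes(rng, 1, config)[0]
                chrom, dstart, dend = _place_deletion(rng, gene, size)
                second = {
                    "class": "large_deletion", "kind": "large_deletion",
                    "chrom": chrom, "start": dstart, "end": dend,
                }
            else:
                chrom, cstart, cend = _place_cnloh(rng, gene)
                second = {
                    "class": "cn_loh", "kind": "cn_loh",
                    "chrom": chrom, "start": cstart, "end": cend,
                }
        arm_events = []
        if rng.random() < config.arm_event_rate:
            arm = "p" if rng.random() < 0.5 else "q"
            state = "gain" if rng.random() < 0.5 else "loss"
            arm_events.append({"chrom": "chr10", "arm": arm, "state": state})

        # background somatic SNVs/INDELs, clonal heterozygous, diploid loci
        callable_b = int(
            max(1e6, rng.normal(config.callable_mb, 1.5) * 1e6)
        )
        callable_bases[lesion_id] = callable_b
        n_som = rng.poisson(config.somatic_rate_per_mb * callable_b / 1e6)
        blocked: list[tuple[str, int, int]] = []
        if second is not None and second["kind"] != "point":
            blocked.append((second["chrom"], second["start"], second["end"]))
        if germline is not None and germline["class"] == "large_deletion":
            blocked.append((germline["chrom"], germline["start"], germline["end"]))
        for ev in arm_events:
            blocked.append((ev["chrom"],) + ARMS[(ev["chrom"], ev["arm"])])
        chroms = list(GENOME)
        lens = np.array([GENOME[c] for c in chroms], dtype=float)
        for _ in range(n_som):
            for _attempt in range(50):
                c = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
                pos = int(rng.integers(0, GENOME[c]))
                if not any(bc == c and bs <= pos < be for bc, bs, be in blocked):
                    break
            somatic_bg.append(
                {
                    "lesion_id": lesion_id,
                    "chrom": c,
                    "pos": pos,
                    "is_indel": bool(rng.random() < 0.2),
                    "silent": bool(rng.random() < 0.3),
                }
            )
        lesions.append(
            {
                "lesion_id": lesion_id,
                "patient": pid,
                "type": ltype,
                "purity": purity,
                "second_hit": second,
                "arm_events": arm_events,
                "platforms_complete": bool(
                    rng.random() < config.platform_complete_prob
                ),
            }
        )

    # cell-type fractions: tight Dirichlet around the group means
    fractions: dict[str, list[float]] = {}
    conc = 300.0
    group_of = {les["lesion_id"]: les["type"] for les in lesions}
    for k in range(config.n_normals):
        group_of[f"NK{k + 1:02d}"] = "NORMAL_KIDNEY"
        group_of[f"NB{k + 1:02d}"] = "NORMAL_BRAIN"
    for sample, group in group_of.items():
        alpha = np.asarray(MIXTURE_MEANS[group]) * conc
        fractions[sample] = [float(x) for x in rng.dirichlet(alpha)]

    # methylation truth: unmethylated pool in normals; disjoint spike sets
    probes = [f"M{i + 1:05d}" for i in range(config.n_meth_probes)]
    n_unmeth = int(config.meth_unmeth_frac * config.n_meth_probes)
    unmeth = [probes[i] for i in rng.permutation(config.n_meth_probes)[:n_unmeth]]
    pool = list(unmeth)
    spike_sets: dict[str, list[str]] = {}
    for ltype in LESION_TYPES:
        k = min(config.meth_spike_probes.get(ltype, 0), len(pool))
        idx = rng.permutation(len(pool))[:k]
        spike_sets[ltype] = sorted(pool[j] for j in idx)
        pool = [p for j, p in enumerate(pool) if j not in set(idx)]

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    probe_genes = {
        p: [genes[int(rng.integers(0, config.n_genes))]] for p in probes
    }

    # marker genes per cell type, disjoint blocks at the head of the gene list
    marker_genes: dict[str, list[str]] = {}
    k = config.n_markers_per_type
    for t_idx, ctype in enumerate(CELL_TYPES):
        marker_genes[ctype] = genes[t_idx * k : (t_idx + 1) * k]

    return CohortTruth(
        patients=patients,
        lesions=lesions,
        somatic_background=somatic_bg,
        callable_bases=callable_bases,
        fractions=fractions,
        cell_types=CELL_TYPES,
        meth={
            "probes": probes,
            "unmeth_probes": sorted(unmeth),
            "spike_sets": spike_sets,
            "probe_genes": probe_genes,
        },
        marker_genes=marker_genes,
        config=config.to_dict(),
    )


# ---------------------------------------------------------------------------
# data-layer simulation
# ---------------------------------------------------------------------------

def _draw_depth_alt(
    rng: np.random.Generator, depth_mean: float, vaf: float
) -> tuple[int, int]:
    dp = max(1, int(rng.poisson(depth_mean)))
    alt = int(rng.binomial(dp, min(max(vaf, 0.0), 1.0)))
    return dp, alt


def _alleles(rng: np.random.Generator, vclass: str) -> tuple[str, str]:
    ref = str(_BASES[rng.integers(0, 4)])
    if vclass in ("frameshift",):
        return ref + "AG", ref  # 2-bp frameshifting deletion
    if vclass == "inframe_deletion":
        return ref + "CAG", ref
    alt = str(_BASES[rng.integers(0, 4)])
    while alt == ref:
        alt = str(_BASES[rng.integers(0, 4)])
    return ref, alt


def _pathogenic_flag(rng: np.random.Generator) -> str:
    u = rng.random()
    if u < 0.60:
        return "pathogenic"
    if u < 0.70:
        return "probably_pathogenic"
    return "absent"  # accepted via the rare + impactful branch


def _covers(ev: dict | None, chrom: str, pos: int) -> bool:
    return (
        ev is not None
        and ev.get("chrom") == chrom
        and ev.get("start", -1) <= pos < ev.get("end", -1)
    )


def simulate_track(
    chromosome: str,
    length: int,
    events: Sequence[tuple[int, int, tuple[int, int], tuple[int, int]]],
    purity: float,
    rng: np.random.Generator,
    spacing: int = 2_000,
    het_rate: float = 0.35,
    baf_sd: float = 0.03,
    lrr_sd: float = 0.15,
) -> AllelicTrack:
    """Simulate one chromosome's probe track.

    ``events`` is a list of ``(start, end, normal_cn, tumour_cn)`` with
    allele copy-number pairs; probes outside every event are diploid in
    both components.
    """
    positions = np.arange(spacing // 2, length, spacing, dtype=np.int64)
    n = len(positions)
    p_hom = (1.0 - het_rate) / 2.0
    genotype = rng.choice(np.array(["AA", "AB", "BB"]), size=n, p=[p_hom, het_rate, p_hom])

    c1n = np.ones(n); c2n = np.ones(n)
    c1t = np.ones(n); c2t = np.ones(n)
    for start, end, ncn, tcn in events:
        mask = (positions >= start) & (positions < end)
        c1n[mask], c2n[mask] = ncn
        c1t[mask], c2t[mask] = tcn

    total = (c1n + c2n) * (1.0 - purity) + (c1t + c2t) * purity
    total = np.maximum(total, 1e-6)
    lrr_exp = np.log2(total / 2.0)
    # B allele sits on parental chromosome 1 or 2, independently per probe
    b_on_1 = rng.random(n) < 0.5
    bdose = np.where(
        b_on_1,
        c1n * (1.0 - purity) + c1t * purity,
        c2n * (1.0 - purity) + c2t * purity,
    )
    baf_exp = np.where(
        genotype == "AB",
        bdose / total,
        np.where(genotype == "BB", 1.0, 0.0),
    )
    baf = np.clip(baf_exp + rng.normal(0.0, baf_sd, n), 0.0, 1.0)
    lrr = lrr_exp + rng.normal(0.0, lrr_sd, n)
    return AllelicTrack(chromosome, positions, baf, lrr, genotype)


def _lesion_events(patient: dict, lesion: dict) -> dict[str, list]:
    """Copy-number events per chromosome as (start, end, normal_cn, tumour_cn)."""
    ev: dict[str, list] = {c: [] for c in GENOME}
    germ = patient["germline"]
    if germ is not None and germ["class"] == "large_deletion":
        # all cells carry one copy across the deleted interval
        ev[germ["chrom"]].append((germ["start"], germ["end"], (1, 0), (1, 0)))
    second = lesion["second_hit"]
    if second is not None and second["kind"] == "large_deletion":
        ev[second["chrom"]].append((second["start"], second["end"], (1, 1), (1, 0)))
    elif second is not None and second["kind"] == "cn_loh":
        ev[second["chrom"]].append((second["start"], second["end"], (1, 1), (2, 0)))
    for arm_ev in lesion["arm_events"]:
        start, end = ARMS[(arm_ev["chrom"], arm_ev["arm"])]
        tcn = (2, 1) if arm_ev["state"] == "gain" else (1, 0)
        ev[arm_ev["chrom"]].append((start, end, (1, 1), tcn))
    return ev


def _variant_rows(
    truth: CohortTruth, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows: list[dict] = []
    lesions_by_patient = {les["patient"]: les for les in truth.lesions}

    def add(sample, chrom, pos0, ref, alt, dp, alt_reads, impact, flag, pop_af,
            platform, vclass, end0=None):
        rows.append(
            {
                "CHROM": chrom,
                "POS": pos0 + 1,  # VCF dialect is 1-based
                "END": end0,     # 0-based half-open end, symbolic alleles only
                "REF": ref,
                "ALT": alt,
                "SAMPLE": sample,
                "DP": dp,
                "AD_REF": dp - alt_reads,
                "AD_ALT": alt_reads,
                "IMPACT": impact,
                "PATHOGENIC_DB": flag,
                "POP_AF": pop_af,
                "PLATFORM": platform,
                "CLASS": vclass,
            }
        )

    for pat in truth.patients:
        pid = pat["patient"]
        lesion = lesions_by_patient[pid]
        lid = lesion["lesion_id"]
        purity = lesion["purity"]
        normal_id = f"{pid}-N" if pat["matched_normal"] else None
        germ = pat["germline"]
        second = lesion["second_hit"]

        if germ is not None:
            flag = _pathogenic_flag(rng)
            if germ["class"] == "large_deletion":
                chrom, pos = germ["chrom"], germ["start"]
                ref, alt = "N", "<DEL>"
                n_vaf = t_vaf = 0.5
                platform = "SNP_ARRAY"
            else:
                chrom, pos = germ["chrom"], germ["pos"]
                ref, alt = _alleles(rng, germ["class"])
                platform = "TARGETED" if germ["mosaic"] else "WES"
                if germ["mosaic"]:
                    m = germ["mosaic_vaf"]
                    n_vaf = m
                    t_vaf = 0.5 * purity + (1.0 - purity) * m
                else:
                    n_vaf = 0.5
                    t_vaf = 0.5
                    # second hits over the germline locus reshape the tumour VAF
                    if second is not None and second["kind"] == "cn_loh" and _covers(
                        second, chrom, pos
                    ):
                        t_vaf = (1.0 + purity) / 2.0
                    elif second is not None and second[
                        "kind"
                    ] == "large_deletion" and _covers(second, chrom, pos):
                        t_vaf = 1.0 / (2.0 - purity)
            impact = IMPACT_BY_CLASS[germ["class"]]
            depth = (
                config.targeted_depth_mean if platform == "TARGETED"
                else config.depth_mean
            )
            end0 = germ.get("end") if germ["class"] == "large_deletion" else None
            dp, ar = _draw_depth_alt(rng, depth, t_vaf)
            add(lid, chrom, pos, ref, alt, dp, ar, impact, flag, np.nan,
                platform, germ["class"], end0=end0)
            if normal_id is not None:
                dp, ar = _draw_depth_alt(rng, depth, n_vaf)
                add(normal_id, chrom, pos, ref, alt, dp, ar, impact, flag,
                    np.nan, platform, germ["class"], end0=end0)

        if second is not None and second["kind"] == "point":
            chrom, pos = second["chrom"], second["pos"]
            ref, alt = _alleles(rng, second["class"])
            t_vaf = purity / 2.0
            dp, ar = _draw_depth_alt(rng, config.depth_mean, t_vaf)
            add(lid, chrom, pos, ref, alt, dp, ar, IMPACT_BY_CLASS[second["class"]],
                _pathogenic_flag(rng), np.nan, "WES", second["class"])
            if normal_id is not None:
                dp = max(1, int(rng.poisson(config.depth_mean)))
                add(normal_id, chrom, pos, ref, alt, dp, 0,
                    IMPACT_BY_CLASS[second["class"]], "absent", np.nan, "WES",
                    second["class"])
        elif second is not None and second["kind"] == "large_deletion":
            add(lid, second["chrom"], second["start"], "N", "<DEL>",
                int(config.depth_mean), int(config.depth_mean * purity / 2),
                "high", "absent", np.nan, "SNP_ARRAY", "large_deletion",
                end0=second["end"])

        # benign germline decoys in the TSC genes (common SNPs, low impact)
        for _ in range(3):
            gene = "TSC1" if rng.random() < 0.5 else "TSC2"
            chrom, gstart, gend = GENE_LOCI[gene]
            pos = int(rng.integers(gstart, gend))
            ref, alt = _alleles(rng, "missense")
            pop_af = float(10 ** rng.uniform(-3, -0.5))
            flag = "not_pathogenic" if rng.random() < 0.3 else "absent"
            impact = "low" if rng.random() < 0.5 else "moderate"
            for sample, vaf in ((lid, 0.5), (normal_id, 0.5)):
                if sample is None:
                    continue
                dp, ar = _draw_depth_alt(rng, config.depth_mean, vaf)
                add(sample, chrom, pos, ref, alt, dp, ar, impact, flag, pop_af,
                    "WES", "missense")

    # background somatic variants (tumour rows plus clean matched-normal rows)
    matched = {p["patient"]: p["matched_normal"] for p in truth.patients}
    for sv in truth.somatic_background:
        lid = sv["lesion_id"]
        pid = lid.split("-")[0]
        lesion = lesions_by_patient[pid]
        vclass = (
            "frameshift" if sv["is_indel"] else ("silent" if sv["silent"] else "missense")
        )
        ref, alt = _alleles(rng, "frameshift" if sv["is_indel"] else "missense")
        t_vaf = lesion["purity"] / 2.0
        dp, ar = _draw_depth_alt(rng, config.depth_mean, t_vaf)
        add(lid, sv["chrom"], sv["pos"], ref, alt, dp, ar,
            IMPACT_BY_CLASS[vclass], "absent", np.nan, "WES", vclass)
        if matched[pid]:
            dp = max(1, int(rng.poisson(config.depth_mean)))
            add(f"{pid}-N", sv["chrom"], sv["pos"], ref, alt, dp, 0,
                IMPACT_BY_CLASS[vclass], "absent", np.nan, "WES", vclass)

    df = pd.DataFrame(rows)
    return df.sort_values(["SAMPLE", "CHROM", "POS"], kind="stable").reset_index(
        drop=True
    )


def make_reference_profiles(
    truth: CohortTruth, config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Linear expression profile per cell type plus NB replicate count tables.

    Returns (profiles genes x types summing to 1 per column, reference
    counts per type with 2 replicates each).
    """
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    base = rng.lognormal(2.0, 1.0, size=config.n_genes)
    profiles = pd.DataFrame(
        {t: base.copy() for t in truth.cell_types}, index=genes, dtype=float
    )
    for ctype in truth.cell_types:
        idx = [genes.index(g) for g in truth.marker_genes[ctype]]
        profiles.iloc[idx, profiles.columns.get_loc(ctype)] *= rng.uniform(
            20.0, 50.0, size=len(idx)
        )
    profiles = profiles / profiles.sum(axis=0)

    ref_counts: dict[str, pd.DataFrame] = {}
    for ctype in truth.cell_types:
        mu = profiles[ctype].to_numpy() * config.library_size
        reps = {
            f"{ctype}_rep{r + 1}": _nb_draw(rng, mu, config.nb_dispersion)
            for r in range(2)
        }
        ref_counts[ctype] = pd.DataFrame(reps, index=genes)
    return profiles, ref_counts


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def _true_truncating(patient: dict, lesion: dict) -> int:
    """Truncating-allele count implied by the truth (CN-LOH duplicates a
    truncating germline allele)."""
    germ = patient["germline"]
    germ_trunc = germ is not None and germ["class"] in TRUNCATING_CLASSES
    n = 1 if germ_trunc else 0
    second = lesion["second_hit"]
    if second is not None:
        if second["class"] in TRUNCATING_CLASSES:
            n += 1
        elif second["class"] == "cn_loh" and germ_trunc:
            n += 1
    return min(n, 2)


def simulate_variant_table(truth: CohortTruth, config: CohortConfig) -> pd.DataFrame:
    """Only the paired tumour/normal allele-depth table (no array, beta or
    count layers); identical to the variants frame of the full bundle."""
    ss = np.random.SeedSequence([config.seed, 1])
    return _variant_rows(truth, config, np.random.default_rng(ss.spawn(4)[0]))


def simulate_layers(truth: CohortTruth, config: CohortConfig) -> CohortBundle:
    """Render every observable data layer from the cohort truth."""
    ss = np.random.SeedSequence([config.seed, 1])
    rng_var, rng_trk, rng_meth, rng_expr = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    variants = _variant_rows(truth, config, rng_var)

    patients = {p["patient"]: p for p in truth.patients}
    tracks: dict[str, dict[str, AllelicTrack]] = {}
    for lesion in truth.lesions:
        pat = patients[lesion["patient"]]
        events = _lesion_events(pat, lesion)
        tracks[lesion["lesion_id"]] = {
            chrom: simulate_track(
                chrom,
                GENOME[chrom],
                events[chrom],
                lesion["purity"],
                rng_trk,
                spacing=config.probe_spacing,
                het_rate=config.het_rate,
                baf_sd=config.baf_sd,
                lrr_sd=config.lrr_sd,
            )
            for chrom in GENOME
        }

    # methylation betas
    probes = truth.meth["probes"]
    unmeth = set(truth.meth["unmeth_probes"])
    samples = list(truth.fractions)
    n_probes = len(probes)
    low = (2.0, 50.0)      # beta params: unmethylated baseline, mean ~0.04
    mid = (2.0, 2.0)       # variably methylated probes
    spike_mean = config.meth_spike_beta
    spike_a = spike_mean * 20.0
    spike_b = (1.0 - spike_mean) * 20.0
    unmeth_mask = np.array([p in unmeth for p in probes])
    beta_cols = {}
    lesion_type = {les["lesion_id"]: les["type"] for les in truth.lesions}
    for sample in samples:
        col = np.where(
            unmeth_mask,
            rng_meth.beta(low[0], low[1], n_probes),
            rng_meth.beta(mid[0], mid[1], n_probes),
        )
        ltype = lesion_type.get(sample)
        if ltype is not None:
            spiked = set(truth.meth["spike_sets"].get(ltype, []))
            if spiked:
                smask = np.array([p in spiked for p in probes])
                col = np.where(smask, rng_meth.beta(spike_a, spike_b, n_probes), col)
        beta_cols[sample] = col
    betas = pd.DataFrame(beta_cols, index=probes)

    # expression counts: NB mixtures of the reference profiles
    profiles, ref_counts = make_reference_profiles(truth, config, rng_expr)
    count_cols = {}
    for sample in samples:
        f = np.asarray(truth.fractions[sample])
        mu = profiles.to_numpy() @ f * config.library_size
        count_cols[sample] = _nb_draw(rng_expr, mu, config.nb_dispersion)
    counts = pd.DataFrame(count_cols, index=profiles.index)

    # TSC1/TSC2 transcript rows: truncating hits reduce the transcript dose
    pat_of = {les["lesion_id"]: patients[les["patient"]] for les in truth.lesions}
    les_of = {les["lesion_id"]: les for les in truth.lesions}
    base_mu = 1e-4 * config.library_size  # ~100 CPM baseline
    for gene in ("TSC1", "TSC2"):
        row = []
        for sample in counts.columns:
            factor = 1.0
            if sample in les_of:
                pat, les = pat_of[sample], les_of[sample]
                if pat["gene"] == gene:
                    factor = 1.0 - 0.35 * _true_truncating(pat, les)
            row.append(
                int(_nb_draw(rng_expr, np.array([base_mu * factor]),
                             config.nb_dispersion)[0])
            )
        counts.loc[gene] = row

    meta = {
        "seed": config.seed,
        "baf_sd": config.baf_sd,
        "lrr_sd": config.lrr_sd,
        "depth_mean": config.depth_mean,
        "nb_dispersion": config.nb_dispersion,
        "noise_model": "BAF/LRR Gaussian; allele depths Binomial(DP, VAF); "
        "betas Beta; counts Gamma-Poisson",
    }
    return CohortBundle(
        variants=variants,
        tracks=tracks,
        betas=betas,
        counts=counts,
        reference_counts=ref_counts,
        probe_genes=truth.meth["probe_genes"],
        meta=meta,
    )


def generate_cohort(config: CohortConfig) -> tuple[CohortTruth, CohortBundle]:
    """Sample a cohort truth and render all data layers. Deterministic in
    (config, seed)."""
    truth = sample_truth(config)
    bundle = simulate_layers(truth, config)
    return truth, bundle
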