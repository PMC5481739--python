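"""End-to-end orchestration: simulate -> filter -> call -> integrate ->
methylation / expression / deconvolution, with a machine-readable report.

Every stage talks to the others only through the data structures the
module interfaces declare (variant tables, segment lists, matrices), and
all randomness flows from the single seed in the config.  When the cohort
is simulated the report also carries recovery metrics against the truth:
CN-LOH sensitivity, origin-classification accuracy and cell-type fraction
RMSE.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import cna, deconvolution, expression, hits, methylation, variants
from .config import GENE_LOCI, CohortConfig
from .io import write_bundle, write_seg
from .simulate import CohortBundle, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "true_truncating_count"]


def true_truncating_count(patient: dict, lesion: dict) -> int:
    """Ground-truth truncating-allele count of one lesion (0, 1 or 2)."""
    from .simulate import _true_truncating

    return _true_truncating(patient, lesion)


def _segment_lesion(bundle: CohortBundle, lesion_id: str,
                    penalty: float, min_probes: int) -> list[cna.CopySegment]:
    segs: list[cna.CopySegment] = []
    for track in bundle.tracks[lesion_id].values():
        segs.extend(cna.segment_track(track, penalty=penalty, min_probes=min_probes))
    return cna.classify_segments(segs)


def _copy_state_at(segments: list[cna.CopySegment], chrom: str, pos0: int) -> str | None:
    for seg in segments:
        if seg.chromosome == chrom and seg.start <= pos0 < seg.end:
            return seg.state
    return None


def _overlap(seg: cna.CopySegment, chrom: str, start: int, end: int) -> bool:
    return seg.chromosome == chrom and seg.start < end and seg.end > start


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, (pd.Series,)):
        return _jsonable(obj.to_dict())
    return obj


def run_pipeline(
    config: CohortConfig,
    outdir: str | Path | None = None,
    mode: str = "simulate",
    seg_penalty: float = 12.0,
    seg_min_probes: int = 10,
    write_tracks: bool = False,
    n_perm: int = 50,
) -> dict:
    """Run the full analysis over a (simulated) cohort and return the report.

    ``mode='simulate'`` generates the cohort from ``config``; the report
    then includes truth-recovery metrics.  Outputs are written under
    ``outdir`` when given.
    """
    if mode != "simulate":
        raise NotImplementedError(
            "real-data mode is exercised through the per-stage CLI subcommands"
        )
    report: dict = {
        "parameters": {
            "config": config.to_dict(),
            "seg_penalty": seg_penalty,
            "seg_min_probes": seg_min_probes,
            "n_perm": n_perm,
            "thresholds": {
                "classify": vars(cna.ClassifyThresholds()),
                "beta_meth": 0.3, "beta_unmeth": 0.1,
                "lfc_cut": 2.0, "fdr_cut": 0.001,
                "fold_cut": 3.0, "enrich_alpha": 0.05,
            },
        },
        "seed_registry": {"cohort": config.seed, "deconvolution": config.seed + 1},
    }
    truth, bundle = generate_cohort(config)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        paths = write_bundle(bundle, truth, config, out / "bundle",
                             write_tracks=write_tracks)
        report["paths"] = paths

    patients = {p["patient"]: p for p in truth.patients}
    lesions = {l["lesion_id"]: l for l in truth.lesions}
    var = bundle.variants

    # ---- somatic filtering and mutation burden per matched pair ----------
    rates = {}
    somatic_vafs: list[float] = []
    for lesion in truth.lesions:
        pat = patients[lesion["patient"]]
        if not pat["matched_normal"]:
            continue
        lid = lesion["lesion_id"]
        tumour = var[var["SAMPLE"] == lid]
        normal = var[var["SAMPLE"] == f"{lesion['patient']}-N"]
        som = variants.filter_somatic(tumour, normal)
        som = som[~som["ALT"].astype(str).str.startswith("<")]
        rate = variants.mutation_rate(
            som, variants.CallableSummary(lid, truth.callable_bases[lid])
        )
        rates[lid] = rate
        somatic_vafs.extend((som["AD_ALT"] / som["DP"]).tolist())
    report["mutation_rates"] = {
        "per_pair": rates,
        "n_pairs": len(rates),
        "median": float(np.median(list(rates.values()))) if rates else None,
        "median_somatic_vaf": float(np.median(somatic_vafs)) if somatic_vafs else None,
    }

    # ---- copy number / CN-LOH per lesion ---------------------------------
    segments_by_lesion: dict[str, list[cna.CopySegment]] = {}
    arm_rows = []
    for lid in lesions:
        segs = _segment_lesion(bundle, lid, seg_penalty, seg_min_probes)
        segments_by_lesion[lid] = segs
        arm_calls = cna.call_arm_events(segs)
        for row in arm_calls.itertuples():
            arm_rows.append(
                {"lesion": lid, "chrom": row.chrom, "arm": row.arm, "state": row.state}
            )
        if out is not None:
            seg_path = out / "segments.seg"
            write_seg(segs, lid, seg_path, append=True)
    report["arm_events"] = arm_rows

    # arm recovery vs truth
    true_arms = [
        (lid, ev["chrom"], ev["arm"], "3n" if ev["state"] == "gain" else "1n")
        for lid, les in lesions.items() for ev in les["arm_events"]
    ]
    called_arms = {(r["lesion"], r["chrom"], r["arm"], r["state"]) for r in arm_rows}
    arm_found = sum(1 for t in true_arms if t in called_arms)

    # CN-LOH recovery vs truth
    cnloh_total = cnloh_found = 0
    cnloh_eligible_total = cnloh_eligible_found = 0
    false_cnloh = 0
    for lid, les in lesions.items():
        second = les["second_hit"]
        has_true = second is not None and second["kind"] == "cn_loh"
        det = [s for s in segments_by_lesion[lid] if s.state == "cn_loh"]
        if has_true:
            cnloh_total += 1
            found = any(
                _overlap(s, second["chrom"], second["start"], second["end"])
                for s in det
            )
            cnloh_found += found
            if les["purity"] >= 0.4:
                cnloh_eligible_total += 1
                cnloh_eligible_found += found
            false_cnloh += sum(
                1 for s in det
                if not _overlap(s, second["chrom"], second["start"], second["end"])
            )
        else:
            false_cnloh += len(det)

    # ---- origin classification + two-hit integration ---------------------
    genotypes = []
    origin_truth_pairs = []  # (true, predicted, matched, purity)
    for lid, les in lesions.items():
        pat = patients[les["patient"]]
        tumour = var[var["SAMPLE"] == lid]
        accepted = variants.filter_tsc_pathogenic(tumour)
        normal = (
            var[var["SAMPLE"] == f"{les['patient']}-N"]
            if pat["matched_normal"] else None
        )
        if normal is None:
            origins = hits.assign_origins_unmatched(
                accepted, segments_by_lesion[lid], GENE_LOCI
            )
        else:
            origins = []
            for _, call in accepted.iterrows():
                m = normal[
                    (normal["CHROM"] == call["CHROM"]) & (normal["POS"] == call["POS"])
                    & (normal["REF"] == call["REF"]) & (normal["ALT"] == call["ALT"])
                ]
                ncall = m.iloc[0] if len(m) else None
                state = _copy_state_at(
                    segments_by_lesion[lid], call["CHROM"], int(call["POS"]) - 1
                )
                origins.append(hits.classify_origin(call, ncall, state))
        accepted = accepted.assign(ORIGIN=origins)
        geno = hits.integrate_hits(
            accepted, segments_by_lesion[lid], GENE_LOCI,
            patient=les["patient"], lesion_id=lid, lesion_type=les["type"],
            eligible=les["platforms_complete"],
        )
        genotypes.append(geno)

        # truth comparison for point hits in the TSC genes
        germ = pat["germline"]
        for _, call in accepted.iterrows():
            pos0 = int(call["POS"]) - 1
            true_origin = None
            if (
                germ is not None and "pos" in germ
                and germ["chrom"] == call["CHROM"] and germ["pos"] == pos0
            ):
                true_origin = "mosaic" if germ["mosaic"] else "germline"
            second = les["second_hit"]
            if (
                second is not None and second["kind"] == "point"
                and second["chrom"] == call["CHROM"] and second["pos"] == pos0
            ):
                true_origin = "somatic"
            if true_origin is not None:
                origin_truth_pairs.append(
                    (true_origin, call["ORIGIN"], pat["matched_normal"], les["purity"])
                )
    summary = hits.summarize_cohort(genotypes)
    report["genotype_summary"] = summary
    if out is not None:
        pd.DataFrame(
            [
                {
                    "lesion": g.lesion_id, "type": g.lesion_type,
                    "n_hits": g.n_hits, "combination": g.combination,
                    "truncating": g.truncating,
                    "hits": ";".join(f"{h['gene']}:{h['class']}:{h['origin']}"
                                     for h in g.hits),
                }
                for g in genotypes
            ]
        ).to_csv(out / "genotypes.tsv", sep="\t", index=False)

    def _origin_accuracy(matched: bool, min_purity: float = 0.0):
        rel = [
            t for t in origin_truth_pairs if t[2] == matched and t[3] >= min_purity
        ]
        if not matched:
            # a mosaic allele in an unmatched tumour sits at VAF ~ p/2 and is
            # indistinguishable from a somatic hit without normal tissue;
            # mosaics enter the matched stratum only
            rel = [t for t in rel if t[0] != "mosaic"]
        if not rel:
            return None
        strip = lambda o: o.replace("predicted_", "")
        side = lambda o: "germline" if strip(o) in ("germline", "mosaic") else "somatic"
        if matched:
            good = sum(1 for t in rel if t[1] == t[0])
        else:
            good = sum(1 for t in rel if side(t[1]) == side(t[0]))
        return {"n": len(rel), "accuracy_pct": 100.0 * good / len(rel)}

    report["recovery"] = {
        "cnloh_sensitivity_pct": (
            100.0 * cnloh_found / cnloh_total if cnloh_total else None
        ),
        "cnloh_sensitivity_purity_ge_0.4_pct": (
            100.0 * cnloh_eligible_found / cnloh_eligible_total
            if cnloh_eligible_total else None
        ),
        "cnloh_false_calls": false_cnloh,
        "arm_events_recovered": f"{arm_found}/{len(true_arms)}",
        "origin_matched": _origin_accuracy(True),
        "origin_unmatched": _origin_accuracy(False),
        "origin_unmatched_purity_ge_0.5": _origin_accuracy(False, 0.5),
    }

    # ---- expression: TMM + moderated DE ----------------------------------
    counts = expression.filter_low_counts(bundle.counts)
    _, logcpm = expression.normalize_logcpm(counts)
    sample_group = {}
    for lid, les in lesions.items():
        sample_group[lid] = les["type"]
    for col in bundle.counts.columns:
        if col.startswith("NK"):
            sample_group[col] = "NORMAL_KIDNEY"
        elif col.startswith("NB"):
            sample_group[col] = "NORMAL_BRAIN"
    de_results = {}
    contrasts = [
        ("RA", "NORMAL_KIDNEY"), ("SEN_SEGA", "NORMAL_BRAIN"), ("TUB", "NORMAL_BRAIN")
    ]
    for lesion_type, normal_group in contrasts:
        cols = [c for c in logcpm.columns
                if sample_group[c] in (lesion_type, normal_group)]
        labels = [sample_group[c] for c in cols]
        if labels.count(lesion_type) < 3 or labels.count(normal_group) < 3:
            continue
        res = expression.moderated_de(
            logcpm[cols], labels, group_a=normal_group, group_b=lesion_type
        )
        de_results[lesion_type] = res
    report["deg_counts"] = {k: int(v.table["deg"].sum()) for k, v in de_results.items()}
    if "TUB" in de_results and "SEN_SEGA" in de_results:
        report["deg_overlap_tub_sega"] = expression.deg_overlap(
            de_results["TUB"].table, de_results["SEN_SEGA"].table
        )

    # grouped TSC2-transcript test across genotype groups
    trunc_truth = {
        lid: true_truncating_count(patients[les["patient"]], les)
        for lid, les in lesions.items()
    }
    if "TSC2" in logcpm.index:
        vals, labs = [], []
        for col in logcpm.columns:
            if col in lesions:
                pat = patients[lesions[col]["patient"]]
                if pat["gene"] == "TSC2":
                    labs.append(f"TSC2_trunc_{trunc_truth[col]}")
                else:
                    labs.append("NMI_or_TSC1")
            else:
                labs.append("non_TSC")
            vals.append(logcpm.loc["TSC2", col])
        try:
            results, bart, bart_p = hits.grouped_expression_test(
                np.asarray(vals), np.asarray(labs)
            )
            report["tsc2_group_tests"] = {
                "bartlett": bart, "bartlett_p": bart_p,
                "pairs": [
                    {"a": r.group_a, "b": r.group_b, "t": r.t, "df": r.df,
                     "p": r.p, "p_adj": r.p_adj}
                    for r in results
                ],
            }
        except ValueError as exc:
            logger.info("grouped TSC2 test skipped: %s", exc)

    # ---- methylation ------------------------------------------------------
    normal_cols = [c for c in bundle.betas.columns if c.startswith(("NK", "NB"))]
    panel = bundle.betas[normal_cols]
    hyper = {}
    for lid in lesions:
        try:
            hyper[lid] = methylation.hypermethylation_fraction(
                bundle.betas[lid], panel
            )
        except ValueError:
            hyper[lid] = None
    by_type: dict[str, list[float]] = {}
    for lid, frac in hyper.items():
        if frac is not None:
            by_type.setdefault(lesions[lid]["type"], []).append(frac)
    report["hypermethylation_fraction"] = {
        t: {"median": float(np.median(v)), "n": len(v)} for t, v in by_type.items()
    }

    ra_cols = [lid for lid, les in lesions.items() if les["type"] == "RA"]
    nk_cols = [c for c in bundle.betas.columns if c.startswith("NK")]
    chi2_block = None
    if len(ra_cols) >= 3 and len(nk_cols) >= 3:
        probe_table, hyper_genes = methylation.select_specific_probes(
            bundle.betas[ra_cols], bundle.betas[nk_cols], bundle.probe_genes
        )
        report["ra_specific_probes"] = {
            "n_probes": int(len(probe_table)), "n_genes": len(hyper_genes),
        }
        if out is not None:
            probe_table.to_csv(out / "ra_probes.tsv", sep="\t", index=False)
        if "RA" in de_results:
            universe = [g for g in de_results["RA"].table.index]
            deg_set = set(de_results["RA"].degs)
            hyper_set = set(hyper_genes) & set(universe)
            a = len(hyper_set & deg_set)
            b = len(hyper_set - deg_set)
            c = len(deg_set - hyper_set)
            d = len(universe) - a - b - c
            try:
                chi2, dof, p = methylation.association_chi2(
                    methylation.ContingencyTable2x2(a, b, c, d)
                )
                chi2_block = {"table": [a, b, c, d], "chi2": chi2, "df": dof, "p": p}
            except ValueError as exc:
                chi2_block = {"table": [a, b, c, d], "error": str(exc)}
    report["methylation_expression_association"] = chi2_block

    # ---- deconvolution ----------------------------------------------------
    signature = deconvolution.build_signature(
        bundle.reference_counts, k_markers=config.n_markers_per_type
    )
    mixtures = bundle.counts / bundle.counts.sum(axis=0) * 1e6
    estimates = deconvolution.estimate_fractions(
        mixtures, signature, n_perm=n_perm, seed=config.seed + 1
    )
    frac_df = deconvolution.fractions_frame(estimates)
    if out is not None:
        frac_df.to_csv(out / "fractions.tsv", sep="\t", index_label="sample")
    # truth recovery
    errs = []
    for est in estimates:
        true = np.asarray(truth.fractions[est.sample])
        errs.append(np.abs(est.fractions.to_numpy() - true))
    errs = np.asarray(errs)
    sega_cols = [lid for lid, les in lesions.items() if les["type"] == "SEN_SEGA"]
    nb_cols = [c for c in bundle.counts.columns if c.startswith("NB")]
    enrich = None
    if len(sega_cols) >= 3 and len(nb_cols) >= 3:
        fr = frac_df.loc[sega_cols + nb_cols, list(signature.columns)]
        groups = ["SEN_SEGA"] * len(sega_cols) + ["NORMAL_BRAIN"] * len(nb_cols)
        enrich_table = deconvolution.group_enrichment(
            fr, groups, "SEN_SEGA", "NORMAL_BRAIN"
        )
        enrich = enrich_table.to_dict(orient="records")
        if out is not None:
            enrich_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    report["deconvolution"] = {
        "fraction_mae": float(errs.mean()),
        "fraction_rmse": float(np.sqrt((errs**2).mean())),
        "sega_leukocyte_mean_pct": (
            100.0 * float(frac_df.loc[sega_cols, "leukocyte"].mean())
            if sega_cols else None
        ),
        "tub_leukocyte_mean_pct": (
            100.0
            * float(
                frac_df.loc[
                    [l for l, les in lesions.items() if les["type"] == "TUB"],
                    "leukocyte",
                ].mean()
            )
            if any(les["type"] == "TUB" for les in lesions.values()) else None
        ),
        "enrichment_sega_vs_brain": enrich,
    }

    report = _jsonable(report)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
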