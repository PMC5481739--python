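"""Differential expression: TMM + log-CPM, moderated t, DEG overlaps.

Normalizes the cohort count matrix, tests each lesion type against its
normal-tissue counterpart (RA vs kidney, tubers and SEN/SEGA vs brain)
at the |log2FC| > 2, FDR < 0.001 definition, and reports the directional
overlap between the two brain-lesion DEG sets.  Writes
results/degs_<type>.tsv and results/tmm_factors.tsv.

Run after 01:  python analysis/06_expression_de.py
"""

from pathlib import Path

from tscpipe.config import read_config
from tscpipe.expression import (
    deg_overlap,
    filter_low_counts,
    moderated_de,
    normalize_logcpm,
)
from tscpipe.simulate import generate_cohort

OUT = Path("results")

CONTRASTS = [("RA", "NK"), ("TUB", "NB"), ("SEN_SEGA", "NB")]


def main() -> None:
    cfg = read_config(OUT / "cohort" / "config.txt")
    truth, bundle = generate_cohort(cfg)
    group = {l["lesion_id"]: l["type"] for l in truth.lesions}
    for c in bundle.counts.columns:
        if c.startswith("NK"):
            group[c] = "NK"
        elif c.startswith("NB"):
            group[c] = "NB"

    counts = filter_low_counts(bundle.counts)
    factors, logcpm = normalize_logcpm(counts)
    factors.to_csv(OUT / "tmm_factors.tsv", sep="\t", index_label="sample")
    print(f"{counts.shape[0]} genes after the CPM>1-in->=3-samples filter; "
          f"TMM factors in [{factors.min():.3f}, {factors.max():.3f}]")

    results = {}
    for lesion_type, normal_type in CONTRASTS:
        cols = [c for c in logcpm.columns if group[c] in (lesion_type, normal_type)]
        labels = [group[c] for c in cols]
        res = moderated_de(logcpm[cols], labels,
                           group_a=normal_type, group_b=lesion_type)
        results[lesion_type] = res
        res.table.to_csv(OUT / f"degs_{lesion_type}.tsv", sep="\t",
                         index_label="gene")
        up = int((res.table["deg"] & (res.table["log2fc"] > 0)).sum())
        down = int((res.table["deg"] & (res.table["log2fc"] < 0)).sum())
        print(f"{lesion_type} vs {normal_type}: {up + down} DEGs "
              f"({up} up, {down} down); d0={res.d0:.1f}")

    overlap = deg_overlap(results["TUB"].table, results["SEN_SEGA"].table)
    print("TUB / SEN_SEGA DEG overlap:", overlap)


if __name__ == "__main__":
    main()
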