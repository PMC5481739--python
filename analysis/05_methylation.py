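"""Methylation: hypermethylation fractions, RA-specific probes, chi-square.

Computes the per-lesion hypermethylation fraction against the normal
panel, selects probes with enriched methylation in renal angiomyolipomas
versus normal kidney, and tests the association between hypermethylated
genes and RA differential expression with the uncorrected 2x2 chi-square.
Writes results/hypermethylation.tsv and results/ra_probes.tsv.

Run after 06 if you want the chi-square against actual DEGs (it falls
back to the expression stage internally otherwise):
python analysis/05_methylation.py
"""

from pathlib import Path

import pandas as pd

from tscpipe.config import read_config
from tscpipe.expression import filter_low_counts, moderated_de, normalize_logcpm
from tscpipe.methylation import (
    ContingencyTable2x2,
    association_chi2,
    hypermethylation_fraction,
    select_specific_probes,
)
from tscpipe.simulate import generate_cohort

OUT = Path("results")


def main() -> None:
    cfg = read_config(OUT / "cohort" / "config.txt")
    truth, bundle = generate_cohort(cfg)
    lesions = {l["lesion_id"]: l for l in truth.lesions}
    panel_cols = [c for c in bundle.betas.columns if c.startswith(("NK", "NB"))]
    panel = bundle.betas[panel_cols]

    rows = []
    for lid, les in lesions.items():
        frac = hypermethylation_fraction(bundle.betas[lid], panel)
        rows.append({"lesion": lid, "type": les["type"],
                     "hypermethylation_fraction": frac})
    hyper = pd.DataFrame(rows)
    hyper.to_csv(OUT / "hypermethylation.tsv", sep="\t", index=False)
    med = hyper.groupby("type")["hypermethylation_fraction"].median()
    print("median hypermethylation fraction by lesion type:")
    print(med.round(3).to_string())

    ra_cols = [lid for lid, l in lesions.items() if l["type"] == "RA"]
    nk_cols = [c for c in bundle.betas.columns if c.startswith("NK")]
    table, genes = select_specific_probes(
        bundle.betas[ra_cols], bundle.betas[nk_cols], bundle.probe_genes
    )
    table.to_csv(OUT / "ra_probes.tsv", sep="\t", index=False)
    spiked = set(truth.meth["spike_sets"]["RA"])
    print(f"RA-specific probes: {len(table)} (simulated: {len(spiked)}), "
          f"mapping to {len(genes)} genes; "
          f"{len(set(table['probe']) & spiked)} overlap truth")

    # association between hypermethylated genes and RA DEGs
    counts = filter_low_counts(bundle.counts)
    _, logcpm = normalize_logcpm(counts)
    cols = ra_cols + nk_cols
    res = moderated_de(logcpm[cols],
                       ["RA"] * len(ra_cols) + ["NK"] * len(nk_cols),
                       group_a="NK", group_b="RA")
    universe = set(res.table.index)
    deg = set(res.degs)
    hyper_genes = set(genes) & universe
    a = len(hyper_genes & deg)
    b = len(hyper_genes - deg)
    c = len(deg - hyper_genes)
    d = len(universe) - a - b - c
    chi2, df, p = association_chi2(ContingencyTable2x2(a, b, c, d))
    print(f"2x2 table (a,b,c,d) = ({a}, {b}, {c}, {d}); "
          f"chi2(1, n={a+b+c+d}) = {chi2:.3f}, p = {p:.3g}")


if __name__ == "__main__":
    main()
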