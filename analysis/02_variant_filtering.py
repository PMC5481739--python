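"""Variant filtering and somatic mutation burden.

Applies the pathogenic TSC1/TSC2 acceptance rules to every lesion, runs
the stringent somatic SNV/INDEL filters against each matched normal, and
computes mutations per callable megabase per pair.  Writes
results/accepted_tsc.tsv, results/somatic.tsv and results/rates.tsv and
prints the cohort median (the generator is calibrated to 0.31/Mb).

Run after 01:  python analysis/02_variant_filtering.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tscpipe.config import read_config
from tscpipe.simulate import generate_cohort
from tscpipe.variants import (
    CallableSummary,
    filter_somatic,
    filter_tsc_pathogenic,
    mutation_rate,
)

OUT = Path("results")


def main() -> None:
    cfg = read_config(OUT / "cohort" / "config.txt")
    truth, bundle = generate_cohort(cfg)
    var = bundle.variants

    accepted = filter_tsc_pathogenic(var)
    accepted.to_csv(OUT / "accepted_tsc.tsv", sep="\t", index=False)

    somatic_frames, rows = [], []
    vafs = []
    for les in truth.lesions:
        pat = les["patient"]
        normal = var[var["SAMPLE"] == f"{pat}-N"]
        if len(normal) == 0:
            continue
        tumour = var[var["SAMPLE"] == les["lesion_id"]]
        som = filter_somatic(tumour, normal)
        som = som[~som["ALT"].astype(str).str.startswith("<")]
        somatic_frames.append(som)
        rate = mutation_rate(som, CallableSummary(
            les["lesion_id"], truth.callable_bases[les["lesion_id"]]
        ))
        rows.append({"tumour": les["lesion_id"], "normal": f"{pat}-N",
                     "n_somatic": len(som),
                     "callable_mb": truth.callable_bases[les["lesion_id"]] / 1e6,
                     "rate_per_mb": rate})
        vafs.extend((som["AD_ALT"] / som["DP"]).tolist())

    pd.concat(somatic_frames).to_csv(OUT / "somatic.tsv", sep="\t", index=False)
    rates = pd.DataFrame(rows)
    rates.to_csv(OUT / "rates.tsv", sep="\t", index=False)
    print(f"accepted TSC calls: {len(accepted)}")
    print(f"matched pairs: {len(rates)}")
    print(f"median somatic mutation rate: {rates['rate_per_mb'].median():.3f} /Mb "
          f"(range {rates['rate_per_mb'].min():.2f}-{rates['rate_per_mb'].max():.2f})")
    print(f"median somatic VAF: {np.median(vafs):.3f}")


if __name__ == "__main__":
    main()
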