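"""Simulate the study cohort: 66 patients, one lesion each.

Generates the full synthetic bundle — paired tumour/normal variant table,
SNP-array BAF/LRR tracks, methylation betas, expression counts and the
reference cell-type profiles — and writes everything except the (large)
per-sample tracks under results/cohort/.  Every later analysis script
reads the config written here and regenerates the cohort deterministically,
so the tracks never need to sit on disk.

Run:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

from tscpipe.config import CohortConfig
from tscpipe.io import write_bundle
from tscpipe.simulate import generate_cohort

OUT = Path("results/cohort")
SEED = 17


def main() -> None:
    cfg = CohortConfig(n_patients=66, seed=SEED)
    truth, bundle = generate_cohort(cfg)
    paths = write_bundle(bundle, truth, cfg, OUT, write_tracks=False)
    n_gene = sum(1 for p in truth.patients if p["gene"])
    n_second = sum(1 for l in truth.lesions if l["second_hit"])
    print(f"cohort: {cfg.n_patients} patients, {n_gene} with a germline TSC hit, "
          f"{n_second} lesions with a second hit")
    print(f"variant table: {len(bundle.variants)} rows; "
          f"counts: {bundle.counts.shape[0]} genes x {bundle.counts.shape[1]} samples")
    for key, path in paths.items():
        print(f"  {key}: {path}")


if __name__ == "__main__":
    main()
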