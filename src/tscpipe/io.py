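"""File interfaces: the simulated bundle on disk, SEG and BED writers.

Everything is plain text — TSV tables, SEG/BED intervals, JSON truth —
so a cohort written by ``tscpipe simulate`` can be consumed by the other
subcommands exactly as real-data inputs would be.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .cna import CopySegment
from .config import CohortConfig, write_config
from .simulate import AllelicTrack, CohortBundle, CohortTruth

logger = logging.getLogger(__name__)

__all__ = [
    "write_bundle",
    "read_variants",
    "read_track",
    "read_matrix",
    "write_seg",
    "read_seg",
    "write_bed",
    "load_truth",
]

TRACK_COLUMNS = ["chrom", "pos", "baf", "lrr", "genotype"]


def write_bundle(
    bundle: CohortBundle,
    truth: CohortTruth,
    config: CohortConfig,
    outdir: str | Path,
    write_tracks: bool = True,
) -> dict[str, str]:
    """Write every simulated layer under ``outdir``; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _log(key: str, path: Path) -> None:
        paths[key] = str(path)
        logger.info("wrote %s -> %s", key, path)

    p = out / "variants.tsv"
    bundle.variants.to_csv(p, sep="\t", index=False)
    _log("variants", p)

    if write_tracks:
        tdir = out / "tracks"
        tdir.mkdir(exist_ok=True)
        for sample, chrom_tracks in bundle.tracks.items():
            frames = [t.to_frame() for t in chrom_tracks.values()]
            tp = tdir / f"{sample}.tsv"
            pd.concat(frames).to_csv(tp, sep="\t", index=False)
        _log("tracks_dir", tdir)

    for key, df in (("betas", bundle.betas), ("counts", bundle.counts)):
        p = out / f"{key}.tsv"
        df.to_csv(p, sep="\t", index_label="id")
        _log(key, p)

    rdir = out / "reference_counts"
    rdir.mkdir(exist_ok=True)
    for ctype, df in bundle.reference_counts.items():
        df.to_csv(rdir / f"{ctype}.tsv", sep="\t", index_label="gene")
    _log("reference_counts_dir", rdir)

    p = out / "truth.json"
    p.write_text(json.dumps(truth.to_json_dict(), indent=1))
    _log("truth", p)

    p = out / "config.txt"
    write_config(config, p)
    _log("config", p)

    p = out / "probe_genes.tsv"
    pd.DataFrame(
        [(probe, ";".join(genes)) for probe, genes in bundle.probe_genes.items()],
        columns=["probe", "genes"],
    ).to_csv(p, sep="\t", index=False)
    _log("probe_genes", p)
    return paths


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    for col in ("POS", "DP", "AD_REF", "AD_ALT"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df


def read_track(path: str | Path) -> dict[str, AllelicTrack]:
    """Read a per-sample track TSV into one AllelicTrack per chromosome."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: track file missing columns {missing}")
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        out[str(chrom)] = AllelicTrack(
            str(chrom),
            sub["pos"].to_numpy(),
            sub["baf"].to_numpy(dtype=float),
            sub["lrr"].to_numpy(dtype=float),
            sub["genotype"].to_numpy(dtype=object),
        )
    return out


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_seg(
    segments: list[CopySegment], sample: str, path: str | Path, append: bool = False
) -> None:
    """SEG-format output (sample, chrom, start, end, n_probes, mean LRR)
    plus mBAF and state columns."""
    df = pd.DataFrame(
        [
            {
                "sample": sample,
                "chrom": s.chromosome,
                "start": s.start,
                "end": s.end,
                "n_probes": s.n_probes,
                "mean_lrr": s.mean_lrr,
                "mean_mbaf": s.mean_mbaf,
                "state": s.state,
            }
            for s in segments
        ]
    )
    mode = "a" if append and Path(path).exists() else "w"
    df.to_csv(path, sep="\t", index=False, mode=mode, header=mode == "w")


def read_seg(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def seg_to_segments(df: pd.DataFrame) -> list[CopySegment]:
    return [
        CopySegment(
            chromosome=row.chrom,
            start=int(row.start),
            end=int(row.end),
            n_probes=int(row.n_probes),
            mean_lrr=float(row.mean_lrr),
            mean_mbaf=float(row.mean_mbaf),
            state=getattr(row, "state", "normal"),
        )
        for row in df.itertuples()
    ]


def write_bed(intervals: list[tuple[str, int, int, str]], path: str | Path) -> None:
    """BED (0-based half-open) with the 4th column carrying the name/state."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def load_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
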