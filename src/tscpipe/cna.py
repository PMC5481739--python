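"""Copy-number and copy-neutral-LOH calling from SNP-array allelic tracks.

A CN-LOH region is one where B-allele frequencies diverge from the
heterozygous 0.5 while the log-R ratio stays flat; a deletion depresses
LRR; a gain raises it.  Segmentation is binary segmentation with a
BIC-style penalty, minimizing a penalized least-squares cost jointly on
LRR (all probes) and mirrored BAF (probes heterozygous in the matched
normal) — a deliberately simple equivalent of the SNP-array tool chains
(tangent normalization / ASCAT / genoCN) used on real arrays.

Arm-level events follow the "longest run over half the arm" rule: an arm
is reported gained (3n) or lost (1n) iff the longest merged run of
same-state non-normal segments covers more than 50% of the arm's length.

Deletion fine-mapping scans a binned targeted read-depth profile against
a normal-panel median for the longest contiguous run of bins at a depth
ratio consistent with heterozygous loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ARMS
from .simulate import AllelicTrack, expected_allelic_signal

__all__ = [
    "CopySegment",
    "CoordinateError",
    "default_arm_table",
    "mirrored_baf",
    "segment_track",
    "classify_segment",
    "classify_segments",
    "call_arm_events",
    "fine_map_deletion",
    "estimate_purity",
]

logger = logging.getLogger(__name__)


class CoordinateError(ValueError):
    """A segment falls outside every arm of the arm table."""


@dataclass
class CopySegment:
    """Contiguous probe interval with its mean allelic signals and state."""

    chromosome: str
    start: int  # bp, 0-based half-open
    end: int
    n_probes: int
    mean_lrr: float
    mean_mbaf: float  # NaN when the segment has no heterozygous probes
    state: str = "normal"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def mirrored_baf(baf: np.ndarray) -> np.ndarray:
    """Fold BAF onto [0.5, 1]: mBAF = |BAF - 0.5| + 0.5."""
    return np.abs(np.asarray(baf, dtype=float) - 0.5) + 0.5


def default_arm_table() -> pd.DataFrame:
    rows = [
        {"chrom": c, "arm": a, "start": s, "end": e}
        for (c, a), (s, e) in ARMS.items()
    ]
    return pd.DataFrame(rows)


def _robust_var(x: np.ndarray) -> float:
    """Noise variance from median absolute successive differences."""
    x = x[np.isfinite(x)]
    if len(x) < 3:
        return 1.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / 0.6745 / math.sqrt(2.0)
    return max(sigma**2, 1e-8)


class _ChannelCost:
    """O(1) segment SSE via cumulative sums, with a per-probe validity mask."""

    def __init__(self, values: np.ndarray, mask: np.ndarray, var: float):
        v = np.where(mask, values, 0.0)
        self.cs = np.concatenate([[0.0], np.cumsum(v)])
        self.cs2 = np.concatenate([[0.0], np.cumsum(v * v)])
        self.cn = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])
        self.var = var

    def sse(self, i, j):
        n = self.cn[j] - self.cn[i]
        s = self.cs[j] - self.cs[i]
        s2 = self.cs2[j] - self.cs2[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = s2 - np.where(n > 0, s * s / np.maximum(n, 1), 0.0)
        return np.maximum(out, 0.0) / self.var


def segment_track(
    track: AllelicTrack, penalty: float = 12.0, min_probes: int = 10
) -> list[CopySegment]:
    """Binary segmentation of one chromosome's (LRR, mBAF) track.

    A split is accepted when its normalized SSE reduction exceeds
    ``penalty * log(n)`` — a BIC-style cost for the extra changepoint.
    Deterministic for fixed input.  Tracks shorter than ``2 * min_probes``
    are returned as a single segment with a warning.
    """
    n = len(track)
    lrr_cost = _ChannelCost(
        track.lrr, np.isfinite(track.lrr), _robust_var(track.lrr)
    )
    het = track.het_mask
    mbaf = mirrored_baf(track.baf)
    mbaf_cost = _ChannelCost(
        mbaf, het & np.isfinite(mbaf), _robust_var(mbaf[het]) if het.sum() >= 3 else 1.0
    )
    threshold = penalty * math.log(max(n, 2))

    def cost(i, j):
        return lrr_cost.sse(i, j) + mbaf_cost.sse(i, j)

    breakpoints: list[int] = []
    if n < 2 * min_probes:
        logger.warning(
            "track %s has %d probes (< 2*min_probes=%d): returning one segment",
            track.chromosome, n, 2 * min_probes,
        )
    else:
        stack = [(0, n)]
        while stack:
            i, j = stack.pop()
            if j - i < 2 * min_probes:
                continue
            ks = np.arange(i + min_probes, j - min_probes + 1)
            gain = cost(i, j) - cost(i, ks) - cost(ks, j)
            k_best = int(ks[np.argmax(gain)])
            if float(np.max(gain)) > threshold:
                breakpoints.append(k_best)
                stack.append((i, k_best))
                stack.append((k_best, j))
        breakpoints.sort()

    bounds = [0, *breakpoints, n]
    segments = []
    for i, j in zip(bounds[:-1], bounds[1:]):
        seg_het = het[i:j]
        seg_mbaf = mbaf[i:j][seg_het]
        segments.append(
            CopySegment(
                chromosome=track.chromosome,
                start=int(track.positions[i]),
                end=int(track.positions[j - 1]) + 1,
                n_probes=j - i,
                mean_lrr=float(np.mean(track.lrr[i:j])),
                mean_mbaf=float(np.mean(seg_mbaf)) if len(seg_mbaf) else float("nan"),
            )
        )
    return segments


@dataclass(frozen=True)
class ClassifyThresholds:
    baf_dev: float = 0.10     # mBAF divergence above 0.5 declaring LOH
    lrr_stable: float = 0.10  # |LRR| bound for "copy numbers remain stable"
    lrr_event: float = 0.15   # |LRR| threshold for deletion/gain


def classify_segment(
    seg: CopySegment, thresholds: ClassifyThresholds = ClassifyThresholds()
) -> str:
    """State call for one segment.

    CN-LOH: diverged mBAF with stable LRR.  Deletion: depressed LRR with
    at least mildly elevated mBAF (half the LOH divergence; segments
    without heterozygous probes rely on LRR alone).  Gain: elevated LRR.
    """
    t = thresholds
    has_mbaf = math.isfinite(seg.mean_mbaf)
    mbaf_elevated = (not has_mbaf) or seg.mean_mbaf >= 0.5 + t.baf_dev / 2.0
    if seg.mean_lrr <= -t.lrr_event and mbaf_elevated:
        return "deletion"
    if seg.mean_lrr >= t.lrr_event:
        return "gain"
    if (
        has_mbaf
        and seg.mean_mbaf >= 0.5 + t.baf_dev
        and abs(seg.mean_lrr) <= t.lrr_stable
    ):
        return "cn_loh"
    return "normal"


def classify_segments(
    segments: list[CopySegment],
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> list[CopySegment]:
    return [replace(s, state=classify_segment(s, thresholds)) for s in segments]


_STATE_TO_PLOIDY = {"gain": "3n", "deletion": "1n"}


def call_arm_events(
    segments: list[CopySegment], arms: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Arm-level gain/loss calls from classified segments.

    Within each arm, adjacent same-state segments are merged; the arm is
    reported gained (3n) or lost (1n) iff the longest merged non-normal
    run covers more than 50% of the arm's length.
    """
    if arms is None:
        arms = default_arm_table()
    arm_chroms = set(arms["chrom"])
    for seg in segments:
        if seg.chromosome not in arm_chroms:
            raise CoordinateError(
                f"segment {seg.chromosome}:{seg.start}-{seg.end} outside the arm table"
            )
    calls = []
    for arm in arms.itertuples():
        overlapping = sorted(
            (s for s in segments
             if s.chromosome == arm.chrom and s.start < arm.end and s.end > arm.start),
            key=lambda s: s.start,
        )
        best: dict[str, int] = {}
        run_state, run_len = None, 0
        for seg in overlapping:
            clipped = min(seg.end, arm.end) - max(seg.start, arm.start)
            if seg.state == run_state:
                run_len += clipped
            else:
                run_state, run_len = seg.state, clipped
            if run_state in _STATE_TO_PLOIDY:
                best[run_state] = max(best.get(run_state, 0), run_len)
        arm_len = arm.end - arm.start
        for state, covered in best.items():
            if covered > 0.5 * arm_len:
                calls.append(
                    {
                        "chrom": arm.chrom,
                        "arm": arm.arm,
                        "state": _STATE_TO_PLOIDY[state],
                        "covered_fraction": covered / arm_len,
                    }
                )
    return pd.DataFrame(calls, columns=["chrom", "arm", "state", "covered_fraction"])


def fine_map_deletion(
    sample_depth: np.ndarray,
    panel_median_depth: np.ndarray,
    bin_edges: np.ndarray | None = None,
    ratio_threshold: float = 0.65,
    min_span: int = 3,
) -> tuple[int, int] | None:
    """Breakpoint interval of the longest depleted run in a binned profile.

    Bins where the panel median is zero are masked (and logged) and break
    runs.  Returns the outer boundaries of the longest contiguous run of
    bins with sample/panel ratio <= ``ratio_threshold`` spanning at least
    ``min_span`` bins, in ``bin_edges`` units (bin indices if no edges are
    given), or ``None``.
    """
    sample = np.asarray(sample_depth, dtype=float)
    panel = np.asarray(panel_median_depth, dtype=float)
    if sample.shape != panel.shape:
        raise ValueError("sample and panel profiles must be binned identically")
    n = len(sample)
    if bin_edges is None:
        bin_edges = np.arange(n + 1)
    masked = panel <= 0
    if masked.any():
        logger.warning("fine_map_deletion: masking %d zero-coverage panel bins",
                       int(masked.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(masked, np.inf, sample / np.where(masked, 1.0, panel))
    low = ratio <= ratio_threshold
    best_len, best_start = 0, -1
    run_start = None
    for i, flag in enumerate([*low, False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < min_span:
        return None
    return int(bin_edges[best_start]), int(bin_edges[best_start + best_len])


_PURITY_STATES = ((1, 0), (2, 0), (2, 1))


def estimate_purity(segments: list[CopySegment]) -> float | None:
    """Grid-search purity (step 0.01) from the largest aberrant segment.

    Minimizes the squared distance between the segment's observed
    (mBAF, LRR) and the expectation for candidate states (1,0), (2,0),
    (2,1); returns None when no aberrant segment with heterozygous probes
    exists.
    """
    candidates = [
        s for s in segments
        if s.state not in ("normal",) and math.isfinite(s.mean_mbaf)
    ]
    if not candidates:
        return None
    seg = max(candidates, key=lambda s: s.n_probes)
    grid = np.arange(0.01, 1.0 + 1e-9, 0.01)
    best_p, best_err = None, math.inf
    for p in grid:
        for state in _PURITY_STATES:
            (b1, b2), lrr = expected_allelic_signal(state, float(p))
            mbaf_exp = max(b1, b2)
            err = (seg.mean_mbaf - mbaf_exp) ** 2 + (seg.mean_lrr - lrr) ** 2
            if err < best_err:
                best_err, best_p = err, float(p)
    return round(best_p, 2)
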