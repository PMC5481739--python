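"""Cohort configuration and the toy genome the simulator lives on.

The simulator does not model the real human genome: it uses a compact
three-chromosome genome carrying a TSC1-like locus on the long arm of
"chr9" and a TSC2-like locus on the short arm of "chr16", plus a neutral
autosome ("chr10") used for arm-level gain/loss events.  Coordinates are
0-based half-open everywhere inside the package; 1-based positions appear
only in the VCF-dialect variant table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

__all__ = [
    "CohortConfig",
    "ConfigError",
    "GENOME",
    "ARMS",
    "GENE_LOCI",
    "LESION_TYPES",
    "CELL_TYPES",
    "read_config",
    "write_config",
]


class ConfigError(ValueError):
    """Raised when a configuration field violates its invariants."""


#: chromosome -> length (bp) of the simulated genome
GENOME: dict[str, int] = {"chr9": 26_000_000, "chr16": 30_000_000, "chr10": 30_000_000}

#: (chrom, arm) -> (start, end) 0-based half-open
ARMS: dict[tuple[str, str], tuple[int, int]] = {
    ("chr9", "p"): (0, 10_000_000),
    ("chr9", "q"): (10_000_000, 26_000_000),
    ("chr16", "p"): (0, 12_000_000),
    ("chr16", "q"): (12_000_000, 30_000_000),
    ("chr10", "p"): (0, 14_000_000),
    ("chr10", "q"): (14_000_000, 30_000_000),
}

#: gene -> (chrom, start, end); TSC2 sits on 16p near the telomere, TSC1 on 9q
GENE_LOCI: dict[str, tuple[str, int, int]] = {
    "TSC1": ("chr9", 20_000_000, 20_053_000),
    "TSC2": ("chr16", 2_050_000, 2_090_000),
}

LESION_TYPES = ("RA", "TUB", "SEN_SEGA", "CRM", "SK")

#: mutation classes that truncate or remove the transcript
TRUNCATING_CLASSES = frozenset(
    {"nonsense", "frameshift", "splicing", "large_deletion"}
)

#: reference cell types used for the expression mixtures / deconvolution layer
CELL_TYPES = (
    "adipose",
    "smooth_muscle",
    "vessel",
    "fetal_kidney",
    "adult_kidney",
    "leukocyte",
    "neuron",
    "astrocyte",
)

#: mean cell-type fraction per sample group (rows sum to 1); the leukocyte
#: levels encode the neuroinflammation contrast: ~12% in SEN/SEGA vs ~1% in
#: cortical tubers and normal brain.
MIXTURE_MEANS: dict[str, tuple[float, ...]] = {
    # adipose, smooth, vessel, fetal_k, adult_k, leuk, neuron, astro
    "RA":       (0.25, 0.30, 0.15, 0.08, 0.10, 0.10, 0.01, 0.01),
    "TUB":      (0.01, 0.01, 0.04, 0.01, 0.01, 0.01, 0.46, 0.45),
    "SEN_SEGA": (0.01, 0.02, 0.07, 0.03, 0.02, 0.123, 0.337, 0.39),
    "CRM":      (0.05, 0.60, 0.15, 0.05, 0.05, 0.04, 0.03, 0.03),
    "SK":       (0.15, 0.40, 0.20, 0.05, 0.05, 0.09, 0.03, 0.03),
    "NORMAL_KIDNEY": (0.03, 0.05, 0.10, 0.02, 0.76, 0.01, 0.015, 0.015),
    "NORMAL_BRAIN":  (0.005, 0.005, 0.03, 0.005, 0.005, 0.01, 0.47, 0.47),
}

_PROPORTION_FIELDS = ("gene_split", "lesion_mix", "second_hit_class_weights")


@dataclass
class CohortConfig:
    """Parameters of the simulated TSC-like cohort.

    Defaults reproduce the published cohort structure: 84.9% of patients
    carry a TSC2 germline mutation, 12.1% TSC1 and 3% none; second hits
    occur in 35% of cortical tubers and roughly two thirds of the other
    lesion types; large deletions have a log-normal size distribution with
    median 48.6 kb truncated to [462 bp, 4.8 Mb]; the background somatic
    rate is 0.31 mutations per callable megabase.
    """

    n_patients: int = 66
    gene_split: dict[str, float] = field(
        default_factory=lambda: {"TSC2": 0.849, "TSC1": 0.121, "none": 0.030}
    )
    lesion_mix: dict[str, float] = field(
        default_factory=lambda: {
            "RA": 0.30, "TUB": 0.30, "SEN_SEGA": 0.22, "CRM": 0.10, "SK": 0.08
        }
    )
    second_hit_prob: dict[str, float] = field(
        default_factory=lambda: {
            "RA": 0.67, "TUB": 0.35, "SEN_SEGA": 0.67, "CRM": 0.67, "SK": 0.67
        }
    )
    second_hit_class_weights: dict[str, float] = field(
        default_factory=lambda: {"point": 0.35, "large_deletion": 0.15, "cn_loh": 0.50}
    )
    mosaic_rate: float = 0.03
    matched_normal_prob: float = 0.6
    platform_complete_prob: float = 0.9  # all three DNA platforms usable
    purity_range: tuple[float, float] = (0.2, 0.9)
    depth_mean: float = 100.0
    targeted_depth_mean: float = 1000.0  # deep targeted assay (mosaic floor 0.5%)
    somatic_rate_per_mb: float = 0.31
    callable_mb: float = 30.0
    deletion_size_log_median: float = 48_600.0
    deletion_size_range: tuple[float, float] = (462.0, 4.8e6)
    deletion_size_log_sd: float = 1.6  # natural-log sd of the untruncated law
    arm_event_rate: float = 0.12
    probe_spacing: int = 2_000
    het_rate: float = 0.35
    baf_sd: float = 0.03
    lrr_sd: float = 0.15
    # methylation layer
    n_meth_probes: int = 2_000
    meth_unmeth_frac: float = 0.70  # fraction of probes unmethylated in normals
    meth_spike_probes: dict[str, int] = field(
        default_factory=lambda: {"RA": 240, "TUB": 60, "SEN_SEGA": 100, "CRM": 40, "SK": 40}
    )
    meth_spike_beta: float = 0.8
    # expression layer
    n_genes: int = 2_000
    n_markers_per_type: int = 40
    nb_dispersion: float = 0.1
    library_size: float = 2e6
    n_normals: int = 6  # normal panel size per tissue (kidney, brain)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _PROPORTION_FIELDS:
            props = getattr(self, name)
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} proportions sum to {total!r}, not 1")
            if any(v < 0 for v in props.values()):
                raise ConfigError(f"{name} contains a negative proportion")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError(f"purity_range {self.purity_range} not within (0, 1]")
        for name, p in (("mosaic_rate", self.mosaic_rate),
                        ("matched_normal_prob", self.matched_normal_prob),
                        ("arm_event_rate", self.arm_event_rate)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        for t, p in self.second_hit_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"second_hit_prob[{t}]={p} outside [0, 1]")
        dlo, dhi = self.deletion_size_range
        if not (0 < dlo < self.deletion_size_log_median < dhi):
            raise ConfigError("deletion_size_log_median outside deletion_size_range")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _format_value(v) -> str:
    if isinstance(v, Mapping):
        return ",".join(f"{k}:{x}" for k, x in v.items())
    if isinstance(v, (tuple, list)):
        return ",".join(str(x) for x in v)
    return str(v)


def _parse_value(raw: str, template):
    if isinstance(template, Mapping):
        out = {}
        for item in raw.split(","):
            k, _, x = item.partition(":")
            tv = next(iter(template.values()), 0.0)
            out[k.strip()] = type(tv)(float(x)) if isinstance(tv, (int, float)) else x
        return out
    if isinstance(template, tuple):
        parts = [float(x) for x in raw.split(",")]
        return tuple(type(t)(p) for t, p in zip(template, parts))
    if isinstance(template, bool):
        return raw.strip().lower() in ("1", "true", "yes")
    return type(template)(float(raw)) if isinstance(template, (int, float)) else raw


def write_config(config: CohortConfig, path: str | Path) -> None:
    """Write a flat, commented ``key = value`` config file."""
    lines = ["# tscpipe cohort configuration (flat key = value)"]
    for k, v in config.to_dict().items():
        lines.append(f"{k} = {_format_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> CohortConfig:
    """Read a flat key = value config file written by :func:`write_config`."""
    defaults = CohortConfig()
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, raw = line.partition("=")
        if not sep:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key = key.strip()
        if not hasattr(defaults, key):
            raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
        kwargs[key] = _parse_value(raw.strip(), getattr(defaults, key))
    return CohortConfig(**kwargs)
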