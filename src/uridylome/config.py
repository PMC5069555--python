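"""Pipeline configuration: documented defaults, validation, normalisation.

Every threshold the analysis depends on is surfaced here and echoed into the
run manifest so a rerun is fully determined by (config, seed). Validation is
aggregate: all problems in a config file are reported at once.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass
class TailcallConfig:
    """Alignment and tail-calling thresholds.

    trim_min_run: minimal 3'-terminal T-run removed before remapping
        ("more than three Ts" => 4).
    min_u: minimal terminal untemplated U-run for the U+ class
        ("at least 4 Us").
    min_aligned_span: shortest read prefix accepted as an alignment (nt).
    mismatch_window: one mismatch allowed per this many aligned nt.
    uniqueness_margin: best-minus-second-best score difference required to
        call a placement unique.
    max_remainder_frac: largest 3' unaligned remainder, as a fraction of the
        read, tolerated in soft mode.
    pass1_mode: "soft" (3' remainder permitted) or "strict" (exact
        end-to-end; tailed reads are forced through trimming + pass 2).
    seed_k: k-mer size of the seed index.
    """

    trim_min_run: int = 4
    min_u: int = 4
    min_aligned_span: int = 18
    mismatch_window: int = 25
    uniqueness_margin: int = 2
    max_remainder_frac: float = 0.4
    pass1_mode: str = "soft"
    seed_k: int = 12


@dataclass
class ChimeraConfig:
    min_arm: int = 12
    min_gap: int = 4
    max_gap: int = 10_000


@dataclass
class AnnotateConfig:
    trna_extension: int = 60
    downstream_window: int = 200
    min_overlap: int = 1


@dataclass
class ProfilesConfig:
    bins: int = 100
    tss_window: int = 500
    smooth: int = 5


@dataclass
class SimulateConfig:
    n_reads: int = 5000
    chimera_fraction: float = 0.02
    cut_probability: float = 0.5
    minus_strand_fraction: float = 0.0
    reference: dict[str, Any] = field(default_factory=dict)
    tail_model: dict[str, Any] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    seed: int = 0
    reads: str | None = None
    reference: str | None = None
    annotation: str | None = None
    alignments: str | None = None  # optional external SAM/BAM
    tss: str | None = None
    signal_track: str | None = None
    min_mapq: int = 20  # uniqueness floor for imported alignments
    plots: bool = False
    simulate: SimulateConfig | None = None
    tailcall: TailcallConfig = field(default_factory=TailcallConfig)
    chimera: ChimeraConfig = field(default_factory=ChimeraConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    profiles: ProfilesConfig = field(default_factory=ProfilesConfig)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_SECTIONS = {
    "tailcall": TailcallConfig,
    "chimera": ChimeraConfig,
    "annotate": AnnotateConfig,
    "profiles": ProfilesConfig,
    "simulate": SimulateConfig,
}

_RANGE_RULES: dict[tuple[str, str], tuple[float, float | None]] = {
    ("tailcall", "trim_min_run"): (1, None),
    ("tailcall", "min_u"): (1, None),
    ("tailcall", "min_aligned_span"): (1, None),
    ("tailcall", "mismatch_window"): (1, None),
    ("tailcall", "uniqueness_margin"): (1, None),
    ("tailcall", "max_remainder_frac"): (0.0, 1.0),
    ("tailcall", "seed_k"): (4, None),
    ("chimera", "min_arm"): (1, None),
    ("chimera", "min_gap"): (0, None),
    ("chimera", "max_gap"): (1, None),
    ("annotate", "trna_extension"): (0, None),
    ("annotate", "downstream_window"): (0, None),
    ("annotate", "min_overlap"): (1, None),
    ("profiles", "bins"): (1, None),
    ("profiles", "tss_window"): (1, None),
    ("profiles", "smooth"): (1, None),
    ("simulate", "n_reads"): (1, None),
    ("simulate", "chimera_fraction"): (0.0, 1.0),
    ("simulate", "cut_probability"): (0.0, 1.0),
    ("simulate", "minus_strand_fraction"): (0.0, 1.0),
}


def _check_section(
    name: str, cls, raw: Mapping[str, Any], problems: list[str]
):
    known = {f for f in cls.__dataclass_fields__}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            problems.append(f"{name}.{key}: unknown key (accepted: {sorted(known)})")
            continue
        lo_hi = _RANGE_RULES.get((name, key))
        if lo_hi is not None and isinstance(value, (int, float)):
            lo, hi = lo_hi
            if value < lo or (hi is not None and value > hi):
                bound = f">= {lo}" if hi is None else f"in [{lo}, {hi}]"
                problems.append(f"{name}.{key}: {value!r} out of range (must be {bound})")
                continue
        kwargs[key] = value
    if name == "tailcall" and kwargs.get("pass1_mode", "soft") not in ("soft", "strict"):
        problems.append("tailcall.pass1_mode: must be 'soft' or 'strict'")
        kwargs.pop("pass1_mode")
    return cls(**kwargs)


def validate_config(raw: Mapping[str, Any] | None) -> PipelineConfig:
    """Normalise a raw config mapping, filling defaults.

    Raises :class:`ConfigError` listing every problem found. Idempotent:
    validating an already-normalised config dict returns an equal config.
    """
    raw = dict(raw or {})
    problems: list[str] = []
    top_known = {f for f in PipelineConfig.__dataclass_fields__}
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in top_known:
            problems.append(f"{key}: unknown key (accepted: {sorted(top_known)})")
            continue
        if key in _SECTIONS:
            if value is None:
                continue
            if not isinstance(value, Mapping):
                problems.append(f"{key}: must be a mapping")
                continue
            kwargs[key] = _check_section(key, _SECTIONS[key], value, problems)
        else:
            kwargs[key] = value
    if problems:
        raise ConfigError(problems)
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(["top-level config must be a mapping"])
    return validate_config(raw)
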