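"""Pipeline configuration: every printed threshold with its default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    """Thresholds used across the stages.

    min_length/min_exons gate lncRNA candidates; strong/weak thresholds
    drive the fold-change rules; window_size bins chromosomes; the tissue
    cutoff defines leaf-specific transcripts; r/fdr cutoffs filter
    co-expression edges; top_n caps reported enrichment rows; pseudocount
    (FPKM units) stabilizes fold changes.
    """

    min_length: int = 200
    min_exons: int = 2
    strong_threshold: float = 1.0
    weak_threshold: float = 0.0
    window_size: int = 200_000
    tissue_cutoff: float = 0.6
    target_tissue: str = "leaf"
    r_cutoff: float = 0.5
    fdr_cutoff: float = 0.05
    top_n: int = 20
    pseudocount: float = 1.0
    anchor: str = "span_start"
    enrichment_mode: str = "group"
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("min_length", self.min_length >= 1, ">= 1"),
            ("min_exons", self.min_exons >= 1, ">= 1"),
            (
                "strong_threshold/weak_threshold",
                self.strong_threshold > self.weak_threshold >= 0,
                "strong > weak >= 0",
            ),
            ("window_size", self.window_size >= 1, ">= 1"),
            ("tissue_cutoff", 0 <= self.tissue_cutoff <= 1, "in [0, 1]"),
            ("r_cutoff", -1 <= self.r_cutoff <= 1, "in [-1, 1]"),
            ("fdr_cutoff", 0 < self.fdr_cutoff <= 1, "in (0, 1]"),
            ("top_n", self.top_n >= 1, ">= 1"),
            ("pseudocount", self.pseudocount >= 0, ">= 0"),
            ("anchor", self.anchor in ("span_start", "midpoint"), "span_start|midpoint"),
            (
                "enrichment_mode",
                self.enrichment_mode in ("group", "per_lncrna"),
                "group|per_lncrna",
            ),
        ]
        for key, ok, rng in checks:
            if not ok:
                raise ValueError(f"config value {key} out of range (expected {rng})")


_PIPELINE_KEYS = {f.name for f in fields(PipelineConfig)}
_SIM_KEYS = {f.name for f in fields(SimulationConfig)}


def load_config(path: str | Path | None) -> tuple[PipelineConfig, SimulationConfig]:
    """Plain key: value config file -> (pipeline, simulation) configs.

    Keys may belong to either config; unknown keys are rejected.  ``seed``
    is shared.  Tuple-valued simulation fields accept 2-element lists.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be key: value pairs")
        raw = loaded
    unknown = set(raw) - _PIPELINE_KEYS - _SIM_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    pipe_kwargs = {k: v for k, v in raw.items() if k in _PIPELINE_KEYS}
    sim_kwargs = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in raw.items()
        if k in _SIM_KEYS
    }
    if "seed" in raw:
        pipe_kwargs["seed"] = sim_kwargs["seed"] = raw["seed"]
    return PipelineConfig(**pipe_kwargs), SimulationConfig(**sim_kwargs)


def dump_config(pipe: PipelineConfig, sim: SimulationConfig, path: str | Path) -> None:
    """Echo the resolved configuration for provenance."""
    merged = {**asdict(sim), **asdict(pipe)}
    merged = {k: (list(v) if isinstance(v, tuple) else v) for k, v in merged.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(merged, fh, sort_keys=True)
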