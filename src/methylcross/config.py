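"""Configuration objects shared across the pipeline.

Every threshold that the analysis depends on lives here with an explicit
default: the 50-bp DMR window, the three DMR filters (3 cytosines, 0.25
proportion difference, 8 mean reads), the 300-bp bin-joining distance, the
0.05 FDR, the |log2FC| >= 1 differential-expression rule, the 25 %
feature-coverage inclusion rule, and every generator parameter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

CONTEXTS = ("CG", "CHG", "CHH")
TE_CLASSES = ("LTR_retrotransposon", "LINE", "MITE", "TIR")
GENOTYPES = ("A", "P", "H")
PATTERN_CLASSES = ("equal", "peach_up", "almond_up", "hybrid_up", "hybrid_down")


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or missing input data (CLI exit code 3)."""


def _default_context_means() -> dict[str, float]:
    return {"CG": 0.90, "CHG": 0.60, "CHH": 0.15}


def _default_context_dispersion() -> dict[str, float]:
    # beta concentration (a+b); larger = tighter spread around the mean
    return {"CG": 40.0, "CHG": 15.0, "CHH": 15.0}


def _default_pattern_mix() -> dict[str, float]:
    return {
        "equal": 0.783,
        "peach_up": 0.107,
        "almond_up": 0.100,
        "hybrid_up": 0.007,
        "hybrid_down": 0.003,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic hybrid-trio generator.

    The defaults encode the study conditions the generator emulates: two
    parental genomes at ~20 substitutions/kb, feature-level methylation
    centred near 90 % (CG), 60 % (CHG) and 15 % (CHH), ~98 % bisulfite
    conversion measured on an unmethylated chloroplast, 20x coverage, and
    negative-binomial RNA-seq counts with three replicates per genotype.
    """

    seed: int = 0
    genome_length: int = 400_000
    divergence: float = 0.02
    n_te_per_class: int = 12
    n_families: int = 8
    n_genes: int = 30
    chloroplast_length: int = 15_000
    gc_content: float = 0.38
    mean_coverage: float = 20.0
    conversion_rate: float = 0.98
    context_means: dict[str, float] = field(default_factory=_default_context_means)
    context_dispersion: dict[str, float] = field(default_factory=_default_context_dispersion)
    n_spiked_dmrs: int = 8
    spike_delta: float = 0.40
    spike_length: int = 200
    nb_dispersion: float = 0.05
    pattern_mix: dict[str, float] = field(default_factory=_default_pattern_mix)
    lfc_effect: float = 2.0
    mean_expression: float = 100.0
    replicates: int = 3
    unexpressed_fraction: float = 0.05

    def validate(self) -> "SimulationConfig":
        probs = {
            "divergence": self.divergence,
            "conversion_rate": self.conversion_rate,
            "gc_content": self.gc_content,
            "spike_delta": self.spike_delta,
            "unexpressed_fraction": self.unexpressed_fraction,
            **{f"context_means[{k}]": v for k, v in self.context_means.items()},
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.divergence > 0.2:
            raise ConfigError(f"divergence={self.divergence} outside [0, 0.2]")
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        if set(self.context_means) != set(CONTEXTS):
            raise ConfigError(f"context_means must define exactly {CONTEXTS}")
        mix_total = sum(self.pattern_mix.values())
        if abs(mix_total - 1.0) > 1e-6:
            raise ConfigError(f"pattern_mix fractions sum to {mix_total}, expected 1")
        if set(self.pattern_mix) - set(PATTERN_CLASSES):
            raise ConfigError(f"pattern_mix keys must be within {PATTERN_CLASSES}")
        for name in ("genome_length", "chloroplast_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be positive")
        return self


@dataclass
class DmrParams:
    """Windowed DMR-calling parameters.

    window/step tile the genome in adjacent 50-bp bins; windows with fewer
    than `min_cytosines` covered cytosines of the context, an absolute
    methylation-proportion difference below `min_diff`, or a mean per-cytosine
    read total below `min_avg_reads` are discarded before multiple testing.
    Significant same-direction bins closer than `join_distance` are merged.
    """

    window: int = 50
    step: int = 50
    min_cytosines: int = 3
    min_diff: float = 0.25
    min_avg_reads: float = 8.0
    fdr: float = 0.05
    join_distance: int = 300

    def validate(self) -> "DmrParams":
        if self.step <= 0 or self.window < self.step:
            raise ConfigError("window >= step > 0 required")
        for name in ("min_cytosines", "min_diff", "min_avg_reads", "join_distance"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.fdr < 1:
            raise ConfigError("fdr must be in (0, 1)")
        return self


@dataclass
class RunConfig:
    """Top-level configuration of an end-to-end pipeline run."""

    outdir: str = "methylcross_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    dmr: DmrParams = field(default_factory=DmrParams)
    de_fdr: float = 0.05
    de_lfc: float = 1.0
    expression_floor: float = 5.0
    min_coverage_fraction: float = 0.25
    min_position_reads: int = 3
    contexts: tuple[str, ...] = CONTEXTS

    def validate(self) -> "RunConfig":
        self.simulation.validate()
        self.dmr.validate()
        if not 0 < self.de_fdr < 1:
            raise ConfigError("de_fdr must be in (0, 1)")
        if self.de_lfc < 0:
            raise ConfigError("de_lfc must be >= 0")
        if not 0 <= self.min_coverage_fraction <= 1:
            raise ConfigError("min_coverage_fraction must be in [0, 1]")
        for ctx in self.contexts:
            if ctx not in CONTEXTS:
                raise ConfigError(f"unknown context {ctx!r}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        dmr = DmrParams(**raw.pop("dmr", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "contexts" in raw:
            raw["contexts"] = tuple(raw["contexts"])
        cfg = cls(simulation=sim, dmr=dmr, **raw)
        return cfg.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contexts"] = list(self.contexts)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
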