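"""Configuration objects for panel simulation and pipeline runs.

The simulation defaults describe a small recombinant-inbred F1 panel of the
kind used in mouse cognitive-aging studies: ~27 isogenic strains, a handful
of replicate animals per strain, two test ages (6 and 14 months), and three
bounded percentage traits (spontaneous alternation in the y-maze, contextual
fear acquisition, contextual fear memory). Genetic and environmental
variances default to Va = 36 and Ve = 96 squared percentage points, so with
4 replicates per strain the strain-mean heritability
h2_RIx = Va / (Va + Ve/4) = 0.6, in the middle of the moderate-to-strong
band reported for such panels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Traits measured on the same animals at both ages (longitudinal design).
LONGITUDINAL_TRAITS = ("ymaze_alt",)
#: Traits measured on distinct animal cohorts per age (terminal assay).
CROSS_SECTIONAL_TRAITS = ("cfa", "cfm")

DEFAULT_TRAITS = ("ymaze_alt", "cfa", "cfm")

#: Trait baselines on the percent scale, loosely matching a young-adult
#: panel: alternation well above the 50% chance level, freezing traits lower.
DEFAULT_BASELINES = {"ymaze_alt": 70.0, "cfa": 45.0, "cfm": 40.0}


@dataclass(frozen=True)
class QTLSpec:
    """A single planted quantitative trait locus.

    ``pve`` is the proportion of the *genetic* variance (Va) attributable to
    the locus; the remaining genetic variance is polygenic. The effect is
    additive on the 0/1 genotype code of the backcross-style panel
    (0 = B6/B6 homozygote, 1 = B6/D2 heterozygote).
    """

    chromosome: int
    marker_index: int
    pve: float
    trait: str = "ymaze_alt"

    def __post_init__(self) -> None:
        if not 0.0 <= self.pve <= 1.0:
            raise ValueError(f"QTL pve must be in [0, 1], got {self.pve}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic strain panel with known ground truth."""

    n_strains: int = 27
    reps_per_strain_age: int | Sequence[int] = 4
    traits: Sequence[str] = DEFAULT_TRAITS
    va: float | Mapping[str, float] = 36.0
    ve: float | Mapping[str, float] = 96.0
    baseline_mean: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    decline_mean: float = -6.0
    decline_sd: float = 5.0
    qtl_spec: QTLSpec | None = None
    n_chromosomes: int = 19
    markers_per_chromosome: int = 25
    adjacent_marker_recomb_fraction: float = 0.1
    marker_spacing_cm: float = 5.0
    n_modules: int = 5
    genes_per_module: int = 30
    n_background_genes: int = 100
    module_trait_r: float | Sequence[float] = (0.6, 0.0, 0.0, 0.0, 0.0)
    module_loading_range: tuple[float, float] = (0.6, 0.95)
    expression_target_trait: str = "ymaze_alt"
    expression_target_age: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be positive")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValueError("genotype map needs positive marker counts")
        if not 0.0 <= self.adjacent_marker_recomb_fraction <= 0.5:
            raise ValueError("recombination fraction must lie in [0, 0.5]")
        for trait in self.traits:
            va, ve = self.va_for(trait), self.ve_for(trait)
            if va < 0 or ve < 0:
                raise ValueError(f"trait {trait!r}: need Va >= 0 and Ve >= 0")
        for r in self.module_trait_rs():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"module_trait_r must lie in [-1, 1], got {r}")
        reps = self.reps_for_all_strains()
        if len(reps) != self.n_strains or any(r < 1 for r in reps):
            raise ValueError("replicate counts must be positive, one per strain")
        if self.qtl_spec is not None:
            q = self.qtl_spec
            if not (0 <= q.chromosome < self.n_chromosomes):
                raise ValueError(f"QTL chromosome {q.chromosome} outside map")
            if not (0 <= q.marker_index < self.markers_per_chromosome):
                raise ValueError(f"QTL marker index {q.marker_index} outside map")
            if q.trait not in self.traits:
                raise ValueError(f"QTL trait {q.trait!r} not simulated")
        lo, hi = self.module_loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("module loadings must satisfy 0 < lo <= hi <= 1")

    # -- per-trait parameter lookup -------------------------------------
    def _per_trait(self, value: float | Mapping[str, float], trait: str) -> float:
        if isinstance(value, Mapping):
            return float(value[trait])
        return float(value)

    def va_for(self, trait: str) -> float:
        return self._per_trait(self.va, trait)

    def ve_for(self, trait: str) -> float:
        return self._per_trait(self.ve, trait)

    def baseline_for(self, trait: str) -> float:
        return self._per_trait(self.baseline_mean, trait)

    def reps_for_all_strains(self) -> list[int]:
        if isinstance(self.reps_per_strain_age, int):
            return [self.reps_per_strain_age] * self.n_strains
        return [int(r) for r in self.reps_per_strain_age]

    def module_trait_rs(self) -> list[float]:
        if isinstance(self.module_trait_r, (int, float)):
            return [float(self.module_trait_r)] * self.n_modules
        rs = [float(r) for r in self.module_trait_r]
        if len(rs) < self.n_modules:
            rs = rs + [0.0] * (self.n_modules - len(rs))
        return rs[: self.n_modules]

    def strain_ids(self) -> list[str]:
        return [f"BXD{i + 1:03d}" for i in range(self.n_strains)]

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("traits", "module_loading_range"):
            d[key] = list(d[key])
        if not isinstance(d["reps_per_strain_age"], int):
            d["reps_per_strain_age"] = list(d["reps_per_strain_age"])
        if not isinstance(d["module_trait_r"], (int, float)):
            d["module_trait_r"] = list(d["module_trait_r"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if d.get("qtl_spec") is not None and not isinstance(d["qtl_spec"], QTLSpec):
            d["qtl_spec"] = QTLSpec(**d["qtl_spec"])
        if "module_loading_range" in d:
            d["module_loading_range"] = tuple(d["module_loading_range"])
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for an end-to-end panel analysis run.

    Permutation count and significance levels default to the conventions of
    panel QTL studies: 1,000 genome-wide permutations, scan significance at
    alpha 0.05 with a suggestive line at 0.33, FDR 0.05 for module-trait
    screens, and a 99% confidence interval for the above-chance test.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_perm: int = 1000
    scan_alphas: tuple[float, ...] = (0.05, 0.33)
    fdr: float = 0.05
    chance_confidence: float = 0.99
    chance_level: float = 50.0
    power_pve: float = 0.5
    power_target: float = 0.8
    lod_cap: float = 30.0
    scan_declines: bool = True
    run_expression: bool = True
    run_classifier: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for alpha in (*self.scan_alphas, self.fdr):
            if not 0.0 < alpha < 1.0:
                raise ValueError(f"alpha/FDR levels must lie in (0, 1), got {alpha}")
        if not 0.0 < self.chance_confidence < 1.0:
            raise ValueError("chance_confidence must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["scan_alphas"] = list(self.scan_alphas)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and not isinstance(d["simulation"], SimulationConfig):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "scan_alphas" in d:
            d["scan_alphas"] = tuple(d["scan_alphas"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} does not contain a mapping")
    if set(data) <= set(f.name for f in dataclasses.fields(SimulationConfig)):
        # bare simulation config
        return PipelineConfig(simulation=SimulationConfig.from_dict(data))
    return PipelineConfig.from_dict(data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
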