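"""Experiment configuration: a single YAML-serializable record of every
parameter and seed needed to reproduce a phantom/mask/measurement/
reconstruction pipeline run."""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml

__all__ = [
    "PhantomConfig",
    "MaskConfig",
    "NoiseConfig",
    "GraphConfig",
    "SolverConfig",
    "ExperimentConfig",
]

VALID_METHODS = ("zero_fill", "sb_tv", "nltv")


@dataclasses.dataclass
class PhantomConfig:
    kind: str = "textured"
    size: int = 64
    seed: int = 0


@dataclasses.dataclass
class MaskConfig:
    ratio: float = 0.20
    decay: float = 6.0
    center_fraction: float = 0.04
    seed: int = 1


@dataclasses.dataclass
class NoiseConfig:
    model: str = "gaussian"  # none | gaussian | rician
    level: float = 0.01
    seed: int = 2


@dataclasses.dataclass
class GraphConfig:
    patch_radius: int = 2
    search_radius: int = 5
    h: float | None = None  # None: adaptive (median patch distance of guide)
    sigma_patch: float = 1.0
    neighbors_kept: int = 10
    recompute_once: bool = True  # rebuild weights once from an intermediate recon


@dataclasses.dataclass
class SolverConfig:
    mu: float = 100.0
    gamma: float = 10.0
    n_outer: int = 30
    n_inner: int = 1
    gs_sweeps: int = 4
    tol: float = 1e-4
    sweep_mode: str = "gauss_seidel"


@dataclasses.dataclass
class ExperimentConfig:
    """Full description of one reconstruction experiment."""

    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    mask: MaskConfig = dataclasses.field(default_factory=MaskConfig)
    noise: NoiseConfig = dataclasses.field(default_factory=NoiseConfig)
    graph: GraphConfig = dataclasses.field(default_factory=GraphConfig)
    solver: SolverConfig = dataclasses.field(default_factory=SolverConfig)
    methods: tuple = ("zero_fill", "sb_tv", "nltv")
    output_dir: str = "results"

    def __post_init__(self):
        self.methods = tuple(self.methods)
        for m in self.methods:
            if m not in VALID_METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {VALID_METHODS}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        sections = {
            "phantom": PhantomConfig,
            "mask": MaskConfig,
            "noise": NoiseConfig,
            "graph": GraphConfig,
            "solver": SolverConfig,
        }
        kwargs = {}
        for key, klass in sections.items():
            if key in d:
                kwargs[key] = klass(**d[key])
        for key in ("methods", "output_dir"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Short digest embedded in output sidecars for provenance."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
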