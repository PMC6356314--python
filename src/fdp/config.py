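"""Pipeline configuration: every tunable with its recommended default."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunables of the FDP pipeline.

    Parameters
    ----------
    k
        Sigma multiplier of the per-gene activity threshold u + k*sigma*(1-F).
    p_threshold
        Significance cutoff on the minimum AR-order p-value; a gene is
        time-dependent if any order 1..(M-1)/2 beats this.
    noise_mean
        Time-independent genes with mean expression below this are noise.
    mu
        Scale of the exponential edge-clustering-coefficient edge weight.
    K
        Neighbor budget of the KNN kernel and of the interaction-frequency
        entropy.
    diffusion_iters
        Number of cross-diffusion steps per pairwise fusion.
    a
        Restart-complement of the random walk: pr = (1-a)*d + a*H*pr.
    lam
        Weight of the random-walk score in the final blend
        FDP = lam*pr + (1-lam)*IFE.
    eps
        L1 convergence tolerance of the random-walk iteration.
    T_list
        Top-T cutoffs reported by the evaluation stage.
    """

    k: float = 2.5
    p_threshold: float = 0.01
    noise_mean: float = 0.5
    mu: float = 0.5
    K: int = 20
    diffusion_iters: int = 20
    a: float = 0.5
    lam: float = 0.8
    eps: float = 1e-10
    T_list: list[int] = field(default_factory=lambda: [100, 200, 300, 400])
    seed: int = 0
    # switches exposed for sensitivity analysis; defaults follow the method
    population_sd: bool = True
    renormalize_diffusion: bool = False
    transpose_walk: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
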