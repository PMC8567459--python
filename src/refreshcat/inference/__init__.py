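"""Inference engines: exact enumeration, Gibbs sampling, particle filtering."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exact import exact_posterior, exact_label_predictive, block_marginal_loglik_diag
from .gibbs import GibbsConfig, run_gibbs, run_gibbs_fixed
from .particle import ParticleFilterConfig, TrainedParticleFilter, run_particle_filter

__all__ = [
    "PosteriorSampleSet",
    "exact_posterior",
    "exact_label_predictive",
    "block_marginal_loglik_diag",
    "GibbsConfig",
    "run_gibbs",
    "run_gibbs_fixed",
    "ParticleFilterConfig",
    "TrainedParticleFilter",
    "run_particle_filter",
]


@dataclass
class PosteriorSampleSet:
    """Weighted posterior snapshots produced by an inference engine.

    ``samples`` are lightweight state dictionaries (see the engines for
    their keys); ``weights`` are normalized.
    """

    samples: list = field(default_factory=list)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.weights is None:
            self.weights = np.full(n, 1.0 / max(n, 1))
        self.weights = np.asarray(self.weights, dtype=float)
        if n and not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("sample weights must sum to 1")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(zip(self.samples, self.weights))
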