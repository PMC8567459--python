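"""Fixed covariance components for the trained model approximation.

After long experience with real-world categories the hierarchical prior
over cluster covariances is assumed to have collapsed onto a small set of
named diagonal matrices.  Names follow the wide/narrow letter convention:
``Psi_nw`` is narrow on dimension 1 and wide on dimension 2, ``Psi_nnw``
narrow on dimensions 1 and 2, and so on.  The wide standard deviation is
1/c_d on dimension d; singly narrow components shrink one dimension to 10%
of the wide standard deviation and doubly narrow components shrink two
dimensions to 30% (the narrow ratios).  Entries are variances, (rho_d/c_d)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrainedComponentSet",
    "SimulationRegime",
    "build_component_set",
    "developmental_variant",
    "regime_registry",
    "list_regimes",
    "COMPONENT_VOCABULARY",
    "NARROW_RATIO_SINGLE",
    "NARROW_RATIO_DOUBLE",
]

NARROW_RATIO_SINGLE = 0.10
NARROW_RATIO_DOUBLE = 0.30

#: recognized component names, grouped by dimensionality
COMPONENT_VOCABULARY = {
    2: ("ww", "nw", "wn"),
    3: ("www", "nww", "wnw", "wwn", "wnn", "nwn", "nnw"),
}

_SINGLY = {"nw", "wn", "nww", "wnw", "wwn"}
_DOUBLY = {"wnn", "nwn", "nnw"}


def _ratios_for(name: str, narrow_single: float, narrow_double: float) -> np.ndarray:
    if name in _DOUBLY:
        narrow = narrow_double
    else:
        narrow = narrow_single
    return np.array([1.0 if ch == "w" else narrow for ch in name])


@dataclass(frozen=True)
class TrainedComponentSet:
    """A finite set of named fixed diagonal covariance matrices.

    ``matrices[i]`` is the D x D diagonal covariance for ``names[i]``, with
    diagonal entries (rho_d / c_d)^2 where rho_d is 1 on wide dimensions
    and the narrow ratio on narrow ones.  All components share the
    per-dimension scale parameters ``scales`` (c_d); larger c_d shrink
    expected cluster size along that dimension.
    """

    names: tuple[str, ...]
    scales: tuple[float, ...]
    narrow_ratio_single: float = NARROW_RATIO_SINGLE
    narrow_ratio_double: float = NARROW_RATIO_DOUBLE
    matrices: tuple = field(default=())

    def __post_init__(self) -> None:
        dim = len(self.scales)
        if any(c <= 0 for c in self.scales):
            raise ValueError("scale parameters c_d must be positive")
        if self.matrices:
            # explicit matrices (e.g. projections); validate only
            mats = tuple(np.asarray(m, dtype=float) for m in self.matrices)
            for m in mats:
                if m.shape != (dim, dim) or (np.diag(m) <= 0).any():
                    raise ValueError("explicit component matrices must be "
                                     "diagonal SPD of the right dimension")
            object.__setattr__(self, "matrices", mats)
            return
        vocab = COMPONENT_VOCABULARY.get(dim, ())
        mats = []
        for name in self.names:
            if name not in vocab:
                raise ValueError(
                    f"unknown component name {name!r} for dimension {dim}; "
                    f"recognized: {sorted(vocab)}"
                )
            rho = _ratios_for(name, self.narrow_ratio_single, self.narrow_ratio_double)
            sd = rho / np.asarray(self.scales)
            mats.append(np.diag(sd**2))
        object.__setattr__(self, "matrices", tuple(mats))

    @property
    def dim(self) -> int:
        return len(self.scales)

    @property
    def n_components(self) -> int:
        return len(self.names)

    def variances(self) -> np.ndarray:
        """(J, D) array of diagonal variances, one row per component."""
        return np.stack([np.diag(m) for m in self.matrices])

    def project(self, dims: tuple[int, ...]) -> "TrainedComponentSet":
        """Project components onto a dimension subset, preserving entries."""
        names = tuple("".join(n[d] for d in dims) for n in self.names)
        scales = tuple(self.scales[d] for d in dims)
        idx = list(dims)
        mats = tuple(m[np.ix_(idx, idx)] for m in self.matrices)
        return TrainedComponentSet(
            names,
            scales,
            narrow_ratio_single=self.narrow_ratio_single,
            narrow_ratio_double=self.narrow_ratio_double,
            matrices=mats,
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "scales": list(self.scales),
            "narrow_ratio_single": self.narrow_ratio_single,
            "narrow_ratio_double": self.narrow_ratio_double,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedComponentSet":
        return cls(
            tuple(d["names"]),
            tuple(d["scales"]),
            narrow_ratio_single=d.get("narrow_ratio_single", NARROW_RATIO_SINGLE),
            narrow_ratio_double=d.get("narrow_ratio_double", NARROW_RATIO_DOUBLE),
        )


def build_component_set(
    names,
    c_d,
    narrow_ratio_single: float = NARROW_RATIO_SINGLE,
    narrow_ratio_double: float = NARROW_RATIO_DOUBLE,
) -> TrainedComponentSet:
    """Construct a named component set with per-dimension scales ``c_d``."""
    if np.isscalar(c_d):
        dim = len(names[0])
        c_d = (float(c_d),) * dim
    return TrainedComponentSet(
        tuple(names), tuple(float(c) for c in c_d),
        narrow_ratio_single=narrow_ratio_single,
        narrow_ratio_double=narrow_ratio_double,
    )


def developmental_variant(cset: TrainedComponentSet, narrow_sd: float) -> TrainedComponentSet:
    """Widen the narrow dimensions to model less category experience.

    Children are modeled by replacing the adult 10% narrow standard
    deviation with ``narrow_sd`` (on the unit scale, before c_d division):
    0.8 for 3-year-olds, 0.6 for 4-year-olds, 0.5 for 5-year-olds, 0.4 for
    8-year-olds; 0.1 recovers the adult matrices.
    """
    if not 0 < narrow_sd <= 1:
        raise ValueError("narrow_sd must lie in (0, 1]")
    return replace(cset, narrow_ratio_single=narrow_sd, matrices=())


_SINGLY3 = ("nww", "wnw", "wwn")
_ALL3 = ("nww", "wnw", "wwn", "wnn", "nwn", "nnw")


@dataclass(frozen=True)
class SimulationRegime:
    """One named parameter bundle: components, scales, and dispersions."""

    name: str
    component_names: tuple[str, ...]
    c_d: tuple[float, ...]
    alpha: float = 10.0
    alpha_c: float = 0.001
    alpha_g: float = 0.0
    sigma_r2: float = 0.1
    approximation: str = "particle_filter"  # gibbs | particle_filter | exact
    narrow_sd: float = NARROW_RATIO_SINGLE
    note: str = ""

    def component_set(self) -> TrainedComponentSet:
        cset = build_component_set(self.component_names, self.c_d)
        if self.narrow_sd != NARROW_RATIO_SINGLE:
            cset = developmental_variant(cset, self.narrow_sd)
        return cset

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "component_names": list(self.component_names),
            "c_d": list(self.c_d),
            "alpha": self.alpha,
            "alpha_c": self.alpha_c,
            "alpha_g": self.alpha_g,
            "sigma_r2": self.sigma_r2,
            "approximation": self.approximation,
            "narrow_sd": self.narrow_sd,
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationRegime":
        d = dict(d)
        d["component_names"] = tuple(d["component_names"])
        d["c_d"] = tuple(d["c_d"])
        return cls(**d)


def _regimes() -> dict[str, SimulationRegime]:
    reg: dict[str, SimulationRegime] = {}

    def add(r: SimulationRegime) -> None:
        reg[r.name] = r

    add(SimulationRegime(
        "condensation_filtration_separable", ("nw", "wn"), (0.5, 0.5),
        note="filtration easier than condensation; singly narrow pair"))
    add(SimulationRegime(
        "condensation_filtration_unequal", ("nw", "wn"), (0.5, 1.0),
        note="greater discriminability on the vertical dimension"))
    add(SimulationRegime(
        "condensation_filtration_integral", ("ww",), (2.0, 2.0),
        note="isotropic component only; ordering reverses"))
    add(SimulationRegime(
        "shj_separable", _ALL3, (2.1, 2.1, 2.1),
        note="all singly and doubly narrow 3-D components"))
    add(SimulationRegime(
        "shj_integral", ("www",), (2.5, 2.5, 2.5),
        note="isotropic component only; no exclusive-or advantage"))
    add(SimulationRegime(
        "shj_singly_narrow", _SINGLY3, (2.5, 2.5, 2.5),
        note="singly narrow only: fast one-dimensional learning, "
             "little exclusive-or advantage"))
    add(SimulationRegime(
        "shj_no_context_prior", _ALL3, (2.1, 2.1, 2.1), alpha_c=math.inf,
        note="contextual prior removed: Type III catches Type II"))
    add(SimulationRegime(
        "biconditional", ("wwn", "nnw"), (1.3, 1.3, 1.3),
        note="separable pairing uses dims (1,3); integral pairing dims (1,2)"))
    add(SimulationRegime(
        "shj_subtypes_size", _ALL3, (0.7, 2.3, 2.3),
        note="stimuli closer on dimension 1 (size)"))
    add(SimulationRegime(
        "shj_subtypes_shape", _ALL3, (2.3, 0.7, 2.3),
        note="stimuli closer on dimension 2 (shape)"))
    add(SimulationRegime(
        "dimensional_development", ("nw", "wn"), (2.3, 2.3),
        alpha=1.0, sigma_r2=100.0, approximation="exact",
        note="free classification; exact partition posterior; "
             "narrow sd widened for children"))
    add(SimulationRegime(
        "shj_development_adults", _ALL3, (1.5, 1.5, 1.5),
        note="adults: singly and doubly narrow components"))
    add(SimulationRegime(
        "shj_development_children", _SINGLY3, (1.5, 1.5, 1.5),
        note="children: singly narrow only, widened narrow sd per age"))
    add(SimulationRegime(
        "garner_integral", ("www",), (0.3, 0.3, 0.3),
        note="pretrained model, integral dimensions"))
    add(SimulationRegime(
        "garner_separable", ("nww", "wwn"), (0.3, 0.3, 0.3),
        note="pretrained model, separable dimensions"))
    return reg


_REGISTRY = _regimes()


def regime_registry(name: str) -> SimulationRegime:
    """Look up a named simulation regime."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown regime {name!r}; known regimes: {sorted(_REGISTRY)}"
        ) from None


def list_regimes() -> list[SimulationRegime]:
    return [_REGISTRY[k] for k in sorted(_REGISTRY)]
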