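"""Registry of the six causal-inference observer variants.

Every variant shares three parameters — the binding prior ``p_common`` and
the two likelihood SDs ``sigma_V``, ``sigma_A`` — and differs in which
bias mechanism is active:

====================  =  ============================================================
name                  k  mechanism
====================  =  ============================================================
``M4_original``       4  metamodal central Gaussian prior (mean fixed at 0)
``M5_likelihood``     5  likelihood mean shifts (gain biases), flat prior
``M6_likelihood_var`` 6  M5 plus eccentricity-scaled visual likelihood SD
``M8_hybrid``         8  M6 plus a free-mean metamodal Gaussian prior
``M7_priors``         7  visual central Gaussian + auditory mirrored-pair priors
``M9_priors_meta``    9  M7 plus a free-mean metamodal Gaussian prior
====================  =  ============================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core_model import ObserverParams

__all__ = ["ModelSpec", "MODEL_NAMES", "PARAMETER_GLOSSARY", "build_model", "default_bounds"]

PARAMETER_GLOSSARY: Mapping[str, str] = {
    "p_common": "prior probability of a common cause; the tendency to bind the cues",
    "sigma_V": "SD of the visual likelihood (deg); noise in the visual representation",
    "sigma_A": "SD of the auditory likelihood (deg); noise in the auditory representation",
    "dx_V": "gain shift of the visual likelihood center per degree of eccentricity",
    "dx_A": "gain shift of the auditory likelihood center per degree of eccentricity",
    "dsigma_V": "increase in visual likelihood SD (deg) per 6.5-deg eccentric step",
    "sigma_P": "SD of the metamodal spatial prior (deg)",
    "x_P": "mean of the metamodal spatial prior (deg)",
    "sigma_VP": "SD of the visual spatial prior (deg)",
    "x_VP": "mean of the visual spatial prior (deg)",
    "sigma_AP": "SD of each component of the auditory peripheral prior (deg)",
    "x_AP": "half-separation of the mirrored auditory prior components (deg, >= 0)",
}

_SHARED = ("p_common", "sigma_V", "sigma_A")

_MODEL_DEFS: dict[str, tuple[tuple[str, ...], dict[str, float]]] = {
    "M4_original": (_SHARED + ("sigma_P",), {"x_P": 0.0}),
    "M5_likelihood": (_SHARED + ("dx_V", "dx_A"), {}),
    "M6_likelihood_var": (_SHARED + ("dx_V", "dx_A", "dsigma_V"), {}),
    "M8_hybrid": (_SHARED + ("dx_V", "dx_A", "dsigma_V", "sigma_P", "x_P"), {}),
    "M7_priors": (_SHARED + ("sigma_VP", "x_VP", "sigma_AP", "x_AP"), {}),
    "M9_priors_meta": (
        _SHARED + ("sigma_VP", "x_VP", "sigma_AP", "x_AP", "sigma_P", "x_P"),
        {},
    ),
}

MODEL_NAMES = tuple(_MODEL_DEFS)

# Likelihood SDs cover the plausible sensory-noise range; prior SDs reach
# much higher so that a Gaussian prior can become effectively flat over the
# stimulus range — otherwise the flat-prior variants would not nest inside
# the prior-bearing ones (a Gaussian prior capped at 30 deg still shrinks
# an 8-deg-noise cue by ~7%).
_DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "p_common": (0.0, 1.0),
    "sigma_V": (0.1, 30.0),
    "sigma_A": (0.1, 30.0),
    "dx_V": (-0.5, 0.5),
    "dx_A": (-0.5, 0.5),
    "dsigma_V": (0.0, 3.0),
    "sigma_P": (1.0, 200.0),
    "x_P": (-30.0, 30.0),
    "sigma_VP": (1.0, 200.0),
    "x_VP": (-30.0, 30.0),
    "sigma_AP": (1.0, 200.0),
    "x_AP": (0.0, 30.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """One observer-model variant: free parameters, fixed values, box bounds."""

    name: str
    free_params: tuple[str, ...]
    fixed: Mapping[str, float]
    bounds: Mapping[str, tuple[float, float]]

    @property
    def k(self) -> int:
        """Number of free parameters (the BIC complexity penalty uses this)."""
        return len(self.free_params)

    def to_observer_params(self, values: Mapping[str, float]) -> ObserverParams:
        """Combine free-parameter values with the model's fixed values."""
        missing = set(self.free_params) - set(values)
        if missing:
            raise ValueError(f"missing free parameter value(s): {sorted(missing)}")
        extra = set(values) - set(self.free_params)
        if extra:
            raise ValueError(f"unexpected parameter(s) for {self.name}: {sorted(extra)}")
        merged = dict(self.fixed)
        merged.update({k: float(values[k]) for k in self.free_params})
        return ObserverParams.from_dict(merged)

    def vector_to_observer_params(self, theta) -> ObserverParams:
        """Ordered free-parameter vector -> full observer parameters."""
        if len(theta) != self.k:
            raise ValueError(f"{self.name} expects {self.k} values, got {len(theta)}")
        return self.to_observer_params(dict(zip(self.free_params, theta)))


def build_model(name: str) -> ModelSpec:
    """Look up a model variant by name."""
    try:
        free, fixed = _MODEL_DEFS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; known models: {', '.join(MODEL_NAMES)}"
        ) from None
    bounds = {p: _DEFAULT_BOUNDS[p] for p in free}
    return ModelSpec(name=name, free_params=free, fixed=dict(fixed), bounds=bounds)


def default_bounds(spec: ModelSpec) -> dict[str, tuple[float, float]]:
    """Box bounds covering plausible psychophysical ranges for the free parameters."""
    return {p: _DEFAULT_BOUNDS[p] for p in spec.free_params}
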