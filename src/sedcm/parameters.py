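"""Parameterization of the canonical microcircuit (CMC) neural mass model.

The model describes a single cortical column with four coupled populations:
spiny stellate cells (``ss``), superficial pyramidal cells (``sp``),
inhibitory interneurons (``ii``) and deep pyramidal cells (``dp``).  Its
dynamics are governed by 14 *variable* synaptic parameters — four population
time constants, three excitatory couplings, three inhibitory couplings and
four recurrent self-modulatory gains — plus five *nonneuronal* scaling
parameters (innovation and channel-noise amplitudes and the electrode gain).

All parameters are stored as log-scale deviations from fixed default means:
``physical = default * exp(theta)``.  This makes positivity automatic and
matches the convention of convolution-kernel dynamic causal models, where
priors live on log-scaling parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

POPULATIONS = ("ss", "sp", "ii", "dp")

#: default excitatory edges (source, target); glutamatergic
DEFAULT_EXC_EDGES = (("ss", "sp"), ("ss", "ii"), ("dp", "ii"))
#: default inhibitory edges (source, target); GABAergic, all from ``ii``
DEFAULT_INH_EDGES = (("ii", "ss"), ("ii", "sp"), ("ii", "dp"))

TAU_NAMES = tuple(f"tau_{p}" for p in POPULATIONS)
SELF_NAMES = tuple(f"g_self_{p}" for p in POPULATIONS)
NONNEURONAL_NAMES = ("input_white", "input_pink", "noise_white", "noise_pink", "obs_gain")

#: parameter families used by the second-level (group) analysis:
#: t = time constants, e = excitatory, i = inhibitory, m = self-modulatory
FAMILY_LETTERS = ("t", "m", "e", "i")


def edge_name(src: str, dst: str) -> str:
    return f"g_{src}_{dst}"


def _default_means(exc_edges, inh_edges) -> dict[str, float]:
    means = {
        # population kernel time constants, seconds
        "tau_ss": 0.002,
        "tau_sp": 0.002,
        "tau_ii": 0.016,
        "tau_dp": 0.028,
        # innovation (neuronal input) spectral amplitudes, dimensionless
        "input_white": 1.0,
        "input_pink": 1.0,
        # channel (nonneuronal) noise floor, uV^2/Hz
        "noise_white": 1.0,
        "noise_pink": 2.0,
        # electrode gain: maps population depolarization onto uV
        "obs_gain": 30.0,
    }
    for e in exc_edges + inh_edges:
        means[edge_name(*e)] = 2.25
    for n in SELF_NAMES:
        means[n] = 1.0
    return means


@dataclass(frozen=True)
class CMCParameters:
    """Log-scale parameter deviations of the CMC model.

    Attributes
    ----------
    log_scale
        Mapping from parameter name to log-deviation from the default mean.
        Missing names are treated as zero (i.e. at the default).
    exc_edges, inh_edges
        Excitatory / inhibitory edge sets (source, target).  The packaged
        defaults follow the standard CMC layout; both are overridable.
    """

    log_scale: Mapping[str, float] = field(default_factory=dict)
    exc_edges: tuple = DEFAULT_EXC_EDGES
    inh_edges: tuple = DEFAULT_INH_EDGES

    def __post_init__(self):
        unknown = set(self.log_scale) - set(self.names)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")

    # -- name bookkeeping ------------------------------------------------
    @property
    def exc_names(self) -> tuple:
        return tuple(edge_name(*e) for e in self.exc_edges)

    @property
    def inh_names(self) -> tuple:
        return tuple(edge_name(*e) for e in self.inh_edges)

    @property
    def variable_names(self) -> tuple:
        """The 14 variable synaptic parameters, in canonical order."""
        return TAU_NAMES + self.exc_names + self.inh_names + SELF_NAMES

    @property
    def names(self) -> tuple:
        """All parameters: variable synaptic first, then nonneuronal."""
        return self.variable_names + NONNEURONAL_NAMES

    @property
    def families(self) -> dict[str, tuple]:
        return {
            "t": TAU_NAMES,
            "e": self.exc_names,
            "i": self.inh_names,
            "m": SELF_NAMES,
        }

    # -- values ----------------------------------------------------------
    def default_means(self) -> dict[str, float]:
        return _default_means(self.exc_edges, self.inh_edges)

    def deviation(self, name: str) -> float:
        return float(self.log_scale.get(name, 0.0))

    def vector(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = self.names if names is None else tuple(names)
        return np.array([self.deviation(n) for n in names], dtype=float)

    def physical(self) -> dict[str, float]:
        """Physical (strictly positive) values: ``default * exp(deviation)``."""
        means = self.default_means()
        return {n: means[n] * np.exp(self.deviation(n)) for n in self.names}

    def update(self, changes: Mapping[str, float]) -> "CMCParameters":
        """Return a copy with log-deviations *added* on top of the present ones."""
        unknown = set(changes) - set(self.names)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        new = dict(self.log_scale)
        for k, v in changes.items():
            new[k] = new.get(k, 0.0) + float(v)
        return replace(self, log_scale=new)

    def with_vector(self, vec: np.ndarray, names: Iterable[str] | None = None) -> "CMCParameters":
        names = self.names if names is None else tuple(names)
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(names),):
            raise ValueError(f"vector length {vec.shape} does not match {len(names)} names")
        new = dict(self.log_scale)
        new.update({n: float(v) for n, v in zip(names, vec)})
        return replace(self, log_scale=new)

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "log_scale": {k: float(v) for k, v in self.log_scale.items()},
                "exc_edges": [list(e) for e in self.exc_edges],
                "inh_edges": [list(e) for e in self.inh_edges],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CMCParameters":
        d = json.loads(text)
        return cls(
            log_scale=d.get("log_scale", {}),
            exc_edges=tuple(tuple(e) for e in d.get("exc_edges", DEFAULT_EXC_EDGES)),
            inh_edges=tuple(tuple(e) for e in d.get("inh_edges", DEFAULT_INH_EDGES)),
        )


def default_parameters() -> CMCParameters:
    """The packaged default parameterization (all log-deviations zero)."""
    return CMCParameters()


def count_free_parameters(params: CMCParameters) -> int:
    """Number of variable synaptic parameters (excludes nonneuronal scaling)."""
    return len(params.variable_names)


def family_members(params: CMCParameters, letters: str) -> tuple:
    """Parameter names in the union of the given family letters (e.g. ``"ti"``)."""
    fams = params.families
    out: list[str] = []
    for letter in letters:
        if letter not in fams:
            raise ValueError(f"unknown family letter {letter!r}; expected one of {FAMILY_LETTERS}")
        out.extend(fams[letter])
    return tuple(out)
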