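"""Decomposition constants for the five-pool litter model.

The model tracks five chemical compound pools: A (acid-hydrolyzeable),
W (water-soluble), E (soluble in a non-polar solvent), N (neither soluble
nor hydrolyzeable) and H (humus, the recalcitrant end product). Each labile
pool decomposes at a reference rate ``alpha_i`` (yr^-1 at 0 degC, modifier 1);
a fixed fraction of the decomposed mass of pool *i* flows to pool *j*
(``flow_fractions``), a fixed fraction flows to humus (``humus_fraction``)
and the remainder leaves the system as CO2.

The default constants are the published maximum a posteriori point estimate
of the Yasso07 parameterization, shipped as an editable flat key/value file
(``data/yasso07_map.txt``); every operation in the package accepts an
alternative :class:`ParameterSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

#: Pool order used throughout the package.
POOLS = ("A", "W", "E", "N", "H")
#: Labile pools (everything except humus).
LABILE = POOLS[:4]
#: Woody size classes (cm): 0 = non-woody, 2 = fine woody, 10 = coarse woody.
SIZE_CLASSES = (0.0, 2.0, 10.0)

_FLOW_KEYS = [
    (i, j) for i in range(4) for j in range(4) if i != j
]  # 12 off-diagonal source->target pairs among A,W,E,N


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class ParameterSet:
    """All decomposition constants of the model.

    ``flow_fractions[i, j]`` is the fraction of decomposed mass of labile
    pool *i* routed to labile pool *j* (diagonal zero). ``humus_fraction``
    is the fraction of decomposed labile mass routed to H. ``beta1``/
    ``beta2``/``gamma`` are the climate-response coefficients (gamma acts on
    annual precipitation in metres and is negative); ``size_phi1``,
    ``size_phi2`` and ``size_r`` parameterize the woody-size modifier
    ``h(d) = min(1, (1 + phi1 d + phi2 d^2)^r)``.
    """

    alpha_a: float
    alpha_w: float
    alpha_e: float
    alpha_n: float
    alpha_h: float
    flow_fractions: np.ndarray  # (4, 4), [source, target], zero diagonal
    humus_fraction: float
    beta1: float
    beta2: float
    gamma: float
    size_phi1: float
    size_phi2: float
    size_r: float

    def __post_init__(self) -> None:
        flows = np.asarray(self.flow_fractions, dtype=float)
        if flows.shape != (4, 4):
            raise ParameterError(f"flow_fractions must be 4x4, got {flows.shape}")
        object.__setattr__(self, "flow_fractions", flows)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        alphas = [self.alpha_a, self.alpha_w, self.alpha_e, self.alpha_n,
                  self.alpha_h]
        if any(a <= 0 for a in alphas):
            raise ParameterError("all reference rates alpha must be > 0")
        if self.gamma >= 0:
            raise ParameterError("gamma must be < 0 (precipitation saturation)")
        flows = self.flow_fractions
        if np.any(np.diag(flows) != 0):
            raise ParameterError("flow_fractions diagonal must be zero")
        if np.any(flows < 0) or not 0 <= self.humus_fraction <= 1:
            raise ParameterError("mass-flow fractions must be non-negative")
        out = flows.sum(axis=1) + self.humus_fraction
        if np.any(out > 1 + 1e-12):
            bad = [LABILE[i] for i in np.nonzero(out > 1 + 1e-12)[0]]
            raise ParameterError(
                f"outgoing flow fractions exceed 1 for source pool(s) {bad}"
            )

    # -- convenience views --------------------------------------------------
    @property
    def alphas(self) -> np.ndarray:
        """Reference rates (A, W, E, N, H), yr^-1."""
        return np.array([self.alpha_a, self.alpha_w, self.alpha_e,
                         self.alpha_n, self.alpha_h])

    def with_(self, **kwargs) -> "ParameterSet":
        """A copy with some fields replaced."""
        return replace(self, **kwargs)

    # -- flat key/value file ------------------------------------------------
    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        values = _read_flat(Path(path).read_text())
        return cls.from_dict(values)

    @classmethod
    def from_dict(cls, values: dict) -> "ParameterSet":
        flows = np.zeros((4, 4))
        labile = [p.lower() for p in LABILE]
        for i, j in _FLOW_KEYS:
            key = f"flow_{labile[i]}_{labile[j]}"
            flows[i, j] = float(values.pop(key, 0.0))
        scalars = {k: float(v) for k, v in values.items()}
        return cls(flow_fractions=flows, **scalars)

    def to_file(self, path) -> None:
        labile = [p.lower() for p in LABILE]
        lines = []
        for name in ("alpha_a", "alpha_w", "alpha_e", "alpha_n", "alpha_h"):
            lines.append(f"{name} = {getattr(self, name)!r}")
        for i, j in _FLOW_KEYS:
            v = self.flow_fractions[i, j]
            if v:
                lines.append(f"flow_{labile[i]}_{labile[j]} = {v!r}")
        for name in ("humus_fraction", "beta1", "beta2", "gamma",
                     "size_phi1", "size_phi2", "size_r"):
            lines.append(f"{name} = {getattr(self, name)!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def _read_flat(text: str) -> dict:
    values = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"malformed parameter line: {raw!r}")
        key, _, val = line.partition("=")
        values[key.strip().lower()] = val.strip()
    return values


_DEFAULT: ParameterSet | None = None


def default_parameters() -> ParameterSet:
    """The packaged published MAP parameter set (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("socagg.data").joinpath("yasso07_map.txt").read_text()
        _DEFAULT = ParameterSet.from_dict(_read_flat(text))
    return _DEFAULT


def data_path(name: str):
    """A readable traversable for a packaged data table."""
    return resources.files("socagg.data").joinpath(name)
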