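"""Drug-related parameter vector: layout, names, bounds.

The estimation problem has 105 drug-related parameters per compound set:

* 70 tissue-plasma partition coefficients Kp (14 tissues × 5 compounds),
* 5 renal clearances CL_r (ml/min/kg),
* 5 biliary clearances CL_bile (ml/min/kg),
* 5 hepatic metabolic clearances (CES2 ×2, CYP3A4 ×2, UGT; ml/min/kg),
* 20 first-order rate constants (/min): biliary transit k_bile, intestinal
  absorption k_a, small→large intestine transit k_li, and fecal output
  k_feces, each per compound.

Vector positions are fixed: 1-based IDs 1–105 map to 0-based indices, and
the compound order within each block is CPT-11, SN-38, SN-38G, NPC, APC.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .physiology import KP_ORGANS

__all__ = [
    "SPECIES",
    "N_PARAMS",
    "PARAM_NAMES",
    "KP_INDICES",
    "MET_CLEARANCE_NAMES",
    "param_index",
    "kp_index",
    "DrugParameterSet",
    "BoundBox",
    "default_bounds",
]

#: The five compounds tracked by the model, in canonical order.  CPT-11
#: (irinotecan) is hydrolysed by CES2 to SN-38 and oxidised by CYP3A4 to APC
#: and NPC; NPC is hydrolysed by CES2 to SN-38; SN-38 is glucuronidated by
#: UGT1A to SN-38G.
SPECIES = ("CPT-11", "SN-38", "SN-38G", "NPC", "APC")

MET_CLEARANCE_NAMES = ("CL_CES1", "CL_CES2", "CL_3A4_1", "CL_3A4_2", "CL_UGT")

N_PARAMS = 105


def _build_names() -> tuple[str, ...]:
    names: list[str] = []
    for organ in KP_ORGANS:
        names += [f"Kp_{organ}({s})" for s in SPECIES]
    names += [f"CL_r({s})" for s in SPECIES]
    names += [f"CL_bile({s})" for s in SPECIES]
    names += list(MET_CLEARANCE_NAMES)
    for stem in ("k_bile", "k_a", "k_li", "k_feces"):
        names += [f"{stem}({s})" for s in SPECIES]
    return tuple(names)


#: Parameter names indexed by 0-based position (ID = position + 1).
PARAM_NAMES = _build_names()
assert len(PARAM_NAMES) == N_PARAMS

#: 0-based indices of the 70 partition coefficients (IDs 1–70).
KP_INDICES = np.arange(70)

_NAME_TO_INDEX = {n: i for i, n in enumerate(PARAM_NAMES)}
_SPECIES_INDEX = {s: i for i, s in enumerate(SPECIES)}


def param_index(name: str) -> int:
    """0-based vector position of a named parameter."""
    return _NAME_TO_INDEX[name]


def kp_index(organ: str, species: str) -> int:
    """0-based vector position of Kp for one tissue and compound."""
    return KP_ORGANS.index(organ) * 5 + _SPECIES_INDEX[species]


@dataclass(frozen=True)
class DrugParameterSet:
    """A 105-element drug parameter vector with named accessors.

    The underlying vector is the canonical exchange format (cluster
    matrices, CSV dumps); the accessors are used by the simulator.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_PARAMS,):
            raise ValueError(f"parameter vector must have shape ({N_PARAMS},)")
        if not np.all(v > 0):
            bad = int(np.argmin(v > 0))
            raise ValueError(
                f"parameter {PARAM_NAMES[bad]} (ID {bad + 1}) must be positive"
            )
        object.__setattr__(self, "values", v)

    def kp(self, organ: str, species: str) -> float:
        return float(self.values[kp_index(organ, species)])

    def cl_r(self, species: str) -> float:
        return float(self.values[70 + _SPECIES_INDEX[species]])

    def cl_bile(self, species: str) -> float:
        return float(self.values[75 + _SPECIES_INDEX[species]])

    def cl_met(self, name: str) -> float:
        return float(self.values[80 + MET_CLEARANCE_NAMES.index(name)])

    def k_bile(self, species: str) -> float:
        return float(self.values[85 + _SPECIES_INDEX[species]])

    def k_a(self, species: str) -> float:
        return float(self.values[90 + _SPECIES_INDEX[species]])

    def k_li(self, species: str) -> float:
        return float(self.values[95 + _SPECIES_INDEX[species]])

    def k_feces(self, species: str) -> float:
        return float(self.values[100 + _SPECIES_INDEX[species]])


@dataclass(frozen=True)
class BoundBox:
    """Componentwise box 0 < lower < upper for the parameter vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower/upper must be 1-d arrays of equal length")
        if not np.all(lo > 0) or not np.all(lo < hi):
            raise ValueError("bounds must satisfy 0 < lower < upper")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    def __len__(self) -> int:
        return self.lower.size

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.all((x >= self.lower) & (x <= self.upper), axis=-1)


def default_bounds() -> BoundBox:
    """Estimation ranges for the 105 drug parameters (packaged fixture)."""
    import pandas as pd

    with resources.files("pbpkcnm.data").joinpath("bounds.csv").open() as fh:
        tab = pd.read_csv(fh)
    if list(tab["id"]) != list(range(1, N_PARAMS + 1)):
        raise ValueError("bounds fixture IDs must run 1..105")
    return BoundBox(tab["min"].to_numpy(), tab["max"].to_numpy())
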