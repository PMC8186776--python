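"""Sigmoid parameter blocks for the scoring components.

Each component family maps a raw value x through the same parameterised
falling-sigmoid (see :func:`mirstab.scoring.sigmoid_score`) controlled by

* ``iv`` - ideal value: x <= iv scores 100,
* ``ip`` - inflection point: x = ip scores 100/(1+sq),
* ``cs`` - curve slope (exponent),
* ``sq`` - "squeeze" factor,
* ``ca`` - constant add, a floor preventing a near-zero component score
  from annihilating the geometric mean,
* ``w``  - weight of each application of the family in the overall score.

The shipped defaults are the published parameter table of the scoring
system; S_EA's iv/ip are 1/log2(10) and 1/log2(5), i.e. the trimmed mean
CPM at which average-expression starts to be penalised (10 CPM) and scores
50 (5 CPM).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Mapping

import yaml

FAMILIES = (
    "S_DP",
    "S_DL",
    "S_DoO",
    "S_DoU",
    "S_DLc",
    "S_EStD",
    "S_EoH",
    "S_EoL",
    "S_EA",
    "S_Cp",
    "S_Cr",
)

#: component families computed from matched tumor/normal pairs; dropped in
#: multigroup mode
PAIRED_FAMILIES = ("S_DL", "S_DoO", "S_DoU", "S_DLc")

#: families applied once per tissue / subgroup
PER_GROUP_FAMILIES = ("S_EStD", "S_EoH", "S_EoL", "S_Cp", "S_Cr")


@dataclass(frozen=True)
class ComponentParams:
    iv: float
    ip: float
    cs: float
    sq: float
    ca: float
    w: float

    def __post_init__(self) -> None:
        if not self.ip > self.iv:
            raise ValueError(f"ip must exceed iv (iv={self.iv}, ip={self.ip})")
        if self.cs <= 0 or self.sq <= 0 or self.w <= 0 or self.ca < 0:
            raise ValueError("cs, sq, w must be > 0 and ca >= 0")


DEFAULT_COMPONENT_PARAMS: dict[str, ComponentParams] = {
    "S_DP": ComponentParams(iv=0.05, ip=0.25, cs=2.5, sq=1.0, ca=0.0, w=4.0),
    "S_DL": ComponentParams(iv=0.05, ip=0.25, cs=2.5, sq=1.0, ca=0.0, w=4.0),
    "S_DoO": ComponentParams(iv=0.1, ip=0.7, cs=2.5, sq=1.0, ca=10.0, w=1.0),
    "S_DoU": ComponentParams(iv=0.1, ip=0.7, cs=2.5, sq=1.0, ca=10.0, w=1.0),
    "S_DLc": ComponentParams(iv=0.1, ip=0.5, cs=2.5, sq=1.0, ca=5.0, w=2.0),
    "S_EStD": ComponentParams(iv=0.1, ip=0.3, cs=2.0, sq=1.0, ca=5.0, w=1.5),
    "S_EoH": ComponentParams(iv=0.1, ip=0.7, cs=2.5, sq=1.0, ca=5.0, w=0.75),
    "S_EoL": ComponentParams(iv=0.1, ip=0.7, cs=2.5, sq=1.0, ca=5.0, w=0.75),
    "S_EA": ComponentParams(
        iv=1.0 / math.log2(10.0), ip=1.0 / math.log2(5.0), cs=3.0, sq=1.0, ca=0.0, w=6.0
    ),
    "S_Cp": ComponentParams(iv=2.0, ip=4.0, cs=3.0, sq=0.3, ca=5.0, w=0.3),
    "S_Cr": ComponentParams(iv=0.1, ip=0.25, cs=2.5, sq=0.3, ca=5.0, w=0.2),
}


def load_params(path: str | None = None) -> dict[str, ComponentParams]:
    """Load a component parameter table from YAML; None returns the defaults."""
    if path is None:
        return dict(DEFAULT_COMPONENT_PARAMS)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    params = {}
    for family, block in raw.items():
        if family not in FAMILIES:
            raise ValueError(f"unknown component family {family!r}")
        params[family] = ComponentParams(**{k.lower(): float(v) for k, v in block.items()})
    missing = set(FAMILIES) - set(params)
    if missing:
        raise ValueError(f"parameter table missing families {sorted(missing)}")
    return params


def dump_params(params: Mapping[str, ComponentParams], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({f: asdict(p) for f, p in params.items()}, fh, sort_keys=False)
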