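"""Model parameters for the Schlögl reaction network.

The network couples a single dynamic species X to two chemostatted
reservoirs A and B::

    A  <=>  X          (k_plus1 forward, k_minus1 backward)
    3X <=> 2X + B      (k_plus2 forward, k_minus2 backward)

Reservoir concentrations ``a`` and ``b`` are held fixed and drive the
system out of equilibrium; ``b`` is the usual control parameter.  The
system size Ω converts concentrations x into molecule numbers X = Ω·x.

Units: time is measured in units of 1/k_plus2 (so k_plus2 = 1 by
default), entropy in units of k_B.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

__all__ = ["SchloeglParams", "DEFAULT_PARAMS", "load_params", "save_params"]


@dataclasses.dataclass(frozen=True)
class SchloeglParams:
    """Rate constants, reservoir concentrations and system size.

    Defaults are the standard bistable working point of the model:
    k_plus1·a = 0.5, k_minus1 = 3, k_plus2 = k_minus2 = 1, which places
    thermodynamic equilibrium at b0 = 1/6 and a bistable window of b
    roughly between 3.4 and 4.3.
    """

    k_plus1: float = 0.5
    a_conc: float = 1.0
    k_minus1: float = 3.0
    k_plus2: float = 1.0
    k_minus2: float = 1.0
    b_conc: float = 4.0
    omega: float = 100.0

    def __post_init__(self) -> None:
        for name in ("k_plus1", "k_minus1", "k_plus2", "k_minus2"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.a_conc < 0 or self.b_conc < 0:
            raise ValueError("reservoir concentrations must be >= 0")

    @property
    def k1a(self) -> float:
        """Combined birth parameter k_plus1 * a (concentration/time)."""
        return self.k_plus1 * self.a_conc

    def with_(self, **kwargs: Any) -> "SchloeglParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


DEFAULT_PARAMS = SchloeglParams()

# flat config keys accepted by load_params; "k_plus1_a" sets the product
# k_plus1*a with a_conc fixed at 1.
_CONFIG_KEYS = {
    "k_plus1", "a_conc", "k_minus1", "k_plus2", "k_minus2",
    "b_conc", "omega", "k_plus1_a", "b",
}


def _params_from_mapping(cfg: Mapping[str, Any]) -> SchloeglParams:
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, float] = {}
    for key, val in cfg.items():
        if key == "k_plus1_a":
            kwargs["k_plus1"] = float(val)
            kwargs.setdefault("a_conc", 1.0)
        elif key == "b":
            kwargs["b_conc"] = float(val)
        else:
            kwargs[key] = float(val)
    return SchloeglParams(**kwargs)


def load_params(path: str | Path) -> SchloeglParams:
    """Load parameters from a flat YAML or JSON key-value file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, Mapping):
        raise ValueError("config file must contain a flat mapping")
    return _params_from_mapping(cfg)


def save_params(params: SchloeglParams, path: str | Path) -> None:
    """Write parameters as JSON (or YAML for .yml/.yaml paths)."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix in (".yml", ".yaml"):
        import yaml

        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
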