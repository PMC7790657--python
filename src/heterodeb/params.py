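"""Dynamic energy budget parameter sets and structured configuration I/O.

The parameter set follows the standard DEB formulation: a surface-specific
maximum assimilation rate ``pAm_ref``, energy conductance ``v_ref``,
volume-specific somatic maintenance ``pM_ref`` and maturity maintenance rate
coefficient ``kJ_ref``, all quoted at the reference temperature ``TREF`` and
scaled to body temperature with an Arrhenius correction (see
:func:`heterodeb.deb.temperature_correction`).  Allocation is governed by the
kappa rule (``kappa`` to soma, ``1 - kappa`` to maturity/reproduction) with
efficiencies ``kappaR`` (reproduction) and ``kappaX`` (digestion).

Defaults for adult female muskoxen ship in ``data/muskox.yaml``; they were
fixed once by the calibration driver (``analysis/02_calibrate_parameters.py``)
against the percentage-scale overwinter energetics of a Northeast Greenland
study population and are read, never hard-coded, by every experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = [
    "DEBParams",
    "default_params",
    "load_params",
    "save_params",
    "load_config",
    "default_config",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass
class DEBParams:
    """Rate, allocation and conversion constants of the standard DEB model.

    Units: energies MJ, lengths cm, volumes cm^3, masses g, time days,
    temperatures K.  Rates are quoted at ``TREF``.
    """

    #: surface-specific maximum assimilation rate at TREF [MJ d-1 cm-2]
    pAm_ref: float
    #: energy conductance at TREF [cm d-1]
    v_ref: float
    #: volume-specific somatic maintenance at TREF [MJ d-1 cm-3]
    pM_ref: float
    #: maturity maintenance rate coefficient at TREF [d-1]
    kJ_ref: float
    #: volume-specific cost of structure [MJ cm-3]
    EG: float
    #: fraction of mobilized reserve allocated to soma [-]
    kappa: float
    #: reproduction efficiency [-]
    kappaR: float
    #: assimilation (digestion) efficiency, overhead term in FMR [-]
    kappaX: float
    #: Arrhenius temperature [K]
    TAr: float = 8000.0
    #: reference temperature [K]
    TREF: float = 293.15
    #: maturity threshold at puberty [MJ]; adults are frozen at this level
    EHp: float = 60.0
    #: maturity threshold at birth [MJ]; None = birth on the calendar date only
    EHb: Optional[float] = None
    #: structural tissue density [g cm-3]
    struct_density: float = 1.0
    #: reserve tissue energy density [MJ g-1]
    mu_E: float = 0.007
    #: embryo energy-conductance scale (slows fetal development) [-]
    embryo_v_scale: float = 0.6
    #: scaled reserve density endowed to the fetus per unit new structure [-]
    embryo_reserve_density: float = 0.25

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.kappa < 1.0:
            raise ParameterError(f"kappa must be in (0, 1), got {self.kappa}")
        if not 0.0 < self.kappaR <= 1.0:
            raise ParameterError(f"kappaR must be in (0, 1], got {self.kappaR}")
        if not 0.0 < self.kappaX <= 1.0:
            raise ParameterError(f"kappaX must be in (0, 1], got {self.kappaX}")
        for name in ("pAm_ref", "v_ref", "pM_ref", "kJ_ref", "EG", "TAr",
                     "TREF", "struct_density", "mu_E", "embryo_v_scale"):
            value = getattr(self, name)
            if not value > 0.0:
                raise ParameterError(f"{name} must be > 0, got {value}")
        if not (self.Em > 0.0 and self.Em < float("inf")):
            raise ParameterError("maximum reserve density [Em] must be finite "
                                 f"and positive, got {self.Em}")
        if self.EHb is not None and self.EHb <= 0.0:
            raise ParameterError(f"EHb must be > 0 or None, got {self.EHb}")

    @property
    def Em(self) -> float:
        """Maximum reserve density [Em] = pAm_ref / v_ref [MJ cm-3]."""
        return self.pAm_ref / self.v_ref

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "DEBParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown DEB parameter(s): {sorted(unknown)}")
        return cls(**data)


def _default_config_text() -> str:
    return resources.files("heterodeb").joinpath("data/muskox.yaml").read_text()


def default_config() -> dict[str, Any]:
    """Full shipped configuration (DEB, environment, population, mortality)."""
    return yaml.safe_load(_default_config_text())


def default_params() -> DEBParams:
    """Calibrated adult-female muskox DEB parameter set."""
    return DEBParams.from_dict(default_config()["deb"])


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a structured YAML configuration, layered over the defaults.

    Only top-level sections present in the file replace or update the
    shipped defaults; unknown keys inside the ``deb`` section raise.
    """
    with open(path) as handle:
        user = yaml.safe_load(handle) or {}
    if not isinstance(user, dict):
        raise ParameterError(f"{path}: configuration must be a mapping")
    config = default_config()
    for section, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(section), dict):
            config[section] = {**config[section], **value}
        else:
            config[section] = value
    return config


def load_params(path: str | Path) -> DEBParams:
    """Read a DEB parameter set from a YAML config (``deb`` section)."""
    return DEBParams.from_dict(load_config(path)["deb"])


def save_params(params: DEBParams, path: str | Path) -> None:
    """Write a parameter set as a flat key/value YAML mapping (round-trips)."""
    with open(path, "w") as handle:
        yaml.safe_dump({"deb": params.to_dict()}, handle, sort_keys=False)
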