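"""Name-based access to model parameters.

Fitting, sensitivity scans and configuration files all address
parameters through a flat string namespace:

``k11`` / ``k12``
    basal cAMP / cGMP influx (uM/min);
``ki:<drug>``
    competitive inhibition constant of a PDE3 inhibitor (uM);
``influx:<drug>:<dose>``
    local AC influx rate for one administered dose (uM/min);
``kf1`` / ``kf2`` / ``k_syn`` / ``ac_inhibitor_khalf``
    feedback, synergy and AC-inhibitor parameters;
``pde2_active`` / ``pde3_active`` / ``pde5_active``
    active enzyme pools (mg/l) used as initial conditions;
``vasp_r`` / ``vasp_k239`` / ``vasp_kd`` / ``vasp_ka``
    downstream VASP phosphorylation parameters.
"""

from __future__ import annotations

import copy
from dataclasses import replace

from .model import BasalConstants, ConfigurationError, DrugParameters

_CONSTANT_ALIASES = {
    "k11": "camp_influx",
    "k12": "cgmp_influx",
    "k1": "vmax_pde2_camp", "k2": "km_pde2_camp",
    "k3": "vmax_pde3_camp", "k4": "km_pde3_camp",
    "k5": "vmax_pde2_cgmp", "k6": "km_pde2_cgmp",
    "k7": "vmax_pde3_cgmp", "k8": "km_pde3_cgmp",
    "k9": "vmax_pde5_cgmp", "k10": "km_pde5_cgmp",
    "k19": "hill_pde2",
}

POOL_NAMES = ("pde2_active", "pde3_active", "pde5_active")
VASP_NAMES = ("vasp_r", "vasp_k239", "vasp_kd", "vasp_ka")
DRUG_SCALARS = ("kf1", "kf2", "k_syn", "ac_inhibitor_khalf")


def influx_name(drug: str, dose: float) -> str:
    return f"influx:{drug}:{dose:g}"


class ParameterContext:
    """Mutable bundle of everything a parameter name can address."""

    def __init__(self, constants: BasalConstants, drugs: DrugParameters,
                 pools: dict | None = None, vasp: dict | None = None):
        self.constants = constants
        self.drugs = DrugParameters(
            ki=dict(drugs.ki), ac_influx=dict(drugs.ac_influx),
            kf1=drugs.kf1, kf2=drugs.kf2, k_syn=drugs.k_syn,
            ac_inhibitor_khalf=drugs.ac_inhibitor_khalf)
        self.pools = dict(pools or {"pde2_active": 0.05, "pde3_active": 2.3,
                                    "pde5_active": 1.0})
        self.vasp = dict(vasp or {})

    def copy(self) -> "ParameterContext":
        return copy.deepcopy(self)

    def get(self, name: str) -> float:
        if name in _CONSTANT_ALIASES:
            return getattr(self.constants, _CONSTANT_ALIASES[name])
        if hasattr(self.constants, name):
            return getattr(self.constants, name)
        if name in DRUG_SCALARS:
            return getattr(self.drugs, name)
        if name.startswith("ki:"):
            return self.drugs.ki[name[3:]]
        if name.startswith("influx:"):
            _, drug, dose = name.split(":")
            return self.drugs.ac_influx[(drug, float(dose))]
        if name in POOL_NAMES:
            return self.pools[name]
        if name in VASP_NAMES:
            return self.vasp[name]
        raise ConfigurationError(f"unknown parameter {name!r}")

    def set(self, name: str, value: float) -> None:
        if name in _CONSTANT_ALIASES:
            self.constants = replace(self.constants,
                                     **{_CONSTANT_ALIASES[name]: value})
        elif hasattr(self.constants, name):
            self.constants = replace(self.constants, **{name: value})
        elif name in DRUG_SCALARS:
            setattr(self.drugs, name, value)
        elif name.startswith("ki:"):
            drug = name[3:]
            if value <= 0:
                raise ConfigurationError(f"ki for {drug!r} must be > 0")
            self.drugs.ki[drug] = value
        elif name.startswith("influx:"):
            _, drug, dose = name.split(":")
            self.drugs.ac_influx[(drug, float(dose))] = value
        elif name in POOL_NAMES:
            self.pools[name] = value
        elif name in VASP_NAMES:
            self.vasp[name] = value
        else:
            raise ConfigurationError(f"unknown parameter {name!r}")

    def scale(self, name: str, factor: float) -> None:
        self.set(name, self.get(name) * factor)
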