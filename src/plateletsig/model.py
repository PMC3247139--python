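"""Core kinetic model of cyclic-nucleotide signaling in human platelets.

The model tracks ten dynamic quantities: the two second messengers cAMP
and cGMP, active and inactive pools of the three major platelet
phosphodiesterases (PDE2, PDE3, PDE5), and the hydrolysis products AMP
and GMP.  Basal synthesis by adenylyl and guanylyl cyclase is balanced
by Michaelis-Menten (PDE3, PDE5) and Hill-type (PDE2 on cAMP,
coefficient 2) degradation.  Drug action enters through competitive
PDE3 inhibition (Milrinone, Cilostamide), additional adenylyl-cyclase
influx (Iloprost, Forskolin), and two PKA-mediated feedback loops whose
presence defines the nested model variants H0-H3:

* positive feedback -- cAMP (as PKA-activity proxy) raises the PDE3
  Vmax by ``kf1 * c(cAMP)``;
* negative feedback -- cAMP lowers the drug-induced AC influx by
  ``kf2 * c(cAMP)``.

All concentrations of cyclic nucleotides are in uM, enzyme pools in
mg/l, time in minutes.  Vmax constants are in umol/min/mg so that
``Vmax * c(enzyme in mg/l)`` yields uM/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DomainError",
    "ParameterError",
    "ConfigurationError",
    "PlateletState",
    "BasalConstants",
    "DrugParameters",
    "ModelVariant",
    "StimulusEntry",
    "StimulusProtocol",
    "PDE3_INHIBITORS",
    "AC_STIMULATORS",
    "AC_INHIBITOR",
    "reaction_rates",
    "effective_pde3_rate",
    "effective_ac_rate",
    "ode_rhs",
    "basal_state",
]


class DomainError(ValueError):
    """A state or input violates a physical domain constraint."""


class ParameterError(ValueError):
    """A kinetic or drug parameter is outside its admissible range."""


class ConfigurationError(ValueError):
    """A protocol or model configuration cannot be resolved."""


PDE3_INHIBITORS = ("Milrinone", "Cilostamide")
AC_STIMULATORS = ("Iloprost", "Forskolin")
AC_INHIBITOR = "AC-inhibitor"

_STATE_FIELDS = (
    "camp", "cgmp",
    "pde2_active", "pde3_active", "pde5_active",
    "pde2_inactive", "pde3_inactive", "pde5_inactive",
    "amp", "gmp",
)


@dataclass
class PlateletState:
    """The ten dynamic concentrations of the platelet ODE system.

    cAMP, cGMP, AMP, GMP in uM; the six enzyme pools in mg/l.  Active
    and inactive pools of each PDE interconvert only, so their sums are
    conserved along any trajectory.
    """

    camp: float = 4.0
    cgmp: float = 0.4
    pde2_active: float = 0.05
    pde3_active: float = 2.3
    pde5_active: float = 1.0
    pde2_inactive: float = 63.41
    pde3_inactive: float = 222.7
    pde5_inactive: float = 1358.0
    amp: float = 0.0
    gmp: float = 0.0

    def __post_init__(self) -> None:
        for name in _STATE_FIELDS:
            if getattr(self, name) < 0:
                raise DomainError(f"state component {name!r} is negative")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _STATE_FIELDS], float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "PlateletState":
        return cls(**dict(zip(_STATE_FIELDS, map(float, x))))

    @property
    def pde2_total(self) -> float:
        return self.pde2_active + self.pde2_inactive

    @property
    def pde3_total(self) -> float:
        return self.pde3_active + self.pde3_inactive

    @property
    def pde5_total(self) -> float:
        return self.pde5_active + self.pde5_inactive


@dataclass
class BasalConstants:
    """Kinetic constants of the basal (unstimulated) system.

    Vmax in umol/min/mg, Km in uM, influxes in uM/min, (de)activation
    rates in 1/min.  Defaults are the literature values of the resting
    platelet; the PDE (de)activation rates are zero under resting
    conditions, so the active/inactive split enters only through the
    initial pools.
    """

    vmax_pde2_camp: float = 120.0   # k1
    km_pde2_camp: float = 50.0      # k2, compared against c(cAMP)**hill
    vmax_pde3_camp: float = 3.0     # k3
    km_pde3_camp: float = 0.2       # k4
    vmax_pde2_cgmp: float = 120.0   # k5
    km_pde2_cgmp: float = 35.0      # k6
    vmax_pde3_cgmp: float = 0.3     # k7
    km_pde3_cgmp: float = 0.02      # k8
    vmax_pde5_cgmp: float = 5.0     # k9
    km_pde5_cgmp: float = 5.0       # k10
    camp_influx: float = 8.0        # k11, basal AC activity
    cgmp_influx: float = 1.0        # k12, basal GC activity
    pde2_deactivation: float = 0.0  # k13
    pde2_activation: float = 0.0    # k14
    pde3_deactivation: float = 0.0  # k15
    pde3_activation: float = 0.0    # k16
    pde5_deactivation: float = 0.0  # k17
    pde5_activation: float = 0.0    # k18
    hill_pde2: float = 2.0          # k19

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ParameterError(f"constant {name!r} must be >= 0")

    def copy(self, **changes) -> "BasalConstants":
        return replace(self, **changes)


@dataclass
class DrugParameters:
    """Drug-specific and feedback parameters.

    ``ki`` holds the competitive inhibition constant (uM) per PDE3
    inhibitor.  ``ac_influx`` maps ``(drug, dose)`` to the fitted local
    AC influx rate in uM/min (one value per administered dose, the
    paper's local parameters).  ``kf1`` (umol l / (min mg uM)) weights
    the positive feedback of cAMP on the PDE3 Vmax, ``kf2`` (1/min) the
    negative feedback on drug-induced AC influx.  ``k_syn`` scales the
    AC influx when an AC stimulator is combined with a PDE inhibitor
    (over-additive synergy; 1 = purely mechanistic combination).
    ``ac_inhibitor_khalf`` (uM) is the half-inhibition dose of the
    saturating AC-inhibitor model acting on the basal influx.
    """

    ki: dict = field(default_factory=lambda: {"Milrinone": 2.0, "Cilostamide": 5.0})
    ac_influx: dict = field(default_factory=dict)
    kf1: float = 0.0
    kf2: float = 0.0
    k_syn: float = 1.0
    ac_inhibitor_khalf: float = 20.0

    def __post_init__(self) -> None:
        for drug, value in self.ki.items():
            if value <= 0:
                raise ParameterError(f"inhibition constant for {drug!r} must be > 0")
        for key, value in self.ac_influx.items():
            if value < 0:
                raise ParameterError(f"AC influx for {key!r} must be >= 0")
        if self.k_syn < 0:
            raise ParameterError("synergy constant k_syn must be >= 0")
        if self.ac_inhibitor_khalf <= 0:
            raise ParameterError("AC-inhibitor half-inhibition dose must be > 0")

    def influx_for(self, drug: str, dose: float) -> float:
        try:
            return self.ac_influx[(drug, float(dose))]
        except KeyError:
            raise ConfigurationError(
                f"no AC influx rate configured for {drug} at dose {dose}"
            ) from None


@dataclass(frozen=True)
class ModelVariant:
    """Feedback hypothesis: which of the two PKA loops is active.

    H0 = no feedback, H1 = PDE3 activation only, H2 = AC inhibition
    only, H3 = both.
    """

    name: str
    pde3_feedback: bool
    ac_feedback: bool

    _TABLE = {
        "H0": (False, False),
        "H1": (True, False),
        "H2": (False, True),
        "H3": (True, True),
    }

    @classmethod
    def from_name(cls, name: str) -> "ModelVariant":
        try:
            pde3, ac = cls._TABLE[name]
        except KeyError:
            raise ConfigurationError(f"unknown model variant {name!r}") from None
        return cls(name, pde3, ac)


H0 = ModelVariant.from_name("H0")
H1 = ModelVariant.from_name("H1")
H2 = ModelVariant.from_name("H2")
H3 = ModelVariant.from_name("H3")


@dataclass(frozen=True)
class StimulusEntry:
    """One drug administration: dose in the drug's native units
    (uM for PDE inhibitors/Forskolin/AC-inhibitor, nM for Iloprost),
    step or exponentially decaying transient profile."""

    drug: str
    dose: float
    onset: float = 0.0
    profile: str = "step"
    half_life: float | None = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ParameterError("dose must be >= 0")
        if self.profile not in ("step", "transient"):
            raise ConfigurationError(f"unknown stimulus profile {self.profile!r}")
        if self.profile == "transient" and (self.half_life is None or self.half_life <= 0):
            raise ParameterError("transient stimulus requires half_life > 0")

    def effective_dose(self, t: float) -> float:
        if t < self.onset:
            return 0.0
        if self.profile == "step":
            return self.dose
        return self.dose * math.exp(-math.log(2.0) * (t - self.onset) / self.half_life)


@dataclass(frozen=True)
class StimulusProtocol:
    """A set of concurrent or successive drug administrations."""

    entries: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        known = set(PDE3_INHIBITORS) | set(AC_STIMULATORS) | {AC_INHIBITOR}
        for e in self.entries:
            if e.drug not in known:
                raise ConfigurationError(f"unknown drug {e.drug!r}")

    @classmethod
    def single(cls, drug: str, dose: float, **kwargs) -> "StimulusProtocol":
        return cls((StimulusEntry(drug, dose, **kwargs),))

    @property
    def has_pde_inhibitor(self) -> bool:
        return any(e.drug in PDE3_INHIBITORS and e.dose > 0 for e in self.entries)

    @property
    def onsets(self) -> tuple:
        return tuple(sorted({e.onset for e in self.entries}))

    def describe(self) -> str:
        if not self.entries:
            return "basal"
        return "+".join(f"{e.drug}:{e.dose:g}" for e in self.entries)


EMPTY_PROTOCOL = StimulusProtocol()


def basal_state(
    constants: BasalConstants | None = None,
    pde2_active: float = 0.05,
    pde3_active: float = 2.3,
    pde5_active: float = 1.0,
    pde2_total: float = 63.46,
    pde3_total: float = 225.0,
    pde5_total: float = 1359.0,
    camp: float = 4.0,
    cgmp: float = 0.4,
) -> PlateletState:
    """Resting-platelet state: basal nucleotide levels with the given
    active enzyme pools; inactive pools make up the measured totals."""
    return PlateletState(
        camp=camp,
        cgmp=cgmp,
        pde2_active=pde2_active,
        pde3_active=pde3_active,
        pde5_active=pde5_active,
        pde2_inactive=pde2_total - pde2_active,
        pde3_inactive=pde3_total - pde3_active,
        pde5_inactive=pde5_total - pde5_active,
    )


def reaction_rates(state: PlateletState, constants: BasalConstants) -> np.ndarray:
    """Rates v1..v13 of the basal reaction network.

    v1, v2 are the constant cyclase influxes; v3..v7 the PDE-mediated
    hydrolysis steps (Hill kinetics for PDE2 on cAMP, Michaelis-Menten
    otherwise); v8..v13 mass-action (de)activation of the enzyme pools.
    Units: uM/min for v1..v7, mg/l/min for v8..v13.
    """
    k = constants
    s = state
    for name in _STATE_FIELDS:
        if getattr(s, name) < 0:
            raise DomainError(f"state component {name!r} is negative")
    camp_h = s.camp ** k.hill_pde2
    v = np.empty(13)
    v[0] = k.camp_influx
    v[1] = k.cgmp_influx
    v[2] = k.vmax_pde2_camp * camp_h * s.pde2_active / (k.km_pde2_camp + camp_h)
    v[3] = k.vmax_pde3_camp * s.pde3_active * s.camp / (k.km_pde3_camp + s.camp)
    v[4] = k.vmax_pde2_cgmp * s.pde2_active * s.cgmp / (k.km_pde2_cgmp + s.cgmp)
    v[5] = k.vmax_pde3_cgmp * s.pde3_active * s.cgmp / (k.km_pde3_cgmp + s.cgmp)
    v[6] = k.vmax_pde5_cgmp * s.pde5_active * s.cgmp / (k.km_pde5_cgmp + s.cgmp)
    v[7] = k.pde2_activation * s.pde2_inactive
    v[8] = k.pde2_deactivation * s.pde2_active
    v[9] = k.pde3_activation * s.pde3_inactive
    v[10] = k.pde3_deactivation * s.pde3_active
    v[11] = k.pde5_activation * s.pde5_inactive
    v[12] = k.pde5_deactivation * s.pde5_active
    return v


def effective_pde3_rate(
    camp: float,
    active_pde3: float,
    inhibitor_dose: float = 0.0,
    k_i: float = 1.0,
    kf1: float = 0.0,
    constants: BasalConstants | None = None,
) -> float:
    """cAMP hydrolysis rate (uM/min) of PDE3 under competitive
    inhibition and optional positive feedback.

    The inhibitor raises the apparent Km by ``(1 + u/k_i)``; the
    feedback raises the Vmax to ``Vmax + kf1 * c(cAMP)`` (floored at 0
    so a sign-free fitted kf1 cannot produce negative hydrolysis).
    Reduces to the basal PDE3 rate for ``u = 0`` and ``kf1 = 0``.
    """
    if constants is None:
        constants = BasalConstants()
    if inhibitor_dose < 0:
        raise ParameterError("inhibitor dose must be >= 0")
    if k_i <= 0:
        raise ParameterError("inhibition constant k_i must be > 0")
    vmax = max(constants.vmax_pde3_camp + kf1 * camp, 0.0)
    km_eff = (1.0 + inhibitor_dose / k_i) * constants.km_pde3_camp
    return vmax * active_pde3 * camp / (km_eff + camp)


def effective_ac_rate(
    x_drug: float,
    camp: float,
    kf2: float = 0.0,
    basal_influx: float = 0.0,
) -> float:
    """Drug-induced cAMP formation rate (uM/min).

    The net stimulation ``x_drug - kf2 * c(cAMP)`` is floored at zero
    (strong negative feedback cannot turn the cyclase into a sink) and
    added to the basal influx, which the feedback does not touch.
    """
    if x_drug < 0:
        raise ParameterError("AC influx rate must be >= 0")
    return basal_influx + max(x_drug - kf2 * camp, 0.0)


def _ac_inhibition_factor(dose: float, khalf: float) -> float:
    # saturating reduction of basal AC activity, in [0, 1]
    return khalf / (khalf + dose)


def ode_rhs(
    t: float,
    state: PlateletState | np.ndarray,
    constants: BasalConstants,
    drugs: DrugParameters | None = None,
    variant: ModelVariant = H0,
    protocol: StimulusProtocol = EMPTY_PROTOCOL,
) -> np.ndarray:
    """Time derivatives of the ten state variables under a protocol.

    The basal system is modified in place of its cAMP members only:
    the PDE3 hydrolysis step acquires competitive inhibition and the
    kf1 feedback, and the AC influx is augmented by the per-dose drug
    rates subject to the kf2 feedback.  Transient stimuli decay
    exponentially after onset.  The cGMP branch is untouched by any
    cAMP-pathway drug (no cross-talk by construction).
    """
    if isinstance(state, PlateletState):
        s = state
    else:
        s = PlateletState.from_array(np.asarray(state, float).clip(min=0.0))
    if drugs is None:
        drugs = DrugParameters()
    k = constants

    inhibition = 0.0  # sum of u_i / k_i over PDE3 inhibitors
    ac_drug_rate = 0.0
    basal_factor = 1.0
    synergy = drugs.k_syn if protocol.has_pde_inhibitor else 1.0
    kf2 = drugs.kf2 if variant.ac_feedback else 0.0
    kf1 = drugs.kf1 if variant.pde3_feedback else 0.0

    for entry in protocol.entries:
        dose = entry.effective_dose(t)
        if entry.drug in PDE3_INHIBITORS:
            if entry.drug not in drugs.ki:
                _missing_ki(entry.drug)
            inhibition += dose / drugs.ki[entry.drug]
        elif entry.drug in AC_STIMULATORS:
            x = drugs.influx_for(entry.drug, entry.dose)
            scale = dose / entry.dose if entry.dose > 0 else 0.0
            ac_drug_rate += max(synergy * x * scale - kf2 * s.camp, 0.0)
        elif entry.drug == AC_INHIBITOR:
            basal_factor *= _ac_inhibition_factor(dose, drugs.ac_inhibitor_khalf)

    camp_h = s.camp ** k.hill_pde2
    v3 = k.vmax_pde2_camp * camp_h * s.pde2_active / (k.km_pde2_camp + camp_h)
    vmax3 = max(k.vmax_pde3_camp + kf1 * s.camp, 0.0)
    km3 = (1.0 + inhibition) * k.km_pde3_camp
    v4 = vmax3 * s.pde3_active * s.camp / (km3 + s.camp)
    v5 = k.vmax_pde2_cgmp * s.pde2_active * s.cgmp / (k.km_pde2_cgmp + s.cgmp)
    v6 = k.vmax_pde3_cgmp * s.pde3_active * s.cgmp / (k.km_pde3_cgmp + s.cgmp)
    v7 = k.vmax_pde5_cgmp * s.pde5_active * s.cgmp / (k.km_pde5_cgmp + s.cgmp)
    v8 = k.pde2_activation * s.pde2_inactive
    v9 = k.pde2_deactivation * s.pde2_active
    v10 = k.pde3_activation * s.pde3_inactive
    v11 = k.pde3_deactivation * s.pde3_active
    v12 = k.pde5_activation * s.pde5_inactive
    v13 = k.pde5_deactivation * s.pde5_active

    dx = np.empty(10)
    dx[0] = basal_factor * k.camp_influx + ac_drug_rate - v3 - v4   # cAMP
    dx[1] = k.cgmp_influx - v5 - v6 - v7                            # cGMP
    dx[2] = v8 - v9                                                 # PDE2 active
    dx[3] = v10 - v11                                               # PDE3 active
    dx[4] = v12 - v13                                               # PDE5 active
    dx[5] = -v8 + v9                                                # PDE2 inactive
    dx[6] = -v10 + v11                                              # PDE3 inactive
    dx[7] = -v12 + v13                                              # PDE5 inactive
    dx[8] = v3 + v4                                                 # AMP
    dx[9] = v5 + v6 + v7                                            # GMP
    return dx


def _missing_ki(drug: str) -> float:
    raise ConfigurationError(f"no inhibition constant configured for {drug!r}")


def camp_rhs(
    t: float,
    camp: float | np.ndarray,
    constants: BasalConstants,
    drugs: DrugParameters,
    variant: ModelVariant,
    protocol: StimulusProtocol,
    pde2_active: float = 0.05,
    pde3_active: float = 2.3,
):
    """Reduced scalar right-hand side for cAMP alone.

    Valid whenever the PDE (de)activation rates are zero, so the enzyme
    pools are constant and the cAMP equation is autonomous in cAMP.
    Accepts a vector of cAMP values for batched evaluation.
    """
    k = constants
    c = np.asarray(camp, float)
    inhibition = 0.0
    basal_factor = 1.0
    ac = np.zeros_like(c)
    synergy = drugs.k_syn if protocol.has_pde_inhibitor else 1.0
    kf2 = drugs.kf2 if variant.ac_feedback else 0.0
    kf1 = drugs.kf1 if variant.pde3_feedback else 0.0
    for entry in protocol.entries:
        dose = entry.effective_dose(t)
        if entry.drug in PDE3_INHIBITORS:
            if entry.drug not in drugs.ki:
                _missing_ki(entry.drug)
            inhibition += dose / drugs.ki[entry.drug]
        elif entry.drug in AC_STIMULATORS:
            x = drugs.influx_for(entry.drug, entry.dose)
            scale = dose / entry.dose if entry.dose > 0 else 0.0
            ac = ac + np.maximum(synergy * x * scale - kf2 * c, 0.0)
        elif entry.drug == AC_INHIBITOR:
            basal_factor *= _ac_inhibition_factor(dose, drugs.ac_inhibitor_khalf)
    ch = c ** k.hill_pde2
    v3 = k.vmax_pde2_camp * ch * pde2_active / (k.km_pde2_camp + ch)
    vmax3 = np.maximum(k.vmax_pde3_camp + kf1 * c, 0.0)
    v4 = vmax3 * pde3_active * c / ((1.0 + inhibition) * k.km_pde3_camp + c)
    return basal_factor * k.camp_influx + ac - v3 - v4
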