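"""Synthetic study generator.

Emulates the drug-titration study design: four cAMP-elevating drugs at
their administered dose series (Cilostamide 0.5-50 uM, Milrinone 1-100
uM, Iloprost 1-100 nM, Forskolin 1-500 uM), triplicate measurements on
a 7-point time grid over 10 minutes, and Gaussian measurement noise
with standard deviation ``0.1 y + 0.05 max(y)`` per series.  The
default design yields 22 dose series and 154 fitted points, matching
the scale of the original study (N = 155).

Ground-truth drug parameters are generated from smooth dose-response
curves (Emax form) for the local AC influx rates, so that the model
reproduces the reported qualitative behavior: saturating Iloprost
plateaus beyond 50 nM, a Forskolin (500 uM) plateau of roughly 700 uM
cAMP reached within minutes, Milrinone responding more strongly than
Cilostamide at comparable doses, and hardly any Cilostamide effect at
the lowest doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import ExperimentSeries, error_sigma
from .downstream import VaspParameters, vasp_phosphorylation
from .model import (
    AC_STIMULATORS,
    H3,
    BasalConstants,
    ConfigurationError,
    DrugParameters,
    ModelVariant,
    StimulusProtocol,
)
from .params import influx_name
from .simulate import simulate_camp_batch

__all__ = [
    "DEFAULT_DOSES",
    "DEFAULT_TIMES",
    "StudyDesign",
    "true_drug_parameters",
    "iloprost_influx",
    "forskolin_influx",
    "generate_study",
    "generate_vasp_experiment",
]

DEFAULT_DOSES = {
    "Cilostamide": (0.5, 1.0, 5.0, 10.0, 50.0),      # uM
    "Milrinone": (1.0, 5.0, 10.0, 50.0, 100.0),      # uM
    "Iloprost": (1.0, 5.0, 10.0, 50.0, 100.0),       # nM
    "Forskolin": (1.0, 3.0, 10.0, 30.0, 100.0, 200.0, 500.0),  # uM
}

# sampling times (min): dense early, covering the <=5 min plateau approach
DEFAULT_TIMES = (0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0)

# ground-truth generating values (see docs/methods.md for the rationale)
TRUE_KI = {"Milrinone": 2.0, "Cilostamide": 5.0}   # uM
TRUE_KF1 = 0.05    # umol l / (min mg uM): +7% PDE3 Vmax at basal cAMP
TRUE_KF2 = 0.15    # 1/min: subtracts ~0.6 uM/min at basal cAMP
TRUE_K_SYN = 1.443
ILOPROST_EMAX = 10.0    # uM/min
ILOPROST_EC50 = 8.0     # nM
FORSKOLIN_EMAX = 247.5  # uM/min, set by the ~700 uM plateau at 500 uM
FORSKOLIN_EC50 = 150.0  # uM


def iloprost_influx(dose_nm) -> np.ndarray:
    """Ground-truth AC influx (uM/min) induced by Iloprost (dose in nM):
    receptor-mediated, saturating beyond ~50 nM."""
    d = np.asarray(dose_nm, float)
    return ILOPROST_EMAX * d / (d + ILOPROST_EC50)


def forskolin_influx(dose_um) -> np.ndarray:
    """Ground-truth AC influx (uM/min) induced by Forskolin (dose in uM):
    direct, high-capacity cyclase activation."""
    d = np.asarray(dose_um, float)
    return FORSKOLIN_EMAX * d / (d + FORSKOLIN_EC50)


@dataclass
class StudyDesign:
    """Shape of a synthetic titration study.

    ``doses`` maps drug name to its administered dose list (native
    units); every (drug, dose) pair becomes one time-series experiment
    sampled at ``times`` with ``replicates`` independent draws.  The
    seed is mandatory so every generated study is reproducible.
    """

    seed: int
    doses: dict = field(default_factory=lambda: {k: tuple(v) for k, v in
                                                 DEFAULT_DOSES.items()})
    times: tuple = DEFAULT_TIMES
    replicates: int = 3
    noise_scale: float = 1.0
    noise_model: str = "relative+range"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("need at least one replicate")
        if len(self.times) < 1:
            raise ConfigurationError("need at least one time point")
        if self.n_points == 0:
            raise ConfigurationError("design contains zero data points")

    @property
    def n_series(self) -> int:
        return sum(len(v) for v in self.doses.values())

    @property
    def n_points(self) -> int:
        return self.n_series * len(self.times)


def true_drug_parameters(design: StudyDesign | None = None) -> DrugParameters:
    """Ground-truth drug parameters for a design: local influx rates from
    the Emax dose-response curves plus the generating inhibition,
    feedback and synergy constants."""
    doses = design.doses if design is not None else DEFAULT_DOSES
    ac_influx = {}
    for drug, dose_list in doses.items():
        if drug not in AC_STIMULATORS:
            continue
        curve = iloprost_influx if drug == "Iloprost" else forskolin_influx
        for dose in dose_list:
            ac_influx[(drug, float(dose))] = float(curve(dose))
    return DrugParameters(ki=dict(TRUE_KI), ac_influx=ac_influx,
                          kf1=TRUE_KF1, kf2=TRUE_KF2, k_syn=TRUE_K_SYN)


def with_influx_for(drugs: DrugParameters, drug: str, doses) -> DrugParameters:
    """Copy of ``drugs`` with local AC influx rates filled in for any of
    the given doses that lack one, taken from the ground-truth
    dose-response curve of the stimulator."""
    if drug not in AC_STIMULATORS:
        raise ConfigurationError(f"{drug!r} is not an AC stimulator")
    curve = iloprost_influx if drug == "Iloprost" else forskolin_influx
    ac_influx = dict(drugs.ac_influx)
    for dose in doses:
        if dose > 0:
            ac_influx.setdefault((drug, float(dose)), float(curve(dose)))
    return DrugParameters(ki=dict(drugs.ki), ac_influx=ac_influx,
                          kf1=drugs.kf1, kf2=drugs.kf2, k_syn=drugs.k_syn,
                          ac_inhibitor_khalf=drugs.ac_inhibitor_khalf)


def ground_truth_record(drugs: DrugParameters, variant: ModelVariant,
                        pools: dict) -> dict:
    """Flat, JSON-serializable record of the generating parameters,
    keyed by the fitting parameter names."""
    record = {"variant": variant.name,
              "kf1": drugs.kf1 if variant.pde3_feedback else 0.0,
              "kf2": drugs.kf2 if variant.ac_feedback else 0.0,
              "k_syn": drugs.k_syn}
    for drug, ki in drugs.ki.items():
        record[f"ki:{drug}"] = ki
    for (drug, dose), x in drugs.ac_influx.items():
        record[influx_name(drug, dose)] = x
    record.update(pools)
    return record


def generate_study(
    design: StudyDesign,
    constants: BasalConstants | None = None,
    drugs: DrugParameters | None = None,
    variant: ModelVariant = H3,
    pde2_active: float = 0.05,
    pde3_active: float = 2.3,
) -> tuple[list, dict]:
    """Generate a full synthetic titration study.

    Noise-free cAMP trajectories come from the model under the given
    (default: ground-truth) parameters; each replicate adds independent
    Gaussian noise with the study error model, truncated at zero for
    concentrations.  Returns the experiment series (replicate means with
    SEM-style sigma) and the ground-truth record.
    """
    if drugs is None:
        drugs = true_drug_parameters(design)
    if constants is None:
        constants = BasalConstants()
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.times, float)

    protocols = []
    labels = []
    for drug, dose_list in design.doses.items():
        for dose in dose_list:
            protocols.append(StimulusProtocol.single(drug, float(dose)))
            labels.append(f"{drug}_{dose:g}")
    clean = simulate_camp_batch(protocols, [times] * len(protocols),
                                constants, drugs, variant,
                                pde2_active, pde3_active)

    experiments = []
    n_clipped = 0
    for label, protocol, y in zip(labels, protocols, clean):
        sigma = design.noise_scale * error_sigma(y)
        replicates = y[None, :] + sigma[None, :] * rng.standard_normal(
            (design.replicates, times.size))
        n_clipped += int(np.sum(replicates < 0))
        replicates = np.clip(replicates, 0.0, None)
        experiments.append(ExperimentSeries.from_replicates(
            label, protocol, "cAMP", times, replicates))

    pools = {"pde2_active": pde2_active, "pde3_active": pde3_active}
    truth = ground_truth_record(drugs, variant, pools)
    truth["k11"] = constants.camp_influx
    truth["seed"] = design.seed
    truth["n_points"] = design.n_points
    truth["n_clipped"] = n_clipped
    return experiments, truth


def generate_vasp_experiment(
    doses_nm=(2.0, 5.0, 10.0),
    times=DEFAULT_TIMES,
    vasp: VaspParameters | None = None,
    constants: BasalConstants | None = None,
    drugs: DrugParameters | None = None,
    variant: ModelVariant = H3,
    replicates: int = 3,
    noise_scale: float = 1.0,
    seed: int = 0,
    pde2_active: float = 0.05,
    pde3_active: float = 2.3,
) -> tuple[list, dict]:
    """Paired cAMP and per-site VASP phospho-fraction series under
    AC stimulation (Iloprost-like doses in nM).

    The cAMP course drives the two-site phospho-ODE; noise follows the
    study error model and phospho-fractions are clipped back to [0, 1]
    after noise addition (clip count reported in the truth record).
    """
    constants = constants or BasalConstants()
    vasp = vasp or VaspParameters()
    times = np.asarray(times, float)
    rng = np.random.default_rng(seed)

    if drugs is None:
        ac_influx = {("Iloprost", float(d)): float(iloprost_influx(d))
                     for d in doses_nm}
        drugs = DrugParameters(ki=dict(TRUE_KI), ac_influx=ac_influx,
                               kf1=TRUE_KF1, kf2=TRUE_KF2)

    dense_t = np.linspace(0.0, float(times.max()) or 1.0, 201)
    experiments = []
    n_clipped = 0
    for dose in doses_nm:
        protocol = StimulusProtocol.single("Iloprost", float(dose))
        camp_dense = simulate_camp_batch([protocol], [dense_t], constants,
                                         drugs, variant,
                                         pde2_active, pde3_active)[0]
        f157_d, f239_d = vasp_phosphorylation(dense_t, camp_dense, vasp)
        curves = {
            "cAMP": np.interp(times, dense_t, camp_dense),
            "VASP_pS157_ratio": np.interp(times, dense_t, f157_d),
            "VASP_pS239_ratio": np.interp(times, dense_t, f239_d),
        }
        for observable, y in curves.items():
            sigma = noise_scale * error_sigma(y)
            reps = y[None, :] + sigma[None, :] * rng.standard_normal(
                (replicates, times.size))
            if observable == "cAMP":
                n_clipped += int(np.sum(reps < 0))
                reps = np.clip(reps, 0.0, None)
            else:
                n_clipped += int(np.sum((reps < 0) | (reps > 1)))
                reps = np.clip(reps, 0.0, 1.0)
            experiments.append(ExperimentSeries.from_replicates(
                f"Iloprost_{dose:g}_{observable}", protocol, observable,
                times, reps))

    truth = {
        "vasp_r": vasp.site_preference, "vasp_k239": vasp.k239,
        "vasp_kd": vasp.kd, "vasp_ka": vasp.ka_camp,
        "kf1": drugs.kf1, "kf2": drugs.kf2,
        "seed": seed, "n_clipped": n_clipped,
    }
    return experiments, truth
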