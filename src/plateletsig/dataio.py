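"""Readers and writers: time-series CSV, YAML model configuration,
fit-result JSON with provenance.

The time-series schema is one row per replicate value:

    experiment_id, drug, dose, dose_units, time_min, replicate,
    observable, value

Doses are in the drug's native units (nM for Iloprost, uM otherwise);
basal series use drug "none" with dose 0.  Fitting consumes per-time
means with SEM-style sigma from the study error model; raw replicates
are retained on the series.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import ExperimentSeries, FitResult
from .model import (
    BasalConstants,
    ConfigurationError,
    DrugParameters,
    ModelVariant,
    StimulusEntry,
    StimulusProtocol,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "RunConfig",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "save_config",
    "load_config",
    "fit_result_to_json",
    "fit_result_from_json",
]

logger = logging.getLogger("plateletsig")

REQUIRED_COLUMNS = ("experiment_id", "drug", "dose", "dose_units",
                    "time_min", "replicate", "observable", "value")

_NATIVE_UNITS = {"Iloprost": "nM", "none": ""}
_VALID_UNITS = {"uM", "nM", ""}


@dataclass
class RunConfig:
    """Configuration of one analysis run (seed recorded in all outputs)."""

    seed: int
    variant: str = "H3"
    output_dir: str = "."
    data_paths: list = field(default_factory=list)
    verbosity: int = 1
    tolerances: dict = field(default_factory=dict)


def _native_units(drug: str) -> str:
    return _NATIVE_UNITS.get(drug, "uM")


def write_timeseries_csv(experiments, path) -> None:
    """Write experiment series (replicates if available, else means) in
    the long CSV schema.  Combination protocols are written with one
    row per administered drug sharing the replicate value."""
    rows = []
    for e in experiments:
        entries = e.protocol.entries or (StimulusEntry("none", 0.0),)
        values = e.replicates if e.replicates is not None else e.values[None, :]
        for entry in entries:
            for r in range(values.shape[0]):
                for t, v in zip(e.times, values[r]):
                    rows.append({
                        "experiment_id": e.experiment_id,
                        "drug": entry.drug,
                        "dose": entry.dose,
                        "dose_units": _native_units(entry.drug),
                        "time_min": t,
                        "replicate": r + 1,
                        "observable": e.observable,
                        "value": v,
                    })
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)


def read_timeseries_csv(path) -> list:
    """Parse a time-series CSV into experiment series.

    Rows are grouped by experiment_id; the protocol is reconstructed
    from the unique (drug, dose) pairs; per-time means and SEM-style
    sigmas are computed from the replicates.  Malformed files raise
    descriptive errors with 1-based data line numbers.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("time-series file %s is empty", path)
        return []
    if frame.empty:
        logger.warning("time-series file %s has no data rows", path)
        return []
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}")
    frame = frame.fillna({"dose_units": ""})
    bad_units = frame[~frame["dose_units"].isin(_VALID_UNITS)]
    if not bad_units.empty:
        line = int(bad_units.index[0]) + 2  # header is line 1
        raise ConfigurationError(
            f"{path}, line {line}: unparseable dose unit "
            f"{bad_units['dose_units'].iloc[0]!r} (expected uM or nM)")

    experiments = []
    for exp_id, group in frame.groupby("experiment_id", sort=False):
        dup = group.duplicated(subset=["drug", "time_min", "replicate"])
        if dup.any():
            line = int(group.index[dup][0]) + 2
            raise ConfigurationError(
                f"{path}, line {line}: duplicate (experiment, time, replicate) "
                f"entry in experiment {exp_id!r}")
        observables = group["observable"].unique()
        if len(observables) != 1:
            raise ConfigurationError(
                f"{path}: experiment {exp_id!r} mixes observables "
                f"{sorted(observables)}")
        entries = []
        for (drug, dose), _ in group.groupby(["drug", "dose"], sort=False):
            if drug != "none" and dose > 0:
                entries.append(StimulusEntry(str(drug), float(dose)))
        protocol = StimulusProtocol(tuple(entries))
        pivot = group.pivot_table(index="replicate", columns="time_min",
                                  values="value", aggfunc="mean")
        pivot = pivot.sort_index(axis=1)
        times = pivot.columns.to_numpy(float)
        replicates = pivot.to_numpy(float)
        if np.isnan(replicates).any():
            raise ConfigurationError(
                f"{path}: experiment {exp_id!r} has unbalanced replicates")
        experiments.append(ExperimentSeries.from_replicates(
            str(exp_id), protocol, str(observables[0]), times, replicates))
    return experiments


# -- model configuration ---------------------------------------------------

def config_to_dict(constants: BasalConstants, drugs: DrugParameters,
                   variant: ModelVariant, protocol: StimulusProtocol) -> dict:
    return {
        "constants": {k: float(v) for k, v in constants.__dict__.items()},
        "drugs": {
            "ki": {k: float(v) for k, v in drugs.ki.items()},
            "ac_influx": [
                {"drug": d, "dose": float(dose), "rate": float(x)}
                for (d, dose), x in sorted(drugs.ac_influx.items())
            ],
            "kf1": float(drugs.kf1),
            "kf2": float(drugs.kf2),
            "k_syn": float(drugs.k_syn),
            "ac_inhibitor_khalf": float(drugs.ac_inhibitor_khalf),
        },
        "variant": variant.name,
        "protocol": [
            {"drug": e.drug, "dose": float(e.dose), "onset": float(e.onset),
             "profile": e.profile,
             **({"half_life": float(e.half_life)}
                if e.half_life is not None else {})}
            for e in protocol.entries
        ],
    }


def config_from_dict(data: dict):
    constants = BasalConstants(**data.get("constants", {}))
    d = data.get("drugs", {})
    drugs = DrugParameters(
        ki=dict(d.get("ki", {"Milrinone": 2.0, "Cilostamide": 5.0})),
        ac_influx={(e["drug"], float(e["dose"])): float(e["rate"])
                   for e in d.get("ac_influx", [])},
        kf1=float(d.get("kf1", 0.0)),
        kf2=float(d.get("kf2", 0.0)),
        k_syn=float(d.get("k_syn", 1.0)),
        ac_inhibitor_khalf=float(d.get("ac_inhibitor_khalf", 20.0)),
    )
    variant = ModelVariant.from_name(data.get("variant", "H0"))
    protocol = StimulusProtocol(tuple(
        StimulusEntry(e["drug"], float(e["dose"]),
                      onset=float(e.get("onset", 0.0)),
                      profile=e.get("profile", "step"),
                      half_life=e.get("half_life"))
        for e in data.get("protocol", [])
    ))
    return constants, drugs, variant, protocol


def save_config(path, constants, drugs, variant, protocol) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(constants, drugs, variant, protocol),
                       fh, sort_keys=False)


def load_config(path):
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_hash(data: dict) -> str:
    return hashlib.sha256(
        json.dumps(data, sort_keys=True).encode()).hexdigest()[:16]


# -- fit results -----------------------------------------------------------

def fit_result_to_json(result: FitResult, path=None) -> str:
    """Serialize a fit result (parameters, chi2, provenance) to JSON."""
    payload = {
        "parameters": {k: float(v) for k, v in result.parameters.items()},
        "chi2": float(result.chi2),
        "n_points": int(result.n_points),
        "n_free": int(result.n_free),
        "variant": result.variant_name,
        "seed": result.seed,
        "data_hash": result.data_hash,
        "diagnostics": result.diagnostics,
        "trajectories": [np.asarray(t).tolist() for t in result.trajectories],
    }
    text = json.dumps(payload, indent=2, default=float)
    if path is not None:
        Path(path).write_text(text)
    return text


def fit_result_from_json(source) -> FitResult:
    text = Path(source).read_text() if isinstance(source, (str, Path)) and \
        str(source).endswith(".json") else str(source)
    payload = json.loads(text)
    return FitResult(
        parameters=payload["parameters"],
        chi2=payload["chi2"],
        n_points=payload["n_points"],
        n_free=payload["n_free"],
        trajectories=[np.asarray(t) for t in payload["trajectories"]],
        variant_name=payload["variant"],
        diagnostics=payload.get("diagnostics", {}),
        seed=payload.get("seed"),
        data_hash=payload.get("data_hash", ""),
    )
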