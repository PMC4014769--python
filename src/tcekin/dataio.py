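"""Readers and writers: datasets, configs, priors, posterior samples.

All tabular interchange is CSV (serum PK tables have no standard
bioinformatics format); structured configuration is YAML with sections
``physiology``, ``metabolism``, ``dosing`` and ``constants``.  Config
round-trips preserve values exactly (floats are written with full
precision).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .constants import MolecularConstants
from .data import ConcentrationDataset
from .mcmc import PosteriorSamples
from .params import (
    ConfigurationError,
    DoseRegimen,
    MetabolismParams,
    PhysiologyParams,
    default_metabolism,
    default_physiology,
    default_regimen,
)
from .population import PriorSpec

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_config",
    "write_config",
    "read_priors",
    "write_priors",
    "write_simulation_csv",
    "write_posterior",
    "read_posterior",
]


def read_dataset(path) -> ConcentrationDataset:
    """Load a concentration dataset CSV, validating the schema."""
    return ConcentrationDataset.from_csv(path)


def write_dataset(data: ConcentrationDataset, path) -> None:
    data.to_csv(path)


def _asdict_plain(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: v for k, v in d.items()}


def write_config(
    path,
    physiology: PhysiologyParams,
    metabolism: MetabolismParams,
    dosing: DoseRegimen,
    constants: MolecularConstants | None = None,
) -> None:
    doc = {
        "physiology": _asdict_plain(physiology),
        "metabolism": _asdict_plain(metabolism),
        "dosing": _asdict_plain(dosing),
        "constants": {"mw": dict((constants or MolecularConstants()).mw)},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path):
    """Load (physiology, metabolism, dosing, constants) from YAML.

    Missing sections fall back to package defaults; within a present
    section all fields are required (explicit is better than silently
    mixed provenance).
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    try:
        physiology = (
            PhysiologyParams(**doc["physiology"])
            if "physiology" in doc
            else default_physiology()
        )
        metabolism = (
            MetabolismParams(**doc["metabolism"])
            if "metabolism" in doc
            else default_metabolism()
        )
        dosing = (
            DoseRegimen(**doc["dosing"]) if "dosing" in doc else default_regimen()
        )
        constants = (
            MolecularConstants(mw=doc["constants"]["mw"])
            if "constants" in doc
            else MolecularConstants()
        )
    except TypeError as exc:
        raise ConfigurationError(f"bad config {path}: {exc}") from exc
    return physiology, metabolism, dosing, constants


def write_priors(path, priors: dict[str, PriorSpec]) -> None:
    doc = {
        name: {
            k: v
            for k, v in dataclasses.asdict(spec).items()
            if v is not None
        }
        for name, spec in priors.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_priors(path) -> dict[str, PriorSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigurationError(f"priors file {path} is not a mapping")
    out = {}
    for name, spec in doc.items():
        try:
            out[name] = PriorSpec(**spec)
        except TypeError as exc:
            raise ConfigurationError(
                f"bad prior spec for {name!r}: {exc}"
            ) from exc
    return out


def write_simulation_csv(output, path) -> None:
    """Tidy long-format simulation table: time_hr, variable, value, units."""
    output.to_tidy_frame().to_csv(path, index=False)


def write_posterior(samples: PosteriorSamples, csv_path, report_path=None,
                    diagnostics: dict | None = None) -> None:
    """Posterior draws as CSV plus a JSON sidecar with run metadata."""
    samples.to_frame().to_csv(csv_path, index=False)
    if report_path is not None:
        report = {
            "seed": samples.seed,
            "n_chains": samples.n_chains,
            "n_iter": samples.n_iter,
            "burn_fraction": samples.burn_fraction,
            "thin": samples.thin,
            "n_retained": samples.n_retained,
            "parameters": list(samples.names),
        }
        if diagnostics:
            report["gelman_rubin"] = {
                k: (None if not np.isfinite(v) else float(v))
                for k, v in diagnostics.items()
            }
        Path(report_path).write_text(json.dumps(report, indent=2))


def read_posterior(csv_path, **kwargs) -> PosteriorSamples:
    import pandas as pd

    return PosteriorSamples.from_frame(pd.read_csv(csv_path), **kwargs)
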