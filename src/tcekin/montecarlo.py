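"""Forward Monte Carlo uncertainty propagation.

Metabolism and excretion parameters are drawn from normal distributions
on the natural scale (mean = nominal value, SD = CV * mean, redrawn when
negative), all other parameters held fixed; each draw is simulated and
the pointwise percentile envelope of the predicted serum concentrations
summarises the spread.  The default run is 100 iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MEASURED_METABOLITES
from .params import (
    ConfigurationError,
    DoseRegimen,
    MetabolismParams,
    PhysiologyParams,
)
from .pbpk import simulate

__all__ = ["MCSpec", "VARIABLE_PARAMETERS", "sample_parameter_sets", "mc_envelope"]

#: parameters eligible for Monte Carlo variation: metabolism and
#: excretion of TCE, TCA, DCA, DCVG and DCVC
VARIABLE_PARAMETERS: tuple[str, ...] = (
    "VMax",
    "KM",
    "VMaxDCVG",
    "KMDCVG",
    "k_TCA_to_DCA",
    "k_urn_TCA",
    "k_TCOH_to_TCA",
    "k_TCOH_gluc",
    "k_TCOG_excr",
    "k_DCVG_to_DCVC",
    "k_DCVC_elim",
    "k12_DCA",
    "k21_DCA",
    "kE_DCA",
)

ENVELOPE_PERCENTILES: tuple[float, ...] = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass
class MCSpec:
    """What to vary, by how much, and for how many iterations."""

    varied_parameters: tuple[str, ...]
    coefficient_of_variation: float | dict[str, float] = 0.3
    means: dict[str, float] | None = None  # default: take from the base set
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [p for p in self.varied_parameters if p not in VARIABLE_PARAMETERS]
        if unknown:
            raise ConfigurationError(
                f"not metabolism/excretion parameters: {unknown}"
            )
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        for p in self.varied_parameters:
            if self.cv(p) < 0:
                raise ConfigurationError(f"CV for {p} must be >= 0")

    def cv(self, param: str) -> float:
        if isinstance(self.coefficient_of_variation, dict):
            return float(self.coefficient_of_variation[param])
        return float(self.coefficient_of_variation)


@dataclass
class ParameterSample:
    """Drawn parameter sets plus truncation bookkeeping."""

    sets: list[MetabolismParams]
    truncation_fraction: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def sample_parameter_sets(spec: MCSpec, base: MetabolismParams) -> ParameterSample:
    """Draw ``n_iterations`` parameter sets around the base values.

    Each varied parameter is Normal(mean, (CV * mean)^2) truncated at
    zero by redrawing; a parameter whose draws truncate more than half
    the time is flagged in ``warnings`` (its CV is so large the
    distribution is badly distorted).  Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    means = {
        p: (spec.means[p] if spec.means and p in spec.means
            else getattr(base, p))
        for p in spec.varied_parameters
    }
    sets: list[MetabolismParams] = []
    rejects = {p: 0 for p in spec.varied_parameters}
    draws_total = {p: 0 for p in spec.varied_parameters}
    for _ in range(spec.n_iterations):
        changes = {}
        for p in spec.varied_parameters:
            mean = means[p]
            sd = spec.cv(p) * mean
            if sd == 0.0:
                changes[p] = mean
                continue
            value = rng.normal(mean, sd)
            draws_total[p] += 1
            while value <= 0.0:
                rejects[p] += 1
                draws_total[p] += 1
                value = rng.normal(mean, sd)
            changes[p] = float(value)
        sets.append(base.replace(**changes))
    trunc = {
        p: (rejects[p] / draws_total[p] if draws_total[p] else 0.0)
        for p in spec.varied_parameters
    }
    warnings = [
        f"{p}: {frac:.0%} of draws truncated at 0 (CV too large?)"
        for p, frac in trunc.items()
        if frac > 0.5
    ]
    return ParameterSample(sets=sets, truncation_fraction=trunc, warnings=warnings)


def mc_envelope(
    parameter_sets,
    physiology: PhysiologyParams,
    regimen: DoseRegimen,
    times,
    metabolites=MEASURED_METABOLITES,
    percentiles=ENVELOPE_PERCENTILES,
    rtol: float = 1e-6,
) -> pd.DataFrame:
    """Pointwise concentration percentiles across Monte Carlo iterations.

    Returns a tidy frame (time_hr, metabolite, percentile, value); the
    bands are non-crossing by construction of the empirical percentiles.
    Iterations whose simulation fails are dropped, with the count
    recorded in ``frame.attrs['n_failed']``.
    """
    if isinstance(parameter_sets, ParameterSample):
        parameter_sets = parameter_sets.sets
    if len(parameter_sets) < 2:
        raise ValueError("need >= 2 parameter sets for an envelope")
    times = np.asarray(times, dtype=float)
    sims = []
    n_failed = 0
    for params in parameter_sets:
        try:
            out = simulate(physiology, params, regimen, times, rtol=rtol)
        except Exception:
            n_failed += 1
            continue
        sims.append([out.concentrations[m] for m in metabolites])
    if not sims:
        raise RuntimeError("all Monte Carlo simulations failed")
    cube = np.array(sims)  # (iter, metabolite, time)
    rows = []
    for mi, met in enumerate(metabolites):
        bands = np.percentile(cube[:, mi, :], percentiles, axis=0)
        for pi, pct in enumerate(percentiles):
            for ti, t in enumerate(times):
                rows.append((float(t), met, float(pct), float(bands[pi, ti])))
    frame = pd.DataFrame(rows, columns=["time_hr", "metabolite", "percentile",
                                        "value"])
    frame.attrs["n_failed"] = n_failed
    return frame
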