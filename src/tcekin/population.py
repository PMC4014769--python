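"""Hierarchical population model of interstrain variability.

Strains are related to an index strain (B6C3F1/J) through multiplicative
scaling factors psi: for each scaled PBPK parameter, a strain's value is
the study-level value theta times the strain's psi.  The psi are
exchangeable draws from a lognormal population distribution with
log-scale mean ``M_psi`` and variance ``V_psi``; the index strain is
pinned at psi = 1 and never sampled, which identifies theta.

Residuals between log observations and log model predictions are normal
with metabolite-specific variance ``sigma2`` (i.e. lognormal
multiplicative error), and observations below the limit of detection
contribute the probability mass below the LOD (left-censored lognormal
likelihood) rather than being dropped or substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr
from scipy.stats import invgamma

from .constants import MEASURED_METABOLITES
from .data import INDEX_STRAIN, ConcentrationDataset
from .params import ConfigurationError, MetabolismParams, PhysiologyParams

__all__ = [
    "DEFAULT_SCALED_PARAMETERS",
    "PSI_BOUNDS",
    "StrainScaling",
    "PopulationHyperparams",
    "PriorSpec",
    "default_priors",
    "strain_parameterize",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: metabolism and excretion parameters eligible for strain scaling
DEFAULT_SCALED_PARAMETERS: tuple[str, ...] = (
    "VMax",
    "KM",
    "VMaxDCVG",
    "KMDCVG",
    "k_TCA_to_DCA",
    "kE_DCA",
    "k_DCVG_to_DCVC",
    "k_DCVC_elim",
)

#: truncation bounds for strain scaling factors (ratio to the index strain)
PSI_BOUNDS: tuple[float, float] = (1.0 / 50.0, 50.0)


@dataclass
class StrainScaling:
    """Multiplicative ratios of one strain's parameters to the index strain."""

    strain_id: str
    psi: dict[str, float]

    def __post_init__(self) -> None:
        for name, value in self.psi.items():
            if not (math.isfinite(value) and value > 0):
                raise ConfigurationError(
                    f"psi[{name}] must be finite and > 0, got {value}"
                )
        if self.strain_id == INDEX_STRAIN:
            for name, value in self.psi.items():
                if value != 1.0:
                    raise ConfigurationError(
                        f"index strain psi must be exactly 1 (psi[{name}]={value})"
                    )

    @classmethod
    def index(cls, scaled_parameters=DEFAULT_SCALED_PARAMETERS) -> "StrainScaling":
        return cls(INDEX_STRAIN, {p: 1.0 for p in scaled_parameters})


@dataclass
class PopulationHyperparams:
    """Population means/variances (log scale) and residual variances."""

    M_psi: dict[str, float]
    V_psi: dict[str, float]
    sigma2: dict[str, float]
    M_theta: dict[str, float] | None = None
    V_theta: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for label, d in (("V_psi", self.V_psi), ("sigma2", self.sigma2)):
            for name, value in d.items():
                if not value > 0:
                    raise ConfigurationError(
                        f"{label}[{name}] must be > 0, got {value}"
                    )


@dataclass
class PriorSpec:
    """One marginal prior: family, location, scale, optional truncation.

    Families (densities over the natural parameter):

    - ``lognormal``: location/scale are the mean/SD of the log.
    - ``truncated_lognormal``: as lognormal, renormalised to
      [lower, upper] on the natural scale.
    - ``half_normal``: positive half of N(0, scale^2).
    - ``uniform_log``: flat on the log between lower and upper.
    - ``normal``: N(location, scale^2) on the real line.
    - ``inverse_gamma``: shape = location, rate = scale.
    """

    family: str
    location: float = 0.0
    scale: float = 1.0
    lower: float | None = None
    upper: float | None = None

    _FAMILIES = (
        "lognormal",
        "truncated_lognormal",
        "half_normal",
        "uniform_log",
        "normal",
        "inverse_gamma",
    )

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ConfigurationError(f"unknown prior family {self.family!r}")
        if self.family in ("truncated_lognormal", "uniform_log"):
            if self.lower is None or self.upper is None:
                raise ConfigurationError(
                    f"{self.family} requires finite lower/upper bounds"
                )
            if not (0 < self.lower < self.upper):
                raise ConfigurationError("bounds must satisfy 0 < lower < upper")
        if self.family in ("lognormal", "truncated_lognormal", "half_normal",
                           "normal") and not self.scale > 0:
            raise ConfigurationError("scale must be > 0")
        if self.family == "inverse_gamma" and not (
            self.location > 0 and self.scale > 0
        ):
            raise ConfigurationError("inverse_gamma needs shape > 0 and rate > 0")

    def logpdf(self, x: float) -> float:
        f = self.family
        if f == "normal":
            z = (x - self.location) / self.scale
            return -0.5 * (_LOG_2PI + z * z) - math.log(self.scale)
        if x <= 0:
            return -math.inf
        if f == "lognormal":
            u = math.log(x)
            z = (u - self.location) / self.scale
            return -0.5 * (_LOG_2PI + z * z) - math.log(self.scale) - u
        if f == "truncated_lognormal":
            if not (self.lower <= x <= self.upper):
                return -math.inf
            u = math.log(x)
            z = (u - self.location) / self.scale
            za = (math.log(self.lower) - self.location) / self.scale
            zb = (math.log(self.upper) - self.location) / self.scale
            log_z = math.log(ndtr(zb) - ndtr(za))
            return -0.5 * (_LOG_2PI + z * z) - math.log(self.scale) - u - log_z
        if f == "half_normal":
            z = x / self.scale
            return 0.5 * math.log(2.0 / math.pi) - math.log(self.scale) - 0.5 * z * z
        if f == "uniform_log":
            if not (self.lower <= x <= self.upper):
                return -math.inf
            return -math.log(x) - math.log(
                math.log(self.upper) - math.log(self.lower)
            )
        if f == "inverse_gamma":
            return float(invgamma.logpdf(x, self.location, scale=self.scale))
        raise AssertionError(f)

    def median(self) -> float:
        f = self.family
        if f == "normal":
            return self.location
        if f == "lognormal":
            return math.exp(self.location)
        if f == "truncated_lognormal":
            za = (math.log(self.lower) - self.location) / self.scale
            zb = (math.log(self.upper) - self.location) / self.scale
            pm = 0.5 * (ndtr(za) + ndtr(zb))
            from scipy.special import ndtri

            return math.exp(self.location + self.scale * ndtri(pm))
        if f == "half_normal":
            return 0.674489750196082 * self.scale
        if f == "uniform_log":
            return math.sqrt(self.lower * self.upper)
        if f == "inverse_gamma":
            return float(invgamma.median(self.location, scale=self.scale))
        raise AssertionError(f)


def default_priors(
    scaled_parameters=DEFAULT_SCALED_PARAMETERS,
    metabolites=MEASURED_METABOLITES,
) -> dict[str, PriorSpec]:
    """Weakly informative default priors for the hierarchy.

    ``M_psi`` is centred at 0 on the log scale (strains exchangeable
    around the index strain); the population log-scale SD gets a
    half-normal prior with scale ln(2.5); residual variances get an
    inverse-gamma prior allowing residual GSDs from ~1.1 to ~2.5.
    """
    priors: dict[str, PriorSpec] = {}
    for p in scaled_parameters:
        priors[f"M_psi_{p}"] = PriorSpec("normal", 0.0, 0.5)
        priors[f"sd_psi_{p}"] = PriorSpec("half_normal", scale=math.log(2.5))
    for m in metabolites:
        priors[f"sigma2_{m}"] = PriorSpec("inverse_gamma", 2.5, 0.3)
    return priors


def strain_parameterize(
    theta: MetabolismParams,
    psi: StrainScaling,
    phi: PhysiologyParams | None = None,
) -> MetabolismParams:
    """Apply strain scaling factors to the study-level parameter set.

    Every psi key must name a `MetabolismParams` field; the scaled value
    is theta * psi and unscaled parameters pass through.  The fixed
    physiological covariates ``phi`` are not strain-scaled.
    """
    changes = {}
    for name, ratio in psi.psi.items():
        if not hasattr(theta, name) or name == "V_dist":
            raise ConfigurationError(f"psi names unknown parameter {name!r}")
        changes[name] = getattr(theta, name) * ratio
    return theta.replace(**changes)


def log_likelihood(
    data: ConcentrationDataset,
    predictions: np.ndarray,
    sigma2: dict[str, float] | float,
) -> float:
    """Left-censored lognormal log likelihood of the dataset.

    ``predictions`` holds one model prediction (mg/L) per record, in row
    order.  An uncensored record contributes the lognormal density of
    its value about the prediction (log-scale variance sigma2 for its
    metabolite); a censored record contributes the probability that a
    lognormal draw falls below its LOD.  A non-positive prediction
    facing a positive observation yields -inf rather than an exception.
    """
    df = data.frame
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != (len(df),):
        raise ValueError(
            f"need one prediction per record ({len(df)}), got {predictions.shape}"
        )
    if isinstance(sigma2, dict):
        s2 = df["metabolite"].map(sigma2).to_numpy(dtype=float)
    else:
        s2 = np.full(len(df), float(sigma2))
    if np.any(~(s2 > 0)):
        raise ValueError("sigma2 must be > 0 for every metabolite")
    sd = np.sqrt(s2)

    censored = df["below_lod"].to_numpy()
    value = df["value_mg_L"].to_numpy(dtype=float)
    lod = df["lod_mg_L"].to_numpy(dtype=float)

    total = 0.0
    unc = ~censored
    if unc.any():
        f = predictions[unc]
        if np.any(f <= 0):
            return -math.inf
        r = (np.log(value[unc]) - np.log(f)) / sd[unc]
        total += float(
            np.sum(-np.log(value[unc]) - np.log(sd[unc])
                   - 0.5 * (_LOG_2PI + r * r))
        )
    if censored.any():
        f = predictions[censored]
        l = lod[censored]
        with np.errstate(divide="ignore"):
            # prediction 0 => certainly below LOD => contribution 0
            z = np.where(f > 0, (np.log(l) - np.log(np.maximum(f, 1e-300)))
                         / sd[censored], np.inf)
        total += float(np.sum(log_ndtr(z)))
    return total


def _psi_block_logpdf(
    log_psi: np.ndarray, m: float, v: float, bounds=PSI_BOUNDS
) -> float:
    """Log density of strain scalings for one parameter given (M, V).

    Truncated lognormal over the natural psi, expressed in terms of the
    log scalings; returns -inf outside the truncation bounds.
    """
    if not v > 0:
        return -math.inf
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    if np.any(log_psi < lo) or np.any(log_psi > hi):
        return -math.inf
    s = math.sqrt(v)
    z = (log_psi - m) / s
    log_norm = math.log(max(ndtr((hi - m) / s) - ndtr((lo - m) / s), 1e-300))
    return float(
        np.sum(-0.5 * (_LOG_2PI + z * z) - math.log(s) - log_psi)
        - log_norm * log_psi.size
    )


def log_prior(
    theta: MetabolismParams | None,
    psi: dict[str, StrainScaling],
    hyper: PopulationHyperparams,
    priors: dict[str, PriorSpec],
    scaled_parameters=None,
    psi_bounds=PSI_BOUNDS,
    theta_priors: dict[str, PriorSpec] | None = None,
) -> float:
    """Joint log prior of (theta, psi, hyperparameters).

    psi are truncated-lognormal given (M_psi, V_psi); the
    hyperparameters and residual variances follow their `PriorSpec`
    entries; theta parameters named in ``theta_priors`` follow theirs.
    Out-of-support values return -inf (rejection), never an exception.
    """
    if scaled_parameters is None:
        scaled_parameters = tuple(hyper.M_psi)
    total = 0.0
    for p in scaled_parameters:
        m = hyper.M_psi[p]
        v = hyper.V_psi[p]
        log_psi = np.array(
            [
                math.log(sc.psi[p])
                for sc in psi.values()
                if sc.strain_id != INDEX_STRAIN
            ]
        )
        total += _psi_block_logpdf(log_psi, m, v, psi_bounds)
        spec_m = priors.get(f"M_psi_{p}")
        if spec_m is not None:
            total += spec_m.logpdf(m)
        spec_s = priors.get(f"sd_psi_{p}")
        if spec_s is not None:
            total += spec_s.logpdf(math.sqrt(v))
    for name, s2 in hyper.sigma2.items():
        spec = priors.get(f"sigma2_{name}")
        if spec is not None:
            total += spec.logpdf(s2)
    if theta is not None and theta_priors:
        for name, spec in theta_priors.items():
            total += spec.logpdf(getattr(theta, name))
    return total if math.isfinite(total) or total == -math.inf else -math.inf


def log_posterior(
    data: ConcentrationDataset,
    theta: MetabolismParams,
    psi: dict[str, StrainScaling],
    hyper: PopulationHyperparams,
    priors: dict[str, PriorSpec],
    physiology: PhysiologyParams,
    regimen,
    scaled_parameters=None,
    rtol: float = 1e-6,
    theta_priors: dict[str, PriorSpec] | None = None,
) -> float:
    """Reference log posterior: prior plus PBPK-likelihood over strains.

    This is the direct (ODE-solving) path: each strain's parameters come
    from `strain_parameterize` and its records are compared against a
    fresh simulation.  A -inf prior short-circuits without touching the
    solver; a solver failure for a proposed parameter set yields -inf
    for that proposal.
    """
    from .forward import predictions_for_strain

    lp = log_prior(theta, psi, hyper, priors, scaled_parameters,
                   theta_priors=theta_priors)
    if lp == -math.inf:
        return -math.inf
    total = lp
    for strain_id in data.strains:
        scaling = psi.get(strain_id)
        if scaling is None:
            if strain_id != INDEX_STRAIN:
                raise ConfigurationError(f"no psi provided for strain {strain_id}")
            scaling = StrainScaling.index(scaled_parameters or tuple(hyper.M_psi))
        sub = data.for_strain(strain_id)
        try:
            preds = predictions_for_strain(
                sub, theta, scaling, physiology, regimen, rtol=rtol
            )
        except Exception:
            return -math.inf
        total += log_likelihood(sub, preds, hyper.sigma2)
        if total == -math.inf:
            return -math.inf
    return total
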