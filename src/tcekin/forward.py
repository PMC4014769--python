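"""Strain-level forward models and the sampler-facing posterior.

`DirectStrainModel` runs the PBPK ODE for every prediction and is the
reference path.  `TabulatedStrainModel` pre-solves the ODE on a grid of
the (at most two) strain-scaled parameters, refines the surface with a
bicubic spline and answers prediction queries by bilinear interpolation
of log concentrations on a fine grid.  Because a strain's predictions
depend on psi only through the scaled parameters, one table serves all
strains, which turns each Metropolis update into pure array arithmetic.
Tabulation error is far below the residual error of the data (the table
is validated against the direct model in the test suite).

`StrainHierarchyPosterior` assembles the hierarchical log posterior
(psi per strain, residual variances, population mean and SD per scaled
parameter) as a sum of terms with a sparse component->term dependency
map, which the component-wise Metropolis sampler exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.special import log_ndtr, ndtr

from .constants import MEASURED_METABOLITES, MolecularConstants
from .data import INDEX_STRAIN, ConcentrationDataset
from .params import (
    ConfigurationError,
    DoseRegimen,
    MetabolismParams,
    PhysiologyParams,
)
from .pbpk import simulate
from .population import (
    PSI_BOUNDS,
    PriorSpec,
    StrainScaling,
    default_priors,
    strain_parameterize,
)

_LOG_2PI = math.log(2.0 * math.pi)
_LOG_FLOOR = 1e-300


def predictions_for_strain(
    data: ConcentrationDataset,
    theta: MetabolismParams,
    scaling: StrainScaling,
    physiology: PhysiologyParams,
    regimen: DoseRegimen,
    rtol: float = 1e-6,
) -> np.ndarray:
    """Simulate one strain and return a prediction per data record."""
    params = strain_parameterize(theta, scaling, physiology)
    df = data.frame
    times = np.sort(df["time_hr"].unique())
    out = simulate(physiology, params, regimen, times, rtol=rtol)
    t_index = {t: i for i, t in enumerate(times)}
    preds = np.empty(len(df))
    for row, (met, t) in enumerate(zip(df["metabolite"], df["time_hr"])):
        preds[row] = out.concentrations[met][t_index[t]]
    return preds


class DirectStrainModel:
    """ODE-solving forward model: psi values -> log serum predictions.

    Predictions are returned as a flat array over (metabolite, time)
    pairs, metabolite-major, as log concentrations.
    """

    def __init__(
        self,
        physiology: PhysiologyParams,
        theta: MetabolismParams,
        regimen: DoseRegimen,
        times,
        scaled_parameters: tuple[str, ...],
        metabolites: tuple[str, ...] = MEASURED_METABOLITES,
        rtol: float = 1e-6,
    ) -> None:
        self.physiology = physiology
        self.theta = theta
        self.regimen = regimen
        self.times = np.asarray(times, dtype=float)
        self.scaled_parameters = tuple(scaled_parameters)
        self.metabolites = tuple(metabolites)
        self.rtol = rtol

    @property
    def n_outputs(self) -> int:
        return len(self.metabolites) * len(self.times)

    def log_predictions(self, psi_values: np.ndarray) -> np.ndarray:
        scaling = StrainScaling(
            "query", dict(zip(self.scaled_parameters, np.asarray(psi_values, float)))
        )
        params = strain_parameterize(self.theta, scaling, self.physiology)
        out = simulate(self.physiology, params, self.regimen, self.times,
                       rtol=self.rtol)
        flat = np.concatenate(
            [out.concentrations[m] for m in self.metabolites]
        )
        return np.log(np.maximum(flat, _LOG_FLOOR))


class TabulatedStrainModel:
    """Grid-tabulated forward model over one or two scaled parameters."""

    def __init__(
        self,
        direct: DirectStrainModel,
        log_bounds: tuple[float, float] = (
            math.log(PSI_BOUNDS[0]),
            math.log(PSI_BOUNDS[1]),
        ),
        n_solve: int = 33,
        n_fine: int = 321,
    ) -> None:
        if len(direct.scaled_parameters) not in (1, 2):
            raise ConfigurationError(
                "tabulation supports 1 or 2 scaled parameters; "
                "use DirectStrainModel otherwise"
            )
        self.direct = direct
        self.scaled_parameters = direct.scaled_parameters
        self.metabolites = direct.metabolites
        self.times = direct.times
        self.log_lo, self.log_hi = log_bounds
        coarse = np.linspace(self.log_lo, self.log_hi, n_solve)
        fine = np.linspace(self.log_lo, self.log_hi, n_fine)
        self._fine = fine
        self._step = fine[1] - fine[0]
        k = direct.n_outputs

        if len(self.scaled_parameters) == 1:
            vals = np.empty((n_solve, k))
            for i, u in enumerate(coarse):
                vals[i] = direct.log_predictions(np.exp([u]))
            from scipy.interpolate import CubicSpline

            table = CubicSpline(coarse, vals, axis=0)(fine)
            self._table = np.ascontiguousarray(table.T)  # (k, n_fine)
        else:
            vals = np.empty((n_solve, n_solve, k))
            for i, u in enumerate(coarse):
                for j, v in enumerate(coarse):
                    vals[i, j] = direct.log_predictions(np.exp([u, v]))
            table = np.empty((k, n_fine, n_fine))
            for out in range(k):
                spl = RectBivariateSpline(coarse, coarse, vals[:, :, out])
                table[out] = spl(fine, fine)
            self._table = np.ascontiguousarray(table)

    @property
    def n_outputs(self) -> int:
        return self.direct.n_outputs

    def log_predictions(self, psi_values: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of log concentrations at log psi."""
        u = np.log(np.asarray(psi_values, dtype=float))
        if np.any(u < self.log_lo) or np.any(u > self.log_hi):
            raise ValueError("psi outside tabulated range")
        pos = (u - self.log_lo) / self._step
        idx = np.minimum(pos.astype(int), self._fine.size - 2)
        w = pos - idx
        if u.size == 1:
            t = self._table
            return (1 - w[0]) * t[:, idx[0]] + w[0] * t[:, idx[0] + 1]
        t = self._table
        i, j = idx
        wi, wj = w
        return (
            (1 - wi) * (1 - wj) * t[:, i, j]
            + (1 - wi) * wj * t[:, i, j + 1]
            + wi * (1 - wj) * t[:, i + 1, j]
            + wi * wj * t[:, i + 1, j + 1]
        )


@dataclass
class _StrainData:
    """Per-strain record arrays aligned with the forward-model output grid."""

    strain_id: str
    unc_logy: np.ndarray
    unc_combo: np.ndarray
    unc_sig: np.ndarray
    cen_loglod: np.ndarray
    cen_combo: np.ndarray
    cen_sig: np.ndarray


class StrainHierarchyPosterior:
    """Component-wise log posterior of the strain hierarchy.

    Parameter vector (natural scale):

    - ``psi_<param>_<strain>`` for every non-index strain and scaled
      parameter (log-sampled, truncated to the psi bounds),
    - ``sigma2_<metabolite>`` residual log-scale variances,
    - ``M_psi_<param>`` population log-means,
    - ``sd_psi_<param>`` population log-scale SDs.

    The log posterior decomposes into per-strain likelihood terms,
    per-parameter psi-population terms (including hyperpriors) and
    residual-variance prior terms; `term_deps` maps each component to
    the terms it can change, so a Metropolis update touches only those.
    """

    def __init__(
        self,
        data: ConcentrationDataset,
        forward,
        priors: dict[str, PriorSpec] | None = None,
        psi_bounds: tuple[float, float] = PSI_BOUNDS,
    ) -> None:
        self.forward = forward
        self.scaled_parameters = tuple(forward.scaled_parameters)
        self.metabolites = tuple(forward.metabolites)
        self.priors = priors if priors is not None else default_priors(
            self.scaled_parameters, self.metabolites
        )
        self.psi_bounds = psi_bounds
        self._log_lo = math.log(psi_bounds[0])
        self._log_hi = math.log(psi_bounds[1])

        times = list(forward.times)
        mets = list(self.metabolites)
        n_t = len(times)

        self.strains = [s for s in data.strains if s != INDEX_STRAIN]
        self.all_strains = ([INDEX_STRAIN] if INDEX_STRAIN in data.strains else []) \
            + self.strains
        self._strain_data: list[_StrainData] = []
        for s in self.all_strains:
            df = data.for_strain(s).frame
            combo = np.array(
                [mets.index(m) * n_t + times.index(t)
                 for m, t in zip(df["metabolite"], df["time_hr"])]
            )
            sig = np.array([mets.index(m) for m in df["metabolite"]])
            cen = df["below_lod"].to_numpy()
            self._strain_data.append(
                _StrainData(
                    strain_id=s,
                    unc_logy=np.log(df["value_mg_L"].to_numpy()[~cen]),
                    unc_combo=combo[~cen],
                    unc_sig=sig[~cen],
                    cen_loglod=np.log(df["lod_mg_L"].to_numpy()[cen]),
                    cen_combo=combo[cen],
                    cen_sig=sig[cen],
                )
            )

        # parameter bookkeeping
        P = len(self.scaled_parameters)
        S = len(self.strains)
        M = len(self.metabolites)
        self.names: list[str] = []
        self.transforms: list[str] = []
        for p in self.scaled_parameters:
            for s in self.strains:
                self.names.append(f"psi_{p}_{s}")
                self.transforms.append("log")
        for m in mets:
            self.names.append(f"sigma2_{m}")
            self.transforms.append("log")
        for p in self.scaled_parameters:
            self.names.append(f"M_psi_{p}")
            self.transforms.append("none")
        for p in self.scaled_parameters:
            self.names.append(f"sd_psi_{p}")
            self.transforms.append("log")
        self.n_params = len(self.names)
        self._P, self._S, self._M = P, S, M
        self._psi_off = 0
        self._sig_off = P * S
        self._m_off = self._sig_off + M
        self._sd_off = self._m_off + P

        # terms: [strain logliks (len(all_strains))] + [psi blocks (P)] + [sigma2 priors (M)]
        self._n_strain_terms = len(self.all_strains)
        self.n_terms = self._n_strain_terms + P + M
        deps: list[list[int]] = [[] for _ in range(self.n_params)]
        for pi, p in enumerate(self.scaled_parameters):
            for si, s in enumerate(self.strains):
                c = self._psi_off + pi * S + si
                term_strain = self.all_strains.index(s)
                deps[c] = [term_strain, self._n_strain_terms + pi]
        for mi in range(M):
            c = self._sig_off + mi
            deps[c] = list(range(self._n_strain_terms)) + [
                self._n_strain_terms + P + mi
            ]
        for pi in range(P):
            deps[self._m_off + pi] = [self._n_strain_terms + pi]
            deps[self._sd_off + pi] = [self._n_strain_terms + pi]
        self._deps = [np.array(d, dtype=int) for d in deps]

        # per-strain prediction cache: psi tuple -> log predictions
        self._pred_cache: list[tuple[tuple, np.ndarray] | None] = [
            None for _ in self.all_strains
        ]

    # -- sampler protocol -------------------------------------------------

    def term_deps(self, component: int) -> np.ndarray:
        return self._deps[component]

    def _psi_for_strain_term(self, x: np.ndarray, term: int) -> tuple:
        s = self.all_strains[term]
        if s == INDEX_STRAIN:
            return tuple(1.0 for _ in self.scaled_parameters)
        si = self.strains.index(s)
        S = self._S
        return tuple(
            x[self._psi_off + pi * S + si] for pi in range(self._P)
        )

    def _strain_logpreds(self, term: int, psi: tuple) -> np.ndarray:
        cached = self._pred_cache[term]
        if cached is not None and cached[0] == psi:
            return cached[1]
        logpred = self.forward.log_predictions(np.array(psi))
        self._pred_cache[term] = (psi, logpred)
        return logpred

    def _strain_term(self, x: np.ndarray, term: int) -> float:
        psi = self._psi_for_strain_term(x, term)
        for v in psi:
            if not (self.psi_bounds[0] <= v <= self.psi_bounds[1]):
                return -math.inf
        logpred = self._strain_logpreds(term, psi)
        d = self._strain_data[term]
        sigma2 = x[self._sig_off:self._sig_off + self._M]
        total = 0.0
        if d.unc_logy.size:
            sd = np.sqrt(sigma2[d.unc_sig])
            r = (d.unc_logy - logpred[d.unc_combo]) / sd
            total += float(
                np.sum(-d.unc_logy - np.log(sd) - 0.5 * (_LOG_2PI + r * r))
            )
        if d.cen_loglod.size:
            sd = np.sqrt(sigma2[d.cen_sig])
            z = (d.cen_loglod - logpred[d.cen_combo]) / sd
            total += float(np.sum(log_ndtr(z)))
        return total

    def _psi_block_term(self, x: np.ndarray, pi: int) -> float:
        S = self._S
        log_psi = np.log(x[self._psi_off + pi * S:self._psi_off + (pi + 1) * S])
        m = x[self._m_off + pi]
        sd = x[self._sd_off + pi]
        if not sd > 0:
            return -math.inf
        if np.any(log_psi < self._log_lo) or np.any(log_psi > self._log_hi):
            return -math.inf
        z = (log_psi - m) / sd
        log_norm = math.log(
            max(ndtr((self._log_hi - m) / sd) - ndtr((self._log_lo - m) / sd),
                1e-300)
        )
        total = float(
            np.sum(-0.5 * (_LOG_2PI + z * z) - math.log(sd) - log_psi)
            - log_norm * S
        )
        p = self.scaled_parameters[pi]
        total += self.priors[f"M_psi_{p}"].logpdf(m)
        total += self.priors[f"sd_psi_{p}"].logpdf(sd)
        return total

    def _sigma2_term(self, x: np.ndarray, mi: int) -> float:
        m = self.metabolites[mi]
        return self.priors[f"sigma2_{m}"].logpdf(x[self._sig_off + mi])

    def logp_terms_subset(self, x: np.ndarray, idx) -> np.ndarray:
        out = np.empty(len(idx))
        for k, term in enumerate(idx):
            if term < self._n_strain_terms:
                out[k] = self._strain_term(x, term)
            elif term < self._n_strain_terms + self._P:
                out[k] = self._psi_block_term(x, term - self._n_strain_terms)
            else:
                out[k] = self._sigma2_term(
                    x, term - self._n_strain_terms - self._P
                )
        return out

    def logp_terms(self, x: np.ndarray) -> np.ndarray:
        return self.logp_terms_subset(x, np.arange(self.n_terms))

    def logp(self, x: np.ndarray) -> float:
        terms = self.logp_terms(x)
        if np.any(np.isneginf(terms)):
            return -math.inf
        return float(terms.sum())

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Prior medians jittered by up to ±20% on the log scale."""
        x = np.empty(self.n_params)
        S = self._S
        for pi in range(self._P):
            for si in range(S):
                x[self._psi_off + pi * S + si] = math.exp(
                    rng.uniform(-0.2, 0.2)
                )
        for mi, m in enumerate(self.metabolites):
            med = self.priors[f"sigma2_{m}"].median()
            x[self._sig_off + mi] = med * math.exp(rng.uniform(-0.2, 0.2))
        for pi, p in enumerate(self.scaled_parameters):
            x[self._m_off + pi] = self.priors[f"M_psi_{p}"].median() \
                + rng.uniform(-0.2, 0.2)
            x[self._sd_off + pi] = max(
                self.priors[f"sd_psi_{p}"].median(), 0.1
            ) * math.exp(rng.uniform(-0.2, 0.2))
        return x

    # -- convenience ------------------------------------------------------

    def psi_index(self, param: str, strain: str) -> int:
        return self.names.index(f"psi_{param}_{strain}")
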