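"""Hierarchical model: scaling, censored likelihood, priors, posterior."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import lognorm

import tcekin.forward as forward_mod
from tcekin.data import DATASET_COLUMNS, INDEX_STRAIN, ConcentrationDataset
from tcekin.forward import DirectStrainModel, StrainHierarchyPosterior
from tcekin.params import ConfigurationError, DoseRegimen, default_metabolism
from tcekin.population import (
    PopulationHyperparams,
    PriorSpec,
    StrainScaling,
    default_priors,
    log_likelihood,
    log_posterior,
    log_prior,
    strain_parameterize,
)


def _record(metabolite="TCA", time=2.0, value=1.0, censored=False, lod=0.1,
            strain=INDEX_STRAIN):
    return (
        "s1", strain, f"{strain}-a1", metabolite, time,
        float("nan") if censored else value, censored, lod,
    )


def _dataset(rows) -> ConcentrationDataset:
    return ConcentrationDataset(pd.DataFrame(rows, columns=list(DATASET_COLUMNS)))


class TestStrainParameterize:
    def test_unit_scaling_is_identity(self, metabolism):
        psi = StrainScaling("X", {"VMax": 1.0, "VMaxDCVG": 1.0})
        assert strain_parameterize(metabolism, psi) == metabolism

    def test_single_parameter_doubles(self, metabolism):
        psi = StrainScaling("X", {"VMax": 2.0})
        scaled = strain_parameterize(metabolism, psi)
        assert scaled.VMax == pytest.approx(2.0 * metabolism.VMax)
        assert scaled.KM == metabolism.KM
        assert scaled.VMaxDCVG == metabolism.VMaxDCVG

    def test_round_trip_recovers_psi(self, metabolism, rng):
        ratios = {"VMax": 1.7, "KM": 0.4, "k_DCVC_elim": 2.2}
        scaled = strain_parameterize(metabolism, StrainScaling("X", ratios))
        for name, ratio in ratios.items():
            recovered = getattr(scaled, name) / getattr(metabolism, name)
            assert recovered == pytest.approx(ratio, rel=1e-12)

    def test_unknown_parameter_rejected(self, metabolism):
        with pytest.raises(ConfigurationError):
            strain_parameterize(metabolism, StrainScaling("X", {"bogus": 2.0}))

    def test_index_strain_must_be_unscaled(self):
        with pytest.raises(ConfigurationError):
            StrainScaling(INDEX_STRAIN, {"VMax": 2.0})


class TestCensoredLikelihood:
    def test_density_at_mode_of_log_residual(self):
        sigma2 = 0.09
        value = 2.5
        data = _dataset([_record(value=value)])
        ll = log_likelihood(data, np.array([value]), {"TCA": sigma2})
        expected = -0.5 * math.log(2 * math.pi * sigma2) - math.log(value)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_censored_at_lod_equals_log_half(self):
        lod = 0.1
        data = _dataset([_record(censored=True, lod=lod)])
        ll = log_likelihood(data, np.array([lod]), {"TCA": 0.25})
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_vanishing_lod_is_impossible_event(self):
        data = _dataset([_record(censored=True, lod=1e-12)])
        ll = log_likelihood(data, np.array([1.0]), {"TCA": 0.04})
        assert ll < -1e3

    def test_nonpositive_prediction_with_observation_is_minus_inf(self):
        data = _dataset([_record(value=1.0)])
        assert log_likelihood(data, np.array([0.0]), {"TCA": 0.04}) == -math.inf

    def test_censored_contribution_matches_numeric_integration(self):
        """The censored mass equals the integral of the lognormal density
        from 0 to the LOD (independent quadrature oracle)."""
        sigma = 0.5
        pred = 0.7
        for lod in (0.1, 0.5, 0.7, 1.5):
            data = _dataset([_record(censored=True, lod=lod)])
            ll = log_likelihood(data, np.array([pred]), {"TCA": sigma**2})
            integral, _ = quad(
                lambda y: lognorm.pdf(y, s=sigma, scale=pred), 0.0, lod,
                epsabs=1e-12, epsrel=1e-12,
            )
            assert math.exp(ll) == pytest.approx(integral, abs=1e-6)

    def test_sum_over_records(self):
        rows = [_record(value=1.0), _record(metabolite="DCA", value=0.2),
                _record(metabolite="DCVC", censored=True, lod=0.05)]
        data = _dataset(rows)
        preds = np.array([1.2, 0.25, 0.04])
        sigma2 = {"TCA": 0.1, "DCA": 0.2, "DCVC": 0.3}
        total = log_likelihood(data, preds, sigma2)
        parts = sum(
            log_likelihood(_dataset([row]), preds[[i]], sigma2)
            for i, row in enumerate(rows)
        )
        assert total == pytest.approx(parts, rel=1e-12)


def _hyper(scaled=("VMax", "VMaxDCVG")):
    return PopulationHyperparams(
        M_psi={p: 0.0 for p in scaled},
        V_psi={p: 0.25 for p in scaled},
        sigma2={m: 0.07 for m in ("TCA", "DCA", "DCVG", "DCVC")},
    )


def _psi_map(values, scaled=("VMax", "VMaxDCVG")):
    out = {INDEX_STRAIN: StrainScaling.index(scaled)}
    for i, v in enumerate(values):
        out[f"S{i}"] = StrainScaling(f"S{i}", {p: v for p in scaled})
    return out


class TestLogPrior:
    def test_finite_in_truncation_interior(self):
        lp = log_prior(None, _psi_map([1.3, 0.6]), _hyper(), default_priors())
        assert math.isfinite(lp)

    def test_outside_truncation_is_minus_inf(self):
        lp = log_prior(None, _psi_map([60.0]), _hyper(), default_priors())
        assert lp == -math.inf

    def test_density_concentrates_as_population_variance_shrinks(self):
        """psi at the population geometric mean: log-density increases
        monotonically as V_psi decreases toward 0."""
        previous = -math.inf
        for v in (1.0, 0.25, 0.04, 0.01, 0.0025):
            hyper = _hyper()
            hyper.V_psi = {p: v for p in hyper.V_psi}
            lp = log_prior(None, _psi_map([1.0, 1.0]), hyper, default_priors())
            assert lp > previous
            previous = lp

    def test_block_additivity(self):
        """The joint prior is the sum of its psi, hyper and sigma2 blocks."""
        scaled = ("VMax",)
        hyper = _hyper(scaled)
        priors = default_priors(scaled)
        psi = _psi_map([1.5, 0.8], scaled)
        total = log_prior(None, psi, hyper, priors, scaled)

        no_hyper = {k: v for k, v in priors.items()
                    if not (k.startswith("M_psi") or k.startswith("sd_psi")
                            or k.startswith("sigma2"))}
        psi_block = log_prior(None, psi, hyper, no_hyper, scaled)
        hyper_block = (
            priors["M_psi_VMax"].logpdf(hyper.M_psi["VMax"])
            + priors["sd_psi_VMax"].logpdf(math.sqrt(hyper.V_psi["VMax"]))
        )
        sigma_block = sum(
            priors[f"sigma2_{m}"].logpdf(s2) for m, s2 in hyper.sigma2.items()
        )
        assert total == pytest.approx(psi_block + hyper_block + sigma_block,
                                      rel=1e-12)


def _tiny_dataset(strains=("S0", "S1"), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for strain in (INDEX_STRAIN,) + tuple(strains):
        for met, level in (("TCA", 100.0), ("DCVG", 0.5)):
            for t in (2.0, 8.0):
                rows.append(_record(metabolite=met, time=t,
                                    value=level * rng.lognormal(0, 0.2),
                                    strain=strain))
    return _dataset(rows)


class TestLogPosterior:
    scaled = ("VMax", "VMaxDCVG")

    def _args(self, physiology, metabolism, regimen, psi_values=(1.2, 0.8)):
        data = _tiny_dataset()
        psi = {
            INDEX_STRAIN: StrainScaling.index(self.scaled),
            "S0": StrainScaling("S0", dict(zip(self.scaled, psi_values))),
            "S1": StrainScaling("S1", {p: 1.0 for p in self.scaled}),
        }
        return data, metabolism, psi, _hyper(self.scaled), default_priors(self.scaled)

    def test_invalid_prior_short_circuits_without_simulation(
        self, physiology, metabolism, regimen, monkeypatch
    ):
        data, theta, psi, hyper, priors = self._args(physiology, metabolism, regimen)
        psi["S0"] = StrainScaling("S0", {p: 100.0 for p in self.scaled})
        calls = {"n": 0}

        def counting(*args, **kwargs):
            calls["n"] += 1
            raise AssertionError("simulation must not run")

        monkeypatch.setattr(forward_mod, "predictions_for_strain", counting)
        lp = log_posterior(data, theta, psi, hyper, priors, physiology, regimen,
                           self.scaled)
        assert lp == -math.inf
        assert calls["n"] == 0

    def test_posterior_difference_decomposes(self, physiology, metabolism, regimen):
        data, theta, psi_a, hyper, priors = self._args(physiology, metabolism, regimen)
        psi_b = dict(psi_a)
        psi_b["S0"] = StrainScaling("S0", dict(zip(self.scaled, (0.7, 1.4))))

        def lik(psi):
            total = 0.0
            for strain in data.strains:
                sub = data.for_strain(strain)
                preds = forward_mod.predictions_for_strain(
                    sub, theta, psi[strain], physiology, regimen
                )
                total += log_likelihood(sub, preds, hyper.sigma2)
            return total

        delta_post = (
            log_posterior(data, theta, psi_a, hyper, priors, physiology, regimen,
                          self.scaled)
            - log_posterior(data, theta, psi_b, hyper, priors, physiology, regimen,
                            self.scaled)
        )
        delta_prior = (
            log_prior(theta, psi_a, hyper, priors, self.scaled)
            - log_prior(theta, psi_b, hyper, priors, self.scaled)
        )
        delta_lik = lik(psi_a) - lik(psi_b)
        assert delta_post == pytest.approx(delta_prior + delta_lik, rel=1e-9)

    def test_exchangeability_of_non_index_strains(
        self, physiology, metabolism, regimen
    ):
        """Permuting non-index strain labels together with their psi leaves
        the posterior unchanged."""
        data, theta, psi, hyper, priors = self._args(physiology, metabolism, regimen)
        base = log_posterior(data, theta, psi, hyper, priors, physiology, regimen,
                             self.scaled)
        # swap S0 <-> S1 in both data and psi
        swapped_frame = data.frame.copy()
        swapped_frame["strain_id"] = swapped_frame["strain_id"].map(
            {"S0": "S1", "S1": "S0", INDEX_STRAIN: INDEX_STRAIN}
        )
        swapped_frame["animal_id"] = swapped_frame["animal_id"] + "x"
        swapped_data = ConcentrationDataset(swapped_frame)
        swapped_psi = {
            INDEX_STRAIN: psi[INDEX_STRAIN],
            "S0": StrainScaling("S0", dict(psi["S1"].psi)),
            "S1": StrainScaling("S1", dict(psi["S0"].psi)),
        }
        swapped = log_posterior(swapped_data, theta, swapped_psi, hyper, priors,
                                physiology, regimen, self.scaled)
        assert swapped == pytest.approx(base, rel=1e-12)

    def test_hierarchy_posterior_matches_reference_path(
        self, physiology, metabolism, regimen
    ):
        """The sampler-facing posterior (direct forward model) agrees with
        the reference log_posterior function on the same point."""
        data, theta, psi, hyper, priors = self._args(physiology, metabolism, regimen)
        direct = DirectStrainModel(
            physiology, theta, regimen, times=data.times,
            scaled_parameters=self.scaled,
        )
        post = StrainHierarchyPosterior(data, direct, priors=priors)
        x = np.empty(post.n_params)
        for pi, p in enumerate(self.scaled):
            for si, s in enumerate(post.strains):
                x[post._psi_off + pi * post._S + si] = psi[s].psi[p]
        for mi, m in enumerate(post.metabolites):
            x[post._sig_off + mi] = hyper.sigma2[m]
        for pi, p in enumerate(self.scaled):
            x[post._m_off + pi] = hyper.M_psi[p]
            x[post._sd_off + pi] = math.sqrt(hyper.V_psi[p])
        reference = log_posterior(data, theta, psi, hyper, priors, physiology,
                                  regimen, self.scaled)
        assert post.logp(x) == pytest.approx(reference, rel=1e-9)
        # the index strain's psi is fixed at 1 and never enters the
        # parameter vector
        assert not any(INDEX_STRAIN in name for name in post.names)


class TestPriorSpec:
    @pytest.mark.parametrize(
        "spec,x",
        [
            (PriorSpec("lognormal", 0.0, 1.0), 1.0),
            (PriorSpec("truncated_lognormal", 0.0, 1.0, 0.1, 10.0), 1.0),
            (PriorSpec("half_normal", scale=1.0), 0.5),
            (PriorSpec("uniform_log", lower=0.1, upper=10.0), 1.0),
            (PriorSpec("normal", 0.0, 1.0), 0.0),
            (PriorSpec("inverse_gamma", 2.5, 0.3), 0.1),
        ],
    )
    def test_logpdf_normalised(self, spec, x):
        """Each family integrates to 1 over its support (quadrature)."""
        if spec.lower is not None:
            integral, _ = quad(lambda y: math.exp(spec.logpdf(y)),
                               spec.lower, spec.upper, limit=200)
        elif spec.family == "normal":
            integral, _ = quad(lambda y: math.exp(spec.logpdf(y)),
                               -20.0, 20.0, limit=200)
        else:
            # positive unbounded support: integrate on the log scale
            integral, _ = quad(
                lambda u: math.exp(spec.logpdf(math.exp(u)) + u),
                -30.0, 30.0, limit=200,
            )
        assert integral == pytest.approx(1.0, rel=1e-5)
        assert math.isfinite(spec.logpdf(x))

    def test_median_is_median(self):
        for spec in (
            PriorSpec("lognormal", 0.3, 0.7),
            PriorSpec("truncated_lognormal", 0.0, 1.0, 0.5, 4.0),
            PriorSpec("half_normal", scale=2.0),
            PriorSpec("uniform_log", lower=0.2, upper=5.0),
            PriorSpec("inverse_gamma", 2.5, 0.3),
        ):
            med = spec.median()
            mass, _ = quad(lambda y: math.exp(spec.logpdf(y)), 1e-12, med,
                           limit=200)
            assert mass == pytest.approx(0.5, abs=1e-4)
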