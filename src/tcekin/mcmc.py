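"""Multi-chain component-wise Metropolis sampling with diagnostics.

The sampler is a component-wise random-walk Metropolis: positive
parameters are proposed on the log scale (with the Jacobian included in
the acceptance ratio, so the target remains the density over the natural
parameters), and each component carries its own step size, adapted
toward a target acceptance rate during burn-in only and frozen
afterwards so the stationary distribution is preserved.

Convergence is assessed with the split-chain potential scale reduction
factor: each chain is halved, and R is computed from the between- and
within-sequence variances of the resulting half-chains.  This is
stricter than the classic whole-chain diagnostic because it also detects
trends within a chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InitializationError",
    "PosteriorSamples",
    "run_chains",
    "gelman_rubin",
    "burn_thin",
]


class InitializationError(RuntimeError):
    """No finite-posterior starting point could be found."""


@dataclass
class PosteriorSamples:
    """Chain-tagged posterior draws with burn/thin metadata.

    ``draws`` has shape (n_chains, n_retained, n_params) on the natural
    parameter scale.  After `burn_thin`, the retained count per chain is
    floor((n_iter * (1 - burn_fraction)) / thin).
    """

    draws: np.ndarray
    names: list[str]
    n_chains: int
    n_iter: int
    burn_fraction: float = 0.0
    thin: int = 1
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must be (n_chains, n_retained, n_params)")
        if self.draws.shape[0] != self.n_chains:
            raise ValueError("chain count mismatch")
        if self.draws.shape[2] != len(self.names):
            raise ValueError("parameter name count mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.names.index(name)]

    def pooled(self) -> np.ndarray:
        """All chains concatenated: (n_retained, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self):
        import pandas as pd

        n_c, n_r, _ = self.draws.shape
        df = pd.DataFrame(self.pooled(), columns=self.names)
        df.insert(0, "iteration", np.tile(np.arange(n_r), n_c))
        df.insert(0, "chain", np.repeat(np.arange(n_c), n_r))
        return df

    @classmethod
    def from_frame(cls, df, **kwargs) -> "PosteriorSamples":
        names = [c for c in df.columns if c not in ("chain", "iteration")]
        chains = np.sort(df["chain"].unique())
        per_chain = [
            df[df["chain"] == c].loc[:, names].to_numpy() for c in chains
        ]
        draws = np.stack(per_chain)
        defaults = dict(
            n_chains=len(chains), n_iter=draws.shape[1], names=list(names)
        )
        defaults.update(kwargs)
        return cls(draws=draws, **defaults)


class _CallablePosterior:
    """Adapter giving a plain logp callable the terms interface."""

    def __init__(self, logp, x0, transforms=None, names=None):
        x0 = np.asarray(x0, dtype=float)
        self._logp = logp
        self._x0 = x0
        self.n_params = x0.size
        self.transforms = list(transforms) if transforms is not None \
            else ["none"] * self.n_params
        self.names = list(names) if names is not None \
            else [f"p{i}" for i in range(self.n_params)]
        self.n_terms = 1

    def term_deps(self, component: int) -> np.ndarray:
        return np.array([0])

    def logp_terms_subset(self, x, idx) -> np.ndarray:
        return np.array([self._logp(x)], dtype=float)

    def logp_terms(self, x) -> np.ndarray:
        return self.logp_terms_subset(x, [0])

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        jitter = rng.uniform(-0.2, 0.2, size=self.n_params)
        x = self._x0.copy()
        for i, tr in enumerate(self.transforms):
            if tr == "log":
                x[i] *= math.exp(jitter[i])
            else:
                x[i] += jitter[i]
        return x


def _run_one_chain(posterior, n_iter, rng, adapt_until, initial_step,
                   target_accept, max_init_tries):
    n_params = posterior.n_params
    transforms = posterior.transforms
    is_log = np.array([t == "log" for t in transforms])

    x = None
    for _ in range(max_init_tries):
        cand = np.asarray(posterior.initial_point(rng), dtype=float)
        terms = posterior.logp_terms(cand)
        if np.all(np.isfinite(terms)):
            x = cand
            break
    if x is None:
        raise InitializationError(
            f"no finite-posterior initial point in {max_init_tries} tries"
        )
    terms = np.asarray(terms, dtype=float)

    step = np.full(n_params, initial_step)
    acc_count = np.zeros(n_params)
    prop_count = np.zeros(n_params)
    batch = 50
    adapt_round = np.ones(n_params)

    draws = np.empty((n_iter, n_params))
    deps = [posterior.term_deps(c) for c in range(n_params)]

    for it in range(n_iter):
        adapting = it < adapt_until
        for c in range(n_params):
            xc = x[c]
            if is_log[c]:
                u_old = math.log(xc)
                u_new = u_old + step[c] * rng.standard_normal()
                x_new_c = math.exp(u_new)
                log_jac = u_new - u_old
            else:
                x_new_c = xc + step[c] * rng.standard_normal()
                log_jac = 0.0
            dep = deps[c]
            old_terms = terms[dep]
            x[c] = x_new_c
            new_terms = posterior.logp_terms_subset(x, dep)
            if np.any(np.isneginf(new_terms)):
                log_alpha = -math.inf
            else:
                log_alpha = float(np.sum(new_terms - old_terms)) + log_jac
            prop_count[c] += 1
            if log_alpha >= 0.0 or rng.random() < math.exp(log_alpha):
                terms[dep] = new_terms
                acc_count[c] += 1
            else:
                x[c] = xc
            if adapting and prop_count[c] >= batch:
                rate = acc_count[c] / prop_count[c]
                gain = 1.0 / math.sqrt(adapt_round[c])
                step[c] *= math.exp(gain * (rate - target_accept))
                step[c] = min(max(step[c], 1e-6), 50.0)
                acc_count[c] = 0.0
                prop_count[c] = 0.0
                adapt_round[c] += 1.0
        draws[it] = x
    accept_rate = np.where(prop_count > 0, acc_count / np.maximum(prop_count, 1),
                           np.nan)
    return draws, step, accept_rate


def run_chains(
    posterior,
    n_chains: int = 4,
    n_iter: int = 10_000,
    seed: int = 0,
    x0=None,
    transforms=None,
    names=None,
    adapt_fraction: float = 0.5,
    initial_step: float = 0.25,
    target_accept: float = 0.3,
    max_init_tries: int = 100,
) -> PosteriorSamples:
    """Run independent component-wise Metropolis chains.

    ``posterior`` is either an object implementing the terms protocol
    (``names``/``transforms``/``initial_point``/``logp_terms``/
    ``logp_terms_subset``/``term_deps``) or a plain callable
    ``logp(x) -> float``, in which case ``x0`` supplies the starting
    point and dimensionality.  Step sizes adapt toward
    ``target_accept`` during the first ``adapt_fraction`` of iterations
    and are frozen afterwards.  Runs are bit-reproducible given the
    seed.
    """
    if callable(posterior) and not hasattr(posterior, "logp_terms"):
        if x0 is None:
            raise ValueError("x0 is required when posterior is a plain callable")
        posterior = _CallablePosterior(posterior, x0, transforms, names)
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    adapt_until = int(adapt_fraction * n_iter)
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    all_draws = np.empty((n_chains, n_iter, posterior.n_params))
    final_steps = []
    accept_rates = []
    for ci in range(n_chains):
        rng = np.random.default_rng(seeds[ci])
        draws, step, acc = _run_one_chain(
            posterior, n_iter, rng, adapt_until, initial_step,
            target_accept, max_init_tries,
        )
        all_draws[ci] = draws
        final_steps.append(step)
        accept_rates.append(acc)
    return PosteriorSamples(
        draws=all_draws,
        names=list(posterior.names),
        n_chains=n_chains,
        n_iter=n_iter,
        seed=seed,
        meta={
            "adapt_until": adapt_until,
            "final_steps": np.array(final_steps),
            "post_adaptation_accept": np.array(accept_rates),
        },
    )


def burn_thin(samples: PosteriorSamples, burn_fraction: float, thin: int
              ) -> PosteriorSamples:
    """Discard burn-in and retain every ``thin``-th remaining iteration.

    Per chain, the post-burn-in segment has length
    L = floor(n_iter * (1 - burn_fraction)) and the retained count is
    floor(L / thin); the retained iterations are aligned so that the
    final iteration of each chain is kept.
    """
    if not 0.0 <= burn_fraction < 1.0:
        raise ValueError("burn_fraction must be in [0, 1)")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    n_iter = samples.draws.shape[1]
    post_len = int(n_iter * (1.0 - burn_fraction))
    kept = post_len // thin
    if kept == 0:
        raise ValueError(
            f"thin={thin} exceeds post-burn-in length {post_len}; nothing retained"
        )
    idx = n_iter - 1 - thin * np.arange(kept)[::-1]
    return PosteriorSamples(
        draws=samples.draws[:, idx, :].copy(),
        names=list(samples.names),
        n_chains=samples.n_chains,
        n_iter=samples.n_iter,
        burn_fraction=burn_fraction,
        thin=thin,
        seed=samples.seed,
        meta=dict(samples.meta),
    )


def gelman_rubin(samples: PosteriorSamples) -> dict[str, float]:
    """Split-chain potential scale reduction factor per parameter.

    Each chain's retained draws are halved; R is computed from the
    within- and between-sequence variances of the half-chains.  A
    parameter that is constant in every chain (zero within- and
    between-sequence variance) is reported as R = 1 by convention.
    """
    draws = samples.draws
    n_chains, n_kept, n_params = draws.shape
    if n_chains < 2:
        raise ValueError("need >= 2 chains for the diagnostic")
    if n_kept < 10:
        raise ValueError("need >= 10 retained draws per chain")
    half = n_kept // 2
    # 2 * n_chains sequences of length `half` (drop middle draw if odd)
    seqs = np.concatenate(
        [draws[:, :half, :], draws[:, n_kept - half:, :]], axis=0
    )
    m, n = seqs.shape[0], seqs.shape[1]
    means = seqs.mean(axis=1)  # (m, n_params)
    variances = seqs.var(axis=1, ddof=1)  # (m, n_params)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    grand = means.mean(axis=0)
    # variance below float round-off of the draws counts as exactly zero
    tol = 1e-24 * (1.0 + grand**2)
    out: dict[str, float] = {}
    for k, name in enumerate(samples.names):
        if W[k] <= tol[k]:
            out[name] = 1.0 if B[k] <= tol[k] else math.inf
        else:
            var_plus = (n - 1) / n * W[k] + B[k] / n
            out[name] = math.sqrt(var_plus / W[k])
    return out
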