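"""Ensemble MCMC plumbing shared by the windchill and phenology fits.

Thin wrapper around emcee's affine-invariant ensemble sampler with mandatory
seeding, multi-start initialisation from prior draws, and a generic posterior
container (flattened samples, summaries, diagnostics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import emcee

__all__ = ["MCMCConfig", "Posterior", "run_ensemble"]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    Defaults retain 13,200 samples (44 walkers x 300 post-burn-in steps),
    the sample size used for the reference-colony fits; reduce ``n_burn``
    and ``n_steps`` for quick exploratory fits.
    """

    n_walkers: int = 44
    n_burn: int = 1500
    n_steps: int = 300
    thin: int = 1
    n_start: int = 3000  # prior draws scored to seed the walkers
    init_scale: float = 0.02  # relative jitter of the initial walker ball

    @property
    def n_samples(self) -> int:
        return self.n_walkers * (self.n_steps // self.thin)


@dataclass
class Posterior:
    """Flattened MCMC samples plus summaries and diagnostics."""

    param_names: tuple[str, ...]
    samples: pd.DataFrame  # one column per parameter, chains flattened
    log_prob: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    derived: pd.DataFrame | None = None  # per-sample derived quantities

    @property
    def means(self) -> pd.Series:
        return self.samples.mean()

    @property
    def sds(self) -> pd.Series:
        return self.samples.std(ddof=1)

    def interval(self, level: float = 0.68269) -> pd.DataFrame:
        lo = (1.0 - level) / 2.0
        q = self.samples.quantile([lo, 1.0 - lo]).T
        q.columns = ["lower", "upper"]
        return q

    def map_estimate(self) -> pd.Series:
        return self.samples.iloc[int(np.argmax(self.log_prob))]


def run_ensemble(
    log_prob,
    sample_prior,
    ndim: int,
    param_names: tuple[str, ...],
    config: MCMCConfig,
    seed: int,
    start: np.ndarray | None = None,
) -> Posterior:
    """Run a seeded affine-invariant ensemble fit.

    ``sample_prior(rng, n)`` must return an (n, ndim) array of prior draws;
    the ``config.n_start`` best-scoring draws (optionally including an
    explicit ``start`` point) seed a small ball of walkers around the best
    one.  Emits a non-convergence warning when the acceptance fraction drops
    below 5 % or the effective sample size below 10 per parameter; samples
    are returned regardless.
    """
    rng = np.random.RandomState(seed % (2**31))
    draws = sample_prior(rng, config.n_start)
    if start is not None:
        draws = np.vstack([np.atleast_2d(start), draws])
    scores = np.array([log_prob(d) for d in draws])
    best = draws[int(np.nanargmax(np.where(np.isfinite(scores), scores, -np.inf)))]

    p0 = np.empty((config.n_walkers, ndim))
    n_ok = 0
    while n_ok < config.n_walkers:
        cand = best * (
            1.0 + config.init_scale * rng.randn(ndim)
        ) + 1e-4 * config.init_scale * rng.randn(ndim)
        if np.isfinite(log_prob(cand)):
            p0[n_ok] = cand
            n_ok += 1

    sampler = emcee.EnsembleSampler(config.n_walkers, ndim, log_prob)
    sampler.random_state = rng.get_state()
    state = sampler.run_mcmc(p0, config.n_burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, config.n_steps, thin_by=1, progress=False)

    chain = sampler.get_chain(thin=config.thin)  # (steps, walkers, ndim)
    flat = chain.reshape(-1, ndim)
    logp = sampler.get_log_prob(thin=config.thin).reshape(-1)

    accept = float(np.mean(sampler.acceptance_fraction))
    ess = _effective_sample_size(chain)
    diagnostics = {
        "acceptance_fraction": accept,
        "ess_min": float(np.min(ess)),
        "ess": {n: float(e) for n, e in zip(param_names, ess)},
        "n_samples": int(flat.shape[0]),
    }
    if accept < 0.05 or np.min(ess) < 10:
        warnings.warn(
            f"possible non-convergence: acceptance={accept:.3f}, "
            f"min ESS={np.min(ess):.0f}",
            RuntimeWarning,
            stacklevel=2,
        )
    return Posterior(
        param_names=tuple(param_names),
        samples=pd.DataFrame(flat, columns=list(param_names)),
        log_prob=logp,
        diagnostics=diagnostics,
    )


def _effective_sample_size(chain: np.ndarray) -> np.ndarray:
    """Per-parameter ESS via arviz (falls back to sample count on failure)."""
    try:
        import arviz as az

        # arviz expects (chains, draws, dim)
        data = np.moveaxis(chain, 0, 1)
        ess = az.ess(az.convert_to_dataset(data))
        return np.asarray(ess.to_array()).reshape(-1)
    except Exception:  # pragma: no cover - diagnostic fallback only
        return np.full(chain.shape[-1], float(chain.shape[0] * chain.shape[1]))
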