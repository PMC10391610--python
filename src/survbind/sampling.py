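"""Shared posterior-sampling infrastructure for the three binding models.

All models expose a normalized joint log-density (log-prior plus Gaussian
log-likelihood) vectorized over parameter vectors.  Sampling uses the
affine-invariant ensemble (stretch-move) MCMC of `emcee`, warm-started at a
penalized least-squares point estimate, with split-R̂ convergence
diagnostics computed by `arviz` treating each walker as a chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd

RHAT_LIMIT = 1.05


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler schedule.

    ``steps`` are the post-burn-in draws kept per walker; ``walkers`` defaults
    to twice the parameter count (rounded up to an even number, at least 64
    for low-dimensional models so the ensemble stays informative).
    """

    walkers: int | None = None
    steps: int = 500
    burn: int = 500
    seed: int = 0
    prior_only: bool = False
    thin: int = 1

    def resolve_walkers(self, ndim: int) -> int:
        w = self.walkers if self.walkers is not None else max(2 * ndim + 2, 64)
        if w < 2 * ndim:
            raise ValueError(f"need at least {2 * ndim} walkers for {ndim} parameters")
        return w + (w % 2)


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class PosteriorSamples:
    """Tabular posterior draws with chain/draw indices and diagnostics.

    ``draws`` has columns ``chain``, ``draw`` and one column per parameter;
    each walker of the ensemble is treated as one chain.
    """

    draws: pd.DataFrame
    rhat: dict[str, float]
    diagnostics: dict = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return [c for c in self.draws.columns if c not in ("chain", "draw")]

    def values(self, param: str) -> np.ndarray:
        return self.draws[param].to_numpy()

    def mean(self, param: str) -> float:
        return float(self.values(param).mean())

    def median(self, param: str) -> float:
        return float(np.median(self.values(param)))

    def interval(self, param: str, prob: float = 0.95) -> tuple[float, float]:
        """Central credible interval."""
        lo = (1.0 - prob) / 2.0
        q = np.quantile(self.values(param), [lo, 1.0 - lo])
        return float(q[0]), float(q[1])

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for p in self.parameters:
            ci68 = self.interval(p, 0.68)
            ci95 = self.interval(p, 0.95)
            out[p] = {
                "mean": self.mean(p),
                "median": self.median(p),
                "sd": float(self.values(p).std()),
                "ci68_low": ci68[0],
                "ci68_high": ci68[1],
                "ci95_low": ci95[0],
                "ci95_high": ci95[1],
                "rhat": self.rhat.get(p, float("nan")),
            }
        return out

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)


def _rhat(chain: np.ndarray, names: list[str], groups: int = 4) -> dict[str, float]:
    """Split-R̂ per parameter; ``chain`` has shape (walkers, draws, ndim).

    The ensemble is partitioned into ``groups`` walker groups, each treated
    as one chain (walkers' trajectories concatenated), mirroring a
    four-chain schedule: the diagnostic flags disagreement between separate
    parts of the ensemble.
    """
    nw, nd, ndim = chain.shape
    g = min(groups, nw)
    per = nw // g
    grouped = chain[: g * per].reshape(g, per * nd, ndim)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(names):
            ds = az.rhat(az.convert_to_dataset(grouped[:, :, j]))
            out[name] = float(ds["x"].values)
    return out


def _curvature_scales(log_prob, center: np.ndarray) -> np.ndarray:
    """Per-parameter posterior scales from the diagonal second differences
    of the log-density at ``center`` (a Laplace approximation ignoring
    correlations).  Falls back to a small relative scale where the density
    is locally flat or the center sits on a support edge."""
    ndim = center.size
    h = np.maximum(1e-5 * np.abs(center), 1e-9)
    points = np.vstack([center, center + np.diag(h), center - np.diag(h)])
    lp = log_prob(points)
    lp0, lp_plus, lp_minus = lp[0], lp[1 : 1 + ndim], lp[1 + ndim :]
    curv = -(lp_plus - 2.0 * lp0 + lp_minus) / h**2
    fallback = np.maximum(1e-3 * np.abs(center), 1e-4)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = 1.0 / np.sqrt(curv)
    bad = ~np.isfinite(sd) | (sd <= 0)
    sd[bad] = fallback[bad]
    return sd


def run_ensemble(
    model,
    config: SamplerConfig,
    key_params: list[str] | None = None,
) -> PosteriorSamples:
    """Sample a model's posterior (or prior if ``config.prior_only``).

    The model must provide ``param_names``, vectorized ``log_prior`` /
    ``log_likelihood`` over (walkers, ndim) arrays, ``initial_point()`` and
    ``sample_prior(rng, n)``.
    """
    names = list(model.param_names)
    ndim = len(names)
    nwalkers = config.resolve_walkers(ndim)
    rng = np.random.default_rng(config.seed)

    if config.prior_only:

        def log_prob(theta: np.ndarray) -> np.ndarray:
            return model.log_prior(theta)

        p0 = model.sample_prior(rng, nwalkers)
    else:

        def log_prob(theta: np.ndarray) -> np.ndarray:
            lp = model.log_prior(theta)
            ok = np.isfinite(lp)
            out = np.full(lp.shape, -np.inf)
            if np.any(ok):
                out[ok] = lp[ok] + model.log_likelihood(theta[ok])
            return out

        center = np.asarray(model.initial_point(), dtype=float)
        # overdisperse walkers at ~3x the Laplace (diagonal-curvature) scale
        # so the ensemble starts wider than the posterior and the moves see
        # the right length scales immediately
        scale = 3.0 * _curvature_scales(log_prob, center)
        p0 = center + scale * rng.standard_normal((nwalkers, ndim))
        # resample any walker that landed outside the prior support
        bad = ~np.isfinite(model.log_prior(p0))
        tries = 0
        while np.any(bad) and tries < 100:
            p0[bad] = center + scale * rng.standard_normal((int(bad.sum()), ndim))
            bad = ~np.isfinite(model.log_prior(p0))
            tries += 1
        if np.any(bad):
            p0[bad] = model.sample_prior(rng, int(bad.sum()))

    # differential-evolution moves mix far better than the default stretch
    # move once the parameter count is large (the MST model has 4 + 4*n_cap)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)
    ).get_state()
    sampler.run_mcmc(p0, config.burn + config.steps, progress=False)
    chain = sampler.get_chain(discard=config.burn, thin=config.thin)
    chain = np.swapaxes(chain, 0, 1)  # -> (walkers, draws, ndim)

    rhat = _rhat(chain, names)
    key_params = key_params or names
    worst = max(rhat[p] for p in key_params if np.isfinite(rhat[p]))
    if worst > RHAT_LIMIT:
        warnings.warn(
            f"split-R-hat {worst:.3f} exceeds {RHAT_LIMIT} for key parameters; "
            "treat the posterior as unconverged",
            ConvergenceWarning,
        )

    nw, nd, _ = chain.shape
    flat = chain.reshape(nw * nd, ndim)
    df = pd.DataFrame(flat, columns=names)
    df.insert(0, "draw", np.tile(np.arange(nd), nw))
    df.insert(0, "chain", np.repeat(np.arange(nw), nd))
    return PosteriorSamples(
        draws=df,
        rhat=rhat,
        diagnostics={
            "walkers": nw,
            "draws_per_walker": nd,
            "acceptance_fraction": float(sampler.acceptance_fraction.mean()),
            "max_rhat_key_params": worst,
        },
    )


# small normalized log-density helpers shared by the model modules


def log_uniform_pdf(x: np.ndarray, lower: float, upper: float) -> np.ndarray:
    out = np.full(np.shape(x), -np.inf, dtype=float)
    inside = (x >= lower) & (x <= upper)
    out[inside] = -np.log(upper - lower)
    return out


def log_beta_pdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    from scipy.special import betaln

    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, -np.inf)
    inside = (x > 0) & (x < 1)
    xi = x[inside]
    out[inside] = (a - 1) * np.log(xi) + (b - 1) * np.log1p(-xi) - betaln(a, b)
    return out


def log_lognormal_pdf(x: np.ndarray, mu: float = 0.0, tau: float = 1.0) -> np.ndarray:
    """Log-normal with precision parameterization (tau = 1/sigma^2)."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, -np.inf)
    inside = x > 0
    xi = x[inside]
    lx = np.log(xi)
    out[inside] = (
        0.5 * np.log(tau) - np.log(xi) - 0.5 * np.log(2 * np.pi)
        - 0.5 * tau * (lx - mu) ** 2
    )
    return out


def log_truncnorm_pdf(
    x: np.ndarray, mu: float, sigma: float, lower: float
) -> np.ndarray:
    """Normal(mu, sigma) truncated below at ``lower`` (no upper bound)."""
    from scipy.special import log_ndtr

    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, -np.inf)
    inside = x >= lower
    z = (x[inside] - mu) / sigma
    log_z_norm = log_ndtr(-(lower - mu) / sigma)  # log P(X >= lower)
    out[inside] = (
        -np.log(sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * z**2 - log_z_norm
    )
    return out


def gaussian_loglike(y: np.ndarray, mean: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Sum of independent Normal(mean, eps) log-densities.

    ``y`` has shape (N,), ``mean`` (W, N), ``eps`` (W,); returns (W,).
    """
    n = y.shape[-1]
    resid2 = np.sum((y[None, :] - mean) ** 2, axis=-1)
    return -0.5 * n * np.log(2 * np.pi) - n * np.log(eps) - 0.5 * resid2 / eps**2
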