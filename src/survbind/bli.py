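"""Bayesian 1:1 Langmuir kinetics for biolayer-interferometry traces.

Association and dissociation phases of each analyte concentration are
modelled simultaneously.  The association phase rises to the equilibrium
plateau A*c/(KD_app + c) with observed rate k_on*c + k_off; the dissociation
phase decays single-exponentially with rate k_off from a per-trace starting
shift delta0.  k_on is the deterministic ratio k_off / KD_app.  delta0
carries an empirical-Bayes truncated-normal prior built from the first
second of the dissociation phase.

Concentrations are molar inside the model (the printed prior supports are
only sensible in molar); wavelength shifts are dimensionless after division
by 1 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .sampling import (
    PosteriorSamples,
    SamplerConfig,
    gaussian_loglike,
    log_truncnorm_pdf,
    log_uniform_pdf,
    run_ensemble,
)

KD_BOUNDS = (1e-15, 1e-3)  # M
KOFF_BOUNDS = (1e-20, 10.0)  # 1/s
A_BOUNDS = (1e-6, 10.0)
EPS_BOUNDS = (1e-6, 1.0)
DELTA0_LOWER = 1e-20


@dataclass(frozen=True)
class BLITrace:
    """One analyte concentration: association and dissociation samples.

    Each phase has its own clock starting at 0 s.
    """

    trace_id: str
    conc: float  # M
    t_assoc: np.ndarray
    y_assoc: np.ndarray
    t_dissoc: np.ndarray
    y_dissoc: np.ndarray

    def __post_init__(self) -> None:
        if self.conc <= 0:
            raise ValueError(f"trace {self.trace_id}: concentration must be > 0")
        for name in ("t_assoc", "y_assoc", "t_dissoc", "y_dissoc"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        for t, y, phase in (
            (self.t_assoc, self.y_assoc, "association"),
            (self.t_dissoc, self.y_dissoc, "dissociation"),
        ):
            if t.shape != y.shape:
                raise ValueError(f"trace {self.trace_id}: {phase} shape mismatch")
            if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
                raise ValueError(
                    f"trace {self.trace_id}: {phase} times must be >= 0, increasing"
                )
            if not np.all(np.isfinite(y)):
                raise ValueError(f"trace {self.trace_id}: non-finite {phase} shifts")


@dataclass(frozen=True)
class Delta0Prior:
    """Empirical-Bayes prior for the dissociation starting shift."""

    mu: float
    sigma: float
    lower: float = DELTA0_LOWER


def association_mean(t, c, KD_app, k_on, k_off, A):
    """Expected shift during association: plateau times (1 - e^{-(k_on c + k_off) t})."""
    t = np.asarray(t, dtype=float)
    out = A * c / (KD_app + c) * (1.0 - np.exp(-(k_on * c + k_off) * t))
    return out if out.shape else float(out)


def dissociation_mean(t, delta0, k_off):
    """Expected shift during dissociation: delta0 * e^{-k_off t}."""
    t = np.asarray(t, dtype=float)
    out = delta0 * np.exp(-k_off * t)
    return out if out.shape else float(out)


def delta0_prior_params(
    trace: BLITrace,
    window: float = 1.0,
    sigma_floor_frac: float = 1e-3,
) -> Delta0Prior:
    """Truncated-normal prior for delta0 from early-dissociation samples.

    mu is the mean of the samples with t in [0, window]; sigma is one tenth
    of their population standard deviation, floored at ``sigma_floor_frac``
    of |mu| (plus a tiny absolute floor) so a constant window still yields a
    proper prior.
    """
    sel = trace.t_dissoc <= window
    vals = trace.y_dissoc[sel]
    if vals.size < 2:
        raise ValueError(
            f"trace {trace.trace_id}: need >= 2 dissociation samples in "
            f"[0, {window}] s for the empirical-Bayes delta0 prior"
        )
    mu = float(vals.mean())
    sigma = float(np.sqrt(np.mean((vals - mu) ** 2))) / 10.0
    floor = max(sigma_floor_frac * abs(mu), 1e-9)
    return Delta0Prior(mu=mu, sigma=max(sigma, floor), lower=DELTA0_LOWER)


class BLIModel:
    """Shared (KD_app, k_off, A, epsilon) plus per-trace delta0.

    Printed priors: KD_app ~ Uniform(1e-15, 1e-3) M; k_off ~ Uniform(1e-20,
    10) 1/s; A ~ Uniform(1e-6, 10); epsilon ~ Uniform(1e-6, 1); delta0 ~
    TruncatedNormal(empirical-Bayes mu, sigma; lower 1e-20).  Gaussian
    likelihoods with the single scale epsilon in both phases.
    """

    def __init__(self, traces: list[BLITrace]) -> None:
        if not traces:
            raise ValueError("need at least one trace")
        for tr in traces:
            if tr.t_assoc.size == 0 or tr.t_dissoc.size == 0:
                raise ValueError(f"trace {tr.trace_id}: both phases required")
        self.traces = list(traces)
        self.n_tr = len(traces)
        self.delta0_priors = [delta0_prior_params(tr) for tr in traces]
        self.conc = np.array([tr.conc for tr in traces])
        self.ta = np.concatenate([tr.t_assoc for tr in traces])
        self.ya = np.concatenate([tr.y_assoc for tr in traces])
        self.ia = np.concatenate(
            [np.full(tr.t_assoc.size, i) for i, tr in enumerate(traces)]
        )
        self.td = np.concatenate([tr.t_dissoc for tr in traces])
        self.yd = np.concatenate([tr.y_dissoc for tr in traces])
        self.id_ = np.concatenate(
            [np.full(tr.t_dissoc.size, i) for i, tr in enumerate(traces)]
        )
        self.param_names = ["KD_app", "k_off", "A", "epsilon"] + [
            f"delta0_{tr.trace_id}" for tr in traces
        ]

    def _unpack(self, theta: np.ndarray):
        return (
            theta[..., 0],
            theta[..., 1],
            theta[..., 2],
            theta[..., 3],
            theta[..., 4:],
        )

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        KD, koff, A, eps, d0 = self._unpack(theta)
        lp = log_uniform_pdf(KD, *KD_BOUNDS)
        lp = lp + log_uniform_pdf(koff, *KOFF_BOUNDS)
        lp = lp + log_uniform_pdf(A, *A_BOUNDS)
        lp = lp + log_uniform_pdf(eps, *EPS_BOUNDS)
        for j, pr in enumerate(self.delta0_priors):
            lp = lp + log_truncnorm_pdf(d0[..., j], pr.mu, pr.sigma, pr.lower)
        return lp

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        KD, koff, A, eps, d0 = self._unpack(theta)
        kon = koff / KD
        c = self.conc[self.ia][None, :]
        mean_a = (
            A[:, None] * c / (KD[:, None] + c)
            * (1.0 - np.exp(-(kon[:, None] * c + koff[:, None]) * self.ta[None, :]))
        )
        mean_d = d0[:, self.id_] * np.exp(-koff[:, None] * self.td[None, :])
        return gaussian_loglike(self.ya, mean_a, eps) + gaussian_loglike(
            self.yd, mean_d, eps
        )

    def log_density(self, theta: np.ndarray) -> float:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        lp = self.log_prior(theta)
        if not np.isfinite(lp[0]):
            return float(lp[0])
        return float(lp[0] + self.log_likelihood(theta)[0])

    def sample_prior(self, rng: np.random.Generator, n: int) -> np.ndarray:
        from scipy.stats import truncnorm

        cols = [
            rng.uniform(*KD_BOUNDS, n),
            rng.uniform(*KOFF_BOUNDS, n),
            rng.uniform(*A_BOUNDS, n),
            rng.uniform(*EPS_BOUNDS, n),
        ]
        for pr in self.delta0_priors:
            a = (pr.lower - pr.mu) / pr.sigma
            cols.append(
                truncnorm.rvs(
                    a, np.inf, loc=pr.mu, scale=pr.sigma, size=n, random_state=rng
                )
            )
        return np.column_stack(cols)

    def initial_point(self) -> np.ndarray:
        # k_off from a log-linear fit to the highest-concentration dissociation
        hi = int(np.argmax(self.conc))
        tr = self.traces[hi]
        pos = tr.y_dissoc > 0
        if pos.sum() >= 2:
            slope = np.polyfit(tr.t_dissoc[pos], np.log(tr.y_dissoc[pos]), 1)[0]
            koff0 = float(np.clip(-slope, 1e-6, 1.0))
        else:
            koff0 = 1e-3
        KD0 = float(np.median(self.conc))
        plateau = max(float(tr.y_assoc[-5:].mean()), 1e-3)
        A0 = float(np.clip(plateau * (KD0 + tr.conc) / tr.conc, 1e-3, 9.0))
        d00 = np.array([max(pr.mu, 1e-6) for pr in self.delta0_priors])

        x0 = np.concatenate([[KD0, koff0, A0], d00])
        lo = np.concatenate(
            [[KD_BOUNDS[0], 1e-8, A_BOUNDS[0]], np.full(self.n_tr, 1e-12)]
        )
        hi_b = np.concatenate(
            [[KD_BOUNDS[1], KOFF_BOUNDS[1], A_BOUNDS[1]], np.full(self.n_tr, 20.0)]
        )

        def residuals(x: np.ndarray) -> np.ndarray:
            theta = np.concatenate([x[:3], [1.0], x[3:]])[None, :]
            KD, koff, A, _, d0 = self._unpack(theta)
            kon = koff / KD
            c = self.conc[self.ia][None, :]
            ra = self.ya - (
                A[:, None] * c / (KD[:, None] + c)
                * (1 - np.exp(-(kon[:, None] * c + koff[:, None]) * self.ta[None, :]))
            )
            rd = self.yd - d0[:, self.id_] * np.exp(
                -koff[:, None] * self.td[None, :]
            )
            return np.concatenate([ra[0], rd[0]])

        try:
            fit = least_squares(
                residuals, x0, bounds=(lo, hi_b), x_scale="jac", max_nfev=2000
            )
            x = fit.x
            eps = float(np.clip(np.std(fit.fun), EPS_BOUNDS[0] * 2, 0.5))
        except Exception:
            x = x0
            eps = float(np.clip(np.std(residuals(x0)), EPS_BOUNDS[0] * 2, 0.5))
        return np.concatenate([x[:3], [eps], x[3:]])


def build_bli_model(traces: list[BLITrace]) -> BLIModel:
    return BLIModel(traces)


def fit_bli(
    traces: list[BLITrace], config: SamplerConfig = SamplerConfig()
) -> PosteriorSamples:
    model = build_bli_model(traces)
    return run_ensemble(model, config, key_params=["KD_app", "k_off", "A", "epsilon"])


def summarize_bli(posterior: PosteriorSamples, conc_unit: str = "M") -> dict:
    """Point estimates and 68/95% intervals for KD_app, k_off and derived k_on.

    k_on is summarized from the per-draw ratio k_off / KD_app, not refit.
    """
    if posterior.draws.empty:
        raise ValueError("empty posterior")
    scale = {"M": 1.0, "nM": 1e9}[conc_unit]
    kd = posterior.values("KD_app") * scale
    koff = posterior.values("k_off")
    kon = posterior.values("k_off") / posterior.values("KD_app") / scale

    def _summ(x: np.ndarray) -> dict:
        return {
            "mean": float(x.mean()),
            "median": float(np.median(x)),
            "ci68": tuple(float(v) for v in np.quantile(x, [0.16, 0.84])),
            "ci95": tuple(float(v) for v in np.quantile(x, [0.025, 0.975])),
        }

    return {
        "conc_unit": conc_unit,
        "KD_app": _summ(kd),
        "k_off_per_s": _summ(koff),
        "k_on": _summ(kon),
        "rhat": {p: posterior.rhat.get(p) for p in ("KD_app", "k_off", "A", "epsilon")},
    }
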