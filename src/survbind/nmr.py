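"""NMR titration analysis: global intensity, logistic critical-peptide-
concentration (cpc) inference, and 1-2-1 secondary-shift smoothing.

The global signal of a 2D spectrum is quantified as the sum of its 200
highest cells, normalized to the lowest-concentration reference point.
The normalized intensity versus peptide concentration (dimensionless, in
units of 1 mM) is modelled with a logistic function of log10 concentration
whose midpoint is the critical peptide concentration:

    I_norm(c) = L / (1 + exp(-k (log10 c - log10 cpc))) + b

with Gaussian observation noise of scale epsilon < 0.05 a priori.  Because
the functional form is a convenience, the relative ordering of cpc across
peptides is more trustworthy than its absolute magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .sampling import (
    PosteriorSamples,
    SamplerConfig,
    gaussian_loglike,
    log_uniform_pdf,
    run_ensemble,
)

LOG10_CPC_BOUNDS = (-10.0, 1.0)
K_BOUNDS = (-10.0, 10.0)
L_BOUNDS = (-3.0, 3.0)
B_BOUNDS = (-10.0, 10.0)
EPS_UPPER = 0.05


@dataclass(frozen=True)
class NMRTitrationSeries:
    """Normalized global intensity versus dimensionless concentration (c/1 mM)."""

    peptide_id: str
    conc: np.ndarray
    i_norm: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.conc, dtype=float)
        i = np.asarray(self.i_norm, dtype=float)
        object.__setattr__(self, "conc", c)
        object.__setattr__(self, "i_norm", i)
        if c.shape != i.shape or c.ndim != 1:
            raise ValueError("conc and i_norm must be 1-D arrays of equal length")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if not np.all(np.isfinite(i)):
            raise ValueError("non-finite intensities")

    def positive(self) -> "NMRTitrationSeries":
        """Drop zero-concentration (reference-only) points for the logistic fit."""
        sel = self.conc > 0
        return NMRTitrationSeries(self.peptide_id, self.conc[sel], self.i_norm[sel])


def global_intensity(spectrum: np.ndarray, top_n: int = 200) -> float:
    """Sum of the ``top_n`` largest cells of a 2D spectrum matrix."""
    values = np.asarray(spectrum, dtype=float).ravel()
    if values.size < top_n:
        raise ValueError(f"spectrum has {values.size} cells, need >= {top_n}")
    if not np.all(np.isfinite(values)):
        raise ValueError("spectrum contains non-finite values")
    return float(np.partition(values, -top_n)[-top_n:].sum())


def normalize_series(
    conc: np.ndarray, totals: np.ndarray, peptide_id: str = "peptide"
) -> NMRTitrationSeries:
    """Normalize raw global intensities by the lowest-concentration reference."""
    conc = np.asarray(conc, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if conc.shape != totals.shape:
        raise ValueError("conc and totals must have equal length")
    ref = totals[np.argmin(conc)]
    if ref == 0:
        raise ValueError("reference (lowest-concentration) intensity is zero")
    return NMRTitrationSeries(peptide_id, conc, totals / ref)


def logistic_mean(c, log10_cpc, k, L, b):
    """Expected normalized intensity; sigmoidal in log10 c with midpoint cpc."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be > 0 (log10 undefined at 0)")
    out = L / (1.0 + np.exp(-k * (np.log10(c) - log10_cpc))) + b
    return out if out.shape else float(out)


class CPCModel:
    """Posterior over (log10_cpc, k, L, b, epsilon) for one titration series.

    Printed priors: log10 cpc ~ Uniform(-10, 1); k ~ Uniform(-10, 10);
    L ~ Uniform(-3, 3); b ~ Uniform(-10, 10); epsilon ~ Uniform(0, 0.05].
    """

    param_names = ["log10_cpc", "k", "L", "b", "epsilon"]

    def __init__(self, series: NMRTitrationSeries) -> None:
        series = series.positive()
        if series.conc.size < 4:
            raise ValueError("need >= 4 titration points with c > 0")
        self.series = series
        self.log10_c = np.log10(series.conc)
        self.y = series.i_norm

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        lcpc, k, L, b, eps = (theta[..., j] for j in range(5))
        lp = log_uniform_pdf(lcpc, *LOG10_CPC_BOUNDS)
        lp = lp + log_uniform_pdf(k, *K_BOUNDS)
        lp = lp + log_uniform_pdf(L, *L_BOUNDS)
        lp = lp + log_uniform_pdf(b, *B_BOUNDS)
        lp = lp + log_uniform_pdf(eps, 0.0, EPS_UPPER)
        lp = np.where(eps > 0, lp, -np.inf)
        return lp

    def _means(self, theta: np.ndarray) -> np.ndarray:
        lcpc, k, L, b, _ = (theta[..., j] for j in range(5))
        x = self.log10_c[None, :] - lcpc[:, None]
        return L[:, None] / (1.0 + np.exp(-k[:, None] * x)) + b[:, None]

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return gaussian_loglike(self.y, self._means(theta), theta[..., 4])

    def log_density(self, theta: np.ndarray) -> float:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        lp = self.log_prior(theta)
        if not np.isfinite(lp[0]):
            return float(lp[0])
        return float(lp[0] + self.log_likelihood(theta)[0])

    def sample_prior(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.column_stack(
            [
                rng.uniform(*LOG10_CPC_BOUNDS, n),
                rng.uniform(*K_BOUNDS, n),
                rng.uniform(*L_BOUNDS, n),
                rng.uniform(*B_BOUNDS, n),
                rng.uniform(1e-12, EPS_UPPER, n),
            ]
        )

    def initial_point(self) -> np.ndarray:
        """Least-squares start, trying both slope signs."""
        y = self.y
        lcpc0 = float(np.clip(np.median(self.log10_c), *LOG10_CPC_BOUNDS))
        span = float(y.max() - y.min())
        best = None
        for k0 in (-5.0, 5.0):
            x0 = np.array(
                [lcpc0, k0, max(span, 0.05), float(y.min())]
            )
            lo = [LOG10_CPC_BOUNDS[0], K_BOUNDS[0], L_BOUNDS[0], B_BOUNDS[0]]
            hi = [LOG10_CPC_BOUNDS[1], K_BOUNDS[1], L_BOUNDS[1], B_BOUNDS[1]]

            def residuals(x: np.ndarray) -> np.ndarray:
                theta = np.concatenate([x, [1.0]])[None, :]
                return y - self._means(theta)[0]

            try:
                fit = least_squares(residuals, x0, bounds=(lo, hi), max_nfev=1000)
                if best is None or fit.cost < best.cost:
                    best = fit
            except Exception:
                continue
        if best is None:
            x = np.array([lcpc0, -5.0, max(span, 0.05), float(y.min())])
            eps = 0.02
        else:
            x = best.x
            eps = float(np.clip(np.std(best.fun), 1e-4, EPS_UPPER * 0.98))
        return np.concatenate([x, [eps]])


def fit_cpc(
    series: NMRTitrationSeries, config: SamplerConfig = SamplerConfig()
) -> tuple[PosteriorSamples, dict]:
    """Sample the cpc posterior and summarize cpc in mM and uM.

    A series with (numerically) constant intensities is flagged as
    non-identifiable with a warning; the wide posterior is still returned.
    """
    model = CPCModel(series)
    if np.ptp(model.y) < 1e-12:
        warnings.warn(
            f"series {series.peptide_id}: intensities are constant; "
            "cpc is not identifiable and the posterior will be prior-wide"
        )
    posterior = run_ensemble(model, config, key_params=["log10_cpc", "k", "L", "b"])
    cpc_mM = 10.0 ** posterior.values("log10_cpc")
    summary = {
        "peptide_id": series.peptide_id,
        "cpc_mM": {
            "mean": float(cpc_mM.mean()),
            "median": float(np.median(cpc_mM)),
            "ci95": tuple(float(v) for v in np.quantile(cpc_mM, [0.025, 0.975])),
        },
        "cpc_uM": {
            "mean": float(cpc_mM.mean() * 1e3),
            "median": float(np.median(cpc_mM) * 1e3),
            "ci95": tuple(
                float(v * 1e3) for v in np.quantile(cpc_mM, [0.025, 0.975])
            ),
        },
        "rhat_log10_cpc": posterior.rhat.get("log10_cpc", float("nan")),
    }
    return posterior, summary


def weight_secondary_shifts(raw: np.ndarray) -> np.ndarray:
    """1-2-1 smoothing of per-residue secondary shifts.

    Interior residue i maps to (d[i-1] + 2 d[i] + d[i+1]) / 4; at the termini
    (or next to a missing residue) the weights are renormalized over the
    available neighbors, so a constant series is preserved.  Missing (NaN)
    residues stay missing.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("need a non-empty 1-D shift series")
    n = raw.size
    out = np.full(n, np.nan)
    for i in range(n):
        if np.isnan(raw[i]):
            continue
        num, den = 2.0 * raw[i], 2.0
        for j, w in ((i - 1, 1.0), (i + 1, 1.0)):
            if 0 <= j < n and not np.isnan(raw[j]):
                num += w * raw[j]
                den += w
        out[i] = num / den
    return out
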