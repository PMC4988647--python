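"""Population analysis of burst E/S distributions.

Burst-averaged quantities are noisy in proportion to 1/size (the proximity
ratio of a burst of ``n`` photons is a binomial fraction with variance
``E(1-E)/n``), so bursts are weighted proportionally to their size when
building histograms, kernel density estimates and fits.  Size weights are
the only supported weighting scheme: they match the inverse-variance
structure of the PR and any other monotone function of size uses the burst
information less efficiently.

Three estimation routes are provided:

- :func:`fit_histogram` — least-squares fit of a model (1-3 Gaussian peaks,
  or two Gaussians bridged by a flat plateau) to the weighted histogram,
  with reduced χ², AIC and BIC under the Gaussian-residual likelihood;
- :func:`fit_em_gaussian` — weighted expectation-maximization for a
  Gaussian mixture, with weights acting as case multiplicities;
- :func:`weighted_kde` — non-parametric Gaussian-kernel weighted KDE.

The plateau model addresses dynamic samples where two populations are
connected by intermediate-FRET bursts: the bridge absorbs the in-between
mass so the two Gaussian centers stay on the populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .phcore import ValidationError

__all__ = [
    "FitResult", "MODELS", "burst_weights", "weighted_histogram",
    "weighted_kde", "fit_histogram", "fit_em_gaussian",
    "model_function",
]

MODELS = ("gauss1", "gauss2", "gauss3", "gauss2_plateau")


@dataclass
class FitResult:
    """Fit outcome: parameter values, uncertainties and quality statistics.

    ``aic``/``bic`` follow the Gaussian-residual convention
    ``n·ln(RSS/n) + 2k`` / ``+ k·ln(n)``.
    """

    model: str
    values: dict
    stderrs: dict
    redchi: float
    aic: float
    bic: float
    n_data: int
    success: bool = True
    extra: dict = field(default_factory=dict)

    def report(self) -> str:
        lines = [f"model: {self.model}  (n_data={self.n_data})"]
        for name, val in self.values.items():
            err = self.stderrs.get(name)
            err_s = f" +/- {err:.4g}" if err is not None and np.isfinite(err) \
                else ""
            lines.append(f"  {name:12s} = {val:.6g}{err_s}")
        lines.append(f"  redchi = {self.redchi:.4g}   aic = {self.aic:.4g}"
                     f"   bic = {self.bic:.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"model": self.model, "values": self.values,
                "stderrs": self.stderrs, "redchi": self.redchi,
                "aic": self.aic, "bic": self.bic, "n_data": self.n_data,
                "success": self.success}


def burst_weights(bursts, gamma: float = 1.0,
                  add_naa: bool = False) -> np.ndarray:
    """Per-burst weights proportional to the γ-corrected burst size."""
    from .corrections import burst_size
    from .phcore import StateError
    if bursts.counts is None:
        raise StateError("weights require corrected counts")
    return burst_size(bursts.counts, gamma=gamma, add_naa=add_naa)


def weighted_histogram(values, weights=None, binwidth: float = 0.03,
                       vmin: float = 0.0, vmax: float = 1.0,
                       density: bool = False):
    """Weighted histogram with half-open bins ``[e, e+binwidth)``
    left-anchored at ``vmin``.

    The bin mass is the sum of member weights (all-ones weights give the
    unweighted histogram).  The last edge is the first ``vmin + k·binwidth``
    at or beyond ``vmax``, so the default E range [0, 1] with binwidth 0.03
    yields 34 bins covering [0, 1.02).
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValidationError("empty input")
    if binwidth <= 0:
        raise ValidationError("binwidth must be > 0")
    weights = np.ones_like(values) if weights is None \
        else np.asarray(weights, dtype=float)
    n_bins = int(np.ceil((vmax - vmin) / binwidth - 1e-12))
    edges = vmin + np.arange(n_bins + 1) * binwidth
    mass, _ = np.histogram(values, bins=edges, weights=weights)
    if density:
        total = mass.sum()
        if total > 0:
            mass = mass / (total * binwidth)
    return edges, mass


def weighted_kde(values, weights=None, bandwidth: float = 0.03,
                 grid=None):
    """Gaussian-kernel weighted KDE evaluated on a grid.

    ``bandwidth`` is the kernel σ in data units (default 0.03 E-units).
    Returns ``(grid, density)``; the density integrates to 1 over a grid
    covering the data ±4 bandwidths.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValidationError("empty input")
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be > 0")
    weights = np.ones_like(values) if weights is None \
        else np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    if grid is None:
        lo = values.min() - 4 * bandwidth
        hi = values.max() + 4 * bandwidth
        grid = np.linspace(lo, hi, max(int((hi - lo) / bandwidth * 10), 200))
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - values[None, :]) / bandwidth
    dens = (weights[None, :] * np.exp(-0.5 * z ** 2)).sum(axis=1) \
        / (bandwidth * np.sqrt(2 * np.pi))
    return grid, dens


# --------------------------------------------------------------------------
# Histogram models
# --------------------------------------------------------------------------

def _gauss(x, amp, center, sigma):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _bridge(x, c1, s1, c2, s2):
    """Flat plateau on [c1, c2] with Gaussian roll-offs beyond."""
    out = np.ones_like(x)
    left = x < c1
    right = x > c2
    out[left] = np.exp(-0.5 * ((x[left] - c1) / s1) ** 2)
    out[right] = np.exp(-0.5 * ((x[right] - c2) / s2) ** 2)
    return out


def model_function(model: str):
    """Return ``(f(x, *params), parameter names)`` for a model name."""
    if model == "gauss1":
        return (lambda x, a1, c1, s1: _gauss(x, a1, c1, s1),
                ["amp1", "center1", "sigma1"])
    if model == "gauss2":
        return (lambda x, a1, c1, s1, a2, c2, s2:
                _gauss(x, a1, c1, s1) + _gauss(x, a2, c2, s2),
                ["amp1", "center1", "sigma1", "amp2", "center2", "sigma2"])
    if model == "gauss3":
        return (lambda x, a1, c1, s1, a2, c2, s2, a3, c3, s3:
                _gauss(x, a1, c1, s1) + _gauss(x, a2, c2, s2)
                + _gauss(x, a3, c3, s3),
                ["amp1", "center1", "sigma1", "amp2", "center2", "sigma2",
                 "amp3", "center3", "sigma3"])
    if model == "gauss2_plateau":
        return (lambda x, a1, c1, s1, a2, c2, s2, ab:
                _gauss(x, a1, c1, s1) + _gauss(x, a2, c2, s2)
                + ab * _bridge(x, c1, s1, c2, s2),
                ["amp1", "center1", "sigma1", "amp2", "center2", "sigma2",
                 "amp_bridge"])
    raise ValidationError(f"unknown model {model!r}; choose from {MODELS}")


def _weighted_quantile(values, weights, q):
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    return np.interp(q, cdf, v)


def _initial_params(model, values, weights, mass):
    """Factory initial values: centers at weighted 25th/75th percentiles,
    σ = 0.05, amplitudes from bin masses; bounds μ ∈ [-0.1, 1.1],
    σ ∈ [0.005, 0.5]."""
    peak = mass.max() if len(mass) else 1.0
    n_gauss = {"gauss1": 1, "gauss2": 2, "gauss3": 3, "gauss2_plateau": 2}[model]
    if n_gauss == 1:
        centers = [_weighted_quantile(values, weights, 0.5)]
    elif n_gauss == 2:
        centers = list(_weighted_quantile(values, weights, [0.25, 0.75]))
    else:
        centers = list(_weighted_quantile(values, weights, [0.15, 0.5, 0.85]))
    p0, lo, hi = [], [], []
    for c in centers:
        p0 += [peak / n_gauss, c, 0.05]
        lo += [0.0, -0.1, 0.005]
        hi += [np.inf, 1.1, 0.5]
    if model == "gauss2_plateau":
        p0 += [0.05 * peak]
        lo += [0.0]
        hi += [np.inf]
    return np.array(p0), (np.array(lo), np.array(hi))


def _order_components(values: dict, stderrs: dict) -> tuple[dict, dict]:
    """Relabel Gaussian components so centers are non-decreasing."""
    comps = sorted({int(k[-1]) for k in values if k.startswith("center")})
    if len(comps) < 2:
        return values, stderrs
    order = sorted(comps, key=lambda i: values[f"center{i}"])
    if order == comps:
        return values, stderrs
    new_v, new_s = dict(values), dict(stderrs)
    for new_i, old_i in zip(comps, order):
        for prefix in ("amp", "center", "sigma"):
            if f"{prefix}{old_i}" in values:
                new_v[f"{prefix}{new_i}"] = values[f"{prefix}{old_i}"]
                new_s[f"{prefix}{new_i}"] = stderrs.get(f"{prefix}{old_i}")
    return new_v, new_s


def fit_histogram(values, weights=None, model: str = "gauss2",
                  binwidth: float = 0.03, vmin: float = 0.0,
                  vmax: float = 1.0) -> FitResult:
    """Least-squares fit of a peak model to the weighted histogram.

    Residuals are model minus bin mass at bin centers; AIC/BIC and reduced
    χ² are computed from the residual sum of squares under the
    Gaussian-residual likelihood.  Raises on non-convergence (carrying the
    last iterate in the exception message).
    """
    values = np.asarray(values, dtype=float)
    func, names = model_function(model)
    weights_arr = np.ones_like(values) if weights is None \
        else np.asarray(weights, dtype=float)
    edges, mass = weighted_histogram(values, weights_arr, binwidth,
                                     vmin=vmin, vmax=vmax)
    centers = edges[:-1] + binwidth / 2
    k = len(names)
    if (mass > 0).sum() <= k:
        raise ValidationError(
            f"only {(mass > 0).sum()} nonempty bins for {k} parameters")
    # per-bin uncertainty: compound-Poisson variance sum(w^2) per bin
    # (reduces to sqrt(count) for unit weights); the fit and its quality
    # statistics use only bins with mass, where the error model is defined
    var, _ = np.histogram(values, bins=edges, weights=weights_arr ** 2)
    nz = mass > 0
    centers, mass, sigma = centers[nz], mass[nz], np.sqrt(var[nz])
    p0, bounds = _initial_params(model, values, weights_arr, mass)
    try:
        popt, pcov = optimize.curve_fit(func, centers, mass, p0=p0,
                                        sigma=sigma, absolute_sigma=True,
                                        bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise ValidationError(f"histogram fit did not converge: {exc}") from exc
    resid = (func(centers, *popt) - mass) / sigma
    n = len(centers)
    chisq = float(resid @ resid)
    redchi = chisq / max(n - k, 1)
    neg2ll = n * np.log(max(chisq / n, 1e-300))
    perr = np.sqrt(np.diag(pcov))
    values_d = dict(zip(names, map(float, popt)))
    stderr_d = dict(zip(names, map(float, perr)))
    values_d, stderr_d = _order_components(values_d, stderr_d)
    return FitResult(model=model, values=values_d, stderrs=stderr_d,
                     redchi=redchi, aic=neg2ll + 2 * k,
                     bic=neg2ll + k * np.log(n), n_data=n)


# --------------------------------------------------------------------------
# Weighted EM
# --------------------------------------------------------------------------

def fit_em_gaussian(values, weights=None, k: int = 2,
                    tol: float = 1e-8, max_iter: int = 500) -> FitResult:
    """Weighted EM fit of a k-component Gaussian mixture (k in 1..3).

    Weights act as case multiplicities in the weighted log-likelihood
    ``Σ w_i log Σ_j π_j N(x_i; μ_j, σ_j)``, which is non-decreasing every
    iteration.  Initialization is deterministic (weighted quantiles).  A
    collapsing component (σ < 1e-4) triggers one restart with perturbed
    initial means, then an error.
    """
    values = np.asarray(values, dtype=float)
    if k not in (1, 2, 3):
        raise ValidationError("k must be 1, 2 or 3")
    if len(values) <= 10 * k:
        raise ValidationError(f"need more than {10 * k} data points")
    w = np.ones_like(values) if weights is None \
        else np.asarray(weights, dtype=float)
    w = w / w.sum()

    def run(mu):
        sigma = np.full(k, max(np.sqrt(np.sum(w * (values - np.sum(w * values))
                                              ** 2)) / k, 0.02))
        pi = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        ll_history = []
        for _ in range(max_iter):
            # E step
            logp = (-0.5 * ((values[:, None] - mu[None, :]) / sigma) ** 2
                    - np.log(sigma) - 0.5 * np.log(2 * np.pi)
                    + np.log(pi))
            m = logp.max(axis=1, keepdims=True)
            p = np.exp(logp - m)
            tot = p.sum(axis=1, keepdims=True)
            resp = p / tot
            ll = float(np.sum(w * (np.log(tot[:, 0]) + m[:, 0])))
            ll_history.append(ll)
            # M step (weighted closed forms)
            wk = (w[:, None] * resp)
            Nk = wk.sum(axis=0)
            pi = Nk
            mu = (wk * values[:, None]).sum(axis=0) / Nk
            var = (wk * (values[:, None] - mu[None, :]) ** 2).sum(axis=0) / Nk
            sigma = np.sqrt(var)
            if np.any(sigma < 1e-4):
                return None, ll_history
            if ll - ll_prev < tol * max(abs(ll), 1.0) and ll_prev > -np.inf:
                break
            ll_prev = ll
        order = np.argsort(mu)
        return (mu[order], sigma[order], pi[order], ll, ll_history), ll_history

    q = (np.arange(k) + 0.5) / k
    mu0 = np.atleast_1d(_weighted_quantile(values, w, q))
    fit, _ = run(mu0.copy())
    if fit is None:
        fit, _ = run(mu0 + 0.05 * (np.arange(k) - (k - 1) / 2))
        if fit is None:
            raise ValidationError("EM component collapsed (sigma < 1e-4)")
    mu, sigma, pi, ll, ll_history = fit
    n = len(values)
    n_params = 3 * k - 1
    values_d = {}
    for j in range(k):
        values_d[f"center{j + 1}"] = float(mu[j])
        values_d[f"sigma{j + 1}"] = float(sigma[j])
        values_d[f"fraction{j + 1}"] = float(pi[j])
    neg2ll = -2 * ll * n  # weights normalized to 1; rescale to case count
    return FitResult(model=f"em_gauss{k}", values=values_d, stderrs={},
                     redchi=np.nan, aic=neg2ll + 2 * n_params,
                     bic=neg2ll + n_params * np.log(n), n_data=n,
                     extra={"loglik_history": ll_history})
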