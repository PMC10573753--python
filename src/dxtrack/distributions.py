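"""Displacement distributions, Gaussian fits, and mean/σ transitions.

At a fixed time interval Δt, the from-start displacements of all trajectories
that live at least Δt form an empirical distribution; in free rotational
diffusion it is Gaussian with mean drift·Δt and variance growing linearly in
Δt.  Fitting a single Gaussian per Δt and tracking the fitted mean μ as a
function of Δt gives the *mean transition* — the signature of rotational
bias (drift) in the underlying motion.  The σ(Δt) sequence tracks the
broadening of the distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .trajectory import AngularTrajectory


@dataclass
class GaussianSummary:
    """(μ, σ) of the displacement distribution at one time interval."""

    dt: float       # s
    mu: float       # mrad
    sigma: float    # mrad
    n: int          # number of contributing trajectories
    method: str     # "mle" or "histogram_lsq"


@dataclass
class Transition:
    """A (Δt → statistic) series: mean transition or sigma transition."""

    axis: str
    dts: np.ndarray
    values: np.ndarray
    ns: np.ndarray
    statistic: str                 # "mu" or "sigma"
    group: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dt_s": self.dts,
            f"{self.statistic}_mrad": self.values,
            "n": self.ns,
        })


def displacement_samples(trajs, axis: str, dt: float) -> np.ndarray:
    """One from-start displacement per trajectory whose lifetime ≥ dt."""
    out = []
    for tr in trajs:
        d = tr.displacement_from_start(axis, dt)
        if d is not None:
            out.append(d)
    return np.asarray(out, dtype=float)


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian(samples: np.ndarray, dt: float = np.nan,
                 method: str = "mle") -> GaussianSummary:
    """Fit a single Gaussian to displacement samples.

    ``mle``
        Sample mean and (n−1)-denominator standard deviation — the
        binning-free maximum-likelihood/moment estimate.  Needs n ≥ 2.
    ``histogram_lsq``
        Nonlinear least squares of a Gaussian on a Freedman–Diaconis-binned
        density histogram — mirrors fitting a plotted probability
        distribution.  Needs n ≥ 10 and non-degenerate spread.
    """
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    if method == "mle":
        if n < 2:
            raise ValueError("mle fit needs at least 2 samples")
        return GaussianSummary(
            dt=dt,
            mu=float(np.mean(samples)),
            sigma=float(np.std(samples, ddof=1)),
            n=n,
            method="mle",
        )
    if method == "histogram_lsq":
        if n < 10:
            raise ValueError("histogram_lsq fit needs at least 10 samples")
        if np.ptp(samples) == 0:
            raise ValueError(
                "histogram_lsq: all samples identical (degenerate histogram)"
            )
        density, edges = np.histogram(samples, bins="fd", density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mu0 = float(np.mean(samples))
        sigma0 = float(np.std(samples, ddof=1))
        p0 = [1.0 / (sigma0 * np.sqrt(2 * np.pi)), mu0, sigma0]
        popt, _ = curve_fit(_gauss, centers, density, p0=p0, maxfev=10000)
        return GaussianSummary(
            dt=dt, mu=float(popt[1]), sigma=float(abs(popt[2])), n=n,
            method="histogram_lsq",
        )
    raise ValueError(f"unknown fit method {method!r}")


def _transition(trajs, axis: str, dt_grid, statistic: str,
                method: str, min_samples: int, group: str | None) -> Transition:
    trajs = list(trajs)
    dts, values, ns = [], [], []
    for dt in np.asarray(dt_grid, dtype=float):
        samples = displacement_samples(trajs, axis, dt)
        if len(samples) < min_samples:
            continue
        summ = fit_gaussian(samples, dt=dt, method=method)
        dts.append(dt)
        values.append(summ.mu if statistic == "mu" else summ.sigma)
        ns.append(summ.n)
    return Transition(
        axis=axis,
        dts=np.asarray(dts),
        values=np.asarray(values),
        ns=np.asarray(ns, dtype=int),
        statistic=statistic,
        group=group,
    )


def mean_transition(trajs, axis: str, dt_grid, method: str = "mle",
                    min_samples: int = 10,
                    group: str | None = None) -> Transition:
    """μ(Δt): the Gaussian mean of the displacement distribution per Δt.

    Δt entries with fewer than ``min_samples`` contributing trajectories are
    omitted rather than extrapolated.
    """
    return _transition(trajs, axis, dt_grid, "mu", method, min_samples, group)


def sigma_transition(trajs, axis: str, dt_grid, method: str = "mle",
                     min_samples: int = 10,
                     group: str | None = None) -> Transition:
    """σ(Δt): the Gaussian width of the displacement distribution per Δt."""
    return _transition(trajs, axis, dt_grid, "sigma", method, min_samples,
                       group)
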