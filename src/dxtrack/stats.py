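"""Ensemble MSD curves and angular diffusion-coefficient estimation.

The mean square displacement at lag Δt is the ensemble average, over all
trajectories that live at least Δt, of the squared angular displacement from
the trajectory start.  Because displacements are anchored at the start (not
sliding-window averaged), each trajectory contributes exactly one value per
lag and the number of contributors can only shrink as the lag grows.

Diffusion coefficients follow the convention MSD = 4·D·t + A applied per
axis.  For free rotational diffusion with per-axis diffusion coefficient d
(per-axis MSD = 2·d·t), this convention yields D = d/2; the package keeps
the 4Dt form because it is the standard way DXT studies report D, and
documents the factor rather than silently halving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import AngularTrajectory, TIME_TOL


@dataclass
class MSDCurve:
    """Ensemble MSD per lag, with contributor counts and optional 95% band."""

    axis: str
    lags: np.ndarray          # s
    msd: np.ndarray           # mrad²
    n_pairs: np.ndarray       # contributing trajectories per lag
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "lag_s": self.lags,
            "msd_mrad2": self.msd,
            "n_pairs": self.n_pairs,
        })
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        return df


@dataclass
class DiffusionFit:
    """OLS fit of MSD = 4·D·t + A over a set of lags."""

    D: float                  # mrad²/s
    A: float                  # mrad²
    fit_lags: np.ndarray      # s
    residual_rms: float       # mrad²


def _squared_displacements(trajs: list[AngularTrajectory], axis: str,
                           lags: np.ndarray) -> np.ndarray:
    """Matrix (n_traj × n_lags) of squared from-start displacements.

    NaN marks lags a trajectory does not reach.
    """
    lags = np.asarray(lags, dtype=float)
    if len(lags) == 0:
        raise ValueError("empty lag grid")
    if np.any(np.diff(lags) <= 0):
        raise ValueError("lags must be strictly increasing")
    out = np.full((len(trajs), len(lags)), np.nan)
    for i, tr in enumerate(trajs):
        if tr.n_frames < 2:
            continue  # a single-frame trajectory reaches no lag at all
        disp = tr.displacement_series(axis)
        dt = tr.frame_interval
        ks = lags / dt
        ks_round = np.rint(ks).astype(int)
        if np.any(np.abs(ks - ks_round) * dt > TIME_TOL) or np.any(ks_round < 1):
            raise ValueError(
                "lag grid is not on the trajectory frame grid "
                f"(frame_interval = {dt} s)"
            )
        valid = ks_round < tr.n_frames
        out[i, valid] = disp[ks_round[valid]] ** 2
    return out


def ensemble_msd(trajs: list[AngularTrajectory], axis: str,
                 lags: np.ndarray) -> MSDCurve:
    """Ensemble-averaged squared from-start displacement per lag.

    Lags reached by no trajectory are dropped from the curve; if even the
    first lag has no contributor the ensemble is empty and that is an error.
    """
    sq = _squared_displacements(list(trajs), axis, lags)
    lags = np.asarray(lags, dtype=float)
    n = np.sum(~np.isnan(sq), axis=0)
    if n[0] == 0:
        raise ValueError("no trajectory reaches the first lag")
    keep = n > 0
    with np.errstate(invalid="ignore"):
        msd = np.nanmean(sq[:, keep], axis=0)
    return MSDCurve(axis=axis, lags=lags[keep], msd=msd,
                    n_pairs=n[keep].astype(int))


def msd_confidence_band(trajs: list[AngularTrajectory], axis: str,
                        lags: np.ndarray, n_boot: int = 1000,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Percentile-bootstrap 95% band for the ensemble MSD.

    Whole trajectories are resampled with replacement (the trajectory, not
    the frame, is the independent unit), and the 2.5th/97.5th percentiles of
    the resampled curves form the band.  Fully reproducible from ``seed``.
    """
    trajs = list(trajs)
    if len(trajs) < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    sq = _squared_displacements(trajs, axis, lags)
    n = np.sum(~np.isnan(sq), axis=0)
    keep = n > 0
    sq = sq[:, keep]
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, sq.shape[1]))
    idx = rng.integers(0, len(trajs), size=(n_boot, len(trajs)))
    with np.errstate(invalid="ignore"):
        for b in range(n_boot):
            boots[b] = np.nanmean(sq[idx[b]], axis=0)
    ci_low = np.nanpercentile(boots, 2.5, axis=0)
    ci_high = np.nanpercentile(boots, 97.5, axis=0)
    return ci_low, ci_high


def ensemble_msd_with_band(trajs, axis, lags, n_boot: int = 1000,
                           seed: int = 0) -> MSDCurve:
    """Convenience: ensemble MSD plus its bootstrap band in one curve."""
    curve = ensemble_msd(trajs, axis, lags)
    ci_low, ci_high = msd_confidence_band(trajs, axis, lags,
                                          n_boot=n_boot, seed=seed)
    curve.ci_low, curve.ci_high = ci_low, ci_high
    return curve


def fit_diffusion_coefficient(curve: MSDCurve,
                              fit_lags: np.ndarray | None = None) -> DiffusionFit:
    """Ordinary least squares of MSD on lag: MSD = 4·D·t + A.

    ``fit_lags`` selects which lags of the curve enter the fit; by default
    the first five (0.1–0.5 s at the standard frame interval), because a fit
    "at Δt = 0.1 s" still needs several points to determine both slope and
    intercept.
    """
    if fit_lags is None:
        fit_lags = curve.lags[:5]
    fit_lags = np.asarray(fit_lags, dtype=float)
    mask = np.isclose(curve.lags[:, None], fit_lags[None, :],
                      rtol=0, atol=TIME_TOL).any(axis=1)
    t = curve.lags[mask]
    y = curve.msd[mask]
    if len(t) < 2:
        raise ValueError(
            f"need >= 2 usable lags for the MSD fit, got {len(t)}"
        )
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return DiffusionFit(
        D=float(slope / 4.0),
        A=float(intercept),
        fit_lags=t,
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
    )
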