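"""Synthetic rotational-diffusion trajectories and rendered detector movies.

The generator emulates the statistical structure the analysis assumes: each
tracked nanocrystal performs two-axis rotational Brownian motion in (χ, θ)
with per-axis angular diffusion coefficients d (mrad²/s), optional constant
or piecewise-constant drift (mrad/s), and an exponentially distributed
lifetime discretized to the frame grid.  Increments over one frame interval
Δt are exact for constant-coefficient Brownian motion:

    Δangle ~ Normal(mean = drift·Δt, variance = 2·d·Δt)

so no sub-stepping is needed.  Every run is reproducible from a single seed;
per-trajectory substreams are derived deterministically by counter so that
trajectory i is identical no matter how many others are generated.

``render_movie`` turns trajectories into detector image stacks: each live
trajectory contributes one isotropic Gaussian spot at its angles→pixels
position, on a constant background, with optional Poisson counting noise.
This closes the loop: simulate → render → detect/link → angles → analyze.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DetectorGeometry
from .trajectory import AngularTrajectory, FULL_CIRCLE_MRAD


# ---------------------------------------------------------------------------
# drift specification
# ---------------------------------------------------------------------------

@dataclass
class PiecewiseDrift:
    """Piecewise-constant drift rate in mrad/s.

    ``breaks`` are the switch times (s, strictly increasing); ``rates`` has
    one more entry than ``breaks``: rates[i] applies on [breaks[i-1], breaks[i]).
    """

    breaks: list[float]
    rates: list[float]

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.breaks) + 1:
            raise ValueError("need len(rates) == len(breaks) + 1")
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")

    def integral(self, t) -> np.ndarray:
        """∫₀ᵗ rate(s) ds — the deterministic displacement by time t."""
        t = np.asarray(t, dtype=float)
        edges = np.concatenate([[0.0], self.breaks, [np.inf]])
        total = np.zeros_like(t)
        for lo, hi, rate in zip(edges[:-1], edges[1:], self.rates):
            total += rate * np.clip(t - lo, 0.0, hi - lo)
        return total

    def crossing_time(self) -> float | None:
        """First t > 0 where the integrated drift changes sign, if any."""
        t_grid = np.concatenate([self.breaks, [self.breaks[-1] * 100 + 100]])
        prev_t, prev_v = 0.0, 0.0
        sign0 = None
        for t, rate in zip(t_grid, self.rates):
            v = prev_v + rate * (t - prev_t)
            if sign0 is None and prev_v != 0:
                sign0 = np.sign(prev_v)
            if sign0 is not None and np.sign(v) == -sign0:
                # linear within the segment: interpolate the zero
                return prev_t + (0.0 - prev_v) / rate
            prev_t, prev_v = t, v
        return None


def _drift_increments(drift, t_grid: np.ndarray) -> np.ndarray:
    """Deterministic displacement over each frame interval."""
    if isinstance(drift, PiecewiseDrift):
        cum = drift.integral(t_grid)
        return np.diff(cum)
    return float(drift) * np.diff(t_grid)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Conditions of a synthetic DXT run.

    Defaults mirror the acquisition this package targets: 0.1 s frames and
    up to 500 frames (50 s) per spot; diffusion coefficients of order
    0.1–10 mrad²/s with χ motion typically exceeding θ.
    """

    n_traj: int = 1000
    frame_interval: float = 0.1        # s
    max_frames: int = 500              # ≤ 5000
    d_chi: float = 1.0                 # mrad²/s
    d_theta: float = 0.5               # mrad²/s
    drift_chi: float | PiecewiseDrift = 0.0    # mrad/s
    drift_theta: float | PiecewiseDrift = 0.0  # mrad/s
    lifetime_mean: float | None = None  # s; None → every track runs full length
    seed: int = 0
    theta0_mrad: float = 300.0         # initial tilt (sets the ring radius)
    chi0_mode: str = "uniform"         # "uniform" | "even" | "zero"

    def __post_init__(self) -> None:
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if not (1 <= self.max_frames <= 5000):
            raise ValueError("max_frames must be in [1, 5000]")
        if self.d_chi < 0 or self.d_theta < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.lifetime_mean is not None and self.lifetime_mean <= 0:
            raise ValueError("lifetime_mean must be positive")


@dataclass
class GroundTruth:
    """Per-trajectory generating parameters, returned alongside the data."""

    table: pd.DataFrame  # id, d_chi, d_theta, lifetime_s, n_frames


def sample_lifetimes(params: SimulationParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw per-trajectory frame counts from the lifetime model.

    Lifetime L ~ Exponential(lifetime_mean) is discretized to
    n_steps = floor(L/Δt) whole frame intervals, clamped to
    [1, max_frames − 1]; the visible lifetime is n_steps·Δt.
    Returns the number of *samples* per trajectory (n_steps + 1).
    """
    if params.lifetime_mean is None:
        return np.full(params.n_traj, params.max_frames, dtype=int)
    raw = rng.exponential(params.lifetime_mean, size=params.n_traj)
    n_steps = np.floor(raw / params.frame_interval).astype(int)
    n_steps = np.clip(n_steps, 1, params.max_frames - 1)
    return n_steps + 1


def _initial_chi(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    if params.chi0_mode == "uniform":
        return rng.uniform(0.0, FULL_CIRCLE_MRAD, size=params.n_traj)
    if params.chi0_mode == "even":
        return np.arange(params.n_traj) * FULL_CIRCLE_MRAD / params.n_traj
    if params.chi0_mode == "zero":
        return np.zeros(params.n_traj)
    raise ValueError(f"unknown chi0_mode {params.chi0_mode!r}")


def simulate_trajectories(params: SimulationParams,
                          condition: str = "", region: str = ""
                          ) -> tuple[list[AngularTrajectory], GroundTruth]:
    """Generate rotational-Brownian trajectories with ground truth.

    A single seed drives everything: lifetimes and initial positions come
    from the parent stream; each trajectory's increments come from a
    substream spawned at its index, so outputs are bit-identical across runs.
    """
    root = np.random.SeedSequence(params.seed)
    parent = np.random.default_rng(root)
    n_samples = sample_lifetimes(params, parent)
    chi0 = _initial_chi(params, parent)
    children = root.spawn(params.n_traj)

    dt = params.frame_interval
    sd_chi = np.sqrt(2.0 * params.d_chi * dt)
    sd_theta = np.sqrt(2.0 * params.d_theta * dt)

    trajs: list[AngularTrajectory] = []
    truth_rows = []
    for i in range(params.n_traj):
        n = int(n_samples[i])
        t = dt * np.arange(n)
        rng_i = np.random.default_rng(children[i])
        steps = rng_i.normal(size=(2, n - 1)) if n > 1 else np.zeros((2, 0))
        chi_inc = sd_chi * steps[0] + _drift_increments(params.drift_chi, t)
        theta_inc = sd_theta * steps[1] + _drift_increments(params.drift_theta, t)
        chi = chi0[i] + np.concatenate([[0.0], np.cumsum(chi_inc)])
        theta = params.theta0_mrad + np.concatenate([[0.0], np.cumsum(theta_inc)])
        tid = f"sim{i:06d}"
        trajs.append(AngularTrajectory(
            id=tid, t=t, chi=chi, theta=theta,
            condition=condition, region=region,
        ))
        truth_rows.append((tid, params.d_chi, params.d_theta,
                           float(t[-1]), n))
    truth = GroundTruth(table=pd.DataFrame(
        truth_rows, columns=["id", "d_chi", "d_theta", "lifetime_s", "n_frames"]
    ))
    return trajs, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def piecewise_drift_preset(n_traj: int = 2000, seed: int = 0) -> SimulationParams:
    """Drift −3 mrad/s for the first 2 s, +3 mrad/s after.

    The integrated drift crosses zero at t = 4 s, so the mean transition
    μ(Δt) starts negative and turns positive near Δt ≈ 4 s — the qualitative
    sign-change phenomenology seen in chaperonin DXT mean transitions.
    """
    return SimulationParams(
        n_traj=n_traj,
        d_chi=1.0,
        d_theta=0.5,
        drift_chi=PiecewiseDrift(breaks=[2.0], rates=[-3.0, 3.0]),
        max_frames=500,
        seed=seed,
    )


def two_state_preset(n_traj: int = 2000, seed: int = 0,
                     active: bool = False) -> SimulationParams:
    """Demo contrast between a quiet and an activated ensemble.

    The "active" variant couples larger diffusion with a drift sign change;
    it is a demonstration preset only and claims no biophysical fidelity.
    """
    if active:
        return SimulationParams(
            n_traj=n_traj, d_chi=3.0, d_theta=1.0,
            drift_chi=PiecewiseDrift(breaks=[2.0], rates=[-3.0, 3.0]),
            lifetime_mean=3.0, seed=seed,
        )
    return SimulationParams(
        n_traj=n_traj, d_chi=1.0, d_theta=0.5,
        drift_chi=-3.0, lifetime_mean=5.0, seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderParams:
    """How trajectories are drawn onto synthetic detector frames."""

    geometry: DetectorGeometry
    nx: int = 400
    ny: int = 400
    psf_sigma: float = 1.5       # pixels
    amplitude: float = 1000.0    # peak counts above background
    background: float = 10.0     # counts
    noise: str = "poisson"       # "poisson" | "none"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")


def render_movie(trajs: list[AngularTrajectory], render: RenderParams,
                 seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Render trajectories as a detector image stack plus a truth table.

    Each trajectory is live on the frames spanned by its samples (its start
    time divided by the frame interval gives its first frame).  A spot that
    would land outside the image is an error naming the trajectory and frame
    — the caller's geometry does not match its simulation.
    """
    if not trajs:
        return (np.full((1, render.ny, render.nx), render.background,
                        dtype=float),
                pd.DataFrame(columns=["frame", "id", "x", "y"]))
    dt = trajs[0].frame_interval
    first = [int(round(tr.start_time / dt)) for tr in trajs]
    n_frames = max(f0 + tr.n_frames for f0, tr in zip(first, trajs))
    stack = np.full((n_frames, render.ny, render.nx), render.background,
                    dtype=float)
    geom = render.geometry
    truth_rows = []
    half = int(np.ceil(4 * render.psf_sigma))
    for f0, tr in zip(first, trajs):
        x, y = geom.angles_to_pixel(tr.chi, tr.theta)
        bad = ((x < 0) | (x > render.nx - 1) | (y < 0) | (y > render.ny - 1))
        if np.any(bad):
            k = int(np.argmax(bad))
            raise ValueError(
                f"trajectory {tr.id!r} maps off-detector at frame {f0 + k} "
                f"(x = {x[k]:.1f}, y = {y[k]:.1f})"
            )
        for k in range(tr.n_frames):
            xi, yi = float(x[k]), float(y[k])
            cx, cy = int(round(xi)), int(round(yi))
            x0, x1 = max(cx - half, 0), min(cx + half + 1, render.nx)
            y0, y1 = max(cy - half, 0), min(cy + half + 1, render.ny)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            stack[f0 + k, y0:y1, x0:x1] += render.amplitude * np.exp(
                -((xx - xi) ** 2 + (yy - yi) ** 2) / (2 * render.psf_sigma ** 2)
            )
            truth_rows.append((f0 + k, tr.id, xi, yi))
    if render.noise == "poisson":
        rng = np.random.default_rng(seed)
        stack = rng.poisson(stack).astype(float)
    truth = pd.DataFrame(truth_rows, columns=["frame", "id", "x", "y"])
    truth = truth.sort_values(["frame", "id"], kind="stable",
                              ignore_index=True)
    return stack, truth
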