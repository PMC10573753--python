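"""Pipeline orchestration: configuration, stages, and report generation.

The pipeline runs any prefix/suffix of

    simulate → render → detect/link → angles → stats/distributions/lifetimes

from a single YAML config.  Every output table carries a header comment with
the seed and the package version, floats are printed at ten significant
digits, and no timestamps enter file contents, so identical config + seed
reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .distributions import mean_transition, sigma_transition
from .geometry import DetectorGeometry, geometry_from_dict
from .lifetimes import LifetimeThresholds, group_summary
from .simulate import (PiecewiseDrift, RenderParams, SimulationParams,
                       render_movie, simulate_trajectories)
from .stats import ensemble_msd_with_band, fit_diffusion_coefficient
from .tracking import (SpotObservation, TrackingParams, detect_spots,
                       link_spots, read_image_stack, subtract_background,
                       tracks_to_table)
from .trajectory import (AngularTrajectory, make_lag_grid, read_trajectories,
                         write_trajectories)

FLOAT_FMT = "%.10g"


class DataError(RuntimeError):
    """Invalid or inconsistent input data (exit code 2 at the CLI)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisParams:
    n_lags: int = 10
    n_fit_lags: int = 5
    n_boot: int = 1000
    dt_grid_max_s: float | None = None   # default: same grid as the MSD lags
    min_samples: int = 10
    thresholds: LifetimeThresholds = field(default_factory=LifetimeThresholds)
    axes: tuple[str, ...] = ("chi", "theta")


@dataclass
class RunConfig:
    output_dir: str = "dxtrack_out"
    seed: int = 0
    input_trajectories: str | None = None
    input_movie: str | None = None
    geometry: DetectorGeometry | None = None
    simulation: SimulationParams = field(default_factory=SimulationParams)
    render: RenderParams | None = None
    tracking: TrackingParams = field(default_factory=TrackingParams)
    reflection: str | None = None        # ring-gate detections if set
    analysis: AnalysisParams = field(default_factory=AnalysisParams)


def _check_keys(section: dict, allowed, name: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ValueError(
            f"unknown keys in {name!r} config: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def _parse_drift(value):
    if isinstance(value, dict):
        _check_keys(value, {"breaks", "rates"}, "drift")
        return PiecewiseDrift(breaks=list(value["breaks"]),
                              rates=list(value["rates"]))
    return float(value)


def config_from_dict(cfg: dict) -> RunConfig:
    """Build a RunConfig from a nested mapping; unknown keys are errors."""
    top = {"output_dir", "seed", "input_trajectories", "input_movie",
           "geometry", "simulation", "render", "tracking", "reflection",
           "analysis"}
    _check_keys(cfg, top, "run")
    rc = RunConfig()
    rc.output_dir = cfg.get("output_dir", rc.output_dir)
    rc.seed = int(cfg.get("seed", rc.seed))
    rc.input_trajectories = cfg.get("input_trajectories")
    rc.input_movie = cfg.get("input_movie")
    rc.reflection = cfg.get("reflection")

    if "geometry" in cfg:
        rc.geometry = geometry_from_dict(cfg["geometry"])

    if "simulation" in cfg:
        sim = dict(cfg["simulation"])
        simfields = {f.name for f in dataclasses.fields(SimulationParams)}
        _check_keys(sim, simfields, "simulation")
        for key in ("drift_chi", "drift_theta"):
            if key in sim:
                sim[key] = _parse_drift(sim[key])
        sim.setdefault("seed", rc.seed)
        rc.simulation = SimulationParams(**sim)
    else:
        rc.simulation = SimulationParams(seed=rc.seed)

    if "render" in cfg:
        ren = dict(cfg["render"])
        renfields = {f.name for f in dataclasses.fields(RenderParams)}
        _check_keys(ren, renfields - {"geometry"}, "render")
        if rc.geometry is None:
            raise ValueError("render config requires a geometry section")
        rc.render = RenderParams(geometry=rc.geometry, **ren)

    if "tracking" in cfg:
        trk = dict(cfg["tracking"])
        trkfields = {f.name for f in dataclasses.fields(TrackingParams)}
        _check_keys(trk, trkfields, "tracking")
        rc.tracking = TrackingParams(**trk)

    if "analysis" in cfg:
        ana = dict(cfg["analysis"])
        anafields = {f.name for f in dataclasses.fields(AnalysisParams)}
        _check_keys(ana, anafields, "analysis")
        if "thresholds" in ana:
            thr = ana["thresholds"]
            _check_keys(thr, {"t1", "t2", "t3"}, "thresholds")
            ana["thresholds"] = LifetimeThresholds(**thr)
        if "axes" in ana:
            ana["axes"] = tuple(ana["axes"])
        rc.analysis = AnalysisParams(**ana)
    return rc


def load_config(path) -> RunConfig:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return config_from_dict(cfg)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _header(cfg: RunConfig, stage: str) -> str:
    return (f"dxtrack v{__version__} | stage={stage} | seed={cfg.seed}")


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig,
                 stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(cfg, stage)}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def _slug(text: str) -> str:
    return text.replace(" ", "_").replace("/", "-") or "all"


def tracks_to_trajectories(tracks: list[list[SpotObservation]],
                           geom: DetectorGeometry, frame_interval: float,
                           condition: str = "", region: str = ""
                           ) -> list[AngularTrajectory]:
    """Convert linked pixel-space tracks into angular trajectories."""
    trajs = []
    for tid, track in enumerate(tracks):
        frames = np.array([o.frame for o in track])
        pos = geom.pixel_to_angles(
            np.array([o.x for o in track]),
            np.array([o.y for o in track]),
        )
        trajs.append(AngularTrajectory(
            id=f"track{tid:06d}",
            t=frames * frame_interval,
            chi=np.atleast_1d(pos.chi),
            theta=np.atleast_1d(pos.theta),
            condition=condition, region=region,
        ))
    return trajs


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: RunConfig, outdir: Path) -> list[AngularTrajectory]:
    trajs, truth = simulate_trajectories(cfg.simulation)
    write_trajectories(trajs, outdir / "trajectories.csv",
                       header_comment=_header(cfg, "simulate"))
    _write_table(truth.table, outdir / "truth_trajectories.csv", cfg,
                 "simulate")
    return trajs


def run_render(cfg: RunConfig, trajs: list[AngularTrajectory],
               outdir: Path) -> np.ndarray:
    if cfg.render is None:
        raise DataError("render stage requested but no render config given")
    stack, truth = render_movie(trajs, cfg.render, seed=cfg.seed + 1)
    tifffile.imwrite(outdir / "movie.tif",
                     np.round(stack).astype(np.uint16))
    _write_table(truth, outdir / "truth_spots.csv", cfg, "render")
    return stack


def run_track(cfg: RunConfig, stack: np.ndarray,
              outdir: Path) -> list[AngularTrajectory]:
    if cfg.geometry is None:
        raise DataError("track stage requires a geometry section")
    params = cfg.tracking
    per_frame = []
    for i, frame in enumerate(stack):
        corrected = subtract_background(frame, params.min_spot_diameter)
        obs = detect_spots(corrected, params, frame=i)
        if cfg.reflection is not None:
            obs = [o for o in obs
                   if cfg.geometry.ring_gate(o.x, o.y, cfg.reflection)]
        per_frame.append(obs)
    tracks = link_spots(per_frame, params)
    _write_table(tracks_to_table(tracks), outdir / "tracks.csv", cfg, "track")
    trajs = tracks_to_trajectories(
        tracks, cfg.geometry, cfg.simulation.frame_interval
    )
    write_trajectories(trajs, outdir / "trajectories_tracked.csv",
                       header_comment=_header(cfg, "track"))
    return trajs


def run_analyze(cfg: RunConfig, trajs: list[AngularTrajectory],
                outdir: Path) -> dict:
    """Full statistics suite; returns the machine-readable summary dict."""
    if not trajs:
        raise DataError("no trajectories to analyze")
    ana = cfg.analysis
    frame_interval = trajs[0].frame_interval
    lags = make_lag_grid(frame_interval, ana.n_lags)
    fit_lags = lags[:ana.n_fit_lags]
    if ana.dt_grid_max_s is None:
        dt_grid = lags
    else:
        dt_grid = make_lag_grid(
            frame_interval, int(round(ana.dt_grid_max_s / frame_interval))
        )

    summary: dict = {"seed": cfg.seed, "version": __version__, "groups": []}
    by_key: dict[tuple[str, str], list[AngularTrajectory]] = {}
    for tr in trajs:
        by_key.setdefault((tr.condition, tr.region), []).append(tr)

    lifetime_rows = []
    for (condition, region), members in sorted(by_key.items()):
        tag = f"{_slug(condition)}_{_slug(region)}"
        gsum = group_summary(
            members, ana.thresholds, axis="chi", lags=lags,
            fit_lags=fit_lags, dt_grid=dt_grid, n_boot=ana.n_boot,
            seed=cfg.seed + 2, min_samples=ana.min_samples,
            condition=condition, region=region,
        )
        lifetime_rows.append(gsum.counts_frame())
        for axis in ana.axes:
            try:
                curve = ensemble_msd_with_band(
                    members, axis, lags, n_boot=ana.n_boot, seed=cfg.seed + 2
                )
            except ValueError as exc:
                raise DataError(
                    f"analysis failed for condition={condition!r} "
                    f"region={region!r} axis={axis}: {exc}"
                ) from exc
            _write_table(curve.to_frame(), outdir / f"msd_{tag}_{axis}.csv",
                         cfg, "analyze")
            fit = fit_diffusion_coefficient(curve, fit_lags)
            mt = mean_transition(members, axis, dt_grid,
                                 min_samples=ana.min_samples)
            st = sigma_transition(members, axis, dt_grid,
                                  min_samples=ana.min_samples)
            trans = mt.to_frame().merge(st.to_frame(), on=["dt_s", "n"])
            _write_table(trans[["dt_s", "mu_mrad", "sigma_mrad", "n"]],
                         outdir / f"transitions_{tag}_{axis}.csv", cfg,
                         "analyze")
            entry = {
                "condition": condition, "region": region, "axis": axis,
                "group": "all",
                "n_traj": len(members),
                "D_mrad2_per_s": fit.D, "A_mrad2": fit.A,
            }
            summary["groups"].append(entry)
            if axis == "chi":
                for label, gstat in gsum.groups.items():
                    if gstat.fit is None:
                        continue
                    summary["groups"].append({
                        "condition": condition, "region": region,
                        "axis": axis, "group": label,
                        "n_traj": gstat.count,
                        "D_mrad2_per_s": gstat.fit.D,
                        "A_mrad2": gstat.fit.A,
                    })
    _write_table(pd.concat(lifetime_rows, ignore_index=True),
                 outdir / "lifetime_summary.csv", cfg, "analyze")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def run_pipeline(cfg: RunConfig, mode: str = "full") -> dict | None:
    """Execute the requested stages; returns the analysis summary if run.

    Stage failures surface as DataError naming the stage and input.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        _header(cfg, mode),
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"mode: {mode}",
        f"config: {cfg}",
    ]
    trajs: list[AngularTrajectory] | None = None
    stack: np.ndarray | None = None
    summary = None
    try:
        if mode in ("simulate", "full"):
            trajs = run_simulate(cfg, outdir)
            log_lines.append(f"simulate: {len(trajs)} trajectories")
        if mode in ("render", "full"):
            if trajs is None:
                trajs = _load_input_trajectories(cfg)
            stack = run_render(cfg, trajs, outdir)
            log_lines.append(f"render: {stack.shape[0]} frames")
        if mode in ("track", "full"):
            if stack is None:
                if cfg.input_movie is None:
                    raise DataError("track mode requires input_movie")
                stack = read_image_stack(cfg.input_movie)
            trajs = run_track(cfg, stack, outdir)
            log_lines.append(f"track: {len(trajs)} tracks")
        if mode in ("analyze", "full"):
            if mode == "analyze":
                trajs = _load_input_trajectories(cfg)
            if not trajs:
                src = cfg.input_trajectories or "(pipeline)"
                raise DataError(f"no trajectories found in {src}")
            summary = run_analyze(cfg, trajs, outdir)
            log_lines.append(f"analyze: {len(summary['groups'])} summary rows")
    except DataError:
        raise
    except (ValueError, OSError) as exc:
        raise DataError(f"stage {mode!r} failed: {exc}") from exc
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary


def _load_input_trajectories(cfg: RunConfig) -> list[AngularTrajectory]:
    if cfg.input_trajectories is None:
        raise DataError("this mode requires input_trajectories")
    path = Path(cfg.input_trajectories)
    if not path.exists():
        raise DataError(f"input trajectory file not found: {path}")
    try:
        return read_trajectories(path)
    except ValueError as exc:
        raise DataError(str(exc)) from exc
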