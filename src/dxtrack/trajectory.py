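"""Angular trajectories: containers, start conventions, displacements, I/O.

A trajectory is the time-ordered (t, χ, θ) record of one diffraction spot
from its emergence to its vanishing.  The first sample defines the start time
and the angular origin: every displacement reported downstream is measured
from that first sample ("from-start" convention), and a trajectory's lifetime
is t_last − t_first.

χ is an azimuth and therefore only defined modulo the full circle
(2π·10³ mrad); displacement computations unwrap χ to the branch nearest the
previous sample, so trajectories that cross the ±π branch cut behave
continuously.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FULL_CIRCLE_MRAD = 2e3 * np.pi

#: tolerance on sample-time uniformity, seconds
TIME_TOL = 1e-9


@dataclass
class AngularTrajectory:
    """One spot's angular track: uniformly sampled (t, χ, θ) in s and mrad."""

    id: str
    t: np.ndarray
    chi: np.ndarray
    theta: np.ndarray
    condition: str = ""
    region: str = ""

    _chi_unwrapped: np.ndarray | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.chi = np.asarray(self.chi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if not (len(self.t) == len(self.chi) == len(self.theta)):
            raise ValueError(f"trajectory {self.id!r}: column lengths differ")
        if len(self.t) == 0:
            raise ValueError(f"trajectory {self.id!r}: empty")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError(
                f"trajectory {self.id!r}: sample times not strictly increasing"
            )
        if len(dt) and np.any(np.abs(dt - dt[0]) > TIME_TOL):
            raise ValueError(
                f"trajectory {self.id!r}: sample times not uniformly spaced"
            )

    # -- basic quantities ---------------------------------------------------

    @property
    def start_time(self) -> float:
        return float(self.t[0])

    @property
    def frame_interval(self) -> float:
        if len(self.t) < 2:
            return float("nan")
        return float(self.t[1] - self.t[0])

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def lifetime(self) -> float:
        """Visible duration in seconds: t_last − t_first (0 for one frame)."""
        return float(self.t[-1] - self.t[0])

    @property
    def chi_unwrapped(self) -> np.ndarray:
        """χ with each sample moved to the branch nearest its predecessor."""
        if self._chi_unwrapped is None:
            self._chi_unwrapped = np.unwrap(self.chi, period=FULL_CIRCLE_MRAD)
        return self._chi_unwrapped

    def _angles(self, axis: str) -> np.ndarray:
        if axis == "chi":
            return self.chi_unwrapped
        if axis == "theta":
            return self.theta
        raise ValueError(f"axis must be 'chi' or 'theta', got {axis!r}")

    # -- displacements --------------------------------------------------------

    def lag_index(self, lag: float) -> int:
        """Frame index of a lag; error if the lag is off the frame grid."""
        if lag <= 0:
            raise ValueError(f"lag must be positive, got {lag}")
        k = lag / self.frame_interval
        k_round = int(round(k))
        if abs(k - k_round) * self.frame_interval > TIME_TOL or k_round < 1:
            raise ValueError(
                f"lag {lag} s is not a positive multiple of the frame "
                f"interval {self.frame_interval} s"
            )
        return k_round

    def displacement_from_start(self, axis: str, lag: float) -> float | None:
        """angle(start+lag) − angle(start), or None if lifetime < lag."""
        k = self.lag_index(lag)
        if k >= self.n_frames:
            return None
        a = self._angles(axis)
        return float(a[k] - a[0])

    def displacement_series(self, axis: str) -> np.ndarray:
        """Displacements from start at every available lag (index 0 ↔ lag 0)."""
        a = self._angles(axis)
        return a - a[0]


def make_lag_grid(frame_interval: float, n_lags: int) -> np.ndarray:
    """Lag grid Δt, 2Δt, …, n·Δt in seconds (the first lag is one frame)."""
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    return frame_interval * np.arange(1, n_lags + 1)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

COLUMNS = ["id", "condition", "region", "t", "chi_mrad", "theta_mrad"]


def write_trajectories(trajs, path, float_fmt: str = "%.10g",
                       header_comment: str | None = None) -> None:
    """Write trajectories as a comma-delimited table.

    Ten significant digits keep the round trip lossless to 1e−9 relative
    while keeping output byte-reproducible across runs.
    """
    frames = []
    for tr in trajs:
        frames.append(pd.DataFrame({
            "id": tr.id,
            "condition": tr.condition,
            "region": tr.region,
            "t": tr.t,
            "chi_mrad": tr.chi,
            "theta_mrad": tr.theta,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=COLUMNS))
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=float_fmt)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_trajectories(path) -> list[AngularTrajectory]:
    """Read a trajectory table (comma- or tab-delimited, autodetected).

    Rows of one trajectory must be contiguous and time-ordered; a shuffled or
    non-monotone block is reported with the offending id.  Malformed rows are
    reported with their line number.
    """
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    data_start = 0
    while data_start < len(lines) and lines[data_start].startswith("#"):
        data_start += 1
    if data_start >= len(lines) or not lines[data_start].strip():
        raise ValueError(f"{path}: no header line found")
    sep = _sniff_delimiter(lines[data_start])
    body = "\n".join(lines[data_start:])
    try:
        df = pd.read_csv(
            io.StringIO(body), sep=sep,
            dtype={"id": str, "condition": str, "region": str},
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("t", "chi_mrad", "theta_mrad"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering (relative to data start)
            lineno = int(bad.idxmax()) + data_start + 2
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line {lineno}"
            )
        df[col] = pd.to_numeric(df[col])
    df[["condition", "region"]] = df[["condition", "region"]].fillna("")

    # each id must occupy exactly one contiguous run of rows
    if len(df):
        runs = (df["id"] != df["id"].shift()).cumsum()
        runs_per_id = runs.groupby(df["id"]).nunique()
        split = runs_per_id[runs_per_id > 1]
        if len(split):
            raise ValueError(
                f"{path}: rows of trajectory {split.index[0]!r} not contiguous"
            )

    trajs = []
    for tid, block in df.groupby("id", sort=False):
        t = block["t"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"{path}: non-monotone times within trajectory {tid!r} "
                "(rows shuffled?)"
            )
        trajs.append(AngularTrajectory(
            id=str(tid),
            t=t,
            chi=block["chi_mrad"].to_numpy(),
            theta=block["theta_mrad"].to_numpy(),
            condition=str(block["condition"].iloc[0]),
            region=str(block["region"].iloc[0]),
        ))
    return trajs
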