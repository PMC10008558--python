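"""Covariance-based diffusion estimation from noisy, motion-blurred tracks.

For a pure-diffusion trajectory {X_k} sampled every dt with localization
error sigma and motion-blur factor R, the displacements over a time lag j,
D_{k,j} = X_{k+j} - X_k, have the generalized covariance

    <D_{k,j} D_{k',j}> = 2 D (j - 2R) dt + 2 sigma^2      |k - k'| = 0
                         2 D (j - |k - k'|) dt            0 < |k - k'| < j
                         2 D R dt - sigma^2               |k - k'| = j
                         0                                |k - k'| > j

The bands strictly between the diagonal and |k-k'| = j are independent of
sigma, which motivates the extended covariance estimator (ECVE): the mean of
the |k-k'| = 1 products divided by 2 dt (j - 1).  The localization error is
then recovered from the diagonal.  The classic single-step CVE and the MSD
are provided as comparators.

Positions are nm in trajectory containers; diffusion estimates are um^2/s
and variances um^2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, quad

__all__ = [
    "Trajectory",
    "CovarianceSpec",
    "DiffusionSeries",
    "displacements",
    "cov_theory",
    "blur_factor",
    "pattern_blur_factor",
    "ecve",
    "ecve_point",
    "sigma_from_diagonal",
    "cve",
    "msd",
    "simulate_diffusion_track",
]

NM2_TO_UM2 = 1e-6


@dataclass
class Trajectory:
    """Positions (nm) at a fixed sampling interval dt (s).

    ``positions`` is (N, d) for d in {1, 2, 3}; ``gaps`` marks samples where
    localization failed (those split estimation windows; nothing is imputed).
    """

    positions: np.ndarray
    dt_s: float
    gaps: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim == 2 and self.positions.shape[0] == 1 and self.positions.shape[1] > 3:
            self.positions = self.positions.T
        if self.dt_s <= 0:
            raise ValueError("sampling interval must be positive")
        if self.gaps is None:
            self.gaps = ~np.isfinite(self.positions).all(axis=1)
        self.gaps = np.asarray(self.gaps, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    def segments(self, min_len: int = 2) -> list[np.ndarray]:
        """Index arrays of contiguous gap-free runs of at least ``min_len``."""
        out = []
        idx = np.flatnonzero(~self.gaps)
        if len(idx) == 0:
            return out
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for seg in np.split(idx, breaks + 1):
            if len(seg) >= min_len:
                out.append(seg)
        return out


def displacements(traj: Trajectory, j: int) -> np.ndarray:
    """Lag-j displacements D_{k,j} = X_{k+j} - X_k, shape (N - j, d)."""
    if j < 1:
        raise ValueError("lag j must be >= 1")
    if j >= traj.n:
        raise ValueError("lag j must be smaller than the trajectory length")
    return traj.positions[j:] - traj.positions[:-j]


@dataclass(frozen=True)
class CovarianceSpec:
    """Parameters of the displacement covariance: D (um^2/s), sigma (um), R, j, dt (s)."""

    D: float
    sigma: float
    R: float
    j: int
    dt: float

    def __post_init__(self) -> None:
        if not 0 <= self.R <= 0.25:
            raise ValueError("blur factor R must lie in [0, 1/4]")
        if self.j < 1:
            raise ValueError("lag j must be >= 1")
        if self.dt <= 0 or self.D < 0:
            raise ValueError("dt must be positive and D nonnegative")


def cov_theory(spec: CovarianceSpec, lag: int) -> float:
    """Theoretical <D_{k,j} D_{k+lag,j}> (um^2) for step separation ``lag``."""
    lag = abs(int(lag))
    D, s2, R, j, dt = spec.D, spec.sigma**2, spec.R, spec.j, spec.dt
    if lag == 0:
        return 2.0 * D * (j - 2.0 * R) * dt + 2.0 * s2
    if lag < j:
        return 2.0 * D * (j - lag) * dt
    if lag == j:
        return 2.0 * D * R * dt - s2
    return 0.0


def blur_factor(shutter, dt: float = 1.0, n_quad: int = 4096) -> float:
    """Motion-blur factor R = (1/dt) int_0^dt S(t) (1 - S(t)) dt.

    ``shutter`` is either a callable s(t) on [0, dt] or a sampled array over
    a uniform time grid on [0, dt]; it must be nonnegative and integrate to
    1 (a normalized exposure profile).  S is its cumulative integral.  An
    instantaneous shutter gives R = 0; a uniform full-interval shutter 1/6.
    """
    if callable(shutter):
        t = np.linspace(0.0, dt, n_quad)
        s = np.asarray([shutter(ti) for ti in t], dtype=float)
    else:
        s = np.asarray(shutter, dtype=float)
        t = np.linspace(0.0, dt, len(s))
    if np.any(s < 0):
        raise ValueError("shutter function must be nonnegative")
    total = np.trapezoid(s, t)
    if not np.isclose(total, 1.0, rtol=1e-3):
        raise ValueError("shutter function must integrate to 1 over the interval")
    S = cumulative_trapezoid(s, t, initial=0.0)
    return float(np.trapezoid(S * (1.0 - S), t) / dt)


def pattern_blur_factor(schedule, n_per_slot: int = 64) -> float:
    """Blur factor of a shot schedule's excitation profile over one pattern.

    The shutter is the laser-on indicator (each slot's excitation window is
    the latter part of the slot; blanks stay dark), normalized over the
    pattern period.  Close to the uniform-shutter value 1/6 for the
    42-slot schedule.
    """
    period_us = schedule.n_slots * schedule.slot_period_us
    t = np.linspace(0.0, period_us, schedule.n_slots * n_per_slot, endpoint=False)
    s = np.zeros_like(t)
    for slot in schedule.slots:
        if slot.is_blank:
            continue
        on0 = slot.t_start_us + (schedule.slot_period_us - slot.excitation_window_us)
        on1 = slot.t_start_us + schedule.slot_period_us
        s[(t >= on0) & (t < on1)] = 1.0
    s /= np.trapezoid(s, t)
    return blur_factor(s, dt=period_us)


@dataclass
class DiffusionSeries:
    """Sliding-window diffusion point estimates along one trajectory."""

    d_um2s: np.ndarray  # per-window diffusion estimate
    sigma2_um2: np.ndarray  # per-window localization variance estimate
    window_start: np.ndarray  # trajectory index of the first step in each window
    lag: int
    window: int
    dt_s: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": self.window_start,
                "D_um2s": self.d_um2s,
                "sigma2_um2": self.sigma2_um2,
            }
        )


def _axis_products(x_nm: np.ndarray, j: int) -> np.ndarray:
    """Per-axis first-off-diagonal products D_{k,j} D_{k+1,j} (um^2), (n_prod, d)."""
    d = (x_nm[j:] - x_nm[:-j]) * 1e-3  # um
    return d[:-1] * d[1:]


def ecve_point(x_nm: np.ndarray, j: int, dt: float, R: float = 0.0) -> tuple[float, float]:
    """ECVE diffusion and sigma^2 estimate from one gap-free segment.

    Per-axis estimates are averaged over the axes.  Returns (D um^2/s,
    sigma^2 um^2); sigma^2 may come out negative in small samples and is
    reported as-is.
    """
    if j < 2:
        raise ValueError("ECVE needs lag j >= 2 (use cve for j = 1)")
    x_nm = np.atleast_2d(np.asarray(x_nm, dtype=float))
    if x_nm.shape[0] == 1:
        x_nm = x_nm.T
    prod = _axis_products(x_nm, j)
    if len(prod) < 1:
        raise ValueError("segment too short for the requested lag")
    D = float(prod.mean() / (2.0 * dt * (j - 1)))
    disp2 = ((x_nm[j:] - x_nm[:-j]) * 1e-3) ** 2
    s2 = float((disp2.mean() - 2.0 * D * (j - 2.0 * R) * dt) / 2.0)
    return D, s2


def ecve(
    traj: Trajectory, j: int = 8, window: int = 16, R: float = 0.0, stride: int = 1
) -> DiffusionSeries:
    """Sliding-window ECVE series along a trajectory.

    Each estimate averages ``window`` consecutive first-off-diagonal products
    (stride-1 sliding by default); windows never span localization gaps.
    The default lag j = 8 with 16 averaged points matches the intended
    in-vivo operating point of the estimator.
    """
    if j < 2:
        raise ValueError("ECVE needs lag j >= 2 (use cve for j = 1)")
    if window < 1:
        raise ValueError("window must be >= 1")
    Ds, s2s, starts = [], [], []
    for seg in traj.segments(min_len=j + 2):
        x = traj.positions[seg]
        prod = _axis_products(x, j)  # (n_prod, d)
        disp2 = ((x[j:] - x[:-j]) * 1e-3) ** 2
        n_prod = len(prod)
        for k in range(0, n_prod - window + 1, stride):
            p = prod[k : k + window]
            D = float(p.mean() / (2.0 * traj.dt_s * (j - 1)))
            m2 = disp2[k : k + window + 1].mean()
            s2 = float((m2 - 2.0 * D * (j - 2.0 * R) * traj.dt_s) / 2.0)
            Ds.append(D)
            s2s.append(s2)
            starts.append(int(seg[k]))
    return DiffusionSeries(
        np.asarray(Ds), np.asarray(s2s), np.asarray(starts), j, window, traj.dt_s
    )


def sigma_from_diagonal(
    traj: Trajectory, j: int, D: float, R: float = 0.0
) -> tuple[float, bool]:
    """Localization variance sigma^2 (um^2) from the covariance diagonal.

    sigma^2 = (<D_{k,j}^2> - 2 D (j - 2R) dt) / 2.  Returns (sigma2,
    negative_flag); negative small-sample values are reported as-is.
    """
    disp2 = (displacements(traj, j) * 1e-3) ** 2
    s2 = float((disp2.mean() - 2.0 * D * (j - 2.0 * R) * traj.dt_s) / 2.0)
    return s2, s2 < 0


def cve(traj: Trajectory, R: float = 0.0) -> tuple[float, float]:
    """Single-step covariance estimator (j = 1): returns (D um^2/s, sigma^2 um^2).

    D = <d_k^2>/(2 dt) + <d_k d_{k+1}>/dt and
    sigma^2 = R <d_k^2> + (2R - 1) <d_k d_{k+1}>, with d_k the single steps.
    """
    if traj.n < 3:
        raise ValueError("CVE needs at least 3 positions")
    d = displacements(traj, 1) * 1e-3
    m2 = (d**2).mean()
    m11 = (d[:-1] * d[1:]).mean()
    D = float(m2 / (2.0 * traj.dt_s) + m11 / traj.dt_s)
    s2 = float(R * m2 + (2.0 * R - 1.0) * m11)
    return D, s2


def msd(traj: Trajectory, max_lag: int) -> pd.DataFrame:
    """Empirical per-axis-summed mean square displacement curve (um^2)."""
    rows = []
    for j in range(1, max_lag + 1):
        if j >= traj.n:
            break
        d = displacements(traj, j) * 1e-3
        rows.append((j, j * traj.dt_s, float((d**2).sum(axis=1).mean()), float((d**2).mean())))
    return pd.DataFrame(rows, columns=["lag", "t_s", "msd_um2", "msd_per_axis_um2"])


def simulate_diffusion_track(
    D_um2s: float,
    n_steps: int,
    dt_s: float,
    rng: np.random.Generator,
    sigma_nm: float = 0.0,
    R: float = 0.0,
    ndim: int = 1,
    n_substeps: int = 32,
) -> Trajectory:
    """Pure-diffusion trajectory with localization noise and motion blur.

    With R > 0 each recorded position is the uniform-shutter average of
    ``n_substeps`` intra-interval Brownian positions (R = 1/6 in the limit);
    with R = 0 positions are instantaneous samples.  iid Gaussian noise of SD
    ``sigma_nm`` is added per axis.  Serves as the simulation oracle for the
    covariance theory and the estimators.
    """
    step_sd = np.sqrt(2.0 * D_um2s * 1e6 * dt_s)  # nm per full interval
    if R == 0.0:
        pos = np.cumsum(rng.standard_normal((n_steps, ndim)) * step_sd, axis=0)
    else:
        sub_sd = step_sd / np.sqrt(n_substeps)
        walk = np.cumsum(rng.standard_normal((n_steps * n_substeps, ndim)) * sub_sd, axis=0)
        pos = walk.reshape(n_steps, n_substeps, ndim).mean(axis=1)
    if sigma_nm > 0:
        pos = pos + rng.standard_normal(pos.shape) * sigma_nm
    return Trajectory(pos, dt_s)
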