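"""Closed-loop tracking simulation: emitter motion, Poisson photons, feedback.

Emitters either follow a deterministic stage path (circle in xy plus an axial
sinusoid, the bead-scan protocol) or diffuse inside a spherocylindrical
bacterial cell while switching between diffusion states as a continuous-time
Markov chain.  Photon counts per 20 us shot slot are independent Poisson draws
with mean c * Phi(r_p - r_i) (+ background), where r_i is the shot's PSF
displacement.  A software feedback loop re-centers the pattern once per
0.84 ms pattern using a photon-weighted centroid over a sliding window of two
full patterns and a discrete PI controller, standing in for the instrument's
FPGA/piezo loop.

Motion blur is captured at single-slot granularity: the emitter position is
updated for every 20 us laser shot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .localization import Estimate, MapReconstructor, PhotonPattern, PriorConfig, SearchConfig
from .psf_pattern import BeamGeometry, PSFStack, ShotSchedule, shot_displacements

__all__ = [
    "CellGeometry",
    "StateModel",
    "EmitterPath",
    "FeedbackState",
    "TrackingRun",
    "simulate_stage_path",
    "simulate_cell_trajectory",
    "simulate_photons",
    "calibrate_efficiency",
    "centroid_estimate",
    "feedback_update",
    "run_tracking",
]

SLOT_DT_S = 20e-6


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylinder (cylinder with hemispherical caps) cell model.

    ``cylinder_length`` is the length of the straight section (nm); total
    pole-to-pole length is cylinder_length + 2 * radius.  The axis runs along
    x through ``center``.
    """

    cylinder_length: float = 2000.0
    radius: float = 400.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.cylinder_length < 0:
            raise ValueError("cylinder length must be nonnegative")

    def _axis_point(self, p: np.ndarray) -> np.ndarray:
        """Closest point on the axis segment to ``p``."""
        q = p - np.asarray(self.center)
        h = self.cylinder_length / 2.0
        ax = np.clip(q[..., 0], -h, h)
        out = np.zeros_like(q)
        out[..., 0] = ax
        return out + np.asarray(self.center)

    def distance(self, p: np.ndarray) -> np.ndarray:
        """Distance from the axis segment (<= radius means inside)."""
        p = np.asarray(p, dtype=float)
        return np.linalg.norm(p - self._axis_point(p), axis=-1)

    def contains(self, p: np.ndarray) -> np.ndarray:
        return self.distance(p) <= self.radius + 1e-9

    def reflect(self, p: np.ndarray) -> np.ndarray:
        """Reflect a point across the membrane until it lies inside."""
        p = np.asarray(p, dtype=float).copy()
        for _ in range(16):
            q = self._axis_point(p)
            u = p - q
            d = np.linalg.norm(u)
            if d <= self.radius:
                return p
            p = q + u * (2.0 * self.radius - d) / d
        # pathological step far outside: clamp to the membrane
        q = self._axis_point(p)
        u = p - q
        return q + u * self.radius / np.linalg.norm(u)

    def sample_interior(self, rng: np.random.Generator) -> np.ndarray:
        h = self.cylinder_length / 2.0
        lo = np.asarray(self.center) - np.array([h + self.radius] + [self.radius] * 2)
        hi = np.asarray(self.center) + np.array([h + self.radius] + [self.radius] * 2)
        while True:
            p = rng.uniform(lo, hi)
            if self.contains(p):
                return p


@dataclass
class StateModel:
    """K-state diffusion model with CTMC switching.

    ``diffusion_um2s`` are per-state diffusion coefficients; ``rate_matrix``
    is the CTMC generator Q (1/s, rows sum to 0).  The default reproduces a
    three-state chaperone-like kinetic scheme: a slow bound state
    (0.1 um^2/s), a short-lived intermediate site-interrogation state
    (1.4 um^2/s, ~5 ms mean dwell) and a fast free state (6 um^2/s), with
    stationary occupancies approximately 43/18/39 %.
    """

    diffusion_um2s: np.ndarray = field(
        default_factory=lambda: np.array([0.1, 1.4, 6.0])
    )
    rate_matrix: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                # slow -> fast release at 41.9/s (24 ms dwell)
                [-41.86, 0.0, 41.86],
                # intermediate: bind or reject at 100/s each (5 ms dwell)
                [100.0, -200.0, 100.0],
                # fast -> intermediate interrogation at 92.3/s (10.8 ms dwell)
                [0.0, 92.31, -92.31],
            ]
        )
    )
    initial: np.ndarray | None = None  # defaults to the stationary distribution

    def __post_init__(self) -> None:
        self.diffusion_um2s = np.asarray(self.diffusion_um2s, dtype=float)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        K = len(self.diffusion_um2s)
        if self.rate_matrix.shape != (K, K):
            raise ValueError("rate matrix shape must match the number of states")
        if not np.allclose(self.rate_matrix.sum(axis=1), 0.0, atol=1e-6):
            raise ValueError("rate matrix rows must sum to 0")
        if np.any(self.diffusion_um2s < 0):
            raise ValueError("diffusion coefficients must be nonnegative")

    @property
    def n_states(self) -> int:
        return len(self.diffusion_um2s)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the CTMC (left null vector of Q)."""
        w, v = np.linalg.eig(self.rate_matrix.T)
        k = np.argmin(np.abs(w))
        pi = np.real(v[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    def sample_states(self, n_slots: int, dt: float, rng: np.random.Generator) -> np.ndarray:
        """State index at each slot time, by exact CTMC (Gillespie) sampling."""
        p0 = self.stationary() if self.initial is None else np.asarray(self.initial, float)
        state = int(rng.choice(self.n_states, p=p0))
        t_end = n_slots * dt
        jump_times = [0.0]
        jump_states = [state]
        t = 0.0
        while True:
            rate = -self.rate_matrix[state, state]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= t_end:
                break
            p = self.rate_matrix[state].copy()
            p[state] = 0.0
            p /= p.sum()
            state = int(rng.choice(self.n_states, p=p))
            jump_times.append(t)
            jump_states.append(state)
        idx = np.searchsorted(np.asarray(jump_times), np.arange(n_slots) * dt, side="right") - 1
        return np.asarray(jump_states)[idx]


@dataclass
class EmitterPath:
    """Ground-truth emitter positions per shot slot, plus emission parameters."""

    positions: np.ndarray  # (n_slots, 3) nm
    dt_s: float = SLOT_DT_S
    states: np.ndarray | None = None
    efficiency: float = 1.0  # photon-efficiency c (counts per PSF-intensity unit)
    background: float = 0.0  # mean background counts per illuminated slot

    @property
    def n_slots(self) -> int:
        return len(self.positions)


def simulate_stage_path(
    radius_nm: float = 750.0,
    z_peak_to_peak_nm: float = 500.0,
    period_s: float = 1.0,
    duration_s: float = 1.0,
    pause_s: float = 0.0,
    dt_s: float = SLOT_DT_S,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> EmitterPath:
    """Deterministic bead-scan path: xy circle plus axial sinusoid.

    One circle revolution and one axial oscillation per ``period_s``; after
    each ``period_s`` of motion the stage pauses for ``pause_s``.  Sampled at
    every 20 us shot slot.
    """
    if radius_nm < 0 or z_peak_to_peak_nm < 0 or period_s <= 0 or duration_s <= 0:
        raise ValueError("stage-path parameters must be positive")
    t = np.arange(int(round(duration_s / dt_s))) * dt_s
    cycle = period_s + pause_s
    tc = np.mod(t, cycle)
    phase = np.clip(tc, 0.0, period_s) / period_s  # frozen during the pause
    w = 2.0 * np.pi * phase
    pos = np.column_stack(
        [
            radius_nm * np.cos(w),
            radius_nm * np.sin(w),
            0.5 * z_peak_to_peak_nm * np.sin(w),
        ]
    ) + np.asarray(center)
    return EmitterPath(pos, dt_s=dt_s)


def simulate_cell_trajectory(
    geometry: CellGeometry,
    model: StateModel,
    duration_s: float,
    rng: np.random.Generator,
    dt_s: float = SLOT_DT_S,
    start: np.ndarray | None = None,
) -> EmitterPath:
    """Brownian motion with CTMC state switching inside a spherocylinder.

    Euler-Maruyama steps with per-axis variance 2 D(state) dt at every shot
    slot; the membrane reflects.  D is converted from um^2/s to nm^2/s.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s / dt_s))
    states = model.sample_states(n, dt_s, rng)
    sigma = np.sqrt(2.0 * model.diffusion_um2s[states] * 1e6 * dt_s)  # nm
    steps = rng.standard_normal((n, 3)) * sigma[:, None]
    pos = np.empty((n, 3))
    p = geometry.sample_interior(rng) if start is None else np.asarray(start, float)
    for k in range(n):
        p = p + steps[k]
        if not geometry.contains(p):
            p = geometry.reflect(p)
        pos[k] = p
    return EmitterPath(pos, dt_s=dt_s, states=states)


def calibrate_efficiency(
    psf: PSFStack,
    schedule: ShotSchedule,
    geometry: BeamGeometry,
    rate_hz: float = 60e3,
) -> float:
    """Photon efficiency c giving ``rate_hz`` mean detected rate at the center.

    The mean count per pattern for an emitter at the pattern center is
    c * sum_i Phi(-d_i); c is solved so that this equals
    rate_hz * pattern_period.
    """
    disp = shot_displacements(schedule, geometry)[schedule.illuminated]
    s = psf.value(-disp, outside="zero").sum()
    if s <= 0:
        raise ValueError("pattern has no PSF power at its center")
    return rate_hz * schedule.pattern_period_ms * 1e-3 / s


def simulate_photons(
    path: EmitterPath,
    psf: PSFStack,
    schedule: ShotSchedule,
    geometry: BeamGeometry,
    centers: np.ndarray,
    rng: np.random.Generator,
) -> list[PhotonPattern]:
    """Open-loop Poisson photon generation for a known center history.

    ``centers`` is (n_patterns, 3): the pattern center during each full
    pattern.  The emitter path must cover n_patterns * n_slots slots; excess
    slots are ignored.  Blank slots always record zero counts.
    """
    disp = shot_displacements(schedule, geometry)
    foci = schedule.offsets
    illum = schedule.illuminated
    m = schedule.n_slots
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n_patterns = len(centers)
    if path.n_slots < n_patterns * m:
        raise ValueError("emitter path too short for the requested patterns")
    out = []
    for j in range(n_patterns):
        seg = path.positions[j * m : (j + 1) * m]
        shot_pos = centers[j] + disp
        lam = np.zeros(m)
        lam[illum] = path.efficiency * psf.value(
            seg[illum] - shot_pos[illum], outside="zero"
        ) + path.background
        counts = rng.poisson(lam)
        counts[~illum] = 0
        out.append(
            PhotonPattern(
                counts, shot_pos, ~illum, focus_positions=centers[j] + foci, index=j
            )
        )
    return out


def centroid_estimate(
    counts: np.ndarray, focus_positions: np.ndarray
) -> np.ndarray | None:
    """Photon-weighted mean of effective focus positions; None on zero counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return None
    return (counts[:, None] * np.asarray(focus_positions, float)).sum(axis=0) / total


@dataclass
class FeedbackState:
    """Discrete PI re-centering controller, updated once per pattern.

    The sliding centroid window spans two full patterns (84 slots).  The
    instrument's separate slow z-stage is collapsed into the same controller:
    the axial center is driven exactly like the lateral ones.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    kp: float = 0.4
    ki: float = 0.05
    integral: np.ndarray = field(default_factory=lambda: np.zeros(3))


def feedback_update(state: FeedbackState, centroid: np.ndarray | None) -> FeedbackState:
    """Apply one PI update toward the centroid; hold the center on no signal."""
    if centroid is None:
        return state
    error = np.asarray(centroid, float) - state.center
    integral = state.integral + error
    return FeedbackState(
        center=state.center + state.kp * error + state.ki * integral,
        kp=state.kp,
        ki=state.ki,
        integral=integral,
    )


@dataclass
class TrackingRun:
    """Full record of one closed-loop tracking simulation."""

    patterns: list[PhotonPattern]
    centers: np.ndarray  # (n_patterns, 3) pattern center per pattern
    truth: EmitterPath | None
    estimates: list[Estimate | None]
    schedule: ShotSchedule
    seed: int | None = None

    def estimate_frame(self) -> pd.DataFrame:
        """Tabular estimates: one row per pattern, NaN rows for gaps."""
        period_s = self.schedule.pattern_period_ms * 1e-3
        rows = []
        for j, est in enumerate(self.estimates):
            if est is None:
                rows.append((j, j * period_s * 1e3, np.nan, np.nan, np.nan, np.nan, 0, np.nan))
            else:
                rows.append(
                    (j, j * period_s * 1e3, *est.r_tilde, est.c_tilde, est.n_total, est.objective)
                )
        return pd.DataFrame(
            rows,
            columns=["pattern_index", "t_ms", "x_nm", "y_nm", "z_nm", "c_tilde", "n_total", "objective"],
        )

    def truth_per_pattern(self) -> np.ndarray | None:
        """Ground-truth position at each pattern time (mean over the pattern's slots)."""
        if self.truth is None:
            return None
        m = self.schedule.n_slots
        n = len(self.patterns)
        return self.truth.positions[: n * m].reshape(n, m, 3).mean(axis=1)

    def errors(self) -> np.ndarray | None:
        """(n_patterns, 3) estimate minus ground truth; NaN at gaps."""
        t = self.truth_per_pattern()
        if t is None:
            return None
        est = self.estimate_frame()[["x_nm", "y_nm", "z_nm"]].to_numpy()
        return est - t


def run_tracking(
    path: EmitterPath,
    psf: PSFStack,
    schedule: ShotSchedule,
    geometry: BeamGeometry,
    rng: np.random.Generator,
    priors: PriorConfig | None = None,
    search: SearchConfig | None = None,
    feedback: FeedbackState | None = None,
    initial_center: np.ndarray | None = None,
    reconstruct: bool = True,
) -> TrackingRun:
    """Closed-loop simulation followed by offline MAP reconstruction.

    Per pattern: Poisson photon generation at the current pattern center,
    a centroid over the last two patterns, and one PI feedback update.  The
    offline reconstruction consumes only counts, shot positions and the PSF
    (never the ground truth).
    """
    m = schedule.n_slots
    n_patterns = path.n_slots // m
    if n_patterns == 0:
        raise ValueError("emitter path shorter than one pattern")
    fb = feedback or FeedbackState(
        center=np.asarray(
            initial_center if initial_center is not None else path.positions[0], float
        ).copy()
    )
    disp = shot_displacements(schedule, geometry)
    foci = schedule.offsets
    illum = schedule.illuminated
    patterns: list[PhotonPattern] = []
    centers = np.empty((n_patterns, 3))
    win_counts: list[np.ndarray] = []
    win_foci: list[np.ndarray] = []
    for j in range(n_patterns):
        centers[j] = fb.center
        seg = path.positions[j * m : (j + 1) * m]
        shot_pos = fb.center + disp
        lam = np.zeros(m)
        lam[illum] = path.efficiency * psf.value(
            seg[illum] - shot_pos[illum], outside="zero"
        ) + path.background
        counts = rng.poisson(lam)
        counts[~illum] = 0
        patterns.append(
            PhotonPattern(counts, shot_pos, ~illum, focus_positions=fb.center + foci, index=j)
        )
        # sliding window over the last two full patterns
        win_counts.append(counts[illum])
        win_foci.append((fb.center + foci)[illum])
        if len(win_counts) > 2:
            win_counts.pop(0)
            win_foci.pop(0)
        cen = centroid_estimate(np.concatenate(win_counts), np.concatenate(win_foci))
        fb = feedback_update(fb, cen)
    estimates: list[Estimate | None] = []
    if reconstruct:
        rec = MapReconstructor(psf, priors=priors, search=search, volume_center=centers[0])
        for j, pat in enumerate(patterns):
            estimates.append(rec.estimate(pat, volume_center=centers[j]))
    return TrackingRun(patterns, centers, path, estimates, schedule)
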