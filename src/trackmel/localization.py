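"""Cross-entropy MAP localization from structured-excitation photon counts.

A full pattern j yields photon counts {n_i} for shots with known PSF
displacements {r_i}.  With Poisson emission, lambda_i = c * Phi(r - r_i), and
after profiling out the photon-efficiency c, the negative log-likelihood of a
candidate position r reduces (up to a count-only constant) to the
cross-entropy between the observed count ratios and the PSF intensity ratios:

    l(r) = - sum_i n_i * ln( Phi_i(r) / sum_i Phi_i(r) )

The MAP estimate minimizes l (optionally exponentially averaged over past
patterns) plus three weak priors: a binary photon-efficiency bound T_c, a
Gaussian efficiency-smoothness prior G_c around an EWMA of past c values, and
a Gaussian jump prior G_r around an EWMA of past positions.  The jump prior's
width sets an upper bound on the observable diffusion rate:
D_max = sigma_r^2 / (2 dt).

Positions are nm throughout; grids are searched on a fixed 10 nm lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._interp import pattern_nll
from .psf_pattern import PSFStack, RECONSTRUCTION_VOLUME_NM

__all__ = [
    "PhotonPattern",
    "LikelihoodGrid",
    "PriorConfig",
    "PriorState",
    "Estimate",
    "MapReconstructor",
    "SearchConfig",
    "photon_efficiency",
    "neg_log_likelihood_at",
    "neg_log_likelihood_grid",
    "prior_efficiency_bounds",
    "update_c_ewma",
    "prior_c_gaussian",
    "update_r_ewma",
    "prior_jump",
    "tail_average",
    "map_estimate",
    "crlb",
    "fwhm_to_sigma",
    "sigma_r_to_dmax",
]

#: voxels with a PSF-sum below this fraction of the stack peak are unattainable
ATTAINABLE_EPS = 1e-6


def fwhm_to_sigma(fwhm: float | np.ndarray) -> float | np.ndarray:
    """Gaussian FWHM -> standard deviation: sigma = FWHM / (2 sqrt(2 ln 2))."""
    return np.asarray(fwhm) / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def sigma_r_to_dmax(sigma_nm: float, dt_s: float) -> float:
    """Diffusion ceiling (um^2/s) implied by a jump prior of width sigma (nm).

    A displacement of one prior sigma per pattern period corresponds to
    D = sigma^2 / (2 dt); larger jumps are suppressed by the prior.
    """
    return (sigma_nm * 1e-3) ** 2 / (2.0 * dt_s)


@dataclass
class PhotonPattern:
    """Photon counts and shot geometry of one full pattern.

    ``psf_positions`` are absolute PSF displacement vectors (pattern offsets
    plus the feedback center); ``focus_positions`` the absolute effective
    focus positions (used by the real-time centroid, not by the likelihood).
    Blank slots carry zero counts and contribute neither counts nor PSF.
    """

    counts: np.ndarray
    psf_positions: np.ndarray
    is_blank: np.ndarray
    focus_positions: np.ndarray | None = None
    index: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.psf_positions = np.asarray(self.psf_positions, dtype=float)
        self.is_blank = np.asarray(self.is_blank, dtype=bool)
        if len(self.counts) != len(self.psf_positions) or len(self.counts) != len(self.is_blank):
            raise ValueError("counts, psf_positions and is_blank must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be nonnegative")
        if np.any(self.counts[self.is_blank] != 0):
            raise ValueError("blank slots must have zero counts")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def illuminated(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.is_blank
        return self.counts[keep], self.psf_positions[keep]


@dataclass
class LikelihoodGrid:
    """Negative log-likelihood values over a set of candidate positions."""

    points: np.ndarray  # (M, 3) nm
    values: np.ndarray  # (M,)
    attainable: np.ndarray  # (M,) bool


def _psf_at_candidates(
    psf: PSFStack, shot_positions: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """(n_shots, M) matrix of Phi(point - shot_position)."""
    diff = points[None, :, :] - shot_positions[:, None, :]
    return psf.value(diff, outside="zero")


def photon_efficiency(
    pattern: PhotonPattern, psf: PSFStack, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Photon-efficiency estimate c~(r) = sum n_i / sum Phi_i(r) at ``points``.

    Returns ``(c_values, attainable)``; positions where the summed PSF power
    is below the attainability floor are flagged and get c~ = inf (they could
    only produce the observed counts with unphysical efficiency).
    """
    counts, shots = pattern.illuminated()
    phi = _psf_at_candidates(psf, shots, np.atleast_2d(points))
    sphi = phi.sum(axis=0)
    attainable = sphi > ATTAINABLE_EPS * psf.max_intensity
    n = counts.sum()
    with np.errstate(divide="ignore"):
        c = np.where(attainable, n / np.where(attainable, sphi, 1.0), np.inf)
    if n == 0:
        c = np.where(attainable, 0.0, np.inf)
    return c, attainable


def neg_log_likelihood_at(
    pattern: PhotonPattern,
    psf: PSFStack,
    points: np.ndarray,
    background: float = 0.0,
) -> LikelihoodGrid:
    """Cross-entropy negative log-likelihood at candidate positions.

    ``background`` is a constant per-slot intensity added to the PSF model
    (bias from autofluorescence or stray light is treated as part of the
    PSF).  Positions where some illuminated shot has zero model intensity but
    a nonzero count are impossible (+inf); positions with negligible total
    PSF power are marked unattainable.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    counts, shots = pattern.illuminated()
    if counts.sum() == 0:
        raise ValueError("no photons in pattern: likelihood is flat")
    vals = np.empty(len(points))
    sphi = np.empty(len(points))
    # fused kernel, chunked so large grids never build (shots, M) temporaries
    for lo in range(0, len(points), 500_000):
        sl = slice(lo, lo + 500_000)
        vals[sl], sphi[sl] = pattern_nll(
            psf.intensities, psf.origin, psf.voxel_size,
            points[sl], shots, counts, background,
        )
    attainable = sphi > ATTAINABLE_EPS * psf.max_intensity
    vals = np.where(attainable, vals, np.inf)
    return LikelihoodGrid(points, vals, attainable)


def neg_log_likelihood_grid(
    pattern: PhotonPattern,
    psf: PSFStack,
    axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    background: float = 0.0,
) -> LikelihoodGrid:
    """Evaluate the cross-entropy likelihood on a full rectilinear grid."""
    x, y, z = axes
    pts = np.stack(np.meshgrid(x, y, z, indexing="ij"), axis=-1).reshape(-1, 3)
    return neg_log_likelihood_at(pattern, psf, pts, background=background)


def prior_efficiency_bounds(
    pattern: PhotonPattern,
    psf: PSFStack,
    points: np.ndarray,
    c_min: float = 0.0,
    c_max: float = np.inf,
) -> np.ndarray:
    """Binary efficiency-bound prior T_c: 0 where c_min < c~(r) < c_max, inf elsewhere."""
    if not c_min < c_max:
        raise ValueError("c_min must be below c_max")
    c, attainable = photon_efficiency(pattern, psf, points)
    ok = attainable & (c > c_min) & (c < c_max)
    return np.where(ok, 0.0, np.inf)


# --- EWMA priors -----------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Prior and averaging parameters of the MAP estimator.

    gamma_c has a long tail so the efficiency EWMA averages over blinking;
    gamma_r has a short tail so the position EWMA follows the motion.  sigma_c
    is set relative to the current efficiency EWMA.  c_max defaults high
    enough to leave the likelihood untouched.  r_tail = 1 disables likelihood
    tail averaging (only current data).
    """

    gamma_c: float = 0.05
    sigma_c_rel: float = 0.5
    gamma_r: float = 0.5
    fwhm_r_nm: tuple[float, float, float] = (470.0, 470.0, 470.0)
    c_min: float = 0.0
    c_max: float = np.inf
    r_tail: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.gamma_c <= 1 and 0 < self.gamma_r <= 1):
            raise ValueError("EWMA weights must be in (0, 1]")
        if not 0 < self.r_tail <= 1:
            raise ValueError("r_tail must be in (0, 1]")
        if self.sigma_c_rel <= 0 or any(f <= 0 for f in self.fwhm_r_nm):
            raise ValueError("prior widths must be positive")
        if not self.c_min < self.c_max:
            raise ValueError("c_min must be below c_max")

    @property
    def sigma_r_nm(self) -> np.ndarray:
        return fwhm_to_sigma(np.asarray(self.fwhm_r_nm, dtype=float))


@dataclass
class PriorState:
    """Recursive state of the EWMA priors across patterns."""

    config: PriorConfig
    j: int = 0
    c_hat: float = 0.0
    r_hat: np.ndarray | None = None  # volume center for j = 0


def update_c_ewma(state: PriorState, c_prev: float) -> PriorState:
    """ĉ_j = (1 - gamma_c) ĉ_{j-1} + gamma_c c_{j-1}."""
    g = state.config.gamma_c
    return replace(state, c_hat=(1.0 - g) * state.c_hat + g * c_prev)


def prior_c_gaussian(
    state: PriorState, pattern: PhotonPattern, psf: PSFStack, points: np.ndarray
) -> np.ndarray:
    """Efficiency smoothness prior G_c(r) = (ĉ - c~(r))^2 / (2 sigma_c^2); 0 at j = 0."""
    points = np.atleast_2d(points)
    if state.j == 0 or state.c_hat <= 0:
        return np.zeros(len(points))
    c, attainable = photon_efficiency(pattern, psf, points)
    sigma_c = state.config.sigma_c_rel * state.c_hat
    pen = (state.c_hat - np.where(attainable, c, 0.0)) ** 2 / (2.0 * sigma_c**2)
    return np.where(attainable, pen, np.inf)


def update_r_ewma(state: PriorState, r_prev: np.ndarray) -> PriorState:
    """r̂_j = (1 - gamma_r) r̂_{j-1} + gamma_r r̃_{j-1}."""
    g = state.config.gamma_r
    if state.r_hat is None:
        raise ValueError("r_hat must be initialized to the volume center at j = 0")
    return replace(state, r_hat=(1.0 - g) * state.r_hat + g * np.asarray(r_prev, float))


def prior_jump(state: PriorState, points: np.ndarray) -> np.ndarray:
    """Jump prior G_r(r) = sum_a (r̂_a - r_a)^2 / (2 sigma_a^2); 0 at j = 0."""
    points = np.atleast_2d(points)
    if state.j == 0:
        return np.zeros(len(points))
    sig = state.config.sigma_r_nm
    d = (points - state.r_hat) / sig
    return 0.5 * (d**2).sum(axis=1)


def tail_average(l_tail_prev: np.ndarray | None, l_j: np.ndarray, r_tail: float) -> np.ndarray:
    """Exponential likelihood averaging l_tail^j = r l^j + (1 - r) l_tail^{j-1}.

    Initialization: l_tail^0 = l^0.  Applied to the raw likelihood, before
    any priors are added.
    """
    if not 0 < r_tail <= 1:
        raise ValueError("r_tail must be in (0, 1]")
    if l_tail_prev is None or r_tail == 1.0:
        return np.asarray(l_j, dtype=float).copy() if l_tail_prev is None else r_tail * np.asarray(l_j, float)
    return r_tail * np.asarray(l_j, float) + (1.0 - r_tail) * np.asarray(l_tail_prev, float)


@dataclass
class Estimate:
    """A single MAP position estimate on the 10 nm search lattice."""

    r_tilde: np.ndarray
    c_tilde: float
    objective: float
    n_total: int
    index: int = 0


# --- grid search -----------------------------------------------------------

@dataclass(frozen=True)
class SearchConfig:
    """Coarse-to-fine lattice search around the position EWMA r̂.

    The search window must exceed the 3-sigma reach of the jump prior so the
    prior, not the window, bounds admissible jumps.  The lattice is global
    (anchored at the world origin) so estimates are reproducible voxel
    positions independent of the feedback center.
    """

    voxel_nm: float = 10.0
    coarse_nm: float = 80.0
    window_halfwidth_nm: tuple[float, float, float] = (600.0, 600.0, 600.0)
    volume_nm: tuple[float, float, float] = RECONSTRUCTION_VOLUME_NM


def _lattice_axis(lo: float, hi: float, step: float) -> np.ndarray:
    """Global-lattice points with spacing ``step`` inside [lo, hi]."""
    i0 = int(np.ceil(lo / step - 1e-9))
    i1 = int(np.floor(hi / step + 1e-9))
    return step * np.arange(i0, i1 + 1)


def _window_points(center: np.ndarray, half: np.ndarray, step: float,
                   volume_center: np.ndarray, volume_half: np.ndarray) -> np.ndarray:
    axes = []
    for a in range(3):
        lo = max(center[a] - half[a], volume_center[a] - volume_half[a])
        hi = min(center[a] + half[a], volume_center[a] + volume_half[a])
        ax = _lattice_axis(lo, hi, step)
        if len(ax) == 0:
            ax = np.array([step * np.round(np.clip(center[a], lo, hi) / step)])
        axes.append(ax)
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


class MapReconstructor:
    """Sequential MAP position estimation over a stream of photon patterns.

    Maintains the EWMA prior state and (for r_tail < 1) the exponentially
    averaged likelihood on the fine global lattice.  Estimation failures
    (no attainable voxel, or zero photons) propagate as ``None`` gaps.
    """

    def __init__(
        self,
        psf: PSFStack,
        priors: PriorConfig | None = None,
        search: SearchConfig | None = None,
        background: float = 0.0,
        volume_center: np.ndarray | None = None,
    ) -> None:
        self.psf = psf
        self.priors = priors or PriorConfig()
        self.search = search or SearchConfig()
        self.background = background
        self.volume_center = np.zeros(3) if volume_center is None else np.asarray(volume_center, float)
        self.state = PriorState(self.priors, j=0, r_hat=self.volume_center.copy())
        self._tail_vals: np.ndarray | None = None
        self._tail_pts: np.ndarray | None = None
        self._tail_anchor: np.ndarray | None = None

    # -- internals
    def _likelihood_and_c(self, pattern: PhotonPattern, pts: np.ndarray):
        """Single fused PSF evaluation: returns (nll, c~, attainable)."""
        counts, shots = pattern.illuminated()
        nll, sphi = pattern_nll(
            self.psf.intensities, self.psf.origin, self.psf.voxel_size,
            pts, shots, counts, self.background,
        )
        attainable = sphi > ATTAINABLE_EPS * self.psf.max_intensity
        n = counts.sum()
        with np.errstate(divide="ignore"):
            c = np.where(attainable, n / np.where(attainable, sphi, 1.0), np.inf)
        nll = np.where(attainable, nll, np.inf)
        return nll, c, attainable

    def _objective(self, pattern: PhotonPattern, pts: np.ndarray,
                   likelihood: np.ndarray | None = None,
                   c: np.ndarray | None = None,
                   attainable: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        if likelihood is None or c is None:
            likelihood, c, attainable = self._likelihood_and_c(pattern, pts)
        tc_ok = attainable & (c > self.priors.c_min) & (c < self.priors.c_max)
        obj = np.where(tc_ok, likelihood, np.inf)
        if self.state.j > 0:
            if self.state.c_hat > 0:  # no G_c until an efficiency history exists
                sigma_c = self.priors.sigma_c_rel * self.state.c_hat
                gc = (self.state.c_hat - np.where(attainable, c, 0.0)) ** 2 / (2.0 * sigma_c**2)
                obj = obj + np.where(attainable, gc, 0.0)
            obj = obj + prior_jump(self.state, pts)
        return obj, likelihood

    def _pick(self, pts: np.ndarray, obj: np.ndarray) -> int | None:
        finite = np.isfinite(obj)
        if not finite.any():
            return None
        best = obj[finite].min()
        cand = np.flatnonzero(finite & (obj <= best))
        if len(cand) > 1:  # tie-break: nearest r_hat, then lowest index
            d = ((pts[cand] - self.state.r_hat) ** 2).sum(axis=1)
            cand = cand[d == d.min()]
        return int(cand[0])

    def estimate(self, pattern: PhotonPattern, volume_center: np.ndarray | None = None) -> Estimate | None:
        """MAP-estimate the emitter position for one pattern and update priors.

        ``volume_center`` is the current pattern center; the search is
        restricted to the reconstruction volume around it.
        """
        vc = self.volume_center if volume_center is None else np.asarray(volume_center, float)
        vhalf = np.asarray(self.search.volume_nm) / 2.0
        if pattern.n_total == 0:
            self.state = replace(self.state, j=self.state.j + 1)
            return None
        whalf = np.asarray(self.search.window_halfwidth_nm, dtype=float)
        if self.priors.r_tail < 1.0:
            # the averaged-likelihood window sticks to a lattice anchor and
            # recenters only when the position EWMA leaves its inner half,
            # so the argmin never competes with freshly exposed (historyless)
            # voxels on every pattern
            if self._tail_anchor is None or np.any(
                np.abs(self.state.r_hat - self._tail_anchor) > 0.5 * whalf
            ):
                self._tail_anchor = self.search.voxel_nm * np.round(
                    self.state.r_hat / self.search.voxel_nm
                )
            pts = _window_points(self._tail_anchor, whalf, self.search.voxel_nm, vc, vhalf)
            obj, lik = self._objective_with_tail(pattern, pts)
        else:
            # coarse stage
            cpts = _window_points(self.state.r_hat, whalf, self.search.coarse_nm, vc, vhalf)
            cobj, _ = self._objective(pattern, cpts)
            k = self._pick(cpts, cobj)
            if k is None:
                self.state = replace(self.state, j=self.state.j + 1)
                return None
            # fine stage around the coarse minimum
            fhalf = np.full(3, self.search.coarse_nm - self.search.voxel_nm)
            pts = _window_points(cpts[k], fhalf, self.search.voxel_nm, vc, vhalf)
            obj, lik = self._objective(pattern, pts)
        k = self._pick(pts, obj)
        if k is None:
            self.state = replace(self.state, j=self.state.j + 1)
            return None
        r = pts[k]
        c, _ = photon_efficiency(pattern, self.psf, r[None, :])
        est = Estimate(r, float(c[0]), float(obj[k]), pattern.n_total, pattern.index)
        # recursive prior updates with the new estimate
        st = update_c_ewma(self.state, est.c_tilde)
        st = update_r_ewma(st, est.r_tilde)
        self.state = replace(st, j=self.state.j + 1)
        return est

    def _objective_with_tail(self, pattern: PhotonPattern, pts: np.ndarray):
        lik, c, attainable = self._likelihood_and_c(pattern, pts)
        self._tail_c, self._tail_att = c, attainable
        if self._tail_vals is None:
            tail = lik.copy()
        else:
            # re-align the stored tail onto the (possibly shifted) window
            prev = _match_lattice(self._tail_pts, self._tail_vals, pts, self.search.voxel_nm)
            r = self.priors.r_tail
            tail = np.where(
                np.isnan(prev), lik, r * lik + (1.0 - r) * prev
            )
        self._tail_vals, self._tail_pts = tail, pts
        obj, _ = self._objective(pattern, pts, likelihood=tail, c=c, attainable=attainable)
        return obj, tail


def _match_lattice(src_pts: np.ndarray, src_vals: np.ndarray,
                   dst_pts: np.ndarray, step: float) -> np.ndarray:
    """Look up values of a lattice point-set at another; NaN where absent."""
    si = np.round(src_pts / step).astype(np.int64)
    di = np.round(dst_pts / step).astype(np.int64)
    lo = si.min(axis=0)
    shape = si.max(axis=0) - lo + 1
    vol = np.full(tuple(shape), np.nan)
    vol[tuple((si - lo).T)] = src_vals
    rel = di - lo
    ok = np.all((rel >= 0) & (rel < shape), axis=1)
    out = np.full(len(di), np.nan)
    out[ok] = vol[tuple(rel[ok].T)]
    return out


def map_estimate(
    pattern: PhotonPattern,
    psf: PSFStack,
    priors: PriorConfig | None = None,
    search: SearchConfig | None = None,
    state: PriorState | None = None,
    background: float = 0.0,
) -> Estimate | None:
    """One-shot MAP estimate (fresh reconstructor unless a state is supplied)."""
    rec = MapReconstructor(psf, priors=priors, search=search, background=background)
    if state is not None:
        rec.state = state
    return rec.estimate(pattern)


# --- Cramér-Rao lower bound ------------------------------------------------

def crlb(
    psf: PSFStack,
    shot_positions: np.ndarray,
    r_p: np.ndarray,
    total_counts: float,
    delta_nm: float = 2.0,
    background: float = 0.0,
) -> np.ndarray:
    """Numerical per-axis CRLB (nm) for the photon-ratio likelihood.

    The ratio likelihood is multinomial with cell probabilities
    p_i(r) = Phi_i(r) / sum Phi_i(r); the Fisher information for N total
    photons is I_ab = N sum_i (d_a p_i)(d_b p_i) / p_i, with derivatives by
    central finite differences.  Axes carrying no information (singular
    Fisher matrix) are reported as inf.
    """
    r_p = np.asarray(r_p, dtype=float)
    shots = np.asarray(shot_positions, dtype=float)

    def probs(r: np.ndarray) -> np.ndarray:
        phi = psf.value(r[None, :] - shots, outside="zero") + background
        s = phi.sum()
        if s <= 0:
            raise ValueError("PSF has no power at the requested position")
        return phi / s

    p0 = probs(r_p)
    grads = np.zeros((len(p0), 3))
    for a in range(3):
        e = np.zeros(3)
        e[a] = delta_nm
        grads[:, a] = (probs(r_p + e) - probs(r_p - e)) / (2.0 * delta_nm)
    keep = p0 > 1e-300
    fisher = total_counts * np.einsum(
        "ia,ib->ab", grads[keep] / p0[keep, None], grads[keep]
    )
    bounds = np.full(3, np.inf)
    w, v = np.linalg.eigh(fisher)
    tol = max(w.max(), 0.0) * 1e-10
    informative = w > tol
    if not informative.any():
        return bounds
    inv = (v[:, informative] / w[informative]) @ v[:, informative].T
    null = v[:, ~informative]
    for a in range(3):
        # an axis with a null-space component is unbounded
        if null.shape[1] and np.any(np.abs(null[a]) > 1e-6):
            continue
        bounds[a] = np.sqrt(inv[a, a])
    return bounds
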