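"""Hidden Markov segmentation of diffusion point-estimate series.

Sliding-window diffusion estimates from a single trajectory scatter around
the true per-state diffusion coefficient with a heavy right tail; an
inverse-gamma emission distribution captures this shape while keeping the
support positive.  A K-state HMM with inverse-gamma emissions is fitted by
Baum-Welch EM (exact M-step: the scale in closed form, the shape by
root-finding on the digamma equation), decoded by Viterbi, and parameter
uncertainties are obtained by bootstrapping whole trajectories.

States are always reported sorted by emission mean, which resolves the
label-switching symmetry of the likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "InvGammaHMM",
    "FitResult",
    "fit",
    "viterbi",
    "occupancy",
    "bootstrap_se",
]

#: non-positive diffusion estimates are floored here (um^2/s); the
#: inverse-gamma support is strictly positive
D_FLOOR = 1e-4


@dataclass
class InvGammaHMM:
    """K-state HMM with inverse-gamma emissions over diffusion estimates.

    Emission k has density x^-(alpha_k + 1) exp(-beta_k / x) up to
    normalization; its mean is beta / (alpha - 1) for alpha > 1 and its SD is
    defined for alpha > 2.
    """

    transmat: np.ndarray
    startprob: np.ndarray
    shapes: np.ndarray  # alpha_k
    scales: np.ndarray  # beta_k

    def __post_init__(self) -> None:
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.shapes <= 0) or np.any(self.scales <= 0):
            raise ValueError("inverse-gamma parameters must be positive")

    @property
    def n_states(self) -> int:
        return len(self.shapes)

    def emission_means(self) -> np.ndarray:
        """beta / (alpha - 1); inf where alpha <= 1."""
        with np.errstate(divide="ignore"):
            return np.where(self.shapes > 1, self.scales / (self.shapes - 1), np.inf)

    def emission_sds(self) -> np.ndarray:
        """Defined for alpha > 2; inf otherwise."""
        out = np.full(self.n_states, np.inf)
        ok = self.shapes > 2
        a, b = self.shapes[ok], self.scales[ok]
        out[ok] = b / ((a - 1) * np.sqrt(a - 2))
        return out

    def log_emission(self, x: np.ndarray) -> np.ndarray:
        """(T, K) log emission densities."""
        x = np.asarray(x, dtype=float)[:, None]
        a, b = self.shapes[None, :], self.scales[None, :]
        return a * np.log(b) - gammaln(a) - (a + 1) * np.log(x) - b / x

    def sample(self, lengths, rng: np.random.Generator) -> tuple[list, list]:
        """Draw (observations, states) for sequences of the given lengths."""
        obs, sts = [], []
        for n in np.atleast_1d(lengths):
            s = np.empty(int(n), dtype=int)
            x = np.empty(int(n))
            s[0] = rng.choice(self.n_states, p=self.startprob)
            for t in range(1, int(n)):
                s[t] = rng.choice(self.n_states, p=self.transmat[s[t - 1]])
            # inverse-gamma draw: 1 / Gamma(alpha, 1/beta)
            x = self.scales[s] / rng.gamma(self.shapes[s], 1.0, size=int(n))
            obs.append(x)
            sts.append(s)
        return obs, sts


@dataclass
class FitResult:
    """Fitted model plus decoded paths and summary statistics."""

    model: InvGammaHMM
    log_likelihood: float
    ll_history: np.ndarray
    paths: list[np.ndarray]
    converged: bool
    n_floored: int = 0
    bootstrap: dict | None = None
    observations: list[np.ndarray] | None = None

    def occupancy_percent(self) -> np.ndarray:
        return occupancy(self)

    def summary(self) -> str:
        means = self.model.emission_means()
        sds = self.model.emission_sds()
        occ = self.occupancy_percent()
        se = self.bootstrap or {}
        lines = ["state  mean_D[um2/s]     sd_D[um2/s]      occupancy[%]"]
        for k in range(self.model.n_states):
            m = f"{means[k]:.3f}"
            if "mean" in se:
                m += f" ± {se['mean'][k]:.3f}"
            s = f"{sds[k]:.3f}"
            if "sd" in se:
                s += f" ± {se['sd'][k]:.3f}"
            o = f"{occ[k]:.1f}"
            if "occupancy" in se:
                o += f" ± {se['occupancy'][k]:.1f}"
            lines.append(f"{k:<6d} {m:<16s} {s:<16s} {o}")
        return "\n".join(lines)


# --- EM internals ----------------------------------------------------------

def _invgamma_mle(w: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Weighted inverse-gamma MLE: exact M-step of the EM.

    Solves ln(alpha) - digamma(alpha) = <ln x> + ln<1/x> (nonnegative by
    Jensen), then beta = alpha / <1/x>.
    """
    wsum = w.sum()
    minv = float((w / x).sum() / wsum)
    mlog = float((w * np.log(x)).sum() / wsum)
    s = mlog + np.log(minv)
    if s <= 1e-12:  # essentially constant data: very sharp emission
        alpha = 1e6
    else:
        f = lambda a: np.log(a) - digamma(a) - s
        lo, hi = 1e-3, 1e7
        # ln a - psi(a) is decreasing from +inf to 0
        alpha = brentq(f, lo, hi, maxiter=200)
    beta = alpha / minv
    return alpha, beta


def _forward_backward(model: InvGammaHMM, x: np.ndarray):
    """Scaled forward-backward; returns (gamma, xi_sum, loglik)."""
    T = len(x)
    K = model.n_states
    logB = model.log_emission(x)
    shift = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - shift)
    A = model.transmat
    alpha = np.empty((T, K))
    scale = np.empty(T)
    alpha[0] = model.startprob * B[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = alpha[t][:, None] * A * (B[t + 1] * beta[t + 1])[None, :] / scale[t + 1]
        xi_sum += xi
    loglik = float(np.log(scale).sum() + shift.sum())
    return gamma, xi_sum, loglik


def _init_model(obs: list[np.ndarray], K: int, rng: np.random.Generator) -> InvGammaHMM:
    """K-means on log D for emission init, sticky transitions with jitter."""
    from sklearn.cluster import KMeans

    x = np.concatenate(obs)
    km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(np.log(x)[:, None])
    shapes = np.empty(K)
    scales = np.empty(K)
    for k in range(K):
        xk = x[labels == k]
        if len(xk) < 2:
            xk = x
        m, v = xk.mean(), max(xk.var(), 1e-12)
        a = max(m**2 / v + 2.0, 1.2)
        shapes[k] = a * rng.uniform(0.8, 1.25)
        scales[k] = m * (shapes[k] - 1.0)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9)
    A = A * rng.uniform(0.8, 1.25, size=A.shape)
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.dirichlet(np.ones(K) * 5.0)
    return InvGammaHMM(A, pi, shapes, scales)


def _sort_states(model: InvGammaHMM) -> tuple[InvGammaHMM, np.ndarray]:
    order = np.argsort(model.emission_means())
    return (
        InvGammaHMM(
            model.transmat[np.ix_(order, order)],
            model.startprob[order],
            model.shapes[order],
            model.scales[order],
        ),
        order,
    )


def _em_once(
    obs: list[np.ndarray],
    model: InvGammaHMM,
    max_iter: int,
    tol: float,
) -> tuple[InvGammaHMM, np.ndarray, bool]:
    K = model.n_states
    history = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        gammas = []
        xi_tot = np.zeros((K, K))
        start_tot = np.zeros(K)
        ll = 0.0
        for x in obs:
            g, xi, l = _forward_backward(model, x)
            gammas.append(g)
            xi_tot += xi
            start_tot += g[0]
            ll += l
        history.append(ll)
        if ll + tol * abs(ll) < prev:
            logger.warning("EM log-likelihood decreased at iteration %d", it)
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll
        # M-step
        A = xi_tot / np.clip(xi_tot.sum(axis=1, keepdims=True), 1e-300, None)
        A = np.clip(A, 1e-12, None)
        A /= A.sum(axis=1, keepdims=True)
        pi = start_tot / start_tot.sum()
        shapes = model.shapes.copy()
        scales = model.scales.copy()
        allx = np.concatenate(obs)
        allg = np.concatenate(gammas, axis=0)
        for k in range(K):
            wk = allg[:, k]
            if wk.sum() < 1e-8:
                continue
            shapes[k], scales[k] = _invgamma_mle(wk, allx)
        model = InvGammaHMM(A, pi, shapes, scales)
    return model, np.asarray(history), converged


def fit(
    series,
    K: int,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-8,
    d_floor: float = D_FLOOR,
    decode: bool = True,
) -> FitResult:
    """Fit a K-state inverse-gamma HMM to diffusion point-estimate series.

    ``series`` is a list of 1D arrays of diffusion estimates (um^2/s), one
    per trajectory (a DiffusionSeries' ``d_um2s`` attribute is accepted).
    Non-positive values are floored at ``d_floor`` with a logged count.  The
    best of ``n_restarts`` random EM restarts is kept; states are sorted by
    emission mean.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = []
    n_floored = 0
    for s in series:
        x = np.asarray(getattr(s, "d_um2s", s), dtype=float).copy()
        n_floored += int((x < d_floor).sum())
        obs.append(np.clip(x, d_floor, None))
    if n_floored:
        logger.info("floored %d non-positive diffusion estimates at %g", n_floored, d_floor)
    if len(np.unique(np.concatenate(obs))) < K:
        raise ValueError("need at least K distinct diffusion values")
    best = None
    for _ in range(n_restarts):
        m0 = _init_model(obs, K, rng)
        try:
            m, hist, conv = _em_once(obs, m0, max_iter, tol)
        except (ValueError, FloatingPointError):  # degenerate restart
            continue
        if best is None or hist[-1] > best[1][-1]:
            best = (m, hist, conv)
    if best is None:
        raise RuntimeError("all EM restarts failed")
    model, hist, conv = best
    if not conv:
        logger.warning("EM did not converge within %d iterations", max_iter)
    model, _ = _sort_states(model)
    paths = [viterbi(model, x) for x in obs] if decode else []
    return FitResult(model, float(hist[-1]), hist, paths, conv, n_floored, observations=obs)


def viterbi(model: InvGammaHMM, x: np.ndarray) -> np.ndarray:
    """Most probable state path for one observation sequence."""
    x = np.clip(np.asarray(getattr(x, "d_um2s", x), dtype=float), D_FLOOR, None)
    T = len(x)
    K = model.n_states
    logB = model.log_emission(x)
    logA = np.log(np.clip(model.transmat, 1e-300, None))
    delta = np.log(np.clip(model.startprob, 1e-300, None)) + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def path_log_probability(model: InvGammaHMM, x: np.ndarray, path: np.ndarray) -> float:
    """Joint log-probability of (path, observations) under the model."""
    x = np.clip(np.asarray(x, dtype=float), D_FLOOR, None)
    logB = model.log_emission(x)
    lp = np.log(model.startprob[path[0]]) + logB[0, path[0]]
    for t in range(1, len(x)):
        lp += np.log(model.transmat[path[t - 1], path[t]]) + logB[t, path[t]]
    return float(lp)


def occupancy(result: FitResult, posterior: bool = False) -> np.ndarray:
    """Per-state occupancy in percent, from Viterbi state fractions.

    With ``posterior=True`` the soft (posterior-weighted) occupancy is
    returned instead.
    """
    K = result.model.n_states
    if posterior:
        if not result.observations:
            raise ValueError("posterior occupancy needs the stored observations")
        soft = np.zeros(K)
        total = 0
        for x in result.observations:
            g, _, _ = _forward_backward(result.model, x)
            soft += g.sum(axis=0)
            total += len(x)
        return 100.0 * soft / total
    counts = np.zeros(K)
    for p in result.paths:
        counts += np.bincount(p, minlength=K)
    return 100.0 * counts / counts.sum()


def bootstrap_se(
    series,
    K: int,
    B: int = 200,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 5,
    max_iter: int = 300,
) -> dict:
    """Bootstrap standard errors by resampling whole trajectories.

    Refits the HMM on ``B`` resamples (with replacement) of the trajectory
    set; states are matched across replicates by sorted emission means.
    Degenerate refits are excluded with a logged count.  Returns SE arrays
    for emission means, SDs, occupancies and the transition matrix.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    series = list(series)
    means, sds, occs, trans = [], [], [], []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(len(series), size=len(series))
        sample = [series[i] for i in idx]
        try:
            res = fit(sample, K, seed=rng, n_restarts=n_restarts, max_iter=max_iter)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        m = res.model.emission_means()
        if not np.all(np.isfinite(m)):
            n_failed += 1
            continue
        means.append(m)
        sds.append(res.model.emission_sds())
        occs.append(res.occupancy_percent())
        trans.append(res.model.transmat)
    if n_failed:
        logger.info("excluded %d degenerate bootstrap refits", n_failed)
    if len(means) < 2:
        raise RuntimeError("too few successful bootstrap replicates")
    return {
        "mean": np.std(means, axis=0, ddof=1),
        "sd": np.std(sds, axis=0, ddof=1),
        "occupancy": np.std(occs, axis=0, ddof=1),
        "transmat": np.std(trans, axis=0, ddof=1),
        "n_replicates": len(means),
        "n_excluded": n_failed,
    }
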