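"""Gaussian-emission hidden Markov model for behavioural segmentation.

Speed matrices (frames x key-points, z-scored) are partitioned into k
behavioural states by a first-order HMM whose observation model is a
multivariate Gaussian (optionally a Gaussian mixture) per state.  Fitting
is expectation-maximisation from k-means-seeded restarts; decoding returns
both the exact posterior state marginals (forward-backward, scaled) and the
maximum a-posteriori Viterbi path.

The alpha/beta and Viterbi recursions are JIT-compiled (numba) and the
emission densities and M-step are arranged as a few large matrix products,
so fitting k = 15-25 states to hour-long 25-key-point sessions stays in
the tens of seconds on one core.

State labels are 0-based integers 0..k-1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.cluster import KMeans

from .telemetry import SpeedMatrix

__all__ = [
    "HmmParams",
    "StateDecoding",
    "fit_hmm",
    "forward_backward",
    "viterbi_path",
    "binarize_state",
]

_SIMPLEX_TOL = 1e-9


@dataclass
class HmmParams:
    """Parameters of a k-state Gaussian(-mixture) HMM.

    ``means``/``covariances``/``mix_weights`` carry an explicit mixture axis
    even for the default single-component observation model (n_mix = 1).
    """

    init_probs: np.ndarray        # (k,)
    trans: np.ndarray             # (k, k) row-stochastic
    means: np.ndarray             # (k, n_mix, d)
    covariances: np.ndarray       # (k, n_mix, d, d)
    mix_weights: np.ndarray | None = None   # (k, n_mix); uniform if None

    def __post_init__(self) -> None:
        self.init_probs = np.asarray(self.init_probs, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if self.means.ndim == 2:          # accept (k, d) for n_mix == 1
            self.means = self.means[:, None, :]
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 3:
            self.covariances = self.covariances[:, None, :, :]
        if self.mix_weights is None:
            k, m, _ = self.means.shape
            self.mix_weights = np.full((k, m), 1.0 / m)
        else:
            self.mix_weights = np.asarray(self.mix_weights, dtype=float)

    @property
    def k(self) -> int:
        return self.trans.shape[0]

    @property
    def n_mix(self) -> int:
        return self.means.shape[1]

    @property
    def n_features(self) -> int:
        return self.means.shape[2]

    def validate(self) -> None:
        k = self.k
        if self.trans.shape != (k, k) or self.init_probs.shape != (k,):
            raise ValueError("inconsistent state dimensions")
        if abs(self.init_probs.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("init_probs must sum to 1")
        if np.abs(self.trans.sum(axis=1) - 1.0).max() > _SIMPLEX_TOL:
            raise ValueError("transition rows must sum to 1")
        if np.abs(self.mix_weights.sum(axis=1) - 1.0).max() > _SIMPLEX_TOL:
            raise ValueError("mixture weights must sum to 1 per state")
        for z in range(k):
            for m in range(self.n_mix):
                c = self.covariances[z, m]
                if not np.allclose(c, c.T, atol=1e-10):
                    raise ValueError("covariances must be symmetric")
                if np.linalg.eigvalsh(c).min() <= 0:
                    raise ValueError("covariances must be positive-definite")


@dataclass
class StateDecoding:
    """Fitted model plus per-frame posteriors and Viterbi path."""

    posteriors: np.ndarray        # (frames, k), rows sum to 1
    viterbi: np.ndarray           # (frames,) ints in 0..k-1
    log_likelihood: float
    params: HmmParams
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return self.params.k

    @property
    def n_frames(self) -> int:
        return self.posteriors.shape[0]


# ---------------------------------------------------------------------------
# emission densities


def _component_tables(params: HmmParams):
    """Precision matrices and log-normalisers for all state components."""
    k, m, d = params.means.shape
    precs = np.empty((k, m, d, d))
    lognorm = np.empty((k, m))
    for z in range(k):
        for c in range(m):
            L = np.linalg.cholesky(params.covariances[z, c])
            Linv = np.linalg.solve(L, np.eye(d))
            precs[z, c] = Linv.T @ Linv
            logdet = 2.0 * np.log(np.diag(L)).sum()
            lognorm[z, c] = (-0.5 * (logdet + d * np.log(2.0 * np.pi))
                             + np.log(params.mix_weights[z, c]))
    return precs, lognorm


def _log_emissions(params: HmmParams, X: np.ndarray):
    """(T, k) log observation likelihoods; and (T, k, m) per component.

    The Mahalanobis quadratic forms are computed as one GEMM per component
    (x'Px - 2 b'x + mu'b with b = P mu), which is the dominant cost.
    """
    T, d = X.shape
    k, m = params.k, params.n_mix
    precs, lognorm = _component_tables(params)
    logP = np.empty((T, k, m))
    for z in range(k):
        for c in range(m):
            P = precs[z, c]
            mu = params.means[z, c]
            b = P @ mu
            quad = np.einsum("ti,ti->t", X @ P, X)
            logP[:, z, c] = (-0.5 * (quad + mu @ b) + X @ b + lognorm[z, c])
    if m == 1:
        return logP[:, :, 0], logP
    mx = logP.max(axis=2)
    logB = mx + np.log(np.exp(logP - mx[:, :, None]).sum(axis=2))
    return logB, logP


def _as_array(speeds) -> np.ndarray:
    if isinstance(speeds, SpeedMatrix):
        return speeds.values
    return np.asarray(speeds, dtype=float)


# ---------------------------------------------------------------------------
# inference kernels


@njit(cache=True)
def _fb_kernel(pi, A, B):
    """Scaled forward-backward.  Returns (gamma, xi_sum, scale_factors)."""
    T, k = B.shape
    alpha = np.empty((T, k))
    c = np.empty(T)
    s = 0.0
    for j in range(k):
        alpha[0, j] = pi[j] * B[0, j]
        s += alpha[0, j]
    c[0] = s
    if s > 0.0:
        for j in range(k):
            alpha[0, j] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(k):
            acc = 0.0
            for i in range(k):
                acc += alpha[t - 1, i] * A[i, j]
            v = acc * B[t, j]
            alpha[t, j] = v
            s += v
        c[t] = s
        if s <= 0.0:
            return alpha, np.zeros((k, k)), c
        for j in range(k):
            alpha[t, j] /= s

    gamma = np.empty((T, k))
    xi = np.zeros((k, k))
    beta = np.ones(k)
    newbeta = np.empty(k)
    bb = np.empty(k)
    for j in range(k):
        gamma[T - 1, j] = alpha[T - 1, j]
    for t in range(T - 2, -1, -1):
        ct1 = c[t + 1]
        for j in range(k):
            bb[j] = B[t + 1, j] * beta[j]
        for i in range(k):
            acc = 0.0
            for j in range(k):
                z = A[i, j] * bb[j]
                acc += z
                xi[i, j] += alpha[t, i] * z / ct1
            newbeta[i] = acc / ct1
        gsum = 0.0
        for i in range(k):
            beta[i] = newbeta[i]
            g = alpha[t, i] * beta[i]
            gamma[t, i] = g
            gsum += g
        for i in range(k):
            gamma[t, i] /= gsum
    return gamma, xi, c


@njit(cache=True)
def _viterbi_kernel(logpi, logA, logB):
    T, k = logB.shape
    delta = np.empty(k)
    newdelta = np.empty(k)
    psi = np.empty((T, k), dtype=np.int64)
    for j in range(k):
        delta[j] = logpi[j] + logB[0, j]
    for t in range(1, T):
        for j in range(k):
            best = -np.inf
            arg = 0
            for i in range(k):
                v = delta[i] + logA[i, j]
                if v > best:          # strict: ties keep the lower index
                    best = v
                    arg = i
            newdelta[j] = best + logB[t, j]
            psi[t, j] = arg
        for j in range(k):
            delta[j] = newdelta[j]
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for j in range(k):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _forward_backward_core(params: HmmParams, logB: np.ndarray):
    """Scaled alpha/beta recursions.

    Returns (gamma, xi_sum, loglik): posterior marginals, summed two-slice
    posteriors and the data log-likelihood.
    """
    off = logB.max(axis=1)
    B = np.exp(logB - off[:, None])
    gamma, xi_sum, c = _fb_kernel(params.init_probs, params.trans, B)
    if (c <= 0).any():
        t = int(np.flatnonzero(c <= 0)[0])
        raise FloatingPointError(f"zero likelihood at frame {t}")
    loglik = float(np.log(c).sum() + off.sum())
    return gamma, xi_sum, loglik


def forward_backward(params: HmmParams, speeds) -> np.ndarray:
    """Exact posterior state marginals P(state_t | all observations).

    Computed with per-frame scaling (numerically equivalent to log-space);
    every returned row sums to 1.
    """
    params.validate()
    X = _as_array(speeds)
    if X.shape[1] != params.n_features:
        raise ValueError(
            f"observation dimension {X.shape[1]} != model {params.n_features}")
    logB, _ = _log_emissions(params, X)
    gamma, _, _ = _forward_backward_core(params, logB)
    return gamma


def viterbi_path(params: HmmParams, speeds) -> np.ndarray:
    """Maximum a-posteriori state sequence (ties broken to the lower index)."""
    params.validate()
    X = _as_array(speeds)
    if X.shape[1] != params.n_features:
        raise ValueError(
            f"observation dimension {X.shape[1]} != model {params.n_features}")
    logB, _ = _log_emissions(params, X)
    with np.errstate(divide="ignore"):
        logA = np.log(params.trans)
        logpi = np.log(params.init_probs)
    return np.asarray(_viterbi_kernel(logpi, logA, logB), dtype=int)


def binarize_state(decoding: StateDecoding, state: int) -> np.ndarray:
    """Binary indicator of the Viterbi path occupying ``state`` (0-based)."""
    if not 0 <= state < decoding.k:
        raise ValueError(f"state {state} out of range 0..{decoding.k - 1}")
    return (decoding.viterbi == state).astype(int)


# ---------------------------------------------------------------------------
# fitting


def _kmeans_init(X: np.ndarray, k: int, n_mix: int, seed: int,
                 cov_floor: float) -> HmmParams:
    d = X.shape[1]
    km = KMeans(n_clusters=k, n_init=3, random_state=seed % (2**32)).fit(X)
    labels = km.labels_
    means = np.empty((k, n_mix, d))
    covs = np.empty((k, n_mix, d, d))
    rng = np.random.default_rng(seed)
    for z in range(k):
        Xz = X[labels == z]
        if len(Xz) < 2:
            Xz = X[rng.integers(0, len(X), size=max(2, d))]
        base_cov = np.cov(Xz.T) + cov_floor * np.eye(d)
        if n_mix == 1:
            means[z, 0] = Xz.mean(axis=0)
            covs[z, 0] = base_cov
        else:
            sub = KMeans(n_clusters=min(n_mix, len(Xz)), n_init=1,
                         random_state=(seed + 1) % (2**32)).fit(Xz)
            for m in range(n_mix):
                Xm = Xz[sub.labels_ == (m % sub.n_clusters)]
                means[z, m] = Xm.mean(axis=0) if len(Xm) else Xz.mean(axis=0)
                covs[z, m] = base_cov
    trans = np.full((k, k), 0.1 / max(k - 1, 1))
    np.fill_diagonal(trans, 0.9 if k > 1 else 1.0)
    init = np.full(k, 1.0 / k)
    return HmmParams(init, trans, means, covs)


def _em(X: np.ndarray, params: HmmParams, max_iter: int, tol: float,
        cov_floor: float, seed: int):
    """EM iterations; returns (params, loglik_trace)."""
    T, d = X.shape
    k, n_mix = params.k, params.n_mix
    rng = np.random.default_rng(seed)
    global_cov = np.cov(X.T) + cov_floor * np.eye(d)
    floor_eye = cov_floor * np.eye(d)
    reseeded = set()
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logB, logP = _log_emissions(params, X)
        gamma, xi_sum, loglik = _forward_backward_core(params, logB)
        trace.append(loglik)

        # component responsibilities
        if n_mix == 1:
            r = gamma[:, :, None]
        else:
            r = gamma[:, :, None] * np.exp(logP - logB[:, :, None])

        Nkm = r.sum(axis=0)                  # (k, n_mix)
        Nk = Nkm.sum(axis=1)

        collapsed = np.flatnonzero(Nk < 1.0)
        if collapsed.size:
            for z in collapsed:
                if z in reseeded:
                    raise RuntimeError(
                        f"state {z} collapsed twice during EM; "
                        "reduce k or supply more data")
                reseeded.add(int(z))
                idx = rng.integers(0, T)
                params.means[z] = X[idx][None, :]
                params.covariances[z] = global_cov[None, :, :]
                params.mix_weights[z] = 1.0 / n_mix
            continue

        init_probs = gamma[0] / gamma[0].sum()
        trans = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        means = np.empty_like(params.means)
        covs = np.empty_like(params.covariances)
        for z in range(k):
            for m in range(n_mix):
                rz = r[:, z, m]
                mu = rz @ X / Nkm[z, m]
                # uncentred second moment, then subtract the mean outer product
                S = X.T @ (rz[:, None] * X) / Nkm[z, m]
                cov = S - np.outer(mu, mu)
                means[z, m] = mu
                covs[z, m] = 0.5 * (cov + cov.T) + floor_eye
        mix_w = Nkm / Nk[:, None]
        params = HmmParams(init_probs, trans, means, covs, mix_w)

        if np.isfinite(prev) and (loglik - prev) < tol * abs(prev):
            break
        prev = loglik
    return params, np.asarray(trace)


def fit_hmm(speeds, k: int, seed: int = 0, n_restarts: int = 3,
            max_iter: int = 500, tol: float = 1e-6, n_mix: int = 1,
            cov_floor: float = 1e-6, select_iter: int = 15) -> StateDecoding:
    """Fit a k-state Gaussian(-mixture) HMM by EM and decode.

    ``n_restarts`` k-means-seeded initialisations (derived from ``seed``)
    are each run for ``select_iter`` EM iterations; the restart with the
    best log-likelihood is then run to convergence.  The log-likelihood is
    non-decreasing across EM iterations (up to numerical tolerance) by the
    standard EM guarantee.

    Parameters
    ----------
    speeds
        SpeedMatrix or (frames, features) array, typically z-scored speeds.
    k
        Number of hidden states (15 for the block design, 25 for the
        multi-subject dance data by default usage).
    tol
        Relative log-likelihood change for convergence.
    cov_floor
        Ridge added to every covariance to keep it positive-definite.
    """
    X = _as_array(speeds)
    T = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if T <= 10 * k:
        raise ValueError(f"need more than {10 * k} frames to fit k={k}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    if k == 1:
        # degenerate: a single Gaussian; no sequence structure to learn
        mu = X.mean(axis=0)
        cov = np.cov(X.T).reshape(X.shape[1], X.shape[1]) \
            + cov_floor * np.eye(X.shape[1])
        params = HmmParams(np.ones(1), np.ones((1, 1)), mu[None], cov[None])
        logB, _ = _log_emissions(params, X)
        ll = float(logB.sum())
        return StateDecoding(np.ones((T, 1)), np.zeros(T, dtype=int), ll,
                             params, np.asarray([ll]))

    # stage 1: short runs from each initialisation
    candidates = []
    for r in range(n_restarts):
        rseed = int(seed) + 7919 * r
        params0 = _kmeans_init(X, k, n_mix, rseed, cov_floor)
        try:
            p, tr = _em(X, params0, min(select_iter, max_iter), 10 * tol,
                        cov_floor, rseed)
        except (FloatingPointError, RuntimeError):
            continue
        candidates.append((tr[-1], r, p, tr))
    if not candidates:
        raise RuntimeError("all EM restarts failed")

    # stage 2: run the winner to convergence (fall back to the next-best
    # candidate if its EM degenerates late)
    trace = None
    for _, r_best, params, trace0 in sorted(candidates, reverse=True,
                                            key=lambda c: c[0]):
        try:
            params, trace1 = _em(X, params, max_iter - len(trace0), tol,
                                 cov_floor, int(seed) + 7919 * r_best + 1)
        except (FloatingPointError, RuntimeError):
            continue
        trace = np.concatenate([trace0, trace1])
        break
    if trace is None:
        raise RuntimeError("all EM restarts failed")
    params.validate()
    logB, _ = _log_emissions(params, X)
    gamma, _, loglik = _forward_backward_core(params, logB)
    path = viterbi_path(params, X)
    return StateDecoding(gamma, path, loglik, params, trace)
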