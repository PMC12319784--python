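"""Two-level GLM on oscillatory amplitude envelopes.

First level: for every beamformed source, the band-limited time course is
converted to a log amplitude envelope (Hilbert transform) and regressed on
behavioural regressors — cue boxcars or HMM state paths for the block
design; the five limb meta-states plus mean and linear trend for the dance.
Second level: per-source paired t (active vs rest images across trials) or
a 1 x n-state factorial with arbitrary contrasts across dances, with
family-wise error control by max-statistic sign-flip / label permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.fft import next_fast_len

from .source import SourceGrid

__all__ = [
    "DesignMatrix",
    "GlmResult",
    "StatImage",
    "envelope_log",
    "build_design_motor",
    "build_design_dance",
    "fit_glm",
    "second_level_paired_t",
    "second_level_factorial",
    "fwe_correct",
    "display_threshold",
]

LOG_FLOOR = 1e-30


@dataclass
class DesignMatrix:
    """First-level design: samples x regressors, with exactly one mean column."""

    X: np.ndarray
    regressor_names: list[str]
    design_kind: str = "custom"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.regressor_names):
            raise ValueError("X must be (samples, regressors) with one name "
                             "per column")
        if self.regressor_names.count("mean") != 1:
            raise ValueError("design must contain exactly one 'mean' column")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.condition_number = float(np.linalg.cond(self.X))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


@dataclass
class GlmResult:
    betas: np.ndarray              # (n_src, n_regressors)
    residual_variance: np.ndarray  # (n_src,)
    dof: int
    design: DesignMatrix

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.design.regressor_names.index(name)]


@dataclass
class StatImage:
    """Per-source scalar statistic map with optional threshold metadata."""

    values: np.ndarray
    grid: SourceGrid | None = None
    stat: str = "t"
    dof: int | None = None
    info: dict = field(default_factory=dict)

    def peak(self) -> int:
        return int(np.nanargmax(np.abs(self.values)))


# ---------------------------------------------------------------------------
# envelopes


def envelope_log(source_ts: np.ndarray, floor: float = LOG_FLOOR) -> np.ndarray:
    """Natural log of the Hilbert amplitude envelope, floored at ``floor``.

    Operates on the last axis; accepts (T,) or (n_src, T).  The analytic
    signal is computed with an FFT padded to a fast length to keep the
    transform cheap for long recordings.
    """
    x = np.asarray(source_ts, dtype=float)
    if x.size == 0:
        raise ValueError("empty time series")
    n = x.shape[-1]
    env = np.abs(hilbert(x, N=next_fast_len(n), axis=-1))[..., :n]
    if (env <= floor).all():
        warnings.warn("all-zero input: envelope floored everywhere")
    return np.log(np.maximum(env, floor))


# ---------------------------------------------------------------------------
# designs


def build_design_motor(n_samples: int, sample_rate: float,
                       onsets_s: np.ndarray,
                       active: np.ndarray | None = None,
                       active_window=(0.0, 4.0),
                       rest_window=(6.0, 10.0)) -> DesignMatrix:
    """Motor-design matrix: active, rest and mean columns.

    The active column is either the cue boxcar (``active_window`` after
    each trial onset; default 0-4 s) or, when ``active`` is given, an
    HMM-derived binary state path at the MEG rate.  The rest column is a
    boxcar over ``rest_window`` (default 6-10 s) after each onset.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    if (onsets < 0).any() or (onsets * sample_rate >= n_samples).any():
        raise ValueError("trial onsets must fall inside the recording")

    def boxcar(window):
        col = np.zeros(n_samples)
        for t0 in onsets:
            a = int(round((t0 + window[0]) * sample_rate))
            b = int(round((t0 + window[1]) * sample_rate))
            col[a:min(b, n_samples)] = 1.0
        return col

    kind = "motor_block" if active is None else "motor_hmm"
    if active is None:
        active_col = boxcar(active_window)
    else:
        active_col = np.asarray(active, dtype=float)
        if len(active_col) != n_samples:
            raise ValueError("active path length must equal n_samples")
    rest_col = boxcar(rest_window)
    if (active_col * rest_col).any():
        raise ValueError("active and rest supports overlap")
    X = np.column_stack([active_col, rest_col, np.ones(n_samples)])
    return DesignMatrix(X, ["active", "rest", "mean"], kind)


def build_design_dance(meta_paths: dict[str, np.ndarray]) -> DesignMatrix:
    """Dance design: one column per limb meta-state plus mean and linear trend.

    Meta-states are assumed (and checked, to 1% of samples) to be mutually
    disjoint in time, as mutually exclusive Viterbi-derived movement states
    are.  The trend column spans [-0.5, 0.5] and is orthogonal to the mean.
    """
    names = list(meta_paths)
    cols = []
    for name in names:
        col = np.asarray(meta_paths[name], dtype=float)
        if not col.any():
            raise ValueError(f"meta-state {name!r} is never active")
        cols.append(col)
    P = np.column_stack(cols)
    n = P.shape[0]
    overlap = (P.sum(axis=1) > 1).mean()
    if overlap > 0.01:
        warnings.warn(f"meta-states overlap on {overlap:.1%} of samples")
    trend = np.linspace(-0.5, 0.5, n)
    X = np.column_stack([P, np.ones(n), trend])
    return DesignMatrix(X, names + ["mean", "trend"], "dance")


# ---------------------------------------------------------------------------
# first level


def fit_glm(y: np.ndarray, design: DesignMatrix) -> GlmResult:
    """Mass-univariate OLS of each source's series on the design.

    ``y`` is (T,) or (n_src, T).  The design is required to be full column
    rank (checked at construction); residual variance uses the dof
    correction n - rank(X).
    """
    X = design.X
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    if Y.shape[1] != X.shape[0]:
        raise ValueError("y samples must match design rows")
    p = X.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    resid = Y.T - X @ beta
    dof = X.shape[0] - p
    rss = np.einsum("ij,ij->j", resid, resid)
    return GlmResult(beta.T, rss / dof, dof, design)


# ---------------------------------------------------------------------------
# second level


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    m = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(m))
        t = np.where(sd == 0,
                     np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def second_level_paired_t(active_images: np.ndarray, rest_images: np.ndarray,
                          grid: SourceGrid | None = None) -> StatImage:
    """Paired t (active vs rest first-level images) per source.

    Identical to the one-sample t on per-trial differences; dof = pairs - 1.
    """
    A = np.asarray(active_images, dtype=float)
    R = np.asarray(rest_images, dtype=float)
    if A.shape != R.shape:
        raise ValueError("active and rest image stacks must match")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 trial pairs")
    t = _paired_t(A - R)
    return StatImage(t, grid, "t", A.shape[0] - 1,
                     {"contrast": "active - rest", "design": "paired"})


def _factorial_t(images: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """t for c' beta in a one-way cell-means model with units as replicates.

    ``images`` is (units, n_levels, n_src); beta_j is the level mean, the
    residual variance is pooled within levels across units.
    """
    n_units, n_levels, _ = images.shape
    beta = images.mean(axis=0)                       # (levels, n_src)
    resid = images - beta[None]
    dof = n_levels * (n_units - 1)
    sigma2 = np.einsum("uls,uls->s", resid, resid) / dof
    effect = np.tensordot(contrast, beta, axes=(0, 0))
    se = np.sqrt(sigma2 * (contrast @ contrast) / n_units)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
        t = np.where(se == 0,
                     np.where(effect == 0, 0.0, np.sign(effect) * np.inf), t)
    return t


def second_level_factorial(images: np.ndarray, contrast: np.ndarray,
                           grid: SourceGrid | None = None,
                           level_names: list[str] | None = None) -> StatImage:
    """t-contrast across meta-state first-level images (1 x n factorial).

    ``images`` is (units, n_levels, n_src) — e.g. one beta image per dance
    per meta-state — and ``contrast`` weights the n_levels level means.
    """
    images = np.asarray(images, dtype=float)
    contrast = np.asarray(contrast, dtype=float)
    if images.ndim != 3:
        raise ValueError("images must be (units, levels, sources)")
    if contrast.shape != (images.shape[1],):
        raise ValueError("contrast length must equal the number of levels")
    if not contrast.any():
        raise ValueError("contrast must be non-zero")
    t = _factorial_t(images, contrast)
    dof = images.shape[1] * (images.shape[0] - 1)
    return StatImage(t, grid, "t", dof,
                     {"contrast": list(contrast), "design": "factorial",
                      "levels": level_names})


# ---------------------------------------------------------------------------
# inference and display


def fwe_correct(stat: StatImage, images, n_perm: int = 999, seed: int = 0,
                alpha: float = 0.05, rest_images=None,
                contrast=None) -> StatImage:
    """Family-wise-error corrected threshold by max-|t| permutation.

    For a paired design pass ``images`` = active stack and ``rest_images``;
    the null is built by random sign flips of the per-pair differences.
    For a factorial design pass ``images`` = (units, levels, n_src) and the
    ``contrast``; the null permutes level labels within each unit.  The
    corrected p per source is (1 + #{max-null >= |t|}) / (1 + n_perm);
    sources at p >= alpha are zeroed in the returned image.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    obs = np.abs(stat.values)

    if rest_images is not None:
        diffs = np.asarray(images, dtype=float) - np.asarray(rest_images, dtype=float)
        m = diffs.shape[0]
        if m < 8:
            raise ValueError("need >= 8 exchangeable units for a "
                             "meaningful permutation null")
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            signs = rng.choice((-1.0, 1.0), size=m)
            null_max[i] = np.abs(_paired_t(diffs * signs[:, None])).max()
    else:
        imgs = np.asarray(images, dtype=float)
        contrast = np.asarray(contrast, dtype=float)
        n_units, n_levels, _ = imgs.shape
        if n_units < 8:
            raise ValueError("need >= 8 exchangeable units for a "
                             "meaningful permutation null")
        null_max = np.empty(n_perm)
        perm_imgs = np.empty_like(imgs)
        for i in range(n_perm):
            for u in range(n_units):
                perm_imgs[u] = imgs[u, rng.permutation(n_levels)]
            null_max[i] = np.abs(_factorial_t(perm_imgs, contrast)).max()

    p_corr = (1 + (null_max[:, None] >= obs[None, :]).sum(axis=0)) / (1 + n_perm)
    keep = p_corr < alpha if alpha < 1.0 else np.ones_like(p_corr, dtype=bool)
    thresholded = np.where(keep, stat.values, 0.0)
    info = dict(stat.info, fwe_method="max-statistic permutation",
                n_perm=n_perm, alpha=alpha,
                fwe_threshold=float(np.quantile(null_max,
                                                max(0.0, 1.0 - alpha))))
    out = StatImage(thresholded, stat.grid, stat.stat, stat.dof, info)
    out.p_corrected = p_corr
    return out


def display_threshold(stat: StatImage, fraction: float = 0.7) -> StatImage:
    """Zero sub-threshold values for display: keep |t| >= fraction * max|t|.

    Display-only convention; inference is untouched.
    """
    if stat.values.size == 0:
        raise ValueError("empty image")
    cut = fraction * np.abs(stat.values).max()
    vals = np.where(np.abs(stat.values) >= cut, stat.values, 0.0)
    return StatImage(vals, stat.grid, stat.stat, stat.dof,
                     dict(stat.info, display_threshold=fraction))
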