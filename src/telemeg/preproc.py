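"""Conditioning of multichannel wearable-MEG recordings.

Operations, in the order a recording normally traverses them: anti-alias
FIR low-pass and integer downsampling; synchronisation of video-derived
behavioural state paths as trigger channels; homogeneous field correction
(HFC) — projection of uniform-field and linear-gradient interference
patterns out of the sensor data; an automatic bad-channel rule based on
post-HFC residual amplitude; and a sensorimotor (8-30 Hz) band-pass.

All field computations run over *enabled* channels only, and trigger
channels are never filtered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "SensorArray",
    "MEGRecording",
    "ProjectionOperator",
    "antialias_downsample",
    "sync_states",
    "hfc_basis",
    "apply_hfc",
    "bad_channel_rule",
    "compensate_leadfield",
    "bandpass",
]

N_HFC_COMPONENTS = 8     # 3 uniform fields + 5 linear gradients


@dataclass
class SensorArray:
    """Sensor geometry: positions (m), unit sensitive-axis orientations."""

    positions: np.ndarray          # (channels, 3) metres
    orientations: np.ndarray       # (channels, 3) unit vectors
    channel_names: list[str] = field(default_factory=list)
    channel_enabled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.channel_enabled is None:
            self.channel_enabled = np.ones(len(self.positions), dtype=bool)
        else:
            self.channel_enabled = np.asarray(self.channel_enabled, dtype=bool)
        if not self.channel_names:
            self.channel_names = [f"ch{i:03d}" for i in range(len(self.positions))]
        if not np.isfinite(self.positions).all():
            raise ValueError("sensor positions must be finite")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise ValueError("orientations must be unit vectors")

    @property
    def n_channels(self) -> int:
        return len(self.positions)

    @property
    def n_enabled(self) -> int:
        return int(self.channel_enabled.sum())


@dataclass
class MEGRecording:
    """Channels x samples field data (tesla) plus geometry and triggers."""

    data: np.ndarray               # (channels, samples) tesla
    sample_rate: float
    array: SensorArray
    trigger_channels: dict[str, np.ndarray] = field(default_factory=dict)
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.data.shape[0] != self.array.n_channels:
            raise ValueError("data rows must match sensor count")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class ProjectionOperator:
    """Interference-subspace projector over the enabled channels.

    ``basis`` holds the raw (un-orthonormalised) interference field
    patterns; ``projector`` is the symmetric idempotent matrix I - QQ^T
    with Q an orthonormal basis of span(basis).
    """

    basis: np.ndarray              # (n_enabled, 8)
    projector: np.ndarray          # (n_enabled, n_enabled)
    enabled: np.ndarray            # (channels,) bool mask the operator refers to
    removed_rank: int = N_HFC_COMPONENTS


# ---------------------------------------------------------------------------
# filtering / resampling


def antialias_downsample(rec: MEGRecording, cutoff: float = 500.0,
                         order: int = 60, target_rate: float = 2000.0,
                         attenuation_db: float = 60.0) -> MEGRecording:
    """Anti-alias FIR low-pass (Kaiser window) then integer decimation.

    The FIR is applied forward-backward (zero phase).  Trigger channels are
    subsampled without filtering so their binary content is preserved.
    """
    q = rec.sample_rate / target_rate
    if abs(q - round(q)) > 1e-9:
        raise ValueError("target_rate must divide sample_rate")
    q = int(round(q))
    if cutoff >= target_rate / 2:
        raise ValueError("cutoff must be below the target Nyquist rate")
    beta = signal.kaiser_beta(attenuation_db)
    taps = signal.firwin(order + 1, cutoff, window=("kaiser", beta),
                         fs=rec.sample_rate)
    data = signal.filtfilt(taps, [1.0], rec.data, axis=1)[:, ::q]
    triggers = {k: v[::q].copy() for k, v in rec.trigger_channels.items()}
    log = rec.processing_log + [
        f"antialias_downsample(cutoff={cutoff}, order={order}, "
        f"target_rate={target_rate})"]
    return replace(rec, data=data, sample_rate=float(target_rate),
                   trigger_channels=triggers, processing_log=log)


def bandpass(rec: MEGRecording, low: float = 8.0, high: float = 30.0,
             order: int = 4) -> MEGRecording:
    """Zero-phase Butterworth band-pass of the field channels."""
    nyq = rec.sample_rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) at fs={rec.sample_rate}")
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=rec.sample_rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    log = rec.processing_log + [f"bandpass({low}, {high})"]
    return replace(rec, data=data, processing_log=log)


def sync_states(rec: MEGRecording, paths: dict[str, np.ndarray],
                video_rate: float) -> MEGRecording:
    """Attach video-rate binary state paths as MEG-rate trigger channels.

    Video and MEG are assumed to share t = 0 (hardware trigger); each path
    is mapped onto MEG sample times by nearest-neighbour lookup.
    """
    triggers = dict(rec.trigger_channels)
    t_meg = np.arange(rec.n_samples) / rec.sample_rate
    for name, path in paths.items():
        path = np.asarray(path)
        if path.size == 0:
            raise ValueError(f"state path {name!r} is empty")
        mismatch = abs(len(path) / video_rate - rec.duration)
        if mismatch > 5.0:
            raise ValueError(
                f"video/MEG duration mismatch {mismatch:.1f} s for {name!r}")
        if mismatch > 1.0:
            warnings.warn(
                f"video/MEG duration mismatch {mismatch:.1f} s for {name!r}")
        idx = np.clip(np.round(t_meg * video_rate).astype(int), 0, len(path) - 1)
        triggers[name] = path[idx]
    log = rec.processing_log + [f"sync_states({sorted(paths)}, {video_rate})"]
    return replace(rec, trigger_channels=triggers, processing_log=log)


# ---------------------------------------------------------------------------
# homogeneous field correction

# the 5 independent symmetric traceless gradient tensors: B(r) = G r
_GRAD_TENSORS = np.array([
    [[1, 0, 0], [0, -1, 0], [0, 0, 0]],
    [[0, 0, 0], [0, 1, 0], [0, 0, -1]],
    [[0, 1, 0], [1, 0, 0], [0, 0, 0]],
    [[0, 0, 1], [0, 0, 0], [1, 0, 0]],
    [[0, 0, 0], [0, 0, 1], [0, 1, 0]],
], dtype=float)


def interference_basis_fields(positions: np.ndarray,
                              orientations: np.ndarray) -> np.ndarray:
    """Channel-space patterns of 3 uniform fields and 5 linear gradients.

    Positions are referenced to their centroid so the gradient patterns are
    insensitive to the array's absolute placement.
    """
    r = positions - positions.mean(axis=0)
    uniform = orientations.copy()                       # o . e_x etc.
    grads = np.stack([np.einsum("ij,nj,ni->n", G, r, orientations)
                      for G in _GRAD_TENSORS], axis=1)
    return np.hstack([uniform, grads])


def hfc_basis(array: SensorArray) -> ProjectionOperator:
    """Homogeneous-field-correction projector for the enabled channels.

    The interference model is the lowest-order regular expansion of an
    external magnetic field over the sensor array: 3 uniform components and
    5 linear-gradient components (symmetric traceless tensor).  The
    projector removes exactly that 8-dimensional subspace.
    """
    mask = array.channel_enabled
    if mask.sum() < N_HFC_COMPONENTS + 1:
        raise ValueError(
            f"need at least {N_HFC_COMPONENTS + 1} enabled channels for HFC")
    basis = interference_basis_fields(array.positions[mask],
                                      array.orientations[mask])
    q, r = np.linalg.qr(basis)
    diag = np.abs(np.diag(r))
    if (diag < 1e-10 * diag.max()).any():
        raise ValueError(
            "interference basis is rank deficient for this sensor geometry "
            "(collinear or planar array?)")
    n = int(mask.sum())
    projector = np.eye(n) - q @ q.T
    return ProjectionOperator(basis, projector, mask.copy())


def apply_hfc(rec: MEGRecording) -> tuple[MEGRecording, ProjectionOperator]:
    """Project uniform-field and gradient interference out of the data."""
    op = hfc_basis(rec.array)
    data = rec.data.copy()
    m = op.enabled
    data[m] = op.projector @ data[m]
    log = rec.processing_log + [f"apply_hfc(n_enabled={int(m.sum())})"]
    return replace(rec, data=data, processing_log=log), op


def bad_channel_rule(rec: MEGRecording, threshold: float = 100e-12,
                     max_rounds: int = 5) -> tuple[MEGRecording, ProjectionOperator]:
    """Disable channels with excessive post-HFC residual amplitude.

    Channels whose residual RMS amplitude (about the mean) after HFC
    exceeds ``threshold`` (default 100 pT) are disabled; the projection is
    undone, the basis recomputed over the remaining channels, and HFC
    reapplied — iterated to a fixed point (at most ``max_rounds`` rounds).

    ``rec`` must be the *unprojected* recording; the function manages the
    apply/undo cycle internally and returns the projected recording with
    the final operator.
    """
    array = replace(rec.array, channel_enabled=rec.array.channel_enabled.copy())
    work = replace(rec, array=array)
    for _ in range(max_rounds):
        projected, op = apply_hfc(work)
        m = op.enabled
        resid = projected.data[m]
        rms = np.sqrt(np.mean((resid - resid.mean(axis=1, keepdims=True)) ** 2,
                              axis=1))
        bad = rms > threshold
        if not bad.any():
            log = projected.processing_log + [
                f"bad_channel_rule(threshold={threshold}, "
                f"n_disabled={int((~array.channel_enabled).sum())})"]
            return replace(projected, processing_log=log), op
        idx = np.flatnonzero(m)[bad]
        array.channel_enabled[idx] = False
        if array.channel_enabled.sum() < N_HFC_COMPONENTS + 1:
            raise RuntimeError("too few channels remain after bad-channel "
                               "rejection for HFC")
    warnings.warn("bad-channel loop did not reach a fixed point; "
                  "returning last iteration")
    return replace(projected, processing_log=projected.processing_log
                   + ["bad_channel_rule(non-converged)"]), op


def compensate_leadfield(L: np.ndarray, op: ProjectionOperator) -> np.ndarray:
    """Apply the HFC projector to lead-field columns.

    After HFC the data live in the projected subspace; forward models must
    be mapped into the same subspace before inversion.  ``L`` has the
    enabled-channel dimension first; trailing axes (sources, orientations)
    are preserved.
    """
    L = np.asarray(L, dtype=float)
    n = op.projector.shape[0]
    if L.shape[0] != n:
        raise ValueError(
            f"lead field has {L.shape[0]} channels, projector expects {n}")
    return np.einsum("ij,j...->i...", op.projector, L)
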