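"""Synthetic pose telemetry and wearable-MEG with planted ground truth.

Every pipeline stage gets a recovery test without any external data:

* :func:`gen_block_telemetry` — a 4-limb block-design session: visually
  cued movement epochs of one limb's key-points (4 s cue, 10-11 s
  inter-trial interval, 15 trials per condition per block, pseudorandom
  order), with a stochastic cessation lag after the cue (subjects stop
  moving ~1 s late), baseline key-point jitter, and occasional brief
  spurious movements between trials.
* :func:`gen_dance_telemetry` — sessions of a fixed 158 s verse/chorus
  dance schedule (left arm, right arm, left leg, right leg verses, a
  both-arms chorus after each) with per-session timing jitter.
* :func:`gen_sensor_array` — a Fibonacci-spiral scalp sensor array with
  radial (axial-measuring) orientations.
* :func:`gen_meg` — band-limited (8-30 Hz) stochastic dipole sources whose
  amplitude envelope drops by a controlled fraction (event-related
  desynchronisation) while their behavioural state is active, forward
  modelled through the conducting sphere, plus low-frequency uniform-field
  and gradient interference drifts and white sensor noise.

All generators are deterministic under a fixed seed and return their
ground truth next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .preproc import MEGRecording, SensorArray, interference_basis_fields
from .source import dipole_field_sphere
from .states import ConditionTimeline
from .telemetry import BODY25_KEYPOINTS, KeypointSeries

__all__ = [
    "GroundTruth",
    "BLOCK_CONDITIONS",
    "DANCE_STATES",
    "LIMB_KEYPOINTS",
    "gen_block_telemetry",
    "gen_dance_telemetry",
    "gen_sensor_array",
    "gen_meg",
]

BLOCK_CONDITIONS = ["left_arm", "right_arm", "left_leg", "right_leg"]
DANCE_STATES = ["left_arm", "right_arm", "left_leg", "right_leg", "both_arms"]

#: body-25 key-point indices recruited by each movement class
LIMB_KEYPOINTS: dict[str, list[int]] = {
    "left_arm": [5, 6, 7],                 # l_shoulder, l_elbow, l_wrist
    "right_arm": [2, 3, 4],
    "left_leg": [12, 13, 14, 19, 20, 21],  # hip..ankle + foot
    "right_leg": [9, 10, 11, 22, 23, 24],
}
LIMB_KEYPOINTS["both_arms"] = LIMB_KEYPOINTS["left_arm"] + LIMB_KEYPOINTS["right_arm"]


@dataclass
class GroundTruth:
    """Study conditions for the generators (defaults mirror the paradigms)."""

    conditions: list[str] = field(default_factory=lambda: list(BLOCK_CONDITIONS))
    n_trials_per_block: int = 15
    n_blocks: int = 2
    epoch_s: float = 4.0
    iti_range: tuple[float, float] = (10.0, 11.0)
    reaction_lag: tuple[float, float] = (1.0, 0.2)   # cessation delay mean, sd (s)
    movement_amplitude: float = 4.0                  # px/frame during movement
    baseline_amplitude: float = 0.4                  # idle jitter px/frame
    spurious_rate: float = 1.0 / 60.0                # events / s between trials
    spurious_duration: tuple[float, float] = (0.3, 1.0)
    n_rest_modes: int = 8                            # latent idle fidget regimes
    rest_mode_dwell: tuple[float, float] = (2.0, 6.0)  # s, uniform dwell
    erd_depth: float = 0.5                           # fractional envelope drop
    dipole_moment: float = 20e-9                     # A m
    noise_density: float = 15e-15                    # T / sqrt(Hz)
    interference_amplitude: float = 1e-12            # T RMS per component
    dance_jitter_sd: float = 0.5                     # s, per-session onsets
    dance_duration_s: float = 158.0

    def __post_init__(self) -> None:
        if not 0 <= self.erd_depth < 1:
            raise ValueError("erd_depth must lie in [0, 1)")
        if self.reaction_lag[0] < 0:
            raise ValueError("reaction lag mean must be >= 0")


@dataclass
class BlockSession:
    """Synthetic block-design session plus its ground truth."""

    series: KeypointSeries
    cues: ConditionTimeline          # the experiment's nominal boxcars
    movement: ConditionTimeline      # the actual movement support (with lag)
    onsets: dict[str, np.ndarray]    # condition -> trial onsets (s)
    lags: dict[str, np.ndarray]      # condition -> per-trial cessation lag (s)


@dataclass
class DanceSession:
    """Synthetic dance session plus its ground-truth meta-state paths."""

    series: KeypointSeries
    meta_paths: dict[str, np.ndarray]   # state -> (frames,) binary truth
    frame_rate: float


# ---------------------------------------------------------------------------
# telemetry generators


def _integrate_positions(speed: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Positions whose per-frame Euclidean step lengths equal ``speed``.

    Step directions follow a smooth random walk so trajectories look like
    limb motion rather than jitter along one axis.
    """
    T, K = speed.shape
    theta = np.cumsum(rng.normal(0, 0.4, size=(T, K)), axis=0)
    steps = np.stack([speed * np.cos(theta), speed * np.sin(theta)], axis=2)
    start = np.stack([100.0 + 40.0 * np.arange(K),
                      np.full(K, 240.0)], axis=1)
    pos = np.empty((T, K, 2))
    pos[0] = start
    pos[1:] = start + np.cumsum(steps[1:], axis=0)
    return pos


def _baseline_speed(T: int, K: int, truth: "GroundTruth",
                    rng: np.random.Generator,
                    engaged: np.ndarray | None = None) -> np.ndarray:
    """Idle key-point jitter switching among latent fidget regimes.

    Idle behaviour is not one process: subjects shift posture, scratch,
    settle.  Baseline speed therefore follows a semi-Markov sequence of
    ``n_rest_modes`` regimes, each with its own per-key-point jitter scale,
    with dwell times drawn uniformly from ``rest_mode_dwell``.  While the
    subject executes an instructed movement (``engaged`` mask) fidgeting is
    suspended: the baseline drops to a single task-engaged regime.
    """
    n_modes = max(1, truth.n_rest_modes)
    scales = 0.5 + rng.exponential(0.8, size=(n_modes, K))
    frame_rate = 30.0  # dwell resolution only
    mode = np.empty(T, dtype=int)
    t = 0
    while t < T:
        m = rng.integers(n_modes)
        dwell = int(rng.uniform(*truth.rest_mode_dwell) * frame_rate)
        mode[t:t + dwell] = m
        t += dwell
    scale = scales[mode]
    if engaged is not None:
        scale[engaged] = 1.0
    jitter = np.abs(gaussian_filter1d(rng.normal(size=(T, K)), 2.0, axis=0))
    return truth.baseline_amplitude * scale * jitter


def _movement_speed(T: int, mask: np.ndarray, keypoints: list[int],
                    amplitude: float, rng: np.random.Generator,
                    out: np.ndarray) -> None:
    """Add smoothed positive stochastic speed on ``keypoints`` where mask."""
    if not mask.any():
        return
    burst = amplitude * (1.0 + 0.12 * (
        gaussian_filter1d(rng.normal(size=(T, len(keypoints))), 3.0, axis=0)))
    out[:, keypoints] += np.where(mask[:, None], burst, 0.0)


def gen_block_telemetry(truth: GroundTruth, frame_rate: float = 30.0,
                        seed: int = 0) -> BlockSession:
    """Synthesize one block-design pose-telemetry session.

    Trials follow the paradigm in ``truth`` (pseudorandom condition order
    within each block).  Movement of the cued limb's key-points starts at
    the cue and stops a per-trial lag ~ N(reaction_lag) *after* the cue
    ends, so detected movement durations exceed the cue by about the mean
    lag.  The returned ground truth carries both the nominal cue timeline
    and the actual movement timeline.
    """
    rng = np.random.default_rng(seed)
    conds = truth.conditions
    n_cond = len(conds)

    onsets: dict[str, list[float]] = {c: [] for c in conds}
    lags: dict[str, list[float]] = {c: [] for c in conds}
    t = 2.0
    for _ in range(truth.n_blocks):
        order = rng.permutation(np.repeat(np.arange(n_cond),
                                          truth.n_trials_per_block))
        for ci in order:
            onsets[conds[ci]].append(t)
            lags[conds[ci]].append(
                max(0.0, rng.normal(*truth.reaction_lag)))
            t += truth.epoch_s + rng.uniform(*truth.iti_range)
    duration = t + 2.0
    T = int(round(duration * frame_rate))
    K = len(BODY25_KEYPOINTS)

    cues = np.zeros((T, n_cond), dtype=int)
    moves = np.zeros((T, n_cond), dtype=int)
    for ci, c in enumerate(conds):
        for t0, lag in zip(onsets[c], lags[c]):
            a = int(round(t0 * frame_rate))
            cues[a:int(round((t0 + truth.epoch_s) * frame_rate)), ci] = 1
            moves[a:int(round((t0 + truth.epoch_s + lag) * frame_rate)), ci] = 1

    speed = _baseline_speed(T, K, truth, rng, engaged=moves.any(axis=1))
    for ci, c in enumerate(conds):
        _movement_speed(T, moves[:, ci].astype(bool), LIMB_KEYPOINTS[c],
                        truth.movement_amplitude, rng, speed)

    # brief spurious movements in the inter-trial quiet
    quiet = ~moves.any(axis=1)
    n_spur = rng.poisson(truth.spurious_rate * duration)
    for _ in range(n_spur):
        c = conds[rng.integers(n_cond)]
        dur = rng.uniform(*truth.spurious_duration)
        start = rng.uniform(0, duration - dur)
        a, b = int(start * frame_rate), int((start + dur) * frame_rate)
        if quiet[a:b].all():
            m = np.zeros(T, dtype=bool)
            m[a:b] = True
            _movement_speed(T, m, LIMB_KEYPOINTS[c],
                            0.7 * truth.movement_amplitude, rng, speed)

    speed[0] = 0.0
    pos = _integrate_positions(speed, rng)
    series = KeypointSeries(pos, np.ones((T, K)), frame_rate,
                            session_id=f"block_seed{seed}")
    return BlockSession(
        series,
        ConditionTimeline(list(conds), cues, frame_rate),
        ConditionTimeline(list(conds), moves, frame_rate),
        {c: np.asarray(v) for c, v in onsets.items()},
        {c: np.asarray(v) for c, v in lags.items()})


# fixed verse/chorus schedule (state, start s, stop s) inside the 158 s dance
_DANCE_SCHEDULE = [
    ("left_arm", 4.0, 20.0), ("both_arms", 22.0, 30.0),
    ("right_arm", 42.0, 58.0), ("both_arms", 60.0, 68.0),
    ("left_leg", 80.0, 96.0), ("both_arms", 98.0, 106.0),
    ("right_leg", 118.0, 134.0), ("both_arms", 136.0, 144.0),
]


def gen_dance_telemetry(truth: GroundTruth, n_sessions: int = 1,
                        frame_rate: float = 30.0,
                        seed: int = 0) -> list[DanceSession]:
    """Synthesize dance sessions on the fixed verse/chorus schedule.

    Every session follows the same deterministic schedule with independent
    per-segment onset/offset jitter ~ N(0, dance_jitter_sd), emulating
    subjects interpreting the song's timing individually.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(seed)
    T = int(round(truth.dance_duration_s * frame_rate))
    K = len(BODY25_KEYPOINTS)
    sessions = []
    for s in range(n_sessions):
        paths = {name: np.zeros(T, dtype=int) for name in DANCE_STATES}
        for state, t0, t1 in _DANCE_SCHEDULE:
            a = t0 + rng.normal(0, truth.dance_jitter_sd)
            b = t1 + rng.normal(0, truth.dance_jitter_sd)
            a = int(np.clip(round(a * frame_rate), 0, T))
            b = int(np.clip(round(b * frame_rate), a, T))
            paths[state][a:b] = 1
        any_on = np.zeros(T, dtype=bool)
        for state in DANCE_STATES:
            any_on |= paths[state].astype(bool)
        speed = _baseline_speed(T, K, truth, rng, engaged=any_on)
        for state in DANCE_STATES:
            _movement_speed(T, paths[state].astype(bool),
                            LIMB_KEYPOINTS[state],
                            truth.movement_amplitude, rng, speed)
        speed[0] = 0.0
        pos = _integrate_positions(speed, rng)
        series = KeypointSeries(pos, np.ones((T, K)), frame_rate,
                                session_id=f"dance{s}_seed{seed}")
        sessions.append(DanceSession(series, paths, frame_rate))
    return sessions


# ---------------------------------------------------------------------------
# MEG generators


def gen_sensor_array(n_channels: int = 64, head_radius: float = 0.09,
                     offset: float = 0.02, axes: int = 3,
                     cap_zmin: float = -0.15) -> SensorArray:
    """Fibonacci-spiral sensor cap of multi-axis magnetometer sites.

    Sites are spread on the upper cap (z above ``cap_zmin`` x radius) of a
    sphere at scalp radius + standoff.  Each site measures up to three
    orthogonal field components — the axial (scalp-radial) axis first,
    then tangentials — emulating wearable triaxial (``axes=3``), dual-axis
    (``axes=2``) or purely axial (``axes=1``) arrays.  Exactly
    ``n_channels`` channels are returned.
    """
    if n_channels < 9:
        raise ValueError("need at least 9 channels")
    if axes not in (1, 2, 3):
        raise ValueError("axes must be 1, 2 or 3")
    n_sites = int(np.ceil(n_channels / axes))
    i = np.arange(n_sites)
    z = 1.0 - (1.0 - cap_zmin) * (i + 0.5) / n_sites
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    unit = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    ref = np.array([0.0, 0.0, 1.0])
    t1 = np.cross(unit, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(unit, t1)
    positions, orientations = [], []
    for k in range(n_sites):
        for o in (unit[k], t1[k], t2[k])[:axes]:
            positions.append((head_radius + offset) * unit[k])
            orientations.append(o)
    return SensorArray(np.asarray(positions)[:n_channels],
                       np.asarray(orientations)[:n_channels])


def _band_noise(n: int, fs: float, rng: np.random.Generator,
                low: float = 8.0, high: float = 30.0) -> np.ndarray:
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _drift(n: int, fs: float, rng: np.random.Generator,
           cutoff: float = 5.0) -> np.ndarray:
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _resample_path(path: np.ndarray, video_rate: float, n: int,
                   fs: float) -> np.ndarray:
    idx = np.clip(np.round(np.arange(n) / fs * video_rate).astype(int),
                  0, len(path) - 1)
    return path[idx]


def gen_meg(meta_paths: dict[str, np.ndarray], video_rate: float,
            array: SensorArray,
            source_locations: dict[str, tuple[np.ndarray, np.ndarray]],
            fs: float = 1000.0, truth: GroundTruth | None = None,
            seed: int = 0, origin=(0.0, 0.0, 0.0),
            interference: bool = True,
            target_band_snr: float | None = None):
    """Synthesize a MEG recording driven by behavioural state paths.

    Each behavioural state owns one dipolar source (location, orientation in
    ``source_locations``); its activity is band-limited (8-30 Hz) filtered
    noise whose envelope is multiplied by (1 - erd_depth) while the state is
    active — the movement-related envelope decrease.  Interference is a
    low-frequency (< 5 Hz) drift through the 8 uniform/gradient field
    patterns; sensor noise is white.

    ``target_band_snr``, if given, rescales the summed source signal so the
    8-30 Hz power ratio of signal to noise at the best sensor equals it.

    Returns (MEGRecording, truth_dict); truth_dict carries the MEG-rate
    state paths and per-state sensor-space signal topographies.
    """
    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    names = list(meta_paths)
    n = int(round(len(meta_paths[names[0]]) / video_rate * fs))
    pos = array.positions
    ori = array.orientations

    sig = np.zeros((array.n_channels, n))
    paths_meg = {}
    topos = {}
    for name in names:
        loc, moment_dir = source_locations[name]
        loc = np.asarray(loc, dtype=float)
        moment_dir = np.asarray(moment_dir, dtype=float)
        moment_dir = moment_dir / np.linalg.norm(moment_dir)
        B = dipole_field_sphere(loc, truth.dipole_moment * moment_dir,
                                pos, origin)
        lead = np.einsum("ij,ij->i", B, ori)
        active = _resample_path(np.asarray(meta_paths[name]), video_rate, n, fs)
        env = 1.0 - truth.erd_depth * active
        s = _band_noise(n, fs, rng) * env
        sig += np.outer(lead, s)
        paths_meg[name] = active
        topos[name] = lead

    noise_sd = truth.noise_density * np.sqrt(fs / 2.0)
    noise = noise_sd * rng.standard_normal((array.n_channels, n))

    if target_band_snr is not None:
        sos = signal.butter(4, [8.0, 30.0], btype="bandpass", fs=fs,
                            output="sos")
        sig_band = signal.sosfiltfilt(sos, sig, axis=1)
        noise_band = signal.sosfiltfilt(sos, noise, axis=1)
        snr = (sig_band.var(axis=1) / noise_band.var(axis=1)).max()
        sig *= np.sqrt(target_band_snr / snr)

    data = sig + noise
    if interference:
        basis = interference_basis_fields(pos, ori)
        basis = basis / np.sqrt((basis**2).mean(axis=0))
        coeffs = np.stack([_drift(n, fs, rng) for _ in range(basis.shape[1])])
        data = data + truth.interference_amplitude * basis @ coeffs

    rec = MEGRecording(data, fs, array,
                       processing_log=[f"gen_meg(seed={seed})"])
    return rec, {"paths": paths_meg, "topographies": topos,
                 "signal": sig, "noise_sd": noise_sd}
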