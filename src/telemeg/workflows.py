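"""End-to-end analysis workflows on synthetic ground-truth data.

These functions wire the individual modules into the two study pipelines —
the block-design decoding/validation analysis and the dance MEG contrast
analysis — exactly as they would run on real recordings, but driven by the
synthetic generators so every result can be checked against planted truth.
"""

from __future__ import annotations

import numpy as np

from . import glm, hmm, preproc, source, states, synth, telemetry

__all__ = [
    "decode_block_session",
    "beamformer_localization",
    "dance_meg_analysis",
    "DANCE_SOURCES",
]


def decode_block_session(seed: int, truth: synth.GroundTruth | None = None,
                         k: int = 15, n_restarts: int = 3,
                         max_iter: int = 200) -> dict:
    """Generate one block-design session and run the full decoding pipeline.

    Speeds -> z-scores -> k-state HMM -> Jaccard labelling against the cue
    timeline -> confusion/F1/AUC against the generator's actual movement
    timeline (which includes the cessation lag), plus per-trial movement
    duration estimates.
    """
    truth = truth or synth.GroundTruth()
    sess = synth.gen_block_telemetry(truth, seed=seed)
    speeds = telemetry.znormalize(telemetry.to_speed(sess.series))
    dec = hmm.fit_hmm(speeds, k, seed=seed, n_restarts=n_restarts,
                      max_iter=max_iter)
    label_map = states.label_states(dec, sess.cues)

    truth_lab, classes = states._frame_labels(sess.movement)
    pred = states.predicted_labels(dec, label_map)
    report = states.confusion_and_f1(truth_lab, pred, classes)

    # one-vs-all AUC from posterior state probabilities pooled per class
    scores = np.empty((dec.n_frames, len(classes)))
    for ci, cond in enumerate(label_map.conditions):
        cols = sorted(label_map.mapping[cond])
        scores[:, ci] = dec.posteriors[:, cols].sum(axis=1)
    scores[:, -1] = dec.posteriors[:, sorted(label_map.rest_states)].sum(axis=1)
    auc_per_class, auc_macro = states.roc_auc(scores, truth_lab)

    durations = np.concatenate([
        states.movement_durations(
            states.pool_meta_state(dec, label_map.mapping[c]),
            sess.onsets[c], sess.cues.frame_rate)
        for c in label_map.conditions])

    jac = label_map.jaccard_scores
    labelled_j = np.array([jac[ci, sorted(label_map.mapping[c])[0]]
                           for ci, c in enumerate(label_map.conditions)])
    unlabelled_max_j = (jac[:, sorted(label_map.rest_states)].max()
                        if label_map.rest_states else 0.0)

    return {
        "decoding": dec,
        "session": sess,
        "label_map": label_map,
        "report": report,
        "f1_macro": report.f1_macro,
        "auc_macro": auc_macro,
        "auc_per_class": auc_per_class,
        "labelled_jaccard": labelled_j,
        "unlabelled_max_jaccard": float(unlabelled_max_j),
        "mean_duration_s": float(durations.mean()),
        "duration_excess_s": float(durations.mean() - truth.epoch_s),
    }


def beamformer_localization(seed: int, array=None, grid=None, L=None,
                            snr: float = 10.0, fs: float = 250.0,
                            duration_s: float = 60.0) -> dict:
    """Plant one 8-30 Hz dipole at a random grid point and re-localise it.

    Returns the peak displacement (m) of the LCMV variance map from the
    planted point and the worst unit-gain error across the grid.
    """
    rng = np.random.default_rng(seed)
    if array is None:
        array = synth.gen_sensor_array(64)
    if grid is None:
        grid = source.make_grid((0.0025, 0.0025, 0.0025), radius=0.05,
                                spacing=0.005)
    if L is None:
        L = source.reduce_rank_leadfield(source.leadfield_sphere(grid, array))

    # a source neither at the silent centre nor on the rim
    ecc = np.linalg.norm(grid.points, axis=1)
    candidates = np.flatnonzero((ecc > 0.02) & (ecc < 0.045))
    gi = int(rng.choice(candidates))
    loc = grid.points[gi]
    u2 = rng.normal(size=2)
    ori3 = L.ori_basis[gi] @ u2
    ori3 /= np.linalg.norm(ori3)

    truth = synth.GroundTruth(erd_depth=0.0, interference_amplitude=0.0)
    n_frames = int(duration_s * 30.0)
    rec, _ = synth.gen_meg({"src": np.ones(n_frames, dtype=int)}, 30.0,
                           array, {"src": (loc, ori3)}, fs=fs, truth=truth,
                           seed=seed, interference=False,
                           target_band_snr=snr)
    rec = preproc.bandpass(rec, 8.0, 30.0)
    cov = np.cov(rec.data)
    W = source.lcmv_weights(cov, L, discard=0)
    var = source.localize_envelope_power(rec.data, W, depth_normalize=True)
    peak_err = float(np.linalg.norm(grid.points[int(var.argmax())] - loc))

    gain_err = 0.0
    C_inv, _ = source.regularized_inverse(cov, 0)
    for s in range(grid.n_sources):
        l = L.matrix[s] @ (L.ori_basis[s].T @ W.orientations[s])
        gain_err = max(gain_err, abs(float(W.weights[s] @ l) - 1.0))
    return {"peak_error_m": peak_err, "unit_gain_error": gain_err,
            "grid": grid, "planted_index": gi}


# planted cortical sources for the dance analysis: one per limb, arranged
# along the motor strip (arms lateral, legs medial; contralateral control).
# All four sit on the default 5 mm source lattice (centre offset 2.5 mm).
DANCE_SOURCES = {
    "left_arm": (np.array([0.0325, 0.0025, 0.0325]),),    # right hemisphere
    "right_arm": (np.array([-0.0325, 0.0025, 0.0325]),),  # left hemisphere
    "left_leg": (np.array([-0.0125, 0.0025, 0.0475]),),
    "right_leg": (np.array([0.0125, 0.0025, 0.0475]),),
}


def _tangential(loc: np.ndarray) -> np.ndarray:
    t = np.cross(loc, [0.0, 0.0, 1.0])
    if np.linalg.norm(t) < 1e-9:
        t = np.array([1.0, 0.0, 0.0])
    return t / np.linalg.norm(t)


def dance_meg_analysis(seed: int, n_sessions: int = 10, fs: float = 250.0,
                       grid_radius: float = 0.06, spacing: float = 0.005,
                       truth: synth.GroundTruth | None = None,
                       chunk: int = 1024) -> dict:
    """Full dance analysis on synthetic sessions with planted limb sources.

    Each limb owns one cortical source whose 8-30 Hz envelope drops while
    that limb moves; the both-arms state therefore drives *both* arm
    sources (moving both arms is the union of the single-arm movements).
    Per session (dance): homogeneous field correction, 8-30 Hz band-pass,
    LCMV beamforming with the compensated lead field, log-envelope GLM on
    the five meta-state regressors.  Across sessions: 1 x 5 factorial
    contrasts — "left arm - both arms" should peak at the right-arm source
    (disjunctive-union logic) and the pooled leg contrast at a leg source.

    Returns the two contrast images and their peak displacement from the
    expected planted sources.
    """
    truth = truth or synth.GroundTruth()
    array = synth.gen_sensor_array(64)
    grid = source.make_grid((0.0025, 0.0025, 0.0025), radius=grid_radius,
                            spacing=spacing)
    L = source.reduce_rank_leadfield(source.leadfield_sphere(grid, array))
    sessions = synth.gen_dance_telemetry(truth, n_sessions=n_sessions,
                                         seed=seed)

    src_locs = {name: (loc, _tangential(loc))
                for name, (loc,) in DANCE_SOURCES.items()}
    state_names = list(synth.DANCE_STATES)
    images = np.empty((n_sessions, len(state_names), grid.n_sources))

    for si, sess in enumerate(sessions):
        paths = sess.meta_paths
        # each arm source is driven by its own state OR the both-arms state
        drive = {
            "left_arm": paths["left_arm"] | paths["both_arms"],
            "right_arm": paths["right_arm"] | paths["both_arms"],
            "left_leg": paths["left_leg"],
            "right_leg": paths["right_leg"],
        }
        rec, _ = synth.gen_meg(drive, sess.frame_rate, array, src_locs,
                               fs=fs, truth=truth, seed=seed + 101 * si)
        rec, op = preproc.apply_hfc(rec)
        rec = preproc.bandpass(rec, 8.0, 30.0)
        rec = preproc.sync_states(rec, paths, sess.frame_rate)

        Lc = source.compensate(L, op)
        W = source.lcmv_weights(np.cov(rec.data), Lc, discard=8)
        design = glm.build_design_dance(
            {name: rec.trigger_channels[name] for name in state_names})

        for lo in range(0, grid.n_sources, chunk):
            hi = min(lo + chunk, grid.n_sources)
            ts = W.weights[lo:hi] @ rec.data
            res = glm.fit_glm(glm.envelope_log(ts), design)
            images[si, :, lo:hi] = res.betas[:, :len(state_names)].T

    arm_img = glm.second_level_factorial(
        images, [1, 0, 0, 0, -1], grid, state_names)
    leg_img = glm.second_level_factorial(
        images, [0, 0, 0.5, 0.5, 0], grid, state_names)

    arm_peak = grid.points[arm_img.peak()]
    leg_peak = grid.points[leg_img.peak()]
    arm_err = float(np.linalg.norm(arm_peak - DANCE_SOURCES["right_arm"][0]))
    leg_err = float(min(
        np.linalg.norm(leg_peak - DANCE_SOURCES["left_leg"][0]),
        np.linalg.norm(leg_peak - DANCE_SOURCES["right_leg"][0])))
    return {
        "grid": grid,
        "images": images,
        "arm_contrast": arm_img,
        "leg_contrast": leg_img,
        "arm_peak_error_m": arm_err,
        "leg_peak_error_m": leg_err,
    }
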