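"""Shared fixtures: the standard recording setup and one closed-loop run.

The expensive end-to-end artifacts (synthetic single-fish training sessions,
the dyad session, the fitted waveform->pose model and its assignments) are
built once per test session and shared between the pipeline tests and the
acceptance checks.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from pulseid.assign import assign_id, predict_pose, train_eod_model
from pulseid.eod import (
    build_vector,
    detect_eods,
    estimate_noise_sigma,
    extract_events,
)
from pulseid.geometry import standard_setup
from pulseid.pose import SkeletonPose
from pulseid.synth import SyntheticScenario, make_recording, single_fish_scenario

THRESHOLD_SIGMA = 6.0


@pytest.fixture(scope="session")
def setup1():
    """Default tank and electrode configuration 1."""
    return standard_setup(1)


def run_session(scenario, config, match_tol=3):
    """Detect and extract EODs; pair each with its ground-truth row."""
    rec, ttl, tracks, truth = make_recording(scenario, config)
    sigma = estimate_noise_sigma(rec)
    events = extract_events(rec, detect_eods(rec, THRESHOLD_SIGMA * sigma))
    true_peaks = truth["peak_sample"].to_numpy()
    pairs = []
    for ev in events:
        j = int(np.argmin(np.abs(true_peaks - ev.peak_index)))
        if abs(true_peaks[j] - ev.peak_index) <= match_tol:
            pairs.append((ev, truth.iloc[j]))
    return pairs, truth, tracks, ttl


def truth_pose(row) -> SkeletonPose:
    nodes = np.array([[row[f"node{j}_x"], row[f"node{j}_y"]]
                      for j in range(6)])
    return SkeletonPose(nodes)


@dataclass
class ClosedLoopRun:
    model: object
    records: list
    correct: np.ndarray          # per-record ground-truth agreement
    interfish_distance: np.ndarray
    n_true_events: int


@pytest.fixture(scope="session")
def closed_loop(setup1) -> ClosedLoopRun:
    """Detect -> train on single-fish sessions -> assign the dyad session.

    Study conditions: two fish, gamma (shape 3) firing at 20/16.7 Hz mean
    rates, channel SNR 10, ~1,000 EODs in the dyad segment.
    """
    tank, config = setup1
    vectors, poses = [], []
    for fish_index, seed in ((0, 21), (1, 22)):
        scen = single_fish_scenario(
            SyntheticScenario(seed=seed, tank=tank, duration_s=40.0),
            fish_index)
        pairs, _, _, _ = run_session(scen, config)
        for ev, row in pairs:
            vectors.append(build_vector(ev))
            poses.append(truth_pose(row))
    model = train_eod_model(vectors, poses, seed=1)

    dyad = SyntheticScenario(seed=31, tank=tank, duration_s=28.0)
    pairs, truth, _, _ = run_session(dyad, config)
    records, correct, dists = [], [], []
    per_fish = {fid: truth[truth.fish_id == fid] for fid in (1, 2)}
    for ev, row in pairs:
        t = row["eod_time"]
        candidates = {}
        for fid, sub in per_fish.items():
            k = int(np.argmin(np.abs(sub["eod_time"].to_numpy() - t)))
            candidates[fid] = truth_pose(sub.iloc[k])
        pred = predict_pose(model, build_vector(ev))
        rec_ = assign_id(pred, candidates, eod_time=t)
        records.append(rec_)
        correct.append(rec_.assigned_id == row["fish_id"])
        dists.append(np.linalg.norm(candidates[1].anchor
                                    - candidates[2].anchor))
    return ClosedLoopRun(model, records, np.asarray(correct),
                         np.asarray(dists), len(truth))
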