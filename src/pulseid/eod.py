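"""EOD detection, alignment, waveform-vector construction and doublet screening.

A pulse-type fish emits discrete electric organ discharges (EODs) a few
hundred microseconds long.  The pipeline detects threshold crossings on any
of the channels, aligns each event on the peak of the channel-averaged
absolute trace, cuts a fixed window (272 us before / 128 us after the peak at
125 kHz -> 51 samples), concatenates the channels into one vector normalized
to a +/-1 range, and screens for doublets: two fish discharging so close in
time that their pulses overlap within one extraction window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "MultichannelRecording",
    "EodEvent",
    "WaveformVector",
    "DoubletFlag",
    "detect_eods",
    "align_and_extract",
    "extract_events",
    "build_vector",
    "average_waveform",
    "doublet_screen",
    "confirm_doublets",
    "estimate_noise_sigma",
    "PendingReviewError",
]

DEFAULT_PRE_US = 272.0
DEFAULT_POST_US = 128.0
DEFAULT_REFRACTORY_US = 400.0


class PendingReviewError(RuntimeError):
    """Raised when doublet flags are exported before all decisions are in."""


@dataclass
class MultichannelRecording:
    """A multichannel voltage recording (n_channels x T, volts)."""

    samples: np.ndarray
    sampling_rate: float = 125_000.0
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    # -- I/O ---------------------------------------------------------------
    def to_wav(self, path) -> None:
        wavfile.write(path, int(self.sampling_rate),
                      self.samples.T.astype(np.float32))

    @classmethod
    def from_wav(cls, path, scale: float = 1.0) -> "MultichannelRecording":
        """Read a multichannel WAV.  Integer PCM is rescaled to +/-``scale``."""
        rate, data = wavfile.read(path)
        data = np.atleast_2d(data.T)
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.float64) * (
                scale / float(np.iinfo(data.dtype).max))
        return cls(data.astype(np.float64), float(rate))

    def to_raw(self, path) -> None:
        """float32 binary (channel-interleaved) + JSON metadata sidecar."""
        path = Path(path)
        self.samples.T.astype(np.float32).tofile(path)
        meta = {"sampling_rate": self.sampling_rate,
                "n_channels": self.n_channels,
                "start_time": self.start_time, "dtype": "float32",
                "order": "sample_major"}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_raw(cls, path) -> "MultichannelRecording":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        data = np.fromfile(path, dtype=np.float32)
        data = data.reshape(-1, meta["n_channels"]).T.astype(np.float64)
        return cls(data, meta["sampling_rate"], meta.get("start_time", 0.0))


@dataclass
class EodEvent:
    """A detected discharge with its aligned raw multichannel window."""

    peak_index: int
    window: np.ndarray  # (n_channels, W) volts
    pre_samples: int
    post_samples: int
    detect_channel: int = 0

    def __post_init__(self):
        w = self.pre_samples + self.post_samples + 1
        if self.window.shape[1] != w:
            raise ValueError("window width inconsistent with pre/post samples")

    @property
    def width(self) -> int:
        return self.window.shape[1]

    def mean_abs_trace(self, normalize: bool = False) -> np.ndarray:
        """Channel-averaged absolute trace used for alignment and screening."""
        trace = np.abs(self.window).mean(axis=0)
        if normalize:
            peak = trace.max()
            if peak == 0:
                raise ValueError("all-zero window")
            trace = trace / peak
        return trace


@dataclass
class WaveformVector:
    """Concatenated, peak-normalized multichannel EOD window (max |v| = 1)."""

    values: np.ndarray
    source_event: EodEvent | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isclose(np.max(np.abs(self.values)), 1.0):
            raise ValueError("waveform vector must be normalized to max |v| = 1")


@dataclass
class DoubletFlag:
    """A suspected overlap of two fish's EODs in one extraction window."""

    event_index: int
    event: EodEvent
    residual_score: float
    threshold_used: float
    confirmed: str = "pending"  # pending | doublet | clean

    def __post_init__(self):
        if self.residual_score <= self.threshold_used:
            raise ValueError("flag requires residual_score > threshold_used")


def estimate_noise_sigma(rec: MultichannelRecording) -> np.ndarray:
    """Robust per-channel noise sigma (median absolute deviation / 0.6745)."""
    return np.median(np.abs(rec.samples - np.median(
        rec.samples, axis=1, keepdims=True)), axis=1) / 0.6745


def detect_eods(rec: MultichannelRecording, thresholds,
                refractory_us: float = DEFAULT_REFRACTORY_US,
                search_us: float = 400.0) -> np.ndarray:
    """Detect EOD events; returns strictly increasing peak sample indices.

    An event is registered whenever any channel's absolute voltage crosses
    its per-channel threshold (rising crossing of |v|); each crossing is
    aligned to the peak of the cross-channel mean absolute trace within
    ``search_us`` after it.  Aligned events within ``refractory_us`` of the
    previously kept event are discarded — the earlier event is kept — which
    both merges the phases of a single pulse and drops the later of two
    pulses closer than the refractory time.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (rec.n_channels,):
        raise ValueError("need exactly one threshold per channel")
    if np.any(thresholds <= 0):
        raise ValueError("thresholds must be positive")
    above = (np.abs(rec.samples) > thresholds[:, None]).any(axis=0)
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    if len(crossings) == 0:
        return np.asarray([], dtype=int)
    mean_abs = np.abs(rec.samples).mean(axis=0)
    search = int(round(search_us * 1e-6 * rec.sampling_rate))
    back = int(round(DEFAULT_PRE_US * 1e-6 * rec.sampling_rate))
    refractory = int(round(refractory_us * 1e-6 * rec.sampling_rate))
    kept = []
    last = -np.inf
    for c in crossings:
        lo = max(c - back, 0)
        peak = lo + int(np.argmax(mean_abs[lo: c + search + 1]))
        if peak - last >= refractory:
            kept.append(peak)
            last = peak
    return np.asarray(kept, dtype=int)


def align_and_extract(rec: MultichannelRecording, t: int,
                      pre_us: float = DEFAULT_PRE_US,
                      post_us: float = DEFAULT_POST_US,
                      search_us: float = 400.0) -> EodEvent:
    """Align a detection on the mean-absolute-trace peak and cut the window.

    The peak is the argmax of the channel-averaged absolute trace in
    ``[t - pre, t + search]``; all channels are cut with the same indices so
    the peak sits at index ``pre_samples``.  Raises ``IndexError`` when the
    window would cross a recording boundary (the event is to be dropped).
    """
    fs = rec.sampling_rate
    pre = int(round(pre_us * 1e-6 * fs))
    post = int(round(post_us * 1e-6 * fs))
    search = int(round(search_us * 1e-6 * fs))
    lo = max(int(t) - pre, 0)
    hi = min(int(t) + search + 1, rec.n_samples)
    if hi <= lo:
        raise IndexError("search window outside recording")
    local = np.abs(rec.samples[:, lo:hi]).mean(axis=0)
    peak = lo + int(np.argmax(local))
    if peak - pre < 0 or peak + post >= rec.n_samples:
        raise IndexError(
            f"window for event at sample {t} clipped by recording edge")
    window = rec.samples[:, peak - pre: peak + post + 1].copy()
    detect_channel = int(np.argmax(np.abs(window[:, pre])))
    return EodEvent(peak_index=peak, window=window, pre_samples=pre,
                    post_samples=post, detect_channel=detect_channel)


def extract_events(rec: MultichannelRecording, times,
                   pre_us: float = DEFAULT_PRE_US,
                   post_us: float = DEFAULT_POST_US) -> list:
    """Extract events for many detection times, dropping boundary-clipped ones."""
    events = []
    for t in times:
        try:
            events.append(align_and_extract(rec, t, pre_us, post_us))
        except IndexError as exc:
            logger.warning("dropped event: %s", exc)
    return events


def build_vector(ev: EodEvent) -> WaveformVector:
    """Concatenate channels and normalize by the global absolute maximum."""
    flat = ev.window.ravel()
    peak = np.max(np.abs(flat))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero window")
    return WaveformVector(values=flat / peak, source_event=ev)


def average_waveform(events) -> np.ndarray:
    """Average normalized mean-absolute trace over events; peak scaled to 1."""
    if len(events) == 0:
        raise ValueError("no events to average")
    traces = np.stack([ev.mean_abs_trace() for ev in events])
    avg = traces.mean(axis=0)
    return avg / avg.max()


def doublet_screen(events, avg: np.ndarray, flag_fraction: float = 0.01,
                   metric: str = "l1"):
    """Score every event against the average waveform; flag the extreme tail.

    The residual is the L1 (or L2) distance between the event's normalized
    mean-absolute trace and the normalized average; the threshold is the
    (1 - flag_fraction) quantile of all scores.  Returns ``(flags, scores)``
    with flags sorted descending by score.
    """
    if not 0.0 < flag_fraction < 1.0:
        raise ValueError("flag_fraction must lie in (0, 1)")
    if metric not in ("l1", "l2"):
        raise ValueError("metric must be 'l1' or 'l2'")
    scores = np.empty(len(events))
    for i, ev in enumerate(events):
        diff = ev.mean_abs_trace(normalize=True) - avg
        scores[i] = (np.sum(np.abs(diff)) if metric == "l1"
                     else float(np.sqrt(np.sum(diff**2))))
    threshold = float(np.quantile(scores, 1.0 - flag_fraction))
    flagged = np.flatnonzero(scores > threshold)
    order = flagged[np.argsort(scores[flagged])[::-1]]
    flags = [DoubletFlag(int(i), events[int(i)], float(scores[i]), threshold)
             for i in order]
    return flags, scores


def doublet_capture_curve(scores, is_doublet) -> pd.DataFrame:
    """Capture-vs-inspected diagnostic for the screening threshold.

    Events are inspected in descending residual order; each row reports,
    after inspecting the top-n events, the fraction of inspected events
    that are doublets and the fraction of all doublets already found.
    """
    scores = np.asarray(scores, dtype=float)
    is_doublet = np.asarray(is_doublet, dtype=bool)
    if scores.shape != is_doublet.shape:
        raise ValueError("scores and labels must align")
    order = np.argsort(scores)[::-1]
    hits = np.cumsum(is_doublet[order])
    n = np.arange(1, len(scores) + 1)
    total = max(int(is_doublet.sum()), 1)
    return pd.DataFrame({
        "n_checked": n,
        "residual": scores[order],
        "frac_checked_are_doublets": hits / n,
        "frac_doublets_found": hits / total,
    })


def plot_doublet_capture(curve: pd.DataFrame, path) -> None:
    """Write the capture-vs-inspected diagnostic figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["n_checked"], 100 * curve["frac_doublets_found"],
            color="tab:red", label="% of doublets found")
    ax.plot(curve["n_checked"], 100 * curve["frac_checked_are_doublets"],
            color="tab:blue", label="% of checked that are doublets")
    ax.set_xlabel("EODs checked (descending residual)")
    ax.set_ylabel("%")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def confirm_doublets(flags, decisions, sampling_rate: float = 125_000.0
                     ) -> np.ndarray:
    """Resolve flags against user decisions; returns confirmed doublet times (s).

    ``decisions`` maps event index -> bool (doublet or not), or is a CSV path
    with columns (event_id, doublet).  Every flag must be decided.
    """
    if not isinstance(decisions, dict):
        df = pd.read_csv(decisions)
        decisions = {int(r.event_id): bool(r.doublet) for r in df.itertuples()}
    undecided = [f.event_index for f in flags if f.event_index not in decisions]
    if undecided:
        raise PendingReviewError(f"unresolved doublet flags: {undecided}")
    times = []
    for f in flags:
        if decisions[f.event_index]:
            f.confirmed = "doublet"
            times.append(f.event.peak_index / sampling_rate)
        else:
            f.confirmed = "clean"
    return np.sort(np.asarray(times))


def events_to_csv(events, path, sampling_rate: float = 125_000.0) -> None:
    pd.DataFrame({
        "peak_sample": [ev.peak_index for ev in events],
        "peak_time_s": [ev.peak_index / sampling_rate for ev in events],
        "detect_channel": [ev.detect_channel for ev in events],
    }).to_csv(path, index=False)
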