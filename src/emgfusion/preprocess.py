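"""Raw EMG -> model-ready segments: bandpass filtering, windowing, MAV scaling.

The pipeline is deliberately feature-free: a 20-300 Hz Butterworth bandpass
(applied forward-backward for zero phase, since classification is offline),
fixed 750-sample labelled windows, and amplitude normalization by the mean
absolute value (MAV) computed per (subject, session, arm, channel). No
handcrafted features are extracted; the network consumes the normalized
time series directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .gestures import Gesture, as_gesture
from .synth import Recording, RecordingSet, N_CHANNELS

EPS_GUARD = 1e-12


@dataclass(frozen=True)
class FilterSpec:
    low_cut: float = 20.0
    high_cut: float = 300.0
    order: int = 4
    sampling_rate: int = 1000

    def __post_init__(self):
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut >= self.sampling_rate / 2:
            raise ValueError(f"high_cut {self.high_cut} Hz violates the Nyquist limit "
                             f"({self.sampling_rate / 2} Hz)")


def design_bandpass(spec: FilterSpec) -> np.ndarray:
    """Second-order sections of the Butterworth bandpass."""
    return butter(spec.order, [spec.low_cut, spec.high_cut], btype="bandpass",
                  fs=spec.sampling_rate, output="sos")


def bandpass_gain(spec: FilterSpec, freq_hz: float) -> float:
    """Analytic magnitude response of the *single-pass* filter at ``freq_hz``."""
    from scipy.signal import sosfreqz
    sos = design_bandpass(spec)
    _, h = sosfreqz(sos, worN=[freq_hz], fs=spec.sampling_rate)
    return float(np.abs(h[0]))


def filter_recording(rec: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase (forward-backward) bandpass of every channel."""
    if rec.sampling_rate != spec.sampling_rate:
        raise ValueError(f"recording sampled at {rec.sampling_rate} Hz but filter "
                         f"designed for {spec.sampling_rate} Hz")
    sos = design_bandpass(spec)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.signal.shape[0] <= padlen:
        raise ValueError(f"signal of {rec.signal.shape[0]} samples too short for "
                         f"zero-phase filtering (needs > {padlen})")
    filtered = sosfiltfilt(sos, rec.signal, axis=0).astype(np.float32)
    return replace(rec, signal=filtered)


@dataclass(frozen=True)
class Segment:
    """A single labelled 750-sample x 4-channel window."""

    signal: np.ndarray
    label: Gesture
    subject_id: str
    session: str
    arm: str
    repetition: int = 0


@dataclass
class SegmentSet:
    """Segments stacked into one array plus a manifest.

    ``X`` has shape (n_segments, n_samples, 4); ``meta`` carries one row per
    segment with subject_id / session / arm / gesture / repetition.
    ``norm_stats`` holds the MAV divisors once :func:`mav_normalize` ran.
    """

    X: np.ndarray
    meta: pd.DataFrame
    norm_stats: pd.DataFrame | None = None

    def __post_init__(self):
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta rows must match X segments")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def gestures(self) -> pd.Series:
        return self.meta["gesture"]

    def subset(self, mask) -> "SegmentSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SegmentSet(self.X[idx], self.meta.iloc[idx], self.norm_stats)

    def labels_for(self, gesture_order: list) -> np.ndarray:
        """Integer labels relative to an ordered gesture subset."""
        order = {as_gesture(g).value: i for i, g in enumerate(gesture_order)}
        unknown = set(self.gestures) - set(order)
        if unknown:
            raise ValueError(f"segments contain gestures outside the subset: {sorted(unknown)}")
        return self.gestures.map(order).to_numpy(dtype=np.int64)

    def save(self, out_dir: str | Path, fmt: str = "%.6f") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.meta.to_csv(out_dir / "segments_meta.csv", index=False)
        for i in range(len(self)):
            np.savetxt(out_dir / f"seg_{i:05d}.csv", self.X[i], delimiter=",", fmt=fmt)
        if self.norm_stats is not None:
            (out_dir / "norm_stats.json").write_text(
                self.norm_stats.to_json(orient="records", indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "SegmentSet":
        in_dir = Path(in_dir)
        meta = pd.read_csv(in_dir / "segments_meta.csv")
        X = np.stack([np.loadtxt(in_dir / f"seg_{i:05d}.csv", delimiter=",",
                                 dtype=np.float32).reshape(-1, N_CHANNELS)
                      for i in range(len(meta))])
        stats_path = in_dir / "norm_stats.json"
        stats = pd.read_json(stats_path) if stats_path.exists() else None
        return cls(X, meta, stats)


def extract_segments(stream: np.ndarray, markers, labels, *,
                     subject_id: str = "", session: str = "single",
                     arm: str = "paretic", segment_length: int = 750) -> SegmentSet:
    """Cut contiguous ``[start, start + segment_length)`` windows at markers."""
    markers = np.asarray(markers, dtype=np.int64)
    labels = list(labels)
    if len(labels) != len(markers):
        raise ValueError("one label per marker required")
    segs, rows = [], []
    for i, (m, lab) in enumerate(zip(markers, labels)):
        if m < 0 or m + segment_length > stream.shape[0]:
            raise ValueError(f"marker {i} at sample {m} overruns the stream "
                             f"(length {stream.shape[0]})")
        segs.append(stream[m:m + segment_length])
        rows.append({"subject_id": subject_id, "session": session, "arm": arm,
                     "gesture": as_gesture(lab).value, "repetition": i})
    X = (np.stack(segs).astype(np.float32) if segs
         else np.empty((0, segment_length, N_CHANNELS), dtype=np.float32))
    return SegmentSet(X, pd.DataFrame(rows, columns=["subject_id", "session", "arm",
                                                     "gesture", "repetition"]))


def segments_from_recordings(recordings: RecordingSet,
                             spec: FilterSpec | None = None) -> SegmentSet:
    """Filter every recording and stack them into a SegmentSet (vectorized)."""
    spec = spec or FilterSpec(sampling_rate=recordings.recordings[0].sampling_rate
                              if len(recordings) else 1000)
    if not len(recordings):
        return SegmentSet(np.empty((0, 750, N_CHANNELS), dtype=np.float32),
                          pd.DataFrame(columns=["subject_id", "session", "arm",
                                                "gesture", "repetition"]))
    X = np.stack([r.signal for r in recordings.recordings])
    sos = design_bandpass(spec)
    X = sosfiltfilt(sos, X, axis=1).astype(np.float32)
    meta = recordings.manifest()
    return SegmentSet(X, meta)


def mav_normalize(segset: SegmentSet, per_segment: bool = False) -> SegmentSet:
    """Divide each channel by its mean absolute value.

    Default granularity: the MAV is computed per (subject, session, arm,
    channel) over all of that group's segments, preserving between-gesture
    amplitude contrast within a subject. ``per_segment=True`` instead
    normalizes each segment by its own per-channel MAV. A divisor below
    ``EPS_GUARD`` is replaced by 1 and flagged in the stats table.
    """
    if len(segset) == 0:
        raise ValueError("cannot normalize an empty segment set")
    X = segset.X.astype(np.float32).copy()
    rows = []
    if per_segment:
        mav = np.mean(np.abs(X), axis=1, keepdims=True)   # (n, 1, 4)
        guarded = mav < EPS_GUARD
        mav = np.where(guarded, 1.0, mav)
        X /= mav
        for i in range(X.shape[0]):
            for ch in range(N_CHANNELS):
                rows.append({"subject_id": segset.meta.at[i, "subject_id"],
                             "session": segset.meta.at[i, "session"],
                             "arm": segset.meta.at[i, "arm"], "segment": i,
                             "channel": ch, "mav": float(mav[i, 0, ch]),
                             "eps_guarded": bool(guarded[i, 0, ch])})
    else:
        groups = segset.meta.groupby(["subject_id", "session", "arm"],
                                     sort=False).indices
        for (sid, sess, arm), idx in groups.items():
            mav = np.mean(np.abs(X[idx]), axis=(0, 1))    # (4,)
            guarded = mav < EPS_GUARD
            mav = np.where(guarded, 1.0, mav)
            X[idx] /= mav[None, None, :]
            for ch in range(N_CHANNELS):
                rows.append({"subject_id": sid, "session": sess, "arm": arm,
                             "channel": ch, "mav": float(mav[ch]),
                             "eps_guarded": bool(guarded[ch])})
    return SegmentSet(X, segset.meta.copy(), pd.DataFrame(rows))
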