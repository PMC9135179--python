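"""Synthetic EEG generation with the class structure of the study datasets.

Two families are emulated:

* Bonn-style single-channel recordings: 4097 samples at 173.61 Hz, split
  into 23 contiguous chunks for classification.  The background class is
  AR(2)-filtered Gaussian noise scaled to unit variance (a band-limited,
  1/f-ish spectrum); the ictal-like class adds Poisson-timed 3-5 Hz
  spike-wave bursts at 4x amplitude, so low-frequency band power separates
  the classes.
* Schizophrenia-style multichannel matrices (segments x samples x channels,
  canonically 45 x 5000 x 19 per subject): the two classes differ by the
  cross-channel mixing matrix applied to latent noise sources.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _signal

BONN_SAMPLING_RATE_HZ = 173.61
BONN_RECORDING_LENGTH = 4097
BONN_N_CHUNKS = 23

__all__ = [
    "Recording", "EEGSegmentSet", "generate_bonn_like",
    "generate_multichannel_like", "segment_recording", "pool_segments",
    "zscore_segments",
    "save_segment_set", "load_segment_set",
    "BONN_SAMPLING_RATE_HZ", "BONN_RECORDING_LENGTH", "BONN_N_CHUNKS",
]


@dataclass
class Recording:
    """A single-channel EEG recording (microvolt-scale, arbitrary units)."""

    samples: np.ndarray
    sampling_rate_hz: float = BONN_SAMPLING_RATE_HZ
    source_label: str = "synthetic-class0"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D vector")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def class_label(self) -> int:
        """0 for background/healthy-type labels, 1 for ictal-like/positive."""
        return int(self.source_label in ("E", "schizophrenia",
                                         "synthetic-class1"))


@dataclass
class EEGSegmentSet:
    """Labelled fixed-length segments.

    ``segments`` is (n_segments, segment_length) for single-channel data or
    (n_segments, segment_length, n_channels) for multichannel data;
    ``labels`` is an integer vector in {0, 1} aligned row-for-row.
    """

    segments: np.ndarray
    labels: np.ndarray
    channel_count: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.segments.shape[0] != self.labels.shape[0]:
            raise ValueError("segments and labels must align 1:1")
        if not np.isfinite(self.segments).all():
            raise ValueError("segments contain NaN/Inf")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be in {0, 1}")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """Segments as a 2-D design matrix (channels concatenated)."""
        return self.segments.reshape(len(self), -1)


_AR_POLE_RADIUS = 0.92
_AR_PEAK_HZ = 10.0  # healthy background EEG is alpha-dominant


def _ar2_background(n: int, rng: np.random.Generator,
                    fs: float = BONN_SAMPLING_RATE_HZ) -> np.ndarray:
    """Unit-variance AR(2) noise resonant in the alpha band (~10 Hz)."""
    theta = 2.0 * np.pi * _AR_PEAK_HZ / fs
    a1 = -2.0 * _AR_POLE_RADIUS * np.cos(theta)
    a2 = _AR_POLE_RADIUS ** 2
    x = _signal.lfilter([1.0], [1.0, a1, a2], rng.standard_normal(n))
    # a touch of broadband noise so the spectrum is not a pure resonance
    x = x / max(x.std(), 1e-12) + 0.5 * rng.standard_normal(n)
    return x / max(x.std(), 1e-12)


def _spike_wave_bursts(n: int, fs: float, rng: np.random.Generator,
                       rate_hz: float = 2.5, amplitude: float = 4.0
                       ) -> np.ndarray:
    """Poisson-timed bursts of 3-5 Hz spike-wave discharge.

    The default rate and 1-2 s burst durations give near-continuous
    discharge (ictal recordings are continuously abnormal), so that every
    ~1 s analysis chunk of an ictal-like recording carries 3-5 Hz energy.
    """
    out = np.zeros(n)
    t = rng.exponential(1.0 / rate_hz)
    while t * fs < n:
        start = int(t * fs)
        f = rng.uniform(3.0, 5.0)
        dur = int(rng.uniform(1.0, 2.0) * fs)
        idx = np.arange(start, min(start + dur, n))
        phase = 2 * np.pi * f * (idx - start) / fs
        # sharpened sinusoid: spike (cubed lobe) riding on the slow wave
        wave = np.sin(phase) + 0.6 * np.sin(phase) ** 3
        envelope = _signal.windows.tukey(len(idx), 0.25) if len(idx) else wave
        out[idx] += amplitude * wave * envelope
        t += rng.exponential(1.0 / rate_hz)
    return out


def generate_bonn_like(n_recordings_per_class: int,
                       recording_length: int = BONN_RECORDING_LENGTH,
                       seed: int = 0,
                       sampling_rate_hz: float = BONN_SAMPLING_RATE_HZ,
                       burst_amplitude: float = 4.0,
                       burst_rate_hz: float = 2.5) -> list[Recording]:
    """Generate ``2 * n_recordings_per_class`` single-channel recordings.

    Class 0 ("synthetic-class0") is unit-variance AR(2) background noise;
    class 1 ("synthetic-class1") adds high-amplitude 3-5 Hz spike-wave
    bursts, so 3-5 Hz band power separates the classes.
    """
    if n_recordings_per_class <= 0 or recording_length <= 0:
        raise ValueError("counts and lengths must be positive")
    if recording_length < 46:
        raise ValueError("recording_length must be at least 46 samples")
    rng = np.random.default_rng(seed)
    recs: list[Recording] = []
    for label in (0, 1):
        for _ in range(n_recordings_per_class):
            x = _ar2_background(recording_length, rng)
            if label == 1:
                x = x + _spike_wave_bursts(recording_length, sampling_rate_hz,
                                           rng, rate_hz=burst_rate_hz,
                                           amplitude=burst_amplitude)
            recs.append(Recording(x, sampling_rate_hz,
                                  f"synthetic-class{label}"))
    return recs


def generate_multichannel_like(n_subjects_per_class: int = 1,
                               segment_length: int = 5000,
                               n_segments: int = 45,
                               n_channels: int = 19,
                               seed: int = 0) -> EEGSegmentSet:
    """Generate a multichannel segment set with class-dependent covariance.

    Latent AR(2) sources are mixed into channels by a class-specific mixing
    matrix, so the cross-channel covariance carries the class signal.
    Output shape: (n_subjects_per_class * 2 * n_segments, segment_length,
    n_channels).
    """
    if min(n_subjects_per_class, segment_length, n_segments,
           n_channels) <= 0:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng(seed)
    n_sources = max(2, n_channels // 2)
    # fixed per-class mixing matrices (drawn once from the seeded stream)
    mixes = [rng.standard_normal((n_sources, n_channels)) / np.sqrt(n_sources)
             for _ in (0, 1)]
    # make class 1 visibly different: emphasise a low-rank common component
    mixes[1] = mixes[1] + 0.8 * np.outer(np.ones(n_sources) / n_sources,
                                         rng.standard_normal(n_channels))
    segs, labels = [], []
    for label in (0, 1):
        for _ in range(n_subjects_per_class * n_segments):
            src = np.stack([_ar2_background(segment_length, rng)
                            for _ in range(n_sources)], axis=1)
            segs.append(src @ mixes[label])
            labels.append(label)
    segments = np.stack(segs)
    if n_channels == 1:
        pass  # keep trailing channel axis; .flat squeezes when consumed
    return EEGSegmentSet(segments, np.array(labels), n_channels,
                         meta={"generator": "multichannel_like", "seed": seed,
                               "n_subjects_per_class": n_subjects_per_class})


def segment_recording(rec: Recording, n_chunks: int = BONN_N_CHUNKS
                      ) -> EEGSegmentSet:
    """Split a recording into ``n_chunks`` equal-length contiguous segments.

    Segment length is floor(L / n_chunks); trailing remainder samples are
    discarded (4097 samples -> 23 chunks of 178, dropping 3).  Every
    segment inherits the recording's class label.
    """
    if n_chunks <= 0:
        raise ValueError("n_chunks must be positive")
    n = rec.samples.size
    if n_chunks > n:
        raise ValueError(f"n_chunks={n_chunks} exceeds recording length {n}")
    seg_len = n // n_chunks
    segments = rec.samples[: n_chunks * seg_len].reshape(n_chunks, seg_len)
    labels = np.full(n_chunks, rec.class_label)
    return EEGSegmentSet(segments.copy(), labels,
                         meta={"source_label": rec.source_label,
                               "segment_length": seg_len})


def pool_segments(sets: list[EEGSegmentSet]) -> EEGSegmentSet:
    """Concatenate segment sets (same segment shape) into one pool."""
    if not sets:
        raise ValueError("nothing to pool")
    segments = np.concatenate([s.segments for s in sets])
    labels = np.concatenate([s.labels for s in sets])
    return EEGSegmentSet(segments, labels, sets[0].channel_count,
                         meta={"pooled_from": len(sets)})


def zscore_segments(x: np.ndarray) -> np.ndarray:
    """Per-segment (row-wise) z-score; constant rows map to zero."""
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=tuple(range(1, x.ndim)), keepdims=True)
    sd = x.std(axis=tuple(range(1, x.ndim)), keepdims=True)
    return (x - mu) / np.maximum(sd, 1e-12)


def save_segment_set(dataset: EEGSegmentSet, path) -> None:
    """Write a segment set as ``segments.npz`` + a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path / "segments.npz", segments=dataset.segments)
    sidecar = {"labels": dataset.labels.tolist(),
               "channel_count": int(dataset.channel_count),
               "meta": dataset.meta, "schema_version": 1}
    (path / "segments.json").write_text(json.dumps(sidecar))


def load_segment_set(path) -> EEGSegmentSet:
    path = Path(path)
    with np.load(path / "segments.npz") as npz:
        segments = npz["segments"]
    sidecar = json.loads((path / "segments.json").read_text())
    return EEGSegmentSet(segments, np.array(sidecar["labels"]),
                         sidecar["channel_count"], sidecar.get("meta", {}))
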