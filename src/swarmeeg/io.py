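"""Readers for the study's data formats and feature persistence.

* Bonn-style plain text: one sample per line, 4097 lines per recording,
  sampled at 173.61 Hz.
* European Data Format (EDF): multichannel clinical EEG.  Reading is
  delegated to mne; a minimal 16-bit EDF *writer* is provided for
  round-trip fixtures (no installed package writes EDF).
* Feature matrices: lossless ``.npz`` bundle + JSON sidecar with labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthetic import BONN_SAMPLING_RATE_HZ, Recording

__all__ = ["FormatError", "DatasetManifest", "ManifestEntry",
           "read_bonn_text", "read_edf", "write_edf", "save_features",
           "load_features"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    set_label: str
    class_label: int


@dataclass
class DatasetManifest:
    """Index of an on-disk dataset: entries plus their storage format."""

    entries: list[ManifestEntry] = field(default_factory=list)
    format: str = "bonn_text"
    sampling_rate_hz: float = BONN_SAMPLING_RATE_HZ
    seed: int | None = None

    _FORMATS = ("bonn_text", "matrix_bundle", "edf")

    def __post_init__(self):
        if self.format not in self._FORMATS:
            raise ValueError(f"format must be one of {self._FORMATS}")
        paths = [e.path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths must be unique")

    def save(self, directory) -> None:
        payload = {"format": self.format,
                   "sampling_rate_hz": self.sampling_rate_hz,
                   "seed": self.seed,
                   "entries": [vars(e) for e in self.entries]}
        (Path(directory) / "manifest.json").write_text(
            json.dumps(payload, indent=2))

    @classmethod
    def load(cls, directory) -> "DatasetManifest":
        path = Path(directory) / "manifest.json"
        try:
            payload = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise FormatError(f"{path}: unreadable manifest ({exc})") \
                from exc
        entries = [ManifestEntry(e["path"], e["set_label"],
                                 int(e["class_label"]))
                   for e in payload.get("entries", [])]
        return cls(entries, payload.get("format", "bonn_text"),
                   payload.get("sampling_rate_hz", BONN_SAMPLING_RATE_HZ),
                   payload.get("seed"))


def read_bonn_text(path, source_label: str | None = None) -> Recording:
    """Read a one-sample-per-line text recording (Bonn distribution style).

    Tolerates Windows/Unix line endings and trailing blank lines.  The
    sampling rate is fixed at 173.61 Hz, the rate of the source data.
    """
    path = Path(path)
    samples = []
    with open(path, "r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                samples.append(float(text))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: cannot parse {text!r} as a "
                    "number") from None
    if not samples:
        raise FormatError(f"{path}: no samples found")
    if source_label is None:
        source_label = path.stem[:1].upper() if path.stem[:1].upper() in \
            "ABCDE" else "synthetic-class0"
    return Recording(np.array(samples), BONN_SAMPLING_RATE_HZ, source_label)


def read_edf(path) -> list[Recording]:
    """Read an EDF file into one Recording per channel.

    Channel labels are preserved in ``source_label``; the file's sampling
    rate is used.  Malformed files raise :class:`FormatError`.
    """
    import mne  # deferred: mne import is slow and only needed for EDF

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc
    fs = float(raw.info["sfreq"])
    data = raw.get_data()  # channels x samples, in volts for EEG channels
    return [Recording(data[i], fs, raw.ch_names[i])
            for i in range(data.shape[0])]


def write_edf(path, signals: np.ndarray, sampling_rate_hz: float,
              channel_labels: list[str] | None = None,
              physical_range: tuple[float, float] | None = None) -> None:
    """Write a minimal single-record EDF file (16-bit quantization).

    Intended for creating small test fixtures; supports one data record
    holding the full signal per channel and no annotations.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    n_ch, n_samp = signals.shape
    if channel_labels is None:
        channel_labels = [f"CH{i + 1}" for i in range(n_ch)]
    if physical_range is None:
        span = np.abs(signals).max()
        span = float(span) if span > 0 else 1.0
        physical_range = (-span, span)
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    record_duration = n_samp / sampling_rate_hz

    def fixed(text, width):
        return f"{text:<{width}}"[:width].encode("ascii")

    header = b"".join([
        fixed("0", 8), fixed("X X X X", 80), fixed("X X X", 80),
        fixed("01.01.00", 8), fixed("00.00.00", 8),
        fixed(str(256 * (n_ch + 1)), 8), fixed("", 44),
        fixed("1", 8), fixed(f"{record_duration:.6g}", 8), fixed(str(n_ch), 4),
    ])
    per_sig = b"".join([
        b"".join(fixed(lbl, 16) for lbl in channel_labels),
        b"".join(fixed("", 80) for _ in range(n_ch)),
        b"".join(fixed("uV", 8) for _ in range(n_ch)),
        b"".join(fixed(f"{pmin:.6g}", 8) for _ in range(n_ch)),
        b"".join(fixed(f"{pmax:.6g}", 8) for _ in range(n_ch)),
        b"".join(fixed(str(dmin), 8) for _ in range(n_ch)),
        b"".join(fixed(str(dmax), 8) for _ in range(n_ch)),
        b"".join(fixed("", 80) for _ in range(n_ch)),
        b"".join(fixed(str(n_samp), 8) for _ in range(n_ch)),
        b"".join(fixed("", 32) for _ in range(n_ch)),
    ])
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.round((signals - pmin) / gain + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + per_sig)
        fh.write(digital.tobytes())  # record-major == channel-major here


def save_features(matrix: np.ndarray, labels: np.ndarray, path) -> None:
    """Persist a feature matrix + labels losslessly (npz + JSON sidecar)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    labels = np.asarray(labels)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError("matrix must be 2-D and non-empty")
    if matrix.shape[0] != labels.shape[0]:
        raise ValueError("labels length must equal matrix row count")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path.with_suffix(".npz"), features=matrix)
    sidecar = {"labels": labels.tolist(), "n_rows": int(matrix.shape[0]),
               "n_cols": int(matrix.shape[1]), "schema_version": 1}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_features(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        matrix = npz["features"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    labels = np.array(sidecar["labels"])
    if matrix.shape != (sidecar["n_rows"], sidecar["n_cols"]):
        raise FormatError(f"{path}: sidecar/matrix shape mismatch")
    return matrix, labels
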