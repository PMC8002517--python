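"""Signal conditioning: common average referencing, Butterworth band-pass
filtering and static overlapped segmentation.

The processing order follows the pipeline definition: channel selection,
CAR, band-pass, segmentation.  Both filtering variants share one
Butterworth design (second-order sections for numerical stability); the
causal variant applies it in a single forward pass, the zero-phase variant
forward and backward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "SegmentSet",
    "car_filter",
    "bandpass",
    "segment",
    "segment_count",
    "load_edf",
]


@dataclass
class EEGRecording:
    """One subject's multichannel recording.

    ``samples`` is an (H, fs*V) array, one row per channel.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    subject_label: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channel_labels)} channel labels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration V in seconds."""
        return self.n_samples / self.sampling_rate

    def select_channels(self, labels) -> "EEGRecording":
        """Subset (and reorder) channels by label."""
        labels = tuple(labels)
        missing = [l for l in labels if l not in self.channel_labels]
        if missing:
            raise KeyError(f"channel label(s) not in recording: {missing}")
        idx = [self.channel_labels.index(l) for l in labels]
        return EEGRecording(
            samples=self.samples[idx],
            sampling_rate=self.sampling_rate,
            channel_labels=labels,
            subject_label=self.subject_label,
        )


@dataclass
class SegmentSet:
    """All complete overlapped windows of one recording.

    ``segments`` is an (N, H, v*fs) array; every window is full length.
    """

    segments: np.ndarray
    subject_label: int
    channel_labels: tuple[str, ...] = ()
    sampling_rate: float = float("nan")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


def car_filter(rec: EEGRecording) -> EEGRecording:
    """Common average referencing: subtract the instantaneous cross-channel
    mean from every channel.

    The output's column sums are zero; re-applying the filter is a no-op
    (it is a projection).
    """
    if rec.n_channels < 2:
        raise ValueError("CAR needs at least 2 channels")
    mean = rec.samples.mean(axis=0, keepdims=True)
    return EEGRecording(
        samples=rec.samples - mean,
        sampling_rate=rec.sampling_rate,
        channel_labels=rec.channel_labels,
        subject_label=rec.subject_label,
    )


def butter_sos(order: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Band-pass Butterworth design in second-order sections."""
    low, high = band
    nyq = fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < {nyq}")
    if order < 1:
        raise ValueError(f"filter order must be >= 1, got {order}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # SOS poles must all be inside the unit circle; flag a bad design
    # instead of silently returning garbage.
    for section in sos:
        poles = np.roots(section[3:])
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(
                f"unstable Butterworth design for order={order}, band={band}, fs={fs}"
            )
    return sos


def bandpass(
    rec: EEGRecording,
    order: int,
    band: tuple[float, float],
    variant: str = "causal",
) -> EEGRecording:
    """Butterworth band-pass, causal or zero-phase.

    ``causal`` runs the designed filter once forward (transients are kept
    as-is); ``zero_phase`` runs the same design forward and backward,
    doubling the effective attenuation and cancelling phase distortion.
    """
    sos = butter_sos(order, band, rec.sampling_rate)
    if variant == "causal":
        filtered = signal.sosfilt(sos, rec.samples, axis=1)
    elif variant == "zero_phase":
        filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    else:
        raise ValueError(f"filter variant must be 'causal' or 'zero_phase', got {variant!r}")
    return EEGRecording(
        samples=np.asarray(filtered),
        sampling_rate=rec.sampling_rate,
        channel_labels=rec.channel_labels,
        subject_label=rec.subject_label,
    )


def segment_count(duration: float, seg_len: float, overlap: float) -> int:
    """Number of complete windows: N = floor((V - v) / (v*(1-alpha))) + 1.

    Only windows that fit entirely in the signal are counted, so a
    fractional trailing window is dropped rather than padded.
    """
    hop = seg_len * (1.0 - overlap)
    if hop <= 0:
        raise ValueError("hop v*(1-alpha) must be positive")
    if seg_len > duration:
        raise ValueError(f"segment length {seg_len}s exceeds duration {duration}s")
    # guard against float fuzz at exact multiples, e.g. (60-5)/3
    return int(np.floor((duration - seg_len) / hop + 1e-9)) + 1


def segment(rec: EEGRecording, seg_len: float, overlap: float) -> SegmentSet:
    """Static overlapped segmentation into windows of ``seg_len`` seconds
    with overlap fraction ``overlap``; incomplete trailing windows are
    dropped.
    """
    fs = rec.sampling_rate
    if not (0.0 <= overlap < 1.0):
        raise ValueError(f"overlap must lie in [0, 1), got {overlap}")
    win = seg_len * fs
    if abs(win - round(win)) > 1e-9:
        raise ValueError(
            f"segment length {seg_len}s times sampling rate {fs}Hz is not a whole "
            "number of samples; choose v so that v*fs is an integer"
        )
    win = int(round(win))
    hop = seg_len * (1.0 - overlap) * fs
    if abs(hop - round(hop)) > 1e-9:
        raise ValueError(
            f"hop v*(1-alpha)*fs = {hop} samples is not an integer; choose v and "
            "alpha so that the hop is a whole number of samples"
        )
    hop = int(round(hop))
    if hop <= 0:
        raise ValueError("hop must be a positive number of samples")
    if win > rec.n_samples:
        raise ValueError(
            f"segment of {win} samples does not fit in a recording of {rec.n_samples}"
        )
    starts = range(0, rec.n_samples - win + 1, hop)
    segments = np.stack([rec.samples[:, s : s + win] for s in starts])
    return SegmentSet(
        segments=segments,
        subject_label=rec.subject_label,
        channel_labels=rec.channel_labels,
        sampling_rate=fs,
    )


def load_edf(path: str | Path, subject_label: int, channels=None) -> EEGRecording:
    """Read one EDF file into an :class:`EEGRecording` (requires ``mne``).

    Channel labels are normalised by stripping trailing dots (the
    convention in the PhysioNet motor-imagery archive).  ``channels``
    optionally restricts and orders the channel set.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF files requires the optional dependency 'mne' "
            "(pip install eegident[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(name.strip().rstrip(".") for name in raw.ch_names)
    rec = EEGRecording(
        samples=raw.get_data(),
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        subject_label=subject_label,
    )
    if channels is not None:
        rec = rec.select_channels(channels)
    return rec
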