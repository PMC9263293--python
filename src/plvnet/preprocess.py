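"""Band decomposition and epoch segmentation of multichannel recordings.

A recording is filtered as one continuous block (zero-phase, so that
phase-based connectivity downstream is not distorted by filter lag) and only
then cut into non-overlapping epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .errors import (
    InvalidParameterError,
    MontageError,
    RecordingLengthError,
)

__all__ = [
    "EEGRecording",
    "BandDefinition",
    "BANDS",
    "EpochSet",
    "Montage",
    "DEFAULT_MONTAGE",
    "bandpass",
    "segment",
    "normalize_label",
]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class EEGRecording:
    """A channels x samples block of EEG with its sampling rate and labels.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_samples)`` in microvolts.
    sampling_rate_hz
        Sampling rate in Hz.
    channel_labels
        Ordered 10-20 channel names, one per row of ``data``.
    subject_id
        Free-form subject identifier.
    """

    data: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("recording contains NaN or Inf")
        if self.data.shape[0] != len(self.channel_labels):
            raise InvalidParameterError(
                f"{self.data.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        if self.sampling_rate_hz <= 0:
            raise InvalidParameterError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise InvalidParameterError(
                f"band {self.name!r}: need 0 < low < high, "
                f"got ({self.low_hz}, {self.high_hz})"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)


#: Canonical EEG sub-bands.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
}


@dataclass
class EpochSet:
    """Non-overlapping equal-length epochs cut from one recording."""

    epochs: list[np.ndarray]
    epoch_length_s: float
    sampling_rate_hz: float
    channel_labels: list[str]
    band: BandDefinition | None = None
    subject_id: str = ""
    start_samples: list[int] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

_LOBE_MAP = {
    "frontal": ["FP1", "FP2", "F7", "F8", "F3", "F4", "FZ", "FC3", "FCz", "FC4"],
    "parietal": ["CP3", "CPz", "CP4", "P3", "Pz", "P4"],
    "temporal": ["FT7", "FT8", "T3", "T4", "TP7", "TP8", "T5", "T6"],
    "occipital": ["O1", "OZ", "O2"],
    "central": ["C3", "Cz", "C4"],
}


@dataclass
class Montage:
    """Ordered channel list plus a channel -> lobe partition.

    Lobe sets must be disjoint and cover every channel; unknown labels map to
    ``"unassigned"`` via :meth:`lobe_of`.
    """

    channels: list[str]
    lobes: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for lobe, labels in self.lobes.items():
            for lab in labels:
                if lab in seen:
                    raise MontageError(
                        f"channel {lab} assigned to both {seen[lab]} and {lobe}"
                    )
                seen[lab] = lobe
        missing = [c for c in self.channels if c not in seen]
        if missing:
            raise MontageError(f"channels without a lobe: {missing}")
        extra = [c for c in seen if c not in self.channels]
        if extra:
            raise MontageError(f"lobe map labels not in channel list: {extra}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def lobe_of(self, label: str) -> str:
        canon = normalize_label(label, self.channels)
        for lobe, labels in self.lobes.items():
            if canon in labels:
                return lobe
        return "unassigned"

    def subset(self, labels: Sequence[str]) -> "Montage":
        """Montage restricted to ``labels`` (order preserved)."""
        keep = set(labels)
        return Montage(
            channels=[c for c in self.channels if c in keep],
            lobes={
                lobe: [c for c in chans if c in keep]
                for lobe, chans in self.lobes.items()
            },
        )


DEFAULT_MONTAGE = Montage(
    channels=[c for labs in _LOBE_MAP.values() for c in labs],
    lobes={k: list(v) for k, v in _LOBE_MAP.items()},
)


def normalize_label(label: str, canonical: Sequence[str] | None = None) -> str:
    """Map a channel label to its canonical spelling, case-insensitively.

    Labels with no canonical match are returned stripped but otherwise
    untouched (the caller decides whether to warn).
    """
    pool = canonical if canonical is not None else DEFAULT_MONTAGE.channels
    stripped = label.strip()
    for canon in pool:
        if canon.upper() == stripped.upper():
            return canon
    return stripped


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def bandpass(
    recording: EEGRecording,
    band: BandDefinition,
    order: int = 4,
    pre_clean: Callable[[np.ndarray], np.ndarray] | None = None,
) -> EEGRecording:
    """Zero-phase band-pass filter applied to the full continuous record.

    A forward-backward order-``order`` Butterworth filter (doubling the
    effective order and cancelling phase lag). Output shape equals input
    shape. ``pre_clean``, if given, is applied to the raw data matrix before
    filtering (hook for artifact removal; not implemented here).
    """
    nyquist = recording.sampling_rate_hz / 2.0
    if band.high_hz >= nyquist:
        raise InvalidParameterError(
            f"band {band.name!r} upper edge {band.high_hz} Hz >= "
            f"Nyquist {nyquist} Hz"
        )
    data = recording.data
    if pre_clean is not None:
        data = np.asarray(pre_clean(data), dtype=float)
        if data.shape != recording.data.shape:
            raise InvalidParameterError("pre_clean must preserve shape")
    sos = signal.butter(
        order,
        [band.low_hz, band.high_hz],
        btype="bandpass",
        fs=recording.sampling_rate_hz,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, data, axis=1)
    return EEGRecording(
        data=filtered,
        sampling_rate_hz=recording.sampling_rate_hz,
        channel_labels=list(recording.channel_labels),
        subject_id=recording.subject_id,
    )


def segment(
    recording: EEGRecording,
    epoch_length_s: float = 15.0,
    n_epochs: int = 8,
    seed: int | None = None,
    contiguous: bool = False,
    edge_trim_s: float = 1.0,
) -> EpochSet:
    """Cut ``n_epochs`` non-overlapping epochs out of a recording.

    Epoch start offsets are drawn uniformly at random without overlap
    (deterministic given ``seed``) and returned sorted by start time.  With
    ``contiguous=True`` epochs are packed back-to-back from the start of the
    usable range instead.  ``edge_trim_s`` seconds at each end of the record
    are excluded to avoid filter edge transients.
    """
    if n_epochs < 1:
        raise InvalidParameterError("n_epochs must be >= 1")
    if epoch_length_s <= 0:
        raise InvalidParameterError("epoch_length_s must be positive")
    fs = recording.sampling_rate_hz
    epoch_len = int(round(epoch_length_s * fs))
    trim = int(round(edge_trim_s * fs))
    usable = recording.n_samples - 2 * trim
    if usable < n_epochs * epoch_len:
        # retry without the edge trim before giving up
        if recording.n_samples >= n_epochs * epoch_len:
            trim = 0
            usable = recording.n_samples
        else:
            raise RecordingLengthError(
                f"need {n_epochs} x {epoch_len} = {n_epochs * epoch_len} "
                f"samples, have {recording.n_samples}"
            )

    slack = usable - n_epochs * epoch_len
    if contiguous or slack == 0:
        gaps = np.zeros(n_epochs, dtype=int)
    else:
        rng = np.random.default_rng(seed)
        # distribute `slack` spare samples into n_epochs+1 gaps uniformly
        cuts = np.sort(rng.integers(0, slack + 1, size=n_epochs))
        gaps = np.diff(np.concatenate([[0], cuts]))
    starts = []
    pos = trim
    for k in range(n_epochs):
        pos += int(gaps[k])
        starts.append(pos)
        pos += epoch_len
    epochs = [recording.data[:, s : s + epoch_len].copy() for s in starts]
    return EpochSet(
        epochs=epochs,
        epoch_length_s=epoch_length_s,
        sampling_rate_hz=fs,
        channel_labels=list(recording.channel_labels),
        subject_id=recording.subject_id,
        start_samples=starts,
    )
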