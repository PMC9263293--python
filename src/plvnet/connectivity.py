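"""Instantaneous phase and phase-locking-value (PLV) matrices.

PLV between two phase series is the modulus of the time-averaged unit
phasor of their phase difference,

    PLV = sqrt(<cos dphi>^2 + <sin dphi>^2),

which is 1 for perfectly locked phases and approaches 0 for independent
uniform phases.  Phase is taken from the analytic signal (Hilbert
transform) of each band-limited channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .errors import InvalidParameterError, UndefinedPhaseError
from .preprocess import BandDefinition, EpochSet

__all__ = ["PLVMatrix", "instantaneous_phase", "plv", "plv_matrix"]

#: fraction of samples trimmed at each epoch edge before PLV, to suppress
#: Hilbert edge effects
DEFAULT_EDGE_TRIM = 0.05


@dataclass
class PLVMatrix:
    """Symmetric N x N phase-synchronization matrix for one subject/band.

    ``mask`` flags undefined entries (pairs involving a zero-variance
    channel in any epoch); thresholding ranks masked entries last.
    """

    values: np.ndarray
    channel_labels: list[str]
    band: BandDefinition | None = None
    subject_id: str = ""
    n_epochs_used: int = 0
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidParameterError("PLV matrix must be square")
        if self.mask is None:
            self.mask = np.zeros(v.shape, dtype=bool)
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    # -- serialization ------------------------------------------------------

    def write(self, path: str | Path) -> Path:
        """Write as a labelled TSV matrix plus a JSON sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("channel\t" + "\t".join(self.channel_labels) + "\n")
            for lab, row in zip(self.channel_labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
        sidecar = {
            "subject_id": self.subject_id,
            "band": self.band.name if self.band else None,
            "n_epochs_used": self.n_epochs_used,
            "masked_entries": [
                [int(i), int(j)]
                for i, j in zip(*np.nonzero(np.triu(self.mask, 1)))
            ],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
        )
        return path

    @classmethod
    def read(cls, path: str | Path) -> "PLVMatrix":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
        values = np.array(rows)
        mask = np.zeros(values.shape, dtype=bool)
        band = None
        subject_id = ""
        n_epochs = 0
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            subject_id = meta.get("subject_id", "")
            n_epochs = meta.get("n_epochs_used", 0)
            from .preprocess import BANDS

            band = BANDS.get(meta.get("band") or "")
            for i, j in meta.get("masked_entries", []):
                mask[i, j] = mask[j, i] = True
        return cls(
            values=values,
            channel_labels=header,
            band=band,
            subject_id=subject_id,
            n_epochs_used=n_epochs,
            mask=mask,
        )


def instantaneous_phase(signal: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal, in radians.

    Raises :class:`UndefinedPhaseError` for constant (zero-variance) input,
    where phase carries no information.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidParameterError("signal must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("signal contains NaN or Inf")
    if np.ptp(x) == 0:
        raise UndefinedPhaseError("constant signal has no defined phase")
    return np.angle(hilbert(x))


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLV of two equal-length phase series."""
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError(
            f"phase series shapes differ: {a.shape} vs {b.shape}"
        )
    if a.size < 1:
        raise InvalidParameterError("empty phase series")
    d = a - b
    return float(np.hypot(np.cos(d).mean(), np.sin(d).mean()))


def _epoch_plv(
    epoch: np.ndarray, trim: float
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs PLV for one channels x samples epoch.

    Returns the PLV matrix and a boolean vector flagging zero-variance
    (phase-undefined) channels.
    """
    n_ch, n_s = epoch.shape
    dead = np.ptp(epoch, axis=1) == 0
    phases = np.zeros((n_ch, n_s))
    live = ~dead
    if live.any():
        phases[live] = np.angle(hilbert(epoch[live], axis=1))
    k = int(round(trim * n_s))
    sl = slice(k, n_s - k) if n_s - 2 * k >= 2 else slice(None)
    z = np.exp(1j * phases[:, sl])
    m = np.abs(z @ z.conj().T) / z.shape[1]
    return np.clip(m, 0.0, 1.0), dead


def plv_matrix(
    epoch_set: EpochSet,
    edge_trim: float = DEFAULT_EDGE_TRIM,
    concatenate: bool = False,
) -> PLVMatrix:
    """PLV matrix of an epoch set.

    Per-epoch PLV matrices are averaged arithmetically across epochs
    (``concatenate=True`` instead computes one PLV over all epochs joined
    end-to-end).  The diagonal is 1; pairs touching a zero-variance channel
    in any epoch are masked.
    """
    if epoch_set.n_epochs < 1:
        raise InvalidParameterError("need at least one epoch")
    shapes = {e.shape for e in epoch_set.epochs}
    if len(shapes) != 1:
        raise InvalidParameterError(f"inconsistent epoch shapes: {shapes}")

    if concatenate:
        epochs = [np.concatenate(epoch_set.epochs, axis=1)]
    else:
        epochs = epoch_set.epochs

    acc = None
    dead_any = None
    for epoch in epochs:
        m, dead = _epoch_plv(np.asarray(epoch, dtype=float), edge_trim)
        acc = m if acc is None else acc + m
        dead_any = dead if dead_any is None else (dead_any | dead)
    values = acc / len(epochs)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    mask = np.zeros(values.shape, dtype=bool)
    if dead_any.any():
        mask[dead_any, :] = True
        mask[:, dead_any] = True
        np.fill_diagonal(mask, False)  # diagonal is 1 by definition
        values[mask] = 0.0
        np.fill_diagonal(values, 1.0)
    return PLVMatrix(
        values=values,
        channel_labels=list(epoch_set.channel_labels),
        band=epoch_set.band,
        subject_id=epoch_set.subject_id,
        n_epochs_used=epoch_set.n_epochs,
        mask=mask,
    )
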