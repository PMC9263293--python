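"""Recording I/O: EDF and delimited numeric matrices.

The EDF codec implements the plain 16-bit EDF layout (fixed-width ASCII
header, little-endian int16 data records) — enough for lossless-to-
quantization round trips of synthetic recordings; EDF+ annotations are not
supported.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, ParseError
from .preprocess import DEFAULT_MONTAGE, EEGRecording, Montage, normalize_label

__all__ = ["read_recording", "write_recording", "edf_quantization_step"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fit(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # trim trailing float digits until it fits
        if "." in s:
            s = s[:width].rstrip(".")
        else:
            raise InvalidParameterError(f"value {value!r} too wide for EDF field")
    return s.ljust(width).encode("ascii")


def _physical_range(channel: np.ndarray) -> tuple[float, float]:
    lo, hi = float(channel.min()), float(channel.max())
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def edf_quantization_step(channel: np.ndarray) -> float:
    """Quantization step the EDF writer will use for one channel's data."""
    lo, hi = _physical_range(np.asarray(channel, dtype=float))
    return (hi - lo) / (_DIG_MAX - _DIG_MIN)


def _write_edf(recording: EEGRecording, path: Path) -> None:
    data = recording.data
    n_ch, n_samples = data.shape
    fs = recording.sampling_rate_hz
    if abs(fs - round(fs)) < 1e-9 and n_samples % int(round(fs)) == 0:
        spr = int(round(fs))  # one-second records
        n_rec = n_samples // spr
        rec_dur = 1.0
    else:
        spr = n_samples
        n_rec = 1
        rec_dur = n_samples / fs

    pmins, pmaxs, digital = [], [], []
    for ch in range(n_ch):
        lo, hi = _physical_range(data[ch])
        scale = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        dig = np.round((data[ch] - lo) * scale + _DIG_MIN)
        digital.append(np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2"))
        pmins.append(lo)
        pmaxs.append(hi)

    header_bytes = 256 + 256 * n_ch
    with open(path, "wb") as fh:
        fh.write(_fit("0", 8))
        fh.write(_fit(recording.subject_id or "X", 80))
        fh.write(_fit("plvnet", 80))
        fh.write(_fit("01.01.00", 8))
        fh.write(_fit("00.00.00", 8))
        fh.write(_fit(header_bytes, 8))
        fh.write(_fit("", 44))
        fh.write(_fit(n_rec, 8))
        fh.write(_fit(rec_dur if rec_dur != int(rec_dur) else int(rec_dur), 8))
        fh.write(_fit(n_ch, 4))
        for lab in recording.channel_labels:
            fh.write(_fit(lab, 16))
        for _ in range(n_ch):
            fh.write(_fit("", 80))  # transducer
        for _ in range(n_ch):
            fh.write(_fit("uV", 8))
        for v in pmins:
            fh.write(_fit(round(v, 4), 8))
        for v in pmaxs:
            fh.write(_fit(round(v, 4), 8))
        for _ in range(n_ch):
            fh.write(_fit(_DIG_MIN, 8))
        for _ in range(n_ch):
            fh.write(_fit(_DIG_MAX, 8))
        for _ in range(n_ch):
            fh.write(_fit("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_fit(spr, 8))
        for _ in range(n_ch):
            fh.write(_fit("", 32))
        for rec in range(n_rec):
            sl = slice(rec * spr, (rec + 1) * spr)
            for ch in range(n_ch):
                fh.write(digital[ch][sl].tobytes())


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ParseError(f"{path}: too short for an EDF header")

    def f(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        n_rec = int(f(236, 8))
        rec_dur = float(f(244, 8))
        n_ch = int(f(252, 4))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed EDF header ({exc})") from exc
    base = 256
    labels = [f(base + 16 * i, 16) for i in range(n_ch)]
    off = base + n_ch * (16 + 80 + 8)
    pmins = [float(f(off + 8 * i, 8)) for i in range(n_ch)]
    off += n_ch * 8
    pmaxs = [float(f(off + 8 * i, 8)) for i in range(n_ch)]
    off += n_ch * 8
    dmins = [int(f(off + 8 * i, 8)) for i in range(n_ch)]
    off += n_ch * 8
    dmaxs = [int(f(off + 8 * i, 8)) for i in range(n_ch)]
    off += n_ch * 8 + n_ch * 80
    sprs = [int(f(off + 8 * i, 8)) for i in range(n_ch)]
    if len(set(sprs)) != 1:
        raise ParseError(f"{path}: per-channel sampling rates not supported")
    spr = sprs[0]
    data_off = 256 + 256 * n_ch
    expected = data_off + n_rec * n_ch * spr * 2
    if len(raw) < expected:
        raise ParseError(f"{path}: truncated data section")

    out = np.empty((n_ch, n_rec * spr), dtype=float)
    pos = data_off
    for rec in range(n_rec):
        for ch in range(n_ch):
            dig = np.frombuffer(raw, dtype="<i2", count=spr, offset=pos)
            pos += spr * 2
            scale = (pmaxs[ch] - pmins[ch]) / (dmaxs[ch] - dmins[ch])
            out[ch, rec * spr : (rec + 1) * spr] = (
                (dig.astype(float) - dmins[ch]) * scale + pmins[ch]
            )
    fs = spr / rec_dur
    return out, fs, labels


# ---------------------------------------------------------------------------
# Delimited matrices: rows = samples, columns = channels, optional label header
# ---------------------------------------------------------------------------


def _write_delimited(recording: EEGRecording, path: Path, sep: str) -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.data.T, delimiter=sep, fmt="%.10g")


def _read_delimited(path: Path, sep: str) -> tuple[np.ndarray, list[str] | None]:
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ParseError(f"{path}: empty file")
        fields = [x.strip() for x in first.rstrip("\n").split(sep)]
        try:
            [float(x) for x in fields]
            labels = None
            skip = 0
        except ValueError:
            labels = fields
            skip = 1
    try:
        mat = np.loadtxt(path, delimiter=sep, skiprows=skip, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: not a numeric matrix ({exc})") from exc
    return mat.T, labels


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    if suffix == ".csv":
        return "csv"
    raise InvalidParameterError(f"cannot infer recording format from {path.name!r}")


def write_recording(
    recording: EEGRecording, path: str | Path, format: str | None = None
) -> Path:
    """Write a recording as EDF (``.edf``) or a delimited matrix.

    Delimited files hold samples as rows and channels as columns, with a
    header row of channel labels.
    """
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "edf":
        _write_edf(recording, path)
    elif fmt in {"tsv", "txt"}:
        _write_delimited(recording, path, "\t")
    elif fmt == "csv":
        _write_delimited(recording, path, ",")
    else:
        raise InvalidParameterError(f"unknown recording format {fmt!r}")
    return path


def read_recording(
    path: str | Path,
    format: str | None = None,
    sampling_rate_hz: float | None = None,
    montage: Montage | None = None,
    subject_id: str | None = None,
) -> EEGRecording:
    """Read a recording from EDF or a delimited matrix.

    Labels are normalized to canonical 10-20 spellings case-insensitively;
    labels with no canonical counterpart trigger a warning and are kept
    (their lobe is "unassigned"). Delimited files carry no sampling rate, so
    ``sampling_rate_hz`` is required for them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _guess_format(path)
    montage = montage or DEFAULT_MONTAGE

    if fmt == "edf":
        data, fs, labels = _read_edf(path)
    elif fmt in {"tsv", "txt", "csv"}:
        if sampling_rate_hz is None:
            raise InvalidParameterError(
                "sampling_rate_hz is required for delimited recordings"
            )
        data, labels = _read_delimited(path, "\t" if fmt != "csv" else ",")
        fs = sampling_rate_hz
        if labels is None:
            labels = [f"CH{i + 1}" for i in range(data.shape[0])]
    else:
        raise InvalidParameterError(f"unknown recording format {fmt!r}")

    canon = []
    for lab in labels:
        c = normalize_label(lab, montage.channels)
        if c not in montage.channels:
            warnings.warn(
                f"{path.name}: unknown channel label {lab!r}; "
                f"retained with lobe 'unassigned'",
                stacklevel=2,
            )
        canon.append(c)
    if len(canon) != montage.n_channels:
        warnings.warn(
            f"{path.name}: {len(canon)} channels, montage expects "
            f"{montage.n_channels}; continuing with N = {len(canon)}",
            stacklevel=2,
        )
    return EEGRecording(
        data=data,
        sampling_rate_hz=fs,
        channel_labels=canon,
        subject_id=subject_id if subject_id is not None else path.stem,
    )
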