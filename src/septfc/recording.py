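"""Averaged SEP recordings: data model, file I/O, sweep averaging, bandpass filtering.

A somatosensory evoked potential (SEP) recording is a single stimulus-aligned
voltage trace (microvolts) obtained by averaging a few hundred stimulus-locked
sweeps. The canonical epoch used throughout this package is 0-100 ms
post-stimulus sampled at 10 kHz, which covers all component latencies of
interest and satisfies Nyquist for the 10-2000 Hz recording band.

The primary on-disk format is delimited text (one voltage per line) with a
key-value sidecar carrying the acquisition metadata; EDF files can be read
through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Condition",
    "SEPRecording",
    "ValidationError",
    "FormatError",
    "read_recording",
    "write_recording",
    "average_sweeps",
    "bandpass_filter",
    "bandpass_array",
    "DEFAULT_SAMPLING_RATE",
    "DEFAULT_EPOCH_MS",
]

#: canonical sampling rate (Hz) for synthesized / resampled epochs
DEFAULT_SAMPLING_RATE = 10_000.0
#: canonical epoch length (ms post-stimulus)
DEFAULT_EPOCH_MS = 100.0


class ValidationError(ValueError):
    """A recording or argument violates a documented invariant."""


class FormatError(ValueError):
    """A file could not be parsed in the declared format."""


class Condition(str, Enum):
    """Experimental condition of a recording (closed set)."""

    NORMAL = "normal"
    SHAM = "sham"
    C4 = "C4"
    C5 = "C5"
    C6 = "C6"
    UNKNOWN = "unknown"

    @classmethod
    def coerce(cls, value: "str | Condition") -> "Condition":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError as exc:
            raise ValidationError(
                f"unknown condition {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from exc


@dataclass
class SEPRecording:
    """One averaged, stimulus-aligned SEP voltage trace with metadata.

    Parameters
    ----------
    samples
        Voltage series in microvolts, first sample at ``t0_offset_ms``
        relative to stimulus onset.
    sampling_rate
        Sampling rate in Hz. Must exceed twice the bandpass high edge.
    t0_offset_ms
        Time of the first sample relative to stimulus onset (ms).
    n_sweeps_averaged
        Number of stimulus-locked sweeps averaged into this trace
        (0 when unknown).
    bandpass
        ``(low_hz, high_hz)`` of the acquisition filter, or None when unknown.
    condition
        One of :class:`Condition`.
    subject_id
        Opaque subject identifier.
    """

    samples: np.ndarray
    sampling_rate: float
    t0_offset_ms: float = 0.0
    n_sweeps_averaged: int = 0
    bandpass: tuple[float, float] | None = None
    condition: Condition = Condition.UNKNOWN
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("samples must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if not (self.sampling_rate > 0 and math.isfinite(self.sampling_rate)):
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.bandpass is not None:
            low, high = self.bandpass
            if not (0 < low < high):
                raise ValidationError(f"invalid bandpass {self.bandpass}")
            if self.sampling_rate <= 2 * high:
                raise ValidationError(
                    f"sampling_rate {self.sampling_rate} Hz is not Nyquist-consistent "
                    f"with bandpass high edge {high} Hz"
                )
            self.bandpass = (float(low), float(high))
        self.condition = Condition.coerce(self.condition)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        """Epoch duration in ms (n / rate)."""
        return self.n_samples / self.sampling_rate * 1e3

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms post-stimulus."""
        return self.t0_offset_ms + np.arange(self.n_samples) / self.sampling_rate * 1e3

    def copy_with(self, **changes) -> "SEPRecording":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# file I/O

_SIDECAR_SUFFIX = ".meta"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDECAR_SUFFIX)


def write_recording(rec: SEPRecording, path: "str | Path") -> None:
    """Write a recording as delimited text plus a ``<path>.meta`` sidecar.

    Values are written with 10 significant digits so a read-back round trip
    is lossless at that precision.
    """
    path = Path(path)
    np.savetxt(path, rec.samples, fmt="%.10g")
    meta = {
        "sampling_rate": f"{rec.sampling_rate:.10g}",
        "t0_offset_ms": f"{rec.t0_offset_ms:.10g}",
        "n_sweeps_averaged": str(rec.n_sweeps_averaged),
        "condition": rec.condition.value,
        "subject_id": rec.subject_id,
    }
    if rec.bandpass is not None:
        meta["bandpass_low"] = f"{rec.bandpass[0]:.10g}"
        meta["bandpass_high"] = f"{rec.bandpass[1]:.10g}"
    with open(_sidecar_path(path), "w") as fh:
        for key, value in meta.items():
            fh.write(f"{key} = {value}\n")


def _read_sidecar(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    if not path.exists():
        return meta
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"malformed sidecar line in {path}: {line!r}")
        key, _, value = line.partition("=")
        meta[key.strip()] = value.strip()
    return meta


def read_recording(path: "str | Path", format: str = "delimited_text") -> SEPRecording:
    """Read a recording from disk.

    ``delimited_text`` expects one voltage value (µV) per line with metadata
    in a ``<path>.meta`` sidecar; missing optional metadata falls back to
    unknown/0/none with a logged warning. ``edf`` reads the first signal
    channel of a European Data Format file via :mod:`mne` (optional extra).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited_text":
        return _read_delimited(path)
    if format == "edf":
        return _read_edf(path)
    raise ValidationError(f"unknown format {format!r}")


def _read_delimited(path: Path) -> SEPRecording:
    try:
        samples = np.loadtxt(path, dtype=float, ndmin=1)
    except ValueError as exc:
        raise FormatError(f"unparsable voltage values in {path}: {exc}") from exc
    meta = _read_sidecar(_sidecar_path(path))
    if "sampling_rate" not in meta:
        raise FormatError(f"sidecar for {path} is missing sampling_rate")
    try:
        sampling_rate = float(meta["sampling_rate"])
    except ValueError as exc:
        raise FormatError(f"bad sampling_rate in sidecar for {path}") from exc
    if sampling_rate <= 0:
        raise ValidationError(f"sampling_rate must be > 0, got {sampling_rate}")

    missing = [k for k in ("condition", "n_sweeps_averaged", "bandpass_low") if k not in meta]
    if missing:
        logger.warning("sidecar for %s missing optional keys %s; using defaults", path, missing)
    bandpass = None
    if "bandpass_low" in meta and "bandpass_high" in meta:
        bandpass = (float(meta["bandpass_low"]), float(meta["bandpass_high"]))
    return SEPRecording(
        samples=samples,
        sampling_rate=sampling_rate,
        t0_offset_ms=float(meta.get("t0_offset_ms", 0.0)),
        n_sweeps_averaged=int(meta.get("n_sweeps_averaged", 0)),
        bandpass=bandpass,
        condition=meta.get("condition", Condition.UNKNOWN),
        subject_id=meta.get("subject_id", ""),
    )


def _read_edf(path: Path) -> SEPRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF support requires the optional 'mne' dependency (pip install septfc[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0]
    unit_scale = 1e6  # mne returns SI volts; recordings are expressed in µV
    return SEPRecording(
        samples=data * unit_scale,
        sampling_rate=float(raw.info["sfreq"]),
        condition=Condition.UNKNOWN,
        subject_id=path.stem,
    )


# ---------------------------------------------------------------------------
# sweep averaging and filtering


def average_sweeps(sweeps) -> np.ndarray:
    """Pointwise arithmetic mean of equal-length stimulus-locked sweeps.

    Averaging n independent noise sweeps reduces the noise standard deviation
    by a factor 1/sqrt(n), which is the reason evoked potentials are recorded
    as a few-hundred-sweep average in the first place.
    """
    sweeps = list(sweeps)
    if len(sweeps) == 0:
        raise ValidationError("average_sweeps requires at least one sweep")
    lengths = {np.asarray(s).shape for s in sweeps}
    if len(lengths) != 1 or len(next(iter(lengths))) != 1:
        raise ValidationError(f"sweeps must be 1-D and equal-length, got shapes {lengths}")
    return np.mean(np.asarray(sweeps, dtype=float), axis=0)


def bandpass_array(x: np.ndarray, sampling_rate: float, low: float, high: float) -> np.ndarray:
    """Zero-phase spectral bandpass of a 1-D array.

    Implemented in the frequency domain (bins outside [low, high] zeroed),
    which makes the operation exactly idempotent, delay-free and
    unit-gain in band — component latencies and amplitudes are downstream
    classification features, so the filter must not shift or scale them.
    """
    spectrum = np.fft.rfft(np.asarray(x, dtype=float))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / sampling_rate)
    spectrum[(freqs < low) | (freqs > high)] = 0.0
    return np.fft.irfft(spectrum, n=len(x))


def bandpass_filter(rec: SEPRecording, low: float, high: float) -> SEPRecording:
    """Zero-phase bandpass; returns a filtered copy with updated metadata."""
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValidationError(
            f"invalid band ({low}, {high}) Hz for sampling rate {rec.sampling_rate} Hz"
        )
    filtered = bandpass_array(rec.samples, rec.sampling_rate, low, high)
    return rec.copy_with(samples=filtered, bandpass=(low, high))
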