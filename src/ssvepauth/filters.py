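"""Digital front end and FBCCA sub-band filter bank.

The front end emulates the amplifier's built-in digital filtering: a
48-52 Hz notch (band-stop) followed by a 2-60 Hz band-pass, both
fourth-order Butterworth designs at 600 Hz.  The FBCCA bank holds the
sub-band band-pass filters: 2-60 / 12-60 / 20-60 Hz for the
low-frequency stimulus set and a single 35-60 Hz band for the
high-frequency set (whose harmonics, starting at 72 Hz, fall outside
the 60 Hz hardware band, so only the fundamental is usable).

Application is zero-phase (forward-backward, ``sosfiltfilt``) on each
buffer snapshot with a fixed reflective pad, so repeated re-evaluation
of a growing buffer is deterministic and delay-free; a causal mode is
available for strictly streaming use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .simulate import EEGSegment

#: fixed forward-backward edge pad (samples); part of the contract so
#: results are bit-reproducible across runs and machines.
PAD_LEN = 27


class BufferTooShortError(ValueError):
    """Buffer shorter than the zero-phase padding requirement."""


@dataclass(frozen=True)
class FilterSpec:
    """A designed IIR filter in second-order-section form."""

    kind: str  # "bandpass" | "bandstop"
    low: float
    high: float
    order: int
    fs: float
    sos: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "bandstop"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if not self.is_stable():
            raise ValueError("designed filter is unstable")

    def is_stable(self) -> bool:
        _, poles, _ = signal.sos2zpk(self.sos)
        return bool(np.all(np.abs(poles) < 1.0))

    def response_db(self, freqs) -> np.ndarray:
        """Magnitude response in dB at ``freqs`` (Hz)."""
        _, h = signal.sosfreqz(self.sos, worN=np.atleast_1d(freqs), fs=self.fs)
        return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))

    def to_dict(self) -> dict:
        return {"kind": self.kind, "low": self.low, "high": self.high,
                "order": self.order, "fs": self.fs,
                "sos": self.sos.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        return cls(d["kind"], d["low"], d["high"], d["order"], d["fs"],
                   np.asarray(d["sos"], dtype=float))


def _validate_band(low: float, high: float, fs: float, order: int) -> None:
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ValueError(f"upper cutoff {high} Hz >= Nyquist {fs / 2} Hz")
    if order < 1:
        raise ValueError("order must be >= 1")


@lru_cache(maxsize=64)
def _design(kind: str, low: float, high: float, fs: float,
            order: int) -> FilterSpec:
    sos = signal.butter(order, [low, high], btype=kind, fs=fs, output="sos")
    return FilterSpec(kind, low, high, order, fs, sos)


def design_bandpass(low: float, high: float, fs: float,
                    order: int = 4) -> FilterSpec:
    """Butterworth band-pass; -3 dB points at ``low`` and ``high``."""
    _validate_band(low, high, fs, order)
    return _design("bandpass", low, high, fs, order)


def design_notch(low: float = 48.0, high: float = 52.0, fs: float = 600.0,
                 order: int = 4) -> FilterSpec:
    """Butterworth band-stop rejecting the 50 Hz mains band."""
    _validate_band(low, high, fs, order)
    return _design("bandstop", low, high, fs, order)


@dataclass(frozen=True)
class SubbandBank:
    """Ordered band-pass sub-bands for filter-bank CCA."""

    subbands: tuple[tuple[float, float], ...]
    fs: float = 600.0
    order: int = 4
    specs: tuple[FilterSpec, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.subbands) < 1:
            raise ValueError("bank needs at least one sub-band")
        specs = tuple(design_bandpass(lo, hi, self.fs, self.order)
                      for lo, hi in self.subbands)
        object.__setattr__(self, "specs", specs)

    def __len__(self) -> int:
        return len(self.subbands)


def low_set_bank(fs: float = 600.0) -> SubbandBank:
    """Three sub-bands keeping the fundamental and 2nd/3rd harmonics
    while progressively suppressing low-frequency background."""
    return SubbandBank(((2.0, 60.0), (12.0, 60.0), (20.0, 60.0)), fs=fs)


def high_set_bank(fs: float = 600.0) -> SubbandBank:
    """Single broad band around the 36-45 Hz fundamentals."""
    return SubbandBank(((35.0, 60.0),), fs=fs)


def _apply_spec(x: np.ndarray, spec: FilterSpec, causal: bool) -> np.ndarray:
    if causal:
        return signal.sosfilt(spec.sos, x, axis=-1)
    if x.shape[-1] <= PAD_LEN:
        raise BufferTooShortError(
            f"buffer of {x.shape[-1]} samples is shorter than the "
            f"zero-phase pad ({PAD_LEN} samples)")
    return signal.sosfiltfilt(spec.sos, x, axis=-1, padtype="even",
                              padlen=PAD_LEN)


def default_front_end(fs: float = 600.0) -> tuple[FilterSpec, FilterSpec]:
    """(notch 48-52 Hz, band-pass 2-60 Hz) at ``fs``."""
    return design_notch(48.0, 52.0, fs), design_bandpass(2.0, 60.0, fs)


def apply_front_end(segment: EEGSegment,
                    specs: tuple[FilterSpec, FilterSpec] | None = None,
                    causal: bool = False) -> EEGSegment:
    """Notch then band-pass, per channel; length-preserving."""
    if specs is None:
        specs = default_front_end(segment.fs)
    for spec in specs:
        if spec.fs != segment.fs:
            raise ValueError(
                f"filter designed at {spec.fs} Hz, segment at {segment.fs} Hz")
    x = segment.samples
    for spec in specs:
        x = _apply_spec(x, spec, causal)
    return EEGSegment(x, segment.fs, segment.onset_index,
                      segment.channel_names)


def apply_subband(buffer: EEGSegment, subband_index: int,
                  bank: SubbandBank, causal: bool = False) -> EEGSegment:
    """Zero-phase sub-band filtering of a buffer snapshot."""
    if not 0 <= subband_index < len(bank):
        raise IndexError(
            f"subband index {subband_index} out of range for bank of "
            f"{len(bank)}")
    spec = bank.specs[subband_index]
    if spec.fs != buffer.fs:
        raise ValueError("bank/segment sampling-rate mismatch")
    x = _apply_spec(buffer.samples, spec, causal)
    return EEGSegment(x, buffer.fs, buffer.onset_index, buffer.channel_names)
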