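"""Synthetic occipital-EEG generation for SSVEP decoding experiments.

The generator produces multichannel signals with the statistical
structure an FBCCA classifier assumes: a steady-state evoked component
at the stimulation frequency and its harmonics, superimposed on 1/f^beta
broadband background noise, an ~10 Hz alpha rhythm, optional 50 Hz line
interference, and per-channel gain differences across an O1/Oz/O2
montage.  Optionally the two non-target flicker frequencies of the
active set leak in as low-amplitude distractor sinusoids.

Everything is a pure function of (arguments, seed).  Blockwise streaming
and single-shot synthesis are sample-identical for the same seed because
noise is generated by stateful chunk-associative filtering of a
sequentially consumed white-noise stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import signal


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ChannelMontage:
    """Electrode montage with per-channel gains.

    ``ssvep_gains`` multiply the evoked (stimulus-locked) component,
    ``noise_gains`` the background (pink + alpha + line) component, so a
    montage can express the spatial amplitude differences seen across
    occipital electrodes.
    """

    channel_names: tuple[str, ...] = ("O1", "Oz", "O2")
    ssvep_gains: tuple[float, ...] = (1.0, 1.0, 1.0)
    noise_gains: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        n = len(self.channel_names)
        if n < 1:
            raise ValueError("montage needs at least one channel")
        if len(set(self.channel_names)) != n:
            raise ValueError("channel names must be unique")
        for gains in (self.ssvep_gains, self.noise_gains):
            if len(gains) != n:
                raise ValueError("gain count must match channel count")
            arr = np.asarray(gains, dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError("gains must be finite and >= 0")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def subset(self, names: Sequence[str]) -> "ChannelMontage":
        """Montage restricted to ``names`` (e.g. Oz-only single-electrode)."""
        idx = [self.channel_names.index(n) for n in names]
        return ChannelMontage(
            channel_names=tuple(self.channel_names[i] for i in idx),
            ssvep_gains=tuple(self.ssvep_gains[i] for i in idx),
            noise_gains=tuple(self.noise_gains[i] for i in idx),
        )


def single_channel_montage() -> ChannelMontage:
    return ChannelMontage(("Oz",), (1.0,), (1.0,))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-EEG forward model.

    Amplitudes are on a nominal microvolt scale.  ``snr_db`` is the
    power ratio of the SSVEP fundamental to the pink background noise in
    a +-1 Hz band around the fundamental (narrowband, because FBCCA
    sensitivity is narrowband); the fundamental amplitude is derived
    from it analytically.  When ``noise_scale`` is 0 the SNR is
    undefined and ``ssvep_amp`` (default 1.0) is used directly.
    """

    fs: float = 600.0
    snr_db: float = 0.0
    harmonic_count: int = 4
    harmonic_decay: float = 0.55
    alpha_amp: float = 4.0
    alpha_freq: float = 10.0
    line_amp: float = 1.0
    distractor_amps: tuple[float, float] = (0.0, 0.0)
    noise_exponent: float = 1.0
    noise_scale: float = 3.0
    ssvep_amp: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.harmonic_count < 1:
            raise ValueError("harmonic_count must be >= 1")
        if not 0 < self.harmonic_decay <= 1:
            raise ValueError("harmonic_decay must be in (0, 1]")
        if self.noise_exponent < 0:
            raise ValueError("noise spectral exponent must be >= 0")
        for amp in (self.alpha_amp, self.line_amp, self.noise_scale,
                    *self.distractor_amps):
            if amp < 0 or not np.isfinite(amp):
                raise ValueError("amplitudes must be finite and >= 0")


@dataclass(frozen=True)
class EEGSegment:
    """A multichannel EEG sample matrix (channels x n_samples) at ``fs``.

    ``onset_index`` is the index of the first sample relative to
    stimulus onset, so concatenated streaming blocks carry their
    position in the ongoing stimulation.
    """

    samples: np.ndarray
    fs: float
    onset_index: int = 0
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] < 1 or s.shape[0] < 1:
            raise ValueError("samples must be a (channels, n_samples>=1) matrix")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples contain NaN or Inf")
        object.__setattr__(self, "samples", s)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# pink noise filter (Kasdin truncated-AR fractional integrator)


def _pink_filter_denominator(beta: float, n_taps: int = 128) -> np.ndarray:
    """AR coefficients approximating H(z) = (1 - z^-1)^(-beta/2).

    Driving this filter with unit white noise yields noise with power
    spectral density proportional to (2 sin(pi f / fs))^-beta, i.e.
    1/f^beta over the band of interest.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    a = np.empty(n_taps)
    a[0] = 1.0
    for k in range(1, n_taps):
        a[k] = (k - 1.0 - beta / 2.0) * a[k - 1] / k
    return a


def _pink_band_power(beta: float, noise_scale: float, fs: float,
                     f_lo: float, f_hi: float) -> float:
    """Expected pink-noise power in [f_lo, f_hi] (one-sided)."""
    if noise_scale == 0:
        return 0.0
    a = _pink_filter_denominator(beta)
    freqs = np.linspace(max(f_lo, 1e-3), f_hi, 64)
    _, h = signal.freqz(1.0, a, worN=freqs, fs=fs)
    psd = 2.0 * noise_scale**2 * np.abs(h) ** 2 / fs  # V^2 / Hz, one-sided
    return float(np.trapezoid(psd, freqs))


def fundamental_amplitude(frequency: float, cfg: SimConfig) -> float:
    """SSVEP fundamental amplitude realizing ``cfg.snr_db``.

    SNR is defined as (A^2/2) / P_band with P_band the expected pink
    background power within +-1 Hz of the fundamental.
    """
    if cfg.ssvep_amp is not None:
        return cfg.ssvep_amp
    p_band = _pink_band_power(cfg.noise_exponent, cfg.noise_scale, cfg.fs,
                              frequency - 1.0, frequency + 1.0)
    if p_band == 0.0:
        return 1.0
    return float(np.sqrt(2.0 * p_band * 10.0 ** (cfg.snr_db / 10.0)))


def _as_seed_sequence(rng: int | np.random.SeedSequence | np.random.Generator | None,
                      fallback: int) -> np.random.SeedSequence:
    if rng is None:
        return np.random.SeedSequence(fallback)
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, np.random.Generator):
        return rng.bit_generator.seed_seq.spawn(1)[0]  # type: ignore[attr-defined]
    return np.random.SeedSequence(int(rng))


# ---------------------------------------------------------------------------
# the signal process


class SSVEPStream:
    """Phase-continuous generator of one digit's stimulation signal.

    ``next_block(n)`` returns the next ``n`` samples; chunking is
    immaterial: ten 30-sample pulls equal one 300-sample pull with the
    same seed.  Harmonic phases are drawn once at construction and are
    shared across channels (the evoked response is spatially coherent up
    to gain); alpha and line phases are independent per channel.
    """

    def __init__(self, frequency: float, montage: ChannelMontage,
                 cfg: SimConfig,
                 rng: int | np.random.SeedSequence | np.random.Generator | None = None,
                 distractor_freqs: tuple[float, ...] = ()) -> None:
        if frequency <= 0:
            raise ValueError("stimulation frequency must be positive")
        top = max((frequency * cfg.harmonic_count, cfg.alpha_freq, 50.0,
                   *distractor_freqs))
        if cfg.fs <= 2 * top:
            raise ValueError(
                f"fs={cfg.fs} violates Nyquist for highest simulated "
                f"frequency {top} Hz")
        if len(distractor_freqs) > len(cfg.distractor_amps):
            raise ValueError("more distractor frequencies than amplitudes")
        self.frequency = frequency
        self.montage = montage
        self.cfg = cfg
        self.distractor_freqs = tuple(distractor_freqs)

        ss = _as_seed_sequence(rng, cfg.seed)
        children = ss.spawn(1 + montage.n_channels)
        ctrl = np.random.default_rng(children[0])
        self._chan_rngs = [np.random.default_rng(c) for c in children[1:]]

        # draw order is fixed so superposition across amplitude settings holds
        self.harmonic_phases = ctrl.uniform(0, 2 * np.pi, cfg.harmonic_count)
        self.distractor_phases = ctrl.uniform(0, 2 * np.pi,
                                              len(cfg.distractor_amps))
        self.alpha_phases = ctrl.uniform(0, 2 * np.pi, montage.n_channels)
        self.line_phases = ctrl.uniform(0, 2 * np.pi, montage.n_channels)

        self.amplitude = fundamental_amplitude(frequency, cfg)
        a = _pink_filter_denominator(cfg.noise_exponent)
        self._pink_a = a
        self._pink_zi = [np.zeros(len(a) - 1) for _ in range(montage.n_channels)]
        self._index = 0

    def next_block(self, n_samples: int) -> EEGSegment:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        cfg, mont = self.cfg, self.montage
        t = np.arange(self._index, self._index + n_samples) / cfg.fs

        evoked = np.zeros(n_samples)
        for h in range(1, cfg.harmonic_count + 1):
            amp = self.amplitude * cfg.harmonic_decay ** (h - 1)
            evoked += amp * np.sin(2 * np.pi * h * self.frequency * t
                                   + self.harmonic_phases[h - 1])
        for j, f in enumerate(self.distractor_freqs):
            evoked += cfg.distractor_amps[j] * np.sin(
                2 * np.pi * f * t + self.distractor_phases[j])

        out = np.empty((mont.n_channels, n_samples))
        for c in range(mont.n_channels):
            white = self._chan_rngs[c].standard_normal(n_samples)
            pink, self._pink_zi[c] = signal.lfilter(
                [1.0], self._pink_a, cfg.noise_scale * white,
                zi=self._pink_zi[c])
            background = (
                pink
                + cfg.alpha_amp * np.sin(2 * np.pi * cfg.alpha_freq * t
                                         + self.alpha_phases[c])
                + cfg.line_amp * np.sin(2 * np.pi * 50.0 * t
                                        + self.line_phases[c])
            )
            out[c] = (mont.noise_gains[c] * background
                      + mont.ssvep_gains[c] * evoked)

        seg = EEGSegment(out, cfg.fs, onset_index=self._index,
                         channel_names=mont.channel_names)
        self._index += n_samples
        return seg


# ---------------------------------------------------------------------------
# public operations


def generate_ssvep_segment(frequency: float, n_samples: int,
                           montage: ChannelMontage, cfg: SimConfig,
                           rng=None,
                           distractor_freqs: tuple[float, ...] = ()
                           ) -> EEGSegment:
    """One fixed epoch of stimulation at ``frequency`` plus background."""
    return SSVEPStream(frequency, montage, cfg, rng,
                       distractor_freqs).next_block(n_samples)


def generate_noise(n_samples: int, montage: ChannelMontage, cfg: SimConfig,
                   rng=None) -> EEGSegment:
    """Background only: pink noise + alpha + line, no evoked component."""
    silent = replace(cfg, ssvep_amp=0.0)
    # frequency only sets the (zero-amplitude) evoked term; any valid value works
    return SSVEPStream(10.0, montage, silent, rng).next_block(n_samples)


def stream_digit_blocks(digit_frequency: float, montage: ChannelMontage,
                        cfg: SimConfig, rng=None, block_size: int = 30,
                        distractor_freqs: tuple[float, ...] = ()
                        ) -> Iterator[EEGSegment]:
    """Endless 50 ms (30-sample at 600 Hz) blocks of one digit's signal.

    The concatenation of the yielded blocks equals a single continuous
    :func:`generate_ssvep_segment` realization with the same seed.
    """
    stream = SSVEPStream(digit_frequency, montage, cfg, rng, distractor_freqs)
    while True:
        yield stream.next_block(block_size)


# ---------------------------------------------------------------------------
# in-silico cohort


@dataclass(frozen=True)
class PopulationConfig:
    """Ranges from which per-subject simulation parameters are drawn."""

    snr_db_range: tuple[float, float] = (-2.0, 6.0)
    ssvep_gain_range: tuple[float, float] = (0.7, 1.3)
    noise_gain_range: tuple[float, float] = (0.8, 1.2)
    harmonic_decay_range: tuple[float, float] = (0.4, 0.7)
    alpha_amp_range: tuple[float, float] = (2.0, 6.0)
    line_amp_range: tuple[float, float] = (0.5, 2.0)
    base: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for lo, hi in (self.snr_db_range, self.ssvep_gain_range,
                       self.noise_gain_range, self.harmonic_decay_range,
                       self.alpha_amp_range, self.line_amp_range):
            if hi < lo:
                raise ValueError("range bounds must satisfy min <= max")


def sample_subject_profile(subject_index: int,
                           population_cfg: PopulationConfig,
                           rng=None) -> tuple[ChannelMontage, SimConfig]:
    """Deterministic per-subject (montage, config) draw.

    Identical ``(subject_index, seed)`` always yields the identical
    profile; the montage keeps Oz gain fixed at the top of the drawn
    range ordering so the single-electrode condition uses a
    representative channel.
    """
    ss = _as_seed_sequence(rng, population_cfg.base.seed)
    sub = np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=(*ss.spawn_key, 1000 + subject_index))
    g = np.random.default_rng(sub)
    p = population_cfg
    snr = g.uniform(*p.snr_db_range)
    sg = tuple(g.uniform(*p.ssvep_gain_range, 3))
    ng = tuple(g.uniform(*p.noise_gain_range, 3))
    decay = g.uniform(*p.harmonic_decay_range)
    alpha = g.uniform(*p.alpha_amp_range)
    line = g.uniform(*p.line_amp_range)
    montage = ChannelMontage(("O1", "Oz", "O2"), sg, ng)
    cfg = replace(p.base, snr_db=float(snr), harmonic_decay=float(decay),
                  alpha_amp=float(alpha), line_amp=float(line),
                  seed=int(sub.generate_state(1)[0] % (2**31)))
    return montage, cfg
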