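"""Filter-bank canonical correlation analysis (FBCCA) target identification.

For each candidate stimulation frequency f_k a reference matrix of
sine/cosine pairs at the fundamental and its harmonics is correlated
(first canonical correlation) with each band-pass-filtered copy of the
EEG buffer; the per-sub-band correlations are fused by a decaying
weight w(n) = n^(-a) + b over sub-band number n = 1..N, and the
frequency with the largest combined score wins.  A decision is accepted
only when the winner's combined score exceeds the runner-up's by a
margin threshold.

CCA is computed by an orthogonal-decomposition (SVD) method: project
both row-centered sets onto orthonormal bases and take the largest
singular value of the cross-product, with a relative-tolerance rank
truncation so near-degenerate buffers raise instead of returning a
spurious correlation of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .filters import SubbandBank, apply_subband, low_set_bank
from .simulate import EEGSegment

_RANK_RTOL = 1e-10


class DegenerateInputError(ValueError):
    """A signal set has a zero-variance (constant) row."""


# ---------------------------------------------------------------------------
# reference construction


def build_reference(f_k: float, H: int, fs: float, n_samples: int) -> np.ndarray:
    """Sine/cosine reference matrix for frequency ``f_k``.

    Rows are [sin(2*pi*h*f_k*n/fs); cos(2*pi*h*f_k*n/fs)] for
    h = 1..H, n = 0..n_samples-1, giving a (2H, n_samples) matrix.
    The time index restarts at 0 for every buffer snapshot; CCA with
    paired sine/cosine rows is phase-invariant, so alignment to
    stimulus onset is immaterial.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if H * f_k >= fs / 2:
        raise ValueError(
            f"harmonic {H}*{f_k} Hz = {H * f_k} Hz reaches Nyquist "
            f"({fs / 2} Hz)")
    n = np.arange(n_samples)
    rows = np.empty((2 * H, n_samples))
    for h in range(1, H + 1):
        arg = 2 * np.pi * h * f_k * n / fs
        rows[2 * (h - 1)] = np.sin(arg)
        rows[2 * (h - 1) + 1] = np.cos(arg)
    return rows


@lru_cache(maxsize=1024)
def _reference_basis(f_k: float, H: int, fs: float,
                     n_samples: int) -> np.ndarray:
    """Orthonormal basis (n_samples, rank) of the centered reference."""
    y = build_reference(f_k, H, fs, n_samples)
    return _orthonormal_basis(y - y.mean(axis=1, keepdims=True))


def _orthonormal_basis(rows: np.ndarray) -> np.ndarray:
    """Column-orthonormal basis of span(rows^T) with rank truncation."""
    u, s, _ = np.linalg.svd(rows.T, full_matrices=False)
    if s[0] == 0:
        raise DegenerateInputError("signal set is identically zero")
    rank = int(np.sum(s > _RANK_RTOL * s[0]))
    return u[:, :rank]


# ---------------------------------------------------------------------------
# canonical correlation


def _center_check(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D (variables x samples)")
    Xc = X - X.mean(axis=1, keepdims=True)
    scale = np.max(np.abs(X), axis=1)
    var = np.sqrt(np.mean(Xc**2, axis=1))
    if np.any(var <= np.maximum(scale, 1.0) * 1e-13):
        raise DegenerateInputError(f"{name} has a zero-variance row")
    return Xc


def canonical_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """First canonical correlation between row-sets ``X`` and ``Y``.

    Both inputs are (variables, samples); rows are mean-centered
    internally.  Returns a value in [0, 1].
    """
    Xc = _center_check(X, "X")
    Yc = _center_check(Y, "Y")
    if Xc.shape[1] != Yc.shape[1]:
        raise ValueError("X and Y must have the same number of samples")
    n = Xc.shape[1]
    if n <= max(Xc.shape[0], Yc.shape[0]):
        raise ValueError(
            f"need more samples ({n}) than variables "
            f"({max(Xc.shape[0], Yc.shape[0])})")
    ux = _orthonormal_basis(Xc)
    uy = _orthonormal_basis(Yc)
    s = np.linalg.svd(ux.T @ uy, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def subband_weight(n: int, a: float = 1.25, b: float = 0.25) -> float:
    """Decaying fusion weight w(n) = n^(-a) + b for sub-band n >= 1."""
    if n < 1:
        raise ValueError("sub-band number starts at 1")
    return float(n ** (-a) + b)


# ---------------------------------------------------------------------------
# parameters and scores


@dataclass(frozen=True)
class FBCCAParams:
    """Frequencies, harmonics, sub-bands and fusion weights.

    Defaults mirror the low-frequency stimulus set: H = 4 reference
    harmonics, three sub-bands, weights a = 1.25, b = 0.25.  With a
    single sub-band the fusion weight is fixed to 1 so the combined
    score is the raw correlation and margin thresholds stay
    scale-comparable across frequency sets.
    """

    frequencies: tuple[float, ...] = (6.67, 7.50, 8.57)
    harmonics_H: int = 4
    subbands: SubbandBank = field(default_factory=low_set_bank)
    weight_a: float = 1.25
    weight_b: float = 0.25
    combine_squared: bool = False
    fs: float = 600.0

    def __post_init__(self) -> None:
        f = self.frequencies
        if len(f) < 1 or len(set(f)) != len(f) or min(f) <= 0:
            raise ValueError("frequencies must be distinct and positive")
        if self.harmonics_H < 1:
            raise ValueError("H must be >= 1")
        if self.harmonics_H * max(f) >= self.fs / 2:
            raise ValueError("highest harmonic reaches Nyquist")

    def weights(self) -> np.ndarray:
        n_bands = len(self.subbands)
        if n_bands == 1:
            return np.ones(1)
        return np.array([subband_weight(n, self.weight_a, self.weight_b)
                         for n in range(1, n_bands + 1)])


@dataclass(frozen=True)
class FBCCAScores:
    """Per-frequency/sub-band correlations and fused scores."""

    rho: np.ndarray           # (n_frequencies, n_subbands), each in [0, 1]
    combined: np.ndarray      # (n_frequencies,)
    winner: int
    runner_up: int | None
    margin: float

    @classmethod
    def from_combined(cls, rho: np.ndarray,
                      combined: np.ndarray) -> "FBCCAScores":
        order = np.argsort(combined, kind="stable")[::-1]
        winner = int(order[0])
        if len(combined) > 1:
            # exact ties break toward the lower frequency-list index
            top = combined[order[0]]
            tied = np.flatnonzero(combined == top)
            winner = int(tied[0])
            rest = [i for i in np.argsort(-combined, kind="stable")
                    if i != winner]
            runner_up = int(rest[0])
            margin = float(combined[winner] - combined[runner_up])
        else:
            runner_up, margin = None, float(combined[winner])
        return cls(rho, combined, winner, runner_up, margin)


def fbcca_scores(buffer: EEGSegment, params: FBCCAParams,
                 bank: SubbandBank | None = None) -> FBCCAScores:
    """Score every candidate frequency on a (front-end-filtered) buffer.

    For each sub-band the buffer is band-pass filtered once and its
    orthonormal basis reused across frequencies; references are cached
    per (frequency, H, fs, length).
    """
    bank = bank if bank is not None else params.subbands
    weights = params.weights()
    n_freq = len(params.frequencies)
    rho = np.empty((n_freq, len(bank)))
    n = buffer.n_samples
    for bi in range(len(bank)):
        sub = apply_subband(buffer, bi, bank)
        xc = _center_check(sub.samples, "buffer")
        ux = _orthonormal_basis(xc)
        for ki, f_k in enumerate(params.frequencies):
            uy = _reference_basis(f_k, params.harmonics_H, params.fs, n)
            s = np.linalg.svd(ux.T @ uy, compute_uv=False)
            rho[ki, bi] = np.clip(s[0], 0.0, 1.0)
    contrib = rho**2 if params.combine_squared else rho
    combined = contrib @ weights
    return FBCCAScores.from_combined(rho, combined)


def select_target(scores: FBCCAScores,
                  threshold: float) -> tuple[int, float] | None:
    """Margin rule: winner index iff its lead over the runner-up is at
    least ``threshold``; ``None`` means no decision yet."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if scores.margin >= threshold:
        return scores.winner, scores.margin
    return None
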