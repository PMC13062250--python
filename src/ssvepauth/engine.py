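"""Streaming margin-threshold decision engine.

EEG arrives in 30-sample blocks (50 ms at 600 Hz).  Blocks accumulate
in a buffer; once at least 300 samples have been collected since the
last reset, the FBCCA scores of the whole buffer are recomputed after
every block (a 20 Hz evaluation rate) and the top frequency is accepted
as the attended digit when its combined score leads the runner-up by at
least the margin threshold (0.30 by default).  The buffer slides once
it reaches 1,800 samples.  An accepted decision clears the buffer and
starts a 0.5 s gaze-shift period during which incoming blocks are
discarded (the stimulus keeps running while the user re-fixates).

Evaluation happens strictly on the block grid, never on a wall clock,
so offline replays are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .fbcca import FBCCAParams, FBCCAScores, fbcca_scores, select_target
from .filters import apply_front_end, default_front_end
from .simulate import EEGSegment


@dataclass(frozen=True)
class DecisionParams:
    """Streaming constants of the decision loop."""

    block_size: int = 30
    min_samples: int = 300
    max_buffer: int = 1800
    threshold: float = 0.30
    gaze_shift_s: float = 0.5
    fs: float = 600.0
    max_duration_s: float | None = None  # opt-in per-digit timeout

    def __post_init__(self) -> None:
        if min(self.block_size, self.min_samples, self.max_buffer) <= 0:
            raise ValueError("block/min/max sizes must be positive")
        if self.min_samples > self.max_buffer:
            raise ValueError("min_samples must not exceed max_buffer")
        if self.min_samples % self.block_size != 0:
            raise ValueError("min_samples must sit on the block grid")
        if self.threshold < 0 or self.gaze_shift_s < 0 or self.fs <= 0:
            raise ValueError("threshold/gaze_shift/fs must be non-negative")

    @property
    def gaze_shift_samples(self) -> int:
        return int(round(self.gaze_shift_s * self.fs))

    @property
    def evaluation_rate_hz(self) -> float:
        """Evaluations per second: fs / block_size (20 Hz at defaults)."""
        return self.fs / self.block_size


@dataclass(frozen=True)
class ClassificationEvent:
    """An accepted decision for one digit."""

    decided_index: int
    decided_digit: int
    margin: float
    latency_samples: int
    latency_s: float
    correct: bool | None = None
    scores: FBCCAScores | None = None


@dataclass
class EvaluationRecord:
    """One entry of the engine's evaluation log."""

    t_sample: int          # samples collected since reset at evaluation time
    margin: float
    decided: bool
    buffer_len: int
    scores: FBCCAScores | None = None


class DigitTimeoutError(RuntimeError):
    """Opt-in per-digit duration guard fired."""


@dataclass
class EngineState:
    blocks: list[np.ndarray] = field(default_factory=list)
    buffered: int = 0
    samples_since_reset: int = 0
    phase: str = "collecting"  # or "gaze_shift"
    gaze_shift_remaining: int = 0
    evaluation_log: list[EvaluationRecord] = field(default_factory=list)


class DecisionEngine:
    """Blockwise controller tying the filter bank and FBCCA together.

    ``digits`` maps frequency-list indices to the symbols they encode
    (defaults to 1..K, matching the digit->frequency codebooks).
    """

    def __init__(self, params: DecisionParams, fbcca: FBCCAParams,
                 digits: Sequence[int] | None = None,
                 front_end: Callable[[EEGSegment], EEGSegment] | None = None,
                 log_scores: bool = False) -> None:
        self.params = params
        self.fbcca = fbcca
        self.digits = (tuple(digits) if digits is not None
                       else tuple(range(1, len(fbcca.frequencies) + 1)))
        if len(self.digits) != len(fbcca.frequencies):
            raise ValueError("one digit per candidate frequency required")
        if front_end is None:
            specs = default_front_end(params.fs)
            front_end = lambda seg: apply_front_end(seg, specs)  # noqa: E731
        self._front_end = front_end
        self.log_scores = log_scores
        self.state = EngineState()

    # -- core streaming step ------------------------------------------------

    def ingest_block(self, block: EEGSegment) -> ClassificationEvent | None:
        """Consume one block; return an event when a decision fires."""
        st, p = self.state, self.params
        if block.n_samples != p.block_size:
            raise ValueError(
                f"expected blocks of {p.block_size} samples, got "
                f"{block.n_samples}")
        if st.blocks and block.n_channels != st.blocks[0].shape[0]:
            raise ValueError("channel count changed mid-stream")

        if st.phase == "gaze_shift":
            st.gaze_shift_remaining -= block.n_samples
            if st.gaze_shift_remaining <= 0:
                st.gaze_shift_remaining = 0
                st.phase = "collecting"
            return None

        st.blocks.append(block.samples)
        st.buffered += block.n_samples
        st.samples_since_reset += block.n_samples
        while st.buffered > p.max_buffer:  # sliding window: drop oldest
            drop = st.buffered - p.max_buffer
            head = st.blocks[0]
            if head.shape[1] <= drop:
                st.blocks.pop(0)
                st.buffered -= head.shape[1]
            else:
                st.blocks[0] = head[:, drop:]
                st.buffered -= drop

        if st.samples_since_reset < p.min_samples:
            return None
        if (p.max_duration_s is not None
                and st.samples_since_reset / p.fs > p.max_duration_s):
            raise DigitTimeoutError(
                f"no decision within {p.max_duration_s} s")

        buf = EEGSegment(np.concatenate(st.blocks, axis=1), p.fs)
        scores = fbcca_scores(self._front_end(buf), self.fbcca)
        selection = select_target(scores, p.threshold)
        st.evaluation_log.append(EvaluationRecord(
            t_sample=st.samples_since_reset, margin=scores.margin,
            decided=selection is not None, buffer_len=st.buffered,
            scores=scores if self.log_scores else None))
        if selection is None:
            return None
        idx, margin = selection
        event = ClassificationEvent(
            decided_index=idx, decided_digit=self.digits[idx], margin=margin,
            latency_samples=st.samples_since_reset,
            latency_s=st.samples_since_reset / p.fs,
            scores=scores if self.log_scores else None)
        self.reset_for_next_digit()
        return event

    def reset_for_next_digit(self) -> None:
        """Clear the buffer and start the 0.5 s gaze-shift window."""
        st = self.state
        st.blocks.clear()
        st.buffered = 0
        st.samples_since_reset = 0
        st.phase = "gaze_shift"
        st.gaze_shift_remaining = self.params.gaze_shift_samples

    def run_digit(self, stream: Iterator[EEGSegment],
                  true_digit: int | None = None) -> ClassificationEvent:
        """Pull blocks until a decision fires; annotate correctness."""
        for block in stream:
            event = self.ingest_block(block)
            if event is not None:
                if true_digit is not None:
                    event = ClassificationEvent(
                        **{**event.__dict__,
                           "correct": event.decided_digit == true_digit})
                return event
        raise RuntimeError("stream ended before a decision was reached")

    @property
    def samples_consumed_this_digit(self) -> int:
        """Collected samples since the last reset (excludes gaze shift)."""
        return self.state.samples_since_reset
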