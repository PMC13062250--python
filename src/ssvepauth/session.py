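"""Authentication-session orchestration and performance metrics.

A trial presents a random 8-digit one-time code over {1, 2, 3}, one
digit at a time, each digit encoded as a flicker frequency from the
active set (low: 6.67/7.50/8.57 Hz, high: 36/40/45 Hz — all integer
divisors of a 360 Hz display refresh).  The decision engine classifies
each digit from streaming EEG; an incorrect decision still advances the
trial.  Accuracy P is the fraction of the 8 digits decoded correctly;
completion time is the elapsed signal time from the first stimulus
sample to the final digit's classification, spanning the seven 0.5 s
inter-digit gaze-shift windows.

An experiment runs a cohort of synthetic subjects through the four
conditions of the study design ({1, 3} electrodes x {low, high}
frequency set) and reduces per-subject means to Mean +- SD and Student-t
95% confidence intervals per condition.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (ClassificationEvent, DecisionEngine, DecisionParams,
                     DigitTimeoutError)
from .fbcca import FBCCAParams
from .filters import high_set_bank, low_set_bank
from .simulate import (ChannelMontage, PopulationConfig, SimConfig,
                       sample_subject_profile, stream_digit_blocks)

LOW_CODEBOOK: dict[int, float] = {1: 6.67, 2: 7.50, 3: 8.57}
HIGH_CODEBOOK: dict[int, float] = {1: 36.0, 2: 40.0, 3: 45.0}

#: the four study conditions as (n_electrodes, set_name)
CONDITIONS: tuple[tuple[int, str], ...] = (
    (3, "low"), (3, "high"), (1, "low"), (1, "high"))

_CONDITION_KEY = {(3, "low"): "lf3", (3, "high"): "hf3",
                  (1, "low"): "lf1", (1, "high"): "hf1"}


@dataclass(frozen=True)
class FrequencySet:
    """A digit->frequency codebook with its FBCCA parameterization."""

    name: str
    codebook: dict[int, float]
    fbcca_params: FBCCAParams

    def __post_init__(self) -> None:
        freqs = list(self.codebook.values())
        if sorted(self.codebook) != [1, 2, 3] or len(set(freqs)) != 3:
            raise ValueError("codebook must bijectively map {1,2,3}")
        for f in freqs:
            frames = 360.0 / f
            if abs(frames - round(frames)) > 0.05:
                raise ValueError(
                    f"{f} Hz does not divide the 360 Hz refresh rate")

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(self.codebook[d] for d in (1, 2, 3))


def frequency_set(name: str, fs: float = 600.0) -> FrequencySet:
    """Build the 'low' or 'high' stimulus set.

    Low: H = 4 reference harmonics, 3 sub-bands (2-60/12-60/20-60 Hz).
    High: H = 1 (the second harmonic, 72 Hz and up, exceeds the 60 Hz
    hardware band), single 35-60 Hz sub-band.
    """
    if name == "low":
        params = FBCCAParams(frequencies=tuple(LOW_CODEBOOK[d] for d in (1, 2, 3)),
                             harmonics_H=4, subbands=low_set_bank(fs), fs=fs)
        return FrequencySet("low", dict(LOW_CODEBOOK), params)
    if name == "high":
        params = FBCCAParams(frequencies=tuple(HIGH_CODEBOOK[d] for d in (1, 2, 3)),
                             harmonics_H=1, subbands=high_set_bank(fs), fs=fs)
        return FrequencySet("high", dict(HIGH_CODEBOOK), params)
    raise ValueError(f"unknown frequency set {name!r}")


def digit_to_frequency(digit: int, fset: FrequencySet) -> float:
    try:
        return fset.codebook[digit]
    except KeyError:
        raise ValueError(f"digit {digit!r} not in codebook") from None


def frequency_to_digit(frequency: float, fset: FrequencySet) -> int:
    for d, f in fset.codebook.items():
        if f == frequency:
            return d
    raise ValueError(f"{frequency} Hz not in codebook")


def generate_code(length: int = 8, alphabet: Sequence[int] = (1, 2, 3),
                  rng=None) -> tuple[int, ...]:
    """An i.i.d.-uniform one-time code over ``alphabet``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if len(alphabet) == 0:
        raise ValueError("alphabet must be non-empty")
    g = np.random.default_rng(rng)
    return tuple(int(alphabet[i])
                 for i in g.integers(0, len(alphabet), size=length))


# ---------------------------------------------------------------------------
# trials


@dataclass(frozen=True)
class TrialResult:
    code: tuple[int, ...]
    decoded: tuple[int, ...]
    per_digit_latency_s: tuple[float, ...]
    margins: tuple[float, ...]
    accuracy_P: float
    completion_time_s: float
    condition: tuple[int, str]  # (n_electrodes, set_name)
    seed: int

    def to_row(self) -> dict:
        return {"condition": _CONDITION_KEY[self.condition],
                "code": "".join(map(str, self.code)),
                "decoded": "".join(map(str, self.decoded)),
                "accuracy_P": self.accuracy_P,
                "completion_time_s": self.completion_time_s,
                "seed": self.seed}


def _condition_montage(montage: ChannelMontage, n_channels: int
                       ) -> ChannelMontage:
    if n_channels == 3:
        return montage
    if n_channels == 1:
        return montage.subset(["Oz"])
    raise ValueError("electrode count must be 1 or 3")


def run_trial(fset: FrequencySet, n_channels: int, montage: ChannelMontage,
              sim_cfg: SimConfig, params: DecisionParams | None = None,
              seed: int | np.random.SeedSequence = 0,
              code: tuple[int, ...] | None = None,
              log_scores: bool = False) -> TrialResult:
    """One 8-digit authentication trial against simulated EEG.

    Each digit's stimulation is synthesized as an endless block stream
    at its codebook frequency; the stream keeps running through the
    engine's post-decision gaze-shift window (those blocks are
    discarded), mirroring the continuous flicker of the real stimulus.
    """
    params = params or DecisionParams(fs=sim_cfg.fs)
    mont = _condition_montage(montage, n_channels)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(int(seed)))
    seed_id = int(ss.generate_state(1)[0] % (2**31))
    code_ss, *digit_ss = ss.spawn(1 + (8 if code is None else len(code)))
    if code is None:
        code = generate_code(8, rng=np.random.default_rng(code_ss))

    engine = DecisionEngine(params, fset.fbcca_params, log_scores=log_scores)
    decoded: list[int] = []
    latencies: list[float] = []
    margins: list[float] = []
    total_samples = 0
    for digit, dss in zip(code, digit_ss):
        freq = digit_to_frequency(digit, fset)
        stream = stream_digit_blocks(freq, mont, sim_cfg, rng=dss,
                                     block_size=params.block_size)
        remaining = engine.state.gaze_shift_remaining
        consumed = -(-remaining // params.block_size) * params.block_size
        event: ClassificationEvent = engine.run_digit(stream, true_digit=digit)
        decoded.append(event.decided_digit)
        latencies.append(event.latency_s)
        margins.append(event.margin)
        total_samples += consumed + event.latency_samples
    accuracy = sum(d == c for d, c in zip(decoded, code)) / len(code)
    return TrialResult(tuple(code), tuple(decoded), tuple(latencies),
                       tuple(margins), accuracy, total_samples / params.fs,
                       (n_channels, fset.name), seed_id)


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationResult:
    threshold: float
    min_samples: int
    achieved_accuracy: float
    search_trace: tuple[tuple[int, float, float], ...]  # (window, thr, acc)


@dataclass(frozen=True)
class CalibConfig:
    thresholds: tuple[float, ...] = (0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)
    window_start: int = 300
    window_step: int = 30
    window_cap: int = 600
    n_digits: int = 9
    target_accuracy: float = 1.0
    #: session-time budget per calibration digit; a digit that cannot be
    #: decided within it counts as a miss (the operator moves on)
    digit_timeout_s: float = 10.0


def calibrate(montage: ChannelMontage, sim_cfg: SimConfig,
              fset: FrequencySet, calib: CalibConfig | None = None,
              n_channels: int = 3, seed: int = 0) -> CalibrationResult:
    """Greedy threshold/window search before the main trials.

    The margin threshold is swept over its grid (0.2-0.5) at the
    current minimum window; if no threshold reaches the target accuracy
    on the calibration digits, the window is extended in 30-sample
    steps and the sweep repeats, stopping at the target or when the
    window cap exhausts the budget, returning the best setting found.
    """
    calib = calib or CalibConfig()
    if not calib.thresholds or calib.window_step <= 0:
        raise ValueError("empty calibration grid")
    mont = _condition_montage(montage, n_channels)
    ss = np.random.SeedSequence(seed)
    digits = tuple((i % 3) + 1 for i in range(calib.n_digits))
    digit_seeds = ss.spawn(calib.n_digits)

    trace: list[tuple[int, float, float]] = []
    best = (-1.0, calib.window_start, calib.thresholds[0])
    window = calib.window_start
    while window <= calib.window_cap:
        for thr in calib.thresholds:
            params = DecisionParams(min_samples=window, threshold=thr,
                                    fs=sim_cfg.fs,
                                    max_duration_s=calib.digit_timeout_s)
            hits = 0
            for digit, dss in zip(digits, digit_seeds):
                engine = DecisionEngine(params, fset.fbcca_params)
                freq = digit_to_frequency(digit, fset)
                stream = stream_digit_blocks(freq, mont, sim_cfg, rng=dss)
                try:
                    event = engine.run_digit(stream, true_digit=digit)
                except DigitTimeoutError:
                    continue  # undecidable within budget counts as a miss
                hits += bool(event.correct)
            acc = hits / calib.n_digits
            trace.append((window, thr, acc))
            if acc > best[0]:
                best = (acc, window, thr)
            if acc >= calib.target_accuracy:
                return CalibrationResult(thr, window, acc, tuple(trace))
        window += calib.window_step
    acc, window, thr = best
    return CalibrationResult(thr, window, acc, tuple(trace))


# ---------------------------------------------------------------------------
# experiments


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 21
    trials_per_condition: int = 4
    master_seed: int = 0
    population: PopulationConfig = field(default_factory=PopulationConfig)
    decision: DecisionParams = field(default_factory=DecisionParams)


def run_experiment(cohort: CohortConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full in-silico study: subjects x 4 conditions x trials x 8 digits.

    Returns (per-trial table, per-subject table, per-condition summary).
    Odd-numbered subjects are labeled as starting with the
    high-frequency conditions (counterbalancing metadata only; the
    simulator has no fatigue model, so order cannot affect results).
    """
    ss = np.random.SeedSequence(cohort.master_seed)
    rows = []
    for subj in range(1, cohort.n_subjects + 1):
        montage, cfg = sample_subject_profile(subj, cohort.population, rng=ss)
        order = "high-first" if subj % 2 == 1 else "low-first"
        for n_ch, set_name in CONDITIONS:
            fset = frequency_set(set_name, fs=cfg.fs)
            for trial in range(cohort.trials_per_condition):
                trial_ss = np.random.SeedSequence(
                    entropy=ss.entropy,
                    spawn_key=(subj, CONDITIONS.index((n_ch, set_name)), trial))
                res = run_trial(fset, n_ch, montage, cfg,
                                params=replace(cohort.decision, fs=cfg.fs),
                                seed=trial_ss)
                rows.append({"subject": subj, "order": order,
                             "trial": trial + 1, **res.to_row(),
                             "snr_db": cfg.snr_db})
    trials = pd.DataFrame(rows)
    per_subject = (trials.groupby(["subject", "condition"], as_index=False)
                   .agg(accuracy_pct=("accuracy_P", lambda a: 100 * a.mean()),
                        time_s=("completion_time_s", "mean")))
    summary_rows = []
    for cond in _CONDITION_KEY.values():
        sub = per_subject[per_subject.condition == cond]
        for metric, col in (("accuracy_pct", "accuracy_pct"),
                            ("time_s", "time_s")):
            s = summarize(sub[col].to_numpy())
            summary_rows.append({"condition": cond, "metric": metric, **s})
    return trials, per_subject, pd.DataFrame(summary_rows)


def summarize(values: Sequence[float]) -> dict:
    """Mean, sample SD and Student-t 95% CI across subjects."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values for SD/CI")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return {"mean": mean, "sd": sd, "ci95_low": mean - half,
            "ci95_high": mean + half, "n": n}


def load_reference_cohort() -> pd.DataFrame:
    """Per-subject accuracy (%) and completion time (s) of the original
    21-participant study, one column pair per condition."""
    resource = importlib.resources.files("ssvepauth").joinpath(
        "data", "reference_cohort.csv")
    with resource.open() as fh:
        return pd.read_csv(fh)


def reference_summary() -> pd.DataFrame:
    """Condition-level Mean/SD/CI recomputed from the reference cohort."""
    table = load_reference_cohort()
    rows = []
    for cond in ("lf3", "hf3", "lf1", "hf1"):
        for metric, col in (("accuracy_pct", f"{cond}_acc_pct"),
                            ("time_s", f"{cond}_time_s")):
            rows.append({"condition": cond, "metric": metric,
                         **summarize(table[col].to_numpy())})
    return pd.DataFrame(rows)
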