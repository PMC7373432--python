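"""Adaptive one-up three-down 2AFC threshold tracking with dB amplitude steps.

An incorrect response raises the stimulus amplitude on the next trial; three
consecutive correct responses lower it.  Every change multiplies the
amplitude by a fixed decibel factor (amplitude decibels: 2 dB is a factor of
10**(2/20) ~ 1.2589).  The run ends at the fifth change of direction and the
online threshold estimate is the mean amplitude of the last 10 trials up to
and including the trial that triggered that fifth reversal.  This transformed
up-down rule converges near the 75-79% correct point of the psychometric
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StaircaseConfig", "StaircaseRun", "step_amplitude", "run_staircase", "estimate_threshold"]


@dataclass
class StaircaseConfig:
    """Parameters of the transformed up-down procedure.

    step_db : amplitude-decibel step (factor 10**(step_db/20) per change)
    n_down : consecutive correct responses required before a decrease
    n_up : incorrect responses required before an increase
    stop_reversals : direction changes that terminate the run
    start_amplitude : first-trial amplitude, mA
    min_amplitude, max_amplitude : clipping bounds, mA (hardware ceiling 6 mA)
    max_trials : safety cap against non-terminating runs
    """

    step_db: float = 2.0
    n_down: int = 3
    n_up: int = 1
    stop_reversals: int = 5
    start_amplitude: float = 1.0
    min_amplitude: float = 0.0
    max_amplitude: float = 6.0
    max_trials: int = 200

    def __post_init__(self) -> None:
        if self.step_db <= 0:
            raise ValueError("step_db must be positive")
        if self.n_down < 1 or self.n_up < 1 or self.stop_reversals < 1:
            raise ValueError("counters must be >= 1")
        if not (0 <= self.min_amplitude < self.max_amplitude):
            raise ValueError("need 0 <= min_amplitude < max_amplitude")
        if not (self.min_amplitude < self.start_amplitude <= self.max_amplitude):
            raise ValueError("start_amplitude must lie inside the bounds")


@dataclass
class StaircaseRun:
    """Record of one staircase: trials, reversal bookkeeping, and estimate."""

    amplitudes: np.ndarray          # trial amplitudes, mA
    correct: np.ndarray             # boolean responses
    reversal_indices: np.ndarray    # trial indices that triggered a direction change
    threshold_estimate: float       # mA; NaN when undefined
    terminated_normally: bool
    short_estimate: bool = False    # fewer than 10 trials preceded the final reversal
    config: StaircaseConfig | None = None

    @property
    def trials(self) -> list[tuple[float, bool]]:
        return list(zip(self.amplitudes.tolist(), self.correct.tolist()))


def step_amplitude(
    a: float,
    direction: str,
    step_db: float,
    min_amplitude: float = 0.0,
    max_amplitude: float = np.inf,
) -> float:
    """Multiply amplitude by 10**(+/-step_db/20) and clip to the bounds."""
    if not np.isfinite(a) or a <= 0:
        raise ValueError("amplitude must be positive and finite")
    if direction == "up":
        a = a * 10.0 ** (step_db / 20.0)
    elif direction == "down":
        a = a * 10.0 ** (-step_db / 20.0)
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return float(np.clip(a, min_amplitude, max_amplitude))


def run_staircase(
    responder,
    cfg: StaircaseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> StaircaseRun:
    """Run one adaptive staircase against ``responder(amplitude, rng) -> bool``.

    The consecutive-correct counter resets after every amplitude change and
    after any incorrect response.  A reversal is an actual sign change
    between consecutive realized amplitude movements; changes clipped into
    no-ops at the bounds do not create reversals.  The run terminates at the
    ``stop_reversals``-th reversal, or is flagged non-terminated at the
    trial cap.
    """
    cfg = cfg or StaircaseConfig()
    rng = np.random.default_rng(rng)

    amps: list[float] = []
    correct: list[bool] = []
    reversals: list[int] = []
    a = cfg.start_amplitude
    n_correct_streak = 0
    last_move = 0       # -1 down, +1 up, 0 none yet
    aborted = False

    for t in range(cfg.max_trials):
        try:
            resp = bool(responder(a, rng))
        except Exception:
            aborted = True
            break
        amps.append(a)
        correct.append(resp)

        move = 0
        if resp:
            n_correct_streak += 1
            if n_correct_streak >= cfg.n_down:
                move = -1
                n_correct_streak = 0
        else:
            n_correct_streak = 0
            move = +1

        if move != 0:
            new_a = step_amplitude(
                a, "up" if move > 0 else "down", cfg.step_db,
                cfg.min_amplitude, cfg.max_amplitude,
            )
            if new_a != a:   # clipped no-change moves do not count as movement
                if last_move != 0 and move != last_move:
                    reversals.append(t)
                    if len(reversals) >= cfg.stop_reversals:
                        a = new_a
                        break
                last_move = move
                a = new_a

    amps_arr = np.asarray(amps, dtype=float)
    corr_arr = np.asarray(correct, dtype=bool)
    rev_arr = np.asarray(reversals, dtype=int)
    terminated = (not aborted) and len(reversals) >= cfg.stop_reversals
    run = StaircaseRun(
        amplitudes=amps_arr,
        correct=corr_arr,
        reversal_indices=rev_arr,
        threshold_estimate=np.nan,
        terminated_normally=terminated,
        config=cfg,
    )
    if terminated:
        run.threshold_estimate = estimate_threshold(run)
    return run


def estimate_threshold(run: StaircaseRun, n_last: int = 10) -> float:
    """Mean amplitude of the last ``n_last`` trials before the final reversal.

    The window ends at (and includes) the trial whose response triggered the
    terminating reversal.  If fewer than ``n_last`` trials precede it, the
    mean of all available trials is returned and ``run.short_estimate`` set.
    """
    if run.reversal_indices.size == 0:
        raise ValueError("run has no reversals; threshold undefined")
    stop = run.config.stop_reversals if run.config else run.reversal_indices.size
    idx = int(run.reversal_indices[min(stop, run.reversal_indices.size) - 1])
    lo = max(0, idx + 1 - n_last)
    if idx + 1 - n_last < 0:
        run.short_estimate = True
    return float(run.amplitudes[lo : idx + 1].mean())
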