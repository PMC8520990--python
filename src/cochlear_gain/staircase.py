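"""Transformed up-down (2-down/1-up) adaptive tracking.

Simulates the threshold-tracking procedure used in the forward-masking
experiments: a three-interval forced-choice task whose tracked level moves
down one step after two consecutive correct responses and up one step after
any incorrect response, converging on the 70.7%-correct point of the
psychometric function.  Two stopping regimes are supported:

* fixed number of trials (50), step 5 dB until the second reversal then
  2 dB, threshold = mean of the final even number of 2-dB reversals;
* fixed number of reversals (12), step 5 dB until the fourth reversal then
  2 dB, threshold = mean of the final eight reversals.

``staircase_asymptote`` is an exact convergence oracle: it builds the
discrete Markov chain of the 2-down/1-up rule on a level grid and returns
the stationary mean level, independently of the trial-by-trial simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd

from .cochlea import ListenerProfile
from .detection import TrialCondition, percent_correct_3ifc, predicted_threshold

__all__ = [
    "StaircaseConfig",
    "StaircaseRun",
    "run_staircase",
    "extract_threshold",
    "qc_run",
    "staircase_asymptote",
    "EXP12_CONFIG",
    "EXP3_CONFIG",
]


@dataclass(frozen=True)
class StaircaseConfig:
    tracked: Literal["signal", "masker"] = "signal"
    initial_step_dB: float = 5.0
    final_step_dB: float = 2.0
    step_change_at_reversal: int = 2
    stop_rule: Literal["fixed_trials", "fixed_reversals"] = "fixed_trials"
    stop_count: int = 50
    averaging: Literal["final_even_at_final_step", "final_8"] = "final_even_at_final_step"
    start_offset_dB: float = 10.0
    level_floor_dB: float = -20.0
    level_ceil_dB: float = 120.0
    max_trials: int = 400  # safety stop for fixed-reversal runs

    def __post_init__(self) -> None:
        if self.initial_step_dB <= 0 or self.final_step_dB <= 0:
            raise ValueError("step sizes must be positive")
        if self.stop_count <= 0 or self.step_change_at_reversal <= 0:
            raise ValueError("stop parameters must be positive")


# Experiments 1-2: 50 trials, step change at the 2nd reversal, final even
# number of 2-dB reversals averaged.
EXP12_CONFIG = StaircaseConfig()
# Experiment 3: run to 12 reversals, step change at the 4th, final 8 averaged.
EXP3_CONFIG = StaircaseConfig(step_change_at_reversal=4,
                              stop_rule="fixed_reversals", stop_count=12,
                              averaging="final_8")


@dataclass
class StaircaseRun:
    """One completed adaptive track."""

    trials: pd.DataFrame  # columns: trial, level_dB, correct, reversal, step_dB
    reversal_levels: list[float]
    reversal_steps: list[float]
    threshold_estimate_dB: float = float("nan")
    reversal_sd_dB: float = float("nan")
    qc_pass: bool = True
    qc_reason: str = ""
    seed: Optional[int] = None
    condition_label: str = ""


def _simulate_track(p_correct: Callable[[float], float], start_level: float,
                    cfg: StaircaseConfig, rng: np.random.Generator,
                    direction: int) -> tuple[pd.DataFrame, list[float], list[float], str]:
    """Core 2-down/1-up loop.  ``direction=+1`` tracks a signal (correct ->
    level down); ``direction=-1`` tracks a masker (correct -> level up)."""
    level = float(start_level)
    step = cfg.initial_step_dB
    consecutive = 0
    last_move = 0  # -1 down, +1 up, 0 none yet
    records = []
    reversal_levels: list[float] = []
    reversal_steps: list[float] = []
    bounds_fail = ""
    trial = 0
    while True:
        trial += 1
        correct = bool(rng.random() < p_correct(level))
        move = 0
        if correct:
            consecutive += 1
            if consecutive == 2:
                move = -direction
                consecutive = 0
        else:
            move = +direction
            consecutive = 0
        reversal = move != 0 and last_move != 0 and move != last_move
        records.append((trial, level, correct, reversal, step))
        if reversal:
            reversal_levels.append(level)
            reversal_steps.append(step)
            if len(reversal_levels) == cfg.step_change_at_reversal:
                step = cfg.final_step_dB
        if move != 0:
            last_move = move
            level += move * step
            if level > cfg.level_ceil_dB or level < cfg.level_floor_dB:
                bounds_fail = f"level {level:.1f} dB exited bounds"
                level = min(max(level, cfg.level_floor_dB), cfg.level_ceil_dB)
        if cfg.stop_rule == "fixed_trials" and trial >= cfg.stop_count:
            break
        if cfg.stop_rule == "fixed_reversals" and len(reversal_levels) >= cfg.stop_count:
            break
        if trial >= cfg.max_trials:
            bounds_fail = bounds_fail or f"no convergence within {cfg.max_trials} trials"
            break
    df = pd.DataFrame(records, columns=["trial", "level_dB", "correct",
                                        "reversal", "step_dB"])
    return df, reversal_levels, reversal_steps, bounds_fail


def _masker_level_at_threshold(cond: TrialCondition,
                               listener: ListenerProfile) -> float:
    """Masker level at which the condition's fixed signal level sits exactly
    at the predicted (gain-reduction) threshold: the lowest masker level
    where the signal can just be detected.  Bisection to 0.01 dB."""
    from dataclasses import replace

    if cond.masker is None:
        raise ValueError("masker tracking requires a masker in the condition")
    target = cond.signal.level_dB_SPL

    def thr(masker_level: float) -> float:
        m = replace(cond.masker, level_dB_SPL=masker_level)
        return predicted_threshold(TrialCondition(signal=cond.signal, masker=m,
                                                  precursor=cond.precursor),
                                   listener, "gain_reduction")

    lo, hi = -20.0, 120.0
    if thr(lo) > target or thr(hi) < target:
        raise ValueError("fixed signal level unreachable by any masker level in bounds")
    while hi - lo > 0.01:
        mid = 0.5 * (lo + hi)
        if thr(mid) >= target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def run_staircase(cond: TrialCondition, listener: ListenerProfile,
                  cfg: StaircaseConfig = EXP12_CONFIG,
                  seed: Optional[int] = None) -> StaircaseRun:
    """Simulate one adaptive run for ``cond``.

    Trial responses are Bernoulli draws from the listener's 3IFC
    psychometric function centred on the model-true threshold (the
    gain-reduction prediction) plus a per-run Gaussian offset with SD
    ``run_noise_sd_dB``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if cfg.tracked == "signal":
        model_threshold = predicted_threshold(cond, listener, "gain_reduction")
    else:
        model_threshold = _masker_level_at_threshold(cond, listener)
    run_threshold = model_threshold + rng.normal(0.0, listener.run_noise_sd_dB)
    spread = listener.psychometric_spread_dB

    if cfg.tracked == "signal":
        def p_correct(level: float) -> float:
            return percent_correct_3ifc(level, run_threshold, spread)
        direction = +1
        start = run_threshold + cfg.start_offset_dB
    else:
        # masker tracking: higher masker -> harder; probability correct falls
        # with masker level around the masker level that just masks the
        # fixed signal.  Two correct -> masker up, incorrect -> masker down,
        # converging on the lowest masker level where the signal is heard.
        def p_correct(level: float) -> float:
            return percent_correct_3ifc(run_threshold, level, spread)
        direction = -1
        start = run_threshold - cfg.start_offset_dB

    trials, rev_levels, rev_steps, fail = _simulate_track(
        p_correct, start, cfg, rng, direction)
    run = StaircaseRun(trials=trials, reversal_levels=rev_levels,
                       reversal_steps=rev_steps, seed=seed,
                       condition_label=cond.label)
    if fail:
        run.qc_pass = False
        run.qc_reason = fail
    try:
        est, sd = extract_threshold(run, cfg)
        run.threshold_estimate_dB = est
        run.reversal_sd_dB = sd
    except ValueError as exc:
        run.qc_pass = False
        run.qc_reason = run.qc_reason or str(exc)
    if run.qc_pass:
        run.qc_pass, run.qc_reason = qc_run(run, cfg)
    return run


def extract_threshold(run: StaircaseRun, cfg: StaircaseConfig = EXP12_CONFIG
                      ) -> tuple[float, float]:
    """Threshold estimate and reversal SD from a completed run.

    ``final_even_at_final_step``: all reversals at the final step size,
    dropping the earliest if their count is odd.  ``final_8``: the last
    eight reversals regardless of step.
    """
    if cfg.averaging == "final_8":
        if len(run.reversal_levels) < 8:
            raise ValueError("fewer than 8 reversals; cannot extract threshold")
        used = np.asarray(run.reversal_levels[-8:], dtype=float)
    else:
        at_final = [lv for lv, st in zip(run.reversal_levels, run.reversal_steps)
                    if st == cfg.final_step_dB]
        if not at_final:
            raise ValueError("no reversals at the final step size")
        if len(at_final) % 2 == 1:
            at_final = at_final[1:]
        if not at_final:
            raise ValueError("no even count of final-step reversals")
        used = np.asarray(at_final, dtype=float)
    est = float(np.mean(used))
    sd = float(np.std(used, ddof=1)) if len(used) > 1 else 0.0
    return est, sd


def qc_run(run: StaircaseRun, cfg: StaircaseConfig = EXP12_CONFIG
           ) -> tuple[bool, str]:
    """Run-exclusion rule: fail if the reversal SD exceeds 5 dB (strictly)
    or fewer than six reversals occurred."""
    if len(run.reversal_levels) < 6:
        return False, f"only {len(run.reversal_levels)} reversals (< 6)"
    if run.reversal_sd_dB > 5.0:
        return False, f"reversal SD {run.reversal_sd_dB:.2f} dB (> 5 dB)"
    return True, ""


def staircase_asymptote(p_correct: Callable[[float], float],
                        level_min: float, level_max: float,
                        step_dB: float = 2.0) -> float:
    """Stationary mean level of the 2-down/1-up rule (exact oracle).

    Builds the Markov chain over states (level index, consecutive-correct
    count in {0, 1}) on a grid in final-step increments with reflecting
    edges, solves for the stationary distribution, and returns the mean
    level.  Brute force and independent of the trial simulator.
    """
    levels = np.arange(level_min, level_max + 0.5 * step_dB, step_dB)
    n = len(levels)
    if n < 3:
        raise ValueError("level grid too small for the chain")
    p = np.array([p_correct(l) for l in levels])
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        # degenerate responses at a grid edge make the chain reducible
        if p[0] >= 1.0 or p[-1] <= 0.0:
            raise ValueError("degenerate psychometric at grid edge; chain not irreducible")
    # state index: 2*i (no pending correct), 2*i+1 (one correct pending)
    T = np.zeros((2 * n, 2 * n))
    for i in range(n):
        up = min(i + 1, n - 1)
        down = max(i - 1, 0)
        # from (i, 0): correct -> (i, 1); incorrect -> (up, 0)
        T[2 * i, 2 * i + 1] += p[i]
        T[2 * i, 2 * up] += 1 - p[i]
        # from (i, 1): correct -> (down, 0); incorrect -> (up, 0)
        T[2 * i + 1, 2 * down] += p[i]
        T[2 * i + 1, 2 * up] += 1 - p[i]
    # stationary distribution: left eigenvector of T for eigenvalue 1
    w, v = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi) / np.abs(pi).sum()
    level_mass = pi[0::2] + pi[1::2]
    return float(np.dot(level_mass, levels))
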